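drug,parameter,subjects_dosing,dose,identification_of_metabolizer_groups,reference
Amitriptyline,Css,"Patients, MD",25-225 mg,"CYP2C19*2, CYP2C19*3",B9
Amitriptyline,Css,"Patients, MD",150 mg,CYP2C19*2,B10
Amitriptyline,AUC,"Healthy, SD",50 mg,CYP2C19*2,B11
Amitriptyline,Css,"Patients, MD",150 mg,Phenotyping,B12
Amitriptyline,Css,"Patients, MD",100-150 mg,"CYP2C19*2, CYP2C19*17",B13
Amitriptyline,"AUC, MR","Patients, MD",25 mg,"CYP2C19*2, CYP2C19*3",B14
Amitriptyline,AUC,"Healthy, SD",25 mg,"CYP2C19*2, CYP2C19*17",B15
Clomipramine,Css,"Patients, MD",10-250 mg,"CYP2C19*2, CYP2C19*3",B16
Clomipramine,1/CL,"Healthy, SD",100 mg,Phenotyping,B17
Clomipramine,Css,"Patients, MD",25-300 mg,"CYP2C19*2, CYP2C19*17",B13
Doxepine,1/CL,"Healthy, SD",75 mg,CYP2C19*2,B18
Imipramine,1/CL,"Healthy, SD",100 mg,Phenotyping,B19
Imipramine,Css,"Patients, MD",70 mg,Phenotyping,B20
Imipramine,Css,"Patients, MD",50 mg,Phenotyping,B21
Imipramine,Css,"Patients, MD",dose adjusted,CYP2C19*2,B22
Trimipramine,Css,"Patients, MD",350 mg,Phenotyping,B23
Trimipramine,1/CL,"Healthy, SD",75 mg,CYP2C19*2,B24
Citalopram,AUC,"Healthy, MD",40 mg,Phenotyping,B25
Citalopram,Css,"Patients, MD",10-60 mg,"CYP2C19*2, CYP2C19*17",B13
Citalopram,CL,"Healthy, SD",20 mg,CYP2C19*2,B26
Citalopram,Css,"Patients, MD",35 +/- 20/34 +/- 17,CYP2C19*2,B27
Escitalopram,Css,"Patients, MD",4.8-7.4 mg,"CYP2C19*2, CYP2C19*17",B28
Escitalopram,CL,"Healthy, MD",10 mg,Phenotyping,B29
Escitalopram,AUC,"Healthy, SD",5 mg,"CYP2C19*2, CYP2C19*17",B30
Escitalopram,Css,"Patients, MD",16 +/- 5/21 +/- 13,CYP2C19*2,B31
Escitalopram,Css,"Patients, MD",20 +/- 9/22 +/- 10,CYP2C19*2,B27
Escitalopram,"Css, MR","Patients, MD",5-40 mg,"CYP2C19*2, CYP2C19*17",B32
Escitalopram,Css,"Patients, MD",10-20,"CYP2C19*2, CYP2C19*17",B33
Escitalopram,Css,"Patients, MD",10 mg,"CYP2C19*2, CYP2C19*17",B34
Escitalopram,Css,"Patients, MD",5-20 mg,"CYP2C19*2, *3, CYP2C19*17",B35
Escitalopram,Css,"Patients, MD",12.6-18.1 mg,"CYP2C19*2, CYP2C19*17",B36
Escitalopram,MR,"Patients, MD",10-80 mg,"CYP2C19*2, CYP2C19*17",B37
Fluoxetine,"AUC, CL","Healthy, SD",40 mg,"CYP2C19*2, CYP2C19*17",B38
Fluoxetine,Css,"Patients, MD",10-60 mg,"CYP2C19*2, CYP2C19*17",B39
Fluvoxamine,AUC,"Healthy, SD",100 mg,Phenotyping,B40
Sertraline,"AUC, CL","Healthy, SD",100 mg,Phenotyping,B41
Sertraline,CL,"Patients, MD",dose-adjusted,"CYP2C19*2, CYP2C19*17",B42
Sertraline,Css,"Patients, MD",dose-adjusted,"CYP2C19*2, CYP2C19*17",B43
Sertraline,AUC,"Healthy, SD",,"CYP2C19*2, CYP2C19*17",B44
Maprotiline,Css,"Patients, MD",150 mg,Phenotyping,B45
Mianserin,AUC,"Healthy, SD",30 mg,Phenotyping,B46
Moclobemide,1/CL,"Healthy, MD",300 mg; 600 mg,Phenotyping,B47
Venlafaxine,Css,"Patients, MD",<225 mg; >225 mg,"CYP2C19*2, CYP2C19*17",B48
Venlafaxine,Css,"Patients, MD",dose-corrected TDM,"CYP2C19*2, CYP2C19*17",B49
Venlafaxine,Css,"Patients, MD",150 mg,"CYP2C19*2, CYP2C19*17",B50
Clozapine,AUC,"Healthy, SD",10 mg,Phenotyping,B51
Clozapine,Css,"Patients, MD",250 (25-800) mg,"CYP2C19*2, CYP2C19*17",B52
Clozapine,Css,"Patients, MD",433 mg,"CYP2C19*2, CYP2C19*17",B53
Zotepine,1/CL,"Healthy, SD",25 mg,Phenotyping,B54
Etizolam,AUC,"Healthy, SD",1 mg,"CYP2C19*2, *3",B55
Diazepam,CL,"Healthy, SD",10 mg,Phenotyping,B56
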