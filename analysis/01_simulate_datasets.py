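"""Generate the study datasets used by the downstream analyses.

Writes three seeded synthetic sampling-point tables under results/data/:

* ``substrates.csv``  — 12 CYP2C19 substrates (every drug has a real slope),
  the conditions of the activity-score estimation stage;
* ``benchmark.csv``   — the 20-substance mixed benchmark (half
  non-substrates) plus the sparse/dense probe substances used to exercise
  shrinkage;
* ``truth_*.json``    — the generating slopes, pooling effects and noise
  scales, for recovery reporting.
"""

import json
from pathlib import Path

from pgxdose import GeneratorConfig, generate_dataset, write_sampling_points
from pgxdose.simulate import benchmark_dataset

SEED = 20
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sub_cfg = GeneratorConfig(n_substances=12, seed=SEED, prop_nonzero=1.0)
    substrates, sub_truth = generate_dataset(sub_cfg)
    write_sampling_points(substrates, OUT / "substrates.csv")
    (OUT / "truth_substrates.json").write_text(json.dumps(sub_truth.as_dict(), indent=2))
    print(f"substrates: {len(substrates)} sampling points, "
          f"{substrates['substance'].nunique()} drugs, "
          f"{substrates['study_id'].nunique()} studies")

    bench, bench_truth = benchmark_dataset(seed=SEED)
    write_sampling_points(bench, OUT / "benchmark.csv")
    (OUT / "truth_benchmark.json").write_text(json.dumps(bench_truth.as_dict(), indent=2))
    n_null = int((bench_truth.slopes == 0).sum())
    print(f"benchmark: {len(bench)} sampling points across "
          f"{bench['substance'].nunique()} substances ({n_null} true non-substrates); "
          f"group sizes span n={bench['n'].min()}..{bench['n'].max()}")


if __name__ == "__main__":
    main()
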