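"""Sampling-point schema, exclusions and design-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxdose import (
    ActivityScoreMap,
    ConfounderColumn,
    DEFAULT_SCORES,
    NON_SUBSTRATES,
    Phenotype,
    apply_exclusions,
    build_design,
    load_sampling_points,
    load_study_characteristics,
    validate_sampling_points,
    write_sampling_points,
)
from pgxdose.data import COLUMNS, SchemaError, ValidationError


def _raw_row(**kw):
    row = {
        "study_id": "s1",
        "substance": "escitalopram",
        "phenotype": "PM",
        "adjustment": -50.0,
        "n": 10,
        "pool_rm17": 0,
        "pool_im17": 0,
        "pool_em2": 0,
        "pool_em17": 0,
        "pk_param": "AUC",
        "population": "healthy",
        "dosing": "SD",
        "id_method": "genotyping",
    }
    row.update(kw)
    return row


def test_packaged_study_characteristics_lists_51_studies_over_18_drugs():
    df = load_study_characteristics()
    assert len(df) == 51
    assert df["drug"].nunique() == 18


def test_roundtrip_write_then_load_is_identity(small_dataset, tmp_path):
    points, _ = small_dataset
    path = tmp_path / "points.csv"
    write_sampling_points(points, path)
    reloaded = load_sampling_points(path)
    pd.testing.assert_frame_equal(points.reset_index(drop=True), reloaded)


def test_empty_table_with_valid_header_loads_empty(tmp_path):
    path = tmp_path / "empty.csv"
    pd.DataFrame(columns=COLUMNS).to_csv(path, index=False)
    df = load_sampling_points(path)
    assert df.empty


def test_lowercase_phenotype_and_em_zero_are_normalized():
    df = validate_sampling_points(pd.DataFrame([_raw_row(phenotype="em", adjustment=0.0)]))
    assert df.loc[0, "phenotype"] == "EM"


@pytest.mark.parametrize(
    "mutation, exc",
    [
        (lambda r: r.pop("phenotype"), SchemaError),
        (lambda r: r.update(n=0), ValidationError),
        (lambda r: r.update(n=-3), ValidationError),
        (lambda r: r.update(phenotype="XX"), ValidationError),
        (lambda r: r.update(pk_param="Tmax"), ValidationError),
        (lambda r: r.update(adjustment=np.inf), ValidationError),
        (lambda r: r.update(phenotype="EM", adjustment=12.0), ValidationError),
    ],
)
def test_validation_rejects_bad_rows(mutation, exc):
    row = _raw_row()
    mutation(row)
    with pytest.raises(exc):
        validate_sampling_points(pd.DataFrame([row]))


def test_blank_flags_default_to_zero():
    df = validate_sampling_points(pd.DataFrame([_raw_row(pool_em17=None)]))
    assert df.loc[0, "pool_em17"] == 0


def test_mianserine_spelling_normalized_and_excludable():
    df = validate_sampling_points(pd.DataFrame([_raw_row(substance="  Mianserine ")]))
    assert df.loc[0, "substance"] == "mianserin"
    out, log = apply_exclusions(df, drop_substances=list(NON_SUBSTRATES))
    assert out.empty
    assert log[0]["rows_removed"] == 1


def test_drop_em_rows_leaves_no_reference_rows(small_dataset):
    points, _ = small_dataset
    out, _ = apply_exclusions(points, drop_em_rows=True)
    assert not (out["phenotype"] == "EM").any()


def test_drop_pool_rm17_counts_match_enumeration():
    rows = [_raw_row(study_id=f"s{i}", pool_rm17=int(i < 3)) for i in range(10)]
    df = validate_sampling_points(pd.DataFrame(rows))
    out, log = apply_exclusions(df, drop_pool_rm17=True)
    assert len(out) == 7
    assert log[0]["rows_removed"] == 3


def test_unknown_substance_in_rules_warns_but_keeps_rows(small_dataset, caplog):
    points, _ = small_dataset
    with caplog.at_level("WARNING", logger="pgxdose.data"):
        out, _ = apply_exclusions(points, drop_substances=["notadrug"])
    assert len(out) == len(points)
    assert any("notadrug" in r.message for r in caplog.records)


def test_exclusions_idempotent_and_order_preserving(small_dataset):
    points, _ = small_dataset
    rules = dict(drop_em_rows=True, drop_pool_rm17=True)
    once, _ = apply_exclusions(points, **rules)
    twice, _ = apply_exclusions(once, **rules)
    pd.testing.assert_frame_equal(once, twice)
    assert list(once.index) == sorted(once.index)


# --- design matrices -------------------------------------------------------

def _brute_force_X(points, scores, substances):
    """Independent double-loop construction of the slope design matrix."""
    X = np.zeros((len(points), len(substances)))
    for i, (_, row) in enumerate(points.iterrows()):
        for j, sub in enumerate(substances):
            if row["substance"] == sub:
                X[i, j] = scores[row["phenotype"]]
    return X


def test_design_matrix_matches_brute_force_oracle():
    scores = ActivityScoreMap(
        {Phenotype.PM: -2, Phenotype.IM: -1, Phenotype.EM: 0, Phenotype.RM: 0.8, Phenotype.UM: 1.6}
    )
    rows = [
        _raw_row(study_id="a", substance="drugA", phenotype="PM", adjustment=-40),
        _raw_row(study_id="a", substance="drugA", phenotype="IM", adjustment=-20),
        _raw_row(study_id="b", substance="drugB", phenotype="RM", adjustment=15),
        _raw_row(study_id="b", substance="drugB", phenotype="UM", adjustment=30),
        _raw_row(study_id="c", substance="drugA", phenotype="UM", adjustment=35),
        _raw_row(study_id="c", substance="drugB", phenotype="PM", adjustment=-45),
    ]
    points = validate_sampling_points(pd.DataFrame(rows))
    d = build_design(points, scores, confounders=())
    assert d.col_index == ["druga", "drugb"]
    np.testing.assert_allclose(d.X, _brute_force_X(points, scores, d.col_index))
    assert (np.count_nonzero(d.X, axis=1) == 1).all()
    assert not np.any(np.all(d.X == 0.0, axis=0))


def test_pm_row_gets_minus_two_in_its_substance_column(small_design):
    d, working, _ = small_design
    pm = working["phenotype"].to_numpy() == "PM"
    np.testing.assert_allclose(d.X[pm].sum(axis=1), -2.0)


def test_em_rows_block_design_construction(small_dataset):
    points, _ = small_dataset
    with pytest.raises(ValidationError):
        build_design(points)


def test_unflagged_row_codes_zero_in_confounder_column():
    rows = [_raw_row(phenotype="UM", adjustment=30.0, pool_rm17=0),
            _raw_row(study_id="s2", phenotype="RM", adjustment=50.0, pool_rm17=1)]
    points = validate_sampling_points(pd.DataFrame(rows))
    d = build_design(points, DEFAULT_SCORES, (ConfounderColumn("pool_rm17", "flag_on:RM"),))
    np.testing.assert_allclose(d.R[:, 0], [0.0, 1.0])


@settings(max_examples=25, deadline=None)
@given(perm_seed=st.integers(0, 2**31 - 1))
def test_design_is_equivariant_under_row_permutation(small_design, perm_seed):
    d, working, _ = small_design
    rng = np.random.default_rng(perm_seed)
    order = rng.permutation(len(working))
    d2 = build_design(working.iloc[order])
    assert d2.col_index == d.col_index
    np.testing.assert_allclose(d2.X, d.X[order])
    np.testing.assert_allclose(d2.y, d.y[order])
    np.testing.assert_allclose(d2.n, d.n[order])


def test_score_map_enforces_ordering_and_anchor():
    with pytest.raises(ValueError):
        ActivityScoreMap({Phenotype.PM: -2, Phenotype.IM: -1, Phenotype.EM: 0.5,
                          Phenotype.RM: 1, Phenotype.UM: 2})
    with pytest.raises(ValueError):
        ActivityScoreMap({Phenotype.PM: -1, Phenotype.IM: -2, Phenotype.EM: 0,
                          Phenotype.RM: 1, Phenotype.UM: 2})
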