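"""Sampling-point dataset: schema, validation, exclusions and design matrices.

The observational unit is the *sampling point*: one study's reported percent
dose adjustment for a single metabolizer-phenotype / substance combination,
together with the group sample size and the design flags of the study that
produced it.  Adjustments are stored as percentage-point deviations from the
extensive-metabolizer (EM) reference, so EM is identically 0 and the adjusted
dose is ``100 + adjustment`` percent of the label dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Phenotype(str, Enum):
    """CYP2C19 metabolizer phenotype groups; EM is the reference."""

    PM = "PM"
    IM = "IM"
    EM = "EM"
    RM = "RM"
    UM = "UM"


#: Phenotypes ordered by increasing metabolic activity.
PHENOTYPE_ORDER = [Phenotype.PM, Phenotype.IM, Phenotype.EM, Phenotype.RM, Phenotype.UM]

PK_PARAMS = {"AUC", "CL", "CSS", "MR"}
POPULATIONS = {"HEALTHY", "PATIENTS"}
DOSING = {"SD", "MD"}
ID_METHODS = {"PHENOTYPING", "GENOTYPING"}

FLAG_COLUMNS = ["pool_rm17", "pool_im17", "pool_em2", "pool_em17"]

#: Canonical column order of the sampling-point table.
COLUMNS = [
    "study_id",
    "substance",
    "phenotype",
    "adjustment",
    "n",
    *FLAG_COLUMNS,
    "pk_param",
    "population",
    "dosing",
    "id_method",
]

# The literature uses two spellings for mianserin; normalize to one token.
_SUBSTANCE_ALIASES = {"mianserine": "mianserin"}


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ValidationError(ValueError):
    """A row violates the sampling-point invariants."""


@dataclass(frozen=True)
class ActivityScoreMap:
    """Phenotype -> metabolic activity score, anchored at EM = 0, IM = -1."""

    scores: Mapping[Phenotype, float]

    def __post_init__(self) -> None:
        s = dict(self.scores)
        missing = [p for p in Phenotype if p not in s]
        if missing:
            raise ValueError(f"score map missing phenotypes: {missing}")
        if s[Phenotype.EM] != 0.0:
            raise ValueError("EM score must be 0 (EM-anchored scale)")
        ordered = [s[p] for p in PHENOTYPE_ORDER]
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("scores must be strictly increasing PM<IM<EM<RM<UM")

    def __getitem__(self, phenotype: Phenotype | str) -> float:
        return self.scores[Phenotype(phenotype)]

    def as_dict(self) -> dict[str, float]:
        return {p.value: float(self.scores[p]) for p in PHENOTYPE_ORDER}


#: Working score map: PM -2 (two null alleles), IM -1 (one null), EM 0,
#: RM 0.8 (one *17 allele), UM 1.6 (two *17 alleles).
DEFAULT_SCORES = ActivityScoreMap(
    {
        Phenotype.PM: -2.0,
        Phenotype.IM: -1.0,
        Phenotype.EM: 0.0,
        Phenotype.RM: 0.8,
        Phenotype.UM: 1.6,
    }
)


@dataclass(frozen=True)
class ConfounderColumn:
    """One column of the confounder matrix R.

    coding:
      - ``"flag"``: the 0/1 study flag as-is.
      - ``"flag_on:<PHEN>"``: the flag restricted to rows of one phenotype
        (pooling biases the group whose composition it alters).
      - ``"interaction"``: flag x activity score of the row's phenotype.
    """

    name: str
    coding: str = "flag"

    def values(self, df: pd.DataFrame, scores: ActivityScoreMap) -> np.ndarray:
        if self.name not in df.columns:
            raise ValidationError(f"confounder {self.name!r} is not a sampling-point field")
        flag = df[self.name].to_numpy(dtype=float)
        if self.coding == "flag":
            return flag
        if self.coding.startswith("flag_on:"):
            phen = self.coding.split(":", 1)[1]
            return flag * (df["phenotype"].to_numpy() == phen)
        if self.coding == "interaction":
            s = df["phenotype"].map(lambda p: scores[p]).to_numpy(dtype=float)
            return flag * s
        raise ValueError(f"unknown confounder coding {self.coding!r}")

    @property
    def label(self) -> str:
        return self.name if self.coding == "flag" else f"{self.name}[{self.coding}]"


#: Confounders of the main adjustment model: RM-pooling bias only.
DEFAULT_CONFOUNDERS = (ConfounderColumn("pool_rm17", "flag_on:RM"),)

#: Confounders of the preliminary phenotype-factor model.
FACTOR_CONFOUNDERS = (
    ConfounderColumn("pool_rm17", "flag_on:RM"),
    ConfounderColumn("pool_im17", "flag_on:IM"),
)


@dataclass
class DesignMatrices:
    """The y, X, R, n of the no-intercept adjustment model.

    X has one column per substance; the entry in row i is the activity score
    of row i's phenotype if the column is row i's substance, else 0, so each
    row has exactly one nonzero entry and the EM reference needs no intercept.
    """

    y: np.ndarray
    X: np.ndarray
    R: np.ndarray
    n: np.ndarray
    row_index: pd.Index
    col_index: list[str]
    conf_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.y)
        if not (self.X.shape[0] == self.R.shape[0] == len(self.n) == len(self.row_index) == m):
            raise ValueError("design matrix dimensions disagree")
        if self.X.shape[1] != len(self.col_index):
            raise ValueError("X columns and col_index disagree")


def _normalize_enum(series: pd.Series, allowed: set[str], column: str) -> pd.Series:
    out = series.astype(str).str.strip().str.upper()
    bad = sorted(set(out) - allowed)
    if bad:
        raise ValidationError(f"unknown {column} token(s): {bad}; allowed: {sorted(allowed)}")
    return out


def validate_sampling_points(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a raw sampling-point table.

    Enum fields are case-folded; substance tokens are case-folded, trimmed and
    de-aliased; blank design flags default to 0 with a warning (older studies
    predate the *17 allele and simply lack the distinction).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df[COLUMNS].copy()

    df["substance"] = df["substance"].astype(str).str.strip().str.lower()
    df["substance"] = df["substance"].replace(_SUBSTANCE_ALIASES)

    df["phenotype"] = _normalize_enum(df["phenotype"], {p.value for p in Phenotype}, "phenotype")
    df["pk_param"] = _normalize_enum(df["pk_param"], PK_PARAMS, "pk_param")
    df["pk_param"] = df["pk_param"].replace({"CSS": "Css"})
    df["population"] = _normalize_enum(df["population"], POPULATIONS, "population").str.lower()
    df["dosing"] = _normalize_enum(df["dosing"], DOSING, "dosing")
    df["id_method"] = _normalize_enum(df["id_method"], ID_METHODS, "id_method").str.lower()

    for flag in FLAG_COLUMNS:
        blank = df[flag].isna()
        if blank.any():
            logger.warning("%d blank %s flag(s) defaulted to 0", int(blank.sum()), flag)
            df[flag] = df[flag].fillna(0).infer_objects(copy=False)
        df[flag] = df[flag].astype(int)
        if not df[flag].isin([0, 1]).all():
            raise ValidationError(f"{flag} must be 0/1")

    df["adjustment"] = pd.to_numeric(df["adjustment"])
    if not np.isfinite(df["adjustment"]).all():
        rows = df.index[~np.isfinite(df["adjustment"])].tolist()
        raise ValidationError(f"non-finite adjustment in row(s) {rows}")

    df["n"] = pd.to_numeric(df["n"])
    bad_n = df.index[(df["n"] < 1) | (df["n"] != df["n"].astype(int))].tolist()
    if bad_n:
        raise ValidationError(f"sample size n must be a positive integer; bad row(s): {bad_n}")
    df["n"] = df["n"].astype(int)

    em = df["phenotype"] == Phenotype.EM.value
    if em.any() and not np.allclose(df.loc[em, "adjustment"], 0.0):
        rows = df.index[em & (df["adjustment"] != 0)].tolist()
        raise ValidationError(f"EM rows must carry adjustment 0 (reference group); bad row(s): {rows}")

    df["study_id"] = df["study_id"].astype(str)
    return df


def load_sampling_points(source: str | Path) -> pd.DataFrame:
    """Read a sampling-point CSV and return the validated canonical table."""
    df = pd.read_csv(source)
    df = validate_sampling_points(df)
    if df.empty:
        logger.warning("sampling-point table %s is empty", source)
    else:
        logger.info(
            "loaded %d sampling points: %s",
            len(df),
            df.groupby("substance").size().to_dict(),
        )
    return df


def write_sampling_points(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical sampling-point CSV (round-trips through load)."""
    df[COLUMNS].to_csv(path, index=False)


def load_study_characteristics(source: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged study-characteristics table (or a user-supplied one).

    The packaged fixture lists the 51 included studies of psychotropic
    CYP2C19 substrates with their PK parameter, subjects/dosing, dose and
    metabolizer-identification method.
    """
    if source is None:
        ref = resources.files("pgxdose.fixtures").joinpath("study_characteristics.csv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(source)


def apply_exclusions(
    points: pd.DataFrame,
    drop_em_rows: bool = False,
    drop_substances: Sequence[str] = (),
    drop_pool_rm17: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Filter sampling points, returning survivors (order preserved) and a log.

    ``drop_substances`` removes every sampling point of the named substances
    (used for drugs with no visible CYP2C19 effect); ``drop_pool_rm17``
    removes points from studies that pooled *17/*17 carriers into RM;
    ``drop_em_rows`` removes the EM reference rows (not independent data).
    Unknown substance names produce a warning, not an error.
    """
    df = points
    log: list[dict] = []
    if drop_em_rows:
        mask = df["phenotype"] == Phenotype.EM.value
        log.append({"rule": "drop_em_rows", "rows_removed": int(mask.sum())})
        df = df[~mask]
    if drop_substances:
        wanted = {_SUBSTANCE_ALIASES.get(s.strip().lower(), s.strip().lower()) for s in drop_substances}
        present = set(df["substance"])
        for unknown in sorted(wanted - present):
            logger.warning("exclusion rule names unknown substance %r (0 rows removed)", unknown)
        mask = df["substance"].isin(wanted)
        log.append(
            {"rule": "drop_substances", "substances": sorted(wanted), "rows_removed": int(mask.sum())}
        )
        df = df[~mask]
    if drop_pool_rm17:
        mask = df["pool_rm17"] == 1
        log.append({"rule": "drop_pool_rm17", "rows_removed": int(mask.sum())})
        df = df[~mask]
    return df, log


#: Substances with no visible CYP2C19 effect in vivo, excluded before the
#: activity-score estimation stage.
NON_SUBSTRATES = ("mianserin", "maprotiline", "fluoxetine", "fluvoxamine")


def build_design(
    points: pd.DataFrame,
    scores: ActivityScoreMap = DEFAULT_SCORES,
    confounders: Iterable[ConfounderColumn] = DEFAULT_CONFOUNDERS,
) -> DesignMatrices:
    """Assemble y, X, R, n for the no-intercept adjustment model.

    Preconditions: EM rows already removed (the EM reference is encoded by the
    missing intercept, not by data rows). Substances with zero rows are
    dropped from the column index with a warning.
    """
    if (points["phenotype"] == Phenotype.EM.value).any():
        raise ValidationError("EM rows must be removed before building the design")
    confounders = list(confounders)
    substances = sorted(points["substance"].unique())
    col_of = {s: j for j, s in enumerate(substances)}

    m = len(points)
    y = points["adjustment"].to_numpy(dtype=float)
    n = points["n"].to_numpy(dtype=float)
    s_row = points["phenotype"].map(lambda p: scores[p]).to_numpy(dtype=float)
    X = np.zeros((m, len(substances)))
    X[np.arange(m), points["substance"].map(col_of).to_numpy()] = s_row

    keep = ~np.all(X == 0.0, axis=0)
    if not keep.all():
        dropped = [s for s, k in zip(substances, keep) if not k]
        logger.warning("dropping all-zero substance column(s): %s", dropped)
        X = X[:, keep]
        substances = [s for s, k in zip(substances, keep) if k]

    if confounders:
        R = np.column_stack([c.values(points, scores) for c in confounders])
    else:
        R = np.zeros((m, 0))
    return DesignMatrices(
        y=y,
        X=X,
        R=R,
        n=n,
        row_index=points.index.copy(),
        col_index=substances,
        conf_names=[c.label for c in confounders],
    )
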