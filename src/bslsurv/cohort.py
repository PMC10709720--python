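"""Reading, validating, filtering, encoding and splitting patient tables.

The expected input is a registry-style CSV of adult WHO grade 2 glioma
patients: demographics (age, sex, marital status, income band, living area,
reporting region), clinicopathology (histology, tumor location, laterality,
extension, tumor size in mm), a binary surgery column (0 = subtotal
resection, 1 = gross-total resection), follow-up time in months and a
cause-specific death indicator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA",
    "REFERENCE_LEVELS",
    "CohortTable",
    "FilterLog",
    "DesignMatrix",
    "read_cohort",
    "apply_inclusion_filters",
    "encode_design",
    "split_train_test",
    "cv_folds",
]

#: canonical fields -> kind. ``factor`` fields are one-hot encoded with the
#: reference level dropped; ``continuous`` fields are z-scored.
SCHEMA = {
    "patient_id": "id",
    "age": "continuous",
    "sex": "factor",
    "marital": "factor",
    "income": "factor",
    "area": "factor",
    "region": "factor",
    "histology": "factor",
    "location": "factor",
    "laterality": "factor",
    "extension": "factor",
    "tumor_size": "continuous",
    "treatment": "treatment",
    "time": "time",
    "event": "event",
}

VALID_LEVELS = {
    "sex": {"male", "female"},
    "area": {"urban", "rural"},
    "histology": {"astrocytoma", "oligodendroglioma", "oligoastrocytoma"},
    "location": {"frontal", "temporal", "parietal", "occipital", "overlapping", "other"},
    "laterality": {"left", "right"},
    "extension": {"confined", "extended"},
}

#: fixed reference levels so the encoded design is reproducible across runs
REFERENCE_LEVELS = {
    "sex": "female",
    "marital": "unmarried",
    "income": "low",
    "area": "rural",
    "region": "west",
    "histology": "astrocytoma",
    "location": "frontal",
    "laterality": "left",
    "extension": "confined",
}

MISSING_TOKENS = {"", "unknown", "na", "nan", "none", "ambiguous"}


@dataclass
class FilterLog:
    rule_name: str
    n_removed: int
    removed_ids: list


@dataclass
class CohortTable:
    """Typed patient table plus the provenance of any filtering applied."""

    df: pd.DataFrame
    filter_logs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def write_filter_log(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"rule_name": l.rule_name, "n_removed": l.n_removed,
                     "removed_ids": list(map(str, l.removed_ids))}
                    for l in self.filter_logs
                ],
                fh,
                indent=2,
            )


@dataclass
class DesignMatrix:
    """Encoded covariates with treatment/time/event vectors.

    ``columns`` is an ordered list of (column name, source field, level) so
    attributions and coefficients can always be traced back to a covariate.
    The scaler (per-continuous-column mean/sd) is fitted on training rows
    only and reapplied verbatim to any new rows.
    """

    X: np.ndarray
    columns: list
    treatment: np.ndarray
    time: np.ndarray
    event: np.ndarray
    scaler: dict
    ids: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "DesignMatrix":
        idx = np.asarray(idx)
        return DesignMatrix(self.X[idx], self.columns, self.treatment[idx],
                            self.time[idx], self.event[idx], self.scaler,
                            self.ids[idx])

    def column_names(self) -> list:
        return [c[0] for c in self.columns]


def _is_missing(v) -> bool:
    if pd.isna(v):
        return True
    return str(v).strip().lower() in MISSING_TOKENS


def read_cohort(path, schema: dict | None = None) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    ``schema`` maps canonical field names to CSV column names (identity by
    default).  Rows with unparseable numeric fields are reported in the
    raised error rather than silently dropped.
    """
    schema = schema or {}
    colmap = {f: schema.get(f, f) for f in SCHEMA}
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty cohort file: {path}") from exc
    if raw.empty:
        raise ValueError(f"cohort file has no rows: {path}")

    missing_cols = [f for f, c in colmap.items() if c not in raw.columns]
    if missing_cols:
        raise KeyError(
            "cohort CSV is missing required column(s): "
            + ", ".join(sorted(colmap[f] for f in missing_cols))
        )

    df = pd.DataFrame({f: raw[colmap[f]] for f in SCHEMA})
    bad_rows: list[str] = []
    for col in ("age", "tumor_size", "time", "treatment", "event"):
        vals = df[col].astype(str).str.strip()
        ok = vals.apply(lambda v: v.lower() in MISSING_TOKENS) | vals.str.fullmatch(
            r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?"
        )
        for ridx in df.index[~ok]:
            bad_rows.append(f"row {ridx + 1}: {col}={df.at[ridx, col]!r}")
    if bad_rows:
        raise ValueError("unparseable numeric values: " + "; ".join(bad_rows))

    for col in ("age", "tumor_size", "time", "treatment", "event"):
        df[col] = pd.to_numeric(df[col].where(~df[col].apply(_is_missing)), errors="coerce")
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.strip().str.lower()
            df.loc[df[col].isin(MISSING_TOKENS), col] = np.nan
    return CohortTable(df.reset_index(drop=True))


def apply_inclusion_filters(cohort: CohortTable) -> tuple[CohortTable, list]:
    """Apply the cohort inclusion/exclusion rules in a fixed, logged order.

    Order: (1) unknown/ambiguous laterality or tumor size; (2) duplicate
    patient id (first record kept); (3) age < 18; (4) unknown follow-up time
    or surgery; (5) histology outside the three grade-2 entities or treatment
    outside {0, 1}; (6) any remaining missing covariate value.  Each rule's
    removals are logged; an empty result is legal.
    """
    df = cohort.df.copy()
    logs: list[FilterLog] = []

    def drop(mask, name):
        removed = df.index[mask]
        logs.append(FilterLog(name, int(mask.sum()),
                              df.loc[removed, "patient_id"].tolist()))
        return df.loc[~mask]

    m = df["laterality"].isna() | df["tumor_size"].isna() | (df["tumor_size"] <= 0)
    df = drop(m, "unknown_laterality_or_size")

    m = df.duplicated(subset="patient_id", keep="first")
    df = drop(m, "duplicate_patient_id")

    m = df["age"].isna() | (df["age"] < 18)
    df = drop(m, "age_under_18")

    m = df["time"].isna() | (df["time"] <= 0) | df["treatment"].isna()
    df = drop(m, "unknown_time_or_treatment")

    m = ~df["histology"].isin(VALID_LEVELS["histology"]) | ~df["treatment"].isin([0, 1])
    df = drop(m, "histology_or_treatment_out_of_scope")

    m = df.isna().any(axis=1) | ~df["event"].isin([0, 1])
    df = drop(m, "missing_covariates")

    out = CohortTable(df.reset_index(drop=True), cohort.filter_logs + logs)
    return out, logs


def encode_design(cohort: CohortTable, fit_scaler_on=None,
                  scaler: dict | None = None,
                  levels: dict | None = None) -> DesignMatrix:
    """One-hot + z-score encoding with a deterministic column order.

    Factor levels are taken from ``levels`` (or observed, sorted, with the
    configured reference level first and dropped); continuous columns are
    standardized with statistics fitted on ``fit_scaler_on`` rows only, or
    with a previously fitted ``scaler`` (transform mode).  An unseen factor
    level at transform time raises.
    """
    df = cohort.df
    n = len(df)
    if n == 0:
        raise ValueError("cannot encode an empty cohort")

    factor_fields = [f for f, k in SCHEMA.items() if k == "factor"]
    cont_fields = [f for f, k in SCHEMA.items() if k == "continuous"]

    if levels is None:
        levels = {}
        for f in factor_fields:
            obs = sorted(map(str, df[f].dropna().unique()))
            ref = REFERENCE_LEVELS.get(f)
            if ref in obs:
                obs.remove(ref)
                obs = [ref] + obs
            levels[f] = obs
    else:
        for f in factor_fields:
            unseen = set(map(str, df[f].dropna().unique())) - set(levels[f])
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} in factor {f!r}")

    if scaler is None:
        rows = np.arange(n) if fit_scaler_on is None else np.asarray(fit_scaler_on)
        scaler = {}
        for f in cont_fields:
            v = df[f].to_numpy(dtype=float)[rows]
            sd = float(v.std(ddof=0))
            scaler[f] = (float(v.mean()), sd if sd > 0 else 1.0)

    cols, blocks = [], []
    for f in cont_fields:
        mean, sd = scaler[f]
        blocks.append(((df[f].to_numpy(dtype=float) - mean) / sd)[:, None])
        cols.append((f, f, None))
    for f in factor_fields:
        for lev in levels[f][1:]:  # reference level dropped
            blocks.append((df[f].astype(str) == lev).to_numpy(dtype=float)[:, None])
            cols.append((f"{f}={lev}", f, lev))

    return DesignMatrix(
        X=np.ascontiguousarray(np.hstack(blocks)),
        columns=cols,
        treatment=df["treatment"].to_numpy(dtype=int),
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
        scaler={**scaler, "_levels": levels},
        ids=df["patient_id"].to_numpy(),
    )


def _stratified_assign(strata, sizes_fn, rng):
    """Generic stratified index partition.

    ``sizes_fn(m)`` returns the integer group sizes for a stratum of size m.
    Returns an array of group labels per row.
    """
    strata = np.asarray(strata)
    out = np.empty(len(strata), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        sizes = sizes_fn(len(idx))
        labels = np.repeat(np.arange(len(sizes)), sizes)
        out[idx] = labels
    return out


def _strata(dm: DesignMatrix):
    return dm.treatment * 2 + dm.event


def split_train_test(dm: DesignMatrix, test_fraction: float, seed: int):
    """Stratified train/test split on the joint (treatment, event) strata."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata = _strata(dm)
    counts = np.bincount(strata)
    if np.any((counts > 0) & (counts < 2)):
        warnings.warn("a (treatment, event) stratum has < 2 members; "
                      "falling back to a global split")
        strata = np.zeros(dm.n, dtype=int)

    # largest-remainder allocation of the global test size across strata
    uniq = np.unique(strata)
    sizes_by_stratum = {}
    targets = {s: (strata == s).sum() * test_fraction for s in uniq}
    floors = {s: int(np.floor(targets[s])) for s in uniq}
    n_test_total = int(round(dm.n * test_fraction))
    short = n_test_total - sum(floors.values())
    order = sorted(uniq, key=lambda s: targets[s] - floors[s], reverse=True)
    for s in uniq:
        sizes_by_stratum[s] = floors[s]
    for s in order[:max(short, 0)]:
        sizes_by_stratum[s] += 1
    for s in uniq:
        m = (strata == s).sum()
        sizes_by_stratum[s] = min(max(sizes_by_stratum[s], 0), m)

    next_sizes = iter([(int((strata == s).sum()) - sizes_by_stratum[s],
                        sizes_by_stratum[s]) for s in uniq])

    def sizes(m):
        tr, te = next(next_sizes)
        assert tr + te == m
        return [tr, te]

    lab = _stratified_assign(strata, sizes, rng)
    train_idx = np.flatnonzero(lab == 0)
    test_idx = np.flatnonzero(lab == 1)
    return dm.subset(train_idx), dm.subset(test_idx), train_idx, test_idx


def cv_folds(dm: DesignMatrix, k: int, seed: int):
    """k disjoint, exhaustive, (treatment, event)-stratified folds.

    Returns a list of (fit_idx, val_idx) pairs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dm.n:
        raise ValueError(f"k={k} exceeds the number of rows ({dm.n})")
    rng = np.random.default_rng(seed)
    strata = _strata(dm)

    def sizes(m):
        base = m // k
        extra = m % k
        return [base + (1 if i < extra else 0) for i in range(k)]

    lab = _stratified_assign(strata, sizes, rng)
    folds = []
    for f in range(k):
        val = np.flatnonzero(lab == f)
        fit = np.flatnonzero(lab != f)
        folds.append((fit, val))
    return folds
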