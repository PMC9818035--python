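"""Cohort CSV schema, validation, covariate encoding and descriptive summary.

One row per subject: two observed times in months (left and right eye),
two 0/1 event indicators (1 = blind, 0 = right-censored), age in years,
and eight categorical covariates.  Reference levels for dummy coding are
fixed so a coefficient's hazard ratio always reads "level vs reference".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "CATEGORIES",
    "REFERENCE_LEVELS",
    "DESIGN_COLUMNS",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "design_matrix",
    "summarize",
]

TIME_COLUMNS = ("y_left", "y_right")
EVENT_COLUMNS = ("d_left", "d_right")

#: categorical vocabularies; the first level of each list is the reference
CATEGORIES: dict[str, list[str]] = {
    "gender": ["female", "male"],
    "residence": ["rural", "urban"],
    "diabetes": ["no", "yes"],
    "iop": ["normal", "not_normal"],
    "medication": ["diamox", "timoglue", "timolol"],
    "duration": ["long", "medium", "short"],
    "cup_disc": ["gt_0.7", "le_0.7"],
    "stage": ["absolute", "early", "moderate", "advanced"],
}

REFERENCE_LEVELS = {cov: levels[0] for cov, levels in CATEGORIES.items()}

REQUIRED_COLUMNS = (
    ("subject_id",) + TIME_COLUMNS + EVENT_COLUMNS + ("age",) + tuple(CATEGORIES)
)

#: fixed design order: age first, then one dummy per non-reference level
DESIGN_COLUMNS = ["age"] + [
    f"{cov}_{lvl}" for cov, levels in CATEGORIES.items() for lvl in levels[1:]
]


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema."""


def _normalize_category(cov: str, values: pd.Series, strict: bool) -> pd.Series:
    vocab = CATEGORIES[cov]
    vals = values.astype(str)
    if strict:
        bad = ~vals.isin(vocab)
    else:
        vals = vals.str.strip().str.lower().str.replace(" ", "_")
        bad = ~vals.isin(vocab)
    if bad.any():
        rows = [int(r) + 2 for r in np.flatnonzero(bad.to_numpy())[:5]]  # +2: header + 1-based
        raise CohortValidationError(
            f"column {cov!r}: unknown categories {sorted(set(vals[bad]))} "
            f"(valid: {vocab}); first offending file lines: {rows}"
        )
    return vals


def validate_cohort(df: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Validate (and in lenient mode normalise) a cohort table in place-free style."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    out = df.copy()
    for col in TIME_COLUMNS:
        t = pd.to_numeric(out[col], errors="coerce")
        bad = t.isna() | (t <= 0)
        if bad.any():
            rows = [int(r) + 2 for r in np.flatnonzero(bad.to_numpy())[:5]]
            raise CohortValidationError(
                f"column {col!r}: times must be positive numbers "
                f"(follow-up starts at 1 month); offending file lines: {rows}"
            )
        out[col] = t.astype(float)
    for col in EVENT_COLUMNS:
        d = pd.to_numeric(out[col], errors="coerce")
        bad = ~d.isin([0, 1])
        if bad.any():
            rows = [int(r) + 2 for r in np.flatnonzero(bad.to_numpy())[:5]]
            raise CohortValidationError(
                f"column {col!r}: event indicators must be 0 or 1; "
                f"offending file lines: {rows}"
            )
        out[col] = d.astype(int)
    age = pd.to_numeric(out["age"], errors="coerce")
    if age.isna().any():
        rows = [int(r) + 2 for r in np.flatnonzero(age.isna().to_numpy())[:5]]
        raise CohortValidationError(f"column 'age': non-numeric values at file lines {rows}")
    out["age"] = age.astype(float)
    if out["subject_id"].duplicated().any():
        dup = out.loc[out["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortValidationError(f"duplicate subject_id {dup!r}")
    for cov in CATEGORIES:
        out[cov] = _normalize_category(cov, out[cov], strict)
    return out


def read_cohort(path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV (UTF-8 with header)."""
    df = pd.read_csv(path)
    return validate_cohort(df, strict=strict)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def design_matrix(df: pd.DataFrame, reference_levels: dict | None = None):
    """Dummy-code the covariates against fixed reference levels.

    Returns ``(X, names)`` with ``X`` an (n, 13) float array: age as a
    numeric column followed by one 0/1 dummy per non-reference level, in
    the fixed ``DESIGN_COLUMNS`` order.
    """
    refs = dict(REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    cols = [df["age"].to_numpy(dtype=float)]
    names = ["age"]
    for cov, levels in CATEGORIES.items():
        ref = refs[cov]
        if ref not in levels:
            raise CohortValidationError(f"{ref!r} is not a level of {cov!r}")
        for lvl in levels:
            if lvl == ref:
                continue
            cols.append((df[cov] == lvl).to_numpy(dtype=float))
            names.append(f"{cov}_{lvl}")
    return np.column_stack(cols), names


def stack_eyes(df: pd.DataFrame):
    """Long format: one row per eye, with subject id for clustering."""
    base = df.drop(columns=["y_left", "y_right", "d_left", "d_right"])
    rows = []
    for side in ("left", "right"):
        part = base.copy()
        part["time"] = df[f"y_{side}"].to_numpy()
        part["event"] = df[f"d_{side}"].to_numpy()
        part["eye"] = side
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: per covariate level, patient counts, blind counts
    (blind = event in at least one eye) and the pooled-eyes KM median.

    Percentages are of the full cohort, printed to one decimal
    (round-half-even).
    """
    from .marginal_analysis import kaplan_meier

    total = len(df)
    blind = ((df["d_left"] == 1) | (df["d_right"] == 1)).to_numpy()
    rows = []
    for cov, levels in CATEGORIES.items():
        for lvl in levels:
            mask = (df[cov] == lvl).to_numpy()
            n = int(mask.sum())
            nb = int((mask & blind).sum())
            sub = df[mask]
            if n:
                times = np.concatenate([sub["y_left"], sub["y_right"]])
                events = np.concatenate([sub["d_left"], sub["d_right"]])
                km = kaplan_meier(times, events)
                med = km.median
            else:
                med = np.nan
            rows.append({
                "covariate": cov,
                "level": lvl,
                "n": n,
                "pct": np.round(100.0 * n / total, 1),
                "blind_n": nb,
                "blind_pct": np.round(100.0 * nb / total, 1),
                "nonblind_n": n - nb,
                "nonblind_pct": np.round(100.0 * (n - nb) / total, 1),
                "km_median_months": med,
            })
    return pd.DataFrame(rows)
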