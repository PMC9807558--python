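"""Observer-agreement statistics for masked grading of PED classification.

Graders score segmentation and per-tissue classification accuracy on a
0-100 scale at two timepoints.  Agreement is summarized with intraclass
correlations -- ICC(2,1): two-way random effects, absolute agreement,
single measurement -- for intra-observer repeatability (same grader,
two timepoints) and inter-observer reproducibility (different graders),
and with Bland-Altman limits of agreement at mean +- 2 sample SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "CATEGORIES",
    "load_grade_table",
    "validate_grade_table",
    "icc_two_way",
    "repeatability",
    "reproducibility",
    "bland_altman",
    "mean_icc",
]

CATEGORIES = ("segmentation", "serous", "neovascular", "fibrous")


@dataclass
class AgreementResult:
    """An ICC with its variance components and design dimensions."""

    icc: float
    var_subject: float
    var_rater: float
    var_residual: float
    n_subjects: int
    n_measurements: int
    n_dropped: int = 0
    category: str = ""


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    pairs: pd.DataFrame = field(repr=False, default=None)


def validate_grade_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a grade table's schema and ranges; returns the validated frame.

    Required columns: image_id, grader_id, timepoint (1 or 2), category
    (segmentation/serous/neovascular/fibrous), score in [0, 100] or NaN
    (absent tissue gets no grade).
    """
    required = {"image_id", "grader_id", "timepoint", "category", "score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"grade table is missing columns: {sorted(missing)}")
    if not table["timepoint"].isin([1, 2]).all():
        raise ValueError("timepoint must be 1 or 2")
    bad_cat = set(table["category"].unique()) - set(CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown categories: {sorted(bad_cat)}")
    scores = table["score"].dropna()
    if ((scores < 0) | (scores > 100)).any():
        raise ValueError("scores must lie in [0, 100]")
    return table


def load_grade_table(path) -> pd.DataFrame:
    """Read a grade CSV (image_id,grader_id,timepoint,category,score)."""
    return validate_grade_table(pd.read_csv(path))


def icc_two_way(scores: np.ndarray, category: str = "") -> AgreementResult:
    """ICC(2,1) from an (n subjects x k measurements) score matrix.

    Rows with any missing value are dropped (count reported).  Mean squares
    from the two-way ANOVA give

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Variance-component estimates are truncated at zero; a negative ICC is
    reported as computed, with a warning.  A matrix with zero total
    variance reports ICC 1 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must be a 2-D matrix with >= 2 measurement columns")
    complete = ~np.isnan(scores).any(axis=1)
    n_dropped = int((~complete).sum())
    x = scores[complete]
    n, k = x.shape
    if n < 2:
        raise ValueError(f"need >= 2 complete subjects, got {n}")

    grand = x.mean()
    if np.allclose(x, grand, atol=0):
        warnings.warn("zero total variance; reporting ICC = 1")
        return AgreementResult(1.0, 0.0, 0.0, 0.0, n, k, n_dropped, category)

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 1.0
    if icc < 0:
        warnings.warn(f"negative ICC ({icc:.3f}) computed; reported as is")
    return AgreementResult(
        icc=float(icc),
        var_subject=max((msr - mse) / k, 0.0),
        var_rater=max((msc - mse) / n, 0.0),
        var_residual=float(mse),
        n_subjects=n,
        n_measurements=k,
        n_dropped=n_dropped,
        category=category,
    )


def _pivot(table: pd.DataFrame, category: str, index: str, columns: str, values="score") -> pd.DataFrame:
    sub = table[table["category"] == category]
    return sub.pivot_table(index=index, columns=columns, values=values, aggfunc="mean")


def repeatability(table: pd.DataFrame, grader) -> dict[str, AgreementResult]:
    """Intra-observer ICC per category for one grader across two timepoints."""
    validate_grade_table(table)
    sub = table[table["grader_id"] == grader]
    if sub.empty:
        raise ValueError(f"no rows for grader {grader!r}")
    if set(sub["timepoint"].unique()) != {1, 2}:
        raise ValueError(f"grader {grader!r} is missing a timepoint")
    out = {}
    for cat in CATEGORIES:
        if not (sub["category"] == cat).any():
            continue
        wide = _pivot(sub, cat, index="image_id", columns="timepoint")
        out[cat] = icc_two_way(wide.to_numpy(), category=cat)
    return out


def reproducibility(
    table: pd.DataFrame,
    average_timepoints: bool = True,
) -> dict[str, AgreementResult]:
    """Inter-observer ICC per category across graders.

    Each grader's two timepoints are averaged first (default); with
    ``average_timepoints=False`` only timepoint 1 is used.
    """
    validate_grade_table(table)
    if table["grader_id"].nunique() < 2:
        raise ValueError("reproducibility needs >= 2 graders")
    src = table if average_timepoints else table[table["timepoint"] == 1]
    out = {}
    for cat in CATEGORIES:
        if not (src["category"] == cat).any():
            continue
        wide = _pivot(src, cat, index="image_id", columns="grader_id")
        out[cat] = icc_two_way(wide.to_numpy(), category=cat)
    return out


def mean_icc(results: dict[str, AgreementResult]) -> tuple[float, float]:
    """Mean +- sample SD of the ICCs across categories (SD 0 for one cell)."""
    vals = np.array([r.icc for r in results.values()])
    if len(vals) == 0:
        raise ValueError("no ICC results to average")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman limits of agreement at mean difference +- 2 sample SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if len(a) < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(np.std(d, ddof=1))
    pairs = pd.DataFrame({"mean": (a + b) / 2.0, "diff": d})
    return BlandAltmanResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - 2.0 * sd,
        loa_high=mean_diff + 2.0 * sd,
        sd_diff=sd,
        pairs=pairs,
    )
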