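"""Cohort-level comparisons of per-eye flow-deficit biomarkers.

Three-arm omnibus testing (Kruskal–Wallis), pairwise comparisons
(exact or tie-corrected Mann–Whitney, Welch's t), and multivariable
linear regression of FD metrics on clinical covariates.  Both eyes of a
subject are treated as independent observations — the design of the
study this mirrors — so p-values are anticonservative under inter-eye
correlation; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .geometry import ValidationError
from .quant import FDReport

FD_METRICS = ("fd_percent", "fd_count", "fd_mean_size_um2", "fd_total_area_mm2")
COVARIATES = ("age", "treatment_duration", "daily_dose_mg_per_kg", "cumulative_dose_g")
GROUPS = ("1a", "1b", "2")

#: combined sample size at or below which the Mann-Whitney p-value is
#: computed by exact enumeration (when the data contain no ties)
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class EyeRecord:
    """One eye: arm label, FD reports per radius, optional covariates."""

    eye_id: str
    group: str
    reports: Mapping[int, FDReport]
    covariates: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value must lie in [0, 1]")


def _as_arrays(*groups: Sequence[float]) -> list[np.ndarray]:
    return [np.asarray(g, dtype=np.float64) for g in groups]


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    metric: str = "",
    labels: Sequence[str] = (),
) -> ComparisonResult:
    """Rank-based omnibus test across k groups (tie-corrected H, chi2 df=k-1)."""
    arrays = _as_arrays(*groups)
    if len(arrays) < 2:
        raise ValidationError("kruskal_wallis needs at least two groups")
    for a in arrays:
        if a.size < 2:
            raise ValidationError("every group needs >= 2 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # every observation identical: no separation by convention
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return ComparisonResult(metric, "kruskal-wallis", float(h), float(p), tuple(labels))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    labels: Sequence[str] = (),
    mode: str = "auto",
) -> ComparisonResult:
    """Two-sided Mann–Whitney U.

    ``mode='auto'`` (default) uses exact enumeration when the combined
    sample size is <= 12 and there are no ties, else the tie-corrected
    normal approximation with continuity correction; ``'exact'`` and
    ``'normal_approx'`` force either branch.
    """
    xa, xb = _as_arrays(a, b)
    if xa.size == 0 or xb.size == 0:
        raise ValidationError("mann_whitney requires nonempty groups")
    pooled = np.concatenate([xa, xb])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (pooled.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if np.ptp(pooled) == 0:
        u, p = xa.size * xb.size / 2.0, 1.0
    else:
        u, p = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return ComparisonResult(metric, f"mann-whitney ({method})", float(u),
                            float(min(p, 1.0)), tuple(labels))


def welch_t(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    labels: Sequence[str] = (),
) -> ComparisonResult:
    """Two-sided t-test with Welch–Satterthwaite degrees of freedom."""
    xa, xb = _as_arrays(a, b)
    if xa.size < 2 or xb.size < 2:
        raise ValidationError("welch_t requires >= 2 observations per group")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        if xa.mean() == xb.mean():
            return ComparisonResult(metric, "welch-t", 0.0, 1.0, tuple(labels))
        raise ValidationError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(xa, xb, equal_var=False)
    return ComparisonResult(metric, "welch-t", float(t), float(p), tuple(labels))


def fd_regression(
    records: Sequence[EyeRecord],
    metric: str,
    radius: int,
    covariates: Sequence[str] = COVARIATES,
) -> pd.DataFrame:
    """OLS of one FD metric on the clinical covariates, with intercept.

    Returns a coefficient table indexed by term (const + covariates)
    with columns ``estimate``, ``std_err``, ``p_value``.
    """
    if metric not in FD_METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    rows = []
    for rec in records:
        if rec.covariates is None or any(c not in rec.covariates for c in covariates):
            raise ValidationError(f"eye {rec.eye_id}: missing covariates")
        row = {c: float(rec.covariates[c]) for c in covariates}
        row["y"] = getattr(rec.reports[radius], metric)
        rows.append(row)
    if len(rows) < len(covariates) + 2:
        raise ValidationError(
            f"need >= {len(covariates) + 2} records for {len(covariates)} covariates"
        )
    df = pd.DataFrame(rows)
    design = sm.add_constant(df[list(covariates)], has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_columns(design)
        raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(df["y"], design).fit()
    return pd.DataFrame(
        {"estimate": fit.params, "std_err": fit.bse, "p_value": fit.pvalues}
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (the redundant ones)."""
    x = design.to_numpy()
    full = np.linalg.matrix_rank(x)
    return [
        col
        for i, col in enumerate(design.columns)
        if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == full
    ]


def compare_groups(
    records: Sequence[EyeRecord],
    radii: Sequence[int] = (4, 8),
    metrics: Sequence[str] = FD_METRICS,
) -> pd.DataFrame:
    """Omnibus + all pairwise comparisons for each metric at each radius.

    Returns a long table with columns: metric, radius_px, test, groups,
    statistic, p_value.  Needs >= 2 arms with >= 2 eyes each; the
    omnibus row is emitted only when >= 3 arms are present.
    """
    by_group: dict[str, list[EyeRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)
    if len(by_group) < 2:
        raise ValidationError("cohort comparison needs >= 2 groups")
    labels = sorted(by_group)
    out = []
    for radius in radii:
        for metric in metrics:
            values = {
                g: [getattr(r.reports[radius], metric) for r in by_group[g]]
                for g in labels
            }
            if len(labels) >= 3:
                res = kruskal_wallis([values[g] for g in labels], metric, labels)
                out.append(_row(res, radius))
            for ga, gb in combinations(labels, 2):
                res = mann_whitney(values[ga], values[gb], metric, (ga, gb))
                out.append(_row(res, radius))
    return pd.DataFrame(out, columns=["metric", "radius_px", "test", "groups",
                                      "statistic", "p_value"])


def _row(res: ComparisonResult, radius: int) -> dict:
    return {
        "metric": res.metric,
        "radius_px": radius,
        "test": res.test,
        "groups": "|".join(res.groups),
        "statistic": res.statistic,
        "p_value": res.p_value,
    }
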