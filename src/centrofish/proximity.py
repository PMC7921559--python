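"""Per-cell centrosomal proximity statistic and group statistics.

The core statistic is, for each cell, the fraction f of its mRNA spots whose
2D distance to the nearest centrosome centroid is strictly below a radius r
(default 2000 nm, i.e. 2 um).  Group comparisons use a one-sided Welch t test
(unequal variances, Welch-Satterthwaite degrees of freedom); proportions get
Wilson score intervals; 2x2 contingency tables get the two-sided Fisher exact
test; distributions are summarized with linear-interpolation quartiles and
1.5 x IQR whiskers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ProximityConfig",
    "ProximityResult",
    "GroupComparison",
    "ProportionCI",
    "BoxplotSummary",
    "proximity_fraction",
    "welch_one_sided",
    "wilson_ci",
    "fisher_exact_two_sided",
    "summarize_box",
]


@dataclass
class ProximityConfig:
    """r is the proximity radius in nm; spots at exactly r do not count
    (strictly-less-than rule); distances are 2D-projection Euclidean to the
    nearest centrosome centroid."""

    radius_nm: float = 2000.0

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")


@dataclass
class ProximityResult:
    cell_id: int
    n_spots: int
    n_near: int
    fraction: float
    condition: str = ""


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    dof: float
    p_value: float
    alternative: str
    degenerate: bool = False


@dataclass
class ProportionCI:
    k: int
    n: int
    level: float
    low: float
    high: float


@dataclass
class BoxplotSummary:
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


def proximity_fraction(
    spot_coords_nm: np.ndarray,
    centrosome_coords_nm: np.ndarray,
    config: ProximityConfig | None = None,
    cell_id: int = 0,
    condition: str = "",
) -> ProximityResult:
    """Fraction of spots strictly within the proximity radius of the nearest
    centrosome centroid, in the 2D projection plane.

    Coordinates are (..., y, x) nm — only the last two axes are used, so 2D
    and 3D inputs are both accepted.
    """
    config = config or ProximityConfig()
    spots = np.asarray(spot_coords_nm, dtype=float)
    spots = spots.reshape(-1, spots.shape[-1])[:, -2:] if spots.size else spots.reshape(0, 2)
    centros = np.asarray(centrosome_coords_nm, dtype=float)
    centros = (
        centros.reshape(-1, centros.shape[-1])[:, -2:]
        if centros.size
        else centros.reshape(0, 2)
    )
    if len(centros) == 0:
        raise ValueError("at least one centrosome is required (cell filter violated)")
    if len(spots) == 0:
        raise ValueError("at least one spot is required (cell filter violated)")
    d = np.sqrt(
        ((spots[:, None, :] - centros[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    n_near = int(np.sum(d < config.radius_nm))
    return ProximityResult(
        cell_id=cell_id,
        n_spots=len(spots),
        n_near=n_near,
        fraction=n_near / len(spots),
        condition=condition,
    )


def welch_one_sided(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    alternative: str = "greater",
    name_a: str = "a",
    name_b: str = "b",
) -> GroupComparison:
    """One-sided Welch t test of mean(a) vs mean(b).

    ``alternative="greater"`` tests mean(a) > mean(b).  Degenerate input
    (both variances zero, equal means) yields t = 0, p = 0.5 with the
    degenerate flag set.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return GroupComparison(
                name_a, name_b, float(a.mean()), float(b.mean()),
                0.0, float(a.size + b.size - 2), 0.5, alternative, degenerate=True,
            )
        sign = 1.0 if a.mean() > b.mean() else -1.0
        p = 0.0 if (sign > 0) == (alternative == "greater") else 1.0
        return GroupComparison(
            name_a, name_b, float(a.mean()), float(b.mean()),
            sign * np.inf, float(a.size + b.size - 2), p, alternative,
            degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return GroupComparison(
        group_a=name_a,
        group_b=name_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        dof=float(res.df),
        p_value=float(res.pvalue),
        alternative=alternative,
    )


def wilson_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    low, high = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    # guard against float round-off pushing the bounds outside [0, 1]
    low = min(max(float(low), 0.0), k / n)
    high = max(min(float(high), 1.0), k / n)
    return ProportionCI(k=k, n=n, level=level, low=low, high=high)


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding that of the observed table (with a 1 + 1e-7
    relative tolerance); a zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or t[:, 1].sum() == 0:
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def summarize_box(values: np.ndarray) -> BoxplotSummary:
    """Quartiles by linear interpolation; whiskers at the most extreme data
    within q1 - 1.5 IQR and q3 + 1.5 IQR (clipped to the data range)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    within = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        mean=float(v.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(within.min()),
        whisker_high=float(within.max()),
        n=int(v.size),
    )
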