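"""Permutation subsampling, ANOVA/Tukey testing, and trend classification.

Uneven sample sizes across time points are handled by permutation
subsampling: for every subsample size from a minimum (default 3) up to all
available samples, the statistic is recomputed on ``reps`` (default 20)
random draws without replacement, and the replicate distribution is
summarised (median, mean, SD, CV).

Two screening rules operate on the replicate summaries:

* neutrality: a population/time-point is flagged as departing from
  neutrality when the mean Tajima's D across permutations satisfies
  |D| > 1.5 (strict);
* variability: a Watterson's-theta summary is flagged as significantly
  variable when its coefficient of variation exceeds 1.0 (strict).

One-way ANOVA across time periods (with Tukey HSD post hoc adjustment) is
run on the permutation replicate values within each species x site stratum;
the inherited replicate pseudo-replication is a property of this procedure
and is documented, not corrected.

Trend classification over ordered time points uses the rule table:
(pi up, theta up, D down) -> expansion; (pi down, theta down, D up) or
(pi down, theta up, D up) -> contraction; all flat -> stable; otherwise
mixed.  "Flat" is |relative change| below a configurable tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GenotypeMatrix

__all__ = [
    "PermutationSummary",
    "AnovaResult",
    "TrendCall",
    "permute_subsample",
    "neutrality_test_D",
    "variability_test_theta",
    "anova_time_periods",
    "regress_diversity_vs",
    "classify_trend",
]


@dataclass
class PermutationSummary:
    """Replicate distribution of a statistic at one subsample size."""

    population: str
    n_sub: int
    values: np.ndarray

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.values))

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2 or np.ptp(self.values) == 0:
            return 0.0   # identical replicates: exactly zero, no float residue
        return float(np.nanstd(self.values, ddof=1))

    @property
    def cv(self) -> float:
        m = self.mean
        if m == 0 or np.isnan(m):
            return float("nan")
        return self.sd / abs(m)


@dataclass
class AnovaResult:
    F: float
    p: float
    group_means: dict[str, float]
    tukey: pd.DataFrame          # columns: group1, group2, difference, p_adj
    degenerate: bool = False


@dataclass
class TrendCall:
    """Direction of each statistic through time and the resulting class."""

    population: str
    direction_pi: str            # 'up' | 'down' | 'flat'
    direction_theta: str
    direction_d: str
    classification: str          # expansion | contraction | stable | mixed
    neutrality_flags: list[bool] = field(default_factory=list)


# --------------------------------------------------------------------------
# permutation subsampling
# --------------------------------------------------------------------------
def permute_subsample(
    matrix: GenotypeMatrix,
    sample_names: Sequence[str],
    statistic: Callable[[GenotypeMatrix, np.ndarray], float],
    n_min: int = 3,
    reps: int = 20,
    seed: int = 0,
    population: str = "",
) -> list[PermutationSummary]:
    """Recompute ``statistic`` on subsamples of every size n_min..N.

    ``statistic(matrix, mask)`` receives the full matrix and a boolean
    column mask for the drawn subsample.  Draws are without replacement
    from named substreams keyed by (seed, n_sub, replicate), so results
    are reproducible and independent across sizes.

    Raises ValueError when the population has fewer than ``n_min`` samples
    (explicit skip is the caller's decision).
    """
    names = list(sample_names)
    N = len(names)
    if N < n_min:
        raise ValueError(f"population {population!r} has {N} < n_min={n_min} samples")
    base_mask = matrix.sample_mask(names)
    cols = np.flatnonzero(base_mask)
    if len(cols) != N:
        raise ValueError("some sample names missing from matrix")
    out = []
    for n_sub in range(n_min, N + 1):
        vals = np.empty(reps)
        for rep in range(reps):
            rng = np.random.default_rng([seed, n_sub, rep])
            pick = rng.choice(cols, size=n_sub, replace=False)
            mask = np.zeros(matrix.n_samples, dtype=bool)
            mask[pick] = True
            vals[rep] = statistic(matrix, mask)
        out.append(PermutationSummary(population=population, n_sub=n_sub, values=vals))
    return out


def neutrality_test_D(perm: PermutationSummary, critical: float = 1.5) -> bool:
    """Flag departure from neutrality: |mean D across permutations| > 1.5."""
    return bool(abs(perm.mean) > critical)


def variability_test_theta(perm: PermutationSummary, critical: float = 1.0) -> bool:
    """Flag significant variability: CV across replicates > 1.0."""
    cv = perm.cv
    return bool(not np.isnan(cv) and cv > critical)


# --------------------------------------------------------------------------
# ANOVA + Tukey and regressions
# --------------------------------------------------------------------------
def anova_time_periods(groups: dict[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise adjustment.

    ``groups`` maps time-period label -> replicate values.  Identical
    groups give F = 0, p = 1.  Zero within-group variance everywhere with
    unequal means is reported as p ~ 0 and flagged degenerate.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least two values per group")
    means = {k: float(a.mean()) for k, a in zip(labels, arrays)}

    grand = np.concatenate(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ssb = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    df_b = len(labels) - 1
    df_w = len(grand) - len(labels)
    degenerate = False
    if ssw == 0.0:
        if ssb == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
            degenerate = True
    else:
        F = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(F, df_b, df_w))

    pairs = []
    if np.isfinite(F) and ssw > 0:
        res = stats.tukey_hsd(*arrays)
        for i, j in combinations(range(len(labels)), 2):
            pairs.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "difference": float(arrays[j].mean() - arrays[i].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    else:
        for i, j in combinations(range(len(labels)), 2):
            diff = float(arrays[j].mean() - arrays[i].mean())
            pairs.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "difference": diff,
                    "p_adj": 0.0 if diff != 0 else 1.0,
                }
            )
    return AnovaResult(
        F=float(F),
        p=float(p),
        group_means=means,
        tukey=pd.DataFrame(pairs),
        degenerate=degenerate,
    )


def regress_diversity_vs(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of median diversity against a per-population covariate.

    Returns (slope, intercept, r_squared, p) with the slope's t-test p
    value.  Covariates of interest: sample size, number of years sampled,
    sampling timespan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three populations")
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


# --------------------------------------------------------------------------
# trend classification
# --------------------------------------------------------------------------
def _direction(first: float, last: float, rel_tol: float) -> str:
    if not (np.isfinite(first) and np.isfinite(last)):
        return "flat"
    scale = abs(first)
    if scale == 0:
        return "flat" if last == 0 else ("up" if last > 0 else "down")
    delta = (last - first) / scale
    if abs(delta) <= rel_tol:
        return "flat"
    return "up" if delta > 0 else "down"


def classify_trend(
    pi_series: Sequence[float],
    theta_series: Sequence[float],
    d_series: Sequence[float],
    rel_tol: float = 0.02,
    population: str = "",
    neutrality_flags: Sequence[bool] | None = None,
) -> TrendCall:
    """Classify a population's demographic trend from ordered time points.

    Directions compare the last time point against the first, with
    |relative change| <= ``rel_tol`` called flat.  Tajima's D changes are
    judged on the additive scale (D is already normalised and crosses
    zero), using ``rel_tol`` as an absolute tolerance.
    """
    for s in (pi_series, theta_series, d_series):
        if len(s) < 2:
            raise ValueError("need at least two time points")
    dir_pi = _direction(pi_series[0], pi_series[-1], rel_tol)
    dir_th = _direction(theta_series[0], theta_series[-1], rel_tol)
    d0, d1 = d_series[0], d_series[-1]
    if not (np.isfinite(d0) and np.isfinite(d1)) or abs(d1 - d0) <= rel_tol:
        dir_d = "flat"
    else:
        dir_d = "up" if d1 > d0 else "down"

    key = (dir_pi, dir_th, dir_d)
    if key == ("up", "up", "down"):
        cls = "expansion"
    elif key in (("down", "down", "up"), ("down", "up", "up")):
        cls = "contraction"
    elif key == ("flat", "flat", "flat"):
        cls = "stable"
    else:
        cls = "mixed"
    return TrendCall(
        population=population,
        direction_pi=dir_pi,
        direction_theta=dir_th,
        direction_d=dir_d,
        classification=cls,
        neutrality_flags=list(neutrality_flags or []),
    )
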