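"""Season-level summaries: EGI-fraction curves, logistic fits, suppression
statistics, replicate aggregation, and strategy comparisons.

The central fit is the two-parameter logistic ``y = 1 / (1 + exp(-k (x - x0)))``
with asymptotes fixed at 0 and 1 (Levenberg-Marquardt least squares): ``k``
(per day) is the steepness of the engineered-genotype takeover and ``x0``
(day) its midpoint.  Suppression is reported as the percent reduction of the
cumulative adult-female count relative to an untreated control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lifecycle import CLASS_ORDER, STAGE_NAMES

__all__ = [
    "LogisticFit", "StrategyComparison",
    "adult_female_count", "egi_fraction_series", "fit_logistic",
    "suppression_percent", "aggregate_replicates", "compare_strategies",
    "log_pseudocount",
]

_CLS_NAMES = tuple(cl.value for cl in CLASS_ORDER)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters; ``k`` and ``x0`` are meaningful only when
    ``converged`` is True."""

    k: float
    x0: float
    r_squared: float
    converged: bool


def _logistic(x, k, x0):
    return 1.0 / (1.0 + np.exp(-k * (x - x0)))


def adult_female_count(census: pd.DataFrame) -> pd.Series:
    """Total adult females (all genotype classes) per timestep."""
    cols = [f"adult_female_{c}" for c in _CLS_NAMES]
    return census[cols].sum(axis=1)


def egi_fraction_series(census: pd.DataFrame,
                        denominator: str = "all_agents"
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """EGI-class fraction per timestep.

    ``denominator='all_agents'`` divides EGI-class agents of all stages and
    sexes by all living agents; ``'adult_females'`` divides adult EGI females
    by all adult females.  Timesteps with a zero denominator are omitted.
    """
    if denominator == "all_agents":
        num_cols = [f"{st}_{sx}_egi" for st in STAGE_NAMES
                    for sx in ("female", "male")]
        den_cols = [f"{st}_{sx}_{cl}" for st in STAGE_NAMES
                    for sx in ("female", "male") for cl in _CLS_NAMES]
    elif denominator == "adult_females":
        num_cols = ["adult_female_egi"]
        den_cols = [f"adult_female_{c}" for c in _CLS_NAMES]
    elif denominator == "juveniles":
        juv = [st for st in STAGE_NAMES if st != "adult"]
        num_cols = [f"{st}_{sx}_egi" for st in juv
                    for sx in ("female", "male")]
        den_cols = [f"{st}_{sx}_{cl}" for st in juv
                    for sx in ("female", "male") for cl in _CLS_NAMES]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    num = census[num_cols].sum(axis=1).to_numpy(float)
    den = census[den_cols].sum(axis=1).to_numpy(float)
    keep = den > 0
    x = census["timestep"].to_numpy(float)[keep]
    return x, num[keep] / den[keep]


def fit_logistic(x: Sequence[float], y: Sequence[float]) -> LogisticFit:
    """Least-squares logistic fit with asymptotes fixed at 0 and 1.

    Initial guess: ``x0`` at the first ``y >= 0.5`` (else mid-range),
    ``k = 0.1``/day.  Levenberg-Marquardt first; if it fails or leaves the
    admissible band (``0 < k <= 5``, ``x0`` within the data range +- 60
    days), a bounded trust-region fit is attempted.  Returns
    ``converged=False`` (parameters NaN) when no fit succeeds.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for a logistic fit")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    above = np.nonzero(y >= 0.5)[0]
    x0_guess = x[above[0]] if len(above) else 0.5 * (x[0] + x[-1])
    lo, hi = (1e-4, x.min() - 60.0), (5.0, x.max() + 60.0)

    popt = None
    try:
        p, _ = optimize.curve_fit(_logistic, x, y, p0=(0.1, x0_guess),
                                  method="lm", maxfev=10000)
        if lo[0] < p[0] <= hi[0] and lo[1] <= p[1] <= hi[1]:
            popt = p
    except RuntimeError:
        pass
    if popt is None:
        try:
            popt, _ = optimize.curve_fit(
                _logistic, x, y, p0=(0.1, float(np.clip(x0_guess, *((lo[1],
                hi[1]))))), bounds=(lo, hi), method="trf", maxfev=10000)
        except (RuntimeError, ValueError):
            return LogisticFit(np.nan, np.nan, np.nan, converged=False)

    resid = y - _logistic(x, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else -np.inf
    return LogisticFit(k=float(popt[0]), x0=float(popt[1]),
                       r_squared=r2, converged=True)


def suppression_percent(treated_cumulative: float,
                        control_cumulative: float) -> float:
    """Percent reduction of the treated cumulative adult-female count vs the
    untreated control: ``100 (1 - treated/control)``.  At most 100; negative
    values mean the treated population exceeded the control."""
    if control_cumulative <= 0:
        raise ValueError("control cumulative count must be positive")
    return 100.0 * (1.0 - treated_cumulative / control_cumulative)


def aggregate_replicates(series: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and sample SD (ddof=1) across replicate series.

    Accepts aligned 1-D arrays/Series; raises on length or index mismatch.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    arrays = []
    index0 = None
    for s in series:
        if isinstance(s, pd.Series):
            if index0 is None:
                index0 = s.index
            elif not s.index.equals(index0):
                raise ValueError("replicate series have misaligned timesteps")
            arrays.append(s.to_numpy(float))
        else:
            arrays.append(np.asarray(s, float))
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError("replicate series have misaligned timesteps")
    stacked = np.vstack(arrays)
    return stacked.mean(axis=0), stacked.std(axis=0, ddof=1)


@dataclass
class StrategyComparison:
    """One-way ANOVA across strategies with optional pairwise follow-up."""

    anova_p: float
    comparable: bool
    pairwise: Optional[pd.DataFrame]  # columns: a, b, t_p, bonferroni_p


def compare_strategies(values: Mapping[str, Sequence[float]],
                       alpha: float = 0.05) -> StrategyComparison:
    """One-way ANOVA over per-replicate suppression values per strategy;
    when significant at ``alpha``, all pairwise two-sample t-tests are
    reported (unadjusted, with a Bonferroni column for transparency)."""
    names = list(values)
    groups = [np.asarray(values[n], float) for n in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 strategies with >= 2 replicates each")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return StrategyComparison(anova_p=np.nan, comparable=False,
                                  pairwise=None)
    _, anova_p = stats.f_oneway(*groups)
    pairwise = None
    if anova_p < alpha:
        rows = []
        pairs = list(combinations(range(len(names)), 2))
        for i, j in pairs:
            _, p = stats.ttest_ind(groups[i], groups[j])
            rows.append({"a": names[i], "b": names[j], "t_p": p,
                         "bonferroni_p": min(1.0, p * len(pairs))})
        pairwise = pd.DataFrame(rows)
    return StrategyComparison(anova_p=float(anova_p), comparable=True,
                              pairwise=pairwise)


def log_pseudocount(values) -> np.ndarray:
    """Add the pseudo-count of one used for logarithmic display (0 plots
    as 1, 10 as 11, ...)."""
    arr = np.asarray(values, float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return arr + 1.0
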