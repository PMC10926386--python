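"""High-level experiment drivers: replicate batches of seasons under a
release strategy, with the standard resistance-seeding and analysis steps
wired together.  These are the entry points the acceptance checks, examples
and batch runner build on."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .analysis import egi_fraction_series, fit_logistic
from .genetics import GeneticsConfig
from .interventions import (OverwinterConfig, ReleaseStrategy,
                            ResistanceSeedConfig, build_schedule,
                            seed_overwintered)
from .lifecycle import LifecycleParams, SeasonResult, run_season
from .synthetic import TemperatureModelParams, generate_temperature_series

__all__ = [
    "ScenarioConfig", "run_replicates", "mean_cumulative_females",
    "mean_egi_fraction_curve", "midpoint_for",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation condition: strategy + seeding + genetics + lifecycle."""

    strategy: ReleaseStrategy = field(default_factory=ReleaseStrategy)
    resistance: Optional[ResistanceSeedConfig] = field(
        default_factory=ResistanceSeedConfig)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)
    lifecycle: LifecycleParams = field(default_factory=LifecycleParams)
    temperature: TemperatureModelParams = field(
        default_factory=TemperatureModelParams)
    overwinter: Optional[OverwinterConfig] = None


def run_replicates(config: ScenarioConfig, replicates: int,
                   base_seed: int,
                   temperatures=None) -> List[SeasonResult]:
    """Run ``replicates`` seasons; replicate ``r`` uses agent seed
    ``base_seed + r`` and a temperature series drawn with the same seed, so
    each replicate sees an independent weather year.  A caller-supplied
    ``temperatures`` series (e.g. from a CSV) is reused for all replicates.
    """
    import dataclasses as _dc

    schedule = build_schedule(config.strategy)
    composition = (seed_overwintered(config.overwinter)
                   if config.overwinter else {"wildtype": 1.0})
    results = []
    for r in range(replicates):
        seed = base_seed + r
        temps = temperatures if temperatures is not None else \
            generate_temperature_series(
                _dc.replace(config.temperature, seed=seed))
        results.append(run_season(
            params=config.lifecycle,
            temperatures=temps,
            genetics_cfg=config.genetics,
            composition=composition,
            schedule=schedule,
            resistance_cfg=config.resistance,
            seed=seed))
    return results


def mean_cumulative_females(results: Sequence[SeasonResult]) -> float:
    return float(np.mean([r.cumulative_adult_females for r in results]))


def mean_egi_fraction_curve(results: Sequence[SeasonResult],
                            denominator: str = "all_agents"
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Replicate-mean EGI-fraction curve on the union of timesteps.

    Per replicate, timesteps with a zero denominator contribute nothing;
    each retained timestep averages the replicates that observed it.
    """
    n_steps = max(len(r.census) for r in results)
    total = np.zeros(n_steps)
    count = np.zeros(n_steps)
    for r in results:
        x, y = egi_fraction_series(r.census, denominator)
        idx = x.astype(int)
        total[idx] += y
        count[idx] += 1
    keep = count > 0
    return np.flatnonzero(keep).astype(float), total[keep] / count[keep]


def midpoint_for(results: Sequence[SeasonResult],
                 denominator: str = "all_agents"):
    """Logistic fit of the replicate-mean EGI-fraction curve."""
    x, y = mean_egi_fraction_curve(results, denominator)
    return fit_logistic(x, y)
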