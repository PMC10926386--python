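"""Batch runner: resolved run configuration, replicate execution with
derived seeds, and all file outputs (census CSVs, release logs, summary
JSON, reproducibility manifest)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .experiments import ScenarioConfig, midpoint_for, run_replicates
from .genetics import GeneticsConfig
from .interventions import (OverwinterConfig, ReleaseStrategy,
                            ResistanceSeedConfig, resolve_strain)
from .lifecycle import LifecycleParams, TemperatureSeries

__all__ = ["RunConfig", "run_batch"]

logger = logging.getLogger("egisim")


@dataclass
class RunConfig:
    """Fully resolved configuration of a replicate batch.

    ``starting_genotype`` is a strain name (``pyrEGI`` etc.) or a raw
    14-character genotype code; together with
    ``releases_between_alternation`` it determines the release sequence
    when no named ``strategy`` is given (mirroring the positional
    command-line contract of the original tool).
    """

    strategy: Optional[str] = None
    timesteps_between_releases: int = 4
    males_per_release: int = 800
    results_dir: str = "results"
    starting_genotype: str = "pyrEGI"
    releases_between_alternation: int = 1
    replicates: int = 10
    base_seed: int = 1
    reversion_rate: float = 0.0
    strain_set: str = "egi"
    resistance_mode: Optional[str] = "independent_alleles"
    resistance_freq1: float = 0.01
    resistance_freq2: float = 0.01
    gen_snp: int = 32
    double_homozygote_fraction: float = 0.01
    overwinter_strain: Optional[str] = None
    overwinter_fraction: float = 0.0
    initial_adults: int = LifecycleParams().initial_adults
    temperature_csv: Optional[str] = None
    temperature_seed_offset: int = 0

    def resolved_strategy_id(self) -> str:
        if self.strategy:
            return self.strategy
        # positional contract: derive from the starting genotype
        name = self.starting_genotype
        if len(name) == 14:
            from .interventions import identify_strain
            name = identify_strain(name) or name
        name = resolve_strain(name) if len(name) != 14 else name
        return "custom"

    def release_strategy(self) -> ReleaseStrategy:
        sid = self.resolved_strategy_id()
        start = None
        if sid == "custom":
            start = self.starting_genotype
            if len(start) == 14:
                from .interventions import identify_strain
                resolved = identify_strain(start)
                if resolved is None:
                    raise ValueError(
                        f"starting genotype {start!r} is not a library strain")
                start = resolved
        return ReleaseStrategy(
            id=sid,
            males_per_release=self.males_per_release,
            timesteps_between_releases=self.timesteps_between_releases,
            releases_between_alternation=(
                self.releases_between_alternation if sid == "custom" else None),
            strain_set=self.strain_set,
            start_strain=start,
        )

    def scenario(self) -> ScenarioConfig:
        resistance = None
        if self.resistance_mode:
            resistance = ResistanceSeedConfig(
                freq1=self.resistance_freq1, freq2=self.resistance_freq2,
                gen_snp=self.gen_snp, mode=self.resistance_mode,
                double_homozygote_fraction=self.double_homozygote_fraction)
        overwinter = None
        if self.overwinter_strain and self.overwinter_fraction > 0:
            overwinter = OverwinterConfig(strain=self.overwinter_strain,
                                          fraction=self.overwinter_fraction)
        return ScenarioConfig(
            strategy=self.release_strategy(),
            resistance=resistance,
            genetics=GeneticsConfig(reversion_rate=self.reversion_rate),
            lifecycle=LifecycleParams(initial_adults=self.initial_adults),
            overwinter=overwinter,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_batch(config: RunConfig) -> Path:
    """Run ``config.replicates`` seasons (seeds ``base_seed + r``), write
    per-replicate census and release-log CSVs, a summary JSON, and a
    manifest reproducing the resolved configuration; returns the results
    directory."""
    out = Path(config.results_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario()

    temps = (TemperatureSeries.from_csv(config.temperature_csv)
             if config.temperature_csv else None)
    results = []
    for r in range(config.replicates):
        results.extend(run_replicates(scenario, 1, config.base_seed + r,
                                      temperatures=temps))
        logger.info("replicate %d/%d done", r + 1, config.replicates)
        results[-1].census.to_csv(out / f"census_rep{r}.csv", index=False)
        results[-1].releases.to_csv(out / f"releases_rep{r}.csv", index=False)

    cumulative = [res.cumulative_adult_females for res in results]
    summary: Dict = {
        "strategy": config.strategy or config.resolved_strategy_id(),
        "replicates": config.replicates,
        "seeds": [config.base_seed + r for r in range(config.replicates)],
        "cumulative_adult_females": {
            "per_replicate": cumulative,
            "mean": float(np.mean(cumulative)),
            "sd": float(np.std(cumulative, ddof=1)) if len(cumulative) > 1
                  else 0.0,
        },
        "peak_adults": [res.peak_adults for res in results],
        "total_released": int(sum(res.state.cum_released for res in results)
                              / max(1, len(results))),
    }
    fit = None
    try:
        fit = midpoint_for(results)
    except ValueError:
        pass
    if fit is not None and fit.converged:
        summary["logistic"] = {"k": fit.k, "x0": fit.x0,
                               "r_squared": fit.r_squared}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    config.to_yaml(out / "manifest.yaml")
    return out
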