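"""Synthetic inputs: a St.-Paul-like temperature season, deterministic
population fixtures, and an exhaustive cross-outcome oracle.

The temperature model is a cosine annual cycle plus i.i.d. Gaussian daily
noise — a climate stand-in parameterized to the continental upper-Midwest
seasonal envelope (sub-zero March, ~24 C mid-July means with occasional
>30 C days) rather than an estimate fitted to station records.  Its default
parameters are fixtures, tuned once so that an untreated season shows the
expected envelope: growth to a peak on the order of 10^4 adults in early
July followed by a heat-driven decline.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from itertools import product
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from . import genetics
from .genetics import GeneticsConfig, Genotype, GenotypeClass, parse_genotype
from .lifecycle import (ADULT, SEASON_LENGTH, SEASON_START, GenotypeRegistry,
                        PopulationState, TemperatureSeries)

__all__ = [
    "TemperatureModelParams",
    "generate_temperature_series",
    "make_fixture_population",
    "enumerate_cross_outcomes",
    "collapse_outcomes",
]


@dataclass(frozen=True)
class TemperatureModelParams:
    """Cosine-plus-noise daily mean temperature model.

    ``T(d) = annual_mean + amplitude * cos(2 pi (doy(d) - peak_doy) / 365)
    + N(0, noise_sd)`` with ``peak_doy`` 201 (July 20).
    """

    annual_mean: float = 8.0
    amplitude: float = 16.0
    peak_doy: int = 201
    noise_sd: float = 2.0
    seed: int = 0
    n_days: int = SEASON_LENGTH
    start_date: _dt.date = SEASON_START

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")


def generate_temperature_series(params: TemperatureModelParams
                                ) -> TemperatureSeries:
    """Deterministic (given ``params.seed``) daily mean temperature series."""
    rng = np.random.default_rng(params.seed)
    doy = params.start_date.timetuple().tm_yday + np.arange(params.n_days)
    temps = (params.annual_mean
             + params.amplitude * np.cos(2 * np.pi * (doy - params.peak_doy) / 365.0))
    if params.noise_sd > 0:
        temps = temps + rng.normal(0.0, params.noise_sd, params.n_days)
    return TemperatureSeries(start_date=params.start_date, values=temps)


def make_fixture_population(spec: Mapping[str, int],
                            genetics_cfg: Optional[GeneticsConfig] = None,
                            seed: int = 0) -> PopulationState:
    """Deterministic adult population with exact per-genotype counts.

    Keys are strain names (sexes alternate female, male, female, ... within
    the genotype) or explicit 14-character codes (sex fixed by the code).
    Requesting an inviable genotype is an error: fixtures must be legal
    population states.
    """
    from . import interventions  # local import: avoids a module cycle

    registry = GenotypeRegistry(genetics_cfg or GeneticsConfig())
    state = PopulationState(registry=registry,
                            rng=np.random.default_rng(seed))
    gids = []
    for name, count in spec.items():
        if count < 0:
            raise ValueError("fixture counts must be >= 0")
        if len(name) == 14:
            codes = [name] * count
        else:
            codes = [interventions.strain_code(
                name, "female" if k % 2 == 0 else "male")
                for k in range(count)]
        for code in codes:
            g = parse_genotype(code)
            if not genetics.is_viable(g):
                raise ValueError(f"fixture genotype {code!r} is not viable")
            gids.append(registry.id_for(g))
    if gids:
        state.add_agents(np.array(gids, np.int64), ADULT)
    return state


def enumerate_cross_outcomes(mother: Genotype, father: Genotype,
                             cfg: Optional[GeneticsConfig] = None
                             ) -> Dict[str, float]:
    """Brute-force cross oracle: exact egg-genotype distribution as
    ``{canonical 14-char code: probability}``.

    Enumerates, for each parent, all 2^7 per-locus inheritance patterns and
    keeps only those consistent with zero recombination inside each linked
    pair; reversion is expanded by explicit enumeration over revert/keep
    patterns at every revertible site of the egg.  Deliberately naive and
    structurally independent of :func:`genetics.punnett_summary`.
    """
    cfg = cfg or GeneticsConfig()
    if genetics.sex_of(mother) != "female" or genetics.sex_of(father) != "male":
        raise genetics.GenotypeError("oracle requires a female x male pair")

    def parent_gametes(g: Genotype) -> Dict[str, float]:
        out: Dict[str, float] = {}
        n_ok = 0
        patterns = []
        for pattern in product((0, 1), repeat=genetics.N_LOCI):
            ok = all(pattern[a] == pattern[b] for a, b in cfg.linked_pairs)
            if ok:
                patterns.append(pattern)
                n_ok += 1
        for pattern in patterns:
            hap = "".join((g.hapA if c == 0 else g.hapB)[i]
                          for i, c in enumerate(pattern))
            out[hap] = out.get(hap, 0.0) + 1.0 / n_ok
        return out

    rho = cfg.reversion_rate
    result: Dict[str, float] = {}
    for hap_m, p_m in parent_gametes(mother).items():
        for hap_p, p_p in parent_gametes(father).items():
            egg = hap_m + hap_p
            sites = [i for i, a in enumerate(egg) if a in genetics.REVERTIBLE]
            for pattern in product((0, 1), repeat=len(sites)):
                alleles = list(egg)
                prob = p_m * p_p
                for site, flip in zip(sites, pattern):
                    if flip:
                        alleles[site] = genetics.REVERTIBLE[alleles[site]]
                        prob *= rho
                    else:
                        prob *= 1.0 - rho
                if prob == 0.0:
                    continue
                code = Genotype("".join(alleles[:7]),
                                "".join(alleles[7:])).display
                result[code] = result.get(code, 0.0) + prob
    return result


def collapse_outcomes(table: Mapping[str, float],
                      field_conditions: bool = True
                      ) -> Dict[Tuple[GenotypeClass, str], float]:
    """Collapse an oracle genotype table to (GenotypeClass, sex) -> prob."""
    out: Dict[Tuple[GenotypeClass, str], float] = {}
    for code, prob in table.items():
        g = parse_genotype(code)
        key = (genetics.classify(g, field_conditions), genetics.sex_of(g))
        out[key] = out.get(key, 0.0) + prob
    return out
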