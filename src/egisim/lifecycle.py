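"""Daily-timestep agent simulation of a seasonal *Drosophila suzukii* population.

Each agent is an individual fly with a phased 7-locus genotype, a life stage
(egg, larva, pupa, adult), accrued degree-days, and — for adult females — a
stored sire genotype.  The season runs in daily timesteps from March 1
(timestep 0) through October 31 (timestep 244); development, fecundity and
mortality are driven by a daily mean-temperature series.

Internally the population is held as flat NumPy arrays indexed in parallel
(genotype id, stage, degree-days, age, sire id), with genotypes interned in a
:class:`GenotypeRegistry` that caches per-genotype sex/class and exact cross
distributions.  Drawing each egg's genotype from the cached exact cross
distribution is distributionally identical to calling :func:`genetics.cross`
per egg, but runs in vectorized batches.  A scalar :class:`Agent` view and
scalar ``develop`` are provided for inspection and unit-level work.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import genetics
from .genetics import GeneticsConfig, Genotype, GenotypeClass, parse_genotype

logger = logging.getLogger("egisim")

__all__ = [
    "EGG", "LARVA", "PUPA", "ADULT", "STAGE_NAMES",
    "SEASON_START", "SEASON_LENGTH",
    "LifecycleParams", "TemperatureSeries", "Agent",
    "GenotypeRegistry", "PopulationState", "SeasonResult",
    "initialize_population", "develop", "mate", "oviposit", "step",
    "run_season", "census_columns",
]

EGG, LARVA, PUPA, ADULT = 0, 1, 2, 3
STAGE_NAMES = ("egg", "larva", "pupa", "adult")
CLASS_ORDER = (
    GenotypeClass.WILD_TYPE,
    GenotypeClass.RESISTANT_CARRIER,
    GenotypeClass.EGI_LIKE,
    GenotypeClass.EGI,
)
_N_CLS = len(CLASS_ORDER)

#: timestep 0 of every season (places the resistance-seeding timestep 32 at April 2)
SEASON_START = _dt.date(2021, 3, 1)
#: March 1 .. October 31 inclusive
SEASON_LENGTH = 245


@dataclass(frozen=True)
class LifecycleParams:
    """Temperature-dependent development, survival and fecundity parameters.

    Degree-days accrue daily as ``max(0, T - base_temp)``.  A juvenile stage
    completes stochastically: once at least 80% of its degree-day requirement
    is accrued, the per-day completion probability rises linearly from 0 to 1
    at 100% of the requirement.  Adults die with temperature-dependent daily
    mortality (a logistic heat penalty pulls daily survival from
    ``adult_survival`` down toward ``heat_floor`` above ~``heat_midpoint``;
    a small cold penalty applies below ``cold_threshold``) and at
    ``adult_max_age`` days.  Fecundity (eggs/female/day) is a two-sided
    quadratic: zero at or below ``fecundity_tmin``, peak at
    ``fecundity_topt``, zero at or above ``fecundity_tmax``.
    """

    base_temp: float = 7.2
    dd_requirements: Tuple[float, float, float] = (20.0, 120.0, 110.0)
    egg_survival: float = 0.92
    larva_survival: float = 0.90
    pupa_survival: float = 0.90
    adult_survival: float = 0.97
    heat_midpoint: float = 24.5
    heat_scale: float = 1.5
    heat_floor: float = 0.72
    juvenile_heat_floor: float = 0.75
    cold_threshold: float = 2.0
    cold_factor: float = 0.98
    adult_max_age: int = 90
    fecundity_peak: float = 8.0
    fecundity_tmin: float = 10.0
    fecundity_topt: float = 21.0
    fecundity_tmax: float = 29.0
    repro_arrest_midpoint: float = 190.0
    repro_arrest_scale: float = 5.0
    daily_remating_prob: float = 0.15
    initial_adults: int = 8000

    def _heat_fraction(self, temp: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(temp - self.heat_midpoint)
                                         / self.heat_scale)))

    def juvenile_survival(self, temp: Optional[float] = None) -> np.ndarray:
        """Daily survival of (egg, larva, pupa); hot days (above
        ~``heat_midpoint``) scale all juvenile survival down toward
        ``juvenile_heat_floor`` of its baseline."""
        base = np.array([self.egg_survival, self.larva_survival,
                         self.pupa_survival])
        if temp is None:
            return base
        factor = 1.0 - (1.0 - self.juvenile_heat_floor) * self._heat_fraction(temp)
        return base * factor

    def fecundity(self, temp: float, timestep: Optional[int] = None) -> float:
        """Eggs per mated female per day at daily mean temperature ``temp``.

        When a ``timestep`` is given, a logistic late-season factor
        (midpoint ``repro_arrest_midpoint``, around September 1) tapers egg
        laying to zero — the photoperiod-induced reproductive arrest of
        autumn winter-morph females.
        """
        if temp <= self.fecundity_tmin or temp >= self.fecundity_tmax:
            return 0.0
        if temp <= self.fecundity_topt:
            half = self.fecundity_topt - self.fecundity_tmin
        else:
            half = self.fecundity_tmax - self.fecundity_topt
        frac = (temp - self.fecundity_topt) / half
        eggs = self.fecundity_peak * (1.0 - frac * frac)
        if timestep is not None:
            eggs /= 1.0 + np.exp((timestep - self.repro_arrest_midpoint)
                                 / self.repro_arrest_scale)
        return eggs

    def adult_daily_survival(self, temp: float) -> float:
        """Adult daily survival probability at temperature ``temp``."""
        heat = self._heat_fraction(temp)
        s = self.adult_survival - (self.adult_survival - self.heat_floor) * heat
        if temp < self.cold_threshold:
            s *= self.cold_factor
        return float(s)

    def completion_probability(self, stage: int, dd_accrued: float) -> float:
        """Per-day probability a juvenile completes its current stage."""
        req = self.dd_requirements[stage]
        frac = dd_accrued / req
        return float(np.clip((frac - 0.8) / 0.2, 0.0, 1.0))


@dataclass
class TemperatureSeries:
    """Daily mean temperatures (degrees C) from ``start_date`` onward."""

    start_date: _dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def temp(self, timestep: int) -> float:
        return float(self.values[timestep])

    def date(self, timestep: int) -> _dt.date:
        return self.start_date + _dt.timedelta(days=int(timestep))

    def to_csv(self, path) -> None:
        dates = [self.date(t).isoformat() for t in range(len(self))]
        pd.DataFrame({"date": dates, "mean_temp_C": self.values}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        df = pd.read_csv(path)
        start = _dt.date.fromisoformat(str(df["date"].iloc[0]))
        return cls(start_date=start, values=df["mean_temp_C"].to_numpy(float))


@dataclass
class Agent:
    """Scalar view of one fly (used for inspection and unit-level tests)."""

    id: int
    genotype: Genotype
    sex: str
    stage: int = EGG
    degree_days_accrued: float = 0.0
    age_days: int = 0
    mate_genotype: Optional[Genotype] = None


class GenotypeRegistry:
    """Interns phase-unordered genotypes as integer ids.

    Caches, per id: sex, genotype class, pure-wild-type flag; and, per
    (mother id, father id), the exact viable-offspring distribution of the
    cross under the registry's :class:`GeneticsConfig`.
    """

    def __init__(self, cfg: GeneticsConfig = GeneticsConfig(),
                 field_conditions: bool = True) -> None:
        self.cfg = cfg
        self.field_conditions = field_conditions
        self._ids: Dict[Tuple[str, str], int] = {}
        self.genotypes: List[Genotype] = []
        self._male: List[bool] = []
        self._cls: List[int] = []
        self._pure_wild: List[bool] = []
        self._male_arr = np.zeros(0, dtype=bool)
        self._cls_arr = np.zeros(0, dtype=np.int8)
        self._cross_cache: Dict[Tuple[int, int],
                                Tuple[np.ndarray, np.ndarray, float]] = {}

    def __len__(self) -> int:
        return len(self.genotypes)

    def id_for(self, g: Genotype) -> int:
        key = g.key()
        gid = self._ids.get(key)
        if gid is None:
            gid = len(self.genotypes)
            self._ids[key] = gid
            self.genotypes.append(g)
            self._male.append(genetics.sex_of(g) == "male")
            self._cls.append(self._class_code(g))
            self._pure_wild.append(g.display[:12] == "bbddppttllWW")
            self._male_arr = np.array(self._male, dtype=bool)
            self._cls_arr = np.array(self._cls, dtype=np.int8)
        return gid

    def id_for_code(self, code: str) -> int:
        return self.id_for(parse_genotype(code))

    def _class_code(self, g: Genotype) -> int:
        cls = genetics.classify(g, self.field_conditions)
        if cls is GenotypeClass.INVIABLE:
            return -1
        return CLASS_ORDER.index(cls)

    @property
    def male(self) -> np.ndarray:
        return self._male_arr

    @property
    def cls(self) -> np.ndarray:
        return self._cls_arr

    def is_pure_wild(self, gid: int) -> bool:
        return self._pure_wild[gid]

    def cross_offspring(self, mother_id: int, father_id: int
                        ) -> Tuple[np.ndarray, np.ndarray, float]:
        """(viable child ids, their probabilities, inviable probability)."""
        key = (mother_id, father_id)
        hit = self._cross_cache.get(key)
        if hit is not None:
            return hit
        dist = genetics.cross_distribution(
            self.genotypes[mother_id], self.genotypes[father_id], self.cfg)
        ids: List[int] = []
        probs: List[float] = []
        p_inviable = 0.0
        for (hap_a, hap_b), prob in dist.items():
            g = Genotype(hap_a, hap_b)
            if genetics.is_viable(g, self.field_conditions):
                ids.append(self.id_for(g))
                probs.append(prob)
            else:
                p_inviable += prob
        entry = (np.array(ids, dtype=np.int64),
                 np.array(probs, dtype=float), p_inviable)
        self._cross_cache[key] = entry
        return entry


@dataclass
class PopulationState:
    """Struct-of-arrays population plus counters and RNG.

    Only viable genotypes are ever instantiated; inviable eggs are tallied in
    ``cum_inviable_eggs`` and discarded at laying.
    """

    registry: GenotypeRegistry
    rng: np.random.Generator
    timestep: int = 0
    gid: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    stage: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int8))
    dd: np.ndarray = field(default_factory=lambda: np.zeros(0, np.float64))
    age: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int32))
    mate_gid: np.ndarray = field(default_factory=lambda: np.full(0, -1, np.int64))
    cum_eggs: int = 0
    cum_inviable_eggs: int = 0
    cum_deaths: int = 0
    cum_released: int = 0
    cum_adult_females: int = 0
    resistance_seeded: bool = False
    release_log: List[Tuple[int, str, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.gid)

    def is_male(self) -> np.ndarray:
        return self.registry.male[self.gid]

    def add_agents(self, gids: np.ndarray, stage: int,
                   mate: Optional[np.ndarray] = None) -> None:
        k = len(gids)
        if k == 0:
            return
        self.gid = np.concatenate([self.gid, np.asarray(gids, np.int64)])
        self.stage = np.concatenate([self.stage, np.full(k, stage, np.int8)])
        self.dd = np.concatenate([self.dd, np.zeros(k)])
        self.age = np.concatenate([self.age, np.zeros(k, np.int32)])
        if mate is None:
            mate = np.full(k, -1, np.int64)
        self.mate_gid = np.concatenate([self.mate_gid, mate])

    def keep(self, mask: np.ndarray) -> int:
        """Drop agents where ``mask`` is False; returns number removed."""
        removed = int(self.n - mask.sum())
        if removed:
            self.gid = self.gid[mask]
            self.stage = self.stage[mask]
            self.dd = self.dd[mask]
            self.age = self.age[mask]
            self.mate_gid = self.mate_gid[mask]
        return removed

    def agents(self) -> List[Agent]:
        """Materialize scalar :class:`Agent` views (small populations only)."""
        reg = self.registry
        out = []
        for i in range(self.n):
            g = reg.genotypes[self.gid[i]]
            m = self.mate_gid[i]
            out.append(Agent(
                id=i, genotype=g, sex=genetics.sex_of(g),
                stage=int(self.stage[i]),
                degree_days_accrued=float(self.dd[i]),
                age_days=int(self.age[i]),
                mate_genotype=None if m < 0 else reg.genotypes[m]))
        return out


def initialize_population(params: LifecycleParams,
                          composition: Mapping[str, float],
                          rng: np.random.Generator,
                          registry: Optional[GenotypeRegistry] = None,
                          genetics_cfg: Optional[GeneticsConfig] = None,
                          ) -> PopulationState:
    """Create ``params.initial_adults`` adults with the given genotype
    fractions and a 0.5 sex ratio (binomial draw) within each genotype.

    ``composition`` maps strain names (see :mod:`egisim.interventions`) or
    14-character codes to fractions summing to 1.  Genotype counts use
    largest-remainder rounding so the total is exact.
    """
    from . import interventions  # local import: avoids a module cycle

    total = float(sum(composition.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition fractions must sum to 1, got {total}")
    if registry is None:
        registry = GenotypeRegistry(genetics_cfg or GeneticsConfig())
    state = PopulationState(registry=registry, rng=rng)

    n = params.initial_adults
    names = list(composition)
    raw = np.array([composition[k] * n for k in names])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1

    gids = []
    for name, count in zip(names, counts):
        if count == 0:
            continue
        female_code = interventions.strain_code(name, "female")
        male_code = interventions.strain_code(name, "male")
        n_female = rng.binomial(count, 0.5)
        fid = registry.id_for_code(female_code)
        mid = registry.id_for_code(male_code)
        gids.append(np.full(n_female, fid, np.int64))
        gids.append(np.full(count - n_female, mid, np.int64))
    if gids:
        state.add_agents(np.concatenate(gids), ADULT)
    return state


def develop(agent: Agent, temperature: float, params: LifecycleParams,
            rng: np.random.Generator) -> Optional[Agent]:
    """Advance one agent by one day; returns the updated agent or ``None``
    on death.  Scalar counterpart of the vectorized step used in season runs
    (same probability rules, same parameterization)."""
    if agent.stage < ADULT:
        dd = agent.degree_days_accrued + max(0.0, temperature - params.base_temp)
        if rng.random() >= params.juvenile_survival(temperature)[agent.stage]:
            return None
        stage = agent.stage
        if rng.random() < params.completion_probability(stage, dd):
            stage += 1
            dd = 0.0
        return replace(agent, stage=stage, degree_days_accrued=dd,
                       age_days=agent.age_days + 1)
    if rng.random() >= params.adult_daily_survival(temperature):
        return None
    age = agent.age_days + 1
    if age > params.adult_max_age:
        return None
    return replace(agent, age_days=age)


def _develop_all(state: PopulationState, temperature: float,
                 params: LifecycleParams) -> None:
    n = state.n
    if n == 0:
        return
    rng = state.rng
    stage = state.stage
    juv = stage < ADULT
    state.dd[juv] += max(0.0, temperature - params.base_temp)

    surv = np.empty(n)
    juv_s = params.juvenile_survival(temperature)
    surv[juv] = juv_s[stage[juv]]
    surv[~juv] = params.adult_daily_survival(temperature)
    alive = rng.random(n) < surv

    state.age += 1
    alive &= ~((stage == ADULT) & (state.age > params.adult_max_age))
    state.cum_deaths += state.keep(alive)

    # stage completion after survival, on the survivors
    stage = state.stage
    juv = stage < ADULT
    if juv.any():
        req = np.asarray(params.dd_requirements)[stage[juv]]
        frac = state.dd[juv] / req
        p = np.clip((frac - 0.8) / 0.2, 0.0, 1.0)
        adv = np.zeros(state.n, dtype=bool)
        adv[np.flatnonzero(juv)] = state.rng.random(juv.sum()) < p
        state.stage[adv] += 1
        state.dd[adv] = 0.0
        state.age[adv & (state.stage == ADULT)] = 0


def mate(state: PopulationState, rng: Optional[np.random.Generator] = None,
         remating_prob: Optional[float] = None) -> None:
    """Assign a sire, uniformly at random among all adult males (released
    and field males alike), to adult females.

    Virgin adult females always mate when males are present; already-mated
    females redraw their sire with probability ``remating_prob`` per day
    (females store sperm and keep the previous sire otherwise).
    """
    rng = rng or state.rng
    if remating_prob is None:
        remating_prob = getattr(state, "remating_prob", 1.0)
    male = state.is_male()
    adult = state.stage == ADULT
    adult_m = adult & male
    if not adult_m.any():
        return
    females = adult & ~male
    virgin = females & (state.mate_gid < 0)
    eligible = virgin
    if remating_prob > 0:
        mated = females & (state.mate_gid >= 0)
        eligible = virgin | (mated & (rng.random(state.n) < remating_prob))
    k = int(eligible.sum())
    if k == 0:
        return
    sire_gids, counts = np.unique(state.gid[adult_m], return_counts=True)
    draws = rng.multinomial(k, counts / counts.sum())
    state.mate_gid[np.flatnonzero(eligible)] = np.repeat(sire_gids, draws)


def oviposit(state: PopulationState, params: LifecycleParams,
             temperature: float,
             rng: Optional[np.random.Generator] = None) -> Tuple[int, int]:
    """Each mated adult female lays Poisson(fecundity(T)) eggs, generated by
    the exact cross distribution of her genotype and her stored sire's.
    Inviable eggs are tallied and discarded; viable eggs become egg-stage
    agents.  Returns (viable eggs laid, inviable eggs)."""
    rng = rng or state.rng
    fec = params.fecundity(temperature, state.timestep)
    if fec <= 0.0 or state.n == 0:
        return (0, 0)
    mated = (state.stage == ADULT) & (state.mate_gid >= 0)
    if not mated.any():
        return (0, 0)
    reg = state.registry
    m = len(reg)
    pair_key = state.gid[mated] * m + state.mate_gid[mated]
    keys, counts = np.unique(pair_key, return_counts=True)
    new_gids: List[np.ndarray] = []
    laid = inviable = 0
    for key, n_females in zip(keys, counts):
        mother_id, father_id = int(key) // m, int(key) % m
        n_eggs = rng.poisson(n_females * fec)
        if n_eggs == 0:
            continue
        child_ids, probs, p_inv = reg.cross_offspring(mother_id, father_id)
        pvals = np.append(probs, p_inv)
        draw = rng.multinomial(n_eggs, pvals / pvals.sum())
        inviable += int(draw[-1])
        laid += int(n_eggs - draw[-1])
        if len(child_ids):
            new_gids.append(np.repeat(child_ids, draw[:-1]))
    if new_gids:
        state.add_agents(np.concatenate(new_gids), EGG)
    state.cum_eggs += laid + inviable
    state.cum_inviable_eggs += inviable
    return laid, inviable


def census_columns() -> List[str]:
    cols = []
    for st in STAGE_NAMES:
        for sx in ("female", "male"):
            for cl in CLASS_ORDER:
                cols.append(f"{st}_{sx}_{cl.value}")
    return cols


def _census_counts(state: PopulationState) -> np.ndarray:
    reg = state.registry
    if state.n == 0:
        return np.zeros(len(STAGE_NAMES) * 2 * _N_CLS, dtype=np.int64)
    male = reg.male[state.gid].astype(np.int64)
    cls = reg.cls[state.gid].astype(np.int64)
    idx = (state.stage.astype(np.int64) * 2 + male) * _N_CLS + cls
    return np.bincount(idx, minlength=len(STAGE_NAMES) * 2 * _N_CLS)


def step(state: PopulationState, temperature: float, params: LifecycleParams,
         genetics_cfg: GeneticsConfig,
         events: Sequence = (),
         resistance_cfg=None) -> Dict[str, int]:
    """Advance one timestep: scheduled interventions (releases, resistance
    seeding), development + mortality, mating, oviposition.  Returns the
    census row for the completed timestep and increments ``state.timestep``.
    """
    from . import interventions  # local import: avoids a module cycle

    if temperature is None or not np.isfinite(temperature):
        raise ValueError(f"no temperature for timestep {state.timestep}")
    released = 0
    for ev in events:
        if ev.timestep == state.timestep:
            interventions.apply_release(state, ev)
            released += ev.count
    if resistance_cfg is not None and state.timestep == resistance_cfg.gen_snp:
        interventions.seed_resistance(state, resistance_cfg)

    _develop_all(state, temperature, params)
    mate(state, remating_prob=params.daily_remating_prob)
    laid, inviable = oviposit(state, params, temperature)

    counts = _census_counts(state)
    row: Dict[str, int] = dict(zip(census_columns(), (int(c) for c in counts)))
    adult_f = sum(row[f"adult_female_{cl.value}"] for cl in CLASS_ORDER)
    state.cum_adult_females += adult_f
    row.update(
        timestep=state.timestep,
        released_this_step=released,
        eggs_laid=laid,
        inviable_eggs=inviable,
        adult_females=adult_f,
        cumulative_adult_females=state.cum_adult_females,
    )
    state.timestep += 1
    return row


@dataclass
class SeasonResult:
    """Full per-timestep census plus release log for one replicate season."""

    census: pd.DataFrame
    releases: pd.DataFrame
    state: PopulationState

    @property
    def cumulative_adult_females(self) -> int:
        return int(self.census["cumulative_adult_females"].iloc[-1]) \
            if len(self.census) else 0

    @property
    def peak_adults(self) -> int:
        adult_cols = [c for c in self.census.columns if c.startswith("adult_")
                      and c not in ("adult_females",)]
        return int(self.census[adult_cols].sum(axis=1).max()) \
            if len(self.census) else 0


def run_season(params: LifecycleParams,
               temperatures: TemperatureSeries,
               genetics_cfg: Optional[GeneticsConfig] = None,
               composition: Optional[Mapping[str, float]] = None,
               schedule: Sequence = (),
               resistance_cfg=None,
               seed: int = 0,
               rng: Optional[np.random.Generator] = None,
               n_steps: Optional[int] = None) -> SeasonResult:
    """Run one full season and return the per-timestep census.

    Deterministic given ``seed`` (or a caller-supplied ``rng``).
    ``composition`` defaults to 100% wild-type.
    """
    genetics_cfg = genetics_cfg or GeneticsConfig()
    composition = composition or {"wildtype": 1.0}
    rng = rng or np.random.default_rng(seed)
    n_steps = n_steps if n_steps is not None else len(temperatures)
    if len(temperatures) < n_steps:
        raise ValueError("temperature series shorter than the season")

    state = initialize_population(params, composition, rng,
                                  genetics_cfg=genetics_cfg)
    events_by_t: Dict[int, List] = {}
    for ev in schedule:
        events_by_t.setdefault(ev.timestep, []).append(ev)

    rows = []
    tick = max(1, n_steps // 10)
    for t in range(n_steps):
        row = step(state, temperatures.temp(t), params, genetics_cfg,
                   events=events_by_t.get(t, ()),
                   resistance_cfg=resistance_cfg)
        row["date"] = temperatures.date(t).isoformat()
        rows.append(row)
        if (t + 1) % tick == 0:
            logger.debug("timestep %d/%d: %d agents", t + 1, n_steps,
                         state.n)

    census = pd.DataFrame(rows)
    lead = ["timestep", "date"]
    census = census[lead + [c for c in census.columns if c not in lead]]
    releases = pd.DataFrame(state.release_log,
                            columns=["timestep", "strain", "count"])
    return SeasonResult(census=census, releases=releases, state=state)
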