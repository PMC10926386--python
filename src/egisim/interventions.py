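"""Release strategies, resistance seeding, and overwintering compositions.

The strain library covers the wild-type, the two single-target EGI strains
(pyr EGI targeting *pyramus*, hh EGI targeting *hedgehog*), the dual-target
EGI strain, and the linked female-lethal (L-SSIMS) variants of each.  Release
strategies follow the six male-only schemes compared in the study —

* ``i``    iterative release of pyr EGI only
* ``ii``   iterative release of dual EGI
* ``iii``  each release split 50:50 pyr EGI / hh EGI
* ``iv``   alternate pyr/hh every release (rapid cycling)
* ``v``    alternate every 5 releases (medium cycling)
* ``vi``   alternate every 15 releases (long cycling)

— plus reversed variants (``i_r``, ``iv_r``, ``v_r``, ``vi_r``) with pyr and
hh swapped throughout, and ``none`` (untreated control).  Defaults: 800 males
per release, one release every 4 timesteps, 38 events from timestep 37
through 185 (30,400 males per season).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .genetics import Genotype, parse_genotype

__all__ = [
    "STRAIN_BASES", "STRAIN_ALIASES", "strain_code",
    "ReleaseEvent", "ReleaseStrategy", "build_schedule", "apply_release",
    "ResistanceSeedConfig", "seed_resistance",
    "OverwinterConfig", "seed_overwintered",
]

#: loci 0-5 of each named strain; locus 6 is XX or XY by sex
STRAIN_BASES: Dict[str, str] = {
    "wildtype": "bbddppttllWW",
    "pyrEGI": "BBDDppttllWW",
    "hhEGI": "bbddPPTTllWW",
    "dualEGI": "BBDDPPTTllWW",
    "pyrLSSIMS": "BBDDppttLLWW",
    "hhLSSIMS": "bbddPPTTllFF",
    "dualLSSIMS": "BBDDPPTTLLFF",
}

STRAIN_ALIASES: Dict[str, str] = {
    "wild-type": "wildtype", "wild_type": "wildtype", "wt": "wildtype",
    "pyr": "pyrEGI", "hh": "hhEGI", "dual": "dualEGI",
    "pyr_egi": "pyrEGI", "hh_egi": "hhEGI", "dual_egi": "dualEGI",
    "pyr_lssims": "pyrLSSIMS", "hh_lssims": "hhLSSIMS",
    "dual_lssims": "dualLSSIMS",
}

#: maps an EGI strain to its L-SSIMS (linked female-lethal) counterpart
_LSSIMS_OF = {"pyrEGI": "pyrLSSIMS", "hhEGI": "hhLSSIMS",
              "dualEGI": "dualLSSIMS", "wildtype": "wildtype"}


def resolve_strain(name: str) -> str:
    """Normalize a strain name or raise ``KeyError`` for unknown names."""
    name = STRAIN_ALIASES.get(name, name)
    if name not in STRAIN_BASES:
        raise KeyError(f"unknown strain {name!r}; known: {sorted(STRAIN_BASES)}")
    return name


def strain_code(name_or_code: str, sex: str = "male") -> str:
    """14-character genotype code for a named strain (or pass through /
    re-sex a raw 14-character code)."""
    sex_pair = "XY" if sex == "male" else "XX"
    if len(name_or_code) == 14:
        parse_genotype(name_or_code)  # validates
        return name_or_code[:12] + sex_pair
    return STRAIN_BASES[resolve_strain(name_or_code)] + sex_pair


def identify_strain(code: str) -> Optional[str]:
    """Name of the strain with this genotype code, if any."""
    base = code[:12]
    for name, b in STRAIN_BASES.items():
        if b == base:
            return name
    return None


@dataclass(frozen=True)
class ReleaseEvent:
    """One scheduled release of adult males of a single strain."""

    timestep: int
    strain: str
    count: int

    @property
    def genotype_code(self) -> str:
        return strain_code(self.strain, "male")


@dataclass(frozen=True)
class ReleaseStrategy:
    """A named release scheme with its cadence and alternation period.

    ``releases_between_alternation`` overrides the per-strategy default
    (1 for ``iv``, 5 for ``v``, 15 for ``vi``).  ``strain_set='lssims'``
    swaps every released EGI strain for its linked female-lethal variant.
    ``start_strain`` (a strain name) supports ad-hoc strategies: constant
    releases of that strain, alternating with its pyr/hh partner when
    ``releases_between_alternation`` is set.
    """

    id: str = "i"
    males_per_release: int = 800
    timesteps_between_releases: int = 4
    releases_between_alternation: Optional[int] = None
    first_release_timestep: int = 37
    last_release_timestep: int = 185
    strain_set: str = "egi"
    start_strain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.males_per_release < 0:
            raise ValueError("males_per_release must be >= 0")
        if self.timesteps_between_releases < 1:
            raise ValueError("release cadence must be >= 1")


_DEFAULT_ALTERNATION = {"iv": 1, "v": 5, "vi": 15}


def _strain_sequence(strategy: ReleaseStrategy, n_events: int) -> List[List[str]]:
    """Per-event lists of strain names (a 50:50 event lists two strains)."""
    sid = strategy.id
    reverse = sid.endswith("_r")
    base = sid[:-2] if reverse else sid
    first, second = ("hhEGI", "pyrEGI") if reverse else ("pyrEGI", "hhEGI")
    if base == "none":
        return []
    if base == "custom":
        start = resolve_strain(strategy.start_strain or "pyrEGI")
        partner = {"pyrEGI": "hhEGI", "hhEGI": "pyrEGI"}.get(start)
        n_alt = strategy.releases_between_alternation
        if partner is None or not n_alt:
            return [[start]] * n_events
        return [[start if (k // n_alt) % 2 == 0 else partner]
                for k in range(n_events)]
    if base == "i":
        return [[first]] * n_events
    if base == "ii":
        return [["dualEGI"]] * n_events
    if base == "iii":
        return [[first, second]] * n_events
    if base in _DEFAULT_ALTERNATION:
        n_alt = strategy.releases_between_alternation \
            or _DEFAULT_ALTERNATION[base]
        return [[first if (k // n_alt) % 2 == 0 else second]
                for k in range(n_events)]
    raise KeyError(f"unknown release strategy {strategy.id!r}")


def build_schedule(strategy: ReleaseStrategy) -> List[ReleaseEvent]:
    """Expand a strategy into concrete release events.

    Events fall on ``first_release_timestep`` and then every
    ``timesteps_between_releases`` through ``last_release_timestep``.  A
    50:50 event (strategy iii) is emitted as two events at the same timestep
    with the males split evenly.
    """
    timesteps = list(range(strategy.first_release_timestep,
                           strategy.last_release_timestep + 1,
                           strategy.timesteps_between_releases))
    per_event = _strain_sequence(strategy, len(timesteps))
    events: List[ReleaseEvent] = []
    for t, strains in zip(timesteps, per_event):
        share = strategy.males_per_release // len(strains)
        extra = strategy.males_per_release - share * len(strains)
        for j, strain in enumerate(strains):
            if strategy.strain_set == "lssims":
                strain = _LSSIMS_OF[strain]
            events.append(ReleaseEvent(timestep=t, strain=strain,
                                       count=share + (extra if j == 0 else 0)))
    return events


def apply_release(state, event: ReleaseEvent) -> None:
    """Add ``event.count`` unmated adult males of the event strain."""
    from .lifecycle import ADULT  # local import: avoids a module cycle

    if event.count > 0:
        gid = state.registry.id_for_code(event.genotype_code)
        state.add_agents(np.full(event.count, gid, np.int64), ADULT)
        state.cum_released += event.count
    state.release_log.append((event.timestep, event.strain, event.count))


@dataclass(frozen=True)
class ResistanceSeedConfig:
    """How and when natural resistance enters the simulated population.

    ``independent_alleles`` flips each wild-type ``b`` allele copy to ``c``
    with probability ``freq1`` and each ``p`` to ``r`` with probability
    ``freq2``, independently per allele, across every living agent.
    ``double_homozygous_individuals`` instead converts a Bernoulli
    ``double_homozygote_fraction`` of living pure wild-type agents to
    ``cc`` at locus 0 and ``rr`` at locus 2.  Seeding happens once, at
    timestep ``gen_snp`` (default 32 — after the spring admixing decline,
    so a population bottleneck cannot remove or concentrate the alleles).
    """

    freq1: float = 0.01
    freq2: float = 0.01
    gen_snp: int = 32
    mode: str = "independent_alleles"
    double_homozygote_fraction: float = 0.01

    def __post_init__(self) -> None:
        for f in (self.freq1, self.freq2, self.double_homozygote_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("seeding frequencies must lie in [0, 1]")
        if self.mode not in ("independent_alleles",
                             "double_homozygous_individuals"):
            raise ValueError(f"unknown seeding mode {self.mode!r}")


def seed_resistance(state, cfg: ResistanceSeedConfig) -> None:
    """Mutate standing alleles of the living population in place (population
    size is conserved; no agents are added or removed)."""
    if state.resistance_seeded:
        raise RuntimeError("resistance has already been seeded in this state")
    state.resistance_seeded = True
    reg = state.registry
    rng = state.rng
    n = state.n
    if n == 0:
        return
    if cfg.mode == "independent_alleles":
        if cfg.freq1 == 0.0 and cfg.freq2 == 0.0:
            return
        # per agent, 4 independent allele slots: (hapA, hapB) x (locus0, locus2)
        u = rng.random((n, 4))
        for i in range(n):
            g = reg.genotypes[state.gid[i]]
            haps = [list(g.hapA), list(g.hapB)]
            changed = False
            for h in range(2):
                if haps[h][0] == "b" and u[i, h] < cfg.freq1:
                    haps[h][0] = "c"
                    changed = True
                if haps[h][2] == "p" and u[i, 2 + h] < cfg.freq2:
                    haps[h][2] = "r"
                    changed = True
            if changed:
                state.gid[i] = reg.id_for(
                    Genotype("".join(haps[0]), "".join(haps[1])))
    else:
        wild = np.array([reg.is_pure_wild(g) for g in state.gid])
        pick = wild & (rng.random(n) < cfg.double_homozygote_fraction)
        for i in np.flatnonzero(pick):
            g = reg.genotypes[state.gid[i]]
            new_haps = []
            for hap in (g.hapA, g.hapB):
                alleles = list(hap)
                alleles[0], alleles[2] = "c", "r"
                new_haps.append("".join(alleles))
            state.gid[i] = reg.id_for(Genotype(*new_haps))


@dataclass(frozen=True)
class OverwinterConfig:
    """Season-2 founding composition: ``fraction`` of the starting adults
    are the overwintered engineered strain, the rest wild-type, at a 0.5
    sex ratio within each genotype."""

    strain: str = "dualEGI"
    fraction: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("overwintered fraction must lie in [0, 1]")


def seed_overwintered(cfg: OverwinterConfig) -> Dict[str, float]:
    """Composition mapping for :func:`lifecycle.initialize_population`."""
    if cfg.fraction == 0.0:
        return {"wildtype": 1.0}
    strain = resolve_strain(cfg.strain)
    if cfg.fraction == 1.0:
        return {strain: 1.0}
    return {strain: cfg.fraction, "wildtype": 1.0 - cfg.fraction}
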