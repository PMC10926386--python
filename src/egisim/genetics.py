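"""Seven-locus diploid genetics for Engineered Genetic Incompatibility (EGI).

Every fly carries two phased haplotypes over seven loci, written as a
14-character code (two characters per locus, loci 0-6 left to right):

=====  ==========================================================
locus  alleles
=====  ==========================================================
0      ``b`` wild-type promoter, ``B`` engineered promoter mutant,
       ``c`` natural resistant SNP
1      ``d`` wild-type, ``D`` PTA targeting locus 0
2      ``p`` wild-type promoter, ``P`` engineered promoter mutant,
       ``r`` natural resistant SNP
3      ``t`` wild-type, ``T`` PTA targeting locus 2
4      ``l`` wild-type, ``L`` female lethal linked to locus 1
5      ``W`` wild-type, ``F`` female lethal linked to locus 3
6      ``X`` recessive female, ``Y`` dominant male
=====  ==========================================================

A PTA (programmable transcriptional activator) is haplosufficient: one copy
of ``D`` kills any genotype that still carries a sensitive ``b`` allele, and
one copy of ``T`` kills any genotype carrying a sensitive ``p``.  Resistance
(``B``/``c`` at locus 0, ``P``/``r`` at locus 2) is haploinsufficient: both
copies of the target locus must be resistant for a PTA carrier to live.
The female-lethal constructs ``L`` and ``F`` are dominant and act only in
females under field conditions (no tetracycline); each is genetically linked
(zero recombination) to the PTA on the same haplotype: (1,4) and (3,5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "LOCUS_ALPHABETS",
    "N_LOCI",
    "WILD_FEMALE",
    "WILD_MALE",
    "GenotypeError",
    "Genotype",
    "GeneticsConfig",
    "GenotypeClass",
    "parse_genotype",
    "sex_of",
    "is_viable",
    "classify",
    "make_gametes",
    "enumerate_gametes",
    "expand_reversion",
    "cross",
    "cross_distribution",
    "punnett_summary",
    "expected_resistant_fraction",
    "expected_spontaneous_interval",
]

LOCUS_ALPHABETS: Tuple[str, ...] = ("bBc", "dD", "pPr", "tT", "lL", "WF", "XY")
N_LOCI = 7

#: alleles lost by reversion during egg formation, and what they revert to
REVERTIBLE: Mapping[str, str] = {"D": "d", "T": "t", "L": "l", "F": "W"}

#: default linked locus pairs (PTA, female-lethal) with recombination fraction 0
DEFAULT_LINKED_PAIRS: Tuple[Tuple[int, int], ...] = ((1, 4), (3, 5))

WILD_FEMALE = "bbddppttllWWXX"
WILD_MALE = "bbddppttllWWXY"


class GenotypeError(ValueError):
    """Raised for malformed genotype codes or illegal crosses."""


class GenotypeClass(Enum):
    """Phenotypic/strategic classification of a genotype.

    ``EGI`` genotypes are homozygous for every PTA they carry (true-breeding
    incompatible agents); ``EGI_LIKE`` genotypes carry at least one PTA copy
    but are not homozygous for it — the viable field-generated hybrids that
    seed population replacement; ``RESISTANT_CARRIER`` genotypes carry a
    natural resistance SNP but no PTA.
    """

    WILD_TYPE = "wild_type"
    RESISTANT_CARRIER = "resistant_carrier"
    EGI_LIKE = "egi_like"
    EGI = "egi"
    INVIABLE = "inviable"


def _validate_haplotype(hap: str) -> None:
    if len(hap) != N_LOCI:
        raise GenotypeError(f"haplotype must have {N_LOCI} alleles, got {hap!r}")
    for i, a in enumerate(hap):
        if a not in LOCUS_ALPHABETS[i]:
            raise GenotypeError(
                f"allele {a!r} not allowed at locus {i} (alphabet {LOCUS_ALPHABETS[i]!r})"
            )


def _canonical_pair(a: str, b: str) -> str:
    # uppercase first, then alphabetical: stable per-locus display order
    return "".join(sorted((a, b), key=lambda c: (c.islower(), c)))


@dataclass(frozen=True)
class Genotype:
    """A phased diploid genotype: two ordered 7-allele haplotypes.

    Phase is retained so that linkage and reversion-generated cis/trans
    configurations at the linked pairs (1,4) and (3,5) are exact.  The
    canonical display string orders the two alleles at each locus
    uppercase-first then alphabetically, so two genotypes that differ only
    by which haplotype is "A" display identically.
    """

    hapA: str
    hapB: str

    def __post_init__(self) -> None:
        _validate_haplotype(self.hapA)
        _validate_haplotype(self.hapB)
        if self.hapA[6] == "Y" and self.hapB[6] == "Y":
            raise GenotypeError("YY genotypes cannot exist")

    @property
    def display(self) -> str:
        """Canonical 14-character code, e.g. ``'BBDDppttllWWXY'``."""
        return "".join(
            _canonical_pair(self.hapA[i], self.hapB[i]) for i in range(N_LOCI)
        )

    def alleles(self, locus: int) -> Tuple[str, str]:
        return (self.hapA[locus], self.hapB[locus])

    def key(self) -> Tuple[str, str]:
        """Phase-unordered identity (swapping hapA/hapB yields the same key)."""
        return tuple(sorted((self.hapA, self.hapB)))  # type: ignore[return-value]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display


@dataclass(frozen=True)
class GeneticsConfig:
    """Inheritance model parameters.

    Parameters
    ----------
    reversion_rate:
        Probability, per inherited engineered allele (D, T, L, F), that the
        allele reverts to wild-type (d, t, l, W) during egg formation.
        0 by default; 0.1 in the L-SSIMS robustness scenario.
    linked_pairs:
        Locus pairs co-inherited with zero recombination.
    """

    reversion_rate: float = 0.0
    linked_pairs: Tuple[Tuple[int, int], ...] = DEFAULT_LINKED_PAIRS

    def __post_init__(self) -> None:
        if not 0.0 <= self.reversion_rate <= 1.0:
            raise ValueError("reversion_rate must lie in [0, 1]")
        seen: set = set()
        for pair in self.linked_pairs:
            if seen & set(pair):
                raise ValueError("linked pairs must be disjoint")
            seen |= set(pair)

    def inheritance_groups(self) -> Tuple[Tuple[int, ...], ...]:
        """Loci partitioned into independently segregating groups."""
        linked = {i for pair in self.linked_pairs for i in pair}
        groups: List[Tuple[int, ...]] = [tuple(p) for p in self.linked_pairs]
        groups.extend((i,) for i in range(N_LOCI) if i not in linked)
        return tuple(sorted(groups))


_DEFAULT_CFG = GeneticsConfig()


def parse_genotype(code: str) -> Genotype:
    """Parse a 14-character genotype code into a phased :class:`Genotype`.

    The first character of each per-locus pair is assigned to hapA.  Raises
    :class:`GenotypeError` naming the offending locus on bad input.
    """
    if len(code) != 2 * N_LOCI:
        raise GenotypeError(
            f"genotype code must have {2 * N_LOCI} characters, got {len(code)}"
        )
    hap_a, hap_b = [], []
    for i in range(N_LOCI):
        a, b = code[2 * i], code[2 * i + 1]
        for ch in (a, b):
            if ch not in LOCUS_ALPHABETS[i]:
                raise GenotypeError(
                    f"invalid allele {ch!r} at locus {i} in {code!r}"
                )
        hap_a.append(a)
        hap_b.append(b)
    return Genotype("".join(hap_a), "".join(hap_b))


def sex_of(g: Genotype) -> str:
    """``'male'`` iff either haplotype carries Y at locus 6, else ``'female'``."""
    return "male" if "Y" in g.alleles(6) else "female"


def is_viable(g: Genotype, field_conditions: bool = True) -> bool:
    """Apply the EGI lethality rules.

    A genotype dies iff any of:

    * it carries >= 1 ``D`` (PTA vs locus 0) and >= 1 sensitive ``b``;
    * it carries >= 1 ``T`` (PTA vs locus 2) and >= 1 sensitive ``p``;
    * it is female and carries a dominant female-lethal (``L`` or ``F``)
      under field conditions (no tetracycline).

    ``B``/``c`` (locus 0) and ``P``/``r`` (locus 2) both confer resistance,
    but resistance is haploinsufficient: a single sensitive copy suffices
    for lethality.
    """
    l0, l1 = g.alleles(0), g.alleles(1)
    l2, l3 = g.alleles(2), g.alleles(3)
    if "D" in l1 and "b" in l0:
        return False
    if "T" in l3 and "p" in l2:
        return False
    if field_conditions and sex_of(g) == "female":
        if "L" in g.alleles(4) or "F" in g.alleles(5):
            return False
    return True


def classify(g: Genotype, field_conditions: bool = True) -> GenotypeClass:
    """Map a genotype to its :class:`GenotypeClass` (total, deterministic)."""
    if not is_viable(g, field_conditions):
        return GenotypeClass.INVIABLE
    n_d = g.alleles(1).count("D")
    n_t = g.alleles(3).count("T")
    if n_d or n_t:
        homozygous_for_all = (n_d in (0, 2)) and (n_t in (0, 2))
        return GenotypeClass.EGI if homozygous_for_all else GenotypeClass.EGI_LIKE
    if "c" in g.alleles(0) or "r" in g.alleles(2):
        return GenotypeClass.RESISTANT_CARRIER
    return GenotypeClass.WILD_TYPE


def make_gametes(g: Genotype, rng: np.random.Generator,
                 cfg: GeneticsConfig = _DEFAULT_CFG) -> str:
    """Draw one gamete haplotype: each segregation group independently
    contributes hapA's or hapB's alleles with probability 1/2; linked pairs
    are co-inherited (recombination fraction 0)."""
    alleles = [""] * N_LOCI
    for group in cfg.inheritance_groups():
        hap = g.hapA if rng.random() < 0.5 else g.hapB
        for locus in group:
            alleles[locus] = hap[locus]
    return "".join(alleles)


def enumerate_gametes(g: Genotype,
                      cfg: GeneticsConfig = _DEFAULT_CFG) -> List[Tuple[str, float]]:
    """All distinct gametes with exact probabilities (they sum to 1)."""
    groups = cfg.inheritance_groups()
    out: Dict[str, float] = {}
    for choices in product((0, 1), repeat=len(groups)):
        alleles = [""] * N_LOCI
        for group, choice in zip(groups, choices):
            hap = g.hapA if choice == 0 else g.hapB
            for locus in group:
                alleles[locus] = hap[locus]
        gam = "".join(alleles)
        out[gam] = out.get(gam, 0.0) + 0.5 ** len(groups)
    return sorted(out.items())


def expand_reversion(hap: str, rho: float) -> List[Tuple[str, float]]:
    """Analytic reversion expansion of one inherited haplotype.

    Each engineered allele D, T, L, F independently reverts to d, t, l, W
    with probability ``rho``; all other alleles are stable.
    """
    if rho == 0.0:
        return [(hap, 1.0)]
    sites = [i for i, a in enumerate(hap) if a in REVERTIBLE]
    if not sites:
        return [(hap, 1.0)]
    out: List[Tuple[str, float]] = []
    for pattern in product((False, True), repeat=len(sites)):
        alleles = list(hap)
        prob = 1.0
        for site, revert in zip(sites, pattern):
            if revert:
                alleles[site] = REVERTIBLE[alleles[site]]
                prob *= rho
            else:
                prob *= 1.0 - rho
        out.append(("".join(alleles), prob))
    return out


def _revert_sampled(hap: str, rho: float, rng: np.random.Generator) -> str:
    if rho == 0.0:
        return hap
    alleles = list(hap)
    for i, a in enumerate(alleles):
        if a in REVERTIBLE and rng.random() < rho:
            alleles[i] = REVERTIBLE[a]
    return "".join(alleles)


def cross(mother: Genotype, father: Genotype, cfg: GeneticsConfig,
          rng: np.random.Generator) -> Genotype:
    """Generate one egg (before viability filtering).

    One maternal and one paternal gamete are drawn, then every inherited
    D, T, L, F allele independently reverts with probability
    ``cfg.reversion_rate``.  Raises :class:`GenotypeError` on a same-sex pair.
    """
    if sex_of(mother) != "female" or sex_of(father) != "male":
        raise GenotypeError("cross requires a female mother and a male father")
    egg_m = _revert_sampled(make_gametes(mother, rng, cfg), cfg.reversion_rate, rng)
    egg_p = _revert_sampled(make_gametes(father, rng, cfg), cfg.reversion_rate, rng)
    return Genotype(egg_m, egg_p)


def cross_distribution(mother: Genotype, father: Genotype,
                       cfg: GeneticsConfig = _DEFAULT_CFG
                       ) -> Dict[Tuple[str, str], float]:
    """Exact egg genotype distribution of a cross, keyed by phase-unordered
    haplotype pair, reversion applied analytically.  Probabilities sum to 1
    and include inviable genotypes (no viability filtering here)."""
    if sex_of(mother) != "female" or sex_of(father) != "male":
        raise GenotypeError("cross requires a female mother and a male father")
    rho = cfg.reversion_rate
    out: Dict[Tuple[str, str], float] = {}
    for gam_m, p_m in enumerate_gametes(mother, cfg):
        for hap_m, q_m in expand_reversion(gam_m, rho):
            for gam_p, p_p in enumerate_gametes(father, cfg):
                for hap_p, q_p in expand_reversion(gam_p, rho):
                    key = tuple(sorted((hap_m, hap_p)))
                    out[key] = out.get(key, 0.0) + p_m * q_m * p_p * q_p
    return out


def punnett_summary(mother: Genotype, father: Genotype,
                    cfg: GeneticsConfig = _DEFAULT_CFG,
                    field_conditions: bool = True
                    ) -> Dict[Tuple[GenotypeClass, str], float]:
    """Exact offspring table: (GenotypeClass, sex) -> probability.

    Inviable outcomes are reported separately under
    ``(GenotypeClass.INVIABLE, sex)``; the table sums to 1.
    """
    table: Dict[Tuple[GenotypeClass, str], float] = {}
    for (hap_a, hap_b), prob in cross_distribution(mother, father, cfg).items():
        g = Genotype(hap_a, hap_b)
        key = (classify(g, field_conditions), sex_of(g))
        table[key] = table.get(key, 0.0) + prob
    return table


def expected_resistant_fraction(allele_freq: float, n_loci: int) -> float:
    """Fraction of a random-mating diploid population carrying at least one
    resistance allele across ``n_loci`` independent loci, each segregating a
    resistance allele at frequency ``allele_freq``:  1 - (1-f)^(2 n)."""
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError("allele_freq must lie in [0, 1]")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return 1.0 - (1.0 - allele_freq) ** (2 * n_loci)


def expected_spontaneous_interval(mu: float, n_sites: int) -> float:
    """Expected number of agents between spontaneous resistance events when
    ``n_sites`` neutral base pairs each mutate at rate ``mu`` per site per
    generation: 1 / (mu * n_sites)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return 1.0 / (mu * n_sites)
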