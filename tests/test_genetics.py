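"""Unit and property tests for the 7-locus genotype model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egisim import genetics as G
from egisim.genetics import (GeneticsConfig, Genotype, GenotypeClass,
                             GenotypeError, classify, cross, enumerate_gametes,
                             expected_resistant_fraction,
                             expected_spontaneous_interval, is_viable,
                             make_gametes, parse_genotype, punnett_summary,
                             sex_of)

WT_F = "bbddppttllWWXX"
WT_M = "bbddppttllWWXY"
PYR_M = "BBDDppttllWWXY"
HH_M = "bbddPPTTllWWXY"
DUAL_M = "BBDDPPTTllWWXY"


def genotypes_strategy():
    """Random valid phased genotypes (locus 6 fixed per sex by the caller)."""
    loci = [st.sampled_from(a) for a in G.LOCUS_ALPHABETS[:6]]
    hap = st.tuples(*loci).map("".join)
    return st.tuples(hap, hap)


class TestParseAndDisplay:
    @pytest.mark.parametrize("code,sex,cls", [
        (PYR_M, "male", GenotypeClass.EGI),
        (WT_F, "female", GenotypeClass.WILD_TYPE),
        ("cbddppttllWWXY", "male", GenotypeClass.RESISTANT_CARRIER),
        ("bbddrPtTllWWXX", "female", GenotypeClass.EGI_LIKE),
    ])
    def test_roundtrip_sex_class(self, code, sex, cls):
        g = parse_genotype(code)
        assert sex_of(g) == sex
        assert classify(g) is cls
        # canonical display re-parses to the same genotype
        assert parse_genotype(g.display).display == g.display

    @pytest.mark.parametrize("bad", [
        "bbddppttllWWXZ",      # Z not in locus-6 alphabet
        "bbddppttllWWX",       # wrong length
        "Abddppttllwwxy",      # invalid symbols
    ])
    def test_parse_errors(self, bad):
        with pytest.raises(GenotypeError):
            parse_genotype(bad)

    def test_error_names_offending_locus(self):
        with pytest.raises(GenotypeError, match="locus 6"):
            parse_genotype("bbddppttllWWXZ")

    def test_yy_rejected(self):
        with pytest.raises(GenotypeError):
            Genotype("bdptlWY", "bdptlWY")

    def test_sex_invariant_under_phase_swap(self):
        g = parse_genotype("bcdDprtTlLWFXY")
        swapped = Genotype(g.hapB, g.hapA)
        assert sex_of(g) == sex_of(swapped)
        assert g.display == swapped.display


class TestViability:
    @pytest.mark.parametrize("code,viable", [
        ("bBdDppttllWWXX", False),   # wild x pyr hybrid: D with sensitive b
        ("cBDDppttllWWXY", True),    # natural SNP + engineered promoter
        ("ccDDppttllWWXY", True),    # homozygous natural resistance
        ("bbddpPtTllWWXX", False),   # T with sensitive p
        ("bbddrPTTllWWXY", True),    # both locus-2 alleles resistant
        (PYR_M, True),
        (DUAL_M, True),
    ])
    def test_pta_lethality(self, code, viable):
        assert is_viable(parse_genotype(code)) is viable

    def test_female_lethal_field_only(self):
        female = parse_genotype("BBDDppttLLWWXX")
        male = parse_genotype("BBDDppttLLWWXY")
        assert not is_viable(female)                      # field, no tet
        assert is_viable(female, field_conditions=False)  # rearing, tet on
        assert is_viable(male)

    def test_classify_total_and_exclusive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            haps = ["".join(rng.choice(list(a)) for a in G.LOCUS_ALPHABETS[:6])
                    for _ in range(2)]
            g = Genotype(haps[0] + "X", haps[1] + rng.choice(["X", "Y"]))
            cls = classify(g)
            assert (cls is GenotypeClass.INVIABLE) == (not is_viable(g))


class TestGametes:
    def test_homozygote_single_gamete(self):
        gams = enumerate_gametes(parse_genotype("BBDDppttllWWXX"))
        assert gams == [("BDptlWX", 1.0)]

    def test_full_heterozygote_has_32_gametes(self):
        gams = enumerate_gametes(parse_genotype("bcdDprtTlLWFXY"))
        assert len(gams) == 32
        assert all(p == pytest.approx(1 / 32) for _, p in gams)
        assert sum(p for _, p in gams) == pytest.approx(1.0)

    def test_linked_loci_never_recombine(self):
        g = Genotype("bDptLWX", "bdptlWX")  # D-L cis on hapA
        for gam, _ in enumerate_gametes(g):
            assert (gam[1], gam[4]) in {("D", "L"), ("d", "l")}

    @given(genotypes_strategy())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_gamete_probabilities_sum_to_one(self, haps):
        g = Genotype(haps[0] + "X", haps[1] + "Y")
        gams = enumerate_gametes(g)
        assert sum(p for _, p in gams) == pytest.approx(1.0)
        assert all(p > 0 for _, p in gams)

    def test_sampled_gametes_match_enumeration(self, rng):
        g = parse_genotype("bcdDprtTlLWFXY")
        expected = dict(enumerate_gametes(g))
        n = 10_000
        counts = {}
        for _ in range(n):
            gam = make_gametes(g, rng)
            counts[gam] = counts.get(gam, 0) + 1
        # chi-square against exact probabilities
        chi2 = sum((counts.get(k, 0) - n * p) ** 2 / (n * p)
                   for k, p in expected.items())
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.999, df=len(expected) - 1)


class TestCross:
    def test_same_sex_cross_raises(self, cfg, rng):
        with pytest.raises(GenotypeError):
            cross(parse_genotype(WT_M), parse_genotype(WT_M), cfg, rng)

    def test_wild_cross_offspring(self, cfg, rng):
        mother, father = parse_genotype(WT_F), parse_genotype(WT_M)
        sexes = {sex_of(cross(mother, father, cfg, rng)) for _ in range(200)}
        egg = cross(mother, father, cfg, rng)
        assert egg.display[:12] == "bbddppttllWW"
        assert sexes == {"male", "female"}

    def test_wild_by_pyr_all_inviable(self, cfg, rng):
        mother, father = parse_genotype(WT_F), parse_genotype(PYR_M)
        for _ in range(50):
            assert not is_viable(cross(mother, father, cfg, rng))

    def test_reversion_rate_on_inherited_allele(self, rng):
        cfg = GeneticsConfig(reversion_rate=0.1)
        mother = parse_genotype(WT_F)
        father = parse_genotype(PYR_M)  # every egg inherits one D
        n = 20_000
        kept = sum("D" in cross(mother, father, cfg, rng).display
                   for _ in range(n))
        assert kept / n == pytest.approx(0.9, abs=0.01)

    def test_mendelian_neutrality(self, cfg, rng):
        """With no reversion and no selection, allele frequencies are
        conserved in expectation across a generation of random mating."""
        mother = parse_genotype("bcddppttllWWXX")   # c at freq 1/4
        father = parse_genotype("bbddppttllWWXY")
        n = 8000
        c_count = sum(cross(mother, father, cfg, rng).display.count("c")
                      for _ in range(n))
        assert c_count / (2 * n) == pytest.approx(0.25, abs=0.02)


class TestPunnett:
    def test_het_resistant_by_hh_egi_half_viable(self, cfg):
        table = punnett_summary(parse_genotype("bbddprttllWWXX"),
                                parse_genotype(HH_M), cfg)
        inviable = sum(p for (c, _), p in table.items()
                       if c is GenotypeClass.INVIABLE)
        viable_classes = {c for (c, _), p in table.items()
                          if c is not GenotypeClass.INVIABLE and p > 0}
        assert inviable == pytest.approx(0.5)
        assert viable_classes == {GenotypeClass.EGI_LIKE}

    def test_egi_like_by_hh_egi_quarters(self, cfg):
        """An EGI-like female crossed to the dual-susceptible EGI male yields
        the four equal viable quarters (EGI/EGI-like x female/male)."""
        table = punnett_summary(parse_genotype("bbddrPtTllWWXX"),
                                parse_genotype(HH_M), cfg)
        for cls in (GenotypeClass.EGI, GenotypeClass.EGI_LIKE):
            for sex in ("female", "male"):
                assert table[(cls, sex)] == pytest.approx(0.25)

    def test_wild_by_wild(self, cfg):
        table = punnett_summary(parse_genotype(WT_F), parse_genotype(WT_M),
                                cfg)
        assert table == {(GenotypeClass.WILD_TYPE, "female"): pytest.approx(0.5),
                         (GenotypeClass.WILD_TYPE, "male"): pytest.approx(0.5)}

    def test_probabilities_sum_to_one(self, cfg):
        table = punnett_summary(parse_genotype("bcdDprtTlLWFXX"),
                                parse_genotype("bcdDprtTlLWFXY"),
                                GeneticsConfig(reversion_rate=0.1))
        assert sum(table.values()) == pytest.approx(1.0)

    def test_fig_compatibility_matrix(self, cfg):
        """Within-strain crosses are fully viable; crosses between distinct
        EGI strains (and with wild-type) are fully inviable."""
        strains = {"wildtype": "bbddppttllWW", "pyr": "BBDDppttllWW",
                   "hh": "bbddPPTTllWW", "dual": "BBDDPPTTllWW"}
        for name_m, base_m in strains.items():
            for name_f, base_f in strains.items():
                table = punnett_summary(parse_genotype(base_f + "XX"),
                                        parse_genotype(base_m + "XY"), cfg)
                viable = 1.0 - sum(p for (c, _), p in table.items()
                                   if c is GenotypeClass.INVIABLE)
                expected = 1.0 if name_m == name_f else 0.0
                assert viable == pytest.approx(expected), (name_f, name_m)

    def test_egi_strains_true_breeding(self, cfg):
        for base in ("BBDDppttllWW", "bbddPPTTllWW", "BBDDPPTTllWW"):
            table = punnett_summary(parse_genotype(base + "XX"),
                                    parse_genotype(base + "XY"), cfg)
            assert sum(p for (c, _), p in table.items()
                       if c is GenotypeClass.EGI) == pytest.approx(1.0)


class TestClosedForms:
    def test_resistant_fraction_two_loci_one_percent(self):
        assert expected_resistant_fraction(0.01, 2) == \
            pytest.approx(1 - 0.99 ** 4)

    def test_resistant_fraction_monte_carlo(self, rng):
        # f=0.5, one locus: 1 - 0.25 = 0.75
        draws = rng.random((100_000, 2)) < 0.5
        assert draws.any(axis=1).mean() == pytest.approx(
            expected_resistant_fraction(0.5, 1), abs=0.01)

    def test_resistant_fraction_edges(self):
        assert expected_resistant_fraction(0.0, 3) == 0.0
        with pytest.raises(ValueError):
            expected_resistant_fraction(1.5, 1)

    def test_spontaneous_interval(self):
        assert expected_spontaneous_interval(7.7e-9, 44) == \
            pytest.approx(2.95e6, rel=1e-3)
        assert expected_spontaneous_interval(2.8e-9, 44) == \
            pytest.approx(8.12e6, rel=1e-3)
        # doubling the target footprint halves the interval
        assert expected_spontaneous_interval(1e-8, 88) == \
            pytest.approx(expected_spontaneous_interval(1e-8, 44) / 2)
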