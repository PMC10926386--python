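# egisim

Agent-based simulation of **Engineered Genetic Incompatibility (EGI)**
biocontrol in seasonal populations of the invasive fruit-crop pest
*Drosophila suzukii* (spotted wing drosophila, SWD), for researchers in
genetic biocontrol who want to explore how endemic genetic resistance
reshapes male-only incompatible-insect release programs.

EGI is engineered extreme underdominance: an EGI strain is homozygous for a
haplosufficient lethal element (a programmable transcriptional activator,
PTA, that drives lethal ectopic expression of a developmental gene) and a
haploinsufficient resistant promoter at the PTA's target. Hybrids with
wild-type inherit one PTA copy and one *sensitive* promoter copy, and die.
Releasing only EGI males therefore sterilizes wild females'
matings — an incompatible insect technique (IIT) — unless natural
resistance alleles in the wild population let hybrid "EGI-like" offspring
survive. The simulation tracks every fly individually: a phased 7-locus
genotype, temperature-driven development (egg → larva → pupa → adult,
degree-days over 7.2 °C), random mating, Mendelian inheritance with
linkage and reversion, and exact viability rules.

What the package computes, per scenario:

* daily census by life stage × sex × genotype class, plus release logs;
* EGI-fraction takeover curves and logistic fits
  y = 1/(1+e^(−k(x−x₀))) giving steepness k (day⁻¹) and midpoint x₀ (day);
* percent suppression of season-cumulative adult females vs an untreated
  control, with replicate means ± SD and ANOVA / t-test strategy
  comparisons.

It reproduces the central surprise of this system: with 1% natural
resistance, a male-only release program spontaneously generates EGI
**females** in the field and converts IIT into a population-replacement
gene drive — and linking a dominant female-lethal to each PTA (the
L-SSIMS design) eliminates that failure mode even at a 10% reversion rate.

## Worked example

The crosses behind the replacement drive
(`python examples/cross_outcomes.py`):

```
EGI-like female x hh EGI male
  mother bbddrPtTllWWXX  x  father bbddPPTTllWWXY
                 egi female  25.0%
                 egi male    25.0%
            egi_like female  25.0%
            egi_like male    25.0%
```

A quarter of this brood are fully EGI *females* — never released, created
in the field. Running five replicate seasons of the single-strain release
with resistance seeded at 1% (`python examples/logistic_takeover.py`):

```
peak field-generated EGI females per replicate: [81, 75, 111, 48, 15]
logistic fit of the female EGI fraction: k = 0.074 / day, x0 = day 139, R^2 = 0.990
```

The female population becomes majority-EGI around day 139 (mid-July) with
a clean sigmoid. Strategy comparison
(`python examples/release_strategies.py`, 30,400 males released per
season, 800 every 4 days):

```
strategy   i (single-target pyr EGI     ): suppression =  86.9%
strategy  ii (dual-target EGI           ): suppression =  87.6%
strategy  iv (rapid pyr/hh alternation  ): suppression =  87.5%
```

i.e. ≈85–88% fewer cumulative adult females than the untreated control,
with two-target designs edging out the single target. Finally
`python examples/lssims_eradication.py` shows the linked female-lethal
releases driving adult females to zero by late July in every replicate
despite a 10% per-allele reversion rate.

A thin CLI mirrors the original tool's positional invocation and adds a
config file:

```bash
egisim 4 800 results/ pyrEGI 1 --replicates 10 --base-seed 1
egisim --strategy iii --replicates 10 results/
```

writing per-replicate census CSVs, release logs, a summary JSON, and a
manifest YAML that reproduces the batch byte-for-byte.

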