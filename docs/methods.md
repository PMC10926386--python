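# Methods

`egisim` is an individual-based, daily-timestep simulation of a seasonal
*Drosophila suzukii* (spotted wing drosophila, SWD) population subjected to
male-only releases of Engineered Genetic Incompatibility (EGI) agents, with
endemic genetic resistance, mutually incompatible strain pairs, dual-target
strains, and linked female-lethal (L-SSIMS) designs. This note records the
model, its assumptions, the parameter choices that matter, and the limits of
what the synthetic study conditions can show.

## Genetic model

Every fly carries two phased haplotypes over seven loci (see
`egisim.genetics` for the allele alphabet). The core rules:

* **Haplosufficient lethality, haploinsufficient resistance.** One copy of a
  PTA (`D` targeting locus 0, `T` targeting locus 2) kills any genotype that
  retains a single sensitive allele (`b`, `p`) at the targeted locus.
  Engineered promoter mutants (`B`, `P`) and natural resistant SNPs (`c`,
  `r`) are equivalent in conferring protection; both copies of the target
  locus must be resistant for a PTA carrier to survive.
* **Dominant female lethality.** The `L` and `F` constructs kill females
  under field conditions (no tetracycline); males are unaffected. Each is
  linked with zero recombination to the PTA on its haplotype — locus pairs
  (1,4) and (3,5) — which is what makes L-SSIMS self–sex-sorting: a viable
  field hybrid that inherits a PTA necessarily inherits the female-lethal.
* **Reversion.** During egg formation each inherited `D`, `T`, `L`, `F`
  independently reverts to wild-type with probability ρ (0 by default, 0.1
  in the L-SSIMS robustness scenario), modelling silencing or breakdown of
  the engineered elements. `B`, `P`, `c`, `r` never revert.
* **Classification.** A viable genotype is `EGI` when it is homozygous for
  every PTA it carries, `EGI_LIKE` when it carries at least one PTA copy but
  is not homozygous for it, `RESISTANT_CARRIER` when it carries a natural
  resistance SNP and no PTA, otherwise `WILD_TYPE`. EGI-like females are the
  engine of the replacement-drive failure mode: mated to an EGI male they
  produce fully-EGI daughters that were never released.

Cross mathematics are exact: gametes are enumerated per segregation group
(32 at most), reversion is expanded analytically, and the simulation samples
egg genotypes from the cached exact distribution of each (mother, sire)
pair — distributionally identical to per-egg Monte Carlo but vectorised.
An independent brute-force oracle (`egisim.synthetic.enumerate_cross_outcomes`,
inheritance-pattern enumeration with linkage filtering) cross-checks the
analytic machinery to 1e-12 in the test suite.

## Lifecycle model

Daily timesteps from March 1 (timestep 0) to October 31 (timestep 244).
Development uses degree-days above a base temperature of 7.2 °C with stage
requirements egg 20, larva 120, pupa 110 °C·day; a stage completes
stochastically once 80% of its requirement is accrued (per-day completion
probability rising linearly to 1 at 100%). Daily survival is Bernoulli per
agent; fecundity of a mated female is Poisson with a temperature-dependent
mean. Females mate on eclosion and re-mate with probability 0.15 per day
(sperm from the stored sire is used otherwise); sires are drawn uniformly
from all adult males, released and field males alike — the IIT mechanism is
exactly this dilution of fertile matings. Eggs failing the viability rules
are tallied and discarded at laying; no inviable genotype ever becomes an
agent.

### Calibrated default parameters

The lifecycle tables of the underlying SWD model are not public in detail,
so the defaults below are stand-ins calibrated **once** against the
documented seasonal envelope — an untreated population of order 10⁴ adults
at its seasonal peak, heat-limited mid-summer growth, and a season that
winds down by late October — and then frozen. Depending on the weather
year the adult peak falls in late June or in September. They are deliberately in a
*moderate-growth* regime (R₀ ≈ 2–5 per generation) with a standing spring
stock: in a boom-bust regime the fixed 30,400-male release schedule
annihilates the small spring population before the resistance-driven
replacement dynamics can express.

| parameter | default | notes |
|---|---|---|
| daily survival egg / larva / pupa | 0.92 / 0.90 / 0.90 | field mortality incl. predation |
| adult daily survival | 0.97 | ~33-day expected adult life |
| adult max age | 90 d | overwintered founders persist into May |
| heat penalty | logistic, midpoint 24.5 °C, scale 1.5 | adults drop toward 0.72/day; juvenile survival scaled toward 0.75× |
| fecundity | quadratic, 0 at ≤10 °C, peak 8 eggs/♀/day at 21 °C, 0 at ≥29 °C | |
| reproductive arrest | logistic in time, midpoint timestep 190 (≈Sep 7), scale 5 d | photoperiod-induced winter-morph arrest |
| founding adults | 8000 (March 1) | declines to ≈3000 by the April seeding date |
| re-mating probability | 0.15 / day | |

Two mechanisms extend the spec of a plain thermal model and deserve
justification. First, the heat penalty applies to juvenile stages as well
as adults; without it the juvenile pipeline keeps delivering recruits
through the hottest weeks and no mid-summer decline is possible from daily
*mean* temperatures. Second, the late-season reproductive arrest emulates
the well-documented photoperiod-induced reproductive diapause of SWD
winter-morph females: June and September temperatures are nearly identical
in a cosine climate, so without a non-thermal cue an autumn population
explosion is unavoidable in every parameterisation that also produces a
June–July boom. The arrest affects egg laying only; it is not an
overwintering-survival model (second seasons are represented purely by
their founding composition).

## Interventions

Releases follow the six male-only strategies (`i`–`vi`) plus reversed
variants (`i_r`, `iv_r`, `v_r`, `vi_r`): 800 adult males per event, every 4
timesteps, 38 events from timestep 37 through 185 (30,400 males per
season). Alternating strategies switch strains every 1 (`iv`), 5 (`v`) or
15 (`vi`) releases; the 50:50 mixed strategy (`iii`) splits each event
400/400. Natural resistance is seeded at timestep 32 — after the spring
decline, so a bottleneck cannot remove or concentrate the alleles — either
as independent per-allele flips (`b→c`, `p→r` at 1% each) or by converting
1% of pure wild-type individuals to double homozygotes (`cc;rr`).
Overwintered second seasons start with 5/50/95% of the founding adults
being an engineered strain at a 0.5 sex ratio.

## Analysis

The EGI fraction can be computed against three denominators: all living
agents, juveniles only, or adult females. Takeover curves are fit with the
two-parameter logistic y = 1/(1+e^(−k(x−x₀))) (asymptotes fixed at 0 and
1) by Levenberg–Marquardt least squares, falling back to a bounded
trust-region fit (k ∈ (0, 5], x₀ within the data range ± 60 days) when LM
fails or leaves the admissible band; R² is computed on the fitted points.
Midpoint comparisons between strategies use the **adult-female** fraction:
x₀ is defined as the day when half of female agents are EGI, and at this
simulation scale the all-agents fraction is dominated by the standing
released-male stock rather than by replacement. Suppression is
100 × (1 − treated/control) on season-cumulative adult-female counts
(female-days). Replicates are aggregated as mean ± sample SD; strategy
comparisons use one-way ANOVA followed, when significant, by unadjusted
pairwise t-tests (a Bonferroni column is emitted for transparency).

## Synthetic study conditions — what they do and do not show

The temperature generator is a cosine annual cycle (mean 8 °C, amplitude
16 °C, peak July 20) plus i.i.d. Gaussian noise (SD 2.0 °C) — an upper
Midwest climate stand-in, not fitted station data. It lacks multi-day
weather autocorrelation, heat waves, and spring/fall asymmetry; the
reproductive-arrest term substitutes for the missing photoperiod signal.
Populations are well-mixed and isolated: no spatial structure, migration,
or density dependence, so suppression percentages quantify the mating-
dilution and replacement mechanisms only.

Reproduced at these conditions (seeds fixed in the test suite): the
untreated envelope (log₁₀ seasonal peak rounds to 4 in ≥ 8/10 seeds);
≈85% suppression of cumulative adult females by the single-target strategy
with 1% resistance, with every two-target strategy suppressing more
strongly; in-field emergence of EGI females under male-only release with a
clean sigmoid takeover (R² ≈ 0.99, midpoint mid-July); and L-SSIMS
eradication of all adult females by mid-July in every replicate despite
10% reversion.

Not reproduced: the 12–21-day head start of the dual-target strain's
midpoint over the mixed-release strategies under double-homozygous
seeding. At this scale EGI-female cohorts number in the tens, wild females
are extinct by late July under the fixed release schedule, and midpoint
estimates carry ≈ ±10-day replicate noise; moreover a single-target
lineage reaches the EGI class by homozygosing one PTA locus (½ per
compatible brood) where the dual lineage needs both (¼), an advantage that
at cluster-scale population sizes is evidently outweighed by the
cross-suppression of mixed releases. The measured gap is reported as
computed; it fluctuates around zero across seeds.

## Numerical and implementation notes

* One seeded NumPy generator per replicate; replicate r of a batch uses
  seed base + r, and each replicate draws its own weather year from the
  same seed. Runs are bit-reproducible given the seed.
* The population is stored as flat arrays over an interned genotype
  registry; census rows count stage × sex × class each timestep. A
  full-season run takes on the order of a second on one CPU.
* Degenerate inputs: zero founding adults yield an all-zero census; a
  zero-male timestep leaves virgin females unmated (mated females keep
  their stored sire); a zero denominator omits the timestep from fraction
  curves; a failed logistic fit reports `converged=False` rather than
  parameters.
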