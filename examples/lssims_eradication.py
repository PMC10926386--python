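"""Linked female-lethal (L-SSIMS) releases eradicate females despite 10%
reversion.

Repeats the single-strain release with pyr L-SSIMS males — the female-lethal
construct genetically linked to the PTA — while every engineered allele
(PTA and female-lethal alike) reverts to wild-type in 10% of eggs that
inherit it. Escaped EGI-like females are killed by the linked construct, so
the incompatible-male suppression is never converted into a replacement
drive and the female population collapses to zero.
"""

import numpy as np

from egisim import GeneticsConfig, ReleaseStrategy, ResistanceSeedConfig
from egisim.experiments import ScenarioConfig, run_replicates

config = ScenarioConfig(
    strategy=ReleaseStrategy(id="i", strain_set="lssims"),
    resistance=ResistanceSeedConfig(),
    genetics=GeneticsConfig(reversion_rate=0.1))

for rep, run in enumerate(run_replicates(config, 3, 1)):
    females = run.census["adult_females"].to_numpy()
    nonzero = np.nonzero(females)[0]
    last_day = run.census["date"][int(nonzero[-1])] if len(nonzero) else "-"
    print(f"replicate {rep}: last adult female seen {last_day}; "
          f"final count {females[-1]}; "
          f"peak EGI females {int(run.census['adult_female_egi'].max())}")

print("\nAll female lineages collapse by mid-summer; compare with the "
      "plain EGI runs in logistic_takeover.py where EGI females take over.")
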