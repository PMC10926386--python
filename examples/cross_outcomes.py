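"""Exact offspring outcomes of the crosses behind the replacement drive.

Builds the key matings from the resistance pathway — resistant female by an
EGI male, then EGI-like female by an EGI male — and prints their exact
Punnett tables. The second cross shows the quarter of offspring that are
fully EGI females: the agents that convert a male-only incompatible-male
program into a population replacement drive.
"""

from egisim import GeneticsConfig, parse_genotype, punnett_summary

cfg = GeneticsConfig()

crosses = [
    ("wild-type female x pyr EGI male (no resistance)",
     "bbddppttllWWXX", "BBDDppttllWWXY"),
    ("locus-2 resistant carrier female x hh EGI male",
     "bbddprttllWWXX", "bbddPPTTllWWXY"),
    ("EGI-like female x hh EGI male",
     "bbddrPtTllWWXX", "bbddPPTTllWWXY"),
]

for title, mother, father in crosses:
    table = punnett_summary(parse_genotype(mother), parse_genotype(father),
                            cfg)
    print(f"\n{title}")
    print(f"  mother {mother}  x  father {father}")
    for (cls, sex), prob in sorted(table.items(),
                                   key=lambda kv: -kv[1]):
        print(f"    {cls.value:>18} {sex:<6} {prob:6.1%}")

print("""
The first cross is fully inviable (the incompatible-male mechanism), the
second wastes half the brood but founds the EGI-like lineage, and in the
third a quarter of all offspring are EGI females that were never released.
""")
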