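"""Trim a large simulated pedigree down to the proband's relatives.

Simulates a four-generation pedigree, picks a proband in the last
generation, and keeps only individuals within kinship distance
D = log2(1/K) <= 3 of the proband (grandparent/uncle range), plus the
parent couples needed to keep the retained individuals connected.
"""

from pedkit import (
    PedigreeSimConfig,
    generate_random_pedigree,
    trim,
    useful_inds,
)

ped = generate_random_pedigree(PedigreeSimConfig(
    n_founders=10, n_generations=4, mean_sibship=2.5, seed=2024))
proband = ped.records[-1].key
print(f"simulated pedigree: {len(ped)} individuals; proband {proband[1]}")

result = useful_inds(ped, [proband], max_dist=3.0)
trimmed = trim(ped, result)
print(f"kept {len(result.kept_ids)} individuals "
      f"({len(result.structural_ids)} retained only for connectivity)")
print(f"trimmed pedigree validates and has {len(trimmed)} members")

finite = sorted(d for d in result.distance.values() if d != float("inf"))
print(f"distance to proband ranges {finite[0]:g}..{finite[-1]:g} "
      "among related individuals; unrelated individuals are at +inf "
      "and are dropped")
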