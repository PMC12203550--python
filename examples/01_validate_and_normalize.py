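"""Normalize a messy pedigree table and report the repairs.

The raw table below declares individual X as female although X is used as
a father, and gives Z only one known parent.  Normalization fixes the sex,
invents a placeholder mother for Z, and reports both corrections.
"""

import pandas as pd

from pedkit import Pedigree, normalize

raw = pd.DataFrame(
    [
        ("1", "X", "0", "0", "2"),   # declared female, used as a father
        ("1", "M", "0", "0", "2"),
        ("1", "Y", "X", "M", "1"),
        ("1", "Z", "X", "0", "2"),   # only the father is known
    ],
    columns=["famid", "id", "dadid", "momid", "sex"], dtype=str)

records, report = normalize(raw)
print(f"errors: {len(report.errors)}")
for c in report.corrections:
    print(f"correction: {c.action} on {c.ids}: {c.before} -> {c.after}")

ped = Pedigree(records)
print(f"validated pedigree with {len(ped)} members "
      f"(placeholder mother: {ped[('1', 'Z')].momid})")
# Every child now has zero or two parents and every parent has the right
# sex, so downstream kinship and drawing code never sees half-specified
# parentage.
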