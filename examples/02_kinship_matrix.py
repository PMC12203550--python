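"""Compute kinship coefficients and kinship-based distances.

Uses the first-cousins pedigree (grandparent couple, two sib parents
married to unrelated spouses, one child each).  The kinship coefficient
K(i,j) is the probability that randomly drawn alleles from i and j are
identical by descent; D = log2(1/K) re-expresses it as meiotic steps.
"""

from pedkit import fixtures, kinship_autosomal, kinship_to_distance, kinship_x

ped = fixtures()["first_cousins"]
k = kinship_autosomal(ped)

print("autosomal kinship:")
for a, b, label in [("C", "D", "first cousins"),
                    ("A", "C", "parent-child"),
                    ("G1", "C", "grandparent"),
                    ("SA", "SB", "unrelated in-laws")]:
    value = k[a, b]
    dist = kinship_to_distance(value)
    print(f"  K({a},{b}) = {value:.4f}  D = {dist:g}   ({label})")

kx = kinship_x(ped)
print(f"X-linked: K_X(A, C) = {kx['A', 'C']:.2f} "
      "(a father passes his X to every daughter)")

# The matrix over several families is block-diagonal: unrelated families
# are exact structural zeros in the sparse container.
two = fixtures()["two_families"]
k2 = kinship_autosomal(two)
print(f"two families: matrix {k2.shape}, "
      f"cross-family entry = {k2[('1', 'C'), ('2', 'C')]}")
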