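"""Helical-wheel model of TMH indels reorienting the receptor-bound JAK2s.

Each deleted transmembrane-helix residue rotates the downstream intracellular
machinery counterclockwise (top view) by 360/3.5 ~= 103 degrees; insertions
rotate it clockwise.  With both receptors carrying the same indel, the table
marks which counts orient the two JAK2 kinases face to face (within the 30
degree tolerance) — the geometry required for transphosphorylation.
"""

import tcomplex as tc

table = tc.wheel_table()
print(table.to_string(index=False, float_format=lambda v: f"{v:8.1f}"))
print()
facing = sorted(table[table["in_proximity"]]["indels"])
print(f"JAK2s face each other for indel counts {facing}: a three-residue "
      "deletion and a four-residue insertion produce the same net rotation "
      "(they differ by 7 residues = two full helix turns), matching the "
      "constitutively active TMH mutants.")
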