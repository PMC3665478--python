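"""Structural microenvironment and relative solvent accessibility.

Builds a toy C-alpha trace, then reports, for one residue: the residue-type
composition within the 6 A sphere around its C-alpha, and its RSA computed
from the built-in rolling-probe surface fallback.  Compositions sum to 1;
RSA near 0 means buried, near 1 means fully exposed.
"""

from sapgo import (
    compute_accessibility,
    relative_accessibility,
    structural_environment,
)
from sapgo.residues import STANDARD_AA
from sapgo.structure_env import ResidueHandle
from sapgo.synthetic_fixtures import toy_structure

sequence = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
model = toy_structure(30, seed=3, sequence=sequence)
center = ResidueHandle("A", model.chain("A")[14])

env = structural_environment(model, center, radius=6.0)
print(f"residue 15 ({center.residue.name}): {env.neighbor_count} neighbors within 6 A")
for aa, freq in zip(STANDARD_AA, env.frequencies):
    if freq > 0:
        print(f"  {aa}: {freq:.2f}")

acc = compute_accessibility(model)
rsa = relative_accessibility(acc, center)
print(f"RSA = {rsa.rsa:.2f}  (0 = buried, 1 = fully exposed)")
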