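"""Extend standardized molecules with a 2D descriptor block and profile
them against Lipinski's Rule of 5."""

from bbbcurate import (
    class_fractions,
    compute_descriptors,
    ro5_profile,
    standardize_smiles,
)

mols = [standardize_smiles(s) for s in
        ("CCO", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "C" * 40)]
block = compute_descriptors(mols)
print(f"descriptor block: {block.values.shape[0]} molecules x "
      f"{len(block.names)} columns (provider: {block.provider})")

labeled = []
for m, label in zip(mols, ("BBB+", "BBB+", "BBB-")):
    p = ro5_profile(m)
    labeled.append((p, label))
    print(f"{m.smiles[:30]:32} MW={p.mw:6.1f}  HBD={p.hbd}  HBA={p.hba} "
          f"logP={p.logp:5.2f}  passes={p.passes}")

print("per-class Rule-of-5 fractions:", class_fractions(labeled))

# HBD counts O-H/N-H bonds and HBA counts N+O atoms (Lipinski's original
# convention); molecules passing all four rules are more likely to be
# orally bioavailable — and, loosely, BBB-permeant.
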