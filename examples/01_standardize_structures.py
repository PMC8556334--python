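"""Clean raw SMILES strings: whitespace repair, salt stripping,
charge neutralization, element filtering, canonicalization."""

from bbbcurate import standardize_smiles

raw_inputs = [
    "C C O\n",                 # transcription whitespace
    "CC(=O)[O-].[Na+]",        # sodium acetate: salt + charge
    "[NH3+]CC(=O)[O-]",        # glycine zwitterion
    "C[C@H](N)C(=O)O",         # L-alanine (stereocentre must survive)
    "Brc1ccccc1",              # bromine: Z=35 > 20, rejected by default
    "C1CC",                    # malformed ring
]

for raw in raw_inputs:
    out = standardize_smiles(raw)
    if out.accepted:
        print(f"{raw!r:28} -> {out.smiles:20} flags={sorted(out.flags)}")
    else:
        print(f"{raw!r:28} -> REJECTED ({out.rejected_reason})")

# Accepted molecules are canonical, neutral, and metal-free; each
# rejection reason explains which cleaning rule the structure violated.
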