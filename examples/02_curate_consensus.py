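"""Collapse multi-source log BB lists into consensus values with
reliability groups A-D, and derive categorical labels."""

from bbbcurate import assign_numeric_group, filter_outliers, label_from_logbb

cases = {
    "single value": [0.42],
    "concordant replicates": [-0.50, -0.51, -0.50],
    "two discordant values": [0.10, 0.10, 0.30],
    "many discordant values": [0.1, 0.1, 0.3, 0.5],
    "modal tie": [0.1, 0.1, 0.3, 0.3, 0.5],
}

for name, values in cases.items():
    kept, dropped = filter_outliers(values)  # drops instances <= -9
    graded = assign_numeric_group(kept)
    if graded is None:
        print(f"{name:24} {values} -> discarded (no defensible consensus)")
    else:
        group, logbb = graded
        label = label_from_logbb(logbb)  # BBB+ iff log BB >= -1
        print(f"{name:24} {values} -> group {group}, log BB {logbb:+.4f}, {label}")

# Group A/B molecules are the most reliable (one value, or all values
# within 5% of the mean); C and D carry increasing experimental
# disagreement; modal ties are discarded rather than guessed.
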