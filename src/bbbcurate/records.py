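"""Domain record types shared across the curation pipeline.

A *source record* is one raw measurement or label row as reported by one
literature source; a *curated row* is one line of the final deduplicated
dataset. Numeric permeability is expressed as ``log BB``, the base-10
logarithm of the brain-to-blood concentration ratio of a compound, so a
value of 0 means equal partitioning and -1 means a ten-fold lower brain
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

BBB_PLUS = "BBB+"
BBB_MINUS = "BBB-"
LABELS = (BBB_PLUS, BBB_MINUS)

#: Variants accepted on input and normalized to the ASCII forms above.
#: The Unicode minus/en-dash spellings occur in published tables.
_LABEL_ALIASES = {
    "bbb+": BBB_PLUS,
    "+": BBB_PLUS,
    "bbb-": BBB_MINUS,
    "bbb−": BBB_MINUS,  # minus sign
    "bbb–": BBB_MINUS,  # en dash
    "-": BBB_MINUS,
    "−": BBB_MINUS,
}


def normalize_label(raw: str) -> str:
    """Map a raw label spelling onto ``BBB+`` / ``BBB-``.

    Raises ``ValueError`` for anything that is not a recognized spelling.
    """
    key = str(raw).strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized BBB label: {raw!r}") from None


@dataclass
class SourceRecord:
    """One raw row from one source table, with provenance.

    At least one identity field (name, SMILES, CID) and at least one datum
    (log BB value or categorical label) must be present; ``validate``
    enforces this.
    """

    source_id: str
    compound_name: str | None = None
    smiles_raw: str | None = None
    cid: int | None = None
    logbb: float | None = None
    label: str | None = None
    threshold: float | None = None
    reference: str = ""
    notes: list[str] = field(default_factory=list)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.compound_name is None and self.smiles_raw is None and self.cid is None:
            problems.append("no identity")
        if self.logbb is None and self.label is None:
            problems.append("no datum")
        if self.logbb is not None and not math.isfinite(self.logbb):
            problems.append("non-finite logBB")
        if self.label is not None and self.label not in LABELS:
            problems.append("invalid label")
        if self.threshold is not None and not math.isfinite(self.threshold):
            problems.append("non-finite threshold")
        if self.cid is not None and self.cid <= 0:
            problems.append("non-positive CID")
        return problems


@dataclass
class CuratedRow:
    """One row of a curated output table (numeric or categorical track)."""

    compound_name: str = ""
    iupac_name: str | None = None
    smiles: str = ""
    cid: str | None = None
    logbb: float | None = None
    label: str | None = None
    inchi: str = ""
    threshold: float | None = None
    reference: str = ""
    group: str = ""
    comment: str = ""
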