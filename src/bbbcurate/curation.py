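"""Consensus curation of per-molecule measurement sets.

Each molecular identity may carry several independently reported log BB
values and/or categorical BBB+/BBB- labels. This module collapses them
into one consensus value or label per molecule and grades its reliability:

Numeric track (applied after outlier and spread filters):
    A  one unique reported value,
    B  multiple values, all within the relative tolerance of their mean
       (consensus = mean),
    C  exactly two distinct values outside tolerance
       (consensus = multiplicity-weighted mean),
    D  more than two distinct values (consensus = modal value; a modal
       tie discards the molecule).

Categorical track:
    A  molecule has curated numeric data; label derived from log BB at
       the -1 threshold,
    B  all sources agree and all report the -1 threshold,
    C  all sources agree but at least one threshold is unreported,
    D  sources disagree; majority label wins, exact tie discards.

Value distinctness is judged after rounding to ``round_decimals`` places
(default 2, matching typical log BB reporting precision).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .records import BBB_MINUS, BBB_PLUS

DISCARD_MODAL_TIE = "modal_tie"
DISCARD_LABEL_TIE = "label_tie"
DISCARD_SPREAD = "spread_gt_1"
DISCARD_NO_VALUES = "all_values_outliers"
DISCARD_THRESHOLD_MISMATCH = "threshold_mismatch"


@dataclass
class CurationConfig:
    """Tunable thresholds of the consensus rules (defaults as published)."""

    outlier_cutoff: float = -9.0       # drop instances with log BB <= this
    max_spread: float = 1.0            # discard molecules with max-min > this
    rel_tolerance: float = 0.05        # group B: |v - mean| <= tol*|mean|
    round_decimals: int = 2            # distinctness precision
    label_threshold: float = -1.0      # BBB+ iff log BB >= this


@dataclass
class MeasurementSet:
    """All surviving observations attached to one molecular identity."""

    key: str                                     # standard InChI
    logbb_values: list[tuple[float, str]] = field(default_factory=list)
    labels: list[tuple[str, float | None, str]] = field(default_factory=list)

    def value_list(self) -> list[float]:
        return [v for v, _ in self.logbb_values]


@dataclass
class CuratedNumericRecord:
    key: str
    logbb: float
    group: str
    n_values: int
    n_unique: int
    sources: list[str]
    comment: str = ""


@dataclass
class CuratedCategoricalRecord:
    key: str
    label: str
    group: str
    threshold_used: float | None
    sources: list[str]
    n_labels: int = 0
    n_unique_labels: int = 0
    comment: str = ""


@dataclass
class Discard:
    key: str
    track: str
    reason: str


def filter_outliers(
    values: list[float], cutoff: float = -9.0
) -> tuple[list[float], list[float]]:
    """Split values into (kept, dropped) at the outlier cutoff.

    The rule is per-instance: a value <= cutoff is dropped without
    discarding the molecule's other measurements.
    """
    kept = [v for v in values if v > cutoff]
    dropped = [v for v in values if v <= cutoff]
    return kept, dropped


def spread_filter(values: list[float], max_spread: float = 1.0) -> bool:
    """True to keep the molecule: reported values span <= max_spread."""
    if not values:
        raise ValueError("spread_filter requires at least one value")
    return (max(values) - min(values)) <= max_spread


def assign_numeric_group(
    values: list[float], config: CurationConfig | None = None
) -> tuple[str, float] | None:
    """Grade a post-filter value list and return ``(group, consensus)``.

    Returns ``None`` when the molecule must be discarded (modal tie in
    group D). ``values`` must be non-empty and already filtered.
    """
    cfg = config or CurationConfig()
    if not values:
        raise ValueError("assign_numeric_group requires at least one value")
    nd = cfg.round_decimals
    rounded = [round(v, nd) for v in values]
    counts = Counter(rounded)
    mean = sum(values) / len(values)

    if len(counts) == 1:
        return "A", mean
    # group B: every value within rel_tolerance of the mean. Relative
    # tolerance is undefined at mean ~ 0; there, B would require all values
    # identical after rounding, which the A branch already captured.
    if abs(mean) > 1e-8 and all(
        abs(v - mean) <= cfg.rel_tolerance * abs(mean) for v in values
    ):
        return "B", mean
    if len(counts) == 2:
        # multiplicity-weighted mean over the distinct rounded values;
        # equals the plain mean when weights come from repeat counts
        total = sum(counts.values())
        weighted = sum(value * n for value, n in counts.items()) / total
        return "C", weighted
    top = counts.most_common()
    if top[0][1] == top[1][1]:
        return None  # two values tie for greatest frequency
    modal = top[0][0]
    members = [v for v, r in zip(values, rounded) if r == modal]
    return "D", sum(members) / len(members)


def label_from_logbb(logbb: float, threshold: float = -1.0) -> str:
    """Classify a log BB value at a threshold (boundary counts as BBB+)."""
    if not (math.isfinite(logbb) and math.isfinite(threshold)):
        raise ValueError("label_from_logbb requires finite inputs")
    return BBB_PLUS if logbb >= threshold else BBB_MINUS


def assign_categorical_group(
    ms: MeasurementSet,
    numeric: CuratedNumericRecord | None,
    config: CurationConfig | None = None,
) -> tuple[str, str, float | None, str] | Discard:
    """Grade one molecule's categorical evidence.

    Returns ``(group, label, threshold_used, comment)`` or a
    :class:`Discard`. A molecule with curated numeric data is always group
    A with its label recomputed from the consensus log BB.
    """
    cfg = config or CurationConfig()
    if numeric is not None:
        label = label_from_logbb(numeric.logbb, cfg.label_threshold)
        comment = ""
        observed = {lab for lab, _, _ in ms.labels}
        if observed and observed != {label}:
            comment = "source labels conflict with numeric-derived label"
        return "A", label, cfg.label_threshold, comment
    if not ms.labels:
        raise ValueError("categorical grading requires labels or numeric data")
    label_counts = Counter(lab for lab, _, _ in ms.labels)
    if len(label_counts) == 1:
        label = next(iter(label_counts))
        thresholds = [t for _, t, _ in ms.labels]
        if all(t is not None and t == cfg.label_threshold for t in thresholds):
            return "B", label, cfg.label_threshold, ""
        reported = {t for t in thresholds if t is not None}
        if reported - {cfg.label_threshold}:
            # a source graded this label at a different cutoff; its label is
            # not comparable under the common threshold convention
            return Discard(ms.key, "categorical", DISCARD_THRESHOLD_MISMATCH)
        return "C", label, None, ""
    top = label_counts.most_common()
    if top[0][1] == top[1][1]:
        return Discard(ms.key, "categorical", DISCARD_LABEL_TIE)
    return "D", top[0][0], None, "conflicting source labels; majority used"


def curate_numeric(
    sets: list[MeasurementSet], config: CurationConfig | None = None
) -> tuple[list[CuratedNumericRecord], list[Discard]]:
    """Run outlier filter, spread filter and grading over measurement sets."""
    cfg = config or CurationConfig()
    out: list[CuratedNumericRecord] = []
    discards: list[Discard] = []
    for ms in sets:
        if not ms.logbb_values:
            continue
        kept, _ = filter_outliers(ms.value_list(), cfg.outlier_cutoff)
        if not kept:
            discards.append(Discard(ms.key, "numeric", DISCARD_NO_VALUES))
            continue
        if not spread_filter(kept, cfg.max_spread):
            discards.append(Discard(ms.key, "numeric", DISCARD_SPREAD))
            continue
        graded = assign_numeric_group(kept, cfg)
        if graded is None:
            discards.append(Discard(ms.key, "numeric", DISCARD_MODAL_TIE))
            continue
        group, value = graded
        sources = [s for v, s in ms.logbb_values if v > cfg.outlier_cutoff]
        out.append(
            CuratedNumericRecord(
                key=ms.key,
                logbb=value,
                group=group,
                n_values=len(kept),
                n_unique=len({round(v, cfg.round_decimals) for v in kept}),
                sources=sources,
            )
        )
    return out, discards


def curate_categorical(
    sets: list[MeasurementSet],
    numeric_records: list[CuratedNumericRecord],
    config: CurationConfig | None = None,
) -> tuple[list[CuratedCategoricalRecord], list[Discard]]:
    """Grade every molecule that has labels and/or curated numeric data."""
    cfg = config or CurationConfig()
    numeric_by_key = {r.key: r for r in numeric_records}
    out: list[CuratedCategoricalRecord] = []
    discards: list[Discard] = []
    for ms in sets:
        numeric = numeric_by_key.get(ms.key)
        if numeric is None and not ms.labels:
            continue
        result = assign_categorical_group(ms, numeric, cfg)
        if isinstance(result, Discard):
            discards.append(result)
            continue
        group, label, threshold, comment = result
        sources = [s for _, _, s in ms.labels]
        if numeric is not None:
            sources = sorted(set(sources) | set(numeric.sources))
            # group A carries a single curated label derived from the
            # numeric consensus, regardless of raw label multiplicity
            n_labels, n_unique = 1, 1
        else:
            n_labels = len(ms.labels)
            n_unique = len({lab for lab, _, _ in ms.labels})
        out.append(
            CuratedCategoricalRecord(
                key=ms.key,
                label=label,
                group=group,
                threshold_used=threshold,
                sources=sources,
                n_labels=n_labels,
                n_unique_labels=n_unique,
                comment=comment,
            )
        )
    return out, discards
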