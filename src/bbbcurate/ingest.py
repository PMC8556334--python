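"""Reading heterogeneous source tables and writing curated CSV outputs.

Source tables come in incompatible layouts, so each one is read through an
explicit ``schema_map`` (file column → record field); there is no header
guessing. Rows that violate the record invariants are returned as rejects
with reasons — never silently dropped — and can be written to a sidecar
CSV for manual review.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import CuratedRow, SourceRecord, normalize_label

#: Record fields a schema_map may target.
MAPPABLE_FIELDS = (
    "compound_name",
    "smiles_raw",
    "cid",
    "logbb",
    "label",
    "threshold",
    "reference",
)

#: Curated output column layouts. The numeric track omits the label and
#: threshold columns, which only apply to the categorical dataset.
CATEGORICAL_COLUMNS = [
    "compound name",
    "IUPAC name",
    "SMILES",
    "CID",
    "log BB",
    "BBB+/BBB-",
    "InChI",
    "threshold",
    "reference",
    "group",
    "comment",
]
NUMERIC_COLUMNS = [c for c in CATEGORICAL_COLUMNS if c not in ("BBB+/BBB-", "threshold")]


@dataclass
class Reject:
    source_id: str
    row_index: int
    reason: str
    raw: dict = field(default_factory=dict)


def _load_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=object)
    return pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[""])


def _parse_float(value) -> float:
    text = str(value).strip().replace("−", "-").replace("–", "-")
    return float(text)


def read_source_table(
    path: str | Path,
    schema_map: dict[str, str],
    source_id: str,
    default_threshold: float | None = None,
    default_reference: str = "",
) -> tuple[list[SourceRecord], list[Reject]]:
    """Read one source table into records plus a reject list.

    ``schema_map`` maps file column names onto :data:`MAPPABLE_FIELDS`.
    ``default_threshold`` supplies per-source threshold metadata for tables
    that state their cutoff in the text rather than per row. Conservation
    holds: every data row appears in exactly one of the two output lists.
    """
    frame = _load_table(path)
    for col, fld in schema_map.items():
        if fld not in MAPPABLE_FIELDS:
            raise ValueError(f"schema_map targets unknown field {fld!r}")
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path}")

    records: list[SourceRecord] = []
    rejects: list[Reject] = []
    for idx, row in frame.iterrows():
        rec = SourceRecord(source_id=source_id, reference=default_reference)
        problems = []
        for col, fld in schema_map.items():
            value = row[col]
            if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
                continue
            try:
                if fld in ("logbb", "threshold"):
                    setattr(rec, fld, _parse_float(value))
                elif fld == "cid":
                    rec.cid = int(float(str(value).strip()))
                elif fld == "label":
                    rec.label = normalize_label(value)
                else:
                    setattr(rec, fld, str(value).strip())
            except (ValueError, TypeError):
                kind = "numeric" if fld in ("logbb", "threshold", "cid") else "label"
                problems.append(f"unparsable {kind}: {fld}={value!r}")
        if rec.threshold is None and rec.label is not None:
            rec.threshold = default_threshold
        problems.extend(rec.validate())
        if problems:
            rejects.append(
                Reject(source_id, int(idx), "; ".join(problems), dict(row))
            )
        else:
            records.append(rec)
    assert len(records) + len(rejects) == len(frame)
    return records, rejects


def consistency_check(records: list[SourceRecord]) -> dict:
    """Automated sanity counts over raw records (reporting only).

    Checks: non-finite log BB, labels outside the accepted vocabulary,
    byte-identical duplicate rows within one source.
    """
    non_finite = sum(
        1 for r in records if r.logbb is not None and not math.isfinite(r.logbb)
    )
    bad_label = sum(
        1 for r in records if r.label is not None and r.label not in ("BBB+", "BBB-")
    )
    seen = Counter(
        (r.source_id, r.compound_name, r.smiles_raw, r.cid, r.logbb, r.label, r.threshold)
        for r in records
    )
    duplicates = sum(n - 1 for n in seen.values() if n > 1)
    return {
        "n_records": len(records),
        "non_finite_logbb": non_finite,
        "invalid_label": bad_label,
        "duplicate_rows_within_source": duplicates,
    }


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_curated(rows: list[CuratedRow], path: str | Path, track: str) -> None:
    """Write a curated table (``track`` = ``numeric`` | ``categorical``).

    Missing values become empty cells; floats keep six significant digits
    so that a read-back round trip is value-identical at reporting
    precision.
    """
    if track == "numeric":
        columns = NUMERIC_COLUMNS
        if any(r.label is not None or r.threshold is not None for r in rows):
            raise ValueError("numeric track rows must not carry labels/thresholds")
    elif track == "categorical":
        columns = CATEGORICAL_COLUMNS
        if any(r.label is None for r in rows):
            raise ValueError("categorical track rows must carry a label")
    else:
        raise ValueError(f"unknown track {track!r}")

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in rows:
            cells = {
                "compound name": row.compound_name,
                "IUPAC name": row.iupac_name,
                "SMILES": row.smiles,
                "CID": row.cid,
                "log BB": row.logbb,
                "BBB+/BBB-": row.label,
                "InChI": row.inchi,
                "threshold": row.threshold,
                "reference": row.reference,
                "group": row.group,
                "comment": row.comment,
            }
            writer.writerow([_fmt(cells[c]) for c in columns])


def read_curated(path: str | Path) -> list[CuratedRow]:
    """Read back a curated CSV written by :func:`write_curated`.

    Also accepts the Unicode-minus spelling of ``BBB-`` labels seen in
    published tables.
    """
    rows: list[CuratedRow] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            def get(col):
                value = rec.get(col, "")
                return value if value not in ("", None) else None

            label = get("BBB+/BBB-")
            rows.append(
                CuratedRow(
                    compound_name=get("compound name") or "",
                    iupac_name=get("IUPAC name"),
                    smiles=get("SMILES") or "",
                    cid=get("CID"),
                    logbb=float(get("log BB")) if get("log BB") else None,
                    label=normalize_label(label) if label else None,
                    inchi=get("InChI") or "",
                    threshold=float(get("threshold")) if get("threshold") else None,
                    reference=get("reference") or "",
                    group=get("group") or "",
                    comment=get("comment") or "",
                )
            )
    return rows


def write_rejects(rejects: list[Reject], path: str | Path) -> None:
    """Sidecar CSV of rejected rows with reasons, for manual review."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "row_index", "reason", "raw"])
        for rej in rejects:
            writer.writerow(
                [rej.source_id, rej.row_index, rej.reason, json.dumps(rej.raw, default=str)]
            )


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str), encoding="utf-8")
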