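"""End-to-end workflow: ingest → standardize → resolve → merge → curate →
extend → validate.

The runner keeps explicit stage accounting (records in = records out +
rejects at every stage) and writes all artifacts — curated numeric and
categorical CSVs, descriptor-extended CSVs, reject/discard ledgers with
reasons, a consistency report and a QC report — to one output directory.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import curation, descriptors, identity, ingest, qc
from .curation import CurationConfig, MeasurementSet
from .records import CuratedRow, SourceRecord
from .standardize import ElementFilterConfig, standardize_smiles

log = logging.getLogger("bbbcurate")


@dataclass
class SourceSpec:
    path: str
    source_id: str
    schema_map: dict[str, str]
    default_threshold: float | None = None
    reference: str = ""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (loadable from YAML)."""

    sources: list[SourceSpec]
    output_dir: str
    resolver_mode: str = "offline"          # offline | cache | live
    resolver_table: str | None = None       # reserved for file-backed stubs
    cache_path: str | None = None
    element_filter: ElementFilterConfig = field(default_factory=ElementFilterConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    compute_descriptors: bool = True
    descriptor_provider: str = "rdkit"      # rdkit | mordred
    qc_parser: str = "openbabel"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        sources = [SourceSpec(**s) for s in raw.pop("sources")]
        ef = ElementFilterConfig(**raw.pop("element_filter", {}))
        cur = CurationConfig(**raw.pop("curation", {}))
        return cls(sources=sources, element_filter=ef, curation=cur, **raw)

    def validate(self) -> None:
        for spec in self.sources:
            if not Path(spec.path).exists():
                raise FileNotFoundError(f"source table not found: {spec.path}")


def _build_resolver(config: RunConfig) -> identity.Resolver:
    if config.resolver_mode == "offline":
        return identity.OfflineTableResolver()
    if config.resolver_mode == "live":
        inner = identity.PubChemResolver()
        if config.cache_path:
            return identity.CachedResolver(inner, config.cache_path)
        return inner
    if config.resolver_mode == "cache":
        if not config.cache_path:
            raise ValueError("resolver_mode=cache requires cache_path")
        return identity.CachedResolver(identity.OfflineTableResolver(), config.cache_path)
    raise ValueError(f"unknown resolver_mode {config.resolver_mode!r}")


@dataclass
class PipelineResult:
    numeric_records: list
    categorical_records: list
    numeric_rows: list[CuratedRow]
    categorical_rows: list[CuratedRow]
    stage_counts: dict
    qc_report: qc.QCReport | None
    output_dir: Path


def run_pipeline(
    config: RunConfig, resolver: identity.Resolver | None = None
) -> PipelineResult:
    """Execute the full curation workflow.

    ``resolver`` overrides the configured one (used for offline runs with
    a table-backed stub, e.g. on synthetic fixtures).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolver = resolver or _build_resolver(config)
    counts: dict = {}

    # ---- ingest -------------------------------------------------------
    records: list[SourceRecord] = []
    rejects: list[ingest.Reject] = []
    for spec in config.sources:
        recs, rejs = ingest.read_source_table(
            spec.path,
            spec.schema_map,
            spec.source_id,
            default_threshold=spec.default_threshold,
            default_reference=spec.reference,
        )
        records.extend(recs)
        rejects.extend(rejs)
    counts["collected"] = len(records) + len(rejects)
    counts["ingested"] = len(records)
    counts["ingest_rejected"] = len(rejects)
    log.info("ingest: %d rows, %d accepted, %d rejected",
             counts["collected"], len(records), len(rejects))
    ingest.write_report(ingest.consistency_check(records), outdir / "consistency.json")

    # ---- resolve missing identity fields ------------------------------
    resolved = [identity.resolve_missing(r, resolver) for r in records]
    no_smiles = [r for r in resolved if r.smiles_raw is None]
    with_smiles = [r for r in resolved if r.smiles_raw is not None]
    counts["resolved"] = len(with_smiles)
    counts["unresolved"] = len(no_smiles)

    # ---- standardize ---------------------------------------------------
    std_cache: dict[str, object] = {}
    accepted: list[tuple[SourceRecord, object]] = []
    std_rejects: list[tuple[SourceRecord, str]] = []
    for rec in with_smiles:
        std = std_cache.get(rec.smiles_raw)
        if std is None:
            std = standardize_smiles(rec.smiles_raw, config.element_filter)
            std_cache[rec.smiles_raw] = std
        if std.accepted:
            accepted.append((rec, std))
        else:
            std_rejects.append((rec, std.rejected_reason))
    counts["standardized"] = len(accepted)
    counts["standardize_rejected"] = len(std_rejects)
    assert counts["resolved"] == len(accepted) + len(std_rejects)

    # ---- merge by identity key ----------------------------------------
    sets: dict[str, MeasurementSet] = {}
    meta: dict[str, dict] = {}
    for rec, std in accepted:
        key = identity.make_key(std)
        ms = sets.setdefault(key, MeasurementSet(key=key))
        if rec.logbb is not None:
            ms.logbb_values.append((rec.logbb, rec.source_id))
        if rec.label is not None:
            ms.labels.append((rec.label, rec.threshold, rec.source_id))
        info = meta.setdefault(key, {"smiles": std.smiles, "names": [], "cids": [],
                                     "comments": set(), "notes": set()})
        if rec.compound_name:
            info["names"].append(rec.compound_name)
        if rec.cid is not None:
            info["cids"].append(rec.cid)
        if std.comment:
            info["comments"].add(std.comment)
        for note in rec.notes:
            info["notes"].add(note)
    counts["merged_identities"] = len(sets)

    # refresh CIDs and fetch IUPAC names from the standardized structure
    for key, info in meta.items():
        matches = resolver.by_smiles(info["smiles"])
        if matches and matches[0].cid is not None:
            info["cid"] = matches[0].cid
            info["iupac_name"] = matches[0].iupac_name
            if matches[0].name and not info["names"]:
                info["names"].append(matches[0].name)
        else:
            info["cid"] = info["cids"][0] if info["cids"] else None
            info["iupac_name"] = None

    # ---- curate --------------------------------------------------------
    ordered = [sets[k] for k in sorted(sets)]
    numeric_records, num_discards = curation.curate_numeric(ordered, config.curation)
    categorical_records, cat_discards = curation.curate_categorical(
        ordered, numeric_records, config.curation
    )
    counts["curated_numeric"] = len(numeric_records)
    counts["curated_categorical"] = len(categorical_records)
    counts["discarded_numeric"] = len(num_discards)
    counts["discarded_categorical"] = len(cat_discards)
    n_with_numeric = sum(1 for ms in ordered if ms.logbb_values)
    assert len(numeric_records) + len(num_discards) == n_with_numeric
    log.info("curation: %d numeric, %d categorical records",
             len(numeric_records), len(categorical_records))

    def _row(key: str, **kw) -> CuratedRow:
        info = meta[key]
        comment_bits = sorted(info["comments"] | info["notes"])
        return CuratedRow(
            compound_name=info["names"][0] if info["names"] else "",
            iupac_name=info.get("iupac_name"),
            smiles=info["smiles"],
            cid=str(info["cid"]) if info.get("cid") is not None else None,
            inchi=key,
            comment="; ".join(comment_bits),
            **kw,
        )

    numeric_rows = [
        _row(r.key, logbb=r.logbb, group=r.group,
             reference="; ".join(sorted(set(r.sources))))
        for r in numeric_records
    ]
    numeric_by_key = {r.key: r for r in numeric_records}
    categorical_rows = []
    for r in categorical_records:
        num = numeric_by_key.get(r.key)
        row = _row(r.key, label=r.label, group=r.group,
                   threshold=r.threshold_used,
                   logbb=num.logbb if num is not None else None,
                   reference="; ".join(sorted(set(r.sources))))
        if r.comment:
            row.comment = "; ".join(filter(None, [row.comment, r.comment]))
        categorical_rows.append(row)

    ingest.write_curated(numeric_rows, outdir / "curated_numeric.csv", "numeric")
    ingest.write_curated(
        categorical_rows, outdir / "curated_categorical.csv", "categorical"
    )
    ingest.write_rejects(rejects, outdir / "ingest_rejects.csv")
    with (outdir / "discards.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track", "inchi", "reason"])
        for rec2, reason in std_rejects:
            writer.writerow(["standardize", rec2.smiles_raw, reason])
        for d in num_discards + cat_discards:
            writer.writerow([d.track, d.key, d.reason])

    # ---- extend with descriptors --------------------------------------
    if config.compute_descriptors:
        from .standardize import StandardizedMolecule

        mols = [
            StandardizedMolecule(smiles=meta[r.key]["smiles"], inchi=r.key)
            for r in categorical_records
        ]
        provider = (
            descriptors.MordredDescriptorProvider()
            if config.descriptor_provider == "mordred"
            else descriptors.RDKitDescriptorProvider()
        )
        block = descriptors.compute_descriptors(mols, provider)
        frame = block.to_frame()
        frame.insert(0, "SMILES", [m.smiles for m in mols])
        frame.to_csv(outdir / "descriptors_categorical.csv", index_label="InChI")
        counts["descriptor_columns"] = len(block.names)

    # ---- QC ------------------------------------------------------------
    profiles = [
        (descriptors.ro5_profile(meta[r.key]["smiles"]), r.label)
        for r in categorical_records
    ]
    report = qc.qc_report(
        numeric_rows + categorical_rows,
        numeric_records,
        categorical_records,
        profiles,
        parser=config.qc_parser,
    )
    report.metadata["stage_counts"] = counts
    report.write(outdir / "qc_report.json")

    return PipelineResult(
        numeric_records=numeric_records,
        categorical_records=categorical_records,
        numeric_rows=numeric_rows,
        categorical_rows=categorical_rows,
        stage_counts=counts,
        qc_report=report,
        output_dir=outdir,
    )
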