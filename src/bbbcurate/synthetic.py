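"""Synthetic messy multi-source fixtures with known ground truth.

The generator emulates the failure modes of literature-compiled
permeability tables: the same molecule reported by several sources, noisy
log BB replicates, implausible outlier values, flipped categorical labels,
SMILES corrupted by whitespace / appended salts / charged protonation
states, rows identified only by name or only by a registry CID, and
threshold metadata that is only sometimes reported.

Ground truth is stored alongside the emitted tables: the clean structure,
the true log BB and label, every corruption applied, and the consensus
group/value the curation rules *should* produce for the generated records
(computed here with an independent, literal transliteration of the rules —
see :func:`oracle_group`). :func:`score_recovery` compares a pipeline run
against that truth.

Fixtures exercise the rules; they do not emulate assay chemistry or the
structural diversity of real data.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .identity import Match, OfflineTableResolver
from .records import BBB_MINUS, BBB_PLUS
from .standardize import standardize_smiles

#: Hand-listed valid organic structures: alkanes, alcohols, acids, amines,
#: aromatics and heterocycles, a few halogenated (Cl/F) compounds, and one
#: explicit enantiomer pair (L-/D-alanine). All pass the element filter.
MOLECULE_LIBRARY: list[tuple[str, str]] = [
    ("methane", "C"),
    ("ethane", "CC"),
    ("propane", "CCC"),
    ("butane", "CCCC"),
    ("isobutane", "CC(C)C"),
    ("pentane", "CCCCC"),
    ("neopentane", "CC(C)(C)C"),
    ("methanol", "CO"),
    ("ethanol", "CCO"),
    ("propanol", "CCCO"),
    ("isopropanol", "CC(C)O"),
    ("ethylene glycol", "OCCO"),
    ("glycerol", "OCC(O)CO"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("ethylbenzene", "CCc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("acetic acid", "CC(=O)O"),
    ("propionic acid", "CCC(=O)O"),
    ("benzoic acid", "OC(=O)c1ccccc1"),
    ("lactic acid", "CC(O)C(=O)O"),
    ("glycine", "NCC(=O)O"),
    ("L-alanine", "C[C@H](N)C(=O)O"),
    ("D-alanine", "C[C@@H](N)C(=O)O"),
    ("L-valine", "CC(C)[C@H](N)C(=O)O"),
    ("methylamine", "CN"),
    ("ethylamine", "CCN"),
    ("propylamine", "CCCN"),
    ("dimethylamine", "CNC"),
    ("N-methylaniline", "CNc1ccccc1"),
    ("ethanolamine", "OCCN"),
    ("dimethyl ether", "COC"),
    ("diethyl ether", "CCOCC"),
    ("ethyl acetate", "CCOC(C)=O"),
    ("methyl benzoate", "COC(=O)c1ccccc1"),
    ("acetone", "CC(C)=O"),
    ("acetaldehyde", "CC=O"),
    ("benzaldehyde", "O=Cc1ccccc1"),
    ("acetamide", "CC(N)=O"),
    ("N-methylacetamide", "CC(=O)NC"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("trifluoromethylbenzene", "FC(F)(F)c1ccccc1"),
    ("benzonitrile", "N#Cc1ccccc1"),
    ("DMSO", "CS(C)=O"),
    ("urea", "NC(N)=O"),
    ("benzenesulfonamide", "NS(=O)(=O)c1ccccc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
]

_CHAIN_SUFFIXES = ["O", "N", "S", "C#N", "C(=O)O", "C(=O)N", "OC", "c1ccccc1"]


def _molecule_supply(n: int) -> list[tuple[str, str]]:
    """First ``n`` distinct molecules: the library, then a procedural
    family of chain + functional-group structures, deduplicated by InChI."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()

    def try_add(name: str, smi: str) -> None:
        std = standardize_smiles(smi)
        if not std.accepted or std.inchi in seen:
            return
        seen.add(std.inchi)
        out.append((name, smi))

    for name, smi in MOLECULE_LIBRARY:
        if len(out) >= n:
            return out
        try_add(name, smi)
    chain_len = 6
    while len(out) < n:
        for i, suffix in enumerate(_CHAIN_SUFFIXES):
            if len(out) >= n:
                break
            try_add(f"synthetic-c{chain_len}-f{i}", "C" * chain_len + suffix)
        chain_len += 1
    return out


@dataclass
class SyntheticConfig:
    """Generator knobs; the defaults describe a mildly messy corpus."""

    n_molecules: int = 100
    source_mean_records: float = 2.0      # truncated Poisson mean
    source_max_records: int = 23          # per-molecule cap on records
    noise_sd: float = 0.02                # log-unit noise on reported log BB
    outlier_rate: float = 0.02            # extra record with log BB <= -9
    conflict_rate: float = 0.02           # label flipped vs truth
    whitespace_rate: float = 0.05         # SMILES whitespace corruption
    salt_rate: float = 0.05               # counterion appended to SMILES
    charge_rate: float = 0.05             # deprotonated/charged variant
    name_only_rate: float = 0.05          # row keeps only the compound name
    cid_only_rate: float = 0.03           # row keeps only the registry CID
    threshold_report_rate: float = 0.5    # label rows that state their cutoff
    numeric_record_rate: float = 0.5      # record is numeric (vs categorical)
    label_threshold: float = -1.0
    seed: int = 0

    def validate(self) -> None:
        rates = [
            self.outlier_rate, self.conflict_rate, self.whitespace_rate,
            self.salt_rate, self.charge_rate, self.name_only_rate,
            self.cid_only_rate, self.threshold_report_rate,
            self.numeric_record_rate,
        ]
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


def oracle_group(values: list[float], round_decimals: int = 2) -> tuple[str, float] | None:
    """Literal, brute-force restatement of the numeric consensus rules.

    Implemented independently of the curation module, for use as a test
    oracle: A = one unique value; B = all values within 5% of the mean;
    C = exactly two distinct values (weighted mean); D = more than two
    distinct values (modal value, tie → ``None`` = discard).
    """
    if not values:
        raise ValueError("oracle_group requires values")
    rounded = [round(v, round_decimals) for v in values]
    unique = sorted(set(rounded))
    mean = sum(values) / len(values)
    if len(unique) == 1:
        return "A", mean
    if abs(mean) > 1e-8:
        deviations_ok = True
        for v in values:
            if abs(v - mean) > 0.05 * abs(mean):
                deviations_ok = False
        if deviations_ok:
            return "B", mean
    if len(unique) == 2:
        w0 = rounded.count(unique[0])
        w1 = rounded.count(unique[1])
        return "C", (unique[0] * w0 + unique[1] * w1) / (w0 + w1)
    freq = Counter(rounded)
    best = max(freq.values())
    modes = [u for u in unique if freq[u] == best]
    if len(modes) > 1:
        return None
    members = [v for v in values if round(v, round_decimals) == modes[0]]
    return "D", sum(members) / len(members)


def _oracle_categorical(
    labels: list[tuple[str, float | None]],
    numeric_value: float | None,
    threshold: float = -1.0,
) -> tuple[str, str] | None:
    """Literal restatement of the categorical rules (truth bookkeeping)."""
    if numeric_value is not None:
        return "A", (BBB_PLUS if numeric_value >= threshold else BBB_MINUS)
    if not labels:
        return None
    distinct = sorted({lab for lab, _ in labels})
    if len(distinct) == 1:
        if all(t == threshold for _, t in labels):
            return "B", distinct[0]
        if any(t is not None and t != threshold for _, t in labels):
            return None  # foreign threshold, not comparable
        return "C", distinct[0]
    freq = Counter(lab for lab, _ in labels)
    top = freq.most_common()
    if top[0][1] == top[1][1]:
        return None
    return "D", top[0][0]


def _charge_variant(smiles: str) -> str | None:
    """Deprotonated carboxylate form, when the molecule has a -COOH."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    patt = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
    matches = mol.GetSubstructMatches(patt)
    if not matches:
        return None
    rw = Chem.RWMol(mol)
    o_idx = matches[0][2]
    atom = rw.GetAtomWithIdx(o_idx)
    atom.SetFormalCharge(-1)
    atom.SetNumExplicitHs(0)
    try:
        Chem.SanitizeMol(rw)
    except Exception:
        return None
    return Chem.MolToSmiles(rw) + ".[Na+]"


@dataclass
class SyntheticDataset:
    """Generated corpus: per-source tables, ground truth, offline resolver."""

    config: SyntheticConfig
    sources: dict[str, pd.DataFrame]
    truth: dict
    resolver: OfflineTableResolver
    schema_map: dict[str, str] = field(
        default_factory=lambda: {
            "name": "compound_name",
            "smiles": "smiles_raw",
            "cid": "cid",
            "logBB": "logbb",
            "label": "label",
            "threshold": "threshold",
        }
    )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for source_id in sorted(self.sources):
            self.sources[source_id].to_csv(outdir / f"{source_id}.csv", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True), encoding="utf-8"
        )


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate messy source tables plus ground truth (seed-deterministic)."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    supply = _molecule_supply(cfg.n_molecules)

    source_rows: dict[str, list[dict]] = {}
    molecules = []
    corruptions = []
    name_table: dict[str, list[Match]] = {}
    cid_table: dict[int, list[Match]] = {}
    smiles_table: dict[str, list[Match]] = {}

    for i, (name, clean_smiles) in enumerate(supply):
        std = standardize_smiles(clean_smiles)
        cid = 100001 + i
        match = Match(cid=cid, smiles=clean_smiles, name=name, iupac_name=f"iupac-{name}")
        name_table[name] = [match]
        cid_table[cid] = [match]
        smiles_table[std.smiles] = [match]
        smiles_table.setdefault(clean_smiles, [match])

        # true log BB from a two-component normal mixture concentrated on
        # [-2, 2], populating both permeability classes
        center = 0.0 if rng.random() < 0.5 else -1.2
        true_logbb = float(rng.normal(center, 0.5))
        true_label = BBB_PLUS if true_logbb >= cfg.label_threshold else BBB_MINUS

        n_rec = int(min(max(1, rng.poisson(cfg.source_mean_records)), cfg.source_max_records))
        numeric_values: list[float] = []
        labels: list[tuple[str, float | None]] = []
        records = []
        for j in range(n_rec):
            is_numeric = bool(rng.random() < cfg.numeric_record_rate)
            rec: dict = {"name": name, "smiles": clean_smiles, "cid": cid,
                         "logBB": None, "label": None, "threshold": None}
            if is_numeric:
                value = true_logbb + float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else true_logbb
                rec["logBB"] = value
                numeric_values.append(value)
            else:
                label = true_label
                if rng.random() < cfg.conflict_rate:
                    label = BBB_MINUS if label == BBB_PLUS else BBB_PLUS
                    corruptions.append({"molecule": name, "record": j, "kind": "label_flip"})
                threshold = cfg.label_threshold if rng.random() < cfg.threshold_report_rate else None
                rec["label"] = label
                rec["threshold"] = threshold
                labels.append((label, threshold))
            # identity-field omission (mutually exclusive patterns)
            u = rng.random()
            if u < cfg.name_only_rate:
                rec["smiles"] = None
                rec["cid"] = None
                corruptions.append({"molecule": name, "record": j, "kind": "name_only"})
            elif u < cfg.name_only_rate + cfg.cid_only_rate:
                rec["smiles"] = None
                rec["name"] = None
                corruptions.append({"molecule": name, "record": j, "kind": "cid_only"})
            elif rec["smiles"] is not None:
                smi = rec["smiles"]
                if rng.random() < cfg.charge_rate:
                    variant = _charge_variant(smi)
                    if variant is not None:
                        smi = variant
                        corruptions.append({"molecule": name, "record": j, "kind": "charge_variant"})
                elif rng.random() < cfg.salt_rate:
                    smi = smi + ".Cl" if "[" not in smi else smi + ".[Na+]"
                    # appended fragment must not be the chosen parent;
                    # HCl/NaCl fragments are stripped as salts
                    corruptions.append({"molecule": name, "record": j, "kind": "salt_appended"})
                if rng.random() < cfg.whitespace_rate:
                    pos = int(rng.integers(0, len(smi) + 1))
                    smi = smi[:pos] + " " + smi[pos:]
                    corruptions.append({"molecule": name, "record": j, "kind": "whitespace"})
                rec["smiles"] = smi
            records.append(rec)

        if rng.random() < cfg.outlier_rate:
            value = -9.0 - float(rng.uniform(0.0, 3.0))
            records.append({"name": name, "smiles": clean_smiles, "cid": cid,
                            "logBB": value, "label": None, "threshold": None})
            numeric_values.append(value)
            corruptions.append({"molecule": name, "record": len(records) - 1, "kind": "outlier"})

        # expected consensus, by literal application of the rules
        surviving = [v for v in numeric_values if v > -9.0]
        expected_numeric: dict | None = None
        numeric_discard = None
        if numeric_values and not surviving:
            numeric_discard = "all_values_outliers"
        elif surviving:
            if max(surviving) - min(surviving) > 1.0:
                numeric_discard = "spread_gt_1"
            else:
                graded = oracle_group(surviving)
                if graded is None:
                    numeric_discard = "modal_tie"
                else:
                    expected_numeric = {"group": graded[0], "logbb": graded[1]}
        expected_cat = _oracle_categorical(
            labels,
            expected_numeric["logbb"] if expected_numeric else None,
            cfg.label_threshold,
        )

        for j, rec in enumerate(records):
            source_id = f"S{j + 1:02d}"
            source_rows.setdefault(source_id, []).append(rec)

        molecules.append({
            "name": name,
            "smiles_clean": clean_smiles,
            "smiles_std": std.smiles,
            "inchi": std.inchi,
            "cid": cid,
            "logbb_true": true_logbb,
            "label_true": true_label,
            "numeric_values": numeric_values,
            "labels": [{"label": lab, "threshold": t} for lab, t in labels],
            "n_records": len(records),
            "expected_numeric": expected_numeric,
            "numeric_discard_reason": numeric_discard,
            "expected_categorical": (
                {"group": expected_cat[0], "label": expected_cat[1]}
                if expected_cat else None
            ),
        })

    columns = ["name", "smiles", "cid", "logBB", "label", "threshold"]
    sources = {
        sid: pd.DataFrame(rows, columns=columns)
        for sid, rows in source_rows.items()
    }
    truth = {
        "config": asdict(cfg),
        "molecules": molecules,
        "corruptions": corruptions,
    }
    resolver = OfflineTableResolver(names=name_table, cids=cid_table, smiles=smiles_table)
    return SyntheticDataset(config=cfg, sources=sources, truth=truth, resolver=resolver)


@dataclass
class RecoveryReport:
    """End-to-end recovery fractions against generator truth."""

    n_molecules: int
    identity_recovery: float
    numeric_group_recovery: float | None
    value_recovery: float | None
    categorical_group_recovery: float | None
    label_recovery: float | None
    unexpected_keys: int

    def to_dict(self) -> dict:
        return asdict(self)


def score_recovery(
    numeric_records,
    categorical_records,
    truth: dict,
    value_tol: float = 0.05,
) -> RecoveryReport:
    """Compare curated output with the generator's expected consensus.

    Fractions are over the molecules for which truth expects a record in
    the relevant track; ``None`` when no molecule qualifies. Output keys
    that match no truth molecule are counted, not fatal.
    """
    numeric_by_key = {r.key: r for r in numeric_records}
    cat_by_key = {r.key: r for r in categorical_records}
    truth_keys = {m["inchi"] for m in truth["molecules"]}

    id_ok = 0
    grp_hits, grp_total = 0, 0
    val_hits, val_total = 0, 0
    cgrp_hits, cgrp_total = 0, 0
    lab_hits, lab_total = 0, 0
    for m in truth["molecules"]:
        key = m["inchi"]
        expect_any = m["expected_numeric"] is not None or m["expected_categorical"] is not None
        present = key in numeric_by_key or key in cat_by_key
        if expect_any == present:
            id_ok += 1
        if m["expected_numeric"] is not None:
            grp_total += 1
            val_total += 1
            rec = numeric_by_key.get(key)
            if rec is not None and rec.group == m["expected_numeric"]["group"]:
                grp_hits += 1
            if rec is not None and abs(rec.logbb - m["expected_numeric"]["logbb"]) <= value_tol:
                val_hits += 1
        if m["expected_categorical"] is not None:
            cgrp_total += 1
            lab_total += 1
            rec = cat_by_key.get(key)
            if rec is not None and rec.group == m["expected_categorical"]["group"]:
                cgrp_hits += 1
            if rec is not None and rec.label == m["expected_categorical"]["label"]:
                lab_hits += 1
    unexpected = len((set(numeric_by_key) | set(cat_by_key)) - truth_keys)
    n = len(truth["molecules"])
    return RecoveryReport(
        n_molecules=n,
        identity_recovery=id_ok / n if n else 1.0,
        numeric_group_recovery=grp_hits / grp_total if grp_total else None,
        value_recovery=val_hits / val_total if val_total else None,
        categorical_group_recovery=cgrp_hits / cgrp_total if cgrp_total else None,
        label_recovery=lab_hits / lab_total if lab_total else None,
        unexpected_keys=unexpected,
    )
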