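"""Technical-validation analytics over curated datasets.

Three families of checks:

* parse validity — every curated SMILES is re-parsed with an *independent*
  second parser (OpenBabel by default, i.e. a different codebase than the
  RDKit used for cleaning);
* redundancy/multiplicity — cross-tabulations of reliability group versus
  the number of source values / unique values (numeric track) and source
  labels / unique labels (categorical track);
* distribution summaries — the log BB histogram and per-class
  physicochemical summaries, plus recounts over a released curated
  dataset for external validation.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import CuratedCategoricalRecord, CuratedNumericRecord
from .descriptors import Ro5Profile, class_fractions, ro5_profile
from .records import BBB_MINUS, BBB_PLUS, CuratedRow, normalize_label


def _openbabel_valid(smiles_list: list[str]) -> list[bool]:
    """Batch-validate SMILES with the OpenBabel CLI.

    Each entry is tagged with its index; OpenBabel is run with ``-e`` so it
    continues past invalid entries, and the surviving tags identify which
    inputs parsed.
    """
    if shutil.which("obabel") is None:
        raise RuntimeError(
            "OpenBabel ('obabel') not found on PATH; it provides the "
            "independent second-parser check"
        )
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.smi"
        out = Path(tmp) / "out.smi"
        inp.write_text(
            "".join(f"{smi} idx{i}\n" for i, smi in enumerate(smiles_list)),
            encoding="utf-8",
        )
        subprocess.run(
            ["obabel", str(inp), "-osmi", "-O", str(out), "-e"],
            capture_output=True,
            check=False,
        )
        ok = set()
        if out.exists():
            for line in out.read_text(encoding="utf-8").splitlines():
                parts = line.split("\t")
                if len(parts) >= 2 and parts[-1].startswith("idx"):
                    ok.add(int(parts[-1][3:]))
    return [i in ok for i in range(len(smiles_list))]


def _rdkit_valid(smiles_list: list[str]) -> list[bool]:
    from rdkit import Chem

    return [Chem.MolFromSmiles(s) is not None for s in smiles_list]


def validate_parse(
    rows: Sequence[CuratedRow], parser: str = "openbabel"
) -> tuple[float | None, list[CuratedRow]]:
    """Fraction of curated SMILES accepted by the second parser + failures.

    ``parser`` may be ``openbabel`` (default, independent of the cleaning
    toolkit) or ``rdkit`` (same toolkit — a self-check only). Empty input
    returns ``(None, [])``.
    """
    if not rows:
        return None, []
    smiles = [r.smiles for r in rows]
    if parser == "openbabel":
        valid = _openbabel_valid(smiles)
    elif parser == "rdkit":
        valid = _rdkit_valid(smiles)
    else:
        raise ValueError(f"unknown parser {parser!r}")
    failures = [r for r, ok in zip(rows, valid) if not ok]
    return sum(valid) / len(valid), failures


GROUPS = ["A", "B", "C", "D"]


def _crosstab(pairs: list[tuple[str, int]]) -> pd.DataFrame:
    """Group × multiplicity count table (rows = multiplicity)."""
    if not pairs:
        return pd.DataFrame(columns=GROUPS, dtype=int)
    frame = pd.DataFrame(pairs, columns=["group", "multiplicity"])
    tab = pd.crosstab(frame["multiplicity"], frame["group"])
    for g in GROUPS:
        if g not in tab.columns:
            tab[g] = 0
    tab = tab[GROUPS]
    tab.index.name = "multiplicity"
    return tab


def multiplicity_tables(
    numeric: Sequence[CuratedNumericRecord],
    categorical: Sequence[CuratedCategoricalRecord],
) -> dict[str, pd.DataFrame]:
    """Four group × multiplicity tables.

    Keys: ``numeric_source`` (number of source log BB values),
    ``numeric_unique`` (unique values), ``categorical_source`` (source
    labels), ``categorical_unique`` (unique labels). Each table's counts
    sum to the corresponding dataset size.
    """
    return {
        "numeric_source": _crosstab([(r.group, r.n_values) for r in numeric]),
        "numeric_unique": _crosstab([(r.group, r.n_unique) for r in numeric]),
        "categorical_source": _crosstab([(r.group, r.n_labels) for r in categorical]),
        "categorical_unique": _crosstab(
            [(r.group, r.n_unique_labels) for r in categorical]
        ),
    }


def summarize_distributions(
    numeric: Sequence[CuratedNumericRecord],
    profiles: Sequence[tuple[Ro5Profile, str]] = (),
    bin_width: float = 0.25,
    bin_range: tuple[float, float] = (-3.0, 2.0),
) -> dict:
    """log BB histogram and per-class physicochemical summaries.

    The histogram uses the configured equal-width bins over ``bin_range``
    plus open-ended underflow/overflow bins, so counts always sum to the
    dataset size. Returns a JSON-serializable dict.
    """
    values = np.array([r.logbb for r in numeric], dtype=float)
    lo, hi = bin_range
    inner = np.arange(lo, hi + bin_width / 2, bin_width)
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    counts, _ = np.histogram(values, bins=edges)
    hist = {
        "bin_edges": [None] + list(np.round(inner, 6)) + [None],
        "counts": counts.tolist(),
        "bin_width": bin_width,
        "range": list(bin_range),
    }
    frac_in = (
        float(np.mean((values >= -2.0) & (values <= 2.0))) if len(values) else None
    )

    summaries: dict[str, dict] = {}
    by_label: dict[str, list[Ro5Profile]] = {}
    for profile, label in profiles:
        by_label.setdefault(label, []).append(profile)
    for label, members in by_label.items():
        summaries[label] = {}
        for attr in ("mw", "hbd", "hba", "logp"):
            arr = np.array([getattr(p, attr) for p in members], dtype=float)
            summaries[label][attr] = {
                "mean": float(np.mean(arr)),
                "median": float(np.median(arr)),
                "min": float(np.min(arr)),
                "max": float(np.max(arr)),
            }
    return {
        "n_numeric": len(values),
        "logbb_histogram": hist,
        "fraction_logbb_in_minus2_2": frac_in,
        "class_summaries": summaries,
        "ro5_fractions": class_fractions(profiles) if profiles else {},
    }


@dataclass
class QCReport:
    """Aggregated technical-validation report, serializable to JSON."""

    parse_valid_fraction: float | None
    parse_failures: list[str]
    multiplicity: dict[str, pd.DataFrame]
    distributions: dict
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parse_valid_fraction": self.parse_valid_fraction,
            "parse_failures": self.parse_failures,
            "multiplicity": {
                name: {
                    "multiplicity": tab.index.tolist(),
                    **{g: tab[g].tolist() for g in tab.columns},
                }
                for name, tab in self.multiplicity.items()
            },
            "distributions": self.distributions,
            "metadata": self.metadata,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2), encoding="utf-8"
        )


def qc_report(
    rows: Sequence[CuratedRow],
    numeric: Sequence[CuratedNumericRecord],
    categorical: Sequence[CuratedCategoricalRecord],
    profiles: Sequence[tuple[Ro5Profile, str]] = (),
    parser: str = "openbabel",
) -> QCReport:
    """Run the full validation battery over a curated dataset."""
    fraction, failures = validate_parse(rows, parser=parser)
    return QCReport(
        parse_valid_fraction=fraction,
        parse_failures=[r.smiles for r in failures],
        multiplicity=multiplicity_tables(numeric, categorical),
        distributions=summarize_distributions(numeric, profiles),
        metadata={"second_parser": parser, "histogram_bins": "0.25 over [-3, 2]"},
    )


def _find_column(frame: pd.DataFrame, candidates: list[str]) -> str | None:
    lowered = {c.lower().replace(" ", "").replace("_", ""): c for c in frame.columns}
    for cand in candidates:
        key = cand.lower().replace(" ", "").replace("_", "")
        if key in lowered:
            return lowered[key]
    return None


def recount_released(
    numeric: pd.DataFrame, categorical: pd.DataFrame
) -> dict:
    """Dataset-level recounts over a released curated dataset.

    Accepts the numeric and categorical tables (this package's output
    schema, or the released tab-separated layout — column names are
    matched loosely). Computes row counts, BBB+/BBB- class counts,
    per-group counts for both tracks, and the fraction of BBB+ molecules
    with molecular weight under 500 Da. Molecular weight is taken from an
    ``MW`` column when present, otherwise computed from the SMILES.
    """
    out: dict = {
        "numeric_rows": int(len(numeric)),
        "categorical_rows": int(len(categorical)),
    }
    ngroup = _find_column(numeric, ["group"])
    cgroup = _find_column(categorical, ["group"])
    if ngroup:
        counts = numeric[ngroup].astype(str).str.strip().value_counts()
        out["numeric_groups"] = {g: int(counts.get(g, 0)) for g in GROUPS}
    if cgroup:
        counts = categorical[cgroup].astype(str).str.strip().value_counts()
        out["categorical_groups"] = {g: int(counts.get(g, 0)) for g in GROUPS}

    label_col = _find_column(categorical, ["BBB+/BBB-", "label"])
    if label_col is None:
        raise ValueError("categorical table lacks a label column")
    labels = categorical[label_col].map(normalize_label)
    out["n_bbb_plus"] = int((labels == BBB_PLUS).sum())
    out["n_bbb_minus"] = int((labels == BBB_MINUS).sum())

    mw_col = _find_column(categorical, ["MW", "MolWt", "molecular weight"])
    if mw_col is not None:
        mw = pd.to_numeric(categorical[mw_col], errors="coerce")
    else:
        smiles_col = _find_column(categorical, ["SMILES"])
        if smiles_col is None:
            raise ValueError("categorical table lacks SMILES and MW columns")
        from rdkit import Chem
        from rdkit.Chem import Descriptors

        def _mw(smi):
            m = Chem.MolFromSmiles(str(smi))
            return Descriptors.MolWt(m) if m is not None else math.nan

        mw = categorical[smiles_col].map(_mw)
    plus_mw = mw[labels == BBB_PLUS].dropna()
    out["bbb_plus_mw_lt500_pct"] = (
        float(100.0 * (plus_mw < 500.0).mean()) if len(plus_mw) else None
    )
    minus_mw = mw[labels == BBB_MINUS].dropna()
    out["bbb_minus_mw_gt500_pct"] = (
        float(100.0 * (minus_mw > 500.0).mean()) if len(minus_mw) else None
    )
    return out


def plot_logbb_histogram(distributions: dict, path: str | Path) -> None:
    """Render the log BB histogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = distributions["logbb_histogram"]
    inner_counts = hist["counts"][1:-1]
    edges = [e for e in hist["bin_edges"] if e is not None]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], inner_counts, width=hist["bin_width"], align="edge")
    ax.set_xlabel("log BB")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
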