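"""Molecular descriptor extension and Rule-of-5 profiling.

Curated records are extended with a full block of 2D descriptors so the
dataset can feed predictive models without further cheminformatics
preprocessing. The descriptor backend is pluggable:

* :class:`RDKitDescriptorProvider` (default) — RDKit's complete 2D
  descriptor list (about 210 columns);
* :class:`MordredDescriptorProvider` — the mordred 2D set (1613 columns
  at the pinned version), used when the optional ``mordred`` package is
  installed.

The Rule-of-5 profile follows Lipinski's original counting convention:
HBD = number of O-H and N-H bonds, HBA = number of N and O atoms. The
octanol/water partition coefficient is estimated with the Crippen
atom-contribution method; the estimator name is recorded in the block
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .standardize import StandardizedMolecule

#: Column count of the mordred 2D set at the pinned version (1.1.1).
MORDRED_2D_EXPECTED = 1613


class DescriptorProvider(Protocol):
    name: str

    def descriptor_names(self) -> list[str]: ...

    def compute(self, mol: Chem.Mol) -> list[float]: ...


class RDKitDescriptorProvider:
    """Full RDKit 2D descriptor list, in its canonical registration order."""

    name = "rdkit-2d"

    def __init__(self):
        self._desc = list(Descriptors._descList)

    def descriptor_names(self) -> list[str]:
        return [name for name, _ in self._desc]

    def compute(self, mol: Chem.Mol) -> list[float]:
        values = []
        for _, fn in self._desc:
            try:
                v = fn(mol)
                values.append(float(v) if v is not None else math.nan)
            except Exception:
                values.append(math.nan)
        return values


class MordredDescriptorProvider:
    """mordred 2D descriptor set (optional dependency).

    Raises ``ImportError`` with an installation hint when mordred is not
    available; the batch API treats that as fatal by contract.
    """

    name = "mordred-2d"

    def __init__(self):
        try:
            from mordred import Calculator, descriptors as mordred_descriptors
        except ImportError as err:  # pragma: no cover - environment dependent
            raise ImportError(
                "the mordred descriptor backend requires the 'mordred' package; "
                "install with: pip install mordred"
            ) from err
        self._calc = Calculator(mordred_descriptors, ignore_3D=True)

    def descriptor_names(self) -> list[str]:
        return [str(d) for d in self._calc.descriptors]

    def compute(self, mol: Chem.Mol) -> list[float]:
        out = []
        for v in self._calc(mol):
            try:
                out.append(float(v))
            except (TypeError, ValueError):
                out.append(math.nan)
        return out


@dataclass
class DescriptorBlock:
    """Descriptor matrix: one row per molecule key, one column per name."""

    keys: list[str]
    names: list[str]
    values: np.ndarray
    provider: str = ""
    failed_keys: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.keys, columns=self.names)


def compute_descriptors(
    mols: Sequence[StandardizedMolecule],
    provider: DescriptorProvider | None = None,
) -> DescriptorBlock:
    """Compute the full descriptor block for accepted molecules.

    Per-molecule failures produce a row of missing values and are listed
    in ``failed_keys``; they never abort the batch. Column order is the
    provider's deterministic order.
    """
    provider = provider or RDKitDescriptorProvider()
    names = provider.descriptor_names()
    if len(set(names)) != len(names):
        raise ValueError("descriptor provider returned duplicate names")
    keys, rows, failed = [], [], []
    for m in mols:
        if not m.accepted:
            raise ValueError("descriptors are only computed for accepted molecules")
        keys.append(m.inchi)
        rdmol = Chem.MolFromSmiles(m.smiles)
        if rdmol is None:
            rows.append([math.nan] * len(names))
            failed.append(m.inchi)
            continue
        try:
            rows.append(provider.compute(rdmol))
        except Exception:
            rows.append([math.nan] * len(names))
            failed.append(m.inchi)
    values = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(names)), dtype=float)
    )
    return DescriptorBlock(
        keys=keys, names=names, values=values, provider=provider.name, failed_keys=failed
    )


@dataclass
class Ro5Profile:
    """Lipinski Rule-of-5 quantities and pass flags for one molecule.

    mw in Daltons; hbd/hba are counts; logp is the estimated octanol/water
    partition coefficient.
    """

    mw: float
    hbd: int
    hba: int
    logp: float

    @property
    def passes(self) -> dict[str, bool]:
        return {
            "mw": self.mw < 500.0,
            "hbd": self.hbd < 5,
            "hba": self.hba < 10,
            "logp": self.logp < 5.0,
        }


def ro5_profile(mol: StandardizedMolecule | str) -> Ro5Profile:
    """Rule-of-5 profile of an accepted molecule (or a SMILES string)."""
    smiles = mol if isinstance(mol, str) else mol.smiles
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return Ro5Profile(
        mw=Descriptors.MolWt(rdmol),
        hbd=Lipinski.NHOHCount(rdmol),
        hba=Lipinski.NOCount(rdmol),
        logp=Crippen.MolLogP(rdmol),
    )


def class_fractions(
    profiles: Sequence[tuple[Ro5Profile, str]]
) -> dict[str, dict[str, float | None]]:
    """Per-label fraction of molecules satisfying each Rule-of-5 criterion.

    Empty classes report ``None`` for every rule.
    """
    by_label: dict[str, list[Ro5Profile]] = {}
    for profile, label in profiles:
        by_label.setdefault(label, []).append(profile)
    out: dict[str, dict[str, float | None]] = {}
    for label, members in by_label.items():
        n = len(members)
        out[label] = {
            rule: (sum(1 for p in members if p.passes[rule]) / n) if n else None
            for rule in ("mw", "hbd", "hba", "logp")
        }
    return out
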