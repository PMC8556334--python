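"""Structure repair, desalting, neutralization, filtering and canonicalization.

The pipeline takes a raw SMILES string as transcribed from a source table
and produces a :class:`StandardizedMolecule` carrying a canonical
(isomeric, when stereochemistry is annotated) SMILES, a standard InChI and
a set of flags describing what was changed. Order of operations:

1. text repair (whitespace, typographic minus variants),
2. parse,
3. largest-organic-fragment selection (salt/solvent stripping),
4. functional-group normalization and charge neutralization,
5. element filter (metals, heavy atoms, boron clusters),
6. canonical SMILES + InChI generation.

The element filter runs *after* desalting so that a metal counterion does
not doom an otherwise acceptable organic parent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

# rejection reasons
INVALID_SMILES = "invalid_smiles"
METAL_OR_HEAVY = "metal_or_heavy_atom"
BORON_EXCESS = "boron_excess"
UNRESOLVABLE = "unresolvable"

# flags
FLAG_WHITESPACE = "whitespace_fixed"
FLAG_NEUTRALIZED = "charge_neutralized"
FLAG_SALT_STRIPPED = "salt_stripped"
FLAG_REVALENCED = "revalenced"

#: Metals with atomic number <= 20. Everything above 20 is excluded by the
#: atomic-number rule regardless of metallicity.
_LIGHT_METALS = frozenset({3, 4, 11, 12, 13, 19, 20})

_DASH_VARIANTS = re.compile("[‐‑‒–—―−]")
_WHITESPACE = re.compile(r"\s+")


@dataclass
class ElementFilterConfig:
    """Predicate configuration for the element filter.

    The default keeps the strict literal rule: any atom with Z > ``max_z``
    or any metal atom (including light metals such as Li, Na, Mg, K) causes
    rejection, and more than ``max_boron`` boron atoms rejects borane
    clusters that cannot be depicted reliably. The Z > 20 default excludes
    Br- and I-containing compounds; relax ``max_z`` (e.g. to 53) to keep
    halogenated drugs.
    """

    max_z: int = 20
    max_boron: int = 7
    exclude_light_metals: bool = True


@dataclass
class StandardizedMolecule:
    """A cleaned structure, or a rejection with its reason."""

    smiles: str = ""
    inchi: str = ""
    cid: int | None = None
    flags: set[str] = field(default_factory=set)
    rejected_reason: str | None = None
    comment: str = ""

    @property
    def accepted(self) -> bool:
        return self.rejected_reason is None


def fix_smiles_text(raw: str) -> str:
    """Remove whitespace/line breaks and normalize dash variants to ``-``.

    Sources transcribed from PDFs frequently contain interior spaces, line
    breaks, and en-dashes in place of the minus sign of charge annotations
    such as ``[O-]``.
    """
    if raw is None or str(raw) == "":
        raise ValueError("empty SMILES text")
    text = _WHITESPACE.sub("", str(raw))
    text = _DASH_VARIANTS.sub("-", text)
    if not text:
        raise ValueError("SMILES text contains only whitespace")
    return text


def parse_or_reject(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES into an RDKit molecule; ``None`` means invalid."""
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


def desalt_neutralize(mol: Chem.Mol) -> tuple[Chem.Mol | None, set[str], str]:
    """Strip salts/solvents, normalize groups and neutralize charges.

    Returns ``(molecule, flags, comment)``. The molecule is ``None`` when
    no organic parent fragment exists (all-inorganic input). A net formal
    charge that cannot be removed (e.g. quaternary ammonium) is kept and
    noted in the comment rather than rejected.
    """
    flags: set[str] = set()
    comment = ""
    n_frags = len(Chem.GetMolFrags(mol))
    parent = _fragment_chooser.choose(mol)
    if n_frags > 1:
        flags.add(FLAG_SALT_STRIPPED)
    if parent is None or parent.GetNumAtoms() == 0:
        return None, flags, comment
    if not any(a.GetAtomicNum() == 6 for a in parent.GetAtoms()):
        return None, flags, comment

    before = Chem.MolToSmiles(parent)
    normalized = rdMolStandardize.Normalize(parent)
    if Chem.MolToSmiles(normalized) != before:
        flags.add(FLAG_REVALENCED)

    charge_before = Chem.GetFormalCharge(normalized)
    had_charged_atom = any(a.GetFormalCharge() != 0 for a in normalized.GetAtoms())
    neutral = _uncharger.uncharge(normalized)
    still_charged = any(a.GetFormalCharge() != 0 for a in neutral.GetAtoms())
    if had_charged_atom and not still_charged:
        flags.add(FLAG_NEUTRALIZED)
    elif had_charged_atom and still_charged:
        net = Chem.GetFormalCharge(neutral)
        comment = f"charge could not be fully neutralized (net {net:+d})"
        if abs(net) < abs(charge_before):
            flags.add(FLAG_NEUTRALIZED)
    Chem.SanitizeMol(neutral)
    return neutral, flags, comment


def element_filter(mol: Chem.Mol, config: ElementFilterConfig | None = None) -> str | None:
    """Return a rejection reason, or ``None`` to keep the molecule."""
    cfg = config or ElementFilterConfig()
    n_boron = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z > cfg.max_z:
            return METAL_OR_HEAVY
        if cfg.exclude_light_metals and z in _LIGHT_METALS:
            return METAL_OR_HEAVY
        if z == 5:
            n_boron += 1
    if n_boron > cfg.max_boron:
        return BORON_EXCESS
    return None


def canonicalize(mol: Chem.Mol, prefer_isomeric: bool = True) -> StandardizedMolecule:
    """Produce the canonical SMILES and standard InChI for a kept molecule."""
    smiles = Chem.MolToSmiles(mol, isomericSmiles=prefer_isomeric)
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        return StandardizedMolecule(rejected_reason=UNRESOLVABLE)
    return StandardizedMolecule(smiles=smiles, inchi=inchi)


def standardize_smiles(
    raw: str,
    config: ElementFilterConfig | None = None,
    prefer_isomeric: bool = True,
) -> StandardizedMolecule:
    """Run the full cleaning pipeline on one raw SMILES string.

    Never raises on bad structures: every failure mode is returned as a
    :class:`StandardizedMolecule` with ``rejected_reason`` set.
    """
    try:
        text = fix_smiles_text(raw)
    except ValueError:
        return StandardizedMolecule(rejected_reason=INVALID_SMILES)
    flags: set[str] = set()
    if text != str(raw):
        flags.add(FLAG_WHITESPACE)

    mol = parse_or_reject(text)
    if mol is None:
        return StandardizedMolecule(rejected_reason=INVALID_SMILES)

    mol, frag_flags, comment = desalt_neutralize(mol)
    flags |= frag_flags
    if mol is None:
        return StandardizedMolecule(flags=flags, rejected_reason=UNRESOLVABLE)

    reason = element_filter(mol, config)
    if reason is not None:
        return StandardizedMolecule(flags=flags, rejected_reason=reason)

    out = canonicalize(mol, prefer_isomeric=prefer_isomeric)
    if not out.accepted:
        return replace(out, flags=flags)
    out.flags = flags
    out.comment = comment
    return out
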