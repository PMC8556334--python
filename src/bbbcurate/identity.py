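"""Compound identity resolution and the molecular merge key.

Records arrive with any subset of {name, SMILES, CID}; a *resolver*
(an abstraction over a compound registry such as PubChem) fills the
missing fields. Three implementations are provided:

* :class:`OfflineTableResolver` — a table-backed stub, used in tests and
  offline runs;
* :class:`CachedResolver` — wraps another resolver with a persistent
  tab-separated on-disk cache so repeated runs are reproducible and make
  no repeated network calls;
* :class:`PubChemResolver` — a thin PUG-REST client over stdlib urllib
  (name→CID, CID→properties, SMILES→CID).

The merge key for deduplication is the standard InChI of the standardized
structure: resonance-variant SMILES of one molecule collapse to one key,
while enantiomers with explicit stereocentres stay distinct.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol

from .records import SourceRecord
from .standardize import StandardizedMolecule

NOTE_UNRESOLVED = "unresolved"
NOTE_AMBIGUOUS = "ambiguous: first registry match used"


@dataclass
class Match:
    """One registry hit for a query."""

    cid: int | None = None
    smiles: str | None = None
    name: str | None = None
    iupac_name: str | None = None


@dataclass
class ResolverResult:
    query: str
    matches: list[Match] = field(default_factory=list)
    chosen_index: int = 0

    @property
    def ambiguous(self) -> bool:
        return len(self.matches) > 1

    @property
    def chosen(self) -> Match | None:
        if not self.matches:
            return None
        return self.matches[self.chosen_index]


class Resolver(Protocol):
    """Registry lookup interface; every method returns all matches in
    registry order (empty list = not found)."""

    def by_name(self, name: str) -> list[Match]: ...

    def by_cid(self, cid: int) -> list[Match]: ...

    def by_smiles(self, smiles: str) -> list[Match]: ...


class OfflineTableResolver:
    """Stub resolver backed by in-memory tables.

    ``names``/``cids``/``smiles`` map query → list of :class:`Match`.
    Lookup counts are recorded so tests can assert on traffic.
    """

    def __init__(
        self,
        names: dict[str, list[Match]] | None = None,
        cids: dict[int, list[Match]] | None = None,
        smiles: dict[str, list[Match]] | None = None,
    ):
        self.names = names or {}
        self.cids = cids or {}
        self.smiles = smiles or {}
        self.calls = 0

    def by_name(self, name: str) -> list[Match]:
        self.calls += 1
        return list(self.names.get(name, []))

    def by_cid(self, cid: int) -> list[Match]:
        self.calls += 1
        return list(self.cids.get(int(cid), []))

    def by_smiles(self, smiles: str) -> list[Match]:
        self.calls += 1
        return list(self.smiles.get(smiles, []))


class CachedResolver:
    """Persistent cache in front of another resolver.

    The cache file is tab-separated: ``query_type<TAB>query<TAB>json``.
    With a warm cache no call reaches the wrapped resolver, so a second
    run is offline-reproducible.
    """

    def __init__(self, inner: Resolver, path: str | Path):
        self.inner = inner
        self.path = Path(path)
        self._cache: dict[tuple[str, str], list[Match]] = {}
        if self.path.exists():
            for line in self.path.read_text(encoding="utf-8").splitlines():
                if not line.strip():
                    continue
                qtype, query, payload = line.split("\t", 2)
                self._cache[(qtype, query)] = [
                    Match(**m) for m in json.loads(payload)
                ]

    def _lookup(self, qtype: str, query: str, fetch) -> list[Match]:
        key = (qtype, query)
        if key in self._cache:
            return list(self._cache[key])
        matches = fetch()
        self._cache[key] = matches
        with self.path.open("a", encoding="utf-8") as fh:
            payload = json.dumps([m.__dict__ for m in matches])
            fh.write(f"{qtype}\t{query}\t{payload}\n")
        return list(matches)

    def by_name(self, name: str) -> list[Match]:
        return self._lookup("name", name, lambda: self.inner.by_name(name))

    def by_cid(self, cid: int) -> list[Match]:
        return self._lookup("cid", str(int(cid)), lambda: self.inner.by_cid(cid))

    def by_smiles(self, smiles: str) -> list[Match]:
        return self._lookup("smiles", smiles, lambda: self.inner.by_smiles(smiles))


class PubChemResolver:
    """Minimal PUG-REST client (network access required).

    Intended for interactive curation runs; automated tests use
    :class:`OfflineTableResolver`. Transient failures are retried
    ``retries`` times with a fixed delay, then reported as "not found".
    """

    BASE = "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound"
    PROPS = "property/IsomericSMILES,CanonicalSMILES,IUPACName,Title"

    def __init__(self, retries: int = 2, delay_s: float = 0.3, timeout_s: float = 10.0):
        self.retries = retries
        self.delay_s = delay_s
        self.timeout_s = timeout_s

    def _get(self, url: str) -> dict | None:
        for attempt in range(self.retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout_s) as resp:
                    return json.loads(resp.read().decode("utf-8"))
            except urllib.error.HTTPError as err:
                if err.code == 404:
                    return None
                if attempt == self.retries:
                    return None
                time.sleep(self.delay_s)
            except (urllib.error.URLError, TimeoutError):
                if attempt == self.retries:
                    return None
                time.sleep(self.delay_s)
        return None

    def _props(self, namespace: str, query: str) -> list[Match]:
        quoted = urllib.parse.quote(query, safe="")
        data = self._get(f"{self.BASE}/{namespace}/{quoted}/{self.PROPS}/JSON")
        if not data:
            return []
        props = data.get("PropertyTable", {}).get("Properties", [])
        return [
            Match(
                cid=p.get("CID"),
                smiles=p.get("IsomericSMILES") or p.get("CanonicalSMILES"),
                name=p.get("Title"),
                iupac_name=p.get("IUPACName"),
            )
            for p in props
        ]

    def by_name(self, name: str) -> list[Match]:
        return self._props("name", name)

    def by_cid(self, cid: int) -> list[Match]:
        return self._props("cid", str(int(cid)))

    def by_smiles(self, smiles: str) -> list[Match]:
        return self._props("smiles", smiles)


def resolve_missing(record: SourceRecord, resolver: Resolver) -> SourceRecord:
    """Fill absent identity fields of a record from the registry.

    The first registry match is taken; when several matches exist an
    ambiguity note is attached. Resolver misses leave the record unchanged
    with an ``unresolved`` note. The input record is not mutated.
    """
    needs = record.smiles_raw is None or record.cid is None or record.compound_name is None
    if not needs:
        return record
    if record.smiles_raw is not None:
        matches = resolver.by_smiles(record.smiles_raw)
    elif record.cid is not None:
        matches = resolver.by_cid(record.cid)
    elif record.compound_name is not None:
        matches = resolver.by_name(record.compound_name)
    else:
        raise ValueError("record has no identity field")

    out = replace(record, notes=list(record.notes))
    if not matches:
        out.notes.append(NOTE_UNRESOLVED)
        return out
    chosen = matches[0]
    if len(matches) > 1:
        out.notes.append(NOTE_AMBIGUOUS)
    if out.compound_name is None and chosen.name is not None:
        out.compound_name = chosen.name
    if out.smiles_raw is None and chosen.smiles is not None:
        out.smiles_raw = chosen.smiles
    if out.cid is None and chosen.cid is not None:
        out.cid = chosen.cid
    return out


def make_key(mol: StandardizedMolecule) -> str:
    """Merge key of an accepted molecule: its standard InChI, byte-for-byte."""
    if not mol.accepted:
        raise ValueError("cannot key a rejected molecule")
    if not mol.inchi:
        raise ValueError("standardized molecule lacks an InChI")
    return mol.inchi


def update_cid(mol: StandardizedMolecule, resolver: Resolver) -> StandardizedMolecule:
    """Refresh the CID from the standardized SMILES.

    Standardization (desalting, neutralization) changes the structure, so
    the identifier attached to the raw record may point at the salt form;
    the registry is re-queried with the cleaned SMILES. Not found → CID
    absent, with a note in the comment.
    """
    matches = resolver.by_smiles(mol.smiles)
    out = replace(mol, flags=set(mol.flags))
    if matches and matches[0].cid is not None:
        out.cid = matches[0].cid
    else:
        out.cid = None
        note = "CID not found for standardized structure"
        out.comment = f"{out.comment}; {note}" if out.comment else note
    return out
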