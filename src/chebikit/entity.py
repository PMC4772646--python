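"""User-facing entity API.

A :class:`ChebiEntity` is constructed from an identifier of the form
``CHEBI:<n>`` (or bare digits) and exposes getters for every kind of data a
release holds about that compound.  ChEBI merges duplicate entries: a
deprecated (secondary) identifier is kept but linked to the primary entry
that absorbed it.  All getters here resolve through that merged group, so a
caller never has to know whether an identifier is primary or secondary:

* scalar fields (name, definition, formula, mass, ...) are read from the
  primary record, with chemical data falling back to the lowest-id group
  member holding a value;
* list fields (synonyms, cross-references, comments, origins, relations)
  are ordered, de-duplicated unions over the whole group — primary first,
  then secondaries in ascending id;
* ``get_id`` and ``get_parent_id`` alone reflect the record as requested,
  so deprecation remains detectable.

Entities share one lazily parsed :class:`~chebikit.parsers.ReleaseIndex`
per :class:`Release`; structures and literature references are streamed
from disk only when a getter needs them.
"""
from __future__ import annotations

import re
import tempfile
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional, Sequence, Union

from . import cache as _cache
from . import parsers as _parsers
from .cache import CacheConfig, ensure_file
from .exceptions import (
    CorruptChemicalDatumError,
    MalformedIdentifierError,
    OfflineCacheMissError,
    UndefinedChebiIdError,
)
from .parsers import ReleaseIndex, resolve_primary

_ID_PATTERN = re.compile(r"^\s*(?:CHEBI:)?(\d+)\s*$", re.IGNORECASE)


def parse_identifier(identifier: Union[str, int]) -> int:
    """Normalise ``'CHEBI:17234'``, ``'17234'`` or an int to the integer id."""
    if isinstance(identifier, int):
        if identifier < 1:
            raise MalformedIdentifierError(identifier)
        return identifier
    if not isinstance(identifier, str):
        raise MalformedIdentifierError(identifier)
    match = _ID_PATTERN.match(identifier)
    if match is None:
        raise MalformedIdentifierError(identifier)
    value = int(match.group(1))
    if value < 1:
        raise MalformedIdentifierError(identifier)
    return value


def _accession(compound_id: int) -> str:
    return f"CHEBI:{compound_id}"


# --- returned value objects -------------------------------------------------

@dataclass(frozen=True)
class Name:
    name: str
    name_type: str
    source: str
    adapted: bool
    language: str


@dataclass(frozen=True)
class Relation:
    relation_type: str
    target_chebi_accession: str
    status: str


@dataclass(frozen=True)
class DatabaseAccession:
    accession_type: str
    accession_number: str
    source: str


@dataclass(frozen=True)
class Comment:
    created_on: Union[date, str, None]
    datatype: str
    text: str


@dataclass(frozen=True)
class CompoundOrigin:
    species_text: str
    species_accession: Optional[str]
    component_text: Optional[str]
    strain_text: Optional[str]
    source_type: Optional[str]
    source_accession: Optional[str]
    comments: Optional[str]


@dataclass(frozen=True)
class Reference:
    reference_id: str
    reference_db: str
    location_in_ref: Optional[str]
    reference_name: Optional[str]


def _truthy(text: str) -> bool:
    return str(text).strip().upper() in {"Y", "YES", "T", "TRUE", "1"}


class Release:
    """Handle to one flat-file release: resolves file paths and owns the
    shared, lazily built index.

    Exactly one of ``release_dir`` (a local directory of decompressed flat
    files, bypassing the cache entirely) or ``cache_config`` (the managed
    download cache) supplies the files.
    """

    def __init__(
        self,
        release_dir: Union[str, Path, None] = None,
        cache_config: Optional[CacheConfig] = None,
        *,
        strict: bool = False,
        swap_relation_direction: bool = False,
    ) -> None:
        if (release_dir is None) == (cache_config is None):
            raise ValueError("give exactly one of release_dir or cache_config")
        self.release_dir = Path(release_dir) if release_dir is not None else None
        self.cache_config = cache_config
        self.strict = strict
        self.swap_relation_direction = swap_relation_direction
        self._index: Optional[ReleaseIndex] = None
        self._mol_dir: Optional[Path] = None

    # -- file resolution ----------------------------------------------------

    def path_for(self, logical_name: str) -> Optional[Path]:
        """Local path of one logical file, fetching through the cache if
        this release is cache-backed.  None if the table is absent."""
        if self.release_dir is not None:
            path = self.release_dir / _cache.LOGICAL_FILES[logical_name]
            return path if path.exists() else None
        record = ensure_file(logical_name, self.cache_config)
        return record.local_path

    @property
    def index(self) -> ReleaseIndex:
        """The shared index, parsed on first access.  Only the nine TSV
        tables are read; structures and references stay on disk."""
        if self._index is None:
            paths = {}
            for logical in _cache.LOGICAL_FILES:
                if logical in ("structures", "reference"):
                    continue
                if self.release_dir is not None:
                    path = self.path_for(logical)
                    if path is not None:
                        paths[logical] = path
                else:
                    if logical == "compounds":
                        paths[logical] = self.path_for(logical)
                    else:
                        try:
                            paths[logical] = self.path_for(logical)
                        except (OfflineCacheMissError, _cache.FetchFailedError):
                            pass  # optional table absent upstream or offline
            self._index = _parsers.parse_release(
                paths,
                strict=self.strict,
                swap_relation_direction=self.swap_relation_direction,
            )
        return self._index

    def entity(self, identifier: Union[str, int]) -> "ChebiEntity":
        return ChebiEntity(identifier, release=self)

    def mol_cache_dir(self) -> Path:
        """Directory for materialised molfiles, reused per compound."""
        if self.cache_config is not None:
            path = Path(self.cache_config.cache_dir) / "mol"
        else:
            if self._mol_dir is None:
                self._mol_dir = Path(tempfile.mkdtemp(prefix="chebikit-mol-"))
            path = self._mol_dir
        path.mkdir(parents=True, exist_ok=True)
        return path


_default_release: Optional[Release] = None


def set_default_release(release: Optional[Release]) -> None:
    """Install the release used by ``ChebiEntity`` when none is passed."""
    global _default_release
    _default_release = release


def get_default_release() -> Release:
    """The process-wide default release; lazily created over the standard
    cache directory (``~/.chebikit``) on first use."""
    global _default_release
    if _default_release is None:
        _default_release = Release(
            cache_config=CacheConfig(cache_dir=Path.home() / ".chebikit")
        )
    return _default_release


class ChebiEntity:
    """One chemical entity, addressed by any identifier in its merged group."""

    def __init__(
        self,
        identifier: Union[str, int],
        release: Optional[Release] = None,
    ) -> None:
        self._release = release if release is not None else get_default_release()
        self.requested_id = parse_identifier(identifier)
        index = self._release.index
        if self.requested_id not in index.compounds:
            raise UndefinedChebiIdError(_accession(self.requested_id))
        self.primary_id = resolve_primary(self.requested_id, index)

    # -- internals ----------------------------------------------------------

    @property
    def _index(self) -> ReleaseIndex:
        return self._release.index

    @property
    def _group(self) -> list[int]:
        """Group member ids: primary first, then secondaries ascending."""
        members = self._index.group_of.get(self.primary_id, {self.primary_id})
        rest = sorted(m for m in members if m != self.primary_id)
        return [self.primary_id, *rest]

    def _primary_record(self) -> _parsers.CompoundRecord:
        return self._index.compounds[self.primary_id]

    def _requested_record(self) -> _parsers.CompoundRecord:
        return self._index.compounds[self.requested_id]

    def _group_union(self, per_compound: dict, key) -> list:
        """Ordered union over the group with first-wins de-duplication."""
        out = []
        seen = set()
        for member in self._group:
            for record in per_compound.get(member, []):
                k = key(record)
                if k in seen:
                    continue
                seen.add(k)
                out.append(record)
        return out

    def _chemical_data(self, datum_type: str) -> Optional[_parsers.ChemicalDatumRecord]:
        """Primary's record of this type, else the lowest-id member's."""
        for member in self._group:
            for record in self._index.chemical_data.get(member, []):
                if record.datum_type == datum_type:
                    return record
        return None

    def _numeric_datum(self, datum_type: str) -> Optional[float]:
        record = self._chemical_data(datum_type)
        if record is None:
            return None
        try:
            return float(record.value)
        except ValueError:
            raise CorruptChemicalDatumError(record.id, record.value) from None

    # -- identity -----------------------------------------------------------

    def get_id(self) -> str:
        """Accession of the identifier as requested (not the primary's)."""
        return _accession(self.requested_id)

    def get_parent_id(self) -> Optional[str]:
        """Accession of the requested record's parent, if it is secondary."""
        parent = self._requested_record().parent_id
        return None if parent is None else _accession(parent)

    # -- scalar fields of the primary record --------------------------------

    def get_name(self) -> Optional[str]:
        return self._primary_record().name

    def get_definition(self) -> Optional[str]:
        return self._primary_record().definition

    def get_status(self) -> str:
        return self._primary_record().status

    def get_source(self) -> str:
        return self._primary_record().source

    def get_created_by(self) -> Optional[str]:
        return self._primary_record().created_by

    def get_modified_on(self) -> Union[date, str, None]:
        return self._primary_record().modified_on

    def get_star(self) -> int:
        return self._primary_record().star

    # -- names --------------------------------------------------------------

    def get_names(self) -> list[Name]:
        """All name rows of the merged group, primary's first, duplicates by
        (name, type, language) removed keeping the first occurrence."""
        records = self._group_union(
            self._index.names, key=lambda r: (r.name, r.name_type, r.language)
        )
        return [
            Name(
                name=r.name,
                name_type=r.name_type,
                source=r.source,
                adapted=_truthy(r.adapted),
                language=r.language,
            )
            for r in records
        ]

    # -- chemical data -------------------------------------------------------

    def get_formula(self) -> Optional[str]:
        record = self._chemical_data("FORMULA")
        return None if record is None else record.value

    def get_formulae(self) -> list[tuple[str, str]]:
        """(formula, source) pairs over the whole group, in group order."""
        out = []
        for member in self._group:
            for record in self._index.chemical_data.get(member, []):
                if record.datum_type == "FORMULA":
                    out.append((record.value, record.source))
        return out

    def get_mass(self) -> Optional[float]:
        """Molecular mass in unified atomic mass units."""
        return self._numeric_datum("MASS")

    def get_monoisotopic_mass(self) -> Optional[float]:
        return self._numeric_datum("MONOISOTOPIC MASS")

    def get_charge(self) -> Optional[int]:
        """Formal charge in units of elementary charge; None (not 0) when
        no CHARGE row exists anywhere in the group."""
        value = self._numeric_datum("CHARGE")
        return None if value is None else int(value)

    # -- cross-references, comments, origins ---------------------------------

    def get_database_accessions(self) -> list[DatabaseAccession]:
        records = self._group_union(
            self._index.accessions,
            key=lambda r: (r.accession_type, r.accession_number, r.source),
        )
        return [
            DatabaseAccession(
                accession_type=r.accession_type,
                accession_number=r.accession_number,
                source=r.source,
            )
            for r in records
        ]

    def get_comments(self) -> list[Comment]:
        records = self._group_union(
            self._index.comments,
            key=lambda r: (r.created_on, r.datatype, r.text),
        )
        return [
            Comment(created_on=r.created_on, datatype=r.datatype, text=r.text)
            for r in records
        ]

    def get_compound_origins(self) -> list[CompoundOrigin]:
        records = self._group_union(
            self._index.origins,
            key=lambda r: (
                r.species_text, r.species_accession, r.component_text,
                r.strain_text, r.source_type, r.source_accession, r.comments,
            ),
        )
        return [
            CompoundOrigin(
                species_text=r.species_text,
                species_accession=r.species_accession,
                component_text=r.component_text,
                strain_text=r.strain_text,
                source_type=r.source_type,
                source_accession=r.source_accession,
                comments=r.comments,
            )
            for r in records
        ]

    # -- structures (streamed, never indexed) --------------------------------

    def get_inchi(self) -> Optional[str]:
        for member in self._group:
            inchi = self._index.inchis.get(member)
            if inchi is not None:
                return inchi
        return None

    def _stream_structure_for_group(
        self, wanted_type: str
    ) -> Optional[_parsers.StructureRecord]:
        path = self._release.path_for("structures")
        if path is None:
            return None
        for member in self._group:
            record = _parsers.stream_structure(member, wanted_type, path)
            if record is not None:
                return record
        return None

    def get_inchi_key(self) -> Optional[str]:
        record = self._stream_structure_for_group("InChIKey")
        return None if record is None else record.structure_text

    def get_smiles(self) -> Optional[str]:
        record = self._stream_structure_for_group("SMILES")
        return None if record is None else record.structure_text

    def get_mol(self) -> Optional[str]:
        """The group's default molfile text, verbatim (embedded newlines
        preserved); primary's structure preferred."""
        record = self._stream_structure_for_group("mol")
        return None if record is None else record.structure_text

    def get_mol_filename(self) -> Optional[str]:
        """Write the molfile to a managed file (reused per compound) and
        return its path; None when the group has no mol structure."""
        mol = self.get_mol()
        if mol is None:
            return None
        path = self._release.mol_cache_dir() / f"CHEBI_{self.primary_id}.mol"
        if not path.exists() or path.read_text(encoding="utf-8") != mol:
            path.write_text(mol, encoding="utf-8")
        return str(path)

    # -- literature references (streamed) ------------------------------------

    def get_references(self) -> list[Reference]:
        path = self._release.path_for("reference")
        if path is None:
            return []
        out = []
        seen = set()
        for member in self._group:
            for r in _parsers.stream_references(member, path):
                k = (r.reference_id, r.reference_db, r.location_in_ref, r.reference_name)
                if k in seen:
                    continue
                seen.add(k)
                out.append(
                    Reference(
                        reference_id=r.reference_id,
                        reference_db=r.reference_db,
                        location_in_ref=r.location_in_ref,
                        reference_name=r.reference_name,
                    )
                )
        return out

    # -- ontology relations ---------------------------------------------------

    def _relations(self, table: dict, target_side: str) -> list[Relation]:
        seen = set()
        out = []
        for member in self._group:
            for rel in table.get(member, []):
                target = rel.final_id if target_side == "final" else rel.init_id
                item = Relation(
                    relation_type=rel.relation_type,
                    target_chebi_accession=_accession(target),
                    status=rel.status,
                )
                if item in seen:
                    continue
                seen.add(item)
                out.append(item)
        out.sort(
            key=lambda r: (
                r.relation_type,
                int(r.target_chebi_accession.split(":")[1]),
                r.status,
            )
        )
        return out

    def get_outgoings(self) -> list[Relation]:
        """Relations originating at any member of the merged group, ordered
        by predicate then target id."""
        return self._relations(self._index.outgoing, "final")

    def get_incomings(self) -> list[Relation]:
        """Relations terminating at any member of the merged group."""
        return self._relations(self._index.incoming, "init")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ChebiEntity({self.get_id()!r})"
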