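"""Parsers for the ChEBI flat-file release tables.

Nine tables are tab-separated with a header row and the literal token
``null`` marking an absent field; the structures table is an RFC-4180-style
quoted CSV whose STRUCTURE field may span many lines (it carries MDL
molfile text verbatim).  :func:`parse_release` builds the in-memory
:class:`ReleaseIndex` from the TSV tables; structures and literature
references are deliberately *not* indexed — those two files dominate the
release's size, so they are streamed on demand by :func:`stream_structure`
and :func:`stream_references` instead of being held resident.

Secondary (merged/deprecated) compounds carry a parent link; the index
precomputes the parent map and the transitive merged groups so identifier
resolution is a dictionary lookup.

Column layouts follow the release dialect used throughout this package;
``column_maps`` re-points any table at a different header vocabulary if a
live release dialect differs.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

from .exceptions import (
    CorruptStructuresFileError,
    CyclicParentError,
    DanglingParentError,
    IncompleteReleaseError,
    MalformedRowError,
    UndefinedChebiIdError,
)

logger = logging.getLogger(__name__)

NULL_TOKEN = "null"

#: Ontology predicates observed in the relation table.
RELATION_TYPES = (
    "is_a",
    "has_part",
    "has_role",
    "is_conjugate_acid_of",
    "is_conjugate_base_of",
    "is_tautomer_of",
    "is_enantiomer_of",
    "has_functional_parent",
    "has_parent_hydride",
    "is_substituent_group_from",
)

NAME_TYPES = ("NAME", "SYNONYM", "IUPAC NAME", "INN", "BRAND NAME")
CHEMICAL_DATA_TYPES = ("FORMULA", "MASS", "CHARGE", "MONOISOTOPIC MASS")
NUMERIC_DATA_TYPES = ("MASS", "CHARGE", "MONOISOTOPIC MASS")
STRUCTURE_TYPES = ("mol", "SMILES", "InChIKey")

#: Default header layout per table; overridable via ``column_maps``.
DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "compounds": (
        "ID", "STATUS", "CHEBI_ACCESSION", "SOURCE", "PARENT_ID",
        "NAME", "DEFINITION", "MODIFIED_ON", "CREATED_BY", "STAR",
    ),
    "names": ("ID", "COMPOUND_ID", "TYPE", "SOURCE", "NAME", "ADAPTED", "LANGUAGE"),
    "chemical_data": ("ID", "COMPOUND_ID", "SOURCE", "TYPE", "CHEMICAL_DATA"),
    "database_accession": ("ID", "COMPOUND_ID", "SOURCE", "TYPE", "ACCESSION_NUMBER"),
    "relation": ("ID", "TYPE", "INIT_ID", "FINAL_ID", "STATUS"),
    "inchi": ("CHEBI_ID", "INCHI"),
    "comments": ("ID", "COMPOUND_ID", "CREATED_ON", "DATATYPE", "COMMENT"),
    "reference": (
        "COMPOUND_ID", "REFERENCE_ID", "REFERENCE_DB_NAME",
        "LOCATION_IN_REF", "REFERENCE_NAME",
    ),
    "compound_origins": (
        "ID", "COMPOUND_ID", "SPECIES_TEXT", "SPECIES_ACCESSION",
        "COMPONENT_TEXT", "STRAIN_TEXT", "SOURCE_TYPE",
        "SOURCE_ACCESSION", "COMMENTS",
    ),
    "structures": ("ID", "COMPOUND_ID", "STRUCTURE", "TYPE", "DIMENSION", "DEFAULT_STRUCTURE"),
}


# --- record types ----------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One row of the compounds table.

    ``parent_id`` being present marks the entry as secondary: it has been
    merged into (and is resolved through) the parent compound.
    """

    id: int
    status: str
    chebi_accession: str
    source: str
    parent_id: Optional[int] = None
    name: Optional[str] = None
    definition: Optional[str] = None
    modified_on: Union[date, str, None] = None
    created_by: Optional[str] = None
    star: int = 0


@dataclass(frozen=True)
class NameRecord:
    id: int
    compound_id: int
    name_type: str
    source: str
    name: str
    adapted: str = "F"
    language: str = "en"


@dataclass(frozen=True)
class ChemicalDatumRecord:
    id: int
    compound_id: int
    source: str
    datum_type: str
    value: str


@dataclass(frozen=True)
class AccessionRecord:
    id: int
    compound_id: int
    source: str
    accession_type: str
    accession_number: str


@dataclass(frozen=True)
class RelationRecord:
    """A typed directed ontology edge ``init_id --relation_type--> final_id``."""

    id: int
    relation_type: str
    init_id: int
    final_id: int
    status: str


@dataclass(frozen=True)
class StructureRecord:
    id: int
    compound_id: int
    structure_text: str
    structure_type: str
    dimension: str
    is_default: bool


@dataclass(frozen=True)
class InchiRecord:
    compound_id: int
    inchi_text: str


@dataclass(frozen=True)
class CommentRecord:
    id: int
    compound_id: int
    created_on: Union[date, str, None]
    datatype: str
    text: str


@dataclass(frozen=True)
class ReferenceRecord:
    compound_id: int
    reference_id: str
    reference_db: str
    location_in_ref: Optional[str] = None
    reference_name: Optional[str] = None


@dataclass(frozen=True)
class OriginRecord:
    id: int
    compound_id: int
    species_text: str
    species_accession: Optional[str] = None
    component_text: Optional[str] = None
    strain_text: Optional[str] = None
    source_type: Optional[str] = None
    source_accession: Optional[str] = None
    comments: Optional[str] = None


@dataclass
class ReleaseIndex:
    """In-memory index over the parsed TSV tables.

    Structures and references are intentionally absent: they are streamed
    from disk on demand rather than held in memory.
    """

    compounds: dict[int, CompoundRecord] = field(default_factory=dict)
    names: dict[int, list[NameRecord]] = field(default_factory=dict)
    chemical_data: dict[int, list[ChemicalDatumRecord]] = field(default_factory=dict)
    accessions: dict[int, list[AccessionRecord]] = field(default_factory=dict)
    outgoing: dict[int, list[RelationRecord]] = field(default_factory=dict)
    incoming: dict[int, list[RelationRecord]] = field(default_factory=dict)
    inchis: dict[int, str] = field(default_factory=dict)
    comments: dict[int, list[CommentRecord]] = field(default_factory=dict)
    origins: dict[int, list[OriginRecord]] = field(default_factory=dict)
    parent_of: dict[int, int] = field(default_factory=dict)
    group_of: dict[int, set[int]] = field(default_factory=dict)
    skipped_rows: int = 0


# --- low-level helpers -----------------------------------------------------

def _opt(value: str) -> Optional[str]:
    """Map the ``null`` sentinel (and empty text) to an absent value."""
    if value == NULL_TOKEN or value == "":
        return None
    return value


def _opt_int(value: str) -> Optional[int]:
    text = _opt(value)
    return None if text is None else int(text)


def _opt_date(value: str) -> Union[date, str, None]:
    text = _opt(value)
    if text is None:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError:
        logger.warning("unparseable date %r kept as raw text", text)
        return text


def _iter_tsv(
    path: Path,
    table: str,
    columns: tuple[str, ...],
    strict: bool,
    counters: dict[str, int],
) -> Iterator[dict[str, str]]:
    """Yield rows of a TSV table as header-keyed dicts.

    The header row is read first and used to locate each expected column,
    so a reordered live dialect still parses.  Rows with the wrong column
    count are skipped with a warning (strict mode upgrades this to an
    error).  Accepts both LF and CRLF line endings.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        lines = (line.rstrip("\r\n") for line in fh)
        try:
            header = next(lines).split("\t")
        except StopIteration:
            return
        try:
            positions = [header.index(col) for col in columns]
        except ValueError as exc:
            raise MalformedRowError(
                f"{table}: header {header} lacks an expected column: {exc}"
            ) from exc
        width = len(header)
        for lineno, line in enumerate(lines, start=2):
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != width:
                counters["skipped"] += 1
                message = (
                    f"{table}:{lineno}: expected {width} columns, "
                    f"got {len(fields)}; row skipped"
                )
                if strict:
                    raise MalformedRowError(message)
                logger.warning(message)
                continue
            yield dict(zip(columns, (fields[p] for p in positions)))


# --- per-table parsers -----------------------------------------------------

def _parse_compounds(rows: Iterator[dict[str, str]]) -> dict[int, CompoundRecord]:
    compounds: dict[int, CompoundRecord] = {}
    for row in rows:
        record = CompoundRecord(
            id=int(row["ID"]),
            status=row["STATUS"],
            chebi_accession=row["CHEBI_ACCESSION"],
            source=row["SOURCE"],
            parent_id=_opt_int(row["PARENT_ID"]),
            name=_opt(row["NAME"]),
            definition=_opt(row["DEFINITION"]),
            modified_on=_opt_date(row["MODIFIED_ON"]),
            created_by=_opt(row["CREATED_BY"]),
            star=int(row["STAR"]),
        )
        compounds[record.id] = record
    return compounds


def _resolve_parents(
    compounds: dict[int, CompoundRecord],
) -> tuple[dict[int, int], dict[int, set[int]]]:
    """Validate parent links and compute the parent map and merged groups.

    Raises on a dangling parent or a parent cycle; otherwise the links form
    a forest and every id resolves to a unique primary.
    """
    parent_of: dict[int, int] = {}
    for record in compounds.values():
        if record.parent_id is not None:
            if record.parent_id not in compounds:
                raise DanglingParentError(record.id, record.parent_id)
            parent_of[record.id] = record.parent_id

    group_of: dict[int, set[int]] = {}
    for start in compounds:
        seen: list[int] = []
        current = start
        while current in parent_of:
            if current in seen:
                cycle = seen[seen.index(current):] + [current]
                raise CyclicParentError(cycle)
            seen.append(current)
            current = parent_of[current]
        group_of.setdefault(current, set()).add(start)
        group_of[current].add(current)
    return parent_of, group_of


def parse_release(
    paths: Mapping[str, Union[str, Path]],
    *,
    strict: bool = False,
    column_maps: Optional[Mapping[str, tuple[str, ...]]] = None,
    swap_relation_direction: bool = False,
) -> ReleaseIndex:
    """Parse a release into a :class:`ReleaseIndex`.

    ``paths`` maps logical table names to decompressed local files.  The
    compounds table is mandatory; any other table may be absent, yielding
    empty maps.  ``structures`` and ``reference`` paths are accepted but
    ignored here — those tables are streamed on demand, never indexed.

    ``swap_relation_direction`` inverts the INIT/FINAL orientation of the
    relation table for dialects that store edges the other way around.
    """
    if "compounds" not in paths:
        raise IncompleteReleaseError(
            "incomplete release: the mandatory compounds table is missing"
        )
    columns = dict(DEFAULT_COLUMNS)
    if column_maps:
        columns.update(column_maps)
    counters = {"skipped": 0}

    def rows(table: str) -> Iterator[dict[str, str]]:
        if table not in paths or paths[table] is None:
            return iter(())
        return _iter_tsv(Path(paths[table]), table, columns[table], strict, counters)

    index = ReleaseIndex()
    index.compounds = _parse_compounds(rows("compounds"))
    index.parent_of, index.group_of = _resolve_parents(index.compounds)

    for row in rows("names"):
        record = NameRecord(
            id=int(row["ID"]),
            compound_id=int(row["COMPOUND_ID"]),
            name_type=row["TYPE"],
            source=row["SOURCE"],
            name=row["NAME"],
            adapted=row["ADAPTED"],
            language=row["LANGUAGE"],
        )
        index.names.setdefault(record.compound_id, []).append(record)

    for row in rows("chemical_data"):
        datum = ChemicalDatumRecord(
            id=int(row["ID"]),
            compound_id=int(row["COMPOUND_ID"]),
            source=row["SOURCE"],
            datum_type=row["TYPE"],
            value=row["CHEMICAL_DATA"],
        )
        index.chemical_data.setdefault(datum.compound_id, []).append(datum)

    for row in rows("database_accession"):
        acc = AccessionRecord(
            id=int(row["ID"]),
            compound_id=int(row["COMPOUND_ID"]),
            source=row["SOURCE"],
            accession_type=row["TYPE"],
            accession_number=row["ACCESSION_NUMBER"],
        )
        index.accessions.setdefault(acc.compound_id, []).append(acc)

    for row in rows("relation"):
        init_id = int(row["INIT_ID"])
        final_id = int(row["FINAL_ID"])
        if swap_relation_direction:
            init_id, final_id = final_id, init_id
        rel = RelationRecord(
            id=int(row["ID"]),
            relation_type=row["TYPE"],
            init_id=init_id,
            final_id=final_id,
            status=row["STATUS"],
        )
        if rel.init_id not in index.compounds or rel.final_id not in index.compounds:
            counters["skipped"] += 1
            message = (
                f"relation {rel.id} references unknown compound "
                f"({rel.init_id} -> {rel.final_id}); row skipped"
            )
            if strict:
                raise MalformedRowError(message)
            logger.warning(message)
            continue
        index.outgoing.setdefault(rel.init_id, []).append(rel)
        index.incoming.setdefault(rel.final_id, []).append(rel)

    for row in rows("inchi"):
        index.inchis[int(row["CHEBI_ID"])] = row["INCHI"]

    for row in rows("comments"):
        comment = CommentRecord(
            id=int(row["ID"]),
            compound_id=int(row["COMPOUND_ID"]),
            created_on=_opt_date(row["CREATED_ON"]),
            datatype=row["DATATYPE"],
            text=row["COMMENT"],
        )
        index.comments.setdefault(comment.compound_id, []).append(comment)

    for row in rows("compound_origins"):
        origin = OriginRecord(
            id=int(row["ID"]),
            compound_id=int(row["COMPOUND_ID"]),
            species_text=row["SPECIES_TEXT"],
            species_accession=_opt(row["SPECIES_ACCESSION"]),
            component_text=_opt(row["COMPONENT_TEXT"]),
            strain_text=_opt(row["STRAIN_TEXT"]),
            source_type=_opt(row["SOURCE_TYPE"]),
            source_accession=_opt(row["SOURCE_ACCESSION"]),
            comments=_opt(row["COMMENTS"]),
        )
        index.origins.setdefault(origin.compound_id, []).append(origin)

    index.skipped_rows = counters["skipped"]
    return index


def resolve_primary(compound_id: int, index: ReleaseIndex) -> int:
    """Follow parent links from ``compound_id`` to its primary compound.

    Idempotent: the primary of a primary is itself.  The parent maps were
    validated acyclic at parse time, so this always terminates.
    """
    if compound_id not in index.compounds:
        raise UndefinedChebiIdError(str(compound_id))
    current = compound_id
    while current in index.parent_of:
        current = index.parent_of[current]
    return current


# --- on-demand streaming of the big files ----------------------------------

def _truthy(text: str) -> bool:
    return text.strip().upper() in {"Y", "YES", "T", "TRUE", "1"}


def _iter_structures(
    structures_path: Union[str, Path],
    columns: tuple[str, ...],
) -> Iterator[StructureRecord]:
    try:
        with open(structures_path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                return
            positions = [header.index(col) for col in columns]
            for fields in reader:
                if len(fields) != len(header):
                    logger.warning(
                        "structures row with %d fields skipped", len(fields)
                    )
                    continue
                row = dict(zip(columns, (fields[p] for p in positions)))
                yield StructureRecord(
                    id=int(row["ID"]),
                    compound_id=int(row["COMPOUND_ID"]),
                    structure_text=row["STRUCTURE"],
                    structure_type=row["TYPE"],
                    dimension=row["DIMENSION"],
                    is_default=_truthy(row["DEFAULT_STRUCTURE"]),
                )
    except (OSError, ValueError, csv.Error) as exc:
        raise CorruptStructuresFileError(
            f"corrupt structures file {structures_path}: {exc}"
        ) from exc


def stream_structure(
    compound_id: int,
    wanted_type: str,
    structures_path: Union[str, Path],
    *,
    column_map: Optional[tuple[str, ...]] = None,
) -> Optional[StructureRecord]:
    """Scan the structures CSV for one compound's structure of a given type.

    The file is read sequentially and never materialised: only the current
    row and at most one fallback candidate are resident at any point.  A
    row flagged as the default structure wins immediately; otherwise the
    first matching row is returned once the scan completes.
    """
    columns = column_map or DEFAULT_COLUMNS["structures"]
    fallback: Optional[StructureRecord] = None
    for record in _iter_structures(structures_path, columns):
        if record.compound_id != compound_id:
            continue
        if record.structure_type.lower() != wanted_type.lower():
            continue
        if record.is_default:
            return record
        if fallback is None:
            fallback = record
    return fallback


def stream_references(
    compound_id: int,
    references_path: Union[str, Path],
    *,
    column_map: Optional[tuple[str, ...]] = None,
) -> list[ReferenceRecord]:
    """Scan the reference TSV and return all rows for one compound, in file
    order.  Nothing beyond the returned rows is retained."""
    columns = column_map or DEFAULT_COLUMNS["reference"]
    counters = {"skipped": 0}
    results: list[ReferenceRecord] = []
    try:
        for row in _iter_tsv(
            Path(references_path), "reference", columns, False, counters
        ):
            if int(row["COMPOUND_ID"]) != compound_id:
                continue
            results.append(
                ReferenceRecord(
                    compound_id=compound_id,
                    reference_id=row["REFERENCE_ID"],
                    reference_db=row["REFERENCE_DB_NAME"],
                    location_in_ref=_opt(row["LOCATION_IN_REF"]),
                    reference_name=_opt(row["REFERENCE_NAME"]),
                )
            )
    except OSError as exc:
        raise CorruptStructuresFileError(
            f"corrupt references file {references_path}: {exc}"
        ) from exc
    return results
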