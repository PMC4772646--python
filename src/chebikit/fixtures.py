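"""Deterministic miniature release generator.

Generates small, internally consistent ChEBI-style flat-file releases plus
a ground-truth :class:`FixtureManifest`, so the whole library is testable
offline: the generated directory stands in for the remote flat-file area,
and the manifest is the oracle every test compares against.

The manifest's expected per-entity outputs are computed here by direct
brute force over the generated rows (transitive closure of parent links by
repeated scanning, unions by nested loops) — deliberately independent of
the parsing and entity modules they are used to check.

Generated releases exercise the parsers' corner cases on purpose: ``null``
sentinels, parent chains deeper than one hop, duplicate synonyms shared
across a merged group, a multi-line molfile with embedded double quotes in
the quoted CSV, a CRLF-terminated table, and gzip-compressed variants of
every file.  Names and formulae come from a small embedded vocabulary of
real compounds so failures stay human-readable; chemical realism beyond
that (valence-correct structures etc.) is a non-goal.
"""
from __future__ import annotations

import csv
import dataclasses
import gzip
import json
import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Union

from .cache import LOGICAL_FILES
from .exceptions import UnsatisfiableFixtureSpecError
from .parsers import (
    DEFAULT_COLUMNS,
    RELATION_TYPES,
    AccessionRecord,
    ChemicalDatumRecord,
    CommentRecord,
    CompoundRecord,
    InchiRecord,
    NameRecord,
    OriginRecord,
    ReferenceRecord,
    RelationRecord,
    StructureRecord,
)

#: Optional tables a spec may include (compounds is always emitted).
OPTIONAL_TABLES = frozenset(
    {
        "names",
        "chemical_data",
        "database_accession",
        "relation",
        "inchi",
        "comments",
        "reference",
        "compound_origins",
        "structures",
    }
)

# (name, formula, mass, monoisotopic mass, charge, smiles, inchi, inchikey,
#  synonyms)
_VOCABULARY = [
    ("water", "H2O", "18.01530", "18.01056", 0, "O",
     "InChI=1S/H2O/h1H2", "XLYOFNOQVPJJNP-UHFFFAOYSA-N", ["H2O", "aqua"]),
    ("D-glucose", "C6H12O6", "180.15588", "180.06339", 0,
     "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O",
     "InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2",
     "WQZGKKKJIJFFOK-GASJEMHNSA-N", ["dextrose", "grape sugar"]),
    ("ethanol", "C2H6O", "46.06844", "46.04186", 0, "CCO",
     "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3", "LFQSCWFLJHTTHZ-UHFFFAOYSA-N",
     ["ethyl alcohol", "EtOH"]),
    ("glycine", "C2H5NO2", "75.06660", "75.03203", 0, "NCC(O)=O",
     "InChI=1S/C2H5NO2/c3-1-2(4)5/h1,3H2,(H,4,5)",
     "DHMQDGOQFOQNFH-UHFFFAOYSA-N", ["aminoacetic acid"]),
    ("acetate", "C2H3O2", "59.04400", "59.01385", -1, "CC([O-])=O",
     "InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)/p-1",
     "QTBSBXVTEAMEQO-UHFFFAOYSA-M", ["acetic acid anion"]),
    ("ammonium", "H4N", "18.03850", "18.03437", 1, "[NH4+]",
     "InChI=1S/H3N/h1H3/p+1", "QGZKDVFQNNGYKY-UHFFFAOYSA-O", ["NH4+"]),
    ("pyruvate", "C3H3O3", "87.05400", "87.00877", -1, "CC(=O)C([O-])=O",
     "InChI=1S/C3H4O3/c1-2(4)3(5)6/h1H3,(H,5,6)/p-1",
     "LCTONWCANYUPML-UHFFFAOYSA-M", ["2-oxopropanoate"]),
    ("caffeine", "C8H10N4O2", "194.19060", "194.08038", 0,
     "Cn1cnc2n(C)c(=O)n(C)c(=O)c12",
     "InChI=1S/C8H10N4O2/c1-10-4-9-6-5(10)7(13)12(3)8(14)11(6)2/h4H,1-3H3",
     "RYYVLZVUVIJVGH-UHFFFAOYSA-N", ["1,3,7-trimethylxanthine"]),
    ("L-alanine", "C3H7NO2", "89.09320", "89.04768", 0, "C[C@H](N)C(O)=O",
     "InChI=1S/C3H7NO2/c1-2(4)3(5)6/h2H,4H2,1H3,(H,5,6)/t2-/m0/s1",
     "QNAYBMKLOCPYGJ-REOHCLBHSA-N", ["(S)-2-aminopropanoic acid"]),
    ("citrate", "C6H5O7", "189.09970", "189.00408", -3,
     "OC(CC([O-])=O)(CC([O-])=O)C([O-])=O",
     "InChI=1S/C6H8O7/c7-3(8)1-6(13,5(11)12)2-4(9)10/h13H,1-2H2,(H,7,8)(H,9,10)(H,11,12)/p-3",
     "KRKNYBCHXYNGOX-UHFFFAOYSA-K", ["citric acid trianion"]),
    ("urea", "CH4N2O", "60.05526", "60.03236", 0, "NC(N)=O",
     "InChI=1S/CH4N2O/c2-1(3)4/h(H4,2,3,4)", "XSQUKJJJFZCRTK-UHFFFAOYSA-N",
     ["carbamide"]),
    ("glycerol", "C3H8O3", "92.09382", "92.04734", 0, "OCC(O)CO",
     "InChI=1S/C3H8O3/c4-1-3(5)2-6/h3-6H,1-2H2",
     "PEDCQBHIVMGVHV-UHFFFAOYSA-N", ["glycerine", "propane-1,2,3-triol"]),
]

_EXTERNAL_DBS = ["KEGG COMPOUND", "HMDB", "CAS Registry Number", "MetaCyc", "LIPID MAPS"]
_SOURCES = ["ChEBI", "KEGG COMPOUND", "SUBMITTER"]
_CURATORS = ["curator_a", "curator_b", "curator_c"]
_SPECIES = [
    ("Homo sapiens", "NCBI:9606"),
    ("Escherichia coli", "NCBI:562"),
    ("Saccharomyces cerevisiae", "NCBI:4932"),
]
_EPOCH = date(2016, 1, 1)


def _molfile(name: str, quoted_comment: bool = False) -> str:
    """A small, syntactically molfile-shaped 2D block (3 atoms, 2 bonds).

    Chemical validity is a non-goal; this exists to exercise verbatim
    multi-line text inside one quoted CSV field.
    """
    comment = '"synthetic" fixture structure' if quoted_comment else "synthetic fixture structure"
    lines = [
        name,
        "  chebikit          2D",
        comment,
        "  3  2  0  0  0  0  0  0  0  0999 V2000",
        "    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0",
        "    0.8660    0.5000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0",
        "   -0.8660    0.5000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0",
        "  1  2  1  0  0  0  0",
        "  1  3  1  0  0  0  0",
        "M  END",
    ]
    return "\n".join(lines)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated miniature release.

    The same (spec, seed) always produces byte-identical output.
    """

    n_primary: int = 10
    n_secondary: int = 5
    max_parent_chain: int = 2
    relation_density: float = 1.5
    seed: int = 0
    include: frozenset[str] = OPTIONAL_TABLES

    def validate(self) -> None:
        if self.n_primary < 0 or self.n_secondary < 0:
            raise UnsatisfiableFixtureSpecError("counts must be non-negative")
        if self.n_secondary > 0 and self.n_primary == 0:
            raise UnsatisfiableFixtureSpecError(
                "secondary entries need at least one primary to merge into"
            )
        if self.max_parent_chain < 1:
            raise UnsatisfiableFixtureSpecError("max_parent_chain must be >= 1")
        unknown = set(self.include) - OPTIONAL_TABLES
        if unknown:
            raise UnsatisfiableFixtureSpecError(
                f"unknown optional tables: {sorted(unknown)}"
            )


@dataclass
class FixtureManifest:
    """Complete ground truth for one generated release.

    Holds every record of every table plus precomputed answers (parent
    resolution, merged groups, expected getter outputs per entity), so it
    can serve as the oracle for parsing and entity lookups alike.
    """

    spec: Optional[FixtureSpec]
    compounds: list[CompoundRecord] = field(default_factory=list)
    names: list[NameRecord] = field(default_factory=list)
    chemical_data: list[ChemicalDatumRecord] = field(default_factory=list)
    accessions: list[AccessionRecord] = field(default_factory=list)
    relations: list[RelationRecord] = field(default_factory=list)
    inchis: list[InchiRecord] = field(default_factory=list)
    comments: list[CommentRecord] = field(default_factory=list)
    references: list[ReferenceRecord] = field(default_factory=list)
    origins: list[OriginRecord] = field(default_factory=list)
    structures: list[StructureRecord] = field(default_factory=list)
    parent_resolution: dict[int, int] = field(default_factory=dict)
    groups: dict[int, list[int]] = field(default_factory=dict)
    entities: dict[int, dict] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        """Total rows across all ten tables."""
        return sum(
            len(table)
            for table in (
                self.compounds, self.names, self.chemical_data,
                self.accessions, self.relations, self.inchis, self.comments,
                self.references, self.origins, self.structures,
            )
        )

    def to_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, date):
                return obj.isoformat()
            if isinstance(obj, frozenset):
                return sorted(obj)
            raise TypeError(f"not JSON-serialisable: {type(obj)}")

        payload = {
            "spec": self.spec,
            "tables": {
                "compounds": self.compounds,
                "names": self.names,
                "chemical_data": self.chemical_data,
                "database_accession": self.accessions,
                "relation": self.relations,
                "inchi": self.inchis,
                "comments": self.comments,
                "reference": self.references,
                "compound_origins": self.origins,
                "structures": self.structures,
            },
            "parent_resolution": self.parent_resolution,
            "groups": self.groups,
            "entities": self.entities,
        }
        return json.dumps(payload, default=encode, indent=1, sort_keys=False)


# --- model construction -----------------------------------------------------

def _build_model(spec: FixtureSpec) -> FixtureManifest:
    rng = random.Random(spec.seed)
    manifest = FixtureManifest(spec=spec)
    row_ids = {"names": 0, "chem": 0, "acc": 0, "rel": 0, "com": 0, "org": 0, "str": 0}

    def next_id(kind: str) -> int:
        row_ids[kind] += 1000
        return row_ids[kind] + rng.randrange(100)

    primary_ids = list(range(1, spec.n_primary + 1))
    secondary_ids = list(
        range(spec.n_primary + 1, spec.n_primary + spec.n_secondary + 1)
    )

    # -- compounds ----------------------------------------------------------
    vocab = {}
    for i, cid in enumerate(primary_ids):
        entry = _VOCABULARY[i % len(_VOCABULARY)]
        name = entry[0] if i < len(_VOCABULARY) else f"{entry[0]} analogue {i}"
        vocab[cid] = entry
        manifest.compounds.append(
            CompoundRecord(
                id=cid,
                status=rng.choice("CCE"),
                chebi_accession=f"CHEBI:{cid}",
                source=rng.choice(_SOURCES),
                parent_id=None,
                name=name,
                definition=(
                    None if rng.random() < 0.34 else f"A fixture entry for {name}."
                ),
                modified_on=_EPOCH + timedelta(days=rng.randrange(365)),
                created_by=None if rng.random() < 0.25 else rng.choice(_CURATORS),
                star=rng.randint(1, 5),
            )
        )

    # Secondary entries: parent chains up to max_parent_chain deep.  The
    # first two secondaries are forced into a depth-2 chain when the spec
    # allows one, so deep resolution is always exercised.
    depth: dict[int, int] = {}
    for j, cid in enumerate(secondary_ids):
        chainable = [s for s in secondary_ids[:j] if depth[s] < spec.max_parent_chain]
        force_chain = j == 1 and spec.max_parent_chain >= 2 and chainable
        if chainable and (force_chain or rng.random() < 0.3):
            parent = rng.choice(chainable)
        else:
            parent = rng.choice(primary_ids)
        depth[cid] = depth.get(parent, 0) + 1
        manifest.compounds.append(
            CompoundRecord(
                id=cid,
                status=rng.choice("OD"),
                chebi_accession=f"CHEBI:{cid}",
                source=rng.choice(_SOURCES),
                parent_id=parent,
                name=None if rng.random() < 0.5 else f"retired entry {cid}",
                definition=None,
                modified_on=_EPOCH + timedelta(days=rng.randrange(365)),
                created_by=None,
                star=rng.randint(1, 3),
            )
        )

    compound_ids = primary_ids + secondary_ids

    # -- parent resolution & groups, by brute force -------------------------
    parent_of = {
        c.id: c.parent_id for c in manifest.compounds if c.parent_id is not None
    }
    for cid in compound_ids:
        current = cid
        while current in parent_of:
            current = parent_of[current]
        manifest.parent_resolution[cid] = current
    for cid in compound_ids:
        primary = manifest.parent_resolution[cid]
        manifest.groups.setdefault(primary, [])
        if cid not in manifest.groups[primary]:
            manifest.groups[primary].append(cid)
    for primary, members in manifest.groups.items():
        members.sort()

    # -- names --------------------------------------------------------------
    if "names" in spec.include:
        for i, cid in enumerate(primary_ids):
            entry = vocab[cid]
            manifest.names.append(
                NameRecord(
                    id=next_id("names"), compound_id=cid, name_type="NAME",
                    source="ChEBI", name=entry[0], adapted="F", language="en",
                )
            )
            for synonym in entry[8]:
                manifest.names.append(
                    NameRecord(
                        id=next_id("names"), compound_id=cid,
                        name_type="SYNONYM", source=rng.choice(_SOURCES),
                        name=synonym, adapted=rng.choice("FT"), language="en",
                    )
                )
        for cid in secondary_ids:
            primary = manifest.parent_resolution[cid]
            entry = vocab[primary]
            if rng.random() < 0.5:
                # Duplicate an existing synonym of the primary on the
                # secondary: the group union must keep only one copy.
                manifest.names.append(
                    NameRecord(
                        id=next_id("names"), compound_id=cid,
                        name_type="SYNONYM", source="SUBMITTER",
                        name=entry[8][0], adapted="F", language="en",
                    )
                )
            manifest.names.append(
                NameRecord(
                    id=next_id("names"), compound_id=cid, name_type="SYNONYM",
                    source="SUBMITTER", name=f"{entry[0].upper()} (deprecated {cid})",
                    adapted="F", language="en",
                )
            )

    # -- chemical data -------------------------------------------------------
    if "chemical_data" in spec.include:
        for i, cid in enumerate(primary_ids):
            entry = vocab[cid]
            # One primary in ~5 lacks its CHARGE row (absence is distinct
            # from zero); one in ~5 gets its FORMULA only via a secondary.
            omit_charge = rng.random() < 0.2
            formula_on_secondary = (
                rng.random() < 0.2
                and len(manifest.groups.get(cid, [cid])) > 1
            )
            formula_holder = (
                min(m for m in manifest.groups[cid] if m != cid)
                if formula_on_secondary
                else cid
            )
            manifest.chemical_data.append(
                ChemicalDatumRecord(
                    id=next_id("chem"), compound_id=formula_holder,
                    source="ChEBI", datum_type="FORMULA", value=entry[1],
                )
            )
            manifest.chemical_data.append(
                ChemicalDatumRecord(
                    id=next_id("chem"), compound_id=cid, source="ChEBI",
                    datum_type="MASS", value=entry[2],
                )
            )
            manifest.chemical_data.append(
                ChemicalDatumRecord(
                    id=next_id("chem"), compound_id=cid, source="ChEBI",
                    datum_type="MONOISOTOPIC MASS", value=entry[3],
                )
            )
            if not omit_charge:
                manifest.chemical_data.append(
                    ChemicalDatumRecord(
                        id=next_id("chem"), compound_id=cid, source="ChEBI",
                        datum_type="CHARGE", value=str(entry[4]),
                    )
                )

    # -- database accessions --------------------------------------------------
    if "database_accession" in spec.include:
        for cid in compound_ids:
            for _ in range(rng.randrange(3)):
                db = rng.choice(_EXTERNAL_DBS)
                manifest.accessions.append(
                    AccessionRecord(
                        id=next_id("acc"), compound_id=cid,
                        source=rng.choice(_SOURCES), accession_type=db,
                        accession_number=f"{db[:1]}{rng.randrange(10000, 99999)}",
                    )
                )

    # -- relations ------------------------------------------------------------
    if "relation" in spec.include and len(compound_ids) > 1:
        for cid in primary_ids:
            n_rel = int(spec.relation_density)
            if rng.random() < spec.relation_density - n_rel:
                n_rel += 1
            for _ in range(n_rel):
                # A quarter of edges originate at a secondary member so the
                # merged-group union of relations is exercised.
                group = manifest.groups.get(cid, [cid])
                init = (
                    rng.choice(group)
                    if len(group) > 1 and rng.random() < 0.25
                    else cid
                )
                final = rng.choice([c for c in compound_ids if c != init])
                manifest.relations.append(
                    RelationRecord(
                        id=next_id("rel"),
                        relation_type=rng.choice(RELATION_TYPES),
                        init_id=init, final_id=final, status="C",
                    )
                )

    # -- inchi ----------------------------------------------------------------
    if "inchi" in spec.include:
        for cid in primary_ids:
            if rng.random() < 0.9:
                manifest.inchis.append(InchiRecord(cid, vocab[cid][6]))

    # -- comments -------------------------------------------------------------
    if "comments" in spec.include:
        for cid in compound_ids:
            if rng.random() < 0.4:
                manifest.comments.append(
                    CommentRecord(
                        id=next_id("com"), compound_id=cid,
                        created_on=_EPOCH + timedelta(days=rng.randrange(365)),
                        datatype="General Comment",
                        text=f"Fixture comment on CHEBI:{cid}.",
                    )
                )

    # -- references -----------------------------------------------------------
    if "reference" in spec.include:
        for k, cid in enumerate(compound_ids):
            n_ref = 3 if k == 0 else rng.randrange(3)
            for r in range(n_ref):
                manifest.references.append(
                    ReferenceRecord(
                        compound_id=cid,
                        reference_id=f"PMID:{rng.randrange(10_000_000, 30_000_000)}",
                        reference_db="PubMed",
                        location_in_ref=None if rng.random() < 0.5 else f"p.{r + 1}",
                        reference_name=f"Fixture study {k}-{r}",
                    )
                )

    # -- compound origins -----------------------------------------------------
    if "compound_origins" in spec.include:
        for cid in primary_ids:
            if rng.random() < 0.35:
                species, accession = rng.choice(_SPECIES)
                manifest.origins.append(
                    OriginRecord(
                        id=next_id("org"), compound_id=cid,
                        species_text=species, species_accession=accession,
                        component_text=None if rng.random() < 0.5 else "cytoplasm",
                        strain_text=None,
                        source_type="metabolite",
                        source_accession=None,
                        comments=None,
                    )
                )

    # -- structures -----------------------------------------------------------
    if "structures" in spec.include:
        for i, cid in enumerate(primary_ids):
            entry = vocab[cid]
            if rng.random() < 0.15:
                continue  # a compound with no structure rows at all
            # The first compound's molfile embeds double quotes to exercise
            # RFC-4180 quote doubling; the second gets a non-default extra
            # mol row so default-preference is exercised.
            manifest.structures.append(
                StructureRecord(
                    id=next_id("str"), compound_id=cid,
                    structure_text=_molfile(entry[0], quoted_comment=i == 0),
                    structure_type="mol", dimension="2D", is_default=True,
                )
            )
            if i == 1:
                manifest.structures.append(
                    StructureRecord(
                        id=next_id("str"), compound_id=cid,
                        structure_text=_molfile(entry[0] + " (alt)"),
                        structure_type="mol", dimension="3D", is_default=False,
                    )
                )
            manifest.structures.append(
                StructureRecord(
                    id=next_id("str"), compound_id=cid,
                    structure_text=entry[5], structure_type="SMILES",
                    dimension="1D", is_default=True,
                )
            )
            manifest.structures.append(
                StructureRecord(
                    id=next_id("str"), compound_id=cid,
                    structure_text=entry[7], structure_type="InChIKey",
                    dimension="1D", is_default=True,
                )
            )

    _compute_expected_entities(manifest)
    return manifest


# --- brute-force expected outputs -------------------------------------------

def _compute_expected_entities(manifest: FixtureManifest) -> None:
    """Fill ``manifest.entities`` with the expected getter outputs of every
    compound, computed by plain loops over the generated rows."""
    by_id = {c.id: c for c in manifest.compounds}

    for cid in sorted(by_id):
        primary = manifest.parent_resolution[cid]
        group = [primary] + [m for m in manifest.groups[primary] if m != primary]
        record = by_id[cid]
        prim = by_id[primary]

        def rows_for(table, member):
            return [r for r in table if r.compound_id == member]

        names = []
        seen = set()
        for member in group:
            for r in rows_for(manifest.names, member):
                key = (r.name, r.name_type, r.language)
                if key in seen:
                    continue
                seen.add(key)
                names.append(
                    {
                        "name": r.name,
                        "name_type": r.name_type,
                        "source": r.source,
                        "adapted": r.adapted in ("T", "Y"),
                        "language": r.language,
                    }
                )

        def chem(datum_type):
            for member in group:
                for r in rows_for(manifest.chemical_data, member):
                    if r.datum_type == datum_type:
                        return r.value
            return None

        formulae = []
        for member in group:
            for r in rows_for(manifest.chemical_data, member):
                if r.datum_type == "FORMULA":
                    formulae.append([r.value, r.source])

        accessions = []
        seen = set()
        for member in group:
            for r in rows_for(manifest.accessions, member):
                key = (r.accession_type, r.accession_number, r.source)
                if key in seen:
                    continue
                seen.add(key)
                accessions.append(
                    {
                        "accession_type": r.accession_type,
                        "accession_number": r.accession_number,
                        "source": r.source,
                    }
                )

        comments = []
        seen = set()
        for member in group:
            for r in rows_for(manifest.comments, member):
                key = (r.created_on, r.datatype, r.text)
                if key in seen:
                    continue
                seen.add(key)
                comments.append(
                    {
                        "created_on": r.created_on,
                        "datatype": r.datatype,
                        "text": r.text,
                    }
                )

        origins = []
        seen = set()
        for member in group:
            for r in rows_for(manifest.origins, member):
                key = (
                    r.species_text, r.species_accession, r.component_text,
                    r.strain_text, r.source_type, r.source_accession, r.comments,
                )
                if key in seen:
                    continue
                seen.add(key)
                origins.append(
                    {
                        "species_text": r.species_text,
                        "species_accession": r.species_accession,
                        "component_text": r.component_text,
                        "strain_text": r.strain_text,
                        "source_type": r.source_type,
                        "source_accession": r.source_accession,
                        "comments": r.comments,
                    }
                )

        inchi = None
        for member in group:
            for r in manifest.inchis:
                if r.compound_id == member:
                    inchi = r.inchi_text
                    break
            if inchi is not None:
                break

        def structure(wanted_type):
            for member in group:
                fallback = None
                for r in manifest.structures:
                    if r.compound_id != member:
                        continue
                    if r.structure_type.lower() != wanted_type.lower():
                        continue
                    if r.is_default:
                        return r.structure_text
                    if fallback is None:
                        fallback = r.structure_text
                if fallback is not None:
                    return fallback
            return None

        references = []
        seen = set()
        for member in group:
            for r in manifest.references:
                if r.compound_id != member:
                    continue
                key = (r.reference_id, r.reference_db, r.location_in_ref, r.reference_name)
                if key in seen:
                    continue
                seen.add(key)
                references.append(
                    {
                        "reference_id": r.reference_id,
                        "reference_db": r.reference_db,
                        "location_in_ref": r.location_in_ref,
                        "reference_name": r.reference_name,
                    }
                )

        def relations(target_side):
            items = []
            for member in group:
                for r in manifest.relations:
                    origin = r.init_id if target_side == "final" else r.final_id
                    if origin != member:
                        continue
                    target = r.final_id if target_side == "final" else r.init_id
                    item = {
                        "relation_type": r.relation_type,
                        "target_chebi_accession": f"CHEBI:{target}",
                        "status": r.status,
                    }
                    if item not in items:
                        items.append(item)
            items.sort(
                key=lambda d: (
                    d["relation_type"],
                    int(d["target_chebi_accession"].split(":")[1]),
                    d["status"],
                )
            )
            return items

        manifest.entities[cid] = {
            "id": f"CHEBI:{cid}",
            "parent_id": None if record.parent_id is None else f"CHEBI:{record.parent_id}",
            "primary_id": primary,
            "name": prim.name,
            "definition": prim.definition,
            "status": prim.status,
            "source": prim.source,
            "created_by": prim.created_by,
            "modified_on": prim.modified_on,
            "star": prim.star,
            "names": names,
            "formula": chem("FORMULA"),
            "formulae": formulae,
            "mass": None if chem("MASS") is None else float(chem("MASS")),
            "monoisotopic_mass": (
                None
                if chem("MONOISOTOPIC MASS") is None
                else float(chem("MONOISOTOPIC MASS"))
            ),
            "charge": None if chem("CHARGE") is None else int(chem("CHARGE")),
            "database_accessions": accessions,
            "comments": comments,
            "compound_origins": origins,
            "inchi": inchi,
            "inchi_key": structure("InChIKey"),
            "smiles": structure("SMILES"),
            "mol": structure("mol"),
            "references": references,
            "outgoings": relations("final"),
            "incomings": relations("init"),
        }


# --- rendering to flat files -------------------------------------------------

def _render(value) -> str:
    if value is None:
        return "null"
    if isinstance(value, date):
        return value.isoformat()
    return str(value)


def _write_tsv(path: Path, header: tuple[str, ...], rows: list[tuple], crlf: bool) -> None:
    eol = "\r\n" if crlf else "\n"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + eol)
        for row in rows:
            fh.write("\t".join(_render(v) for v in row) + eol)


def _gzip_variant(path: Path) -> None:
    data = path.read_bytes()
    # mtime pinned so regeneration is byte-identical
    path.with_name(path.name + ".gz").write_bytes(gzip.compress(data, mtime=0))


def write_release(manifest: FixtureManifest, out_dir: Union[str, Path]) -> Path:
    """Render a manifest to a release directory (all ten flat files, plus a
    gzip variant of each, plus ``manifest.json``).

    Rendering is a pure function of the manifest, so regenerating files
    from the same manifest is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, tuple[tuple[str, ...], list[tuple]]] = {
        "compounds": (
            DEFAULT_COLUMNS["compounds"],
            [
                (c.id, c.status, c.chebi_accession, c.source, c.parent_id,
                 c.name, c.definition, c.modified_on, c.created_by, c.star)
                for c in manifest.compounds
            ],
        ),
        "names": (
            DEFAULT_COLUMNS["names"],
            [
                (n.id, n.compound_id, n.name_type, n.source, n.name,
                 n.adapted, n.language)
                for n in manifest.names
            ],
        ),
        "chemical_data": (
            DEFAULT_COLUMNS["chemical_data"],
            [
                (d.id, d.compound_id, d.source, d.datum_type, d.value)
                for d in manifest.chemical_data
            ],
        ),
        "database_accession": (
            DEFAULT_COLUMNS["database_accession"],
            [
                (a.id, a.compound_id, a.source, a.accession_type, a.accession_number)
                for a in manifest.accessions
            ],
        ),
        "relation": (
            DEFAULT_COLUMNS["relation"],
            [
                (r.id, r.relation_type, r.init_id, r.final_id, r.status)
                for r in manifest.relations
            ],
        ),
        "inchi": (
            DEFAULT_COLUMNS["inchi"],
            [(i.compound_id, i.inchi_text) for i in manifest.inchis],
        ),
        "comments": (
            DEFAULT_COLUMNS["comments"],
            [
                (c.id, c.compound_id, c.created_on, c.datatype, c.text)
                for c in manifest.comments
            ],
        ),
        "reference": (
            DEFAULT_COLUMNS["reference"],
            [
                (r.compound_id, r.reference_id, r.reference_db,
                 r.location_in_ref, r.reference_name)
                for r in manifest.references
            ],
        ),
        "compound_origins": (
            DEFAULT_COLUMNS["compound_origins"],
            [
                (o.id, o.compound_id, o.species_text, o.species_accession,
                 o.component_text, o.strain_text, o.source_type,
                 o.source_accession, o.comments)
                for o in manifest.origins
            ],
        ),
    }

    for logical, (header, rows) in tables.items():
        path = out_dir / LOGICAL_FILES[logical]
        # comments is written CRLF-terminated so both line endings are
        # always represented in a generated release
        _write_tsv(path, header, rows, crlf=logical == "comments")
        _gzip_variant(path)

    structures_path = out_dir / LOGICAL_FILES["structures"]
    with open(structures_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DEFAULT_COLUMNS["structures"])
        for s in manifest.structures:
            writer.writerow(
                (s.id, s.compound_id, s.structure_text, s.structure_type,
                 s.dimension, "Y" if s.is_default else "N")
            )
    _gzip_variant(structures_path)

    (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return out_dir


def generate(
    spec: FixtureSpec, out_dir: Union[str, Path]
) -> tuple[Path, FixtureManifest]:
    """Generate a miniature release under ``out_dir``; return the directory
    and its ground-truth manifest."""
    spec.validate()
    manifest = _build_model(spec)
    return write_release(manifest, out_dir), manifest


# --- the canonical hand-written fixture --------------------------------------

def canonical_mini_release(
    out_dir: Union[str, Path, None] = None,
) -> tuple[Optional[Path], FixtureManifest]:
    """The fixed four-compound release used in all documentation examples.

    CHEBI:1 "water" (H2O, charge 0, mass 18.0153, InChI, default 2D mol),
    CHEBI:2 a deprecated entry merged into water with synonym "WATER",
    CHEBI:3 "D-glucose" (C6H12O6, charge 0, several synonyms) and
    CHEBI:4 "aldohexose", linked by the ontology edge 3 --is_a--> 4.

    If ``out_dir`` is given the release is also written there.
    """
    manifest = FixtureManifest(spec=None)
    manifest.compounds = [
        CompoundRecord(1, "C", "CHEBI:1", "ChEBI", None, "water",
                       "An oxygen hydride consisting of an oxygen atom "
                       "bonded to two hydrogen atoms.",
                       date(2016, 1, 15), "curator_a", 3),
        CompoundRecord(2, "O", "CHEBI:2", "ChEBI", 1, None, None,
                       date(2016, 1, 15), None, 1),
        CompoundRecord(3, "C", "CHEBI:3", "ChEBI", None, "D-glucose",
                       "The D-enantiomer of glucose.",
                       date(2016, 2, 1), "curator_b", 3),
        CompoundRecord(4, "C", "CHEBI:4", "ChEBI", None, "aldohexose",
                       "A hexose with a terminal aldehyde group.",
                       date(2016, 2, 1), "curator_b", 3),
    ]
    manifest.names = [
        NameRecord(1001, 1, "NAME", "ChEBI", "water", "F", "en"),
        NameRecord(1002, 1, "SYNONYM", "ChEBI", "H2O", "F", "en"),
        NameRecord(1003, 2, "SYNONYM", "SUBMITTER", "WATER", "F", "en"),
        NameRecord(1004, 3, "NAME", "ChEBI", "D-glucose", "F", "en"),
        NameRecord(1005, 3, "SYNONYM", "KEGG COMPOUND", "dextrose", "F", "en"),
        NameRecord(1006, 3, "SYNONYM", "ChEBI", "grape sugar", "F", "en"),
        NameRecord(1007, 3, "IUPAC NAME", "IUPAC", "D-glucopyranose", "F", "en"),
        NameRecord(1008, 4, "NAME", "ChEBI", "aldohexose", "F", "en"),
    ]
    manifest.chemical_data = [
        ChemicalDatumRecord(2001, 1, "ChEBI", "FORMULA", "H2O"),
        ChemicalDatumRecord(2002, 1, "ChEBI", "MASS", "18.01530"),
        ChemicalDatumRecord(2003, 1, "ChEBI", "CHARGE", "0"),
        ChemicalDatumRecord(2004, 1, "ChEBI", "MONOISOTOPIC MASS", "18.01056"),
        ChemicalDatumRecord(2005, 3, "ChEBI", "FORMULA", "C6H12O6"),
        ChemicalDatumRecord(2006, 3, "ChEBI", "MASS", "180.15588"),
        ChemicalDatumRecord(2007, 3, "ChEBI", "CHARGE", "0"),
    ]
    manifest.accessions = [
        AccessionRecord(3001, 1, "ChEBI", "CAS Registry Number", "7732-18-5"),
        AccessionRecord(3002, 3, "ChEBI", "KEGG COMPOUND", "C00031"),
    ]
    manifest.relations = [
        RelationRecord(4001, "is_a", 3, 4, "C"),
    ]
    manifest.inchis = [
        InchiRecord(1, "InChI=1S/H2O/h1H2"),
        InchiRecord(3, "InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2"),
    ]
    manifest.comments = [
        CommentRecord(5001, 3, date(2016, 2, 2), "General Comment",
                      "Principal metabolic fuel in most organisms."),
    ]
    manifest.references = [
        ReferenceRecord(3, "PMID:23180789", "PubMed", None,
                        "Glucose metabolism fixture reference"),
    ]
    manifest.origins = [
        OriginRecord(6001, 3, "Homo sapiens", "NCBI:9606", "blood plasma",
                     None, "metabolite", None, None),
    ]
    manifest.structures = [
        StructureRecord(7001, 1, _molfile("water", quoted_comment=True),
                        "mol", "2D", True),
        StructureRecord(7002, 1, "O", "SMILES", "1D", True),
        StructureRecord(7003, 1, "XLYOFNOQVPJJNP-UHFFFAOYSA-N", "InChIKey",
                        "1D", True),
        StructureRecord(7004, 3,
                        "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O",
                        "SMILES", "1D", True),
        StructureRecord(7005, 3, "WQZGKKKJIJFFOK-GASJEMHNSA-N", "InChIKey",
                        "1D", True),
    ]
    manifest.parent_resolution = {1: 1, 2: 1, 3: 3, 4: 4}
    manifest.groups = {1: [1, 2], 3: [3], 4: [4]}
    _compute_expected_entities(manifest)

    path = None
    if out_dir is not None:
        path = write_release(manifest, out_dir)
    return path, manifest
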