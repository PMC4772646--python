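"""Flat-file parsing: dialects, the null sentinel, malformed rows, parent
resolution, relation duality, and on-demand streaming of the big files."""
from __future__ import annotations

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chebikit import (
    CyclicParentError,
    DanglingParentError,
    IncompleteReleaseError,
    MalformedRowError,
    UndefinedChebiIdError,
    parse_release,
    resolve_primary,
    stream_references,
    stream_structure,
)
from chebikit.parsers import ReleaseIndex, StructureRecord

from conftest import index_paths

COMPOUNDS_HEADER = (
    "ID\tSTATUS\tCHEBI_ACCESSION\tSOURCE\tPARENT_ID\tNAME\tDEFINITION"
    "\tMODIFIED_ON\tCREATED_BY\tSTAR"
)


def write_compounds(tmp_path, rows, header=COMPOUNDS_HEADER, eol="\n"):
    path = tmp_path / "compounds.tsv"
    path.write_text(eol.join([header, *rows]) + eol, encoding="utf-8")
    return path


def compound_row(cid, parent="null", name="x", definition="null"):
    return (
        f"{cid}\tC\tCHEBI:{cid}\tChEBI\t{parent}\t{name}\t{definition}"
        f"\t2016-01-01\tnull\t3"
    )


class TestParseRelease:
    def test_header_only_file_yields_empty_index(self, tmp_path):
        path = write_compounds(tmp_path, [])
        index = parse_release({"compounds": path})
        assert index.compounds == {}
        assert index.skipped_rows == 0

    def test_missing_compounds_table_is_incomplete_release(self):
        with pytest.raises(IncompleteReleaseError):
            parse_release({"names": "/nonexistent"})

    def test_generated_release_reproduces_manifest(self, generated):
        release_dir, manifest = generated
        index = parse_release(index_paths(release_dir), strict=True)
        assert index.compounds == {c.id: c for c in manifest.compounds}
        assert index.parent_of == {
            c.id: c.parent_id for c in manifest.compounds if c.parent_id is not None
        }
        assert index.group_of == {
            primary: set(members) for primary, members in manifest.groups.items()
        }
        flat_names = [n for rows in index.names.values() for n in rows]
        assert sorted(flat_names, key=lambda n: n.id) == sorted(
            manifest.names, key=lambda n: n.id
        )
        flat_rel = [r for rows in index.outgoing.values() for r in rows]
        assert sorted(flat_rel, key=lambda r: r.id) == sorted(
            manifest.relations, key=lambda r: r.id
        )
        assert index.inchis == {
            r.compound_id: r.inchi_text for r in manifest.inchis
        }

    def test_null_token_reads_as_absent_value(self, tmp_path):
        path = write_compounds(tmp_path, [compound_row(7, name="null")])
        record = parse_release({"compounds": path}).compounds[7]
        assert record.name is None
        assert record.definition is None
        assert record.created_by is None

    def test_crlf_line_endings_accepted(self, tmp_path):
        path = write_compounds(tmp_path, [compound_row(1), compound_row(2)], eol="\r\n")
        index = parse_release({"compounds": path})
        assert set(index.compounds) == {1, 2}

    def test_reordered_header_still_parses(self, tmp_path):
        header = (
            "STAR\tID\tSTATUS\tCHEBI_ACCESSION\tSOURCE\tPARENT_ID\tNAME"
            "\tDEFINITION\tMODIFIED_ON\tCREATED_BY"
        )
        row = "4\t9\tC\tCHEBI:9\tChEBI\tnull\tthing\tnull\t2016-01-01\tnull"
        path = write_compounds(tmp_path, [row], header=header)
        record = parse_release({"compounds": path}).compounds[9]
        assert record.star == 4
        assert record.name == "thing"

    def test_malformed_row_skipped_counted_and_warned(self, tmp_path, caplog):
        path = write_compounds(tmp_path, [compound_row(1), "3\tC\ttoo-few"])
        with caplog.at_level("WARNING"):
            index = parse_release({"compounds": path})
        assert set(index.compounds) == {1}
        assert index.skipped_rows == 1
        assert any("skipped" in r.message for r in caplog.records)

    def test_strict_mode_raises_on_malformed_row(self, tmp_path):
        path = write_compounds(tmp_path, ["3\tC\ttoo-few"])
        with pytest.raises(MalformedRowError):
            parse_release({"compounds": path}, strict=True)

    def test_unparseable_date_kept_as_raw_text(self, tmp_path):
        row = "1\tC\tCHEBI:1\tChEBI\tnull\tx\tnull\t01/02/2016\tnull\t3"
        path = write_compounds(tmp_path, [row])
        assert parse_release({"compounds": path}).compounds[1].modified_on == "01/02/2016"


class TestParentResolution:
    def test_dangling_parent_names_offending_id(self, tmp_path):
        path = write_compounds(tmp_path, [compound_row(5, parent=99)])
        with pytest.raises(DanglingParentError, match="99"):
            parse_release({"compounds": path})

    def test_cyclic_parent_chain_lists_cycle(self, tmp_path):
        rows = [compound_row(1, parent=2), compound_row(2, parent=1)]
        path = write_compounds(tmp_path, rows)
        with pytest.raises(CyclicParentError) as excinfo:
            parse_release({"compounds": path})
        assert set(excinfo.value.cycle) >= {1, 2}

    def test_chain_resolves_to_root_and_group_contains_chain(self, tmp_path):
        rows = [compound_row(1), compound_row(3, parent=1), compound_row(5, parent=3)]
        path = write_compounds(tmp_path, rows)
        index = parse_release({"compounds": path})
        assert resolve_primary(5, index) == 1
        assert resolve_primary(3, index) == 1
        assert resolve_primary(1, index) == 1  # idempotent on a primary
        assert index.group_of[1] >= {1, 3, 5}

    def test_resolution_matches_bruteforce_over_manifest(self, generated):
        release_dir, manifest = generated
        index = parse_release(index_paths(release_dir))
        parent_pairs = {
            c.id: c.parent_id for c in manifest.compounds if c.parent_id is not None
        }
        for compound in manifest.compounds:
            expected = compound.id
            while expected in parent_pairs:  # brute-force chain following
                expected = parent_pairs[expected]
            assert resolve_primary(compound.id, index) == expected

    def test_unknown_id_raises(self, tmp_path):
        path = write_compounds(tmp_path, [compound_row(1)])
        index = parse_release({"compounds": path})
        with pytest.raises(UndefinedChebiIdError):
            resolve_primary(999, index)


class TestRelationDuality:
    def test_every_relation_appears_once_on_each_side(self, generated):
        release_dir, _ = generated
        index = parse_release(index_paths(release_dir))
        outgoing = [r for rows in index.outgoing.values() for r in rows]
        incoming = [r for rows in index.incoming.values() for r in rows]
        assert sorted(outgoing, key=lambda r: r.id) == sorted(
            incoming, key=lambda r: r.id
        )
        for relation in outgoing:
            assert relation in index.outgoing[relation.init_id]
            assert relation in index.incoming[relation.final_id]


class TestMemoryContract:
    def test_index_has_no_structure_or_reference_fields(self):
        field_names = {f.name for f in dataclasses.fields(ReleaseIndex)}
        assert "structures" not in field_names
        assert "references" not in field_names

    def test_no_structure_or_reference_record_reachable_from_index(self, generated):
        import gc

        release_dir, _ = generated
        index = parse_release(index_paths(release_dir))
        from chebikit.parsers import ReferenceRecord

        seen: set[int] = set()
        frontier = [index]
        while frontier:
            obj = frontier.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            assert not isinstance(obj, (StructureRecord, ReferenceRecord))
            if isinstance(obj, (dict, list, tuple, set)) or dataclasses.is_dataclass(obj):
                frontier.extend(gc.get_referents(obj))


class TestStreaming:
    def test_compound_without_structures_is_absent(self, canonical):
        release_dir, _ = canonical
        record = stream_structure(4, "mol", release_dir / "structures.csv")
        assert record is None

    def test_default_molfile_returned_byte_identical(self, canonical):
        release_dir, manifest = canonical
        record = stream_structure(1, "mol", release_dir / "structures.csv")
        assert record.structure_text == manifest.entities[1]["mol"]
        assert "\n" in record.structure_text  # embedded newlines survive CSV
        assert '"' in record.structure_text  # doubled quotes survive CSV

    def test_default_preferred_over_earlier_nondefault(self, tmp_path):
        import csv

        path = tmp_path / "structures.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ("ID", "COMPOUND_ID", "STRUCTURE", "TYPE", "DIMENSION",
                 "DEFAULT_STRUCTURE")
            )
            writer.writerow((1, 7, "alt\nmol", "mol", "3D", "N"))
            writer.writerow((2, 7, "main\nmol", "mol", "2D", "Y"))
        record = stream_structure(7, "mol", path)
        assert record.structure_text == "main\nmol"
        assert record.is_default

    def test_streamed_structures_match_manifest_rows(self, generated):
        release_dir, manifest = generated
        path = release_dir / "structures.csv"
        for cid, expected in manifest.entities.items():
            record = stream_structure(cid, "SMILES", path)
            got = None if record is None else record.structure_text
            # only the entity layer resolves through the merged group
            own_rows = [
                s.structure_text
                for s in manifest.structures
                if s.compound_id == cid and s.structure_type == "SMILES"
            ]
            assert got == (own_rows[0] if own_rows else None)

    def test_references_returned_in_file_order(self, generated):
        release_dir, manifest = generated
        path = release_dir / "reference.tsv"
        first_compound = manifest.compounds[0].id
        expected = [
            r for r in manifest.references if r.compound_id == first_compound
        ]
        assert len(expected) == 3
        assert stream_references(first_compound, path) == expected

    def test_reference_results_independent_of_call_order(self, generated):
        release_dir, manifest = generated
        path = release_dir / "reference.tsv"
        ids = [c.id for c in manifest.compounds[:4]]
        forward = {cid: stream_references(cid, path) for cid in ids}
        backward = {cid: stream_references(cid, path) for cid in reversed(ids)}
        assert forward == backward

    def test_compound_with_no_reference_rows_yields_empty_list(self, canonical):
        release_dir, _ = canonical
        assert stream_references(4, release_dir / "reference.tsv") == []


@settings(deadline=None, max_examples=30)
@given(
    name=st.text(
        alphabet=st.characters(blacklist_characters="\t\n\r", min_codepoint=32),
        min_size=1,
        max_size=40,
    )
)
def test_null_token_vs_literal_text_roundtrip(tmp_path_factory, name):
    """The 4-character token 'null' always means absent; any other text is
    preserved verbatim through write-then-parse."""
    tmp_path = tmp_path_factory.mktemp("prop")
    path = write_compounds(tmp_path, [compound_row(1, name=name)])
    record = parse_release({"compounds": path}).compounds[1]
    if name == "null":
        assert record.name is None
    else:
        assert record.name == name
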