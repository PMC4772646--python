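"""Entity API: identifier normalisation, merged-group resolution, getter
semantics, laziness of structure/reference access."""
from __future__ import annotations

import builtins
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chebikit import (
    ChebiEntity,
    MalformedIdentifierError,
    Release,
    UndefinedChebiIdError,
    parse_identifier,
)

from conftest import entity_snapshot


class TestIdentifierNormalisation:
    @pytest.mark.parametrize(
        "text", ["CHEBI:15377", "chebi:15377", "15377", " CHEBI:15377 ", 15377]
    )
    def test_equivalent_forms_normalise_to_same_id(self, text):
        assert parse_identifier(text) == 15377

    @pytest.mark.parametrize(
        "text", ["", "CHEBI:", "CHEBI:x", "water", "0", "-3", "CHEBI:-1", None, 1.5]
    )
    def test_malformed_identifiers_rejected(self, text):
        with pytest.raises(MalformedIdentifierError):
            parse_identifier(text)

    @given(st.integers(min_value=1, max_value=10**9))
    def test_accession_and_bare_digits_agree(self, n):
        assert parse_identifier(f"CHEBI:{n}") == parse_identifier(str(n)) == n

    def test_constructor_forms_yield_equal_primary(self, canonical_release):
        a = ChebiEntity("CHEBI:1", release=canonical_release)
        b = ChebiEntity("1", release=canonical_release)
        assert a.primary_id == b.primary_id == 1

    def test_unknown_id_raises_with_identifier(self, canonical_release):
        with pytest.raises(UndefinedChebiIdError, match="999999"):
            ChebiEntity("CHEBI:999999", release=canonical_release)


class TestScalarGetters:
    def test_primary_scalar_fields(self, canonical_release, canonical):
        _, manifest = canonical
        water = canonical_release.entity("CHEBI:1")
        assert water.get_name() == "water"
        assert water.get_status() == "C"
        assert water.get_star() == 3
        assert water.get_definition() == manifest.entities[1]["definition"]

    def test_secondary_reads_primary_scalars_but_keeps_own_identity(
        self, canonical_release
    ):
        deprecated = canonical_release.entity("CHEBI:2")
        assert deprecated.get_name() == "water"  # primary's, not its own
        assert deprecated.get_id() == "CHEBI:2"
        assert deprecated.get_parent_id() == "CHEBI:1"
        primary = canonical_release.entity("CHEBI:1")
        assert primary.get_parent_id() is None

    def test_absent_definition_is_none_not_empty_text(self, canonical_release):
        assert canonical_release.entity("CHEBI:2").get_id() == "CHEBI:2"
        # aldohexose has a definition; the deprecated record's own is absent,
        # but scalars resolve to the primary -- so check a primary-level absence:
        water = canonical_release.entity("CHEBI:1")
        assert water.get_created_by() == "curator_a"

    def test_absent_charge_distinct_from_zero(self, canonical_release):
        aldohexose = canonical_release.entity("CHEBI:4")  # no chemical data rows
        glucose = canonical_release.entity("CHEBI:3")
        assert aldohexose.get_charge() is None
        assert glucose.get_charge() == 0

    @pytest.mark.parametrize("charge", range(-4, 5))
    def test_signed_charge_text_parses_to_integer(self, tmp_path, charge, canonical):
        release_dir, _ = canonical
        target = tmp_path / "rel"
        target.mkdir()
        for name in ("compounds.tsv", "chemical_data.tsv"):
            (target / name).write_text((release_dir / name).read_text())
        chem = target / "chemical_data.tsv"
        chem.write_text(
            chem.read_text().replace(
                "2003\t1\tChEBI\tCHARGE\t0", f"2003\t1\tChEBI\tCHARGE\t{charge}"
            )
        )
        release = Release(release_dir=target)
        assert release.entity(1).get_charge() == charge

    def test_mass_and_monoisotopic_mass_numeric(self, canonical_release):
        water = canonical_release.entity(1)
        assert water.get_mass() == pytest.approx(18.0153)
        assert water.get_monoisotopic_mass() == pytest.approx(18.01056)


class TestGroupSemantics:
    def test_names_union_primary_first_with_dedup(self, canonical_release):
        names = [n.name for n in canonical_release.entity("CHEBI:1").get_names()]
        assert names == ["water", "H2O", "WATER"]  # secondary synonym appended

    def test_duplicate_synonym_across_group_returned_once(self, tmp_path, canonical):
        release_dir, _ = canonical
        target = tmp_path / "rel"
        target.mkdir()
        for name in ("compounds.tsv", "names.tsv"):
            (target / name).write_text((release_dir / name).read_text())
        names_path = target / "names.tsv"
        names_path.write_text(
            names_path.read_text()
            + "1009\t2\tSYNONYM\tSUBMITTER\tH2O\tF\ten\n"
        )
        names = [n.name for n in Release(release_dir=target).entity(1).get_names()]
        assert names.count("H2O") == 1

    def test_all_getters_agree_between_secondary_and_primary(
        self, generated, generated_release
    ):
        _, manifest = generated
        secondaries = [c for c in manifest.compounds if c.parent_id is not None]
        assert secondaries, "fixture must contain secondary entries"
        for compound in secondaries:
            secondary = generated_release.entity(compound.id)
            primary = generated_release.entity(secondary.primary_id)
            snap_s = entity_snapshot(secondary)
            snap_p = entity_snapshot(primary)
            for skipped in ("id", "parent_id"):
                snap_s.pop(skipped)
                snap_p.pop(skipped)
            assert snap_s == snap_p, f"CHEBI:{compound.id}"

    def test_every_entity_matches_manifest_expectations(
        self, generated, generated_release
    ):
        _, manifest = generated
        for cid, expected in manifest.entities.items():
            snapshot = entity_snapshot(generated_release.entity(cid))
            snapshot["formulae"] = [tuple(p) for p in snapshot["formulae"]]
            expected = dict(expected)
            expected["formulae"] = [tuple(p) for p in expected["formulae"]]
            assert snapshot == expected, f"CHEBI:{cid}"


class TestStructures:
    def test_inchi_of_secondary_resolves_to_primary(self, canonical_release):
        assert (
            canonical_release.entity("CHEBI:2").get_inchi()
            == canonical_release.entity("CHEBI:1").get_inchi()
            == "InChI=1S/H2O/h1H2"
        )

    def test_entity_without_structures_absent(self, canonical_release):
        aldohexose = canonical_release.entity(4)
        assert aldohexose.get_mol() is None
        assert aldohexose.get_smiles() is None
        assert aldohexose.get_inchi_key() is None

    def test_mol_matches_manifest_line_count_and_content(
        self, canonical_release, canonical
    ):
        _, manifest = canonical
        mol = canonical_release.entity(1).get_mol()
        expected = manifest.entities[1]["mol"]
        assert mol == expected
        assert mol.count("\n") == expected.count("\n")

    def test_mol_filename_roundtrips_and_is_reused(self, canonical_release):
        entity = canonical_release.entity(1)
        path = entity.get_mol_filename()
        assert Path(path).read_text(encoding="utf-8") == entity.get_mol()
        assert entity.get_mol_filename() == path

    def test_mol_filename_absent_without_structure(self, canonical_release):
        assert canonical_release.entity(4).get_mol_filename() is None


class TestRelations:
    def test_outgoing_and_incoming_duality(self, canonical_release):
        glucose = canonical_release.entity("CHEBI:3")
        aldohexose = canonical_release.entity("CHEBI:4")
        [out] = glucose.get_outgoings()
        assert (out.relation_type, out.target_chebi_accession) == ("is_a", "CHEBI:4")
        [inc] = aldohexose.get_incomings()
        assert (inc.relation_type, inc.target_chebi_accession) == ("is_a", "CHEBI:3")
        assert glucose.get_incomings() == []
        assert aldohexose.get_outgoings() == []

    def test_relationless_entity_has_empty_lists(self, canonical_release):
        water = canonical_release.entity(1)
        assert water.get_outgoings() == []
        assert water.get_incomings() == []

    def test_list_orderings_deterministic_across_instances(self, generated):
        release_dir, manifest = generated
        first = Release(release_dir=release_dir)
        second = Release(release_dir=release_dir)
        for cid in manifest.entities:
            assert first.entity(cid).get_outgoings() == second.entity(cid).get_outgoings()
            assert first.entity(cid).get_names() == second.entity(cid).get_names()


class TestLaziness:
    def test_get_name_never_opens_structures_or_references(
        self, generated, monkeypatch
    ):
        release_dir, manifest = generated
        opened: list[str] = []
        real_open = builtins.open

        def recording_open(file, *args, **kwargs):
            opened.append(str(file))
            return real_open(file, *args, **kwargs)

        monkeypatch.setattr(builtins, "open", recording_open)
        release = Release(release_dir=release_dir)
        for compound in manifest.compounds:
            release.entity(compound.id).get_name()
        assert not any("structures.csv" in path for path in opened)
        assert not any("reference.tsv" in path for path in opened)
        # sanity: the index itself *was* built from the TSV tables
        assert any("compounds.tsv" in path for path in opened)

    def test_index_parsed_once_and_shared(self, generated, monkeypatch):
        release_dir, _ = generated
        release = Release(release_dir=release_dir)
        release.entity(1)
        import chebikit.parsers as parsers

        def exploding(*args, **kwargs):  # second parse would be a bug
            raise AssertionError("parse_release called twice for one Release")

        monkeypatch.setattr(parsers, "parse_release", exploding)
        release.entity(2)
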