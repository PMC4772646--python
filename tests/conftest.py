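"""Shared fixtures: generated releases, the canonical mini-release, an
instrumented transport, and a local mock HTTP server standing in for the
remote flat-file area."""
from __future__ import annotations

import dataclasses
import threading
from functools import partial
from http.server import SimpleHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

import pytest

from chebikit import Release
from chebikit.cache import LOGICAL_FILES, default_transport
from chebikit.fixtures import FixtureSpec, canonical_mini_release, generate


def index_paths(release_dir: Path) -> dict[str, Path]:
    """Paths of the nine indexable TSV tables of a release directory."""
    return {
        logical: release_dir / filename
        for logical, filename in LOGICAL_FILES.items()
        if logical not in ("structures", "reference")
        and (release_dir / filename).exists()
    }


def entity_snapshot(entity) -> dict:
    """All getter outputs of an entity, shaped like a manifest expectation."""
    return {
        "id": entity.get_id(),
        "parent_id": entity.get_parent_id(),
        "primary_id": entity.primary_id,
        "name": entity.get_name(),
        "definition": entity.get_definition(),
        "status": entity.get_status(),
        "source": entity.get_source(),
        "created_by": entity.get_created_by(),
        "modified_on": entity.get_modified_on(),
        "star": entity.get_star(),
        "names": [dataclasses.asdict(n) for n in entity.get_names()],
        "formula": entity.get_formula(),
        "formulae": [list(pair) for pair in entity.get_formulae()],
        "mass": entity.get_mass(),
        "monoisotopic_mass": entity.get_monoisotopic_mass(),
        "charge": entity.get_charge(),
        "database_accessions": [
            dataclasses.asdict(a) for a in entity.get_database_accessions()
        ],
        "comments": [dataclasses.asdict(c) for c in entity.get_comments()],
        "compound_origins": [
            dataclasses.asdict(o) for o in entity.get_compound_origins()
        ],
        "inchi": entity.get_inchi(),
        "inchi_key": entity.get_inchi_key(),
        "smiles": entity.get_smiles(),
        "mol": entity.get_mol(),
        "references": [dataclasses.asdict(r) for r in entity.get_references()],
        "outgoings": [dataclasses.asdict(r) for r in entity.get_outgoings()],
        "incomings": [dataclasses.asdict(r) for r in entity.get_incomings()],
    }


class CountingTransport:
    """Transport wrapper recording every remote access."""

    def __init__(self, inner=default_transport):
        self.inner = inner
        self.calls: list[str] = []

    def __call__(self, url: str) -> bytes:
        self.calls.append(url)
        return self.inner(url)


@pytest.fixture()
def counting_transport():
    return CountingTransport()


@pytest.fixture(scope="session")
def canonical(tmp_path_factory):
    """(release directory, manifest) of the fixed documentation fixture."""
    out = tmp_path_factory.mktemp("canonical")
    path, manifest = canonical_mini_release(out)
    return path, manifest


@pytest.fixture(scope="session")
def canonical_release(canonical):
    path, _ = canonical
    return Release(release_dir=path)


@pytest.fixture(scope="session")
def generated(tmp_path_factory):
    """A mid-sized generated release with deep parent chains."""
    out = tmp_path_factory.mktemp("generated")
    spec = FixtureSpec(n_primary=11, n_secondary=6, max_parent_chain=3, seed=42)
    path, manifest = generate(spec, out)
    return path, manifest


@pytest.fixture(scope="session")
def generated_release(generated):
    path, _ = generated
    return Release(release_dir=path)


@pytest.fixture()
def mock_server(tmp_path_factory):
    """Serve a directory over local HTTP; yields (base_url, directory)."""
    directory = tmp_path_factory.mktemp("served")

    class SilentHandler(SimpleHTTPRequestHandler):
        def log_message(self, *args):
            pass

    handler = partial(SilentHandler, directory=str(directory))
    server = ThreadingHTTPServer(("127.0.0.1", 0), handler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    host, port = server.server_address
    yield f"http://{host}:{port}", directory
    server.shutdown()
    thread.join(timeout=5)
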