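# chebikit

Local, offline-capable programmatic access to ChEBI flat-file releases.

ChEBI (Chemical Entities of Biological Interest) is a human-curated
database and ontology of small molecules. Each entry is keyed by an
accession of the form `CHEBI:<n>` and carries names and synonyms, chemical
data (formula, mass, charge), structures (molfile, SMILES, InChI),
cross-references to external databases, literature references and typed
ontology relations such as `is_a` or `has_role`. Because the database is
curated, duplicate entries are merged: a deprecated identifier is retained
but linked to the primary entry that absorbed it, and any software reading
the raw release tables has to re-implement that identifier mapping.

`chebikit` hides all of this behind one entry point. It maintains a local
cache of the release flat files (downloaded on demand, decompressed, and
refreshed automatically once older than a configurable age — 30 days by
default, matching the monthly release cycle), parses the tab-separated
tables into an in-memory index, and exposes every entity through a
`ChebiEntity` whose getters transparently resolve secondary identifiers
through their merged group. The two large files — structures and
literature references — are never held in memory; they are streamed from
disk only when a getter needs them. Once the cache is populated, no
network access is required at all.

The package also ships a deterministic fixture generator that emits
complete miniature releases together with a ground-truth manifest, so
applications (and this package's own test suite) can run fully offline
against realistic data.

## Worked example

```python
from chebikit import Release, canonical_mini_release

release_dir, manifest = canonical_mini_release("demo-release")
release = Release(release_dir=release_dir)

glucose = release.entity("CHEBI:3")
print(glucose.get_name())       # D-glucose
print(glucose.get_formula())    # C6H12O6
print(glucose.get_charge())     # 0
print([n.name for n in glucose.get_names()])
# ['D-glucose', 'dextrose', 'grape sugar', 'D-glucopyranose']
for rel in glucose.get_outgoings():
    print(rel.relation_type, rel.target_chebi_accession)  # is_a CHEBI:4

old_id = release.entity("CHEBI:2")   # a deprecated identifier
print(old_id.get_name())             # water  (resolved through its parent)
print(old_id.get_parent_id())        # CHEBI:1
```

`get_id()` always echoes the identifier you asked for, while every other
getter answers for the merged group, so deprecated ids keep working and
remain detectable via `get_parent_id()`.

Against a live release, construct the entity directly and let the cache
fetch the files on first use:

```python
from chebikit import CacheConfig, ChebiEntity, Release, set_default_release

set_default_release(Release(cache_config=CacheConfig(cache_dir="~/.chebikit")))
water = ChebiEntity("CHEBI:15377")
```

The same operations are available from the shell:

```
chebikit fixture --out demo-release --seed 7
chebikit --release-dir demo-release entity CHEBI:1 --fields name,formula,charge
chebikit --release-dir demo-release relations CHEBI:3 --direction out
chebikit --cache-dir ~/.chebikit cache status
```

Exit codes: 0 success, 2 user error, 3 offline cache miss, 4 fetch
failure. Data goes to stdout and logging to stderr, so output is
pipe-safe.

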