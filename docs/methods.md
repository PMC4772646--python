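# Methods

## The access model

ChEBI distributes its content as a set of flat-file tables refreshed
monthly: compounds, names, chemical data, database accessions, relations,
InChI, comments, literature references, compound origins, and structures.
`chebikit` treats one such set as a *release* and layers three mechanisms
over it:

1. **A download cache** (`chebikit.cache`). Before any table is parsed, a
   check decides whether a usable local copy exists. A file is fetched
   from the configured base location only when missing or *stale*, i.e.
   retrieved more than `max_age` ago. Containers (`.gz`, `.zip`) are
   recognised by suffix and unpacked transparently; a zip with several
   members selects the member matching the logical file name. The payload
   is decompressed in full and moved into place with an atomic rename, so
   an interrupted or corrupt download can never leave a truncated table
   behind — the previous valid copy (or no file) survives. With
   `offline=True` no remote access is ever attempted: a present copy is
   served regardless of age, a missing one raises an offline-cache-miss
   error naming the file.

2. **Parsers and the in-memory index** (`chebikit.parsers`). Nine tables
   are TSV with a header row; the literal token `null` denotes an absent
   value and round-trips to `None`, never to four-character text. Headers
   are located by name, so a reordered dialect still parses, and a
   column-map override re-points any table at a different header
   vocabulary. The structures table is RFC-4180 quoted CSV whose
   STRUCTURE field carries MDL molfile text verbatim, including embedded
   newlines and doubled quotes. `parse_release` builds dictionaries from
   compound id to typed records and precomputes the secondary-identifier
   machinery: `parent_of` (immediate parent links) and `group_of` (each
   primary's full merged group, the transitive closure of parent links).
   Parent links are validated to form a forest — a dangling parent or a
   cycle aborts the parse with a named error.

3. **The entity surface** (`chebikit.entity`). A `ChebiEntity` accepts
   `CHEBI:<n>` (case-insensitive) or bare digits and resolves to its
   primary at construction. Getter semantics over the merged group:
   scalar fields come from the primary record; chemical-data getters
   prefer the primary's row and fall back to the lowest-id member holding
   one; list getters return ordered, de-duplicated unions over the group
   (primary first, then secondaries ascending; within a member, file
   order; first occurrence wins). Relations are unioned the same way and
   sorted by predicate then target id, making orderings reproducible
   across runs and platforms. Only `get_id`/`get_parent_id` reflect the
   requested record itself, so deprecation stays visible.

## The memory contract

The structures and references files dominate a release's size, so they
are never indexed: `ReleaseIndex` has no field for either, and
`stream_structure`/`stream_references` scan the files sequentially,
holding at most the current row and one fallback candidate. A structure
row flagged as default wins immediately; otherwise the first matching row
is used. Consequently, constructing entities and reading names, formulae
or relations never opens those files at all — a property the test suite
asserts with an instrumented `open` and a reachability walk over the
index.

## Merged-group design choices

How reads should behave across a merged group is genuinely open; the
choices here are:

- list fields are unions over the whole group rather than the primary's
  rows only, so curated synonyms attached to absorbed entries are never
  lost;
- de-duplication keys are the user-visible fields (for names:
  name/type/language), so the same synonym recorded by two sources
  appears once;
- absent values are `None`, distinct from `0` or empty text — a compound
  with no CHARGE row reports no charge, not zero.

## The fixture generator

`chebikit.fixtures` is a public module, not test scaffolding: it emits a
complete miniature release (all ten tables, plus a gzip variant of each,
plus `manifest.json`) that is internally consistent and deterministic —
the same spec and seed are byte-identical, with gzip timestamps pinned.
Defaults are 10 primary and 5 secondary compounds, parent chains up to
depth 2, and 1.5 relations per primary; names, formulae, masses and line
notations come from a small embedded vocabulary of real small molecules
so failures stay readable. Generated releases deliberately cover the
parsers' corner cases: `null` sentinels, a CRLF-terminated table, parent
chains deeper than one hop, duplicate synonyms across a group, a
compound with no charge row, a formula held only by a secondary member,
multiple mol rows with one default, and a multi-line molfile containing
double quotes.

The manifest is the ground truth: every record of every table plus
expected getter outputs for every entity, computed by brute force (chain
following, nested-loop unions) independently of the parsing and entity
code it is used to check. What the fixtures do *not* emulate: the scale
of a live release (tens of thousands of entities), its exact column
order, or chemically valid structures — molfile blocks are shaped like
molfiles but carry no chemistry. Passing tests therefore demonstrate the
correctness of the mechanics (parsing, resolution, caching, streaming,
ordering), not compatibility with any particular live dialect; the
column-map and relation-direction switches exist precisely so a
differing live layout can be accommodated without code changes.

## Numerical and policy details

- Staleness is judged from the local retrieval timestamp kept in a
  sidecar file (`retrieved.tsv`), falling back to file mtime if the
  sidecar is lost; the default `max_age` is 30 days. Age exactly equal to
  `max_age` is still fresh (strict inequality).
- The clock and the transport are constructor-injectable, which is how
  staleness and fetch counting are tested deterministically.
- Malformed rows (wrong column count) are skipped, logged and counted;
  `strict=True` upgrades them to errors. Unknown single-letter status
  codes are accepted as-is.
- Dates are parsed as ISO-8601; an unparseable date is kept as raw text
  with a warning rather than failing the row.
- MASS / MONOISOTOPIC MASS parse to floats (unified atomic mass units),
  CHARGE to an integer (elementary charge, range includes signs); a
  non-numeric token where a number is required raises an error naming
  the row.
- The relation table is read as `INIT_ID --TYPE--> FINAL_ID`, an entity's
  outgoing edges being rows with `INIT_ID` equal to a group member; a
  `swap_relation_direction` switch inverts this for dialects oriented the
  other way.

## Problem sizes

The test suite and `scripts/acceptance.py` run over twenty generated
releases of 8–12 primaries and 3–6 secondaries each (≈3,400 records in
total), one mid-sized shared release, and the fixed four-compound
canonical release. These sizes exercise every code path while keeping the
whole suite in the low seconds; the generator accepts larger counts
(≈10⁴ records) for users who want heavier fixtures.

## Known limitations

- No text search, no transitive ontology closure (only one-hop
  outgoing/incoming relations), no entity depictions, and no SDF/OBO/OWL
  parsing — the flat files are the only supported format.
- Structures are returned verbatim; no sanitisation, canonicalisation or
  chemical interpretation is performed.
- Staleness is age-based; the upstream server's own modification time is
  not consulted, so a mid-cycle upstream fix is picked up only after the
  local copy ages out (or an explicit `cache update`/`purge`).
- Downloads are not resumable and no upstream checksums are verified
  beyond the container format's own integrity checking.
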