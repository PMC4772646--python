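"""Exception hierarchy for chebikit.

Every error raised deliberately by the package derives from
:class:`ChebiKitError`, so callers can catch one type at an API boundary.
"""


class ChebiKitError(Exception):
    """Base class for all chebikit errors."""


# --- cache layer -----------------------------------------------------------

class CacheError(ChebiKitError):
    """Base class for download-cache failures."""


class OfflineCacheMissError(CacheError):
    """Offline mode is set and the requested file has no local copy."""

    def __init__(self, logical_name: str):
        self.logical_name = logical_name
        super().__init__(
            f"offline cache miss: no local copy of {logical_name!r} and "
            "offline mode forbids fetching"
        )


class FetchFailedError(CacheError):
    """A remote fetch failed (network error or missing remote file)."""


class CorruptDownloadError(CacheError):
    """A downloaded container could not be decompressed; the partial file
    has been removed."""


# --- parsing layer ---------------------------------------------------------

class ParseError(ChebiKitError):
    """Base class for flat-file parsing failures."""


class IncompleteReleaseError(ParseError):
    """The mandatory compounds table is missing from a release."""


class DanglingParentError(ParseError):
    """A compound's parent id does not exist in the compounds table."""

    def __init__(self, child_id: int, parent_id: int):
        self.child_id = child_id
        self.parent_id = parent_id
        super().__init__(
            f"dangling parent: compound {child_id} points at parent "
            f"{parent_id}, which is not in the compounds table"
        )


class CyclicParentError(ParseError):
    """Parent links form a cycle instead of a forest."""

    def __init__(self, cycle: list[int]):
        self.cycle = list(cycle)
        chain = " -> ".join(str(i) for i in self.cycle)
        super().__init__(f"cyclic parent chain: {chain}")


class MalformedRowError(ParseError):
    """A row has the wrong column count (raised only in strict mode)."""


class CorruptStructuresFileError(ParseError):
    """The structures CSV could not be read."""


class CorruptChemicalDatumError(ParseError):
    """A chemical-data value that must be numeric does not parse as one."""

    def __init__(self, row_id: int, value: str):
        self.row_id = row_id
        self.value = value
        super().__init__(
            f"corrupt chemical datum: row {row_id} holds non-numeric "
            f"value {value!r}"
        )


# --- entity layer ----------------------------------------------------------

class UndefinedChebiIdError(ChebiKitError, KeyError):
    """The identifier is well-formed but names no compound in the release."""

    def __init__(self, identifier: str):
        self.identifier = identifier
        super().__init__(f"undefined ChEBI id: {identifier!r}")

    def __str__(self) -> str:  # KeyError would repr-quote the message
        return self.args[0]


class MalformedIdentifierError(ChebiKitError, ValueError):
    """The identifier text is not of the form 'CHEBI:<n>' or '<n>'."""

    def __init__(self, identifier):
        self.identifier = identifier
        super().__init__(f"malformed identifier: {identifier!r}")


class UnsatisfiableFixtureSpecError(ChebiKitError, ValueError):
    """A fixture specification cannot be realised (e.g. secondaries with
    no primaries to attach them to)."""
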