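"""Download cache for ChEBI flat-file releases.

ChEBI publishes its release as a set of flat files that are refreshed
monthly.  This module implements the check–fetch–parse flow: before a table
is parsed, a check decides whether a usable local copy exists; if it is
missing or older than the configured maximum age, the file is fetched from
the remote base location, decompressed and atomically moved into place.
Once all files are cached the library works fully offline.

Both the clock and the transport are injectable so staleness and fetch
behaviour are deterministically testable without a network.
"""
from __future__ import annotations

import contextlib
import gzip
import io
import logging
import os
import shutil
import tempfile
import urllib.error
import urllib.request
import zipfile
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Callable

from .exceptions import (
    CorruptDownloadError,
    FetchFailedError,
    OfflineCacheMissError,
)

logger = logging.getLogger(__name__)

#: Logical file identity -> decompressed local filename.  The ten tables of
#: a flat-file release.
LOGICAL_FILES: dict[str, str] = {
    "compounds": "compounds.tsv",
    "names": "names.tsv",
    "chemical_data": "chemical_data.tsv",
    "database_accession": "database_accession.tsv",
    "relation": "relation.tsv",
    "inchi": "chebiId_inchi.tsv",
    "comments": "comments.tsv",
    "reference": "reference.tsv",
    "compound_origins": "compound_origins.tsv",
    "structures": "structures.csv",
}

#: Default remote flat-file area of the ChEBI FTP site.
DEFAULT_BASE_URL = (
    "https://ftp.ebi.ac.uk/pub/databases/chebi/Flat_file_tab_delimited"
)

#: Name of the sidecar key-value file holding retrieval timestamps.
SIDECAR_NAME = "retrieved.tsv"


def _utcnow() -> datetime:
    return datetime.now(timezone.utc)


def default_transport(url: str) -> bytes:
    """Fetch ``url`` and return its raw bytes.

    Understands http(s)/ftp/file URLs via :mod:`urllib`; anything without a
    scheme is treated as a local directory path (the primary mode in tests
    and air-gapped deployments).  Raises :class:`FileNotFoundError` or
    :class:`urllib.error.URLError` on failure; callers wrap these.
    """
    if "://" in url:
        with urllib.request.urlopen(url) as resp:  # noqa: S310 - scheme checked by caller config
            return resp.read()
    return Path(url).read_bytes()


@dataclass
class CacheConfig:
    """Where and how the release cache operates.

    Parameters
    ----------
    cache_dir:
        Directory holding one decompressed file per logical name plus a
        sidecar timestamp file.  Created on first use.
    base_url:
        Remote location of the flat files (http(s)/ftp URL or a local
        directory for tests).
    max_age:
        Age beyond which a cached file is considered stale and re-fetched.
        The release is refreshed monthly upstream, hence the 30-day default.
    offline:
        If true, no remote access is ever attempted; a missing file raises
        :class:`OfflineCacheMissError` instead.
    clock, transport:
        Injection points for tests.
    """

    cache_dir: Path
    base_url: str = DEFAULT_BASE_URL
    max_age: timedelta = timedelta(days=30)
    offline: bool = False
    clock: Callable[[], datetime] = field(default=_utcnow, repr=False)
    transport: Callable[[str], bytes] = field(default=default_transport, repr=False)

    def __post_init__(self) -> None:
        self.cache_dir = Path(self.cache_dir)
        if isinstance(self.max_age, (int, float)):
            self.max_age = timedelta(days=self.max_age)


@dataclass(frozen=True)
class FileRecord:
    """A usable, decompressed local copy of one logical file."""

    logical_name: str
    local_path: Path
    retrieved_at: datetime
    decompressed: bool


def is_stale(record: FileRecord, now: datetime, max_age: timedelta) -> bool:
    """True iff ``record`` was retrieved more than ``max_age`` ago.

    Pure function of its arguments; the strict inequality means a file of
    age exactly ``max_age`` is still fresh.
    """
    return (now - record.retrieved_at) > max_age


# --- sidecar metadata ------------------------------------------------------

def _read_sidecar(cache_dir: Path) -> dict[str, datetime]:
    sidecar = cache_dir / SIDECAR_NAME
    stamps: dict[str, datetime] = {}
    if not sidecar.exists():
        return stamps
    for line in sidecar.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        name, _, ts = line.partition("\t")
        try:
            stamps[name] = datetime.fromisoformat(ts)
        except ValueError:
            logger.warning("ignoring unparseable sidecar line: %r", line)
    return stamps


def _write_sidecar(cache_dir: Path, stamps: dict[str, datetime]) -> None:
    sidecar = cache_dir / SIDECAR_NAME
    body = "".join(f"{k}\t{v.isoformat()}\n" for k, v in sorted(stamps.items()))
    tmp = sidecar.with_suffix(".tmp")
    tmp.write_text(body, encoding="utf-8")
    os.replace(tmp, sidecar)


# --- fetch & decompress ----------------------------------------------------

def _remote_candidates(logical_name: str) -> list[str]:
    """Remote filenames tried in order: gzip, zip, then plain."""
    base = LOGICAL_FILES[logical_name]
    return [base + ".gz", base + ".zip", base]


def _decompress(raw: bytes, remote_name: str, logical_name: str) -> bytes:
    """Unpack ``raw`` according to the container suffix of ``remote_name``.

    A zip holding several members selects the member matching the logical
    file's name.  Raises :class:`CorruptDownloadError` on a truncated or
    invalid container.
    """
    try:
        if remote_name.endswith(".gz"):
            return gzip.decompress(raw)
        if remote_name.endswith(".zip"):
            with zipfile.ZipFile(io.BytesIO(raw)) as zf:
                names = zf.namelist()
                wanted = LOGICAL_FILES[logical_name]
                member = next(
                    (n for n in names if Path(n).name == wanted),
                    None,
                )
                if member is None:
                    member = next(
                        (n for n in names if logical_name in Path(n).name),
                        None,
                    )
                if member is None:
                    if len(names) == 1:
                        member = names[0]
                    else:
                        raise CorruptDownloadError(
                            f"zip for {logical_name!r} has no matching "
                            f"member among {names}"
                        )
                return zf.read(member)
        return raw
    except CorruptDownloadError:
        raise
    except Exception as exc:  # gzip.BadGzipFile, zipfile.BadZipFile, EOFError...
        raise CorruptDownloadError(
            f"corrupt download for {logical_name!r}: {exc}"
        ) from exc


def ensure_file(logical_name: str, config: CacheConfig) -> FileRecord:
    """Return a readable decompressed local copy of ``logical_name``.

    Fetches from ``config.base_url`` only when the local copy is missing or
    stale.  The fetched payload is decompressed in full and moved into place
    with an atomic rename, so a failed download never leaves a truncated
    file behind.
    """
    if logical_name not in LOGICAL_FILES:
        raise ValueError(
            f"unknown logical file {logical_name!r}; expected one of "
            f"{sorted(LOGICAL_FILES)}"
        )
    cache_dir = config.cache_dir
    cache_dir.mkdir(parents=True, exist_ok=True)
    local = cache_dir / LOGICAL_FILES[logical_name]
    now = config.clock()
    stamps = _read_sidecar(cache_dir)

    if local.exists() and local.stat().st_size > 0:
        retrieved = stamps.get(logical_name)
        if retrieved is None:
            # Sidecar lost (e.g. hand-copied cache): fall back to file mtime.
            retrieved = datetime.fromtimestamp(local.stat().st_mtime, timezone.utc)
        record = FileRecord(logical_name, local, retrieved, decompressed=True)
        if config.offline or not is_stale(record, now, config.max_age):
            return record

    if config.offline:
        raise OfflineCacheMissError(logical_name)

    base = config.base_url.rstrip("/")
    last_error: Exception | None = None
    for remote_name in _remote_candidates(logical_name):
        url = f"{base}/{remote_name}"
        try:
            raw = config.transport(url)
        except Exception as exc:
            last_error = exc
            logger.debug("fetch of %s failed: %s", url, exc)
            continue
        payload = _decompress(raw, remote_name, logical_name)
        if not payload:
            raise CorruptDownloadError(
                f"fetched {logical_name!r} from {url} but payload is empty"
            )
        fd, tmp_path = tempfile.mkstemp(
            dir=cache_dir, prefix=local.name + ".", suffix=".part"
        )
        try:
            with os.fdopen(fd, "wb") as fh:
                fh.write(payload)
            os.replace(tmp_path, local)
        except BaseException:
            with contextlib.suppress(FileNotFoundError):
                os.unlink(tmp_path)
            raise
        stamps[logical_name] = now
        _write_sidecar(cache_dir, stamps)
        logger.info("fetched %s from %s", logical_name, url)
        return FileRecord(
            logical_name, local, now, decompressed=remote_name != LOGICAL_FILES[logical_name]
        )
    raise FetchFailedError(
        f"fetch failed for {logical_name!r} from {base}: {last_error}"
    ) from last_error


def purge(config: CacheConfig) -> int:
    """Remove all managed files from the cache; return how many flat files
    were removed.  A missing cache directory is a no-op returning 0."""
    cache_dir = Path(config.cache_dir)
    if not cache_dir.is_dir():
        return 0
    removed = 0
    for filename in LOGICAL_FILES.values():
        path = cache_dir / filename
        if path.exists():
            path.unlink()
            removed += 1
    sidecar = cache_dir / SIDECAR_NAME
    if sidecar.exists():
        sidecar.unlink()
    molcache = cache_dir / "mol"
    if molcache.is_dir():
        shutil.rmtree(molcache)
    return removed
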