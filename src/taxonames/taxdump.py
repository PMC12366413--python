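"""Acquire, parse, validate and cache a local copy of the NCBI taxonomy.

The NCBI taxonomy is distributed as a "taxdump" archive of pipe-delimited
``*.dmp`` tables. This module loads those tables into an immutable
:class:`TaxonomyStore`, enforces referential integrity (every parent exists,
no cycles, one scientific name per node), resolves merged/deleted ids, tracks
staleness of the local copy, and round-trips the store through an Apache
Arrow cache for fast reloads.

The dmp dialect: fields are separated by the three-character sequence
``\\t|\\t`` and each record is terminated by ``\\t|`` before the newline.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import os
import tarfile
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pyarrow as pa
import pyarrow.feather as feather

from .errors import (
    CacheVersionError,
    ChecksumMismatchError,
    DeletedTaxonError,
    DmpParseError,
    IntegrityError,
    TaxdumpLoadError,
    UnknownTaxonError,
)

logger = logging.getLogger(__name__)

FIELD_SEP = "\t|\t"
RECORD_TERMINATOR = "\t|"

#: files that must be present in a taxdump directory
MANDATORY_FILES = ("names.dmp", "nodes.dmp", "division.dmp")
OPTIONAL_FILES = ("merged.dmp", "delnodes.dmp")

#: default download location of the full taxdump archive
TAXDUMP_URL = "https://ftp.ncbi.nlm.nih.gov/pub/taxonomy/taxdump.tar.gz"

#: bumped whenever the cache layout changes
CACHE_SCHEMA_VERSION = 1

STALE_AFTER_DAYS = 90
_SECONDS_PER_DAY = 86400.0

ENV_STORAGE_VAR = "NCBITAXONOMY_PATH"


@dataclass(frozen=True, slots=True)
class NameRecord:
    """One row of the names table."""

    tax_id: int
    name_txt: str
    unique_name: str
    name_class: str


@dataclass(frozen=True, slots=True)
class NodeRecord:
    """One row of the nodes table (columns beyond division id are dropped)."""

    tax_id: int
    parent_tax_id: int
    rank: str
    division_id: int


@dataclass(frozen=True, slots=True)
class DivisionRecord:
    """One row of the divisions table."""

    division_id: int
    code: str
    name: str


@dataclass
class TaxonomyStore:
    """An indexed, immutable snapshot of one taxdump version.

    All query operations across the library are pure; nothing mutates the
    tables after :func:`load_taxdump` returns. Secondary indexes (name
    lookup maps, children map) are built lazily and cached.
    """

    names: tuple[NameRecord, ...]
    nodes: dict[int, NodeRecord]
    divisions: dict[int, DivisionRecord]
    merged: dict[int, int]
    deleted: frozenset[int]
    created_at: float
    source_checksum: str = ""

    # lazily built secondary indexes (not part of identity/equality)
    _names_by_id: dict[int, tuple[NameRecord, ...]] | None = field(
        default=None, repr=False, compare=False
    )
    _scientific: dict[int, str] | None = field(default=None, repr=False, compare=False)
    _exact_index: dict[str, tuple[NameRecord, ...]] | None = field(
        default=None, repr=False, compare=False
    )
    _folded_index: dict[str, tuple[NameRecord, ...]] | None = field(
        default=None, repr=False, compare=False
    )
    _children: dict[int, tuple[int, ...]] | None = field(
        default=None, repr=False, compare=False
    )

    # -- basic accessors ---------------------------------------------------

    @property
    def names_by_id(self) -> Mapping[int, tuple[NameRecord, ...]]:
        if self._names_by_id is None:
            by_id: dict[int, list[NameRecord]] = {}
            for rec in self.names:
                by_id.setdefault(rec.tax_id, []).append(rec)
            self._names_by_id = {k: tuple(v) for k, v in by_id.items()}
        return self._names_by_id

    def scientific_name(self, tax_id: int) -> str:
        if self._scientific is None:
            self._scientific = {
                r.tax_id: r.name_txt
                for r in self.names
                if r.name_class == "scientific name"
            }
        return self._scientific[tax_id]

    def children_of(self, tax_id: int) -> tuple[int, ...]:
        if self._children is None:
            kids: dict[int, list[int]] = {}
            for node in self.nodes.values():
                if node.tax_id == node.parent_tax_id:  # root
                    continue
                kids.setdefault(node.parent_tax_id, []).append(node.tax_id)
            self._children = {k: tuple(sorted(v)) for k, v in kids.items()}
        return self._children.get(tax_id, ())

    def division_id_by_name(self, name: str) -> int | None:
        for div in self.divisions.values():
            if div.name == name:
                return div.division_id
        return None


# ---------------------------------------------------------------------------
# dmp parsing and serialization
# ---------------------------------------------------------------------------


def parse_dmp_record(line: str, filename: str = "<string>", lineno: int = 0) -> list[str]:
    """Split one ``*.dmp`` record into its fields.

    Fields are separated by ``\\t|\\t``; the record is terminated by ``\\t|``.
    Whitespace *inside* fields is preserved exactly.
    """
    line = line.rstrip("\r\n")
    if not line.endswith(RECORD_TERMINATOR):
        raise DmpParseError(
            f"malformed dmp record (missing terminator {RECORD_TERMINATOR!r}): {line!r}",
            filename,
            lineno,
        )
    return line[: -len(RECORD_TERMINATOR)].split(FIELD_SEP)


def format_dmp_record(fields: Iterable[str]) -> str:
    """Inverse of :func:`parse_dmp_record` (without the newline)."""
    return FIELD_SEP.join(str(f) for f in fields) + RECORD_TERMINATOR


def _iter_dmp(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            yield lineno, parse_dmp_record(line, filename=path.name, lineno=lineno)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_taxdump(directory: str | os.PathLike, source_checksum: str = "") -> TaxonomyStore:
    """Parse a taxdump directory into a validated :class:`TaxonomyStore`.

    ``names.dmp``, ``nodes.dmp`` and ``division.dmp`` are mandatory;
    ``merged.dmp`` and ``delnodes.dmp`` are treated as empty when absent.
    ``created_at`` is the earliest modification time of the raw files.
    """
    directory = Path(directory)
    for fname in MANDATORY_FILES:
        if not (directory / fname).is_file():
            raise TaxdumpLoadError(f"mandatory file {fname} not found in {directory}")

    nodes: dict[int, NodeRecord] = {}
    for lineno, fields in _iter_dmp(directory / "nodes.dmp"):
        if len(fields) < 5:
            raise DmpParseError(
                f"nodes.dmp record needs >= 5 fields, got {len(fields)}",
                "nodes.dmp",
                lineno,
            )
        node = NodeRecord(
            tax_id=int(fields[0]),
            parent_tax_id=int(fields[1]),
            rank=fields[2],
            division_id=int(fields[4]),
        )
        nodes[node.tax_id] = node

    names: list[NameRecord] = []
    for lineno, fields in _iter_dmp(directory / "names.dmp"):
        if len(fields) < 4:
            raise DmpParseError(
                f"names.dmp record needs 4 fields, got {len(fields)}",
                "names.dmp",
                lineno,
            )
        names.append(
            NameRecord(
                tax_id=int(fields[0]),
                name_txt=fields[1],
                unique_name=fields[2],
                name_class=fields[3],
            )
        )

    divisions: dict[int, DivisionRecord] = {}
    for lineno, fields in _iter_dmp(directory / "division.dmp"):
        div = DivisionRecord(
            division_id=int(fields[0]), code=fields[1], name=fields[2]
        )
        divisions[div.division_id] = div

    merged: dict[int, int] = {}
    if (directory / "merged.dmp").is_file():
        for _, fields in _iter_dmp(directory / "merged.dmp"):
            merged[int(fields[0])] = int(fields[1])

    deleted: set[int] = set()
    if (directory / "delnodes.dmp").is_file():
        for _, fields in _iter_dmp(directory / "delnodes.dmp"):
            deleted.add(int(fields[0]))

    created_at = min(
        (directory / f).stat().st_mtime
        for f in MANDATORY_FILES + OPTIONAL_FILES
        if (directory / f).is_file()
    )

    store = TaxonomyStore(
        names=tuple(names),
        nodes=nodes,
        divisions=divisions,
        merged=merged,
        deleted=frozenset(deleted),
        created_at=created_at,
        source_checksum=source_checksum,
    )
    validate_store(store)
    return store


def validate_store(store: TaxonomyStore) -> None:
    """Check referential integrity; raise :class:`IntegrityError` on failure."""
    nodes = store.nodes

    orphans = [
        n.tax_id for n in nodes.values() if n.parent_tax_id not in nodes
    ]
    if orphans:
        raise IntegrityError("node parent_tax_id missing from nodes table", orphans)

    self_parented = [
        n.tax_id for n in nodes.values() if n.parent_tax_id == n.tax_id
    ]
    if self_parented != [1]:
        raise IntegrityError(
            "exactly tax_id 1 must be its own parent (the root)", self_parented
        )

    # every node must reach the root; memoized upward walk detects cycles
    reaches_root: set[int] = {1}
    for start in nodes:
        path: list[int] = []
        current = start
        while current not in reaches_root:
            if current in path:
                raise IntegrityError("cycle in parent links", path)
            path.append(current)
            current = nodes[current].parent_tax_id
        reaches_root.update(path)

    dangling_names = sorted({r.tax_id for r in store.names} - set(nodes))
    if dangling_names:
        raise IntegrityError("name records reference unknown nodes", dangling_names)

    sci_count: dict[int, int] = {}
    for rec in store.names:
        if rec.name_class == "scientific name":
            sci_count[rec.tax_id] = sci_count.get(rec.tax_id, 0) + 1
    bad = sorted(
        tid for tid in nodes if sci_count.get(tid, 0) != 1
    )
    if bad:
        raise IntegrityError(
            "every node needs exactly one 'scientific name' record", bad
        )

    unknown_div = sorted(
        {n.tax_id for n in nodes.values() if n.division_id not in store.divisions}
    )
    if unknown_div:
        raise IntegrityError("nodes reference unknown division ids", unknown_div)

    merged_current = sorted(set(store.merged) & set(nodes))
    if merged_current:
        raise IntegrityError("merged old ids still present in nodes", merged_current)

    del_overlap = sorted(store.deleted & (set(nodes) | set(store.merged)))
    if del_overlap:
        raise IntegrityError("deleted ids present in nodes or merged", del_overlap)


# ---------------------------------------------------------------------------
# id resolution and staleness
# ---------------------------------------------------------------------------


def resolve_tax_id(store: TaxonomyStore, tax_id: int) -> int:
    """Map a possibly merged tax_id to its current id.

    Transitive merges are followed to a fixed point. Deleted ids raise
    :class:`DeletedTaxonError`; ids absent everywhere raise
    :class:`UnknownTaxonError`.
    """
    seen: set[int] = set()
    current = tax_id
    while current not in store.nodes:
        if current in store.deleted:
            raise DeletedTaxonError(current)
        if current not in store.merged or current in seen:
            raise UnknownTaxonError(tax_id)
        seen.add(current)
        current = store.merged[current]
    return current


def staleness_days(store: TaxonomyStore, now: float) -> tuple[int, bool]:
    """Age of the raw files in whole days and whether the copy is stale.

    The copy counts as stale when strictly more than ``STALE_AFTER_DAYS``
    (90) days old. Staleness is advisory: queries keep working, a warning
    is logged.
    """
    age_days = int((now - store.created_at) // _SECONDS_PER_DAY)
    stale = age_days > STALE_AFTER_DAYS
    if stale:
        logger.warning(
            "local taxonomy copy is %d days old (> %d); consider rebuilding",
            age_days,
            STALE_AFTER_DAYS,
        )
    return age_days, stale


# ---------------------------------------------------------------------------
# Arrow cache
# ---------------------------------------------------------------------------

_META_FILE = "meta.json"
_TABLE_FILES = {
    "names": "names.feather",
    "nodes": "nodes.feather",
    "divisions": "divisions.feather",
    "merged": "merged.feather",
    "deleted": "deleted.feather",
}


def _names_table(store: TaxonomyStore) -> pa.Table:
    return pa.table(
        {
            "tax_id": pa.array([r.tax_id for r in store.names], pa.int64()),
            "name_txt": pa.array([r.name_txt for r in store.names], pa.string()),
            "unique_name": pa.array([r.unique_name for r in store.names], pa.string()),
            "name_class": pa.array([r.name_class for r in store.names], pa.string()),
        }
    )


def write_cache(store: TaxonomyStore, path: str | os.PathLike) -> Path:
    """Serialize the store to a directory of Arrow (feather v2) tables.

    Column order is canonical and compression is disabled so identical
    stores produce byte-identical cache files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    nodes = sorted(store.nodes.values(), key=lambda n: n.tax_id)
    divisions = sorted(store.divisions.values(), key=lambda d: d.division_id)
    merged = sorted(store.merged.items())
    deleted = sorted(store.deleted)

    tables = {
        "names": _names_table(store),
        "nodes": pa.table(
            {
                "tax_id": pa.array([n.tax_id for n in nodes], pa.int64()),
                "parent_tax_id": pa.array([n.parent_tax_id for n in nodes], pa.int64()),
                "rank": pa.array([n.rank for n in nodes], pa.string()),
                "division_id": pa.array([n.division_id for n in nodes], pa.int64()),
            }
        ),
        "divisions": pa.table(
            {
                "division_id": pa.array([d.division_id for d in divisions], pa.int64()),
                "code": pa.array([d.code for d in divisions], pa.string()),
                "name": pa.array([d.name for d in divisions], pa.string()),
            }
        ),
        "merged": pa.table(
            {
                "old_tax_id": pa.array([m[0] for m in merged], pa.int64()),
                "new_tax_id": pa.array([m[1] for m in merged], pa.int64()),
            }
        ),
        "deleted": pa.table({"tax_id": pa.array(deleted, pa.int64())}),
    }
    for key, fname in _TABLE_FILES.items():
        feather.write_feather(
            tables[key], path / fname, compression="uncompressed"
        )

    meta = {
        "schema_version": CACHE_SCHEMA_VERSION,
        "created_at": store.created_at,
        "source_checksum": store.source_checksum,
    }
    with open(path / _META_FILE, "w", encoding="utf-8") as handle:
        json.dump(meta, handle, sort_keys=True)
        handle.write("\n")
    return path


def read_cache(path: str | os.PathLike) -> TaxonomyStore:
    """Load a store previously written by :func:`write_cache`."""
    path = Path(path)
    meta_path = path / _META_FILE
    if not meta_path.is_file():
        raise TaxdumpLoadError(f"no cache metadata at {meta_path}")
    with open(meta_path, encoding="utf-8") as handle:
        meta = json.load(handle)
    if meta.get("schema_version") != CACHE_SCHEMA_VERSION:
        raise CacheVersionError(meta.get("schema_version"), CACHE_SCHEMA_VERSION)

    t = {k: feather.read_table(path / f) for k, f in _TABLE_FILES.items()}

    names = tuple(
        NameRecord(tax_id, name_txt, unique_name, name_class)
        for tax_id, name_txt, unique_name, name_class in zip(
            t["names"]["tax_id"].to_pylist(),
            t["names"]["name_txt"].to_pylist(),
            t["names"]["unique_name"].to_pylist(),
            t["names"]["name_class"].to_pylist(),
        )
    )
    nodes = {
        tax_id: NodeRecord(tax_id, parent, rank, div)
        for tax_id, parent, rank, div in zip(
            t["nodes"]["tax_id"].to_pylist(),
            t["nodes"]["parent_tax_id"].to_pylist(),
            t["nodes"]["rank"].to_pylist(),
            t["nodes"]["division_id"].to_pylist(),
        )
    }
    divisions = {
        div_id: DivisionRecord(div_id, code, name)
        for div_id, code, name in zip(
            t["divisions"]["division_id"].to_pylist(),
            t["divisions"]["code"].to_pylist(),
            t["divisions"]["name"].to_pylist(),
        )
    }
    merged = dict(
        zip(
            t["merged"]["old_tax_id"].to_pylist(),
            t["merged"]["new_tax_id"].to_pylist(),
        )
    )
    deleted = frozenset(t["deleted"]["tax_id"].to_pylist())

    return TaxonomyStore(
        names=names,
        nodes=nodes,
        divisions=divisions,
        merged=merged,
        deleted=deleted,
        created_at=meta["created_at"],
        source_checksum=meta.get("source_checksum", ""),
    )


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


def storage_path(explicit: str | os.PathLike | None = None) -> Path:
    """Resolve where the local taxonomy lives.

    Order: explicit argument > ``NCBITAXONOMY_PATH`` environment variable >
    a per-user data directory. The path is created if missing.
    """
    if explicit is not None:
        path = Path(explicit)
    elif os.environ.get(ENV_STORAGE_VAR):
        path = Path(os.environ[ENV_STORAGE_VAR])
    else:
        base = os.environ.get("XDG_DATA_HOME", os.path.join(Path.home(), ".local", "share"))
        path = Path(base) / "taxonames"
    path.mkdir(parents=True, exist_ok=True)
    return path


def md5sum(path: str | os.PathLike) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def fetch_taxdump(
    dest: str | os.PathLike,
    url: str = TAXDUMP_URL,
    verify_checksum: bool = True,
    timeout: float = 60.0,
) -> tuple[Path, str]:
    """Download and extract the taxdump archive into ``dest``.

    The archive's MD5 is checked against the published ``.md5`` sidecar
    file. Returns the extraction directory and the archive checksum.
    Isolated here so everything else stays network-free.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    archive = dest / "taxdump.tar.gz"
    with urllib.request.urlopen(url, timeout=timeout) as response, open(
        archive, "wb"
    ) as out:
        while chunk := response.read(1 << 20):
            out.write(chunk)
    checksum = md5sum(archive)
    if verify_checksum:
        with urllib.request.urlopen(url + ".md5", timeout=timeout) as response:
            expected = response.read().decode().split()[0]
        if expected != checksum:
            raise ChecksumMismatchError(expected, checksum)
    with tarfile.open(archive, "r:gz") as tar:
        tar.extractall(dest, filter="data")
    return dest, checksum
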