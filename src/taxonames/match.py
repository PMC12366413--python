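"""Resolve name strings to taxa with typed, non-interactive failures.

Resolution is staged: an exact lookup (case-sensitive or folded) first,
then — only when requested with ``strict=False`` — a fuzzy search over the
name pool keeping all minimal-distance candidates within ``max_distance``
edits. Ambiguity is never resolved by guessing: if several distinct taxa
survive, the caller receives a :class:`MatchFailure` of kind
``MULTIPLE_MATCHES`` listing every candidate. No code path ever prompts for
input, so batch jobs on clusters run unattended.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyNameError
from .names import exact_lookup, normalize_name
from .taxdump import NameRecord, TaxonomyStore, resolve_tax_id

#: name classes considered vernacular
VERNACULAR_CLASSES = frozenset({"common name", "genbank common name"})
#: classes suppressed by prefer_scientific (vernaculars plus loose mappings)
NON_SCIENTIFIC_CLASSES = VERNACULAR_CLASSES | {"includes", "in-part"}

DEFAULT_MAX_DISTANCE = 2


@dataclass(frozen=True, slots=True)
class Taxon:
    """A resolved taxonomic identity (always a *current* tax_id)."""

    id: int
    name: str
    rank: str
    division_id: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} (ncbi:{self.id})"


@dataclass(frozen=True, slots=True)
class MatchCandidate:
    """One possible interpretation of a query string."""

    record: NameRecord
    taxon: Taxon
    distance: int

    @property
    def matched_class(self) -> str:
        return self.record.name_class


class MatchFailureKind(enum.Enum):
    NO_DIRECT_MATCH = "no_direct_match"
    MULTIPLE_MATCHES = "multiple_matches"


@dataclass(frozen=True)
class MatchFailure:
    """Typed resolution failure; a value, not an exception."""

    kind: MatchFailureKind
    query: str
    candidates: tuple[MatchCandidate, ...] = ()

    def __str__(self) -> str:
        if self.kind is MatchFailureKind.NO_DIRECT_MATCH:
            return (
                f"no direct match for {self.query!r}; "
                "try similar_names() for fuzzy suggestions"
            )
        listing = "; ".join(
            f"{c.taxon.name} (ncbi:{c.taxon.id}, {c.matched_class})"
            for c in self.candidates
        )
        return (
            f"multiple matches for {self.query!r}: {listing}; "
            "use alternative_taxa() or restrict the search pool"
        )


@dataclass
class SearchStats:
    """Instrumentation for fuzzy searches (candidate comparison count)."""

    comparisons: int = 0


def levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Edit distance between two strings.

    With ``max_dist``, the search abandons early and returns ``max_dist + 1``
    as soon as the true distance provably exceeds the cutoff.
    """
    if a == b:
        return 0
    if len(a) > len(b):
        a, b = b, a
    if max_dist is not None and len(b) - len(a) > max_dist:
        return max_dist + 1
    previous = list(range(len(a) + 1))
    for i, cb in enumerate(b, start=1):
        current = [i] + [0] * len(a)
        for j, ca in enumerate(a, start=1):
            current[j] = min(
                previous[j] + 1,
                current[j - 1] + 1,
                previous[j - 1] + (ca != cb),
            )
        if max_dist is not None and min(current) > max_dist:
            return max_dist + 1
        previous = current
    distance = previous[-1]
    if max_dist is not None and distance > max_dist:
        return max_dist + 1
    return distance


def taxon_by_id(store: TaxonomyStore, tax_id: int) -> Taxon:
    """The taxon for a (possibly merged) identifier."""
    current = resolve_tax_id(store, tax_id)
    node = store.nodes[current]
    return Taxon(
        id=current,
        name=store.scientific_name(current),
        rank=node.rank,
        division_id=node.division_id,
    )


def _pool_ids(pool) -> frozenset[int] | None:
    if pool is None:
        return None
    return pool.member_ids


def _pool_records(store: TaxonomyStore, pool) -> Sequence[NameRecord]:
    if pool is None:
        return store.names
    return pool.records()


def _candidates_from_records(
    store: TaxonomyStore, records: Iterable[NameRecord], distance: int
) -> list[MatchCandidate]:
    return [
        MatchCandidate(record=rec, taxon=taxon_by_id(store, rec.tax_id), distance=distance)
        for rec in records
    ]


def _apply_filters(
    candidates: list[MatchCandidate],
    rank: str | None,
    prefer_scientific: bool,
) -> list[MatchCandidate]:
    if rank is not None:
        candidates = [c for c in candidates if c.taxon.rank == rank]
    if prefer_scientific:
        kept = [c for c in candidates if c.matched_class not in NON_SCIENTIFIC_CLASSES]
        scientific = [c for c in kept if c.matched_class == "scientific name"]
        candidates = scientific if scientific else kept
    return candidates


def _sorted_candidates(candidates: list[MatchCandidate]) -> tuple[MatchCandidate, ...]:
    return tuple(
        sorted(
            candidates,
            key=lambda c: (
                c.distance,
                c.record.name_txt,
                c.taxon.id,
                c.record.name_class,
            ),
        )
    )


def _decide(
    query: str, candidates: list[MatchCandidate]
) -> Taxon | MatchFailure:
    distinct = {c.taxon.id for c in candidates}
    if len(distinct) == 1:
        return candidates[0].taxon
    if not candidates:
        return MatchFailure(MatchFailureKind.NO_DIRECT_MATCH, query)
    return MatchFailure(
        MatchFailureKind.MULTIPLE_MATCHES, query, _sorted_candidates(candidates)
    )


def resolve_name(
    store: TaxonomyStore,
    query: str,
    pool=None,
    strict: bool = True,
    case_sensitive: bool = True,
    rank: str | None = None,
    prefer_scientific: bool = False,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    stats: SearchStats | None = None,
) -> Taxon | MatchFailure:
    """Resolve ``query`` to a single taxon, or return a typed failure.

    Several name records pointing at the *same* tax_id (a synonym plus the
    scientific name, say) count as one match, not an ambiguity. Fuzzy
    comparison always works on case-folded normalized keys — case errors are
    treated as typos — while ``case_sensitive`` governs the exact stage only.
    """
    if not query or not query.strip():
        raise EmptyNameError("empty query")
    if not strict and max_distance < 1:
        raise ValueError("max_distance must be >= 1 for fuzzy matching")

    pool_ids = _pool_ids(pool)

    hits = list(exact_lookup(store, query, fold_case=not case_sensitive))
    if pool_ids is not None:
        hits = [r for r in hits if r.tax_id in pool_ids]
    candidates = _apply_filters(
        _candidates_from_records(store, hits, 0), rank, prefer_scientific
    )
    if candidates or strict:
        return _decide(query, candidates)

    fuzzy = _fuzzy_candidates(store, query, pool, max_distance, stats)
    fuzzy = _apply_filters(fuzzy, rank, prefer_scientific)
    if fuzzy:
        best = min(c.distance for c in fuzzy)
        fuzzy = [c for c in fuzzy if c.distance == best]
    return _decide(query, fuzzy)


def _fuzzy_candidates(
    store: TaxonomyStore,
    query: str,
    pool,
    max_distance: int,
    stats: SearchStats | None = None,
) -> list[MatchCandidate]:
    key = normalize_name(query, fold_case=True)
    out: list[MatchCandidate] = []
    for rec in _pool_records(store, pool):
        if stats is not None:
            stats.comparisons += 1
        d = levenshtein(key, normalize_name(rec.name_txt, fold_case=True), max_distance)
        if d <= max_distance:
            out.append(
                MatchCandidate(record=rec, taxon=taxon_by_id(store, rec.tax_id), distance=d)
            )
    return out


def similar_names(
    store: TaxonomyStore,
    query: str,
    pool=None,
    limit: int = 10,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    stats: SearchStats | None = None,
) -> list[MatchCandidate]:
    """Ranked fuzzy suggestions for a query that failed to match.

    Sorted by (distance, name); when the ``limit`` cut would split a group
    of equal-distance candidates, the whole group is included, keeping the
    output deterministic.
    """
    candidates = _sorted_candidates(
        _fuzzy_candidates(store, query, pool, max_distance, stats)
    )
    if len(candidates) <= limit:
        return list(candidates)
    cut = limit
    while cut < len(candidates) and candidates[cut].distance == candidates[limit - 1].distance:
        cut += 1
    return list(candidates[:cut])


def alternative_taxa(store: TaxonomyStore, name: str) -> list[Taxon]:
    """All distinct taxa carrying a name record exactly equal to ``name``."""
    if not name or not name.strip():
        raise EmptyNameError("empty name")
    records = exact_lookup(store, name, fold_case=False)
    taxa = {taxon_by_id(store, r.tax_id) for r in records}
    return sorted(taxa, key=lambda t: t.id)


RECONCILE_COLUMNS = [
    "query",
    "status",
    "matched_name",
    "tax_id",
    "rank",
    "matched_class",
    "distance",
]


def reconcile_list(
    store: TaxonomyStore,
    queries: Sequence[str],
    pool=None,
    strict: bool = True,
    case_sensitive: bool = True,
    rank: str | None = None,
    prefer_scientific: bool = False,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Reconcile a batch of names; one output row per input, order kept.

    ``status`` is one of ``ok`` / ``no_match`` / ``ambiguous``. Failures are
    rows, never exceptions, so pipelines keep running. The deduplicated
    richness of the list is the number of distinct tax_ids over ``ok`` rows.
    """
    if len(queries) == 0:
        raise ValueError("queries must be non-empty")
    rows = []
    for query in queries:
        outcome = resolve_name(
            store,
            query,
            pool=pool,
            strict=strict,
            case_sensitive=case_sensitive,
            rank=rank,
            prefer_scientific=prefer_scientific,
            max_distance=max_distance,
        )
        if isinstance(outcome, Taxon):
            # recover the matched record to report class + distance
            best = _best_record(store, query, outcome, case_sensitive, max_distance if not strict else 0)
            rows.append(
                {
                    "query": query,
                    "status": "ok",
                    "matched_name": outcome.name,
                    "tax_id": outcome.id,
                    "rank": outcome.rank,
                    "matched_class": best[0],
                    "distance": best[1],
                }
            )
        else:
            status = (
                "no_match"
                if outcome.kind is MatchFailureKind.NO_DIRECT_MATCH
                else "ambiguous"
            )
            rows.append(
                {
                    "query": query,
                    "status": status,
                    "matched_name": "",
                    "tax_id": pd.NA,
                    "rank": "",
                    "matched_class": "",
                    "distance": pd.NA,
                }
            )
    frame = pd.DataFrame(rows, columns=RECONCILE_COLUMNS)
    frame["tax_id"] = frame["tax_id"].astype("Int64")
    frame["distance"] = frame["distance"].astype("Int64")
    return frame


def _best_record(
    store: TaxonomyStore,
    query: str,
    taxon: Taxon,
    case_sensitive: bool,
    max_distance: int,
) -> tuple[str, int]:
    """(name_class, distance) of the closest record of ``taxon`` to ``query``."""
    key = normalize_name(query, fold_case=True)
    best_class, best_d = "", max_distance + 1
    exact = exact_lookup(store, query, fold_case=not case_sensitive)
    for rec in exact:
        if rec.tax_id == taxon.id:
            return rec.name_class, 0
    for rec in store.names_by_id.get(taxon.id, ()):
        d = levenshtein(key, normalize_name(rec.name_txt, fold_case=True), max_distance)
        if d < best_d:
            best_class, best_d = rec.name_class, d
    return best_class, best_d
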