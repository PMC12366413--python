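"""Taxonomy graph navigation and taxonomy-based distance matrices.

Navigation follows the parent links stored in the nodes table: ``parent``,
``children``, ``descendants`` (iterative, no recursion — the real taxonomy
is deep and wide), ``lineage`` and lowest common ancestors. Per-taxon
metadata helpers expose rank, synonyms, vernacular names and the taxonomic
authority.

``taxonomic_distance`` scores each species pair by the rank at which the
pair first connects: 0 within a species, 1 within a genus, 2 within a
family, 3 within a subclass, 4 otherwise. The score table is data, so any
rank can be re-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NotAnAncestorError
from .match import Taxon, taxon_by_id
from .taxdump import TaxonomyStore

ROOT_TAX_ID = 1

#: rank -> score used when no custom table is supplied
DEFAULT_RANK_SCORES = {"species": 0.0, "genus": 1.0, "family": 2.0, "subclass": 3.0}
DEFAULT_FALLBACK_SCORE = 4.0


@dataclass(frozen=True)
class RankScoreTable:
    """Scores assigned to ranks when building taxonomic distance matrices."""

    scores: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RANK_SCORES))
    fallback_score: float = DEFAULT_FALLBACK_SCORE

    def __post_init__(self):
        if any(v < 0 for v in self.scores.values()) or self.fallback_score < 0:
            raise ValueError("rank scores must be non-negative")

    def score_for(self, rank: str) -> float | None:
        return self.scores.get(rank)


@dataclass
class DistanceMatrix:
    """A square symmetric matrix of taxonomy-based distances."""

    taxa: list[Taxon]
    values: np.ndarray

    def __post_init__(self):
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} taxa"
            )


def parent(store: TaxonomyStore, t: Taxon) -> Taxon:
    """The taxon ``t`` directly descends from; the root is its own parent."""
    return taxon_by_id(store, store.nodes[t.id].parent_tax_id)


def is_root(t: Taxon) -> bool:
    return t.id == ROOT_TAX_ID


def children(store: TaxonomyStore, t: Taxon) -> set[Taxon]:
    """Nodes directly descended from ``t``."""
    return {taxon_by_id(store, child) for child in store.children_of(t.id)}


def descendants(store: TaxonomyStore, t: Taxon) -> set[Taxon]:
    """Transitive closure of ``children``, excluding ``t`` itself."""
    out: set[Taxon] = set()
    stack = list(store.children_of(t.id))
    while stack:
        tax_id = stack.pop()
        out.add(taxon_by_id(store, tax_id))
        stack.extend(store.children_of(tax_id))
    return out


def _lineage_ids(store: TaxonomyStore, tax_id: int) -> list[int]:
    ids = [tax_id]
    while ids[-1] != ROOT_TAX_ID:
        ids.append(store.nodes[ids[-1]].parent_tax_id)
    ids.reverse()
    return ids


def lineage(store: TaxonomyStore, t: Taxon, stop_at: Taxon | None = None) -> list[Taxon]:
    """Ancestors of ``t`` from ``stop_at`` (default: root) down to ``t``."""
    ids = _lineage_ids(store, t.id)
    if stop_at is not None:
        if stop_at.id not in ids:
            raise NotAnAncestorError(stop_at, t)
        ids = ids[ids.index(stop_at.id):]
    return [taxon_by_id(store, i) for i in ids]


def lca(store: TaxonomyStore, a: Taxon, b: Taxon) -> Taxon:
    """Deepest taxon present on both lineages."""
    ancestors_a = set(_lineage_ids(store, a.id))
    current = b.id
    while current not in ancestors_a:
        current = store.nodes[current].parent_tax_id
    return taxon_by_id(store, current)


def rank(store: TaxonomyStore, t: Taxon) -> str:
    return store.nodes[t.id].rank


def _names_of_classes(store: TaxonomyStore, t: Taxon, classes: frozenset[str] | set[str]) -> list[str]:
    return sorted(
        r.name_txt
        for r in store.names_by_id.get(t.id, ())
        if r.name_class in classes
    )


def synonyms(store: TaxonomyStore, t: Taxon) -> list[str]:
    """Alternative valid scientific names (synonym + equivalent name records)."""
    return _names_of_classes(store, t, {"synonym", "equivalent name"})


def vernacular(store: TaxonomyStore, t: Taxon) -> list[str]:
    """English common names."""
    return _names_of_classes(store, t, {"common name", "genbank common name"})


def authority(store: TaxonomyStore, t: Taxon) -> list[str]:
    """Full taxonomic authority strings, when recorded."""
    return _names_of_classes(store, t, {"authority"})


def _pair_score(
    store: TaxonomyStore, a: Taxon, b: Taxon, scores: RankScoreTable
) -> float:
    """Score of the most specific common ancestor with a mapped rank.

    The walk starts at the LCA and proceeds rootward until a rank present in
    the score table is found; lineages are sparse in mapped ranks ("no rank"
    clades abound), so this keeps the default table total. If no ancestor has
    a mapped rank, the fallback applies.
    """
    current = lca(store, a, b).id
    while True:
        score = scores.score_for(store.nodes[current].rank)
        if score is not None:
            return score
        if current == ROOT_TAX_ID:
            return scores.fallback_score
        current = store.nodes[current].parent_tax_id


def taxonomic_distance(
    store: TaxonomyStore,
    taxa: list[Taxon],
    scores: RankScoreTable | None = None,
) -> DistanceMatrix:
    """Distance matrix over ``taxa`` from the rank of each pair's LCA."""
    out = DistanceMatrix(
        taxa=list(taxa), values=np.zeros((len(taxa), len(taxa)), dtype=float)
    )
    return taxonomic_distance_into(store, taxa, scores, out)


def taxonomic_distance_into(
    store: TaxonomyStore,
    taxa: list[Taxon],
    scores: RankScoreTable | None,
    out: DistanceMatrix,
) -> DistanceMatrix:
    """Recompute a distance matrix into ``out`` without new matrix storage."""
    if not taxa:
        raise ValueError("taxa must be non-empty")
    if len({t.id for t in taxa}) != len(taxa):
        raise ValueError("taxa must be distinct")
    n = len(taxa)
    if out.values.shape != (n, n):
        raise ValueError(
            f"output matrix shape {out.values.shape} does not match {n} taxa"
        )
    if scores is None:
        scores = RankScoreTable()
    out.taxa = list(taxa)
    for i in range(n):
        out.values[i, i] = 0.0
        for j in range(i + 1, n):
            d = _pair_score(store, taxa[i], taxa[j], scores)
            out.values[i, j] = d
            out.values[j, i] = d
    return out
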