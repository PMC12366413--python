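"""Restricted name pools: division- and subtree-scoped search spaces.

The full NCBI names table holds millions of rows; restricting a search to a
known division (Mammals, Viruses, ...) or to a clade both speeds up fuzzy
matching — the comparison count is exactly the pool size — and avoids
cross-group homonym collisions. Pools are materialized id-sets so repeated
searches amortize the restriction cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownDivisionError
from .match import Taxon
from .taxdump import NameRecord, TaxonomyStore
from .tree import descendants


@dataclass
class NamePool:
    """A restricted view of the names table used to scope searches."""

    store: TaxonomyStore
    member_ids: frozenset[int]
    label: str = ""
    _records: tuple[NameRecord, ...] | None = field(
        default=None, repr=False, compare=False
    )

    def records(self) -> tuple[NameRecord, ...]:
        """Name records of pool members (materialized on first use)."""
        if self._records is None:
            self._records = tuple(
                r for r in self.store.names if r.tax_id in self.member_ids
            )
        return self._records

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.member_ids

    def __len__(self) -> int:
        return len(self.member_ids)


def division_pool(store: TaxonomyStore, division_names: list[str]) -> NamePool:
    """Pool of all taxa whose division is one of ``division_names``."""
    wanted: set[int] = set()
    valid = [d.name for d in store.divisions.values()]
    for name in division_names:
        div_id = store.division_id_by_name(name)
        if div_id is None:
            raise UnknownDivisionError(name, valid)
        wanted.add(div_id)
    members = frozenset(
        n.tax_id for n in store.nodes.values() if n.division_id in wanted
    )
    return NamePool(store, members, label=" + ".join(division_names))


def subtree_pool(store: TaxonomyStore, ancestor: Taxon) -> NamePool:
    """Pool of a taxon and all of its descendants."""
    members = frozenset({ancestor.id} | {t.id for t in descendants(store, ancestor)})
    return NamePool(store, members, label=f"subtree of {ancestor.name}")


def mammal_pool(store: TaxonomyStore, inclusive: bool = True) -> NamePool:
    """Mammals; with ``inclusive``, also the Primates and Rodents divisions.

    NCBI places primates and rodents in their own divisions, so the plain
    Mammals division excludes them.
    """
    names = ["Mammals"]
    if inclusive:
        names += ["Primates", "Rodents"]
    return division_pool(store, names)


def primate_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Primates"])


def rodent_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Rodents"])


def vertebrate_pool(store: TaxonomyStore, inclusive: bool = True) -> NamePool:
    """Vertebrates; with ``inclusive``, also Mammals/Primates/Rodents."""
    names = ["Vertebrates"]
    if inclusive:
        names += ["Mammals", "Primates", "Rodents"]
    return division_pool(store, names)


def invertebrate_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Invertebrates"])


def plant_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Plants and Fungi"])


def virus_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Viruses"])


def phage_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Phages"])


def bacteria_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Bacteria"])


def environmental_pool(store: TaxonomyStore) -> NamePool:
    return division_pool(store, ["Environmental samples"])
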