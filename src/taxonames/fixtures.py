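"""Generate taxdump-dialect directories for offline testing and demos.

Two generators are provided: :func:`reference_fixture`, a small hand-built
taxonomy exercising every tricky reconciliation case the library handles
(homonym genera, synonym chains, vernacular names, ligature variants,
case-variant virus names, merged and deleted ids), and
:func:`random_taxonomy`, a seeded generator of pseudo-Latin taxonomies used
for perturbation-recovery experiments. Both serialize to the exact dmp
dialect NCBI ships, so anything that loads a real taxdump loads these.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path

from .match import levenshtein
from .taxdump import (
    DivisionRecord,
    NameRecord,
    NodeRecord,
    format_dmp_record,
)

#: real NCBI division table (ids and codes as shipped in division.dmp)
STANDARD_DIVISIONS = (
    DivisionRecord(0, "BCT", "Bacteria"),
    DivisionRecord(1, "INV", "Invertebrates"),
    DivisionRecord(2, "MAM", "Mammals"),
    DivisionRecord(3, "PHG", "Phages"),
    DivisionRecord(4, "PLN", "Plants and Fungi"),
    DivisionRecord(5, "PRI", "Primates"),
    DivisionRecord(6, "ROD", "Rodents"),
    DivisionRecord(7, "SYN", "Synthetic and Chimeric"),
    DivisionRecord(8, "UNA", "Unassigned"),
    DivisionRecord(9, "VRL", "Viruses"),
    DivisionRecord(10, "VRT", "Vertebrates"),
    DivisionRecord(11, "ENV", "Environmental samples"),
)

# tax_ids: 36219 is the real id of Boops boops; every other id is taken from
# a reserved high range so mixed tests never collide with real NCBI ids.
_BASE = 10_000_000


@dataclass
class FixtureSpec:
    """In-memory definition of a taxdump directory."""

    nodes: list[NodeRecord]
    names: list[NameRecord]
    divisions: tuple[DivisionRecord, ...] = STANDARD_DIVISIONS
    merged: dict[int, int] = field(default_factory=dict)
    deleted: set[int] = field(default_factory=set)
    seed: int | None = None

    def scientific_names(self) -> list[NameRecord]:
        return [r for r in self.names if r.name_class == "scientific name"]


def write_fixture(spec: FixtureSpec, directory: str | Path) -> Path:
    """Serialize a :class:`FixtureSpec` as a standard taxdump directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(fname: str, rows: list[list[str]]) -> None:
        with open(directory / fname, "w", encoding="utf-8", newline="\n") as out:
            for row in rows:
                out.write(format_dmp_record(row) + "\n")

    dump(
        "nodes.dmp",
        [
            [str(n.tax_id), str(n.parent_tax_id), n.rank, "", str(n.division_id)]
            for n in sorted(spec.nodes, key=lambda n: n.tax_id)
        ],
    )
    dump(
        "names.dmp",
        [
            [str(r.tax_id), r.name_txt, r.unique_name, r.name_class]
            for r in sorted(
                spec.names, key=lambda r: (r.tax_id, r.name_class, r.name_txt)
            )
        ],
    )
    dump(
        "division.dmp",
        [
            [str(d.division_id), d.code, d.name, ""]
            for d in sorted(spec.divisions, key=lambda d: d.division_id)
        ],
    )
    dump(
        "merged.dmp",
        [[str(old), str(new)] for old, new in sorted(spec.merged.items())],
    )
    dump("delnodes.dmp", [[str(t)] for t in sorted(spec.deleted)])
    return directory


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------

# stable ids for the reference fixture, importable by tests
REF = {
    "root": 1,
    "Eukaryota": _BASE + 1,
    "Metazoa": _BASE + 2,
    "Chordata": _BASE + 3,
    "Vertebrata": _BASE + 4,
    "Actinopteri": _BASE + 5,
    "Sparidae": _BASE + 6,
    "Boops": _BASE + 7,
    "Boops boops": 36219,
    "Boops lineatus": _BASE + 8,
    "Cyprinidae": _BASE + 9,
    "Squalius": _BASE + 10,
    "Squalius cephalus": _BASE + 11,
    "Cyprinus": _BASE + 12,
    "Cyprinus carpio": _BASE + 13,
    "Lepidosauria": _BASE + 14,
    "Mammalia": _BASE + 15,
    "Bovidae": _BASE + 17,
    "Bos": _BASE + 18,
    "Bos taurus": _BASE + 19,
    "Ovis": _BASE + 20,
    "Ovis aries": _BASE + 21,
    "Hominidae": _BASE + 22,
    "Pan": _BASE + 23,
    "Muridae": _BASE + 24,
    "Mus": _BASE + 25,
    "Mus subgenus": _BASE + 26,
    "Mus musculus": _BASE + 27,
    "Arthropoda": _BASE + 28,
    "Hemiptera": _BASE + 29,
    "Reduviidae": _BASE + 30,
    "Lisarda": _BASE + 31,
    "Mollusca": _BASE + 32,
    "Pleuroceridae": _BASE + 33,
    "Io mollusc": _BASE + 34,
    "Viridiplantae": _BASE + 35,
    "Asteraceae": _BASE + 36,
    "Io aster": _BASE + 37,
    "Isoetaceae": _BASE + 38,
    "Isoetes": _BASE + 39,
    "Isoetes minima": _BASE + 40,
    "Viruses": _BASE + 41,
    "Adeno-associated virus 3b": _BASE + 42,
    "Influenza strain": _BASE + 43,
    "merged old": _BASE + 98,
    "deleted": _BASE + 99,
}


def reference_fixture() -> FixtureSpec:
    """The deterministic built-in demo taxonomy.

    Small enough to read, but rich enough to reproduce every hard case:
    the ``Io`` homonym pair (aster vs mollusc), the ``Mus`` genus/sub-genus
    pair, synonym and vernacular resolution for the riverine-fish survey,
    ligature variants of *Isoetes minima*, case variants of an
    adeno-associated virus name (synthetic stand-ins), an influenza strain
    name with alphanumeric codes, one merged id and one deleted id.
    """
    R = REF
    # (key, parent key, rank, division id)
    topology = [
        ("root", "root", "no rank", 8),
        ("Eukaryota", "root", "superkingdom", 8),
        ("Metazoa", "Eukaryota", "kingdom", 8),
        ("Chordata", "Metazoa", "phylum", 10),
        ("Vertebrata", "Chordata", "clade", 10),
        ("Actinopteri", "Vertebrata", "class", 10),
        ("Sparidae", "Actinopteri", "family", 10),
        ("Boops", "Sparidae", "genus", 10),
        ("Boops boops", "Boops", "species", 10),
        ("Boops lineatus", "Boops", "species", 10),
        ("Cyprinidae", "Actinopteri", "family", 10),
        ("Squalius", "Cyprinidae", "genus", 10),
        ("Squalius cephalus", "Squalius", "species", 10),
        ("Cyprinus", "Cyprinidae", "genus", 10),
        ("Cyprinus carpio", "Cyprinus", "species", 10),
        ("Lepidosauria", "Vertebrata", "class", 10),
        ("Mammalia", "Vertebrata", "class", 2),
        ("Bovidae", "Mammalia", "family", 2),
        ("Bos", "Bovidae", "genus", 2),
        ("Bos taurus", "Bos", "species", 2),
        ("Ovis", "Bovidae", "genus", 2),
        ("Ovis aries", "Ovis", "species", 2),
        ("Hominidae", "Mammalia", "family", 5),
        ("Pan", "Hominidae", "genus", 5),
        ("Muridae", "Mammalia", "family", 6),
        ("Mus", "Muridae", "genus", 6),
        ("Mus subgenus", "Mus", "subgenus", 6),
        ("Mus musculus", "Mus subgenus", "species", 6),
        ("Arthropoda", "Metazoa", "phylum", 1),
        ("Hemiptera", "Arthropoda", "order", 1),
        ("Reduviidae", "Hemiptera", "family", 1),
        ("Lisarda", "Reduviidae", "genus", 1),
        ("Mollusca", "Metazoa", "phylum", 1),
        ("Pleuroceridae", "Mollusca", "family", 1),
        ("Io mollusc", "Pleuroceridae", "genus", 1),
        ("Viridiplantae", "Eukaryota", "kingdom", 4),
        ("Asteraceae", "Viridiplantae", "family", 4),
        ("Io aster", "Asteraceae", "genus", 4),
        ("Isoetaceae", "Viridiplantae", "family", 4),
        ("Isoetes", "Isoetaceae", "genus", 4),
        ("Isoetes minima", "Isoetes", "species", 4),
        ("Viruses", "root", "superkingdom", 9),
        ("Adeno-associated virus 3b", "Viruses", "species", 9),
        ("Influenza strain", "Viruses", "no rank", 9),
    ]
    nodes = [
        NodeRecord(R[key], R[parent], rank, div)
        for key, parent, rank, div in topology
    ]

    names: list[NameRecord] = []

    def add(key: str, name_txt: str, name_class: str, unique_name: str = "") -> None:
        names.append(NameRecord(R[key], name_txt, unique_name, name_class))

    # scientific names; the two Io genera and the two Mus ranks are homonyms
    for key, _, _, _ in topology:
        if key == "Io mollusc":
            add(key, "Io", "scientific name", "Io <Mollusca>")
        elif key == "Io aster":
            add(key, "Io", "scientific name", "Io <Asteraceae>")
        elif key == "Mus subgenus":
            add(key, "Mus", "scientific name", "Mus <subgenus>")
        elif key == "Mus":
            add(key, "Mus", "scientific name", "Mus <genus>")
        elif key == "Influenza strain":
            add(key, "Influenza A virus (A/Sydney/05/97-like(H3N2))", "scientific name")
        else:
            add(key, key, "scientific name")

    add("Boops boops", "bogue", "genbank common name")
    add("Squalius cephalus", "Leuciscus cephalus", "synonym")
    add("Squalius cephalus", "Cyprinus cephalus", "synonym")
    add("Squalius cephalus", "European chub", "common name")
    add("Bos taurus", "Bos primigenius taurus", "synonym")
    add("Bos taurus", "cattle", "genbank common name")
    add("Bos taurus", "Bos taurus Linnaeus, 1758", "authority")
    add("Ovis aries", "lamb", "common name")
    add("Ovis aries", "sheep", "genbank common name")
    add("Ovis aries", "wild sheep", "common name")
    add("Ovis aries", "domestic sheep", "common name")
    add("Pan", "chimpanzees", "common name")
    # case variants (synthetic stand-ins for equal-distance virus names)
    add("Adeno-associated virus 3b", "Adeno-Associated Virus 3b", "equivalent name")
    add("Adeno-associated virus 3b", "Adeno-associated Virus 3B", "equivalent name")

    return FixtureSpec(
        nodes=nodes,
        names=names,
        merged={R["merged old"]: R["Bos taurus"]},
        deleted={R["deleted"]},
    )


# ---------------------------------------------------------------------------
# random taxonomies
# ---------------------------------------------------------------------------

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"
_EPITHET_SUFFIXES = ("us", "a", "um", "is", "ensis", "icus", "alis")

DEFAULT_RANK_LADDER = ("phylum", "class", "order", "family", "genus")


def _syllables(rng: random.Random, count: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(count)
    )


def _fresh_name(
    rng: random.Random,
    make: "callable",
    taken: list[str],
    min_distance: int,
) -> str:
    """Draw names until one is far enough from everything already taken."""
    for _ in range(10_000):
        name = make(rng)
        if min_distance <= 1:
            if name not in taken:
                return name
        elif all(
            levenshtein(name.lower(), other.lower(), min_distance - 1) >= min_distance
            for other in taken
        ):
            return name
    raise RuntimeError("could not draw a sufficiently distinct name")


def random_taxonomy(
    n_taxa: int,
    ranks: tuple[str, ...] = DEFAULT_RANK_LADDER,
    branching: int = 3,
    seed: int = 0,
    min_name_distance: int = 0,
) -> FixtureSpec:
    """A seeded random taxonomy with ``n_taxa`` species leaves.

    Internal levels follow the ``ranks`` ladder with roughly ``branching``
    children per node; species carry unique pseudo-Latin binomials. With
    ``min_name_distance`` > 0, every pair of scientific names is kept at
    least that many edits apart (needed by perturbation-recovery
    experiments where a typo must have a unique closest name).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(seed)
    next_id = _BASE + 1
    nodes = [NodeRecord(1, 1, "no rank", 8)]
    names = [NameRecord(1, "root", "", "scientific name")]
    taken = ["root"]

    def make_internal(rng: random.Random) -> str:
        return _syllables(rng, rng.randint(2, 4)).capitalize()

    # build the internal ladder top-down: level k has ~n_taxa/branching^(depth-k)
    levels: list[list[int]] = [[1]]
    n_levels = len(ranks)
    for depth, rank_name in enumerate(ranks, start=1):
        width = max(1, round(n_taxa / branching ** (n_levels - depth + 1)))
        level: list[int] = []
        for i in range(width):
            parent_id = levels[-1][i % len(levels[-1])]
            node_id = next_id
            next_id += 1
            nodes.append(NodeRecord(node_id, parent_id, rank_name, 8))
            name = _fresh_name(rng, make_internal, taken, min_name_distance)
            taken.append(name)
            names.append(NameRecord(node_id, name, "", "scientific name"))
            level.append(node_id)
        levels.append(level)

    genera = levels[-1]
    genus_names = {nid: names[-len(genera) + i].name_txt for i, nid in enumerate(genera)}

    for i in range(n_taxa):
        genus_id = genera[i % len(genera)]

        def make_species(rng: random.Random, _g=genus_names[genus_id]) -> str:
            epithet = _syllables(rng, rng.randint(2, 3)) + rng.choice(_EPITHET_SUFFIXES)
            return f"{_g} {epithet}"

        node_id = next_id
        next_id += 1
        nodes.append(NodeRecord(node_id, genus_id, "species", 8))
        name = _fresh_name(rng, make_species, taken, min_name_distance)
        taken.append(name)
        names.append(NameRecord(node_id, name, "", "scientific name"))

    return FixtureSpec(nodes=nodes, names=names, seed=seed)


# ---------------------------------------------------------------------------
# name perturbation
# ---------------------------------------------------------------------------

DEFAULT_EDIT_OPS = {
    "substitute": 1.0,
    "delete": 1.0,
    "insert": 1.0,
    "transpose": 1.0,
    "case-flip": 1.0,
    "ligature-swap": 0.0,
}

#: worst-case plain edit distance contributed by one application of each op
_OP_COST = {
    "substitute": 1,
    "delete": 1,
    "insert": 1,
    "transpose": 2,
    "case-flip": 1,
    "ligature-swap": 2,
}


@dataclass
class PerturbationSpec:
    """How to corrupt sampled names (mimicking manual data entry errors)."""

    n_queries: int
    edit_ops: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EDIT_OPS))
    max_edits: int = 1
    seed: int = 0


def _apply_op(rng: random.Random, op: str, s: str) -> str | None:
    """One edit; None when the op does not apply to this string."""
    letters = string.ascii_lowercase
    if op == "substitute":
        i = rng.randrange(len(s))
        c = rng.choice(letters)
        while c == s[i]:
            c = rng.choice(letters)
        return s[:i] + c + s[i + 1:]
    if op == "delete":
        if len(s) < 2:
            return None
        i = rng.randrange(len(s))
        return s[:i] + s[i + 1:]
    if op == "insert":
        i = rng.randrange(len(s) + 1)
        return s[:i] + rng.choice(letters) + s[i:]
    if op == "transpose":
        positions = [i for i in range(len(s) - 1) if s[i] != s[i + 1]]
        if not positions:
            return None
        i = rng.choice(positions)
        return s[:i] + s[i + 1] + s[i] + s[i + 2:]
    if op == "case-flip":
        positions = [i for i, c in enumerate(s) if c.isalpha()]
        if not positions:
            return None
        i = rng.choice(positions)
        return s[:i] + s[i].swapcase() + s[i + 1:]
    if op == "ligature-swap":
        if "oe" in s:
            return s.replace("oe", "œ", 1)
        if "ae" in s:
            return s.replace("ae", "æ", 1)
        return None
    raise ValueError(f"unknown edit op {op!r}")


def perturb_names(
    spec: FixtureSpec, p: PerturbationSpec
) -> list[tuple[str, int, int]]:
    """Corrupted copies of sampled scientific names.

    Returns (query, true tax_id, edit count) triples where the edit count is
    the oracle-verified edit distance between query and source; draws that
    collide back onto an existing name or overshoot ``max_edits`` are
    redrawn.
    """
    sci = spec.scientific_names()
    if not sci:
        raise ValueError("fixture has no scientific names")
    ops = [op for op, w in p.edit_ops.items() if w > 0]
    weights = [p.edit_ops[op] for op in ops]
    if not ops:
        raise ValueError("no edit ops enabled")
    existing = {r.name_txt for r in sci}
    rng = random.Random(p.seed)

    out: list[tuple[str, int, int]] = []
    for _ in range(p.n_queries):
        for _attempt in range(1000):
            source = rng.choice(sci)
            query = source.name_txt
            budget = p.max_edits
            n_ops = rng.randint(1, p.max_edits)
            for _k in range(n_ops):
                applicable = [o for o in ops if _OP_COST[o] <= budget]
                if not applicable:
                    break
                op = rng.choices(
                    applicable, weights=[p.edit_ops[o] for o in applicable]
                )[0]
                edited = _apply_op(rng, op, query)
                if edited is None:
                    continue
                query = edited
                budget -= _OP_COST[op]
            distance = levenshtein(query, source.name_txt)
            if 1 <= distance <= p.max_edits and query not in existing:
                out.append((query, source.tax_id, distance))
                break
        else:
            raise RuntimeError("could not generate a valid perturbation")
    return out
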