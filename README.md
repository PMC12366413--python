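# taxonames

Reconcile arbitrary biological name strings against a locally stored copy of
the NCBI taxonomy.

Biological name lists are messy: the same species hides behind synonyms
(*Bos primigenius taurus* → *Bos taurus*), vernaculars ("European chub" →
*Squalius cephalus*), typos ("Boops bops"), ligature variants ("Isœtes"),
case variants of alphanumeric virus names, and homonyms (the genus *Io* is
both an aster and a mollusc). `taxonames` resolves such strings to stable
NCBI tax_ids with explicit, typed ambiguity signalling — no interactive
prompts, ever — so large batches can run unattended on a cluster.

Features:

- **Local taxonomy store** — parse the NCBI taxdump dialect (`names.dmp`,
  `nodes.dmp`, `division.dmp`, `merged.dmp`, `delnodes.dmp`), validate
  referential integrity, cache as Apache Arrow tables for fast reloads, and
  flag copies older than 90 days as stale (a warning, never an error).
- **Staged matching** — strict exact lookup, case-insensitive lookup, and
  fuzzy matching by Levenshtein distance, with optional rank restriction and
  a prefer-scientific-name mode. Failures are values: `NO_DIRECT_MATCH` or
  `MULTIPLE_MATCHES` with the full candidate list.
- **Restricted pools** — scope any search to NCBI divisions (mammals
  inclusive of rodents and primates, viruses, plants, ...) or to an
  arbitrary subtree. Pools both disambiguate homonyms and cut the fuzzy
  search cost to exactly the pool size.
- **Lineage navigation** — parent / children / descendants / lineage /
  lowest common ancestor, plus per-taxon synonyms, vernaculars, authority
  and rank.
- **Taxonomic distance matrices** — score each species pair by the rank at
  which it first connects (defaults: species 0, genus 1, family 2,
  subclass 3, everything else 4; any rank can be re-weighted), with an
  in-place recompute variant that reuses the allocated matrix.
- **Fixture generators** — a hand-built reference taxonomy embedding all of
  the hard cases above, and seeded random taxonomies with controlled name
  perturbations, so everything is testable offline.

## Library quick start

```python
import taxonames as tx

# offline demo: generate the bundled reference taxonomy and load it
tx.write_fixture(tx.reference_fixture(), "demo_taxdump")
store = tx.load_taxdump("demo_taxdump")

tx.resolve_name(store, "Boops boops")            # Taxon(id=36219, ...)
tx.resolve_name(store, "Boops bops", strict=False)  # fuzzy -> same taxon
tx.resolve_name(store, "Io")                     # MatchFailure(MULTIPLE_MATCHES)
tx.resolve_name(store, "Io", pool=tx.plant_pool(store))  # unique hit

report = tx.reconcile_list(store, [
    "European chub", "Cyprinus cephalus", "Leuciscus cephalus", "Squalius cephalus",
])
report["tax_id"].nunique()                       # 1 — all the same species

mouse = tx.resolve_name(store, "Mus musculus")
tx.lineage(store, mouse)                         # root ... genus Mus ... species
species = [tx.resolve_name(store, n) for n in ("Boops boops", "Boops lineatus")]
tx.taxonomic_distance(store, species).values     # [[0, 1], [1, 0]]
```

For a real database, point `NCBITAXONOMY_PATH` at a per-project directory
and build the cache once; analyses then re-run against a pinned snapshot.

## CLI

```sh
# one-time: build the local cache (download, checksum-verify, parse, cache)
taxonames build                       # or: taxonames build --from-dir DIR

taxonames get "Boops boops"           # name, tax_id, rank, lineage
taxonames get "Io"                    # candidates on stderr, exit 1
taxonames get "Io" --division "Plants and Fungi"
taxonames get "Boops bops" --fuzzy --json

taxonames reconcile names.txt --fuzzy --out report.tsv
taxonames reconcile table.csv --column species

taxonames lineage 36219
taxonames distance --names names.txt --out matrix.csv [--scores scores.cfg]
taxonames fixtures write --kind reference --out demo_taxdump
taxonames fixtures write --kind random --n 100 --seed 1 --out rand_taxdump
```

Exit codes: `0` all inputs resolved, `1` at least one unmatched/ambiguous
input, `2` usage or data error. Reports go to stdout/`--out`; logs and
summaries go to stderr. `--db PATH` overrides `NCBITAXONOMY_PATH`.

The score config for `distance` is one `rank=score` per line, e.g.
`genus=0.5`, with an optional `fallback=` line.

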