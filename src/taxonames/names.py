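"""Name normalization and exact-lookup indexes over the names table.

Normalization defines the comparison form used before *any* matching:
Unicode NFC, ligature expansion (the "œ"/"æ" graphemes frequently appear in
typeset botanical names), whitespace canonicalization, and an optional
simple case fold. Diacritic folding exists behind an option but defaults to
off.
"""

from __future__ import annotations

import unicodedata

from .errors import EmptyNameError
from .taxdump import NameRecord, TaxonomyStore

_LIGATURES = {
    "œ": "oe",  # œ
    "Œ": "Oe",  # Œ
    "æ": "ae",  # æ
    "Æ": "Ae",  # Æ
}


def normalize_name(
    s: str, fold_case: bool = False, fold_diacritics: bool = False
) -> str:
    """Return the comparison form of a name string.

    Idempotent. Raises :class:`EmptyNameError` for empty/whitespace-only
    input.
    """
    if s is None or not s.strip():
        raise EmptyNameError("empty or whitespace-only name")
    text = unicodedata.normalize("NFC", s)
    for ligature, expansion in _LIGATURES.items():
        text = text.replace(ligature, expansion)
    text = " ".join(text.split())
    if fold_diacritics:
        decomposed = unicodedata.normalize("NFD", text)
        text = unicodedata.normalize(
            "NFC", "".join(c for c in decomposed if not unicodedata.combining(c))
        )
    if fold_case:
        text = text.casefold()
    return text


def build_indexes(store: TaxonomyStore) -> TaxonomyStore:
    """Build (or rebuild) the exact-lookup maps and return the same store.

    Two maps are kept: case-preserving normalized key -> records, and
    case-folded key -> records. Both preserve multiplicity so homonyms map
    to several records.
    """
    exact: dict[str, list[NameRecord]] = {}
    folded: dict[str, list[NameRecord]] = {}
    for rec in store.names:
        exact.setdefault(normalize_name(rec.name_txt), []).append(rec)
        folded.setdefault(normalize_name(rec.name_txt, fold_case=True), []).append(rec)
    store._exact_index = {k: tuple(v) for k, v in exact.items()}
    store._folded_index = {k: tuple(v) for k, v in folded.items()}
    return store


def exact_lookup(
    store: TaxonomyStore, query: str, fold_case: bool = False
) -> tuple[NameRecord, ...]:
    """All name records whose normalized form equals the normalized query."""
    if store._exact_index is None or store._folded_index is None:
        build_indexes(store)
    key = normalize_name(query, fold_case=fold_case)
    index = store._folded_index if fold_case else store._exact_index
    assert index is not None
    return index.get(key, ())
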