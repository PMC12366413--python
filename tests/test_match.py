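"""Name resolution: staged matching, typed failures, batch reconciliation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxonames import (
    DeletedTaxonError,
    EmptyNameError,
    MatchFailure,
    MatchFailureKind,
    Taxon,
    UnknownTaxonError,
    alternative_taxa,
    levenshtein,
    reconcile_list,
    resolve_name,
    similar_names,
    taxon_by_id,
)

from ._oracle import dp_levenshtein

short_text = st.text(
    alphabet=st.characters(min_codepoint=32, max_codepoint=0x2FF), max_size=30
)


@given(short_text, short_text)
@settings(max_examples=300)
def test_levenshtein_matches_dp_oracle(a, b):
    assert levenshtein(a, b) == dp_levenshtein(a, b)


@given(short_text, short_text, st.integers(min_value=0, max_value=5))
@settings(max_examples=300)
def test_levenshtein_cutoff_consistent_with_oracle(a, b, cutoff):
    truth = dp_levenshtein(a, b)
    bounded = levenshtein(a, b, max_dist=cutoff)
    if truth <= cutoff:
        assert bounded == truth
    else:
        assert bounded == cutoff + 1


class TestTaxonById:
    def test_bogue_by_id(self, store):
        taxon = taxon_by_id(store, 36219)
        assert taxon.name == "Boops boops"
        assert taxon.id == 36219
        assert taxon.rank == "species"

    def test_root(self, store):
        assert taxon_by_id(store, 1).id == 1

    def test_merged_id_resolves_to_new_taxon(self, store, ref_ids):
        taxon = taxon_by_id(store, ref_ids["merged old"])
        assert taxon.id == ref_ids["Bos taurus"]
        assert taxon.name == "Bos taurus"

    def test_deleted_and_unknown(self, store, ref_ids):
        with pytest.raises(DeletedTaxonError):
            taxon_by_id(store, ref_ids["deleted"])
        with pytest.raises(UnknownTaxonError):
            taxon_by_id(store, 555555555)


class TestResolveName:
    def test_strict_exact(self, store):
        assert resolve_name(store, "Boops boops") == taxon_by_id(store, 36219)

    def test_fuzzy_catches_typo(self, store):
        outcome = resolve_name(store, "Boops bops", strict=False)
        assert isinstance(outcome, Taxon)
        assert outcome.name == "Boops boops"
        assert dp_levenshtein("boops bops", "boops boops") == 1

    def test_homonym_is_multiple_matches(self, store):
        outcome = resolve_name(store, "Io")
        assert isinstance(outcome, MatchFailure)
        assert outcome.kind is MatchFailureKind.MULTIPLE_MATCHES
        assert len(outcome.candidates) == 2
        assert len({c.taxon.id for c in outcome.candidates}) == 2

    def test_vernacular_resolves(self, store, ref_ids):
        outcome = resolve_name(store, "European chub")
        assert isinstance(outcome, Taxon)
        assert outcome.name == "Squalius cephalus"

    def test_synonym_resolves_without_ambiguity(self, store):
        outcome = resolve_name(store, "Cyprinus cephalus")
        assert isinstance(outcome, Taxon)
        assert outcome.name == "Squalius cephalus"

    def test_unknown_name_is_no_direct_match(self, store):
        outcome = resolve_name(store, "Nosuchname xyz")
        assert isinstance(outcome, MatchFailure)
        assert outcome.kind is MatchFailureKind.NO_DIRECT_MATCH
        assert outcome.candidates == ()

    def test_case_insensitive_search_is_deterministic(self, store, ref_ids):
        outcomes = {
            resolve_name(store, "adeno-associated virus 3b", case_sensitive=False)
            for _ in range(5)
        }
        assert outcomes == {taxon_by_id(store, ref_ids["Adeno-associated virus 3b"])}

    def test_case_sensitive_misses_wrong_case(self, store):
        outcome = resolve_name(store, "adeno-associated virus 3b")
        assert isinstance(outcome, MatchFailure)
        assert outcome.kind is MatchFailureKind.NO_DIRECT_MATCH

    def test_rank_restriction_disambiguates_mus(self, store, ref_ids):
        ambiguous = resolve_name(store, "Mus")
        assert isinstance(ambiguous, MatchFailure)
        assert ambiguous.kind is MatchFailureKind.MULTIPLE_MATCHES
        genus = resolve_name(store, "Mus", rank="genus")
        assert isinstance(genus, Taxon)
        assert genus.id == ref_ids["Mus"]
        subgenus = resolve_name(store, "Mus", rank="subgenus")
        assert isinstance(subgenus, Taxon)
        assert subgenus.id == ref_ids["Mus subgenus"]

    def test_prefer_scientific_suppresses_vernacular(self, store, ref_ids):
        # "sheep" only matches vernacular records of Ovis aries
        assert isinstance(resolve_name(store, "sheep"), Taxon)
        suppressed = resolve_name(store, "sheep", prefer_scientific=True)
        assert isinstance(suppressed, MatchFailure)
        assert suppressed.kind is MatchFailureKind.NO_DIRECT_MATCH

    def test_empty_query_rejected(self, store):
        with pytest.raises(EmptyNameError):
            resolve_name(store, "   ")

    def test_fuzzy_needs_positive_max_distance(self, store):
        with pytest.raises(ValueError):
            resolve_name(store, "Boops bops", strict=False, max_distance=0)

    def test_ligature_variant_matches_strictly(self, store, ref_ids):
        outcome = resolve_name(store, "Isœtes minima")
        assert isinstance(outcome, Taxon)
        assert outcome.id == ref_ids["Isoetes minima"]

    def test_staged_consistency_strict_success_implies_same_fuzzy(self, store):
        sci_names = sorted(
            {r.name_txt for r in store.names if r.name_class == "scientific name"}
        )
        for name in sci_names:
            strict_outcome = resolve_name(store, name)
            if isinstance(strict_outcome, Taxon):
                for max_distance in (1, 3):
                    fuzzy_outcome = resolve_name(
                        store, name, strict=False, max_distance=max_distance
                    )
                    assert fuzzy_outcome == strict_outcome

    def test_determinism(self, store):
        queries = ["Io", "Boops bops", "Mus", "Nosuchname xyz", "Lizard"]
        for query in queries:
            first = resolve_name(store, query, strict=False)
            for _ in range(3):
                assert resolve_name(store, query, strict=False) == first

    def test_synonym_collapse(self, store):
        from taxonames import synonyms

        seen = 0
        for tax_id in store.nodes:
            taxon = taxon_by_id(store, tax_id)
            alt = synonyms(store, taxon)
            if not alt:
                continue
            seen += 1
            outcomes = [resolve_name(store, name) for name in alt + [taxon.name]]
            assert all(isinstance(o, Taxon) for o in outcomes)
            assert {o.id for o in outcomes} == {tax_id}
        assert seen >= 2  # fixture has several synonym-bearing taxa


class TestSimilarNames:
    def test_typo_ranked_first(self, store):
        candidates = similar_names(store, "Boops bops")
        assert candidates[0].record.name_txt == "Boops boops"
        assert candidates[0].distance == 1
        assert candidates[0].distance == dp_levenshtein("boops bops", "boops boops")

    def test_lizard_pitfall(self, store):
        candidates = similar_names(store, "Lizard", max_distance=8)
        names = [c.record.name_txt for c in candidates]
        assert names[0] == "Lisarda"
        by_name = {c.record.name_txt: c.distance for c in candidates}
        assert by_name["Lisarda"] == dp_levenshtein("lizard", "lisarda") == 2
        if "Lepidosauria" in by_name:
            assert by_name["Lisarda"] < by_name["Lepidosauria"]

    def test_chimpanzees_in_primate_pool(self, store):
        from taxonames import primate_pool

        candidates = similar_names(
            store, "chimpanzees", pool=primate_pool(store), max_distance=2
        )
        assert any(
            c.record.name_txt == "chimpanzees" and c.taxon.name == "Pan"
            for c in candidates
        )

    def test_sorted_and_tie_groups_kept(self, store):
        candidates = similar_names(store, "Boops", max_distance=6, limit=3)
        keys = [(c.distance, c.record.name_txt) for c in candidates]
        assert keys == sorted(keys)
        if len(candidates) > 3:
            assert candidates[2].distance == candidates[3].distance

    def test_empty_result_allowed(self, store):
        assert similar_names(store, "qqqqqqqqqqqq", max_distance=1) == []


class TestAlternativeTaxa:
    def test_io_two_taxa(self, store):
        taxa = alternative_taxa(store, "Io")
        assert len(taxa) == 2
        assert [t.id for t in taxa] == sorted(t.id for t in taxa)

    def test_mus_two_taxa(self, store, ref_ids):
        taxa = alternative_taxa(store, "Mus")
        assert {t.id for t in taxa} == {ref_ids["Mus"], ref_ids["Mus subgenus"]}

    def test_unique_name_single_taxon(self, store):
        taxa = alternative_taxa(store, "Boops boops")
        assert [t.id for t in taxa] == [36219]


class TestReconcileList:
    def test_riverine_fish_dedup(self, store):
        queries = [
            "European chub",
            "Cyprinus cephalus",
            "Leuciscus cephalus",
            "Squalius cephalus",
        ]
        report = reconcile_list(store, queries)
        assert list(report["query"]) == queries
        assert list(report["status"]) == ["ok"] * 4
        assert report["tax_id"].nunique() == 1

    def test_empty_rejected_single_ok(self, store):
        with pytest.raises(ValueError):
            reconcile_list(store, [])
        report = reconcile_list(store, ["Boops boops"])
        assert len(report) == 1
        assert report["tax_id"].nunique() == 1

    def test_failures_are_rows_not_exceptions(self, store):
        report = reconcile_list(store, ["Io", "Nosuchname xyz", "Boops boops"])
        assert list(report["status"]) == ["ambiguous", "no_match", "ok"]
        assert len(report) == 3

    def test_perturbation_recovery(self, store):
        from taxonames import PerturbationSpec, perturb_names, random_taxonomy, load_taxdump, write_fixture
        import tempfile

        spec = random_taxonomy(60, seed=11, min_name_distance=4)
        with tempfile.TemporaryDirectory() as tmp:
            rand_store = load_taxdump(write_fixture(spec, tmp))
        queries = perturb_names(
            spec,
            PerturbationSpec(
                n_queries=100, edit_ops={"substitute": 1.0}, max_edits=1, seed=7
            ),
        )
        recovered = 0
        for query, true_id, _edits in queries:
            outcome = resolve_name(rand_store, query, strict=False, max_distance=2)
            if isinstance(outcome, Taxon) and outcome.id == true_id:
                recovered += 1
        assert recovered >= 95
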