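"""Running-sum enrichment score, permutation null and FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stromaging as sg
from conftest import exhaustive_gene_label_p, make_ranked, running_sum_oracle


class TestRankGenes:
    def test_descending_by_fold_change(self):
        table = pd.DataFrame(
            {"signed_fc": [2.0, -3.0, 1.2]}, index=["A", "B", "C"]
        )
        ranked = sg.rank_genes(table)
        assert ranked.symbols == ("A", "C", "B")
        assert list(ranked.scores) == [2.0, 1.2, -3.0]

    def test_ties_break_lexicographically(self):
        table = pd.DataFrame(
            {"signed_fc": [1.5, 1.5, 1.5]}, index=["ZZZ", "AAA", "MMM"]
        )
        assert sg.rank_genes(table).symbols == ("AAA", "MMM", "ZZZ")

    def test_duplicate_symbols_rejected(self):
        table = pd.DataFrame({"signed_fc": [1.0, 2.0]}, index=["A", "A"])
        with pytest.raises(ValueError, match="duplicate"):
            sg.rank_genes(table)

    def test_most_up_in_old_gene_ranks_last(self, fixture_ranking):
        assert fixture_ranking.symbols[-1] == "SPP1"
        assert fixture_ranking.scores[-1] == pytest.approx(-4.79)


class TestEnrichmentScore:
    def test_singleton_at_top_is_plus_one(self):
        ranked = make_ranked(10)
        es, _ = sg.enrichment_score(ranked, {ranked.symbols[0]})
        assert es == pytest.approx(1.0)

    def test_singleton_at_bottom_is_minus_one(self):
        ranked = make_ranked(10)
        es, _ = sg.enrichment_score(ranked, {ranked.symbols[-1]})
        assert es == pytest.approx(-1.0)

    def test_worked_case_hits_1_3_5_of_10(self):
        ranked = make_ranked(10)
        hits = {ranked.symbols[i] for i in (0, 2, 4)}
        es, running = sg.enrichment_score(ranked, hits)
        assert es == pytest.approx(5.0 / 7.0)
        oracle_es, oracle_trace = running_sum_oracle(10, [0, 2, 4])
        assert es == pytest.approx(oracle_es)
        np.testing.assert_allclose(running, oracle_trace)

    def test_running_sum_ends_at_zero_unweighted(self):
        ranked = make_ranked(40, seed=3)
        es, running = sg.enrichment_score(
            ranked, set(ranked.symbols[5:9]) | {ranked.symbols[20]}
        )
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_oracle_equivalence_small_instances(self):
        """Unweighted ES equals the literal-walk oracle on every
        (N <= 12, set size <= 4) instance."""
        for n in range(2, 13):
            ranked = make_ranked(n, seed=n)
            for k in range(1, min(4, n - 1) + 1):
                for combo in itertools.combinations(range(n), k):
                    hits = {ranked.symbols[i] for i in combo}
                    es, _ = sg.enrichment_score(ranked, hits)
                    oracle_es, _ = running_sum_oracle(n, combo)
                    assert es == pytest.approx(oracle_es, abs=1e-12), (n, combo)

    def test_weighted_mode_matches_oracle(self):
        ranked = make_ranked(15, seed=9)
        combo = (0, 4, 9, 13)
        hits = {ranked.symbols[i] for i in combo}
        es, _ = sg.enrichment_score(ranked, hits, weight_mode="weighted")
        oracle_es, _ = running_sum_oracle(15, combo, weights=np.abs(ranked.scores))
        assert es == pytest.approx(oracle_es, abs=1e-12)

    @given(
        st.integers(min_value=4, max_value=60),
        st.integers(min_value=0, max_value=10**6),
        st.sampled_from(["unweighted", "weighted"]),
    )
    def test_es_bounded_in_unit_interval(self, n, seed, weight_mode):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, n))
        ranked = make_ranked(n, seed=seed % 2**31)
        hits = {ranked.symbols[i] for i in rng.choice(n, k, replace=False)}
        es, running = sg.enrichment_score(ranked, hits, weight_mode=weight_mode)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert np.abs(running).max() == pytest.approx(abs(es), abs=1e-12)

    @given(st.integers(min_value=4, max_value=40), st.integers(0, 10**6))
    def test_reversing_ranking_negates_es(self, n, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, n))
        ranked = make_ranked(n, seed=seed % 2**31)
        hits = {ranked.symbols[i] for i in rng.choice(n, k, replace=False)}
        es, running = sg.enrichment_score(ranked, hits)
        es_rev, _ = sg.enrichment_score(ranked.reversed(), hits)
        if abs(running.max() + running.min()) > 1e-9:  # skip exact +/- ties
            assert es_rev == pytest.approx(-es, abs=1e-12)
        else:
            assert abs(es_rev) == pytest.approx(abs(es), abs=1e-12)

    def test_zero_overlap_raises(self):
        ranked = make_ranked(10)
        with pytest.raises(ValueError, match="no overlap"):
            sg.enrichment_score(ranked, {"ABSENT"})

    def test_full_universe_set_raises(self):
        ranked = make_ranked(5)
        with pytest.raises(ValueError, match="whole universe"):
            sg.enrichment_score(ranked, set(ranked.symbols))


class TestPermutationTest:
    def test_exhaustive_singleton_two_sided(self):
        """A singleton at the very top attains |ES| = 1, which also
        occurs at the very bottom: the two-sided enumeration p over all
        6 placements is 2/6."""
        ranked = make_ranked(6)
        p = sg.permutation_test(ranked, {ranked.symbols[0]}, exhaustive=True)
        oracle_p, _ = exhaustive_gene_label_p(6, 1, [0])
        assert p == pytest.approx(oracle_p) == pytest.approx(2.0 / 6.0)

    def test_sampled_agrees_with_exhaustive_within_3_se(self):
        ranked = make_ranked(6, seed=4)
        hits = {ranked.symbols[0], ranked.symbols[2]}
        p0, _ = exhaustive_gene_label_p(6, 2, [0, 2])
        n_perm = 2000
        p_hat = sg.permutation_test(ranked, hits, n_perm=n_perm, seed=11)
        se = np.sqrt(p0 * (1 - p0) / n_perm)
        assert abs(p_hat - p0) <= 3 * se + 1.0 / (n_perm + 1)

    def test_p_never_zero(self):
        ranked = make_ranked(500, seed=8)
        hits = set(ranked.symbols[:10])  # extreme concentration at the top
        p = sg.permutation_test(ranked, hits, n_perm=500, seed=1)
        assert 0 < p <= 1
        assert p == pytest.approx(1.0 / 501.0)

    def test_seed_reproducibility(self):
        ranked = make_ranked(300, seed=2)
        hits = set(ranked.symbols[10:18])
        kwargs = dict(n_perm=300, seed=42)
        assert sg.permutation_test(ranked, hits, **kwargs) == sg.permutation_test(
            ranked, hits, **kwargs
        )

    def test_phenotype_scheme_on_injected_module(self):
        cfg = sg.SimulationConfig(
            seed=6,
            n_genes=300,
            module_specs=(sg.ModuleSpec("mod", 15, 0.8, "old"),),
        )
        matrix, truth, _ = sg.simulate(cfg)
        results = sg.run_diffexp(matrix.collapse_probes(), compute_wilcoxon=False)
        ranked = sg.rank_genes(results)
        p = sg.permutation_test(
            ranked,
            frozenset(truth.module_members["mod"]),
            n_perm=200,
            seed=7,
            scheme="phenotype",
            matrix=matrix,
        )
        assert p < 0.05


class TestFDR:
    def test_single_result_identity(self):
        recs = [sg.gsea.EnrichmentRecord("a", 0.5, 5, 0.04)]
        assert sg.fdr_adjust(recs)[0].q_fdr == pytest.approx(0.04)

    def test_bh_step_up_hand_case(self):
        ps = [0.01, 0.02, 0.03, 0.04]
        recs = [
            sg.gsea.EnrichmentRecord(f"s{i}", 0.1, 5, p) for i, p in enumerate(ps)
        ]
        qs = [r.q_fdr for r in sg.fdr_adjust(recs)]
        assert qs == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        recs = [sg.gsea.EnrichmentRecord(f"s{i}", 0.0, 5, 1.0) for i in range(3)]
        assert [r.q_fdr for r in sg.fdr_adjust(recs)] == [1.0, 1.0, 1.0]

    def test_q_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(0)
        ps = sorted(rng.uniform(size=12))
        recs = [
            sg.gsea.EnrichmentRecord(f"s{i}", 0.1, 5, p) for i, p in enumerate(ps)
        ]
        qs = [r.q_fdr for r in sg.fdr_adjust(recs)]
        assert all(q2 >= q1 for q1, q2 in zip(qs, qs[1:]))
        assert all(q >= p for p, q in zip(ps, qs))


class TestRunGsea:
    def test_injected_module_detected_with_negative_es(self):
        cfg = sg.SimulationConfig(
            seed=3,
            n_genes=2000,
            module_specs=(sg.ModuleSpec("shifted", 20, 0.6, "old"),),
        )
        matrix, _, sets = sg.simulate(cfg)
        results = sg.run_diffexp(matrix.collapse_probes(), compute_wilcoxon=False)
        enrichment = sg.run_gsea(results, sets, n_perm=2000, seed=5)
        rec = enrichment["shifted"]
        assert rec.es < 0
        assert rec.p_perm < 0.05

    def test_no_shift_module_usually_non_significant(self):
        hits = 0
        reps = 20
        for i in range(reps):
            cfg = sg.SimulationConfig(
                seed=100 + i,
                n_genes=400,
                module_specs=(sg.ModuleSpec("nullmod", 20, 0.0, "old"),),
            )
            matrix, _, sets = sg.simulate(cfg)
            results = sg.run_diffexp(matrix.collapse_probes(), compute_wilcoxon=False)
            enrichment = sg.run_gsea(results, sets, n_perm=200, seed=200 + i)
            if enrichment["nullmod"].p_perm <= 0.05:
                hits += 1
        assert hits <= 0.1 * reps + 1

    def test_sets_below_min_hits_skipped_with_reason(self, fixture_ranking, curated_sets):
        enrichment = sg.run_gsea(
            fixture_ranking, curated_sets, n_perm=200, seed=1, min_hits=3
        )
        # only the secretome set overlaps the published 227-gene list
        # in >= 3 genes (IL8, CXCL2, TNFRSF11B, CCL8)
        assert [r.set_name for r in enrichment.records] == ["sasp"]
        assert enrichment["sasp"].n_hits == 4
        assert set(enrichment.skipped) == {"senescence", "ddr", "ast"}

    def test_secretome_enriched_up_in_old_on_published_ranking(
        self, fixture_ranking, curated_sets
    ):
        """Three of the four secretome genes in the published list are
        up-regulated in old (IL8, CXCL2, TNFRSF11B vs CCL8), so the ES
        on this truncated universe must be negative."""
        enrichment = sg.run_gsea(
            fixture_ranking, curated_sets, n_perm=500, seed=1
        )
        assert enrichment["sasp"].es < 0

    def test_all_sets_skipped_is_error(self):
        ranked = make_ranked(20)
        sets = sg.GeneSetCollection(
            (sg.GeneSet("foreign", ("NOTPRESENT",)),)
        )
        with pytest.raises(ValueError, match="no gene set"):
            sg.run_gsea(ranked, sets, n_perm=200, seed=1)

    def test_summary_lists_every_set(self, fixture_ranking, curated_sets):
        enrichment = sg.run_gsea(fixture_ranking, curated_sets, n_perm=200, seed=1)
        text = enrichment.summary()
        for name in curated_sets.names:
            assert name in text
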