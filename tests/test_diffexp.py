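"""Signed fold change, Wilcoxon rank-sum and the DE call."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stromaging as sg
from conftest import wilcoxon_enumeration_p

values_st = st.lists(
    st.floats(min_value=0.0, max_value=14.0, allow_nan=False), min_size=2, max_size=9
)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "young, old, expected",
        [
            ([5.0, 5.0], [5.0, 5.0], 1.0),            # identical groups
            ([3.0, 3.0], [2.0, 2.0], 2.0),            # young doubles old
            ([2.0, 2.0], [3.0, 3.0], -2.0),           # antisymmetric case
            ([1.0, 3.0], [2.0, 2.0], 1.25),           # (2+8)/2 / (4+4)/2 = 5/4
        ],
    )
    def test_hand_computed_cases(self, young, old, expected):
        assert sg.signed_fold_change(young, old) == pytest.approx(expected)

    @given(values_st, values_st)
    def test_matches_explicit_linearisation_oracle(self, young, old):
        r = np.mean([2.0**v for v in young]) / np.mean([2.0**v for v in old])
        expected = r if r >= 1 else -1.0 / r
        got = sg.signed_fold_change(young, old)
        assert got == pytest.approx(expected, abs=1e-12, rel=1e-12)
        assert abs(got) >= 1.0

    @given(values_st, values_st)
    def test_group_swap_antisymmetry(self, young, old):
        # a ratio of exactly 1 maps to +1 in either orientation (the
        # signed convention has no values inside (-1, 1)); away from
        # that boundary the swap negates the fold change exactly
        fwd = sg.signed_fold_change(young, old)
        rev = sg.signed_fold_change(old, young)
        if abs(fwd) > 1 + 1e-9:
            assert fwd == pytest.approx(-rev, abs=1e-9)
        else:
            assert abs(rev) == pytest.approx(1.0, abs=1e-9)

    @given(values_st, values_st, st.floats(min_value=0.01, max_value=3.0))
    def test_raising_old_group_weakly_decreases_fc(self, young, old, delta):
        base = sg.signed_fold_change(young, old)
        shifted = sg.signed_fold_change(young, [v + delta for v in old])
        assert shifted <= base + 1e-9

    def test_diff_of_log_means_mode(self):
        # geometric-mean ratio: 2**(mean([1,3]) - mean([2,2])) = 2**0 = 1
        assert sg.signed_fold_change(
            [1.0, 3.0], [2.0, 2.0], fc_mode="diff_of_log_means"
        ) == pytest.approx(1.0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            sg.signed_fold_change([1.0, np.nan], [2.0, 2.0])


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        assert sg.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert sg.wilcoxon_rank_sum([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_all_identical_values_degenerate_convention(self):
        assert sg.wilcoxon_rank_sum([5, 5, 5], [5, 5]) == 1.0

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(size=5)
        assert sg.wilcoxon_rank_sum(a, b) == pytest.approx(
            sg.wilcoxon_rank_sum(b, a)
        )

    @pytest.mark.parametrize("n_total", [4, 5, 6, 7, 8])
    def test_exact_p_matches_full_enumeration(self, n_total):
        """Every split of n distinct values agrees with the enumeration
        oracle over all C(n, k) group assignments."""
        values = np.arange(1.0, n_total + 1.0)
        for k in range(2, n_total - 1):
            for combo in itertools.combinations(range(n_total), k):
                a = values[list(combo)]
                b = np.delete(values, list(combo))
                expected = wilcoxon_enumeration_p(a, b)
                assert sg.wilcoxon_rank_sum(a, b) == pytest.approx(expected), (
                    combo,
                    k,
                )


class TestRunDiffexp:
    def test_injected_effect_recovered(self):
        cfg = sg.SimulationConfig(
            seed=2, n_genes=50, de_fraction=0.02, de_log2fc=1.0, noise_sd=0.05
        )
        matrix, truth, _ = sg.simulate(cfg)
        results = sg.run_diffexp(matrix.collapse_probes())
        (gene,) = truth.de_genes
        rec = results.table.loc[gene]
        assert rec["is_de"]
        if truth.de_genes[gene] == "up_in_old":
            assert rec["signed_fc"] < -1.5
        else:
            assert rec["signed_fc"] > 1.5

    def test_null_matrix_has_low_de_fraction(self):
        """Monte-Carlo check of P(|FC| >= 1.5) under the null design
        (sd 0.3, 9 vs 8); the rate is small but nonzero."""
        cfg = sg.SimulationConfig(seed=3, n_genes=2000, noise_sd=0.3)
        matrix, _, _ = sg.simulate(cfg)
        results = sg.run_diffexp(matrix.collapse_probes(), compute_wilcoxon=False)
        rate = results.table["is_de"].mean()
        assert rate < 0.02

    def test_fixture_values_all_pass_threshold_rule(self):
        from stromaging.pipeline import replay_de_fixture

        results = replay_de_fixture()
        assert results.table["is_de"].all()
        assert (results.n_up_old, results.n_up_young) == (120, 107)

    def test_records_sorted_most_up_in_old_first(self, small_matrix):
        results = sg.run_diffexp(small_matrix)
        fc = results.table["signed_fc"].to_numpy()
        assert np.all(np.diff(fc) >= 0)
        assert results.table.index[0] == "GDOWN"

    def test_wilcoxon_reported_but_not_filtered_on(self, small_matrix):
        results = sg.run_diffexp(small_matrix)
        assert results.table["wilcoxon_p"].notna().all()
        # GUP/GDOWN have |FC| = 2 >= 1.5: called DE regardless of p
        assert results.table.loc["GUP", "is_de"]
        assert results.table.loc["GDOWN", "is_de"]
        assert not results.table.loc["GFLAT", "is_de"]

    def test_group_label_swap_negates_fc_and_keeps_p(self, small_matrix):
        swapped = small_matrix.with_groups(
            small_matrix.groups.map({"young": "old", "old": "young"})
        )
        a = sg.run_diffexp(small_matrix).table
        b = sg.run_diffexp(swapped).table.loc[a.index]
        changed = a["signed_fc"].abs() > 1
        assert np.allclose(a.loc[changed, "signed_fc"], -b.loc[changed, "signed_fc"])
        assert np.allclose(b.loc[~changed, "signed_fc"].abs(), 1.0)
        assert np.allclose(a["wilcoxon_p"], b["wilcoxon_p"])

    def test_threshold_at_most_one_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="exceed 1"):
            sg.run_diffexp(small_matrix, threshold=1.0)

    def test_summary_mentions_counts(self, small_matrix):
        text = sg.run_diffexp(small_matrix).summary()
        assert "up in old" in text and "1.5" in text
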