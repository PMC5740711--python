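import numpy as np
import pytest
from scipy import stats as sps

from superdelta import (
    SuperDeltaConfig,
    normalize_global,
    pairwise_t_stats,
    select_baseline_genes,
    summarize_statistics,
    superdelta_test,
    two_sample_t,
)
from superdelta.superdelta_core import SQRT2, InsufficientBaselineError
from superdelta.simulation import SimulationScenario, simulate_dataset

from conftest import make_design, make_matrix


def _delta_fixture():
    """Two genes whose per-sample difference is (1,3 | 0,2): hand t = 1/sqrt(2)."""
    values = np.array([[1.0, 3.0, 0.0, 2.0], [0.0, 0.0, 0.0, 0.0]])
    return make_matrix(values), make_design(2, 2)


class TestPairwiseTStats:
    def test_hand_computed_value(self):
        matrix, design = _delta_fixture()
        t = pairwise_t_stats(matrix, design, ["g1"], ["g2"])
        assert t[0, 0] == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_antisymmetry(self, rng):
        matrix = make_matrix(rng.normal(size=(6, 8)))
        design = make_design(4, 4)
        ids = matrix.gene_ids
        t = pairwise_t_stats(matrix, design, ids, ids)
        np.testing.assert_allclose(t, -t.T, atol=1e-10, equal_nan=True)

    def test_diagonal_undefined(self, rng):
        matrix = make_matrix(rng.normal(size=(5, 6)))
        t = pairwise_t_stats(matrix, make_design(3, 3), matrix.gene_ids, matrix.gene_ids)
        assert np.isnan(np.diag(t)).all()

    def test_matches_naive_double_loop(self, rng):
        """Sufficient-statistic fast path equals per-pair t-tests on delta rows."""
        matrix = make_matrix(rng.normal(7, 1, size=(20, 10)))
        design = make_design(5, 5)
        t = pairwise_t_stats(matrix, design, matrix.gene_ids, matrix.gene_ids)
        values = matrix.values
        for i in range(20):
            for k in range(20):
                if i == k:
                    continue
                delta = values[i] - values[k]
                expected = sps.ttest_ind(delta[:5], delta[5:], equal_var=True).statistic
                assert t[i, k] == pytest.approx(expected, abs=1e-10)

    def test_per_sample_shift_cancels(self, rng):
        matrix = make_matrix(rng.normal(size=(8, 6)))
        design = make_design(3, 3)
        alpha = rng.normal(0, 5, size=6)
        shifted = matrix.with_values(matrix.values + alpha[None, :])
        t0 = pairwise_t_stats(matrix, design, matrix.gene_ids, matrix.gene_ids)
        t1 = pairwise_t_stats(shifted, design, matrix.gene_ids, matrix.gene_ids)
        np.testing.assert_allclose(t0, t1, atol=1e-10, equal_nan=True)

    def test_global_scaling_invariance(self, rng):
        matrix = make_matrix(rng.normal(size=(6, 6)))
        design = make_design(3, 3)
        scaled = matrix.with_values(matrix.values * 3.7)
        t0 = pairwise_t_stats(matrix, design, matrix.gene_ids, matrix.gene_ids)
        t1 = pairwise_t_stats(scaled, design, matrix.gene_ids, matrix.gene_ids)
        np.testing.assert_allclose(t0, t1, atol=1e-10, equal_nan=True)

    def test_agrees_with_two_sample_t_on_delta_rows(self, rng):
        matrix = make_matrix(rng.normal(size=(4, 8)))
        design = make_design(4, 4)
        t = pairwise_t_stats(matrix, design, matrix.gene_ids, matrix.gene_ids)
        delta = make_matrix(matrix.values - matrix.values[2][None, :])
        table = two_sample_t(delta, design, variant="pooled")
        for i in (0, 1, 3):
            assert t[i, 2] == pytest.approx(table["statistic"].iloc[i], abs=1e-12)


class TestSummarizeStatistics:
    def test_mftm_hand_example(self):
        stat, pairing = summarize_statistics(
            np.array([1.0, 2, 3, 4, 5]), "mftm", 0.2, seed=3
        )
        assert stat == pytest.approx(2.5 * SQRT2)
        assert pairing in (1, 2)

    def test_all_zero_rows(self):
        for summarizer in ("mftm", "median", "mean"):
            stat, _ = summarize_statistics(np.zeros(6), summarizer, 0.2, seed=0)
            assert stat == 0.0

    def test_median_odd_length(self):
        stat, pairing = summarize_statistics(np.array([-1.0, 0.0, 3.0]), "median")
        assert stat == 0.0
        assert pairing == 1

    def test_mean_has_no_pairing(self):
        stat, pairing = summarize_statistics(np.array([1.0, 2.0, 3.0]), "mean")
        assert stat == pytest.approx(2.0 * SQRT2)
        assert pairing is None

    def test_nan_entries_ignored(self):
        row = np.array([np.nan, 1.0, 2.0, 3.0, np.nan])
        stat, pairing = summarize_statistics(row, "median")
        assert stat == pytest.approx(2.0 * SQRT2)
        assert pairing == 2

    def test_insufficient_entries_raise(self):
        with pytest.raises(InsufficientBaselineError):
            summarize_statistics(np.array([1.0, np.nan, np.nan, 2.0]), "mftm")


class TestBaselineSelection:
    def test_all_sentinel(self, rng):
        matrix = make_matrix(rng.normal(size=(5, 4)))
        assert select_baseline_genes(matrix, "all", 0) == matrix.gene_ids

    def test_deterministic_for_seed(self, rng):
        matrix = make_matrix(rng.normal(size=(30, 4)))
        assert select_baseline_genes(matrix, 10, 42) == select_baseline_genes(
            matrix, 10, 42
        )

    def test_distinct_valid_ids(self, rng):
        matrix = make_matrix(rng.normal(size=(10, 4)))
        ids = select_baseline_genes(matrix, 3, 7)
        assert len(set(ids)) == 3 and set(ids) <= set(matrix.gene_ids)

    def test_too_many_requested(self, rng):
        matrix = make_matrix(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            select_baseline_genes(matrix, 6, 0)


@pytest.fixture(scope="module")
def small_run():
    scenario = SimulationScenario(m=120, n_up=6, n_down=10, n_a=8, n_b=8, seed=5)
    data = simulate_dataset(scenario, 3)
    config = SuperDeltaConfig(n_baseline=40, seed=9)
    return data, config, superdelta_test(data.y, data.design, config)


class TestSuperdeltaTest:
    def test_per_sample_shift_leaves_everything(self, small_run, rng):
        data, config, result = small_run
        alpha = rng.normal(0, 4, size=data.y.n_samples)
        shifted = data.y.with_values(data.y.values + alpha[None, :])
        other = superdelta_test(shifted, data.design, config)
        for col in ("statistic", "p_raw", "p_adj", "effect_log2"):
            np.testing.assert_allclose(
                result.table[col], other.table[col], atol=1e-8
            )
        assert (result.table["pairing_gene"] == other.table["pairing_gene"]).all()

    def test_p_values_match_t_distribution(self, small_run):
        _, _, result = small_run
        df = 8 + 8 - 2
        expected = 2 * sps.t.sf(result.table["statistic"].abs(), df)
        np.testing.assert_allclose(result.table["p_raw"], expected, atol=1e-12)
        # statistic 2.0 at pooled df 98 would give the familiar ~0.0483
        assert 2 * sps.t.sf(2.0, 98) == pytest.approx(0.0483, abs=5e-4)

    def test_bh_matches_standalone(self, small_run):
        from superdelta import bh_adjust

        _, _, result = small_run
        np.testing.assert_array_equal(
            result.table["p_adj"], bh_adjust(result.table["p_raw"].to_numpy())
        )
        assert (result.table["p_adj"] >= result.table["p_raw"]).all()

    def test_pairing_gene_contract(self, small_run):
        _, _, result = small_run
        for gene, pairing in result.table["pairing_gene"].items():
            assert pairing != gene
            assert pairing in result.baseline_gene_ids

    def test_matches_row_by_row_summaries(self, small_run):
        """The vectorized pipeline reproduces per-row summarize_statistics."""
        data, config, result = small_run
        t_mat = pairwise_t_stats(
            data.y, data.design, data.y.gene_ids, result.baseline_gene_ids
        )
        for i in range(0, data.y.n_genes, 7):
            stat, _ = summarize_statistics(
                t_mat[i], config.summarizer, config.trim_proportion, seed=0
            )
            assert result.table["statistic"].iloc[i] == pytest.approx(stat, abs=1e-10)

    def test_mean_summarizer_tracks_global_normalization(self):
        scenario = SimulationScenario(m=300, n_up=15, n_down=25, n_a=10, n_b=10, seed=2)
        data = simulate_dataset(scenario, 1)
        config = SuperDeltaConfig(summarizer="mean", n_baseline="all", seed=1)
        result = superdelta_test(data.y, data.design, config)
        pooled = two_sample_t(normalize_global(data.y), data.design, "pooled")
        r = np.corrcoef(result.table["statistic"], pooled["statistic"])[0, 1]
        assert r > 0.99

    def test_welch_df_rule_runs_and_matches_pooled_at_equal_n(self, small_run):
        data, config, result = small_run
        welch = superdelta_test(
            data.y,
            data.design,
            SuperDeltaConfig(n_baseline=40, seed=9, df_rule="welch"),
        )
        # equal group sizes: welch statistic equals pooled statistic
        np.testing.assert_allclose(
            welch.table["statistic"], result.table["statistic"], atol=1e-9
        )

    def test_null_data_yields_no_bh_calls(self):
        """Under the global null, BH at 5% makes no calls in nearly all replicates."""
        scenario = SimulationScenario(m=500, n_up=0, n_down=0, n_a=50, n_b=50, seed=8)
        config = SuperDeltaConfig(n_baseline=100, seed=4)
        clean = 0
        n_reps = 20
        for r in range(n_reps):
            data = simulate_dataset(scenario, r)
            result = superdelta_test(data.y, data.design, config)
            if (result.table["p_adj"] < 0.05).sum() == 0:
                clean += 1
        assert clean >= int(0.95 * n_reps)
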