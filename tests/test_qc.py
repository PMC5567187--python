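"""Preprocessing cascade: batch adjustment, filtering, imputation, centering."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_annotation, make_beta
from oracles import knn_impute_bruteforce

from doublehit import (
    FilterThresholds,
    combat_adjust,
    filter_probes,
    knn_impute,
    preprocess,
    zero_mean_normalize,
)


class TestCombat:
    def test_single_batch_is_identity(self, small_beta):
        out = combat_adjust(small_beta)
        np.testing.assert_allclose(out.values.to_numpy(), small_beta.values.to_numpy(),
                                   atol=1e-8)

    def test_pure_location_shift_removed_exactly(self):
        # no noise: each probe constant within batch, batches differ by +0.2
        rng = np.random.default_rng(0)
        base = np.tile(rng.uniform(0.3, 0.7, size=(30, 1)), (1, 6))
        shifted = np.concatenate([base, base + 0.2], axis=1)
        m = make_beta(shifted, batches=["b0"] * 6 + ["b1"] * 6)
        out = combat_adjust(m).values.to_numpy()
        means_b0 = out[:, :6].mean(axis=1)
        means_b1 = out[:, 6:].mean(axis=1)
        np.testing.assert_allclose(means_b0, means_b1, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_monte_carlo_batch_mean_gap_shrinks_tenfold(self, seed):
        rng = np.random.default_rng(seed)
        n_probes, per_batch = 200, 15
        base = rng.uniform(0.3, 0.7, n_probes)
        b0 = base[:, None] + rng.normal(0, 0.03, (n_probes, per_batch))
        b1 = base[:, None] + 0.1 + rng.normal(0, 0.05, (n_probes, per_batch))
        m = make_beta(np.concatenate([b0, b1], axis=1),
                      batches=["b0"] * per_batch + ["b1"] * per_batch)
        before = np.abs(b0.mean(axis=1) - b1.mean(axis=1)).mean()
        out = combat_adjust(m).values.to_numpy()
        after = np.abs(out[:, :per_batch].mean(axis=1) - out[:, per_batch:].mean(axis=1)).mean()
        assert after < before / 10

    def test_small_batch_rejected_by_name(self, small_beta):
        batches = ["b0"] * 9 + ["lonely"]
        with pytest.raises(ValueError, match="lonely"):
            combat_adjust(small_beta, pd.Series(batches, index=small_beta.sample_ids))

    def test_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.2, 0.8, size=(40, 12))
        batches = ["b0", "b1"] * 6
        m = make_beta(X, batches=batches)
        out = combat_adjust(m)
        perm = rng.permutation(12)
        m_perm = make_beta(X[:, perm], batches=[batches[i] for i in perm])
        out_perm = combat_adjust(m_perm)
        np.testing.assert_allclose(out_perm.values.to_numpy(),
                                   out.values.to_numpy()[:, perm], atol=1e-10)

    def test_logit_scale_variant_keeps_unit_support(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.2, 0.6, size=(60, 30))
        X[:, 15:] += 0.2
        m = make_beta(X, batches=["b0"] * 15 + ["b1"] * 15)
        out = combat_adjust(m, scale="logit").values.to_numpy()
        assert (out > 0).all() and (out < 1).all()
        gap_before = np.abs(X[:, :15].mean(1) - X[:, 15:].mean(1)).mean()
        gap_after = np.abs(out[:, :15].mean(1) - out[:, 15:].mean(1)).mean()
        assert gap_after < gap_before / 5

    def test_missing_cells_stay_missing_and_tolerated(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.2, 0.8, size=(30, 10))
        X[2, 3] = np.nan
        m = make_beta(X, batches=["b0"] * 5 + ["b1"] * 5)
        out = combat_adjust(m).values.to_numpy()
        assert np.isnan(out[2, 3])
        assert np.isfinite(out[~np.isnan(X)]).all()


class TestFilterProbes:
    def test_rule_counts_and_conservation_by_construction(self):
        # 100 probes: 10 XY, 5 MAF .2, 5 control, 10 intergenic, rest clean
        n = 100
        probes = [f"cg{i:05d}" for i in range(n)]
        ann = make_annotation(probes)
        ann.iloc[0:10, ann.columns.get_loc("chromosome")] = "X"
        ann.iloc[10:15, ann.columns.get_loc("snp_maf")] = 0.2
        ann.iloc[15:20, ann.columns.get_loc("control_probe")] = True
        ann.iloc[20:30, ann.columns.get_loc("region_class")] = "intergenic"
        m = make_beta(np.full((n, 10), 0.5))
        kept, report = filter_probes(m, ann)
        assert report.removed == {"missingness": 0, "xy_chromosome": 10, "snp_maf": 5,
                                  "control_probe": 5, "blacklist": 0, "region": 10}
        assert report.retained_probes == 70
        assert sum(report.removed.values()) + report.retained_probes == report.input_probes

    def test_missingness_rule_strict_and_first(self):
        X = np.full((2, 10), 0.5)
        X[0, :3] = np.nan  # 30% > 20% -> removed
        X[1, :2] = np.nan  # 20% boundary -> retained
        m = make_beta(X)
        ann = make_annotation(list(m.probe_ids), chromosome=["X", "1"])  # first probe also XY
        kept, report = filter_probes(m, ann)
        # first failing rule wins: claimed by missingness, not XY
        assert report.removed["missingness"] == 1
        assert report.removed["xy_chromosome"] == 0
        assert list(kept.probe_ids) == [m.probe_ids[1]]

    def test_maf_boundary_retained(self):
        m = make_beta(np.full((2, 4), 0.5))
        ann = make_annotation(list(m.probe_ids), snp_maf=[0.1, 0.100001])
        kept, _ = filter_probes(m, ann)
        assert list(kept.probe_ids) == [m.probe_ids[0]]

    def test_unknown_region_class_rejected(self):
        m = make_beta(np.full((1, 4), 0.5))
        ann = make_annotation(list(m.probe_ids), region_class=["Promoter"])
        with pytest.raises(ValueError, match="region_class"):
            filter_probes(m, ann)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_annotations(self, seed):
        from doublehit import MethylSimConfig, simulate_methylation
        beta, ann, _ = simulate_methylation(MethylSimConfig(
            n_cases=5, n_controls=5, n_probes=300, n_true_dmp=0, seed=seed))
        _, report = filter_probes(beta, ann)
        assert sum(report.removed.values()) + report.retained_probes == 300


class TestKnnImpute:
    def test_complete_matrix_identity(self, small_beta):
        out = knn_impute(small_beta)
        pd.testing.assert_frame_equal(out.values, small_beta.values)

    def test_mean_of_three_neighbors(self):
        # target probe identical to three donors except one masked cell
        X = np.array([
            [0.5, 0.5, 0.5, np.nan],
            [0.5, 0.5, 0.5, 0.2],
            [0.5, 0.5, 0.5, 0.4],
            [0.5, 0.5, 0.5, 0.6],
            [0.9, 0.1, 0.9, 0.9],
        ])
        out = knn_impute(make_beta(X), k=3).values.to_numpy()
        assert out[0, 3] == pytest.approx((0.2 + 0.4 + 0.6) / 3)

    def test_twin_probe_restores_masked_cell(self):
        rng = np.random.default_rng(1)
        row = rng.uniform(0.2, 0.8, 8)
        X = np.vstack([row, row, rng.uniform(0.2, 0.8, (6, 8))])
        X[0, 5] = np.nan
        out = knn_impute(make_beta(X), k=1).values.to_numpy()
        assert out[0, 5] == pytest.approx(row[5], abs=1e-12)

    def test_fully_missing_probe_rejected(self):
        X = np.full((3, 4), 0.5)
        X[1] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            knn_impute(make_beta(X))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(30, 12))
        mask = rng.random(X.shape) < 0.1
        X[mask] = np.nan
        assert not np.isnan(X).all(axis=1).any()
        expected = knn_impute_bruteforce(X, k=3)
        got = knn_impute(make_beta(X), k=3).values.to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestZeroMean:
    def test_simple_row(self):
        out = zero_mean_normalize(make_beta(np.array([[0.2, 0.4, 0.6]])))
        np.testing.assert_allclose(out.values.to_numpy(), [[-0.2, 0.0, 0.2]], atol=1e-15)

    def test_rows_centered_and_idempotent(self, small_beta):
        once = zero_mean_normalize(small_beta)
        np.testing.assert_allclose(once.values.mean(axis=1), 0.0, atol=1e-12)
        twice = zero_mean_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(), atol=1e-15)

    def test_rejects_missing(self):
        X = np.full((2, 3), 0.5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            zero_mean_normalize(make_beta(X))


def test_preprocess_runs_cascade_in_order():
    from doublehit import MethylSimConfig, simulate_methylation
    beta, ann, _ = simulate_methylation(MethylSimConfig(
        n_cases=10, n_controls=10, n_probes=200, n_true_dmp=0, seed=0))
    processed, report = preprocess(beta, ann, FilterThresholds())
    assert processed.values.shape[0] == report.retained_probes
    assert not processed.values.isna().any().any()
    np.testing.assert_allclose(processed.values.mean(axis=1), 0.0, atol=1e-12)
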