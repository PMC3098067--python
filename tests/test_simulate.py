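"""Synthetic mixed-tissue data generator."""

import numpy as np
import pytest

from deconfound.matrices import SignatureMatrix, ValidationError
from deconfound.simulate import (
    SimulationConfig,
    add_noise,
    simulate_dataset,
    simulate_proportions,
    simulate_signature,
    spike_differential_expression,
)


class TestSignature:
    def test_gamma_level_matches_moments(self):
        cfg = SimulationConfig(n_genes=10000, random_seed=1)
        S = simulate_signature(cfg)
        non_marker = S.values[cfg.n_markers :, :]
        assert non_marker.mean() == pytest.approx(8.125, abs=0.1)
        assert non_marker.var() == pytest.approx(5.28, rel=0.1)

    def test_marker_rows_fixed(self):
        cfg = SimulationConfig(n_genes=100, n_markers=10, n_diff=10, random_seed=2)
        S = simulate_signature(cfg)
        np.testing.assert_allclose(S.values[:5], np.tile([12.0, 6.0], (5, 1)))
        np.testing.assert_allclose(S.values[5:10], np.tile([6.0, 12.0], (5, 1)))

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(gamma_scale=0.0)


class TestProportions:
    def test_degenerate_bounds(self):
        cfg = SimulationConfig(proportion_bounds=(0.5, 0.5))
        C = simulate_proportions(cfg, 7)
        np.testing.assert_allclose(C.values, 0.5)

    def test_uniform_mean_and_sum(self):
        cfg = SimulationConfig(proportion_bounds=(0.2, 0.8), random_seed=3)
        C = simulate_proportions(cfg, 10000)
        assert C.values[0].mean() == pytest.approx(0.5, abs=0.01)
        np.testing.assert_allclose(C.values.sum(axis=0), 1.0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(proportion_bounds=(0.8, 0.2))


class TestNoise:
    def _expr(self, values):
        from deconfound.matrices import ExpressionMatrix

        return ExpressionMatrix(
            values,
            [f"g{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])],
        )

    def test_noise_free_limit_is_identity(self):
        cfg = SimulationConfig(cv_biological=0.0, var_technical=0.0)
        X = self._expr(np.full((50, 4), 7.0))
        np.testing.assert_array_equal(add_noise(X, cfg).values, X.values)

    def test_constant_cv(self):
        cfg = SimulationConfig(cv_biological=0.17, var_technical=0.0, random_seed=4)
        X = self._expr(np.full((200, 50), 10.0))
        noisy = add_noise(X, cfg).values
        cv = noisy.std() / noisy.mean()
        assert cv == pytest.approx(0.17, abs=0.005)

    def test_additive_term_alone_on_zero_signal(self):
        cfg = SimulationConfig(cv_biological=0.17, var_technical=0.1, random_seed=5)
        X = self._expr(np.zeros((200, 200)))
        out = add_noise(X, cfg).values
        # clipped N(0, chi): mean of max(eps, 0) is sigma / sqrt(2 pi)
        assert out.min() == 0.0
        assert out.mean() == pytest.approx(np.sqrt(0.1) / np.sqrt(2 * np.pi), abs=0.01)


class TestSpike:
    def _base(self, rows, n_markers=2):
        cfg = SimulationConfig(
            n_genes=len(rows) + n_markers,
            n_markers=n_markers,
            n_diff=len(rows),
            delta_diff=2.0,
            random_seed=6,
        )
        S = simulate_signature(cfg)
        vals = S.values.copy()
        vals[n_markers:] = rows
        return cfg, SignatureMatrix(vals, list(S.gene_ids), list(S.cell_type_labels))

    def test_up_first_only(self):
        cfg, S1 = self._base(np.array([[8.0, 8.0]]))
        S2, de_ids, dirs = spike_differential_expression(S1, cfg)
        np.testing.assert_allclose(S2.values[2], [10.0, 8.0])
        assert dirs[de_ids[0]] == (1, 0)

    def test_reverse_cancels_balanced_mixture(self):
        cfg, S1 = self._base(np.array([[8.0, 8.0]]))
        cfg = SimulationConfig(**{**cfg.__dict__, "de_pattern": "reverse"})
        S2, de_ids, _ = spike_differential_expression(S1, cfg)
        np.testing.assert_allclose(S2.values[2], [10.0, 6.0])
        c = np.array([0.5, 0.5])
        assert S2.values[2] @ c == pytest.approx(S1.values[2] @ c)

    def test_reverse_floors_at_zero(self):
        cfg, S1 = self._base(np.array([[8.0, 3.0]]))
        cfg = SimulationConfig(
            **{**cfg.__dict__, "de_pattern": "reverse", "delta_diff": 5.0}
        )
        S2, *_ = spike_differential_expression(S1, cfg)
        np.testing.assert_allclose(S2.values[2], [13.0, 0.0])

    def test_mixed_pattern_uses_all_directions(self):
        cfg = SimulationConfig(
            n_genes=2000, n_diff=600, de_pattern="mixed", random_seed=7
        )
        S1 = simulate_signature(cfg)
        _, _, dirs = spike_differential_expression(S1, cfg)
        assert set(dirs.values()) == {
            (1, 1), (1, 0), (1, -1), (0, 1), (0, -1), (-1, 1), (-1, 0), (-1, -1)
        }

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(delta_diff=0.0, n_diff=10)


class TestDataset:
    def test_fixed_seed_bit_identical(self):
        cfg = SimulationConfig(n_genes=300, n_diff=20, n_samples_per_group=6, random_seed=8)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        for g in cfg.group_labels:
            np.testing.assert_array_equal(a.X[g].values, b.X[g].values)
            np.testing.assert_array_equal(a.C[g].values, b.C[g].values)
        assert a.de_gene_ids == b.de_gene_ids

    def test_mixture_identity_exact_before_noise(self):
        cfg = SimulationConfig(
            n_genes=300, n_diff=20, n_samples_per_group=6,
            cv_biological=0.0, var_technical=0.0, random_seed=9,
        )
        ds = simulate_dataset(cfg)
        for g in cfg.group_labels:
            np.testing.assert_allclose(
                ds.X[g].values, ds.S[g].values @ ds.C[g].values, rtol=0, atol=1e-12
            )

    def test_pure_cell_type_limit(self):
        cfg = SimulationConfig(
            n_genes=100, n_diff=0, n_samples_per_group=4,
            cv_biological=0.0, var_technical=0.0,
            proportion_bounds=(1.0, 1.0), random_seed=10,
        )
        ds = simulate_dataset(cfg)
        g = cfg.group_labels[0]
        np.testing.assert_allclose(
            ds.X[g].values, np.tile(ds.S[g].values[:, :1], (1, 4)), atol=1e-12
        )

    def test_reverse_pattern_cancellation_in_mixture(self):
        """Group means of the mixed DE-gene signal agree within Monte-Carlo
        error when proportions are centred on one half."""
        cfg = SimulationConfig(
            n_genes=1000, n_diff=100, de_pattern="reverse",
            n_samples_per_group=200, random_seed=11,
        )
        ds = simulate_dataset(cfg)
        idx = [ds.X["A"].gene_ids.index(g) for g in ds.de_gene_ids]
        a = ds.X["A"].values[idx, :].mean(axis=0)  # per-sample mean over DE genes
        b = ds.X["B"].values[idx, :].mean(axis=0)
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) < 2 * se

    def test_validation_cases_reuse_signatures(self):
        cfg = SimulationConfig(n_genes=200, n_diff=10, n_samples_per_group=4, random_seed=12)
        ds = simulate_dataset(cfg)
        X_val, C_val, labels = ds.simulate_validation(9, seed=13)
        assert X_val.n_samples == 9 and C_val.n_samples == 9
        assert labels.count("A") == 5 and labels.count("B") == 4
        np.testing.assert_allclose(C_val.values.sum(axis=0), 1.0)
        # determinism
        X_val2, _, _ = ds.simulate_validation(9, seed=13)
        np.testing.assert_array_equal(X_val.values, X_val2.values)

    def test_markers_and_de_genes_disjoint(self, small_dataset):
        assert not set(small_dataset.de_gene_ids) & set(small_dataset.markers.all_markers)
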