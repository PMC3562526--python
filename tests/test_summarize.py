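"""RMA components against independent oracles, and the assembled pipeline."""

import numpy as np
import pytest
from scipy import integrate, stats

from xspecies.chip_model import ExpressionMatrix
from xspecies.diffexpr import de_test
from xspecies.masking import apply_mask, build_mask
from xspecies.summarize import (
    BackgroundModel,
    RmaOptions,
    background_correct,
    estimate_background,
    median_polish,
    median_polish_summarize,
    quantile_normalize,
    rma,
)
from xspecies.synth import SimulationConfig, simulate


def posterior_mean_oracle(x: float, mu: float, sigma: float, alpha: float) -> float:
    """E[s | x] under x = s + b, s ~ Exp(alpha), b ~ N(mu, sigma^2), by quadrature."""
    def integrand_num(s):
        return s * stats.norm.pdf(x - s, mu, sigma) * alpha * np.exp(-alpha * s)

    def integrand_den(s):
        return stats.norm.pdf(x - s, mu, sigma) * alpha * np.exp(-alpha * s)

    # integrand is sharply peaked near s = x - mu; a finite window with an
    # interior break point keeps the quadrature honest
    peak = max(x - mu, 0.0)
    hi = peak + 12 * sigma
    pts = [peak] if 0 < peak < hi else None
    num, _ = integrate.quad(integrand_num, 0, hi, limit=400, points=pts)
    den, _ = integrate.quad(integrand_den, 0, hi, limit=400, points=pts)
    return num / den


class TestBackgroundCorrect:
    def test_matches_quadrature_oracle(self):
        model = BackgroundModel(mu=0.0, sigma=1.0, alpha=1.0)
        for x in [-2.0, 0.0, 0.5, 1.0, 3.0, 10.0]:
            expected = posterior_mean_oracle(x, 0.0, 1.0, 1.0)
            got = float(background_correct(np.array([x]), model)[0])
            assert got == pytest.approx(expected, abs=1e-6)

    def test_degenerate_limit_is_plain_subtraction(self):
        model = BackgroundModel(mu=50.0, sigma=1e-6, alpha=1e-9)
        x = np.array([120.0, 300.0])
        np.testing.assert_allclose(background_correct(x, model), x - 50.0, atol=1e-4)

    def test_strictly_increasing_and_positive(self):
        model = BackgroundModel(mu=100.0, sigma=15.0, alpha=0.01)
        x = np.linspace(0, 500, 200)
        out = background_correct(x, model)
        assert np.all(out > 0)
        assert np.all(np.diff(out) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            background_correct(np.array([1.0, np.nan]), BackgroundModel(0, 1, 1))


class TestEstimateBackground:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        x = rng.normal(100, 10, 50_000) + rng.exponential(1 / 0.01, 50_000)
        model = estimate_background(x)
        assert model.mu == pytest.approx(100, abs=5)
        assert model.alpha == pytest.approx(0.01, abs=0.003)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(100, 10, 20_000) + rng.exponential(100, 20_000)
        m1 = estimate_background(x)
        m2 = estimate_background(2 * x)
        assert m2.mu == pytest.approx(2 * m1.mu, rel=0.1)
        assert m2.sigma == pytest.approx(2 * m1.sigma, rel=0.1)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_background(np.full(1000, 7.0))

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="100"):
            estimate_background(np.arange(50, dtype=float))


class TestQuantileNormalize:
    def test_hand_oracle(self):
        m = np.array([[5.0, 4.0], [2.0, 1.0], [3.0, 6.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], [5.5, 1.5, 3.5])
        np.testing.assert_allclose(out[:, 1], [3.5, 1.5, 5.5])

    def test_matches_sort_average_assign_oracle_on_random(self, rng):
        """Independent oracle: sort each column, average per rank, re-assign."""
        for _ in range(50):
            m = rng.normal(size=(rng.integers(3, 20), rng.integers(2, 6)))
            out = quantile_normalize(m)
            target = np.sort(m, axis=0).mean(axis=1)
            expected = np.empty_like(m)
            for j in range(m.shape[1]):
                expected[np.argsort(m[:, j], kind="stable"), j] = target
            np.testing.assert_array_equal(out, expected)

    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0])
        m = np.column_stack([col, col, col])
        np.testing.assert_array_equal(quantile_normalize(m), m)

    def test_idempotent(self, rng):
        m = rng.normal(size=(40, 4))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_column_sums_equal(self, rng):
        out = quantile_normalize(rng.exponential(size=(30, 5)))
        sums = out.sum(axis=0)
        np.testing.assert_allclose(sums, sums[0])

    def test_single_array_warns_noop(self):
        m = np.array([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single array"):
            out = quantile_normalize(m)
        np.testing.assert_array_equal(out, m)


class TestMedianPolish:
    def test_hand_example(self):
        expr = median_polish_summarize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(expr, [2.0, 3.0])
        overall, _, col_eff, _ = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert overall == pytest.approx(2.5)
        np.testing.assert_allclose(col_eff, [-0.5, 0.5])

    def test_additive_matrix_is_fixed_point(self, rng):
        r = rng.normal(size=6)
        c = rng.normal(size=4)
        m = r[:, None] + c[None, :]
        expr = median_polish_summarize(m)
        np.testing.assert_allclose(expr - expr.mean(), c - c.mean(), atol=1e-12)

    def test_location_equivariance(self, rng):
        m = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            median_polish_summarize(m + 7.5), median_polish_summarize(m) + 7.5, atol=1e-9
        )

    def test_residual_medians_vanish(self, rng):
        for _ in range(10):
            m = rng.normal(size=(rng.integers(3, 12), rng.integers(2, 6)))
            _, _, _, resid = median_polish(m, max_iter=50)
            assert np.max(np.abs(np.median(resid, axis=0))) <= 1e-6
            assert np.max(np.abs(np.median(resid, axis=1))) <= 1e-6


class TestRma:
    def test_noiseless_recovers_planted_shift(self):
        """Noiseless clean data: the ripe-unripe difference reproduces the
        planted log2 fold change up to quantile-normalization rank
        displacement (exactness holds per stage, not across the rank map)."""
        cfg = SimulationConfig(
            n_probe_sets=200, de_fraction=0.1, de_log2fc=1.0, noise_sd=0.0,
            divergence_fraction=0.0, nonspecific_scale=0.0, seed=5,
        )
        layout, _, rna, truth = simulate(cfg)
        expr = rma(rna, layout, RmaOptions(background=False))
        de = de_test(expr)
        errs = np.array([de.frame.log2fc[s] - truth.de_sets[s] for s in truth.true_de_ids])
        assert np.mean(np.abs(errs)) < 0.05
        assert set(truth.true_de_ids) <= set(de.selected_ids)

    def test_array_order_permutes_columns_only(self, clean_dataset):
        cfg, (layout, _, rna, _) = clean_dataset
        expr = rma(rna, layout, RmaOptions(background=False))
        perm = [3, 0, 5, 1, 4, 2]
        expr_p = rma([rna[i] for i in perm], layout, RmaOptions(background=False))
        assert expr_p.array_ids == [expr.array_ids[i] for i in perm]
        inverse = np.argsort(perm)
        # column-mean accumulation order shifts the last float bits
        np.testing.assert_allclose(expr_p.values[:, inverse], expr.values, atol=1e-12)

    def test_deterministic(self, small_dataset):
        cfg, (layout, gdna, rna, _) = small_dataset
        masked = apply_mask(layout, build_mask(gdna, layout, 75.0))
        a = rma(rna, masked)
        b = rma(rna, masked)
        np.testing.assert_array_equal(a.values, b.values)

    def test_masking_improves_fold_change_accuracy(self):
        """With half the probes diverged, masking shrinks the mean absolute
        fold-change error over the planted DE sets."""
        cfg = SimulationConfig(n_probe_sets=400, divergence_fraction=0.5, seed=7)
        layout, gdna, rna, truth = simulate(cfg)
        de_full = de_test(rma(rna, layout))
        masked = apply_mask(layout, build_mask(gdna, layout, 75.0))
        de_mask = de_test(rma(rna, masked))
        td = truth.true_de_ids
        err_full = np.mean([abs(de_full.frame.log2fc[s] - truth.de_sets[s]) for s in td])
        err_mask = np.mean([abs(de_mask.frame.log2fc[s] - truth.de_sets[s])
                            for s in td if s in de_mask.frame.index])
        assert err_mask < err_full

    def test_single_array_rejected(self, clean_dataset):
        cfg, (layout, _, rna, _) = clean_dataset
        with pytest.raises(ValueError, match="2 arrays"):
            rma(rna[:1], layout)
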