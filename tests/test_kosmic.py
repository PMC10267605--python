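"""Truncation-search estimator: truncated ML, KS scoring, recovery."""

import numpy as np
import pytest
from scipy.special import ndtr

from indirect_ri import (
    KosmicConfig,
    fit_kosmic,
    ks_truncated,
    model_ri,
    truncated_gauss_ml,
)
from indirect_ri.errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
)
from indirect_ri.kosmic import _ml_fixed_point, _suffstat_nll
from indirect_ri.synthetic import generate
from .conftest import gaussian_spec, make_series


class TestTruncatedML:
    def test_untruncated_matches_sample_moments(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 100_000)
        mu, sigma = truncated_gauss_ml(y, -10, 10)
        assert mu == pytest.approx(y.mean(), abs=0.02)
        assert sigma == pytest.approx(y.std(), abs=0.02)

    def test_heavy_truncation_recovers_sigma(self):
        """Inside [-1, 1] the naive SD is ~0.54; the truncated MLE must
        undo the truncation bias."""
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 100_000)
        naive = y[(y >= -1) & (y <= 1)].std()
        assert naive == pytest.approx(0.54, abs=0.02)
        mu, sigma = truncated_gauss_ml(y, -1, 1)
        assert mu == pytest.approx(0.0, abs=0.03)
        assert sigma == pytest.approx(1.0, abs=0.05)

    def test_agrees_with_brute_force_grid(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.3, 0.8, 20_000)
        t1, t2 = -0.5, 1.0
        mu, sigma = truncated_gauss_ml(y, t1, t2)
        inside = y[(y >= t1) & (y <= t2)]
        m, s1, s2 = inside.size, inside.sum(), np.square(inside).sum()
        grid_mu = np.linspace(mu - 0.2, mu + 0.2, 81)
        grid_sg = np.linspace(max(sigma - 0.2, 0.05), sigma + 0.2, 81)
        nll = np.array(
            [[_suffstat_nll(m_, s_, t1, t2, m, s1, s2) for s_ in grid_sg]
             for m_ in grid_mu]
        )
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        assert mu == pytest.approx(grid_mu[i], abs=0.01)
        assert sigma == pytest.approx(grid_sg[j], abs=0.01)

    def test_symmetric_data_symmetric_bounds(self):
        rng = np.random.default_rng(4)
        half = rng.normal(0, 1, 50_000)
        y = np.concatenate([half, -half])  # exactly symmetric
        mu, _ = truncated_gauss_ml(y, -1.2, 1.2)
        assert mu == pytest.approx(0.0, abs=1e-6)

    def test_too_few_insiders(self):
        with pytest.raises(InsufficientDataError):
            truncated_gauss_ml(np.linspace(-5, 5, 1000), 4.9, 5.0)

    def test_vectorized_fixed_point_matches_scipy(self):
        rng = np.random.default_rng(5)
        y = rng.normal(1.0, 2.0, 50_000)
        windows = [(-1.0, 3.0), (0.0, 2.0), (-3.0, 5.0), (0.5, 4.0)]
        a = np.array([w[0] for w in windows])
        b = np.array([w[1] for w in windows])
        means, vars_, ms = [], [], []
        for lo, hi in windows:
            inside = y[(y >= lo) & (y <= hi)]
            means.append(inside.mean())
            vars_.append(inside.var())
            ms.append(inside.size)
        mu_v, sg_v, conv, _ = _ml_fixed_point(
            a, b, np.array(ms, float), np.array(means), np.array(vars_), 1e-9
        )
        assert conv.all()
        for k, (lo, hi) in enumerate(windows):
            mu_s, sg_s = truncated_gauss_ml(y, lo, hi, tolerance=1e-9)
            assert mu_v[k] == pytest.approx(mu_s, abs=1e-3)
            assert sg_v[k] == pytest.approx(sg_s, abs=1e-3)


class TestKsTruncated:
    @staticmethod
    def brute_ks(y, mu, sigma, t1, t2):
        inside = np.sort(y[(y >= t1) & (y <= t2)])
        m = inside.size
        Z = ndtr((t2 - mu) / sigma) - ndtr((t1 - mu) / sigma)
        d = 0.0
        for i, v in enumerate(inside):
            F = (ndtr((v - mu) / sigma) - ndtr((t1 - mu) / sigma)) / Z
            d = max(d, abs(F - (i + 1) / m), abs(F - i / m))
        return d

    def test_matches_direct_sup_difference(self):
        rng = np.random.default_rng(6)
        y = np.round(rng.normal(0, 1, 2_000), 2)
        d = ks_truncated(y, (0.1, 0.9), -1.5, 1.5)
        assert d == pytest.approx(self.brute_ks(y, 0.1, 0.9, -1.5, 1.5), abs=1e-12)

    def test_small_for_model_samples(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 400_000)
        d = ks_truncated(y[(y >= -1) & (y <= 1)], (0.0, 1.0), -1, 1)
        assert d < 0.01

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            y = rng.uniform(-2, 2, 500)
            mu, sigma = rng.normal(0, 2), rng.uniform(0.1, 3)
            d = ks_truncated(y, (mu, sigma), -2, 2)
            assert 0.0 <= d <= 1.0

    def test_empty_inside_raises(self):
        with pytest.raises(DomainError):
            ks_truncated(np.array([5.0, 6.0]), (0, 1), -1, 1)


class TestFitKosmic:
    def test_parameter_recovery_zero_contamination(self, gaussian_series):
        series, truth = gaussian_series
        fit = fit_kosmic(series, KosmicConfig(lambda_grid=(1.0,)))
        assert fit.model.mu == pytest.approx(99.0, rel=0.02)
        assert fit.model.sigma == pytest.approx(10.0, rel=0.02)
        assert fit.ri.lower == pytest.approx(truth.lower, rel=0.02)
        assert fit.ri.upper == pytest.approx(truth.upper, rel=0.02)

    def test_ri_equals_model_ri_exactly(self, gaussian_series):
        series, _ = gaussian_series
        fit = fit_kosmic(series, KosmicConfig(lambda_grid=(1.0,)))
        ri = model_ri(fit.model, method="kosmic")
        assert fit.ri.lower == ri.lower and fit.ri.upper == ri.upper

    def test_truncation_inside_data_range(self, gaussian_series):
        series, _ = gaussian_series
        fit = fit_kosmic(series, KosmicConfig(lambda_grid=(1.0,)))
        assert series.values.min() <= fit.t1 < fit.t2 <= series.values.max()

    def test_scale_equivariance_lambda_fixed(self):
        series, _ = generate(gaussian_spec(n=20_000, seed=23))
        scaled = make_series(np.round(series.values * 2, 1), decimals=1)
        cfg = KosmicConfig(lambda_grid=(1.0,))
        f1, f2 = fit_kosmic(series, cfg), fit_kosmic(scaled, cfg)
        assert f2.ri.lower == pytest.approx(2 * f1.ri.lower, rel=0.01)
        assert f2.ri.upper == pytest.approx(2 * f1.ri.upper, rel=0.01)

    def test_deterministic(self):
        series, _ = generate(gaussian_spec(n=5_000, seed=29))
        cfg = KosmicConfig(lambda_grid=(0.5, 1.0))
        assert fit_kosmic(series, cfg) == fit_kosmic(series, cfg)

    def test_hard_floor_on_n(self):
        with pytest.raises(InsufficientDataError):
            fit_kosmic(make_series(np.arange(1, 41), decimals=0))

    def test_warns_below_recommended_n(self):
        series, _ = generate(gaussian_spec(n=400, seed=31))
        with pytest.warns(UserWarning, match="unstable"):
            fit_kosmic(series, KosmicConfig(lambda_grid=(1.0,)))

    def test_penalization_prefers_wider_windows(self):
        """Without the sqrt(inside-fraction) penalty the objective
        collapses onto narrow windows; with it the chosen window covers
        a healthy majority of the data."""
        series, _ = generate(gaussian_spec(n=20_000, seed=37))
        fit = fit_kosmic(series, KosmicConfig(lambda_grid=(1.0,)))
        q1, q2 = fit.quantile_window
        assert q2 - q1 > 0.5


class TestKosmicConfig:
    def test_bounds_validation(self):
        with pytest.raises(ConfigurationError):
            KosmicConfig(t1_min=0.4, t1_max=0.3)
        with pytest.raises(ConfigurationError):
            KosmicConfig(tolerance=-1)

    def test_from_yaml_upstream_names(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "t1min: 0.05\nt1max: 0.3\nt2min: 0.7\nt2max: 0.95\n"
            "tolerance: 1.0e-07\nsd: 0.8\n"
        )
        cfg = KosmicConfig.from_yaml(p)
        assert cfg.t1_min == 0.05 and cfg.t2_max == 0.95
        assert cfg.tolerance == pytest.approx(1e-7)
        assert cfg.sd_param == pytest.approx(0.8)
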