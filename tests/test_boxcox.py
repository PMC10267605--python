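"""Transform machinery and the closed-form percentile map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from indirect_ri import (
    BoxCoxGaussian,
    ReferenceInterval,
    boxcox,
    inv_boxcox,
    model_percentile,
    model_ri,
)
from indirect_ri.errors import DomainError

# published truncation-search fits for the three thyroid analytes,
# (lam, mu, sigma) with their printed 2.5/50/97.5 percentiles
ANALYTE_MODELS = {
    "TSH": ((0.07, 0.734424, 0.688931), (0.532845, 2.04658, 7.00022)),
    "fT3": ((0.99, 2.77787, 0.717507), (2.37839, 3.8005, 5.22808)),
    "fT4": ((0.4, -0.157573, 0.171608), (0.576794, 0.849797, 1.18847)),
}


class TestBoxcox:
    @pytest.mark.parametrize(
        "x, lam, expected",
        [
            (2.0, 1.0, 1.0),
            (1.0, 0.0, 0.0),
            (1.0, 0.5, 0.0),
            (1.0, -1.3, 0.0),
            (np.e, 0.0, 1.0),
        ],
    )
    def test_known_values(self, x, lam, expected):
        assert boxcox(x, lam) == pytest.approx(expected, abs=1e-12)

    def test_tsh_upper_limit_transforms_to_mu_plus_z_sigma(self):
        # direct evaluation (7.00022**0.07 - 1)/0.07 is the oracle
        direct = (7.00022 ** 0.07 - 1.0) / 0.07
        assert boxcox(7.00022, 0.07) == pytest.approx(direct, rel=1e-12)
        (lam, mu, sigma), _ = ANALYTE_MODELS["TSH"]
        assert direct == pytest.approx(mu + 1.959964 * sigma, abs=1e-3)

    def test_log_limit_continuity(self):
        x = np.array([0.01, 0.5, 1.0, 3.0, 250.0])
        assert np.allclose(boxcox(x, 1e-6), np.log(x), atol=1e-5)
        assert np.allclose(boxcox(x, 0.0), np.log(x))

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            boxcox(bad, 0.5)

    def test_inverse_trivials(self):
        assert inv_boxcox(0.0, 0.7) == pytest.approx(1.0)
        assert inv_boxcox(0.0, 0.0) == pytest.approx(1.0)
        assert inv_boxcox(1.0, 1.0) == pytest.approx(2.0)
        with pytest.raises(DomainError):
            inv_boxcox(-3.0, 1.0)  # lam*y + 1 < 0

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        x=st.floats(min_value=1e-3, max_value=1e3),
        lam=st.floats(min_value=-2.0, max_value=2.0),
    )
    def test_round_trip(self, x, lam):
        assert inv_boxcox(boxcox(x, lam), lam) == pytest.approx(x, rel=1e-10)


class TestPercentileMap:
    @pytest.mark.parametrize("name", list(ANALYTE_MODELS))
    def test_published_percentiles(self, name):
        """The printed (lam, mu, sigma) reproduce the printed 2.5/50/97.5
        percentiles — internal consistency of the published fits."""
        (lam, mu, sigma), (p025, p50, p975) = ANALYTE_MODELS[name]
        m = BoxCoxGaussian(lam, mu, sigma)
        assert model_percentile(m, 0.025) == pytest.approx(p025, rel=2e-3)
        assert model_percentile(m, 0.5) == pytest.approx(p50, rel=2e-3)
        assert model_percentile(m, 0.975) == pytest.approx(p975, rel=2e-3)

    def test_tight_examples(self):
        tsh = BoxCoxGaussian(0.07, 0.734424, 0.688931)
        assert model_percentile(tsh, 0.975) == pytest.approx(7.00022, abs=1e-3)
        ft4 = BoxCoxGaussian(0.4, -0.157573, 0.171608)
        assert model_percentile(ft4, 0.025) == pytest.approx(0.576794, abs=5e-4)
        assert model_percentile(BoxCoxGaussian(1, 0, 1), 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "model",
        [BoxCoxGaussian(*ANALYTE_MODELS[k][0]) for k in ANALYTE_MODELS]
        + [BoxCoxGaussian(0.0, 1.0, 0.5), BoxCoxGaussian(1.0, 99.0, 10.0)],
    )
    def test_monotone_in_p(self, model):
        grid = np.linspace(0.005, 0.995, 60)
        vals = [model_percentile(model, p) for p in grid]
        assert np.all(np.diff(vals) > 0)

    def test_out_of_support(self):
        with pytest.raises(DomainError):
            model_percentile(BoxCoxGaussian(1.0, 0.0, 1.0), 1e-7)
        with pytest.raises(DomainError):
            model_percentile(BoxCoxGaussian(1.0, 0.0, 1.0), 1.5)


class TestModelRI:
    def test_shifted_gaussian_closed_form(self):
        # lam=1 maps y -> y+1, so the limits are mu + 1 -/+ z*sigma
        ri = model_ri(BoxCoxGaussian(1.0, 99.0, 10.0))
        assert ri.lower == pytest.approx(100 - 1.959964 * 10, abs=1e-4)
        assert ri.upper == pytest.approx(100 + 1.959964 * 10, abs=1e-4)

    @pytest.mark.parametrize(
        "name, expected",
        [("TSH", (0.532845, 7.00022)), ("fT3", (2.37839, 5.22808))],
    )
    def test_published_ri(self, name, expected):
        m = BoxCoxGaussian(*ANALYTE_MODELS[name][0])
        ri = model_ri(m)
        assert ri.lower == pytest.approx(expected[0], rel=2e-3)
        assert ri.upper == pytest.approx(expected[1], rel=2e-3)

    def test_interval_validation(self):
        with pytest.raises(DomainError):
            ReferenceInterval(lower=5.0, upper=1.0)
        with pytest.raises(DomainError):
            ReferenceInterval(lower=-1.0, upper=1.0)
        with pytest.raises(DomainError):
            ReferenceInterval(lower=1.0, upper=2.0, ci_lower=(1.5, 0.5))

    def test_sigma_validation(self):
        with pytest.raises(DomainError):
            BoxCoxGaussian(0.5, 0.0, 0.0)
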