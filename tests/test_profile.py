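"""Release-rate profiles, ex-Gaussian onset filters, multi-spike combination."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import exponnorm

from presyn.profile import (
    ReleaseComponent,
    ReleaseModel,
    SpikeTrain,
    arrival_delay_cdf,
    eval_profile_filtered,
    eval_profile_unfiltered,
    ex_gaussian_pdf,
    multi_spike_profile,
)
from presyn.profile import _filtered_component_shape

#: single-component toy profile used throughout: P=5, tau=10 ms, k=0.5 /ms,
#: mu=5 ms, sigma=1 ms
TOY = ReleaseComponent(mass_P=5.0, tau=10.0, filt_k=0.5, filt_mu=5.0, filt_sigma=1.0)


class TestUnfiltered:
    def test_before_spike_profile_is_spontaneous(self, sync_model):
        t = np.array([-50.0, -1.0, -1e-9])
        assert eval_profile_unfiltered(sync_model, t) == pytest.approx(
            np.full(3, sync_model.r0), rel=1e-15
        )

    def test_long_time_approaches_spontaneous_rate(self, sync_model):
        r = eval_profile_unfiltered(sync_model, np.array([5e4]))
        assert r[0] == pytest.approx(sync_model.r0, rel=1e-6)

    def test_component_masses_recovered_by_quadrature(self, sync_model):
        # composite grid: fine where the 0.163 ms component lives
        t = np.concatenate([np.arange(0.0, 5.0, 1e-4), np.arange(5.0, 50 * 1000.0, 0.25)])
        r = eval_profile_unfiltered(sync_model, t) - sync_model.r0
        integral = np.trapezoid(r, t)
        assert integral == pytest.approx(sync_model.total_mass, rel=1e-3)
        assert sync_model.total_mass == pytest.approx(0.039528, rel=1e-6)


class TestExGaussian:
    @pytest.mark.parametrize(
        "k,mu,sigma",
        [(0.5, 5.0, 1.0), (18.0, 3.56, 0.0977), (0.0337, 76.5, 21.9), (0.142, 50.0, 11.5)],
    )
    def test_matches_reference_distribution(self, k, mu, sigma):
        """Closed form agrees with scipy's exponentially modified normal."""
        t = np.linspace(mu - 8 * sigma, mu + 20 / k, 801)
        K = 1.0 / (k * sigma)
        assert ex_gaussian_pdf(t, k, mu, sigma) == pytest.approx(
            exponnorm.pdf(t, K, loc=mu, scale=sigma), abs=1e-12
        )
        assert arrival_delay_cdf(t, k, mu, sigma) == pytest.approx(
            exponnorm.cdf(t, K, loc=mu, scale=sigma), abs=1e-9
        )

    def test_normalization(self):
        val, _ = quad(lambda t: ex_gaussian_pdf(t, 0.5, 5.0, 1.0), -30, 300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_sigma_zero_is_shifted_exponential(self):
        t = np.linspace(-5, 40, 901)
        k, mu = 0.7, 5.0
        expected = np.where(t >= mu, k * np.exp(-k * (t - mu)), 0.0)
        assert ex_gaussian_pdf(t, k, mu, 0.0) == pytest.approx(expected, rel=1e-12)
        exp_cdf = np.where(t >= mu, 1.0 - np.exp(-k * (t - mu)), 0.0)
        assert arrival_delay_cdf(t, k, mu, 0.0) == pytest.approx(exp_cdf, rel=1e-12)
        assert arrival_delay_cdf(np.array([mu]), k, mu, 0.0)[0] == 0.0

    def test_matches_numeric_convolution(self):
        """Brute-force convolution of the exponential and Gaussian densities."""
        k, mu, sigma = 0.5, 5.0, 1.0
        t_grid = np.linspace(0, 40, 9)

        def conv(t):
            # integrand support: the Gaussian bump, capped at s <= t
            hi = min(t, mu + 10 * sigma)
            if hi <= mu - 10 * sigma:
                return 0.0
            val, _ = quad(
                lambda s: k
                * np.exp(-k * (t - s))
                * np.exp(-0.5 * ((s - mu) / sigma) ** 2)
                / (sigma * np.sqrt(2 * np.pi)),
                mu - 10 * sigma,
                hi,
                limit=200,
            )
            return val

        ref = np.array([conv(t) for t in t_grid])
        assert ex_gaussian_pdf(t_grid, k, mu, sigma) == pytest.approx(ref, abs=1e-8)

    def test_cdf_monotone_and_saturates(self):
        t = np.linspace(-50, 2000, 5001)
        d = arrival_delay_cdf(t, 0.05, 10.0, 3.0)
        assert np.all(np.diff(d) >= -1e-15)
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d[-1] == pytest.approx(1.0, abs=1e-6)

    def test_cdf_derivative_is_pdf(self):
        t = np.linspace(-5, 60, 6501)
        d = arrival_delay_cdf(t, 0.5, 5.0, 1.0)
        deriv = np.gradient(d, t)
        pdf = ex_gaussian_pdf(t, 0.5, 5.0, 1.0)
        assert deriv == pytest.approx(pdf, abs=1e-5)

    def test_overflow_safe_for_large_k_sigma(self):
        # k*sigma = 500: naive evaluation of exp(k^2 sigma^2 / 2) overflows
        t = np.linspace(0, 100, 101)
        vals = ex_gaussian_pdf(t, 50.0, 10.0, 10.0)
        assert np.all(np.isfinite(vals))
        assert np.all(vals >= 0)
        cdf = arrival_delay_cdf(t, 50.0, 10.0, 10.0)
        assert np.all(np.isfinite(cdf))


class TestFilteredProfile:
    def test_mass_preserved_by_filter(self, sync_model):
        t = np.arange(-20.0, 60000.0, 0.05)
        for c in sync_model.components:
            shape = _filtered_component_shape(t, c)
            assert np.trapezoid(shape, t) == pytest.approx(1.0, rel=1e-3)

    def test_closed_form_matches_grid_convolution(self):
        """Component response equals quadrature of decay x delay filter."""
        c = TOY

        def conv(t):
            val, _ = quad(
                lambda s: ex_gaussian_pdf(np.array([s]), c.filt_k, c.filt_mu, c.filt_sigma)[0]
                * np.exp(-(t - s) / c.tau)
                / c.tau,
                -20.0,
                t,
                limit=200,
            )
            return val

        t_grid = np.array([2.0, 5.0, 8.0, 12.0, 20.0, 40.0, 80.0])
        ref = np.array([conv(t) for t in t_grid])
        ours = _filtered_component_shape(t_grid, c)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_delta_filter_limit_recovers_shifted_profile(self):
        # sigma -> 0, k -> large: filter approaches delta(t - mu)
        c = ReleaseComponent(mass_P=2.0, tau=8.0, filt_k=5e4, filt_mu=4.0, filt_sigma=0.0)
        t = np.linspace(5.0, 60.0, 111)
        ours = _filtered_component_shape(t, c)
        shifted = np.exp(-(t - c.filt_mu) / c.tau) / c.tau
        assert ours == pytest.approx(shifted, rel=1e-3)

    def test_degenerate_filter_rate_equals_decay_rate(self):
        # |k - 1/tau| below the guard: Erlang-Gaussian limit, still unit mass
        c = ReleaseComponent(mass_P=1.0, tau=2.0, filt_k=0.5, filt_mu=3.0, filt_sigma=0.7)
        near = ReleaseComponent(mass_P=1.0, tau=2.0, filt_k=0.5 + 5e-8, filt_mu=3.0, filt_sigma=0.7)
        t = np.arange(-10.0, 400.0, 0.01)
        exact = _filtered_component_shape(t, c)
        assert np.trapezoid(exact, t) == pytest.approx(1.0, rel=1e-4)
        assert exact == pytest.approx(_filtered_component_shape(t, near), abs=1e-6)

    def test_filtered_profile_nonnegative_and_baselined(self, sync_model):
        t = np.linspace(-50, 4000, 8001)
        r = eval_profile_filtered(sync_model, t)
        assert np.all(r >= 0)
        assert r[0] == pytest.approx(sync_model.r0, rel=1e-9)


class TestMultiSpike:
    def test_single_spike_reduces_to_filtered_profile(self, sync_model):
        t = np.linspace(-10, 300, 1001)
        spikes = SpikeTrain(np.array([7.0]))
        combined = multi_spike_profile(sync_model, spikes, t)
        single = eval_profile_filtered(sync_model, t, spike_at=7.0)
        assert combined == pytest.approx(single, rel=1e-12)

    def test_far_separated_spikes_decouple(self):
        model = ReleaseModel(r0=1e-6, components=(TOY,), mechanism="synchronous")
        t = np.linspace(4990, 5200, 501)
        both = multi_spike_profile(model, SpikeTrain(np.array([0.0, 5000.0])), t)
        lone = multi_spike_profile(model, SpikeTrain(np.array([5000.0])), t)
        assert np.abs(both - lone).max() < 1e-9

    def test_earlier_spike_suppressed_by_delay_cdf(self):
        """In a train, the first spike's contribution is cut by (1 - D) per
        later spike: the suppression factor lies in [0, 1] and decreases
        with time."""
        model = ReleaseModel(r0=0.0, components=(TOY,), mechanism="synchronous")
        spikes = SpikeTrain(np.array([0.0, 15.0, 20.0, 30.0, 50.0]))
        t = np.linspace(0.0, 100.0, 2001)
        combined = multi_spike_profile(model, spikes, t)
        unswitched = sum(
            eval_profile_filtered(model, t, spike_at=s) for s in spikes.times
        )
        assert np.all(combined <= unswitched + 1e-12)
        # suppression of the first spike alone: product of survivor functions
        c = TOY
        supp = np.ones_like(t)
        for s in spikes.times[1:]:
            supp *= 1.0 - arrival_delay_cdf(t - s, c.filt_k, c.filt_mu, c.filt_sigma)
        assert np.all((supp >= 0) & (supp <= 1))
        assert np.all(np.diff(supp) <= 1e-12)

    def test_fixed_arrivals_hard_switching(self):
        model = ReleaseModel(r0=0.0, components=(TOY,), mechanism="synchronous")
        spikes = SpikeTrain(np.array([0.0, 30.0]))
        arrivals = np.array([[6.0], [36.0]])
        t = np.linspace(0, 100, 2001)
        r = multi_spike_profile(model, spikes, t, mode="fixed_arrivals", arrivals=arrivals)
        before = t < 6.0
        between = (t >= 6.0) & (t < 36.0)
        after = t >= 36.0
        assert np.all(r[before] == 0)
        expect_mid = (TOY.mass_P / TOY.tau) * np.exp(-(t[between] - 6.0) / TOY.tau)
        assert r[between] == pytest.approx(expect_mid, rel=1e-12)
        expect_post = (TOY.mass_P / TOY.tau) * np.exp(-(t[after] - 36.0) / TOY.tau)
        assert r[after] == pytest.approx(expect_post, rel=1e-12)

    def test_fixed_arrivals_requires_arrivals(self, sync_model):
        with pytest.raises(ValueError, match="arrival"):
            multi_spike_profile(
                sync_model, SpikeTrain(np.array([0.0])), np.linspace(0, 10, 11),
                mode="fixed_arrivals",
            )

    def test_spontaneous_rate_added_once(self, sync_model):
        t = np.array([-100.0])
        for n_spikes in (1, 3, 5):
            spikes = SpikeTrain(np.arange(n_spikes) * 10.0)
            r = multi_spike_profile(sync_model, spikes, t)
            assert r[0] == pytest.approx(sync_model.r0, rel=1e-9)


class TestValidation:
    def test_component_invariants(self):
        with pytest.raises(ValueError):
            ReleaseComponent(mass_P=-0.1, tau=1.0, filt_k=1.0)
        with pytest.raises(ValueError):
            ReleaseComponent(mass_P=0.1, tau=0.0, filt_k=1.0)
        with pytest.raises(ValueError):
            ReleaseComponent(mass_P=0.1, tau=1.0, filt_k=1.0, filt_sigma=-1.0)

    def test_spike_train_strictly_increasing(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.0, 5.0, 5.0]))

    def test_mass_may_exceed_one(self):
        c = ReleaseComponent(mass_P=5.0, tau=1.0, filt_k=1.0)
        assert c.mass_P == 5.0
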