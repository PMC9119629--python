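"""Phenomenological multi-exponential release-rate profiles.

Driving the sensor chains of :mod:`presyn.kinetics` with realistic
calcium transients yields single-spike hazards that are well described by
a baseline spontaneous rate plus a sum of exponentially decaying
components,

    r(t) = r0 + sum_c (P_c / tau_c) exp(-t / tau_c) u(t),

where ``P_c`` is the expected number of releases contributed by component
``c`` (a mass, not a probability; it may exceed one) and ``u`` the
Heaviside step.  Calcium does not reach the sensor at the instant of the
spike: buffered diffusion delays the onset by an ex-Gaussian random time
(exponential of rate ``k`` plus normal of mean ``mu`` and s.d.
``sigma``).  Convolving each component with that delay density smears the
start time without changing its mass.

For spike trains, the response to one spike is cut short when calcium
from the next spike arrives: with fixed arrival times the earlier
profile is switched off by a hard step (``fixed_arrivals`` mode); in
expectation over arrival delays the step becomes the delay CDF
``D_c(t)``, and each spike's component response is multiplied by
``prod_{later j} (1 - D_c(t - t_sj))`` (``expected`` mode).

All closed forms are evaluated in log space (via ``scipy.special
.log_ndtr``) so that large ``k * sigma`` products cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "ReleaseComponent",
    "ReleaseModel",
    "SpikeTrain",
    "eval_profile_unfiltered",
    "ex_gaussian_pdf",
    "arrival_delay_cdf",
    "eval_profile_filtered",
    "multi_spike_profile",
]

#: below this |k - 1/tau| (ms^-1) the exponential-times-EMG closed form is
#: numerically degenerate and the Erlang-Gaussian limit is used instead
_DEGENERATE_RATE_GAP = 1e-9


@dataclass(frozen=True)
class ReleaseComponent:
    """One exponential component of a release profile with its onset filter.

    Attributes
    ----------
    mass_P : float
        Expected releases per spike (dimensionless; may exceed 1).
    tau : float
        Decay constant of the component (ms).
    filt_k : float
        Exponential rate of the onset-delay filter (ms^-1).
    filt_mu : float
        Gaussian mean of the onset-delay filter (ms).
    filt_sigma : float
        Gaussian s.d. of the onset-delay filter (ms).
    """

    mass_P: float
    tau: float
    filt_k: float
    filt_mu: float = 0.0
    filt_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_P < 0:
            raise ValueError("mass_P must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.filt_k <= 0:
            raise ValueError("filt_k must be positive")
        if self.filt_sigma < 0:
            raise ValueError("filt_sigma must be non-negative")


@dataclass(frozen=True)
class ReleaseModel:
    """Baseline spontaneous rate plus ordered release components."""

    r0: float
    components: tuple[ReleaseComponent, ...]
    mechanism: str = "synchronous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.r0 < 0:
            raise ValueError("r0 must be non-negative")
        if len(self.components) < 1:
            raise ValueError("at least one release component is required")
        if self.mechanism not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def total_mass(self) -> float:
        """Expected spike-evoked releases, sum of component masses."""
        return sum(c.mass_P for c in self.components)


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing stimulus spike times (ms)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def eval_profile_unfiltered(model: ReleaseModel, t: np.ndarray | float) -> np.ndarray:
    """Evaluate the raw multi-exponential profile at times ``t`` (ms).

    ``t`` is time since the spike; for ``t < 0`` the profile equals the
    spontaneous rate ``r0``.
    """
    t = np.asarray(t, dtype=float)
    r = np.full(t.shape, model.r0)
    live = t >= 0
    for c in model.components:
        r[live] += (c.mass_P / c.tau) * np.exp(-t[live] / c.tau)
    return r


def _log_emg_pdf(t: np.ndarray, k: float, mu: float, sigma: float) -> np.ndarray:
    """log of the ex-Gaussian density, stable for large k*sigma."""
    z = (t - (mu + sigma**2 * k)) / sigma
    return np.log(k) - k * (t - mu) + 0.5 * (k * sigma) ** 2 + log_ndtr(z)


def ex_gaussian_pdf(t: np.ndarray | float, k: float, mu: float, sigma: float) -> np.ndarray:
    """Density of the onset delay: Exponential(rate k) + Normal(mu, sigma).

        a(t) = k exp(-k (t - mu - k sigma^2 / 2)) Phi((t - mu - k sigma^2) / sigma)

    With ``sigma = 0`` this degenerates to the shifted exponential
    ``k exp(-k (t - mu)) u(t - mu)``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t = np.asarray(t, dtype=float)
    if sigma == 0.0:
        out = np.zeros(t.shape)
        live = t >= mu
        out[live] = k * np.exp(-k * (t[live] - mu))
        return out
    return np.exp(_log_emg_pdf(t, k, mu, sigma))


def arrival_delay_cdf(t: np.ndarray | float, k: float, mu: float, sigma: float) -> np.ndarray:
    """CDF of the onset delay,

        D(t) = Phi((t - mu)/sigma) - exp(-k (t - mu - k sigma^2/2)) Phi((t - mu - k sigma^2)/sigma),

    reducing to ``(1 - exp(-k (t - mu))) u(t - mu)`` when ``sigma = 0``.
    Monotone nondecreasing from 0 to 1.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t = np.asarray(t, dtype=float)
    if sigma == 0.0:
        out = np.zeros(t.shape)
        live = t >= mu
        out[live] = 1.0 - np.exp(-k * (t[live] - mu))
        return out
    d = ndtr((t - mu) / sigma) - np.exp(_log_emg_pdf(t, k, mu, sigma)) / k
    return np.clip(d, 0.0, 1.0)


def _filtered_component_shape(t: np.ndarray, c: ReleaseComponent) -> np.ndarray:
    """Closed form of ``(1/tau) exp(-t/tau) u(t) (*) a(t; k, mu, sigma)``.

    The convolution of an exponential decay with the ex-Gaussian filter
    is a difference of two EMG densities,

        (k / (tau (k - lam))) EMG(t; lam, mu, sigma)/lam - ... ,

    with ``lam = 1/tau``; when ``k`` is within ``1e-9`` of ``1/tau`` the
    expression is replaced by its Erlang-Gaussian limit

        lam [(t - mu - lam sigma^2) EMG(t; lam, mu, sigma) + lam sigma^2 phi_sigma(t - mu)].

    Integrates to one; the caller scales by the component mass.
    """
    lam = 1.0 / c.tau
    k, mu, sigma = c.filt_k, c.filt_mu, c.filt_sigma
    if sigma == 0.0:
        # pure exponential filter: convolution of two exponentials, shifted by mu
        x = t - mu
        out = np.zeros(t.shape)
        live = x >= 0
        if abs(k - lam) < _DEGENERATE_RATE_GAP:
            out[live] = lam**2 * x[live] * np.exp(-lam * x[live])
        else:
            out[live] = (k * lam / (k - lam)) * (
                np.exp(-lam * x[live]) - np.exp(-k * x[live])
            )
        return out
    emg_lam = ex_gaussian_pdf(t, lam, mu, sigma)
    if abs(k - lam) < _DEGENERATE_RATE_GAP:
        x = t - mu
        phi = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
        return lam * ((x - lam * sigma**2) * emg_lam + lam * sigma**2 * phi)
    emg_k = ex_gaussian_pdf(t, k, mu, sigma)
    return (k / (k - lam)) * emg_lam - (lam / (k - lam)) * emg_k


def eval_profile_filtered(
    model: ReleaseModel,
    t: np.ndarray | float,
    spike_at: float = 0.0,
) -> np.ndarray:
    """Single-spike profile with each component's onset filter applied.

        r(t) = r0 + sum_c P_c * [(1/tau_c) exp(-./tau_c) u(.) (*) a(.; k_c, mu_c, sigma_c)](t - spike_at)

    The filter preserves each component's mass ``P_c``: it changes the
    timing of release, never its probability.
    """
    t = np.asarray(t, dtype=float)
    r = np.full(t.shape, model.r0)
    lag = t - spike_at
    for c in model.components:
        r += c.mass_P * _filtered_component_shape(lag, c)
    return r


def multi_spike_profile(
    model: ReleaseModel,
    spikes: SpikeTrain,
    t: np.ndarray,
    per_spike_masses: np.ndarray | None = None,
    mode: str = "expected",
    arrivals: np.ndarray | None = None,
) -> np.ndarray:
    """Combine per-spike release responses across a train.

    Parameters
    ----------
    per_spike_masses : array (n_spikes, n_components), optional
        Facilitated masses ``P_c(n)``; defaults to the baseline masses
        for every spike.
    mode : {"expected", "fixed_arrivals"}
        ``expected``: each spike's filtered component response is
        multiplied by ``prod_{later j} (1 - D_c(t - t_sj))`` using that
        component's own filter parameters; the spontaneous rate is added
        once.  ``fixed_arrivals``: hard Heaviside switching at the given
        per-component arrival times (no filter smearing).
    arrivals : array (n_spikes, n_components), required in fixed mode
        Calcium arrival times for every spike and component; switching is
        applied in arrival-time order per component.
    """
    t = np.asarray(t, dtype=float)
    n_spk = len(spikes)
    n_cmp = len(model.components)
    if per_spike_masses is None:
        per_spike_masses = np.tile([c.mass_P for c in model.components], (n_spk, 1))
    per_spike_masses = np.asarray(per_spike_masses, dtype=float)
    if per_spike_masses.shape != (n_spk, n_cmp):
        raise ValueError(
            f"per_spike_masses shape {per_spike_masses.shape} != ({n_spk}, {n_cmp})"
        )
    r = np.full(t.shape, model.r0)
    if n_spk == 0:
        return r
    if mode == "expected":
        for ci, c in enumerate(model.components):
            for i in range(n_spk):
                resp = per_spike_masses[i, ci] * _filtered_component_shape(
                    t - spikes.times[i], c
                )
                for j in range(i + 1, n_spk):
                    resp *= 1.0 - arrival_delay_cdf(
                        t - spikes.times[j], c.filt_k, c.filt_mu, c.filt_sigma
                    )
                r += resp
        return r
    if mode == "fixed_arrivals":
        if arrivals is None:
            raise ValueError("fixed_arrivals mode requires arrival times")
        arrivals = np.asarray(arrivals, dtype=float)
        if arrivals.shape != (n_spk, n_cmp):
            raise ValueError(f"arrivals shape {arrivals.shape} != ({n_spk}, {n_cmp})")
        for ci, c in enumerate(model.components):
            # switching in arrival-time order keeps the truncation well
            # defined even if a later spike's calcium arrives first
            order = np.argsort(arrivals[:, ci], kind="stable")
            for pos, i in enumerate(order):
                t_arr = arrivals[i, ci]
                lag = t - t_arr
                resp = np.where(
                    lag >= 0,
                    (per_spike_masses[i, ci] / c.tau) * np.exp(-np.clip(lag, 0, None) / c.tau),
                    0.0,
                )
                for j in order[pos + 1:]:
                    resp = np.where(t >= arrivals[j, ci], 0.0, resp)
                r += resp
        return r
    raise ValueError(f"unknown mode {mode!r}")
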