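"""Calcium-sensor kinetics as continuous-time Markov chains with killing.

Each release mechanism (synchronous Syt-1 with 5 calcium binding sites,
asynchronous Syt-7 with 2) is a birth-death chain over the number of
bound calcium ions.  Binding from state ``n`` proceeds at
``(N - n) * k_on * [Ca]``; unbinding at ``n * b**(n-1) * k_off``, where
``b < 1`` expresses binding cooperativity (ions unbind more slowly the
more are bound).  The fully bound state additionally "fuses" at rate
``gamma``, draining probability into an untracked release state.

Tracking a single vesicle that is removed on release would confound the
release-rate readout with depletion, so the state vector is renormalized
to sum to one after every step: the chain is conditioned on survival, and
``gamma * s_N(t)`` is the instantaneous release rate given that no
release has yet occurred (the hazard).  At constant calcium this hazard
converges to the quasi-stationary rate of the killed generator.

Matrix convention: column = current state, row = next state, so a step is
the left-multiplication ``s(t + dt) = (I + dt * T) s(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from presyn.calcium import CalciumTrace

__all__ = [
    "SensorKinetics",
    "SensorState",
    "build_sensor_rate_matrix",
    "propagate_renormalized",
    "equilibrium_state",
    "quasi_stationary_state",
    "quasi_stationary_rate",
    "conditional_release_trace",
    "generic_ctmc_step",
]

#: default propagation step (ms); small enough that the linear propagator
#: I + dt*T stays positive for any physiological calcium level
DEFAULT_DT = 0.005


@dataclass(frozen=True)
class SensorKinetics:
    """Rate constants and site count for one release mechanism.

    Units are uM^-1 ms^-1 for ``k_on`` and ms^-1 for ``k_off`` and
    ``gamma_fuse``; published per-molar per-second constants must be
    converted at load time (see :mod:`presyn.params`).

    Attributes
    ----------
    n_sites : int
        Number of calcium binding sites (5 synchronous, 2 asynchronous).
    k_on : float
        Binding rate per free site per unit concentration (uM^-1 ms^-1).
    k_off : float
        Base unbinding rate (ms^-1).
    coop_b : float
        Unbinding cooperativity factor, 0 < b <= 1.
    gamma_fuse : float
        Fusion rate out of the fully bound state (ms^-1).
    refractory_eps : float
        Post-release refractory time constant (ms); used only by the
        event sampler.
    """

    n_sites: int
    k_on: float
    k_off: float
    coop_b: float
    gamma_fuse: float
    refractory_eps: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.k_on <= 0 or self.k_off <= 0 or self.gamma_fuse <= 0:
            raise ValueError("k_on, k_off and gamma_fuse must be positive")
        if not (0 < self.coop_b <= 1):
            raise ValueError(f"coop_b must lie in (0, 1], got {self.coop_b}")
        if self.refractory_eps < 0:
            raise ValueError("refractory_eps must be non-negative")

    @property
    def n_states(self) -> int:
        return self.n_sites + 1

    def unbinding_rate(self, n: int) -> float:
        """Rate of the n -> n-1 transition, ``n * b**(n-1) * k_off``."""
        return n * self.coop_b ** (n - 1) * self.k_off

    def binding_rate(self, n: int, ca: float) -> float:
        """Rate of the n -> n+1 transition, ``(N - n) * k_on * [Ca]``."""
        return (self.n_sites - n) * self.k_on * ca


@dataclass(frozen=True)
class SensorState:
    """Occupancy probabilities over bound-ion counts at one instant."""

    probs: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if np.any(self.probs < 0):
            raise ValueError("state probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("state probabilities must sum to 1")


def build_sensor_rate_matrix(kin: SensorKinetics, ca: float) -> np.ndarray:
    """Infinitesimal generator T of the killed sensor chain at fixed [Ca].

    Columns sum to zero (conservation) except the fully bound column,
    which sums to ``-gamma_fuse``: fused probability leaves the tracked
    state space.
    """
    if ca < 0:
        raise ValueError(f"calcium concentration must be non-negative, got {ca}")
    m = kin.n_states
    T = np.zeros((m, m))
    for n in range(kin.n_sites):
        T[n + 1, n] = kin.binding_rate(n, ca)
    for n in range(1, m):
        T[n - 1, n] = kin.unbinding_rate(n)
    for n in range(m):
        out = 0.0
        if n < kin.n_sites:
            out += T[n + 1, n]
        if n > 0:
            out += T[n - 1, n]
        T[n, n] = -out
    T[kin.n_sites, kin.n_sites] -= kin.gamma_fuse
    return T


def generic_ctmc_step(probs: np.ndarray, rate_matrix: np.ndarray, dt: float) -> np.ndarray:
    """One linear (un-renormalized) step ``s <- (I + dt*T) s``.

    Supports any user-supplied molecular species (channel, buffer, pump)
    whose generator comes from configuration.  A conservative matrix
    (columns summing to zero) preserves the total probability mass.
    """
    probs = np.asarray(probs, dtype=float)
    rate_matrix = np.asarray(rate_matrix, dtype=float)
    if rate_matrix.ndim != 2 or rate_matrix.shape[0] != rate_matrix.shape[1]:
        raise ValueError("rate matrix must be square")
    if probs.shape != (rate_matrix.shape[0],):
        raise ValueError(
            f"state vector length {probs.shape} does not match matrix {rate_matrix.shape}"
        )
    out = probs + dt * (rate_matrix @ probs)
    if np.any(out < 0):
        raise ValueError("negative probability after step; reduce dt")
    return out


def propagate_renormalized(
    state: SensorState,
    kin: SensorKinetics,
    ca_of_t: CalciumTrace,
    dt: float = DEFAULT_DT,
) -> tuple[np.ndarray, np.ndarray]:
    """Drive the sensor along a calcium trace with survival renormalization.

    The trace is linearly interpolated onto the propagation grid ``dt``;
    after each linear step the state is divided by its sum, conditioning
    on no release having occurred.  Returns ``(times, trajectory)`` where
    ``trajectory[i]`` is the state distribution at ``times[i]`` on the
    propagation grid (the first row is the initial state).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    trace = ca_of_t.resample(dt)
    ca = trace.values
    times = trace.times
    m = kin.n_states
    traj = np.empty((ca.size, m))
    s = state.probs.copy()
    traj[0] = s
    # generator entries are affine in [Ca]: T = T0 + ca * T1
    T0 = build_sensor_rate_matrix(kin, 0.0)
    T1 = (build_sensor_rate_matrix(kin, 1.0) - T0)
    for i in range(1, ca.size):
        T = T0 + ca[i - 1] * T1
        s = s + dt * (T @ s)
        if np.any(s < -1e-15):
            raise ValueError(
                f"negative probability at t = {times[i]:.6g} ms; dt = {dt} too large "
                f"for [Ca] = {ca[i - 1]:.6g} uM"
            )
        np.clip(s, 0.0, None, out=s)
        s /= s.sum()
        traj[i] = s
    return times, traj


def equilibrium_state(kin: SensorKinetics, ca0: float) -> SensorState:
    """Detailed-balance equilibrium of the pure binding/unbinding chain.

    Computed without the killing term:
    ``pi_{n+1}/pi_n = (N - n) k_on ca0 / ((n+1) b**n k_off)``, normalized.
    Work in log space so extreme concentrations cannot overflow.
    """
    if ca0 < 0:
        raise ValueError(f"calcium concentration must be non-negative, got {ca0}")
    m = kin.n_states
    if ca0 == 0.0:
        probs = np.zeros(m)
        probs[0] = 1.0
        return SensorState(probs=probs)
    log_pi = np.zeros(m)
    for n in range(kin.n_sites):
        ratio = kin.binding_rate(n, ca0) / kin.unbinding_rate(n + 1)
        log_pi[n + 1] = log_pi[n] + np.log(ratio)
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi /= pi.sum()
    return SensorState(probs=pi)


def quasi_stationary_state(
    kin: SensorKinetics,
    ca0: float,
    dt: float = DEFAULT_DT,
    rel_tol_per_ms: float = 1e-10,
    max_ms: float = 1e6,
) -> SensorState:
    """Limiting survival-conditioned distribution at constant calcium.

    Renormalized power iteration on the linear propagator
    ``P = I + dt * T``: the chain is advanced in 1 ms blocks (with the
    block matrix built once by repeated squaring) until the conditional
    release rate changes by less than ``rel_tol_per_ms`` relative per ms.
    """
    if ca0 < 0:
        raise ValueError(f"calcium concentration must be non-negative, got {ca0}")
    if ca0 == 0.0:
        probs = np.zeros(kin.n_states)
        probs[0] = 1.0
        return SensorState(probs=probs)
    T = build_sensor_rate_matrix(kin, ca0)
    # positivity of the linear propagator: dt * max |diagonal| < 1
    step = dt
    max_out = float(np.abs(np.diag(T)).max())
    if step * max_out >= 1.0:
        step = 0.5 / max_out
    steps_per_ms = max(int(round(1.0 / step)), 1)
    P = np.eye(kin.n_states) + step * T
    P_ms = np.linalg.matrix_power(P, steps_per_ms)
    s = equilibrium_state(kin, ca0).probs
    top = kin.n_sites
    rate = kin.gamma_fuse * s[top]
    for _ in range(int(max_ms)):
        s = P_ms @ s
        s /= s.sum()
        new_rate = kin.gamma_fuse * s[top]
        if new_rate == rate or abs(new_rate - rate) <= rel_tol_per_ms * abs(new_rate):
            return SensorState(probs=s)
        rate = new_rate
    raise RuntimeError(
        f"quasi-stationary iteration did not converge within {max_ms:g} ms "
        f"at [Ca] = {ca0:g} uM"
    )


def quasi_stationary_rate(kin: SensorKinetics, ca0: float, **kwargs) -> float:
    """Asymptotic conditional release rate ``gamma * s_N`` at constant [Ca].

    This is the steady-state spontaneous release rate of the mechanism at
    resting calcium ``ca0``; it vanishes at ``ca0 = 0``, grows as
    ``ca0**n_sites`` at low calcium, and saturates at ``gamma_fuse`` as
    ``ca0`` tends to infinity.
    """
    if ca0 == 0.0:
        return 0.0
    qs = quasi_stationary_state(kin, ca0, **kwargs)
    return float(kin.gamma_fuse * qs.probs[kin.n_sites])


def quasi_stationary_rate_eigen(kin: SensorKinetics, ca0: float) -> float:
    """Cross-check oracle: leading eigen-solution of the killed generator.

    The quasi-stationary distribution is the eigenvector of T with the
    largest (least negative) real eigenvalue, normalized to sum to one;
    the conditional rate is ``gamma * v_N``.
    """
    if ca0 < 0:
        raise ValueError(f"calcium concentration must be non-negative, got {ca0}")
    if ca0 == 0.0:
        return 0.0
    T = build_sensor_rate_matrix(kin, ca0)
    w, v = np.linalg.eig(T)
    lead = np.argmax(w.real)
    vec = np.real(v[:, lead])
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    vec /= vec.sum()
    return float(kin.gamma_fuse * vec[kin.n_sites])


def conditional_release_trace(
    kin: SensorKinetics,
    ca_of_t: CalciumTrace,
    dt: float = DEFAULT_DT,
    initial_state: SensorState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Hazard ``r(t) = gamma * s_N(t)`` along a calcium trace.

    By default the run starts from the quasi-stationary state at the
    trace's first value, so the rate starts at its resting value; pass
    ``initial_state`` to override.  Returns ``(times, rates)`` on the
    propagation grid.
    """
    if initial_state is None:
        initial_state = quasi_stationary_state(kin, float(ca_of_t.values[0]), dt=dt)
    times, traj = propagate_renormalized(initial_state, kin, ca_of_t, dt=dt)
    rates = kin.gamma_fuse * traj[:, kin.n_sites]
    return times, rates
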