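"""Saturating, nonlinear, multi-timescale facilitation of release fidelity.

Across a spike train, the mass ``P_c`` of each release component scales
as ``P_c(n) = P_c0 * F_c(n)``, where the facilitation factor is a
nonlinear combination of linear factors,

    F_c(n) = prod_i f_ci(n) ** xi_ci.

Each linear factor decays exponentially between spikes (time constant
``tau_ci``) and increments by one at each spike — the roughly equal
calcium influx per action potential.  Unbounded, this is

    f(n) = f(n-1) exp(-dt/tau) + 1;

physically the factor saturates at ``N`` linear steps, enforced smoothly
by subtracting ``(d / N)**N`` from the increment (``d`` the decayed
previous value), so ``f`` can never exceed ``N`` and the factor
contributes at most ``L = N**xi`` to ``F``.  A component with ``N = 1``
and ``xi = 0`` does not facilitate (``L = 1``).

All spikes are treated equally: the state before the first spike is
fully decayed (``f = 0``), so the first spike's update gives ``f = 1``
and ``F = 1``, exactly as a spike after an infinitely long rest.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from presyn.profile import SpikeTrain

__all__ = [
    "FacilitationComponent",
    "FacilitationState",
    "facil_update",
    "facil_factor",
    "apply_facilitation_to_train",
]


@dataclass(frozen=True)
class FacilitationComponent:
    """Metaparameters of one linear facilitation factor.

    Attributes
    ----------
    tau_f : float
        Decay constant of the factor between spikes (ms).  Irrelevant
        (by convention infinity) for a non-facilitating component.
    n_steps : float
        Number of linear steps to saturation, ``N >= 1``.
    xi : float
        Nonlinearity exponent applied when combining into ``F``.
    """

    tau_f: float
    n_steps: float
    xi: float

    def __post_init__(self) -> None:
        if self.tau_f <= 0:
            raise ValueError("tau_f must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def limit_L(self) -> float:
        """Saturating contribution to the facilitation factor, ``N**xi``."""
        return self.n_steps**self.xi


#: a non-facilitating component: one step, zero nonlinearity, L = 1
NO_FACILITATION = FacilitationComponent(tau_f=math.inf, n_steps=1.0, xi=0.0)


@dataclass
class FacilitationState:
    """Running linear factors for the components of one release component."""

    f_values: np.ndarray
    last_spike_time: float | None = None

    @classmethod
    def resting(cls, n_components: int) -> "FacilitationState":
        """Fully decayed state: the next spike sees f = 1, F = 1."""
        return cls(f_values=np.zeros(n_components), last_spike_time=None)


def facil_update(
    f_prev: float,
    comp: FacilitationComponent,
    delta_t: float,
    mode: str = "saturating",
) -> float:
    """Per-spike update of one linear facilitation factor.

    ``delta_t`` is the interval since the previous spike (``inf`` for the
    first spike or after a long rest, giving ``f = 1``).  Saturating
    mode: ``f <- d + 1 - (d / N)**N`` with ``d = f_prev exp(-dt/tau)``;
    unbounded mode drops the subtracted term.
    """
    if delta_t <= 0:
        raise ValueError(f"interspike interval must be positive, got {delta_t}")
    d = 0.0 if math.isinf(delta_t) else f_prev * math.exp(-delta_t / comp.tau_f)
    if mode == "unbounded":
        return d + 1.0
    if mode == "saturating":
        return d + 1.0 - (d / comp.n_steps) ** comp.n_steps
    raise ValueError(f"unknown mode {mode!r}")


def facil_factor(state: FacilitationState, comps: list[FacilitationComponent]) -> float:
    """Nonlinear combination ``F = prod_i f_i ** xi_i`` of the current factors."""
    if len(comps) != state.f_values.size:
        raise ValueError("component list length does not match state")
    F = 1.0
    for f, comp in zip(state.f_values, comps):
        F *= f**comp.xi
    return F


def apply_facilitation_to_train(
    params: list[list[FacilitationComponent]],
    baselines: np.ndarray | list[float],
    spikes: SpikeTrain,
    mode: str = "saturating",
) -> np.ndarray:
    """Facilitated per-spike masses ``P_c(n)`` for every release component.

    Parameters
    ----------
    params : list of per-release-component facilitation component lists
        ``params[c]`` holds the (one or two) linear factors of release
        component ``c``; an empty list means no facilitation.
    baselines : sequence of float
        Un-facilitated masses ``P_c0``.
    spikes : SpikeTrain

    Returns
    -------
    array (n_spikes, n_components)
        ``out[n, c] = P_c0 * F_c(n)``; the first spike's masses equal the
        baselines exactly.
    """
    baselines = np.asarray(baselines, dtype=float)
    if len(params) != baselines.size:
        raise ValueError("params and baselines length mismatch")
    n_spk = len(spikes)
    out = np.empty((n_spk, baselines.size))
    for c, (comps, p0) in enumerate(zip(params, baselines)):
        state = FacilitationState.resting(len(comps))
        for n in range(n_spk):
            dt = (
                math.inf
                if state.last_spike_time is None
                else spikes.times[n] - state.last_spike_time
            )
            for i, comp in enumerate(comps):
                state.f_values[i] = facil_update(state.f_values[i], comp, dt, mode=mode)
            state.last_spike_time = spikes.times[n]
            out[n, c] = p0 * (facil_factor(state, comps) if comps else 1.0)
    return out
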