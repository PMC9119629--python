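"""Synthetic presynaptic calcium transients.

Free calcium at a release site sits at a ~100 nM resting level maintained
by membrane pumps.  Each action potential adds a transient whose peak
amplitude decays exponentially with the distance between the sensor and
the calcium-channel cluster (length constant 0.204 um) and whose time
course is a sum of exponentially decaying components shaped by the
calbindin buffer.  This module generates such traces on a uniform grid so
that the sensor kinetics in :mod:`presyn.kinetics` can be driven without
any spatial reaction-diffusion simulation.  The generator is linear:
transients from successive spikes superpose, and buffer saturation near
the source is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalciumTrace", "CaTransientSpec", "synth_ca_trace", "ca_impulse_trace"]


@dataclass(frozen=True)
class CalciumTrace:
    """Uniformly sampled free calcium concentration vs time.

    Attributes
    ----------
    t0 : float
        Time of the first sample (ms).
    dt : float
        Grid spacing (ms).
    values : numpy.ndarray
        Concentrations (uM), one per grid point.
    baseline : float
        Resting concentration (uM) the trace relaxes to.
    """

    t0: float
    dt: float
    values: np.ndarray
    baseline: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("calcium concentrations must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def resample(self, dt: float) -> "CalciumTrace":
        """Linearly interpolate the trace onto a finer (or coarser) grid."""
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        if dt == self.dt:
            return self
        n = int(np.floor(self.duration / dt)) + 1
        t_new = self.t0 + dt * np.arange(n)
        vals = np.interp(t_new, self.times, self.values)
        return CalciumTrace(t0=self.t0, dt=dt, values=vals, baseline=self.baseline)


@dataclass(frozen=True)
class CaTransientSpec:
    """Shape of the spike-evoked calcium transient at a release site.

    ``components`` are (amplitude uM, decay tau ms) pairs describing the
    multi-exponential decay of the transient as measured at the reference
    distance ``distance = 0``; the actual amplitude seen by a sensor at
    ``distance`` um is scaled by ``exp(-distance / length_constant)``.
    ``onset_delay`` shifts the transient relative to the spike time,
    absorbing the convention that the spike time is taken immediately
    prior to the rising phase of the action potential.
    """

    baseline: float = 0.1
    components: tuple[tuple[float, float], ...] = ((2.0, 1.5), (0.12, 20.0), (0.015, 250.0))
    onset_delay: float = 1.0
    distance: float = 0.0
    length_constant: float = 0.204

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple((float(a), float(t)) for a, t in self.components))
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.length_constant <= 0:
            raise ValueError("length_constant must be positive")
        for amp, tau in self.components:
            if amp < 0:
                raise ValueError(f"component amplitude must be non-negative, got {amp}")
            if tau <= 0:
                raise ValueError(f"component decay constant must be positive, got {tau}")

    @property
    def distance_gain(self) -> float:
        return float(np.exp(-self.distance / self.length_constant))


def synth_ca_trace(
    spec: CaTransientSpec,
    spikes: np.ndarray | list[float],
    duration: float,
    dt: float = 0.1,
    t0: float = 0.0,
) -> CalciumTrace:
    """Superpose spike-evoked multi-exponential transients on the baseline.

    Each spike at ``t_s`` contributes, for ``t >= t_s + onset_delay``,

        sum_j A_j * exp(-distance/lambda) * exp(-(t - t_s - onset_delay)/tau_j)

    on top of the resting level.  Transients from different spikes add
    linearly.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size and np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted ascending")
    if spikes.size and spikes[-1] > t0 + duration:
        raise ValueError("duration does not cover all spikes")
    n = int(np.floor(duration / dt)) + 1
    t = t0 + dt * np.arange(n)
    vals = np.full(n, spec.baseline, dtype=float)
    gain = spec.distance_gain
    for t_s in spikes:
        lag = t - (t_s + spec.onset_delay)
        live = lag >= 0
        for amp, tau in spec.components:
            vals[live] += amp * gain * np.exp(-lag[live] / tau)
    return CalciumTrace(t0=t0, dt=dt, values=vals, baseline=spec.baseline)


def ca_impulse_trace(
    ca0: float,
    impulse_amplitude: float,
    t_impulse: float,
    duration: float,
    dt: float = 0.005,
    t0: float = 0.0,
) -> CalciumTrace:
    """Constant trace at ``ca0`` with a single elevated grid sample.

    The sample nearest ``t_impulse`` is raised by ``impulse_amplitude``,
    delivering an instantaneous calcium impulse whose integral above
    baseline is ``impulse_amplitude * dt``.
    """
    if impulse_amplitude < 0:
        raise ValueError("impulse amplitude must be non-negative")
    if ca0 < 0:
        raise ValueError("baseline concentration must be non-negative")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not (t0 <= t_impulse <= t0 + duration):
        raise ValueError(f"t_impulse={t_impulse} outside trace window [{t0}, {t0 + duration}]")
    n = int(np.floor(duration / dt)) + 1
    vals = np.full(n, ca0, dtype=float)
    idx = int(round((t_impulse - t0) / dt))
    vals[idx] += impulse_amplitude
    return CalciumTrace(t0=t0, dt=dt, values=vals, baseline=ca0)
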