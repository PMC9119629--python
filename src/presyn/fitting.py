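"""Fitting release profiles and facilitation metaparameters.

The machinery mirrors a two-stage procedure: stage 1 fits the per-spike
component masses ``P_c`` of a release profile to a rate trace (decay
constants and onset-filter parameters held fixed), stage 2 fits the
facilitation metaparameters (``tau``, ``N``, ``L = N**xi`` per linear
factor, explored in log space) to the pattern of final-spike masses
across a bank of ramp-probe spike trains.

The cost is a weighted sum of the fraction of variance unexplained (FVU)
in linear and in log space: the linear term weights the high peaks of
fast components, the log term the slopes (hence time constants) of slow
ones.  Optimization is derivative-free Nelder-Mead with parameters in
log space (which also enforces positivity) and optional seeded restarts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.signal import savgol_filter

from presyn.facilitation import FacilitationComponent, apply_facilitation_to_train
from presyn.profile import ReleaseModel, SpikeTrain, eval_profile_filtered

__all__ = [
    "FitConfig",
    "ProtocolSpec",
    "instantaneous_tau",
    "fvu_cost",
    "fit_profile",
    "fit_facilitation_metaparams",
    "make_protocol",
    "FitResult",
]


@dataclass(frozen=True)
class FitConfig:
    """Weights, iteration limits and seeding for the simplex fits."""

    alpha: float = 1.0  # linear-FVU weight
    beta: float = 1.0  # log-FVU weight
    max_iter: int = 4000
    restarts: int = 3
    restart_jitter: float = 0.3  # s.d. of log-space perturbation per restart
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulus protocol grid: ramp lengths, ramp ISIs, probe delays (ms)."""

    ramp_counts: tuple[int, ...] = (1, 2, 3, 4, 5)
    ramp_isis: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0)
    probe_delays: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.ramp_counts):
            raise ValueError("ramp counts must be >= 1")
        if any(v <= 0 for v in self.ramp_isis) or any(v <= 0 for v in self.probe_delays):
            raise ValueError("ISIs and probe delays must be positive")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a simplex fit."""

    model: object
    cost: float
    converged: bool
    n_iter: int


def instantaneous_tau(
    times: np.ndarray,
    rates: np.ndarray,
    baseline: float,
    smooth_window: int = 5,
) -> np.ndarray:
    """Instantaneous decay time constant of a rate trace,

        tau(t) = -1 / (d/dt ln(r(t) - r(0))),

    via smoothed central differences (Savitzky-Golay window of
    ``smooth_window`` points, linear order) on the log excess rate.
    Samples where the excess rate is non-positive are NaN-flagged, never
    silently dropped.
    """
    times = np.asarray(times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if times.shape != rates.shape:
        raise ValueError("times and rates must have the same shape")
    excess = rates - baseline
    out = np.full(times.shape, np.nan)
    ok = excess > 0
    if ok.sum() < max(smooth_window, 3):
        return out
    log_exc = np.full(times.shape, np.nan)
    log_exc[ok] = np.log(excess[ok])
    # derivative only over the contiguous valid span to avoid NaN bleed
    idx = np.flatnonzero(ok)
    start, stop = idx[0], idx[-1] + 1
    span = log_exc[start:stop]
    if np.any(~np.isfinite(span)):
        finite = np.isfinite(span)
        span = np.interp(np.arange(span.size), np.flatnonzero(finite), span[finite])
    window = min(smooth_window, span.size if span.size % 2 else span.size - 1)
    if window >= 3:
        span = savgol_filter(span, window, polyorder=1)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    slope = np.gradient(span, dt)
    with np.errstate(divide="ignore"):
        tau = -1.0 / slope
    tau[slope >= 0] = np.nan
    out[start:stop] = tau
    out[~ok] = np.nan
    return out


def fvu(y: np.ndarray, f: np.ndarray) -> float:
    """Fraction of the variance of ``y`` unexplained by ``f``."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError("traces must have equal length")
    denom = np.sum((y - y.mean()) ** 2)
    if denom == 0:
        return 0.0 if np.allclose(y, f) else np.inf
    return float(np.sum((y - f) ** 2) / denom)


def fvu_cost(y: np.ndarray, f: np.ndarray, cfg: FitConfig = FitConfig()) -> float:
    """Weighted linear + log FVU, ``alpha*FVU(y,f) + beta*FVU(log y, log f)``."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    cost = 0.0
    if cfg.alpha > 0:
        cost += cfg.alpha * fvu(y, f)
    if cfg.beta > 0:
        if np.any(y <= 0) or np.any(f <= 0):
            raise ValueError("log-FVU requires strictly positive traces")
        cost += cfg.beta * fvu(np.log(y), np.log(f))
    return cost


def _pack_model(model: ReleaseModel, free: dict[str, bool]) -> np.ndarray:
    theta = []
    for c in model.components:
        if free.get("P", False):
            theta.append(np.log(c.mass_P))
        if free.get("tau", False):
            theta.append(np.log(c.tau))
        if free.get("k", False):
            theta.append(np.log(c.filt_k))
        if free.get("mu", False):
            theta.append(np.log(c.filt_mu))
        if free.get("sigma", False):
            theta.append(np.log(c.filt_sigma))
    return np.array(theta)


def _unpack_model(theta: np.ndarray, model: ReleaseModel, free: dict[str, bool]) -> ReleaseModel:
    comps = []
    i = 0
    for c in model.components:
        kw = {}
        for name, attr in (("P", "mass_P"), ("tau", "tau"), ("k", "filt_k"),
                           ("mu", "filt_mu"), ("sigma", "filt_sigma")):
            if free.get(name, False):
                kw[attr] = float(np.exp(theta[i]))
                i += 1
        comps.append(replace(c, **kw))
    return ReleaseModel(r0=model.r0, components=tuple(comps), mechanism=model.mechanism)


def fit_profile(
    times: np.ndarray,
    target: np.ndarray,
    init: ReleaseModel,
    free: dict[str, bool] | None = None,
    cfg: FitConfig = FitConfig(),
    spike_at: float = 0.0,
) -> FitResult:
    """Fit the free parameters of a release model to a rate trace.

    Parameters are optimized in log space (positivity by construction)
    with Nelder-Mead; ``cfg.restarts`` seeded jittered restarts mitigate
    local minima, ties broken by lowest cost then earliest restart.
    ``free`` maps parameter names ("P", "tau", "k", "mu", "sigma") to
    whether they vary; default frees only the masses, mirroring the
    stage-1 protocol fits.
    """
    if free is None:
        free = {"P": True}
    times = np.asarray(times, dtype=float)
    target = np.asarray(target, dtype=float)

    def objective(theta: np.ndarray) -> float:
        model = _unpack_model(theta, init, free)
        pred = eval_profile_filtered(model, times, spike_at=spike_at)
        try:
            return fvu_cost(target, pred, cfg)
        except ValueError:
            return np.inf

    theta0 = _pack_model(init, free)
    rng = np.random.default_rng(cfg.seed)
    best = None
    for r in range(max(cfg.restarts, 1)):
        start = theta0 if r == 0 else theta0 + rng.normal(0, cfg.restart_jitter, theta0.shape)
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"maxiter": cfg.max_iter, "xatol": 1e-8, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    model = _unpack_model(best.x, init, free)
    return FitResult(model=model, cost=float(best.fun), converged=bool(best.success),
                     n_iter=int(best.nit))


def make_protocol(spec: ProtocolSpec = ProtocolSpec(), kind: str = "ramp_probe") -> list[SpikeTrain]:
    """Generate the stimulus spike trains.

    ``ppf``: paired pulses, one train per probe delay.  ``ramp_probe``:
    every combination of ramp length (1..5 spikes), ramp ISI and probe
    delay (plus the no-probe case), de-duplicated — a one-spike ramp has
    no ISI, so its cases coincide across ramp ISIs (160 raw cases, 136
    unique trains for the default grid).
    """
    return [train for _, train in make_protocol_labeled(spec, kind)]


def make_protocol_labeled(
    spec: ProtocolSpec = ProtocolSpec(), kind: str = "ramp_probe"
) -> list[tuple[str, SpikeTrain]]:
    """Like :func:`make_protocol` but with a systematic name per train."""
    if kind == "ppf":
        return [
            (f"ppf_isi{d:g}", SpikeTrain(np.array([0.0, d])))
            for d in spec.probe_delays
        ]
    if kind != "ramp_probe":
        raise ValueError(f"unknown protocol kind {kind!r}")
    # a one-spike ramp has no ISI, so its cases repeat across ramp ISIs;
    # those repeats are the ones collapsed (160 raw -> 136 trains)
    trains: list[tuple[str, SpikeTrain]] = []
    for count, isi in itertools.product(spec.ramp_counts, spec.ramp_isis):
        if count == 1 and isi != spec.ramp_isis[0]:
            continue
        ramp = [i * isi for i in range(count)]
        for probe in (*spec.probe_delays, None):
            times = tuple(ramp) if probe is None else (*ramp, ramp[-1] + probe)
            label = f"ramp{count}_isi{isi:g}_probe{'none' if probe is None else f'{probe:g}'}"
            if count == 1:
                label = f"ramp1_probe{'none' if probe is None else f'{probe:g}'}"
            trains.append((label, SpikeTrain(np.array(times))))
    return trains


def raw_case_count(spec: ProtocolSpec = ProtocolSpec()) -> int:
    """Number of raw protocol cases, ramps x ISIs x (probes + no-probe)."""
    return len(spec.ramp_counts) * len(spec.ramp_isis) * (len(spec.probe_delays) + 1)


def predict_final_masses(
    params: list[list[FacilitationComponent]],
    baselines: np.ndarray,
    trains: list[SpikeTrain],
) -> np.ndarray:
    """Final-spike facilitated masses for every train, (n_trains, n_components)."""
    out = np.empty((len(trains), len(baselines)))
    for i, train in enumerate(trains):
        out[i] = apply_facilitation_to_train(params, baselines, train)[-1]
    return out


def fit_facilitation_metaparams(
    per_case_masses: np.ndarray,
    trains: list[SpikeTrain],
    baselines: np.ndarray | list[float],
    n_factors: list[int],
    cfg: FitConfig = FitConfig(),
    init: list[list[FacilitationComponent]] | None = None,
) -> tuple[list[list[FacilitationComponent]], float]:
    """Stage-2 fit: facilitation metaparameters from per-case final masses.

    For each release component ``c`` with ``n_factors[c]`` linear factors,
    the triple (log tau, log N, log L) of every factor is optimized with
    Nelder-Mead to minimize the FVU of the observed final-spike masses
    across all trains.  ``n_factors[c] = 0`` pins the component to
    non-facilitating (constant masses).  Returns the fitted parameters
    and the summed FVU.
    """
    per_case_masses = np.asarray(per_case_masses, dtype=float)
    baselines = np.asarray(baselines, dtype=float)
    n_comp = baselines.size
    if per_case_masses.shape != (len(trains), n_comp):
        raise ValueError(
            f"per_case_masses shape {per_case_masses.shape} != ({len(trains)}, {n_comp})"
        )
    fitted: list[list[FacilitationComponent]] = []
    total = 0.0
    rng = np.random.default_rng(cfg.seed)
    for c in range(n_comp):
        m = n_factors[c]
        if m == 0:
            fitted.append([])
            continue
        if 3 * m > len(trains):
            raise ValueError("fewer cases than free metaparameters")
        y = per_case_masses[:, c]
        p0 = baselines[c]

        def unpack(theta: np.ndarray) -> list[FacilitationComponent]:
            comps = []
            for i in range(m):
                tau, N, L = np.exp(np.clip(theta[3 * i: 3 * i + 3], -50.0, 50.0))
                N = max(N, 1.0 + 1e-12)
                xi = np.log(L) / np.log(N)
                comps.append(FacilitationComponent(tau_f=tau, n_steps=N, xi=xi))
            return comps

        def objective(theta: np.ndarray) -> float:
            comps = unpack(theta)
            pred = np.array(
                [
                    apply_facilitation_to_train([comps], [p0], tr)[-1, 0]
                    for tr in trains
                ]
            )
            return fvu(y, pred)

        if init is not None and init[c]:
            theta0 = np.concatenate(
                [np.log([fc.tau_f, fc.n_steps, fc.limit_L]) for fc in init[c]]
            )
        else:
            # data-driven start: split the observed peak facilitation across
            # the factors, spread time constants over the probed decades
            f_max = max(float(np.max(y) / p0), 1.0 + 1e-6)
            l_each = f_max ** (1.0 / m) * 2.0
            theta0 = np.concatenate(
                [np.log([15.0 * 6.0**i, 5.0, l_each]) for i in range(m)]
            )
        best = None
        for r in range(max(cfg.restarts, 1)):
            start = theta0 if r == 0 else theta0 + rng.normal(0, cfg.restart_jitter, theta0.shape)
            res = minimize(
                objective,
                start,
                method="Nelder-Mead",
                options={"maxiter": cfg.max_iter, "xatol": 1e-8, "fatol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        # polish: restarting the simplex at (or kicked slightly off) the
        # incumbent escapes the collapsed-simplex stalls Nelder-Mead is
        # prone to on nearly flat valleys; kicks are kept only on descent
        stalls = 0
        for _ in range(12):
            kick = 0.0 if stalls == 0 else rng.normal(0, 0.02 * stalls, best.x.shape)
            res = minimize(
                objective,
                best.x + kick,
                method="Nelder-Mead",
                options={"maxiter": cfg.max_iter, "xatol": 1e-10, "fatol": 1e-14},
            )
            if res.fun < best.fun * (1 - 1e-6):
                best = res
                stalls = 0
            else:
                best = res if res.fun < best.fun else best
                stalls += 1
                if stalls > 3:
                    break
        if m == 2 and best.fun > 1e-20:
            # the two-factor cost surface has nearly flat shelves along the
            # split of the total saturation between the factors; scan the
            # split (both factor orderings) deterministically and keep the
            # best basin, stopping once the cost is at the numerical floor
            incumbent = best.x.copy()
            l_tot = incumbent[2] + incumbent[5]
            log_n0 = np.log(5.0)  # reset step counts: the stalled N is poisoned
            for s in (0.1, 0.3, 0.5, 0.7, 0.9):
                for swapped in (False, True):
                    taus = (
                        (incumbent[3], incumbent[0]) if swapped
                        else (incumbent[0], incumbent[3])
                    )
                    x2 = np.array(
                        [taus[0], log_n0, s * l_tot, taus[1], log_n0, (1 - s) * l_tot]
                    )
                    res = minimize(
                        objective, x2, method="Nelder-Mead",
                        options={"maxiter": cfg.max_iter, "xatol": 1e-10, "fatol": 1e-14},
                    )
                    for _ in range(6):
                        r2 = minimize(
                            objective, res.x, method="Nelder-Mead",
                            options={"maxiter": cfg.max_iter, "xatol": 1e-10, "fatol": 1e-14},
                        )
                        if r2.fun < res.fun * (1 - 1e-6):
                            res = r2
                        else:
                            res = r2 if r2.fun < res.fun else res
                            break
                    if res.fun < best.fun:
                        best = res
                if best.fun <= 1e-20:
                    break
        fitted.append(unpack(best.x))
        total += float(best.fun)
    return fitted, total
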