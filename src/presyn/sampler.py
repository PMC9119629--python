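"""Event-driven stochastic realization of release times.

The deterministic profile of :mod:`presyn.profile` is the rate of a
time-varying Poisson process — the ensemble mean over infinitely many
trials.  A single trial is realized by sampling, for every spike and
release component:

1. a calcium arrival time: spike time + Normal(mu, sigma) + Exp(rate k);
2. an event count ~ Poisson(P_c(n)) with the (facilitated) mass;
3. candidate release times: arrival + Exp(mean tau_c) each;
4. truncation: candidates at or after that component's *next* calcium
   arrival are discarded — the sensor stops responding to one spike when
   the next spike's calcium takes over.

Spontaneous events form a homogeneous Poisson process at the baseline
rate throughout.  ``single_vesicle`` mode keeps only the first event of a
trial (the hazard reading of the profile), optionally re-arming after an
exponential refractory delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from presyn.facilitation import FacilitationComponent, apply_facilitation_to_train
from presyn.profile import ReleaseComponent, ReleaseModel, SpikeTrain

__all__ = ["EventRecord", "sample_arrival_delays", "sample_release_events"]


@dataclass(frozen=True)
class EventRecord:
    """One sampled release event."""

    time: float
    mechanism: str  # synchronous | asynchronous | spontaneous
    component: int  # component index, -1 for spontaneous
    spike_index: int  # index of the evoking spike, -1 for spontaneous


def sample_arrival_delays(
    comp: ReleaseComponent,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` ex-Gaussian onset delays for one release component.

    Each delay is Normal(mu_c, sigma_c) + Exponential(rate k_c); attached
    to spike times these form the calcium arrival times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    normal = rng.normal(comp.filt_mu, comp.filt_sigma, size=n) if comp.filt_sigma > 0 else np.full(n, comp.filt_mu)
    return normal + rng.exponential(1.0 / comp.filt_k, size=n)


def _spontaneous_events(r0: float, duration: float, rng) -> list[EventRecord]:
    if r0 <= 0:
        return []
    count = rng.poisson(r0 * duration)
    times = np.sort(rng.uniform(0.0, duration, size=count))
    return [EventRecord(float(t), "spontaneous", -1, -1) for t in times]


def sample_release_events(
    model: ReleaseModel,
    spikes: SpikeTrain,
    facil: list[list[FacilitationComponent]] | None = None,
    duration: float | None = None,
    mode: str = "poisson",
    refractory: bool = False,
    refractory_eps: float = 6.34,
    rng: np.random.Generator | int | None = None,
) -> list[EventRecord]:
    """Sample one trial of release events for a spike train.

    Parameters
    ----------
    facil : facilitation parameters, optional
        Per-release-component lists of :class:`FacilitationComponent`;
        when omitted, baseline masses are used for every spike.
    mode : {"poisson", "single_vesicle"}
        ``poisson`` emits every sampled event (ensemble histograms then
        converge to the deterministic profile); ``single_vesicle`` keeps
        only the first event, optionally re-arming after an
        Exponential(mean ``refractory_eps``) recovery when ``refractory``
        is on.
    """
    if mode not in ("poisson", "single_vesicle"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    if duration is None:
        duration = (float(spikes.times[-1]) if len(spikes) else 0.0) + 500.0
    if len(spikes) and duration < spikes.times[-1]:
        raise ValueError("duration does not cover the spike train")
    n_spk = len(spikes)
    baselines = np.array([c.mass_P for c in model.components])
    if facil is not None:
        masses = apply_facilitation_to_train(facil, baselines, spikes)
    else:
        masses = np.tile(baselines, (n_spk, 1))

    events: list[EventRecord] = _spontaneous_events(model.r0, duration, rng)
    for ci, comp in enumerate(model.components):
        if n_spk == 0:
            break
        delays = sample_arrival_delays(comp, n_spk, rng)
        arrivals = spikes.times + delays
        # truncation in arrival-time order keeps the hand-off well defined
        # even if a later spike's calcium arrives before an earlier one's
        order = np.argsort(arrivals, kind="stable")
        sorted_arr = arrivals[order]
        for pos, i in enumerate(order):
            cutoff = sorted_arr[pos + 1] if pos + 1 < n_spk else np.inf
            count = rng.poisson(masses[i, ci])
            if count == 0:
                continue
            times = arrivals[i] + rng.exponential(comp.tau, size=count)
            for t in times:
                if t < cutoff and t <= duration:
                    events.append(EventRecord(float(t), model.mechanism, ci, int(i)))
    events.sort(key=lambda e: e.time)
    if mode == "poisson":
        return events
    # single-vesicle: the profile is a hazard; only the first event counts,
    # then (optionally) the vesicle re-arms after a refractory delay
    kept: list[EventRecord] = []
    armed_at = 0.0
    for ev in events:
        if ev.time < armed_at:
            continue
        kept.append(ev)
        if not refractory:
            break
        armed_at = ev.time + rng.exponential(refractory_eps)
    return kept
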