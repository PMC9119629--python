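"""Built-in parameter tables and parameter-bundle serialization.

Three named built-ins ship with the package:

* ``table1`` — SNARE state-transition constants for the synchronous
  (Syt-1) and asynchronous (Syt-7) sensors.  Published values are in
  per-molar per-second units; they are converted to the package's
  internal uM/ms units at load time (6.12e7 M^-1 s^-1 -> 0.0612
  uM^-1 ms^-1).
* ``table2_400nm`` — multi-exponential release-profile parameters for
  both mechanisms, valid for sensors 400 nm from a cluster of 100
  voltage-dependent calcium channels.
* ``table3`` — facilitation metaparameters paired with the table2
  baselines, keyed by release component (S11, S12, S21, S22, S3, S4,
  A11, A12, A2, A3).

User parameter files are JSON with the same structure; unknown keys are
rejected and every invariant of the constituent types is checked on
load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from presyn.calcium import CaTransientSpec
from presyn.facilitation import FacilitationComponent
from presyn.kinetics import SensorKinetics
from presyn.profile import ReleaseComponent, ReleaseModel

__all__ = ["ParameterBundle", "load_parameters", "BUILTIN_NAMES"]

#: conversion from M^-1 s^-1 to uM^-1 ms^-1 (1e-6 per molar, 1e-3 per second)
_PER_MOLAR_SECOND_TO_UM_MS = 1e-9
#: conversion from s^-1 to ms^-1
_PER_SECOND_TO_MS = 1e-3

# --- built-in table data (published units) ---------------------------------

_TABLE1 = {
    "synchronous": {
        "n_sites": 5,
        "k_on_per_M_s": 6.12e7,
        "k_off_per_s": 2.32e3,
        "coop_b": 0.25,
        "gamma_per_s": 6.0e3,
        "refractory_eps_ms": 6.34,
    },
    "asynchronous": {
        "n_sites": 2,
        "k_on_per_M_s": 3.82e6,
        "k_off_per_s": 13.0,
        "coop_b": 0.25,
        "gamma_per_s": 50.0,
        "refractory_eps_ms": 6.34,
    },
}

# spontaneous rates at the 100 nM resting level (ms^-1)
_SPONTANEOUS = {"synchronous": 5.70e-9, "asynchronous": 1.84e-5}

# component rows: (P, tau ms, k ms^-1, mu ms, sigma ms)
_TABLE2 = {
    "synchronous": [
        (0.0175, 0.163, 1.79, 3.41, 0.168),
        (0.0220, 6.50, 18.0, 3.56, 0.0977),
        (1.70e-5, 80.0, 0.526, 10.0, 4.44),
        (1.10e-5, 1000.0, 0.142, 50.0, 11.5),
    ],
    "asynchronous": [
        (3.72e-3, 17.7, 1.60, 3.05, 0.243),
        (0.0111, 76.9, 0.0759, 4.00, 1.14),
        (0.0136, 1000.0, 0.0337, 76.5, 21.9),
    ],
}

# facilitation factors per release component: (tau ms, N, xi); slowest
# (1000 ms) components are constrained non-facilitating
_TABLE3 = {
    "synchronous": [
        [(95.9, 7.00, 1.27), (7.66, 2.32, 2.93)],  # S11, S12
        [(13.1, 10.0, 1.23), (114.0, 17.6, 1.68)],  # S21, S22
        [(199.0, 12.5, 2.67)],  # S3
        [],  # S4: does not facilitate
    ],
    "asynchronous": [
        [(141.0, 12.2, 1.48), (17.2, 12.5, 0.996)],  # A11, A12
        [(126.0, 12.1, 1.67)],  # A2
        [],  # A3: does not facilitate
    ],
}

BUILTIN_NAMES = ("table1", "table2_400nm", "table3")


@dataclass(frozen=True)
class ParameterBundle:
    """Validated aggregate of sensor, profile and facilitation parameters."""

    sensors: dict[str, SensorKinetics]
    release_models: dict[str, ReleaseModel]
    facilitation: dict[str, list[list[FacilitationComponent]]]
    calcium_spec: CaTransientSpec = field(default_factory=CaTransientSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for mech, model in self.release_models.items():
            fac = self.facilitation.get(mech)
            if fac is not None and len(fac) != len(model.components):
                raise ValueError(
                    f"facilitation lists for {mech!r} do not match its "
                    f"{len(model.components)} release components"
                )


def _sensor_from_published(d: dict) -> SensorKinetics:
    allowed = {"n_sites", "k_on_per_M_s", "k_off_per_s", "coop_b", "gamma_per_s",
               "refractory_eps_ms"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown sensor keys: {sorted(unknown)}")
    return SensorKinetics(
        n_sites=int(d["n_sites"]),
        k_on=d["k_on_per_M_s"] * _PER_MOLAR_SECOND_TO_UM_MS * 1.0,
        k_off=d["k_off_per_s"] * _PER_SECOND_TO_MS,
        coop_b=d["coop_b"],
        gamma_fuse=d["gamma_per_s"] * _PER_SECOND_TO_MS,
        refractory_eps=d.get("refractory_eps_ms", 0.0),
    )


def _builtin_sensors() -> dict[str, SensorKinetics]:
    return {mech: _sensor_from_published(d) for mech, d in _TABLE1.items()}


def _builtin_release_models() -> dict[str, ReleaseModel]:
    out = {}
    for mech, rows in _TABLE2.items():
        comps = tuple(
            ReleaseComponent(mass_P=p, tau=tau, filt_k=k, filt_mu=mu, filt_sigma=sig)
            for p, tau, k, mu, sig in rows
        )
        out[mech] = ReleaseModel(r0=_SPONTANEOUS[mech], components=comps, mechanism=mech)
    return out


def _builtin_facilitation() -> dict[str, list[list[FacilitationComponent]]]:
    out = {}
    for mech, comps in _TABLE3.items():
        out[mech] = [
            [FacilitationComponent(tau_f=t, n_steps=n, xi=x) for t, n, x in factors]
            for factors in comps
        ]
    return out


def builtin_bundle(seed: int = 0) -> ParameterBundle:
    """The shipped defaults: table1 + table2_400nm + table3."""
    return ParameterBundle(
        sensors=_builtin_sensors(),
        release_models=_builtin_release_models(),
        facilitation=_builtin_facilitation(),
        seed=seed,
    )


def _bundle_from_dict(data: dict) -> ParameterBundle:
    allowed = {"sensors", "release_models", "facilitation", "calcium_spec", "seed"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown bundle keys: {sorted(unknown)}")
    errors: list[str] = []
    sensors: dict[str, SensorKinetics] = {}
    for mech, d in data.get("sensors", {}).items():
        try:
            sensors[mech] = _sensor_from_published(d)
        except (ValueError, KeyError) as exc:
            errors.append(f"sensor {mech!r}: {exc}")
    models: dict[str, ReleaseModel] = {}
    for mech, d in data.get("release_models", {}).items():
        try:
            comps = tuple(
                ReleaseComponent(
                    mass_P=row["P"], tau=row["tau_ms"], filt_k=row["k_per_ms"],
                    filt_mu=row.get("mu_ms", 0.0), filt_sigma=row.get("sigma_ms", 0.0),
                )
                for row in d["components"]
            )
            models[mech] = ReleaseModel(r0=d["r0_per_ms"], components=comps, mechanism=mech)
        except (ValueError, KeyError) as exc:
            errors.append(f"release model {mech!r}: {exc}")
    facilitation: dict[str, list[list[FacilitationComponent]]] = {}
    for mech, comp_lists in data.get("facilitation", {}).items():
        try:
            facilitation[mech] = [
                [
                    FacilitationComponent(
                        tau_f=f.get("tau_ms", math.inf), n_steps=f["N"], xi=f["xi"]
                    )
                    for f in factors
                ]
                for factors in comp_lists
            ]
        except (ValueError, KeyError) as exc:
            errors.append(f"facilitation {mech!r}: {exc}")
    spec = CaTransientSpec()
    if "calcium_spec" in data:
        try:
            d = data["calcium_spec"]
            spec = CaTransientSpec(
                baseline=d.get("baseline_uM", 0.1),
                components=tuple(
                    (c["amplitude_uM"], c["tau_ms"]) for c in d.get("components", [])
                ) or CaTransientSpec().components,
                onset_delay=d.get("onset_delay_ms", 1.0),
                distance=d.get("distance_um", 0.0),
                length_constant=d.get("length_constant_um", 0.204),
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"calcium_spec: {exc}")
    if errors:
        raise ValueError("parameter validation failed:\n  " + "\n  ".join(errors))
    return ParameterBundle(
        sensors=sensors,
        release_models=models,
        facilitation=facilitation,
        calcium_spec=spec,
        seed=int(data.get("seed", 0)),
    )


def load_parameters(source: str | Path) -> ParameterBundle:
    """Load a parameter bundle from a built-in name or a JSON file.

    Built-ins ("table1", "table2_400nm", "table3") all resolve to the
    full shipped bundle, since the tables cross-reference each other.
    """
    if isinstance(source, str) and source in BUILTIN_NAMES:
        return builtin_bundle()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a built-in ({', '.join(BUILTIN_NAMES)}) nor a file"
        )
    with open(path) as fh:
        data = json.load(fh)
    return _bundle_from_dict(data)
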