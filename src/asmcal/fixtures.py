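"""Self-contained synthetic datasets emulating the SBR and CSTR experiments.

The original reactor measurements behind the calibration studies this
package emulates are not publicly deposited, so every test and example runs
against synthetic data: a scenario is simulated at known "truth" parameters,
observed at realistic sampling times, and corrupted with additive Gaussian
noise truncated at zero (concentrations cannot be negative).  The truth
record travels as a sidecar next to the dataset and is never read by the
calibrator.

Scenarios:

* ``sbr_complete_nitrification`` — 14 L working volume, 50% volume exchange,
  aerobic-anoxic cycle (3 min feed, 4 h aeration at DO 2, 2 h anoxic, 1 h
  settle, 6 min decant, 1 min idle); samples every 15 min through the
  reacting phases.  Truth overrides use literature point estimates for an
  SBR sludge: k_STO = 4.37 1/d, mu_AOB = 1.02 1/d, mu_NOB = 0.76 1/d.
* ``sbr_partial_nitrification`` — same cycle with shorter, low-DO aeration
  so nitrite accumulates.
* ``cstr_partial_nitritation`` — 4 L reactor, 8 L/d flow, SRT 12 d, low DO;
  daily effluent samples over 113 d, split at day 75 into calibration and
  validation ranges.  Truth overrides include K_H_NO3 = 5.69 g N/m3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import Dataset
from .model import GujerModel, OBSERVABLE_NAMES, load_model
from .protocol import CalibrationContext
from .scenarios import (CSTRConfig, Phase, SBRSchedule, Trajectory, observe,
                        simulate_cstr, simulate_sbr)

__all__ = [
    "FixtureSpec",
    "default_truths",
    "sbr_schedule",
    "sbr_initial_state",
    "sbr_influent",
    "cstr_config",
    "cstr_initial_state",
    "make_dataset",
    "make_sbr_context",
]

SCENARIOS = ("sbr_complete_nitrification", "sbr_partial_nitrification",
             "cstr_partial_nitritation")

MINUTE = 1.0 / 1440.0
HOUR = 1.0 / 24.0

CSTR_SPLIT_DAY = 75.0
CSTR_DURATION = 113.0


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset (scenario, truths, sampling, noise)."""

    scenario: str = "sbr_complete_nitrification"
    overrides: Mapping[str, float] | None = None   # None -> default truths
    sample_times: tuple[float, ...] | None = None  # None -> scenario default
    noise_fraction: float = 0.0     # sigma as a fraction of observable range
    sigma: Mapping[str, float] | None = None       # absolute sigma, wins
    seed: int = 0
    n_cycles: int = 1

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")


def default_truths(scenario: str) -> dict[str, float]:
    """Documented truth overrides per scenario (literature point estimates)."""
    if scenario.startswith("sbr"):
        return {"k_STO": 4.37, "mu_AOB": 1.02, "mu_NOB": 0.76}
    if scenario.startswith("cstr"):
        # K_H_NO3 from the literature CSTR estimate; the DO half-saturation
        # pair is chosen so low DO favours nitrite accumulation (AOB win).
        return {"K_H_NO3": 5.69, "K_AOB_O2": 0.4, "K_NOB_O2": 2.0}
    raise ValueError(f"unknown scenario {scenario!r}")


def sbr_schedule(mode: str = "complete") -> SBRSchedule:
    """Aerobic-anoxic SBR cycle; 14 L working volume, 7 L exchange."""
    influent = sbr_influent()
    if mode == "complete":
        aerobic = Phase("aerobic", 4 * HOUR, do=2.0)
    elif mode == "partial":
        aerobic = Phase("aerobic", 2.5 * HOUR, do=0.8)
    else:
        raise ValueError("mode must be 'complete' or 'partial'")
    return SBRSchedule(
        phases=(
            Phase("feed", 3 * MINUTE, volume=7.0, composition=influent),
            aerobic,
            Phase("anoxic", 2 * HOUR),
            Phase("settle", 1 * HOUR),
            Phase("decant", 6 * MINUTE, volume=7.0),
            Phase("idle", 1 * MINUTE),
        ),
        volume0=7.0,
    )


def sbr_influent() -> dict[str, float]:
    """Municipal-strength influent, g/m3 (COD fractions) and g N/m3."""
    return {
        "S_I": 30.0, "S_S": 250.0, "S_NH4": 45.0, "S_ALK": 7.0,
        "X_I": 25.0, "X_S": 120.0, "X_H": 20.0,
    }


def sbr_initial_state(model: GujerModel) -> np.ndarray:
    """Start-of-cycle (post-decant) mixed-liquor state."""
    state = {
        "S_O2": 0.0, "S_I": 30.0, "S_S": 5.0, "S_NH4": 2.0,
        "S_NO2": 0.5, "S_NO3": 8.0, "S_N2": 0.0, "S_ALK": 4.0,
        "X_I": 600.0, "X_S": 80.0, "X_H": 1200.0, "X_STO": 60.0,
        "X_AOB": 60.0, "X_NOB": 40.0,
    }
    return np.array([state[c] for c in model.components])


def cstr_config() -> CSTRConfig:
    return CSTRConfig(
        volume=4.0, flow=8.0, srt=12.0, clarifier_volume=3.5,
        influent={
            "S_I": 30.0, "S_S": 180.0, "S_NH4": 60.0, "S_ALK": 8.0,
            "X_I": 20.0, "X_S": 80.0,
        },
        do=0.5,
    )


def cstr_initial_state(model: GujerModel) -> np.ndarray:
    state = {
        "S_O2": 0.5, "S_I": 30.0, "S_S": 10.0, "S_NH4": 20.0,
        "S_NO2": 5.0, "S_NO3": 2.0, "S_N2": 0.0, "S_ALK": 5.0,
        "X_I": 400.0, "X_S": 60.0, "X_H": 800.0, "X_STO": 40.0,
        "X_AOB": 40.0, "X_NOB": 15.0,
    }
    return np.array([state[c] for c in model.components])


def _default_sample_times(spec: FixtureSpec, schedule: SBRSchedule | None) -> np.ndarray:
    if spec.scenario.startswith("sbr"):
        react_end = sum(p.duration for p in schedule.phases[:3])  # feed+aer+anox
        times = np.arange(0.0, react_end * spec.n_cycles + 1e-12, 15 * MINUTE)
        return times[times <= schedule.cycle_duration * spec.n_cycles]
    return np.arange(0.0, CSTR_DURATION + 1e-9, 1.0)


def simulate_truth(spec: FixtureSpec, model: GujerModel | None = None
                   ) -> tuple[Trajectory, np.ndarray, GujerModel]:
    """Simulate the scenario at its truth parameters."""
    model = model or load_model()
    overrides = dict(spec.overrides if spec.overrides is not None
                     else default_truths(spec.scenario))
    pvec = model.params.vector(overrides)
    try:
        if spec.scenario.startswith("sbr"):
            mode = "complete" if "complete" in spec.scenario else "partial"
            schedule = sbr_schedule(mode)
            traj = simulate_sbr(model, schedule, pvec,
                                sbr_initial_state(model), n_cycles=spec.n_cycles)
        else:
            traj = simulate_cstr(model, cstr_config(), pvec,
                                 cstr_initial_state(model), CSTR_DURATION)
    except Exception as exc:
        raise RuntimeError(
            f"truth simulation failed for scenario {spec.scenario!r}: {exc}"
        ) from exc
    return traj, pvec, model


def make_dataset(spec: FixtureSpec, model: GujerModel | None = None
                 ) -> tuple[Dataset, dict]:
    """Simulate at truth, observe, add truncated Gaussian noise.

    Returns the dataset plus the sidecar truth record (overrides, sigma per
    observable, seed) — the sidecar is for auditing only and must never be
    fed to the calibrator.
    """
    traj, pvec, model = simulate_truth(spec, model)
    schedule = (sbr_schedule("complete" if "complete" in spec.scenario else "partial")
                if spec.scenario.startswith("sbr") else None)
    times = (np.asarray(spec.sample_times, float)
             if spec.sample_times is not None
             else _default_sample_times(spec, schedule))
    ds = observe(traj, times)

    sigma_map: dict[str, float] = {}
    for name in OBSERVABLE_NAMES:
        if spec.sigma is not None and name in spec.sigma:
            sigma_map[name] = float(spec.sigma[name])
        elif spec.noise_fraction > 0:
            v = ds.values(name)
            sigma_map[name] = float(spec.noise_fraction * (v.max() - v.min()))
        else:
            sigma_map[name] = 0.0

    rng = np.random.default_rng(spec.seed)
    frame = ds.frame.copy()
    for name, s in sigma_map.items():
        sel = frame["observable"] == name
        if s > 0:
            noisy = frame.loc[sel, "value"] + rng.normal(0.0, s, int(sel.sum()))
            frame.loc[sel, "value"] = np.maximum(noisy, 0.0)
            frame.loc[sel, "sigma"] = s
    truth = {
        "scenario": spec.scenario,
        "seed": spec.seed,
        "overrides": dict(spec.overrides if spec.overrides is not None
                          else default_truths(spec.scenario)),
        "sigma": sigma_map,
        "n_cycles": spec.n_cycles,
    }
    meta = {"scenario": spec.scenario, "seed": spec.seed}
    if spec.scenario.startswith("cstr"):
        meta["calibration_range"] = (0.0, CSTR_SPLIT_DAY)
        meta["validation_range"] = (CSTR_SPLIT_DAY, CSTR_DURATION)
    return Dataset(frame, meta), truth


def make_sbr_context(dataset: Dataset, model: GujerModel | None = None,
                     mode: str = "complete", n_cycles: int = 1,
                     dt_out: float = 1.0 / 288.0) -> CalibrationContext:
    """Calibration context binding the SBR forward model to a dataset.

    The forward simulation runs one (or more) SBR cycles and interpolates
    the four observables at the dataset sampling times.  The coarser output
    grid (5 min) keeps estimation affordable; interpolation error is far
    below measurement scales.
    """
    model = model or load_model()
    schedule = sbr_schedule(mode)
    init = sbr_initial_state(model)
    obs_names = dataset.observables
    times = {name: dataset.times(name) for name in obs_names}

    def predict_full(pvec: np.ndarray) -> dict[str, np.ndarray]:
        traj = simulate_sbr(model, schedule, pvec, init, n_cycles=n_cycles,
                            dt_out=dt_out)
        return {name: np.interp(times[name], traj.t, traj.observable(name))
                for name in obs_names}

    return CalibrationContext(
        names=model.params.names, defaults=model.params.defaults,
        lower=model.params.lower, upper=model.params.upper,
        predict_full=predict_full, dataset=dataset)
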