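"""Reactor scenario engine: SBR cycles and CSTR-with-clarifier simulations.

Two operating regimes are supported, matching the experiments the package
emulates:

* a sequencing batch reactor (SBR) run through a fixed phase schedule
  (feed / aerobic / anoxic / settle / decant / idle), with dissolved oxygen
  imposed as a forcing during reacting phases, and
* a continuous stirred-tank reactor (CSTR) with an idealised clarifier:
  solubles leave at the hydraulic rate Q/V, particulates at 1/SRT.

All times in days.  Dissolved oxygen is a zero-order-hold forcing; feeding
is continuous inflow over the stated feed duration.  The stiff integrator
(LSODA) runs at rtol 1e-6 / atol 1e-8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .datasets import Dataset
from .model import GujerModel, OBSERVABLE_NAMES

__all__ = [
    "Forcing",
    "Phase",
    "SBRSchedule",
    "CSTRConfig",
    "Trajectory",
    "simulate_sbr",
    "simulate_cstr",
    "observe",
]

RTOL_DEFAULT = 1e-6
ATOL_DEFAULT = 1e-8


class Forcing:
    """Zero-order-hold time series forcing (e.g. dissolved oxygen)."""

    def __init__(self, times: Sequence[float] | float, values: Sequence[float] | None = None):
        if values is None:  # constant forcing
            self.times = np.array([0.0])
            self.values = np.array([float(times)])
        else:
            self.times = np.asarray(times, float)
            self.values = np.asarray(values, float)
            if self.times.ndim != 1 or self.times.shape != self.values.shape:
                raise ValueError("forcing series must be two aligned 1-D arrays")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("forcing times must be strictly increasing")

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def __call__(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.values[max(i, 0)])

    def require_cover(self, duration: float) -> None:
        if self.times[0] > 0.0:
            raise ValueError("forcing series does not cover t=0")
        # ZOH extends the last sample forward only within the sampled horizon
        if len(self.times) > 1 and self.t_end < duration:
            raise ValueError(
                f"forcing series ends at {self.t_end:g} d, before duration {duration:g} d"
            )


@dataclass(frozen=True)
class Phase:
    """One SBR phase.

    kind: feed | aerobic | anoxic | settle | decant | idle.
    ``do`` is the DO forcing during the phase (constant or series); feed,
    anoxic, settle, decant and idle default to DO = 0.  ``volume`` is the
    fed volume (feed) or withdrawn volume (decant), in litres.
    ``react`` controls whether biology runs during settle/decant.
    """

    kind: str
    duration: float
    do: object = None
    volume: float = 0.0
    composition: Mapping[str, float] | None = None
    react: bool = True

    def __post_init__(self):
        if self.kind not in ("feed", "aerobic", "anoxic", "settle", "decant", "idle"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError(f"{self.kind} phase duration must be > 0")
        if self.kind == "feed" and (self.volume <= 0 or self.composition is None):
            raise ValueError("feed phase needs volume > 0 and a composition")
        if self.kind == "decant" and self.volume <= 0:
            raise ValueError("decant phase needs volume > 0")

    def do_forcing(self) -> Forcing:
        if self.kind == "aerobic":
            if self.do is None:
                raise ValueError("aerobic phase needs a DO forcing")
            return self.do if isinstance(self.do, Forcing) else Forcing(self.do)
        if self.do is not None:
            return self.do if isinstance(self.do, Forcing) else Forcing(self.do)
        return Forcing(0.0)


@dataclass(frozen=True)
class SBRSchedule:
    """Ordered SBR phases plus the start-of-cycle (post-decant) volume in L."""

    phases: tuple[Phase, ...]
    volume0: float

    def __post_init__(self):
        if self.volume0 <= 0:
            raise ValueError("volume0 must be > 0")
        fed = sum(p.volume for p in self.phases if p.kind == "feed")
        decanted = sum(p.volume for p in self.phases if p.kind == "decant")
        if decanted > fed + 1e-12:
            raise ValueError("decant volume exceeds fed volume")
        if abs(decanted - fed) > 1e-9:
            raise ValueError(
                "volume does not return to its start-of-cycle value "
                f"(fed {fed:g} L, decanted {decanted:g} L)"
            )

    @property
    def cycle_duration(self) -> float:
        return sum(p.duration for p in self.phases)


@dataclass(frozen=True)
class CSTRConfig:
    """CSTR with idealised clarifier: solubles at HRT, particulates at SRT."""

    volume: float                     # L
    flow: float                       # L/d
    srt: float                        # d
    influent: Mapping[str, float] | None = None
    do: object = 0.5                  # forcing (constant or Forcing)
    clarifier_volume: float = 0.0     # L, informational (lumped into 1/SRT)

    def __post_init__(self):
        if self.volume <= 0 or self.flow <= 0:
            raise ValueError("volume and flow must be > 0")
        hrt = self.volume / self.flow
        if self.srt <= hrt:
            raise ValueError(f"SRT ({self.srt:g} d) must exceed HRT ({hrt:g} d)")

    def do_forcing(self) -> Forcing:
        return self.do if isinstance(self.do, Forcing) else Forcing(self.do)


@dataclass
class Trajectory:
    """Simulated state trajectory with derived observables.

    ``observables`` has shape (4, n): COD (S_S + S_I), S_NH4, S_NO2, S_NO3.
    """

    t: np.ndarray
    states: np.ndarray
    volume: np.ndarray
    components: tuple[str, ...]
    observables: np.ndarray = field(default=None)
    observable_names: tuple[str, ...] = OBSERVABLE_NAMES

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def component(self, name: str) -> np.ndarray:
        return self.states[:, self.components.index(name)]

    def observable(self, name: str) -> np.ndarray:
        return self.observables[self.observable_names.index(name)]


def _composition_vector(model: GujerModel, comp: Mapping[str, float]) -> np.ndarray:
    v = np.zeros(len(model.components))
    for name, value in comp.items():
        v[model.component_index(name)] = float(value)
    return v


def _integrate_phase(model, pvec, nu_T, y0, duration, do, feed=None,
                     rtol=RTOL_DEFAULT, atol=ATOL_DEFAULT, dt_out=1.0 / 720.0,
                     react=True):
    """Integrate one well-mixed phase; returns (t_local, states, V_series)."""
    do.require_cover(duration)
    if feed is not None:
        v0, q, c_in = feed
    rates = model.rates_unchecked

    def fun(t, y):
        yy = y.copy()
        yy[0] = do(t)
        dy = nu_T @ rates(yy, pvec) if react else np.zeros_like(y)
        if feed is not None:
            dil = q / (v0 + q * t)
            dy = dy + dil * (c_in - y)
        dy[0] = 0.0
        return dy

    n_out = max(int(round(duration / dt_out)), 2)
    t_eval = np.linspace(0.0, duration, n_out + 1)
    sol = solve_ivp(fun, (0.0, duration), y0, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T.copy()
    # record the forced DO and floor tiny undershoots
    states[:, 0] = [do(t) for t in sol.t]
    np.clip(states, 0.0, None, out=states)
    if feed is not None:
        vol = v0 + q * sol.t
    else:
        vol = np.full_like(sol.t, np.nan)  # filled by caller
    return sol.t, states, vol


def simulate_sbr(model: GujerModel, schedule: SBRSchedule, pvec: np.ndarray,
                 init: np.ndarray, n_cycles: int = 1,
                 rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT,
                 dt_out: float = 1.0 / 720.0) -> Trajectory:
    """Simulate ``n_cycles`` SBR cycles from the start-of-cycle state ``init``.

    Feed is continuous inflow with volume increase; decant removes
    particle-free supernatant at the end of the decant phase (soluble
    concentrations unchanged, particulate mass conserved on the reduced
    volume).
    """
    pvec = np.asarray(pvec, float)
    model.params.validate(pvec)
    nu_T = model.stoichiometry(pvec).T
    y = np.asarray(init, float).copy()
    if np.any(y < 0):
        bad = model.components[int(np.argmax(y < 0))]
        raise ValueError(f"negative initial state component {bad!r}")
    V = schedule.volume0
    t0 = 0.0
    ts, ys, vs = [], [], []

    for _ in range(int(n_cycles)):
        for ph in schedule.phases:
            do = ph.do_forcing()
            if ph.kind == "feed":
                c_in = _composition_vector(model, ph.composition)
                q = ph.volume / ph.duration
                tl, st, vol = _integrate_phase(
                    model, pvec, nu_T, y, ph.duration, do,
                    feed=(V, q, c_in), rtol=rtol, atol=atol, dt_out=dt_out)
                V = V + ph.volume
            else:
                react = ph.react if ph.kind in ("settle", "decant") else (
                    ph.kind in ("aerobic", "anoxic", "idle"))
                tl, st, vol = _integrate_phase(
                    model, pvec, nu_T, y, ph.duration, do,
                    rtol=rtol, atol=atol, dt_out=dt_out, react=react)
                vol = np.full_like(tl, V)
            y = st[-1].copy()
            keep = slice(1, None) if ts else slice(None)
            ts.append(tl[keep] + t0)
            ys.append(st[keep])
            vs.append(vol[keep])
            t0 += ph.duration
            if ph.kind == "decant":
                v_post = V - ph.volume
                if v_post <= 0:
                    raise ValueError("decant would empty the reactor")
                scale = V / v_post
                y[~model.soluble_mask] *= scale  # particulates retained
                V = v_post
        if abs(V - schedule.volume0) > 1e-9:
            raise ValueError("volume bookkeeping violated over the cycle")

    t = np.concatenate(ts)
    states = np.concatenate(ys)
    volume = np.concatenate(vs)
    H = model.observable_matrix()
    return Trajectory(t=t, states=states, volume=volume,
                      components=model.components,
                      observables=H @ states.T)


def simulate_cstr(model: GujerModel, config: CSTRConfig, pvec: np.ndarray,
                  init: np.ndarray, duration: float,
                  rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT,
                  dt_out: float = 0.02) -> Trajectory:
    """Simulate a CSTR with clarifier for ``duration`` days."""
    pvec = np.asarray(pvec, float)
    model.params.validate(pvec)
    nu_T = model.stoichiometry(pvec).T
    y0 = np.asarray(init, float).copy()
    do = config.do_forcing()
    do.require_cover(duration)
    c_in = _composition_vector(model, config.influent or {})
    dilution = config.flow / config.volume
    wastage = 1.0 / config.srt
    soluble = model.soluble_mask
    rates = model.rates_unchecked

    def fun(t, y):
        yy = y.copy()
        yy[0] = do(t)
        dy = nu_T @ rates(yy, pvec)
        dy = dy + np.where(soluble,
                           dilution * (c_in - y),
                           dilution * c_in - wastage * y)
        dy[0] = 0.0
        return dy

    n_out = max(int(round(duration / dt_out)), 2)
    t_eval = np.linspace(0.0, duration, n_out + 1)
    sol = solve_ivp(fun, (0.0, duration), y0, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"CSTR integration failed: {sol.message}")
    states = sol.y.T.copy()
    states[:, 0] = [do(t) for t in sol.t]
    np.clip(states, 0.0, None, out=states)
    H = model.observable_matrix()
    return Trajectory(t=sol.t, states=states,
                      volume=np.full_like(sol.t, config.volume),
                      components=model.components,
                      observables=H @ states.T)


def observe(traj: Trajectory, sample_times: Sequence[float],
            observables: Sequence[str] = OBSERVABLE_NAMES) -> Dataset:
    """Linear interpolation of trajectory observables at ``sample_times``.

    No noise is added here; extrapolation outside the trajectory span is an
    error.
    """
    import pandas as pd

    st = np.asarray(sample_times, float)
    if st.min() < traj.t[0] - 1e-12 or st.max() > traj.t[-1] + 1e-12:
        raise ValueError(
            f"sample times [{st.min():g}, {st.max():g}] extend beyond the "
            f"trajectory span [{traj.t[0]:g}, {traj.t[-1]:g}]")
    rows = []
    for name in observables:
        y = traj.observable(name)
        vals = np.interp(st, traj.t, y)
        for t, v in zip(st, vals):
            rows.append((name, t, v, np.nan))
    frame = pd.DataFrame(rows, columns=list(Dataset.COLUMNS))
    return Dataset(frame)
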