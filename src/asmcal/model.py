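"""Extended ASM3 core: parameter set, Gujer matrix, process rates, ODE right-hand side.

The biokinetic model (two-step nitrification/denitrification ASM3) is declared
in a versioned YAML file (``data/asm3_2step.yaml``): components with
conservation weights, 40 stoichiometric/kinetic parameters with box bounds,
and processes given as rate-factor products plus explicit stoichiometric
expressions.  This module loads that declaration, evaluates the stoichiometric
matrix for a given parameter vector, and compiles the process-rate vector into
a fast numba-jitted function (with a pure-Python fallback).

Units throughout: g COD m^-3, g N m^-3, g O2 m^-3, mol m^-3 (alkalinity),
d^-1.  Rates are evaluated on ``max(state, 0)`` so that the right-hand side
stays smooth when the integrator undershoots zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "GujerModel",
    "load_model",
    "DEFAULT_MODEL_FILE",
]

DEFAULT_MODEL_FILE = "asm3_2step.yaml"

# evaluation namespace for stoichiometric / composition expressions
_EXPR_GLOBALS = {"__builtins__": {}, "sqrt": math.sqrt, "exp": math.exp}


def _eval_expr(code, params: Mapping[str, float]) -> float:
    return float(eval(code, _EXPR_GLOBALS, dict(params)))


@dataclass(frozen=True)
class ParameterSet:
    """Named parameter vector with units and box bounds.

    ``defaults``, ``lower`` and ``upper`` are aligned with ``names``; the
    invariant 0 < lower <= default <= upper is enforced at load time.
    """

    names: tuple[str, ...]
    units: tuple[str, ...]
    defaults: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.names)}
        )
        if not np.all(self.lower > 0):
            bad = self.names[int(np.argmin(self.lower))]
            raise ValueError(f"parameter {bad!r}: lower bound must be > 0")
        if not np.all((self.lower <= self.defaults) & (self.defaults <= self.upper)):
            bad = [
                n
                for n, d, lo, up in zip(self.names, self.defaults, self.lower, self.upper)
                if not (lo <= d <= up)
            ]
            raise ValueError(f"default outside bounds for {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Default vector with named overrides applied."""
        v = self.defaults.copy()
        for name, value in (overrides or {}).items():
            v[self.index(name)] = float(value)
        return v

    def as_dict(self, vector: np.ndarray | None = None) -> dict[str, float]:
        v = self.defaults if vector is None else np.asarray(vector, float)
        return dict(zip(self.names, v.tolist()))

    def bounds_for(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = [self.index(n) for n in names]
        return self.lower[idx].copy(), self.upper[idx].copy()

    def validate(self, vector: np.ndarray, clip_tol: float = 0.0) -> None:
        v = np.asarray(vector, float)
        if v.shape != self.defaults.shape:
            raise ValueError("parameter vector has wrong length")
        if np.any(np.isnan(v)):
            bad = self.names[int(np.argmax(np.isnan(v)))]
            raise ValueError(f"NaN in parameter {bad!r}")


def _factor_expr(f: Mapping, comp_ix: Mapping[str, int], par_ix: Mapping[str, int]) -> str:
    """Render one declared kinetic factor as source code over s{} / p[]."""
    kind = f["type"]
    if kind == "monod":
        s, K = f"s{comp_ix[f['var']]}", f"p[{par_ix[f['K']]}]"
        return f"({s}/({K} + {s}))"
    if kind == "inhib":
        s, K = f"s{comp_ix[f['var']]}", f"p[{par_ix[f['K']]}]"
        return f"({K}/({K} + {s}))"
    if kind == "ratio_monod":
        num = f"s{comp_ix[f['num']]}"
        den = f"s{comp_ix[f['den']]}"
        K = f"p[{par_ix[f['K']]}]"
        # algebraically (num/den)/(K + num/den); written denominator-safe
        return f"({num}/({K}*{den} + {num} + 1e-30))"
    if kind == "linear":
        return f"s{comp_ix[f['var']]}"
    raise ValueError(f"unknown rate factor type {kind!r}")


class GujerModel:
    """Biokinetic model: components, processes, stoichiometry and rates."""

    def __init__(self, definition: Mapping):
        self.definition = definition
        self.name = definition.get("name", "model")
        comps = definition["components"]
        self.components: tuple[str, ...] = tuple(c["name"] for c in comps)
        self.component_units = tuple(c["unit"] for c in comps)
        self.soluble_mask = np.array([c["phase"] == "soluble" for c in comps])
        self._comp_ix = {n: i for i, n in enumerate(self.components)}

        pars = definition["parameters"]
        self.params = ParameterSet(
            names=tuple(p["name"] for p in pars),
            units=tuple(p["unit"] for p in pars),
            defaults=np.array([p["default"] for p in pars], float),
            lower=np.array([p["lower"] for p in pars], float),
            upper=np.array([p["upper"] for p in pars], float),
        )
        self._par_ix = {n: i for i, n in enumerate(self.params.names)}

        procs = definition["processes"]
        self.processes: tuple[str, ...] = tuple(pr["name"] for pr in procs)
        self._proc_defs = procs

        # compiled stoichiometric expressions: (proc, comp, code)
        self._stoich_codes = []
        for ip, pr in enumerate(procs):
            for comp, expr in pr["stoichiometry"].items():
                if comp not in self._comp_ix:
                    raise ValueError(
                        f"process {pr['name']!r}: unknown component {comp!r}"
                    )
                code = compile(str(expr), f"<stoich {pr['name']}:{comp}>", "eval")
                self._stoich_codes.append((ip, self._comp_ix[comp], code))

        # composition (conservation) weight expressions per component
        self._comp_weight_codes = {
            key: [compile(str(c[key]), f"<{key} {c['name']}>", "eval") for c in comps]
            for key in ("cod", "nitrogen", "charge")
        }

        self._rates_py = self._build_rate_function()
        self._rates_fast = self._jit_rates(self._rates_py)

    # -- construction helpers -------------------------------------------------

    def _build_rate_function(self) -> Callable:
        lines = ["def _rates(y, p):"]
        for i in range(len(self.components)):
            lines.append(f"    s{i} = y[{i}] if y[{i}] > 0.0 else 0.0")
        lines.append(f"    r = np.empty({len(self.processes)})")
        for ip, pr in enumerate(self._proc_defs):
            terms = [f"p[{self._par_ix[name]}]" for name in pr["rate"]["rate_params"]]
            terms += [
                _factor_expr(f, self._comp_ix, self._par_ix)
                for f in pr["rate"]["factors"]
            ]
            lines.append(f"    r[{ip}] = " + " * ".join(terms))
        lines.append("    return r")
        src = "\n".join(lines)
        ns: dict = {"np": np}
        exec(compile(src, f"<rates {self.name}>", "exec"), ns)
        fn = ns["_rates"]
        fn.__source__ = src
        return fn

    def _jit_rates(self, fn: Callable) -> Callable:
        probe_y = np.zeros(len(self.components))
        probe_p = np.ones(len(self.params))
        try:
            import numba

            jitted = numba.njit(cache=False, fastmath=False)(fn)
            jitted(probe_y, probe_p)  # force compile; also a smoke test
            return jitted
        except Exception:  # pragma: no cover - numba unavailable/failed
            fn(probe_y, probe_p)
            return fn

    # -- public API -----------------------------------------------------------

    def component_index(self, name: str) -> int:
        try:
            return self._comp_ix[name]
        except KeyError:
            raise KeyError(f"unknown component {name!r}") from None

    def stoichiometry(self, pvec: np.ndarray | None = None) -> np.ndarray:
        """Stoichiometric matrix nu (process x component) at parameters ``pvec``."""
        pvec = self.params.defaults if pvec is None else np.asarray(pvec, float)
        self.params.validate(pvec)
        env = self.params.as_dict(pvec)
        nu = np.zeros((len(self.processes), len(self.components)))
        for ip, ic, code in self._stoich_codes:
            nu[ip, ic] = _eval_expr(code, env)
        return nu

    def composition_matrix(self, pvec: np.ndarray | None = None) -> np.ndarray:
        """Conservation weights, rows (cod, nitrogen, charge) x component."""
        pvec = self.params.defaults if pvec is None else np.asarray(pvec, float)
        env = self.params.as_dict(pvec)
        rows = []
        for key in ("cod", "nitrogen", "charge"):
            rows.append([_eval_expr(c, env) for c in self._comp_weight_codes[key]])
        return np.array(rows)

    def continuity_residuals(self, pvec: np.ndarray | None = None) -> np.ndarray:
        """Per-process (COD, N, charge) balance residuals; all ~0 for a sound matrix."""
        nu = self.stoichiometry(pvec)
        w = self.composition_matrix(pvec)
        return nu @ w.T

    def check_continuity(self, pvec: np.ndarray | None = None, tol: float = 1e-6) -> None:
        res = self.continuity_residuals(pvec)
        worst = float(np.abs(res).max())
        if worst > tol:
            ip, ib = np.unravel_index(int(np.abs(res).argmax()), res.shape)
            balance = ("COD", "N", "charge")[ib]
            raise ValueError(
                f"continuity violated: process {self.processes[ip]!r} "
                f"{balance} residual {res[ip, ib]:.3e} (tol {tol:g})"
            )

    def process_rates(self, state: np.ndarray, pvec: np.ndarray) -> np.ndarray:
        """Process rate vector rho(state, params), with input validation."""
        state = np.asarray(state, float)
        if state.shape != (len(self.components),):
            raise ValueError("state vector has wrong length")
        if not np.all(np.isfinite(state)):
            bad = self.components[int(np.argmax(~np.isfinite(state)))]
            raise ValueError(f"non-finite state component {bad!r}")
        if np.any(state < 0):
            bad = self.components[int(np.argmax(state < 0))]
            raise ValueError(f"negative state component {bad!r}")
        pvec = np.asarray(pvec, float)
        self.params.validate(pvec)
        return self._rates_fast(state, pvec)

    def rates_unchecked(self, state: np.ndarray, pvec: np.ndarray) -> np.ndarray:
        """Hot path used by the integrators: no validation, clipping inside."""
        return self._rates_fast(state, pvec)

    def rhs(
        self,
        state: np.ndarray,
        pvec: np.ndarray,
        nu_T: np.ndarray | None = None,
        do_forced: bool = False,
        do_value: float = 0.0,
        transport: np.ndarray | None = None,
    ) -> np.ndarray:
        """dstate/dt = nu^T rho + transport.

        When ``do_forced`` is true the oxygen state is replaced by
        ``do_value`` in the rate evaluation and its derivative set to zero
        (algebraic substitution of the DO forcing).
        """
        if nu_T is None:
            nu_T = self.stoichiometry(pvec).T
        y = np.asarray(state, float)
        if do_forced:
            y = y.copy()
            y[0] = do_value
        dy = nu_T @ self._rates_fast(y, pvec)
        if transport is not None:
            dy = dy + transport
        if do_forced:
            dy[0] = 0.0
        return dy

    # convenience observables -------------------------------------------------

    def observable_matrix(self, include_particulate_cod: bool = False) -> np.ndarray:
        """Rows mapping the state to (COD, S_NH4, S_NO2, S_NO3).

        COD is filtered (S_S + S_I) by default; optionally includes the
        particulate COD pools.
        """
        H = np.zeros((4, len(self.components)))
        H[0, self.component_index("S_S")] = 1.0
        H[0, self.component_index("S_I")] = 1.0
        if include_particulate_cod:
            for name in ("X_I", "X_S", "X_H", "X_STO", "X_AOB", "X_NOB"):
                H[0, self.component_index(name)] = 1.0
        H[1, self.component_index("S_NH4")] = 1.0
        H[2, self.component_index("S_NO2")] = 1.0
        H[3, self.component_index("S_NO3")] = 1.0
        return H


OBSERVABLE_NAMES = ("COD", "S_NH4", "S_NO2", "S_NO3")


def load_model(path: str | None = None) -> GujerModel:
    """Load a Gujer-matrix model definition (default: packaged extended ASM3)."""
    if path is None:
        ref = resources.files("asmcal.data") / DEFAULT_MODEL_FILE
        text = ref.read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    definition = yaml.safe_load(text)
    model = GujerModel(definition)
    model.check_continuity()
    return model
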