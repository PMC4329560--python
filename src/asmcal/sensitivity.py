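"""Derivative-based global sensitivity measures (DGSM) for factor fixing.

The screening measure averages squared relative parameter sensitivities of
the model outputs over the parameter box, sampled with a Sobol
low-discrepancy sequence:

* relative time-varying sensitivity  s_ij(t) = (dy_i(t)/dtheta_j) * theta_j / sc_i,
  computed by central finite differences with relative step ``h``; the
  per-observable scale sc_i is the maximum of |y_i| over the output grid at
  the unperturbed point (a trajectory scale — pointwise normalisation
  diverges where observables cross zero);
* per-sample aggregation: mean over time of s_ij(t)^2, summed over
  observables with weights (a root-mean-square time aggregation);
* the DGSM nu-measure: the mean of that quantity over the quasi-Monte-Carlo
  sample, with the square root taken at the index stage;
* normalised index I_j = sqrt(nu_j) / sum_k sqrt(nu_k), so the indices sum
  to one and give the per-parameter share of output influence.

A config switch selects mean-absolute instead of mean-square averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = ["SensitivityConfig", "SensitivityReport", "relative_sensitivity", "dgsm_indices"]


@dataclass(frozen=True)
class SensitivityConfig:
    """Settings for the DGSM estimator."""

    n_samples: int = 64
    h: float = 1e-3                 # relative finite-difference step
    seed: int = 0
    scramble: bool = True
    weights: tuple[float, ...] | None = None   # per-observable, default 1
    aggregation: str = "squared"    # "squared" (nu-measure) or "abs"
    max_invalid_fraction: float = 0.2

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (1e-8 <= self.h <= 1e-1):
            raise ValueError("finite-difference step h must be in [1e-8, 1e-1]")
        if self.aggregation not in ("squared", "abs"):
            raise ValueError("aggregation must be 'squared' or 'abs'")


@dataclass
class SensitivityReport:
    """Normalised per-parameter influence indices and their ranking."""

    names: tuple[str, ...]
    indices: np.ndarray             # I_j >= 0, sums to 1
    nu: np.ndarray                  # raw (un-normalised) DGSM measure
    ranking: tuple[int, ...]        # parameter positions, most influential first
    n_samples: int
    n_invalid: int
    convergence: float              # half-sample split: max index discrepancy

    def index_of(self, name: str) -> float:
        return float(self.indices[self.names.index(name)])

    def ranked_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.ranking)

    def to_frame(self):
        import pandas as pd

        order = np.argsort(-self.indices, kind="stable")
        return pd.DataFrame({
            "parameter": [self.names[i] for i in order],
            "index": self.indices[order],
            "rank": np.arange(1, len(order) + 1),
        })


def _as_2d(y) -> np.ndarray:
    y = np.asarray(y, float)
    return y[None, :] if y.ndim == 1 else y


def relative_sensitivity(simulate: Callable[[np.ndarray], np.ndarray],
                         theta: np.ndarray, h: float = 1e-3,
                         scale: np.ndarray | None = None,
                         max_retries: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference relative sensitivities at one parameter point.

    ``simulate(theta)`` returns observable trajectories, shape (n_obs, n_t)
    (a 1-D array is treated as one observable).  Returns ``(s, y0)`` with
    ``s`` of shape (n_obs, n_t, p).  On simulation failure at a perturbed
    point the step is halved up to ``max_retries`` times before the point
    is declared invalid (raises RuntimeError).
    """
    theta = np.asarray(theta, float)
    y0 = _as_2d(simulate(theta))
    n_obs, n_t = y0.shape
    if scale is None:
        scale = np.abs(y0).max(axis=1)
    scale = np.maximum(np.asarray(scale, float), 1e-12)
    p = len(theta)
    s = np.empty((n_obs, n_t, p))
    for j in range(p):
        step = h
        for attempt in range(max_retries + 1):
            dp = step * abs(theta[j])
            if dp == 0.0:
                s[:, :, j] = 0.0
                break
            tp, tm = theta.copy(), theta.copy()
            tp[j] += dp
            tm[j] -= dp
            try:
                yp = _as_2d(simulate(tp))
                ym = _as_2d(simulate(tm))
            except Exception:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"simulation failed around component {j} after "
                        f"{max_retries} step halvings") from None
                step /= 2.0
                continue
            s[:, :, j] = (yp - ym) / (2.0 * dp) * theta[j] / scale[:, None]
            break
    return s, y0


def sobol_sample(lower: np.ndarray, upper: np.ndarray, n: int,
                 seed: int = 0, scramble: bool = True) -> np.ndarray:
    """Sobol low-discrepancy sample of the parameter box, shape (n, p)."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))
            and np.all(lower < upper)):
        raise ValueError("bounds must be finite with lower < upper")
    sampler = qmc.Sobol(d=len(lower), scramble=scramble, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two n
        u = sampler.random(n)
    return qmc.scale(u, lower, upper)


def dgsm_indices(simulate: Callable[[np.ndarray], np.ndarray],
                 lower: np.ndarray, upper: np.ndarray,
                 config: SensitivityConfig = SensitivityConfig(),
                 names: Sequence[str] | None = None) -> SensitivityReport:
    """DGSM influence indices of every parameter over the box [lower, upper]."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    p = len(lower)
    names = tuple(names) if names is not None else tuple(f"p{j}" for j in range(p))
    thetas = sobol_sample(lower, upper, config.n_samples,
                          seed=config.seed, scramble=config.scramble)
    per_sample = []
    n_invalid = 0
    for theta in thetas:
        try:
            s, y0 = relative_sensitivity(simulate, theta, h=config.h)
        except RuntimeError:
            n_invalid += 1
            continue
        if not np.all(np.isfinite(s)):
            n_invalid += 1
            continue
        if config.aggregation == "squared":
            g = (s ** 2).mean(axis=1)          # (n_obs, p): time RMS^2
        else:
            g = np.abs(s).mean(axis=1)
        w = (np.asarray(config.weights, float)
             if config.weights is not None else np.ones(g.shape[0]))
        per_sample.append(w @ g)
    if n_invalid > config.max_invalid_fraction * config.n_samples:
        raise RuntimeError(
            f"{n_invalid}/{config.n_samples} quasi-Monte-Carlo points failed "
            "to simulate: parameter bounds are likely improper")
    G = np.asarray(per_sample)                  # (K, p)
    nu = G.mean(axis=0)
    if config.aggregation == "squared":
        raw = np.sqrt(nu)
    else:
        raw = nu
    total = raw.sum()
    indices = raw / total if total > 0 else np.zeros(p)
    ranking = tuple(int(i) for i in np.argsort(-indices, kind="stable"))
    # convergence diagnostic: indices from each half of the sample
    half = len(G) // 2
    if half >= 1:
        def _norm(block):
            r = np.sqrt(block.mean(axis=0)) if config.aggregation == "squared" \
                else block.mean(axis=0)
            t = r.sum()
            return r / t if t > 0 else np.zeros(p)
        conv = float(np.abs(_norm(G[:half]) - _norm(G[half:])).max())
    else:
        conv = np.inf
    return SensitivityReport(names=names, indices=indices, nu=nu,
                             ranking=ranking, n_samples=len(G),
                             n_invalid=n_invalid, convergence=conv)
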