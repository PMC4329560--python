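"""Pseudo-global parameter correlation analysis for non-identifiability detection.

At each quasi-Monte-Carlo point of the parameter box a local Fisher
information matrix is built from the output sensitivities,
FIM = sum_t S_t^T Q S_t with Q the diagonal measurement-precision weighting;
its (pseudo-)inverse approximates the local estimator covariance.  The local
covariances are then averaged over the box with the objective-function value
at each point as the weight ("pseudo-global" covariance), converted to a
correlation matrix, and parameter pairs with |r| above a threshold are
flagged as practically non-identifiable.  Parameters flagged against two or
more partners are labelled "crossing".

Local FIMs of overparameterised biokinetic models are routinely singular;
the pseudo-inverse (singular values below 1e-10 of the largest truncated)
is therefore used instead of a plain inverse, and the per-sample condition
numbers are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .sensitivity import SensitivityConfig, relative_sensitivity, sobol_sample

__all__ = [
    "CorrelationReport",
    "local_fim",
    "local_covariance",
    "pseudo_global_covariance",
    "correlation_matrix",
    "detect_pairs",
    "pseudo_global_correlation",
]

SV_TRUNCATION = 1e-10


@dataclass
class CorrelationReport:
    """Pseudo-global covariance/correlation with flagged parameter pairs."""

    names: tuple[str, ...]
    covariance: np.ndarray
    correlation: np.ndarray
    pairs: tuple[tuple[int, int, float], ...]   # (i, j, r) with |r| > threshold
    crossing: tuple[int, ...]                   # parameters in >= 2 flagged pairs
    threshold: float
    condition_numbers: np.ndarray
    weights: np.ndarray
    zero_variance: tuple[int, ...] = ()

    def pair_names(self) -> tuple[tuple[str, str, float], ...]:
        return tuple((self.names[i], self.names[j], r) for i, j, r in self.pairs)

    def crossing_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.crossing)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.correlation, index=self.names, columns=self.names)


def local_fim(s: np.ndarray, q: np.ndarray | None = None) -> np.ndarray:
    """Fisher information from a sensitivity tensor.

    ``s`` has shape (n_obs, n_t, p) or (n_t, p); ``q`` holds the positive
    diagonal weights per observable (default 1).
    """
    s = np.asarray(s, float)
    if s.ndim == 2:
        s = s[None]
    if not np.all(np.isfinite(s)):
        raise ValueError("NaN/inf in sensitivity matrix: sample invalid")
    n_obs = s.shape[0]
    q = np.ones(n_obs) if q is None else np.asarray(q, float)
    if np.any(q <= 0):
        raise ValueError("weighting Q must be positive")
    fim = np.zeros((s.shape[2], s.shape[2]))
    for i in range(n_obs):
        Si = s[i]                    # (n_t, p)
        fim += q[i] * (Si.T @ Si)
    return 0.5 * (fim + fim.T)


def local_covariance(fim: np.ndarray) -> tuple[np.ndarray, float]:
    """Moore-Penrose pseudo-inverse of the FIM and its condition number.

    Singular values below ``1e-10 * sigma_max`` are truncated, so singular
    information matrices (structurally non-identifiable parameter sets)
    yield a well-defined covariance instead of an error.
    """
    fim = np.asarray(fim, float)
    if not np.allclose(fim, fim.T, atol=1e-8 * (1 + np.abs(fim).max())):
        raise ValueError("FIM must be symmetric")
    u, sv, vt = np.linalg.svd(0.5 * (fim + fim.T))
    if sv.size == 0 or sv[0] == 0.0:
        return np.zeros_like(fim), np.inf
    keep = sv > SV_TRUNCATION * sv[0]
    inv = np.zeros_like(sv)
    inv[keep] = 1.0 / sv[keep]
    cov = (vt.T * inv) @ u.T
    cond = float(sv[0] / sv[keep][-1]) if keep.any() else np.inf
    return 0.5 * (cov + cov.T), cond


def pseudo_global_covariance(covariances: Sequence[np.ndarray],
                             weights: Sequence[float]) -> np.ndarray:
    """Objective-value-weighted average of local covariance matrices."""
    covariances = [np.asarray(c, float) for c in covariances]
    if not covariances:
        raise ValueError("need at least one valid sample")
    w = np.asarray(weights, float)
    if w.shape != (len(covariances),):
        raise ValueError("one weight per covariance required")
    if np.all(w == 0):
        warnings.warn("all pseudo-global weights are zero; falling back to "
                      "uniform weighting", RuntimeWarning)
        w = np.ones_like(w)
    w = w / w.sum()
    out = np.zeros_like(covariances[0])
    for wk, ck in zip(w, covariances):
        out += wk * ck
    return out


def correlation_matrix(C: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Correlation R_jk = C_jk / sqrt(C_jj C_kk); returns (R, zero-variance rows).

    Zero-variance parameters get off-diagonal zeros and are reported so the
    caller can flag them.
    """
    C = np.asarray(C, float)
    d = np.diag(C).copy()
    if np.any(d < -1e-12):
        raise ValueError("covariance has negative diagonal entries")
    d = np.maximum(d, 0.0)
    zero = tuple(int(i) for i in np.nonzero(d == 0)[0])
    denom = np.sqrt(np.outer(d, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, C / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(R, 1.0)
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)
    return R, zero


def detect_pairs(R: np.ndarray, threshold: float = 0.95
                 ) -> tuple[tuple[tuple[int, int, float], ...], tuple[int, ...]]:
    """All unordered pairs with |R_jk| > threshold, plus "crossing" parameters.

    A parameter appearing in two or more flagged pairs is crossing (highly
    correlated with more than one partner).
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    pairs = []
    counts = np.zeros(p, int)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(R[i, j]) > threshold:
                pairs.append((i, j, float(R[i, j])))
                counts[i] += 1
                counts[j] += 1
    crossing = tuple(int(i) for i in np.nonzero(counts >= 2)[0])
    return tuple(pairs), crossing


def pseudo_global_correlation(
        simulate: Callable[[np.ndarray], np.ndarray],
        lower: np.ndarray, upper: np.ndarray,
        objective: Callable[[np.ndarray], float] | None = None,
        sigma: np.ndarray | None = None,
        config: SensitivityConfig = SensitivityConfig(n_samples=16),
        names: Sequence[str] | None = None,
        threshold: float = 0.95,
        weight_mode: str = "objective") -> CorrelationReport:
    """Full pipeline: QMC sampling, local FIM/covariance, weighted averaging.

    ``objective(theta)`` supplies the weighting of each sample (the literal
    reading of the averaging rule: w_k = J_k; ``weight_mode='likelihood'``
    uses exp(-J_k/2) instead, ``'uniform'`` ignores the objective).
    ``sigma`` holds per-observable measurement scales; default 5% of each
    observable's range at the box centre.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    p = len(lower)
    names = tuple(names) if names is not None else tuple(f"p{j}" for j in range(p))
    if weight_mode not in ("objective", "likelihood", "uniform"):
        raise ValueError("weight_mode must be objective|likelihood|uniform")

    center = 0.5 * (lower + upper)
    y_c = simulate(center)
    y_c = y_c[None, :] if y_c.ndim == 1 else y_c
    if sigma is None:
        span = y_c.max(axis=1) - y_c.min(axis=1)
        sigma = np.maximum(0.05 * span, 1e-6)
    sigma = np.asarray(sigma, float)

    thetas = sobol_sample(lower, upper, config.n_samples,
                          seed=config.seed, scramble=config.scramble)
    covs, weights, conds = [], [], []
    for theta in thetas:
        try:
            s, y0 = relative_sensitivity(simulate, theta, h=config.h)
        except RuntimeError:
            continue
        if not np.all(np.isfinite(s)):
            continue
        scale = np.maximum(np.abs(y0).max(axis=1), 1e-12)
        q = (scale / sigma) ** 2          # precision weighting of scaled sens.
        fim = local_fim(s, q)
        cov, cond = local_covariance(fim)
        if weight_mode == "uniform" or objective is None:
            w = 1.0
        else:
            J = float(objective(theta))
            w = np.exp(-J / 2.0) if weight_mode == "likelihood" else J
        covs.append(cov)
        weights.append(w)
        conds.append(cond)
    if not covs:
        raise RuntimeError("no valid quasi-Monte-Carlo sample: check bounds")
    C = pseudo_global_covariance(covs, weights)
    R, zero = correlation_matrix(C)
    pairs, crossing = detect_pairs(R, threshold)
    return CorrelationReport(names=names, covariance=C, correlation=R,
                             pairs=pairs, crossing=crossing, threshold=threshold,
                             condition_numbers=np.asarray(conds),
                             weights=np.asarray(weights), zero_variance=zero)
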