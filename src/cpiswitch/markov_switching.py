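"""Two-state Gaussian Markov-switching model for annualized inflation.

The observed inflation rate is modelled as

    pi_t = mu_{s_t} + eps_t,      eps_t ~ N(0, sigma_{s_t}^2),

where s_t is a latent first-order Markov chain over two regimes
("low inflation" s = 1, "high inflation" s = 2) with row-stochastic
transition matrix

    P = [[p11, 1 - p11],
         [1 - p22, p22]].

The likelihood is evaluated exactly by the Hamilton forward filter with
the chain initialized at its stationary distribution; full-sample regime
probabilities come from the Kim backward smoother.  Maximum likelihood
uses multi-start quasi-Newton optimization in a transformed space (logits
for the self-transition probabilities, logs for the regime standard
deviations) so the optimizer stays interior and the Hessian is usable for
standard errors.  Optional non-switching autoregressive terms enter as a
regime-dependent-intercept form in which the reported mu stays the regime
mean.

The expected sojourn time (persistence) of regime i is 1/(1 - p_ii)
months.  Model structure is summarized by AIC = -2l + 2k and
BIC = -2l + k ln(n).

The estimator class follows scikit-learn conventions (``fit``,
``predict``, trailing-underscore fitted attributes) and the module-level
functions are thin wrappers over it.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .series_io import InflationSeries

__all__ = [
    "ModelSpec",
    "ModelParams",
    "RegimeProbabilities",
    "FitResult",
    "StdErrors",
    "FitError",
    "FilterError",
    "MarkovSwitchingModel",
    "hamilton_filter",
    "brute_force_loglik",
    "brute_force_posteriors",
    "kim_smoother",
    "fit",
    "standard_errors",
    "expected_duration",
    "stationary_distribution",
    "information_criteria",
    "classify_regimes",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


class FilterError(ValueError):
    """The forward filter hit a non-finite density or invalid probability."""


class FitError(RuntimeError):
    """Maximum-likelihood estimation failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[list] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices: two regimes, variance switching, AR order."""

    n_states: int = 2
    switching_variance: bool = False
    ar_order: int = 0

    def __post_init__(self):
        if self.n_states != 2:
            raise ValueError("only the two-regime model is supported")
        if self.ar_order < 0:
            raise ValueError("ar_order must be >= 0")

    @property
    def n_params(self) -> int:
        """Free parameters: 2 means + 2 transitions + 1 or 2 sigmas + AR."""
        return 5 + int(self.switching_variance) + self.ar_order

    def describe(self) -> str:
        var = "switching" if self.switching_variance else "shared"
        return f"ar{self.ar_order}-{var}_variance"


@dataclass(frozen=True)
class ModelParams:
    """theta = (p11, p22, mu_1, mu_2, sigma_1, sigma_2, phi).

    ``sigma`` always holds one value per regime; under a shared-variance
    spec both entries are equal.  Canonical regime order puts the lower
    mean first (mu[0] < mu[1]), matching the "low inflation" label s = 1.
    """

    p11: float
    p22: float
    mu: tuple[float, float]
    sigma: tuple[float, float]
    phi: tuple[float, ...] = ()

    def __post_init__(self):
        if not (0.0 < self.p11 < 1.0 and 0.0 < self.p22 < 1.0):
            raise ValueError("self-transition probabilities must lie in (0, 1)")
        mu = tuple(float(m) for m in self.mu)
        sigma = tuple(float(s) for s in self.sigma)
        if len(mu) != 2:
            raise ValueError("mu must have one entry per regime")
        if len(sigma) == 1:
            sigma = (sigma[0], sigma[0])
        if len(sigma) != 2:
            raise ValueError("sigma must have one entry per regime (or one shared)")
        if any(s < 0 for s in sigma):
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "phi", tuple(float(p) for p in self.phi))

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array(
            [[self.p11, 1.0 - self.p11], [1.0 - self.p22, self.p22]], dtype=float
        )

    def swapped(self) -> "ModelParams":
        """Relabel the regimes (1 <-> 2)."""
        return ModelParams(
            p11=self.p22,
            p22=self.p11,
            mu=(self.mu[1], self.mu[0]),
            sigma=(self.sigma[1], self.sigma[0]),
            phi=self.phi,
        )

    def canonical(self) -> "ModelParams":
        """Order regimes so that mu[0] < mu[1] (low-inflation state first)."""
        return self.swapped() if self.mu[0] > self.mu[1] else self


@dataclass(frozen=True)
class RegimeProbabilities:
    """Per-month regime probability pairs from the filter/smoother.

    ``predicted[t]`` is P(s_t | y_{1..t-1}), ``filtered[t]`` is
    P(s_t | y_{1..t}), ``smoothed[t]`` (when present) is P(s_t | y_{1..T}).
    """

    predicted: np.ndarray
    filtered: np.ndarray
    smoothed: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("predicted", "filtered", "smoothed"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must be a (T, 2) array")
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > 1e-10:
                raise ValueError(f"{name} probability pairs must sum to 1")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.filtered)

    def to_frame(self, start_month=None) -> pd.DataFrame:
        """Tabulate regime-1 (low inflation) probabilities per month."""
        data = {
            "predicted_low": self.predicted[:, 0],
            "filtered_low": self.filtered[:, 0],
        }
        if self.smoothed is not None:
            data["smoothed_low"] = self.smoothed[:, 0]
        frame = pd.DataFrame(data)
        if start_month is not None:
            frame.insert(
                0,
                "date",
                pd.period_range(start_month, periods=len(frame), freq="M").astype(str),
            )
        return frame


@dataclass(frozen=True)
class StdErrors:
    """Standard errors on the natural scale, aligned with ModelParams."""

    p11: float
    p22: float
    mu: tuple[float, float]
    sigma: tuple[float, float]
    phi: tuple[float, ...]
    durations: tuple[float, float]
    kind: str = "robust"
    cov_transformed: Optional[np.ndarray] = None


@dataclass
class FitResult:
    """Everything the estimation produces for one product/series."""

    spec: ModelSpec
    params: ModelParams
    se: Optional[StdErrors]
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    probs: RegimeProbabilities
    durations: tuple[float, float]
    converged: bool
    warnings: list = field(default_factory=list)
    start_month: Optional[pd.Period] = None

    def to_dict(self) -> dict:
        se = self.se
        return {
            "spec": {
                "n_states": self.spec.n_states,
                "switching_variance": self.spec.switching_variance,
                "ar_order": self.spec.ar_order,
            },
            "params": {
                "p11": self.params.p11,
                "p22": self.params.p22,
                "mu": list(self.params.mu),
                "sigma": list(self.params.sigma),
                "phi": list(self.params.phi),
            },
            "se": None
            if se is None
            else {
                "kind": se.kind,
                "p11": se.p11,
                "p22": se.p22,
                "mu": list(se.mu),
                "sigma": list(se.sigma),
                "phi": list(se.phi),
                "durations": list(se.durations),
            },
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "durations": list(self.durations),
            "converged": self.converged,
            "warnings": list(self.warnings),
            "start_month": None if self.start_month is None else str(self.start_month),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------


def _pack(params: ModelParams, spec: ModelSpec) -> np.ndarray:
    """Natural -> unconstrained optimizer space."""
    x = [logit(params.p11), logit(params.p22), params.mu[0], params.mu[1],
         math.log(params.sigma[0])]
    if spec.switching_variance:
        x.append(math.log(params.sigma[1]))
    x.extend(params.phi[: spec.ar_order])
    return np.asarray(x, dtype=float)


def _unpack(x: np.ndarray, spec: ModelSpec) -> ModelParams:
    """Unconstrained optimizer space -> natural parameters."""
    p11 = float(expit(x[0]))
    p22 = float(expit(x[1]))
    mu = (float(x[2]), float(x[3]))
    s1 = float(math.exp(x[4]))
    if spec.switching_variance:
        s2 = float(math.exp(x[5]))
        k = 6
    else:
        s2 = s1
        k = 5
    phi = tuple(float(v) for v in x[k : k + spec.ar_order])
    return ModelParams(p11=p11, p22=p22, mu=mu, sigma=(s1, s2), phi=phi)


def _as_values(y) -> np.ndarray:
    vals = y.values if isinstance(y, InflationSeries) else np.asarray(y, dtype=float)
    vals = np.asarray(vals, dtype=float).ravel()
    if vals.size == 0 or not np.all(np.isfinite(vals)):
        raise ValueError("inflation input must be a non-empty finite 1-D array")
    return vals


def _conditional_means(y: np.ndarray, params: ModelParams, spec: ModelSpec) -> np.ndarray:
    """Per-month regime-conditional means, (T - ar_order, 2).

    With AR terms the model keeps mu as the regime *mean* via a
    regime-dependent intercept: m_t(s) = mu_s (1 - sum phi) + sum_j phi_j y_{t-j}.
    """
    r = spec.ar_order
    mu = np.asarray(params.mu)
    if r == 0:
        return np.broadcast_to(mu, (y.size, 2)).copy()
    phi = np.asarray(params.phi[:r])
    if phi.size != r:
        raise ValueError(f"ar_order={r} requires {r} AR coefficients, got {phi.size}")
    ar_part = np.zeros(y.size - r)
    for j in range(1, r + 1):
        ar_part += phi[j - 1] * y[r - j : y.size - j]
    return mu[None, :] * (1.0 - phi.sum()) + ar_part[:, None]


# ---------------------------------------------------------------------------
# filtering / smoothing / oracles
# ---------------------------------------------------------------------------


def stationary_distribution(p11: float, p22: float) -> tuple[float, float]:
    """Stationary distribution of the 2-state chain: pi P = pi.

    Returns (p21/(p12+p21), p12/(p12+p21)) with p12 = 1-p11, p21 = 1-p22.
    """
    for name, p in (("p11", p11), ("p22", p22)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    p12 = 1.0 - p11
    p21 = 1.0 - p22
    if p12 + p21 == 0.0:
        raise ValueError("p11 = p22 = 1 gives a reducible chain with no unique stationary law")
    return (p21 / (p12 + p21), p12 / (p12 + p21))


def _filter_loop_py(
    logdens: np.ndarray, P: np.ndarray, pi0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Sequential normalized forward recursion (pure-python fallback).

    Returns (predicted, filtered, contributions, fail_t); fail_t >= 0 marks
    the step at which the predictive density degenerated.
    """
    T = logdens.shape[0]
    predicted = np.empty((T, 2))
    filtered = np.empty((T, 2))
    contributions = np.empty(T)
    pred0, pred1 = pi0[0], pi0[1]
    for t in range(T):
        predicted[t, 0] = pred0
        predicted[t, 1] = pred1
        ld0 = logdens[t, 0]
        ld1 = logdens[t, 1]
        a = ld0 if ld0 > ld1 else ld1
        j0 = pred0 * math.exp(ld0 - a)
        j1 = pred1 * math.exp(ld1 - a)
        s = j0 + j1
        if not (s > 0.0) or not np.isfinite(s):
            return predicted, filtered, contributions, t
        contributions[t] = a + math.log(s)
        f0 = j0 / s
        f1 = j1 / s
        filtered[t, 0] = f0
        filtered[t, 1] = f1
        pred0 = f0 * P[0, 0] + f1 * P[1, 0]
        pred1 = f0 * P[0, 1] + f1 * P[1, 1]
    return predicted, filtered, contributions, -1


try:  # compiled inner loop; estimation calls it thousands of times
    from numba import njit as _njit

    _filter_loop = _njit(cache=False)(_filter_loop_py)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _filter_loop = _filter_loop_py


def _run_filter(y: np.ndarray, params: ModelParams, spec: ModelSpec) -> dict:
    """Normalized Hamilton recursion; log densities guard against underflow."""
    r = spec.ar_order
    if y.size <= r:
        raise ValueError(f"series of length {y.size} too short for ar_order={r}")
    sig = np.asarray(params.sigma)
    if np.any(sig <= 0):
        raise FilterError("regime standard deviations must be strictly positive")
    means = _conditional_means(y, params, spec)
    obs = y[r:]
    # (T, 2) log N(y_t | m_t(s), sigma_s)
    z = (obs[:, None] - means) / sig[None, :]
    logdens = -0.5 * (z * z) - np.log(sig)[None, :] - 0.5 * _LOG_2PI
    if not np.all(np.isfinite(logdens)):
        raise FilterError("non-finite emission density (sigma underflow?)")

    P = params.transition_matrix
    pi0 = np.array(stationary_distribution(params.p11, params.p22))
    predicted, filtered, contributions, fail_t = _filter_loop(logdens, P, pi0)
    if fail_t >= 0:
        raise FilterError(
            f"filter degenerated at step {fail_t}: zero predictive density"
        )
    return {
        "loglik": float(contributions.sum()),
        "predicted": predicted,
        "filtered": filtered,
        "contributions": contributions,
        "n_obs": obs.size,
    }


def hamilton_filter(
    y, params: ModelParams, spec: Optional[ModelSpec] = None
) -> tuple[float, RegimeProbabilities]:
    """Exact log marginal likelihood and one-pass regime probabilities.

    The chain starts from the stationary distribution of P; with AR terms
    the first ``ar_order`` observations condition the recursion and do not
    contribute to the likelihood.
    """
    spec = spec or ModelSpec(ar_order=len(params.phi))
    out = _run_filter(_as_values(y), params, spec)
    return out["loglik"], RegimeProbabilities(
        predicted=out["predicted"], filtered=out["filtered"]
    )


def kim_smoother(
    probs: RegimeProbabilities, params: ModelParams
) -> RegimeProbabilities:
    """Backward pass producing full-sample regime probabilities.

    smoothed_T = filtered_T; going backwards,
    smoothed_t = filtered_t * (P @ (smoothed_{t+1} / predicted_{t+1})).
    """
    P = params.transition_matrix
    filtered = probs.filtered
    predicted = probs.predicted
    T = filtered.shape[0]
    smoothed = np.empty_like(filtered)
    smoothed[-1] = filtered[-1]
    for t in range(T - 2, -1, -1):
        ratio = np.divide(
            smoothed[t + 1],
            predicted[t + 1],
            out=np.zeros(2),
            where=predicted[t + 1] > 0,
        )
        sm = filtered[t] * (P @ ratio)
        smoothed[t] = sm / sm.sum()
    return RegimeProbabilities(
        predicted=predicted, filtered=filtered, smoothed=smoothed
    )


_BRUTE_FORCE_MAX_T = 14


def _path_log_weights(
    y: np.ndarray, params: ModelParams, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Log posterior weight (up to the marginal) of every regime path."""
    r = spec.ar_order
    means = _conditional_means(y, params, spec)
    obs = y[r:]
    T = obs.size
    if T > _BRUTE_FORCE_MAX_T:
        raise ValueError(
            f"brute-force enumeration limited to {_BRUTE_FORCE_MAX_T} effective "
            f"observations (got {T})"
        )
    paths = np.array(list(itertools.product((0, 1), repeat=T)), dtype=int)
    pi0 = np.array(stationary_distribution(params.p11, params.p22))
    logP = np.log(params.transition_matrix)
    log_prior = np.log(pi0)[paths[:, 0]]
    for t in range(1, T):
        log_prior = log_prior + logP[paths[:, t - 1], paths[:, t]]
    sig = np.asarray(params.sigma)
    log_emis = norm.logpdf(
        obs[None, :], loc=means[np.arange(T)[None, :], paths], scale=sig[paths]
    ).sum(axis=1)
    return paths, log_prior + log_emis


def brute_force_loglik(y, params: ModelParams, spec: Optional[ModelSpec] = None) -> float:
    """Likelihood by explicit summation over all 2^T regime paths.

    Testing oracle, independent of the forward recursion; limited to short
    series.
    """
    spec = spec or ModelSpec(ar_order=len(params.phi))
    vals = _as_values(y)
    _, logw = _path_log_weights(vals, params, spec)
    return float(logsumexp(logw))


def brute_force_posteriors(y, params: ModelParams, spec: Optional[ModelSpec] = None) -> np.ndarray:
    """Per-month smoothed marginals P(s_t | y_{1..T}) by path enumeration."""
    spec = spec or ModelSpec(ar_order=len(params.phi))
    vals = _as_values(y)
    paths, logw = _path_log_weights(vals, params, spec)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    T = paths.shape[1]
    post = np.empty((T, 2))
    post[:, 1] = w @ paths
    post[:, 0] = 1.0 - post[:, 1]
    return post


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def expected_duration(p_stay: float) -> float:
    """Mean sojourn time in a regime, 1/(1 - p_stay) months."""
    if not (0.0 <= p_stay <= 1.0):
        raise ValueError(f"a probability is required, got {p_stay}")
    if p_stay == 1.0:
        raise ValueError("p_stay = 1 gives an infinite expected duration")
    return 1.0 / (1.0 - p_stay)


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2l + 2k and BIC = -2l + k ln(n)."""
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * math.log(n_obs)
    return aic, bic


def classify_regimes(
    probs: RegimeProbabilities,
    threshold: float = 0.5,
    start_month=None,
) -> tuple[np.ndarray, list]:
    """Label months and locate regime breaks from smoothed probabilities.

    A month is labelled high-inflation (2) when the smoothed probability of
    regime 2 strictly exceeds ``threshold``; otherwise low (1).  Breaks are
    the months at which the label changes, with direction "up" (into the
    high regime) or "down".
    """
    if probs.smoothed is None:
        raise ValueError("smoothed probabilities required; run kim_smoother first")
    labels = np.where(probs.smoothed[:, 1] > threshold, 2, 1)
    change = np.flatnonzero(np.diff(labels)) + 1
    months = (
        pd.period_range(start_month, periods=len(labels), freq="M")
        if start_month is not None
        else np.arange(len(labels))
    )
    breaks = [
        (months[i], "up" if labels[i] == 2 else "down") for i in change
    ]
    return labels, breaks


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------


def _numerical_gradient(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h * max(1.0, abs(x[i]))
        g[i] = (f(x + e) - f(x - e)) / (2 * e[i])
    return g


def _hessian_direct(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central second differences of f (one differentiation scheme)."""
    n = x.size
    H = np.empty((n, n))
    hs = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = hs[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / hs[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def _hessian_from_gradient(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Finite differences of the numerical gradient (independent scheme)."""
    n = x.size
    H = np.empty((n, n))
    hs = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        e = np.zeros(n)
        e[i] = hs[i]
        gp = _numerical_gradient(f, x + e)
        gm = _numerical_gradient(f, x - e)
        H[i] = (gp - gm) / (2 * hs[i])
    return 0.5 * (H + H.T)


def _natural_jacobian(x: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, int]:
    """Jacobian of [p11, p22, mu1, mu2, sigma(s), phi..., dur1, dur2] wrt x."""
    k = x.size
    p11 = float(expit(x[0]))
    p22 = float(expit(x[1]))
    n_sig = 2 if spec.switching_variance else 1
    n_nat = 4 + n_sig + spec.ar_order + 2
    J = np.zeros((n_nat, k))
    J[0, 0] = p11 * (1 - p11)
    J[1, 1] = p22 * (1 - p22)
    J[2, 2] = 1.0
    J[3, 3] = 1.0
    for s in range(n_sig):
        J[4 + s, 4 + s] = math.exp(x[4 + s])
    for a in range(spec.ar_order):
        J[4 + n_sig + a, 4 + n_sig + a] = 1.0
    # durations: d(1/(1-p))/dlogit(p) = p(1-p)/(1-p)^2 = p/(1-p)
    J[n_nat - 2, 0] = p11 / (1 - p11)
    J[n_nat - 1, 1] = p22 / (1 - p22)
    return J, n_sig


def standard_errors(
    y,
    params: ModelParams,
    spec: Optional[ModelSpec] = None,
    kind: Literal["hessian", "robust"] = "robust",
) -> StdErrors:
    """Delta-method standard errors at a (local) optimum.

    ``hessian`` inverts the negative Hessian of the log-likelihood;
    ``robust`` is the sandwich H^{-1} OPG H^{-1} combining the Hessian with
    the outer product of numerically differentiated per-observation scores.
    Errors are mapped from the transformed optimization space to the
    natural scale (including the expected durations) by the delta method.
    """
    spec = spec or ModelSpec(ar_order=len(params.phi))
    vals = _as_values(y)
    x = _pack(params, spec)

    def total(xv: np.ndarray) -> float:
        return _run_filter(vals, _unpack(xv, spec), spec)["loglik"]

    H = _hessian_direct(total, x)
    neg_H = -H
    cond = np.linalg.cond(neg_H)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "Hessian of the log-likelihood is singular or near-singular "
            f"(condition number {cond:.3g}); the regimes may not be identified. "
            "Consider adding a ridge, simplifying the spec, or re-fitting."
        )
    H_inv = np.linalg.inv(neg_H)
    if kind == "hessian":
        cov = H_inv
    elif kind == "robust":
        def contribs(xv: np.ndarray) -> np.ndarray:
            return _run_filter(vals, _unpack(xv, spec), spec)["contributions"]

        T = vals.size - spec.ar_order
        S = np.empty((T, x.size))
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = 1e-5 * max(1.0, abs(x[i]))
            S[:, i] = (contribs(x + e) - contribs(x - e)) / (2 * e[i])
        opg = S.T @ S
        cov = H_inv @ opg @ H_inv
    else:
        raise ValueError(f"unknown SE kind {kind!r}; use 'hessian' or 'robust'")

    J, n_sig = _natural_jacobian(x, spec)
    nat_var = np.diag(J @ cov @ J.T)
    if np.any(nat_var < -1e-8):
        warnings.warn("negative variance from the delta method; clipping to 0")
    nat_se = np.sqrt(np.clip(nat_var, 0.0, None))
    sig_se = tuple(nat_se[4 : 4 + n_sig])
    if n_sig == 1:
        sig_se = (sig_se[0], sig_se[0])
    off = 4 + n_sig
    return StdErrors(
        p11=float(nat_se[0]),
        p22=float(nat_se[1]),
        mu=(float(nat_se[2]), float(nat_se[3])),
        sigma=(float(sig_se[0]), float(sig_se[1])),
        phi=tuple(float(v) for v in nat_se[off : off + spec.ar_order]),
        durations=(float(nat_se[-2]), float(nat_se[-1])),
        kind=kind,
        cov_transformed=cov,
    )


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _start_points(
    y: np.ndarray, spec: ModelSpec, n_starts: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded multi-start grid: regime means at data quantiles, sticky chains.

    Base starts place (mu1, mu2) at the (25, 75) and (10, 90) percent
    quantiles with p_stay in {0.9, 0.95}; further starts are seeded
    perturbations of the base grid.
    """
    q10, q25, q75, q90 = np.quantile(y, [0.10, 0.25, 0.75, 0.90])
    sd = max(float(np.std(y)), 1e-4)
    base = []
    for mu_pair in ((q25, q75), (q10, q90)):
        for p_stay in (0.9, 0.95):
            params = ModelParams(
                p11=p_stay,
                p22=p_stay,
                mu=mu_pair if mu_pair[0] < mu_pair[1] else (mu_pair[0] - sd, mu_pair[1] + sd),
                sigma=(0.5 * sd, 0.5 * sd),
                phi=(0.0,) * spec.ar_order,
            )
            base.append(_pack(params, spec))
    starts = []
    for i in range(n_starts):
        x0 = base[i % len(base)].copy()
        if i >= len(base):
            x0 = x0 + rng.normal(scale=0.3, size=x0.size)
        starts.append(x0)
    return starts


class MarkovSwitchingModel(BaseEstimator):
    """Two-regime Gaussian Markov-switching mean (and variance) model.

    scikit-learn style estimator: construct with structural choices, call
    :meth:`fit` on a 1-D inflation series (decimal fractions), then read
    the trailing-underscore attributes or the bundled :attr:`result_`.

    Parameters
    ----------
    switching_variance : bool, default False
        Estimate a separate innovation standard deviation per regime.
    ar_order : int, default 0
        Number of non-switching autoregressive terms.  The default
        mean-only form is pi_t = mu_{s_t} + eps_t.
    n_starts : int, default 8
        Number of seeded optimizer starts (the likelihood is multimodal).
    se_kind : {"robust", "hessian", None}, default "robust"
        Standard-error flavour; None skips SE computation.
    sigma_floor : float, default 1e-6
        Lower bound on regime standard deviations during optimization,
        guarding against likelihood spikes at point masses.
    random_state : int or numpy Generator, optional
        Seeds the start-point perturbations.

    Attributes
    ----------
    params_ : ModelParams
        Canonically ordered (mu low < mu high) maximum-likelihood estimates.
    loglik_, aic_, bic_ : float
    probs_ : RegimeProbabilities
        Predicted, filtered and smoothed regime probabilities.
    durations_ : (float, float)
        Expected sojourn months per regime, 1/(1 - p_ii).
    se_ : StdErrors or None
    converged_ : bool
    result_ : FitResult
    """

    def __init__(
        self,
        switching_variance: bool = False,
        ar_order: int = 0,
        n_starts: int = 8,
        se_kind: Optional[str] = "robust",
        sigma_floor: float = 1e-6,
        random_state=None,
    ):
        self.switching_variance = switching_variance
        self.ar_order = ar_order
        self.n_starts = n_starts
        self.se_kind = se_kind
        self.sigma_floor = sigma_floor
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            switching_variance=self.switching_variance, ar_order=self.ar_order
        )

    def _bounds(self, spec: ModelSpec):
        bounds = [(-15.0, 15.0), (-15.0, 15.0), (None, None), (None, None)]
        n_sig = 2 if spec.switching_variance else 1
        bounds += [(math.log(self.sigma_floor), 10.0)] * n_sig
        bounds += [(-2.0, 2.0)] * spec.ar_order
        return bounds

    # -- estimation -------------------------------------------------------

    def fit(self, X, y=None):
        """Maximum-likelihood fit by multi-start L-BFGS-B.

        ``X`` is the inflation series (InflationSeries or 1-D array of
        decimal fractions); ``y`` is ignored (sklearn signature).
        """
        spec = self._spec()
        start_month = X.start_month + spec.ar_order if isinstance(X, InflationSeries) else None
        vals = _as_values(X)
        if vals.size < spec.ar_order + 6:
            raise ValueError(
                f"series of length {vals.size} is too short to identify the model"
            )
        if isinstance(self.random_state, np.random.Generator):
            rng = self.random_state
        else:
            rng = np.random.default_rng(self.random_state)
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

        def neg_loglik(x: np.ndarray) -> float:
            try:
                return -_run_filter(vals, _unpack(x, spec), spec)["loglik"]
            except FilterError:
                return 1e12

        diagnostics = []
        best = None
        for i, x0 in enumerate(_start_points(vals, spec, self.n_starts, rng)):
            res = optimize.minimize(
                neg_loglik,
                x0,
                method="L-BFGS-B",
                bounds=self._bounds(spec),
                options={"ftol": 1e-11, "gtol": 1e-6, "maxiter": 500},
            )
            grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
            ok = bool(res.success) or grad_norm < 1e-3
            diagnostics.append(
                {"start": i, "loglik": -float(res.fun), "converged": ok,
                 "message": str(res.message), "grad_norm": grad_norm}
            )
            logger.debug("start %d: loglik=%.6f converged=%s", i, -res.fun, ok)
            if ok and np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitError(
                "no optimizer start converged; see .diagnostics", diagnostics
            )

        x_hat = best.x
        params = _unpack(x_hat, spec).canonical()
        fit_warnings = []
        if any(s <= self.sigma_floor * (1 + 1e-6) for s in params.sigma):
            msg = (
                "a regime standard deviation hit its lower bound; the "
                "likelihood may be spiking around a point mass"
            )
            warnings.warn(msg)
            fit_warnings.append(msg)

        filt = _run_filter(vals, params, spec)
        probs = kim_smoother(
            RegimeProbabilities(predicted=filt["predicted"], filtered=filt["filtered"]),
            params,
        )
        loglik = filt["loglik"]
        n_obs = filt["n_obs"]
        aic, bic = information_criteria(loglik, spec.n_params, n_obs)
        durations = (expected_duration(params.p11), expected_duration(params.p22))

        se = None
        if self.se_kind is not None:
            try:
                se = standard_errors(vals, params, spec, kind=self.se_kind)
            except np.linalg.LinAlgError as exc:
                msg = f"standard errors unavailable: {exc}"
                warnings.warn(msg)
                fit_warnings.append(msg)

        self.spec_ = spec
        self.params_ = params
        self.se_ = se
        self.loglik_ = loglik
        self.aic_ = aic
        self.bic_ = bic
        self.n_obs_ = n_obs
        self.n_params_ = spec.n_params
        self.probs_ = probs
        self.durations_ = durations
        self.converged_ = True
        self.diagnostics_ = diagnostics
        self.result_ = FitResult(
            spec=spec,
            params=params,
            se=se,
            loglik=loglik,
            aic=aic,
            bic=bic,
            n_obs=n_obs,
            n_params=spec.n_params,
            probs=probs,
            durations=durations,
            converged=True,
            warnings=fit_warnings,
            start_month=start_month,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Smoothed regime probabilities for a series under the fitted params."""
        self._check_fitted()
        filt = _run_filter(_as_values(X), self.params_, self.spec_)
        probs = kim_smoother(
            RegimeProbabilities(predicted=filt["predicted"], filtered=filt["filtered"]),
            self.params_,
        )
        return probs.smoothed

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Regime labels (1 = low, 2 = high inflation) per month."""
        proba = self.predict_proba(X)
        return np.where(proba[:, 1] > threshold, 2, 1)

    def score(self, X, y=None) -> float:
        """Total log-likelihood of a series under the fitted parameters."""
        self._check_fitted()
        return _run_filter(_as_values(X), self.params_, self.spec_)["loglik"]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("this MarkovSwitchingModel instance is not fitted yet")


def fit(
    y,
    spec: Optional[ModelSpec] = None,
    starts: int = 8,
    seed: Optional[int] = None,
    se_kind: Optional[str] = "robust",
) -> FitResult:
    """Functional wrapper over :class:`MarkovSwitchingModel`."""
    spec = spec or ModelSpec()
    model = MarkovSwitchingModel(
        switching_variance=spec.switching_variance,
        ar_order=spec.ar_order,
        n_starts=starts,
        se_kind=se_kind,
        random_state=seed,
    )
    model.fit(y)
    return model.result_
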