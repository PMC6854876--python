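"""Structure selection: AR order and variance switching by AIC/BIC.

All candidate specifications are refit on an identical observation window
(the first ``max_ar`` inflation observations are reserved as lags for
every candidate), so their information criteria are comparable.  The
headline choice minimizes AIC or BIC among converged candidates; a
likelihood-ratio test for equality of the two regime variances is
reported as a diagnostic alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .markov_switching import (
    FitError,
    FitResult,
    MarkovSwitchingModel,
    ModelSpec,
    _as_values,
)
from .series_io import InflationSeries

__all__ = ["SelectionResult", "ModelSelector", "select_spec"]


@dataclass
class SelectionResult:
    """Outcome of fitting a family of candidate specifications."""

    candidates: list  # (ModelSpec, FitResult | None)
    best_aic: ModelSpec
    best_bic: ModelSpec
    variance_lr_stat: Optional[float] = None
    variance_lr_pvalue: Optional[float] = None

    def fit_for(self, spec: ModelSpec) -> FitResult:
        for s, f in self.candidates:
            if s == spec and f is not None:
                return f
        raise KeyError(f"no converged fit for {spec}")

    @property
    def best_bic_fit(self) -> FitResult:
        return self.fit_for(self.best_bic)

    @property
    def best_aic_fit(self) -> FitResult:
        return self.fit_for(self.best_aic)

    def table(self) -> pd.DataFrame:
        rows = []
        for spec, res in self.candidates:
            rows.append(
                {
                    "spec": spec.describe(),
                    "ar_order": spec.ar_order,
                    "switching_variance": spec.switching_variance,
                    "loglik": np.nan if res is None else res.loglik,
                    "k": spec.n_params,
                    "aic": np.nan if res is None else res.aic,
                    "bic": np.nan if res is None else res.bic,
                    "converged": res is not None and res.converged,
                }
            )
        return pd.DataFrame(rows)


class ModelSelector(BaseEstimator):
    """Grid of Markov-switching specs scored by information criteria.

    Parameters
    ----------
    max_ar : int, default 0
        Largest autoregressive order to consider.
    variance_options : {"shared", "switching", "both"}, default "both"
        Which variance structures enter the candidate grid.
    n_starts : int, default 8
        Optimizer starts per candidate.
    random_state : int, optional

    Attributes
    ----------
    selection_ : SelectionResult
    best_bic_, best_aic_ : ModelSpec
    best_estimator_ : fitted MarkovSwitchingModel for the BIC choice.
    """

    def __init__(
        self,
        max_ar: int = 0,
        variance_options: Literal["shared", "switching", "both"] = "both",
        n_starts: int = 8,
        random_state=None,
    ):
        self.max_ar = max_ar
        self.variance_options = variance_options
        self.n_starts = n_starts
        self.random_state = random_state

    def _variance_flags(self) -> list[bool]:
        opts = {"shared": [False], "switching": [True], "both": [False, True]}
        if self.variance_options not in opts:
            raise ValueError(
                "variance_options must be 'shared', 'switching' or 'both'"
            )
        return opts[self.variance_options]

    def fit(self, X, y=None):
        if self.max_ar < 0:
            raise ValueError("max_ar must be >= 0")
        vals = _as_values(X)
        start = X.start_month if isinstance(X, InflationSeries) else None

        candidates: list = []
        models: dict = {}
        rng = np.random.default_rng(self.random_state)
        for ar in range(self.max_ar + 1):
            for sv in self._variance_flags():
                spec = ModelSpec(switching_variance=sv, ar_order=ar)
                # common-sample rule: every candidate's likelihood covers
                # observations max_ar..T-1, so shorter-lag models drop the
                # unused leading points instead of scoring them
                sub = vals[self.max_ar - ar :]
                model = MarkovSwitchingModel(
                    switching_variance=sv,
                    ar_order=ar,
                    n_starts=self.n_starts,
                    se_kind=None,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                try:
                    model.fit(sub)
                    res = model.result_
                    if start is not None:
                        res.start_month = start + self.max_ar
                    candidates.append((spec, res))
                    models[spec] = model
                except (FitError, ValueError):
                    candidates.append((spec, None))

        converged = [(s, f) for s, f in candidates if f is not None]
        if not converged:
            raise FitError("no candidate specification converged")

        def argmin(key):
            return min(converged, key=lambda sf: (key(sf[1]), sf[0].n_params))[0]

        best_aic = argmin(lambda f: f.aic)
        best_bic = argmin(lambda f: f.bic)

        lr_stat = lr_p = None
        by_spec = dict(converged)
        shared = ModelSpec(switching_variance=False, ar_order=best_bic.ar_order)
        switching = ModelSpec(switching_variance=True, ar_order=best_bic.ar_order)
        if shared in by_spec and switching in by_spec:
            lr_stat = 2.0 * (by_spec[switching].loglik - by_spec[shared].loglik)
            lr_stat = max(lr_stat, 0.0)
            lr_p = float(stats.chi2.sf(lr_stat, df=1))

        self.selection_ = SelectionResult(
            candidates=candidates,
            best_aic=best_aic,
            best_bic=best_bic,
            variance_lr_stat=lr_stat,
            variance_lr_pvalue=lr_p,
        )
        self.best_aic_ = best_aic
        self.best_bic_ = best_bic
        self.best_estimator_ = models[best_bic]
        return self


def select_spec(
    y,
    max_ar: int = 0,
    variance_options: Literal["shared", "switching", "both"] = "both",
    starts: int = 8,
    seed: Optional[int] = None,
) -> SelectionResult:
    """Functional wrapper over :class:`ModelSelector`."""
    selector = ModelSelector(
        max_ar=max_ar,
        variance_options=variance_options,
        n_starts=starts,
        random_state=seed,
    )
    selector.fit(y)
    return selector.selection_
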