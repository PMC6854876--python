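"""Report assembly: estimate tables, regime probabilities, break dates.

Internal quantities stay as decimal fractions; percent formatting (two
decimals) happens only here, with an opt-in decimal-comma locale for
Spanish-style tables.  Significance stars follow the usual two-sided
z-test convention: * P < 0.1, ** P < 0.05, *** P < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .markov_switching import (
    FitError,
    FitResult,
    ModelSpec,
    classify_regimes,
    fit as _fit,
)
from .model_selection import select_spec
from .series_io import (
    CPISeries,
    DescriptiveStats,
    InflationSeries,
    annualized_inflation,
    descriptive_stats,
)

__all__ = [
    "ProductReport",
    "build_report",
    "significance_stars",
    "format_percent",
    "plot_report",
]


def significance_stars(estimate: float, se: float) -> str:
    """Stars from a two-sided z-test of H0: parameter = 0."""
    if se is None or not np.isfinite(se) or se <= 0:
        return ""
    p = 2.0 * norm.sf(abs(estimate) / se)
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def format_percent(x: float, decimals: int = 2, decimal_comma: bool = False) -> str:
    s = f"{100.0 * x:.{decimals}f}%"
    return s.replace(".", ",") if decimal_comma else s


def _fmt(x: float, decimals: int = 4, decimal_comma: bool = False) -> str:
    s = f"{x:.{decimals}f}"
    return s.replace(".", ",") if decimal_comma else s


@dataclass
class ProductReport:
    """All published-table-shaped outputs for one product."""

    product: str
    stats: Optional[DescriptiveStats]
    fit: Optional[FitResult]
    inflation: Optional[InflationSeries] = None
    labels: Optional[np.ndarray] = None
    breaks: list = field(default_factory=list)
    threshold: float = 0.5
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None and self.fit is not None

    def estimates_table(self, decimal_comma: bool = False) -> pd.DataFrame:
        """Regime means, sigmas, transitions and durations with stars/SEs."""
        if not self.ok:
            raise RuntimeError(f"report failed: {self.error}")
        f = self.fit
        p, se = f.params, f.se

        def cell(est, s):
            stars = significance_stars(est, s) if s is not None else ""
            return f"{_fmt(est, 4, decimal_comma)}{stars}"

        def se_cell(s):
            return "" if s is None or not np.isfinite(s) else f"({_fmt(s, 4, decimal_comma)})"

        rows = {
            "mu_low": cell(p.mu[0], se.mu[0] if se else None),
            "mu_low_se": se_cell(se.mu[0] if se else None),
            "mu_high": cell(p.mu[1], se.mu[1] if se else None),
            "mu_high_se": se_cell(se.mu[1] if se else None),
            "sigma": _fmt(p.sigma[0], 4, decimal_comma),
            "sigma_se": se_cell(se.sigma[0] if se else None),
        }
        if f.spec.switching_variance:
            rows["sigma_high"] = _fmt(p.sigma[1], 4, decimal_comma)
            rows["sigma_high_se"] = se_cell(se.sigma[1] if se else None)
        rows.update(
            {
                "p11": _fmt(p.p11, 4, decimal_comma),
                "p12": _fmt(1 - p.p11, 4, decimal_comma),
                "p12_se": se_cell(se.p11 if se else None),
                "p21": _fmt(1 - p.p22, 4, decimal_comma),
                "p22": _fmt(p.p22, 4, decimal_comma),
                "p22_se": se_cell(se.p22 if se else None),
                "duration_low": _fmt(f.durations[0], 4, decimal_comma),
                "duration_low_se": se_cell(se.durations[0] if se else None),
                "duration_high": _fmt(f.durations[1], 4, decimal_comma),
                "duration_high_se": se_cell(se.durations[1] if se else None),
                "loglik": _fmt(f.loglik, 4, decimal_comma),
                "aic": _fmt(f.aic, 4, decimal_comma),
                "bic": _fmt(f.bic, 4, decimal_comma),
            }
        )
        return pd.DataFrame({self.product: rows})

    def breaks_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"month": str(m), "direction": d} for m, d in self.breaks],
            columns=["month", "direction"],
        )

    def probabilities_frame(self) -> pd.DataFrame:
        if not self.ok:
            raise RuntimeError(f"report failed: {self.error}")
        return self.fit.probs.to_frame(start_month=self.fit.start_month)


def build_report(
    product: str,
    cpi: CPISeries,
    spec: Optional[ModelSpec] = None,
    select: bool = False,
    max_ar: int = 0,
    variance_options: str = "both",
    starts: int = 8,
    seed: Optional[int] = None,
    threshold: float = 0.5,
    se_kind: Optional[str] = "robust",
) -> ProductReport:
    """Run transform -> (optional selection) -> fit -> classify for one product.

    Estimation failures (e.g. a constant series) are surfaced as a report
    with ``error`` set rather than an exception.
    """
    try:
        infl = annualized_inflation(cpi)
        stats = descriptive_stats(infl)
    except ValueError as exc:
        return ProductReport(product=product, stats=None, fit=None, error=str(exc))

    try:
        if select:
            selection = select_spec(
                infl,
                max_ar=max_ar,
                variance_options=variance_options,
                starts=starts,
                seed=seed,
            )
            chosen = selection.best_bic
        else:
            chosen = spec or ModelSpec()
        result = _fit(infl, spec=chosen, starts=starts, seed=seed, se_kind=se_kind)
    except (FitError, ValueError) as exc:
        return ProductReport(
            product=product, stats=stats, fit=None, inflation=infl, error=str(exc)
        )

    labels, breaks = classify_regimes(
        result.probs, threshold=threshold, start_month=result.start_month
    )
    return ProductReport(
        product=product,
        stats=stats,
        fit=result,
        inflation=infl,
        labels=labels,
        breaks=breaks,
        threshold=threshold,
    )


def plot_report(report: ProductReport, path) -> None:
    """Two-panel figure: annualized inflation path on top, smoothed
    low-regime probability below.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not report.ok:
        raise RuntimeError(f"report failed: {report.error}")
    probs = report.fit.probs
    months = np.arange(len(probs))
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    infl = report.inflation.values[-len(probs) :]
    ax1.plot(months, 100.0 * infl)
    ax1.set_ylabel("annualized inflation (%)")
    ax1.set_title(report.product)
    ax2.plot(months, probs.smoothed[:, 0])
    ax2.set_ylim(-0.05, 1.05)
    ax2.set_ylabel("P(low-inflation regime)")
    ax2.set_xlabel("month")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
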