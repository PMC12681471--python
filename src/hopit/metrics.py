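"""Fit metrics and coefficient standardization for fitted models.

Covers the usual reporting surface for this model class: standardized
latent-health coefficients (rescaled so the fitted latent index spans
[0, 1] over the sample), the likelihood ratio (McFadden) index against
the intercept-only ordered probit, the share of correctly classified
levels (Count R2), and the AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import LatentDesign, ThresholdDesign
from .model import FittedHopit, category_probabilities, latent_index

__all__ = [
    "FitReport",
    "standardize_coefficients",
    "likelihood_ratio_index",
    "count_r2",
    "aic",
    "fit_report",
]


def standardize_coefficients(
    fit: FittedHopit, latent: LatentDesign
) -> np.ndarray:
    """Rescale latent slopes so the fitted index spans [0, 1].

    Computes h_i = x_i'beta over the observed sample and divides every
    slope by max(h) - min(h): after subtracting min(h) and rescaling, the
    worst observed profile sits at 1 and the best at 0 (or vice versa for
    a health-decrement coding). The range is taken over observed rows, not
    over all theoretically possible covariate combinations.
    """
    h = latent_index(fit.params, latent)
    span = float(h.max() - h.min())
    if span <= 0:
        raise ValueError("fitted latent index is degenerate (max == min)")
    return fit.params.beta / span


def likelihood_ratio_index(fit: FittedHopit, formula: str = "mcfadden") -> float:
    """Pseudo-R2 comparing the fitted and intercept-only log-likelihoods.

    ``"mcfadden"`` (default) returns 1 - lnL_full / lnL_null, which lies
    in [0, 1) for negative log-likelihoods and matches the magnitudes
    conventionally reported for this model family. ``"inverse_ratio"``
    returns 1 - lnL_null / lnL_full, the other reading of the same
    verbal definition; it is negative whenever the fitted model improves
    on the null.
    """
    if fit.loglik_null == 0:
        raise ValueError("null log-likelihood is zero; index undefined")
    if formula == "mcfadden":
        return 1.0 - fit.loglik / fit.loglik_null
    if formula == "inverse_ratio":
        return 1.0 - fit.loglik_null / fit.loglik
    raise ValueError(f"unknown formula {formula!r}")


def count_r2(
    fit: FittedHopit,
    latent: LatentDesign,
    threshold: ThresholdDesign,
    outcome: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted share of rows whose modal predicted level is observed.

    The predicted level is the argmax of the five category probabilities;
    exact ties resolve to the less severe level (ties have measure zero
    under continuous parameters).
    """
    outcome = np.asarray(outcome, dtype=int)
    n = outcome.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    probs = category_probabilities(fit.params, latent, threshold)
    predicted = np.argmax(probs, axis=1) + 1  # argmax takes first (lowest) on ties
    return float(w[predicted == outcome].sum() / w.sum())


def aic(fit: FittedHopit) -> float:
    """Akaike information criterion, 2k - 2 lnL with k the free-parameter
    count (latent slopes + 4 cut-point intercepts + 4 slope vectors)."""
    return 2.0 * fit.n_free - 2.0 * fit.loglik


@dataclass(frozen=True)
class FitReport:
    """One dimension's reporting block: standardized main-effect
    coefficients plus the fit battery."""

    dimension: str
    standardized_beta: pd.Series
    loglik: float
    aic: float
    lr_index: float
    count_r2: float


def fit_report(
    fit: FittedHopit,
    latent: LatentDesign,
    threshold: ThresholdDesign,
    outcome: np.ndarray,
    weights: np.ndarray | None = None,
) -> FitReport:
    std = standardize_coefficients(fit, latent)
    return FitReport(
        dimension=fit.dimension,
        standardized_beta=pd.Series(std, index=list(latent.column_names)),
        loglik=fit.loglik,
        aic=aic(fit),
        lr_index=likelihood_ratio_index(fit),
        count_r2=count_r2(fit, latent, threshold, outcome, weights),
    )


def report_table(reports: list[FitReport]) -> pd.DataFrame:
    """Wide table: rows = latent columns plus fit rows, columns = dimensions."""
    frame = pd.DataFrame(
        {r.dimension: r.standardized_beta for r in reports}
    )
    fit_rows = pd.DataFrame(
        {
            r.dimension: pd.Series(
                {
                    "Log-likelihood": r.loglik,
                    "AIC": r.aic,
                    "Likelihood ratio index": r.lr_index,
                    "Count R2": r.count_r2,
                }
            )
            for r in reports
        }
    )
    return pd.concat([frame, fit_rows])
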