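"""Whole-genome methylation-level score and its logistic calibration.

The ML-score of an embryo is the absolute deviation of its whole-genome
methylation level from the optimum level (0.26 by default), ``|ML - 0.26|``.
A binomial GLM (logistic regression of live birth on ML-score) converts the
score into an expected live-birth probability; with a negative slope, larger
deviations from the optimum mean lower birth probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["DEFAULT_OPTIMUM_ML", "GlmFit", "ml_score", "fit_outcome_glm",
           "predict_birth_probability"]

#: Whole-genome methylation level with the highest live-birth rate.  Imported
#: from prior clinical work, not estimated from data.
DEFAULT_OPTIMUM_ML = 0.26


def ml_score(ml, optimum: float = DEFAULT_OPTIMUM_ML):
    """Absolute deviation of a whole-genome methylation level from the optimum.

    Accepts a scalar or array of levels in [0, 1]; returns ``|ml - optimum|``.
    """
    arr = np.asarray(ml, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("methylation level outside [0, 1]")
    out = np.abs(arr - optimum)
    return float(out) if np.isscalar(ml) else out


@dataclass(frozen=True)
class GlmFit:
    """Fitted binomial GLM of live birth on ML-score."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    converged: bool
    cov_params: np.ndarray  # 2x2 covariance, order (intercept, slope)
    n: int

    def linear_predictor(self, scores):
        return self.intercept + self.slope * np.asarray(scores, dtype=float)


def fit_outcome_glm(scores, outcomes) -> GlmFit:
    """Fit the logistic model ``outcome ~ ml_score`` by maximum likelihood.

    ``outcomes`` are coded 1 for live birth and 0 for failure; both classes
    must be present and n >= 10.  Non-convergence is reported in the
    returned fit, never silently ignored.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have the same length")
    if s.size < 10:
        raise ValueError("at least 10 embryos are required for the GLM")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")

    X = sm.add_constant(s)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit()
    if not res.converged:
        raise RuntimeError("binomial GLM did not converge")
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    return GlmFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        se_intercept=float(bse[0]),
        se_slope=float(bse[1]),
        converged=bool(res.converged),
        cov_params=np.asarray(res.cov_params()),
        n=int(s.size),
    )


def predict_birth_probability(fit: GlmFit, scores) -> pd.DataFrame:
    """Predicted birth probability with delta-method standard errors.

    Returns one row per grid point with columns ``ml_score``, ``prob``,
    ``se`` and the reporting band ``band_low``/``band_high`` (prob -/+ 1 SE,
    with any band value below 0 clipped to 0; the predictions themselves lie
    in (0, 1) by construction of the inverse logit).
    """
    if not fit.converged:
        raise ValueError("cannot predict from an unconverged fit")
    s = np.atleast_1d(np.asarray(scores, dtype=float))
    eta = fit.linear_predictor(s)
    prob = 1.0 / (1.0 + np.exp(-eta))
    X = np.column_stack([np.ones_like(s), s])
    var_eta = np.einsum("ij,jk,ik->i", X, fit.cov_params, X)
    se = prob * (1.0 - prob) * np.sqrt(var_eta)
    return pd.DataFrame({
        "ml_score": s,
        "prob": prob,
        "se": se,
        "band_low": np.clip(prob - se, 0.0, None),
        "band_high": prob + se,
    })
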