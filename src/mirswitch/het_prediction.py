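"""Predict the heterozygote reporter-ratio distribution from wild type.

Halving the miRNA gene dosage shifts both stable miRNA levels of the
bistable feedback loop.  The prediction pipeline:

1. fit the wild-type ratio sample with the two-component log-normal
   mixture (high-/low-activity states);
2. map each component median through the inverted reporter calibration to
   a miRNA level;
3. scale each level by the ratio of stable fixed-point miRNA levels at
   dosage 0.5 versus dosage 1 from the feedback model (high-activity
   state -> high-miRNA branch, low-activity state -> low-miRNA branch);
4. map the scaled levels back through the calibration to ratio space,
   keeping the wild-type component log-widths (medians commute exactly
   with the monotone calibration; for a near-unit Hill coefficient the
   width distortion is second order);
5. fit only the two component weights (state occupancies) to the observed
   heterozygote sample by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import ks_1samp

from .bistability_model import FeedbackParams, find_fixed_points
from .errors import InvalidInputError, ModelInapplicableError
from .reporter_model import ReporterCalibration, hill_response, invert_response
from .state_mixture import LogNormalMixture, fit_two_lognormal

__all__ = ["HetPrediction", "predict_het_distribution", "compare_distributions",
           "dosage_scale_factors"]


@dataclass(frozen=True)
class HetPrediction:
    """Predicted heterozygote mixture with fitted state occupancies."""

    wt_mixture: LogNormalMixture
    scale_high: float          # het/wt stable miRNA level, high-miRNA branch
    scale_low: float           # het/wt stable miRNA level, low-miRNA branch
    predicted_mixture: LogNormalMixture
    fitted_weights: tuple      # (w_high_activity, w_low_activity)
    goodness: float            # log-likelihood of the het sample


def _stable_X(params: FeedbackParams) -> tuple[float, float]:
    """(low-branch X, high-branch X) of a bistable parameter set."""
    stable = [p for p in find_fixed_points(params) if p.stable]
    if len(stable) != 2:
        raise ModelInapplicableError(
            f"feedback model is not bistable at dosage {params.dosage} "
            f"(found {len(stable)} stable point(s)); the two-state prediction needs two branches"
        )
    return stable[0].X, stable[-1].X


def dosage_scale_factors(params: FeedbackParams) -> tuple[float, float]:
    """Per-branch ratio of heterozygote to wild-type stable miRNA levels.

    Returns (scale_high, scale_low) for the high-miRNA and low-miRNA
    branches; M = alpha K_1 X with shared alpha, so the ratio of stable X
    values at dosage 0.5 versus dosage 1 is the miRNA-level ratio.
    """
    wt = replace(params, dosage=1.0)
    het = replace(params, dosage=0.5)
    x_low_wt, x_high_wt = _stable_X(wt)
    x_low_het, x_high_het = _stable_X(het)
    scale_high = x_high_het / x_high_wt
    scale_low = x_low_het / x_low_wt
    if not (0.0 < scale_high <= 1.0 + 1e-12 and 0.0 < scale_low <= 1.0 + 1e-12):
        raise ModelInapplicableError(
            "dosage reduction produced a scale factor outside (0, 1]"
        )
    return min(scale_high, 1.0), min(scale_low, 1.0)


def _fit_weights(mixture: LogNormalMixture, ratios: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood fit of the two component weights only."""
    x = np.log(ratios)
    from scipy.stats import norm

    lp_high = norm.logpdf(x, mixture.mu_high, mixture.sigma_high)
    lp_low = norm.logpdf(x, mixture.mu_low, mixture.sigma_low)

    def nll(w: float) -> float:
        return -float(np.sum(np.logaddexp(np.log(w) + lp_high, np.log1p(-w) + lp_low)))

    res = minimize_scalar(nll, bounds=(1e-6, 1 - 1e-6), method="bounded",
                          options={"xatol": 1e-10})
    w = float(res.x)
    return w, 1.0 - w


def predict_het_distribution(wt_ratios, het_ratios, calib: ReporterCalibration,
                             params: FeedbackParams, rng=None) -> HetPrediction:
    """Full prediction pipeline; only the state occupancies are fitted.

    ``wt_ratios`` and ``het_ratios`` are positive reporter-ratio samples;
    ``calib`` the reporter calibration; ``params`` a parameter set that is
    bistable at both dosage 1 and dosage 0.5.
    """
    wt = np.asarray(wt_ratios, dtype=float)
    het = np.asarray(het_ratios, dtype=float)
    if np.any(wt <= 0) or np.any(het <= 0):
        raise InvalidInputError("ratios must be positive")

    wt_mix = fit_two_lognormal(wt, rng=rng)
    scale_high, scale_low = dosage_scale_factors(params)

    # high-activity component (low ratio) = high-miRNA branch
    med_high_act, med_low_act = wt_mix.medians
    med_high_act = min(med_high_act, calib.r0 * (1 - 1e-12))
    med_low_act = min(med_low_act, calib.r0 * (1 - 1e-12))
    m_high = invert_response(calib, med_high_act) * scale_high
    m_low = invert_response(calib, med_low_act) * scale_low
    new_med_high_act = hill_response(calib, m_high)
    new_med_low_act = hill_response(calib, m_low)

    predicted = LogNormalMixture(
        w_high=wt_mix.w_high, w_low=wt_mix.w_low,
        mu_high=float(np.log(new_med_high_act)),
        mu_low=float(np.log(new_med_low_act)),
        sigma_high=wt_mix.sigma_high, sigma_low=wt_mix.sigma_low,
    )
    w_high, w_low = _fit_weights(predicted, het)
    fitted = LogNormalMixture(
        w_high=w_high, w_low=w_low,
        mu_high=predicted.mu_high, mu_low=predicted.mu_low,
        sigma_high=predicted.sigma_high, sigma_low=predicted.sigma_low,
    )
    goodness = float(np.sum(fitted.log_pdf(het)))
    return HetPrediction(
        wt_mixture=wt_mix,
        scale_high=scale_high,
        scale_low=scale_low,
        predicted_mixture=fitted,
        fitted_weights=(w_high, w_low),
        goodness=goodness,
    )


def compare_distributions(predicted: LogNormalMixture, observed) -> dict:
    """Goodness report: per-observation log-likelihood and a one-sample
    Kolmogorov-Smirnov test of the observations against the mixture CDF."""
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise InvalidInputError("observed sample must be non-empty")
    ll = float(np.mean(predicted.log_pdf(obs)))
    if obs.size >= 2:
        ks = ks_1samp(obs, predicted.cdf)
        stat, pval = float(ks.statistic), float(ks.pvalue)
        low_power = obs.size < 20
    else:
        stat = float(abs(predicted.cdf(obs[0]) - 0.5) + 0.5)
        pval = float("nan")
        low_power = True
    return {
        "log_likelihood_per_obs": ll,
        "ks_statistic": stat,
        "ks_pvalue": pval,
        "n": int(obs.size),
        "low_power": low_power,
    }
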