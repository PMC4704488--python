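"""Two-state decomposition of reporter-ratio distributions.

Reporter ratios across single cells are bimodal: a low-ratio mode (high
miRNA activity) and a high-ratio mode (low miRNA activity), each well
described by a log-normal.  This module fits the two-component log-normal
mixture by EM on log-ratios, gates single cells by posterior membership,
standardizes ratios to z-scores, and deconvolves dye-dilution intensity
histograms into division cycles (a Gaussian mixture whose component means
are pinned ln 2 apart, one two-fold dye dilution per division).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "LogNormalMixture",
    "GateResult",
    "DivisionCycleMixture",
    "fit_two_lognormal",
    "gate_cells",
    "ratio_zscore",
    "fit_division_cycles",
]

LN2 = float(np.log(2.0))

# EM convergence: per-observation log-likelihood increase below this stops.
EM_TOL_PER_OBS = 1e-8
EM_MAX_ITER = 2000
EM_N_RESTARTS = 5
MIN_OBS_MIXTURE = 50
MIN_OBS_DYE = 100


@dataclass(frozen=True)
class LogNormalMixture:
    """Two-component log-normal mixture over reporter ratios.

    Component ``high_activity`` (index 0) has the *smaller* log-ratio
    location: high miRNA activity represses the detector, so those cells sit
    at low reporter ratios.  Locations/scales are natural-log based.
    """

    w_high: float
    w_low: float
    mu_high: float
    mu_low: float
    sigma_high: float
    sigma_low: float
    log_likelihood: float | None = field(default=None, compare=False)
    effectively_unimodal: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.w_high + self.w_low, 1.0, atol=1e-9):
            raise InvalidInputError("mixture weights must sum to 1")
        if not (0.0 <= self.w_high <= 1.0 and 0.0 <= self.w_low <= 1.0):
            raise InvalidInputError("mixture weights must lie in [0, 1]")
        if not (self.sigma_high > 0 and self.sigma_low > 0):
            raise InvalidInputError("mixture sigmas must be positive")
        if self.mu_high > self.mu_low:
            raise InvalidInputError(
                "high_activity component must have the smaller location "
                "(high activity means low reporter ratio)"
            )

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_high, self.w_low])

    @property
    def mus(self) -> np.ndarray:
        return np.array([self.mu_high, self.mu_low])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_high, self.sigma_low])

    @property
    def medians(self) -> np.ndarray:
        """Component medians in ratio space (exp of locations)."""
        return np.exp(self.mus)

    def log_pdf(self, ratios) -> np.ndarray:
        """Mixture log-density over positive ratios (includes the 1/r Jacobian)."""
        r = np.asarray(ratios, dtype=float)
        if np.any(r <= 0):
            raise InvalidInputError("ratios must be positive")
        x = np.log(r)
        comp = (
            np.log(self.weights)[:, None]
            + norm.logpdf(x[None, :], self.mus[:, None], self.sigmas[:, None])
        )
        return logsumexp(comp, axis=0) - x

    def cdf(self, ratios) -> np.ndarray:
        """Mixture CDF over ratios."""
        r = np.asarray(ratios, dtype=float)
        x = np.log(np.maximum(r, np.finfo(float).tiny))
        out = sum(
            w * norm.cdf(x, mu, s)
            for w, mu, s in zip(self.weights, self.mus, self.sigmas)
        )
        out = np.where(r <= 0, 0.0, out)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "w_high": self.w_high,
            "w_low": self.w_low,
            "mu_high": self.mu_high,
            "mu_low": self.mu_low,
            "sigma_high": self.sigma_high,
            "sigma_low": self.sigma_low,
            "log_likelihood": self.log_likelihood,
            "effectively_unimodal": self.effectively_unimodal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogNormalMixture":
        return cls(
            w_high=float(d["w_high"]),
            w_low=float(d["w_low"]),
            mu_high=float(d["mu_high"]),
            mu_low=float(d["mu_low"]),
            sigma_high=float(d["sigma_high"]),
            sigma_low=float(d["sigma_low"]),
            log_likelihood=d.get("log_likelihood"),
            effectively_unimodal=bool(d.get("effectively_unimodal", False)),
        )


@dataclass(frozen=True)
class GateResult:
    """Per-cell state assignment from a fitted mixture.

    ``threshold`` is the ratio at which the two posterior memberships are
    equal (the 0.5/0.5 point); it lies strictly between the component
    medians.  ``labels`` are the posterior argmax ('high'/'low' activity),
    ``posterior_high`` the soft membership of the high-activity component.
    ``fraction_high`` is the mean posterior (soft state fraction) with a
    binomial standard error.
    """

    threshold: float
    labels: np.ndarray
    posterior_high: np.ndarray
    fraction_high: float
    fraction_high_se: float


@dataclass(frozen=True)
class DivisionCycleMixture:
    """Gaussian mixture over log dye intensity with division-locked means.

    Component d (d = 0..D divisions) has mean ``mu0 - d*ln 2`` — the dye
    halves at every division — and all components share one sigma.
    """

    mu0: float
    sigma: float
    weights: np.ndarray
    log_likelihood: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise InvalidInputError("division-cycle weights must sum to 1")
        if self.sigma <= 0:
            raise InvalidInputError("sigma must be positive")
        object.__setattr__(self, "weights", w)

    @property
    def means(self) -> np.ndarray:
        return self.mu0 - np.arange(len(self.weights)) * LN2

    @property
    def mean_divisions(self) -> float:
        """Weight-averaged division count of the population."""
        return float(np.dot(self.weights, np.arange(len(self.weights))))


# ---------------------------------------------------------------------------
# two-component EM on log-ratios


def _em_two_gaussian(x: np.ndarray, mu_init: np.ndarray, sigma_init: np.ndarray,
                     w_init: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Plain EM for a two-component 1-D Gaussian mixture.

    Asserts the log-likelihood never decreases across iterations (up to a
    tiny numerical slack) — a defining property of EM used as an internal
    sanity check.
    """
    mu, sigma, w = mu_init.copy(), sigma_init.copy(), w_init.copy()
    n = x.size
    prev_ll = -np.inf
    sigma_floor = max(1e-6, 1e-3 * np.std(x))
    for _ in range(EM_MAX_ITER):
        log_comp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sigma[:, None])
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        assert ll >= prev_ll - 1e-7 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        resp = np.exp(log_comp - log_norm[None, :])
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = np.einsum("kn,kn->k", resp, (x[None, :] - mu[:, None]) ** 2) / nk
        sigma = np.sqrt(np.maximum(var, sigma_floor**2))
        if ll - prev_ll < EM_TOL_PER_OBS * n and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    return mu, sigma, w, prev_ll


def fit_two_lognormal(ratios, rng=None) -> LogNormalMixture:
    """Fit the two-component log-normal mixture to positive ratios by EM.

    Initialization is a median split of log-ratios; 4 additional seeded
    random restarts are run and the best log-likelihood kept.  Components
    are returned ordered so that ``high_activity`` has the smaller location.
    If the two fitted locations are closer than a quarter of the pooled
    sigma the result is flagged ``effectively_unimodal``.

    Parameters
    ----------
    ratios : positive sequence, at least 50 observations.
    rng : RandomSpec, numpy Generator, int seed, or None
        Drives the random restarts only; the median-split restart makes the
        default fit deterministic for fixed input.
    """
    from .synthetic_data import as_generator

    r = np.asarray(ratios, dtype=float)
    if r.size < MIN_OBS_MIXTURE:
        raise InsufficientDataError(
            f"need at least {MIN_OBS_MIXTURE} observations to fit a mixture, got {r.size}"
        )
    if np.any(r <= 0):
        raise InvalidInputError("ratios must be positive")
    x = np.log(r)
    if np.ptp(x) == 0:
        raise DegenerateInputError("all ratios identical")

    gen = as_generator(rng, stream_id="fit_two_lognormal")
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    sd_all = np.std(x)

    starts = [(
        np.array([lo.mean(), hi.mean() if hi.size else lo.mean() + sd_all]),
        np.array([max(lo.std(), 1e-3 * sd_all + 1e-9),
                  max(hi.std() if hi.size else sd_all, 1e-3 * sd_all + 1e-9)]),
        np.array([0.5, 0.5]),
    )]
    for _ in range(EM_N_RESTARTS - 1):
        mu0 = np.sort(gen.choice(x, size=2, replace=False))
        starts.append((mu0, np.array([sd_all, sd_all]) * 0.5 + 1e-9, np.array([0.5, 0.5])))

    best = None
    for mu_i, sg_i, w_i in starts:
        mu, sg, w, ll = _em_two_gaussian(x, mu_i, sg_i, w_i)
        if best is None or ll > best[3]:
            best = (mu, sg, w, ll)

    mu, sg, w, ll = best
    order = np.argsort(mu)  # smaller location first = high activity
    mu, sg, w = mu[order], sg[order], w[order]
    unimodal = _is_effectively_unimodal(w, mu, sg)
    return LogNormalMixture(
        w_high=float(w[0]), w_low=float(w[1]),
        mu_high=float(mu[0]), mu_low=float(mu[1]),
        sigma_high=float(sg[0]), sigma_low=float(sg[1]),
        log_likelihood=ll, effectively_unimodal=bool(unimodal),
    )


def _is_effectively_unimodal(w: np.ndarray, mu: np.ndarray, sg: np.ndarray) -> bool:
    """True when the fitted two-component density has no dip between the
    component locations, i.e. the mixture fails to resolve two modes."""
    if mu[1] - mu[0] < 1e-12:
        return True
    grid = np.linspace(mu[0], mu[1], 512)
    pdf = (w[0] / sg[0] * np.exp(-0.5 * ((grid - mu[0]) / sg[0]) ** 2)
           + w[1] / sg[1] * np.exp(-0.5 * ((grid - mu[1]) / sg[1]) ** 2))
    interior = pdf[1:-1]
    has_dip = np.any((interior < pdf[:-2]) & (interior < pdf[2:]))
    return not has_dip


def gate_threshold(mixture: LogNormalMixture) -> float:
    """Ratio at which the two posterior memberships are equal.

    Solves w_h N(t; mu_h, s_h) = w_l N(t; mu_l, s_l) for t = log(ratio) —
    a quadratic in t — and returns exp of the root between the component
    locations (for equal weights and sigmas this is the geometric mean of
    the component medians).
    """
    w1, w2 = mixture.w_high, mixture.w_low
    m1, m2 = mixture.mu_high, mixture.mu_low
    s1, s2 = mixture.sigma_high, mixture.sigma_low
    if w1 == 0.0 or w2 == 0.0:
        # degenerate gate: all mass in one component; use midpoint
        return float(np.exp(0.5 * (m1 + m2)))
    c = np.log(w1 / s1) - np.log(w2 / s2)
    # (t-m1)^2/(2 s1^2) - (t-m2)^2/(2 s2^2) = c
    a = 0.5 * (1 / s1**2 - 1 / s2**2)
    b = -(m1 / s1**2 - m2 / s2**2)
    d = 0.5 * (m1**2 / s1**2 - m2**2 / s2**2) - c
    if abs(a) < 1e-14:
        t = -d / b
    else:
        disc = b**2 - 4 * a * d
        if disc < 0:
            t = 0.5 * (m1 + m2)
        else:
            roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
            inside = roots[(roots > m1) & (roots < m2)]
            t = float(inside[0]) if inside.size else float(
                roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))]
            )
    return float(np.exp(t))


def gate_cells(mixture: LogNormalMixture, ratios) -> GateResult:
    """Assign cells to high/low activity states by posterior membership."""
    r = np.asarray(ratios, dtype=float)
    if np.any(r <= 0):
        raise InvalidInputError("ratios must be positive")
    x = np.log(r)
    log_comp = (
        np.log(np.maximum(mixture.weights, np.finfo(float).tiny))[:, None]
        + norm.logpdf(x[None, :], mixture.mus[:, None], mixture.sigmas[:, None])
    )
    log_norm = logsumexp(log_comp, axis=0)
    post_high = np.exp(log_comp[0] - log_norm)
    labels = np.where(post_high >= 0.5, "high", "low")
    f = float(post_high.mean())
    se = float(np.sqrt(max(f * (1 - f), 0.0) / r.size))
    return GateResult(
        threshold=gate_threshold(mixture),
        labels=labels,
        posterior_high=post_high,
        fraction_high=f,
        fraction_high_se=se,
    )


def ratio_zscore(ratios) -> np.ndarray:
    """Standardize log-ratios: z = (log r - mean) / population SD."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise InsufficientDataError("need at least 2 cells for a z-score")
    if np.any(r <= 0):
        raise InvalidInputError("ratios must be positive")
    x = np.log(r)
    sd = np.std(x)  # population SD, ddof=0: deterministic image-wide normalization
    if sd == 0:
        raise DegenerateInputError("zero variance: z-scores undefined")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# dye-dilution division-cycle deconvolution


def fit_division_cycles(log_intensities, max_divisions: int, rng=None,
                        mu0: float | None = None) -> DivisionCycleMixture:
    """Deconvolve a log dye-intensity sample into division-cycle components.

    Constrained EM for a Gaussian mixture whose component d has mean
    ``mu0 - d*ln 2`` (one two-fold dilution per division) and a sigma shared
    by all components; free parameters are the weights, sigma, and — unless
    anchored — mu0.

    The absolute division count is only identifiable when the undivided-peak
    location is known (in practice from the day-0 staining measurement):
    pass it as ``mu0`` to anchor the ladder.  With ``mu0`` free, the fit is
    normalized so that the brightest occupied cycle is labeled division 0,
    i.e. counts are relative to the least-divided cells observed.

    Parameters
    ----------
    log_intensities : sequence, natural-log fluorescence, >= 100 observations.
    max_divisions : int >= 1, highest division cycle modeled (components 0..max).
    mu0 : optional known log-intensity of undivided cells; fixed during EM
        when given.
    """
    x = np.asarray(log_intensities, dtype=float)
    if max_divisions < 1:
        raise InvalidInputError("max_divisions must be >= 1")
    if x.size < MIN_OBS_DYE:
        raise InsufficientDataError(
            f"need at least {MIN_OBS_DYE} observations, got {x.size}"
        )

    D = int(max_divisions)
    d_idx = np.arange(D + 1, dtype=float)
    fixed_mu0 = mu0 is not None
    mu0 = float(np.quantile(x, 0.995)) if mu0 is None else float(mu0)
    sigma = max(float(np.std(x)) / max(D, 1), 1e-3)
    w = np.full(D + 1, 1.0 / (D + 1))

    prev_ll = -np.inf
    n = x.size
    for _ in range(EM_MAX_ITER):
        means = mu0 - d_idx * LN2
        log_comp = np.log(np.maximum(w, 1e-300))[:, None] + norm.logpdf(
            x[None, :], means[:, None], sigma
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        assert ll >= prev_ll - 1e-7 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        resp = np.exp(log_comp - log_norm[None, :])
        nk = np.maximum(resp.sum(axis=1), 1e-12)
        w = nk / n
        if not fixed_mu0:
            # shared-mu0 update: each point votes for x_i + d*ln2
            mu0 = float(np.einsum("kn,kn->", resp,
                                  x[None, :] + (d_idx * LN2)[:, None]) / n)
        means = mu0 - d_idx * LN2
        var = np.einsum("kn,kn->", resp, (x[None, :] - means[:, None]) ** 2) / n
        sigma = float(np.sqrt(max(var, 1e-10)))
        if ll - prev_ll < EM_TOL_PER_OBS * n and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll

    if not fixed_mu0:
        # canonical labeling: drop leading empty cycles so the brightest
        # occupied component is division 0
        occupied = np.nonzero(w > 1e-6)[0]
        shift = int(occupied[0]) if occupied.size else 0
        if shift:
            mu0 -= shift * LN2
            w = np.concatenate([w[shift:], np.zeros(shift)])
            w = w / w.sum()

    return DivisionCycleMixture(mu0=mu0, sigma=sigma, weights=w, log_likelihood=prev_ll)


def divisions_per_day(daily_log_intensities, max_divisions: int,
                      mu0: float | None = None) -> float:
    """Average divisions per sampling interval from consecutive dye samples.

    Fits :func:`fit_division_cycles` to each day's sample — all anchored to
    one undivided-peak location ``mu0`` (fitted from the first sample when
    not given, assuming it contains undivided cells) — and returns the
    least-squares slope of mean division count against day index.
    """
    samples = list(daily_log_intensities)
    if len(samples) < 2:
        raise InsufficientDataError("need at least 2 daily samples")
    if mu0 is None:
        mu0 = fit_division_cycles(samples[0], max_divisions=max_divisions).mu0
    counts = [
        fit_division_cycles(day, max_divisions=max_divisions, mu0=mu0).mean_divisions
        for day in samples
    ]
    days = np.arange(len(counts), dtype=float)
    slope = np.polyfit(days, counts, 1)[0]
    return float(slope)
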