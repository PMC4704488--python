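"""Two-state interconversion kinetics with equal proliferation.

Cells occupy a high- or low-activity state and switch with first-order
rates k_hl (high -> low) and k_lh (low -> high) per cell division, while
both states proliferate at the same rate.  With H and L the state counts
and equal division rate k, the population obeys

    dH/dt = k H - k_hl H + k_lh L
    dL/dt = k L + k_hl H - k_lh L

whose closed form is

    H(t) = f_eq (H0 + L0) (1 - e^{-(k_hl+k_lh) t}) e^{kt} + H0 e^{-(k_hl+k_lh) t} e^{kt}

with f_eq = k_lh / (k_hl + k_lh).  Because proliferation is equal, the
high-state *fraction* relaxes exponentially to f_eq independently of growth:

    f(t) = f_eq + (f0 - f_eq) e^{-(k_hl+k_lh) t}

Time is measured in divisions internally; an hours-per-division factor
(default 12 h) converts at I/O.  Rate fitting from state-fraction time
courses uses a binomial likelihood, since fractions come from counting
gated cells out of a finite sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitFailureError, InsufficientDataError, InvalidInputError

__all__ = [
    "SwitchingRates",
    "PopulationState",
    "analytic_population",
    "analytic_fraction",
    "fit_rates",
    "switching_timescales",
    "fit_growth",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SwitchingRates:
    """Per-division switching rates plus the (shared) proliferation rate.

    ``k_hl``: high -> low rate; ``k_lh``: low -> high rate, both per cell
    division.  ``k_div`` is the exponential growth rate per division-time
    unit (ln 2 by default: the population doubles each division);
    ``hours_per_division`` converts division time to wall clock (12 h).
    In the per-division simulator limit the rates are switching
    probabilities, so their sum must stay below 1.
    """

    k_hl: float
    k_lh: float
    k_div: float = LN2
    hours_per_division: float = 12.0
    se_hl: float | None = field(default=None, compare=False)
    se_lh: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.k_hl < 0 or self.k_lh < 0:
            raise InvalidInputError("switching rates must be non-negative")
        if self.k_hl + self.k_lh >= 1:
            raise InvalidInputError(
                "k_hl + k_lh must be < 1 (per-division switching probabilities)"
            )
        if self.hours_per_division <= 0:
            raise InvalidInputError("hours_per_division must be positive")

    @property
    def k_sum(self) -> float:
        return self.k_hl + self.k_lh

    @property
    def f_eq(self) -> float:
        """Equilibrium high-state fraction k_lh / (k_hl + k_lh)."""
        if self.k_sum == 0:
            raise InvalidInputError("equilibrium undefined when both rates are zero")
        return self.k_lh / self.k_sum

    def to_dict(self) -> dict:
        d = {
            "k_hl": self.k_hl,
            "k_lh": self.k_lh,
            "k_div": self.k_div,
            "hours_per_division": self.hours_per_division,
            "se_hl": self.se_hl,
            "se_lh": self.se_lh,
        }
        if self.k_sum > 0:
            d["f_eq"] = self.f_eq
        return d


@dataclass(frozen=True)
class PopulationState:
    """Cell counts in each state at time t (divisions)."""

    H: float
    L: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.H < 0 or self.L < 0:
            raise InvalidInputError("cell counts must be non-negative")

    @property
    def total(self) -> float:
        return self.H + self.L

    @property
    def fraction_high(self) -> float:
        if self.total == 0:
            raise InvalidInputError("fraction undefined for an empty population")
        return self.H / self.total


def analytic_population(rates: SwitchingRates, init: PopulationState, t: float) -> PopulationState:
    """Closed-form population counts after ``t`` divisions.

    Matches forward numerical integration of the two linear ODEs; with both
    switching rates zero it reduces to pure exponential growth of each
    state.
    """
    if t < 0:
        raise InvalidInputError("time must be non-negative")
    ks = rates.k_sum
    growth = math.exp(rates.k_div * t)
    total0 = init.total
    if ks == 0:
        H = init.H * growth
    else:
        decay = math.exp(-ks * t)
        H = (rates.f_eq * total0 * (1.0 - decay) + init.H * decay) * growth
    L = total0 * growth - H
    return PopulationState(H=H, L=max(L, 0.0), t=init.t + t)


def analytic_fraction(rates: SwitchingRates, f0_high: float, t) -> float | np.ndarray:
    """High-state fraction after ``t`` divisions, starting from f0_high.

    f(t) = f_eq + (f0 - f_eq) exp(-(k_hl + k_lh) t); the shared growth
    factor cancels.  Accepts scalar or array t.
    """
    if not 0.0 <= f0_high <= 1.0:
        raise InvalidInputError("initial fraction must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    ks = rates.k_sum
    if ks == 0:
        out = np.full_like(t, f0_high, dtype=float)
    else:
        feq = rates.f_eq
        out = feq + (f0_high - feq) * np.exp(-ks * t)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# rate fitting


def _neg_loglik(params: np.ndarray, courses: list[pd.DataFrame],
                fixed_f0: list[float | None]) -> float:
    k_hl, k_lh = np.exp(params[0]), np.exp(params[1])
    if k_hl + k_lh >= 1:
        return 1e12
    try:
        rates = SwitchingRates(k_hl=k_hl, k_lh=k_lh)
    except InvalidInputError:
        return 1e12
    nll = 0.0
    j = 2
    for course, f0fix in zip(courses, fixed_f0):
        if f0fix is None:
            f0 = 1.0 / (1.0 + math.exp(-params[j]))
            j += 1
        else:
            f0 = f0fix
        f = analytic_fraction(rates, f0, course["t_divisions"].to_numpy())
        f = np.clip(f, 1e-12, 1 - 1e-12)
        k = course["n_high"].to_numpy()
        n = course["n_total"].to_numpy()
        nll -= float(np.sum(k * np.log(f) + (n - k) * np.log1p(-f)))
    return nll


def _numeric_hessian(fun, x0: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x0.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x0 + ei + ej) - fun(x0 + ei - ej)
                - fun(x0 - ei + ej) + fun(x0 - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_rates(timecourse, f0=None, method: str = "ml") -> SwitchingRates:
    """Fit (k_hl, k_lh) from one or several state-fraction time courses.

    Each course is a table with columns ``t_divisions``, ``n_high``,
    ``n_total``.  The default is a maximum-likelihood fit under binomial
    observation of the analytic fraction; ``method="ls"`` falls back to
    unweighted least squares on the fractions.  Several courses (e.g. one
    started from purified high cells, one from purified low cells) share
    the two rates but carry separate initial fractions.

    Parameters
    ----------
    timecourse : DataFrame or sequence of DataFrames.
    f0 : None, float, or sequence matching the courses.  ``None`` leaves the
        initial fraction(s) free; a number fixes them.
    method : "ml" (binomial maximum likelihood) or "ls" (least squares).

    Returns
    -------
    SwitchingRates with asymptotic standard errors ``se_hl``/``se_lh``.
    """
    courses = [timecourse] if isinstance(timecourse, pd.DataFrame) else list(timecourse)
    if not courses:
        raise InvalidInputError("no time courses given")
    for c in courses:
        if len(c) < 3:
            raise InsufficientDataError("each time course needs at least 3 timepoints")
        if (c["n_total"] <= 0).any() or (c["n_high"] < 0).any() or (c["n_high"] > c["n_total"]).any():
            raise InvalidInputError("counts must satisfy 0 <= n_high <= n_total, n_total > 0")

    if f0 is None:
        fixed_f0: list[float | None] = [None] * len(courses)
    elif np.isscalar(f0):
        fixed_f0 = [float(f0)] * len(courses)
    else:
        fixed_f0 = [None if v is None else float(v) for v in f0]
        if len(fixed_f0) != len(courses):
            raise InvalidInputError("f0 sequence length must match the number of courses")

    fracs = np.concatenate([(c["n_high"] / c["n_total"]).to_numpy() for c in courses])
    if np.ptp(fracs) == 0:
        raise FitFailureError("state fractions are constant: rates not identifiable")

    x0 = [math.log(0.05), math.log(0.05)]
    for c, f0fix in zip(courses, fixed_f0):
        if f0fix is None:
            first = float(np.clip(c["n_high"].iloc[0] / c["n_total"].iloc[0], 0.02, 0.98))
            x0.append(math.log(first / (1 - first)))
    x0 = np.asarray(x0)

    if method == "ls":
        def objective(p):
            return _ls_objective(p, courses, fixed_f0)
    elif method == "ml":
        def objective(p):
            return _neg_loglik(p, courses, fixed_f0)
    else:
        raise InvalidInputError(f"unknown method {method!r}")

    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000,
                                     "maxfev": 20000})
    res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000,
                                     "maxfev": 20000})
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise FitFailureError("rate fit did not converge")

    k_hl, k_lh = float(np.exp(res.x[0])), float(np.exp(res.x[1]))

    se_hl = se_lh = None
    if method == "ml":
        try:
            H = _numeric_hessian(objective, res.x)
            cov = np.linalg.inv(H)
            # delta method: se(k) = k * se(log k)
            if cov[0, 0] > 0:
                se_hl = k_hl * math.sqrt(cov[0, 0])
            if cov[1, 1] > 0:
                se_lh = k_lh * math.sqrt(cov[1, 1])
        except np.linalg.LinAlgError:
            pass

    return SwitchingRates(k_hl=k_hl, k_lh=k_lh, se_hl=se_hl, se_lh=se_lh)


def _ls_objective(params, courses, fixed_f0) -> float:
    k_hl, k_lh = np.exp(params[0]), np.exp(params[1])
    if k_hl + k_lh >= 1:
        return 1e12
    rates = SwitchingRates(k_hl=k_hl, k_lh=k_lh)
    sse = 0.0
    j = 2
    for course, f0fix in zip(courses, fixed_f0):
        if f0fix is None:
            f0 = 1.0 / (1.0 + math.exp(-params[j]))
            j += 1
        else:
            f0 = f0fix
        f = analytic_fraction(rates, f0, course["t_divisions"].to_numpy())
        obs = (course["n_high"] / course["n_total"]).to_numpy()
        sse += float(np.sum((f - obs) ** 2))
    return sse


def switching_timescales(rates: SwitchingRates) -> dict:
    """Characteristic switching timescales in divisions.

    Returns rounded mean divisions per high->low event (1/k_hl), per
    low->high event (1/k_lh) and the relaxation time 1/(k_hl + k_lh),
    alongside the unrounded values.  A zero rate maps to ``math.inf``.
    """
    def inv(k: float) -> float:
        return math.inf if k == 0 else 1.0 / k

    hl, lh, relax = inv(rates.k_hl), inv(rates.k_lh), inv(rates.k_sum)

    def rnd(v: float):
        return math.inf if math.isinf(v) else int(round(v))

    return {
        "divisions_per_hl_switch": rnd(hl),
        "divisions_per_lh_switch": rnd(lh),
        "relaxation_divisions": rnd(relax),
        "divisions_per_hl_switch_exact": hl,
        "divisions_per_lh_switch_exact": lh,
        "relaxation_divisions_exact": relax,
    }


def fit_growth(counts: pd.DataFrame) -> dict:
    """Per-condition exponential growth rates with a slope-equality test.

    ``counts`` holds columns ``t_divisions``, ``n_cells``, ``condition``.
    Each condition's log cell count is regressed on time (ordinary least
    squares); for two conditions, the equality of slopes is tested via the
    time-by-condition interaction term.
    """
    import statsmodels.api as sm

    if not {"t_divisions", "n_cells", "condition"}.issubset(counts.columns):
        raise InvalidInputError("expected columns t_divisions, n_cells, condition")
    if (counts["n_cells"] <= 0).any():
        raise InvalidInputError("cell counts must be positive")

    out: dict = {"conditions": {}}
    for cond, grp in counts.groupby("condition", sort=False):
        if len(grp) < 3:
            raise InsufficientDataError(
                f"condition {cond!r} needs at least 3 timepoints, got {len(grp)}"
            )
        X = sm.add_constant(grp["t_divisions"].to_numpy())
        fit = sm.OLS(np.log(grp["n_cells"].to_numpy()), X).fit()
        out["conditions"][str(cond)] = {
            "growth_rate": float(fit.params[1]),
            "se": float(fit.bse[1]),
            "doubling_divisions": float(LN2 / fit.params[1]) if fit.params[1] > 0 else math.inf,
        }

    conds = list(out["conditions"])
    if len(conds) == 2:
        t = counts["t_divisions"].to_numpy()
        is_b = (counts["condition"] == counts["condition"].unique()[1]).to_numpy().astype(float)
        X = np.column_stack([np.ones_like(t), t, is_b, t * is_b])
        fit = sm.OLS(np.log(counts["n_cells"].to_numpy()), X).fit()
        out["slope_difference"] = float(fit.params[3])
        out["slope_equality_p"] = float(fit.pvalues[3])
    return out
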