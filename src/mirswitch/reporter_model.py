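"""Hill repression model linking miRNA concentration to the reporter ratio.

A bidirectional-promoter reporter expresses a detector transcript carrying a
miRNA target site and a normalizer transcript without one.  The observed
ratio r (detector / normalizer) falls with miRNA concentration M following a
Hill repression curve

    r(M) = r0 / (1 + (M / K)**n)

with binding constant K (in whatever abundance unit M is measured in),
Hill coefficient n, and unrepressed ratio r0 (1 for ratios normalized to the
no-miRNA level).  Non-cooperative binding corresponds to n close to 1.

The module provides forward evaluation, exact inversion, and least-squares
calibration from (miRNA level, ratio) pairs.  Fitting is performed on
log-transformed ratios because reporter noise is multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidInputError, OutOfDomainError

__all__ = ["ReporterCalibration", "hill_response", "invert_response", "fit_calibration"]


@dataclass(frozen=True)
class ReporterCalibration:
    """Parameters of the Hill repression of the detector by the miRNA.

    Attributes
    ----------
    K : float
        Binding constant, in the same (arbitrary) abundance units as the
        miRNA levels used for fitting.  Must be positive.
    n : float
        Dimensionless Hill coefficient; 1 means non-cooperative binding.
    r0 : float
        Reporter ratio at zero miRNA (scale factor), default 1.
    se_K, se_n, se_r0 : float or None
        Standard errors from the calibration fit, when available.
    """

    K: float
    n: float
    r0: float = 1.0
    se_K: float | None = field(default=None, compare=False)
    se_n: float | None = field(default=None, compare=False)
    se_r0: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.n > 0 and self.r0 > 0):
            raise InvalidInputError(
                f"ReporterCalibration requires K, n, r0 > 0; got K={self.K}, n={self.n}, r0={self.r0}"
            )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "n": self.n,
            "r0": self.r0,
            "se_K": self.se_K,
            "se_n": self.se_n,
            "se_r0": self.se_r0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReporterCalibration":
        return cls(
            K=float(d["K"]),
            n=float(d["n"]),
            r0=float(d.get("r0", 1.0)),
            se_K=d.get("se_K"),
            se_n=d.get("se_n"),
            se_r0=d.get("se_r0"),
        )


def hill_response(calib: ReporterCalibration, M):
    """Reporter ratio at miRNA level(s) ``M``: ``r0 / (1 + (M/K)**n)``.

    Strictly decreasing in M; equals r0 at M = 0 and tends to 0 as M grows.
    Accepts scalars or arrays; raises :class:`InvalidInputError` on negative M.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise InvalidInputError("miRNA level must be non-negative")
    out = calib.r0 / (1.0 + (M / calib.K) ** calib.n)
    return out if out.ndim else float(out)


def invert_response(calib: ReporterCalibration, r):
    """miRNA level at which the reporter ratio equals ``r``.

    Closed form ``K * (r0/r - 1)**(1/n)``, the exact inverse of
    :func:`hill_response` on the open domain 0 < r < r0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(r >= calib.r0):
        raise OutOfDomainError(
            f"ratio must lie strictly in (0, r0={calib.r0}); zero miRNA gives r = r0 exactly"
        )
    out = calib.K * (calib.r0 / r - 1.0) ** (1.0 / calib.n)
    return out if out.ndim else float(out)


def fit_calibration(pairs, fix_r0: float | None = 1.0) -> ReporterCalibration:
    """Fit (K, n[, r0]) to (miRNA level, ratio) pairs by nonlinear least squares.

    The fit is performed on log(ratio) so that multiplicative (log-normal)
    measurement noise becomes additive.  Standard errors come from the
    Jacobian-based covariance of the fit.

    Parameters
    ----------
    pairs : DataFrame with columns ``mirna_level``, ``ratio``, or a 2-column
        array-like of (level, ratio) rows.
    fix_r0 : float or None
        If a number (default 1), the unrepressed ratio is held fixed at that
        value; if None, r0 is fitted as a third free parameter.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 pairs.
    FitFailureError
        Degenerate data (all levels identical, < 4-fold level span) or a
        non-converging fit.
    """
    M, r = _coerce_pairs(pairs)
    if len(M) < 4:
        raise InsufficientDataError(f"need at least 4 calibration pairs, got {len(M)}")
    if np.any(r <= 0):
        raise InvalidInputError("ratios must be positive")
    pos = M[M > 0]
    if pos.size == 0 or np.ptp(M) == 0:
        raise FitFailureError("all miRNA levels identical: K and n are not identifiable")
    if pos.max() / pos.min() < 4.0:
        raise FitFailureError(
            "miRNA levels must span at least a 4-fold range for a stable Hill fit"
        )

    logr = np.log(r)
    K0 = float(np.median(pos))

    if fix_r0 is not None:
        def model(m, logK, n):
            return np.log(fix_r0) - np.log1p((m / np.exp(logK)) ** n)

        p0 = [np.log(K0), 1.0]
    else:
        def model(m, logK, n, logr0):
            return logr0 - np.log1p((m / np.exp(logK)) ** n)

        p0 = [np.log(K0), 1.0, float(np.max(logr))]

    try:
        popt, pcov = curve_fit(model, M, logr, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitFailureError(f"Hill calibration fit did not converge: {exc}") from exc

    perr = np.sqrt(np.diag(pcov))
    K = float(np.exp(popt[0]))
    n = float(popt[1])
    se_K = float(K * perr[0]) if np.isfinite(perr[0]) else None  # delta method on logK
    se_n = float(perr[1]) if np.isfinite(perr[1]) else None
    if fix_r0 is not None:
        return ReporterCalibration(K=K, n=n, r0=float(fix_r0), se_K=se_K, se_n=se_n)
    r0 = float(np.exp(popt[2]))
    se_r0 = float(r0 * perr[2]) if np.isfinite(perr[2]) else None
    return ReporterCalibration(K=K, n=n, r0=r0, se_K=se_K, se_n=se_n, se_r0=se_r0)


def _coerce_pairs(pairs):
    """Extract (levels, ratios) arrays from a DataFrame or 2-column array."""
    if hasattr(pairs, "columns"):
        M = np.asarray(pairs["mirna_level"], dtype=float)
        r = np.asarray(pairs["ratio"], dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidInputError("calibration pairs must be a 2-column table")
        M, r = arr[:, 0], arr[:, 1]
    if np.any(M < 0):
        raise InvalidInputError("miRNA levels must be non-negative")
    return M, r
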