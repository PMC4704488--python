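"""The miRNA-ERK double-negative feedback loop as a bistable ODE system.

A microRNA M represses activation of the kinase ERK, and active ERK E
represses production of the microRNA.  With degradation rates k_d1, k_d2,
production rate k_1, maximal ERK activation rate k_2, repression constants
K_1 and K_E and Hill exponents n_1 (miRNA on ERK) and n_E (ERK on miRNA,
2 for the dimerizing kinase):

    dM/dt = -k_d1 M + k_1 / (1 + (E/K_E)**n_E)
    dE/dt = -k_d2 E + k_2 (E_tot - E) / (1 + (M/K_1)**n_1)

Rescaling with alpha = k_1/(K_1 k_d1), beta = E_tot/K_E, gamma = k_2/k_d2,
X = M/(alpha K_1), Y = E/E_tot gives

    dX/dt = k_d1 [ -X + d / (1 + (beta Y)**n_E) ]
    dY/dt = k_d2 [ -Y + gamma (1 - Y) / (1 + (alpha X)**n_1) ]

where d is the gene-dosage multiplier on miRNA production (1 wild type,
0.5 heterozygote).  The nullclines follow directly from the ODEs:

    Y = gamma / (1 + gamma + (alpha X)**n_1)        (dY/dt = 0)
    X = d / (1 + (beta Y)**n_E)                     (dX/dt = 0)

Their intersections are the fixed points; for suitable (alpha, beta,
gamma) two stable points (high-miRNA/low-ERK and low-miRNA/high-ERK)
coexist with a saddle between them.  Fixed points are found by reducing
to one scalar equation in Y, dense sign-scanning, and bisection
refinement; stability comes from the analytic Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import InvalidInputError

__all__ = [
    "FeedbackParams",
    "FixedPoint",
    "PhaseDiagram",
    "rhs",
    "nullcline_Y_of_X",
    "nullcline_X_of_Y",
    "find_fixed_points",
    "phase_diagram",
    "steady_state_curve",
    "saddle_node_alphas",
    "critical_beta",
    "simulate_trajectory",
]

# residual tolerance every reported fixed point must satisfy
FP_RESIDUAL_TOL = 1e-9
# minimum sign-scan density in Y for root bracketing
SCAN_POINTS = 2000


@dataclass(frozen=True)
class FeedbackParams:
    """Rescaled parameters of the feedback loop.

    alpha : rescaled miRNA turnover k_1/(K_1 k_d1) (production over
        degradation in units of the repression constant).
    beta : total ERK over its repression affinity, E_tot/K_E.
    gamma : ERK activation over deactivation turnover, k_2/k_d2.
    k_d1, k_d2 : degradation rates setting the time unit (default 1; the
        fixed-point structure depends only on alpha, beta, gamma, dosage).
    n_E, n_1 : Hill exponents of the two repressive arms (default 2, 2).
    dosage : miRNA production multiplier, 1 wild type, 0.5 heterozygote.
    """

    alpha: float
    beta: float
    gamma: float
    k_d1: float = 1.0
    k_d2: float = 1.0
    n_E: float = 2.0
    n_1: float = 2.0
    dosage: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError("alpha and beta must be non-negative")
        if self.gamma <= 0:
            raise InvalidInputError("gamma must be positive")
        if self.k_d1 <= 0 or self.k_d2 <= 0:
            raise InvalidInputError("degradation rates must be positive")
        if not 0.0 < self.dosage <= 1.0:
            raise InvalidInputError("dosage must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta, "gamma": self.gamma,
            "k_d1": self.k_d1, "k_d2": self.k_d2,
            "n_E": self.n_E, "n_1": self.n_1, "dosage": self.dosage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackParams":
        return cls(**{k: float(v) for k, v in d.items()
                      if k in {"alpha", "beta", "gamma", "k_d1", "k_d2",
                               "n_E", "n_1", "dosage"}})


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the rescaled system with its linear stability."""

    X: float
    Y: float
    stability: str           # 'stable', 'saddle' or 'unstable'
    eigenvalues: tuple

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class PhaseDiagram:
    """Stable-state counts over an (alpha, gamma) grid at fixed beta."""

    alpha_grid: np.ndarray
    gamma_grid: np.ndarray
    beta: float
    n_stable: np.ndarray     # shape (len(alpha_grid), len(gamma_grid))

    @property
    def bistable_mask(self) -> np.ndarray:
        return self.n_stable == 2

    def to_frame(self) -> pd.DataFrame:
        a, g = np.meshgrid(self.alpha_grid, self.gamma_grid, indexing="ij")
        return pd.DataFrame({
            "alpha": a.ravel(), "gamma": g.ravel(),
            "beta": self.beta, "n_stable": self.n_stable.ravel(),
        })


def rhs(params: FeedbackParams, X, Y):
    """Time derivatives (dX/dt, dY/dt) of the rescaled system."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    dX = params.k_d1 * (-X + params.dosage / (1.0 + (params.beta * Y) ** params.n_E))
    dY = params.k_d2 * (
        -Y + params.gamma * (1.0 - Y) / (1.0 + (params.alpha * X) ** params.n_1)
    )
    if dX.ndim == 0:
        return float(dX), float(dY)
    return dX, dY


def nullcline_Y_of_X(params: FeedbackParams, X):
    """dY/dt = 0 curve: Y = gamma / (1 + gamma + (alpha X)**n_1)."""
    X = np.asarray(X, dtype=float)
    out = params.gamma / (1.0 + params.gamma + (params.alpha * X) ** params.n_1)
    return out if out.ndim else float(out)


def nullcline_X_of_Y(params: FeedbackParams, Y):
    """dX/dt = 0 curve: X = dosage / (1 + (beta Y)**n_E)."""
    Y = np.asarray(Y, dtype=float)
    out = params.dosage / (1.0 + (params.beta * Y) ** params.n_E)
    return out if out.ndim else float(out)


def _jacobian(params: FeedbackParams, X: float, Y: float) -> np.ndarray:
    a, b, g = params.alpha, params.beta, params.gamma
    nE, n1 = params.n_E, params.n_1
    denX = 1.0 + (b * Y) ** nE
    denY = 1.0 + (a * X) ** n1
    j12 = 0.0
    if b > 0 and Y > 0:
        j12 = -params.k_d1 * params.dosage * nE * b**nE * Y ** (nE - 1) / denX**2
    j21 = 0.0
    if a > 0 and X > 0:
        j21 = -params.k_d2 * g * (1.0 - Y) * n1 * a**n1 * X ** (n1 - 1) / denY**2
    return np.array([
        [-params.k_d1, j12],
        [j21, params.k_d2 * (-1.0 - g / denY)],
    ])


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.all(re < 0):
        return "stable"
    if re.min() < 0 < re.max():
        return "saddle"
    return "unstable"


def _y_scan_grid(n_points: int = SCAN_POINTS) -> np.ndarray:
    """Scan grid over Y in (0, 1): log-dense near 0 (high-miRNA fixed points
    sit at tiny active-ERK fractions for large alpha), linear elsewhere,
    log-dense near 1."""
    g = np.concatenate([
        np.logspace(-9, -0.3, int(0.5 * n_points)),
        np.linspace(1e-4, 1.0 - 1e-9, int(0.45 * n_points)),
        1.0 - np.logspace(-9, -1.0, int(0.1 * n_points)),
    ])
    g = np.unique(np.clip(g, 1e-12, 1.0 - 1e-12))
    return np.sort(g)


_Y_GRID = _y_scan_grid()


def _scalar_equation(params: FeedbackParams):
    """F(Y) = Y (1 + gamma + (alpha X(Y))**n_1) - gamma, whose roots in
    (0, 1) are the fixed-point Y values (X(Y) is the dX/dt = 0 curve)."""
    a, g = params.alpha, params.gamma
    n1 = params.n_1

    def F(Y):
        X = nullcline_X_of_Y(params, Y)
        return Y * (1.0 + g + (a * X) ** n1) - g

    return F


def find_fixed_points(params: FeedbackParams, y_grid: np.ndarray | None = None) -> list[FixedPoint]:
    """All fixed points with stability, sorted by X ascending.

    Substituting the X-nullcline into the Y-nullcline reduces the problem
    to one scalar equation in Y, which is sign-scanned on a dense grid and
    refined by bisection; each root is classified by the Jacobian
    eigenvalues.  For this pair of monotone rational curves the count is 1
    or 3, alternating stable / saddle / stable when 3.
    """
    F = _scalar_equation(params)
    grid = _Y_GRID if y_grid is None else y_grid
    vals = F(grid)
    roots: list[float] = []
    sign = np.signbit(vals)
    idx = np.nonzero(sign[:-1] != sign[1:])[0]
    for i in idx:
        y = brentq(F, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16, maxiter=200)
        roots.append(float(y))
    for i in np.nonzero(vals == 0.0)[0]:       # exact grid hits
        roots.append(float(grid[i]))
    roots = sorted(set(roots))

    points = []
    for y in roots:
        x = float(nullcline_X_of_Y(params, y))
        dx, dy = rhs(params, x, y)
        if abs(dx) > FP_RESIDUAL_TOL or abs(dy) > FP_RESIDUAL_TOL:
            continue
        eigs = np.linalg.eigvals(_jacobian(params, x, y))
        points.append(FixedPoint(X=x, Y=y, stability=_classify(eigs),
                                 eigenvalues=tuple(eigs)))
    points.sort(key=lambda p: p.X)
    return points


def n_stable_states(params: FeedbackParams) -> int:
    return sum(p.stable for p in find_fixed_points(params))


def phase_diagram(alpha_grid, gamma_grid, beta: float,
                  template: FeedbackParams | None = None) -> PhaseDiagram:
    """Stable-state count over an (alpha, gamma) grid at fixed beta."""
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if alpha_grid.size == 0 or gamma_grid.size == 0:
        raise InvalidInputError("grids must be non-empty")
    base = template or FeedbackParams(alpha=1.0, beta=beta, gamma=1.0)
    counts = _bistable_counts(alpha_grid, gamma_grid, beta,
                              base.n_E, base.n_1, base.dosage)
    return PhaseDiagram(alpha_grid=alpha_grid, gamma_grid=gamma_grid,
                        beta=float(beta), n_stable=counts)


def _bistable_counts(alphas: np.ndarray, gammas: np.ndarray, beta: float,
                     nE: float, n1: float, dosage: float) -> np.ndarray:
    """Vectorized stable-state counts: 3 nullcline intersections => 2 stable,
    1 intersection => 1 stable (the outer intersections of these monotone
    curves are always stable, the middle one a saddle)."""
    Y = _Y_GRID
    X = dosage / (1.0 + (beta * Y) ** nE)
    AX = (alphas[:, None] * X[None, :]) ** n1          # (nA, nY)
    counts = np.empty((alphas.size, gammas.size), dtype=int)
    for j, g in enumerate(gammas):
        Fv = Y[None, :] * (1.0 + g + AX) - g
        sign = np.signbit(Fv)
        ncross = np.sum(sign[:, :-1] != sign[:, 1:], axis=1)
        counts[:, j] = np.where(ncross >= 3, 2, 1)
    return counts


def steady_state_curve(alpha_range, beta: float = 10.0, gamma: float = 1.0,
                       template: FeedbackParams | None = None) -> pd.DataFrame:
    """Stable miRNA branches along an alpha sweep at fixed (beta, gamma).

    Returns one row per alpha with the stable rescaled levels X (low/high
    branch), the absolute levels M = alpha K_1 X (K_1 = 1 in rescaled
    units), the stable-state count and the regime label.  Along increasing
    alpha the system passes from a single low-miRNA state through a
    bistable window to a single high-miRNA state.
    """
    alphas = np.asarray(alpha_range, dtype=float)
    base = template or FeedbackParams(alpha=1.0, beta=beta, gamma=gamma)
    rows = []
    for a in alphas:
        p = replace(base, alpha=float(a), beta=float(beta), gamma=float(gamma))
        fps = find_fixed_points(p)
        stable = [fp for fp in fps if fp.stable]
        rows.append({
            "alpha": float(a),
            "n_stable": len(stable),
            "X_low": stable[0].X if stable else np.nan,
            "X_high": stable[-1].X if len(stable) > 1 else np.nan,
            "M_low": float(a) * stable[0].X if stable else np.nan,
            "M_high": float(a) * stable[-1].X if len(stable) > 1 else np.nan,
        })
    df = pd.DataFrame(rows)

    # regime labels: single-stable alphas before the bistable window are the
    # low branch, after it the high branch
    bist = df["n_stable"].to_numpy() == 2
    regime = np.empty(len(df), dtype=object)
    if bist.any():
        first, last = np.nonzero(bist)[0][[0, -1]]
        regime[:first] = "low"
        regime[first:last + 1] = np.where(bist[first:last + 1], "bistable", "mixed")
        regime[last + 1:] = "high"
    else:
        # no bistable window sampled: label by continuity of the branch
        regime[:] = "low"
    df["regime"] = regime
    return df


def saddle_node_alphas(beta: float = 10.0, gamma: float = 1.0,
                       alpha_max: float = 40.0, tol: float = 1e-4,
                       template: FeedbackParams | None = None) -> tuple[float, float]:
    """Bistable-window boundaries in alpha at fixed (beta, gamma).

    Bisects the stable-state-count indicator to locate the two saddle-node
    alphas bracketing the bistable window, each to absolute tolerance
    ``tol``.  Raises if no bistability is found up to ``alpha_max``.
    """
    base = template or FeedbackParams(alpha=1.0, beta=beta, gamma=gamma)

    def nstab(a: float) -> int:
        return n_stable_states(replace(base, alpha=a, beta=beta, gamma=gamma))

    scan = np.linspace(1e-3, alpha_max, 400)
    ns = np.array([nstab(a) for a in scan])
    inside = np.nonzero(ns == 2)[0]
    if inside.size == 0:
        raise InvalidInputError(
            f"no bistability found for beta={beta}, gamma={gamma} up to alpha={alpha_max}"
        )

    def bisect(lo: float, hi: float, want_low_inside: bool) -> float:
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if (nstab(mid) == 2) == want_low_inside:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    a_on = bisect(scan[inside[0] - 1], scan[inside[0]], want_low_inside=True) \
        if inside[0] > 0 else scan[0]
    a_off = bisect(scan[inside[-1]], scan[min(inside[-1] + 1, scan.size - 1)],
                   want_low_inside=False) if inside[-1] < scan.size - 1 else scan[-1]
    return float(a_on), float(a_off)


def critical_beta(alpha_grid=None, gamma_grid=None, beta_grid=None,
                  n_E: float = 2.0, n_1: float = 2.0,
                  dosage: float = 1.0) -> float | None:
    """Smallest beta on the grid for which any (alpha, gamma) node is bistable.

    Defaults reproduce the reference scan: beta in [1, 4] step 0.05, alpha
    0 plus 200 log-spaced points up to 100, gamma 100 log-spaced points
    over [0.05, 50].  Returns ``None`` (sentinel) when no scanned beta
    yields bistability.
    """
    if beta_grid is None:
        beta_grid = np.arange(1.0, 4.0 + 1e-9, 0.05)
    if alpha_grid is None:
        alpha_grid = np.concatenate([[0.0], np.logspace(-2, 2, 200)])
    if gamma_grid is None:
        gamma_grid = np.logspace(math.log10(0.05), math.log10(50.0), 100)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    for beta in np.sort(np.asarray(beta_grid, dtype=float)):
        counts = _bistable_counts(alpha_grid, gamma_grid, float(beta), n_E, n_1, dosage)
        if np.any(counts == 2):
            return float(beta)
    return None


def simulate_trajectory(params: FeedbackParams, X0: float, Y0: float,
                        t_end: float, dt: float) -> dict:
    """Integrate the ODEs from (X0, Y0) and report the basin of attraction.

    Uses adaptive Runge-Kutta (RK45) sampled every ``dt``; the terminal
    state is matched against the stable fixed points.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    if X0 < 0 or not 0.0 <= Y0 <= 1.0:
        raise InvalidInputError("start must satisfy X >= 0 and Y in [0, 1]")

    def f(_t, z):
        return rhs(params, z[0], z[1])

    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)
    sol = solve_ivp(f, (0.0, t_end), [X0, Y0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, method="RK45")
    X, Y = sol.y
    stable = [p for p in find_fixed_points(params) if p.stable]
    basin = None
    dist = math.inf
    for i, p in enumerate(stable):
        d = math.hypot(X[-1] - p.X, Y[-1] - p.Y)
        if d < dist:
            dist, basin = d, i
    return {
        "t": sol.t, "X": X, "Y": Y,
        "terminal": (float(X[-1]), float(Y[-1])),
        "basin_index": basin,
        "distance_to_fixed_point": float(dist) if stable else math.inf,
        "stable_points": stable,
    }
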