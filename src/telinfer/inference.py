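"""Maximum-likelihood inference and practical identifiability (a posteriori).

Given an observed mRNA count histogram, the log-likelihood of a telegraph
parameter set theta under capture rate beta is

    LL(theta) = sum_x n_x log P_x(theta)

where n_x is the number of cells with x observed copies and P_x the
capture-transformed model marginal.  The pipeline minimizes -LL:

1. evaluate the coarse objective surface over the model library;
2. refine with a bounded derivative-free simplex search in log10 parameter
   space, seeded at the coarse argmin and confined to the box spanned by
   the low-lying coarse region;
3. profile each parameter over the library range (nuisance parameters
   re-optimized per point, warm-started from the neighboring point) and cut
   confidence intervals at the chi-square threshold chi2_1(0.95)/2 ~ 1.92;
4. summarize CI width per parameter with the APM precision metric
   APM = log_T(theta_ub / theta_lb); the parameter set is called
   practically identifiable when the maximum APM over parameters is < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .cme import ParamVector
from .library import (
    PARAM_NAMES,
    PROB_FLOOR,
    GridSpec,
    ModelLibrary,
    search_bounds_from_surface,
    surface_from_weights,
)
from .noise import CaptureModel, captured_marginal

__all__ = [
    "CountHistogram",
    "APMConfig",
    "ProfileCurve",
    "ProfileResult",
    "MLEFit",
    "CI_THRESHOLD",
    "log_likelihood",
    "fit_mle",
    "profile_likelihood",
    "apm",
    "classify_identifiability",
    "profile_all",
]

#: 95% profile-likelihood CI threshold: chi2(df=1).ppf(0.95) / 2 ~= 1.9207
CI_THRESHOLD = float(chi2.ppf(0.95, df=1) / 2.0)

#: simplex convergence tolerance in log10-parameter units
XATOL_LOG10 = 1e-4
#: number of profile points spanning the library range per parameter
PROFILE_POINTS = 40
#: extra profile points within +/- 0.5 decades of the MLE
PROFILE_DENSE_POINTS = 10


@dataclass(frozen=True)
class CountHistogram:
    """Observed counts n_x per mRNA copy number x for one gene.

    ``counts`` is a dense vector with counts[x] = n_x; N = sum(n_x) cells.
    """

    counts: np.ndarray
    name: str = ""

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1 or len(c) == 0:
            raise ValueError("counts must be a nonempty 1D vector")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if self.N < 1:
            raise ValueError("histogram must contain at least one cell")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    def count_vector(self) -> np.ndarray:
        return self.counts

    @classmethod
    def from_cells(cls, cell_counts, name: str = "") -> "CountHistogram":
        """Build from a per-cell vector of observed copy numbers."""
        cc = np.asarray(cell_counts, dtype=np.int64)
        if np.any(cc < 0):
            raise ValueError("cell counts must be nonnegative")
        return cls(counts=np.bincount(cc), name=name)

    @classmethod
    def from_mapping(cls, mapping: dict, name: str = "") -> "CountHistogram":
        top = max(mapping)
        vec = np.zeros(top + 1, dtype=np.int64)
        for x, n in mapping.items():
            vec[x] = n
        return cls(counts=vec, name=name)


@dataclass(frozen=True)
class APMConfig:
    """Per-parameter tolerance factors T and identifiability cutoff.

    APM compares the CI bound ratio against T on a log scale; T is larger
    for the switching rates (whose biologically plausible values span many
    orders of magnitude) than for ksyn.
    """

    T: dict = field(
        default_factory=lambda: {"ksyn": 3.0, "kon": 100.0, "koff": 100.0}
    )
    cutoff: float = 1.0

    def __post_init__(self):
        if any(t <= 1 for t in self.T.values()):
            raise ValueError("APM tolerance factors T must be > 1")
        if self.cutoff <= 0:
            raise ValueError("APM cutoff must be > 0")


@dataclass
class MLEFit:
    theta: ParamVector
    minus_ll: float
    boundary_flags: dict
    used_fallback: bool = False
    bounds_log10: list = field(default_factory=list)
    surface: np.ndarray | None = None


@dataclass
class ProfileCurve:
    """Profile likelihood of one parameter with its CI and APM."""

    param: str
    values: np.ndarray            # profiled parameter values, linear units
    minus_ll: np.ndarray          # profiled objective at each value
    ci: tuple[float, float]
    lower_at_edge: bool
    upper_at_edge: bool
    apm: float


@dataclass
class ProfileResult:
    mle: ParamVector
    minus_ll_min: float
    curves: dict                  # param name -> ProfileCurve
    overall_apm: float
    identifiable: bool


class WeightedNegLogLik:
    """-sum_x w_x log P_x(theta) with the probability floor.

    With w_x = n_x this is the negative log-likelihood of a histogram; with
    w_x = N * P_tar(x) it is the a priori cross-entropy surrogate H.
    Callable on a log10 parameter triple (the optimizer's coordinates).
    """

    def __init__(self, weights, capture: CaptureModel, tol: float = 1e-4):
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("empty target: weights sum to zero")
        self.support = np.nonzero(w)[0]
        self.w = w[self.support]
        self.capture = (
            capture if isinstance(capture, CaptureModel) else CaptureModel(capture)
        )
        self.tol = tol

    def weights_vector(self) -> np.ndarray:
        K = int(self.support.max()) + 1
        w = np.zeros(K)
        w[self.support] = self.w
        return w

    def at_theta(self, theta: ParamVector) -> float:
        p = captured_marginal(theta, self.capture, tol=self.tol).probabilities
        q = np.full(len(self.support), PROB_FLOOR)
        inside = self.support < len(p)
        q[inside] = np.maximum(p[self.support[inside]], PROB_FLOOR)
        return float(-(self.w @ np.log(q)))

    def __call__(self, x_log10) -> float:
        return self.at_theta(ParamVector.from_array(10.0 ** np.asarray(x_log10)))


def log_likelihood(
    hist: CountHistogram,
    theta: ParamVector,
    capture: CaptureModel | float = 1.0,
    tol: float = 1e-4,
) -> float:
    """Log-likelihood LL(theta) = sum_x n_x log P_x(theta) (floored)."""
    obj = WeightedNegLogLik(hist.count_vector(), capture, tol=tol)
    return -obj.at_theta(theta)


def _refine(objective, x0, bounds_log10, f0=None, xatol=XATOL_LOG10):
    """Bounded Nelder-Mead in log10 space; never worse than the seed.

    The seed is nudged strictly inside the box: a vertex exactly on a bound
    makes the default initial simplex degenerate (the reflected vertex clips
    back onto the seed) and the search stalls in that coordinate.
    """
    lo = np.array([b[0] for b in bounds_log10])
    hi = np.array([b[1] for b in bounds_log10])
    eps = 1e-3 * np.maximum(hi - lo, 1e-6)
    x0 = np.clip(x0, np.minimum(lo + eps, hi), np.maximum(hi - eps, lo))
    if f0 is None:
        f0 = objective(x0)
    # function tolerance scales with the objective magnitude (proportional to
    # the total cell weight) so convergence behaves identically at any N
    fatol = 1e-9 * max(1.0, abs(f0))
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=bounds_log10,
        options={"xatol": XATOL_LOG10, "fatol": fatol, "maxiter": 400 * len(x0)},
    )
    if res.fun <= f0:
        return np.asarray(res.x), float(res.fun), False
    return np.asarray(x0), float(f0), True


def fit_mle(
    target,
    library: ModelLibrary,
    capture: CaptureModel | None = None,
    tol: float = 1e-4,
) -> MLEFit:
    """Coarse library scan followed by bounded fine optimization.

    ``target`` is a CountHistogram or an (exact distribution, N) pair.  The
    library's capture rate defines beta unless overridden.
    """
    if capture is None:
        capture = CaptureModel(library.capture_rate)
    from .library import _target_weights

    weights, _ = _target_weights(target)
    objective = WeightedNegLogLik(weights, capture, tol=tol)
    surface = surface_from_weights(objective.weights_vector(), library)
    bounds, x0 = search_bounds_from_surface(surface, library.grid)
    x, fmin, fell_back = _refine(objective, x0, bounds)
    flags = {}
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = bounds[i]
        flags[name] = {
            "lower": bool(abs(x[i] - lo) < 1e-6),
            "upper": bool(abs(x[i] - hi) < 1e-6),
        }
    return MLEFit(
        theta=ParamVector.from_array(10.0 ** x),
        minus_ll=fmin,
        boundary_flags=flags,
        used_fallback=fell_back,
        bounds_log10=bounds,
        surface=surface,
    )


def _profile_grid(
    grid: GridSpec,
    name: str,
    mle_log10: float,
    n_points: int = PROFILE_POINTS,
    n_dense: int = PROFILE_DENSE_POINTS,
) -> np.ndarray:
    """Log10 profile locations: range-spanning points plus a dense patch
    around the MLE."""
    lo, hi = np.log10(grid.range_of(name))
    pts = np.linspace(lo, hi, n_points)
    dense = np.linspace(mle_log10 - 0.5, mle_log10 + 0.5, n_dense)
    dense = dense[(dense > lo) & (dense < hi)]
    out = np.unique(np.concatenate([pts, dense, [mle_log10]]))
    return out


def _profile_one(
    objective,
    param_index: int,
    mle_log10: np.ndarray,
    minus_ll_min: float,
    bounds_log10: list,
    grid: GridSpec,
    n_points: int = PROFILE_POINTS,
    n_dense: int = PROFILE_DENSE_POINTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile curve for one parameter: at each fixed value, minimize the
    objective over the other two parameters, warm-starting each point from
    its neighbor (outward sweep from the MLE)."""
    name = PARAM_NAMES[param_index]
    values = _profile_grid(grid, name, mle_log10[param_index], n_points, n_dense)
    free = [i for i in range(3) if i != param_index]
    nuis_bounds = [bounds_log10[i] for i in free]
    pl = np.empty_like(values)

    def solve(v, nuis0):
        def f2(y):
            x = np.empty(3)
            x[param_index] = v
            x[free[0]], x[free[1]] = y
            return objective(x)

        y, fv, _ = _refine(f2, nuis0, nuis_bounds)
        return y, fv

    anchor = int(np.argmin(np.abs(values - mle_log10[param_index])))
    # sweep right then left from the anchor, warm-starting nuisances
    nuis0 = mle_log10[free]
    for idx in range(anchor, len(values)):
        nuis0, pl[idx] = solve(values[idx], nuis0)
    nuis0 = mle_log10[free]
    for idx in range(anchor - 1, -1, -1):
        nuis0, pl[idx] = solve(values[idx], nuis0)
    # the curve can never dip below the global minimum (numerical slack)
    pl = np.maximum(pl, minus_ll_min - 1e-6)
    return values, pl


def _ci_from_curve(
    values_log10: np.ndarray,
    pl: np.ndarray,
    minus_ll_min: float,
    grid_range: tuple[float, float],
    threshold: float = CI_THRESHOLD,
):
    """First threshold crossings outward from the curve minimum, linearly
    interpolated in (log10 value, profile) coordinates.  A side that never
    crosses is pinned to the grid-range edge and flagged."""
    level = minus_ll_min + threshold
    k0 = int(np.argmin(pl))
    lo_edge, hi_edge = np.log10(grid_range)

    def cross(direction):
        idx = range(k0 + 1, len(values_log10)) if direction > 0 else range(k0 - 1, -1, -1)
        prev = k0
        for j in idx:
            if pl[j] > level:
                v0, v1 = values_log10[prev], values_log10[j]
                f0, f1 = pl[prev], pl[j]
                t = (level - f0) / (f1 - f0)
                return v0 + t * (v1 - v0), False
            prev = j
        return (hi_edge if direction > 0 else lo_edge), True

    ub_log10, upper_at_edge = cross(+1)
    lb_log10, lower_at_edge = cross(-1)
    return (10.0 ** lb_log10, 10.0 ** ub_log10), lower_at_edge, upper_at_edge


def apm(ci: tuple[float, float], T: float) -> float:
    """APM = log_T(theta_ub / theta_lb); 0 for a point CI, 1 when the CI
    bound ratio equals T."""
    lb, ub = ci
    if lb <= 0:
        raise ValueError(f"CI lower bound must be > 0, got {lb}")
    if ub < lb:
        raise ValueError(f"CI upper bound {ub} below lower bound {lb}")
    if T <= 1:
        raise ValueError(f"T must be > 1, got {T}")
    return float(np.log(ub / lb) / np.log(T))


def classify_identifiability(
    profile: ProfileResult, config: APMConfig | None = None
) -> tuple[bool, float]:
    """Overall APM = max over parameters; identifiable iff below cutoff."""
    if config is None:
        config = APMConfig()
    overall = max(c.apm for c in profile.curves.values())
    return overall < config.cutoff, overall


def profile_likelihood(
    target,
    library: ModelLibrary,
    param_index: int,
    config: APMConfig | None = None,
    fit: MLEFit | None = None,
    capture: CaptureModel | None = None,
    tol: float = 1e-4,
) -> ProfileCurve:
    """Profile one parameter of the likelihood for a target histogram."""
    if config is None:
        config = APMConfig()
    if capture is None:
        capture = CaptureModel(library.capture_rate)
    if fit is None:
        fit = fit_mle(target, library, capture=capture, tol=tol)
    from .library import _target_weights

    weights, _ = _target_weights(target)
    objective = WeightedNegLogLik(weights, capture, tol=tol)
    name = PARAM_NAMES[param_index]
    mle_log10 = np.log10(fit.theta.as_array())
    values_log10, pl = _profile_one(
        objective, param_index, mle_log10, fit.minus_ll, fit.bounds_log10, library.grid
    )
    ci, lo_edge, hi_edge = _ci_from_curve(
        values_log10, pl, fit.minus_ll, library.grid.range_of(name)
    )
    return ProfileCurve(
        param=name,
        values=10.0 ** values_log10,
        minus_ll=pl,
        ci=ci,
        lower_at_edge=lo_edge,
        upper_at_edge=hi_edge,
        apm=apm(ci, config.T[name]),
    )


def profile_all(
    target,
    library: ModelLibrary,
    config: APMConfig | None = None,
    capture: CaptureModel | None = None,
    tol: float = 1e-4,
) -> ProfileResult:
    """MLE plus all three profile curves, CIs, APMs and the overall verdict."""
    if config is None:
        config = APMConfig()
    fit = fit_mle(target, library, capture=capture, tol=tol)
    curves = {}
    for i, name in enumerate(PARAM_NAMES):
        curves[name] = profile_likelihood(
            target, library, i, config=config, fit=fit, capture=capture, tol=tol
        )
    result = ProfileResult(
        mle=fit.theta,
        minus_ll_min=fit.minus_ll,
        curves=curves,
        overall_apm=np.nan,
        identifiable=False,
    )
    result.identifiable, result.overall_apm = classify_identifiability(result, config)
    return result
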