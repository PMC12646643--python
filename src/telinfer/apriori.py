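"""A priori (sampling-free) identifiability analysis.

For a hypothetical experiment with N cells at ground truth theta_tar, the
expected negative log-likelihood is the scaled cross-entropy

    H(theta) = -N sum_x P_tar(x) log P_sim(x | theta)

which, by Gibbs' inequality, is minimized exactly at theta_tar.  Profile
likelihoods built from H ("ground-truth profiles") equal the average over
infinitely many sampled replicates of N cells, so identifiability can be
assessed without generating data.  Because N enters only as a scalar
multiple, profiles are computed once per target at N = 1 and rescaled to
any cell number; only the CI threshold crossing must be re-found per N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cme import MarginalDistribution, ParamVector
from .inference import (
    APMConfig,
    CI_THRESHOLD,
    ProfileCurve,
    ProfileResult,
    WeightedNegLogLik,
    _ci_from_curve,
    _profile_one,
    apm,
    classify_identifiability,
    fit_mle,
)
from .library import PARAM_NAMES, GridSpec, ModelLibrary, surface_from_weights
from .noise import CaptureModel, captured_marginal

__all__ = [
    "AprioriTarget",
    "UnitProfile",
    "LandscapeResult",
    "cross_entropy_objective",
    "ground_truth_profile",
    "unit_profile",
    "profile_at_n",
    "scan_landscape",
    "cells_for_identifiability",
]


@dataclass(frozen=True)
class AprioriTarget:
    """Exact model-generated target: ground truth, cell count, capture."""

    theta_tar: ParamVector
    N: float
    capture: CaptureModel = field(default_factory=CaptureModel)
    tol: float = 1e-4

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("hypothetical cell count N must be >= 1")

    @property
    def p_tar(self) -> MarginalDistribution:
        return captured_marginal(self.theta_tar, self.capture, tol=self.tol)


def cross_entropy_objective(target: AprioriTarget, theta: ParamVector) -> float:
    """H(theta) = -N sum_x P_tar(x) log P_sim(x | theta)."""
    obj = WeightedNegLogLik(
        target.N * np.asarray(target.p_tar.probabilities),
        target.capture,
        tol=target.tol,
    )
    return obj.at_theta(theta)


@dataclass
class UnitProfile:
    """Per-cell (N = 1) ground-truth profile curves for one target.

    ``curves`` maps parameter name -> (values_log10, per-cell profile);
    ``h_min`` is the per-cell objective minimum (the Shannon entropy of the
    floored target distribution, which Gibbs' inequality makes exact).
    """

    theta_tar: ParamVector
    beta: float
    grid: GridSpec
    h_min: float
    curves: dict


def unit_profile(
    theta_tar: ParamVector,
    capture: CaptureModel | float,
    library: ModelLibrary,
    tol: float = 1e-4,
    n_points: int | None = None,
    n_dense: int | None = None,
) -> UnitProfile:
    """Fine ground-truth profile curves at N = 1 (rescalable to any N).

    ``n_points``/``n_dense`` override the profile-grid resolution (used by
    landscape scans to trade CI precision for speed)."""
    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    if abs(capture.beta - library.capture_rate) > 1e-12:
        raise ValueError(
            f"library built at beta={library.capture_rate}, target at {capture.beta}"
        )
    target = AprioriTarget(theta_tar=theta_tar, N=1, capture=capture, tol=tol)
    weights = np.asarray(target.p_tar.probabilities, dtype=float)
    objective = WeightedNegLogLik(weights, capture, tol=tol)
    fit = fit_mle((target.p_tar, 1.0), library, capture=capture, tol=tol)
    # Gibbs: theta_tar is the exact global minimizer of H; keep whichever of
    # (optimizer result, target itself) is lower
    h_at_tar = objective.at_theta(theta_tar)
    if h_at_tar <= fit.minus_ll:
        fit.theta = theta_tar
        fit.minus_ll = h_at_tar
    mle_log10 = np.log10(fit.theta.as_array())
    from .inference import PROFILE_DENSE_POINTS, PROFILE_POINTS

    np_, nd_ = (
        PROFILE_POINTS if n_points is None else n_points,
        PROFILE_DENSE_POINTS if n_dense is None else n_dense,
    )
    curves = {}
    for i, name in enumerate(PARAM_NAMES):
        values_log10, pl = _profile_one(
            objective, i, mle_log10, fit.minus_ll, fit.bounds_log10, library.grid,
            n_points=np_, n_dense=nd_,
        )
        curves[name] = (values_log10, pl)
    return UnitProfile(
        theta_tar=theta_tar,
        beta=capture.beta,
        grid=library.grid,
        h_min=fit.minus_ll,
        curves=curves,
    )


def profile_at_n(
    unit: UnitProfile, N: float, config: APMConfig | None = None
) -> ProfileResult:
    """Rescale a unit profile to N cells and re-cut CIs and APMs."""
    if config is None:
        config = APMConfig()
    curves = {}
    for name, (values_log10, pl_unit) in unit.curves.items():
        pl = N * pl_unit
        ci, lo_edge, hi_edge = _ci_from_curve(
            values_log10, pl, N * unit.h_min, unit.grid.range_of(name)
        )
        curves[name] = ProfileCurve(
            param=name,
            values=10.0 ** values_log10,
            minus_ll=pl,
            ci=ci,
            lower_at_edge=lo_edge,
            upper_at_edge=hi_edge,
            apm=apm(ci, config.T[name]),
        )
    result = ProfileResult(
        mle=unit.theta_tar,
        minus_ll_min=N * unit.h_min,
        curves=curves,
        overall_apm=np.nan,
        identifiable=False,
    )
    result.identifiable, result.overall_apm = classify_identifiability(result, config)
    return result


def ground_truth_profile(
    target: AprioriTarget,
    library: ModelLibrary,
    config: APMConfig | None = None,
) -> ProfileResult:
    """Ground-truth profile likelihood and APM verdict for one target."""
    unit = unit_profile(target.theta_tar, target.capture, library, tol=target.tol)
    return profile_at_n(unit, target.N, config=config)


# -- landscape scans --------------------------------------------------------


@dataclass
class LandscapeResult:
    """Per-point APM over a scanned sub-grid of ground-truth parameter sets."""

    table: pd.DataFrame
    N: float
    beta: float

    @property
    def fraction_identifiable(self) -> float:
        return float(self.table["identifiable"].mean())


def _coarse_profile_result(
    weights: np.ndarray,
    h_min: float,
    library: ModelLibrary,
    N: float,
    config: APMConfig,
) -> ProfileResult:
    """Library-resolution ground-truth profiles: the profile of parameter i
    is the minimum of the coarse surface over the other two grid axes, with
    CI crossings interpolated between grid nodes."""
    surface = surface_from_weights(weights, library)
    smin = np.nanmin(surface)
    h_min = min(h_min, smin)
    curves = {}
    for i, name in enumerate(PARAM_NAMES):
        other = tuple(j for j in range(3) if j != i)
        pl_unit = np.nanmin(surface, axis=other)
        values_log10 = np.log10(library.grid.axis(name))
        pl = N * pl_unit
        ci, lo_edge, hi_edge = _ci_from_curve(
            values_log10, pl, N * h_min, library.grid.range_of(name)
        )
        curves[name] = ProfileCurve(
            param=name,
            values=10.0 ** values_log10,
            minus_ll=pl,
            ci=ci,
            lower_at_edge=lo_edge,
            upper_at_edge=hi_edge,
            apm=apm(ci, config.T[name]),
        )
    flat_argmin = int(np.nanargmin(surface.reshape(-1)))
    result = ProfileResult(
        mle=library.grid.param_at(flat_argmin),
        minus_ll_min=N * h_min,
        curves=curves,
        overall_apm=np.nan,
        identifiable=False,
    )
    result.identifiable, result.overall_apm = classify_identifiability(result, config)
    return result


def subsample_axis_indices(n_points: int, k: int) -> np.ndarray:
    """k roughly evenly spaced axis indices out of n_points (ends included)."""
    return np.unique(np.round(np.linspace(0, n_points - 1, k)).astype(int))


def scan_landscape(
    library: ModelLibrary,
    N: float,
    config: APMConfig | None = None,
    subgrid: int | None = None,
    fine: bool = True,
    profile_points: int = 14,
    dense_points: int = 6,
    tol: float = 1e-4,
) -> LandscapeResult:
    """APM landscape: each scanned library grid point acts as ground truth.

    ``subgrid`` keeps only that many points per axis (evenly spaced within
    the library grid); the default scans the whole library.  The default
    mode computes one ground-truth profile per point with nuisance
    parameters re-optimized continuously, at a reduced profile-grid
    resolution (``profile_points`` range-spanning values per parameter).
    ``fine=False`` restricts nuisance minimization to the library grid:
    much faster, but it cannot follow the narrow kon/koff compensation
    valleys, so it systematically understates CI widths (overstates
    identifiability) in the fast- and compensating-switching regimes; use
    it only for rough previews.
    """
    if config is None:
        config = APMConfig()
    capture = CaptureModel(library.capture_rate)
    per_axis = []
    for name in PARAM_NAMES:
        n = library.grid.points_of(name)
        per_axis.append(
            np.arange(n) if subgrid is None else subsample_axis_indices(n, subgrid)
        )
    rows = []
    for i in per_axis[0]:
        for j in per_axis[1]:
            for k in per_axis[2]:
                flat = int(np.ravel_multi_index((i, j, k), library.grid.shape))
                theta = library.grid.param_at(flat)
                p = library.distributions[flat]
                if p is None:
                    rows.append(
                        {"kon": theta.kon, "koff": theta.koff, "ksyn": theta.ksyn,
                         "failed": True}
                    )
                    continue
                if fine:
                    unit = unit_profile(
                        theta, capture, library, tol=tol,
                        n_points=profile_points, n_dense=dense_points,
                    )
                    res = profile_at_n(unit, N, config=config)
                else:
                    w = np.asarray(p, dtype=float)
                    h_min = float(-(w[w > 0] @ np.log(w[w > 0])))
                    res = _coarse_profile_result(w, h_min, library, N, config)
                row = {
                    "kon": theta.kon,
                    "koff": theta.koff,
                    "ksyn": theta.ksyn,
                    "failed": False,
                    "apm_max": res.overall_apm,
                    "identifiable": res.identifiable,
                }
                for name, c in res.curves.items():
                    row[f"apm_{name}"] = c.apm
                rows.append(row)
    table = pd.DataFrame(rows)
    return LandscapeResult(table=table, N=N, beta=library.capture_rate)


def cells_for_identifiability(
    theta_tar: ParamVector,
    capture: CaptureModel | float,
    N_ladder,
    library: ModelLibrary,
    config: APMConfig | None = None,
    tol: float = 1e-4,
):
    """Smallest cell count on an increasing ladder reaching overall APM <
    cutoff, or None if no ladder entry suffices.

    Profiles are computed once at N = 1 and rescaled per ladder entry (the
    objective is exactly linear in N); by PL N-scaling the verdict is
    monotone along the ladder, so the first success is returned.
    """
    if config is None:
        config = APMConfig()
    ladder = list(N_ladder)
    if any(b > a for a, b in zip(ladder[1:], ladder[:-1])):
        raise ValueError("N_ladder must be increasing")
    unit = unit_profile(theta_tar, capture, library, tol=tol)
    for N in ladder:
        res = profile_at_n(unit, N, config=config)
        if res.identifiable:
            return N
    return None
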