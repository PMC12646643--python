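"""Coarse-grained reference library of telegraph-model steady states.

The library tabulates the capture-transformed stationary mRNA distribution
on a 3D log10-spaced grid over (kon, koff, ksyn).  The production default is
60 points per axis over kon, koff in [1e-3, 1e3] and ksyn in
[10^-0.3, 10^2.3]; reduced grids (e.g. 12^3) serve tests and quick scans.

Against a target histogram (or an exact target distribution with a
hypothetical cell count N) the library yields, in one vectorized pass, the
negative log-likelihood (or the cross-entropy surrogate) at every grid
point: a coarse objective surface whose argmin seeds the fine optimizer and
whose low-lying region defines its search box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import __version__
from .cme import MarginalDistribution, ParamVector, TruncationError
from .noise import CaptureModel, captured_marginal

__all__ = [
    "GridSpec",
    "ModelLibrary",
    "build_library",
    "coarse_surface",
    "search_bounds_from_surface",
]

#: floor applied to model probabilities inside logarithms
PROB_FLOOR = 1e-12

#: coarse search box margin above the CI threshold (1.92 + safety)
SEARCH_DELTA = 1.92 + 2.0

PARAM_NAMES = ("kon", "koff", "ksyn")


@dataclass(frozen=True)
class GridSpec:
    """Log10-spaced parameter grid.

    Ranges are (low, high) in linear units; ``n_points`` applies to every
    axis unless a per-axis count (``kon_points`` etc.) overrides it.
    """

    kon_range: tuple[float, float] = (1e-3, 1e3)
    koff_range: tuple[float, float] = (1e-3, 1e3)
    ksyn_range: tuple[float, float] = (10 ** -0.3, 10 ** 2.3)
    n_points: int = 60
    kon_points: int | None = None
    koff_points: int | None = None
    ksyn_points: int | None = None

    def __post_init__(self):
        for name in PARAM_NAMES:
            if self.points_of(name) < 2:
                raise ValueError("grids need at least 2 points per axis")
            lo, hi = getattr(self, f"{name}_range")
            if not (0 < lo < hi < np.inf):
                raise ValueError(f"bad {name} range ({lo}, {hi})")

    def points_of(self, name: str) -> int:
        override = getattr(self, f"{name}_points")
        return int(self.n_points if override is None else override)

    def axis(self, name: str) -> np.ndarray:
        """Grid values for one parameter, log10-spaced, ascending."""
        lo, hi = getattr(self, f"{name}_range")
        return np.logspace(np.log10(lo), np.log10(hi), self.points_of(name))

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.axis(n) for n in PARAM_NAMES)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.points_of(n) for n in PARAM_NAMES)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def param_at(self, flat_index: int) -> ParamVector:
        """Parameter vector at a flat grid index (kon-major ordering)."""
        i, j, k = np.unravel_index(flat_index, self.shape)
        kon_ax, koff_ax, ksyn_ax = self.axes
        return ParamVector(kon_ax[i], koff_ax[j], ksyn_ax[k])

    def range_of(self, name: str) -> tuple[float, float]:
        return getattr(self, f"{name}_range")

    def to_dict(self) -> dict:
        return {
            "kon_range": list(self.kon_range),
            "koff_range": list(self.koff_range),
            "ksyn_range": list(self.ksyn_range),
            "n_points": self.n_points,
            "kon_points": self.kon_points,
            "koff_points": self.koff_points,
            "ksyn_points": self.ksyn_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            kon_range=tuple(d["kon_range"]),
            koff_range=tuple(d["koff_range"]),
            ksyn_range=tuple(d["ksyn_range"]),
            n_points=int(d["n_points"]),
            kon_points=d.get("kon_points"),
            koff_points=d.get("koff_points"),
            ksyn_points=d.get("ksyn_points"),
        )


@dataclass
class ModelLibrary:
    """Grid of capture-transformed stationary distributions.

    ``distributions`` is a flat list aligned with kon-major flat grid
    indices; entries are probability vectors of per-point length.  Points
    whose truncation failed are None and listed in ``failed_points``.
    """

    grid: GridSpec
    capture_rate: float
    distributions: list
    tail_tol: float
    failed_points: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def marginal_at(self, flat_index: int) -> MarginalDistribution:
        p = self.distributions[flat_index]
        if p is None:
            raise TruncationError(f"grid point {flat_index} failed to build", np.nan)
        return MarginalDistribution(
            probabilities=p, truncation_bound=len(p) - 1, tail_mass_error=self.tail_tol
        )

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write to HDF5: flat probability array + offsets + grid metadata."""
        lengths = np.array(
            [0 if p is None else len(p) for p in self.distributions], dtype=np.int64
        )
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        flat = np.concatenate(
            [p for p in self.distributions if p is not None]
            if any(p is not None for p in self.distributions)
            else [np.zeros(0)]
        )
        with h5py.File(path, "w") as f:
            f.create_dataset("probabilities", data=flat)
            f.create_dataset("offsets", data=offsets)
            f.attrs["capture_rate"] = self.capture_rate
            f.attrs["tail_tol"] = self.tail_tol
            f.attrs["grid_json"] = json.dumps(self.grid.to_dict())
            f.attrs["failed_points"] = json.dumps(self.failed_points)
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def load(cls, path) -> "ModelLibrary":
        with h5py.File(path, "r") as f:
            flat = f["probabilities"][...]
            offsets = f["offsets"][...]
            grid = GridSpec.from_dict(json.loads(f.attrs["grid_json"]))
            beta = float(f.attrs["capture_rate"])
            tol = float(f.attrs["tail_tol"])
            failed = json.loads(f.attrs["failed_points"])
            prov = json.loads(f.attrs["provenance"])
        dists = []
        for i in range(len(offsets) - 1):
            lo, hi = offsets[i], offsets[i + 1]
            dists.append(None if hi == lo else flat[lo:hi])
        return cls(
            grid=grid,
            capture_rate=beta,
            distributions=dists,
            tail_tol=tol,
            failed_points=failed,
            provenance=prov,
        )


def build_library(
    grid: GridSpec,
    capture: CaptureModel | float = 1.0,
    tol: float = 1e-4,
    progress: bool = False,
) -> ModelLibrary:
    """Solve the CME at every grid point and store the captured marginals.

    Deterministic given (grid, capture, tol).  Truncation failures are
    recorded per point and the build continues.
    """
    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    dists: list = []
    failed: list = []
    iterator = range(grid.size)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(iterator, desc="building library")
    for flat in iterator:
        theta = grid.param_at(flat)
        try:
            m = captured_marginal(theta, capture, tol=tol)
            dists.append(np.asarray(m.probabilities, dtype=float))
        except TruncationError as exc:
            dists.append(None)
            failed.append({"index": flat, "error": str(exc)})
    return ModelLibrary(
        grid=grid,
        capture_rate=capture.beta,
        distributions=dists,
        tail_tol=tol,
        failed_points=failed,
        provenance={"version": __version__, "n_points": grid.n_points},
    )


def _target_weights(target) -> tuple[np.ndarray, float]:
    """Normalize a target into (weights over x = 0..K, total N).

    Accepts a CountHistogram-like object (``.count_vector()``/``.N``) or a
    pair (MarginalDistribution, N) for the exact (a priori) mode where the
    weights are N * P_tar(x).
    """
    from .inference import CountHistogram

    if isinstance(target, CountHistogram):
        return target.count_vector().astype(float), float(target.N)
    if isinstance(target, tuple) and len(target) == 2:
        dist, n = target
        return float(n) * np.asarray(dist.probabilities, dtype=float), float(n)
    raise TypeError(f"unsupported target type {type(target)!r}")


def surface_from_weights(weights: np.ndarray, library: ModelLibrary) -> np.ndarray:
    """Grid-shaped array of -sum_x w_x log P_x(theta) over all grid points."""
    K = len(weights)
    out = np.full(library.grid.size, np.nan)
    logw_support = weights > 0
    for flat, p in enumerate(library.distributions):
        if p is None:
            continue
        if len(p) >= K:
            q = p[:K]
        else:
            q = np.concatenate([p, np.zeros(K - len(p))])
        out[flat] = -(weights[logw_support] @ np.log(np.maximum(q[logw_support], PROB_FLOOR)))
    return out.reshape(library.grid.shape)


def coarse_surface(target, library: ModelLibrary) -> np.ndarray:
    """Coarse objective surface of the target against every library entry.

    For a sampled histogram this is the negative log-likelihood
    -sum_x n_x log P_x(theta); for an exact target distribution with
    hypothetical cell count N it is the cross-entropy surrogate
    H(theta) = -N sum_x P_tar(x) log P_x(theta).  Returned with the grid
    shape (kon, koff, ksyn); failed grid points are NaN.
    """
    weights, n = _target_weights(target)
    if weights.sum() <= 0:
        raise ValueError("empty target: no cells / no probability mass")
    return surface_from_weights(weights, library)


def search_bounds_from_surface(
    surface: np.ndarray, grid: GridSpec, delta: float = SEARCH_DELTA
):
    """Optimization box and seed from the coarse surface.

    The box encloses every grid point within ``delta`` of the surface
    minimum, expanded by one grid step per side and clipped to the grid
    range; the seed is the coarse argmin (lowest flat index on ties,
    kon-major ordering).  Returns (bounds_log10, x0_log10) where both are in
    log10 parameter units and bounds_log10 is a list of three (lo, hi).
    """
    s = np.asarray(surface)
    finite = np.isfinite(s)
    if not finite.any():
        raise ValueError("coarse surface has no finite values")
    smin = np.nanmin(s)
    flat_argmin = int(np.nanargmin(s.reshape(-1)))
    within = (s <= smin + delta) & finite
    bounds = []
    for axis_idx, name in enumerate(PARAM_NAMES):
        ax = np.log10(grid.axis(name))
        step = ax[1] - ax[0]
        mask = within.any(axis=tuple(i for i in range(3) if i != axis_idx))
        idx = np.where(mask)[0]
        lo = max(ax[0], ax[idx.min()] - step)
        hi = min(ax[-1], ax[idx.max()] + step)
        bounds.append((lo, hi))
    theta0 = grid.param_at(flat_argmin)
    x0 = np.log10(theta0.as_array())
    return bounds, x0
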