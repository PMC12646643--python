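"""Synthetic count data from the telegraph model, and distribution summaries.

Steady-state snapshots of N cells are exactly N iid draws from the
capture-transformed stationary marginal, so sampling is multinomial over the
truncated support (a stochastic-simulation run would give the same law at
far higher cost).  Bootstrap replicates drive the consistency check between
sampled-MLE spread and the ground-truth profile likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cme import MarginalDistribution, ParamVector
from .inference import CountHistogram, MLEFit, fit_mle
from .library import ModelLibrary
from .noise import CaptureModel, captured_marginal

__all__ = [
    "ReplicateSet",
    "sample_histogram",
    "bootstrap_mles",
    "summary_statistics",
]


@dataclass
class ReplicateSet:
    """Reproducible bundle of sampled histograms (and optional MLEs)."""

    theta_true: ParamVector
    N: int
    beta: float
    seed: int
    histograms: list = field(default_factory=list)
    mles: list | None = None


def sample_histogram(
    theta: ParamVector,
    N: int,
    capture: CaptureModel | float = 1.0,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-4,
) -> CountHistogram:
    """Histogram of N iid cells drawn from the captured model marginal."""
    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    if N < 1:
        raise ValueError("need at least one cell")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(captured_marginal(theta, capture, tol=tol).probabilities)
    p = p / p.sum()
    counts = rng.multinomial(N, p)
    return CountHistogram(counts=counts)


def bootstrap_mles(
    theta: ParamVector,
    N: int,
    capture: CaptureModel | float,
    n_reps: int,
    seed: int,
    library: ModelLibrary,
    tol: float = 1e-4,
) -> ReplicateSet:
    """Sample ``n_reps`` histograms and fit the MLE on each.

    Per-replicate seeds are spawned from the master seed, so the set is
    reproducible and replicates are independent.
    """
    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    master = np.random.SeedSequence(seed)
    out = ReplicateSet(theta_true=theta, N=N, beta=capture.beta, seed=seed, mles=[])
    for child in master.spawn(n_reps):
        rng = np.random.default_rng(child)
        hist = sample_histogram(theta, N, capture, seed=rng, tol=tol)
        out.histograms.append(hist)
        fit: MLEFit = fit_mle(hist, library, capture=capture, tol=tol)
        out.mles.append(fit.theta)
    return out


def _probabilities_of(obj) -> np.ndarray:
    if isinstance(obj, CountHistogram):
        return obj.count_vector() / obj.N
    if isinstance(obj, MarginalDistribution):
        return np.asarray(obj.probabilities, dtype=float)
    p = np.asarray(obj, dtype=float)
    return p / p.sum()


def summary_statistics(hist_or_dist) -> dict:
    """Moment and shape summaries of a count histogram or distribution.

    Returns mean, variance, Fano factor (variance/mean; None when the mean
    is zero), skewness, zero fraction, and a bimodality indicator: the
    number of interior local maxima of the probability sequence after a
    window-3 moving-average smooth.
    """
    p = _probabilities_of(hist_or_dist)
    if len(p) == 0 or p.sum() <= 0:
        raise ValueError("empty input")
    x = np.arange(len(p))
    mean = float(x @ p)
    var = float((x - mean) ** 2 @ p)
    fano = var / mean if mean > 0 else None
    if var > 0:
        skewness = float(((x - mean) ** 3 @ p) / var ** 1.5)
    else:
        skewness = 0.0
    smoothed = np.convolve(p, np.ones(3) / 3.0, mode="same")
    interior = smoothed[1:-1]
    n_modes = int(
        np.sum((interior > smoothed[:-2]) & (interior > smoothed[2:]))
    ) if len(p) >= 3 else 0
    return {
        "mean": mean,
        "variance": var,
        "fano": fano,
        "skewness": skewness,
        "zero_fraction": float(p[0]),
        "n_modes": n_modes,
    }
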