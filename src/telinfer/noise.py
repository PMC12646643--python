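"""Binomial capture ("dropout") model for scRNA-seq measurement noise.

Each true mRNA molecule is observed independently with probability
``beta`` (the capture rate, assumed known), so an underlying copy number x
yields an observed count y ~ Binomial(x, beta).  On distributions this acts
as a lower-triangular binomial downsampling matrix.  For the telegraph model
this transform is equivalent to scaling the synthesis rate ksyn by beta;
the matrix transform is kept as the canonical route because it applies
unchanged to models without that equivalence, while the ksyn-scaling
shortcut is exposed as a fast path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .cme import MarginalDistribution

__all__ = [
    "CaptureModel",
    "downsample_distribution",
    "downsample_counts",
    "captured_marginal",
]


@dataclass(frozen=True)
class CaptureModel:
    """Known per-molecule capture probability beta in (0, 1]."""

    beta: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"capture rate must be in (0, 1], got {self.beta!r}")


from functools import lru_cache


@lru_cache(maxsize=64)
def _binomial_matrix_cached(n_states: int, beta: float) -> np.ndarray:
    x = np.arange(n_states)
    return binom.pmf(x[:, None], x[None, :], beta)


def binomial_matrix(n_states: int, beta: float) -> np.ndarray:
    """Dense (n_states x n_states) matrix B with B[y, x] = P(Bin(x, beta) = y).

    Built from the log-PMF so it stays finite for supports well beyond the
    overflow point of the binomial coefficient.
    """
    return _binomial_matrix_cached(int(n_states), float(beta))


def downsample_distribution(
    p: MarginalDistribution, capture: CaptureModel
) -> MarginalDistribution:
    """Push a copy-number distribution through binomial capture at rate beta.

    output[y] = sum_{x >= y} p[x] * C(x, y) * beta^y * (1-beta)^(x-y).
    """
    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    if capture.beta == 1.0:
        return p
    probs = np.asarray(p.probabilities, dtype=float)
    B = binomial_matrix(len(probs), capture.beta)
    q = B @ probs
    q = np.where(q < 0, 0.0, q)
    q = q / q.sum()
    return MarginalDistribution(
        probabilities=q,
        truncation_bound=p.truncation_bound,
        tail_mass_error=p.tail_mass_error,
    )


def captured_marginal(
    theta,
    capture: CaptureModel,
    tol: float = None,
    fast: bool = False,
):
    """Capture-transformed model marginal P(y | theta, beta).

    ``fast=True`` uses the telegraph-specific equivalence (binomial thinning
    of the stationary law equals solving the model with ksyn scaled by beta);
    the default route solves the model and applies the downsampling matrix,
    which generalizes beyond the telegraph model.
    """
    from . import cme

    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    if tol is None:
        tol = cme.DEFAULT_TAIL_TOL
    if fast and capture.beta < 1.0:
        scaled = cme.ParamVector(theta.kon, theta.koff, theta.ksyn * capture.beta)
        return cme.cached_marginal(scaled, tol=tol)
    p = cme.cached_marginal(theta, tol=tol)
    return downsample_distribution(p, capture)


def downsample_counts(x: int, capture: CaptureModel, rng_seed) -> int:
    """Single binomial thinning draw y ~ Binomial(x, beta); reproducible."""
    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    if x < 0:
        raise ValueError(f"mRNA count must be nonnegative, got {x}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return int(rng.binomial(x, capture.beta))
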