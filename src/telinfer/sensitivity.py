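"""Structural identifiability via the steady-state sensitivity matrix.

S[j, i] = d y_j / d theta_i, where y_j is the capture-transformed stationary
probability of observing j mRNA and theta_i ranges over (kon, koff, ksyn) in
log10 units (matching the log-spaced grid geometry).  A strictly positive
minimum singular value of S means no direction in parameter space leaves the
model output unchanged to first order — structural identifiability — even
where the value is tiny and finite data cannot exploit it (the practical
identifiability question answered by the profile-likelihood pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cme import ParamVector
from .library import PARAM_NAMES, GridSpec
from .noise import CaptureModel, captured_marginal

__all__ = ["SensitivityResult", "sensitivity_matrix", "scan_min_singular_values"]

#: central finite-difference step in log10-parameter units (decades)
FD_STEP = 1e-3


@dataclass
class SensitivityResult:
    theta: ParamVector
    S: np.ndarray                  # (n_states, 3), columns ordered kon, koff, ksyn
    singular_values: np.ndarray    # descending
    min_singular_value: float


def _padded(p: np.ndarray, length: int) -> np.ndarray:
    if len(p) >= length:
        return p[:length]
    return np.concatenate([p, np.zeros(length - len(p))])


def sensitivity_matrix(
    theta: ParamVector,
    capture: CaptureModel | float = 1.0,
    step: float = FD_STEP,
    tol: float = 1e-4,
) -> SensitivityResult:
    """Central finite differences of the captured marginal in log10 rates.

    All six perturbed solves are aligned on a common support (the longest
    truncation among them, shorter vectors zero-padded: any mass there is
    below the truncation tolerance by construction).
    """
    if not isinstance(capture, CaptureModel):
        capture = CaptureModel(capture)
    base = np.log10(theta.as_array())
    plus, minus = [], []
    for i in range(3):
        for sign, store in ((+1, plus), (-1, minus)):
            x = base.copy()
            x[i] += sign * step
            p = captured_marginal(
                ParamVector.from_array(10.0 ** x), capture, tol=tol
            ).probabilities
            store.append(np.asarray(p, dtype=float))
    length = max(len(p) for p in plus + minus)
    cols = []
    for i in range(3):
        d = (_padded(plus[i], length) - _padded(minus[i], length)) / (2.0 * step)
        cols.append(d)
    S = np.column_stack(cols)
    sv = np.linalg.svd(S, compute_uv=False)
    return SensitivityResult(
        theta=theta,
        S=S,
        singular_values=sv,
        min_singular_value=float(sv[-1]),
    )


def scan_min_singular_values(
    grid: GridSpec,
    capture: CaptureModel | float = 1.0,
    subgrid: int | None = None,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Minimum singular value of S at each (sub-)grid point.

    Per-point failures are recorded (NaN + failed flag) and the scan
    continues.
    """
    from .apriori import subsample_axis_indices

    per_axis = []
    for name in PARAM_NAMES:
        n = grid.points_of(name)
        per_axis.append(
            np.arange(n) if subgrid is None else subsample_axis_indices(n, subgrid)
        )
    rows = []
    for i in per_axis[0]:
        for j in per_axis[1]:
            for k in per_axis[2]:
                flat = int(np.ravel_multi_index((i, j, k), grid.shape))
                theta = grid.param_at(flat)
                row = {"kon": theta.kon, "koff": theta.koff, "ksyn": theta.ksyn}
                try:
                    res = sensitivity_matrix(theta, capture, tol=tol)
                    row["min_singular_value"] = res.min_singular_value
                    row["failed"] = False
                except Exception as exc:  # noqa: BLE001 - per-point isolation
                    row["min_singular_value"] = np.nan
                    row["failed"] = True
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)
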