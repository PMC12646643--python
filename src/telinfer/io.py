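"""Count-matrix readers, result writers, and run configuration.

Counts are raw (UMI-like) integer molecule counts: a genes x cells dense
TSV/CSV (gene names in the first column, cell IDs in the header) or a
MatrixMarket MTX triplet with features/barcodes sidecars.  Normalized or
log-transformed matrices are rejected — the likelihood requires raw counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from . import __version__
from .inference import CountHistogram

logger = logging.getLogger("telinfer")

__all__ = ["RunConfig", "read_counts", "read_long_histograms", "write_results"]


@dataclass
class RunConfig:
    """Run-level settings, serialized verbatim into every output."""

    capture_rate: float = 1.0
    library_path: str | None = None
    grid_points: int = 60
    apm_T: dict = field(default_factory=lambda: {"ksyn": 3.0, "kon": 100.0, "koff": 100.0})
    apm_cutoff: float = 1.0
    tail_tol: float = 1e-4
    xatol_log10: float = 1e-4
    profile_points: int = 40
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0 < self.capture_rate <= 1):
            raise ValueError("capture_rate must be in (0, 1]")
        if self.tail_tol <= 0 or self.apm_cutoff <= 0:
            raise ValueError("tolerances must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _matrix_to_histograms(matrix: np.ndarray, gene_names) -> dict:
    if not np.allclose(matrix, np.round(matrix)):
        raise ValueError(
            "non-integer counts: expected raw molecule counts, not normalized values"
        )
    if np.any(matrix < 0):
        raise ValueError("negative counts encountered")
    matrix = matrix.astype(np.int64)
    out = {}
    for name, row in zip(gene_names, matrix):
        if row.sum() == 0 and len(row) == 0:
            logger.warning("gene %s has no cells; skipped", name)
            continue
        out[str(name)] = CountHistogram.from_cells(row, name=str(name))
    return out


def read_counts(path, fmt: str = "auto") -> dict:
    """Read a genes x cells count matrix into per-gene CountHistograms.

    Returns an ordered mapping gene name -> CountHistogram.  ``fmt`` is one
    of auto/tsv/csv/mtx; auto dispatches on the file extension.
    """
    path = Path(path)
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        if df.isna().any().any():
            raise ValueError("count matrix contains missing entries")
        return _matrix_to_histograms(df.to_numpy(), df.index)
    if fmt == "mtx":
        m = mmread(path)
        dense = np.asarray(m.todense() if hasattr(m, "todense") else m)
        features = path.parent / "features.tsv"
        if not features.exists():
            features = path.parent / "genes.tsv"
        if features.exists():
            names = pd.read_csv(features, sep="\t", header=None)[0].tolist()
        else:
            names = [f"gene{i}" for i in range(dense.shape[0])]
        return _matrix_to_histograms(dense, names)
    raise ValueError(f"unknown format {fmt!r}")


def read_long_histograms(path) -> dict:
    """Read long-format simulate output (columns replicate, x, nx) back into
    per-replicate CountHistograms."""
    df = pd.read_csv(path, sep="\t")
    expected = {"replicate", "x", "nx"}
    if set(df.columns) != expected:
        raise ValueError(f"expected columns {sorted(expected)}, got {list(df.columns)}")
    out = {}
    for rep, grp in df.groupby("replicate"):
        vec = np.zeros(int(grp["x"].max()) + 1, dtype=np.int64)
        vec[grp["x"].to_numpy()] = grp["nx"].to_numpy()
        out[int(rep)] = CountHistogram(counts=vec, name=f"replicate{rep}")
    return out


RESULT_COLUMNS = [
    "gene", "N",
    "mle_kon", "mle_koff", "mle_ksyn", "minus_ll",
    "ci_kon_lb", "ci_kon_ub", "ci_koff_lb", "ci_koff_ub",
    "ci_ksyn_lb", "ci_ksyn_ub",
    "edge_kon_lb", "edge_kon_ub", "edge_koff_lb", "edge_koff_ub",
    "edge_ksyn_lb", "edge_ksyn_ub",
    "apm_kon", "apm_koff", "apm_ksyn", "apm_max", "identifiable",
]


def result_row(gene: str, N: int, profile) -> dict:
    """Flatten a ProfileResult into one TSV row."""
    row = {
        "gene": gene,
        "N": N,
        "mle_kon": profile.mle.kon,
        "mle_koff": profile.mle.koff,
        "mle_ksyn": profile.mle.ksyn,
        "minus_ll": profile.minus_ll_min,
        "apm_max": profile.overall_apm,
        "identifiable": profile.identifiable,
    }
    for name, c in profile.curves.items():
        row[f"ci_{name}_lb"], row[f"ci_{name}_ub"] = c.ci
        row[f"edge_{name}_lb"] = c.lower_at_edge
        row[f"edge_{name}_ub"] = c.upper_at_edge
        row[f"apm_{name}"] = c.apm
    return row


def write_results(rows, path, config: RunConfig | None = None) -> None:
    """Write result rows as TSV plus a JSON provenance sidecar.

    Deterministic column order, floats at 6 significant digits; a rerun with
    identical inputs produces a byte-identical TSV.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no results to write")
    df = pd.DataFrame(rows)
    cols = [c for c in RESULT_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in RESULT_COLUMNS
    ]
    df = df[cols]
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "version": __version__,
        "config": asdict(config) if config is not None else None,
        "n_rows": len(df),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
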