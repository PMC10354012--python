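"""Dynamic cross-correlation matrices (DCCM) of residue motions.

The DCCM entry for residues *i*, *j* is the normalized isotropic covariance
of their mean-centered displacement vectors,

    C_ij = <dr_i . dr_j> / sqrt(<dr_i . dr_i> <dr_j . dr_j>),

ranging from -1 (fully anti-correlated motion) through 0 (independent) to +1
(fully correlated).  Multiple replicates are accumulated by mean-centering
each replicate independently and concatenating, so slow inter-replicate
drift cannot masquerade as correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DisplacementSeries",
    "DCCMatrix",
    "BlockSummary",
    "read_displacement_table",
    "compute_dccm",
    "extract_block",
    "export_heatmap",
    "read_dccm_matrix",
]

DISPLACEMENT_COLUMNS = ("frame", "residue_id", "segment", "dx", "dy", "dz")


@dataclass(frozen=True)
class DisplacementSeries:
    """Per-frame 3-component displacement vectors for a set of residues."""

    residues: tuple[str, ...]
    segments: tuple[str, ...]
    vectors: np.ndarray  # (n_frames, n_residues, 3)
    replicate_id: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError("vectors must have shape (n_frames, n_residues, 3)")
        if v.shape[1] != len(self.residues) or len(self.segments) != len(self.residues):
            raise ValueError("residues/segments must match vector columns")
        if v.shape[0] < 2:
            raise ValueError("at least 2 frames required")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite displacement values")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n_f, n_r, _ = self.vectors.shape
        frames = np.repeat(np.arange(n_f), n_r)
        res = np.tile(np.array(self.residues, dtype=object), n_f)
        seg = np.tile(np.array(self.segments, dtype=object), n_f)
        flat = self.vectors.reshape(n_f * n_r, 3)
        return pd.DataFrame(
            {
                "frame": frames,
                "residue_id": res,
                "segment": seg,
                "dx": flat[:, 0],
                "dy": flat[:, 1],
                "dz": flat[:, 2],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_displacement_table(path: str | Path) -> DisplacementSeries:
    """Read a displacement table (frame, residue_id, segment, dx, dy, dz)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in DISPLACEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    residues = list(dict.fromkeys(df["residue_id"].astype(str)))
    seg_of = {
        str(r): str(s)
        for r, s in df.drop_duplicates("residue_id")[["residue_id", "segment"]].values
    }
    frames = np.sort(df["frame"].unique())
    wide = df.pivot_table(
        index="frame", columns="residue_id", values=["dx", "dy", "dz"], sort=True
    )
    if wide.isna().any().any():
        raise ValueError(f"{path}: missing residue rows for some frames")
    n_f, n_r = len(frames), len(residues)
    vec = np.empty((n_f, n_r, 3))
    for k, comp in enumerate(("dx", "dy", "dz")):
        vec[:, :, k] = wide[comp][residues].to_numpy()
    return DisplacementSeries(
        residues=tuple(residues),
        segments=tuple(seg_of[r] for r in residues),
        vectors=vec,
    )


@dataclass(frozen=True)
class DCCMatrix:
    residues: tuple[str, ...]
    segments: tuple[str, ...]
    matrix: np.ndarray
    n_frames: int
    undefined: tuple[str, ...] = ()  # zero-variance residues, entries are NaN

    def index_of(self, residue: str) -> int:
        try:
            return self.residues.index(residue)
        except ValueError:
            raise KeyError(f"unknown residue label {residue!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residues, columns=self.residues)


def compute_dccm(
    series: DisplacementSeries | Sequence[DisplacementSeries],
    *,
    zero_variance_tol: float = 1e-300,
) -> DCCMatrix:
    """Compute the DCCM, accumulating replicates by centered concatenation.

    Each replicate is mean-centered per residue before concatenation; the
    result therefore equals the correlation of the concatenated centered
    series, which is *not* the average of per-replicate DCCMs.  Residues with
    zero displacement variance get NaN rows/columns and are reported in
    ``undefined`` rather than silently zeroed.
    """
    if isinstance(series, DisplacementSeries):
        series = [series]
    if not series:
        raise ValueError("no displacement series supplied")
    residues = series[0].residues
    segments = series[0].segments
    for s in series[1:]:
        if s.residues != residues:
            raise ValueError("replicates must share the same residue set and order")

    centered = []
    for s in series:
        v = s.vectors
        centered.append(v - v.mean(axis=0, keepdims=True))
    x = np.concatenate(centered, axis=0)  # (frames_total, n_res, 3)
    n = x.shape[0]

    # isotropic covariance: sum over frames of dot products
    cov = np.einsum("tik,tjk->ij", x, x) / n
    var = np.diag(cov).copy()
    bad = var <= zero_variance_tol
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    corr = np.clip(corr, -1.0, 1.0)
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    corr[np.diag_indices_from(corr)] = np.where(bad, np.nan, 1.0)
    return DCCMatrix(
        residues=residues,
        segments=segments,
        matrix=corr,
        n_frames=n,
        undefined=tuple(r for r, b in zip(residues, bad) if b),
    )


@dataclass(frozen=True)
class BlockSummary:
    mean: float
    mean_abs: float
    min_value: float
    max_value: float
    n_pairs: int
    set_a: tuple[str, ...]
    set_b: tuple[str, ...]


def extract_block(
    dccm: DCCMatrix, set_a: Iterable[str], set_b: Iterable[str]
) -> BlockSummary:
    """Summarize the rectangular DCCM block between two disjoint residue sets.

    Used to contrast e.g. M4-versus-neighboured-filter-loop coupling against
    M4-versus-opposing-loop coupling.
    """
    a = list(set_a)
    b = list(set_b)
    if not a or not b:
        raise ValueError("residue sets must be non-empty")
    if set(a) & set(b):
        raise ValueError("residue sets must be disjoint")
    ia = [dccm.index_of(r) for r in a]
    ib = [dccm.index_of(r) for r in b]
    undef = set(dccm.undefined) & (set(a) | set(b))
    if undef:
        raise ValueError(f"residues with undefined correlation in block: {sorted(undef)}")
    block = dccm.matrix[np.ix_(ia, ib)]
    return BlockSummary(
        mean=float(block.mean()),
        mean_abs=float(np.abs(block).mean()),
        min_value=float(block.min()),
        max_value=float(block.max()),
        n_pairs=block.size,
        set_a=tuple(a),
        set_b=tuple(b),
    )


def export_heatmap(
    dccm: DCCMatrix, matrix_path: str | Path, image_path: str | Path | None = None
) -> None:
    """Write the matrix as bit-exact TSV and render a heat map.

    The colour scale is symmetric about zero (blue = -1, red = +1) so that
    anti-correlated and correlated blocks are visually comparable.
    """
    matrix_path = Path(matrix_path)
    df = dccm.to_frame()
    df.to_csv(matrix_path, sep="\t", float_format="%.17g", index_label="residue")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(dccm.matrix, cmap="RdBu_r", vmin=-1.0, vmax=1.0)
        ax.set_xticks(range(len(dccm.residues)))
        ax.set_yticks(range(len(dccm.residues)))
        ax.set_xticklabels(dccm.residues, rotation=90, fontsize=6)
        ax.set_yticklabels(dccm.residues, fontsize=6)
        fig.colorbar(im, ax=ax, label="motion correlation")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)


def read_dccm_matrix(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the TSV written by :func:`export_heatmap`."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
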