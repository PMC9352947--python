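"""Recurrence matrices from 1-D signal segments.

A segment is delay-embedded into phase space (dimension ``m``, delay
``tau``); the recurrence matrix stores, for every pair of phase-space
points, either the raw Euclidean distance (unthresholded mode, the
default here — it keeps the full texture) or the binary indicator
that the distance is within a radius ``epsilon`` (classic thresholded
plot, Heaviside convention: the boundary counts as recurrent).

Defaults are m=1, tau=1, i.e. the pairwise |x_i - x_j| of the raw
samples; embedding is exposed because the recurrence literature
usually embeds. Matrices can be min-max or z-score normalized (per
matrix) and area-average downsampled to the classifier resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EmbeddingParams", "RecurrenceMatrix", "embed", "unthresholded_rp",
    "thresholded_rp", "normalize", "resize_rp", "rp_from_segment",
    "save_rp_png", "save_rp_hdf5",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: dimension m >= 1, delay tau >= 1."""

    m: int = 1
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError(f"need m >= 1 and tau >= 1, got m={self.m}, tau={self.tau}")


@dataclass
class RecurrenceMatrix:
    """Square recurrence matrix for one lead's segment.

    ``values`` is symmetric with a zero diagonal in unthresholded mode
    (all-ones diagonal when thresholded, since a point always recurs
    with itself).
    """

    values: np.ndarray
    mode: str = "unthresholded"          # or "thresholded"
    epsilon: float | None = None         # thresholded only
    normalization: str = "none"          # none | minmax | zscore

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"recurrence matrix must be square, got {v.shape}")
        self.values = v

    @property
    def side(self) -> int:
        return self.values.shape[0]


def embed(segment: np.ndarray, p: EmbeddingParams = EmbeddingParams()) -> np.ndarray:
    """Delay-embed a scalar series into [N, m] phase-space points.

    N = L0 - (m-1)*tau; point i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}).
    With m=1 the points are the raw samples.
    """
    x = np.asarray(segment, dtype=float).ravel()
    n = x.size - (p.m - 1) * p.tau
    if n < 1:
        raise ValueError(
            f"segment of length {x.size} too short for m={p.m}, tau={p.tau} "
            f"(needs at least {(p.m - 1) * p.tau + 1} samples)")
    idx = np.arange(n)[:, None] + p.tau * np.arange(p.m)[None, :]
    return x[idx]


def unthresholded_rp(points: np.ndarray) -> RecurrenceMatrix:
    """Pairwise Euclidean distances between phase-space points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]     # scalar samples as 1-D phase-space points
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 phase-space points")
    d = squareform(pdist(pts, metric="euclidean"))
    return RecurrenceMatrix(values=d, mode="unthresholded")


def thresholded_rp(points: np.ndarray, epsilon: float) -> RecurrenceMatrix:
    """Binary recurrence: 1 where the pairwise distance <= epsilon.

    The boundary is recurrent (Heaviside of zero is one), so the
    diagonal is all ones.
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    dist = unthresholded_rp(points)
    return RecurrenceMatrix(values=(dist.values <= epsilon).astype(float),
                            mode="thresholded", epsilon=float(epsilon))


def normalize(rp: RecurrenceMatrix, method: str = "zscore") -> RecurrenceMatrix:
    """Normalize one matrix by its own entry statistics.

    minmax maps onto [0, 1]; zscore centers to mean 0, sd 1. Degenerate
    (constant) matrices map to all zeros in either mode so constant
    segments never propagate NaNs.
    """
    v = rp.values
    if method == "none":
        return rp
    if method == "minmax":
        lo, hi = v.min(), v.max()
        out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    elif method == "zscore":
        mu, sd = v.mean(), v.std()
        out = np.zeros_like(v) if sd == 0 else (v - mu) / sd
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return replace(rp, values=out, normalization=method)


def resize_rp(rp: RecurrenceMatrix, side: int) -> RecurrenceMatrix:
    """Area-averaged downsampling to side x side.

    Block means preserve symmetry; upsizing is refused — generate a
    longer segment instead of interpolating texture.
    """
    if side < 2:
        raise ValueError(f"side must be >= 2, got {side}")
    n = rp.side
    if side > n:
        raise ValueError(f"cannot resize {n}x{n} up to {side}x{side}; only "
                         "downsampling is supported")
    if side == n:
        return rp
    # Partition [0, n) into `side` near-equal contiguous bins and take
    # block means; exact block means when side divides n.
    edges = (np.arange(side + 1) * n) // side
    csum = np.zeros((n + 1, n + 1))
    csum[1:, 1:] = rp.values.cumsum(0).cumsum(1)
    e0, e1 = edges[:-1], edges[1:]
    block = (csum[e1][:, e1] - csum[e0][:, e1] - csum[e1][:, e0] + csum[e0][:, e0])
    area = (e1 - e0)[:, None] * (e1 - e0)[None, :]
    return replace(rp, values=block / area)


def rp_from_segment(segment: np.ndarray,
                    p: EmbeddingParams = EmbeddingParams(),
                    normalization: str = "zscore",
                    side: int | None = 128,
                    decimate: int = 1) -> RecurrenceMatrix:
    """Segment -> (optional decimation) -> embed -> unthresholded RP
    -> normalize -> (optional) resize. The one-stop pipeline used when
    building classifier volumes.
    """
    seg = np.asarray(segment, dtype=float)
    if decimate > 1:
        seg = seg[::decimate]
    rp = unthresholded_rp(embed(seg, p))
    rp = normalize(rp, normalization)
    if side is not None and side < rp.side:
        rp = resize_rp(rp, side)
    return rp


def save_rp_png(rp: RecurrenceMatrix, path: str | Path) -> Path:
    """8-bit grayscale export (min-max scaled) for visual inspection only."""
    from PIL import Image

    v = rp.values
    lo, hi = v.min(), v.max()
    img = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path)
    return path


def save_rp_hdf5(rp: RecurrenceMatrix, path: str | Path) -> Path:
    """Float32 dataset "rp" with mode/normalization attributes."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rp", data=rp.values.astype(np.float32))
        d.attrs["mode"] = rp.mode
        d.attrs["normalization"] = rp.normalization
        if rp.epsilon is not None:
            d.attrs["epsilon"] = rp.epsilon
    return path
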