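"""Canonical connectome representation.

A subject's functional connectome over R regions is stored as a flat vector
of L = R(R+1)/2 Fisher-z connectivity values: all region-to-region Pearson
correlations plus the R within-region values, under one canonical ordering
shared by every module.

Canonical ordering
------------------
Lower triangle with diagonal, column-major: for column ``j`` ascending and
rows ``i <= j`` ascending, ``index(i, j) = j(j+1)/2 + i``. For R = 64 this
yields 2016 between-region + 64 within-region = 2080 entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import RegionAtlas
from .exceptions import ConfigurationError, DegenerateDataError

#: correlations are clipped to +/- (1 - CLIP_EPS) before arctanh so every
#: Fisher-z value stays finite for downstream linear algebra
CLIP_EPS = 1e-7
_R_MAX = 1.0 - CLIP_EPS


def n_pairs(n_regions: int) -> int:
    """Number of connectivity values for an ``n_regions`` parcellation."""
    return n_regions * (n_regions + 1) // 2


def pair_index(i: int, j: int, n_regions: int) -> int:
    """Canonical flat index of the (i, j) connection.

    Symmetric in (i, j) and bijective onto ``0 .. R(R+1)/2 - 1``.
    """
    if not (0 <= i < n_regions and 0 <= j < n_regions):
        raise IndexError(f"region ids ({i}, {j}) out of range for R={n_regions}")
    if i > j:
        i, j = j, i
    return j * (j + 1) // 2 + i


def index_to_pair(index: int, n_regions: int) -> tuple[int, int]:
    """Inverse of :func:`pair_index`: flat index -> (i, j) with i <= j."""
    if not (0 <= index < n_pairs(n_regions)):
        raise IndexError(f"index {index} out of range for R={n_regions}")
    j = int((np.sqrt(8 * index + 1) - 1) // 2)
    while j * (j + 1) // 2 > index:
        j -= 1
    while (j + 1) * (j + 2) // 2 <= index:
        j += 1
    i = index - j * (j + 1) // 2
    return i, j


def pair_labels(n_regions: int) -> list[str]:
    """Column labels ``c<i>_<j>`` in canonical order."""
    return [
        f"c{i}_{j}"
        for j in range(n_regions)
        for i in range(j + 1)
    ]


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Flatten a symmetric R x R matrix into the canonical vector."""
    matrix = np.asarray(matrix)
    r = matrix.shape[0]
    if matrix.shape != (r, r):
        raise ValueError("matrix must be square")
    out = np.empty(n_pairs(r), dtype=float)
    for j in range(r):
        base = j * (j + 1) // 2
        out[base : base + j + 1] = matrix[: j + 1, j]
    return out


def matrixize(vector: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Rebuild the symmetric R x R matrix from a canonical vector."""
    vector = np.asarray(vector, dtype=float)
    if n_regions is None:
        n_regions = int((np.sqrt(8 * vector.size + 1) - 1) // 2)
    if n_pairs(n_regions) != vector.size:
        raise ValueError(
            f"vector of length {vector.size} is not a {n_regions}-region connectome"
        )
    mat = np.empty((n_regions, n_regions), dtype=float)
    for j in range(n_regions):
        base = j * (j + 1) // 2
        mat[: j + 1, j] = vector[base : base + j + 1]
        mat[j, : j + 1] = vector[base : base + j + 1]
    return mat


def fisher_z(r):
    """Fisher (arctanh) transform with clipping at ``|r| = 1 - 1e-7``.

    Accepts scalars or arrays; values outside [-1, 1] only through the
    clipping contract (e.g. ``r = 1.0`` maps to ``arctanh(1 - 1e-7)``).
    """
    arr = np.asarray(r, dtype=float)
    out = np.arctanh(np.clip(arr, -_R_MAX, _R_MAX))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    arr = np.asarray(z, dtype=float)
    out = np.tanh(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ChannelTimeSeries:
    """Channel-level signals with a channel -> region assignment.

    Stands in for voxel-level time series averaged per seed region: regions
    own >= 2 channels each so that within-region connectivity is defined.
    """

    values: np.ndarray          # T x C
    channel_region: np.ndarray  # length C, region ids

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        channel_region = np.asarray(self.channel_region, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_region", channel_region)
        if values.ndim != 2 or values.shape[0] < 3:
            raise ConfigurationError("time series must be T x C with T >= 3")
        if values.shape[1] != channel_region.size:
            raise ConfigurationError("channel_region length must equal channel count")
        if np.any(values.std(axis=0) == 0):
            raise DegenerateDataError("constant-in-time channel in time series")


@dataclass(frozen=True)
class ConnectivityVector:
    """One subject's connectome in canonical order (Fisher-z units)."""

    z: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.size != n_pairs(self.n_regions):
            raise ValueError("vector length does not match region count")
        if not np.all(np.isfinite(z)):
            raise ValueError("connectivity values must be finite")

    def to_matrix(self) -> np.ndarray:
        return matrixize(self.z, self.n_regions)


def compute_connectome(ts: ChannelTimeSeries, atlas: RegionAtlas) -> ConnectivityVector:
    """Connectome from channel-level time series.

    Between-region entries are the Fisher-z of the Pearson correlation of
    the two region-mean series. The within-region entry of region ``i`` is
    the Fisher-z of the *mean* pairwise Pearson correlation over all
    distinct channel pairs inside region ``i`` (mean of r, then arctanh).
    """
    r_regions = atlas.n_regions
    values = ts.values
    region_means = np.empty((values.shape[0], r_regions))
    within = np.empty(r_regions)
    for region in range(r_regions):
        cols = np.flatnonzero(ts.channel_region == region)
        if cols.size < 2:
            raise ConfigurationError(
                f"region {region} has {cols.size} channel(s); >= 2 required"
            )
        block = values[:, cols]
        region_means[:, region] = block.mean(axis=1)
        corr = np.corrcoef(block, rowvar=False)
        iu = np.triu_indices(cols.size, k=1)
        within[region] = fisher_z(float(corr[iu].mean()))
    if np.any(region_means.std(axis=0) == 0):
        bad = int(np.flatnonzero(region_means.std(axis=0) == 0)[0])
        raise DegenerateDataError(f"region {bad} mean time series is constant")

    between = fisher_z(np.corrcoef(region_means, rowvar=False))
    out = vectorize(between)
    # overwrite the diagonal entries with the within-region convention
    for region in range(r_regions):
        out[pair_index(region, region, r_regions)] = within[region]
    return ConnectivityVector(z=out, n_regions=r_regions)
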