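"""Per-subject functional and structural connectivity matrices.

Functional edges are Pearson correlations between preprocessed ROI time
series (raw r, unthresholded, no Fisher transform).  Structural edges come
from probabilistic-tractography fiber tallies through the normalization

    A_ij = 2 * Fcount_ij / (C_i + V_j)

where ``Fcount_ij`` is the number of sampled fibers from seed region i
reaching region j after filtering, ``C_i`` is the total number of fibers
sampled from i (seed voxels x streamlines per voxel, 1000 by default) and
``V_j`` is the volume of region j in mm^3.  The sum C_i + V_j mixes a count
with a volume; the expression is kept exactly as defined, as a normalization
heuristic with heterogeneous units.  The asymmetric A is symmetrized by
averaging with its transpose:  W_ij = (A_ij + A_ji) / 2.

Fibers shorter than 10 mm and looping fibers (seed region equals end region)
are excluded before tallying.  Both matrices carry a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .atlas import Atlas
from .preprocess import TimeSeriesPanel

#: Streamlines sampled per seed voxel by the tractography protocol.
DEFAULT_STREAMLINES_PER_VOXEL = 1000

#: Minimum fiber length retained, in mm.
DEFAULT_MIN_FIBER_LENGTH_MM = 10.0


class Modality(str, Enum):
    FUNCTIONAL = "functional"
    STRUCTURAL = "structural"


@dataclass(frozen=True)
class FiberRecord:
    """One sampled streamline: seed region, end region, length in mm."""

    seed_region: int
    end_region: int
    length_mm: float

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ValueError("fiber length must be positive")


@dataclass(frozen=True)
class FiberTally:
    """Asymmetric fiber-count matrix plus per-region seed metadata.

    ``fcount[i, j]`` is the number of retained fibers seeded in region i that
    reach region j.  ``voxel_count`` and ``volume_mm3`` are per-region seed
    voxel counts and volumes.
    """

    fcount: np.ndarray
    voxel_count: np.ndarray
    volume_mm3: np.ndarray
    streamlines_per_voxel: int = DEFAULT_STREAMLINES_PER_VOXEL
    subject_id: str = ""

    def __post_init__(self):
        fcount = np.asarray(self.fcount)
        if fcount.ndim != 2 or fcount.shape[0] != fcount.shape[1]:
            raise ValueError("fcount must be a square matrix")
        if (fcount < 0).any():
            raise ValueError("fiber counts must be non-negative")
        if np.diag(fcount).any():
            raise ValueError("fcount diagonal must be zero (loops are excluded)")
        vox = np.asarray(self.voxel_count, dtype=int)
        vol = np.asarray(self.volume_mm3, dtype=float)
        r = fcount.shape[0]
        if vox.shape != (r,) or vol.shape != (r,):
            raise ValueError("voxel_count and volume_mm3 must have one entry per region")
        if (vox < 1).any():
            raise ValueError("every region needs at least one seed voxel")
        if (vol <= 0).any():
            raise ValueError("region volumes must be positive")
        if self.streamlines_per_voxel < 1:
            raise ValueError("streamlines_per_voxel must be >= 1")
        object.__setattr__(self, "fcount", fcount)
        object.__setattr__(self, "voxel_count", vox)
        object.__setattr__(self, "volume_mm3", vol)

    @property
    def n_regions(self) -> int:
        return self.fcount.shape[0]

    @property
    def total_sampled(self) -> np.ndarray:
        """C_i: fibers sampled per seed region."""
        return self.voxel_count * self.streamlines_per_voxel


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric weighted R x R network for one subject and one modality."""

    weights: np.ndarray
    modality: Modality
    subject_id: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be exactly symmetric")
        if np.diag(w).any():
            raise ValueError("diagonal must be zero")
        modality = Modality(self.modality)
        if modality is Modality.FUNCTIONAL:
            off = w[~np.eye(w.shape[0], dtype=bool)]
            if ((off < -1) | (off > 1)).any():
                raise ValueError("functional weights must lie in [-1, 1]")
        elif (w < 0).any():
            raise ValueError("structural weights must be non-negative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "modality", modality)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def filter_fibers(
    records: Iterable[FiberRecord],
    min_length_mm: float = DEFAULT_MIN_FIBER_LENGTH_MM,
) -> list[FiberRecord]:
    """Drop fibers shorter than ``min_length_mm`` and loops, preserving order."""
    return [
        r
        for r in records
        if r.length_mm >= min_length_mm and r.seed_region != r.end_region
    ]


def tally_fibers(records: Sequence[FiberRecord], atlas: Atlas) -> np.ndarray:
    """Count already-filtered records into an R x R seed-by-target matrix."""
    n = atlas.n_regions
    fcount = np.zeros((n, n), dtype=int)
    for r in records:
        if not (0 <= r.seed_region < n and 0 <= r.end_region < n):
            raise ValueError(
                f"fiber record ({r.seed_region} -> {r.end_region}) outside the "
                f"{n}-region atlas"
            )
        if r.seed_region == r.end_region:
            raise ValueError("looping record found; run filter_fibers first")
        fcount[r.seed_region, r.end_region] += 1
    return fcount


def structural_network(tally: FiberTally) -> ConnectivityMatrix:
    """Normalize a fiber tally into the symmetric structural network."""
    c = tally.total_sampled.astype(float)  # C_i per seed region
    v = tally.volume_mm3
    denom = c[:, None] + v[None, :]  # C_i + V_j
    a = 2.0 * tally.fcount / denom
    w = 0.5 * (a + a.T)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, Modality.STRUCTURAL, tally.subject_id)


def functional_network(panel: TimeSeriesPanel) -> ConnectivityMatrix:
    """Pearson-correlation network of a preprocessed ROI panel."""
    if panel.missing_series.any():
        bad = [int(i) for i in np.flatnonzero(panel.missing_series)]
        raise ValueError(f"cannot correlate flagged empty series at indices {bad}")
    sd = panel.data.std(axis=0)
    if (sd == 0).any():
        bad = [int(i) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance series at region indices {bad}")
    w = np.corrcoef(panel.data, rowvar=False)
    w = np.clip(0.5 * (w + w.T), -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, Modality.FUNCTIONAL, panel.subject_id)
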