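"""Per-ROI density estimation and KL-similarity network construction.

Each ROI's voxel-value distribution is estimated with a Gaussian kernel on a
grid shared within each ROI pair; the edge weight between two ROIs is
exp(-[KL(p||q) + KL(q||p)]), which lies in (0, 1] and equals 1 exactly when
the two discretized distributions are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .roi_io import MorphNetwork, RoiSampleSet

DEFAULT_GRID_POINTS = 512
DEFAULT_FLOOR = 1e-12


@dataclass
class GridSpec:
    """Evaluation grid policy: n_points over [min - pad*h, max + pad*h]."""

    n_points: int = DEFAULT_GRID_POINTS
    pad_bandwidths: float = 3.0
    floor: float = DEFAULT_FLOOR

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if not (0 < self.floor < 1e-3):
            raise ValueError("floor must be a small positive probability")


@dataclass
class Density:
    """A discrete probability distribution on a fixed value grid."""

    grid: np.ndarray
    mass: np.ndarray
    bandwidth: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.shape != self.mass.shape:
            raise ValueError("grid and mass shapes differ")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mass <= 0):
            raise ValueError("mass must be strictly positive after flooring")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1 within 1e-9")


def silverman_bandwidth(samples: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5); falls back to sd when IQR is 0."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    sd = samples.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant samples: bandwidth would be zero")
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def estimate_pdf(
    samples,
    grid_spec: GridSpec | None = None,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> Density:
    """Gaussian-kernel density of a sample vector, floored and renormalized.

    When ``grid`` is omitted, the grid spans the sample range padded by
    ``pad_bandwidths`` bandwidths with ``n_points`` points.
    """
    grid_spec = grid_spec or GridSpec()
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(samples)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        pad = grid_spec.pad_bandwidths * bandwidth
        grid = np.linspace(samples.min() - pad, samples.max() + pad,
                           grid_spec.n_points)
    grid = np.asarray(grid, dtype=float)
    dens = np.exp(-((grid[:, None] - samples[None, :]) ** 2)
                  / (2.0 * bandwidth ** 2)).sum(axis=1)
    mass = dens / dens.sum()
    mass = np.maximum(mass, grid_spec.floor)
    mass = mass / mass.sum()
    return Density(grid=grid, mass=mass, bandwidth=bandwidth)


def kl_divergence(p: Density, q: Density) -> float:
    """KL(p||q) over the shared discrete grid masses."""
    _check_grids(p, q)
    return float(np.sum(p.mass * np.log(p.mass / q.mass)))


def kl_similarity(p: Density, q: Density) -> float:
    """exp(-[KL(p||q) + KL(q||p)]); symmetric, in (0, 1], 1 iff identical."""
    _check_grids(p, q)
    return float(np.exp(-(kl_divergence(p, q) + kl_divergence(q, p))))


def _check_grids(p: Density, q: Density) -> None:
    if p.grid.shape != q.grid.shape or not np.array_equal(p.grid, q.grid):
        raise ValueError("densities are on different grids")


def pair_similarity(samples_a, samples_b, grid_spec: GridSpec | None = None) -> float:
    """KLS of two raw sample vectors on their shared per-pair grid."""
    grid_spec = grid_spec or GridSpec()
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    ha, hb = silverman_bandwidth(a), silverman_bandwidth(b)
    h = max(ha, hb)
    lo = min(a.min(), b.min()) - grid_spec.pad_bandwidths * h
    hi = max(a.max(), b.max()) + grid_spec.pad_bandwidths * h
    grid = np.linspace(lo, hi, grid_spec.n_points)
    p = estimate_pdf(a, grid_spec, grid=grid, bandwidth=ha)
    q = estimate_pdf(b, grid_spec, grid=grid, bandwidth=hb)
    return kl_similarity(p, q)


def build_network(roi_samples: RoiSampleSet,
                  grid_spec: GridSpec | None = None) -> MorphNetwork:
    """Per-subject symmetric KLS matrix over all unordered ROI pairs.

    Densities for each pair are estimated on a shared grid spanning the
    pooled sample range; the diagonal is zero by construction.
    """
    grid_spec = grid_spec or GridSpec()
    bad = []
    for lab, s in zip(roi_samples.roi_labels, roi_samples.samples):
        if s.size < 2 or np.std(s) == 0 or not np.all(np.isfinite(s)):
            bad.append(lab)
    if bad:
        raise ValueError(f"degenerate ROI sample vector(s): {bad}")

    values = np.concatenate(roi_samples.samples).astype(np.float64)
    offsets = np.zeros(roi_samples.n_rois + 1, dtype=np.int64)
    np.cumsum([s.size for s in roi_samples.samples], out=offsets[1:])
    bandwidths = np.array([silverman_bandwidth(s) for s in roi_samples.samples])
    mins = np.array([s.min() for s in roi_samples.samples])
    maxs = np.array([s.max() for s in roi_samples.samples])

    matrix = _kernels.kls_matrix(values, offsets, bandwidths, mins, maxs,
                                 grid_spec.n_points, grid_spec.floor)
    matrix = np.minimum(matrix, 1.0)  # guard against exp(-0) rounding above 1
    return MorphNetwork(subject_id=roi_samples.subject_id,
                        roi_labels=list(roi_samples.roi_labels),
                        matrix=matrix)


def target_strengths(roi_samples: RoiSampleSet, target_roi: int,
                     grid_spec: GridSpec | None = None) -> np.ndarray:
    """KLS of one ROI against all others (a single matrix row), cheaply."""
    grid_spec = grid_spec or GridSpec()
    values = np.concatenate(roi_samples.samples).astype(np.float64)
    offsets = np.zeros(roi_samples.n_rois + 1, dtype=np.int64)
    np.cumsum([s.size for s in roi_samples.samples], out=offsets[1:])
    bandwidths = np.array([silverman_bandwidth(s) for s in roi_samples.samples])
    mins = np.array([s.min() for s in roi_samples.samples])
    maxs = np.array([s.max() for s in roi_samples.samples])
    return _kernels.kls_row(values, offsets, bandwidths, mins, maxs,
                            int(target_roi), grid_spec.n_points, grid_spec.floor)
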