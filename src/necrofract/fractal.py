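"""Box-counting fractal dimension and grid lacunarity of binary masks.

The scan protocol follows the FracLac-style convention used for necrosis
patterns on MRI: box sizes range from a minimum of 2 pixels up to 45% of
the larger linear dimension of the cropped region, twelve grid placements
are scanned (one anchored at the crop origin, the rest at seeded random
offsets), and FD and lacunarity are computed per grid then averaged.

Definitions
-----------
FD per grid is the negated least-squares slope of ln N(eps) against
ln eps, where N(eps) is the number of boxes of side eps containing
foreground. Lacunarity per (eps, grid) is the squared coefficient of
variation (sigma/mu)^2 of per-box foreground masses with empty boxes
included; per-grid lacunarity averages over sizes, and the slice value
averages over grids. Box masses are raw pixel counts; partial boxes at the
crop edge participate with their true (smaller) capacity. Variances are
population variances, since lacunarity is a moment ratio of the box-mass
distribution, not an estimate from a sample.

Per-patient features are unweighted means over all necrosis-bearing
slices; slices with empty necrosis are skipped upstream with a log entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from necrofract.errors import (
    EmptyRegionError,
    InsufficientScalingError,
    ParameterError,
    ProtocolError,
)
from necrofract.util import derive_rng

logger = logging.getLogger(__name__)

__all__ = [
    "ScanProtocol",
    "BoxScanSeries",
    "FractalFeatures",
    "extract_analysis_region",
    "build_scan",
    "fd_from_scan",
    "lacunarity_from_scan",
    "slice_features",
    "patient_features",
]


@dataclass(frozen=True)
class ScanProtocol:
    """Box-counting scan parameters.

    ``max_frac`` is a fraction of the larger linear dimension of the
    scanned region (the FracLac parameter is linear, not areal: an areal
    reading would permit boxes larger than the image). ``box_sizes``, when
    given, overrides the log-spaced size schedule — used for exact
    power-of-b validation scans.
    """

    min_box: int = 2
    max_frac: float = 0.45
    n_grids: int = 12
    n_sizes: int = 12
    seed: int = 0
    box_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.min_box < 2:
            raise ParameterError("min_box must be >= 2")
        if not 0.0 < self.max_frac < 1.0:
            raise ParameterError("max_frac must lie in (0, 1)")
        if self.n_grids < 1:
            raise ParameterError("n_grids must be >= 1")
        if self.n_sizes < 2:
            raise ParameterError("n_sizes must be >= 2")
        if self.box_sizes is not None:
            sizes = tuple(int(s) for s in self.box_sizes)
            if len(sizes) < 1 or any(s < 1 for s in sizes) or sorted(set(sizes)) != list(sizes):
                raise ParameterError("box_sizes must be strictly increasing positive integers")
            object.__setattr__(self, "box_sizes", sizes)

    def sizes_for(self, shape: tuple[int, int]) -> tuple[int, ...]:
        """Resolve the box-size schedule for a mask of the given shape."""
        if self.box_sizes is not None:
            return self.box_sizes
        extent = max(shape)
        largest = int(np.floor(self.max_frac * extent))
        if largest < self.min_box:
            raise ProtocolError(
                f"mask extent {shape} admits no box size: "
                f"max {largest} px < min {self.min_box} px"
            )
        sizes = np.unique(
            np.round(np.geomspace(self.min_box, largest, self.n_sizes)).astype(int)
        )
        return tuple(int(s) for s in sizes)


@dataclass
class BoxScanSeries:
    """Per-(box size, grid offset) foreground masses of one scanned mask.

    ``masses[s][g]`` is the vector of per-box pixel counts for size index
    ``s`` and grid index ``g``, empty boxes included; ``nonempty[s, g]`` is
    N(eps), the count of boxes with mass > 0. ``offsets[g, s]`` is the
    (row, col) lattice shift in [0, eps).
    """

    box_sizes: tuple[int, ...]
    offsets: np.ndarray
    masses: list[list[np.ndarray]]
    nonempty: np.ndarray
    total_foreground: int
    shape: tuple[int, int] = field(default=(0, 0))

    @property
    def n_grids(self) -> int:
        return self.offsets.shape[0]


def extract_analysis_region(
    tumor_mask: np.ndarray, necrosis_mask: np.ndarray
) -> np.ndarray:
    """Crop the necrosis pattern to the tumor bounding box.

    The tumor ROI acts only as the border of the analysis window; the
    binarized foreground submitted to box counting is the necrosis alone.
    Necrosis pixels outside the tumor are clipped with a warning.
    """
    tumor = np.asarray(tumor_mask, bool)
    necrosis = np.asarray(necrosis_mask, bool)
    if tumor.shape != necrosis.shape:
        raise ParameterError("tumor and necrosis masks must share a shape")
    if not tumor.any():
        raise EmptyRegionError("tumor mask is empty")
    outside = necrosis & ~tumor
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} necrosis pixels outside the tumor mask were clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        necrosis = necrosis & tumor
    if not necrosis.any():
        raise EmptyRegionError("necrosis mask is empty within the tumor")
    rows = np.flatnonzero(tumor.any(axis=1))
    cols = np.flatnonzero(tumor.any(axis=0))
    return necrosis[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def build_scan(mask: np.ndarray, protocol: ScanProtocol) -> BoxScanSeries:
    """Tile the mask with boxes at every (size, grid offset) and record masses.

    Grid 0 is anchored at the crop origin; grids 1..n_grids-1 use offsets
    drawn from the protocol seed, uniform over [0, eps)^2 per size. Boxes
    tile the full mask extent, partial edge boxes included.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise EmptyRegionError("cannot scan an empty mask")
    h, w = mask.shape
    sizes = protocol.sizes_for(mask.shape)
    if max(sizes) < protocol.min_box and protocol.box_sizes is None:  # pragma: no cover
        raise ProtocolError("degenerate size range")

    rng = derive_rng(protocol.seed, "grid_offsets")
    offsets = np.zeros((protocol.n_grids, len(sizes), 2), dtype=int)
    for g in range(1, protocol.n_grids):
        for s, eps in enumerate(sizes):
            offsets[g, s] = rng.integers(0, eps, size=2)

    fg_rows, fg_cols = np.nonzero(mask)
    total = int(fg_rows.size)

    masses: list[list[np.ndarray]] = []
    nonempty = np.zeros((len(sizes), protocol.n_grids), dtype=int)
    for s, eps in enumerate(sizes):
        per_grid: list[np.ndarray] = []
        for g in range(protocol.n_grids):
            dr, dc = offsets[g, s]
            # lattice lines at multiples of eps shifted by -d: pixel p falls
            # in box (p + d) // eps; covers the extent with partial boxes
            row_idx = (fg_rows + dr) // eps
            col_idx = (fg_cols + dc) // eps
            n_rows = (h - 1 + dr) // eps + 1
            n_cols = (w - 1 + dc) // eps + 1
            m = np.bincount(row_idx * n_cols + col_idx, minlength=n_rows * n_cols)
            assert m.sum() == total, "box masses must conserve foreground"
            per_grid.append(m)
            nonempty[s, g] = int(np.count_nonzero(m))
        masses.append(per_grid)

    return BoxScanSeries(
        box_sizes=sizes,
        offsets=offsets,
        masses=masses,
        nonempty=nonempty,
        total_foreground=total,
        shape=(h, w),
    )


def fd_from_scan(scan: BoxScanSeries) -> tuple[np.ndarray, float]:
    """Per-grid box-counting dimension and its mean over grids.

    FD per grid is the negated least-squares slope of ln N(eps) vs ln eps
    over the sizes with N > 0.
    """
    eps = np.asarray(scan.box_sizes, float)
    per_grid = np.empty(scan.n_grids)
    for g in range(scan.n_grids):
        counts = scan.nonempty[:, g].astype(float)
        usable = counts > 0
        if usable.sum() < 2:
            raise InsufficientScalingError(
                f"grid {g}: only {int(usable.sum())} usable box sizes"
            )
        slope = np.polyfit(np.log(eps[usable]), np.log(counts[usable]), 1)[0]
        per_grid[g] = -slope
    return per_grid, float(per_grid.mean())


def lacunarity_from_scan(scan: BoxScanSeries) -> tuple[np.ndarray, float]:
    """Per-grid lacunarity and its mean over grids.

    lambda(eps, g) = (sigma/mu)^2 of the box masses (population variance,
    empty boxes included); per-grid value averages over sizes.
    """
    per_grid = np.empty(scan.n_grids)
    for g in range(scan.n_grids):
        lam = []
        for s in range(len(scan.box_sizes)):
            m = scan.masses[s][g].astype(float)
            mu = m.mean()
            if mu == 0:
                raise EmptyRegionError("zero mean box mass: empty region")
            lam.append(m.var() / mu**2)
        per_grid[g] = float(np.mean(lam))
    return per_grid, float(per_grid.mean())


@dataclass(frozen=True)
class FractalFeatures:
    """Slice- or patient-level fractal features."""

    fd: float
    lacunarity: float
    n_slices_aggregated: int = 1
    fd_per_grid: tuple[float, ...] | None = None
    lacunarity_per_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fd <= 2.0 + 1e-9:
            warnings.warn(
                f"FD {self.fd:.3f} outside [0, 2] for a 2D mask", RuntimeWarning, stacklevel=2
            )
        if self.lacunarity < 0:
            raise ParameterError("lacunarity must be >= 0")


def slice_features(
    tumor_mask: np.ndarray,
    necrosis_mask: np.ndarray,
    protocol: ScanProtocol | None = None,
) -> FractalFeatures:
    """FD and lacunarity of one necrosis slice under the scan protocol."""
    protocol = protocol or ScanProtocol()
    region = extract_analysis_region(tumor_mask, necrosis_mask)
    scan = build_scan(region, protocol)
    fd_grids, fd_mean = fd_from_scan(scan)
    lac_grids, lac_mean = lacunarity_from_scan(scan)
    return FractalFeatures(
        fd=fd_mean,
        lacunarity=lac_mean,
        n_slices_aggregated=1,
        fd_per_grid=tuple(fd_grids),
        lacunarity_per_grid=tuple(lac_grids),
    )


def patient_features(per_slice: list[FractalFeatures]) -> FractalFeatures:
    """Unweighted mean of slice features; the patient-level summary."""
    if not per_slice:
        raise ParameterError("patient has no slice with valid features")
    return FractalFeatures(
        fd=float(np.mean([f.fd for f in per_slice])),
        lacunarity=float(np.mean([f.lacunarity for f in per_slice])),
        n_slices_aggregated=len(per_slice),
    )
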