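"""Moment-based phosphene shape descriptors.

Each drawing is partitioned into maximal 8-connected foreground regions
("phosphenes"). Per region the four classic parameter-free descriptors are
computed from raw image moments

    M_ij = sum_x sum_y x^i y^j I(x, y)

with ``x`` the column and ``y`` the row index (0-based): area ``A = M00``,
centroid ``(M10/M00, M01/M00)``, and major/minor axis lengths from the
eigenvalues of the second-central-moment covariance matrix using the
``4 * sqrt(lambda)`` equal-second-moment-ellipse convention. The perimeter is
the length of a polyline through the centers of connected border pixels
(Benkrid-style estimator, as implemented by ``skimage.measure.perimeter``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from phoskit.errors import DomainError, EmptyDrawingError

DESCRIPTOR_NAMES = ("area", "perimeter", "major", "minor")


@dataclass(frozen=True)
class PhospheneShape:
    """Shape descriptors of a single connected phosphene region (pixel units)."""

    area: float
    perimeter: float
    major_axis_length: float
    minor_axis_length: float
    centroid: tuple[float, float]
    pixel_count: int

    @property
    def degenerate(self) -> bool:
        """True for regions too small to carry axis information."""
        return self.pixel_count < 2

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area,
            "perimeter": self.perimeter,
            "major": self.major_axis_length,
            "minor": self.minor_axis_length,
            "cx": self.centroid[0],
            "cy": self.centroid[1],
        }


@dataclass(frozen=True)
class DrawingDescriptors:
    """Per-region descriptors of one drawing plus the region count."""

    phosphenes: tuple[PhospheneShape, ...]

    @property
    def n_phosphenes(self) -> int:
        return len(self.phosphenes)


def _as_bool(mask) -> np.ndarray:
    arr = np.asarray(getattr(mask, "pixels", mask), dtype=bool)
    if arr.ndim != 2:
        raise ValueError("mask must be a 2-D raster")
    return arr


def connected_regions(mask, connectivity: int = 2) -> list[np.ndarray]:
    """Split foreground into maximal connected components.

    Returns full-size boolean masks ordered by descending area; ties are
    broken by the raster position (row, then column) of each region's first
    pixel. Default connectivity is 8-neighborhood (``connectivity=2``).
    """
    arr = _as_bool(mask)
    if not arr.any():
        raise EmptyDrawingError("mask has no foreground pixels")
    labels = measure.label(arr, connectivity=connectivity)
    regions = []
    for idx in range(1, labels.max() + 1):
        region = labels == idx
        ys, xs = np.nonzero(region)
        first = int(ys[0]) * arr.shape[1] + int(xs[0])
        regions.append((int(region.sum()), first, region))
    regions.sort(key=lambda t: (-t[0], t[1]))
    return [r for _, _, r in regions]


def raw_moment(mask, i: int, j: int) -> float:
    """Raw image moment M_ij = sum x^i y^j over foreground pixels."""
    if i < 0 or j < 0:
        raise DomainError("moment orders must be non-negative")
    arr = _as_bool(mask)
    ys, xs = np.nonzero(arr)
    return float(np.sum(xs.astype(float) ** i * ys.astype(float) ** j))


def centroid(mask) -> tuple[float, float]:
    """Center of mass (x̄, ȳ) = (M10/M00, M01/M00)."""
    arr = _as_bool(mask)
    m00 = arr.sum()
    if m00 == 0:
        raise EmptyDrawingError("centroid of an empty mask is undefined")
    ys, xs = np.nonzero(arr)
    return float(xs.mean()), float(ys.mean())


def central_covariance(mask) -> np.ndarray:
    """2x2 covariance matrix of foreground pixel coordinates.

    Entries are the normalized second central moments
    mu'_20 = M20/M00 - x̄², mu'_11 = M11/M00 - x̄ȳ, mu'_02 = M02/M00 - ȳ².
    """
    arr = _as_bool(mask)
    ys, xs = np.nonzero(arr)
    if xs.size == 0:
        raise EmptyDrawingError("covariance of an empty mask is undefined")
    x = xs.astype(float)
    y = ys.astype(float)
    mu20 = np.mean(x * x) - x.mean() ** 2
    mu02 = np.mean(y * y) - y.mean() ** 2
    mu11 = np.mean(x * y) - x.mean() * y.mean()
    return np.array([[mu20, mu11], [mu11, mu02]])


def axis_lengths(mask) -> tuple[float, float]:
    """Full major/minor axis lengths of the equal-second-moment ellipse.

    With eigenvalues λ1 ≥ λ2 of the covariance matrix, the lengths are
    (4√λ1, 4√λ2). A single-pixel region yields (0, 0).
    """
    cov = central_covariance(mask)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    return float(4.0 * np.sqrt(lam[1])), float(4.0 * np.sqrt(lam[0]))


def perimeter(mask) -> float:
    """Length of the polyline through the centers of connected border pixels.

    A single-pixel region has no border steps and measures 0 by convention.
    """
    arr = _as_bool(mask)
    return float(measure.perimeter(arr, neighborhood=4))


def describe_region(region: np.ndarray) -> PhospheneShape:
    arr = _as_bool(region)
    n = int(arr.sum())
    major, minor = axis_lengths(arr) if n > 1 else (0.0, 0.0)
    return PhospheneShape(
        area=float(n),
        perimeter=perimeter(arr),
        major_axis_length=major,
        minor_axis_length=minor,
        centroid=centroid(arr),
        pixel_count=n,
    )


def describe_drawing(mask) -> DrawingDescriptors:
    """Descriptors for every connected region of a cleaned drawing."""
    regions = connected_regions(mask)
    return DrawingDescriptors(tuple(describe_region(r) for r in regions))
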