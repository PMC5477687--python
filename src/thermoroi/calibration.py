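"""Fiducial-based planar calibration from pixels to metric body coordinates.

Four aluminium-foil disks taped to the skin appear distinctly cooler
(~28-31 °C) than the surrounding skin and mark the corners of a known
rectangle on the body plane (default 18 cm horizontally between the
subclavicular disks, 8 cm vertically up to the trapezius disks). Detecting
their centroids and solving the exact four-point homography yields a 3x3
matrix mapping pixel coordinates to centimetres, so ROI pixel counts convert
to physical areas and pose changes can be separated from genuine temperature
changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure
from skimage.transform import ProjectiveTransform

from .exceptions import DegenerateGeometryError, FiducialDetectionError, ShapeError
from .io import RoiMask, ThermalFrame

__all__ = [
    "FiducialLayout",
    "PlanarTransform",
    "detect_fiducials",
    "estimate_transform",
    "roi_area_m2",
    "DEFAULT_FIDUCIAL_BAND_C",
]

#: Temperature band (°C) in which the foil disks appear.
DEFAULT_FIDUCIAL_BAND_C = (28.0, 31.0)


def _collinear(p, q, r, tol=1e-9) -> bool:
    (ux, uy), (vx, vy) = np.subtract(q, p), np.subtract(r, p)
    return abs(ux * vy - uy * vx) <= tol


@dataclass(frozen=True)
class FiducialLayout:
    """Physical positions (cm) of the four disk centres on the body plane.

    Points are ordered upper-left, upper-right, lower-left, lower-right with
    x growing rightwards and y growing downwards (image-like axes), so the
    default rectangle places the two trapezius disks at y = 0 and the two
    subclavicular disks 8 cm below, 18 cm apart horizontally.
    """

    points_cm: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (18.0, 0.0),
        (0.0, 8.0),
        (18.0, 8.0),
    )
    disk_diameter_mm: float = 5.0

    def __post_init__(self):
        pts = np.asarray(self.points_cm, dtype=float)
        if pts.shape != (4, 2):
            raise ShapeError("layout must contain exactly 4 (x, y) points")
        if len({tuple(p) for p in pts}) != 4:
            raise DegenerateGeometryError("layout points must be distinct")
        for i in range(4):
            others = [j for j in range(4) if j != i]
            if _collinear(pts[others[0]], pts[others[1]], pts[others[2]]):
                raise DegenerateGeometryError("no three layout points may be collinear")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.points_cm, dtype=float)


@dataclass
class PlanarTransform:
    """3x3 homography mapping homogeneous pixel coordinates to cm.

    The matrix acts on (x, y, 1) with x = column and y = row. ``residual_cm``
    is the RMS distance between the mapped fiducial pixels and the layout
    points (zero up to round-off for an exact four-point solve).
    """

    matrix: np.ndarray
    residual_cm: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ShapeError("transform matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-15:
            raise DegenerateGeometryError("transform matrix is singular")

    def map_xy(self, points_xy: np.ndarray) -> np.ndarray:
        """Map (n, 2) pixel points given as (x=col, y=row) to cm."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def map_rowcol(self, points_rc: np.ndarray) -> np.ndarray:
        """Map (n, 2) pixel points given as (row, col) to cm (x, y)."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        return self.map_xy(pts[:, ::-1])

    def jacobian_det(self, points_xy: np.ndarray) -> np.ndarray:
        """Signed area scale (cm² per px²) at pixel points (x=col, y=row).

        For a homography H the Jacobian determinant at (x, y) is
        det(H) / w³ with w the homogeneous denominator at that point.
        """
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        w = self.matrix[2, 0] * pts[:, 0] + self.matrix[2, 1] * pts[:, 1] + self.matrix[2, 2]
        return np.linalg.det(self.matrix) / w**3

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"matrix": self.matrix.tolist(), "residual_cm": self.residual_cm},
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "PlanarTransform":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(np.asarray(data["matrix"]), data.get("residual_cm", 0.0))


def detect_fiducials(
    frame: ThermalFrame,
    band: tuple[float, float] = DEFAULT_FIDUCIAL_BAND_C,
    min_blob_px: int = 4,
) -> np.ndarray:
    """Locate the four cool fiducial disks; returns (4, 2) sub-pixel (row, col)
    centroids ordered upper-left, upper-right, lower-left, lower-right.

    Pixels inside the temperature band are grouped into 8-connected blobs;
    blobs smaller than ``min_blob_px`` are discarded. Anything other than
    exactly four surviving blobs raises :class:`FiducialDetectionError`
    carrying the candidate centroids.
    """
    lo, hi = band
    in_band = frame.valid_mask & (frame.values >= lo) & (frame.values <= hi)
    labels = measure.label(in_band, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_blob_px]
    centroids = np.array([p.centroid for p in props], dtype=float).reshape(-1, 2)
    if len(props) != 4:
        raise FiducialDetectionError(
            f"expected 4 fiducial blobs in band {band}, found {len(props)}",
            candidates=centroids,
        )
    order = np.argsort(centroids[:, 0])  # by row: two upper, two lower
    upper = centroids[order[:2]]
    lower = centroids[order[2:]]
    upper = upper[np.argsort(upper[:, 1])]
    lower = lower[np.argsort(lower[:, 1])]
    return np.vstack([upper, lower])


def fiducial_exclusion_mask(
    frame: ThermalFrame,
    band: tuple[float, float] = DEFAULT_FIDUCIAL_BAND_C,
    dilate_px: int = 1,
) -> np.ndarray:
    """Boolean mask of fiducial-band pixels (optionally dilated) to exclude
    from segmentation windows, since the cool disks would distort growth."""
    from scipy.ndimage import binary_dilation

    lo, hi = band
    in_band = frame.valid_mask & (frame.values >= lo) & (frame.values <= hi)
    if dilate_px > 0:
        in_band = binary_dilation(in_band, iterations=dilate_px)
    return in_band


def estimate_transform(
    pixel_centers_rc: np.ndarray, layout: FiducialLayout | None = None
) -> PlanarTransform:
    """Exact four-point homography from detected disk centres to the layout.

    ``pixel_centers_rc`` are (row, col) points in the same corner order as the
    layout. With four correspondences the 8-DOF homography is determined
    exactly, so the stored residual is zero up to numerical round-off.
    """
    if layout is None:
        layout = FiducialLayout()
    pts = np.asarray(pixel_centers_rc, dtype=float)
    if pts.shape != (4, 2):
        raise ShapeError("need exactly 4 pixel centres")
    src_xy = pts[:, ::-1]  # (x=col, y=row)
    dst = layout.array
    for i in range(4):
        others = [j for j in range(4) if j != i]
        if _collinear(src_xy[others[0]], src_xy[others[1]], src_xy[others[2]]):
            raise DegenerateGeometryError("three pixel centres are collinear")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src_xy, dst)
        ok = bool(tf)
    else:  # scikit-image < 0.26
        tf = ProjectiveTransform()
        ok = tf.estimate(src_xy, dst)
    if not ok or not np.all(np.isfinite(tf.params)):
        raise DegenerateGeometryError("homography estimation failed")
    mapped = tf(src_xy)
    residual = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return PlanarTransform(tf.params, residual_cm=residual)


def roi_area_m2(mask: RoiMask | np.ndarray, transform: PlanarTransform) -> float:
    """Physical ROI area in m² by per-pixel Jacobian integration.

    Each member pixel contributes the local metric area of one pixel cell —
    the absolute Jacobian determinant of the homography at the pixel centre
    (cm² per px²). For a pure-scale transform this reduces to
    pixel count x scale², the simple calibration of a frontal view; the
    Jacobian form stays correct under perspective.
    """
    arr = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(arr)
    if rows.size == 0:
        return 0.0
    pts_xy = np.column_stack([cols.astype(float), rows.astype(float)])
    area_cm2 = float(np.abs(transform.jacobian_det(pts_xy)).sum())
    return area_cm2 * 1e-4
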