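"""Image model, beam geometry and ROI sampling shared by all QA analyses.

Coordinate convention (declared once, consumed everywhere):

* Continuous panel coordinates are in millimetres with the origin at the
  projection of the beam central axis / collimator-rotation axis.
* ``x`` is crossplane (transverse), increasing with column index;
  ``y`` is inplane (radial), increasing toward the gantry, i.e. image
  row 0 sits at the most positive ``y``.
* ROI dimensions and off-axis distances are declared in the isocenter
  plane and projected onto the panel by the divergent-beam magnification
  ``sid / sad``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np


class GeometryError(ValueError):
    """Invalid beam/panel geometry."""


class RoiError(ValueError):
    """ROI cannot be sampled (outside image, zero area, ...)."""


class EdgeDetectionError(ValueError):
    """Field edges could not be located on a profile."""


@dataclass(frozen=True)
class BeamGeometry:
    """Source/axis/panel distances and collimating-device heights.

    Distances are in mm from the x-ray target. The jaw and MLC planes sit
    at different heights in the treatment head, which is what makes the
    four-field focal-spot triangulation solvable. Default heights are
    typical C-arm values and should be overridden with machine-specific
    ones where known.
    """

    sad: float = 1000.0
    sid: float = 1500.0
    h_mlc: float = 509.0
    h_jaw_x: float = 367.0
    h_jaw_y: float = 279.0

    def __post_init__(self) -> None:
        for name in ("h_mlc", "h_jaw_x", "h_jaw_y"):
            h = getattr(self, name)
            if not 0 < h < self.sad:
                raise GeometryError(f"{name}={h} must satisfy 0 < h < sad={self.sad}")
        if not self.sad < self.sid:
            raise GeometryError(f"need sad < sid, got sad={self.sad}, sid={self.sid}")

    @property
    def magnification(self) -> float:
        """Isocenter-to-panel projection factor sid/sad (> 1)."""
        return self.sid / self.sad


@dataclass
class EpidImage:
    """Calibrated-unit EPID raster with panel geometry.

    Parameters
    ----------
    pixels:
        2-D array of calibrated units (CU), finite and non-negative.
    pixel_pitch:
        Pixel spacing in mm at the panel plane.
    sid:
        Source-to-imager distance in mm.
    origin:
        Continuous ``(row, col)`` position of the beam central axis.
        Defaults to the image center.
    """

    pixels: np.ndarray
    pixel_pitch: float
    sid: float = 1500.0
    origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise GeometryError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise GeometryError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise GeometryError("pixels must be non-negative CU")
        if self.pixel_pitch <= 0:
            raise GeometryError("pixel_pitch must be > 0")
        if self.sid <= 0:
            raise GeometryError("sid must be > 0")
        if self.origin is None:
            self.origin = ((self.pixels.shape[0] - 1) / 2.0,
                           (self.pixels.shape[1] - 1) / 2.0)
        r0, c0 = self.origin
        nr, nc = self.pixels.shape
        if not (-0.5 <= r0 <= nr - 0.5 and -0.5 <= c0 <= nc - 0.5):
            raise GeometryError("origin must lie inside the image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def x_panel(self) -> np.ndarray:
        """Crossplane panel coordinate (mm) of each column center."""
        return (np.arange(self.shape[1]) - self.origin[1]) * self.pixel_pitch

    def y_panel(self) -> np.ndarray:
        """Inplane panel coordinate (mm) of each row center (row 0 at +y)."""
        return (self.origin[0] - np.arange(self.shape[0])) * self.pixel_pitch

    def scaled(self, factor: float) -> "EpidImage":
        """Return a copy with every pixel multiplied by ``factor``."""
        return EpidImage(self.pixels * factor, self.pixel_pitch, self.sid,
                         self.origin)


@dataclass(frozen=True)
class RoiSpec:
    """ROI declared in the isocenter plane; projected to the panel when sampled.

    ``shape`` is ``circle`` (uses ``radius``), or ``rect``/``band`` (use
    ``width`` along x and ``height`` along y). All dimensions in mm.
    """

    shape: Literal["circle", "rect", "band"]
    center: tuple[float, float] = (0.0, 0.0)
    radius: float | None = None
    width: float | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "circle":
            if self.radius is None or self.radius <= 0:
                raise RoiError("circle ROI needs radius > 0")
        elif self.shape in ("rect", "band"):
            if (self.width is None or self.height is None
                    or self.width <= 0 or self.height <= 0):
                raise RoiError(f"{self.shape} ROI needs width > 0 and height > 0")
        else:
            raise RoiError(f"unknown ROI shape {self.shape!r}")


@dataclass(frozen=True)
class EdgeSet:
    """50%-threshold field edges along one profile, isocenter-plane mm."""

    left: float
    right: float

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise EdgeDetectionError("left edge must be < right edge")

    @property
    def field_center(self) -> float:
        return 0.5 * (self.left + self.right)

    @property
    def field_width(self) -> float:
        return self.right - self.left


def project_length(length_iso: float, geom: BeamGeometry) -> float:
    """Scale a length from the isocenter plane to the panel plane.

    Pure divergent-beam ratio: ``length_iso * sid / sad``.
    """
    if length_iso <= 0:
        raise GeometryError("length_iso must be > 0")
    return length_iso * geom.magnification


def roi_mean(img: EpidImage, roi: RoiSpec, sad: float = 1000.0,
             supersample: int = 32) -> float:
    """Area-weighted mean CU over an ROI declared in the isocenter plane.

    Pixels fully inside the projected ROI get weight 1; boundary pixels are
    weighted by the fraction of their area inside the ROI. Rectangular ROIs
    use exact interval-overlap fractions; circular ROIs use
    ``supersample``² midpoint subpixel sampling (>= 16 enforced).
    """
    if supersample < 16:
        raise ValueError("supersample must be >= 16")
    mag = img.sid / sad
    pitch = img.pixel_pitch
    half = pitch / 2.0
    cx = roi.center[0] * mag
    cy = roi.center[1] * mag
    xs = img.x_panel()
    ys = img.y_panel()

    # panel extent covered by pixel areas
    x_lo_img, x_hi_img = xs[0] - half, xs[-1] + half
    y_lo_img, y_hi_img = ys[-1] - half, ys[0] + half

    if roi.shape == "circle":
        r = roi.radius * mag
        bx_lo, bx_hi, by_lo, by_hi = cx - r, cx + r, cy - r, cy + r
    else:
        w = roi.width * mag
        h = roi.height * mag
        bx_lo, bx_hi, by_lo, by_hi = cx - w / 2, cx + w / 2, cy - h / 2, cy + h / 2

    if bx_lo < x_lo_img or bx_hi > x_hi_img or by_lo < y_lo_img or by_hi > y_hi_img:
        raise RoiError("projected ROI extends outside the image")

    if roi.shape in ("rect", "band"):
        ox = np.clip(np.minimum(xs + half, bx_hi) - np.maximum(xs - half, bx_lo),
                     0.0, pitch) / pitch
        oy = np.clip(np.minimum(ys + half, by_hi) - np.maximum(ys - half, by_lo),
                     0.0, pitch) / pitch
        weights = np.outer(oy, ox)
        total = weights.sum()
        if total <= 0:
            raise RoiError("ROI covers zero pixel area")
        return float((weights * img.pixels).sum() / total)

    # circle
    cols = np.nonzero(np.abs(xs - cx) <= r + half)[0]
    rows = np.nonzero(np.abs(ys - cy) <= r + half)[0]
    if cols.size == 0 or rows.size == 0:
        raise RoiError("ROI covers zero pixel area")
    dx = xs[cols] - cx
    dy = ys[rows] - cy
    dist = np.hypot(dx[None, :], dy[:, None])
    half_diag = half * np.sqrt(2.0)
    weights = np.zeros_like(dist)
    weights[dist <= r - half_diag] = 1.0
    boundary = (dist > r - half_diag) & (dist < r + half_diag)
    if np.any(boundary):
        bi, bj = np.nonzero(boundary)
        off = (np.arange(supersample) + 0.5) / supersample - 0.5
        off = off * pitch
        # subpixel sample coordinates relative to the circle center
        sx = dx[bj][:, None] + off[None, :]          # (nb, ss)
        sy = dy[bi][:, None] + off[None, :]          # (nb, ss)
        inside = (sx[:, None, :] ** 2 + sy[:, :, None] ** 2) <= r * r
        weights[bi, bj] = inside.mean(axis=(1, 2))
    total = weights.sum()
    if total <= 0:
        raise RoiError("ROI covers zero pixel area")
    sub = img.pixels[np.ix_(rows, cols)]
    return float((weights * sub).sum() / total)


def detect_edges(positions: np.ndarray, values: np.ndarray,
                 threshold_frac: float = 0.5) -> EdgeSet:
    """Locate the two field edges of a profile by threshold crossing.

    The plateau is estimated as the mean of the central 50% of the
    above-threshold region; each edge is the linearly interpolated crossing
    of ``threshold_frac * plateau``. Positions are returned in the same
    units they were supplied in (isocenter-plane mm by convention).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.ndim != 1 or positions.shape != values.shape:
        raise ValueError("positions and values must be matching 1-D arrays")
    if positions.size < 4:
        raise EdgeDetectionError("profile too short")
    if not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")

    vmax = values.max()
    if vmax <= 0:
        raise EdgeDetectionError("no crossing found: profile is non-positive")
    above = values >= threshold_frac * vmax
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        raise EdgeDetectionError("no crossing found")
    # demand one contiguous plateau region
    if np.any(np.diff(idx) > 1):
        raise EdgeDetectionError("multiple plateaus detected")
    lo, hi = idx[0], idx[-1]
    span = hi - lo + 1
    c0 = lo + span // 4
    c1 = hi - span // 4
    plateau = float(values[c0:c1 + 1].mean())
    thr = threshold_frac * plateau

    s = values - thr
    sign = s > 0
    changes = np.nonzero(sign[1:] != sign[:-1])[0]
    if changes.size == 0:
        raise EdgeDetectionError("no crossing found")
    if changes.size > 2:
        raise EdgeDetectionError("multiple plateaus detected")

    def _interp(i: int) -> float:
        x0, x1 = positions[i], positions[i + 1]
        v0, v1 = values[i], values[i + 1]
        return x0 + (thr - v0) * (x1 - x0) / (v1 - v0)

    rising = [i for i in changes if values[i + 1] > values[i]]
    falling = [i for i in changes if values[i + 1] < values[i]]
    if not rising or not falling:
        raise EdgeDetectionError("no crossing found on one shoulder")
    left = _interp(rising[0])
    right = _interp(falling[-1])
    return EdgeSet(left=left, right=right)


def extract_profile(img: EpidImage, axis: Literal["x", "y"],
                    sad: float = 1000.0,
                    strip_width: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Profile along one axis, averaged over a central strip of the other.

    ``strip_width`` is in isocenter-plane mm; returned positions are
    isocenter-plane mm along the requested axis.
    """
    mag = img.sid / sad
    half = strip_width * mag / 2.0
    if axis == "x":
        rows = np.abs(img.y_panel()) <= half
        if not rows.any():
            raise RoiError("strip contains no rows")
        values = img.pixels[rows, :].mean(axis=0)
        pos = img.x_panel() / mag
    elif axis == "y":
        cols = np.abs(img.x_panel()) <= half
        if not cols.any():
            raise RoiError("strip contains no columns")
        values = img.pixels[:, cols].mean(axis=1)
        pos = img.y_panel() / mag
        order = np.argsort(pos)
        pos, values = pos[order], values[order]
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return pos, values
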