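"""The six EPID QA analyses: wedge factor, central-axis dose, symmetry,
focal spot (two-field and four-field) and the VMAT band tests.

All analyses consume :class:`~epidqa.geometry.EpidImage` objects and emit
typed result records. Every metric here is a ratio or difference of ROI
means, so results are invariant to a global rescaling of the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .geometry import (BeamGeometry, EdgeSet, EpidImage, GeometryError,
                       RoiError, RoiSpec, detect_edges, extract_profile,
                       roi_mean)
from .simulate import DRGS_CENTERS_CM, LEAFSPEED_CENTERS_CM, FocalSpotImages


class AnalysisError(ValueError):
    """Analysis preconditions violated (geometry mismatch, zero reading, ...)."""


# ---------------------------------------------------------------------------
# result records


@dataclass(frozen=True)
class WedgeFactorResult:
    """Wedge factor: central-band reading ratio wedged/open."""

    wf: float
    wedge_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.wf <= 1.05:
            raise AnalysisError(f"wedge factor {self.wf} outside (0, 1.05]")


@dataclass(frozen=True)
class CentralDoseResult:
    """Mean CU of the central circular ROI, optionally vs. a baseline."""

    cu_mean: float
    percent_change_from_baseline: float | None = None

    def __post_init__(self) -> None:
        if self.cu_mean <= 0:
            raise AnalysisError("cu_mean must be > 0")


@dataclass(frozen=True)
class SymmetryResult:
    """Axial/transverse symmetry from the five cardinal ROIs (percent).

    axial = 100 * (top - bottom) / bottom;
    transverse = 100 * (right - left) / left.
    """

    axial: float
    transverse: float
    roi_means: dict[str, float]


@dataclass(frozen=True)
class ProfileCA:
    """Profile-center offsets from the central axis (mm) at the two
    opposing collimator angles, for one axis."""

    ca90: float
    ca270: float


@dataclass(frozen=True)
class FocalSpotResult:
    """Lateral source displacement (mm, signed) and the per-device
    apparent field centers (panel-plane mm) it was solved from."""

    sx: float
    sy: float
    apparent_centers: dict[str, float]

    @property
    def total(self) -> float:
        """Total deviation from the central axis, |(sx, sy)|."""
        return float(np.hypot(self.sx, self.sy))


@dataclass(frozen=True)
class VmatBandResult:
    """Per-band VMAT metrics: Rcorr = 100*R_LS/R_open,
    Diff = Rcorr - mean(Rcorr), pass iff |Diff| <= tolerance (%)."""

    r_ls: np.ndarray
    r_open: np.ndarray
    rcorr: np.ndarray
    diff: np.ndarray
    passed: np.ndarray
    tolerance: float
    centers_cm: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(float(self.diff.sum())) > 1e-9:
            raise AnalysisError("Diff values must sum to zero")

    @property
    def all_passed(self) -> bool:
        return bool(np.all(self.passed))


# ---------------------------------------------------------------------------
# analyses


def _check_same_geometry(a: EpidImage, b: EpidImage) -> None:
    if (a.shape != b.shape or a.pixel_pitch != b.pixel_pitch
            or a.sid != b.sid or a.origin != b.origin):
        raise AnalysisError("images have mismatched geometry")


def wedge_factor(wedged: EpidImage, open_: EpidImage,
                 wedge_angle_deg: float | None = None,
                 band_width: float = 5.0, band_frac: float = 0.8,
                 gradient_axis: Literal["x", "y"] = "y",
                 sad: float = 1000.0) -> WedgeFactorResult:
    """Wedge factor from a central band ROI, wedged/open reading ratio.

    The band is ``band_width`` mm (isocenter plane) along the wedge-gradient
    axis and spans ``band_frac`` of the detected field length along the
    unwedged axis, so the gradient is sampled only at the axis.
    """
    _check_same_geometry(wedged, open_)
    other: Literal["x", "y"] = "x" if gradient_axis == "y" else "y"
    pos, vals = extract_profile(open_, other, sad=sad)
    edges = detect_edges(pos, vals)
    length = band_frac * edges.field_width
    if gradient_axis == "y":
        roi = RoiSpec("band", center=(edges.field_center, 0.0),
                      width=length, height=band_width)
    else:
        roi = RoiSpec("band", center=(0.0, edges.field_center),
                      width=band_width, height=length)
    denom = roi_mean(open_, roi, sad=sad)
    if denom <= 0:
        raise AnalysisError("open-field band reading is zero")
    wf = roi_mean(wedged, roi, sad=sad) / denom
    return WedgeFactorResult(wf=wf, wedge_angle_deg=wedge_angle_deg)


def central_axis_dose(img: EpidImage,
                      baseline: "CentralDoseResult | float | None" = None,
                      roi_radius: float = 5.0,
                      sad: float = 1000.0) -> CentralDoseResult:
    """Mean CU within a central circle (default 5 mm radius at isocenter).

    The radius is configurable to mirror the size of the ion chamber being
    compared against. With a baseline, the percent change is reported.
    """
    cu = roi_mean(img, RoiSpec("circle", radius=roi_radius), sad=sad)
    if cu <= 0:
        raise AnalysisError("central ROI reading is zero")
    change = None
    if baseline is not None:
        ref = baseline.cu_mean if isinstance(baseline, CentralDoseResult) else float(baseline)
        if ref <= 0:
            raise AnalysisError("baseline reading must be > 0")
        change = 100.0 * (cu / ref - 1.0)
    return CentralDoseResult(cu_mean=cu, percent_change_from_baseline=change)


def symmetry(img: EpidImage, field_size: float = 180.0, offset: float = 75.0,
             roi_diameter: float = 5.0, scale_with_field: bool = False,
             sad: float = 1000.0) -> SymmetryResult:
    """Symmetry from five circular ROIs: center plus four cardinal points.

    The four off-axis ROIs sit ``offset`` mm (isocenter plane) from the
    axis; with ``scale_with_field`` the 75 mm / 90 mm ratio of the 18x18 cm
    reference field is kept constant as the field size changes.
    axial = 100*(top-bottom)/bottom, transverse = 100*(right-left)/left.
    """
    if scale_with_field:
        offset = offset / 90.0 * field_size / 2.0
    r = roi_diameter / 2.0
    means = {
        "center": roi_mean(img, RoiSpec("circle", (0.0, 0.0), radius=r), sad=sad),
        "top": roi_mean(img, RoiSpec("circle", (0.0, offset), radius=r), sad=sad),
        "bottom": roi_mean(img, RoiSpec("circle", (0.0, -offset), radius=r), sad=sad),
        "right": roi_mean(img, RoiSpec("circle", (offset, 0.0), radius=r), sad=sad),
        "left": roi_mean(img, RoiSpec("circle", (-offset, 0.0), radius=r), sad=sad),
    }
    if means["bottom"] <= 0 or means["left"] <= 0:
        raise AnalysisError("off-axis ROI reading is zero; ROI outside field?")
    axial = 100.0 * (means["top"] - means["bottom"]) / means["bottom"]
    transverse = 100.0 * (means["right"] - means["left"]) / means["left"]
    return SymmetryResult(axial=axial, transverse=transverse, roi_means=means)


def focal_spot_twofield(ca90, ca270):
    """Two-field focal-spot position from opposing-collimator profile
    offsets: -(CA90 - CA270)/2, applied per axis (array-friendly)."""
    return -(np.asarray(ca90, dtype=float) - np.asarray(ca270, dtype=float)) / 2.0


def _field_centers_panel(img: EpidImage, geom: BeamGeometry) -> tuple[float, float]:
    """Field center (panel-plane mm) along x and y via 50% edge detection."""
    mag = geom.magnification
    centers = []
    for axis in ("x", "y"):
        pos, vals = extract_profile(img, axis, sad=geom.sad)
        centers.append(detect_edges(pos, vals).field_center * mag)
    return centers[0], centers[1]


def focal_spot_epid(images: FocalSpotImages, geom: BeamGeometry,
                    min_height_gap: float = 1e-6) -> FocalSpotResult:
    """Four-field focal-spot triangulation from MLC- and jaw-defined fields.

    For a source displaced laterally by ``s``, a device at height ``h``
    projects its field center to panel position ``s * (1 - sid/h)``.
    Averaging each device's two opposing-collimator centers cancels device
    miscentering, and the MLC/jaw difference solves for ``s``:

        s = (A_mlc - A_jaw) / (sid * (1/h_jaw - 1/h_mlc))

    using the jaw height of the matching axis.
    """
    mlc_a = _field_centers_panel(images.mlc_a, geom)
    mlc_b = _field_centers_panel(images.mlc_b, geom)
    jaw_a = _field_centers_panel(images.jaw_a, geom)
    jaw_b = _field_centers_panel(images.jaw_b, geom)
    centers: dict[str, float] = {}
    shifts = []
    for axis, i, h_jaw in (("x", 0, geom.h_jaw_x), ("y", 1, geom.h_jaw_y)):
        a_mlc = 0.5 * (mlc_a[i] + mlc_b[i])
        a_jaw = 0.5 * (jaw_a[i] + jaw_b[i])
        centers[f"mlc_{axis}"] = a_mlc
        centers[f"jaw_{axis}"] = a_jaw
        gap = 1.0 / h_jaw - 1.0 / geom.h_mlc
        if abs(gap) < min_height_gap:
            raise GeometryError(
                f"jaw and MLC heights too close on axis {axis}: geometry unsolvable")
        shifts.append((a_mlc - a_jaw) / (geom.sid * gap))
    return FocalSpotResult(sx=shifts[0], sy=shifts[1], apparent_centers=centers)


def vmat_analysis(dynamic: EpidImage, open_: EpidImage,
                  kind: Literal["drgs", "leafspeed"],
                  tolerance: float = 2.0,
                  centers_cm: Sequence[float] | None = None,
                  sad: float = 1000.0) -> VmatBandResult:
    """VMAT dose-rate/gantry-speed or leaf-speed band analysis.

    Per band: R_LS and R_open are ROI means of the dynamic and open images
    (leaf speed: 1 cm x 16 cm ROIs; DRGS: 0.75 cm x 17 cm ROIs, both with
    fractional-pixel weighting); Rcorr = 100*R_LS/R_open and
    Diff = Rcorr - mean(Rcorr), pass iff |Diff| <= tolerance (default 2%).
    """
    _check_same_geometry(dynamic, open_)
    if kind == "leafspeed":
        centers = LEAFSPEED_CENTERS_CM if centers_cm is None else tuple(centers_cm)
        roi_w, roi_h = 10.0, 160.0
    elif kind == "drgs":
        centers = DRGS_CENTERS_CM if centers_cm is None else tuple(centers_cm)
        roi_w, roi_h = 7.5, 170.0
    else:
        raise ValueError("kind must be 'drgs' or 'leafspeed'")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")

    r_ls = np.empty(len(centers))
    r_open = np.empty(len(centers))
    for i, c in enumerate(centers):
        roi = RoiSpec("band", center=(c * 10.0, 0.0), width=roi_w, height=roi_h)
        r_ls[i] = roi_mean(dynamic, roi, sad=sad)
        r_open[i] = roi_mean(open_, roi, sad=sad)
    if np.any(r_open <= 0):
        raise AnalysisError("open-field band reading is zero")
    rcorr = 100.0 * r_ls / r_open
    diff = rcorr - rcorr.mean()
    passed = np.abs(diff) <= tolerance
    return VmatBandResult(r_ls=r_ls, r_open=r_open, rcorr=rcorr, diff=diff,
                          passed=passed, tolerance=tolerance,
                          centers_cm=tuple(centers))
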