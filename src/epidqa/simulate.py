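"""Synthetic EPID image generator with known ground truth.

Emulates the deliveries used to exercise each QA analysis: flattened/FFF
open fields with logistic penumbra, EDW-style exponential wedge gradients,
four-field focal-spot sets with projected edges under a laterally displaced
source, and VMAT band pairs built from per-segment MU fractions. Additive
Gaussian pixel noise is seeded and bit-reproducible.

The geometric heart is the projection of a collimating edge from its device
plane to the panel under a displaced source: a device edge at physical
lateral position ``e`` and height ``h`` below the target projects, for a
source displaced laterally by ``s``, to panel position

    p = s + (e - s) * sid / h

so devices at different heights (MLC vs jaws) shift by different amounts —
the lever the focal-spot analysis triangulates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Literal, Sequence

import numpy as np

from .geometry import BeamGeometry, EpidImage, GeometryError

#: logistic scale such that penumbra_sigma is the 80%-20% penumbra width
_P8020 = 2.0 * math.log(4.0)

#: detector/band center positions (cm at isocenter) for the two VMAT tests
LEAFSPEED_CENTERS_CM = (-4.5, -1.5, 1.5, 4.5)
DRGS_CENTERS_CM = (-5.1, -3.1, -1.1, 0.9, 2.9, 4.9, 6.9)

#: modified-plan MU fractions used as study conditions
LEAFSPEED_MODIFIED_FRACTIONS = (0.16, 0.21, 0.29, 0.34)
DRGS_MODIFIED_FRACTIONS = (0.08, 0.14, 0.15, 0.15, 0.16, 0.16, 0.16)


@dataclass(frozen=True)
class FieldModel:
    """Beam + panel model for one simulated delivery.

    ``field_size`` is (x, y) in cm at isocenter. ``horn_coeff`` is the
    quadratic off-axis coefficient: positive horns for a flattened beam,
    or the peak-falloff coefficient for ``mode='fff'``.
    ``penumbra_sigma`` is the 80-20% penumbra width in isocenter mm.
    ``noise_sd`` is additive Gaussian noise in CU per pixel.
    """

    field_size: tuple[float, float] = (18.0, 18.0)
    mode: Literal["flattened", "fff"] = "flattened"
    plateau_cu: float = 1.0
    horn_coeff: float = 0.03
    penumbra_sigma: float = 3.0
    noise_sd: float = 0.005
    seed: int = 0
    panel_shape: tuple[int, int] = (512, 512)
    pixel_pitch: float = 0.8

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.plateau_cu <= 0:
            raise ValueError("plateau_cu must be > 0")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")


@dataclass(frozen=True)
class ErrorSpec:
    """Injected machine/plan errors.

    ``output_scale`` multiplies the whole image (MU change); ``tilt_*`` are
    fractional linear asymmetries per 100 mm off-axis (beam-steering);
    ``focal_shift`` is the lateral source displacement (mm);
    ``segment_fractions`` are per-segment MU fractions for VMAT pairs.
    """

    output_scale: float = 1.0
    tilt_x: float = 0.0
    tilt_y: float = 0.0
    focal_shift: tuple[float, float] = (0.0, 0.0)
    wedge_angle: float = 0.0
    segment_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.output_scale <= 0:
            raise ValueError("output_scale must be > 0")
        if self.segment_fractions is not None:
            if abs(sum(self.segment_fractions) - 1.0) > 1e-9:
                raise ValueError("segment_fractions must sum to 1")


@dataclass(frozen=True)
class FocalSpotImages:
    """The four-field focal-spot set, tagged by defining device and
    collimator orientation (a/b are the opposing-collimator pair)."""

    mlc_a: EpidImage
    mlc_b: EpidImage
    jaw_a: EpidImage
    jaw_b: EpidImage


def wedge_factor_true(angle_deg: float, gamma: float = 0.002,
                      y_heel: float = -90.0) -> float:
    """Ground-truth wedge factor of the exponential wedge model at the axis.

    The wedge transmission is G(y) = exp(-gamma * tan(theta) * (y - y_heel));
    the wedge factor is its value on the central axis, G(0).
    """
    return math.exp(-gamma * math.tan(math.radians(angle_deg)) * (0.0 - y_heel))


def tilt_symmetry_true(tilt: float, offset: float = 75.0) -> float:
    """Closed-form symmetry (%) produced by a linear tilt.

    The radial profile and penumbra are even in the off-axis coordinate, so
    the ratio of model values at +/-offset reduces to the tilt factor alone:
    100 * (P(+d) - P(-d)) / P(-d) with P = 1 + tilt * d / 100.
    """
    up = 1.0 + tilt * offset / 100.0
    dn = 1.0 - tilt * offset / 100.0
    return 100.0 * (up - dn) / dn


def _logistic(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def _edge_pair_iso(half_iso: float, height: float, shift: float,
                   device_offset: float, geom: BeamGeometry) -> tuple[float, float]:
    """Project the two device edges to the panel (returned in iso-equivalent
    mm, i.e. panel mm divided by the magnification)."""
    mag = geom.magnification
    edges = []
    for e_iso in (-half_iso + device_offset, half_iso + device_offset):
        e_phys = e_iso * height / geom.sad
        p = shift + (e_phys - shift) * geom.sid / height
        edges.append(p / mag)
    return edges[0], edges[1]


def _render(fm: FieldModel, err: ErrorSpec, geom: BeamGeometry,
            heights: tuple[float, float] | None = None,
            device_offset: tuple[float, float] = (0.0, 0.0),
            extra: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
            rng: np.random.Generator | None = None) -> EpidImage:
    """Render one field. ``heights`` are the (x-edge, y-edge) defining-device
    heights; default is the jaw pair. ``extra`` multiplies an additional
    fluence factor evaluated on isocenter-plane (X, Y) grids."""
    if heights is None:
        heights = (geom.h_jaw_x, geom.h_jaw_y)
    nr, nc = fm.panel_shape
    origin = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    mag = geom.magnification
    x_iso = (np.arange(nc) - origin[1]) * fm.pixel_pitch / mag
    y_iso = (origin[0] - np.arange(nr)) * fm.pixel_pitch / mag
    X, Y = np.meshgrid(x_iso, y_iso)

    fx_half = fm.field_size[0] * 10.0 / 2.0
    fy_half = fm.field_size[1] * 10.0 / 2.0
    mag_check = max(fx_half, fy_half) * mag
    if mag_check > min(nr, nc) / 2.0 * fm.pixel_pitch:
        raise GeometryError("field exceeds panel")

    sx, sy = err.focal_shift
    s_log = fm.penumbra_sigma / _P8020
    xl, xr = _edge_pair_iso(fx_half, heights[0], sx, device_offset[0], geom)
    yl, yr = _edge_pair_iso(fy_half, heights[1], sy, device_offset[1], geom)
    fluence = (_logistic((X - xl) / s_log) * _logistic((xr - X) / s_log)
               * _logistic((Y - yl) / s_log) * _logistic((yr - Y) / s_log))

    r2 = (X ** 2 + Y ** 2) / fx_half ** 2
    if fm.mode == "flattened":
        profile = 1.0 + fm.horn_coeff * r2
    else:
        profile = 1.0 - fm.horn_coeff * r2
    profile = np.clip(profile, 0.0, None)

    tilt = 1.0 + err.tilt_x * X / 100.0 + err.tilt_y * Y / 100.0
    pixels = err.output_scale * fm.plateau_cu * profile * np.clip(tilt, 0.0, None) * fluence
    if extra is not None:
        pixels = pixels * extra(X, Y)
    if fm.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(fm.seed)
        pixels = pixels + rng.normal(0.0, fm.noise_sd, pixels.shape)
        pixels = np.clip(pixels, 0.0, None)
    return EpidImage(pixels, fm.pixel_pitch, geom.sid, origin)


def make_open_field(fm: FieldModel, err: ErrorSpec = ErrorSpec(),
                    geom: BeamGeometry = BeamGeometry()) -> EpidImage:
    """Open (unwedged, static) field with the requested errors injected."""
    return _render(fm, err, geom)


def make_wedge_field(fm: FieldModel, angle_deg: float,
                     err: ErrorSpec = ErrorSpec(),
                     geom: BeamGeometry = BeamGeometry(),
                     gamma: float = 0.002, y_heel: float = -90.0) -> EpidImage:
    """Wedged field: open field times the exponential wedge transmission.

    G(y; theta) = exp(-gamma * tan(theta) * (y - y_heel)). The ground-truth
    wedge factor is G(0) = :func:`wedge_factor_true`. ``gamma`` and
    ``y_heel`` are model constants chosen so the wedge factor decreases
    monotonically over 10-60 degrees.
    """
    if not 0.0 < angle_deg <= 60.0:
        raise ValueError("wedge angle must be in (0, 60] degrees")
    a = gamma * math.tan(math.radians(angle_deg))

    def wedge(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return np.exp(-a * (Y - y_heel))

    return _render(fm, err, geom, extra=wedge)


def make_focal_spot_set(fm: FieldModel, shift: tuple[float, float] = (0.0, 0.0),
                        geom: BeamGeometry = BeamGeometry(),
                        device_offset: float = 0.0) -> FocalSpotImages:
    """Four-field focal-spot set for a source displaced by ``shift`` (mm).

    Two fields are defined by the MLC (both axes at ``h_mlc``) and two by
    the jaws (x at ``h_jaw_x``, y at ``h_jaw_y``); each pair is delivered at
    opposing collimator angles, which flips the sign of any device
    miscentering ``device_offset`` (mm at isocenter) so the analysis can
    cancel it.
    """
    err = ErrorSpec(focal_shift=shift)
    rng = np.random.default_rng(fm.seed)
    mlc_h = (geom.h_mlc, geom.h_mlc)
    jaw_h = (geom.h_jaw_x, geom.h_jaw_y)
    c = device_offset
    return FocalSpotImages(
        mlc_a=_render(fm, err, geom, mlc_h, (c, c), rng=rng),
        mlc_b=_render(fm, err, geom, mlc_h, (-c, -c), rng=rng),
        jaw_a=_render(fm, err, geom, jaw_h, (c, c), rng=rng),
        jaw_b=_render(fm, err, geom, jaw_h, (-c, -c), rng=rng),
    )


def make_vmat_pair(kind: Literal["drgs", "leafspeed"],
                   fractions: Sequence[float] | None = None,
                   fm: FieldModel = FieldModel(),
                   geom: BeamGeometry = BeamGeometry(),
                   centers_cm: Sequence[float] | None = None,
                   band_width_cm: float | None = None,
                   normalize: bool = True) -> tuple[EpidImage, EpidImage]:
    """(dynamic, open) image pair for a VMAT band test.

    The open image is a uniform plateau; the dynamic image consists of
    disjoint vertical bands at the test's detector positions. With
    ``normalize=True`` band i reads ``fraction_i * n * plateau`` so the
    baseline equal-fraction plan yields bands equal to the open plateau;
    with ``normalize=False`` band i reads ``fraction_i * plateau``.
    """
    if kind == "leafspeed":
        centers = LEAFSPEED_CENTERS_CM if centers_cm is None else tuple(centers_cm)
        width = 3.0 if band_width_cm is None else band_width_cm
    elif kind == "drgs":
        centers = DRGS_CENTERS_CM if centers_cm is None else tuple(centers_cm)
        width = 2.0 if band_width_cm is None else band_width_cm
    else:
        raise ValueError("kind must be 'drgs' or 'leafspeed'")
    n = len(centers)
    if fractions is None:
        fractions = np.full(n, 1.0 / n)
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size != n:
        raise ValueError(f"expected {n} fractions, got {fractions.size}")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    nr, nc = fm.panel_shape
    origin = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    mag = geom.magnification
    x_iso = (np.arange(nc) - origin[1]) * fm.pixel_pitch / mag
    y_iso = (origin[0] - np.arange(nr)) * fm.pixel_pitch / mag
    X, Y = np.meshgrid(x_iso, y_iso)

    rng = np.random.default_rng(fm.seed)
    scale = n if normalize else 1.0
    y_half = fm.field_size[1] * 10.0 / 2.0
    in_y = np.abs(Y) <= y_half
    dyn = np.zeros_like(X)
    for c, f in zip(centers, fractions):
        band = (np.abs(X - c * 10.0) <= width * 10.0 / 2.0) & in_y
        dyn[band] = f * scale * fm.plateau_cu
    open_pix = np.full_like(X, fm.plateau_cu)
    if fm.noise_sd > 0:
        dyn = np.clip(dyn + rng.normal(0.0, fm.noise_sd, dyn.shape), 0.0, None)
        open_pix = np.clip(open_pix + rng.normal(0.0, fm.noise_sd, open_pix.shape),
                           0.0, None)
    dynamic = EpidImage(dyn, fm.pixel_pitch, geom.sid, origin)
    open_ = EpidImage(open_pix, fm.pixel_pitch, geom.sid, origin)
    return dynamic, open_
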