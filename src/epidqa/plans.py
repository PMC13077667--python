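"""RT Plan meterset editing for VMAT error injection.

The VMAT band tests are perturbed by redistributing how much of the total
MU each segment delivers. In a DICOM RT Plan that is encoded in the control
points' cumulative meterset weights (monotone 0 -> 1); this module reads a
beam's weights, remaps them so each segment delivers a requested MU
fraction, and writes the plan back with everything else untouched.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence as DicomSequence
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

RT_PLAN_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.481.5"

_BOUNDARY_TOL = 1e-9


class PlanError(ValueError):
    """Malformed or unsupported RT Plan content."""


@dataclass
class PlanSegments:
    """One beam's control-point weights plus its segment partition.

    ``weights`` are the cumulative meterset weights normalized to [0, 1];
    ``boundaries`` are the n+1 cumulative weights delimiting the n segments
    (0 = first, 1 = last). ``dataset`` keeps the source DICOM dataset so the
    plan can be written back with only the weights changed.
    """

    beam_id: str
    weights: np.ndarray
    boundaries: np.ndarray
    total_mu: float | None = None
    dataset: "pydicom.Dataset | None" = None
    beam_index: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.weights.size < 2:
            raise PlanError("need at least two control points")
        if np.any(np.diff(self.weights) < 0):
            raise PlanError("cumulative meterset weights must be non-decreasing")
        if abs(self.weights[0]) > _BOUNDARY_TOL or abs(self.weights[-1] - 1.0) > _BOUNDARY_TOL:
            raise PlanError("cumulative weights must run from 0 to 1")
        if (self.boundaries.size < 2 or abs(self.boundaries[0]) > _BOUNDARY_TOL
                or abs(self.boundaries[-1] - 1.0) > _BOUNDARY_TOL
                or np.any(np.diff(self.boundaries) <= 0)):
            raise PlanError("segment boundaries must increase from 0 to 1")

    @property
    def n_segments(self) -> int:
        return self.boundaries.size - 1

    def segment_fractions(self) -> np.ndarray:
        """MU fraction each segment delivers (boundary-weight spans)."""
        return np.diff(self.boundaries)


def _infer_equal_boundaries(weights: np.ndarray) -> np.ndarray:
    """Largest n such that every multiple j/n occurs among the weights."""
    for n in range(weights.size - 1, 0, -1):
        grid = np.arange(n + 1) / n
        if all(np.any(np.abs(weights - g) <= 1e-9) for g in grid):
            return grid
    return np.array([0.0, 1.0])


def read_plan(path: str | Path, beam_index: int = 0,
              n_segments: int | None = None,
              boundaries: Sequence[float] | None = None) -> PlanSegments:
    """Parse one beam's control points from a DICOM RT Plan.

    Segments are taken from explicit ``boundaries`` (cumulative weights),
    from an equal partition into ``n_segments``, or — by default — inferred
    as the finest equal partition whose boundary weights all occur among
    the control points (matching equally-spaced-segment test plans).
    """
    ds = pydicom.dcmread(str(path))
    beams = getattr(ds, "BeamSequence", None)
    if not beams:
        raise PlanError("plan has no BeamSequence")
    beam = beams[beam_index]
    cps = getattr(beam, "ControlPointSequence", None)
    if not cps:
        raise PlanError("beam has no ControlPointSequence")
    raw = np.array([float(cp.CumulativeMetersetWeight) for cp in cps])
    final = float(getattr(beam, "FinalCumulativeMetersetWeight", raw[-1]))
    if final <= 0:
        raise PlanError("final cumulative meterset weight must be > 0")
    weights = raw / final
    if np.any(np.diff(weights) < 0):
        raise PlanError("cumulative meterset weights must be non-decreasing")

    total_mu = None
    fg = getattr(ds, "FractionGroupSequence", None)
    if fg:
        refs = getattr(fg[0], "ReferencedBeamSequence", None)
        if refs and beam_index < len(refs):
            total_mu = float(getattr(refs[beam_index], "BeamMeterset", 0.0)) or None

    if boundaries is not None:
        b = np.asarray(boundaries, dtype=float)
    elif n_segments is not None:
        b = np.arange(n_segments + 1) / n_segments
    else:
        b = _infer_equal_boundaries(weights)
    return PlanSegments(beam_id=str(getattr(beam, "BeamName", beam_index)),
                        weights=weights, boundaries=b, total_mu=total_mu,
                        dataset=ds, beam_index=beam_index)


def redistribute(plan: PlanSegments, fractions: Sequence[float]) -> PlanSegments:
    """Rescale each segment's MU share to ``fractions``.

    The map is piecewise affine in cumulative-weight space: segment i's old
    span [b_i, b_{i+1}] is mapped onto [c_i, c_{i+1}] with c = cumsum of the
    requested fractions, preserving the relative spacing of interior
    control points within each segment.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != plan.n_segments:
        raise PlanError(f"expected {plan.n_segments} fractions, got {fr.size}")
    if np.any(fr <= 0):
        raise PlanError("fractions must be > 0")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise PlanError("fractions must sum to 1")
    old_b = plan.boundaries
    new_b = np.concatenate([[0.0], np.cumsum(fr)])
    new_b[-1] = 1.0

    seg = np.clip(np.searchsorted(old_b, plan.weights, side="right") - 1,
                  0, plan.n_segments - 1)
    lo, hi = old_b[seg], old_b[seg + 1]
    t = (plan.weights - lo) / (hi - lo)
    new_w = new_b[seg] + t * (new_b[seg + 1] - new_b[seg])
    new_w[0], new_w[-1] = 0.0, 1.0
    return PlanSegments(beam_id=plan.beam_id, weights=new_w, boundaries=new_b,
                        total_mu=plan.total_mu,
                        dataset=copy.deepcopy(plan.dataset) if plan.dataset is not None else None,
                        beam_index=plan.beam_index)


def write_plan(plan: PlanSegments, path: str | Path) -> None:
    """Write the plan back, differing only in cumulative meterset weights."""
    if plan.dataset is None:
        raise PlanError("plan carries no DICOM dataset to write")
    ds = copy.deepcopy(plan.dataset)
    beam = ds.BeamSequence[plan.beam_index]
    final = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0))
    cps = beam.ControlPointSequence
    if len(cps) != plan.weights.size:
        raise PlanError("control-point count mismatch")
    for cp, w in zip(cps, plan.weights):
        cp.CumulativeMetersetWeight = w * final
    ds.save_as(str(path), enforce_file_format=True)


def make_demo_plan(n_segments: int = 7, cps_per_segment: int = 1,
                   total_mu: float = 100.0, beam_name: str = "VMAT-QA") -> Dataset:
    """Synthetic equally-partitioned VMAT test plan (for fixtures/demos).

    Builds a minimal RT Plan dataset with one dynamic beam whose control
    points land on the j/n cumulative-weight grid (plus ``cps_per_segment``
    - 1 evenly spaced interior points per segment), with per-control-point
    gantry angles and sliding MLC positions as geometry payload.
    """
    n_cp = n_segments * cps_per_segment + 1
    weights = np.linspace(0.0, 1.0, n_cp)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RT_PLAN_STORAGE_UID
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = RT_PLAN_STORAGE_UID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = beam_name

    beam = Dataset()
    beam.BeamName = beam_name
    beam.BeamNumber = 1
    beam.BeamType = "DYNAMIC"
    beam.RadiationType = "PHOTON"
    beam.FinalCumulativeMetersetWeight = 1.0
    beam.NumberOfControlPoints = n_cp

    cps = []
    for i, w in enumerate(weights):
        cp = Dataset()
        cp.ControlPointIndex = i
        cp.CumulativeMetersetWeight = float(w)
        cp.GantryAngle = 180.0 - 360.0 * w if w <= 0.5 else 360.0 - (360.0 * w - 180.0)
        cp.GantryRotationDirection = "CW"
        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        # 10-leaf-pair sliding window sweeping -90 -> 90 mm
        left = -90.0 + 170.0 * w
        right = left + 10.0
        bld.LeafJawPositions = [left] * 10 + [right] * 10
        cp.BeamLimitingDevicePositionSequence = DicomSequence([bld])
        cps.append(cp)
    beam.ControlPointSequence = DicomSequence(cps)
    ds.BeamSequence = DicomSequence([beam])

    ref = Dataset()
    ref.ReferencedBeamNumber = 1
    ref.BeamMeterset = total_mu
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = DicomSequence([ref])
    ds.FractionGroupSequence = DicomSequence([fg])
    return ds


def ideal_diff(fractions: Sequence[float]) -> np.ndarray:
    """Expected Diff values (%) for given segment fractions under the
    unscaled Rcorr convention: 100*f - mean(100*f)."""
    r = 100.0 * np.asarray(fractions, dtype=float)
    return r - r.mean()
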