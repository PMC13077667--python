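"""Readers/writers for EPID images.

Two formats are supported: DICOM RT Image (modality RTIMAGE, the format
portal imagers export) and a plain-text fallback — a whitespace-separated
raster plus a JSON sidecar ``{pixel_pitch_mm, sid_mm, origin_rc}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .geometry import EpidImage

RT_IMAGE_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.481.1"


def read_rtimage(path: str | Path) -> EpidImage:
    """Read a DICOM RT Image into an :class:`EpidImage`.

    Applies rescale slope/intercept to CU, takes the SID from RT Image SID
    and the pitch from the image-plane pixel spacing; the beam-axis origin
    comes from RT Image Position when present, else the image center.
    """
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "ImagePlanePixelSpacing", None)
    if spacing is None:
        spacing = ds.PixelSpacing
    row_sp, col_sp = float(spacing[0]), float(spacing[1])
    if abs(row_sp - col_sp) > 1e-6:
        raise ValueError("non-square pixels are not supported")
    sid = float(getattr(ds, "RTImageSID", 1500.0))
    origin = None
    pos = getattr(ds, "RTImagePosition", None)
    if pos is not None:
        # (x, y) of the upper-left pixel center; beam axis is at (0, 0)
        origin = (float(pos[1]) / row_sp, -float(pos[0]) / col_sp)
    return EpidImage(arr, pixel_pitch=row_sp, sid=sid, origin=origin)


def write_rtimage(img: EpidImage, path: str | Path) -> None:
    """Write an :class:`EpidImage` as a minimal DICOM RT Image.

    Pixel CU values are stored as uint16 with a rescale slope; the
    round-trip is exact to the 16-bit quantization.
    """
    vmax = float(img.pixels.max())
    slope = vmax / 65535.0 if vmax > 0 else 1.0
    stored = np.round(img.pixels / slope).astype(np.uint16)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RT_IMAGE_STORAGE_UID
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = RT_IMAGE_STORAGE_UID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = 0.0
    ds.ImagePlanePixelSpacing = [img.pixel_pitch, img.pixel_pitch]
    ds.RTImageSID = img.sid
    r0, c0 = img.origin
    ds.RTImagePosition = [-c0 * img.pixel_pitch, r0 * img.pixel_pitch]
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_raster(path: str | Path, sidecar: str | Path | None = None) -> EpidImage:
    """Read the plain-text raster fallback format."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text())
    arr = np.loadtxt(path)
    origin = meta.get("origin_rc")
    return EpidImage(arr, pixel_pitch=float(meta["pixel_pitch_mm"]),
                     sid=float(meta["sid_mm"]),
                     origin=tuple(origin) if origin is not None else None)


def write_raster(img: EpidImage, path: str | Path) -> None:
    """Write the plain-text raster fallback format (array + JSON sidecar)."""
    path = Path(path)
    np.savetxt(path, img.pixels, fmt="%.8g")
    meta = {"pixel_pitch_mm": img.pixel_pitch, "sid_mm": img.sid,
            "origin_rc": list(img.origin)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_image(path: str | Path) -> EpidImage:
    """Dispatch on extension: ``.dcm`` -> RT Image, else raster fallback."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return read_rtimage(path)
    return read_raster(path)
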