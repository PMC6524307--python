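"""CT image data model, readers/writers, and HU windowing.

The package works on single transversal CT slices in Hounsfield units (HU).
Three on-disk forms are supported: a DICOM series directory, a NIfTI volume,
and a plain RAW+JSON fixture (flat 32-bit-float binary plus a JSON sidecar)
used for synthetic data.

All block matching, transforms and dictionary work operate on a windowed
8-bit-like intensity scale; :func:`apply_window` / :func:`unwindow` convert
between HU and that [0, 255] processing scale.  The soft-tissue window
(width 400 HU, level 40 HU) is the default throughout.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError


class Modality(str, Enum):
    MVCT = "MVCT"
    KVCT = "KVCT"
    SYNTHETIC = "SYNTHETIC"


@dataclass
class CTImage:
    """A single 2D CT slice with HU-valued pixels.

    Parameters
    ----------
    pixels : 2D float array of HU values (finite).
    spacing : (row, col) pixel spacing in mm, strictly positive.
    modality : acquisition modality tag.
    slice_index : position of the slice within its series.
    meta : free-form provenance dictionary (method, config hash, ...).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    modality: Modality = Modality.SYNTHETIC
    slice_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("HU values must be finite")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if min(self.spacing) <= 0:
            raise ValidationError("spacing must be strictly positive")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class CTSeries:
    """An ordered stack of same-grid CT slices."""

    slices: list[CTImage]
    reconstruction_interval: float = 2.0

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValidationError("series must contain at least one slice")
        shape = self.slices[0].shape
        spacing = self.slices[0].spacing
        for s in self.slices:
            if s.shape != shape:
                raise ValidationError("all slices must share one shape")
            if s.spacing != spacing:
                raise ValidationError("all slices must share one spacing")
        idx = [s.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("slice_index must be strictly increasing")
        if self.reconstruction_interval <= 0:
            raise ValidationError("reconstruction_interval must be positive")

    def __len__(self) -> int:
        return len(self.slices)

    def volume(self) -> np.ndarray:
        """Stack pixels to a (rows, cols, n_slices) HU volume."""
        return np.stack([s.pixels for s in self.slices], axis=-1)


@dataclass(frozen=True)
class WindowingSpec:
    """A display/processing window: ``width`` HU wide, centred at ``level``."""

    width: float = 400.0
    level: float = 40.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("window width must be > 0")

    @property
    def low(self) -> float:
        return self.level - self.width / 2.0

    @property
    def high(self) -> float:
        return self.level + self.width / 2.0


def apply_window(img: "CTImage | np.ndarray", w: WindowingSpec) -> np.ndarray:
    """Map HU to the [0, 255] processing scale.

    HU at or below ``level - width/2`` clip to 0, at or above
    ``level + width/2`` clip to 255, linear in between.  Monotone
    non-decreasing in HU; invertible strictly inside the window.
    """
    hu = img.pixels if isinstance(img, CTImage) else np.asarray(img, float)
    return np.clip((hu - w.low) * (255.0 / w.width), 0.0, 255.0)


def unwindow(values: np.ndarray, w: WindowingSpec) -> np.ndarray:
    """Inverse of :func:`apply_window` on the open interval (0, 255)."""
    return w.low + np.asarray(values, float) * (w.width / 255.0)


# ---------------------------------------------------------------------------
# Readers / writers


class SeriesFormat(str, Enum):
    DICOM = "DICOM"
    NIFTI = "NIfTI"
    RAW_JSON = "RAW+JSON"


def _infer_format(path: Path) -> SeriesFormat:
    if path.is_dir():
        return SeriesFormat.DICOM
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return SeriesFormat.NIFTI
    if name.endswith((".json", ".raw")):
        return SeriesFormat.RAW_JSON
    raise ValidationError(f"cannot infer series format from {path}")


def read_series(path: "str | os.PathLike", fmt: "SeriesFormat | str | None" = None) -> CTSeries:
    """Read a CT series from disk.

    ``fmt`` may be omitted, in which case it is inferred: a directory is
    treated as DICOM, ``.nii``/``.nii.gz`` as NIfTI, ``.raw``/``.json`` as
    the RAW+JSON fixture format.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = SeriesFormat(fmt) if fmt is not None else _infer_format(p)
    if fmt is SeriesFormat.DICOM:
        return _read_dicom(p)
    if fmt is SeriesFormat.NIFTI:
        return _read_nifti(p)
    return _read_raw(p)


def write_series(series: CTSeries, path: "str | os.PathLike",
                 fmt: "SeriesFormat | str | None" = None) -> Path:
    """Write a series; returns the primary path written."""
    p = Path(path)
    fmt = SeriesFormat(fmt) if fmt is not None else _infer_format(p)
    if fmt is SeriesFormat.DICOM:
        return _write_dicom(series, p)
    if fmt is SeriesFormat.NIFTI:
        return _write_nifti(series, p)
    return _write_raw(series, p)


# -- RAW+JSON fixtures -------------------------------------------------------

def _raw_paths(p: Path) -> tuple[Path, Path]:
    stem = p.with_suffix("") if p.suffix in {".raw", ".json"} else p
    return stem.with_suffix(".raw"), stem.with_suffix(".json")


def _write_raw(series: CTSeries, p: Path) -> Path:
    raw, sidecar = _raw_paths(p)
    vol = np.stack([s.pixels for s in series.slices]).astype(np.float32)
    raw.parent.mkdir(parents=True, exist_ok=True)
    vol.tofile(raw)
    meta = {
        "shape": list(vol.shape),
        "spacing": list(series.slices[0].spacing),
        "modality": series.slices[0].modality.value,
        "slice_indices": [s.slice_index for s in series.slices],
        "reconstruction_interval": series.reconstruction_interval,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return raw


def _read_raw(p: Path) -> CTSeries:
    raw, sidecar = _raw_paths(p)
    if not raw.exists() or not sidecar.exists():
        raise FileNotFoundError(f"RAW+JSON fixture needs both {raw} and {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    data = np.fromfile(raw, dtype=np.float32)
    if data.size != int(np.prod(shape)):
        raise ValidationError("RAW payload size does not match sidecar shape")
    vol = data.reshape(shape)
    spacing = tuple(meta.get("spacing", (1.0, 1.0)))
    modality = Modality(meta.get("modality", "SYNTHETIC"))
    indices = meta.get("slice_indices", list(range(shape[0])))
    slices = [CTImage(vol[i], spacing, modality, int(indices[i]))
              for i in range(shape[0])]
    return CTSeries(slices, float(meta.get("reconstruction_interval", 2.0)))


# -- DICOM -------------------------------------------------------------------

def _read_dicom(p: Path) -> CTSeries:
    import pydicom

    files = sorted(f for f in p.iterdir() if f.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {p}")
    loaded = []
    for f in files:
        ds = pydicom.dcmread(f)
        z = float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2])
        inst = int(getattr(ds, "InstanceNumber", 0))
        loaded.append((z, inst, ds))
    loaded.sort(key=lambda t: (t[0], t[1]))
    slices = []
    shapes = set()
    for i, (_, inst, ds) in enumerate(loaded):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        shapes.add(hu.shape)
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0]))
        modality = Modality.MVCT if getattr(ds, "Modality", "CT") == "CT" else Modality.SYNTHETIC
        slices.append(CTImage(hu, spacing, modality, inst if inst else i))
    if len(shapes) > 1:
        raise ValidationError("inconsistent slice shapes in DICOM series")
    interval = 2.0
    if len(loaded) > 1:
        interval = abs(loaded[1][0] - loaded[0][0]) or 2.0
    return CTSeries(slices, interval)


def _write_dicom(series: CTSeries, p: Path) -> Path:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    p.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    series_uid = generate_uid()
    for i, s in enumerate(series.slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = s.slice_index
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * series.reconstruction_interval]
        ds.PixelSpacing = [s.spacing[0], s.spacing[1]]
        ds.Rows, ds.Columns = s.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed, HU stored directly
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        stored = np.rint(s.pixels).astype(np.int16)
        ds.PixelData = stored.tobytes()
        ds.save_as(p / f"slice_{i:04d}.dcm", enforce_file_format=True)
    return p


# -- NIfTI -------------------------------------------------------------------

def _read_nifti(p: Path) -> CTSeries:
    import nibabel as nib

    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValidationError("NIfTI volume must be 2D or 3D")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    interval = float(zooms[2]) if len(zooms) > 2 and zooms[2] > 0 else 2.0
    slices = [CTImage(data[..., k], spacing, Modality.SYNTHETIC, k)
              for k in range(data.shape[2])]
    return CTSeries(slices, interval)


def _write_nifti(series: CTSeries, p: Path) -> Path:
    import nibabel as nib

    vol = series.volume().astype(np.float32)
    sp = series.slices[0].spacing
    affine = np.diag([sp[0], sp[1], series.reconstruction_interval, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((sp[0], sp[1], series.reconstruction_interval))
    p.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(p))
    return p
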