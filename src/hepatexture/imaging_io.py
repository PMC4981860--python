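"""DICOM reading/writing and window normalisation for MR studies.

A study is a set of single-frame axial MR slices grouped by acquisition
protocol.  Each slice carries its intensity window ``[window_min,
window_max]``; pixel values are clipped into that window on load so every
downstream stage sees a bounded numerical matrix.  Geometry (field of view,
matrix size, slice thickness) is preserved because the sampling-grid size
is derived from it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .protocols import Protocol, match_protocol

__all__ = [
    "MRSlice",
    "MRStudy",
    "MissingAttributeError",
    "load_series",
    "select_slices",
    "write_series",
    "write_manifest",
]

#: DICOM attributes a slice file must provide (pixel geometry + data).
_REQUIRED_ATTRS = ("PixelData", "PixelSpacing", "SliceThickness")

_MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"


class MissingAttributeError(ValueError):
    """A DICOM file lacks a required attribute (named in the message)."""

    def __init__(self, path: str, attribute: str):
        self.path = path
        self.attribute = attribute
        super().__init__(f"{path}: missing required DICOM attribute {attribute}")


@dataclass(frozen=True)
class MRSlice:
    """One window-normalised MR slice plus the geometry needed for sampling.

    ``pixels`` are dimensionless windowed intensities, clipped into
    ``[window_min, window_max]``.  ``fov_mm`` is (row extent, column
    extent) in millimetres.
    """

    pixels: np.ndarray
    fov_mm: tuple[float, float]
    thickness_mm: float
    window_min: float
    window_max: float
    protocol: Protocol
    slice_index: int

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if self.thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        if self.fov_mm[0] <= 0 or self.fov_mm[1] <= 0:
            raise ValueError("field of view must be positive")
        if not self.window_min < self.window_max:
            raise ValueError("window_min must be strictly below window_max")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        """(row spacing, column spacing) in mm, strictly positive."""
        return (self.fov_mm[0] / self.rows, self.fov_mm[1] / self.cols)

    def normalized(self) -> MRSlice:
        """Return a copy with pixels clipped into the window (idempotent)."""
        return replace(self, pixels=np.clip(self.pixels, self.window_min,
                                            self.window_max))


@dataclass
class MRStudy:
    """Slices of one patient grouped by protocol, plus slice selections."""

    patient_id: str
    slices: dict[Protocol, list[MRSlice]] = field(default_factory=dict)
    selected: dict[Protocol, list[int]] = field(default_factory=dict)

    def protocol_slices(self, protocol: Protocol,
                        selected_only: bool = True) -> list[MRSlice]:
        group = self.slices.get(protocol, [])
        idx = self.selected.get(protocol)
        if selected_only and idx is not None:
            chosen = set(idx)
            return [s for s in group if s.slice_index in chosen]
        return list(group)


def _window_bounds(ds: Dataset, raw: np.ndarray) -> tuple[float, float]:
    """Window from WindowCenter/WindowWidth, else the slice min/max."""
    wc, ww = ds.get("WindowCenter"), ds.get("WindowWidth")
    if wc is not None and ww is not None:
        wc = float(wc[0] if isinstance(wc, pydicom.multival.MultiValue) else wc)
        ww = float(ww[0] if isinstance(ww, pydicom.multival.MultiValue) else ww)
        if ww > 0:
            return wc - ww / 2.0, wc + ww / 2.0
    lo, hi = float(raw.min()), float(raw.max())
    if lo == hi:  # constant slice: widen to a valid window
        hi = lo + 1.0
    return lo, hi


def load_series(path: str | os.PathLike,
                aliases: dict[str, Protocol] | None = None,
                patient_id: str | None = None) -> MRStudy:
    """Read a directory of single-frame DICOM files into an :class:`MRStudy`.

    Slices are grouped by protocol (SeriesDescription matched against the
    alias table), sorted by InstanceNumber, and their pixels clipped into
    the per-slice window.  Files missing pixel geometry raise
    :class:`MissingAttributeError`; mixed matrix sizes within one protocol
    raise ``ValueError``.
    """
    path = os.fspath(path)
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    groups: dict[Protocol, list[tuple[int, MRSlice]]] = {}
    pid = patient_id
    n_read = 0
    for fp in files:
        try:
            ds = pydicom.dcmread(fp)
        except Exception:
            continue  # non-DICOM clutter is ignored
        for attr in _REQUIRED_ATTRS:
            if getattr(ds, attr, None) is None:
                raise MissingAttributeError(fp, attr)
        raw = ds.pixel_array.astype(np.float64)
        spacing = [float(v) for v in ds.PixelSpacing]
        wmin, wmax = _window_bounds(ds, raw)
        proto = match_protocol(str(ds.get("SeriesDescription", "")), aliases)
        order = int(ds.get("InstanceNumber", n_read + 1))
        slc = MRSlice(
            pixels=np.clip(raw, wmin, wmax),
            fov_mm=(spacing[0] * raw.shape[0], spacing[1] * raw.shape[1]),
            thickness_mm=float(ds.SliceThickness),
            window_min=wmin,
            window_max=wmax,
            protocol=proto,
            slice_index=order - 1,
        )
        groups.setdefault(proto, []).append((order, slc))
        if pid is None and ds.get("PatientID"):
            pid = str(ds.PatientID)
        n_read += 1
    if n_read == 0:
        raise ValueError(f"{path}: no readable DICOM files")

    study = MRStudy(patient_id=pid or "anonymous")
    for proto, items in groups.items():
        items.sort(key=lambda t: t[0])
        slices = [s for _, s in items]
        shapes = {(s.rows, s.cols) for s in slices}
        if len(shapes) > 1:
            raise ValueError(
                f"protocol {proto}: mixed matrix sizes {sorted(shapes)}")
        study.slices[proto] = slices
    return study


def select_slices(study: MRStudy, protocol: Protocol,
                  indices: list[int]) -> MRStudy:
    """Mark 1-6 consecutive slices of one protocol for analysis.

    Returns a new study; the input is untouched.
    """
    if not 1 <= len(indices) <= 6:
        raise ValueError("between 1 and 6 slices must be selected")
    idx = list(indices)
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError(f"selected slices must be consecutive, got {idx}")
    present = {s.slice_index for s in study.slices.get(protocol, [])}
    missing = [i for i in idx if i not in present]
    if missing:
        raise ValueError(f"slice indices {missing} not present in {protocol}")
    out = MRStudy(patient_id=study.patient_id,
                  slices={p: list(v) for p, v in study.slices.items()},
                  selected=dict(study.selected))
    out.selected[protocol] = idx
    return out


def _slice_dataset(slc: MRSlice, patient_id: str, series_uid: str,
                   study_uid: str, instance_uid: str) -> Dataset:
    px = slc.pixels
    if not np.all(px == np.round(px)) or px.min() < 0 or px.max() > 65535:
        raise ValueError(
            "write_series requires integer pixel values in [0, 65535]")
    ds = Dataset()
    ds.SOPClassUID = _MR_IMAGE_STORAGE
    ds.SOPInstanceUID = instance_uid
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = study_uid
    ds.Modality = "MR"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.SeriesDescription = str(slc.protocol)
    ds.InstanceNumber = slc.slice_index + 1
    ds.Rows, ds.Columns = slc.rows, slc.cols
    ds.PixelSpacing = [slc.fov_mm[0] / slc.rows, slc.fov_mm[1] / slc.cols]
    ds.SliceThickness = slc.thickness_mm
    ds.WindowCenter = (slc.window_min + slc.window_max) / 2.0
    ds.WindowWidth = slc.window_max - slc.window_min
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = px.astype(np.uint16).tobytes()

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _MR_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    return ds


def write_series(study: MRStudy, path: str | os.PathLike) -> list[str]:
    """Write a study as part-10 DICOM files, one per slice.

    Pixels must be integer-valued in the unsigned 16-bit range (phantom
    studies are generated that way); the written files round-trip through
    :func:`load_series` bit-exactly.
    """
    if not any(study.slices.values()):
        raise ValueError("cannot write an empty study")
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    written: list[str] = []
    study_uid = generate_uid()
    for proto, slices in study.slices.items():
        series_uid = generate_uid()
        for slc in slices:
            ds = _slice_dataset(slc, study.patient_id, series_uid,
                                study_uid, generate_uid())
            fp = os.path.join(path, f"{proto}_{slc.slice_index:03d}.dcm")
            ds.save_as(fp, enforce_file_format=True)
            written.append(fp)
    return written


def write_manifest(study: MRStudy, path: str | os.PathLike) -> None:
    """Write a JSON study manifest (patient, protocols, selections)."""
    doc = {
        "patient_id": study.patient_id,
        "protocols": {
            str(p): {
                "n_slices": len(v),
                "rows": v[0].rows,
                "cols": v[0].cols,
                "fov_mm": list(v[0].fov_mm),
                "thickness_mm": v[0].thickness_mm,
            }
            for p, v in study.slices.items() if v
        },
        "selected": {str(p): idx for p, idx in study.selected.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
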