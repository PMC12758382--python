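"""Reading and writing of volumes, segmentations and rating reports.

Images are exchanged as NIfTI-1/2 (optionally gzipped).  All quality
measures operate in native voxel space: the affine is read but only the
voxel sizes enter any computation.  Tissue segmentations can arrive either
as a single partial-volume-effect (PVE) label map with CSF=1, GM=2, WM=3
(fractional values encode mixed voxels, CAT "p0" style) or as three
per-class fraction/probability maps on the same grid.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

MEASURES = ("NCR", "ICR", "RES", "ECR", "FEC")

RAW_FIELDS = ("ncr_raw", "icr_raw", "res_rms", "ecr_raw", "fec_raw", "c_min")


class QcError(Exception):
    """Base class for all quality-control errors."""


class FormatError(QcError):
    """File is not a readable NIfTI volume."""


class DimensionalityError(QcError):
    """Input volume is not a single 3-D frame."""


class GridMismatchError(QcError):
    """Segmentation grid does not match the intensity volume."""


class DialectError(QcError):
    """Segmentation values outside the supported label/fraction range."""


class UnsegmentableError(QcError):
    """Too little confidently-labelled white matter to rate the scan."""


@dataclass
class ScalarVolume:
    """A 3-D intensity grid with physical voxel sizes in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    id: str = ""
    n_nonfinite: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D grid, got shape {self.data.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or not all(np.isfinite(v) and v > 0 for v in vs):
            raise QcError(f"voxel sizes must be positive and finite, got {vs}")
        self.voxel_size = vs
        bad = ~np.isfinite(self.data)
        if bad.any():
            self.n_nonfinite += int(bad.sum())
            self.data = np.where(bad, 0.0, self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return replace(self, data=data)


@dataclass
class TissueSegmentation:
    """Per-voxel CSF/GM/WM fractions on the grid of a paired ScalarVolume."""

    csf: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    voxel_size: tuple[float, float, float]
    dialect: str = "probmaps"  # "pve" or "probmaps"

    def __post_init__(self) -> None:
        self.csf = np.asarray(self.csf, dtype=np.float64)
        self.gm = np.asarray(self.gm, dtype=np.float64)
        self.wm = np.asarray(self.wm, dtype=np.float64)
        if not (self.csf.shape == self.gm.shape == self.wm.shape):
            raise GridMismatchError("tissue fraction grids differ in shape")
        for a in (self.csf, self.gm, self.wm):
            if a.ndim != 3:
                raise DimensionalityError(
                    f"tissue fractions must be 3-D, got shape {a.shape}"
                )
            if a.min() < -1e-6 or a.max() > 1 + 1e-6:
                raise DialectError("tissue fractions must lie in [0, 1]")
        total = self.csf + self.gm + self.wm
        if total.max() > 1 + 1e-6:
            raise DialectError("per-voxel tissue fractions sum to more than 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.csf.shape

    def check_ratable(self, min_wm_voxels: int = 100) -> None:
        n_wm = int(np.count_nonzero(self.wm > 0.9))
        if n_wm < min_wm_voxels:
            raise UnsegmentableError(
                f"only {n_wm} voxels with WM fraction > 0.9 "
                f"(need {min_wm_voxels}); scan rejected as unsegmentable"
            )


@dataclass
class RatingRecord:
    """Per-scan raw measures, standardized grades/rps/letters and SIQR."""

    scan_id: str
    raw: dict = field(default_factory=dict)
    grades: dict = field(default_factory=dict)
    rps: dict = field(default_factory=dict)
    letters: dict = field(default_factory=dict)
    siqr_grade: float | None = None
    siqr_rps: float | None = None
    siqr_letter: str | None = None
    site: str | None = None
    nsiqr: float | None = None
    flag: str | None = None
    notes: list = field(default_factory=list)


def _load_nifti(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header / not NIfTI
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    return img, data


def _squeeze_to_3d(data: np.ndarray, path) -> np.ndarray:
    if data.ndim > 3:
        extra = data.shape[3:]
        if all(n == 1 for n in extra):
            data = data.reshape(data.shape[:3])
        else:
            raise DimensionalityError(
                f"{path}: expected a single 3-D frame, got shape {data.shape}"
            )
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    return data


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a T1-weighted intensity volume from a NIfTI file.

    Voxel sizes come from the header; non-finite voxels are replaced by 0
    and counted in ``n_nonfinite``.
    """
    img, data = _load_nifti(path)
    data = _squeeze_to_3d(data, path)
    zooms = img.header.get_zooms()[:3]
    return ScalarVolume(
        data=data.astype(np.float64),
        voxel_size=tuple(float(z) for z in zooms),
        id=Path(path).name,
    )


def fractions_from_pve(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a PVE label map (CSF=1, GM=2, WM=3) to class fractions.

    Class k receives fraction max(0, 1 - |v - k|), so integer labels map to
    pure classes and e.g. 2.5 to an equal GM/WM mixture.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.min() < 0 or labels.max() > 3.0001:
        raise DialectError(
            f"PVE labels must lie in [0, 3.0001], got range "
            f"[{labels.min():g}, {labels.max():g}]"
        )
    out = []
    for k in (1.0, 2.0, 3.0):
        out.append(np.maximum(0.0, 1.0 - np.abs(labels - k)))
    return out[0], out[1], out[2]


def read_segmentation(
    path_or_paths: str | Path | Sequence[str | Path],
    grid: ScalarVolume,
) -> TissueSegmentation:
    """Read a tissue segmentation matching ``grid``.

    One path is interpreted as a PVE label map; three paths as CSF/GM/WM
    fraction maps (clipped to [0, 1] and renormalized where the sum
    exceeds 1).
    """
    if isinstance(path_or_paths, (str, Path)):
        paths = [path_or_paths]
    else:
        paths = list(path_or_paths)
    if len(paths) not in (1, 3):
        raise DialectError(f"expected 1 or 3 segmentation files, got {len(paths)}")

    arrays = []
    for p in paths:
        img, data = _load_nifti(p)
        data = _squeeze_to_3d(data, p).astype(np.float64)
        data = np.where(np.isfinite(data), data, 0.0)
        if data.shape != grid.shape:
            raise GridMismatchError(
                f"{p}: segmentation shape {data.shape} does not match "
                f"volume shape {grid.shape}"
            )
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if not np.allclose(zooms, grid.voxel_size, rtol=1e-4):
            raise GridMismatchError(
                f"{p}: voxel size {zooms} does not match volume "
                f"{grid.voxel_size}"
            )
        arrays.append(data)

    if len(arrays) == 1:
        csf, gm, wm = fractions_from_pve(arrays[0])
        dialect = "pve"
    else:
        csf, gm, wm = (np.clip(a, 0.0, 1.0) for a in arrays)
        total = csf + gm + wm
        scale = np.where(total > 1.0, total, 1.0)
        csf, gm, wm = csf / scale, gm / scale, wm / scale
        dialect = "probmaps"

    seg = TissueSegmentation(
        csf=csf, gm=gm, wm=wm, voxel_size=grid.voxel_size, dialect=dialect
    )
    seg.check_ratable()
    return seg


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a ScalarVolume as NIfTI (diagonal affine from voxel sizes)."""
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def write_segmentation(seg: TissueSegmentation, path_prefix: str | Path) -> list[Path]:
    """Write CSF/GM/WM fraction maps as three NIfTI files."""
    paths = []
    affine = np.diag(list(seg.voxel_size) + [1.0])
    for name, arr in (("csf", seg.csf), ("gm", seg.gm), ("wm", seg.wm)):
        p = Path(f"{path_prefix}_{name}.nii.gz")
        img = nib.Nifti1Image(arr.astype(np.float32), affine)
        img.header.set_zooms(seg.voxel_size)
        nib.save(img, str(p))
        paths.append(p)
    return paths


# --- rating reports ---------------------------------------------------------

_CSV_COLUMNS = (
    ["id"]
    + list(MEASURES)
    + ["SIQR"]
    + list(RAW_FIELDS)
    + ["site", "nSIQR", "flag"]
)


def _record_to_row(r: RatingRecord) -> dict:
    row: dict = {"id": r.scan_id}
    for m in MEASURES:
        row[m] = r.rps.get(m)
    row["SIQR"] = r.siqr_rps
    for f in RAW_FIELDS:
        row[f] = r.raw.get(f)
    row["site"] = r.site
    row["nSIQR"] = r.nsiqr
    row["flag"] = r.flag
    return row


def _row_to_record(row: dict) -> RatingRecord:
    def _num(v):
        if v is None:
            return None
        if isinstance(v, float) and np.isnan(v):
            return None
        if isinstance(v, str) and v.strip() == "":
            return None
        return float(v)

    def _txt(v):
        if v is None:
            return None
        if isinstance(v, float) and np.isnan(v):
            return None
        s = str(v)
        return s if s.strip() else None

    rec = RatingRecord(scan_id=str(row["id"]))
    for m in MEASURES:
        v = _num(row.get(m))
        if v is not None:
            rec.rps[m] = v
            rec.grades[m] = (105.0 - v) / 10.0
    rec.siqr_rps = _num(row.get("SIQR"))
    if rec.siqr_rps is not None:
        rec.siqr_grade = (105.0 - rec.siqr_rps) / 10.0
    for f in RAW_FIELDS:
        v = _num(row.get(f))
        if v is not None:
            rec.raw[f] = v
    rec.site = _txt(row.get("site"))
    rec.nsiqr = _num(row.get("nSIQR"))
    rec.flag = _txt(row.get("flag"))
    return rec


def write_report(
    records: Sequence[RatingRecord], path: str | Path, format: str | None = None
) -> None:
    """Write rating records as CSV, JSON or XML.

    CSV has one row per scan with a fixed column order (rps values at 4
    decimals, raw values at 6); JSON/XML nest raw and scaled values under
    each scan id.  Missing values are written as empty fields, never 0.
    """
    if not records:
        raise QcError("cannot write an empty report")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "csv").lower()
    if fmt not in ("csv", "json", "xml"):
        raise QcError(f"unknown report format: {fmt}")

    if fmt == "csv":
        rows = []
        for r in records:
            row = _record_to_row(r)
            for m in list(MEASURES) + ["SIQR", "nSIQR"]:
                if row.get(m) is not None:
                    row[m] = round(float(row[m]), 4)
            for f in RAW_FIELDS:
                if row.get(f) is not None:
                    row[f] = round(float(row[f]), 6)
            rows.append(row)
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        df.to_csv(path, index=False)
        return

    payload = {}
    for r in records:
        entry = {
            "raw": {f: r.raw.get(f) for f in RAW_FIELDS if r.raw.get(f) is not None},
            "rps": dict(r.rps),
            "grades": dict(r.grades),
            "letters": dict(r.letters),
            "SIQR": {
                "grade": r.siqr_grade,
                "rps": r.siqr_rps,
                "letter": r.siqr_letter,
            },
        }
        if r.site is not None:
            entry["site"] = r.site
        if r.nsiqr is not None:
            entry["nSIQR"] = r.nsiqr
        if r.flag is not None:
            entry["flag"] = r.flag
        payload[r.scan_id] = entry

    if fmt == "json":
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return

    root = ET.Element("qc_report")
    for scan_id, entry in payload.items():
        scan = ET.SubElement(root, "scan", id=scan_id)
        raw_el = ET.SubElement(scan, "raw")
        for k, v in entry["raw"].items():
            ET.SubElement(raw_el, k).text = repr(float(v))
        rps_el = ET.SubElement(scan, "rps")
        for k, v in entry["rps"].items():
            ET.SubElement(rps_el, k).text = repr(float(v))
        grades_el = ET.SubElement(scan, "grades")
        for k, v in entry["grades"].items():
            ET.SubElement(grades_el, k).text = repr(float(v))
        letters_el = ET.SubElement(scan, "letters")
        for k, v in entry["letters"].items():
            ET.SubElement(letters_el, k).text = str(v)
        siqr_el = ET.SubElement(scan, "SIQR")
        for k, v in entry["SIQR"].items():
            if v is not None:
                ET.SubElement(siqr_el, k).text = (
                    repr(float(v)) if k != "letter" else str(v)
                )
        for k in ("site", "nSIQR", "flag"):
            if k in entry:
                ET.SubElement(scan, k).text = str(entry[k])
    try:
        ET.indent(root)
    except AttributeError:  # pragma: no cover - py<3.9
        pass
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def read_report(path: str | Path, format: str | None = None) -> list[RatingRecord]:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "csv").lower()

    if fmt == "csv":
        df = pd.read_csv(path, dtype={"id": str, "site": str, "flag": str})
        return [_row_to_record(row) for row in df.to_dict("records")]

    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        records = []
        for scan_id, entry in payload.items():
            rec = RatingRecord(scan_id=scan_id)
            rec.raw = {k: float(v) for k, v in entry.get("raw", {}).items()}
            rec.rps = {k: float(v) for k, v in entry.get("rps", {}).items()}
            rec.grades = {k: float(v) for k, v in entry.get("grades", {}).items()}
            rec.letters = dict(entry.get("letters", {}))
            siqr = entry.get("SIQR", {})
            rec.siqr_grade = siqr.get("grade")
            rec.siqr_rps = siqr.get("rps")
            rec.siqr_letter = siqr.get("letter")
            rec.site = entry.get("site")
            rec.nsiqr = entry.get("nSIQR")
            rec.flag = entry.get("flag")
            records.append(rec)
        return records

    if fmt == "xml":
        root = ET.parse(path).getroot()
        records = []
        for scan in root.findall("scan"):
            rec = RatingRecord(scan_id=scan.get("id"))
            for section, target in (
                ("raw", rec.raw),
                ("rps", rec.rps),
                ("grades", rec.grades),
            ):
                el = scan.find(section)
                if el is not None:
                    for child in el:
                        target[child.tag] = float(child.text)
            el = scan.find("letters")
            if el is not None:
                for child in el:
                    rec.letters[child.tag] = child.text
            siqr = scan.find("SIQR")
            if siqr is not None:
                g = siqr.find("grade")
                r = siqr.find("rps")
                letter = siqr.find("letter")
                rec.siqr_grade = float(g.text) if g is not None else None
                rec.siqr_rps = float(r.text) if r is not None else None
                rec.siqr_letter = letter.text if letter is not None else None
            for k, attr in (("site", "site"), ("flag", "flag")):
                el = scan.find(k)
                if el is not None:
                    setattr(rec, attr, el.text)
            el = scan.find("nSIQR")
            if el is not None:
                rec.nsiqr = float(el.text)
            records.append(rec)
        return records

    raise QcError(f"unknown report format: {fmt}")
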