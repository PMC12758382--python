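"""Standardization of raw measures onto the grade/rps/letter scales.

Grades live on [0.5, 10.5] (lower = better); rating points (rps) on
[0, 100] (higher = better) via rps = 105 - 10*grade; letters label 10-rps
bands A-F, with A+ reserved for the top quarter of the A band.  Each raw
measure is scaled linearly through two anchors: the best regular value BQM
(grade 1, 95 rps) and the worst regular value WQM (grade 5, 55 rps),

    grade = clamp(1 + 4*(QM - BQM)/(WQM - BQM), 0.5, 10.5).

The composite SIQR is the fourth-power mean of the NCR, RES, ECR and FEC
grades; ICR is excluded because preprocessing handles bias well and its
intensity effects are already reflected in NCR.  The power-4 mean sits
between the arithmetic mean and the maximum, so one severely degraded
aspect dominates the composite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .quality_measures import MeasureSet
from .volume_io import QcError, RatingRecord

GRADE_MIN, GRADE_MAX = 0.5, 10.5

#: Default (BQM, WQM) anchor pairs.  ECR is oriented sharp-is-best, so its
#: best anchor is the larger value.
DEFAULT_ANCHORS: dict[str, tuple[float, float]] = {
    "NCR": (0.0183, 0.0868),
    "ICR": (0.2270, 1.3949),
    "RES": (0.5, 2.5),
    "ECR": (0.1003, 0.0202),
    "FEC": (130.0, 470.0),
}


class RangeError(QcError):
    """Value outside the grade/rps scale."""


@dataclass
class ScaleAnchors:
    """Per-measure (BQM, WQM) pairs, overridable for recalibration."""

    anchors: dict = field(default_factory=lambda: dict(DEFAULT_ANCHORS))

    def __post_init__(self) -> None:
        for name, (bqm, wqm) in self.anchors.items():
            if bqm == wqm:
                raise QcError(f"{name}: BQM and WQM anchors must differ")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.anchors[name]

    @classmethod
    def from_file(cls, path: str | Path) -> "ScaleAnchors":
        """Read ``NAME = bqm, wqm`` overrides from a plain-text config."""
        anchors = dict(DEFAULT_ANCHORS)
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, _, rest = line.partition("=")
            name = name.strip().upper()
            if name not in anchors:
                raise QcError(f"unknown measure in anchor config: {name!r}")
            parts = [p for p in rest.replace(",", " ").split() if p]
            if len(parts) != 2:
                raise QcError(f"anchor line needs two values: {line!r}")
            anchors[name] = (float(parts[0]), float(parts[1]))
        return cls(anchors=anchors)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {b}, {w}" for k, (b, w) in self.anchors.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def scale_measure(qm: float, bqm: float, wqm: float) -> float:
    """Linear grade through (BQM -> 1) and (WQM -> 5), clamped to the scale.

    Works for anchors in either order; a non-finite measure maps to the
    worst grade.
    """
    if bqm == wqm:
        raise QcError("BQM and WQM anchors must differ")
    if not math.isfinite(qm):
        return GRADE_MAX
    grade = 1.0 + 4.0 * (qm - bqm) / (wqm - bqm)
    return min(GRADE_MAX, max(GRADE_MIN, grade))


def grade_to_rps(grade: float) -> float:
    """rps = 105 - 10*grade, clipped to [0, 100]."""
    if not GRADE_MIN <= grade <= GRADE_MAX:
        raise RangeError(f"grade {grade} outside [{GRADE_MIN}, {GRADE_MAX}]")
    return min(100.0, max(0.0, 105.0 - 10.0 * grade))


def rps_to_grade(rps: float) -> float:
    """Inverse conversion, grade = (105 - rps)/10."""
    if not 0.0 <= rps <= 100.0:
        raise RangeError(f"rps {rps} outside [0, 100]")
    return (105.0 - rps) / 10.0


def rps_to_letter(rps: float) -> str:
    """Letter bands of 10 rps: A >= 90 ... F < 50; A+ for rps >= 97.5."""
    if not 0.0 <= rps <= 100.0:
        raise RangeError(f"rps {rps} outside [0, 100]")
    if rps >= 97.5:
        return "A+"
    for letter, lo in (("A", 90), ("B", 80), ("C", 70), ("D", 60), ("E", 50)):
        if rps >= lo:
            return letter
    return "F"


def siqr(ncr_g: float, res_g: float, ecr_g: float, fec_g: float) -> float:
    """Fourth-power mean of the four component grades."""
    grades = (ncr_g, res_g, ecr_g, fec_g)
    for g in grades:
        if g is None or not math.isfinite(g):
            raise QcError("SIQR requires all four component grades")
        if not GRADE_MIN <= g <= GRADE_MAX:
            raise RangeError(f"grade {g} outside [{GRADE_MIN}, {GRADE_MAX}]")
    return (sum(g**4 for g in grades) / 4.0) ** 0.25


def rate(
    measures: MeasureSet,
    anchors: ScaleAnchors | None = None,
    scan_id: str = "",
) -> RatingRecord:
    """Scale a MeasureSet onto grades/rps/letters and aggregate into SIQR."""
    anchors = anchors or ScaleAnchors()
    raw = {
        "NCR": measures.ncr_raw,
        "ICR": measures.icr_raw,
        "RES": measures.res_rms,
        "ECR": measures.ecr_raw,
        "FEC": measures.fec_raw,
    }
    rec = RatingRecord(scan_id=scan_id)
    rec.raw = {
        "ncr_raw": measures.ncr_raw,
        "icr_raw": measures.icr_raw,
        "res_rms": measures.res_rms,
        "ecr_raw": measures.ecr_raw,
        "fec_raw": measures.fec_raw,
        "c_min": measures.c_min,
    }
    rec.notes = list(measures.flags)
    for name, qm in raw.items():
        if qm is None or not math.isfinite(qm):
            rec.notes.append(f"{name}: missing raw value")
            continue
        bqm, wqm = anchors[name]
        g = scale_measure(qm, bqm, wqm)
        rec.grades[name] = g
        rec.rps[name] = grade_to_rps(g)
        rec.letters[name] = rps_to_letter(rec.rps[name])
    needed = ("NCR", "RES", "ECR", "FEC")
    if all(m in rec.grades for m in needed):
        rec.siqr_grade = siqr(*(rec.grades[m] for m in needed))
        rec.siqr_rps = grade_to_rps(rec.siqr_grade)
        rec.siqr_letter = rps_to_letter(rec.siqr_rps)
    else:
        rec.notes.append("SIQR: missing component grade")
    return rec
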