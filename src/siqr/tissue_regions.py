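"""Intensity normalization, tissue statistics and optimized QC regions.

All downstream measures work on a WM-normalized image (WM median = 1), so
tissue contrast and noise are expressed in a unit that is invariant to the
scanner's arbitrary intensity scaling.  Evaluation regions deliberately
avoid partial-volume boundaries, hypointense WM lesions / perivascular
spaces and thin sulcal CSF: noise and inhomogeneity are estimated only in
near-pure, eroded tissue cores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import QcError, ScalarVolume, TissueSegmentation

PURE_FRACTION = 0.9  # class-membership threshold before erosion
WME_EROSION_ITERS = 3  # keeps local-SD reach and smoothing ramps out of the core
WM_DEEP_EXTRA_ITERS = 3  # additional depth clearing the Dirichlet shell (ICR)
CSFE_EROSION_ITERS = 1  # ventricles must survive at 1 mm
CSFE_MIN_COMPONENT = 27  # voxels; suppresses sulcal slivers
LESION_MIN_COMPONENT = 27  # hypointense blobs smaller than this are noise
MIN_CLASS_VOXELS = 10  # below this, per-class stats are flagged missing

# 6-connectivity structuring element used by every erosion step
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class ContrastError(QcError):
    """Tissue contrast missing or degenerate; the scan cannot be rated."""


class MaskError(QcError):
    """An evaluation mask is empty after optimization."""


@dataclass
class TissueStats:
    """Per-class intensity statistics on the WM-normalized image.

    Medians are used for class intensities (robust to lesions and partial
    volume); means over the same voxels are kept for the CJV diagnostic.
    Volumes integrate the fractional segmentation, in ml.
    """

    m_csf: float | None
    m_gm: float | None
    m_wm: float | None
    sd_csf: float | None
    sd_gm: float | None
    sd_wm: float | None
    mean_gm: float | None
    mean_wm: float | None
    c_min: float
    vol_csf_ml: float
    vol_gm_ml: float
    vol_wm_ml: float
    rgmv: float
    missing: set = field(default_factory=set)


@dataclass
class QcRegions:
    """Optimized evaluation masks: WM core, CSF core, GM/WM boundary band.

    ``wm_deep`` is a further-eroded WM core used as the evaluation domain
    of the inhomogeneity measure; it is eroded from the pure-WM core
    *before* the intensity threshold is applied, because eroding a mask
    already pocked by noise-driven threshold holes collapses it.
    """

    csfe: np.ndarray
    wme: np.ndarray
    boundary_band: np.ndarray
    wm_deep: np.ndarray | None = None
    csfe_fallback: bool = False

    @property
    def n_csfe(self) -> int:
        return int(np.count_nonzero(self.csfe))

    @property
    def n_wme(self) -> int:
        return int(np.count_nonzero(self.wme))

    @property
    def n_boundary(self) -> int:
        return int(np.count_nonzero(self.boundary_band))


def normalize_intensity(vol: ScalarVolume, seg: TissueSegmentation) -> ScalarVolume:
    """Divide by the median intensity of near-pure WM, so WM median = 1."""
    if vol.shape != seg.shape:
        raise QcError(
            f"volume shape {vol.shape} does not match segmentation {seg.shape}"
        )
    wm_core = seg.wm > PURE_FRACTION
    if not wm_core.any():
        raise ContrastError("no voxels with WM fraction > 0.9")
    med = float(np.median(vol.data[wm_core]))
    if not np.isfinite(med) or med <= 0:
        raise ContrastError(f"WM median intensity is {med!r}; scan unratable")
    return vol.with_data(vol.data / med)


def tissue_stats(vol_norm: ScalarVolume, seg: TissueSegmentation) -> TissueStats:
    """Per-class medians/SDs over near-pure voxels, c_min and volumes.

    c_min is the smaller of |m_GM − m_CSF| and |m_WM − m_GM|; zero
    differences (degenerate contrast) are dropped, and if no positive
    difference remains the scan is unratable.
    """
    stats = {}
    missing = set()
    for name, frac in (("csf", seg.csf), ("gm", seg.gm), ("wm", seg.wm)):
        sel = frac > PURE_FRACTION
        if np.count_nonzero(sel) < MIN_CLASS_VOXELS:
            missing.add(name)
            stats[name] = (None, None, None)
            continue
        vals = vol_norm.data[sel]
        stats[name] = (
            float(np.median(vals)),
            float(np.std(vals)),
            float(np.mean(vals)),
        )

    m_csf, sd_csf, _ = stats["csf"]
    m_gm, sd_gm, mean_gm = stats["gm"]
    m_wm, sd_wm, mean_wm = stats["wm"]

    diffs = []
    if m_csf is not None and m_gm is not None:
        diffs.append(abs(m_gm - m_csf))
    if m_gm is not None and m_wm is not None:
        diffs.append(abs(m_wm - m_gm))
    diffs = [d for d in diffs if d > 1e-9]
    if not diffs:
        raise ContrastError(
            "no positive tissue contrast between CSF/GM/WM medians"
        )
    c_min = min(diffs)

    voxel_ml = float(np.prod(vol_norm.voxel_size)) / 1000.0
    vol_csf = float(seg.csf.sum()) * voxel_ml
    vol_gm = float(seg.gm.sum()) * voxel_ml
    vol_wm = float(seg.wm.sum()) * voxel_ml
    total = vol_csf + vol_gm + vol_wm
    rgmv = vol_gm / total if total > 0 else 0.0

    return TissueStats(
        m_csf=m_csf,
        m_gm=m_gm,
        m_wm=m_wm,
        sd_csf=sd_csf,
        sd_gm=sd_gm,
        sd_wm=sd_wm,
        mean_gm=mean_gm,
        mean_wm=mean_wm,
        c_min=c_min,
        vol_csf_ml=vol_csf,
        vol_gm_ml=vol_gm,
        vol_wm_ml=vol_wm,
        rgmv=rgmv,
        missing=missing,
    )


def cjv(stats: TissueStats) -> float:
    """Coefficient of joint variation, (σ_GM + σ_WM)/|μ_GM + μ_WM|.

    Diagnostic only; it is not standardized onto the rating scale.
    """
    if "gm" in stats.missing or "wm" in stats.missing:
        raise ContrastError("CJV requires GM and WM statistics")
    denom = abs(stats.mean_gm + stats.mean_wm)
    if denom < 1e-9:
        raise ContrastError("CJV undefined: |mean_GM + mean_WM| ~ 0")
    return (stats.sd_gm + stats.sd_wm) / denom


def optimize_masks(
    vol_norm: ScalarVolume, seg: TissueSegmentation, stats: TissueStats
) -> QcRegions:
    """Build the eroded WM/CSF evaluation cores and the GM/WM boundary band.

    WMe: near-pure WM eroded three 6-connected steps — deep enough that
    the 5^3 local-SD neighborhoods of the noise measure and the Dirichlet
    data of the inhomogeneity measure stay clear of partial-volume and
    smoothing ramps at the GM/WM boundary — with hypointense voxels
    (below the GM/WM midpoint shifted toward WM) removed so WM lesions and
    perivascular spaces do not masquerade as noise.  CSFe: near-pure CSF
    eroded one step, keeping only connected components of >= 27 voxels; if
    nothing survives (thin sulci only) the noise measure falls back to WMe
    alone.  The boundary band is the partial-volume GM/WM interface
    (0.25 <= WM fraction <= 0.75) minus anything 26-adjacent to CSF, which
    stands in for the exclusion of extreme CSF/WM and vessel gradients.
    """
    wm_core = seg.wm > PURE_FRACTION
    wme = ndimage.binary_erosion(
        wm_core, structure=STRUCT_6, iterations=WME_EROSION_ITERS
    )
    wm_deep = ndimage.binary_erosion(
        wme, structure=STRUCT_6, iterations=WM_DEEP_EXTRA_ITERS
    )
    if stats.m_wm is not None and stats.m_gm is not None:
        # exclude coherent hypointense blobs (lesions, perivascular spaces);
        # isolated subthreshold voxels are noise and must not pock the mask
        lesion_thr = stats.m_wm - 0.5 * (stats.m_wm - stats.m_gm)
        hypo = (vol_norm.data < lesion_thr) & wme
        if hypo.any():
            labels, n = ndimage.label(hypo, structure=STRUCT_6)
            counts = np.bincount(labels.ravel())
            big = np.zeros(n + 1, dtype=bool)
            big[1:] = counts[1:] >= LESION_MIN_COMPONENT
            lesion = big[labels]
            wme &= ~lesion
            wm_deep &= ~lesion
    if not wme.any():
        raise MaskError("WM evaluation mask empty after optimization")

    csf_core = seg.csf > PURE_FRACTION
    csfe = ndimage.binary_erosion(
        csf_core, structure=STRUCT_6, iterations=CSFE_EROSION_ITERS
    )
    if csfe.any():
        labels, n = ndimage.label(csfe, structure=STRUCT_6)
        counts = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = counts[1:] >= CSFE_MIN_COMPONENT
        csfe = keep[labels]
    fallback = not csfe.any()
    if fallback:
        warnings.warn(
            "CSF evaluation mask empty; noise estimation falls back to WM only",
            stacklevel=2,
        )

    band = (seg.wm >= 0.25) & (seg.wm <= 0.75)
    near_csf = ndimage.binary_dilation(seg.csf > 0.25, structure=STRUCT_26)
    band &= ~near_csf
    band &= ~(wme | csfe)

    return QcRegions(
        csfe=csfe,
        wme=wme,
        boundary_band=band,
        wm_deep=wm_deep,
        csfe_fallback=fallback,
    )
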