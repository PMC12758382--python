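"""The five raw quality measures of the segmentation-based QC framework.

* NCR (noise): minimum of the mean local standard deviation of the
  bias-corrected image over the optimized CSF and WM cores, divided by the
  minimum tissue contrast c_min.
* ICR (inhomogeneity): standard deviation over the WM core of a
  Laplacian-smoothed (Dirichlet) copy of the image, divided by c_min.
  Smoothing removes noise-driven variance so only the slow bias survives.
* RES (voxel resolution): RMS of the three voxel dimensions in mm.  The
  RMS penalizes a single low-resolution axis more than the plain mean
  (RESM, kept as a diagnostic).
* ECR (edge sharpness): mean intensity-gradient magnitude over the GM/WM
  boundary band in per-mm units, divided by c_min.  Unlike RES it reacts
  to smoothing and resample-blurring that leave the stored voxel size
  untouched.
* FEC (surface topology): Euler-characteristic defect of the whole-brain
  WM isosurfaces, extracted at 2 mm after a maximum filter, at WM-fraction
  thresholds 0.25 and 0.75.  A clean closed surface has chi = 2; every
  handle or speckle component moves chi away from 2.

All measures are deterministic and oriented so that larger raw values mean
worse quality, except ECR where sharper (larger) is better; the rating
scale handles orientation through its anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .tissue_regions import (
    STRUCT_6,
    QcRegions,
    TissueStats,
    normalize_intensity,
    optimize_masks,
    tissue_stats,
)
from .volume_io import QcError, ScalarVolume, TissueSegmentation

BIAS_POLY_DEGREE = 3  # per-axis degree of the smooth bias basis
FEC_RESOLUTION_MM = 2.0
FEC_THRESHOLDS = (0.25, 0.75)
MIN_GRID_VOXELS = 8  # per axis, for measure computation


class ParameterError(QcError):
    """Invalid parameter value."""


class MeasureError(QcError):
    """A quality measure cannot be computed on this scan."""


class TopologyError(QcError):
    """Surface extraction failed (empty foreground)."""


@dataclass
class MeasureSet:
    """Raw, unscaled quality measures plus the intermediates they share."""

    ncr_raw: float
    icr_raw: float
    res_rms: float
    resm_mean: float
    ecr_raw: float
    fec_raw: float
    c_min: float
    chi_025: int | None
    chi_075: int | None
    flags: list = field(default_factory=list)


# --- bias field --------------------------------------------------------------


def _legendre_design(coords: list[np.ndarray], degree: int) -> np.ndarray:
    """Tensor-product Legendre basis, per-axis degree <= degree, total <= degree + 1."""
    polys = [np.polynomial.legendre.legvander(c, degree) for c in coords]
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1):
            for k in range(degree + 1):
                if i + j + k > degree + 1:
                    continue
                cols.append(polys[0][:, i] * polys[1][:, j] * polys[2][:, k])
    return np.stack(cols, axis=1)


def estimate_bias_field(
    vol_norm: ScalarVolume, regions: QcRegions, degree: int = BIAS_POLY_DEGREE
) -> tuple[ScalarVolume, bool]:
    """Smooth multiplicative bias estimate from WM-core intensities.

    Weighted least-squares fit of a low-order tensor Legendre basis to the
    log intensity of the WM-core voxels (a smooth-field model in the style
    of polynomial/DCT bias correction), exponentiated, evaluated on the
    whole grid and renormalized to mean 1 over WMe.  The basis is too
    stiff to follow noise or anatomy but captures the slowly varying coil
    sensitivity.  Returns the field and a failure flag; values <= 0.1 are
    clipped at 0.1 and flagged.
    """
    wme = regions.wme
    if not wme.any():
        raise MeasureError("bias estimation requires a non-empty WM mask")
    shape = vol_norm.shape
    # normalized coordinates in [-1, 1]
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    ii, jj, kk = np.where(wme)
    vals = vol_norm.data[wme]
    pos = vals > 1e-6
    if not pos.any():
        raise MeasureError("WM intensities non-positive; cannot fit bias")
    # keep the fit well-determined on small (e.g., heavily downsampled) grids
    n_fit = int(pos.sum())
    while degree > 1:
        n_basis = sum(
            1
            for i in range(degree + 1)
            for j in range(degree + 1)
            for k in range(degree + 1)
            if i + j + k <= degree + 1
        )
        if n_fit >= 20 * n_basis:
            break
        degree -= 1
    design = _legendre_design(
        [axes[0][ii[pos]], axes[1][jj[pos]], axes[2][kk[pos]]], degree
    )
    coef, *_ = np.linalg.lstsq(design, np.log(vals[pos]), rcond=None)

    # separable evaluation on the full grid
    vx, vy, vz = (np.polynomial.legendre.legvander(a, degree) for a in axes)
    tensor = np.zeros((degree + 1,) * 3)
    idx = 0
    for i in range(degree + 1):
        for j in range(degree + 1):
            for k in range(degree + 1):
                if i + j + k > degree + 1:
                    continue
                tensor[i, j, k] = coef[idx]
                idx += 1
    log_field = np.einsum("xi,yj,zk,ijk->xyz", vx, vy, vz, tensor)
    field = np.exp(np.clip(log_field, -2.0, 2.0))
    field /= float(np.mean(field[wme]))
    failed = bool((field <= 0.1).any())
    if failed:
        field = np.maximum(field, 0.1)
    return vol_norm.with_data(field), failed


def bias_correct(
    vol_norm: ScalarVolume, bias: ScalarVolume, wm_mask: np.ndarray
) -> ScalarVolume:
    """Divide by the field and re-normalize the WM median to 1."""
    if (bias.data <= 0).any():
        raise ParameterError("bias field must be strictly positive")
    cbc = vol_norm.data / bias.data
    med = float(np.median(cbc[wm_mask]))
    if med <= 0 or not np.isfinite(med):
        raise MeasureError("WM median non-positive after bias correction")
    return vol_norm.with_data(cbc / med)


# --- noise -------------------------------------------------------------------


def local_std(
    vol: ScalarVolume, k: int = 5, mask: np.ndarray | None = None
) -> ScalarVolume:
    """Per-voxel population SD over a k^3 neighborhood.

    Neighborhoods are truncated at the grid edges (the divisor is the
    number of contributing voxels, not k^3).  With ``mask``, only in-mask
    voxels contribute, so the estimate inside a tissue region never mixes
    in partial-volume voxels from across its boundary; outside the mask
    the result is 0.  Masked estimates are rescaled by the normal-theory
    small-sample factor (1/(c4(n)*sqrt((n-1)/n))), because thin regions
    have few in-mask neighbors and an uncorrected SD would read several
    percent low there, making noise look milder in CSF than in WM.
    """
    if k % 2 == 0 or k < 3:
        raise ParameterError(f"neighborhood size must be odd and >= 3, got {k}")
    d = vol.data
    kv = float(k**3)
    if mask is None:
        w = np.ones_like(d)
        dw = d
    else:
        w = np.asarray(mask, dtype=np.float64)
        dw = d * w
    cnt = ndimage.uniform_filter(w, size=k, mode="constant") * kv
    s1 = ndimage.uniform_filter(dw, size=k, mode="constant") * kv
    s2 = ndimage.uniform_filter(dw * d, size=k, mode="constant") * kv
    ok = cnt > 0.5
    cnt = np.where(ok, cnt, 1.0)
    mean = s1 / cnt
    var = np.maximum(s2 / cnt - mean * mean, 0.0)
    sd = np.where(ok, np.sqrt(var), 0.0)
    if mask is not None:
        n = np.maximum(np.rint(cnt), 1.0)
        nm1 = np.maximum(n - 1.0, 1.0)
        c4 = 1.0 - 1.0 / (4.0 * nm1) - 7.0 / (32.0 * nm1 * nm1)
        corr = 1.0 / (c4 * np.sqrt(nm1 / n))
        sd = np.where(n > 1.5, sd * corr, 0.0)
        sd = np.where(np.asarray(mask, dtype=bool), sd, 0.0)
    return vol.with_data(sd)


def ncr_raw(
    cbc: ScalarVolume, regions: QcRegions, c_min: float, k: int = 5
) -> float:
    """Noise-to-contrast ratio before scaling.

    Mean local SD within CSFe and within WMe separately (neighborhoods
    restricted to the region, so partial-volume voxels across the boundary
    never contaminate the estimate); the minimum of the two, divided by
    c_min.  When the CSF core is unusable the WM core alone is used
    (common in young subjects with thin sulci).
    """
    if not regions.wme.any():
        raise MeasureError("NCR requires a non-empty WM mask")
    if c_min <= 0:
        raise MeasureError("NCR requires positive tissue contrast")
    ls_wm = local_std(cbc, k=k, mask=regions.wme).data
    sigma_wm = float(np.mean(ls_wm[regions.wme]))
    if regions.csfe_fallback or not regions.csfe.any():
        sigma = sigma_wm
    else:
        ls_csf = local_std(cbc, k=k, mask=regions.csfe).data
        sigma_csf = float(np.mean(ls_csf[regions.csfe]))
        sigma = min(sigma_csf, sigma_wm)
    return sigma / c_min


# --- inhomogeneity -----------------------------------------------------------


def laplace_smooth(
    vol: ScalarVolume,
    mask: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 2000,
    boundary_k: int = 5,
) -> ScalarVolume:
    """Laplacian relaxation inside ``mask`` with Dirichlet boundary values.

    Interior voxels (all six neighbors inside the mask) are iteratively
    replaced by the mean of their neighbors; mask-boundary voxels are held
    fixed as Dirichlet data.  The Dirichlet values are the in-mask
    ``boundary_k``^3 local means of the observed boundary intensities
    (``boundary_k=1`` keeps them raw): the relaxed field follows its
    boundary data, so noisy raw values would re-inject exactly the
    high-frequency variance the filter exists to remove.  Iteration stops
    when the largest update falls below tol times the in-mask intensity
    range, or at max_iter.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("mask must be non-empty")
    if boundary_k % 2 == 0 or boundary_k < 1:
        raise ParameterError("boundary_k must be odd and >= 1")
    interior = ndimage.binary_erosion(mask, structure=STRUCT_6)
    out = vol.data.copy()
    if not interior.any():
        warnings.warn("mask has no interior; returning input unchanged",
                      stacklevel=2)
        return vol.with_data(out)
    if boundary_k > 1:
        w = mask.astype(np.float64)
        s1 = ndimage.uniform_filter(vol.data * w, size=boundary_k,
                                    mode="constant")
        cnt = ndimage.uniform_filter(w, size=boundary_k, mode="constant")
        shell = mask & ~interior
        out[shell] = (s1[shell] / np.maximum(cnt[shell], 1e-12))

    vals = out[mask]
    rng = float(vals.max() - vals.min())
    if rng == 0.0:
        return vol.with_data(out)
    thr = tol * rng

    # work on the bounding box of the mask (1-voxel margin) in float64
    sl = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
    sl = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n))
        for s, n in zip(sl, mask.shape)
    )
    box = out[sl].astype(np.float32)
    ibox = interior[sl]
    idx = np.where(ibox)

    for _ in range(max_iter):
        nb = (
            np.roll(box, 1, 0) + np.roll(box, -1, 0)
            + np.roll(box, 1, 1) + np.roll(box, -1, 1)
            + np.roll(box, 1, 2) + np.roll(box, -1, 2)
        ) / 6.0
        new = nb[idx]
        delta = float(np.max(np.abs(new - box[idx])))
        box[idx] = new
        if delta < thr:
            break

    keep_boundary = out[sl].copy()
    keep_boundary[ibox] = box[ibox]
    out[sl] = keep_boundary  # Dirichlet shell and interior; outside untouched
    out[~mask] = vol.data[~mask]
    return vol.with_data(out)


def icr_raw(
    vol_norm: ScalarVolume, regions: QcRegions, c_min: float
) -> float:
    """Inhomogeneity-to-contrast ratio before scaling.

    SD of the Laplacian-smoothed WM field over the deep interior of WMe
    (``regions.wm_deep``).  The Dirichlet shell and the layers just inside
    it are excluded: the harmonic extension of residual boundary noise
    decays over a few voxels, and counting the shallow layers would let
    noise re-enter the measure that the smoothing exists to suppress.
    """
    if regions.n_wme < 27:
        raise MeasureError(
            f"WM mask too small for inhomogeneity estimation ({regions.n_wme} voxels)"
        )
    if c_min <= 0:
        raise MeasureError("ICR requires positive tissue contrast")
    cs = laplace_smooth(vol_norm, regions.wme)
    domain = regions.wm_deep
    if domain is None or np.count_nonzero(domain) < 27:
        domain = regions.wme
    return float(np.std(cs.data[domain])) / c_min


# --- resolution --------------------------------------------------------------


def res_rms(voxel_size: tuple[float, float, float]) -> tuple[float, float]:
    """RMS and mean of the three voxel dimensions in mm (RES, RESM)."""
    vs = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in vs):
        raise ParameterError(f"voxel sizes must be positive, got {vs}")
    rms = float(np.sqrt(sum(v * v for v in vs) / 3.0))
    mean = float(sum(vs) / 3.0)
    return rms, mean


def ecr_raw(
    cbc: ScalarVolume,
    regions: QcRegions,
    c_min: float,
    seg: TissueSegmentation | None = None,
) -> float:
    """Edge-to-contrast ratio: mean intensity slope across the GM/WM band.

    Central differences in per-mm units.  When a segmentation is supplied,
    the gradient is projected onto the boundary normal (the direction of
    the WM-fraction gradient), so the measure reads the slope *across* the
    interface; the projection keeps orthogonal noise gradients from
    inflating the estimate.  Without a segmentation the plain gradient
    magnitude is used.  Larger means sharper anatomy.
    """
    band = regions.boundary_band
    if np.count_nonzero(band) < 50:
        raise MeasureError(
            f"GM/WM boundary band too small ({np.count_nonzero(band)} voxels)"
        )
    if c_min <= 0:
        raise MeasureError("ECR requires positive tissue contrast")
    gx, gy, gz = np.gradient(cbc.data, *cbc.voxel_size)
    mag = np.sqrt(gx * gx + gy * gy + gz * gz)
    if seg is None:
        return float(np.mean(mag[band])) / c_min
    nx, ny, nz = np.gradient(seg.wm, *cbc.voxel_size)
    nmag = np.sqrt(nx * nx + ny * ny + nz * nz)
    ok = band & (nmag > 1e-9)
    slope = np.abs(gx * nx + gy * ny + gz * nz) / np.where(nmag > 1e-9, nmag, 1.0)
    vals = np.where(ok, slope, mag)  # fall back to magnitude off-normal
    return float(np.mean(vals[band])) / c_min


# --- surface topology --------------------------------------------------------


def euler_characteristic(binary: np.ndarray) -> int:
    """chi = V - E + F of the closed isosurface of a binary volume.

    The foreground is padded by one background layer so that components
    touching the grid edge still yield closed surfaces, then triangulated
    marching-cubes style at level 0.5.
    """
    binary = np.asarray(binary).astype(bool)
    if not binary.any():
        raise TopologyError("empty foreground; no surface to extract")
    padded = np.pad(binary, 1).astype(np.float32)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5)
    v = len(verts)
    f = len(faces)
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]], axis=0
    )
    edges = np.sort(edges, axis=1)
    e = len(np.unique(edges, axis=0))
    return int(v - e + f)


def fec_raw(
    seg: TissueSegmentation,
) -> tuple[float, int | None, int | None, bool]:
    """Euler defect of the 2-mm whole-brain WM surface at two thresholds.

    The WM fraction is resampled to 2 mm isotropic (linear), stabilized by
    a 3^3 maximum filter, binarized at 0.25 and 0.75, and chi computed for
    each surface.  Returns (fec_raw, chi_025, chi_075, fallback) with
    fec_raw = (|2 - chi_025| + |2 - chi_075|)/2; if the 0.75 surface is
    empty, fec_raw uses the 0.25 surface alone and is flagged.
    """
    factors = [v / FEC_RESOLUTION_MM for v in seg.voxel_size]
    wm2 = ndimage.zoom(seg.wm, factors, order=1, prefilter=False)
    wm2 = ndimage.maximum_filter(wm2, size=3)
    b_lo = wm2 >= FEC_THRESHOLDS[0]
    b_hi = wm2 >= FEC_THRESHOLDS[1]
    if not b_lo.any():
        raise TopologyError("resampled WM empty at threshold 0.25")
    chi_lo = euler_characteristic(b_lo)
    if b_hi.any():
        chi_hi = euler_characteristic(b_hi)
        fec = (abs(2 - chi_lo) + abs(2 - chi_hi)) / 2.0
        return fec, chi_lo, chi_hi, False
    warnings.warn(
        "resampled WM empty at threshold 0.75; FEC uses the 0.25 surface only",
        stacklevel=2,
    )
    return float(abs(2 - chi_lo)), chi_lo, None, True


# --- orchestration -----------------------------------------------------------


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, QcError):
                raise type(exc)(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


@dataclass
class QcIntermediates:
    """Intermediate volumes and masks of one measure run, for inspection."""

    vol_norm: ScalarVolume
    bias: ScalarVolume
    cbc: ScalarVolume
    regions: QcRegions
    stats: TissueStats


def compute_measures(
    vol: ScalarVolume,
    seg: TissueSegmentation,
    return_intermediates: bool = False,
) -> MeasureSet | tuple[MeasureSet, QcIntermediates]:
    """Run the full raw-measure pipeline on one scan.

    normalize -> tissue stats -> masks -> bias field -> NCR/ICR/RES/ECR/FEC.
    Deterministic for fixed inputs; errors name the failing stage.
    """
    if min(vol.shape) < MIN_GRID_VOXELS:
        raise MeasureError(
            f"grid too small for measure computation: {vol.shape}"
        )
    seg.check_ratable()
    flags: list[str] = []

    with _stage("normalize"):
        vol_norm = normalize_intensity(vol, seg)
    with _stage("tissue-stats"):
        stats: TissueStats = tissue_stats(vol_norm, seg)
    with _stage("masks"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regions = optimize_masks(vol_norm, seg, stats)
    if regions.csfe_fallback:
        flags.append("csfe-fallback")

    with _stage("bias-field"):
        bias, bias_failed = estimate_bias_field(vol_norm, regions)
        if bias_failed:
            flags.append("bias-estimation-clipped")
        cbc = bias_correct(vol_norm, bias, seg.wm > 0.9)

    # c_min on the bias-corrected image: tissue medians drift under strong
    # bias, and the contrast unit should not couple the other measures to it
    with _stage("tissue-stats"):
        stats_bc: TissueStats = tissue_stats(cbc, seg)
    c_min = stats_bc.c_min

    with _stage("ncr"):
        ncr = ncr_raw(cbc, regions, c_min)
    with _stage("icr"):
        icr = icr_raw(vol_norm, regions, c_min)
    with _stage("res"):
        rms, resm = res_rms(vol.voxel_size)
    with _stage("ecr"):
        ecr = ecr_raw(cbc, regions, c_min, seg=seg)
    with _stage("fec"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fec, chi_lo, chi_hi, fec_fallback = fec_raw(seg)
        if fec_fallback:
            flags.append("fec-single-threshold")

    result = MeasureSet(
        ncr_raw=ncr,
        icr_raw=icr,
        res_rms=rms,
        resm_mean=resm,
        ecr_raw=ecr,
        fec_raw=fec,
        c_min=c_min,
        chi_025=chi_lo,
        chi_075=chi_hi,
        flags=flags,
    )
    if return_intermediates:
        inter = QcIntermediates(
            vol_norm=vol_norm, bias=bias, cbc=cbc, regions=regions,
            stats=stats_bc,
        )
        return result, inter
    return result
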