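"""Synthetic T1-like brain phantoms with ground-truth segmentations.

The phantom emulates the parameterization of the classic simulated-MRI
calibration datasets: a nested set of ellipsoid shells (WM core, GM shell,
CSF shell) with T1-like intensities CSF < GM < WM, to which controlled
perturbations are applied — additive Gaussian/Rician noise at 1-9+ percent
of the WM intensity, smooth multiplicative bias fields of 20-100 percent
amplitude in three fixed shapes, voxel sizes of 1-2 mm, Gaussian smoothing,
and segmentation errors by erosion/dilation of tissue classes.  An optional
sinusoidal folding of the WM boundary gives the GM/WM interface gyrus-like
structure.  Geometry is analytic, so class volumes and WM topology have
closed-form oracles; partial-volume fractions come from 4x supersampling of
the analytic shapes followed by block averaging.

This is a test harness for the quality measures, not an anatomical atlas:
it has no skull, no vasculature, and no spatially realistic cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .tissue_regions import STRUCT_6
from .volume_io import QcError, ScalarVolume, TissueSegmentation


class SpecError(QcError):
    """Degenerate phantom geometry."""


class ParameterError(QcError):
    """Invalid perturbation parameter."""


class PerturbationError(QcError):
    """A segmentation perturbation annihilated a tissue class."""


class EvaluationError(QcError):
    """Segmentation-overlap evaluation has an empty domain."""


@dataclass
class PhantomSpec:
    """Geometry, intensity and perturbation parameters of one phantom.

    Radii and thicknesses are in mm.  ``noise_pct`` is the noise SD as a
    percentage of the WM intensity; ``bias_pct`` the peak-to-peak amplitude
    of the multiplicative field.  Identical spec + seed give bitwise
    identical output.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_mm: float = 1.0
    wm_radii: tuple[float, float, float] = (24.0, 30.0, 22.0)
    gm_thickness: float = 3.0
    csf_thickness: float = 3.0
    fold_amplitude_mm: float = 2.0
    fold_frequency: int = 6
    intensities: tuple[float, float, float] = (0.2, 0.6, 1.0)  # CSF, GM, WM
    background: float = 0.0
    noise_pct: float = 0.0
    noise_kind: str = "gaussian"
    bias_pct: float = 0.0
    bias_field_id: str = "A"
    smooth_fwhm_mm: float = 0.0
    target_mm: float | tuple[float, float, float] | None = None
    reinterpolate: bool = False
    seed: int = 0
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.gm_thickness <= 0 or self.csf_thickness <= 0:
            raise SpecError("shell thicknesses must be positive")
        if any(r <= 0 for r in self.wm_radii):
            raise SpecError("WM radii must be positive")
        if self.fold_amplitude_mm >= self.gm_thickness:
            raise SpecError("folding amplitude must stay inside the GM shell")
        if not 0.0 <= self.noise_pct <= 20.0:
            raise ParameterError("noise_pct must lie in [0, 20]")
        if not 0.0 <= self.bias_pct <= 100.0:
            raise ParameterError("bias_pct must lie in [0, 100]")
        half = min(n * self.voxel_mm for n in self.shape) / 2.0
        outer = max(self.wm_radii) + self.gm_thickness + self.csf_thickness
        if outer >= half:
            raise SpecError(
                f"phantom (outer radius {outer} mm) does not fit the grid "
                f"(half extent {half} mm)"
            )


def analytic_volumes(spec: PhantomSpec) -> tuple[float, float, float]:
    """Closed-form CSF/GM/WM volumes in ml (valid for zero folding)."""
    a, b, c = spec.wm_radii
    tg, tc = spec.gm_thickness, spec.csf_thickness

    def ell(a, b, c):
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    v_wm = ell(a, b, c)
    v_gm = ell(a + tg, b + tg, c + tg) - v_wm
    v_csf = ell(a + tg + tc, b + tg + tc, c + tg + tc) - v_wm - v_gm
    return v_csf, v_gm, v_wm


def _block_mean(a: np.ndarray, ss: int) -> np.ndarray:
    n0, n1, n2 = (s // ss for s in a.shape)
    return (
        a.reshape(n0, ss, n1, ss, n2, ss)
        .mean(axis=(1, 3, 5), dtype=np.float64)
    )


def make_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, TissueSegmentation]:
    """Build the clean phantom image and its ground-truth segmentation.

    Partial-volume fractions come from ``supersample``-fold oversampling of
    the analytic geometry followed by block averaging; the intensity is the
    fraction-weighted mix of the class intensities.
    """
    ss = spec.supersample
    vs = spec.voxel_mm
    shape = spec.shape
    centers = [n * vs / 2.0 for n in shape]

    # supersampled physical coordinates relative to the center, mm
    def ax(i):
        n = shape[i] * ss
        return ((np.arange(n, dtype=np.float32) + 0.5) * (vs / ss) - centers[i])

    x = ax(0)[:, None, None]
    y = ax(1)[None, :, None]
    z = ax(2)[None, None, :]

    a, b, c = spec.wm_radii
    tg = spec.gm_thickness
    tc = spec.csf_thickness

    rho2_wm = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    if spec.fold_amplitude_mm > 0:
        r_mean = (a + b + c) / 3.0
        theta = np.arctan2(y, x)  # broadcasts to (nx, ny, 1)
        rxy = np.sqrt(x * x + y * y)
        psi = np.arctan2(z, rxy)
        fold = 1.0 + (spec.fold_amplitude_mm / r_mean) * (
            np.sin(spec.fold_frequency * theta) * np.sin(spec.fold_frequency * psi)
        )
        wm_in = rho2_wm <= fold * fold
        del theta, rxy, psi, fold
    else:
        wm_in = rho2_wm <= 1.0
    del rho2_wm

    gm_in = ((x / (a + tg)) ** 2 + (y / (b + tg)) ** 2 + (z / (c + tg)) ** 2) <= 1.0
    csf_in = (
        (x / (a + tg + tc)) ** 2
        + (y / (b + tg + tc)) ** 2
        + (z / (c + tg + tc)) ** 2
    ) <= 1.0

    wm = _block_mean(wm_in.astype(np.float32), ss)
    gm = _block_mean((gm_in & ~wm_in).astype(np.float32), ss)
    csf = _block_mean((csf_in & ~gm_in).astype(np.float32), ss)
    del wm_in, gm_in, csf_in

    for name, arr in (("CSF", csf), ("GM", gm), ("WM", wm)):
        if not (arr > 0.5).any():
            raise SpecError(f"{name} class empty for this geometry")

    i_csf, i_gm, i_wm = spec.intensities
    data = (
        spec.background * (1.0 - csf - gm - wm)
        + i_csf * csf
        + i_gm * gm
        + i_wm * wm
    )
    voxel_size = (vs, vs, vs)
    vol = ScalarVolume(data=data, voxel_size=voxel_size, id=f"phantom-{spec.seed}")
    seg = TissueSegmentation(csf=csf, gm=gm, wm=wm, voxel_size=voxel_size)
    return vol, seg


# --- perturbations -----------------------------------------------------------


def add_noise(
    vol: ScalarVolume,
    pct: float,
    kind: str = "gaussian",
    seed: int | None = None,
    wm_intensity: float = 1.0,
) -> ScalarVolume:
    """Add noise with SD = pct/100 of the WM intensity.

    Gaussian noise is additive; Rician noise is the magnitude of the
    signal plus complex Gaussian noise of the same SD per channel, the
    physically correct model for magnitude MRI.
    """
    if pct < 0:
        raise ParameterError("noise percentage must be non-negative")
    if pct == 0:
        return vol.with_data(vol.data.copy())
    sd = pct / 100.0 * wm_intensity
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        out = vol.data + rng.normal(0.0, sd, vol.shape)
    elif kind == "rician":
        re = vol.data + rng.normal(0.0, sd, vol.shape)
        im = rng.normal(0.0, sd, vol.shape)
        out = np.sqrt(re * re + im * im)
    else:
        raise ParameterError(f"unknown noise kind: {kind!r}")
    return vol.with_data(out)


_FIELD_IDS = ("A", "B", "C")


def bias_field_volume(
    shape: tuple[int, int, int], pct: float, field_id: str = "A"
) -> np.ndarray:
    """Smooth multiplicative field with peak-to-peak amplitude pct percent.

    Three fixed low-order cosine shapes (A, B, C); the raw field spans
    exactly [1, 1 + pct/100] before any brain-mean normalization, so the
    max/min ratio is 1 + pct/100.
    """
    if not 0.0 <= pct <= 100.0:
        raise ParameterError("bias percentage must lie in [0, 100]")
    t = [np.linspace(0.0, 1.0, n, dtype=np.float64) for n in shape]
    tx = t[0][:, None, None]
    ty = t[1][None, :, None]
    tz = t[2][None, None, :]
    if field_id == "A":
        g = np.sin(np.pi * tx) * np.sin(np.pi * ty) * np.sin(np.pi * tz)
    elif field_id == "B":
        g = np.cos(np.pi * tx) + np.cos(np.pi * ty) + np.cos(np.pi * tz)
    elif field_id == "C":
        g = np.sin(np.pi * (tx + ty) / 2.0) * np.cos(np.pi * tz / 2.0)
    else:
        raise ParameterError(
            f"unknown bias field id {field_id!r}; expected one of {_FIELD_IDS}"
        )
    g = g - g.min()
    peak = g.max()
    if peak > 0:
        g = g / peak
    return 1.0 + (pct / 100.0) * g


def apply_bias(
    vol: ScalarVolume, pct: float, field_id: str = "A"
) -> ScalarVolume:
    """Multiply by a bias field normalized to mean 1 over the brain."""
    if pct == 0:
        return vol.with_data(vol.data.copy())
    fld = bias_field_volume(vol.shape, pct, field_id)
    brain = vol.data > 0.05 * float(vol.data.max())
    if brain.any():
        fld = fld / float(np.mean(fld[brain]))
    return vol.with_data(vol.data * fld)


def smooth(vol: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Gaussian smoothing with the given FWHM in mm (voxel-size aware)."""
    if fwhm_mm < 0:
        raise ParameterError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in vol.voxel_size]
    return vol.with_data(ndimage.gaussian_filter(vol.data, sigma_vox))


def _match_shape(a: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Crop or edge-pad to an exact target shape (off-by-one after zoom)."""
    slices = tuple(slice(0, min(s, n)) for s, n in zip(a.shape, shape))
    a = a[slices]
    pads = tuple((0, n - s) for s, n in zip(a.shape, shape))
    if any(p[1] for p in pads):
        a = np.pad(a, pads, mode="edge")
    return a


def degrade_resolution(
    vol: ScalarVolume,
    target_mm: float | tuple[float, float, float],
    reinterpolate: bool = False,
) -> ScalarVolume:
    """Linear downsampling to a coarser grid, optionally reinterpolated.

    Without reinterpolation the stored voxel size becomes the target; with
    it, the data are linearly upsampled back to the native grid and the
    stored voxel size is unchanged — the case where a purely header-based
    resolution score is blind to the information loss.
    """
    if np.isscalar(target_mm):
        target = (float(target_mm),) * 3
    else:
        target = tuple(float(v) for v in target_mm)
    for t, v in zip(target, vol.voxel_size):
        if t < v - 1e-9:
            raise ParameterError(
                f"target voxel size {t} mm finer than native {v} mm"
            )
    factors = [v / t for v, t in zip(vol.voxel_size, target)]
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return vol.with_data(vol.data.copy())
    down = ndimage.zoom(vol.data, factors, order=1, prefilter=False)
    if not reinterpolate:
        return ScalarVolume(
            data=down, voxel_size=target, id=vol.id, n_nonfinite=0
        )
    up_factors = [n / d for n, d in zip(vol.shape, down.shape)]
    up = ndimage.zoom(down, up_factors, order=1, prefilter=False)
    up = _match_shape(up, vol.shape)
    return vol.with_data(up)


def perturb_segmentation(
    seg: TissueSegmentation,
    op: str,
    tissue: str,
    voxels: int = 1,
    seed: int | None = None,
) -> TissueSegmentation:
    """Erode or dilate one tissue class, emulating segmentation errors.

    The binarized class (fraction > 0.5) is eroded/dilated by 6-connected
    steps; displaced mass moves to/from the spatially adjacent class, so
    per-voxel fraction sums stay valid.  Deterministic; ``seed`` is kept
    for interface symmetry with the noise operators.
    """
    if voxels < 1:
        raise ParameterError("perturbation size must be >= 1 voxel")
    if op not in ("erode", "dilate"):
        raise ParameterError(f"unknown perturbation op: {op!r}")
    if tissue not in ("csf", "gm", "wm"):
        raise ParameterError(f"unknown tissue class: {tissue!r}")

    csf = seg.csf.copy()
    gm = seg.gm.copy()
    wm = seg.wm.copy()
    frac = {"csf": csf, "gm": gm, "wm": wm}
    target = frac[tissue]
    mask = target > 0.5

    if op == "erode":
        new = ndimage.binary_erosion(mask, structure=STRUCT_6, iterations=voxels)
        if not new.any():
            raise PerturbationError(
                f"eroding {tissue} by {voxels} voxel(s) annihilates the class"
            )
        changed = mask & ~new
        # displaced mass goes to the locally dominant neighbor: another
        # tissue class in the interior, background at the outer brain skin
        others = [n for n in ("csf", "gm", "wm") if n != tissue]
        neigh = {n: ndimage.uniform_filter(frac[n], size=3) for n in others}
        neigh["background"] = ndimage.uniform_filter(
            1.0 - csf - gm - wm, size=3
        )
        names = others + ["background"]
        stacked = np.stack([neigh[n] for n in names])
        recipient = np.argmax(stacked, axis=0)
        for i, name in enumerate(others):
            sel = changed & (recipient == i)
            frac[name][sel] += target[sel]
        target[changed] = 0.0  # background-recipient mass simply vanishes
    else:
        new = ndimage.binary_dilation(mask, structure=STRUCT_6, iterations=voxels)
        added = new & ~mask
        # the target class absorbs whatever tissue is present there
        total = csf + gm + wm
        for name in ("csf", "gm", "wm"):
            if name != tissue:
                frac[name][added] = 0.0
        target[added] = total[added]

    return TissueSegmentation(
        csf=np.clip(csf, 0.0, 1.0),
        gm=np.clip(gm, 0.0, 1.0),
        wm=np.clip(wm, 0.0, 1.0),
        voxel_size=seg.voxel_size,
        dialect=seg.dialect,
    )


# --- evaluation --------------------------------------------------------------


@dataclass
class KappaResult:
    """Cohen's kappa agreement between two segmentations."""

    kappa_csf: float
    kappa_gm: float
    kappa_wm: float
    mean_kappa: float
    confusion: np.ndarray = field(repr=False, default=None)


def hard_labels(seg: TissueSegmentation) -> np.ndarray:
    """Argmax labels (CSF=1, GM=2, WM=3); background where all fractions < 0.5."""
    stack = np.stack([seg.csf, seg.gm, seg.wm])
    arg = np.argmax(stack, axis=0) + 1
    return np.where(stack.max(axis=0) >= 0.5, arg, 0)


def _binary_kappa(a: np.ndarray, b: np.ndarray) -> float:
    p_o = float(np.mean(a == b))
    pa, pb = float(a.mean()), float(b.mean())
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if 1.0 - p_e < 1e-12:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa(
    seg_a: TissueSegmentation,
    seg_b: TissueSegmentation,
    domain: np.ndarray | None = None,
) -> KappaResult:
    """Per-class one-vs-rest Cohen's kappa and their mean.

    The evaluation domain defaults to voxels labelled non-background in
    either map.
    """
    if seg_a.shape != seg_b.shape:
        raise EvaluationError("segmentations live on different grids")
    la = hard_labels(seg_a)
    lb = hard_labels(seg_b)
    if domain is None:
        domain = (la > 0) | (lb > 0)
    domain = np.asarray(domain, dtype=bool)
    if not domain.any():
        raise EvaluationError("empty evaluation domain")
    la, lb = la[domain], lb[domain]

    ks = [_binary_kappa(la == k, lb == k) for k in (1, 2, 3)]
    confusion = np.zeros((4, 4), dtype=np.int64)
    np.add.at(confusion, (la, lb), 1)
    return KappaResult(
        kappa_csf=ks[0],
        kappa_gm=ks[1],
        kappa_wm=ks[2],
        mean_kappa=float(np.mean(ks)),
        confusion=confusion,
    )


def threshold_resegment(
    vol: ScalarVolume,
    intensities: tuple[float, float, float] = (0.2, 0.6, 1.0),
    mask: np.ndarray | None = None,
) -> TissueSegmentation:
    """Intensity-driven re-segmentation with partial-volume fractions.

    Voxels inside ``mask`` (default: above half the CSF intensity) are
    mapped to a continuous CSF=1 / GM=2 / WM=3 label by piecewise-linear
    interpolation between the nominal class intensities, then converted to
    class fractions.  This mimics the simplest partial-volume segmentation
    a processing pipeline would produce from the (possibly degraded)
    image; it has no spatial regularization, so per-voxel noise shows up
    directly as misclassification.
    """
    from .volume_io import fractions_from_pve

    i_csf, i_gm, i_wm = intensities
    d = vol.data
    if mask is None:
        mask = d > (i_csf / 2.0)
    label = (
        1.0
        + np.clip((d - i_csf) / (i_gm - i_csf), 0.0, 1.0)
        + np.clip((d - i_gm) / (i_wm - i_gm), 0.0, 1.0)
    )
    label = np.where(mask, label, 0.0)
    csf, gm, wm = fractions_from_pve(np.clip(label, 0.0, 3.0))
    return TissueSegmentation(
        csf=csf, gm=gm, wm=wm, voxel_size=vol.voxel_size, dialect="pve"
    )


def simulate(spec: PhantomSpec) -> tuple[ScalarVolume, TissueSegmentation]:
    """Generate a phantom and apply the full perturbation chain.

    Order mirrors acquisition physics: anatomical blurring (smoothing),
    then the multiplicative coil bias, then receiver noise, then the
    sampling grid (resolution degradation).  The returned segmentation is
    the ground truth, resampled when the grid changes.
    """
    vol, seg = make_phantom(spec)
    if spec.smooth_fwhm_mm > 0:
        vol = smooth(vol, spec.smooth_fwhm_mm)
    if spec.bias_pct > 0:
        vol = apply_bias(vol, spec.bias_pct, spec.bias_field_id)
    if spec.noise_pct > 0:
        vol = add_noise(
            vol,
            spec.noise_pct,
            kind=spec.noise_kind,
            seed=spec.seed,
            wm_intensity=spec.intensities[2],
        )
    if spec.target_mm is not None:
        vol = degrade_resolution(vol, spec.target_mm, spec.reinterpolate)
        if not spec.reinterpolate:
            factors = [
                v / t
                for v, t in zip(
                    seg.voxel_size,
                    (spec.target_mm,) * 3
                    if np.isscalar(spec.target_mm)
                    else spec.target_mm,
                )
            ]
            seg = TissueSegmentation(
                csf=np.clip(ndimage.zoom(seg.csf, factors, order=1, prefilter=False), 0, 1),
                gm=np.clip(ndimage.zoom(seg.gm, factors, order=1, prefilter=False), 0, 1),
                wm=np.clip(ndimage.zoom(seg.wm, factors, order=1, prefilter=False), 0, 1),
                voxel_size=vol.voxel_size,
            )
    return vol, seg


def phantom_spec_to_text(spec: PhantomSpec) -> str:
    """Serialize a spec as plain ``key = value`` lines (seed included)."""
    lines = []
    for k, v in vars(spec).items():
        lines.append(f"{k} = {v!r}")
    return "\n".join(lines) + "\n"
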