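"""Synthetic multi-setting MRI studies with controllable scanner effects.

Three study designs mirror the usual bench and in-vivo material of
scanner-effect work:

* a *homogeneous phantom*: nine cylindrical tubes of distinct constant
  intensities (mimicking CSF-like homogeneous media);
* a *heterogeneous phantom*: six tubes filled with correlated Gaussian
  texture (mimicking white-matter-like tissue);
* a *brain-like volume*: an ellipsoidal head with WM/GM/CSF compartments
  in T1 ordering (WM brightest) and a corpus-callosum subregion of WM
  sampled in the sagittal plane.

Each study is generated once as a clean ground-truth volume and then
"acquired" under each :class:`~mriharm.core.AcquisitionSetting` via
:func:`apply_scanner_effect`, which applies, in order: resampling to the
setting's voxel spacing, a smooth multiplicative bias field, a global
gain and offset, and additive Gaussian noise.  ROI geometry is defined in
physical coordinates and rasterized per setting, so paired settings at
equal spacing carry voxel-identical masks: any downstream feature
difference is attributable to the injected scanner effect alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import AcquisitionSetting, ImageVolume, ROIMask, ROISet
from .preprocess import resample_volume

__all__ = [
    "PhantomConfig",
    "BrainConfig",
    "default_field_strength_pair",
    "generate_homogeneous_phantom",
    "generate_heterogeneous_phantom",
    "generate_brain_volume",
    "apply_scanner_effect",
]

SLICE_SPACING_MM = 4.0  # slice thickness shared by all settings


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and ground-truth intensities of the tube phantoms.

    Tube means are equally spaced and separated by much more than the
    default noise levels, so the tube classes stay identifiable.
    """

    tube_means: tuple[float, ...] = tuple(60.0 + 25.0 * k for k in range(9))
    tube_radius_frac: float = 0.09  # of in-plane extent
    # ROIs nearly fill the tubes, as in the usual phantom protocol where
    # circular ROI radii are printed close to the tube radius
    roi_radius_frac: float = 0.9
    # heterogeneous phantom: per-tube texture variance and correlation
    # length — distinct materials differ in both amplitude and scale
    texture_variances: tuple[float, ...] = (16.0, 25.0, 36.0, 49.0, 64.0, 81.0)
    correlation_lengths_mm: tuple[float, ...] = (3.0, 4.5, 6.0, 8.0, 10.0, 12.0)


@dataclass(frozen=True)
class BrainConfig:
    """Compartment means (T1 ordering WM > GM > CSF) and ROI geometry."""

    wm_mean: float = 200.0
    gm_mean: float = 120.0
    csf_mean: float = 40.0
    texture_sigma: float = 5.0
    texture_corr_mm: float = 5.0
    n_slices: int = 32
    # ROI radius as a fraction of the in-plane matrix, mirroring the usual
    # protocol scale of manually drawn circular brain ROIs (14 px at 256)
    roi_radius_frac: float = 0.055

    def roi_radius_px(self, matrix: int) -> int:
        return max(2, int(round(self.roi_radius_frac * matrix)))


def default_field_strength_pair(
    matrix: int = 128, fov: float = 24.0
) -> list[AcquisitionSetting]:
    """The default paired study emulating a 1.5T-vs-3T scanner change.

    The 3T arm has a 1.8x global gain and slightly higher noise, so raw
    histograms show a large gap between the two arms' mean intensities.
    """
    return [
        AcquisitionSetting(
            setting_id="1p5T", field_strength=1.5, fov=fov, matrix=matrix,
            gain=1.0, offset=0.0, bias_amplitude=0.05, noise_sigma=2.0,
            seed_offset=0,
        ),
        AcquisitionSetting(
            setting_id="3T", field_strength=3.0, fov=fov, matrix=matrix,
            gain=1.8, offset=0.0, bias_amplitude=0.05, noise_sigma=3.0,
            seed_offset=1,
        ),
    ]


# ---------------------------------------------------------------------------
# helpers


def _reference_setting(settings: Sequence[AcquisitionSetting]) -> AcquisitionSetting:
    """The finest-grid setting defines the clean (ground-truth) grid."""
    if not settings:
        raise ValueError("settings list is empty")
    return min(settings, key=lambda s: s.inplane_spacing)


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *streams]))


def _disk_mask_2d(shape, spacing, center_mm, radius_mm):
    ii, jj = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing[0],
        (np.arange(shape[1]) + 0.5) * spacing[1],
        indexing="ij",
    )
    return (ii - center_mm[0]) ** 2 + (jj - center_mm[1]) ** 2 <= radius_mm**2


def _correlated_texture(rng, shape, spacing, corr_mm):
    """Zero-mean unit-variance correlated Gaussian field on a grid."""
    white = rng.standard_normal(shape)
    sigma_vox = np.maximum(np.asarray(corr_mm, dtype=float) / np.asarray(spacing), 1e-6)
    tex = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = tex.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (tex - tex.mean()) / sd


def _tube_centers(n_tubes: int, extent_mm: float) -> list[tuple[float, float]]:
    """Tube centers on a regular lattice spanning the in-plane extent."""
    if n_tubes == 9:
        fr = (0.25, 0.5, 0.75)
        return [(extent_mm * a, extent_mm * b) for a in fr for b in fr]
    if n_tubes == 6:
        fa, fb = (0.28, 0.72), (0.2, 0.5, 0.8)
        return [(extent_mm * a, extent_mm * b) for a in fa for b in fb]
    raise ValueError(f"unsupported tube count {n_tubes}")


def _roi_radius_px(reference_radius_px: float, reference_spacing: float, spacing: float) -> int:
    """Pixel radius scaled inversely with voxel spacing (FOV-dependent radii)."""
    r = int(round(reference_radius_px * reference_spacing / spacing))
    return max(r, 1)


# ---------------------------------------------------------------------------
# phantoms


def _generate_phantom(
    n_slices: int,
    settings: Sequence[AcquisitionSetting],
    seed: int,
    config: PhantomConfig,
    heterogeneous: bool,
) -> list[tuple[ImageVolume, ROISet]]:
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    ref = _reference_setting(settings)
    s_ref = ref.inplane_spacing
    extent = ref.fov * 10.0
    n = ref.matrix
    shape = (n, n, n_slices)
    spacing = (s_ref, s_ref, SLICE_SPACING_MM)

    means = config.tube_means[:6] if heterogeneous else config.tube_means
    n_tubes = len(means)
    centers = _tube_centers(n_tubes, extent)
    tube_radius_mm = config.tube_radius_frac * extent

    # geometry feasibility: tubes must fit the grid without touching
    if tube_radius_mm * 2 >= extent * (0.25 if not heterogeneous else 0.2):
        raise ValueError("tubes do not fit the grid: reduce tube_radius_frac")

    clean = np.zeros(shape)
    rng = _rng(seed, 0)
    for t, (c, mu) in enumerate(zip(centers, means)):
        disk = _disk_mask_2d(shape[:2], spacing[:2], c, tube_radius_mm)
        tube3d = np.repeat(disk[:, :, None], n_slices, axis=2)
        clean[tube3d] = mu
        if heterogeneous:
            var = config.texture_variances[t % len(config.texture_variances)]
            corr = config.correlation_lengths_mm[t % len(config.correlation_lengths_mm)]
            tex = _correlated_texture(rng, shape, spacing, corr)
            # pin the in-tube sample variance to the configured value
            in_tube = tex[tube3d]
            sd = in_tube.std()
            if sd > 1e-12 and var > 0:
                clean[tube3d] += (in_tube - in_tube.mean()) / sd * np.sqrt(var)

    clean_vol = ImageVolume(values=clean, spacing=spacing, subject_id="phantom")

    roi_radius_ref_px = max(
        int(round(config.roi_radius_frac * tube_radius_mm / s_ref)), 1
    )

    out = []
    for setting in settings:
        observed = apply_scanner_effect(clean_vol, setting, seed)
        sp = observed.spacing
        r_px = _roi_radius_px(roi_radius_ref_px, s_ref, sp[0])
        masks = []
        for t, c in enumerate(centers):
            for k in range(observed.shape[2]):
                disk = _disk_mask_2d(observed.shape[:2], sp[:2], c, r_px * sp[0])
                m3 = np.zeros(observed.shape, dtype=bool)
                m3[:, :, k] = disk
                masks.append(
                    ROIMask(tissue_class=f"tube{t + 1}", roi_id=f"tube{t + 1}_s{k:02d}", mask=m3)
                )
        roiset = ROISet(masks=masks, plane="transverse")
        roiset.validate_against(observed)
        out.append((observed, roiset))
    return out


def generate_homogeneous_phantom(
    n_slices: int,
    settings: Sequence[AcquisitionSetting],
    seed: int,
    config: PhantomConfig = PhantomConfig(),
) -> list[tuple[ImageVolume, ROISet]]:
    """Nine constant-intensity tubes; one circular ROI per tube per slice."""
    return _generate_phantom(n_slices, settings, seed, config, heterogeneous=False)


def generate_heterogeneous_phantom(
    n_slices: int,
    settings: Sequence[AcquisitionSetting],
    seed: int,
    config: PhantomConfig = PhantomConfig(),
) -> list[tuple[ImageVolume, ROISet]]:
    """Six textured tubes (correlated Gaussian texture); six ROIs per slice."""
    return _generate_phantom(n_slices, settings, seed, config, heterogeneous=True)


# ---------------------------------------------------------------------------
# brain


def _ellipsoid(shape, center, semiaxes):
    grids = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _place_disk_in_slice(rng, allowed_2d, r_px, existing, max_tries=200):
    """One non-overlapping disk center, Euclidean-separated from ``existing``."""
    cand = np.argwhere(allowed_2d)
    if len(cand) == 0:
        return None
    min_d2 = (2 * r_px + 1) ** 2
    for _ in range(max_tries):
        ci, cj = cand[rng.integers(len(cand))]
        if all((ci - pi) ** 2 + (cj - pj) ** 2 > min_d2 for pi, pj in existing):
            return int(ci), int(cj)
    return None


def generate_brain_volume(
    settings: Sequence[AcquisitionSetting],
    rois_per_tissue: int = 20,
    seed: int = 0,
    subject_id: str = "sub00",
    config: BrainConfig = BrainConfig(),
) -> list[tuple[ImageVolume, ROISet, np.ndarray]]:
    """Brain-like volume with WM/GM/CSF compartments and circular ROIs.

    The default protocol emits 60 ROIs per acquisition: 20 WM and 20 GM
    in the transverse plane plus 20 corpus-callosum (CC, a WM subregion)
    in the sagittal plane — identical geometry across settings.  Returns,
    per setting, the observed volume, its ROI set and the brain mask.
    """
    if rois_per_tissue < 1:
        raise ValueError("rois_per_tissue must be >= 1")
    ref = _reference_setting(settings)
    s_ref = ref.inplane_spacing
    n = ref.matrix
    nz = config.n_slices
    shape = (n, n, nz)
    spacing = (s_ref, s_ref, SLICE_SPACING_MM)

    center = (n / 2, n / 2, nz / 2)
    brain = _ellipsoid(shape, center, (0.42 * n, 0.40 * n, 0.46 * nz))
    wm = _ellipsoid(shape, center, (0.28 * n, 0.26 * n, 0.34 * nz))
    csf = _ellipsoid(shape, center, (0.08 * n, 0.07 * n, 0.12 * nz))
    gm = brain & ~wm
    wm = wm & ~csf

    # corpus callosum: midline band of WM around the central sagittal planes
    cc_band = np.zeros(shape, dtype=bool)
    half_band = max(1, n // 16)
    cc_band[n // 2 - half_band : n // 2 + half_band + 1, :, :] = True
    cc = wm & cc_band

    rng = _rng(seed, 1)
    clean = np.zeros(shape)
    tex = _correlated_texture(rng, shape, spacing, config.texture_corr_mm)
    clean[csf] = config.csf_mean
    clean[gm] = config.gm_mean
    clean[wm] = config.wm_mean
    clean[brain] += config.texture_sigma * tex[brain]
    clean_vol = ImageVolume(values=clean, spacing=spacing, subject_id=subject_id)

    r_px_ref = config.roi_radius_px(ref.matrix)

    # --- place ROI geometry once, on the reference grid -------------------
    placement_rng = _rng(seed, 2)
    geom: list[tuple[str, str, str, int, tuple[int, int]]] = []
    # transverse WM / GM: central slice band where compartments are widest
    k_band = [k for k in range(nz) if abs(k - nz // 2) <= nz // 4]
    for cls, region in (("WM", wm & ~cc), ("GM", gm)):
        eroded = {
            k: ndimage.binary_erosion(region[:, :, k], iterations=r_px_ref + 1)
            for k in k_band
        }
        placed_total = 0
        retries = 0
        while placed_total < rois_per_tissue:
            k = k_band[placement_rng.integers(len(k_band))]
            existing = [(a, b) for c2, _, _, kk, (a, b) in geom if c2 == cls and kk == k]
            pt = _place_disk_in_slice(placement_rng, eroded[k], r_px_ref, existing)
            if pt is not None:
                geom.append((cls, f"{cls}{placed_total:02d}", "transverse", k, pt))
                placed_total += 1
                retries = 0
            else:
                retries += 1
                if retries > 50 * rois_per_tissue:
                    raise RuntimeError(
                        f"could not place {rois_per_tissue} ROIs in class {cls}"
                    )
    # sagittal CC ROIs over central sagittal planes
    i_band = list(range(n // 2 - half_band, n // 2 + half_band + 1))
    placed_total = 0
    retries = 0
    r_sag = max(r_px_ref - 1, 1)
    eroded_sag = {
        i: ndimage.binary_erosion(cc[i, :, :], iterations=r_sag + 1) for i in i_band
    }
    while placed_total < rois_per_tissue:
        i = i_band[placement_rng.integers(len(i_band))]
        existing = [(a, b) for c2, _, _, ii, (a, b) in geom if c2 == "CC" and ii == i]
        pt = _place_disk_in_slice(placement_rng, eroded_sag[i], r_sag, existing)
        if pt is not None:
            geom.append(("CC", f"CC{placed_total:02d}", "sagittal", i, pt))
            placed_total += 1
            retries = 0
        else:
            retries += 1
            if retries > 50 * rois_per_tissue:
                raise RuntimeError(f"could not place {rois_per_tissue} CC ROIs")

    # --- acquire under each setting ---------------------------------------
    out = []
    for setting in settings:
        observed = apply_scanner_effect(clean_vol, setting, seed)
        sp = observed.spacing
        scale = s_ref / sp[0]
        r_px = _roi_radius_px(r_px_ref, s_ref, sp[0])
        masks = []
        for cls, roi_id, plane, k, (a, b) in geom:
            m3 = np.zeros(observed.shape, dtype=bool)
            if plane == "transverse":
                ai = int(round((a + 0.5) * scale - 0.5))
                bj = int(round((b + 0.5) * scale - 0.5))
                ii, jj = np.meshgrid(
                    np.arange(observed.shape[0]), np.arange(observed.shape[1]),
                    indexing="ij",
                )
                m3[:, :, k] = (ii - ai) ** 2 + (jj - bj) ** 2 <= r_px**2
            else:  # sagittal: plane index along axis 0, grid over (axis1, axis2)
                i_new = int(round((k + 0.5) * scale - 0.5))
                aj = int(round((a + 0.5) * scale - 0.5))
                jj, kk = np.meshgrid(
                    np.arange(observed.shape[1]), np.arange(observed.shape[2]),
                    indexing="ij",
                )
                r_sag = max(r_px - 1, 1)
                m3[i_new, :, :] = (jj - aj) ** 2 + (kk - b) ** 2 <= r_sag**2
            masks.append(ROIMask(tissue_class=cls, roi_id=roi_id, mask=m3))
        roiset = ROISet(masks=masks, plane="mixed")
        roiset.validate_against(observed)

        brain_mask = brain
        if observed.shape != shape:
            from .preprocess import resample_mask

            brain_mask = resample_mask(brain.astype(bool), spacing, sp)
        out.append((observed, roiset, brain_mask))
    return out


# ---------------------------------------------------------------------------
# acquisition model


def apply_scanner_effect(
    clean: ImageVolume,
    setting: AcquisitionSetting,
    seed: int,
    bias_smoothness_mm: float = 80.0,
) -> ImageVolume:
    """Acquire a clean volume under a scanner setting.

    observed = gain * bias_field(x) * resample(clean) + offset + N(0, noise_sigma)

    The bias field is a smoothed Gaussian random field rescaled so its
    grid mean is exactly 1 and its peak deviation from 1 is exactly
    ``setting.bias_amplitude``.  With identity parameters and matching
    spacing the output equals the input.
    """
    target = (setting.inplane_spacing, setting.inplane_spacing, clean.spacing[2])
    vol = resample_volume(clean, target, mode="image")

    rng = _rng(seed + setting.seed_offset, 17)
    vals = vol.values
    if setting.bias_amplitude > 0:
        g = _correlated_texture(rng, vals.shape, vol.spacing, bias_smoothness_mm)
        g = g - g.mean()
        peak = np.abs(g).max()
        if peak > 1e-12:
            g = g * (setting.bias_amplitude / peak)
        field = 1.0 + g
    else:
        rng.standard_normal(vals.shape)  # keep the stream aligned across amplitudes
        field = 1.0

    out = setting.gain * field * vals + setting.offset
    if setting.noise_sigma > 0:
        out = out + rng.normal(0.0, setting.noise_sigma, size=vals.shape)
    return ImageVolume(
        values=out, spacing=vol.spacing, setting=setting, subject_id=clean.subject_id
    )
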