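"""Seeded synthetic B-mode phantom cohorts and layered abdominal geometries.

Real pancreatic ultrasound of the target population is not publicly
available, so every downstream stage is exercised on speckle phantoms whose
class structure mirrors the contrasts reported for diabetic (DM) versus
non-diabetic pancreata: DM regions are smaller, sit slightly shallower and
more medial, are more elongated, and show *more uniform* texture (higher
co-occurrence uniformity and LBP energy, lower entropies), while non-DM
regions carry stronger large-scale echogenicity heterogeneity.

The speckle model is the magnitude of a smoothed complex circular-Gaussian
field (Rayleigh envelope statistics with a tunable correlation length),
log-compressed through a fixed dynamic-range window and quantized to 8 bits.
Class effects act through configurable knobs (see :class:`PhantomSpec` and
:data:`DM_EFFECTS`); their defaults were chosen once to realize the
documented effect directions with comfortable margins and are NOT
literature-calibrated magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .images import PancreasMask, UltrasoundImage
from .thermal import TissueStack, make_layer

DB_WINDOW = (-35.0, 40.0)  # fixed log-compression window, dB


# ---------------------------------------------------------------------------
# speckle primitives

def _unit_gaussian_noise_pair(shape, rng):
    return rng.standard_normal(shape), rng.standard_normal(shape)


def _filter_l2_norm(sigma: float, shape) -> float:
    """L2 norm of the Gaussian smoothing kernel (via an impulse response)."""
    n = min(int(8 * sigma) * 2 + 1, min(shape))
    imp = np.zeros((n, n))
    imp[n // 2, n // 2] = 1.0
    resp = gaussian_filter(imp, sigma)
    return float(np.sqrt((resp**2).sum()))


def _speckle_components(shape, correlation_length: float, rng):
    """Unit-variance real/imaginary parts of a smoothed complex field."""
    if correlation_length < 0:
        raise ValueError("correlation length must be >= 0")
    re, im = _unit_gaussian_noise_pair(shape, rng)
    if correlation_length > 0:
        norm = _filter_l2_norm(correlation_length, shape)
        re = gaussian_filter(re, correlation_length) / norm
        im = gaussian_filter(im, correlation_length) / norm
    return re, im


def speckle_envelope(shape, correlation_length: float, rng,
                     coarse_fraction: float = 0.0,
                     coarse_corr_px: float = 6.0) -> np.ndarray:
    """Pre-log speckle envelope with unit-variance complex components.

    The envelope is the magnitude of a complex circular-Gaussian field whose
    real and imaginary parts are smoothed with a Gaussian of width
    ``correlation_length`` (pixels) and renormalized to unit variance, so the
    pointwise distribution is Rayleigh with scale 1 for every correlation
    length.  ``coarse_fraction`` mixes in a second, longer-scale complex
    field carrying that fraction of the total power (a two-scale scatterer
    population); the sum of circular Gaussians stays circular Gaussian, so
    the marginal remains exactly Rayleigh.
    """
    re, im = _speckle_components(shape, correlation_length, rng)
    if coarse_fraction > 0:
        rc, ic = _speckle_components(shape, coarse_corr_px, rng)
        wf, wc = math.sqrt(1.0 - coarse_fraction), math.sqrt(coarse_fraction)
        re, im = wf * re + wc * rc, wf * im + wc * ic
    return np.hypot(re, im)


def log_compress(envelope: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Fixed-window log compression to [0, 1] with optional gamma shaping."""
    lo, hi = DB_WINDOW
    db = 20.0 * np.log10(np.maximum(envelope, 1e-8))
    x = np.clip((db - lo) / (hi - lo), 0.0, 1.0)
    return x**gamma if gamma != 1.0 else x


def smooth_field(shape, correlation_length: float, rng) -> np.ndarray:
    """Zero-mean, unit-variance smooth random field (shading component)."""
    f = gaussian_filter(rng.standard_normal(shape), correlation_length)
    return (f - f.mean()) / f.std()


def foci_field(shape, density_per_px2: float, radius_px: float, rng) -> np.ndarray:
    """Sparse field of smooth bumps (peak height 1) modelling hypoechoic
    lobular/ductal foci; multiplied into the envelope as exp(-strength * f)."""
    n = rng.poisson(density_per_px2 * shape[0] * shape[1])
    field = np.zeros(shape)
    if n > 0:
        r = rng.integers(0, shape[0], n)
        c = rng.integers(0, shape[1], n)
        np.add.at(field, (r, c), 1.0)
        field = gaussian_filter(field, radius_px) * (2 * math.pi * radius_px**2)
    return field


def generate_speckle(shape, correlation_length: float, seed: int) -> np.ndarray:
    """Envelope-detected speckle image, quantized to uint8 0-255."""
    if len(shape) != 2 or shape[0] < 8 or shape[1] < 8:
        raise ValueError("shape must be at least 8x8")
    rng = np.random.default_rng(seed)
    env = speckle_envelope(shape, correlation_length, rng)
    return np.round(log_compress(env) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# phantom specification

@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic B-mode phantom.

    Defaults describe the non-DM class; :data:`DM_EFFECTS` lists the knobs
    :func:`default_spec` changes for the DM class (smaller/shallower/more
    medial and elongated region; longer single-scale speckle correlation;
    loss of the coarse scatterer scale, hypoechoic foci, pixel noise and
    most shading; few strong hyperechoic spots that stretch the dynamic
    range).
    """

    class_label: str = "non-DM"  # 'DM' or 'non-DM'
    image_shape: tuple = (160, 192)  # rows x cols
    pixel_spacing_mm: float = 0.4
    pancreas_area_mean_mm2: float = 420.0
    pancreas_area_sd_mm2: float = 55.0
    pancreas_depth_mean_cm: float = 3.6
    pancreas_depth_sd_cm: float = 0.4
    lateral_offset_cm: float = 0.0
    aspect_mean: float = 1.8
    aspect_sd: float = 0.15
    texture_smoothing: float = 1.2  # speckle correlation length, px
    coarse_fraction: float = 0.65  # power fraction of the coarse speckle scale
    coarse_corr_px: float = 6.0
    shading_amplitude: float = 0.3  # lognormal large-scale echogenicity
    shading_corr_px: float = 14.0
    foci_strength: float = 1.2  # hypoechoic focal heterogeneity depth
    foci_density_per_mm2: float = 0.08  # foci per mm^2 of image
    foci_radius_px: float = 3.0
    bright_foci_strength: float = 1.2  # sparse hyperechoic spots
    bright_foci_density_per_mm2: float = 0.016
    bright_foci_radius_px: float = 2.0
    pixel_noise: float = 0.28  # independent per-pixel lognormal noise (Np)
    gamma: float = 1.0
    echogenicity_offset: float = 0.0  # gray-level shift inside the mask
    boundary_wobble: float = 0.06  # rms radial Fourier perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_shape[0] < 64 or self.image_shape[1] < 64:
            raise ValueError("image must be at least 64x64")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.texture_smoothing < 0:
            raise ValueError("texture smoothing must be >= 0")
        if self.class_label not in ("DM", "non-DM"):
            raise ValueError("class_label must be 'DM' or 'non-DM'")


#: Multiplicative / additive DM class effects applied on top of the shared
#: baseline by :func:`default_spec`.  All configurable; magnitudes are
#: package choices, not literature values.
DM_EFFECTS = dict(
    area_factor=0.8,
    depth_shift_cm=-0.5,
    lateral_shift_cm=-0.3,
    aspect_factor=1.15,
    smoothing_factor=1.5,
    coarse_fraction=0.0,
    shading_amplitude=0.15,
    foci_strength=0.0,
    bright_foci_strength=3.4,
    bright_foci_density_per_mm2=0.012,
    bright_foci_radius_px=0.9,
    pixel_noise=0.0,
    gamma=1.0,
)


def default_spec(class_label: str, seed: int = 0, effects: dict | None = None,
                 **overrides) -> PhantomSpec:
    """Default per-class phantom spec; ``effects`` overrides the DM knobs."""
    base = PhantomSpec(seed=seed, **overrides)
    if class_label == "non-DM":
        return replace(base, class_label="non-DM")
    eff = dict(DM_EFFECTS)
    if effects:
        eff.update(effects)
    return replace(
        base, class_label="DM",
        pancreas_area_mean_mm2=base.pancreas_area_mean_mm2 * eff["area_factor"],
        pancreas_area_sd_mm2=base.pancreas_area_sd_mm2 * eff["area_factor"],
        pancreas_depth_mean_cm=base.pancreas_depth_mean_cm + eff["depth_shift_cm"],
        lateral_offset_cm=base.lateral_offset_cm + eff["lateral_shift_cm"],
        aspect_mean=base.aspect_mean * eff["aspect_factor"],
        texture_smoothing=base.texture_smoothing * eff["smoothing_factor"],
        coarse_fraction=eff["coarse_fraction"],
        shading_amplitude=eff["shading_amplitude"],
        foci_strength=eff["foci_strength"],
        bright_foci_strength=eff["bright_foci_strength"],
        bright_foci_density_per_mm2=eff["bright_foci_density_per_mm2"],
        bright_foci_radius_px=eff["bright_foci_radius_px"],
        pixel_noise=eff["pixel_noise"],
        gamma=eff["gamma"])


def null_spec(class_label: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Spec with every class effect switched off (null-calibration cohorts)."""
    return replace(default_spec("non-DM", seed=seed, **overrides),
                   class_label=class_label)


# ---------------------------------------------------------------------------
# blob geometry

def _blob_mask(shape, center_rc, semi_axes_px, wobble_rms, rng) -> np.ndarray:
    """Simply-connected ellipse with low-order Fourier boundary perturbation."""
    amps = rng.normal(0.0, wobble_rms / math.sqrt(4), size=4)  # modes 2..5
    phases = rng.uniform(0, 2 * math.pi, size=4)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dy = (rr - center_rc[0]) / semi_axes_px[0]
    dx = (cc - center_rc[1]) / semi_axes_px[1]
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    mod = np.ones_like(theta)
    for m, (a, ph) in enumerate(zip(amps, phases), start=2):
        mod += a * np.cos(m * theta + ph)
    return rho <= mod


def _blob_in_bounds(mask: np.ndarray, margin: int = 2) -> bool:
    if not mask.any():
        return False
    rows, cols = np.nonzero(mask)
    return (rows.min() >= margin and cols.min() >= margin and
            rows.max() < mask.shape[0] - margin and
            cols.max() < mask.shape[1] - margin)


# ---------------------------------------------------------------------------
# phantom generation

def generate_phantom(spec: PhantomSpec
                     ) -> tuple[UltrasoundImage, PancreasMask, str]:
    """One phantom: background speckle, a pancreas-shaped blob at a sampled
    depth, and class-dependent in-mask texture.

    A blob that would exceed the image bounds is retried with a 10% shrink,
    up to 10 attempts, before raising.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    sp_mm = spec.pixel_spacing_mm

    area = max(rng.normal(spec.pancreas_area_mean_mm2, spec.pancreas_area_sd_mm2),
               0.2 * spec.pancreas_area_mean_mm2)
    depth_cm = rng.normal(spec.pancreas_depth_mean_cm, spec.pancreas_depth_sd_cm)
    aspect = max(rng.normal(spec.aspect_mean, spec.aspect_sd), 1.05)
    center_col = shape[1] / 2 + rng.normal(0, 3) + spec.lateral_offset_cm * 10 / sp_mm
    center_row = depth_cm * 10.0 / sp_mm

    # semi-axes in px from area = pi * a_lat * b_vert and a_lat/b_vert = aspect
    mask = None
    scale = 1.0
    for _attempt in range(10):
        b_mm = math.sqrt(area * scale**2 / (math.pi * aspect))
        a_mm = aspect * b_mm
        axes_px = (b_mm / sp_mm, a_mm / sp_mm)  # (vertical, lateral)
        cand = _blob_mask(shape, (center_row, center_col), axes_px,
                          spec.boundary_wobble, np.random.default_rng(
                              rng.integers(2**31)))
        if _blob_in_bounds(cand):
            mask = cand
            break
        scale *= 0.9
    if mask is None:
        raise ValueError("pancreas blob cannot be placed inside the image")

    # background texture: baseline speckle with mild shading
    env_bg = speckle_envelope(shape, 1.2, rng)
    env_bg *= np.exp(0.2 * smooth_field(shape, 14.0, rng) - 0.5 * 0.2**2)
    bg = log_compress(env_bg)

    # in-mask texture: class-dependent smoothing/scale mixture, shading,
    # focal heterogeneity (hypo- and hyperechoic) and gamma
    env_in = speckle_envelope(shape, spec.texture_smoothing, rng,
                              coarse_fraction=spec.coarse_fraction,
                              coarse_corr_px=spec.coarse_corr_px)
    amp = spec.shading_amplitude
    env_in *= np.exp(amp * smooth_field(shape, spec.shading_corr_px, rng)
                     - 0.5 * amp**2)
    if spec.foci_strength > 0 and spec.foci_density_per_mm2 > 0:
        foci = foci_field(shape, spec.foci_density_per_mm2 * sp_mm**2,
                          spec.foci_radius_px, rng)
        env_in *= np.exp(-spec.foci_strength * foci)
    if spec.bright_foci_strength > 0 and spec.bright_foci_density_per_mm2 > 0:
        bright = foci_field(shape, spec.bright_foci_density_per_mm2 * sp_mm**2,
                            spec.bright_foci_radius_px, rng)
        env_in *= np.exp(spec.bright_foci_strength * bright)
    if spec.pixel_noise > 0:
        env_in *= np.exp(spec.pixel_noise * rng.standard_normal(shape))
    inside = log_compress(env_in, gamma=spec.gamma)

    img = np.round(bg * 255)
    img[mask] = np.round(np.clip(inside[mask] * 255 + spec.echogenicity_offset,
                                 0, 255))
    image = UltrasoundImage(pixels=img.astype(np.uint8), pixel_spacing_mm=sp_mm,
                            class_label=spec.class_label)
    return image, PancreasMask(mask=mask, region_label="whole"), spec.class_label


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    n_dm: int = 11
    n_non_dm: int = 11
    images_per_patient: int = 1
    dm_spec: PhantomSpec = field(default_factory=lambda: default_spec("DM"))
    non_dm_spec: PhantomSpec = field(default_factory=lambda: default_spec("non-DM"))
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dm < 1 or self.n_non_dm < 1:
            raise ValueError("each class needs at least one patient")
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")


def _derive_seed(master_seed: int, patient_idx: int, image_idx: int) -> int:
    ss = np.random.SeedSequence(entropy=(master_seed, patient_idx, image_idx))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def generate_cohort(spec: CohortSpec):
    """Deterministic phantom cohort plus a patient metadata table.

    Returns ``(entries, metadata)`` where entries is a list of
    (image, mask, label) tuples and metadata mirrors a clinical cohort table
    (id, dm_status, age, sex, n_images).
    """
    meta_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(spec.master_seed, 0xC0)))
    entries, meta = [], []
    patient_idx = 0
    for label, n, pspec in (("DM", spec.n_dm, spec.dm_spec),
                            ("non-DM", spec.n_non_dm, spec.non_dm_spec)):
        for _ in range(n):
            pid = f"P{patient_idx + 1:03d}"
            age = int(meta_rng.integers(2, 19))
            sex = str(meta_rng.choice(["F", "M"]))
            for img_idx in range(spec.images_per_patient):
                seed = _derive_seed(spec.master_seed, patient_idx, img_idx)
                image, mask, _ = generate_phantom(replace(pspec, seed=seed))
                image.patient_id = pid
                entries.append((image, mask, label))
            meta.append(dict(id=pid, dm_status=label, age=age, sex=sex,
                             n_images=spec.images_per_patient))
            patient_idx += 1
    return entries, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# layered geometry sampling

@dataclass(frozen=True)
class GeometrySpec:
    """Thickness distributions (cm) for the beam-path tissue layers and the
    admissible pancreas proximal-depth range."""

    layer_order: tuple = ("skin", "muscle", "bowel", "blood", "pancreas")
    thickness_mean_cm: dict = field(default_factory=lambda: dict(
        skin=0.2, muscle=1.2, bowel=1.8, blood=0.3, pancreas=2.5))
    thickness_sd_cm: dict = field(default_factory=lambda: dict(
        skin=0.03, muscle=0.3, bowel=0.5, blood=0.1, pancreas=0.4))
    pancreas_depth_range_cm: tuple = (2.0, 6.0)
    max_total_depth_cm: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(self.thickness_mean_cm[n] <= 0 for n in self.layer_order):
            raise ValueError("thickness means must be positive")


def generate_tissue_stack(spec: GeometrySpec, max_tries: int = 200) -> TissueStack:
    """Sample a layered stack whose pancreas proximal boundary falls inside
    the requested depth range (rejection sampling)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pancreas_depth_range_cm
    pre = [n for n in spec.layer_order if n != "pancreas"]
    min_depth = sum(max(spec.thickness_mean_cm[n] - 4 * spec.thickness_sd_cm[n],
                        0.02) for n in pre)
    if min_depth > hi:
        raise ValueError("depth range incompatible with layer thicknesses")
    for _ in range(max_tries):
        thick = {n: max(rng.normal(spec.thickness_mean_cm[n],
                                   spec.thickness_sd_cm[n]), 0.02)
                 for n in spec.layer_order}
        proximal = sum(thick[n] for n in pre)
        total = proximal + thick.get("pancreas", 0.0)
        if lo <= proximal <= hi and total <= spec.max_total_depth_cm:
            return TissueStack(layers=tuple(
                make_layer(n, thick[n]) for n in spec.layer_order))
    raise ValueError("could not sample a stack satisfying the depth range")
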