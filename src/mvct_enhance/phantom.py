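"""Synthetic Catphan-like phantoms and a simulated MVCT/KVCT noise model.

The digital phantom is a uniform circular body disc in air with circular
plugs of differing HU — a simplified stand-in for a physical image-quality
phantom.  The degradation model emulates the two dominant megavoltage-CT
defects relative to diagnostic kilovoltage CT: amplified noise (additive
Gaussian in HU) and reduced soft-tissue contrast (multiplicative
compression of soft-tissue HU toward the body mean), with optional
detector blur.  No scatter or beam-hardening physics is simulated; the
model is deliberately simple but exercises every algorithmic path of the
enhancement pipeline, and everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dictionary import TrainingPair
from .errors import ValidationError
from .evaluation import ROISpec
from .image_io import CTImage, Modality


@dataclass
class PhantomSpec:
    """Geometry of the digital phantom (all lengths in pixels, HU values)."""

    side: int = 256
    body_center: "tuple[float, float] | None" = None
    body_radius: float = 100.0
    body_hu: float = 0.0
    plugs: "list[tuple[tuple[float, float], float, float]] | None" = None
    background_hu: float = -1000.0

    def __post_init__(self) -> None:
        if self.side < 16:
            raise ValidationError("phantom side must be >= 16")
        if self.body_radius <= 0:
            raise ValidationError("body radius must be > 0")
        if self.body_center is None:
            self.body_center = (self.side / 2.0, self.side / 2.0)
        if self.plugs is None:
            self.plugs = default_plugs(self)
        for (pc, pr, _) in self.plugs:
            if pr <= 0:
                raise ValidationError("plug radius must be > 0")
            dist = np.hypot(pc[0] - self.body_center[0], pc[1] - self.body_center[1])
            if dist + pr > self.body_radius:
                raise ValidationError("plug must lie inside the body disc")


def default_plugs(spec: PhantomSpec) -> list:
    """Four plugs at {-100, -40, +40, +120} HU on the disc diagonals.

    The +/-40 pair mimics low-contrast soft-tissue inserts; radius and
    offset scale with the body radius.
    """
    cr, cc = spec.body_center
    off = 0.5 * spec.body_radius
    rad = 0.18 * spec.body_radius
    d = off / np.sqrt(2.0)
    return [
        ((cr - d, cc - d), rad, -100.0),
        ((cr - d, cc + d), rad, -40.0),
        ((cr + d, cc - d), rad, 40.0),
        ((cr + d, cc + d), rad, 120.0),
    ]


@dataclass
class NoiseModel:
    """MVCT-like degradation: contrast compression, blur, Gaussian noise."""

    gaussian_sd: float = 20.0       # HU
    blur_sd: float = 0.0            # pixels
    contrast_scale: float = 1.0     # in (0, 1]; 1 = no compression
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.blur_sd < 0:
            raise ValidationError("noise/blur sd must be >= 0")
        if not (0 < self.contrast_scale <= 1):
            raise ValidationError("contrast_scale must lie in (0, 1]")


def mvct_noise_model(seed: int = 0) -> NoiseModel:
    """Default MVCT degradation: 20 HU noise, 0.5 px blur, 0.7 contrast."""
    return NoiseModel(gaussian_sd=20.0, blur_sd=0.5, contrast_scale=0.7, seed=seed)


def kvct_noise_model(seed: int = 0) -> NoiseModel:
    """Planning-CT-like reference: 2 HU noise, no blur, full contrast."""
    return NoiseModel(gaussian_sd=2.0, blur_sd=0.0, contrast_scale=1.0, seed=seed)


def make_phantom(spec: "PhantomSpec | None" = None, slice_index: int = 0) -> CTImage:
    """Rasterize the piecewise-constant phantom (deterministic)."""
    spec = spec or PhantomSpec()
    rr, cc = np.ogrid[:spec.side, :spec.side]
    img = np.full((spec.side, spec.side), spec.background_hu)
    cr, ccen = spec.body_center
    body = (rr - cr) ** 2 + (cc - ccen) ** 2 <= spec.body_radius**2
    img[body] = spec.body_hu
    for (pc, pr, hu) in spec.plugs:
        m = (rr - pc[0]) ** 2 + (cc - pc[1]) ** 2 <= pr**2
        img[m] = hu
    return CTImage(img, modality=Modality.SYNTHETIC, slice_index=slice_index)


def body_mask(spec: PhantomSpec) -> np.ndarray:
    rr, cc = np.ogrid[:spec.side, :spec.side]
    cr, ccen = spec.body_center
    return (rr - cr) ** 2 + (cc - ccen) ** 2 <= spec.body_radius**2


_SOFT_RANGE = (-300.0, 300.0)  # HU band treated as soft tissue


def _degrade(clean: CTImage, noise: NoiseModel, rng: np.random.Generator,
             modality: Modality) -> CTImage:
    hu = clean.pixels.copy()
    soft = (hu >= _SOFT_RANGE[0]) & (hu <= _SOFT_RANGE[1])
    if noise.contrast_scale < 1 and soft.any():
        centre = hu[soft].mean()
        hu[soft] = centre + noise.contrast_scale * (hu[soft] - centre)
    if noise.blur_sd > 0:
        hu = gaussian_filter(hu, noise.blur_sd)
    if noise.gaussian_sd > 0:
        hu = hu + rng.normal(0.0, noise.gaussian_sd, hu.shape)
    return CTImage(hu, clean.spacing, modality, clean.slice_index)


def simulate_mvct(clean: CTImage, noise: "NoiseModel | None" = None) -> CTImage:
    """Apply the MVCT degradation model (seeded, reproducible)."""
    noise = noise or mvct_noise_model()
    rng = np.random.default_rng(noise.seed)
    return _degrade(clean, noise, rng, Modality.MVCT)


def simulate_kvct(clean: CTImage, noise: "NoiseModel | None" = None) -> CTImage:
    """Apply the small-noise KVCT reference model."""
    noise = noise or kvct_noise_model()
    rng = np.random.default_rng(noise.seed)
    return _degrade(clean, noise, rng, Modality.KVCT)


def make_training_pairs(spec: "PhantomSpec | None" = None,
                        n_slices: int = 5,
                        mvct: "NoiseModel | None" = None,
                        kvct: "NoiseModel | None" = None,
                        seed: int = 0) -> list[TrainingPair]:
    """Registered KVCT/MVCT slice pairs with per-slice independent noise.

    ``n_slices`` must reach the dictionary atom depth (default 5).
    """
    spec = spec or PhantomSpec()
    mvct = mvct or mvct_noise_model()
    kvct = kvct or kvct_noise_model()
    if n_slices < 1:
        raise ValidationError("n_slices must be >= 1")
    ss = np.random.SeedSequence(seed)
    pairs = []
    for i, child in enumerate(ss.spawn(n_slices)):
        rng_k, rng_m = [np.random.default_rng(s) for s in child.spawn(2)]
        clean = make_phantom(spec, slice_index=i)
        hq = _degrade(clean, kvct, rng_k, Modality.KVCT)
        lq = _degrade(clean, mvct, rng_m, Modality.MVCT)
        pairs.append(TrainingPair(hq, lq))
    return pairs


def canonical_rois(spec: PhantomSpec) -> tuple[ROISpec, ROISpec]:
    """Soft-tissue target/background ROIs: inside the low-contrast +40 HU
    plug, and an adjacent uniform body region of the same size."""
    target_plug = min(spec.plugs, key=lambda p: abs(p[2] - 40.0))
    (pr_r, pr_c), prad, _ = target_plug
    roi_rad = max(3.0, 0.6 * prad)
    cr, cc = spec.body_center
    # plugs sit on the disc diagonals, so an axis direction is plug-free
    bg_center = (cr, cc - 0.5 * spec.body_radius)
    target = ROISpec("circle", (pr_r, pr_c), radius=roi_rad, role="target")
    background = ROISpec("circle", bg_center, radius=roi_rad, role="background")
    return target, background


def make_eval_scene(spec: "PhantomSpec | None" = None,
                    noise: "NoiseModel | None" = None,
                    seed: int = 0):
    """(clean, mvct, target ROI, background ROI) for one evaluation run."""
    spec = spec or PhantomSpec()
    noise = noise or mvct_noise_model()
    rng = np.random.default_rng(seed)
    clean = make_phantom(spec)
    noisy = _degrade(clean, noise, rng, Modality.MVCT)
    target, background = canonical_rois(spec)
    return clean, noisy, target, background
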