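"""Image-quality evaluation: CNR, canny edge maps, batch statistics and the
HU-density-stability proxy.

The contrast-to-noise ratio between a target and a background region of
interest is

    CNR = 2 |A_t - A_b| / sqrt(a_t^2 + a_b^2)

with A the ROI means and a the (population) ROI standard deviations.  It
is computed on HU values so results are comparable across acquisitions,
and is invariant to adding a constant to, or positively rescaling, the
whole image.

Because enhanced CT is only clinically useful if the density (HU) content
it feeds to dose calculation is unchanged, :func:`hu_stability` reports
the per-ROI mean HU drift, the RMS drift over a body mask and the maximum
absolute drift between an original and an enhanced slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .image_io import CTImage


@dataclass
class ROISpec:
    """A circular or rectangular region of interest.

    ``extents`` is (height, width) in pixels for rectangles; ``radius`` is
    in pixels for circles.  ROIs must lie fully inside the image and cover
    at least 8 pixels.
    """

    shape: str                      # "circle" | "rectangle"
    center: tuple[float, float]     # (row, col)
    radius: "float | None" = None
    extents: "tuple[int, int] | None" = None
    role: str = "target"            # "target" | "background"

    def __post_init__(self) -> None:
        if self.shape not in {"circle", "rectangle"}:
            raise ValidationError("ROI shape must be circle or rectangle")
        if self.shape == "circle" and (self.radius is None or self.radius <= 0):
            raise ValidationError("circle ROI needs a positive radius")
        if self.shape == "rectangle" and (
                self.extents is None or min(self.extents) < 1):
            raise ValidationError("rectangle ROI needs positive extents")
        if self.role not in {"target", "background"}:
            raise ValidationError("ROI role must be target or background")

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        r0, c0 = self.center
        if self.shape == "circle":
            rad = float(self.radius)
            if (r0 - rad < -0.5 or c0 - rad < -0.5
                    or r0 + rad > image_shape[0] - 0.5
                    or c0 + rad > image_shape[1] - 0.5):
                raise ValidationError("ROI extends outside the image")
            rr, cc = np.ogrid[:image_shape[0], :image_shape[1]]
            m = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        else:
            h, w = self.extents
            top, left = int(round(r0 - h / 2)), int(round(c0 - w / 2))
            if top < 0 or left < 0 or top + h > image_shape[0] or left + w > image_shape[1]:
                raise ValidationError("ROI extends outside the image")
            m = np.zeros(image_shape, dtype=bool)
            m[top:top + h, left:left + w] = True
        if m.sum() < 8:
            raise ValidationError("ROI must cover at least 8 pixels")
        return m


@dataclass
class CNRResult:
    cnr: float
    mean_target: float
    mean_background: float
    sd_target: float
    sd_background: float


@dataclass
class StabilityReport:
    roi_mean_diff: list[float]      # enhanced - original, per ROI
    rms_diff: float                 # over the body mask
    max_abs_diff: float

    def __post_init__(self) -> None:
        if self.rms_diff < 0:
            raise ValidationError("RMS must be >= 0")


def _pixels(img: "CTImage | np.ndarray") -> np.ndarray:
    return img.pixels if isinstance(img, CTImage) else np.asarray(img, float)


def cnr(img: "CTImage | np.ndarray", target: ROISpec, background: ROISpec,
        ddof: int = 0) -> CNRResult:
    """Contrast-to-noise ratio between two disjoint ROIs (population sd)."""
    px = _pixels(img)
    mt = target.mask(px.shape)
    mb = background.mask(px.shape)
    if np.any(mt & mb):
        raise ValidationError("target and background ROIs overlap")
    at, ab = float(px[mt].mean()), float(px[mb].mean())
    st, sb = float(px[mt].std(ddof=ddof)), float(px[mb].std(ddof=ddof))
    denom = np.hypot(st, sb)
    if denom == 0:
        # noiseless degenerate: equal means -> no contrast, else unbounded
        value = 0.0 if at == ab else np.inf
    else:
        value = 2.0 * abs(at - ab) / denom
    return CNRResult(float(value), at, ab, st, sb)


def edge_map(img: "CTImage | np.ndarray", low: float = 0.1, high: float = 0.2,
             sigma_blur: float = 1.4) -> tuple[np.ndarray, int]:
    """Canny edge map; thresholds are fractions of the gradient maximum.

    Gaussian blur -> Sobel gradient -> non-maximum suppression ->
    hysteresis, via scikit-image; deterministic for fixed inputs.
    """
    if not (0 < low <= high):
        raise ValidationError("need 0 < low <= high")
    from scipy.ndimage import gaussian_filter
    from skimage import feature, filters

    px = _pixels(img)
    span = px.max() - px.min()
    x = (px - px.min()) / span if span > 0 else np.zeros_like(px)
    gmax = float(filters.sobel(gaussian_filter(x, sigma_blur)).max())
    if gmax == 0:
        return np.zeros(px.shape, dtype=bool), 0
    edges = feature.canny(x, sigma=sigma_blur,
                          low_threshold=low * gmax, high_threshold=high * gmax)
    return edges, int(edges.sum())


def batch_cnr(series_pairs, target: ROISpec, background: ROISpec) -> dict:
    """Per-arm CNR summary and a two-sided paired t-test.

    ``series_pairs`` is a list of (original, enhanced) slices sharing the
    ROI layout.  Returns means/sds of both arms and the paired t statistic
    on per-slice CNR differences; identical arms are reported as "no
    difference" with t = 0, p = 1.
    """
    if len(series_pairs) < 2:
        raise ValidationError("need at least 2 slice pairs")
    orig = np.array([cnr(a, target, background).cnr for a, _ in series_pairs])
    enh = np.array([cnr(b, target, background).cnr for _, b in series_pairs])
    diff = enh - orig
    if np.allclose(diff, 0):
        t, p, note = 0.0, 1.0, "no difference"
    else:
        t, p = stats.ttest_rel(enh, orig)
        t, p, note = float(t), float(p), ""
    return {
        "n": len(series_pairs),
        "original_mean": float(orig.mean()), "original_sd": float(orig.std(ddof=1)),
        "enhanced_mean": float(enh.mean()), "enhanced_sd": float(enh.std(ddof=1)),
        "mean_difference": float(diff.mean()),
        "t": t, "p": p, "note": note,
    }


def hu_stability(original: "CTImage | np.ndarray", enhanced: "CTImage | np.ndarray",
                 rois: list[ROISpec], body_mask: "np.ndarray | None" = None) -> StabilityReport:
    """HU drift of the enhanced image relative to the original."""
    a = _pixels(original)
    b = _pixels(enhanced)
    if a.shape != b.shape:
        raise ValidationError("images must share one grid")
    d = b - a
    mask = np.ones(a.shape, bool) if body_mask is None else np.asarray(body_mask, bool)
    roi_means = [float(d[roi.mask(a.shape)].mean()) for roi in rois]
    rms = float(np.sqrt(np.mean(d[mask] ** 2))) if mask.any() else 0.0
    return StabilityReport(roi_means, rms, float(np.abs(d).max()))
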