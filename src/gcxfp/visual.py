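"""Composite class images and colorized fuzzy-ratio difference rendering.

Pairwise comparison of aligned class composites: the per-point signed
difference (analyzed − reference) is mapped into a hue/intensity/saturation
color space — green where the analyzed class responds more, red where the
reference does, white where the detector responses are nearly equal.
Saturation grows as |d| / (|d| + ε), so the "nearly equal" band is set by ε
(default three times the composite noise SD); brightness falls off with the
log-scaled magnitude so large differences stand out as dark saturated
patches on a white field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .peaks import estimate_noise

_GREEN_HUE = 1.0 / 3.0
_RED_HUE = 0.0


def composite_class_image(rasters: list[np.ndarray]) -> np.ndarray:
    """Per-point mean raster over the (aligned) runs of one class."""
    if not rasters:
        raise ValueError("class composite requires at least one run")
    shapes = {np.asarray(r).shape for r in rasters}
    if len(shapes) != 1:
        raise ValueError("class rasters must share a shape")
    return np.stack([np.asarray(r, dtype=float) for r in rasters]).mean(axis=0)


@dataclass
class DifferenceImage:
    """Signed difference raster and its fuzzy-ratio rendering."""

    difference: np.ndarray      # analyzed − reference
    rgb: np.ndarray             # float in [0, 1], shape (n, m, 3)
    epsilon: float

    def to_png(self, path) -> None:
        img = (np.clip(self.rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(img, mode="RGB").save(path, format="PNG")


def fuzzy_ratio_image(analyzed: np.ndarray, reference: np.ndarray,
                      epsilon: float | None = None,
                      log_intensity: bool = True,
                      darkness: float = 0.6) -> DifferenceImage:
    """Colorized fuzzy-ratio rendering of two aligned rasters.

    hue: green for d > 0, red for d < 0.  saturation = |d| / (|d| + ε),
    so near-equal points render white.  brightness drops with the
    (log-scaled) magnitude of the difference.  Antisymmetric: swapping the
    arguments exchanges green and red exactly, and adding a constant to
    both rasters leaves the rendering unchanged.
    """
    a = np.asarray(analyzed, dtype=float)
    r = np.asarray(reference, dtype=float)
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {r.shape}")
    d = a - r
    if epsilon is None:
        epsilon = 3.0 * max(estimate_noise(a), estimate_noise(r))
        if epsilon == 0.0:
            epsilon = 1.0
    mag = np.abs(d)
    sat = mag / (mag + epsilon)
    dmax = float(mag.max())
    if dmax > 0:
        level = (np.log1p(mag) / np.log1p(dmax)) if log_intensity else mag / dmax
    else:
        level = np.zeros_like(mag)
    value = 1.0 - darkness * level
    hue = np.where(d > 0, _GREEN_HUE, _RED_HUE)
    hsv = np.stack([hue, sat, value], axis=-1)
    return DifferenceImage(difference=d, rgb=hsv_to_rgb(hsv), epsilon=float(epsilon))
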