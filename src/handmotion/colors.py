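"""Color models for glove detection.

Gloves are identified by hue/saturation/value ranges rather than RGB
distance, so that detection tolerates brightness changes across a video.
Hue is expressed in degrees on [0, 360) and may wrap around 0 (reds).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorSpec",
    "specs_overlap",
    "check_separability",
    "GREEN_GLOVE",
    "ORANGE_GLOVE",
    "DEFAULT_DISTRACTOR_RGBS",
]


@dataclass(frozen=True)
class ColorSpec:
    """An HSV box describing one glove color.

    Parameters
    ----------
    name:
        Label for the hand this color marks (e.g. ``"dominant"``).
    hue_range:
        ``(low, high)`` in degrees.  ``low > high`` denotes a range that
        wraps through 0/360 (e.g. ``(340, 20)`` for red).
    saturation_range, value_range:
        ``(low, high)`` on [0, 1].
    """

    name: str
    hue_range: tuple[float, float]
    saturation_range: tuple[float, float] = (0.35, 1.0)
    value_range: tuple[float, float] = (0.15, 1.0)

    def __post_init__(self) -> None:
        for lo, hi, label in (
            (*self.saturation_range, "saturation"),
            (*self.value_range, "value"),
        ):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"{label}_range must satisfy 0 <= low < high <= 1")
        h0, h1 = self.hue_range
        if not (0.0 <= h0 <= 360.0 and 0.0 <= h1 <= 360.0):
            raise ValueError("hue_range endpoints must lie in [0, 360]")
        if h0 == h1:
            raise ValueError("hue_range must be non-empty")

    @property
    def wraps(self) -> bool:
        return self.hue_range[0] > self.hue_range[1]

    def mask(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside this HSV box.

        ``hsv`` is an (H, W, 3) float array with hue scaled to [0, 1]
        (the scikit-image convention) and saturation/value on [0, 1].
        """
        hue_deg = hsv[..., 0] * 360.0
        h0, h1 = self.hue_range
        if self.wraps:
            hue_ok = (hue_deg >= h0) | (hue_deg <= h1)
        else:
            hue_ok = (hue_deg >= h0) & (hue_deg <= h1)
        s0, s1 = self.saturation_range
        v0, v1 = self.value_range
        return (
            hue_ok
            & (hsv[..., 1] >= s0)
            & (hsv[..., 1] <= s1)
            & (hsv[..., 2] >= v0)
            & (hsv[..., 2] <= v1)
        )

    def contains_rgb(self, rgb: tuple[int, int, int]) -> bool:
        """Whether an 8-bit RGB triplet falls inside this HSV box."""
        h, s, v = colorsys.rgb_to_hsv(*(c / 255.0 for c in rgb))
        px = np.array([[[h, s, v]]])
        return bool(self.mask(px)[0, 0])


def _hue_intervals(spec: ColorSpec) -> list[tuple[float, float]]:
    h0, h1 = spec.hue_range
    if spec.wraps:
        return [(h0, 360.0), (0.0, h1)]
    return [(h0, h1)]


def specs_overlap(a: ColorSpec, b: ColorSpec) -> bool:
    """True when the two HSV boxes intersect (some pixel matches both)."""
    hue_hit = any(
        ia[0] < ib[1] and ib[0] < ia[1]
        for ia in _hue_intervals(a)
        for ib in _hue_intervals(b)
    )
    sat_hit = a.saturation_range[0] < b.saturation_range[1] and b.saturation_range[0] < a.saturation_range[1]
    val_hit = a.value_range[0] < b.value_range[1] and b.value_range[0] < a.value_range[1]
    return hue_hit and sat_hit and val_hit


def check_separability(specs: list[ColorSpec]) -> None:
    """Raise ``ValueError`` if any two specs could claim the same pixel."""
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            if specs_overlap(a, b):
                raise ValueError(
                    f"color specs {a.name!r} and {b.name!r} overlap in HSV space; "
                    "gloves must be separable"
                )


def rgb_frame_to_hsv(frame: np.ndarray) -> np.ndarray:
    """Vectorized RGB -> HSV for (H, W, 3) frames, hue on [0, 1].

    Numerically equivalent to ``skimage.color.rgb2hsv`` but several times
    faster on whole frames, which dominates video tracking time.  uint8
    input is scaled to [0, 1]; float input is assumed already on [0, 1].
    """
    rgb = np.asarray(frame)
    if rgb.dtype == np.uint8:
        rgb = rgb.astype(np.float32) / 255.0
    else:
        rgb = rgb.astype(np.float32, copy=False)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = np.max(rgb, axis=-1)
    c = v - np.min(rgb, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(v > 0, c / v, 0.0)
        safe_c = np.where(c > 0, c, 1.0)
        h = np.where(
            v == r,
            (g - b) / safe_c,
            np.where(v == g, 2.0 + (b - r) / safe_c, 4.0 + (r - g) / safe_c),
        )
    h = np.where(c > 0, (h / 6.0) % 1.0, 0.0)
    return np.stack([h, s, v], axis=-1)


# Defaults mirroring the study convention: green marks the dominant hand,
# orange the non-dominant hand.
GREEN_GLOVE = ColorSpec("dominant", hue_range=(85.0, 165.0))
ORANGE_GLOVE = ColorSpec("nondominant", hue_range=(10.0, 50.0))

# Render colors used by the synthetic scene: chosen to sit near the center
# of the default HSV boxes (or, for distractors, outside both).
GREEN_GLOVE_RGB = (30, 200, 70)
ORANGE_GLOVE_RGB = (245, 140, 20)
DEFAULT_DISTRACTOR_RGBS = [(40, 80, 230), (200, 40, 200)]  # blue, magenta
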