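"""Per-frame glove detection and whole-video hand tracking.

Each frame is processed independently: pixels inside a glove's HSV box are
grouped into connected components, the largest component (if big enough) is
kept, and the hand position is the center of that component's minimal
axis-aligned bounding box.  Statelessness per frame is what gives the
tracker its lock-on/re-acquire behavior: a hand that leaves the field is
simply absent until its color reappears.

Coordinates use the image convention: origin at the top-left corner,
x to the right, y down, in pixel units; frame indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .colors import ColorSpec, check_separability, rgb_frame_to_hsv

__all__ = [
    "FrameDetection",
    "HandTrack",
    "detect_hand",
    "track_video",
    "track_frames",
    "read_frames",
    "default_min_pixels",
    "write_tracks_csv",
    "read_tracks_csv",
]

# Reference frame for the min_pixels default: 30 px at 1080p, scaled by area.
_REF_AREA = 1920 * 1080
_REF_MIN_PIXELS = 30


def default_min_pixels(frame_shape: tuple[int, ...]) -> int:
    """Minimum blob size threshold, scaled from 30 px at a 1080p frame."""
    area = frame_shape[0] * frame_shape[1]
    return max(1, round(_REF_MIN_PIXELS * area / _REF_AREA))


@dataclass(frozen=True)
class FrameDetection:
    """One hand's detection result in one frame.

    When ``valid`` is False no glove-colored blob of sufficient size was
    found and ``centroid``/``bbox`` are ``None``.
    """

    frame_index: int
    hand: str
    valid: bool
    centroid: tuple[float, float] | None = None
    bbox: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1), inclusive
    pixel_count: int = 0


class HandTrack:
    """Centroid sequence for one hand, one record per frame.

    Attributes
    ----------
    hand : str
        Hand label.
    frame_rate : float
        Frames per second of the source video.
    valid : ndarray of bool, shape (n_frames,)
    x, y : ndarray of float, shape (n_frames,)
        Centroid coordinates; NaN where ``valid`` is False.
    pixel_count : ndarray of int
    bbox : ndarray of float, shape (n_frames, 4)
        (x0, y0, x1, y1); NaN rows where invalid.
    """

    def __init__(
        self,
        hand: str,
        frame_rate: float,
        valid: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        pixel_count: np.ndarray | None = None,
        bbox: np.ndarray | None = None,
    ) -> None:
        if frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        n = len(valid)
        if len(x) != n or len(y) != n:
            raise ValueError("valid, x, y must have equal length")
        self.hand = hand
        self.frame_rate = float(frame_rate)
        self.valid = np.asarray(valid, dtype=bool)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.pixel_count = (
            np.asarray(pixel_count, dtype=int) if pixel_count is not None else np.zeros(n, int)
        )
        self.bbox = np.asarray(bbox, dtype=float) if bbox is not None else np.full((n, 4), np.nan)

    def __len__(self) -> int:
        return len(self.valid)

    @property
    def n_frames(self) -> int:
        return len(self.valid)

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Maximal runs of invalid frames as inclusive (start, end) pairs.

        The gaps exactly partition the invalid frames.
        """
        out: list[tuple[int, int]] = []
        invalid = ~self.valid
        i = 0
        n = len(invalid)
        while i < n:
            if invalid[i]:
                j = i
                while j + 1 < n and invalid[j + 1]:
                    j += 1
                out.append((i, j))
                i = j + 1
            else:
                i += 1
        return out

    @classmethod
    def from_detections(
        cls, hand: str, frame_rate: float, detections: Iterable[FrameDetection]
    ) -> "HandTrack":
        dets = list(detections)
        n = len(dets)
        valid = np.zeros(n, bool)
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        npx = np.zeros(n, int)
        bbox = np.full((n, 4), np.nan)
        for i, d in enumerate(dets):
            if d.frame_index != i:
                raise ValueError("detections must be consecutive from frame 0")
            valid[i] = d.valid
            npx[i] = d.pixel_count
            if d.valid:
                x[i], y[i] = d.centroid  # type: ignore[misc]
                bbox[i] = d.bbox
        return cls(hand, frame_rate, valid, x, y, npx, bbox)

    def to_frame(self) -> pd.DataFrame:
        bbox = self.bbox
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "hand": self.hand,
                "valid": self.valid.astype(int),
                "x": self.x,
                "y": self.y,
                "bbox_x0": bbox[:, 0],
                "bbox_y0": bbox[:, 1],
                "bbox_x1": bbox[:, 2],
                "bbox_y1": bbox[:, 3],
                "pixel_count": self.pixel_count,
            }
        )


def detect_hand(frame: np.ndarray, spec: ColorSpec, min_pixels: int | None = None,
                frame_index: int = 0) -> FrameDetection:
    """Detect one glove in one frame.

    The largest connected component of in-range pixels is selected (small
    specks of a similar color elsewhere in the scene cannot steal the
    detection), its minimal axis-aligned bounding box is computed, and the
    hand position is the bbox center.

    Parameters
    ----------
    frame:
        (H, W, 3) RGB image, uint8 or float in [0, 1].
    spec:
        HSV color box for this glove.
    min_pixels:
        Minimum component size for a valid detection; defaults to a
        frame-area-scaled threshold (30 px at 1080p).
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3 or frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError("frame must be a non-empty (H, W, 3) color image")
    if min_pixels is None:
        min_pixels = default_min_pixels(frame.shape)
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")

    hsv = rgb_frame_to_hsv(frame)
    return _detect_in_hsv(hsv, spec, min_pixels, frame_index)


def _detect_in_hsv(
    hsv: np.ndarray, spec: ColorSpec, min_pixels: int, frame_index: int
) -> FrameDetection:
    """Detection on an already-converted HSV frame (shared between hands)."""
    mask = spec.mask(hsv)
    if not mask.any():
        return FrameDetection(frame_index, spec.name, valid=False)

    labels, n_comp = cc_label(mask, connectivity=2, return_num=True)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    best = int(np.argmax(counts))
    if counts[best] < min_pixels:
        return FrameDetection(frame_index, spec.name, valid=False)

    ys, xs = np.nonzero(labels == best)
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    centroid = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
    return FrameDetection(
        frame_index,
        spec.name,
        valid=True,
        centroid=centroid,
        bbox=(x0, y0, x1, y1),
        pixel_count=int(counts[best]),
    )


def read_frames(path: str | Path) -> Iterator[np.ndarray]:
    """Yield RGB frames from a multi-frame image file.

    Multi-page TIFF is the native container written by the synthetic
    renderer; any other multi-frame format imageio can decode also works.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            for page in tf.pages:
                yield page.asarray()
    else:
        import imageio.v3 as iio

        for frame in iio.imiter(path):
            yield np.asarray(frame)


def track_frames(
    frames: Iterable[np.ndarray],
    specs: tuple[ColorSpec, ColorSpec],
    frame_rate: float,
    min_pixels: int | None = None,
) -> tuple[HandTrack, HandTrack]:
    """Run per-frame detection for two gloves over an iterable of frames."""
    check_separability(list(specs))
    dets: tuple[list[FrameDetection], list[FrameDetection]] = ([], [])
    i = -1
    for i, frame in enumerate(frames):
        frame = np.asarray(frame)
        if frame.ndim != 3 or frame.shape[-1] != 3:
            raise ValueError(f"frame {i} is not a color image")
        if min_pixels is None:
            min_pixels = default_min_pixels(frame.shape)
        hsv = rgb_frame_to_hsv(frame)
        for k, spec in enumerate(specs):
            dets[k].append(_detect_in_hsv(hsv, spec, min_pixels, frame_index=i))
    if not dets[0]:
        raise ValueError("video contains no frames")
    return tuple(  # type: ignore[return-value]
        HandTrack.from_detections(spec.name, frame_rate, d)
        for spec, d in zip(specs, dets)
    )


def track_video(
    path: str | Path,
    specs: tuple[ColorSpec, ColorSpec],
    frame_rate: float = 50.0,
    min_pixels: int | None = None,
) -> tuple[HandTrack, HandTrack]:
    """Track both gloves through a video file.

    Detection is purely per-frame, so identical input bytes always produce
    identical tracks, and a hand re-entering the field is re-acquired with
    no carried state.
    """
    return track_frames(read_frames(path), specs, frame_rate, min_pixels)


def write_tracks_csv(tracks: Iterable[HandTrack], path: str | Path) -> None:
    """Write one or more hand tracks to a single CSV file."""
    df = pd.concat([t.to_frame() for t in tracks], ignore_index=True)
    df.to_csv(path, index=False)


def read_tracks_csv(path: str | Path, frame_rate: float) -> dict[str, HandTrack]:
    """Read tracks written by :func:`write_tracks_csv`, keyed by hand label."""
    df = pd.read_csv(path)
    out: dict[str, HandTrack] = {}
    for hand, g in df.groupby("hand", sort=False):
        g = g.sort_values("frame_index")
        bbox = g[["bbox_x0", "bbox_y0", "bbox_x1", "bbox_y1"]].to_numpy(float)
        out[str(hand)] = HandTrack(
            str(hand),
            frame_rate,
            g["valid"].to_numpy(bool),
            g["x"].to_numpy(float),
            g["y"].to_numpy(float),
            g["pixel_count"].to_numpy(int),
            bbox,
        )
    return out
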