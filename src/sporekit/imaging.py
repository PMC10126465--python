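"""Spore localisation and intensity-trace extraction from time-lapse stacks.

Implements the trace-level half of the single-spore germination assay:
find each spore in the first phase-contrast frame, average a 20x20-pixel
window over it in every frame, and endpoint-normalize the resulting
trace (first frame to 1, recording tail to 0) so that kinetic
breakpoints can be fitted on a common scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImageStack",
    "SporeROI",
    "IntensityTrace",
    "DetectionResult",
    "detect_spores",
    "extract_trace",
    "normalize_trace",
    "extract_all_traces",
    "read_stack",
    "write_stack",
    "traces_to_frame",
]

HALF_WINDOW = 10  # the 20x20 analysis window is [c-10, c+10) per axis


@dataclass
class ImageStack:
    """Ordered grayscale frames with a uniform inter-frame interval."""

    frames: np.ndarray  # (n_frames, height, width)
    frame_interval: float  # minutes
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.frames.shape[0] < 2:
            raise ValueError("stack needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError("pixel values outside bit-depth range")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class SporeROI:
    """A 20x20-pixel analysis window centred on one spore."""

    spore_id: str
    x: int
    y: int

    def window(self) -> tuple[slice, slice]:
        return (
            slice(self.y - HALF_WINDOW, self.y + HALF_WINDOW),
            slice(self.x - HALF_WINDOW, self.x + HALF_WINDOW),
        )

    def inside(self, height: int, width: int) -> bool:
        return (
            self.x - HALF_WINDOW >= 0
            and self.x + HALF_WINDOW <= width
            and self.y - HALF_WINDOW >= 0
            and self.y + HALF_WINDOW <= height
        )


@dataclass
class IntensityTrace:
    """Per-spore mean-window intensity over time.

    ``normalized`` maps the first frame to 1 and the mean of the last
    ``tail_frames`` raw values to 0; it is defined only for germination
    candidates (traces whose endpoint drop clears the threshold).
    """

    spore_id: str
    times: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray | None = None
    germination_candidate: bool | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.times.shape != self.raw.shape:
            raise ValueError("times and raw must have equal length")


@dataclass
class DetectionResult:
    """Accepted ROIs plus the count of edge-clipped detections."""

    rois: list[SporeROI]
    n_edge_discarded: int = 0

    def __iter__(self) -> Iterator[SporeROI]:
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)


def detect_spores(
    first_frame: np.ndarray,
    smoothing_sd: float = 2.0,
    threshold_k: float = 5.0,
    min_separation: int = 20,
) -> DetectionResult:
    """Locate spore centers in the first frame.

    The frame is Gaussian-smoothed, background is estimated as the
    median and its spread as MAD * 1.4826; local maxima above
    ``median + threshold_k * robust_sd`` become candidates.  Candidates
    are accepted greedily in order of decreasing height (ties broken
    toward the lexicographically smaller (y, x)) subject to a pairwise
    separation of ``min_separation`` pixels.  Detections whose 20x20
    window would cross the frame edge are discarded and counted.
    """
    frame = np.asarray(first_frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    smooth = ndimage.gaussian_filter(frame, smoothing_sd)
    med = np.median(smooth)
    mad = np.median(np.abs(smooth - med))
    threshold = med + threshold_k * mad * 1.4826

    local_max = smooth == ndimage.maximum_filter(smooth, size=3)
    cand = np.argwhere(local_max & (smooth > threshold))  # (y, x) rows
    if cand.size == 0:
        return DetectionResult([], 0)
    heights = smooth[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -heights))
    cand = cand[order]

    kept: list[tuple[int, int]] = []
    sep2 = min_separation * min_separation
    for y, x in cand:
        ok = True
        for ky, kx in kept:
            if (ky - y) ** 2 + (kx - x) ** 2 < sep2:
                ok = False
                break
        if ok:
            kept.append((int(y), int(x)))

    h, w = frame.shape
    rois: list[SporeROI] = []
    n_clipped = 0
    for i, (y, x) in enumerate(sorted(kept)):
        roi = SporeROI(spore_id=f"roi_{i:04d}", x=x, y=y)
        if roi.inside(h, w):
            rois.append(roi)
        else:
            n_clipped += 1
    # renumber after discarding clipped windows
    rois = [dataclasses.replace(r, spore_id=f"roi_{i:04d}") for i, r in enumerate(rois)]
    return DetectionResult(rois, n_clipped)


def extract_trace(stack: ImageStack, roi: SporeROI) -> IntensityTrace:
    """Mean intensity of the ROI's 20x20 window in every frame."""
    _, h, w = stack.frames.shape
    if not roi.inside(h, w):
        raise ValueError(f"{roi.spore_id}: window out of bounds")
    ys, xs = roi.window()
    raw = stack.frames[:, ys, xs].mean(axis=(1, 2))
    return IntensityTrace(spore_id=roi.spore_id, times=stack.times, raw=raw)


def normalize_trace(
    trace: IntensityTrace,
    drop_fraction_threshold: float = 0.4,
    tail_frames: int = 4,
) -> IntensityTrace:
    """Endpoint-normalize a raw trace.

    With ``I0 = raw[0]`` and ``Iend`` the mean of the last
    ``tail_frames`` raw values, a trace is a germination candidate when
    the relative drop ``(I0 - Iend) / I0`` reaches
    ``drop_fraction_threshold``; candidates get
    ``normalized = (raw - Iend) / (I0 - Iend)`` (first value exactly 1,
    tail mean 0).  Non-candidates keep ``normalized=None`` — forcing a
    flat trace to end at 0 would fabricate a release event.
    """
    raw = trace.raw
    if tail_frames < 1 or tail_frames > raw.size:
        raise ValueError("tail_frames must be in [1, n_frames]")
    i0 = raw[0]
    iend = raw[-tail_frames:].mean()
    if i0 == iend or i0 == 0:
        return dataclasses.replace(trace, normalized=None, germination_candidate=False)
    drop = (i0 - iend) / i0
    if drop < drop_fraction_threshold:
        return dataclasses.replace(trace, normalized=None, germination_candidate=False)
    normalized = (raw - iend) / (i0 - iend)
    return dataclasses.replace(trace, normalized=normalized, germination_candidate=True)


def extract_all_traces(
    stack: ImageStack,
    rois: Sequence[SporeROI] | DetectionResult,
    drop_fraction_threshold: float = 0.4,
    tail_frames: int = 4,
) -> list[IntensityTrace]:
    """Extract and normalize one trace per ROI."""
    return [
        normalize_trace(
            extract_trace(stack, roi),
            drop_fraction_threshold=drop_fraction_threshold,
            tail_frames=tail_frames,
        )
        for roi in rois
    ]


# ---------------------------------------------------------------------------
# I/O


def read_stack(path: str, frame_interval: float = 0.25, bit_depth: int = 12) -> ImageStack:
    """Read a stack from multi-page TIFF or NPZ (keys: frames,
    frame_interval, bit_depth)."""
    if str(path).endswith(".npz"):
        with np.load(path) as data:
            return ImageStack(
                frames=data["frames"],
                frame_interval=float(data["frame_interval"]) if "frame_interval" in data else frame_interval,
                bit_depth=int(data["bit_depth"]) if "bit_depth" in data else bit_depth,
            )
    import tifffile

    frames = tifffile.imread(path)
    return ImageStack(frames=frames, frame_interval=frame_interval, bit_depth=bit_depth)


def write_stack(path: str, stack: ImageStack) -> None:
    """Write a stack as NPZ, or as 16-bit multi-page TIFF (rounded)."""
    if str(path).endswith(".npz"):
        np.savez_compressed(
            path,
            frames=stack.frames,
            frame_interval=stack.frame_interval,
            bit_depth=stack.bit_depth,
        )
        return
    import tifffile

    tifffile.imwrite(path, np.round(stack.frames).astype(np.uint16))


def traces_to_frame(traces: Sequence[IntensityTrace]) -> pd.DataFrame:
    """Long-format table: spore_id, frame, time_min, raw, normalized."""
    parts = []
    for tr in traces:
        df = pd.DataFrame(
            {
                "spore_id": tr.spore_id,
                "frame": np.arange(tr.raw.size),
                "time_min": tr.times,
                "raw": tr.raw,
                "normalized": tr.normalized if tr.normalized is not None else np.nan,
            }
        )
        df["germination_candidate"] = bool(tr.germination_candidate)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)
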