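"""Per-frame foreground segmentation and body-centroid extraction.

The runner is isolated from each frame by subtracting a background image
captured before the run, thresholding the absolute grayscale difference,
cleaning the binary mask with a median filter, and taking the centroid of the
largest connected foreground component (the geometric centre of mass of the
detected blob).  A frame where no component survives the area filter yields a
missing value, never an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "CentroidTrack",
    "denoise_mask",
    "detect_track",
    "locate_centroid",
    "subtract_background",
    "threshold_and_binarize",
]

#: 8-connectivity structuring element for component labelling: keeps
#: diagonally-touching limb pixels in a single blob.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CentroidTrack:
    """Per-frame pixel centroid of the detected body for one camera.

    ``x_px``/``y_px`` are float arrays aligned with ``frame_index``; a failed
    detection is NaN in both.
    """

    camera_id: str
    frame_index: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        fi = np.asarray(self.frame_index, dtype=int)
        if fi.ndim != 1 or (fi.size > 1 and np.any(np.diff(fi) <= 0)):
            raise ValueError("frame indices must be 1-D and strictly increasing")
        object.__setattr__(self, "frame_index", fi)
        object.__setattr__(self, "x_px", np.asarray(self.x_px, dtype=float))
        object.__setattr__(self, "y_px", np.asarray(self.y_px, dtype=float))
        if not (len(self.frame_index) == len(self.x_px) == len(self.y_px)):
            raise ValueError("frame_index, x_px and y_px must have equal length")

    @property
    def n_detected(self) -> int:
        return int(np.isfinite(self.x_px).sum())

    @property
    def detection_rate(self) -> float:
        return self.n_detected / len(self.frame_index)


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Absolute grayscale difference |F - B| between a frame and the background.

    The absolute value detects the body whether it is darker or lighter than
    the track behind it; the output stays within [0, 255].
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match background {background.shape}"
        )
    return _absdiff_u8(frame.astype(np.uint8), background.astype(np.uint8))


def _absdiff_u8(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|a - b| for uint8 arrays without widening: max(a,b) - min(a,b)."""
    return np.maximum(a, b) - np.minimum(a, b)


def threshold_and_binarize(diff: np.ndarray, tau: float) -> np.ndarray:
    """Binary foreground mask: 1 where the difference strictly exceeds tau."""
    if not 0 <= tau <= 255:
        raise ValueError(f"tau must lie in [0, 255], got {tau}")
    return (np.asarray(diff) > tau).astype(np.uint8)


def _binary_majority(mask: np.ndarray, kernel_px: int) -> np.ndarray:
    """Majority vote over a kernel_px x kernel_px neighbourhood (edge replicated).

    For a binary image and an odd kernel this equals the sliding-window median
    exactly: the median of k*k zeros/ones is 1 iff ones hold the majority.
    Works on a single mask or an (n, h, w) stack (each frame filtered
    independently); the count runs in integer shifted adds, so the result is
    exact, with no float rounding at the majority cut.
    """
    k = kernel_px
    half = k // 2
    dtype = np.uint8 if k * k <= 255 else np.uint16
    pad = [(0, 0)] * (mask.ndim - 2) + [(half, half), (half, half)]
    padded = np.pad(mask.astype(dtype), pad, mode="edge")
    h, w = mask.shape[-2], mask.shape[-1]
    rowsum = np.zeros(mask.shape[:-2] + (h, w + 2 * half), dtype=dtype)
    for i in range(k):
        rowsum += padded[..., i : i + h, :]
    counts = np.zeros(mask.shape, dtype=dtype)
    for j in range(k):
        counts += rowsum[..., :, j : j + w]
    return (counts > (k * k) // 2).astype(np.uint8)


def denoise_mask(mask: np.ndarray, kernel_px: int) -> np.ndarray:
    """Median-filter a binary mask (edge replication at the borders)."""
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel_px}")
    mask = np.asarray(mask)
    if kernel_px == 1:
        return mask.astype(np.uint8)
    return _binary_majority(mask, kernel_px)


def locate_centroid(
    mask: np.ndarray, min_blob_area_px: int = 25
) -> tuple[float, float] | None:
    """Centroid (x, y) of the largest 8-connected component, or None.

    Components smaller than ``min_blob_area_px`` pixels are discarded; among
    the survivors the largest wins, ties broken by the smallest (row, column)
    of the bounding-box top-left corner.  The centroid is the arithmetic mean
    of the component's pixel coordinates.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndi.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    eligible = np.flatnonzero(areas >= max(min_blob_area_px, 1)) + 1
    if eligible.size == 0:
        return None
    best = eligible[areas[eligible - 1] == areas[eligible - 1].max()]
    if best.size > 1:  # tie-break on bounding-box top-left corner
        slices = ndi.find_objects(labels)
        corners = [(slices[lab - 1][0].start, slices[lab - 1][1].start) for lab in best]
        best = best[int(np.lexsort((np.array(corners)[:, 1], np.array(corners)[:, 0]))[0])]
    else:
        best = best[0]
    rows, cols = np.nonzero(labels == best)
    return float(cols.mean()), float(rows.mean())


def detect_track(seq, background: np.ndarray, config) -> CentroidTrack:
    """Run subtract -> threshold -> median -> centroid on every frame.

    ``seq`` is a :class:`~sprintvision.frames_io.FrameSequence`; the result has
    one entry per frame with NaN where no blob passed the filters.  The first
    three stages are evaluated on the whole frame stack at once; they are
    element-wise/per-frame operations, so the result is identical to applying
    the single-frame functions frame by frame.
    """
    background = np.asarray(background)
    if background.shape != seq.frames.shape[1:]:
        raise ValueError(
            f"camera {seq.camera_id}: background shape {background.shape} does "
            f"not match frame shape {seq.frames.shape[1:]}"
        )
    diff = _absdiff_u8(seq.frames, background.astype(np.uint8))
    masks = (diff > config.threshold_tau).astype(np.uint8)
    del diff
    if config.median_kernel_px > 1:
        masks = _binary_majority(masks, config.median_kernel_px)

    n = seq.n_frames
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    # cheap rejection: a frame with fewer foreground pixels than the area
    # floor cannot contain an eligible component
    counts = masks.sum(axis=(1, 2))
    for i in np.flatnonzero(counts >= max(config.min_blob_area_px, 1)):
        found = locate_centroid(masks[i], config.min_blob_area_px)
        if found is not None:
            x[i], y[i] = found
    return CentroidTrack(
        seq.camera_id, np.arange(n), x, y, frame_rate_hz=seq.frame_rate_hz
    )
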