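"""Cell identification in the cleaned phase video.

Cleaned half-resolution frames are thresholded (0.3 rad) to binary
masks and cross-correlated along the lateral axis with a detection
kernel: a +1 disk of roughly one cell diameter flanked by strongly
negative bands along the top and bottom frame edges, so that a cell
centred in the short axis scores high while a cell clipped by the field
of view is rejected.  Correlations over an 80-frame batch form a
(frames x columns) correlation map whose local maxima mark the frame
and lateral position at which each flowing cell crosses the centre of
the field of view — no motion tracking is needed.  Frames whose maximum
correlation is near zero are empty and serve as background references
for refocusing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve

from .config import PipelineConfig

__all__ = [
    "CellDetection",
    "make_kernel",
    "binarize",
    "correlate_batch",
    "detect_cells",
    "find_background_frames",
    "assign_background_frames",
]


@dataclass
class CellDetection:
    """One detected cell: the frame where it is vertically centred."""

    frame_index: int
    x_half: int
    score: float
    background_frame: int | None = None

    @property
    def x_full(self) -> int:
        return 2 * self.x_half


def make_kernel(cfg: PipelineConfig | None = None, height: int | None = None,
                width: int | None = None, disk_diameter: int | None = None,
                edge_rows: int | None = None,
                edge_value: float | None = None) -> np.ndarray:
    """Detection kernel: +1 interior disk, negative edge bands, else 0."""
    cfg = cfg or PipelineConfig()
    height = height if height is not None else cfg.optics.half_shape[0]
    width = width if width is not None else cfg.kernel_width
    disk_diameter = disk_diameter if disk_diameter is not None else cfg.kernel_disk_diameter
    edge_rows = edge_rows if edge_rows is not None else cfg.kernel_edge_rows
    edge_value = edge_value if edge_value is not None else cfg.kernel_edge_value

    k = np.zeros((height, width))
    k[:edge_rows, :] = edge_value
    k[height - edge_rows:, :] = edge_value
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    y = np.arange(height)[:, None] - cy
    x = np.arange(width)[None, :] - cx
    disk = np.hypot(y, x) <= disk_diameter / 2.0
    k[disk] = 1.0
    return k


def binarize(frame: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Binary mask of cleaned phase above the threshold (radians)."""
    return np.asarray(frame) > threshold


def correlate_batch(masks: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Lateral cross-correlation of each mask with the kernel.

    ``masks`` is (n_frames, height, width) boolean; the kernel spans the
    full frame height, so each frame yields a 1D score over lateral
    positions: score[t, x] = sum_{y,u} mask[t, y, x+u-cx] * kernel[y, u]
    (zero-padded borders).  Computed via FFT; identical to the
    brute-force sliding dot product to numerical precision.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError("masks must be (n_frames, height, width)")
    if masks.shape[0] < 1:
        raise ValueError("batch must contain at least one frame")
    if masks.shape[1] != kernel.shape[0]:
        raise ValueError("kernel height must equal the mask height")
    h, kw = kernel.shape
    cx = kw // 2
    full = fftconvolve(masks.astype(np.float64),
                       kernel[None, ::-1, ::-1], mode="full", axes=(1, 2))
    row = full[:, h - 1, :]
    start = kw - 1 - cx
    return row[:, start: start + masks.shape[2]]


def detect_cells(corr_map: np.ndarray, peak_threshold: float,
                 min_separation_x: int = 24, min_separation_t: int = 5,
                 frame_offset: int = 0,
                 previous: list[CellDetection] | None = None,
                 ) -> list[CellDetection]:
    """Local maxima of the correlation map, greedily deduplicated.

    8-neighbourhood maxima at or above ``peak_threshold`` are accepted
    in descending score; an accepted peak excludes later peaks within
    ``min_separation_t`` frames *and* ``min_separation_x`` columns (the
    same cell appears in several consecutive frames).  ``previous``
    carries accepted detections from the preceding batch so cells whose
    exclusion window crosses the batch boundary are not emitted twice.
    ``frame_offset`` converts in-batch rows to acquisition frame indices.
    """
    corr = np.asarray(corr_map, dtype=np.float64)
    local_max = corr >= maximum_filter(corr, size=3, mode="constant",
                                       cval=-np.inf)
    cand = np.argwhere(local_max & (corr >= peak_threshold))
    order = np.lexsort((cand[:, 1], cand[:, 0], -corr[cand[:, 0], cand[:, 1]]))
    accepted: list[CellDetection] = []
    guard = [(p.frame_index, p.x_half) for p in (previous or [])]
    for t, x in cand[order]:
        gt = int(t) + frame_offset
        clash = any(abs(gt - pt) < min_separation_t and abs(int(x) - px) < min_separation_x
                    for pt, px in guard)
        if clash:
            continue
        det = CellDetection(frame_index=gt, x_half=int(x),
                            score=float(corr[t, x]))
        accepted.append(det)
        guard.append((gt, int(x)))
    accepted.sort(key=lambda d: (d.frame_index, d.x_half))
    return accepted


def find_background_frames(corr_map: np.ndarray, zero_threshold: float,
                           frame_offset: int = 0) -> list[int]:
    """Frames whose correlation magnitude stays below ``zero_threshold``.

    The magnitude matters: a cell sliver entering at the frame edge
    scores strongly *negative* (edge penalty) and must not pass as an
    empty background frame.
    """
    corr = np.asarray(corr_map)
    peak = np.abs(corr).max(axis=1) if corr.size else np.array([])
    return [int(i) + frame_offset for i in np.nonzero(peak < zero_threshold)[0]]


def assign_background_frames(detections: list[CellDetection],
                             background_frames: list[int]) -> None:
    """Attach the temporally nearest empty frame to each detection.

    Detections keep ``background_frame=None`` when no empty frame
    exists; refocusing skips those cells with a warning.
    """
    if not background_frames:
        return
    bg = np.asarray(sorted(background_frames))
    for det in detections:
        i = int(np.argmin(np.abs(bg - det.frame_index)))
        det.background_frame = int(bg[i])
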