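"""Post-processing of unwrapped phase batches.

Three cleaning steps run on batches of consecutive unwrapped frames
(40 by default):

1. *Temporal 2*pi correction* — any pixel value deviating from its
   temporal median by more than 2*pi is shifted by the nearest integer
   multiple of 2*pi (residual unwrapping errors are isolated in time).
2. *Per-row cubic background* — the smooth optical-path background is
   fitted row-wise with a third-order polynomial (the field of view is
   ~43x wider than tall, so row-wise fits replace a full 2D surface)
   and subtracted.  One robust re-fit excludes pixels whose residual
   exceeds a threshold so cells do not bias the curve.
3. *Static background* — channel walls, dust and persistent unwrap
   errors survive the temporal median of the batch, which is subtracted
   from every frame; transient cells occupy any one pixel in only a
   minority of frames and are preserved.
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = [
    "correct_temporal_jumps",
    "subtract_row_background",
    "static_background",
    "postprocess_batch",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


def correct_temporal_jumps(batch: np.ndarray) -> np.ndarray:
    """Snap per-pixel outliers back by integer multiples of 2*pi.

    For each pixel the temporal median over the batch is the reference;
    frame values deviating by more than 2*pi are shifted by the multiple
    of 2*pi that brings them nearest the median.  Requires >= 3 frames.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.shape[0] < 3:
        raise ValueError("temporal jump correction needs at least 3 frames")
    med = np.median(batch, axis=0)
    dev = batch - med[None]
    shift = np.where(np.abs(dev) > TWO_PI, np.rint(dev / TWO_PI), 0.0)
    return batch - TWO_PI * shift


def subtract_row_background(frame: np.ndarray, mask_threshold: float = 0.5,
                            degree: int = 3, robust: bool = True) -> np.ndarray:
    """Fit and subtract a cubic polynomial from every row.

    With ``robust`` set, each row is re-fitted once excluding pixels
    whose first-pass residual exceeds ``mask_threshold`` (radians), so
    cells do not raise the curve; rows left with fewer than degree+1
    usable pixels fall back to the all-pixel fit.
    """
    frame = np.asarray(frame, dtype=np.float64)
    rows, cols = frame.shape
    if cols < degree + 1:
        raise ValueError("frame too narrow for the polynomial degree")
    x = np.arange(cols, dtype=np.float64)
    coeffs = P.polyfit(x, frame.T, degree)          # (degree+1, rows)
    fit = P.polyval(x, coeffs).reshape(rows, cols)
    if robust:
        resid = frame - fit
        for i in range(rows):
            keep = np.abs(resid[i]) <= mask_threshold
            n = int(keep.sum())
            if degree + 1 <= n < cols:
                ci = P.polyfit(x[keep], frame[i, keep], degree)
                fit[i] = P.polyval(x, ci)
    return frame - fit


def static_background(batch: np.ndarray) -> np.ndarray:
    """Pixel-wise temporal median of the batch (the persistent background).

    Requires >= 5 frames so transient cells cannot dominate the median.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.shape[0] < 5:
        raise ValueError("static background estimation needs at least 5 frames")
    return np.median(batch, axis=0)


def postprocess_batch(batch: np.ndarray, mask_threshold: float = 0.5,
                      robust: bool = True, degree: int = 3) -> np.ndarray:
    """Temporal 2*pi correction, row-wise cubic removal, static subtraction.

    Batches shorter than the per-step minima skip that step with a
    warning (trailing partial batches of an acquisition).
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.shape[0] >= 3:
        batch = correct_temporal_jumps(batch)
    else:
        log.warning("batch of %d frames: skipping temporal jump correction",
                    batch.shape[0])
    batch = np.stack([
        subtract_row_background(f, mask_threshold=mask_threshold,
                                robust=robust, degree=degree)
        for f in batch])
    if batch.shape[0] >= 5:
        batch = batch - static_background(batch)[None]
    else:
        log.warning("batch of %d frames: skipping static background removal",
                    batch.shape[0])
    return batch
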