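"""Off-axis interferogram demodulation.

An off-axis interferogram I = |r + s|^2 carries the sample field s on a
spatial-frequency carrier: its Fourier transform holds the
cross-correlation term (sideband) away from DC.  Demodulation locates
that sideband once per acquisition on the first frame, then for every
frame crops a fixed spectral ROI around it, recentres the crop in an
otherwise empty spectrum, and inverse transforms — at two zero-padding
sizes, giving a half-resolution (48 x 2048) field used for unwrapping
and detection and a full-resolution (96 x 4096) field kept for
refocusing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import OpticsConfig
from .unwrap import wrap

__all__ = [
    "CarrierCalibration",
    "ComplexField",
    "CarrierNotFoundError",
    "calibrate_carrier",
    "demodulate",
    "wrapped_phase",
]


class CarrierNotFoundError(ValueError):
    """No off-axis carrier peak stands out in the spectrum."""


@dataclass(frozen=True)
class CarrierCalibration:
    """Sideband location in the centred (fftshifted) spectrum.

    ``peak_index`` is the (row, col) of the spectral local maximum;
    ``crop_window`` is (row_start, col_start, rows, cols) of the ROI,
    placed centred on the peak and clipped in-bounds.
    """

    peak_index: tuple[int, int]
    crop_window: tuple[int, int, int, int]


@dataclass
class ComplexField:
    """Reconstructed complex optical field at half or full resolution."""

    values: np.ndarray
    resolution: str          # "half" | "full"
    pixel_um: float

    def __post_init__(self) -> None:
        if self.resolution not in ("half", "full"):
            raise ValueError("resolution must be 'half' or 'full'")


def calibrate_carrier(first_frame: np.ndarray, cfg: OpticsConfig,
                      min_peak_ratio: float = 10.0,
                      dc_exclude_rows: int = 8,
                      dc_exclude_cols: int = 64) -> CarrierCalibration:
    """Locate the off-axis carrier on the first captured frame.

    The peak is the argmax of FFT magnitude over the positive-fx
    half-plane, excluding a centred DC zone of +-``dc_exclude_rows``
    rows by +-``dc_exclude_cols`` columns (picking one of the two
    conjugate sidebands deterministically; argmax ties resolve to the
    lowest (row, col)).  Raises :class:`CarrierNotFoundError` when the
    peak does not exceed ``min_peak_ratio`` times the median spectral
    magnitude.
    """
    frame = np.asarray(first_frame, dtype=np.float64)
    if frame.shape != cfg.frame_shape:
        raise ValueError(f"frame shape {frame.shape} != {cfg.frame_shape}")
    rows, cols = frame.shape
    mag = np.abs(np.fft.fftshift(np.fft.fft2(frame)))
    cr, cc = rows // 2, cols // 2

    allowed = np.zeros_like(mag, dtype=bool)
    allowed[:, cc + 1:] = True                       # positive-fx half-plane
    allowed[cr - dc_exclude_rows: cr + dc_exclude_rows + 1,
            cc - dc_exclude_cols: cc + dc_exclude_cols + 1] = False

    masked = np.where(allowed, mag, -np.inf)
    flat = int(np.argmax(masked))                    # first max, row-major
    peak = (flat // cols, flat % cols)
    if not mag[peak] > min_peak_ratio * float(np.median(mag)):
        raise CarrierNotFoundError(
            "no off-axis carrier found: spectral peak is "
            f"{mag[peak] / max(float(np.median(mag)), 1e-300):.1f}x the median, "
            f"below the required {min_peak_ratio}x")

    crows, ccols = cfg.crop_shape
    row_start = int(np.clip(peak[0] - crows // 2, 0, rows - crows))
    col_start = int(np.clip(peak[1] - ccols // 2, 0, cols - ccols))
    return CarrierCalibration(peak_index=peak,
                              crop_window=(row_start, col_start, crows, ccols))


def _embed_and_invert(crop: np.ndarray, peak_in_crop: tuple[int, int],
                      out_shape: tuple[int, int], in_shape: tuple[int, int],
                      ) -> np.ndarray:
    """Place a spectral crop with its peak at centre and inverse transform.

    The result is scaled by (N_out/N_in) per axis so zero-padding does
    not change the mean field amplitude (a unit-modulation fringe
    pattern demodulates to mean amplitude ~1).
    """
    out_r, out_c = out_shape
    spec = np.zeros(out_shape, dtype=complex)
    pr, pc = peak_in_crop
    r0 = out_r // 2 - pr
    c0 = out_c // 2 - pc
    if r0 < 0 or c0 < 0 or r0 + crop.shape[0] > out_r or c0 + crop.shape[1] > out_c:
        raise ValueError("spectral crop does not fit in the output spectrum")
    spec[r0: r0 + crop.shape[0], c0: c0 + crop.shape[1]] = crop
    scale = (out_r / in_shape[0]) * (out_c / in_shape[1])
    return np.fft.ifft2(np.fft.ifftshift(spec)) * scale


def demodulate(frame: np.ndarray, calib: CarrierCalibration,
               cfg: OpticsConfig) -> tuple[ComplexField, ComplexField]:
    """Demodulate one interferogram into half- and full-resolution fields."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != cfg.frame_shape:
        raise ValueError(f"frame shape {frame.shape} != {cfg.frame_shape}")
    spec = np.fft.fftshift(np.fft.fft2(frame))
    r0, c0, crows, ccols = calib.crop_window
    crop = spec[r0: r0 + crows, c0: c0 + ccols]
    peak_in_crop = (calib.peak_index[0] - r0, calib.peak_index[1] - c0)

    half = _embed_and_invert(crop, peak_in_crop, cfg.half_shape, cfg.frame_shape)
    full = _embed_and_invert(crop, peak_in_crop, cfg.full_shape, cfg.frame_shape)
    return (ComplexField(half, "half", cfg.half_pixel_um),
            ComplexField(full, "full", cfg.pixel_um))


def wrapped_phase(field: ComplexField | np.ndarray,
                  return_valid: bool = False):
    """Element-wise principal argument mapped to (-pi, pi].

    Zero-magnitude pixels get phase 0 and are flagged False in the
    validity mask returned when ``return_valid`` is set.
    """
    values = field.values if isinstance(field, ComplexField) else np.asarray(field)
    valid = values != 0
    psi = wrap(np.angle(values))
    psi = np.where(valid, psi, 0.0)
    if return_valid:
        return psi, valid
    return psi
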