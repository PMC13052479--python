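"""Digital refocusing by angular-spectrum propagation.

Each detected cell is cropped (96 x 96 full-resolution pixels) together
with a background crop from the nearest empty frame; the background is
removed by complex division (no unwrapping needed for thin objects with
< 2*pi phase delay), and the field is numerically propagated to the
plane minimising the variance of its amplitude — a pure phase object
shows minimal amplitude contrast in focus.

Exhaustive autofocus over a 32-point grid in [-24, 24] um is applied to
the first cells of an acquisition; a quadratic curve of refocus distance
versus lateral position is then fitted to those cells (the focal plane
of the instrument is tilted along the long axis), after which each cell
is refocused at only three depths: the calibrated distance and one
regression standard deviation above and below.

Sign convention: the stored refocus distance is the distance passed to
:func:`propagate` that restores focus, so a cell defocused by +d in the
object space carries refocus distance -d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "CellCrop",
    "FocusCalibration",
    "RefocusedCell",
    "Propagator",
    "propagate",
    "thin_object_phase",
    "divide_background",
    "amplitude_variance",
    "autofocus",
    "calibrate_focus",
    "refocus_cell",
]

log = logging.getLogger(__name__)


@dataclass
class CellCrop:
    """A cell field and its empty-background field at the same columns."""

    cell_field: np.ndarray        # complex, full resolution
    background_field: np.ndarray  # complex, same shape and column range
    pixel_um: float
    x_full: int = 0               # lateral cell position, full-res columns
    frame_index: int = 0
    background_frame: int | None = None

    def __post_init__(self) -> None:
        if self.cell_field.shape != self.background_field.shape:
            raise ValueError("cell and background crops must share a shape")


@dataclass(frozen=True)
class FocusCalibration:
    """Quadratic refocus-distance model d(x) = a*x^2 + b*x + c (um)."""

    coeffs: tuple[float, float, float]
    residual_std: float
    n_cells_used: int

    def __post_init__(self) -> None:
        if self.residual_std < 0:
            raise ValueError("residual_std must be nonnegative")

    def predict(self, x) -> np.ndarray | float:
        a, b, c = self.coeffs
        return a * np.asarray(x, dtype=float) ** 2 + b * np.asarray(x, dtype=float) + c


@dataclass
class RefocusedCell:
    """Result of refocusing one cell."""

    phase: np.ndarray                 # radians, background-divided, refocused
    distance_um: float
    candidates_um: np.ndarray
    variances: np.ndarray
    field: np.ndarray = field(repr=False, default=None)


# ----------------------------------------------------------------------
# angular spectrum propagation


@lru_cache(maxsize=32)
def _kz_grid(shape: tuple[int, int], pixel_um: float, wavelength_um: float):
    """sqrt(1/lambda^2 - fx^2 - fy^2) - 1/lambda, evanescent region zeroed.

    The constant 1/lambda is subtracted so the transfer function is 1 at
    DC (piston-free form): the plane-wave phase advance exp(i*2*pi*d/lambda)
    carries no imaging information and would otherwise rotate the global
    phase of every refocused image with distance.
    """
    fy = np.fft.fftfreq(shape[0], d=pixel_um)
    fx = np.fft.fftfreq(shape[1], d=pixel_um)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    arg = 1.0 / wavelength_um ** 2 - f2
    propagating = arg > 0
    kz = np.sqrt(np.where(propagating, arg, 0.0)) - 1.0 / wavelength_um
    return kz, propagating


class Propagator:
    """Propagates one field to many distances, re-using its spectrum."""

    def __init__(self, field: np.ndarray, wavelength_um: float, pixel_um: float):
        field = np.asarray(field, dtype=complex)
        self._spectrum = np.fft.fft2(field)
        self._kz, self._mask = _kz_grid(field.shape, float(pixel_um),
                                        float(wavelength_um))

    def at(self, d_um: float) -> np.ndarray:
        h = np.exp(2j * np.pi * d_um * self._kz)
        spec = np.where(self._mask, self._spectrum * h, 0.0)
        return np.fft.ifft2(spec)

    def variance_at(self, d_um: float) -> float:
        return amplitude_variance(self.at(d_um))


def propagate(field: np.ndarray, d_um: float, wavelength_um: float,
              pixel_um: float) -> np.ndarray:
    """Angular-spectrum propagation of a complex field by ``d_um``.

    U' = IFFT(FFT(U) * H) with H = exp(i*2*pi*d*sqrt(1/lambda^2 - fx^2 - fy^2))
    on propagating frequencies and 0 on the evanescent remainder.
    """
    return Propagator(field, wavelength_um, pixel_um).at(d_um)


def thin_object_phase(field: np.ndarray) -> np.ndarray:
    """Phase of a background-divided thin object, in (-pi/2, 3*pi/2].

    A thin cell delays the light by a nonnegative phase below 2*pi, so
    the mod-2*pi ambiguity of the quotient's argument is resolved by
    picking the branch that keeps delays nonnegative while leaving small
    negative excursions (noise, diffraction ringing) intact — no
    unwrapping required.
    """
    phase = np.angle(np.asarray(field))
    return np.where(phase < -0.5 * np.pi, phase + 2.0 * np.pi, phase)


def divide_background(cell: CellCrop) -> np.ndarray:
    """Element-wise cell/background division; removes the common background.

    Near-zero background pixels (below 1e-6 of the median background
    amplitude) are replaced by a phase-preserving value of that floor
    magnitude so the quotient stays finite.
    """
    bg = cell.background_field
    amp = np.abs(bg)
    floor = 1e-6 * float(np.median(amp))
    bad = amp < floor
    if bad.any():
        log.warning("divide_background: %d near-zero background pixels floored",
                    int(bad.sum()))
        phase = np.where(amp > 0, bg / np.maximum(amp, 1e-300), 1.0)
        bg = np.where(bad, floor * phase, bg)
    return cell.cell_field / bg


def amplitude_variance(field: np.ndarray) -> float:
    """Population variance of |field| over all pixels (focus metric)."""
    return float(np.var(np.abs(field)))


def autofocus(field: np.ndarray, wavelength_um: float, pixel_um: float,
              d_min: float = -24.0, d_max: float = 24.0, n: int = 32,
              ) -> tuple[float, np.ndarray, np.ndarray]:
    """Exhaustive amplitude-variance autofocus on a uniform distance grid.

    Returns (d*, distances, variances); ties resolve to the smaller |d|.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    distances = np.linspace(d_min, d_max, n)
    prop = Propagator(field, wavelength_um, pixel_um)
    variances = np.array([prop.variance_at(d) for d in distances])
    best = min(range(n), key=lambda i: (variances[i], abs(distances[i])))
    return float(distances[best]), distances, variances


def calibrate_focus(first_cells, n_target: int = 128) -> FocusCalibration:
    """Quadratic least-squares fit of refocus distance vs lateral position.

    ``first_cells`` is a sequence of (x_full, d*) pairs, normally the
    first 128 cells of an acquisition.  ``residual_std`` is the
    (population) standard deviation of the fit residuals.
    """
    pairs = list(first_cells)
    if len(pairs) < 3:
        raise ValueError("insufficient calibration cells (need at least 3)")
    if len(pairs) < 8:
        log.warning("focus calibration from only %d cells (target %d)",
                    len(pairs), n_target)
    x = np.array([p[0] for p in pairs], dtype=float)
    d = np.array([p[1] for p in pairs], dtype=float)
    coeffs = np.polyfit(x, d, 2)
    resid = d - np.polyval(coeffs, x)
    return FocusCalibration(coeffs=tuple(float(c) for c in coeffs),
                            residual_std=float(np.std(resid)),
                            n_cells_used=len(pairs))


def refocus_cell(crop: CellCrop, calib: FocusCalibration,
                 wavelength_um: float,
                 propagate_before_divide: bool = False) -> RefocusedCell:
    """Three-depth refocusing around the calibrated distance.

    Candidates are {d(x)-s, d(x), d(x)+s} with s the regression standard
    deviation; the candidate of minimal amplitude variance is selected
    (ties favour the calibrated middle depth).  By default the
    background-divided quotient is propagated once; with
    ``propagate_before_divide`` cell and background are propagated
    separately and divided afterwards (the two orders agree to numerical
    noise because the same transfer function applies to both).
    """
    d0 = float(calib.predict(crop.x_full))
    s = calib.residual_std
    candidates = np.array([d0 - s, d0, d0 + s])

    if propagate_before_divide:
        cprop = Propagator(crop.cell_field, wavelength_um, crop.pixel_um)
        bprop = Propagator(crop.background_field, wavelength_um, crop.pixel_um)

        def refocused(d):
            moved = CellCrop(cprop.at(d), bprop.at(d), crop.pixel_um,
                             crop.x_full, crop.frame_index)
            return divide_background(moved)
    else:
        quotient = divide_background(crop)
        qprop = Propagator(quotient, wavelength_um, crop.pixel_um)

        def refocused(d):
            return qprop.at(d)

    fields = [refocused(d) for d in candidates]
    variances = np.array([amplitude_variance(f) for f in fields])
    best = min(range(3), key=lambda i: (variances[i], abs(candidates[i] - d0)))
    return RefocusedCell(phase=thin_object_phase(fields[best]),
                         distance_um=float(candidates[best]),
                         candidates_um=candidates,
                         variances=variances,
                         field=fields[best])
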