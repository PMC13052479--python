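"""Per-cell quantification of refocused phase images.

A refocused cell image is offset-corrected (mean of the four 8x8 corner
blocks), thresholded to a binary mask cleaned by morphological opening,
and reduced to standard red-blood-cell descriptors:

* projection area  A = (number of mask pixels) * dA,  dA = pixel_um^2
* optical path length per pixel  OPL = phi * lambda / (2*pi)
* optical volume  OV = dA * sum_mask(OPL)  (a dry-mass-like quantity)
* eccentricity of the moment-equivalent ellipse, in [0, 1)
* circularity 4*pi*A/C^2 with C the Crofton perimeter (1 for a circle)

Rule-based bounds on these parameters separate single red blood cells
from debris, doublets and other non-RBC objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton, regionprops

from .config import OpticsConfig

__all__ = [
    "CellMorphology",
    "RBCFilter",
    "NoObjectError",
    "corner_offset",
    "cell_mask",
    "measure",
    "filter_cell",
]

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class NoObjectError(ValueError):
    """The thresholded image contains no object."""


@dataclass
class CellMorphology:
    """Morphological descriptors of one segmented cell."""

    area_um2: float
    ov_um3: float
    mean_opl_um: float
    eccentricity: float
    circularity: float
    perimeter_um: float
    n_pixels: int
    degenerate: bool = False   # single-pixel mask: circularity undefined


@dataclass(frozen=True)
class RBCFilter:
    """Closed-interval acceptance bounds for single red blood cells.

    The defaults bracket healthy-RBC literature ranges generously; they
    are configuration, not measurements.
    """

    area_um2: tuple[float, float] = (20.0, 90.0)
    ov_um3: tuple[float, float] = (10.0, 150.0)
    eccentricity_max: float = 0.8
    circularity_min: float = 0.7

    def __post_init__(self) -> None:
        for lo, hi in (self.area_um2, self.ov_um3):
            if lo > hi:
                raise ValueError("filter bound: min exceeds max")


def corner_offset(img: np.ndarray, block: int = 8) -> float:
    """Mean phase of the four corner blocks (background offset)."""
    img = np.asarray(img)
    if img.shape[0] < 2 * block or img.shape[1] < 2 * block:
        raise ValueError("image too small for corner offset estimation")
    corners = np.concatenate([
        img[:block, :block].ravel(), img[:block, -block:].ravel(),
        img[-block:, :block].ravel(), img[-block:, -block:].ravel()])
    return float(corners.mean())


def cell_mask(img: np.ndarray, threshold: float = 0.3,
              opening_radius: int = 1) -> np.ndarray:
    """Threshold, open, and keep the largest 4-connected component."""
    bw = np.asarray(img) > threshold
    if opening_radius > 0:
        r = opening_radius
        y, x = np.ogrid[-r: r + 1, -r: r + 1]
        footprint = (y ** 2 + x ** 2) <= r ** 2
        bw = ndimage.binary_opening(bw, structure=footprint)
    labels, n = ndimage.label(bw, structure=FOUR_CONN)
    if n == 0:
        raise NoObjectError("no object above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def measure(img: np.ndarray, mask: np.ndarray,
            cfg: OpticsConfig | None = None, pixel_um: float | None = None,
            circularity_printed_form: bool = False) -> CellMorphology:
    """Morphological parameters of a masked phase image.

    ``circularity_printed_form`` switches to the inverted ratio
    4*pi*C^2/A (which evaluates to ~157.9 for a perfect circle) instead
    of the standard bounded 4*pi*A/C^2.
    """
    cfg = cfg or OpticsConfig()
    pixel_um = pixel_um if pixel_um is not None else cfg.pixel_um
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise NoObjectError("empty mask")
    dA = pixel_um ** 2
    area = n_px * dA
    opl = img * cfg.wavelength_um / (2.0 * np.pi)
    mean_opl = float(opl[mask].mean())
    ov = dA * float(opl[mask].sum())

    degenerate = n_px < 2
    if degenerate:
        ecc, circ, perim = 0.0, float("nan"), 0.0
    else:
        perim = float(perimeter_crofton(mask, directions=4)) * pixel_um
        props = regionprops(mask.astype(np.uint8))[0]
        ecc = float(props.eccentricity)
        if perim > 0:
            circ = (4.0 * np.pi * perim ** 2 / area if circularity_printed_form
                    else 4.0 * np.pi * area / perim ** 2)
        else:
            circ, degenerate = float("nan"), True
    return CellMorphology(area_um2=area, ov_um3=ov, mean_opl_um=mean_opl,
                          eccentricity=ecc, circularity=circ,
                          perimeter_um=perim, n_pixels=n_px,
                          degenerate=degenerate)


def filter_cell(m: CellMorphology, f: RBCFilter | None = None) -> bool:
    """True iff every parameter lies within its (closed) bounds."""
    f = f or RBCFilter()
    if m.degenerate or not np.isfinite(m.circularity):
        return False
    return (f.area_um2[0] <= m.area_um2 <= f.area_um2[1]
            and f.ov_um3[0] <= m.ov_um3 <= f.ov_um3[1]
            and m.eccentricity <= f.eccentricity_max
            and m.circularity >= f.circularity_min)
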