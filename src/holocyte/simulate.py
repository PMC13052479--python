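"""Seeded synthetic holographic-cytometry acquisitions with ground truth.

The generator emulates the raw data of a flow-channel off-axis
interferometer so every pipeline stage can be tested without an
instrument: an off-axis carrier fringe pattern, cell-like phase objects
flowing along the short (row) axis, channel-wall phase steps larger than
pi, a smooth low-order background, an x-dependent quadratic defocus tilt
of the focal plane, and additive intensity noise.

Each frame is I = |r + s|^2 with reference r = A*exp(-i*2*pi*(fy*y+fx*x))
and sample s = exp(i*phi_true), so the sideband at +(fy, fx) demodulates
to +phi_true.  Defocus is applied per cell by propagating the cell's
sub-field by d(x_center) before it is multiplied into the sample field.
Ground truth (in-focus phase maps, per-cell focused crops, true defocus,
detection coordinates) is recorded before noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import tifffile

from .config import OpticsConfig
from .refocus import CellCrop, propagate

__all__ = [
    "CellSpec",
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "make_cell_phase",
    "synthesize_frames",
    "make_defocused_population",
    "write_acquisition",
    "read_acquisition",
]

log = logging.getLogger(__name__)

PROFILES = ("disk", "biconcave", "bead")


@dataclass(frozen=True)
class CellSpec:
    """One flowing cell-like phase object.

    The cell crosses the field of view along the short (row) axis at
    ``flow_rows_per_frame`` rows per frame and is vertically centred at
    ``center_frame``.
    """

    center_frame: int
    x_center: int                  # full-resolution column
    radius_um: float = 4.0         # ~RBC radius
    peak_phase_rad: float = 3.6    # thick/high-index RBC end, < 2*pi (thin object)
    profile: str = "biconcave"
    flow_rows_per_frame: float = 12.0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}")
        if not 0 < self.peak_phase_rad < 2 * np.pi:
            raise ValueError("peak_phase_rad must lie in (0, 2*pi)")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic acquisition.

    Defaults reflect the instrument conditions: a 0.25 cycles/px row
    carrier with the column carrier inside the spectral crop, channel
    walls with a 4 rad (> pi) phase step near both lateral edges, a
    ~1 rad low-order background, and a focal-plane tilt d(x) spanning
    roughly 2-15 um across the 4096-column field of view.
    """

    n_frames: int
    cells: tuple[CellSpec, ...] = ()
    wall_positions_x: tuple[int, ...] = (150, 3950)
    wall_step_rad: float = 4.0
    background_poly_coeffs: tuple[float, float, float, float] = (0.5, 1.0, -0.8, 0.6)
    background_y_tilt_rad: float = 0.2
    carrier_freq: tuple[float, float] = (0.25, 600.0 / 4096.0)  # (fy, fx) cycles/px
    defocus_curve_coeffs: tuple[float, float, float] = (1.0e-6, -8.0e-4, 2.0)
    noise_sigma: float = 0.02
    amp_ratio: float = 1.0        # reference/sample amplitude ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")

    def defocus_at(self, x) -> np.ndarray | float:
        a, b, c = self.defocus_curve_coeffs
        x = np.asarray(x, dtype=float)
        return a * x ** 2 + b * x + c


@dataclass
class CellTruth:
    """Ground truth for one planted cell."""

    frame_index: int
    x_full: int
    defocus_um: float          # propagation applied when synthesising
    refocus_um: float          # distance that restores focus (= -defocus_um)
    focused_phase: np.ndarray  # 96 x 96 in-focus phase crop


@dataclass
class GroundTruth:
    """Everything the simulator knows, recorded before noise."""

    true_phase: np.ndarray                 # (n_frames, rows, cols) float32, in focus
    cells: list[CellTruth] = dfield(default_factory=list)

    @property
    def detections(self) -> list[tuple[int, int]]:
        """(frame, x_full) of every planted, in-range cell."""
        return [(c.frame_index, c.x_full) for c in self.cells]


# ----------------------------------------------------------------------
# phase phantoms


def make_cell_phase(spec: CellSpec, pixel_um: float,
                    shape: tuple[int, int],
                    center: tuple[float, float] | None = None) -> np.ndarray:
    """Nonnegative smooth phase image of one cell.

    ``disk``: uniform phi0 inside the radius.  ``biconcave``: radially
    symmetric with a central dimple, phi0*(1 - 0.5*exp(-r^2/(0.25*R^2)))
    inside r < R, cosine-tapered to 0 over the outer 20% of the radius.
    ``bead``: spherical-cap profile phi0*sqrt(1 - (r/R)^2).
    """
    rows, cols = shape
    radius_px = spec.radius_um / pixel_um
    if 2 * radius_px > min(rows, cols):
        raise ValueError(
            f"cell of radius {radius_px:.1f} px does not fit in {shape}")
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    cy, cx = center
    y = np.arange(rows)[:, None] - cy
    x = np.arange(cols)[None, :] - cx
    r = np.hypot(y, x)
    inside = r < radius_px
    phi0 = spec.peak_phase_rad
    out = np.zeros(shape, dtype=np.float64)
    if spec.profile == "disk":
        out[inside] = phi0
    elif spec.profile == "bead":
        rr = np.clip(r / radius_px, 0.0, 1.0)
        out = np.where(inside, phi0 * np.sqrt(1.0 - rr ** 2), 0.0)
    else:  # biconcave
        base = phi0 * (1.0 - 0.5 * np.exp(-r ** 2 / (0.25 * radius_px ** 2)))
        edge = np.clip((r - 0.8 * radius_px) / (0.2 * radius_px), 0.0, 1.0)
        taper = np.cos(0.5 * np.pi * edge) ** 2
        out = np.where(inside, base * taper, 0.0)
    return out


# ----------------------------------------------------------------------
# frame synthesis


def _static_phase(scene: SceneSpec, cfg: OpticsConfig) -> np.ndarray:
    """Cell-free phase background: per-row cubic plus channel-wall steps."""
    rows, cols = cfg.frame_shape
    xn = np.linspace(0.0, 1.0, cols)
    c0, c1, c2, c3 = scene.background_poly_coeffs
    poly = c0 + c1 * xn + c2 * xn ** 2 + c3 * xn ** 3
    ytilt = scene.background_y_tilt_rad * np.linspace(0.0, 1.0, rows)
    phi = poly[None, :] + ytilt[:, None]
    for wx in scene.wall_positions_x:
        if not 0 <= wx < cols:
            raise ValueError(f"wall position {wx} outside the frame")
        if wx < cols // 2:
            phi[:, :wx] += scene.wall_step_rad
        else:
            phi[:, wx:] += scene.wall_step_rad
    return phi


def _check_carrier(scene: SceneSpec, cfg: OpticsConfig) -> tuple[int, int]:
    """Carrier bin offsets; error when demodulation would be impossible."""
    rows, cols = cfg.frame_shape
    fy, fx = scene.carrier_freq
    py, px = int(round(fy * rows)), int(round(fx * cols))
    crows, ccols = cfg.crop_shape
    # the crop window centred on the peak must stay inside the spectrum
    if not (crows // 2 <= py + rows // 2 <= rows - (crows - crows // 2)
            and ccols // 2 <= px + cols // 2 <= cols - (ccols - ccols // 2)):
        raise ValueError("carrier peak outside the demodulation crop support")
    if px <= 0:
        raise ValueError("carrier fx must be positive (positive-fx sideband)")
    return py, px


def synthesize_frames(scene: SceneSpec, cfg: OpticsConfig | None = None,
                      ) -> tuple[np.ndarray, GroundTruth]:
    """Render the raw interferogram stack and its ground truth.

    Returns a float32 array of shape (n_frames, rows, cols) and a
    :class:`GroundTruth`.  Identical (scene, cfg) give bit-identical
    output.
    """
    cfg = cfg or OpticsConfig()
    rows, cols = cfg.frame_shape
    _check_carrier(scene, cfg)
    rng = np.random.default_rng(scene.seed)

    fy, fx = scene.carrier_freq
    yy = np.arange(rows)[:, None]
    xx = np.arange(cols)[None, :]
    carrier = np.exp(2j * np.pi * (fy * yy + fx * xx))   # conj(reference)

    phi_static = _static_phase(scene, cfg)
    s_static = np.exp(1j * phi_static)

    half = 48  # cell crops are 96 x 96 at full resolution
    frames = np.empty((scene.n_frames, rows, cols), dtype=np.float32)
    truth = GroundTruth(
        true_phase=np.empty((scene.n_frames, rows, cols), dtype=np.float32))

    for cell in scene.cells:
        if 0 <= cell.center_frame < scene.n_frames:
            focused = make_cell_phase(cell, cfg.pixel_um, (2 * half, 2 * half))
            d = float(scene.defocus_at(cell.x_center))
            if abs(d) > 24.0:
                raise ValueError("|defocus| exceeds the 24 um search range")
            truth.cells.append(CellTruth(frame_index=cell.center_frame,
                                         x_full=cell.x_center,
                                         defocus_um=d,
                                         refocus_um=-d,
                                         focused_phase=focused))

    for t in range(scene.n_frames):
        phi_true = phi_static.copy()
        s = s_static.copy()
        for cell in scene.cells:
            y_c = rows / 2.0 + cell.flow_rows_per_frame * (t - cell.center_frame)
            radius_px = cell.radius_um / cfg.pixel_um
            if y_c < -radius_px or y_c > rows + radius_px:
                continue  # not in the field of view at this frame
            x0 = cell.x_center - half
            x1 = cell.x_center + half
            cx0, cx1 = max(x0, 0), min(x1, cols)
            if cx0 >= cx1:
                continue
            phi_cell = make_cell_phase(cell, cfg.pixel_um, (rows, 2 * half),
                                       center=(y_c, cell.x_center - x0))
            phi_true[:, cx0:cx1] += phi_cell[:, cx0 - x0: cx1 - x0]
            u_cell = np.exp(1j * phi_cell)
            d = float(scene.defocus_at(cell.x_center))
            if d != 0.0:
                u_cell = propagate(u_cell, d, cfg.wavelength_um, cfg.pixel_um)
            s[:, cx0:cx1] = s[:, cx0:cx1] * u_cell[:, cx0 - x0: cx1 - x0]
        truth.true_phase[t] = phi_true
        intensity = (scene.amp_ratio ** 2 + np.abs(s) ** 2
                     + 2.0 * scene.amp_ratio * np.real(s * carrier))
        if scene.noise_sigma > 0:
            intensity = intensity + rng.normal(0.0, scene.noise_sigma,
                                               size=intensity.shape)
            np.clip(intensity, 0.0, None, out=intensity)
        frames[t] = intensity.astype(np.float32)
    return frames, truth


# ----------------------------------------------------------------------
# direct cell-crop population (refocusing/evaluation harness)


@dataclass
class PopulationCell:
    """One synthetic defocused cell crop with its ground truth."""

    crop: CellCrop
    defocus_um: float
    refocus_um: float
    focused_phase: np.ndarray


def make_defocused_population(n_cells: int, cfg: OpticsConfig | None = None,
                              defocus_curve: tuple[float, float, float] = (1.0e-6, -8.0e-4, 2.0),
                              defocus_jitter_um: float = 0.5,
                              seed: int = 0,
                              crop_size: int = 96,
                              background_amp_rad: float = 0.3,
                              ) -> list[PopulationCell]:
    """Generate defocused cell crops following a quadratic focal-plane tilt.

    Cells are placed at uniform lateral positions; each true defocus is
    the tilt curve at that position plus Gaussian jitter (clipped to the
    +-24 um search range).  A smooth low-order background phase common
    to the cell and its background crop is included so complex division
    has something to remove.
    """
    cfg = cfg or OpticsConfig()
    rng = np.random.default_rng(seed)
    cols = cfg.frame_shape[1]
    a, b, c = defocus_curve
    out: list[PopulationCell] = []
    yy = np.linspace(0.0, 1.0, crop_size)
    for i in range(n_cells):
        x = int(rng.integers(crop_size // 2, cols - crop_size // 2))
        d = a * x ** 2 + b * x + c + rng.normal(0.0, defocus_jitter_um)
        d = float(np.clip(d, -23.0, 23.0))
        spec = CellSpec(center_frame=0, x_center=x,
                        radius_um=float(rng.uniform(3.4, 4.4)),
                        peak_phase_rad=float(rng.uniform(3.0, 4.0)),
                        profile="biconcave")
        focused = make_cell_phase(spec, cfg.pixel_um, (crop_size, crop_size))
        # smooth background phase shared by cell and background frames
        cbg = rng.normal(0.0, background_amp_rad, size=3)
        phi_bg = (cbg[0] + cbg[1] * yy[:, None] + cbg[2] * yy[None, :])
        bg_field = np.exp(1j * phi_bg)
        cell_field = propagate(np.exp(1j * focused), d,
                               cfg.wavelength_um, cfg.pixel_um) * bg_field
        crop = CellCrop(cell_field=cell_field, background_field=bg_field,
                        pixel_um=cfg.pixel_um, x_full=x, frame_index=i)
        out.append(PopulationCell(crop=crop, defocus_um=d, refocus_um=-d,
                                  focused_phase=focused))
    return out


# ----------------------------------------------------------------------
# I/O


def write_acquisition(out_dir: str | Path, frames: np.ndarray,
                      scene: SceneSpec, truth: GroundTruth | None = None) -> Path:
    """Write a frame stack as multi-page TIFF plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / "frames.tif"
    tifffile.imwrite(tif, frames, photometric="minisblack")
    side = {
        "scene": {
            "n_frames": scene.n_frames,
            "cells": [vars(c) for c in scene.cells],
            "wall_positions_x": list(scene.wall_positions_x),
            "wall_step_rad": scene.wall_step_rad,
            "background_poly_coeffs": list(scene.background_poly_coeffs),
            "background_y_tilt_rad": scene.background_y_tilt_rad,
            "carrier_freq": list(scene.carrier_freq),
            "defocus_curve_coeffs": list(scene.defocus_curve_coeffs),
            "noise_sigma": scene.noise_sigma,
            "amp_ratio": scene.amp_ratio,
            "seed": scene.seed,
        },
    }
    if truth is not None:
        side["ground_truth"] = {
            "detections": [[int(f), int(x)] for f, x in truth.detections],
            "defocus_um": [c.defocus_um for c in truth.cells],
        }
    (out_dir / "scene.json").write_text(json.dumps(side, indent=2))
    return tif


def read_acquisition(path: str | Path) -> np.ndarray:
    """Read a frame stack (multi-page TIFF) as (n, rows, cols) float64."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return np.asarray(frames, dtype=np.float64)
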