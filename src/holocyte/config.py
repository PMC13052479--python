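"""Optical constants and pipeline configuration.

Every physical constant and tunable used anywhere in the pipeline lives
here, so the processing modules are free of magic numbers.  The defaults
describe a line-scan holographic cytometer: a 20x objective (NA 0.4), a
640 nm pulsed source, 0.203 um detector pixels, and 96 x 4096 pixel
interferogram frames acquired at 300 fps while cells flow along the short
(row) axis of the sensor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "OpticsConfig",
    "PipelineConfig",
    "lateral_resolution",
    "spot_diameter_pixels",
]


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass(frozen=True)
class OpticsConfig:
    """Physical constants and frame geometry of the instrument.

    Parameters
    ----------
    wavelength_um :
        Illumination wavelength in micrometres.
    pixel_um :
        Detector pixel size at full resolution, micrometres.
    numerical_aperture :
        NA of the imaging objective (dimensionless, in (0, 1)).
    frame_rate_hz :
        Camera frame rate.
    frame_shape :
        (rows, cols) of a raw interferogram; rows is the short flow axis
        "y", cols the long lateral axis "x".  0-based indexing throughout.
    crop_shape :
        (rows, cols) of the spectral region of interest cut around the
        off-axis carrier peak.
    """

    wavelength_um: float = 0.640
    pixel_um: float = 0.203
    numerical_aperture: float = 0.4
    frame_rate_hz: float = 300.0
    frame_shape: tuple[int, int] = (96, 4096)
    crop_shape: tuple[int, int] = (20, 874)

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ConfigError("wavelength_um must be positive")
        if self.pixel_um <= 0:
            raise ConfigError("pixel_um must be positive")
        if not 0 < self.numerical_aperture < 1:
            raise ConfigError("numerical_aperture must lie in (0, 1)")
        if self.frame_rate_hz <= 0:
            raise ConfigError("frame_rate_hz must be positive")
        rows, cols = self.frame_shape
        if rows % 2 or cols % 2:
            raise ConfigError("frame_shape dimensions must be even")
        crows, ccols = self.crop_shape
        if not (0 < crows <= rows and 0 < ccols <= cols):
            raise ConfigError("crop_shape must fit inside the spectral support")

    @property
    def half_shape(self) -> tuple[int, int]:
        """Frame shape with both dimensions halved (half resolution)."""
        return (self.frame_shape[0] // 2, self.frame_shape[1] // 2)

    @property
    def full_shape(self) -> tuple[int, int]:
        return self.frame_shape

    @property
    def half_pixel_um(self) -> float:
        """Pixel size of the half-resolution reconstruction (2x pixel_um)."""
        return 2.0 * self.pixel_um


def lateral_resolution(cfg: OpticsConfig) -> float:
    """Rayleigh lateral resolution 0.61*lambda/NA in micrometres."""
    return 0.61 * cfg.wavelength_um / cfg.numerical_aperture


def spot_diameter_pixels(cfg: OpticsConfig) -> int:
    """Diffraction spot diameter on the detector, nearest whole pixel."""
    return int(round(lateral_resolution(cfg) / cfg.pixel_um))


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables on top of the optics constants.

    Units: phases in radians, distances in micrometres, positions in
    pixels (full resolution unless a field name says half).
    """

    optics: OpticsConfig = field(default_factory=OpticsConfig)

    # --- phase retrieval ---
    carrier_min_peak_ratio: float = 10.0   # peak must exceed ratio x median |spectrum|
    dc_exclude_rows: int = 8               # half-height of the DC exclusion zone
    dc_exclude_cols: int = 64              # half-width of the DC exclusion zone

    # --- unwrapping ---
    unwrap_block_cols: int = 20
    unwrap_overlap_cols: int = 4
    unwrap_batch_frames: int = 20
    branchcut_max_box: int = 8

    # --- post-processing ---
    postprocess_batch_frames: int = 40
    row_fit_degree: int = 3
    row_fit_mask_threshold: float = 0.5    # rad; residuals above this excluded on re-fit
    row_fit_robust: bool = True

    # --- cell detection ---
    detect_batch_frames: int = 80
    mask_threshold: float = 0.3            # rad, binary mask threshold
    kernel_width: int = 24                 # half-res px
    kernel_disk_diameter: int = 20         # half-res px
    kernel_edge_rows: int = 4
    kernel_edge_value: float = -8.0
    peak_threshold: float | None = None    # default: 0.5 x kernel positive sum
    background_threshold_frac: float = 0.1
    min_separation_frames: int = 5

    # --- refocusing ---
    crop_size: int = 96                    # full-res px, cell and background crop
    autofocus_d_min: float = -24.0
    autofocus_d_max: float = 24.0
    autofocus_n: int = 32
    calib_n_cells: int = 128
    fine_step_um: float = 0.1
    propagate_before_divide: bool = False  # True: propagate cell & background separately

    # --- morphology ---
    morph_threshold: float = 0.3           # rad; reuses the detection threshold
    opening_radius: int = 1
    circularity_printed_form: bool = False
    filter_area_um2: tuple[float, float] = (20.0, 90.0)
    filter_ov_um3: tuple[float, float] = (10.0, 150.0)
    filter_eccentricity_max: float = 0.8
    filter_circularity_min: float = 0.7

    # --- evaluation ---
    ssim_c1: float = 2.22e-3
    ssim_c2: float = 2.00e-2

    def __post_init__(self) -> None:
        if self.unwrap_overlap_cols >= self.unwrap_block_cols:
            raise ConfigError("unwrap_overlap_cols must be smaller than unwrap_block_cols")
        if self.autofocus_n < 2:
            raise ConfigError("autofocus_n must be at least 2")
        if not self.autofocus_d_min < self.autofocus_d_max:
            raise ConfigError("autofocus distance range is empty")
        for name in ("filter_area_um2", "filter_ov_um3"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: min exceeds max")
        if self.ssim_c1 <= 0 or self.ssim_c2 <= 0:
            raise ConfigError("SSIM stabilizing constants must be positive")

    # ------------------------------------------------------------------
    @property
    def effective_peak_threshold(self) -> float:
        """Detection peak threshold; default half the kernel's positive mass."""
        if self.peak_threshold is not None:
            return self.peak_threshold
        from .detection import make_kernel  # local import avoids a cycle

        k = make_kernel(self)
        return 0.5 * float(k[k > 0].sum())

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    # ------------------------------------------------------------------
    # flat key-value (YAML) serialisation
    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        optics_fields = {f.name for f in dataclasses.fields(OpticsConfig)}
        pipe_fields = {f.name for f in dataclasses.fields(cls)} - {"optics"}
        tuple_fields = {
            "frame_shape", "crop_shape", "filter_area_um2", "filter_ov_um3",
        }
        okw: dict[str, Any] = {}
        pkw: dict[str, Any] = {}
        for key, value in data.items():
            if key in tuple_fields and isinstance(value, (list, tuple)):
                value = tuple(value)
            if key in optics_fields:
                okw[key] = value
            elif key in pipe_fields:
                pkw[key] = value
            else:
                raise ConfigError(f"unknown configuration key: {key!r}")
        return cls(optics=OpticsConfig(**okw), **pkw)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(OpticsConfig):
            out[f.name] = getattr(self.optics, f.name)
        for f in dataclasses.fields(type(self)):
            if f.name != "optics":
                out[f.name] = getattr(self, f.name)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in out.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a flat key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
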