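"""Refocusing-quality evaluation harness.

The three-depth real-time refocusing is benchmarked against a
"traditional" oracle: exhaustive amplitude-variance minimisation on a
0.1 um grid.  For every cell three images are compared — the
background-divided crop *before* refocusing, the real-time *after*
image, and the finely refocused reference — via five morphological
parameter errors (optical volume, projection area and mean OPL as
percent errors; eccentricity and circularity as absolute differences),
the RMSE of the optical-path-length map, and a global SSIM.  The
population report gives mean and 95th percentile of each metric before
and after, with the before/after improvement factor (not defined for
SSIM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import OpticsConfig, PipelineConfig
from .morphology import NoObjectError, cell_mask, corner_offset, measure
from .refocus import CellCrop, Propagator, divide_background, thin_object_phase

__all__ = [
    "SSIMParams",
    "EvaluationReport",
    "fine_refocus",
    "ssim",
    "rmse_opl",
    "compare_populations",
    "acquisition_rate",
    "format_report",
]

METRICS = [
    "ov_percent_error",
    "area_percent_error",
    "mean_opl_percent_error",
    "eccentricity_abs_diff",
    "circularity_abs_diff",
    "rmse_opl_um",
    "ssim",
]


@dataclass(frozen=True)
class SSIMParams:
    """Stabilising constants of the global structural-similarity index."""

    c1: float = 2.22e-3
    c2: float = 2.00e-2

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM constants must be positive")


@dataclass
class EvaluationReport:
    """Population comparison of refocusing quality, one row per metric."""

    metrics: dict
    n_cells: int
    n_skipped: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"n_cells": self.n_cells, "n_skipped": self.n_skipped,
             "metrics": self.metrics}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        data = json.loads(Path(path).read_text())
        return cls(metrics=data["metrics"], n_cells=data["n_cells"],
                   n_skipped=data.get("n_skipped", 0))


def fine_refocus(crop: CellCrop | np.ndarray, wavelength_um: float | None = None,
                 pixel_um: float | None = None, d_min: float = -24.0,
                 d_max: float = 24.0, step: float = 0.1) -> float:
    """Exhaustive amplitude-variance refocus on a fine distance grid.

    Accepts a :class:`CellCrop` (background-divided first) or a raw
    complex field.  This is the traditional, per-cell refocusing used as
    ground truth when assessing the calibrated three-depth method.
    """
    if isinstance(crop, CellCrop):
        field = divide_background(crop)
        pixel_um = crop.pixel_um
    else:
        field = np.asarray(crop, dtype=complex)
    if wavelength_um is None:
        wavelength_um = OpticsConfig().wavelength_um
    if pixel_um is None:
        pixel_um = OpticsConfig().pixel_um
    distances = np.arange(d_min, d_max + step / 2.0, step)
    prop = Propagator(field, wavelength_um, pixel_um)
    variances = np.array([prop.variance_at(d) for d in distances])
    best = min(range(distances.size),
               key=lambda i: (variances[i], abs(distances[i])))
    return float(distances[best])


def ssim(x: np.ndarray, y: np.ndarray, p: SSIMParams | None = None) -> float:
    """Global structural similarity from whole-image statistics.

    SSIM = (2*mu_x*mu_y + c1)(2*sigma_xy + c2)
         / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)),
    with population variances and covariance over all pixels.
    """
    p = p or SSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float((2 * mx * my + p.c1) * (2 * cov + p.c2)
                 / ((mx ** 2 + my ** 2 + p.c1) * (vx + vy + p.c2)))


def rmse_opl(x: np.ndarray, y: np.ndarray,
             wavelength_um: float = 0.640) -> float:
    """Root mean square error on the optical-path-length scale (um)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    return float(np.sqrt(np.mean((x - y) ** 2)) * wavelength_um / (2.0 * np.pi))


# ----------------------------------------------------------------------
# population comparison


def _params(img: np.ndarray, cfg: PipelineConfig):
    """Offset-correct, mask and measure one phase image."""
    img = img - corner_offset(img)
    mask = cell_mask(img, threshold=cfg.morph_threshold,
                     opening_radius=cfg.opening_radius)
    return img, measure(img, mask, cfg.optics,
                        circularity_printed_form=cfg.circularity_printed_form)


def _percent(v: float, ref: float) -> float:
    return abs(v - ref) / abs(ref) * 100.0


def _cell_metrics(img: np.ndarray, ref_img: np.ndarray,
                  cfg: PipelineConfig, params: SSIMParams) -> dict:
    imgc, m = _params(img, cfg)
    refc, r = _params(ref_img, cfg)
    return {
        "ov_percent_error": _percent(m.ov_um3, r.ov_um3),
        "area_percent_error": _percent(m.area_um2, r.area_um2),
        "mean_opl_percent_error": _percent(m.mean_opl_um, r.mean_opl_um),
        "eccentricity_abs_diff": abs(m.eccentricity - r.eccentricity),
        "circularity_abs_diff": abs(m.circularity - r.circularity),
        "rmse_opl_um": rmse_opl(imgc, refc, cfg.optics.wavelength_um),
        "ssim": ssim(imgc, refc, params),
    }


def compare_populations(cells, cfg: PipelineConfig | None = None,
                        ) -> EvaluationReport:
    """Table of refocusing-quality statistics over a cell population.

    ``cells`` is a sequence of (before, after, fine) phase-image
    triplets: the unrefocused background-divided crop, the real-time
    three-depth result, and the finely refocused reference.  Cells in
    which any of the three images yields no segmentable object are
    skipped and counted.  Percentile is the linear-interpolation
    quantile; factors are before/after (omitted for SSIM).
    """
    cfg = cfg or PipelineConfig()
    params = SSIMParams(cfg.ssim_c1, cfg.ssim_c2)
    cells = list(cells)
    if len(cells) < 2:
        raise ValueError("population comparison needs at least 2 cells")
    before_rows, after_rows = [], []
    skipped = 0
    for before, after, fine in cells:
        try:
            before_rows.append(_cell_metrics(before, fine, cfg, params))
            after_rows.append(_cell_metrics(after, fine, cfg, params))
        except NoObjectError:
            skipped += 1
    if not before_rows:
        raise ValueError("no measurable cells in the population")

    metrics: dict = {}
    for key in METRICS:
        b = np.array([row[key] for row in before_rows])
        a = np.array([row[key] for row in after_rows])
        entry = {
            "mean_before": float(b.mean()),
            "mean_after": float(a.mean()),
            "p95_before": float(np.percentile(b, 95)),
            "p95_after": float(np.percentile(a, 95)),
        }
        if key == "ssim":
            entry["mean_factor"] = None
            entry["p95_factor"] = None
        else:
            # factor undefined when the "after" error is exactly zero
            entry["mean_factor"] = (entry["mean_before"] / entry["mean_after"]
                                    if entry["mean_after"] else None)
            entry["p95_factor"] = (entry["p95_before"] / entry["p95_after"]
                                   if entry["p95_after"] else None)
        metrics[key] = entry
    return EvaluationReport(metrics=metrics, n_cells=len(before_rows),
                            n_skipped=skipped)


def evaluate_synthetic_population(n_cells: int = 200,
                                  cfg: PipelineConfig | None = None,
                                  seed: int = 0,
                                  calib_n: int | None = None):
    """Run the full refocusing-quality benchmark on synthetic cells.

    Generates a defocused cell population along the default focal-plane
    tilt, calibrates the quadratic refocus curve on the first cells by
    exhaustive autofocus (as the pipeline does), applies three-depth
    refocusing to every cell, finely refocuses each on the 0.1 um grid,
    and returns (report, info) where ``info`` carries the calibration
    and per-cell refocus distances.
    """
    from .refocus import autofocus, calibrate_focus, refocus_cell
    from .simulate import make_defocused_population

    cfg = cfg or PipelineConfig()
    opt = cfg.optics
    calib_n = calib_n if calib_n is not None else cfg.calib_n_cells
    population = make_defocused_population(n_cells, opt, seed=seed)

    pairs = []
    for cell in population[:min(calib_n, n_cells)]:
        quotient = divide_background(cell.crop)
        d_star, _, _ = autofocus(quotient, opt.wavelength_um, opt.pixel_um,
                                 d_min=cfg.autofocus_d_min,
                                 d_max=cfg.autofocus_d_max, n=cfg.autofocus_n)
        pairs.append((cell.crop.x_full, d_star))
    calib = calibrate_focus(pairs, n_target=calib_n)

    triplets = []
    fine_d, realtime_d = [], []
    for cell in population:
        quotient = divide_background(cell.crop)
        before = thin_object_phase(quotient)
        ref = refocus_cell(cell.crop, calib, opt.wavelength_um,
                           propagate_before_divide=cfg.propagate_before_divide)
        d_fine = fine_refocus(quotient, opt.wavelength_um, opt.pixel_um,
                              d_min=cfg.autofocus_d_min,
                              d_max=cfg.autofocus_d_max, step=cfg.fine_step_um)
        fine = thin_object_phase(Propagator(quotient, opt.wavelength_um,
                                               opt.pixel_um).at(d_fine))
        triplets.append((before, ref.phase, fine))
        fine_d.append(d_fine)
        realtime_d.append(ref.distance_um)
    report = compare_populations(triplets, cfg)
    info = {
        "calibration": calib,
        "fine_distances_um": np.array(fine_d),
        "realtime_distances_um": np.array(realtime_d),
        "true_refocus_um": np.array([c.refocus_um for c in population]),
    }
    return report, info


def acquisition_rate(n_objects: int, n_frames: int, fps: float) -> float:
    """Objects per second of acquisition, to 2 decimals."""
    if n_frames <= 0 or fps <= 0:
        raise ValueError("n_frames and fps must be positive")
    return round(n_objects / (n_frames / fps), 2)


_LABELS = {
    "ov_percent_error": "OV (% error)",
    "area_percent_error": "Area (% error)",
    "mean_opl_percent_error": "Mean OPL (% error)",
    "eccentricity_abs_diff": "Eccentricity (abs diff)",
    "circularity_abs_diff": "Circularity (abs diff)",
    "rmse_opl_um": "RMSE of OPL (um)",
    "ssim": "SSIM",
}


def format_report(report: EvaluationReport) -> str:
    """Plain-text table: mean and 95th percentile, before/after/factor."""
    lines = [
        f"Refocusing evaluation over {report.n_cells} cells"
        + (f" ({report.n_skipped} skipped)" if report.n_skipped else ""),
        f"{'Metric':<26}{'mean before':>12}{'mean after':>12}{'factor':>8}"
        f"{'p95 before':>12}{'p95 after':>12}{'factor':>8}",
    ]
    for key in METRICS:
        e = report.metrics[key]

        def fmt(v):
            return "NA" if v is None else f"{v:.4g}"

        lines.append(
            f"{_LABELS[key]:<26}{fmt(e['mean_before']):>12}"
            f"{fmt(e['mean_after']):>12}{fmt(e['mean_factor']):>8}"
            f"{fmt(e['p95_before']):>12}{fmt(e['p95_after']):>12}"
            f"{fmt(e['p95_factor']):>8}")
    return "\n".join(lines)
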