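"""End-to-end orchestration: raw interferogram stack to per-cell outputs.

Frames stream through the stages in batches — demodulation per frame,
unwrapping, post-processing in 40-frame batches, detection in 80-frame
batches — then each detected cell is cropped from the full-resolution
complex field, background-divided, refocused (exhaustive autofocus for
the first cells, the calibrated three-depth method afterwards) and
quantified.  Accepted cells are written as one 32-bit float TIFF each,
with detections and morphology in CSV and a JSON run manifest.

Processing is deterministic: a given input stack and configuration
always produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .background import postprocess_batch
from .config import PipelineConfig
from .detection import (CellDetection, assign_background_frames, binarize,
                        correlate_batch, detect_cells, find_background_frames,
                        make_kernel)
from .morphology import NoObjectError, RBCFilter, cell_mask, corner_offset, \
    filter_cell, measure
from .refocus import (CellCrop, Propagator, autofocus, calibrate_focus,
                      divide_background, refocus_cell, thin_object_phase)
from .retrieval import calibrate_carrier, demodulate, wrapped_phase
from .simulate import read_acquisition
from .unwrap import place_branch_cuts, residues, unwrap_frame

__all__ = ["RunManifest", "CellResult", "run_pipeline", "subsample_cells"]

log = logging.getLogger(__name__)


@dataclass
class CellResult:
    """One refocused, measured cell."""

    cell_id: int
    frame_index: int
    x_full: int
    score: float
    background_frame: int | None
    refocus_distance_um: float
    phase: np.ndarray = field(repr=False, default=None)
    morphology: object = None
    accepted: bool = False


@dataclass
class RunManifest:
    """Counts and calibration artefacts of one pipeline run."""

    frames_read: int = 0
    objects_detected: int = 0
    cells_refocused: int = 0
    cells_accepted: int = 0
    carrier_peak: tuple[int, int] | None = None
    crop_window: tuple[int, int, int, int] | None = None
    focus_coeffs: tuple[float, float, float] | None = None
    focus_residual_std: float | None = None
    focus_n_cells: int = 0
    config_digest: str = ""
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _batches(n: int, size: int, minimum: int = 1):
    """Slices of `size`; a trailing remnant shorter than `minimum` merges
    into the previous batch."""
    starts = list(range(0, n, size))
    slices = [(s, min(s + size, n)) for s in starts]
    if len(slices) > 1 and slices[-1][1] - slices[-1][0] < minimum:
        s0, _ = slices[-2]
        slices[-2] = (s0, n)
        slices.pop()
    return slices


def run_pipeline(frames: np.ndarray | str | Path, cfg: PipelineConfig | None = None,
                 out_dir: str | Path | None = None,
                 ) -> tuple[RunManifest, list[CellResult]]:
    """Process an acquisition; returns the manifest and per-cell results.

    ``frames`` is an (n, rows, cols) intensity array or the path of a
    multi-page TIFF.  Aborts on carrier-calibration failure; per-cell
    failures (no background frame, unsegmentable object, edge crops)
    are logged and skipped.
    """
    cfg = cfg or PipelineConfig()
    opt = cfg.optics
    if isinstance(frames, (str, Path)):
        frames = read_acquisition(frames)
    frames = np.asarray(frames)
    n_frames = frames.shape[0]
    manifest = RunManifest(frames_read=n_frames, config_digest=cfg.digest())

    calib = calibrate_carrier(frames[0], opt,
                              min_peak_ratio=cfg.carrier_min_peak_ratio,
                              dc_exclude_rows=cfg.dc_exclude_rows,
                              dc_exclude_cols=cfg.dc_exclude_cols)
    manifest.carrier_peak = calib.peak_index
    manifest.crop_window = calib.crop_window

    kernel = make_kernel(cfg)
    peak_thr = cfg.effective_peak_threshold
    zero_thr = cfg.background_threshold_frac * peak_thr
    rbc_filter = RBCFilter(area_um2=cfg.filter_area_um2,
                           ov_um3=cfg.filter_ov_um3,
                           eccentricity_max=cfg.filter_eccentricity_max,
                           circularity_min=cfg.filter_circularity_min)

    half = cfg.crop_size // 2
    cols_full = opt.frame_shape[1]
    detections: list[CellDetection] = []
    results: list[CellResult] = []
    first_cells: list[tuple[int, float]] = []   # (x_full, d*) calibration pairs
    focus_calib = None
    last_bg: tuple[int, np.ndarray] | None = None   # most recent empty frame
    prev_accepted: list[CellDetection] = []
    cell_id = 0

    def crop_cols(x_full: int) -> tuple[int, int] | None:
        lo, hi = x_full - half, x_full + half
        if lo < 0 or hi > cols_full:
            return None
        return lo, hi

    def refocus_and_measure(det: CellDetection, crop: CellCrop,
                            distance: float | None) -> CellResult:
        nonlocal cell_id
        quotient = divide_background(crop)
        if distance is None:
            ref = refocus_cell(crop, focus_calib, opt.wavelength_um,
                               propagate_before_divide=cfg.propagate_before_divide)
            phase, dist = ref.phase, ref.distance_um
        else:
            moved = Propagator(quotient, opt.wavelength_um, crop.pixel_um).at(distance)
            phase, dist = thin_object_phase(moved), distance
        res = CellResult(cell_id=cell_id, frame_index=det.frame_index,
                         x_full=det.x_full, score=det.score,
                         background_frame=det.background_frame,
                         refocus_distance_um=dist, phase=phase)
        cell_id += 1
        img = phase - corner_offset(phase)
        try:
            mask = cell_mask(img, threshold=cfg.morph_threshold,
                             opening_radius=cfg.opening_radius)
            res.morphology = measure(img, mask, opt,
                                     circularity_printed_form=cfg.circularity_printed_form)
            res.accepted = filter_cell(res.morphology, rbc_filter)
        except NoObjectError:
            log.info("cell %d at frame %d: no object after refocus",
                     res.cell_id, det.frame_index)
        return res

    for b0, b1 in _batches(n_frames, cfg.detect_batch_frames):
        halves = []
        fulls = []
        for t in range(b0, b1):
            h, f = demodulate(frames[t], calib, opt)
            halves.append(h)
            fulls.append(f.values.astype(np.complex64))
        psis = [wrapped_phase(h) for h in halves]
        unwrapped = []
        for psi in psis:
            res = residues(psi)
            cuts = place_branch_cuts(res, psi.shape, max_box=cfg.branchcut_max_box)
            unwrapped.append(unwrap_frame(psi, cuts,
                                          block_cols=cfg.unwrap_block_cols,
                                          overlap_cols=cfg.unwrap_overlap_cols))
        unwrapped = np.stack(unwrapped)
        cleaned = np.concatenate([
            postprocess_batch(unwrapped[s0:s1],
                              mask_threshold=cfg.row_fit_mask_threshold,
                              robust=cfg.row_fit_robust,
                              degree=cfg.row_fit_degree)
            for s0, s1 in _batches(b1 - b0, cfg.postprocess_batch_frames,
                                   minimum=5)])
        masks = binarize(cleaned, cfg.mask_threshold)
        corr = correlate_batch(masks, kernel)
        dets = detect_cells(corr, peak_thr,
                            min_separation_x=cfg.kernel_width,
                            min_separation_t=cfg.min_separation_frames,
                            frame_offset=b0, previous=prev_accepted)
        bg_frames = find_background_frames(corr, zero_thr, frame_offset=b0)
        if last_bg is not None:
            assign_background_frames(dets, bg_frames + [last_bg[0]])
        else:
            assign_background_frames(dets, bg_frames)
        detections.extend(dets)
        prev_accepted = dets

        bg_fields = {i: fulls[i - b0] for i in bg_frames}
        if last_bg is not None:
            bg_fields[last_bg[0]] = last_bg[1]
        if bg_frames:
            last_bg = (bg_frames[-1], fulls[bg_frames[-1] - b0])

        for det in dets:
            if det.background_frame is None:
                log.warning("detection at frame %d has no background frame; "
                            "refocusing skipped", det.frame_index)
                continue
            cc = crop_cols(det.x_full)
            if cc is None:
                log.info("detection at frame %d, x=%d: crop exceeds the frame",
                         det.frame_index, det.x_full)
                continue
            lo, hi = cc
            cell_field = fulls[det.frame_index - b0][:, lo:hi].astype(complex)
            bg_field = bg_fields[det.background_frame][:, lo:hi].astype(complex)
            crop = CellCrop(cell_field=cell_field, background_field=bg_field,
                            pixel_um=opt.pixel_um, x_full=det.x_full,
                            frame_index=det.frame_index,
                            background_frame=det.background_frame)
            if focus_calib is None:
                quotient = divide_background(crop)
                d_star, _, _ = autofocus(quotient, opt.wavelength_um,
                                         opt.pixel_um,
                                         d_min=cfg.autofocus_d_min,
                                         d_max=cfg.autofocus_d_max,
                                         n=cfg.autofocus_n)
                first_cells.append((det.x_full, d_star))
                results.append(refocus_and_measure(det, crop, d_star))
                if len(first_cells) >= cfg.calib_n_cells:
                    focus_calib = calibrate_focus(first_cells,
                                                  n_target=cfg.calib_n_cells)
            else:
                results.append(refocus_and_measure(det, crop, None))

    if focus_calib is None and len(first_cells) >= 3:
        focus_calib = calibrate_focus(first_cells, n_target=cfg.calib_n_cells)
    if focus_calib is not None:
        manifest.focus_coeffs = focus_calib.coeffs
        manifest.focus_residual_std = focus_calib.residual_std
        manifest.focus_n_cells = focus_calib.n_cells_used

    manifest.objects_detected = len(detections)
    manifest.cells_refocused = len(results)
    manifest.cells_accepted = sum(r.accepted for r in results)

    if out_dir is not None:
        _write_outputs(Path(out_dir), manifest, detections, results)
    return manifest, results


def _write_outputs(out_dir: Path, manifest: RunManifest,
                   detections: list[CellDetection],
                   results: list[CellResult]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    det_df = pd.DataFrame([{
        "frame_index": d.frame_index, "x_half": d.x_half, "x_full": d.x_full,
        "score": d.score, "background_frame": d.background_frame,
    } for d in detections])
    det_df.to_csv(out_dir / "detections.csv", index=False, float_format="%.6g")

    rows = []
    cells_dir = out_dir / "cells"
    cells_dir.mkdir(exist_ok=True)
    for r in results:
        m = r.morphology
        rows.append({
            "cell_id": r.cell_id, "frame_index": r.frame_index,
            "x_full": r.x_full, "refocus_distance_um": r.refocus_distance_um,
            "area_um2": m.area_um2 if m else np.nan,
            "ov_um3": m.ov_um3 if m else np.nan,
            "mean_opl_um": m.mean_opl_um if m else np.nan,
            "eccentricity": m.eccentricity if m else np.nan,
            "circularity": m.circularity if m else np.nan,
            "accepted": bool(r.accepted),
        })
        if r.accepted:
            tifffile.imwrite(cells_dir / f"cell_{r.cell_id:06d}.tif",
                             r.phase.astype(np.float32))
    pd.DataFrame(rows).to_csv(out_dir / "cells.csv", index=False,
                              float_format="%.6g")
    manifest.to_json(out_dir / "manifest.json")


def subsample_cells(detections: list, keep_fraction: float | None = None,
                    duplicate_factor: int | None = None, seed: int = 0) -> list:
    """Seeded random subset or cyclic duplication of a detection list.

    Emulates different cell concentrations by ignoring or repeatedly
    processing a proportion of cells from the same acquisition.
    """
    if (keep_fraction is None) == (duplicate_factor is None):
        raise ValueError("give exactly one of keep_fraction or duplicate_factor")
    if keep_fraction is not None:
        if not 0 < keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if keep_fraction == 1.0:
            return list(detections)
        rng = np.random.default_rng(seed)
        n = int(round(keep_fraction * len(detections)))
        idx = np.sort(rng.choice(len(detections), size=n, replace=False))
        return [detections[i] for i in idx]
    if duplicate_factor < 1:
        raise ValueError("duplicate_factor must be >= 1")
    return [d for _ in range(duplicate_factor) for d in detections]
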