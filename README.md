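# holocyte

CPU processing pipeline for high-throughput off-axis quantitative phase
microscopy (QPM) of flowing cells — holographic cytometry.

Holographic cytometry records off-axis interferograms of cells streaming
through a microfluidic channel under stroboscopic illumination, at rates
of hundreds of cells per second.  Each raw 96 × 4096 frame encodes the
complex optical field of the sample on a spatial-frequency carrier; the
phase of that field is proportional to the optical path delay through
each cell and yields quantitative morphology — without labels.  This
package implements the complete chain from raw frames to per-cell
measurements, plus a seeded simulator so every stage is testable without
an instrument:

1. **Demodulation** — locate the cross-correlation sideband in the 2D
   spectrum of the first frame, then per frame crop a 20 × 874 spectral
   ROI, recentre it, and inverse transform at two paddings: a 48 × 2048
   half-resolution field (unwrapping, detection) and a 96 × 4096
   full-resolution field (refocusing).
2. **Goldstein branch-cut unwrapping**, in tiled form: residues
   R = Sign(Σ Wrap(Δψ)) on every 2 × 2 loop, shortest branch cuts to
   opposite charges or the frame edge, flood-fill integration
   φ(x,y) = φ(x′,y′) + Wrap(ψ(x,y) − ψ(x′,y′)) in 128 blocks of
   20 × 48 px with 4-column overlaps, merged by the mode of the
   2π-rounded block differences.
3. **Background removal** over 40-frame batches: temporal 2π-jump
   correction against the per-pixel median, per-row cubic polynomial
   fits (the field of view is 43× wider than tall), and subtraction of
   the temporal-median static map (channel walls, dust, residual
   unwrapping errors).
4. **Cell detection** over 80-frame batches: threshold at 0.3 rad,
   FFT cross-correlation along x with a kernel whose negative edge
   bands reject cells clipped by the field of view; local maxima of the
   80 × 2048 correlation map are cells centred in the short axis, and
   near-zero-correlation frames become background references.
5. **Digital refocusing**: 96 × 96 cell and background crops, complex
   division (thin objects need no unwrapping), angular-spectrum
   propagation U′ = F⁻¹{F{U}·exp(i2πd√(1/λ² − f²))}, and amplitude-
   variance autofocus over 32 distances in [−24, 24] µm.  The first 128
   cells calibrate a quadratic d(x) = ax² + bx + c of refocus distance
   versus lateral position (the focal plane is tilted); every later
   cell is refocused at just three depths, d(x) and d(x) ± σ of the
   regression.
6. **Morphology**: projection area A, optical volume
   OV = dA·Σ φλ/2π, mean optical path length, moment eccentricity, and
   circularity 4πA/C², with rule-based bounds selecting single red
   blood cells.
7. **Evaluation**: a 0.1 µm exhaustive-refocus oracle, per-cell errors
   of five morphological parameters, RMSE of the OPL map, global SSIM,
   and a population report of means, 95th percentiles and improvement
   factors.

## Worked example

Simulate an 80-frame acquisition with 6 flowing cells and process it:

```sh
$ holocyte simulate --out-dir demo --seed 7 --n-frames 80 --n-cells 6
wrote 80 frames to demo/frames.tif

$ holocyte process demo/frames.tif --out-dir demo/run
frames: 80  detected: 6  accepted: 6

$ head -4 demo/run/cells.csv
cell_id,frame_index,x_full,refocus_distance_um,area_um2,ov_um3,mean_opl_um,eccentricity,circularity,accepted
0,8,3604,-11.6129,49.3684,12.2467,0.248068,0.193909,0.992878,True
1,18,2486,-5.41935,48.2145,12.1,0.250962,0.191681,1.00947,True
2,28,2690,-6.96774,51.6761,12.681,0.245393,0.160456,0.983149,True
```

All six planted cells are detected at the frame where they cross the
centre of the field of view.  `refocus_distance_um` is the propagation
distance that restored focus: the simulated focal plane tilts across
the sensor, so the cell at column 3604 needed −11.6 µm while the cell
at column 2486 needed −5.4 µm.  Areas near 50 µm², optical volumes near
12 µm³, eccentricities below 0.2 and circularities near 1 are what a
healthy, nearly circular red-blood-cell phantom should measure, so all
rows pass the RBC filter (`accepted`).  Refocused cell images are
written as 32-bit float TIFFs under `demo/run/cells/`, and
`demo/run/manifest.json` records the carrier peak and the fitted focus
curve.

Benchmark three-depth refocusing against the 0.1 µm exhaustive oracle:

```sh
$ holocyte evaluate --n-cells 40 --seed 3 --out report.json
```

prints a table of mean/95th-percentile errors before and after
refocusing with improvement factors; mean SSIM rises from ~0.86
(defocused crops) to ~0.996 after three-depth refocusing.

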