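"""Goldstein unwrapping: residues, cuts, flood fill, tiled merging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from holocyte.unwrap import (floodfill_block, place_branch_cuts, residues,
                             unwrap_batch, unwrap_frame, unwrap_phase, wrap,
                             wrap_diff)
from tests.conftest import smooth_wrapped_field

TWO_PI = 2 * np.pi


# ----------------------------------------------------------------------
# wrapping arithmetic


@pytest.mark.parametrize("a,b,expected", [
    (0.0, 0.0, 0.0),
    (-3 * np.pi / 4, 3 * np.pi / 4, -np.pi / 2),   # wrap(3*pi/2)
    (0.3, 0.3 + np.pi, np.pi),                     # boundary maps to +pi
    (-2.0, -2.0 + np.pi, np.pi),
])
def test_wrap_diff_hand_values(a, b, expected):
    assert wrap_diff(a, b) == pytest.approx(expected, abs=1e-12)


@given(st.floats(-50, 50))
def test_wrap_principal_interval(x):
    w = float(wrap(x))
    assert -np.pi < w <= np.pi
    # differs from the input by an integer multiple of 2*pi
    k = (x - w) / TWO_PI
    assert abs(k - round(k)) < 1e-9


# ----------------------------------------------------------------------
# residues


def test_constant_field_has_no_residues():
    assert not residues(np.full((8, 9), 1.3)).any()


def test_single_vortex_plaquette_charge():
    # counter-clockwise values 0, pi/2, pi, -pi/2 around one 2x2 loop:
    # four wrapped steps of pi/2 sum to 2*pi -> charge +1
    psi = np.array([[0.0, -np.pi / 2],
                    [np.pi / 2, np.pi]])
    assert residues(psi)[0, 0] == 1
    assert residues(-psi)[0, 0] == -1


@given(hnp.arrays(np.float64, (6, 7), elements=st.floats(-3.14, 3.14)))
def test_residues_antisymmetric_and_bounded(psi):
    # antisymmetry holds wherever no difference sits exactly on the +-pi
    # boundary, where the half-open (-pi, pi] interval breaks the symmetry
    r = residues(psi)
    assert set(np.unique(r)).issubset({-1, 0, 1})
    np.testing.assert_array_equal(residues(-psi), -r)


def test_residues_of_spiral_phase():
    # a phase vortex centred mid-grid leaves exactly one net charge
    y, x = np.mgrid[0:16, 0:16]
    psi = wrap(np.arctan2(y - 7.5, x - 7.5))
    r = residues(psi)
    assert np.abs(r).sum() == 1


# ----------------------------------------------------------------------
# branch cuts


def test_no_residues_no_cuts():
    cuts = place_branch_cuts(np.zeros((7, 7), dtype=np.int8), (8, 8))
    assert not cuts.any()


def test_lone_residue_cuts_to_nearest_edge():
    res = np.zeros((15, 15), dtype=np.int8)
    res[2, 7] = 1    # distance 2 from the top edge, far from all others
    cuts = place_branch_cuts(res, (16, 16))
    assert cuts[0, 7] and cuts[1, 7] and cuts[2, 7]
    assert cuts.sum() == 3   # a straight vertical cut of length 2 (inclusive)


def test_dipole_joined_without_edge_cut():
    res = np.zeros((15, 15), dtype=np.int8)
    res[7, 6] = 1
    res[7, 7] = -1
    cuts = place_branch_cuts(res, (16, 16))
    assert cuts[7, 6] and cuts[7, 7]
    assert cuts.sum() == 2
    assert not cuts[0].any() and not cuts[-1].any()


def test_all_residues_balanced_or_edge_connected():
    rng = np.random.default_rng(7)
    psi = wrap(rng.uniform(-8, 8, size=(20, 30)))
    res = residues(psi)
    cuts = place_branch_cuts(res, psi.shape)
    # every residue must lie on the cut mask it generated
    rr, cc = np.nonzero(res)
    assert cuts[rr, cc].all()


# ----------------------------------------------------------------------
# flood fill


def test_smooth_field_unchanged_by_flood_fill():
    rng = np.random.default_rng(0)
    psi = np.cumsum(rng.uniform(-0.1, 0.1, size=(10, 12)), axis=1) + 0.2
    out = floodfill_block(psi)
    np.testing.assert_allclose(out, psi, atol=1e-12)


def test_ramp_recovered_against_cumsum_oracle():
    x = np.arange(200, dtype=float)
    phi_true = 0.4 * x                      # wraps many times
    psi = wrap(phi_true)[None, :]
    # independent oracle: cumulative sum of wrapped differences
    oracle = np.concatenate([[psi[0, 0]],
                             psi[0, 0] + np.cumsum(wrap(np.diff(psi[0])))])
    out = floodfill_block(psi)
    np.testing.assert_allclose(out[0], oracle, atol=1e-9)
    offs = (out[0] - phi_true) / TWO_PI
    assert np.allclose(offs, round(float(offs[0])), atol=1e-9)


def test_output_minus_input_is_2pi_multiple():
    _, psi = smooth_wrapped_field((24, 40), seed=3)
    out = floodfill_block(psi)
    k = (out - psi) / TWO_PI
    np.testing.assert_allclose(k, np.rint(k), atol=1e-9)


def test_flood_fill_needs_a_seed():
    with pytest.raises(ValueError, match="no seed"):
        floodfill_block(np.zeros((4, 4)), np.ones((4, 4), dtype=bool))


def test_cut_pixels_do_not_propagate():
    # a vertical cut splits the block; the right side must still unwrap
    # consistently from its own seed, and cut pixels get assigned last
    phi = np.tile(0.5 * np.arange(12), (6, 1))
    psi = wrap(phi)
    cuts = np.zeros((6, 12), dtype=bool)
    cuts[:, 5] = True
    out = floodfill_block(psi, cuts)
    assert np.isfinite(out).all()
    k = (out - psi) / TWO_PI
    np.testing.assert_allclose(k, np.rint(k), atol=1e-9)


# ----------------------------------------------------------------------
# tiled unwrapping


def test_128_blocks_for_half_resolution_frame():
    from holocyte.unwrap import _block_starts

    starts = _block_starts(2048, 20, 4)
    assert len(starts) == 128
    assert starts[0] == 0 and starts[-1] == 2032


def test_block_merge_equals_whole_frame_oracle():
    _, psi = smooth_wrapped_field((48, 2048), seed=11)
    assert not residues(psi).any()
    tiled = unwrap_frame(psi)
    whole = floodfill_block(psi)
    k = (tiled - whole) / TWO_PI
    k0 = round(float(np.median(k)))
    np.testing.assert_allclose(k, k0, atol=1e-9)


def test_wrap_consistency_everywhere():
    _, psi = smooth_wrapped_field((48, 512), seed=5)
    out = unwrap_frame(psi)
    np.testing.assert_allclose(wrap(out), psi, atol=1e-9)


def test_block_size_invariance_on_residue_free_field():
    _, psi = smooth_wrapped_field((32, 320), seed=9)
    a = unwrap_frame(psi, block_cols=20, overlap_cols=4)
    b = unwrap_frame(psi, block_cols=40, overlap_cols=8)
    diff = a - b
    assert np.ptp(diff) < 1e-9
    assert abs(diff[0, 0] / TWO_PI - round(diff[0, 0] / TWO_PI)) < 1e-9


def test_unwrap_agrees_with_independent_reference_unwrapper():
    # cross-check against an entirely different algorithm (skimage's
    # reliability-sorted unwrapper) on a residue-free surface
    from skimage.restoration import unwrap_phase as sk_unwrap

    phi, psi = smooth_wrapped_field((48, 256), seed=21)
    ours = unwrap_frame(psi)
    theirs = np.asarray(sk_unwrap(psi))
    d = ours - theirs
    assert np.ptp(d) < 1e-6
    assert abs(d[0, 0] / TWO_PI - round(d[0, 0] / TWO_PI)) < 1e-6


def test_mode_offset_tie_prefers_smallest_magnitude():
    from holocyte.unwrap import _mode_offset

    diff = np.array([TWO_PI, TWO_PI, -2 * TWO_PI, -2 * TWO_PI])
    assert _mode_offset(diff) == pytest.approx(TWO_PI)


def test_batch_matches_per_frame_processing():
    fields = [smooth_wrapped_field((24, 96), seed=s)[1] for s in range(3)]
    batch = unwrap_batch(fields)
    single = [unwrap_phase(psi) for psi in fields]
    for a, b in zip(batch, single):
        np.testing.assert_array_equal(a, b)
    assert unwrap_batch([]) == []
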