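"""Goldstein branch-cut phase unwrapping in tiled (parallel) form.

The wrapped phase psi in (-pi, pi] relates to the true phase phi by
psi = phi + 2*pi*k with integer k.  Unwrapping proceeds in four stages:

1. *Residues*: on every 2x2 plaquette the four wrapped neighbour
   differences are summed around a closed counter-clockwise loop; a sum
   of +-2*pi marks a +-1 residue, a point where path-dependent unwrapping
   would occur.
2. *Branch cuts*: residues are connected to opposite-charge residues or
   to the image edge by the shortest segments (Goldstein's growing-box
   search); unwrapping paths may not cross cuts.
3. *Flood fill*: breadth-first region growing from a seed, each pixel
   unwrapped from an already-unwrapped 4-neighbour by adding the wrapped
   difference; cut pixels are assigned last and never propagate.
4. *Tiled merge*: the frame is split into blocks along the long axis
   (20 columns wide with a 4-column overlap by default, i.e. 128 blocks
   for a 2048-column half-resolution frame), each block is flood-filled
   independently, and adjacent blocks are flattened by the mode of their
   2*pi-rounded phase difference over the overlap.

Residues and cuts are computed once on the whole frame before tiling so
the merge stays consistent across block boundaries.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
from numba import njit

__all__ = [
    "wrap",
    "wrap_diff",
    "residues",
    "place_branch_cuts",
    "floodfill_block",
    "unwrap_frame",
    "unwrap_phase",
    "unwrap_batch",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


def wrap(x):
    """Map phase values to the principal interval (-pi, pi].

    The lower boundary -pi is remapped to +pi.
    """
    return np.pi - np.mod(np.pi - np.asarray(x), TWO_PI)


def wrap_diff(psi1, psi2):
    """Wrapped phase difference Wrap(psi2 - psi1), in (-pi, pi]."""
    return wrap(np.asarray(psi2) - np.asarray(psi1))


def residues(psi: np.ndarray) -> np.ndarray:
    """Residue charges on the (rows-1) x (cols-1) grid of 2x2 plaquettes.

    The closed-loop sum of wrapped differences around each plaquette is
    always in {-2*pi, 0, +2*pi}; the residue is its sign, an int8 array
    with values in {-1, 0, +1}.
    """
    psi = np.asarray(psi, dtype=np.float64)
    a = psi[:-1, :-1]   # (i, j)
    b = psi[:-1, 1:]    # (i, j+1)
    c = psi[1:, 1:]     # (i+1, j+1)
    d = psi[1:, :-1]    # (i+1, j)
    # counter-clockwise in display coordinates (x right, y down):
    # a -> d -> c -> b -> a
    loop = wrap_diff(a, d) + wrap_diff(d, c) + wrap_diff(c, b) + wrap_diff(b, a)
    return np.rint(loop / TWO_PI).astype(np.int8)


# ----------------------------------------------------------------------
# branch cuts


def _bresenham(i0: int, j0: int, i1: int, j1: int):
    """Integer points of the segment (i0,j0)-(i1,j1), inclusive."""
    di, dj = abs(i1 - i0), abs(j1 - j0)
    si = 1 if i1 >= i0 else -1
    sj = 1 if j1 >= j0 else -1
    err = di - dj
    i, j = i0, j0
    while True:
        yield i, j
        if i == i1 and j == j1:
            return
        e2 = 2 * err
        if e2 > -dj:
            err -= dj
            i += si
        if e2 < di:
            err += di
            j += sj
        else:
            # e2 >= di and e2 <= -dj handled above; nothing extra
            pass


def place_branch_cuts(res: np.ndarray, shape: tuple[int, int],
                      max_box: int = 8) -> np.ndarray:
    """Connect residues into a branch-cut mask over pixels of `shape`.

    Goldstein's growing-box search: each unbalanced residue looks in
    Chebyshev boxes of increasing radius (up to ``max_box``) for an
    opposite-charge unbalanced residue (nearest Euclidean, lexicographic
    tie-break) or for the image edge, and is connected by a straight
    rasterized segment.  Every residue ends balanced or edge-connected,
    so the search always terminates.
    """
    rows, cols = shape
    cuts = np.zeros(shape, dtype=bool)
    rr, cc = np.nonzero(res)
    if rr.size == 0:
        return cuts
    charge = res[rr, cc].astype(np.int64)
    balanced = np.zeros(rr.size, dtype=bool)
    # spatial index of residues for box queries
    order = np.lexsort((cc, rr))
    rr, cc, charge = rr[order], cc[order], charge[order]

    def edge_distance(i: int, j: int) -> tuple[int, tuple[int, int]]:
        # distance (in pixels) to the nearest frame edge and its endpoint
        cand = [
            (i, (0, j)),                    # top
            (rows - 1 - i, (rows - 1, j)),  # bottom
            (j, (i, 0)),                    # left
            (cols - 1 - j, (i, cols - 1)),  # right
        ]
        return min(cand, key=lambda t: t[0])

    def draw(i0, j0, i1, j1):
        for i, j in _bresenham(i0, j0, i1, j1):
            cuts[i, j] = True

    for a in range(rr.size):
        if balanced[a]:
            continue
        ia, ja = int(rr[a]), int(cc[a])
        edist, epoint = edge_distance(ia, ja)
        done = False
        for k in range(1, max_box + 1):
            # opposite-charge unbalanced residues within Chebyshev radius k
            sel = (~balanced
                   & (charge == -charge[a])
                   & (np.abs(rr - ia) <= k) & (np.abs(cc - ja) <= k))
            idx = np.nonzero(sel)[0]
            if idx.size:
                d2 = (rr[idx] - ia) ** 2 + (cc[idx] - ja) ** 2
                best = idx[np.lexsort((cc[idx], rr[idx], d2))[0]]
                draw(ia, ja, int(rr[best]), int(cc[best]))
                balanced[a] = balanced[best] = True
                done = True
                break
            if edist <= k:
                draw(ia, ja, *epoint)
                balanced[a] = True
                done = True
                break
        if not done:
            draw(ia, ja, *epoint)
            balanced[a] = True
    return cuts


# ----------------------------------------------------------------------
# flood fill


@njit(cache=True)
def _floodfill_kernel(psi, cuts, phi, visited):  # pragma: no cover - jit
    rows, cols = psi.shape
    queue = np.empty(rows * cols, dtype=np.int64)
    pi = np.pi
    two_pi = 2.0 * np.pi
    # stage 1: BFS over non-cut pixels, multi-seed in row-major order
    for si in range(rows):
        for sj in range(cols):
            if cuts[si, sj] or visited[si, sj]:
                continue
            head = 0
            tail = 0
            queue[tail] = si * cols + sj
            tail += 1
            visited[si, sj] = True
            phi[si, sj] = psi[si, sj]
            while head < tail:
                idx = queue[head]
                head += 1
                i = idx // cols
                j = idx % cols
                base = phi[i, j]
                p = psi[i, j]
                for n in range(4):  # up, down, left, right
                    if n == 0:
                        ni, nj = i - 1, j
                    elif n == 1:
                        ni, nj = i + 1, j
                    elif n == 2:
                        ni, nj = i, j - 1
                    else:
                        ni, nj = i, j + 1
                    if ni < 0 or ni >= rows or nj < 0 or nj >= cols:
                        continue
                    if visited[ni, nj] or cuts[ni, nj]:
                        continue
                    d = psi[ni, nj] - p
                    d = pi - (pi - d) % two_pi
                    phi[ni, nj] = base + d
                    visited[ni, nj] = True
                    queue[tail] = ni * cols + nj
                    tail += 1
    # stage 2: cut pixels are assigned from an already-unwrapped
    # neighbour (never propagating further except along cut chains
    # that no non-cut pixel touches)
    changed = True
    while changed:
        changed = False
        for i in range(rows):
            for j in range(cols):
                if visited[i, j]:
                    continue
                for n in range(4):
                    if n == 0:
                        ni, nj = i - 1, j
                    elif n == 1:
                        ni, nj = i + 1, j
                    elif n == 2:
                        ni, nj = i, j - 1
                    else:
                        ni, nj = i, j + 1
                    if ni < 0 or ni >= rows or nj < 0 or nj >= cols:
                        continue
                    if not visited[ni, nj]:
                        continue
                    d = psi[i, j] - psi[ni, nj]
                    d = pi - (pi - d) % two_pi
                    phi[i, j] = phi[ni, nj] + d
                    visited[i, j] = True
                    changed = True
                    break


def floodfill_block(psi: np.ndarray, cuts: np.ndarray | None = None) -> np.ndarray:
    """Flood-fill unwrap one block (or a whole frame).

    The seed is the first non-cut pixel in row-major order, kept at its
    wrapped value; neighbours are visited breadth-first in the fixed
    order up, down, left, right (4-connectivity).  Pixels on branch cuts
    are assigned last from an unwrapped neighbour and never serve as
    references.
    """
    psi = np.ascontiguousarray(psi, dtype=np.float64)
    if cuts is None:
        cuts = np.zeros(psi.shape, dtype=bool)
    else:
        cuts = np.ascontiguousarray(cuts, dtype=bool)
    if cuts.all():
        raise ValueError("no seed available: every pixel lies on a branch cut")
    phi = np.zeros_like(psi)
    visited = np.zeros(psi.shape, dtype=np.bool_)
    _floodfill_kernel(psi, cuts, phi, visited)
    return phi


# ----------------------------------------------------------------------
# tiled unwrapping with mode flattening


def _block_starts(cols: int, block_cols: int, overlap_cols: int) -> list[int]:
    step = block_cols - overlap_cols
    return list(range(0, cols, step))


def _mode_offset(diff: np.ndarray) -> float:
    """Mode of 2*pi-rounded offsets; ties favour the smallest |offset|."""
    k = np.rint(diff / TWO_PI).astype(np.int64)
    counts = Counter(k.ravel().tolist())
    best = min(counts.items(), key=lambda kv: (-kv[1], abs(kv[0]), kv[0]))
    return TWO_PI * best[0]


def unwrap_frame(psi: np.ndarray, cuts: np.ndarray | None = None,
                 block_cols: int = 20, overlap_cols: int = 4) -> np.ndarray:
    """Unwrap a frame by independent block flood fills plus mode flattening.

    Columns are partitioned into blocks of ``block_cols`` starting every
    ``block_cols - overlap_cols`` columns (the final block is clipped to
    the frame edge, giving 128 blocks for a 48 x 2048 frame with the
    defaults).  Blocks are merged left to right: the mode of the
    2*pi-rounded phase difference over the shared columns is added to
    the right block; overlap values are taken from the left block.
    """
    psi = np.asarray(psi, dtype=np.float64)
    rows, cols = psi.shape
    if cuts is None:
        cuts = np.zeros(psi.shape, dtype=bool)
    if overlap_cols >= block_cols:
        raise ValueError("overlap_cols must be smaller than block_cols")

    out = np.empty_like(psi)
    written = 0
    for start in _block_starts(cols, block_cols, overlap_cols):
        end = min(start + block_cols, cols)
        phi_b = floodfill_block(psi[:, start:end], cuts[:, start:end])
        if written == 0:
            out[:, :end] = phi_b
            written = end
            continue
        ov_end = min(written, end)
        left = out[:, start:ov_end]
        right = phi_b[:, : ov_end - start]
        ov_cuts = cuts[:, start:ov_end]
        good = ~ov_cuts
        if good.any():
            offset = _mode_offset(left[good] - right[good])
        elif left.size:
            offset = TWO_PI * float(np.median(np.rint((left - right) / TWO_PI)))
            log.warning("overlap at column %d lies entirely on branch cuts; "
                        "using median offset", start)
        else:
            offset = 0.0
            log.warning("empty overlap at column %d; offset 0", start)
        if end > written:
            out[:, written:end] = phi_b[:, written - start:] + offset
        written = end
    return out


def unwrap_phase(psi: np.ndarray, block_cols: int = 20, overlap_cols: int = 4,
                 max_box: int = 8) -> np.ndarray:
    """Full single-frame unwrap: residues -> branch cuts -> tiled flood fill."""
    res = residues(psi)
    cuts = place_branch_cuts(res, psi.shape, max_box=max_box)
    return unwrap_frame(psi, cuts, block_cols=block_cols, overlap_cols=overlap_cols)


def unwrap_batch(frames, block_cols: int = 20, overlap_cols: int = 4,
                 max_box: int = 8, n_parallel: int = 20) -> list[np.ndarray]:
    """Unwrap a batch of wrapped frames.

    Results are identical to per-frame sequential processing; batching
    (20 frames in the instrument pipeline) only amortises scheduling and
    has no observable contract, so the implementation is sequential.
    """
    return [unwrap_phase(f, block_cols=block_cols, overlap_cols=overlap_cols,
                         max_box=max_box) for f in frames]
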