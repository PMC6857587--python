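"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — exhaustive loops and direct linear
algebra — kept free of any code path from the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_boundary(voxels: np.ndarray, label: int) -> list[tuple[int, int, int]]:
    """Boundary voxels of a label by direct 6-neighbour inspection."""
    nz, ny, nx = voxels.shape
    out = []
    for z, y, x in zip(*np.nonzero(voxels == label)):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                out.append((int(z), int(y), int(x)))
                break
            if voxels[zz, yy, xx] != label:
                out.append((int(z), int(y), int(x)))
                break
    return out


def brute_force_edge_distance(
    voxels: np.ndarray, label_a: int, label_b: int, voxel_size
) -> float:
    """Exhaustive double loop over boundary-voxel pairs.

    The per-pair arithmetic — integer index difference, then scale, then
    square, summed z+y+x, then sqrt — mirrors the documented contract of
    the implementation so that exact equality is a meaningful assertion.
    """
    sz, sy, sx = (float(s) for s in voxel_size)
    best = math.inf
    ba = brute_force_boundary(voxels, label_a)
    bb = brute_force_boundary(voxels, label_b)
    for az, ay, ax in ba:
        for bz, by, bx in bb:
            d = math.sqrt(
                ((az - bz) * sz) ** 2 + ((ay - by) * sy) ** 2 + ((ax - bx) * sx) ** 2
            )
            if d < best:
                best = d
    return best


def circumsphere(simplex_points: np.ndarray):
    """Centre and squared radius of the sphere through d+1 points in d-D.

    Returns None for degenerate (affinely dependent) simplices.
    """
    p = np.asarray(simplex_points, dtype=float)
    p0 = p[0]
    a = 2.0 * (p[1:] - p0)
    b = (p[1:] ** 2).sum(axis=1) - (p0**2).sum()
    try:
        centre = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return None
    r2 = ((p0 - centre) ** 2).sum()
    return centre, r2


def has_empty_circumsphere(points: np.ndarray, i: int, j: int, rel_tol=1e-9) -> bool:
    """Whether some simplex through points i and j has an empty circumsphere.

    Brute force over every (d+1)-subset containing the pair; a point counts
    as inside only when strictly inside beyond a relative tolerance. This is
    the defining property of a Delaunay edge for points in general position.
    """
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    others = [k for k in range(n) if k not in (i, j)]
    for extra in itertools.combinations(others, d - 1):
        idx = (i, j) + extra
        cs = circumsphere(pts[list(idx)])
        if cs is None:
            continue
        centre, r2 = cs
        rest = [k for k in range(n) if k not in idx]
        if not rest:
            return True
        d2 = ((pts[rest] - centre) ** 2).sum(axis=1)
        if (d2 >= r2 * (1.0 - rel_tol)).all():
            return True
    return False


def random_blob_mask(shape, labels, rng, max_voxels=200) -> np.ndarray:
    """Integer mask with one random-walk blob per label (possibly touching)."""
    vox = np.zeros(shape, dtype=np.int32)
    nz, ny, nx = shape
    for lab in labels:
        pos = np.array([rng.integers(0, nz), rng.integers(0, ny), rng.integers(0, nx)])
        n_steps = int(rng.integers(5, max_voxels))
        for _ in range(n_steps):
            if vox[tuple(pos)] == 0:
                vox[tuple(pos)] = lab
            step = rng.integers(-1, 2, size=3)
            pos = np.clip(pos + step, 0, np.array(shape) - 1)
        if not (vox == lab).any():  # walk never found a free voxel at start
            free = np.argwhere(vox == 0)
            vox[tuple(free[rng.integers(0, len(free))])] = lab
    return vox
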