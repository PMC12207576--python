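"""Minimum-image distance helpers for slab (xy-periodic) and bulk boxes.

The slit pore is periodic in x and y only; distances along z are plain
Euclidean because the silica slab interrupts the pore.  Bulk boxes (used
for the neat-water hydrogen-bond reference) are periodic in all three
directions.  All neighbour searches go through scipy's cKDTree; the
non-periodic z direction is handled by giving that dimension an
effectively infinite box length.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# kd-tree boxsize entry used for a non-periodic dimension; positions are
# always far below this, so no image is ever applied there.
_NONPERIODIC = 1.0e6


def min_image_delta(delta: np.ndarray, box: np.ndarray, periodic_z: bool = False) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    delta : (..., 3) array of raw displacements.
    box : (3,) box lengths in nm.
    periodic_z : wrap z as well (bulk boxes); default is slab geometry.
    """
    delta = np.asarray(delta, dtype=float).copy()
    ndim = 3 if periodic_z else 2
    for k in range(ndim):
        delta[..., k] -= box[k] * np.round(delta[..., k] / box[k])
    return delta


def min_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray, periodic_z: bool = False) -> np.ndarray:
    """Minimum-image distance(s) between points ``p`` and ``q``."""
    d = min_image_delta(np.asarray(q, float) - np.asarray(p, float), np.asarray(box, float), periodic_z)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_xy(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap x and y into [0, L); z is left untouched (slab geometry)."""
    pos = np.array(positions, dtype=float, copy=True)
    pos[:, 0] %= box[0]
    pos[:, 1] %= box[1]
    return pos


def _tree_boxsize(box: np.ndarray, periodic_z: bool) -> np.ndarray:
    bs = np.asarray(box, dtype=float).copy()
    if not periodic_z:
        bs[2] = _NONPERIODIC
    return bs


def build_tree(points: np.ndarray, box: np.ndarray, periodic_z: bool = False) -> cKDTree:
    """cKDTree over ``points`` honouring the slab/bulk periodicity."""
    pts = np.asarray(points, dtype=float)
    bs = _tree_boxsize(box, periodic_z)
    return cKDTree(np.mod(pts, bs), boxsize=bs)


def pairs_within(
    centers: np.ndarray,
    points: np.ndarray,
    cutoff: float,
    box: np.ndarray,
    periodic_z: bool = False,
):
    """All (center index, point index, distance) triples with r <= cutoff.

    Boundary inclusive: a pair at exactly the cutoff distance is reported.
    Returns three 1-d arrays (ci, pi, dist).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0 or len(centers) == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, float))
    bs = _tree_boxsize(box, periodic_z)
    tree = cKDTree(np.mod(points, bs), boxsize=bs)
    cw = np.mod(centers, bs)
    # small eps then exact filter keeps floating-point boundary cases inclusive
    lists = tree.query_ball_point(cw, cutoff * (1.0 + 1e-12))
    ci, pi = [], []
    for i, hits in enumerate(lists):
        ci.extend([i] * len(hits))
        pi.extend(hits)
    ci = np.asarray(ci, dtype=int)
    pi = np.asarray(pi, dtype=int)
    if len(ci) == 0:
        return ci, pi, np.empty(0, float)
    dist = min_image_distance(centers[ci], points[pi], np.asarray(box, float), periodic_z)
    keep = dist <= cutoff
    return ci[keep], pi[keep], dist[keep]


def counts_within(
    centers: np.ndarray,
    points: np.ndarray,
    cutoff: float,
    box: np.ndarray,
    periodic_z: bool = False,
) -> np.ndarray:
    """Number of ``points`` within r <= cutoff of each center (inclusive)."""
    ci, _, _ = pairs_within(centers, points, cutoff, box, periodic_z)
    n = np.atleast_2d(centers).shape[0]
    return np.bincount(ci, minlength=n)
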