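"""Analyte orientation relative to the silica surface.

The orientation of a substituted aromatic analyte is traced through the
angle φ between the surface normal (pointing from the surface into the
pore) and a compound-specific molecular vector from a ring carbon to the
functional group or side-chain terminus.  By convention cos φ < 0 means
the group points at the silica surface and cos φ > 0 at the bulk liquid.
Unsubstituted analytes (benzene, naphthalene) carry no vector and are
skipped — they show no preferential orientation to resolve.

Profiles are 2-D histograms with 0.05 nm z bins and 0.1-wide cos φ bins,
each z slice normalised to a probability distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, GeometryError, UndefinedAverageError
from .geometry import min_image_delta
from .model import RegionSpec, SlitPoreFrame, Topology, folded_z, molecule_com

N_COS_BINS = 20  # bin width 0.1 on [-1, 1]


@dataclass
class OrientationProfile:
    """P(cos φ | z) with per-bin visit counts.

    Besides the binned distribution, exact per-z accumulators of cos φ are
    kept so that mean orientations are free of histogram-discretisation
    bias (a molecule at cos φ = −1 contributes −1, not the lowest bin
    centre).
    """

    z_edges: np.ndarray
    cos_edges: np.ndarray
    prob: np.ndarray  # (n_z, n_cos); rows sum to 1 where visited, else 0
    counts: np.ndarray  # raw visit counts
    cos_sum: np.ndarray  # (n_z,) exact sum of cos φ per z bin

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def cos_centers(self) -> np.ndarray:
        return 0.5 * (self.cos_edges[:-1] + self.cos_edges[1:])

    def mean_cos(self) -> np.ndarray:
        """Per-z mean cos φ from the exact accumulators (NaN unvisited)."""
        n = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.cos_sum / np.maximum(n, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        zz, cc = np.meshgrid(self.z_centers, self.cos_centers, indexing="ij")
        return pd.DataFrame(
            {"z_center": zz.ravel(), "cos_phi": cc.ravel(), "p": self.prob.ravel()}
        )


def orientation_profile(
    frames: Sequence[SlitPoreFrame],
    topology: Topology,
    compound: Optional[str] = None,
    regions: Optional[RegionSpec] = None,
) -> OrientationProfile:
    """Histogram of cos φ vs distance from the surface.

    cos φ is the dot product of the unit molecular vector (topology
    ``vector_tail_id`` → ``vector_head_id``) with the unit surface normal
    pointing into the pore; for molecules in the upper pore half the
    normal is -z, which keeps the surface/bulk sign convention after the
    two halves are pooled.
    """
    regions = regions or RegionSpec()
    frames = list(frames)
    if not frames:
        raise EmptySelectionError("no frames supplied")
    first = frames[0]
    if first.surface_planes is None:
        raise GeometryError("orientation analysis requires slab frames")
    mols = topology.by_compound(compound) if compound else topology.by_role("analyte")
    mols = [m for m in mols if m.vector_tail_id is not None]
    if not mols:
        raise EmptySelectionError(
            "no molecules with an orientation vector (unsubstituted analytes are skipped)"
        )
    half = first.pore_half_width
    z_edges = regions.bin_edges(half)
    cos_edges = np.linspace(-1.0, 1.0, N_COS_BINS + 1)
    counts = np.zeros((len(z_edges) - 1, N_COS_BINS))
    cos_sum = np.zeros(len(z_edges) - 1)
    for frame in frames:
        lo, hi = frame.surface_planes
        mid = 0.5 * (lo + hi)
        for mol in mols:
            tail = frame.positions[mol.vector_tail_id]
            head = frame.positions[mol.vector_head_id]
            v = min_image_delta(head - tail, frame.box, periodic_z=False)
            norm = np.linalg.norm(v)
            if norm == 0:
                raise GeometryError(f"molecule {mol.molecule_id}: zero-length molecular vector")
            com = molecule_com(frame, mol.particle_ids)
            sign = 1.0 if com[2] <= mid else -1.0  # into-pore normal flips on the upper half
            cos_phi = sign * v[2] / norm
            z = float(folded_z(com[2], frame.surface_planes))
            iz = min(int(z / regions.bin_width), len(z_edges) - 2)
            ic = min(int((cos_phi + 1.0) / 0.1), N_COS_BINS - 1)
            counts[iz, ic] += 1.0
            cos_sum[iz] += cos_phi
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(row_sums > 0, counts / row_sums, 0.0)
    return OrientationProfile(
        z_edges=z_edges, cos_edges=cos_edges, prob=prob, counts=counts, cos_sum=cos_sum
    )


@dataclass
class PreferredOrientation:
    """Density-weighted mean cos φ over a z interval with its reading."""

    mean_cos: float
    interval: tuple[float, float]
    interpretation: str  # surface-oriented / bulk-oriented / isotropic


def preferred_orientation(
    profile: OrientationProfile,
    analyte_density,
    z_interval: tuple[float, float],
    isotropy_threshold: float = 0.05,
) -> PreferredOrientation:
    """Analyte-density-weighted mean cos φ in a z interval.

    The per-z mean of the binned cos φ distribution is averaged with the
    analyte density as weight; |mean| below the isotropy threshold reads
    as "isotropic".
    """
    lo, hi = z_interval
    centers = profile.z_centers
    mask = (centers >= lo) & (centers <= hi)
    if not np.allclose(profile.z_edges, analyte_density.bin_edges):
        raise UndefinedAverageError("orientation and density profiles use different bin grids")
    rho = analyte_density.values[mask]
    visited = profile.counts.sum(axis=1)[mask] > 0
    w = np.where(visited, rho, 0.0)
    if w.sum() <= 0:
        raise UndefinedAverageError(f"no analyte density in z interval [{lo}, {hi}]")
    m = profile.mean_cos()[mask]
    mean = float(np.sum(np.where(visited, m, 0.0) * w) / w.sum())
    if abs(mean) < isotropy_threshold:
        reading = "isotropic"
    elif mean < 0:
        reading = "surface-oriented"
    else:
        reading = "bulk-oriented"
    return PreferredOrientation(mean_cos=mean, interval=(lo, hi), interpretation=reading)
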