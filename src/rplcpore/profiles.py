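"""Species density profiles and partitioning/adsorption peak decomposition.

All profiles are number densities versus distance z from the silica
surface, with both pore halves folded onto one axis (the two surfaces are
statistically equivalent, so pooling doubles the statistics; the per-bin
volume therefore carries a factor of two).  Bins start at z = 0 at the
surface plane with a default width of 0.05 nm; values are reported at bin
centres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, GeometryError, UndefinedDecompositionError
from .model import RegionSpec, SlitPoreFrame, Topology, folded_z, molecule_com


@dataclass
class DensityProfile:
    """Binned number density of one species vs distance from the surface."""

    bin_edges: np.ndarray  # nm, len = n_bins + 1
    values: np.ndarray  # molecules (or atoms) nm^-3 per bin
    label: str
    n_frames: int
    counts: np.ndarray  # raw pooled counts per bin
    bin_volume: float  # nm^3: Lx * Ly * bin_width * n_surfaces

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mean_count_per_frame(self) -> float:
        """Mass-conservation check: integral times the slab cross-section."""
        return float(self.counts.sum() / self.n_frames)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_center": self.centers, "value": self.values, "species": self.label})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def _selected_points(
    frame: SlitPoreFrame,
    topology: Topology,
    role: Optional[str],
    compound: Optional[str],
    site: str,
) -> np.ndarray:
    """Positions to histogram for one frame, per the selector rule."""
    if compound is not None:
        mols = topology.by_compound(compound)
    elif role is not None:
        mols = topology.by_role(role)
    else:
        raise EmptySelectionError("selector needs a role or a compound")
    if not mols:
        what = f"compound {compound!r}" if compound else f"role {role!r}"
        raise EmptySelectionError(f"selector matched no molecules ({what})")
    points = []
    for mol in mols:
        if site == "com":
            points.append(molecule_com(frame, mol.particle_ids))
        elif site == "ring_com":
            for ring in mol.aromatic_rings:
                points.append(molecule_com(frame, ring))
        elif site == "all":
            points.extend(frame.positions[mol.particle_ids])
        else:  # a named site
            ids = [pid for pid in mol.particle_ids if frame.site_names[pid] == site]
            points.extend(frame.positions[ids])
    if not points:
        raise EmptySelectionError(f"site rule {site!r} matched no particles")
    return np.asarray(points)


def density_profile(
    frames: Sequence[SlitPoreFrame],
    topology: Topology,
    role: Optional[str] = None,
    compound: Optional[str] = None,
    site: str = "com",
    regions: Optional[RegionSpec] = None,
    label: Optional[str] = None,
) -> DensityProfile:
    """Density of the selected species vs distance from the silica surface.

    ``site`` chooses what is counted per molecule: the centre of mass
    (``"com"``), the aromatic ring centre(s) (``"ring_com"``), every
    particle (``"all"``), or particles with a given site name (e.g.
    ``"OW"`` for water oxygens, giving atoms nm⁻³).
    """
    regions = regions or RegionSpec()
    frames = list(frames)
    if not frames:
        raise EmptySelectionError("no frames supplied")
    first = frames[0]
    if first.surface_planes is None:
        raise GeometryError("density_profile requires slab frames")
    half = first.pore_half_width
    edges = regions.bin_edges(half)
    counts = np.zeros(len(edges) - 1)
    for frame in frames:
        pts = _selected_points(frame, topology, role, compound, site)
        z = folded_z(pts[:, 2], frame.surface_planes)
        c, _ = np.histogram(z, bins=edges)
        counts += c
    bin_volume = first.box[0] * first.box[1] * regions.bin_width * 2.0
    values = counts / (bin_volume * len(frames))
    return DensityProfile(
        bin_edges=edges,
        values=values,
        label=label or compound or role or "selection",
        n_frames=len(frames),
        counts=counts,
        bin_volume=bin_volume,
    )


@dataclass
class PeakDecomposition:
    """Split of the stationary-phase analyte density into its three peaks.

    ``fractions`` are (surface, partitioning, adsorption) shares of the
    analyte density at z <= z_sp.  The surface peak (silica-surface
    adsorption, default window z <= 0.55 nm) is reported separately but
    merged into the partitioning share when the conventional two-way split
    is requested.
    """

    boundary_z: float  # partitioning/adsorption divide, nm
    surface_peak_z_max: float
    z_sp: float
    fractions: tuple[float, float, float]

    @property
    def adsorption_fraction(self) -> float:
        return self.fractions[2]

    @property
    def partitioning_fraction_two_way(self) -> float:
        """Partitioning share with the surface peak folded in."""
        return self.fractions[0] + self.fractions[1]


def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge replication."""
    padded = np.r_[values[:1], values, values[-1:]]
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def find_peak_boundary(profile: DensityProfile, regions: RegionSpec) -> float:
    """Inter-peak minimum of the smoothed analyte profile near the
    bonded-phase/interfacial border; falls back to the border itself when
    the smoothed profile has no interior local minimum in the search
    window (z_bp_end - 0.15, z_bp_end + 0.25)."""
    centers = profile.centers
    smoothed = _smooth3(profile.values)
    lo, hi = regions.z_bp_end - 0.15, regions.z_bp_end + 0.25
    window = np.flatnonzero((centers > lo) & (centers < hi))
    best_z, best_v = None, np.inf
    for i in window:
        if i == 0 or i == len(centers) - 1:
            continue
        if smoothed[i] < smoothed[i - 1] and smoothed[i] < smoothed[i + 1]:
            if smoothed[i] < best_v:
                best_v = smoothed[i]
                best_z = centers[i]
    return float(best_z) if best_z is not None else float(regions.z_bp_end)


def decompose_peaks(
    profile: DensityProfile,
    regions: RegionSpec,
    surface_peak_z_max: float = 0.55,
    boundary_z: Optional[float] = None,
) -> PeakDecomposition:
    """Empirical mass split of the analyte density at z <= z_sp.

    The three domains are z <= surface_peak_z_max (silica-surface peak),
    up to the inter-peak boundary (partitioning peak) and up to z_sp
    (adsorption peak).  Fractions are invariant under uniform rescaling of
    the profile.
    """
    if regions.z_sp is None:
        raise UndefinedDecompositionError("regions.z_sp must be set before decomposing peaks")
    z_sp = regions.z_sp
    if boundary_z is None:
        boundary_z = find_peak_boundary(profile, regions)
    centers = profile.centers
    inside = centers <= z_sp
    mass = profile.values[inside]
    if mass.sum() <= 0:
        raise UndefinedDecompositionError("analyte profile is zero everywhere at z <= z_sp")
    z_in = centers[inside]
    m_surface = mass[z_in <= surface_peak_z_max].sum()
    m_part = mass[(z_in > surface_peak_z_max) & (z_in <= boundary_z)].sum()
    m_ads = mass[z_in > boundary_z].sum()
    total = m_surface + m_part + m_ads
    return PeakDecomposition(
        boundary_z=float(boundary_z),
        surface_peak_z_max=surface_peak_z_max,
        z_sp=float(z_sp),
        fractions=(m_surface / total, m_part / total, m_ads / total),
    )
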