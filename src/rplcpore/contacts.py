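"""Bonded-phase contact statistics and the stationary-phase limit.

The retentivity of the solvated stationary phase toward an analyte is
measured by the number of bonded-phase united-atom sites within a
compound-specific contact radius r_BP of the analyte's centre of mass
(boundary inclusive, r <= r_BP).  Binning the per-molecule counts by
distance from the surface gives the contact profile C_BP(z); the
stationary-phase limit z_SP is the distance beyond which a molecule
averages fewer than one contact per observation window, and the
density-weighted averages ⟨C_BP⟩_SP and ⟨z⟩_SP over z <= z_SP are the
retention statistics that track experimental retention factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    NoMinimumError,
    NoStationaryPhaseError,
    TruncationError,
    UndefinedAverageError,
    WindowError,
)
from .geometry import counts_within
from .model import RegionSpec, SlitPoreFrame, Topology, folded_z, molecule_com
from .profiles import DensityProfile

#: compound- and solvent-specific contact radii (nm) as published for the
#: C18 system; reference data, not recomputed by this package.
RBP_REFERENCE: dict[tuple[str, str], float] = {
    ("naphthalene", "MeOH"): 0.84,
    ("ethylbenzene", "MeOH"): 0.84,
    ("acetophenone", "MeOH"): 0.81,
    ("benzyl_alcohol", "MeOH"): 0.80,
    ("phenol", "MeOH"): 0.79,
    ("benzene", "MeOH"): 0.79,
    ("naphthalene", "ACN"): 0.83,
    ("ethylbenzene", "ACN"): 0.83,
    ("acetophenone", "ACN"): 0.81,
    ("benzyl_alcohol", "ACN"): 0.79,
    ("benzene", "ACN"): 0.79,
    ("phenol", "ACN"): 0.78,
}


@dataclass(frozen=True)
class ContactRadius:
    """Contact radius r_BP with its provenance."""

    r_bp: float  # nm
    provenance: str = "configured"  # or "derived-from-RDF" / "reference-table"

    def __post_init__(self) -> None:
        if not 0.5 <= self.r_bp <= 1.2:
            raise ValueError(f"r_bp = {self.r_bp} nm outside the sanity window [0.5, 1.2]")


def reference_rbp(compound: str, os_type: str) -> ContactRadius:
    """Published contact radius for one of the six analytes."""
    try:
        return ContactRadius(RBP_REFERENCE[(compound, os_type)], provenance="reference-table")
    except KeyError as exc:
        raise KeyError(f"no reference r_BP for ({compound!r}, {os_type!r})") from exc


def _bp_positions(frame: SlitPoreFrame, include_endcaps: bool) -> np.ndarray:
    mask = frame.roles == "bonded_phase"
    if include_endcaps:
        mask |= frame.roles == "endcap"
    return frame.positions[mask]


def count_contacts(
    frame: SlitPoreFrame,
    molecule_id: int,
    r_bp: ContactRadius | float,
    topology: Topology,
    include_endcaps: bool = False,
) -> int:
    """Bonded-phase sites within r <= r_BP of one analyte's centre of mass.

    Distances use the laboratory frame with minimum-image x,y; endcap and
    residual-silanol sites are excluded unless ``include_endcaps`` pulls
    the trimethylsilane groups in.
    """
    r = r_bp.r_bp if isinstance(r_bp, ContactRadius) else float(r_bp)
    com = molecule_com(frame, topology.molecules[molecule_id].particle_ids)
    bp = _bp_positions(frame, include_endcaps)
    if len(bp) == 0:
        return 0
    return int(counts_within(com[None, :], bp, r, frame.box, periodic_z=frame.periodic_z)[0])


@dataclass
class ContactProfile:
    """Mean bonded-phase contacts per analyte molecule vs z."""

    bin_edges: np.ndarray
    c_bp: np.ndarray  # NaN where no molecule ever visited the bin
    n_visits: np.ndarray
    window_ns: float
    n_windows: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_center": self.centers, "c_bp": self.c_bp, "n": self.n_visits})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def contact_profile(
    frames: Sequence[SlitPoreFrame],
    r_bp: ContactRadius | float,
    topology: Topology,
    regions: Optional[RegionSpec] = None,
    window_ns: float = 40.0,
    compound: Optional[str] = None,
    include_endcaps: bool = False,
) -> ContactProfile:
    """Contact profile C_BP(z) from non-overlapping observation windows.

    Frames are grouped into consecutive windows by timestamp; the per-bin
    mean contact count is formed within each complete window and then
    averaged across windows.  A partial trailing window is dropped.
    """
    regions = regions or RegionSpec()
    frames = list(frames)
    if not frames:
        raise WindowError("no frames supplied")
    r = r_bp.r_bp if isinstance(r_bp, ContactRadius) else float(r_bp)
    times = np.array([f.time for f in frames])
    dt = float(np.median(np.diff(np.sort(times)))) if len(frames) > 1 else 0.0
    span = times.max() - times.min() + dt
    if span + 1e-9 < window_ns:
        raise WindowError(
            f"frames span {span:.3f} ns < one {window_ns} ns window; "
            f"pass a smaller window_ns"
        )
    n_windows = int(np.floor(span / window_ns + 1e-9))
    w_index = np.floor((times - times.min()) / window_ns).astype(int)

    half = frames[0].pore_half_width
    edges = regions.bin_edges(half)
    n_bins = len(edges) - 1
    sums = np.zeros((n_windows, n_bins))
    visits = np.zeros((n_windows, n_bins))
    mols = topology.by_role("analyte")
    if compound is not None:
        mols = [m for m in mols if m.compound == compound]
    for frame, w in zip(frames, w_index):
        if w >= n_windows:  # partial trailing window
            continue
        bp = _bp_positions(frame, include_endcaps)
        coms = np.array([molecule_com(frame, m.particle_ids) for m in mols])
        if len(coms) == 0:
            continue
        counts = (
            counts_within(coms, bp, r, frame.box, periodic_z=False)
            if len(bp)
            else np.zeros(len(coms), dtype=int)
        )
        z = folded_z(coms[:, 2], frame.surface_planes)
        bins = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
        np.add.at(sums[w], bins, counts)
        np.add.at(visits[w], bins, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_window = sums / visits  # NaN where a window never visited a bin
    visited = visits.sum(axis=0)
    window_count = (visits > 0).sum(axis=0)
    c_bp = np.where(
        window_count > 0,
        np.nansum(per_window, axis=0) / np.maximum(window_count, 1),
        np.nan,
    )
    return ContactProfile(
        bin_edges=edges,
        c_bp=c_bp,
        n_visits=visited,
        window_ns=window_ns,
        n_windows=n_windows,
    )


def stationary_phase_limit(profile: ContactProfile) -> float:
    """Distance z_SP where the contact profile drops below one for good.

    Scanning outward from the surface, z_SP is the crossing of C_BP(z)
    through 1 after the last bin with C_BP >= 1 (all non-missing bins
    beyond it are < 1).  The crossing is linearly interpolated between the
    bracketing bin centres; when the outer bracketing bin is exactly zero
    the crossing is degenerate and z_SP is the shared bin edge.  Plateaus
    at exactly 1.0 resolve outward (the larger z), a conservative reading
    of the stationary phase.
    """
    c = profile.c_bp
    centers = profile.centers
    valid = ~np.isnan(c)
    if not np.any(c[valid] >= 1.0):
        raise NoStationaryPhaseError("contact profile is everywhere below one contact")
    if not np.any(c[valid] < 1.0):
        raise TruncationError("contact profile never drops below one contact; pore too small")
    inside_idx = np.flatnonzero(valid & (c >= 1.0))
    # last bin with >= 1 contact such that everything beyond stays < 1
    i = int(inside_idx.max())
    outer = np.flatnonzero(valid[i + 1 :]) + i + 1
    if len(outer) == 0:
        raise TruncationError("no bins outside the contact region; pore too small")
    j = int(outer[0])
    ci, cj = float(c[i]), float(c[j])
    if cj == 0.0:
        # degenerate step: contacts cease at the bin boundary
        return float(profile.bin_edges[i + 1])
    return float(centers[i] + (centers[j] - centers[i]) * (ci - 1.0) / (ci - cj))


@dataclass
class StationaryPhaseSummary:
    """Density-weighted retention statistics over z <= z_SP."""

    z_sp: float
    mean_contacts: float  # ⟨C_BP⟩_SP
    mean_position: float  # ⟨z⟩_SP, nm
    sd_contacts: float

    def to_dict(self) -> dict:
        return {
            "z_sp": self.z_sp,
            "mean_contacts": self.mean_contacts,
            "mean_position": self.mean_position,
            "sd_contacts": self.sd_contacts,
        }


def stationary_phase_summary(
    contact_prof: ContactProfile,
    analyte_density: DensityProfile,
    z_sp: float,
) -> StationaryPhaseSummary:
    """⟨C_BP⟩_SP and ⟨z⟩_SP: analyte-density-weighted bin averages.

    Both profiles must share the bin grid.  Bins inside z_SP that carry
    analyte density but no contact statistics are an inconsistency and
    raise rather than silently skew the average.
    """
    if len(contact_prof.centers) != len(analyte_density.centers) or not np.allclose(
        contact_prof.bin_edges, analyte_density.bin_edges
    ):
        raise UndefinedAverageError("contact and density profiles use different bin grids")
    centers = contact_prof.centers
    inside = centers <= z_sp
    rho = analyte_density.values[inside]
    c = contact_prof.c_bp[inside]
    if rho.sum() <= 0:
        raise UndefinedAverageError("zero total analyte density at z <= z_sp")
    if np.any(np.isnan(c) & (rho > 0)):
        raise UndefinedAverageError("missing contact bins carry nonzero analyte density")
    w = rho / rho.sum()
    ok = rho > 0
    mean_c = float(np.sum(c[ok] * w[ok]))
    mean_z = float(np.sum(centers[inside][ok] * w[ok]))
    var_c = float(np.sum(((c[ok] - mean_c) ** 2) * w[ok]))
    return StationaryPhaseSummary(
        z_sp=float(z_sp),
        mean_contacts=mean_c,
        mean_position=mean_z,
        sd_contacts=float(np.sqrt(var_c)),
    )


# ---------------------------------------------------------------------------
# RDF-based contact radii


@dataclass
class RDF:
    """Radial distribution function between analyte com and bonded-phase sites."""

    r: np.ndarray  # bin centres, nm
    g: np.ndarray
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.g) < 0):
            raise ValueError("g(r) must be nonnegative")


def compute_rdf(
    frames: Sequence[SlitPoreFrame],
    topology: Topology,
    r_max: float = 1.5,
    dr: float = 0.01,
    regions: Optional[RegionSpec] = None,
    include_endcaps: bool = False,
) -> RDF:
    """Analyte-com / bonded-phase RDF for deriving r_BP on novel systems.

    The slab is strongly inhomogeneous, so g(r) is normalised by the mean
    bonded-phase site density within the bonded-phase region (z <=
    z_bp_end); only the location of the first minimum matters downstream,
    not the asymptote.
    """
    regions = regions or RegionSpec()
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    n_com = 0
    rho_ref = 0.0
    from .geometry import pairs_within  # local import to avoid cycle at module load

    for frame in frames:
        bp = _bp_positions(frame, include_endcaps)
        mols = topology.by_role("analyte")
        coms = np.array([molecule_com(frame, m.particle_ids) for m in mols])
        if len(coms) == 0 or len(bp) == 0:
            continue
        ci, pi_, dist = pairs_within(coms, bp, r_max, frame.box, periodic_z=frame.periodic_z)
        c, _ = np.histogram(dist, bins=edges)
        counts += c
        n_com += len(coms)
        zbp = folded_z(bp[:, 2], frame.surface_planes)
        slab_vol = frame.box[0] * frame.box[1] * regions.z_bp_end * 2.0
        rho_ref += np.sum(zbp <= regions.z_bp_end) / slab_vol
    if n_com == 0:
        raise UndefinedAverageError("no analyte/bonded-phase pairs to build an RDF from")
    rho_ref /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers**2 * dr
    g = counts / (n_com * shell_vol * max(rho_ref, 1e-12))
    return RDF(r=centers, g=g, n_pairs=int(counts.sum()))


def derive_rbp(rdfs: Sequence[RDF]) -> ContactRadius:
    """Contact radius from the first minimum after the first peak of the
    averaged, 3-bin-smoothed RDF, rounded to 0.01 nm."""
    if not rdfs:
        raise ValueError("need at least one RDF")
    r = rdfs[0].r
    for rdf in rdfs[1:]:
        if len(rdf.r) != len(r) or not np.allclose(rdf.r, r):
            raise ValueError("RDFs must share a common r grid to be averaged")
    g = np.mean([rdf.g for rdf in rdfs], axis=0)
    padded = np.r_[g[:1], g, g[-1:]]
    smooth = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    peak = int(np.argmax(smooth))
    for i in range(peak + 1, len(smooth) - 1):
        if smooth[i] < smooth[i - 1] and smooth[i] <= smooth[i + 1]:
            return ContactRadius(round(float(r[i]), 2), provenance="derived-from-RDF")
    raise NoMinimumError("RDF has no minimum after its first peak")
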