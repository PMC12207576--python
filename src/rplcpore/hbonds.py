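"""Distance-criterion hydrogen-bond detection and derived statistics.

A solute–solvent hydrogen bond is declared whenever the distance between
a solute site and the complementary solvent atom satisfies r <= r_HB —
a pure distance criterion with no angular term, which is a deliberate
deviation from the usual geometric (distance + angle) definitions.  Three
solute site classes exist:

``donor_H``
    a polar hydrogen of the solute (phenolic/benzylic OH), paired with the
    acceptor heavy atom of a solvent molecule (O of W or MeOH, N of ACN);
``acceptor``
    a solute acceptor heavy atom (hydroxyl or carbonyl O), paired with a
    donor H of W or MeOH;
``pi``
    the centre of mass of an aromatic ring's carbon atoms, paired with a
    donor H of W (r_HB = 0.30 nm) or MeOH (r_HB = 0.32 nm).

The π cutoffs are literature values; the site–site cutoffs default to
plausible first-minimum distances but are configuration-supplied and must
be replaced when reproducing a specific force-field system (they are not
validated against any published table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CriteriaError,
    GeometryError,
    UndefinedAverageError,
)
from .geometry import pairs_within
from .model import RegionSpec, SlitPoreFrame, Topology, folded_z, molecule_com

#: default pair cutoffs in nm; the π entries are published values, the
#: site–site entries are package defaults (see module docstring).
DEFAULT_CUTOFFS: dict[tuple[str, str], float] = {
    ("donor_H", "O_W"): 0.245,
    ("donor_H", "O_MeOH"): 0.245,
    ("donor_H", "N_ACN"): 0.255,
    ("acceptor", "H_W"): 0.245,
    ("acceptor", "H_MeOH"): 0.245,
    ("pi", "H_W"): 0.30,
    ("pi", "H_MeOH"): 0.32,
}

#: solvent site name -> (atom class, species)
_SOLVENT_CLASSES: dict[str, tuple[str, str]] = {
    "OW": ("O_W", "W"),
    "HW": ("H_W", "W"),
    "O_MeOH": ("O_MeOH", "MeOH"),
    "H_MeOH": ("H_MeOH", "MeOH"),
    "N_ACN": ("N_ACN", "ACN"),
}

#: heavy "key" atom whose density defines the partner-density profiles
KEY_ATOM_CLASSES = ("O_W", "O_MeOH", "N_ACN")


@dataclass(frozen=True)
class HBondCriteria:
    """Pair cutoff table keyed by (solute site class, solvent atom class)."""

    cutoffs: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def __post_init__(self) -> None:
        for key, r in self.cutoffs.items():
            if not 0.15 < r < 0.45:
                raise CriteriaError(f"cutoff {key} = {r} nm outside the plausible (0.15, 0.45) window")

    def require(self, solute_class: str, solvent_class: str) -> float:
        try:
            return self.cutoffs[(solute_class, solvent_class)]
        except KeyError as exc:
            raise CriteriaError(
                f"no hydrogen-bond cutoff configured for site class "
                f"({solute_class!r}, {solvent_class!r})"
            ) from exc


_TABLE_COLUMNS = [
    "time",
    "analyte_molecule_id",
    "site_kind",
    "site_id",
    "analyte_z",
    "partner_molecule_id",
    "partner_species",
    "partner_class",
    "distance",
    "partner_x",
    "partner_y",
    "partner_z",
    "partner_z_folded",
]


def _solute_sites(frame: SlitPoreFrame, topology: Topology):
    """(kind, site id, position, molecule id, analyte folded z) per site."""
    analytes = topology.by_role("analyte")
    sites = []
    for mol in analytes:
        com = molecule_com(frame, mol.particle_ids)
        if frame.surface_planes is not None:
            z_a = float(folded_z(com[2], frame.surface_planes))
        else:
            z_a = np.nan
        for pid in mol.donor_ids:
            sites.append(("donor_H", pid, frame.positions[pid], mol.molecule_id, z_a))
        for pid in mol.acceptor_ids:
            sites.append(("acceptor", pid, frame.positions[pid], mol.molecule_id, z_a))
        for k, ring in enumerate(mol.aromatic_rings):
            ring_com = molecule_com(frame, ring)
            sites.append(("pi", -(k + 1), ring_com, mol.molecule_id, z_a))
    return sites


def detect_hbonds(
    frame: SlitPoreFrame,
    topology: Topology,
    criteria: Optional[HBondCriteria] = None,
) -> pd.DataFrame:
    """All solute–solvent hydrogen bonds of one frame (boundary inclusive).

    A solute site may bind several partners simultaneously; every
    satisfying pair is one row, so per-molecule bond numbers can exceed
    one.  Minimum-image distances respect the frame's periodicity (x,y for
    slab frames, x,y,z for bulk boxes).
    """
    criteria = criteria or HBondCriteria()
    sites = _solute_sites(frame, topology)
    # solvent atoms grouped by class
    solv_mask = (frame.roles == "water") | (frame.roles == "organic_solvent")
    solv_idx = np.flatnonzero(solv_mask)
    classes: dict[str, np.ndarray] = {}
    for name in np.unique(frame.site_names[solv_idx]):
        if str(name) in _SOLVENT_CLASSES:
            cls, _ = _SOLVENT_CLASSES[str(name)]
            sel = solv_idx[frame.site_names[solv_idx] == name]
            classes.setdefault(cls, np.empty(0, int))
            classes[cls] = np.concatenate([classes[cls], sel])
    # key atom position per solvent molecule
    key_pos: dict[int, np.ndarray] = {}
    for cls in KEY_ATOM_CLASSES:
        for idx in classes.get(cls, ()):  # first key atom of a molecule wins
            key_pos.setdefault(int(frame.molecule_ids[idx]), frame.positions[idx])

    annotated = sorted({kind for kind, *_ in sites})
    pairable = set(DEFAULT_CUTOFFS)
    for kind in annotated:
        for cls in classes:
            if (kind, cls) in pairable:
                criteria.require(kind, cls)  # raises CriteriaError when absent

    rows: list[dict] = []
    by_kind: dict[str, list] = {}
    for s in sites:
        by_kind.setdefault(s[0], []).append(s)
    for kind, kind_sites in by_kind.items():
        positions = np.array([s[2] for s in kind_sites])
        for cls, atom_idx in classes.items():
            if (kind, cls) not in criteria.cutoffs:
                continue
            cutoff = criteria.cutoffs[(kind, cls)]
            ci, pi_, dist = pairs_within(
                positions, frame.positions[atom_idx], cutoff, frame.box, periodic_z=frame.periodic_z
            )
            for c, p, r in zip(ci, pi_, dist):
                skind, sid, _, smol, z_a = kind_sites[c]
                pidx = int(atom_idx[p])
                pmid = int(frame.molecule_ids[pidx])
                species = _SOLVENT_CLASSES[str(frame.site_names[pidx])][1]
                kp = key_pos.get(pmid, frame.positions[pidx])
                rows.append(
                    {
                        "time": frame.time,
                        "analyte_molecule_id": smol,
                        "site_kind": skind,
                        "site_id": sid,
                        "analyte_z": z_a,
                        "partner_molecule_id": pmid,
                        "partner_species": species,
                        "partner_class": cls,
                        "distance": float(r),
                        "partner_x": float(kp[0]),
                        "partner_y": float(kp[1]),
                        "partner_z": float(kp[2]),
                        "partner_z_folded": (
                            float(folded_z(kp[2], frame.surface_planes))
                            if frame.surface_planes is not None
                            else np.nan
                        ),
                    }
                )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def detect_hbonds_ensemble(
    frames: Iterable[SlitPoreFrame],
    topology: Topology,
    criteria: Optional[HBondCriteria] = None,
) -> pd.DataFrame:
    """Concatenated hydrogen-bond table over a frame ensemble."""
    tables = [detect_hbonds(f, topology, criteria) for f in frames]
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=_TABLE_COLUMNS)


@dataclass
class HBondProfile:
    """Mean hydrogen bonds per analyte molecule vs distance from surface."""

    bin_edges: np.ndarray
    total: np.ndarray  # per-bin mean HB per molecule visit (NaN where unvisited)
    functional: np.ndarray  # donor/acceptor contribution
    pi: np.ndarray  # π contribution
    n_visits: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def hbond_profile(
    table: pd.DataFrame,
    analyte_density,
    regions: Optional[RegionSpec] = None,
) -> HBondProfile:
    """Per-z mean hydrogen bonds per analyte molecule.

    The per-bin molecule visit counts are recovered from the analyte
    density profile (which stores its own normalisation); the table
    contributes the bond counts, split into functional-group and π
    contributions.
    """
    import warnings as _warnings

    edges = analyte_density.bin_edges
    visits = analyte_density.counts.astype(float)
    if len(table) == 0:
        _warnings.warn("empty hydrogen-bond table; profile is all-missing", stacklevel=2)
    z = table["analyte_z"].to_numpy() if len(table) else np.empty(0)
    is_pi = (table["site_kind"] == "pi").to_numpy() if len(table) else np.empty(0, bool)
    counts_fn, _ = np.histogram(z[~is_pi], bins=edges)
    counts_pi, _ = np.histogram(z[is_pi], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        fn = np.where(visits > 0, counts_fn / visits, np.nan)
        pi = np.where(visits > 0, counts_pi / visits, np.nan)
    return HBondProfile(
        bin_edges=edges,
        total=fn + pi,
        functional=fn,
        pi=pi,
        n_visits=visits,
    )


@dataclass
class HBondSummary:
    """Stationary-phase hydrogen-bond statistics of one run."""

    hb_sp: float  # density-weighted HB per molecule over z <= z_sp
    hb_bulk: float  # bulk-liquid reference (input)
    recovery: float  # hb_sp / hb_bulk
    hb_functional_sp: float
    hb_pi_sp: float
    w_contribution_sp: float  # fraction of bonds with a W partner, z <= z_sp
    w_contribution_bulk: float  # same for the bulk region


def _weighted_mean(values: np.ndarray, weights: np.ndarray, what: str) -> float:
    mask = weights > 0
    if not np.any(mask):
        raise UndefinedAverageError(f"zero total density for {what}")
    if np.any(np.isnan(values[mask])):
        raise UndefinedAverageError(f"{what}: missing profile bins carry nonzero density")
    return float(np.sum(values[mask] * weights[mask]) / np.sum(weights[mask]))


def hbond_summary(
    profile: HBondProfile,
    analyte_density,
    z_sp: float,
    hb_bulk: float,
    table: pd.DataFrame,
    regions: Optional[RegionSpec] = None,
) -> HBondSummary:
    """Density-weighted stationary-phase averages and the recovery fraction.

    Weighting follows the same rule as the bonded-phase contact average:
    the analyte density at z <= z_sp is the weight of each bin.
    """
    regions = regions or RegionSpec()
    if hb_bulk <= 0:
        raise UndefinedAverageError("hb_bulk must be positive to define a recovery fraction")
    centers = profile.centers
    inside = centers <= z_sp
    rho = analyte_density.values[inside]
    hb_sp = _weighted_mean(profile.total[inside], rho, "stationary-phase HB average")
    hb_fn = _weighted_mean(profile.functional[inside], rho, "stationary-phase HB average")
    hb_pi = _weighted_mean(profile.pi[inside], rho, "stationary-phase HB average")
    w_sp = _w_fraction(table, table["analyte_z"] <= z_sp)
    w_bulk = _w_fraction(table, table["analyte_z"] > regions.z_bulk_start)
    return HBondSummary(
        hb_sp=hb_sp,
        hb_bulk=hb_bulk,
        recovery=hb_sp / hb_bulk,
        hb_functional_sp=hb_fn,
        hb_pi_sp=hb_pi,
        w_contribution_sp=w_sp,
        w_contribution_bulk=w_bulk,
    )


def _w_fraction(table: pd.DataFrame, mask) -> float:
    sub = table[mask] if len(table) else table
    if len(sub) == 0:
        return np.nan
    return float((sub["partner_species"] == "W").mean())


@dataclass
class PartnerDensityProfile:
    """Engaged-partner key-atom densities, conditioned on the analyte peak."""

    bin_edges: np.ndarray
    densities: dict[tuple[str, str], np.ndarray]  # (peak, species) -> atoms nm^-3
    window: tuple[float, float]
    integrated: dict[tuple[str, str], float]  # integral over the window, atoms nm^-2
    species_share: dict[tuple[str, str], float]  # (peak, species) -> fraction of bonds
    n_excluded: int  # rows whose analyte sits beyond z_sp

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def partner_density(
    table: pd.DataFrame,
    boundary_z: float,
    z_sp: float,
    box: Sequence[float],
    n_frames: int,
    regions: Optional[RegionSpec] = None,
    window: tuple[float, float] = (1.5, 2.25),
    z_max: Optional[float] = None,
) -> PartnerDensityProfile:
    """Partner key-atom density profiles for the partitioning/adsorption peaks.

    Each engaged partner atom is binned by *its own* distance from the
    surface while the row is assigned to the peak containing the analyte's
    centre of mass (partitioning: z <= boundary_z, adsorption:
    boundary_z < z <= z_sp).  Rows whose analyte lies beyond z_sp are
    excluded and tallied.  The default integration window 1.5–2.25 nm is
    where the bulk of the adsorption-peak partners reside.
    """
    regions = regions or RegionSpec()
    box = np.asarray(box, float)
    if z_max is None:
        z_max = float(regions.z_bulk_start + 1.0)
    edges = regions.bin_edges(z_max)
    vol = box[0] * box[1] * regions.bin_width * 2.0  # two pooled surfaces
    z_analyte = table["analyte_z"].to_numpy()
    excluded = z_analyte > z_sp
    peaks = np.where(z_analyte <= boundary_z, "partitioning", "adsorption")
    densities: dict[tuple[str, str], np.ndarray] = {}
    integrated: dict[tuple[str, str], float] = {}
    share: dict[tuple[str, str], float] = {}
    for peak in ("partitioning", "adsorption"):
        sel_peak = (peaks == peak) & ~excluded
        n_peak = int(sel_peak.sum())
        for species in ("W", "MeOH", "ACN"):
            sel = sel_peak & (table["partner_species"] == species).to_numpy()
            if not sel.any() and species not in set(table["partner_species"]):
                continue
            zp = table.loc[sel, "partner_z_folded"].to_numpy()
            counts, _ = np.histogram(zp, bins=edges)
            dens = counts / (vol * n_frames)
            densities[(peak, species)] = dens
            centers = 0.5 * (edges[:-1] + edges[1:])
            in_win = (centers >= window[0]) & (centers <= window[1])
            integrated[(peak, species)] = float(np.sum(dens[in_win]) * regions.bin_width)
            share[(peak, species)] = float(sel.sum() / n_peak) if n_peak else np.nan
    return PartnerDensityProfile(
        bin_edges=edges,
        densities=densities,
        window=window,
        integrated=integrated,
        species_share=share,
        n_excluded=int(excluded.sum()),
    )


def hb_max_neat_water(
    frames: Sequence[SlitPoreFrame],
    topology: Topology,
    criteria: Optional[HBondCriteria] = None,
) -> dict[str, float]:
    """Mean solute–water hydrogen bonds per molecule in a neat-water bulk box.

    Returns the total together with its functional-group and π splits,
    mirroring how the solute's hydrogen-bond requirement is tabulated.
    """
    n_analyte = len(topology.by_role("analyte"))
    if n_analyte == 0:
        raise GeometryError("no analyte molecules in topology")
    for frame in frames:
        if frame.surface_planes is not None:
            raise GeometryError("hb_max_neat_water expects bulk frames, got a slab frame")
    table = detect_hbonds_ensemble(frames, topology, criteria)
    n_mol_frames = n_analyte * len(list(frames))
    if n_mol_frames == 0:
        raise GeometryError("no frames supplied")
    n_pi = int((table["site_kind"] == "pi").sum()) if len(table) else 0
    n_fn = int(len(table) - n_pi)
    return {
        "hb_max": (n_fn + n_pi) / n_mol_frames,
        "hb_max_functional": n_fn / n_mol_frames,
        "hb_max_pi": n_pi / n_mol_frames,
    }


#: neat-water hydrogen-bond requirements per molecule (HB_solute-W,max) as
#: published — reference data from the original trajectory campaign, not
#: recomputed here.  Polar analytes with an OH donor carry two entries:
#: bonds formed with donor solvents (water donating to the solute's
#: acceptor sites and π system) and with acceptor solvents (the solute's
#: OH donating).
HB_MAX_REFERENCE: dict[str, dict[str, float]] = {
    "naphthalene": {"with_donor_solvents": 1.79},
    "ethylbenzene": {"with_donor_solvents": 1.14},
    "benzene": {"with_donor_solvents": 1.14},
    "acetophenone": {"with_donor_solvents": 2.18},
    "benzyl_alcohol": {"with_donor_solvents": 2.37, "with_acceptor_solvents": 1.01},
    "phenol": {"with_donor_solvents": 1.98, "with_acceptor_solvents": 1.00},
}
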