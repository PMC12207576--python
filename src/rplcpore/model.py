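"""Domain types for slit-pore configurations and their interchange formats.

A configuration of the pore model — silica slab, grafted C18 bonded phase
with trimethylsilane endcaps and residual silanols, water/organic-solvent
mobile phase and analyte molecules — is held as a :class:`SlitPoreFrame`
(array-of-columns layout, one row per interaction site).  Molecule-level
annotation (compound identity, aromatic rings, hydrogen-bond donor and
acceptor sites, the molecular orientation vector) lives in a separate
:class:`Topology`, shared by all frames of an ensemble.

The on-disk formats are deliberately plain text so fixtures stay diffable:
an extended-XYZ variant with per-particle ``site_name x y z role
molecule_id`` columns and a key=value comment line, plus a tab-separated
topology table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import GeometryWarning, ParseError, TopologyError
from .geometry import min_image_delta, wrap_xy

#: the seven particle roles of the slit-pore model
ROLES = (
    "silica",
    "bonded_phase",
    "endcap",
    "residual_OH",
    "water",
    "organic_solvent",
    "analyte",
)


@dataclass(frozen=True)
class Particle:
    """A single interaction site (atom or united-atom bead)."""

    particle_id: int
    site_name: str
    role: str
    molecule_id: int
    element: str
    position: np.ndarray  # (3,) nm


@dataclass
class SlitPoreFrame:
    """One configuration of the slit-pore (or bulk) system.

    Positions are laboratory coordinates in nm.  ``surface_planes`` holds
    the z-coordinates of the two silica surface planes bounding the pore;
    it is ``None`` for bulk (fully periodic) boxes.
    """

    time: float  # ns
    box: np.ndarray  # (3,) nm
    site_names: np.ndarray  # (N,) str
    roles: np.ndarray  # (N,) str
    molecule_ids: np.ndarray  # (N,) int
    positions: np.ndarray  # (N, 3) nm
    surface_planes: Optional[tuple[float, float]] = None
    folded: bool = False

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.site_names = np.asarray(self.site_names)
        self.roles = np.asarray(self.roles)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.surface_planes is not None:
            lo, hi = self.surface_planes
            if not lo < hi:
                raise TopologyError(f"surface_planes must be ordered, got {self.surface_planes}")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise TopologyError(f"unknown particle roles: {sorted(bad)}")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def periodic_z(self) -> bool:
        """Bulk boxes (no surface planes) are periodic in z as well."""
        return self.surface_planes is None

    @property
    def pore_half_width(self) -> float:
        if self.surface_planes is None:
            raise TopologyError("bulk frame has no pore geometry")
        lo, hi = self.surface_planes
        return 0.5 * (hi - lo)

    def particles(self) -> Iterator[Particle]:
        for i in range(self.n_particles):
            yield Particle(
                particle_id=i,
                site_name=str(self.site_names[i]),
                role=str(self.roles[i]),
                molecule_id=int(self.molecule_ids[i]),
                element=_element_of(str(self.site_names[i])),
                position=self.positions[i],
            )

    def select(self, role: str) -> np.ndarray:
        """Positions of all particles with the given role."""
        return self.positions[self.roles == role]


def _element_of(site_name: str) -> str:
    """Leading element symbol of a site name (CH3 -> C, OW -> O, HW -> H)."""
    if len(site_name) > 1 and site_name[:2].isalpha() and site_name[1].islower():
        return site_name[:2]
    return site_name[0]


@dataclass
class MoleculeRecord:
    """Per-molecule annotation used by the analysis stages."""

    molecule_id: int
    compound: str
    role: str
    particle_ids: list[int]
    aromatic_rings: list[list[int]] = field(default_factory=list)
    donor_ids: list[int] = field(default_factory=list)
    acceptor_ids: list[int] = field(default_factory=list)
    vector_tail_id: Optional[int] = None
    vector_head_id: Optional[int] = None


@dataclass
class Topology:
    """Molecule table for a frame ensemble."""

    molecules: dict[int, MoleculeRecord]

    def __post_init__(self) -> None:
        all_ids: set[int] = set()
        for mol in self.molecules.values():
            pid_set = set(mol.particle_ids)
            all_ids |= pid_set
            for ring in mol.aromatic_rings:
                if len(ring) < 5:
                    raise TopologyError(
                        f"molecule {mol.molecule_id}: aromatic ring with {len(ring)} members (<5)"
                    )
                if not set(ring) <= pid_set:
                    raise TopologyError(f"molecule {mol.molecule_id}: ring references foreign particles")
            for ids in (mol.donor_ids, mol.acceptor_ids):
                if not set(ids) <= pid_set:
                    raise TopologyError(f"molecule {mol.molecule_id}: site ids outside molecule")
            if mol.vector_tail_id is not None or mol.vector_head_id is not None:
                if mol.vector_tail_id == mol.vector_head_id:
                    raise TopologyError(f"molecule {mol.molecule_id}: vector endpoints coincide")
                for pid in (mol.vector_tail_id, mol.vector_head_id):
                    if pid is None or pid not in pid_set:
                        raise TopologyError(f"molecule {mol.molecule_id}: bad vector endpoint {pid}")

    @property
    def n_particles(self) -> int:
        return sum(len(m.particle_ids) for m in self.molecules.values())

    def by_role(self, role: str) -> list[MoleculeRecord]:
        return [m for m in self.molecules.values() if m.role == role]

    def by_compound(self, compound: str) -> list[MoleculeRecord]:
        return [m for m in self.molecules.values() if m.compound == compound]


@dataclass
class RegionSpec:
    """Region bookkeeping for the solvated stationary phase.

    z is distance from the silica surface after folding.  The defaults are
    the conventional boundaries of the bonded-phase region (z <= 1.05 nm)
    and the bulk liquid region (z > 2.55 nm); ``z_sp`` (the stationary-phase
    limit) is produced by the contacts stage and filled in afterwards.
    """

    z_bp_end: float = 1.05
    z_bulk_start: float = 2.55
    z_sp: Optional[float] = None
    bin_width: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.z_bp_end < self.z_bulk_start:
            raise TopologyError("need 0 < z_bp_end < z_bulk_start")
        if self.bin_width <= 0:
            raise TopologyError("bin_width must be positive")

    def bin_edges(self, z_max: float) -> np.ndarray:
        """Bin edges starting at z = 0 (surface plane) up to at least z_max."""
        n = int(np.ceil(z_max / self.bin_width - 1e-9))
        return self.bin_width * np.arange(n + 1)


# ---------------------------------------------------------------------------
# folding


def folded_z(z: np.ndarray, surface_planes: tuple[float, float]) -> np.ndarray:
    """Distance from the nearest silica surface plane."""
    lo, hi = surface_planes
    return np.minimum(np.abs(np.asarray(z, float) - lo), np.abs(hi - np.asarray(z, float)))


def fold_to_surface(frame: SlitPoreFrame, bin_width: float = 0.05) -> SlitPoreFrame:
    """Map both pore halves onto a single distance-from-surface z axis.

    Every particle's z is replaced by its distance to the nearest surface
    plane; x and y are untouched.  Idempotent: folding a folded frame keeps
    z unchanged because after the first fold the lower plane is z = 0.
    """
    if frame.surface_planes is None:
        raise TopologyError("fold_to_surface requires a slab frame with surface planes")
    if frame.folded:
        return replace(frame, positions=frame.positions.copy())
    z = folded_z(frame.positions[:, 2], frame.surface_planes)
    half = frame.pore_half_width
    over = z > half + bin_width
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} particle(s) beyond both surface planes by > {bin_width} nm; clamped",
            GeometryWarning,
            stacklevel=2,
        )
        z = np.where(over, half, z)
    pos = frame.positions.copy()
    pos[:, 2] = z
    return replace(
        frame,
        positions=pos,
        surface_planes=(0.0, 2.0 * half),
        folded=True,
    )


def molecule_com(frame: SlitPoreFrame, particle_ids: Sequence[int]) -> np.ndarray:
    """Geometric centre of a molecule, minimum-image safe in x,y.

    United-atom sites carry no masses in the interchange format, so the
    unweighted site centre stands in for the centre of mass.
    """
    ids = np.asarray(particle_ids, dtype=int)
    pos = frame.positions[ids]
    anchor = pos[0]
    rel = min_image_delta(pos - anchor, frame.box, periodic_z=frame.periodic_z)
    return anchor + rel.mean(axis=0)


def molecule_coms(frame: SlitPoreFrame) -> tuple[np.ndarray, np.ndarray]:
    """(molecule ids, com positions) for every molecule in the frame.

    Vectorised over contiguous molecule blocks; falls back to a stable sort
    when particle order does not group molecules.
    """
    mids = frame.molecule_ids
    order = np.arange(len(mids))
    if np.any(np.diff(mids) < 0):
        order = np.argsort(mids, kind="stable")
    m_sorted = mids[order]
    pos = frame.positions[order]
    starts = np.flatnonzero(np.r_[True, np.diff(m_sorted) != 0])
    uniq = m_sorted[starts]
    anchors = pos[starts]
    rel = min_image_delta(pos - np.repeat(anchors, np.diff(np.r_[starts, len(pos)]), axis=0),
                          frame.box, periodic_z=frame.periodic_z)
    sums = np.add.reduceat(rel, starts, axis=0)
    counts = np.diff(np.r_[starts, len(pos)])
    coms = anchors + sums / counts[:, None]
    return uniq, coms


# ---------------------------------------------------------------------------
# extended-XYZ reader/writer


def write_frames(frames: Iterable[SlitPoreFrame], path: str | Path) -> None:
    """Write frames in the package's extended-XYZ interchange format."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_particles}\n")
            hdr = (
                f"time_ns={frame.time:.6f} Lx={frame.box[0]:.6f} "
                f"Ly={frame.box[1]:.6f} Lz={frame.box[2]:.6f}"
            )
            if frame.surface_planes is not None:
                lo, hi = frame.surface_planes
                hdr += f" surf_lo={lo:.6f} surf_hi={hi:.6f}"
            fh.write(hdr + "\n")
            for name, p, role, mid in zip(
                frame.site_names, frame.positions, frame.roles, frame.molecule_ids
            ):
                fh.write(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {role} {mid}\n")


def read_frames(path: str | Path, topology: Optional[Topology] = None) -> list[SlitPoreFrame]:
    """Read an extended-XYZ trajectory written by :func:`write_frames`.

    x,y are wrapped into the box on read; z is kept as stored (the slab
    interrupts z periodicity).  When a topology is supplied, each frame's
    particle count is validated against it.
    """
    path = Path(path)
    frames: list[SlitPoreFrame] = []
    with path.open() as fh:
        lines = fh.readlines()
    i = 0
    n_line = len(lines)
    frame_no = 0
    while i < n_line:
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected particle count, got {lines[i]!r}") from exc
        if i + 1 >= n_line:
            raise ParseError(f"line {i + 1}: truncated frame header")
        header = _parse_header(lines[i + 1], i + 2)
        body = lines[i + 2 : i + 2 + count]
        if len(body) < count:
            raise ParseError(f"line {i + 2}: frame {frame_no} truncated ({len(body)}/{count} particles)")
        if topology is not None and count != topology.n_particles:
            raise TopologyError(
                f"frame {frame_no}: {count} particles but topology defines {topology.n_particles}"
            )
        names, roles, mids, pos = [], [], [], []
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) != 6:
                raise ParseError(f"line {i + 3 + j}: expected 6 columns, got {len(parts)}")
            names.append(parts[0])
            try:
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
                mids.append(int(parts[5]))
            except ValueError as exc:
                raise ParseError(f"line {i + 3 + j}: bad numeric field") from exc
            roles.append(parts[4])
        box = np.array([header["Lx"], header["Ly"], header["Lz"]])
        planes = None
        if "surf_lo" in header:
            planes = (header["surf_lo"], header["surf_hi"])
        frames.append(
            SlitPoreFrame(
                time=header.get("time_ns", 0.0),
                box=box,
                site_names=np.array(names),
                roles=np.array(roles),
                molecule_ids=np.array(mids),
                positions=wrap_xy(np.array(pos), box),
                surface_planes=planes,
            )
        )
        i = i + 2 + count
    return frames


def _parse_header(line: str, lineno: int) -> dict[str, float]:
    out: dict[str, float] = {}
    for token in line.split():
        if "=" not in token:
            raise ParseError(f"line {lineno}: malformed header token {token!r}")
        key, val = token.split("=", 1)
        try:
            out[key] = float(val)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric header value {token!r}") from exc
    for key in ("Lx", "Ly", "Lz"):
        if key not in out:
            raise ParseError(f"line {lineno}: header missing {key}")
    return out


# ---------------------------------------------------------------------------
# topology TSV

_TOPOLOGY_COLUMNS = (
    "molecule_id\tcompound\trole\tparticle_ids\taromatic_ring_ids\t"
    "donor_ids\tacceptor_ids\tvector_tail_id\tvector_head_id"
)


def _ids_to_str(ids: Sequence[int]) -> str:
    return ";".join(str(i) for i in ids) if ids else "-"


def _str_to_ids(s: str) -> list[int]:
    return [] if s in ("-", "") else [int(t) for t in s.split(";")]


def write_topology(topology: Topology, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_TOPOLOGY_COLUMNS + "\n")
        for mol in topology.molecules.values():
            rings = "|".join(";".join(str(i) for i in ring) for ring in mol.aromatic_rings) or "-"
            tail = "-" if mol.vector_tail_id is None else str(mol.vector_tail_id)
            head = "-" if mol.vector_head_id is None else str(mol.vector_head_id)
            fh.write(
                f"{mol.molecule_id}\t{mol.compound}\t{mol.role}\t{_ids_to_str(mol.particle_ids)}\t"
                f"{rings}\t{_ids_to_str(mol.donor_ids)}\t{_ids_to_str(mol.acceptor_ids)}\t{tail}\t{head}\n"
            )


def read_topology(path: str | Path) -> Topology:
    path = Path(path)
    molecules: dict[int, MoleculeRecord] = {}
    with path.open() as fh:
        header = fh.readline()
        if header.strip() != _TOPOLOGY_COLUMNS.strip():
            raise ParseError(f"{path}: unexpected topology header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path} line {lineno}: expected 9 columns, got {len(parts)}")
            mid = int(parts[0])
            rings = (
                [] if parts[4] == "-" else [[int(i) for i in ring.split(";")] for ring in parts[4].split("|")]
            )
            molecules[mid] = MoleculeRecord(
                molecule_id=mid,
                compound=parts[1],
                role=parts[2],
                particle_ids=_str_to_ids(parts[3]),
                aromatic_rings=rings,
                donor_ids=_str_to_ids(parts[5]),
                acceptor_ids=_str_to_ids(parts[6]),
                vector_tail_id=None if parts[7] == "-" else int(parts[7]),
                vector_head_id=None if parts[8] == "-" else int(parts[8]),
            )
    return Topology(molecules=molecules)


# ---------------------------------------------------------------------------
# optional GRO import


def read_gro(
    path: str | Path,
    topology: Topology,
    surface_planes: Optional[tuple[float, float]] = None,
    time: float = 0.0,
) -> SlitPoreFrame:
    """Import a single GRO-format coordinate file.

    Roles and molecule membership come from the topology table (by particle
    order); the GRO residue/atom names are kept as site names.  Velocities,
    if present, are ignored.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GRO file")
    try:
        count = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path} line 2: expected atom count") from exc
    if count != topology.n_particles:
        raise TopologyError(f"{path}: {count} atoms but topology defines {topology.n_particles}")
    names, pos = [], []
    for j in range(count):
        line = lines[2 + j]
        names.append(line[10:15].strip())
        try:
            pos.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
        except ValueError as exc:
            raise ParseError(f"{path} line {3 + j}: bad coordinate field") from exc
    box_tokens = lines[2 + count].split()
    box = np.array([float(t) for t in box_tokens[:3]])
    roles = np.empty(count, dtype=object)
    mids = np.empty(count, dtype=int)
    for mol in topology.molecules.values():
        for pid in mol.particle_ids:
            roles[pid] = mol.role
            mids[pid] = mol.molecule_id
    return SlitPoreFrame(
        time=time,
        box=box,
        site_names=np.array(names),
        roles=roles.astype(str),
        molecule_ids=mids,
        positions=wrap_xy(np.array(pos), box),
        surface_planes=surface_planes,
    )
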