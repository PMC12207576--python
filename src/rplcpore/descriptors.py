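"""Solute descriptors from molecular graphs and retention arithmetic.

The solute properties that rationalise retention order are computed from
a light-weight molecular graph with implicit hydrogens:

* the group-contribution van der Waals volume
  V = Σ atom contributions − 5.92·N_B − 14.7·R_A − 3.8·R_NR,
  with N_B the total bond count (including bonds to implicit H) and
  R_A/R_NR the aromatic/nonaromatic ring counts;
* N(CH_x), the number of hydrophobic CH_x groups (x = 0…3), which for
  the analyte ensemble equals the carbon count — quaternary and aromatic
  carbons count as CH_0;
* chromatographic arithmetic: the retention factor k = t_r/t_0 − 1 and
  the selectivity factor α = k_2/k_1 (ordered so α ≥ 1).

log K_OW, log K_HW and the neat-water hydrogen-bond requirement are
literature inputs carried alongside, not predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigError

#: atom contributions to the van der Waals volume, Å³ (group-contribution
#: scheme with per-bond and per-ring corrections)
ATOM_CONTRIBUTIONS: dict[str, float] = {
    "H": 7.24,
    "C": 20.58,
    "N": 15.60,
    "O": 14.71,
    "F": 13.31,
    "Cl": 22.45,
    "S": 24.43,
}

BOND_CORRECTION = 5.92  # Å³ per bond
AROMATIC_RING_CORRECTION = 14.7  # Å³ per aromatic ring
NONAROMATIC_RING_CORRECTION = 3.8  # Å³ per nonaromatic ring


@dataclass(frozen=True)
class GraphAtom:
    element: str
    aromatic: bool = False
    n_h: int = 0  # implicit hydrogens


@dataclass
class MolecularGraph:
    """Heavy-atom graph with implicit hydrogens and a ring census."""

    name: str
    atoms: list[GraphAtom]
    bonds: list[tuple[int, int]]  # heavy-heavy bonds
    r_aromatic: int = 0
    r_nonaromatic: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ConfigError(f"{self.name}: bad bond ({i}, {j})")
        if not self._connected():
            raise ConfigError(f"{self.name}: molecular graph is not connected")
        # Euler check for a single connected component with rings
        if self.n_bonds != self.n_atoms - 1 + self.r_aromatic + self.r_nonaromatic:
            raise ConfigError(
                f"{self.name}: bond count {self.n_bonds} inconsistent with "
                f"{self.n_atoms} atoms and {self.r_aromatic}+{self.r_nonaromatic} rings"
            )

    def _connected(self) -> bool:
        if len(self.atoms) <= 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.atoms))}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == len(self.atoms)

    @property
    def n_atoms(self) -> int:
        """All atoms including implicit hydrogens."""
        return len(self.atoms) + sum(a.n_h for a in self.atoms)

    @property
    def n_bonds(self) -> int:
        """All bonds including bonds to implicit hydrogens."""
        return len(self.bonds) + sum(a.n_h for a in self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return [j for a, b in self.bonds for j in ((b,) if a == i else (a,) if b == i else ())]


def vdw_volume(graph: MolecularGraph) -> float:
    """Group-contribution van der Waals volume in Å³ (rounded to 0.01)."""
    total = 0.0
    for atom in graph.atoms:
        try:
            total += ATOM_CONTRIBUTIONS[atom.element]
        except KeyError as exc:
            raise ConfigError(
                f"{graph.name}: no van der Waals contribution for element {atom.element!r}"
            ) from exc
        total += atom.n_h * ATOM_CONTRIBUTIONS["H"]
    total -= BOND_CORRECTION * graph.n_bonds
    total -= AROMATIC_RING_CORRECTION * graph.r_aromatic
    total -= NONAROMATIC_RING_CORRECTION * graph.r_nonaromatic
    return round(total, 2)


def count_chx(graph: MolecularGraph) -> int:
    """Number of hydrophobic CH_x groups (x = 0, 1, 2, 3).

    Calibrated against the six-analyte ensemble: every carbon counts as a
    CH_x group (aromatic and carbonyl carbons are CH_0) unless it is bonded
    exclusively to heteroatoms and bears no hydrogen — a carbon with no
    hydrocarbon character at all.
    """
    count = 0
    for i, atom in enumerate(graph.atoms):
        if atom.element != "C":
            continue
        if atom.n_h > 0:
            count += 1
            continue
        if any(graph.atoms[j].element == "C" for j in graph.neighbors(i)):
            count += 1
    return count


@dataclass
class SoluteDescriptors:
    """Descriptor bundle for one analyte compound."""

    name: str
    v_vdw: float  # Å³
    n_chx: int
    log_kow: Optional[float] = None  # literature input
    log_khw: Optional[float] = None  # literature input
    hb_max: Optional[float] = None  # neat-water HB requirement

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "v_vdw": self.v_vdw,
            "n_chx": self.n_chx,
            "log_kow": self.log_kow,
            "log_khw": self.log_khw,
            "hb_max": self.hb_max,
        }


def retention_factor(t_r: float, t_0: float) -> float:
    """Retention factor k = t_r/t_0 − 1 from elution and dead time."""
    if t_0 <= 0:
        raise ConfigError(f"dead time t_0 must be positive, got {t_0}")
    k = t_r / t_0 - 1.0
    if k < 0:
        warnings.warn(
            f"t_r = {t_r} < t_0 = {t_0}: negative retention factor {k:.4f}", stacklevel=2
        )
    return k


def selectivity(k1: float, k2: float) -> float:
    """Selectivity factor α = k_2/k_1 with k_2 ≥ k_1, so α ≥ 1."""
    if k1 <= 0 or k2 <= 0:
        raise ConfigError("selectivity requires two positive retention factors")
    hi, lo = max(k1, k2), min(k1, k2)
    return hi / lo


# ---------------------------------------------------------------------------
# the analyte ensemble


def _benzene_ring(extra_atoms: list[GraphAtom], extra_bonds: list[tuple[int, int]], name: str,
                  ring_h: int = 5) -> MolecularGraph:
    """Monosubstituted benzene scaffold: atom 0 bears the substituent."""
    atoms = [GraphAtom("C", aromatic=True, n_h=0 if ring_h == 5 else 1)]
    atoms += [GraphAtom("C", aromatic=True, n_h=1) for _ in range(5)]
    bonds = [(i, (i + 1) % 6) for i in range(6)]
    atoms += extra_atoms
    bonds += extra_bonds
    return MolecularGraph(name=name, atoms=atoms, bonds=bonds, r_aromatic=1)


def _make_compounds() -> dict[str, MolecularGraph]:
    c: dict[str, MolecularGraph] = {}
    c["benzene"] = MolecularGraph(
        name="benzene",
        atoms=[GraphAtom("C", aromatic=True, n_h=1) for _ in range(6)],
        bonds=[(i, (i + 1) % 6) for i in range(6)],
        r_aromatic=1,
    )
    # naphthalene: two fused aromatic rings, 8 CH + 2 junction C
    nap_atoms = [GraphAtom("C", aromatic=True, n_h=0 if i in (0, 5) else 1) for i in range(10)]
    nap_bonds = [(i, i + 1) for i in range(9)] + [(9, 0), (0, 5)]
    c["naphthalene"] = MolecularGraph("naphthalene", nap_atoms, nap_bonds, r_aromatic=2)
    c["ethylbenzene"] = _benzene_ring(
        [GraphAtom("C", n_h=2), GraphAtom("C", n_h=3)], [(0, 6), (6, 7)], "ethylbenzene"
    )
    c["phenol"] = _benzene_ring([GraphAtom("O", n_h=1)], [(0, 6)], "phenol")
    c["benzyl_alcohol"] = _benzene_ring(
        [GraphAtom("C", n_h=2), GraphAtom("O", n_h=1)], [(0, 6), (6, 7)], "benzyl_alcohol"
    )
    # acetophenone: ring + carbonyl C (no H) double-bonded O + methyl
    c["acetophenone"] = _benzene_ring(
        [GraphAtom("C", n_h=0), GraphAtom("O", n_h=0), GraphAtom("C", n_h=3)],
        [(0, 6), (6, 7), (6, 8)],
        "acetophenone",
    )
    return c


COMPOUND_GRAPHS: dict[str, MolecularGraph] = _make_compounds()

#: literature partition coefficients (inputs, not predictions)
LITERATURE_PROPERTIES: dict[str, dict[str, float]] = {
    "naphthalene": {"log_kow": 3.30, "log_khw": 3.41},
    "ethylbenzene": {"log_kow": 3.15, "log_khw": 3.20},
    "benzene": {"log_kow": 2.13, "log_khw": 2.15},
    "acetophenone": {"log_kow": 1.58, "log_khw": 1.14},
    "benzyl_alcohol": {"log_kow": 1.10, "log_khw": -0.43},
    "phenol": {"log_kow": 1.46, "log_khw": -1.08},
}


def compound_descriptors(name: str, hb_max: Optional[float] = None) -> SoluteDescriptors:
    """Descriptor bundle for one of the six ensemble compounds."""
    try:
        graph = COMPOUND_GRAPHS[name]
    except KeyError as exc:
        raise ConfigError(f"unknown compound {name!r}; known: {sorted(COMPOUND_GRAPHS)}") from exc
    lit = LITERATURE_PROPERTIES.get(name, {})
    return SoluteDescriptors(
        name=name,
        v_vdw=vdw_volume(graph),
        n_chx=count_chx(graph),
        log_kow=lit.get("log_kow"),
        log_khw=lit.get("log_khw"),
        hb_max=hb_max,
    )
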