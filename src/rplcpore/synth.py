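"""Synthetic slit-pore configuration generator with exact ground truth.

No public trajectory data exist for the solvated C18/silica slit-pore
system, so every analysis stage in this package is validated against
ensembles drawn from a *stated* statistical model of the interface:

* bonded-phase bead density concentrated in the bonded-phase region
  (z <~ 1.05 nm from the surface),
* water density rising sigmoidally from the surface toward a bulk plateau,
* organic-solvent density with the characteristic "ditch" maximum in the
  interfacial region,
* analyte centre-of-mass density as a three-component truncated-Gaussian
  mixture (silica-surface peak, partitioning peak, adsorption peak),
* z-dependent hydrogen-bond engagement of the analyte's donor/acceptor/π
  sites with water or organic-solvent partners, and
* z-dependent analyte orientation drawn from a linear-in-cos-φ law.

Frames are independent samples, not dynamics: every estimator downstream
is a time average, so i.i.d. sampling with timestamp bookkeeping
(``frame_dt``) is sufficient.  The generator records every draw it makes
(mixture component labels, com positions, engagement flags, partner
species, cos φ), which is what makes exact parameter-recovery tests
possible.

Hydrogen-bond geometry is planted, not emergent: with probability
``hb_engage_prob(z)`` a partner molecule is placed so that the distance
criterion is met with a margin drawn uniformly in (0, r_HB]; all other
solvent sites keep an exclusion distance from the solute's donor sites so
that the detector's expected count equals the configured engagement
probability exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .geometry import pairs_within
from .hbonds import DEFAULT_CUTOFFS
from .model import MoleculeRecord, SlitPoreFrame, Topology

# ---------------------------------------------------------------------------
# parameterised profiles

_OH = 0.0957  # O-H bond length, nm (water geometry)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SigmoidRise:
    """``amplitude * sigmoid((z - z_mid) * steepness)`` — solvent onset."""

    amplitude: float
    z_mid: float
    steepness: float

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.amplitude * _sigmoid((np.asarray(z, float) - self.z_mid) * self.steepness)


@dataclass(frozen=True)
class DitchProfile:
    """Sigmoid plateau plus a Gaussian maximum (the organic-solvent ditch)."""

    bulk: SigmoidRise
    ditch_amplitude: float
    ditch_center: float
    ditch_sigma: float

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        g = self.ditch_amplitude * np.exp(-0.5 * ((z - self.ditch_center) / self.ditch_sigma) ** 2)
        return self.bulk(z) + g


@dataclass(frozen=True)
class StepFunction:
    """Piecewise-constant function of z; ``values`` has one more entry than
    ``edges``."""

    edges: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.edges) + 1:
            raise ConfigError("StepFunction needs len(values) == len(edges) + 1")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.edges, float), np.asarray(z, float), side="right")
        return np.asarray(self.values, float)[idx]


@dataclass(frozen=True)
class TruncatedGaussianMixture:
    """Mixture of Gaussians truncated to [lo, hi]; weights sum to one."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sigmas: tuple[float, ...]
    lo: float = 0.0
    hi: float = 5.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("mixture weights must be nonnegative and sum to 1")
        if len(self.weights) != len(self.means) or len(self.means) != len(self.sigmas):
            raise ConfigError("mixture parameter lengths differ")
        for m in self.means:
            if not self.lo <= m <= self.hi:
                raise ConfigError(f"mixture component mean {m} outside [{self.lo}, {self.hi}]")

    def pdf(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        out = np.zeros_like(z, dtype=float)
        for w, mu, sd in zip(self.weights, self.means, self.sigmas):
            zval = norm.cdf((self.hi - mu) / sd) - norm.cdf((self.lo - mu) / sd)
            out += w * norm.pdf((z - mu) / sd) / (sd * zval)
        return np.where((z >= self.lo) & (z <= self.hi), out, 0.0)

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw n samples; returns (z values, component labels)."""
        labels = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        z = np.empty(n)
        mu = np.asarray(self.means)[labels]
        sd = np.asarray(self.sigmas)[labels]
        todo = np.arange(n)
        while len(todo):  # rejection against the truncation interval
            z[todo] = rng.normal(mu[todo], sd[todo])
            todo = todo[(z[todo] < self.lo) | (z[todo] > self.hi)]
        return z, labels


def sample_cos_phi(rng: np.random.Generator, mean: np.ndarray, size: Optional[int] = None) -> np.ndarray:
    """Sample cos φ from the truncated linear law with the given mean(s).

    Density f(c) ∝ max(0, 1 + a c) on [-1, 1]; for |mean| < 1/3 the support
    is the full interval (a = 3·mean), for 1/3 <= |mean| < 2/3 the density
    is truncated at zero (a = sign/(2 - 3|mean|)).  Means beyond ±0.65 are
    not attainable by this family and raise a ConfigError.
    """
    m = np.asarray(mean, float)
    if size is not None and m.ndim == 0:
        m = np.full(size, float(m))
    if np.any(np.abs(m) > 0.65):
        raise ConfigError("orientation bias mean beyond +-0.65 not attainable by the linear law")
    a = np.where(np.abs(m) < 1.0 / 3.0, 3.0 * m, np.sign(m) / (2.0 - 3.0 * np.abs(m)))
    with np.errstate(divide="ignore"):
        inv_a = np.where(a != 0, 1.0 / np.where(a == 0, 1.0, a), np.inf)
    lo = np.where(a > 0, np.maximum(-1.0, -inv_a), -1.0)
    hi = np.where(a < 0, np.minimum(1.0, -inv_a), 1.0)
    t = rng.random(m.shape)
    small = np.abs(a) < 1e-9
    k = lo + 0.5 * a * lo**2
    zn = (hi - lo) + 0.5 * a * (hi**2 - lo**2)
    arg = np.maximum(1.0 + 2.0 * a * (k + t * zn), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(small, lo + t * (hi - lo), (-1.0 + np.sqrt(arg)) / np.where(small, 1.0, a))
    return np.clip(c, -1.0, 1.0)


# ---------------------------------------------------------------------------
# rigid analyte templates

_RING_R = 0.139  # aromatic C-C circumradius, nm


def _hexagon(center_x: float = 0.0, phase_deg: float = 0.0) -> list[tuple[float, float]]:
    out = []
    for k in range(6):
        th = math.radians(phase_deg + 60.0 * k)
        out.append((center_x + _RING_R * math.cos(th), _RING_R * math.sin(th)))
    return out


def _naphthalene_coords() -> tuple[list[tuple[float, float]], list[list[int]]]:
    """Ten aromatic carbons of two fused hexagons, plus per-ring index lists."""
    c = _RING_R * math.sqrt(3.0) / 2.0
    ring1 = _hexagon(-c, 30.0)  # shared-edge vertices land at x = 0
    ring2 = _hexagon(+c, 30.0)
    coords = list(ring1)
    idx2 = []
    for x, y in ring2:
        if abs(x) < 1e-12:  # shared atom, already present
            match = min(range(len(coords)), key=lambda i: (coords[i][0] - x) ** 2 + (coords[i][1] - y) ** 2)
            idx2.append(match)
        else:
            coords.append((x, y))
            idx2.append(len(coords) - 1)
    ring1_idx = list(range(6))
    return coords, [ring1_idx, idx2]


@dataclass(frozen=True)
class AnalyteTemplate:
    """Planar rigid template; local x is the molecular-vector axis."""

    compound: str
    site_names: tuple[str, ...]
    coords: tuple[tuple[float, float], ...]  # (local_x, local_y), nm
    rings: tuple[tuple[int, ...], ...]
    donor_idx: tuple[int, ...] = ()
    acceptor_idx: tuple[int, ...] = ()
    vector_tail: Optional[int] = None  # para ring carbon
    vector_head: Optional[int] = None  # substituent terminus

    @property
    def n_sites(self) -> int:
        """Engageable hydrogen-bond sites: donors + acceptors + one π per ring."""
        return len(self.donor_idx) + len(self.acceptor_idx) + len(self.rings)


def _ring_template(extra: list[tuple[str, float, float]], compound: str, **kw) -> AnalyteTemplate:
    names = ["C_ar"] * 6 + [name for name, _, _ in extra]
    coords = _hexagon(0.0, 0.0) + [(x, y) for _, x, y in extra]
    return AnalyteTemplate(
        compound=compound,
        site_names=tuple(names),
        coords=tuple(coords),
        rings=(tuple(range(6)),),
        **kw,
    )


def _make_templates() -> dict[str, AnalyteTemplate]:
    t: dict[str, AnalyteTemplate] = {}
    t["benzene"] = _ring_template([], "benzene")
    nap_coords, nap_rings = _naphthalene_coords()
    t["naphthalene"] = AnalyteTemplate(
        compound="naphthalene",
        site_names=tuple(["C_ar"] * 10),
        coords=tuple(nap_coords),
        rings=tuple(tuple(r) for r in nap_rings),
    )
    # substituents sit along +local-x; vector tail is the para carbon (index 3)
    r = _RING_R
    t["phenol"] = _ring_template(
        [("O", r + 0.136, 0.0), ("HO", r + 0.136 + _OH, 0.0)],
        "phenol",
        donor_idx=(7,),
        acceptor_idx=(6,),
        vector_tail=3,
        vector_head=6,
    )
    t["ethylbenzene"] = _ring_template(
        [("CH2", r + 0.151, 0.0), ("CH3", r + 0.305, 0.0)],
        "ethylbenzene",
        vector_tail=3,
        vector_head=7,
    )
    t["benzyl_alcohol"] = _ring_template(
        [("CH2", r + 0.151, 0.0), ("O", r + 0.294, 0.0), ("HO", r + 0.294 + _OH, 0.0)],
        "benzyl_alcohol",
        donor_idx=(8,),
        acceptor_idx=(7,),
        vector_tail=3,
        vector_head=7,
    )
    t["acetophenone"] = _ring_template(
        [("C_co", r + 0.149, 0.0), ("O_co", r + 0.271, 0.0), ("CH3", r + 0.226, 0.133)],
        "acetophenone",
        acceptor_idx=(7,),
        vector_tail=3,
        vector_head=7,
    )
    return t


ANALYTE_TEMPLATES = _make_templates()


# ---------------------------------------------------------------------------
# generator configuration

#: default hydrogen-bond engagement probability vs z (rises toward bulk,
#: emulating the growing solvent access across the interfacial region)
DEFAULT_HB_ENGAGE = SigmoidRise(0.8, 1.0, 1.0 / 0.3)

#: default water share among hydrogen-bond partners
DEFAULT_W_SHARE = StepFunction((), (0.7,))

#: default orientation bias: functional group toward the surface in the
#: bonded-phase region, toward the bulk in the adsorption peak, isotropic
#: beyond the stationary phase
DEFAULT_ORIENTATION_BIAS = StepFunction((1.05, 2.1), (-0.3, 0.4, 0.0))


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic slit pore.

    Geometry copies the published simulation box (12.14 × 13.20 × 10.93 nm,
    10 nm pore); the analyte count is the published 10 molecules per box.
    Bead/solvent counts are scaled down from the all-atom system so that
    test ensembles stay cheap; densities keep their literature-anchored
    shapes (water plateau 9.2 atoms nm⁻³ at the 50 vol % MeOH reference
    point).
    """

    box: tuple[float, float, float] = (12.14, 13.20, 10.93)
    pore_width: float = 10.0
    seed: int = 0
    n_frames: int = 100
    frame_dt: float = 0.4  # ns; 100 frames then span one 40 ns window
    compound: str = "phenol"
    os_type: str = "MeOH"
    n_analyte: int = 10
    n_bp_per_surface: int = 400
    n_endcap_per_surface: int = 40
    n_residual_oh_per_surface: int = 60
    n_silica_per_surface: int = 100
    n_water: Optional[int] = None  # None -> integrate water_profile
    n_os: Optional[int] = None
    bp_profile: TruncatedGaussianMixture = field(
        default_factory=lambda: TruncatedGaussianMixture(
            weights=(0.8, 0.2), means=(0.5, 0.95), sigmas=(0.28, 0.15), lo=0.0, hi=1.4
        )
    )
    water_profile: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: SigmoidRise(9.2, 1.0, 4.0)
    )
    os_profile: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: DitchProfile(SigmoidRise(6.8, 1.2, 4.0), 6.0, 1.45, 0.25)
    )
    analyte_mixture: TruncatedGaussianMixture = field(
        default_factory=lambda: TruncatedGaussianMixture(
            weights=(0.03, 0.07, 0.90), means=(0.5, 0.8, 1.6), sigmas=(0.05, 0.10, 0.20)
        )
    )
    hb_engage_prob: Callable[[np.ndarray], np.ndarray] = DEFAULT_HB_ENGAGE
    w_share: Callable[[np.ndarray], np.ndarray] = DEFAULT_W_SHARE
    orientation_bias: Callable[[np.ndarray], np.ndarray] = DEFAULT_ORIENTATION_BIAS

    def __post_init__(self) -> None:
        if self.compound not in ANALYTE_TEMPLATES:
            raise ConfigError(
                f"unknown compound {self.compound!r}; known: {sorted(ANALYTE_TEMPLATES)}"
            )
        if self.os_type not in ("MeOH", "ACN"):
            raise ConfigError(f"os_type must be MeOH or ACN, got {self.os_type!r}")
        if self.pore_width >= self.box[2]:
            raise ConfigError("pore_width must be smaller than the box z length")
        half = 0.5 * self.pore_width
        for m in self.analyte_mixture.means:
            if not 0.0 <= m <= half:
                raise ConfigError(f"analyte mixture mean {m} outside [0, {half}]")

    @property
    def surface_planes(self) -> tuple[float, float]:
        lo = 0.5 * (self.box[2] - self.pore_width)
        return (lo, lo + self.pore_width)

    @property
    def template(self) -> AnalyteTemplate:
        return ANALYTE_TEMPLATES[self.compound]

    def resolved_water_count(self) -> int:
        if self.n_water is not None:
            return self.n_water
        return self._integrate(self.water_profile)

    def resolved_os_count(self) -> int:
        if self.n_os is not None:
            return self.n_os
        return self._integrate(self.os_profile)

    def _integrate(self, profile: Callable[[np.ndarray], np.ndarray]) -> int:
        half = 0.5 * self.pore_width
        z = np.linspace(0.0, half, 2001)
        dens = np.clip(profile(z), 0.0, None)
        per_half = np.trapezoid(dens, z) * self.box[0] * self.box[1]
        return int(round(2.0 * per_half))


@dataclass
class GroundTruth:
    """Everything the generator knows about what it drew.

    ``analyte_draws`` has one row per (frame, analyte) with the mixture
    component label, the folded com z, the pore side and cos φ;
    ``engagement_draws`` has one row per (frame, analyte, site) with the
    engagement flag and partner species.  These recorded draws are the
    oracles for the parameter-recovery tests.
    """

    config: GeneratorConfig
    analyte_draws: pd.DataFrame
    engagement_draws: pd.DataFrame

    @property
    def expected_adsorption_fraction(self) -> float:
        return self.config.analyte_mixture.weights[2]

    def expected_hb_per_molecule(self, z: np.ndarray) -> np.ndarray:
        p = np.asarray(self.config.hb_engage_prob(np.asarray(z, float)), float)
        return p * self.config.template.n_sites

    def expected_mean_cos(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(self.config.orientation_bias(np.asarray(z, float)), float)

    def bp_density(self, z: np.ndarray) -> np.ndarray:
        """Bonded-phase bead number density (nm⁻³) vs distance from one surface."""
        area = self.config.box[0] * self.config.box[1]
        return self.config.n_bp_per_surface * self.config.bp_profile.pdf(z) / area


# ---------------------------------------------------------------------------
# topology layout

_SOLVENT_SITES = {
    # species -> (partner-pool site names, background site name, key atom)
    "W": (("OW", "HW"), "OW", "OW"),
    "MeOH": (("O_MeOH", "H_MeOH", "CH3_MeOH"), "O_MeOH", "O_MeOH"),
    "ACN": (("N_ACN", "C_ACN", "CH3_ACN"), "N_ACN", "N_ACN"),
}

#: key (heavy acceptor) atom per solvent species
KEY_ATOMS = {"W": "OW", "MeOH": "O_MeOH", "ACN": "N_ACN"}


@dataclass
class _Layout:
    """Particle/molecule bookkeeping shared by topology and frame assembly."""

    config: GeneratorConfig
    site_names: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    molecule_ids: list[int] = field(default_factory=list)
    records: dict[int, MoleculeRecord] = field(default_factory=dict)
    next_mid: int = 0
    # index arrays filled as molecules are added
    silica_idx: list[int] = field(default_factory=list)
    bp_idx: list[int] = field(default_factory=list)
    endcap_idx: list[int] = field(default_factory=list)
    oh_idx: list[int] = field(default_factory=list)
    w_partner_slices: list[list[int]] = field(default_factory=list)
    os_partner_slices: list[list[int]] = field(default_factory=list)
    w_background_idx: list[int] = field(default_factory=list)
    os_background_idx: list[int] = field(default_factory=list)
    analyte_slices: list[list[int]] = field(default_factory=list)

    def add_molecule(self, compound: str, role: str, names: list[str], **annot) -> list[int]:
        mid = self.next_mid
        self.next_mid += 1
        start = len(self.site_names)
        ids = list(range(start, start + len(names)))
        self.site_names.extend(names)
        self.roles.extend([role] * len(names))
        self.molecule_ids.extend([mid] * len(names))
        self.records[mid] = MoleculeRecord(
            molecule_id=mid, compound=compound, role=role, particle_ids=ids, **annot
        )
        return ids


def _build_layout(config: GeneratorConfig) -> _Layout:
    lay = _Layout(config=config)
    cfg = config
    for _ in range(2 * cfg.n_silica_per_surface):
        lay.silica_idx.extend(lay.add_molecule("silica", "silica", ["Si"]))
    for _ in range(2 * cfg.n_bp_per_surface):
        lay.bp_idx.extend(lay.add_molecule("C18_bead", "bonded_phase", ["CH2"]))
    for _ in range(2 * cfg.n_endcap_per_surface):
        lay.endcap_idx.extend(lay.add_molecule("TMS", "endcap", ["CH3"]))
    for _ in range(2 * cfg.n_residual_oh_per_surface):
        lay.oh_idx.extend(lay.add_molecule("SiOH", "residual_OH", ["OH"]))
    n_sites = cfg.template.n_sites
    n_pool = cfg.n_analyte * n_sites
    pool_w, _, _ = _SOLVENT_SITES["W"]
    for _ in range(n_pool):
        lay.w_partner_slices.append(lay.add_molecule("W", "water", list(pool_w)))
    if cfg.os_type in ("MeOH", "ACN"):
        pool_os, _, _ = _SOLVENT_SITES[cfg.os_type]
        for _ in range(n_pool):
            lay.os_partner_slices.append(
                lay.add_molecule(cfg.os_type, "organic_solvent", list(pool_os))
            )
    n_w_bg = max(cfg.resolved_water_count() - n_pool, 0)
    n_os_bg = max(cfg.resolved_os_count() - n_pool, 0)
    for _ in range(n_w_bg):
        lay.w_background_idx.extend(lay.add_molecule("W", "water", ["OW"]))
    bg_os = _SOLVENT_SITES[cfg.os_type][1]
    for _ in range(n_os_bg):
        lay.os_background_idx.extend(lay.add_molecule(cfg.os_type, "organic_solvent", [bg_os]))
    tpl = cfg.template
    for _ in range(cfg.n_analyte):
        annot: dict = {}
        ids = lay.add_molecule(tpl.compound, "analyte", list(tpl.site_names))
        rec = lay.records[lay.molecule_ids[ids[0]]]
        rec.aromatic_rings = [[ids[i] for i in ring] for ring in tpl.rings]
        rec.donor_ids = [ids[i] for i in tpl.donor_idx]
        rec.acceptor_ids = [ids[i] for i in tpl.acceptor_idx]
        if tpl.vector_tail is not None:
            rec.vector_tail_id = ids[tpl.vector_tail]
            rec.vector_head_id = ids[tpl.vector_head]
        lay.analyte_slices.append(ids)
    return lay


# ---------------------------------------------------------------------------
# sampling helpers


def _inverse_cdf_sample(
    rng: np.random.Generator,
    profile: Callable[[np.ndarray], np.ndarray],
    n: int,
    z_hi: float,
) -> np.ndarray:
    grid = np.linspace(0.0, z_hi, 4001)
    pdf = np.clip(np.asarray(profile(grid), float), 0.0, None)
    if pdf.sum() <= 0:
        raise ConfigError("profile integrates to zero; cannot sample")
    cdf = np.cumsum(pdf)
    cdf = np.concatenate([[0.0], cdf]) / cdf[-1]
    grid2 = np.concatenate([[0.0], grid])
    return np.interp(rng.random(n), cdf, grid2)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _to_lab_z(d: np.ndarray, side: np.ndarray, planes: tuple[float, float]) -> np.ndarray:
    lo, hi = planes
    return np.where(side == 0, lo + d, hi - d)


class _SlitFrameBuilder:
    """Assembles one frame; holds per-frame scratch state."""

    def __init__(self, lay: _Layout, rng: np.random.Generator):
        self.lay = lay
        self.cfg = lay.config
        self.rng = rng
        self.box = np.asarray(self.cfg.box, float)
        self.planes = self.cfg.surface_planes
        self.half = 0.5 * self.cfg.pore_width
        self.pos = np.zeros((len(lay.site_names), 3))

    def _xy(self, n: int) -> np.ndarray:
        return self.rng.random((n, 2)) * self.box[:2]

    def _place_single_beads(self, idx: list[int], d: np.ndarray) -> None:
        n = len(idx)
        side = np.repeat([0, 1], [n - n // 2, n // 2])
        xy = self._xy(n)
        self.pos[idx, 0] = xy[:, 0]
        self.pos[idx, 1] = xy[:, 1]
        self.pos[idx, 2] = _to_lab_z(d, side, self.planes)

    def place_scaffold(self) -> None:
        cfg, rng = self.cfg, self.rng
        if self.lay.silica_idx:
            d = -0.05 - 0.1 * rng.random(len(self.lay.silica_idx))  # just outside the pore
            self._place_single_beads(self.lay.silica_idx, d)
        if self.lay.bp_idx:
            d, _ = cfg.bp_profile.sample(rng, len(self.lay.bp_idx))
            self._place_single_beads(self.lay.bp_idx, d)
        for idx, scale in ((self.lay.endcap_idx, 0.25), (self.lay.oh_idx, 0.15)):
            if idx:
                d = np.abs(rng.normal(scale, 0.08, len(idx)))
                self._place_single_beads(idx, d)

    def place_analytes(self) -> tuple[pd.DataFrame, list[dict]]:
        cfg, rng, tpl = self.cfg, self.rng, self.cfg.template
        n = cfg.n_analyte
        d, labels = cfg.analyte_mixture.sample(rng, n)
        side = rng.integers(0, 2, n)
        com_xy = self._xy(n)
        mean_cos = np.asarray(cfg.orientation_bias(d), float)
        cos_phi = sample_cos_phi(rng, mean_cos)
        psi = rng.random(n) * 2.0 * np.pi
        rows = []
        sites: list[dict] = []
        local = np.asarray(tpl.coords)  # (m, 2)
        placed_sites: list[np.ndarray] = []
        for i, ids in enumerate(self.lay.analyte_slices):
            c = cos_phi[i]
            s = math.sqrt(max(1.0 - c * c, 0.0))
            # molecular axis in the folded (into-pore) frame, then to lab
            u = np.array([s * math.cos(psi[i]), s * math.sin(psi[i]), c])
            if side[i] == 1:
                u = u * np.array([1.0, 1.0, -1.0])
            # in-plane normal e2 perpendicular to u, random azimuth
            helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            e2 = np.cross(u, helper)
            e2 /= np.linalg.norm(e2)
            ang = rng.random() * 2.0 * np.pi
            e2 = math.cos(ang) * e2 + math.sin(ang) * np.cross(u, e2)
            lab_z = _to_lab_z(d[i], side[i], self.planes)
            # keep the hydrogen-bond sites of different molecules clear of
            # each other (0.75 nm: partner reach + largest cutoff) so that
            # partner placement never competes with a neighbouring solute;
            # only x,y are redrawn, so the configured z marginal is intact
            xy = com_xy[i]
            for _try in range(100):
                com = np.array([xy[0], xy[1], lab_z])
                atoms = com + local[:, :1] * u + local[:, 1:2] * e2
                mol_sites = _template_site_positions(tpl, atoms)
                if not placed_sites or _min_site_distance(
                    mol_sites, np.array(placed_sites), self.box
                ) > 0.75:
                    break
                xy = self._xy(1)[0]
            placed_sites.extend(mol_sites)
            self.pos[ids] = atoms
            mid = self.lay.molecule_ids[ids[0]]
            rows.append(
                {
                    "molecule_id": mid,
                    "component": int(labels[i]),
                    "z": float(d[i]),
                    "side": int(side[i]),
                    "cos_phi": float(c),
                }
            )
            for j_local in tpl.donor_idx:
                sites.append({"mol": mid, "kind": "donor_H", "pos": atoms[j_local], "z": float(d[i])})
            for j_local in tpl.acceptor_idx:
                sites.append({"mol": mid, "kind": "acceptor", "pos": atoms[j_local], "z": float(d[i])})
            for ring in tpl.rings:
                ring_com = atoms[list(ring)].mean(axis=0)
                sites.append({"mol": mid, "kind": "pi", "pos": ring_com, "z": float(d[i])})
        return pd.DataFrame(rows), sites

    # -- hydrogen-bond partner machinery -----------------------------------

    def _partner_atoms(self, site: dict, species: str) -> np.ndarray:
        """Draw partner-molecule atom positions satisfying the bond criterion."""
        rng = self.rng
        kind = site["kind"]
        pos = site["pos"]
        if kind == "donor_H":
            cutoff = DEFAULT_CUTOFFS[("donor_H", f"{'O' if species != 'ACN' else 'N'}_{species}"
                                      if species != "W" else "O_W")]
            d = cutoff * (1.0 - rng.random())
            u = _unit_vectors(rng, 1)[0]
            a = pos + d * u  # the acceptor heavy atom
            if species == "W":
                h = a + _OH * _unit_vectors(rng, 1)[0]
                return np.array([a, h])
            if species == "MeOH":
                w1, w2 = _unit_vectors(rng, 2)
                return np.array([a, a + _OH * w1, a + 0.14 * w2])
            w1 = _unit_vectors(rng, 1)[0]
            return np.array([a, a + 0.116 * w1, a + 0.262 * w1])
        if kind == "acceptor":
            cutoff = DEFAULT_CUTOFFS[("acceptor", f"H_{species}" if species != "W" else "H_W")]
            d = cutoff * (1.0 - rng.random())
            u = _unit_vectors(rng, 1)[0]
            h = pos + d * u
            o = h + _OH * u  # heavy atom points away from the solute
            if species == "W":
                return np.array([o, h])
            return np.array([o, h, o + 0.14 * _unit_vectors(rng, 1)[0]])
        # π site: partner donates an H toward the ring com
        cutoff = DEFAULT_CUTOFFS[("pi", "H_W" if species == "W" else "H_MeOH")]
        d = cutoff * (1.0 - rng.random())
        u = _unit_vectors(rng, 1)[0]
        h = pos + d * u
        o = h + _OH * u
        if species == "W":
            return np.array([o, h])
        return np.array([o, h, o + 0.14 * _unit_vectors(rng, 1)[0]])

    def _violates(self, atoms: np.ndarray, species: str, sites: list[dict], skip: int) -> bool:
        """True if partner atoms satisfy a criterion with any unintended site."""
        heavy = atoms[0]
        hs = atoms[1:2] if species in ("W", "MeOH") else np.empty((0, 3))
        for j, site in enumerate(sites):
            if j == skip:
                continue
            p = site["pos"]
            kind = site["kind"]
            if kind == "donor_H":
                key = ("donor_H", {"W": "O_W", "MeOH": "O_MeOH", "ACN": "N_ACN"}[species])
                if _mi_dist(heavy, p, self.box) <= DEFAULT_CUTOFFS[key]:
                    return True
            elif kind == "acceptor" and len(hs):
                key = ("acceptor", "H_W" if species == "W" else "H_MeOH")
                if _mi_dist(hs[0], p, self.box) <= DEFAULT_CUTOFFS[key]:
                    return True
            elif kind == "pi" and len(hs) and species in ("W", "MeOH"):
                key = ("pi", "H_W" if species == "W" else "H_MeOH")
                if _mi_dist(hs[0], p, self.box) <= DEFAULT_CUTOFFS[key]:
                    return True
        return False

    def engage_partners(self, sites: list[dict]) -> pd.DataFrame:
        cfg, rng = self.cfg, self.rng
        z = np.array([s["z"] for s in sites]) if sites else np.empty(0)
        p = np.asarray(cfg.hb_engage_prob(z), float) if len(z) else np.empty(0)
        engaged = rng.random(len(sites)) < p if len(sites) else np.empty(0, bool)
        wsh = np.asarray(cfg.w_share(z), float) if len(z) else np.empty(0)
        pick_w = rng.random(len(sites)) < wsh if len(sites) else np.empty(0, bool)
        rows = []
        w_used = 0
        os_used = 0
        for j, site in enumerate(sites):
            species = None
            if engaged[j]:
                species = "W" if pick_w[j] else cfg.os_type
                if site["kind"] == "pi" and species == "ACN":
                    species = "W"  # acetonitrile has no donor H for π bonds
                if site["kind"] == "acceptor" and species == "ACN":
                    species = "W"  # nor for the solute's acceptor
                for _try in range(200):
                    atoms = self._partner_atoms(site, species)
                    if not self._violates(atoms, species, sites, skip=j):
                        break
                else:  # pragma: no cover - astronomically unlikely
                    raise ConfigError("could not place hydrogen-bond partner without cross-talk")
                if species == "W":
                    ids = self.lay.w_partner_slices[w_used]
                    w_used += 1
                else:
                    ids = self.lay.os_partner_slices[os_used]
                    os_used += 1
                self.pos[ids] = atoms[: len(ids)]
            rows.append(
                {
                    "mol": site["mol"],
                    "kind": site["kind"],
                    "z": site["z"],
                    "engaged": bool(engaged[j]),
                    "species": species,
                }
            )
        self._park_partners(self.lay.w_partner_slices[w_used:], "W", sites)
        if self.lay.os_partner_slices:
            self._park_partners(self.lay.os_partner_slices[os_used:], cfg.os_type, sites)
        return pd.DataFrame(rows, columns=["mol", "kind", "z", "engaged", "species"])

    def _park_partners(self, slices: list[list[int]], species: str, sites: list[dict]) -> None:
        """Unengaged pool molecules become ordinary solvent, kept clear of
        every solute hydrogen-bond site so detection stays exact."""
        if not slices:
            return
        cfg, rng = self.cfg, self.rng
        profile = cfg.water_profile if species == "W" else cfg.os_profile
        n = len(slices)
        site_pos = np.array([s["pos"] for s in sites]) if sites else np.empty((0, 3))
        anchors = self._clear_positions(profile, n, site_pos, clearance=0.45)
        for k, ids in enumerate(slices):
            base = anchors[k]
            atoms = [base]
            if species == "W":
                atoms.append(base + _OH * _unit_vectors(rng, 1)[0])
            else:
                w1, w2 = _unit_vectors(rng, 2)
                atoms.append(base + (_OH if species == "MeOH" else 0.116) * w1)
                atoms.append(base + (0.14 if species == "MeOH" else 0.262) * w2)
            self.pos[ids] = np.array(atoms)[: len(ids)]

    def _clear_positions(
        self,
        profile: Callable[[np.ndarray], np.ndarray],
        n: int,
        site_pos: np.ndarray,
        clearance: float,
    ) -> np.ndarray:
        rng = self.rng
        d = _inverse_cdf_sample(rng, profile, n, self.half)
        side = rng.integers(0, 2, n)
        out = np.column_stack([self._xy(n), _to_lab_z(d, side, self.planes)])
        if len(site_pos) == 0 or n == 0:
            return out
        for _ in range(100):
            ci, _, _ = pairs_within(out, site_pos, clearance, self.box, periodic_z=False)
            bad = np.unique(ci)
            if len(bad) == 0:
                return out
            d = _inverse_cdf_sample(rng, profile, len(bad), self.half)
            side = rng.integers(0, 2, len(bad))
            out[bad] = np.column_stack([self._xy(len(bad)), _to_lab_z(d, side, self.planes)])
        raise ConfigError("background solvent placement failed to clear solute sites")

    def place_background(self, sites: list[dict]) -> None:
        cfg = self.cfg
        donor_pos = np.array([s["pos"] for s in sites if s["kind"] == "donor_H"])
        if donor_pos.size == 0:
            donor_pos = np.empty((0, 3))
        if self.lay.w_background_idx:
            pos = self._clear_positions(cfg.water_profile, len(self.lay.w_background_idx), donor_pos, 0.27)
            self.pos[self.lay.w_background_idx] = pos
        if self.lay.os_background_idx:
            pos = self._clear_positions(cfg.os_profile, len(self.lay.os_background_idx), donor_pos, 0.27)
            self.pos[self.lay.os_background_idx] = pos


def _template_site_positions(tpl: AnalyteTemplate, atoms: np.ndarray) -> list[np.ndarray]:
    """Hydrogen-bond site positions (donors, acceptors, ring coms) of one
    placed analyte."""
    sites = [atoms[j] for j in tpl.donor_idx]
    sites += [atoms[j] for j in tpl.acceptor_idx]
    sites += [atoms[list(ring)].mean(axis=0) for ring in tpl.rings]
    return sites


def _min_site_distance(sites_a, sites_b: np.ndarray, box: np.ndarray) -> float:
    """Smallest xy-minimum-image distance between two site sets."""
    a = np.asarray(sites_a, float)
    d = a[:, None, :] - sites_b[None, :, :]
    d[..., 0] -= box[0] * np.round(d[..., 0] / box[0])
    d[..., 1] -= box[1] * np.round(d[..., 1] / box[1])
    return float(np.sqrt(np.sum(d * d, axis=-1)).min())


def _mi_dist(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> float:
    d = q - p
    d[0] -= box[0] * round(d[0] / box[0])
    d[1] -= box[1] * round(d[1] / box[1])
    return float(np.sqrt(d @ d))


# ---------------------------------------------------------------------------
# public entry points


def generate_slitpore(config: GeneratorConfig) -> tuple[list[SlitPoreFrame], Topology, GroundTruth]:
    """Draw a frame ensemble from the configured slit-pore statistical model."""
    lay = _build_layout(config)
    topology = Topology(molecules=lay.records)
    rng = np.random.default_rng(config.seed)
    frames: list[SlitPoreFrame] = []
    analyte_frames = []
    engage_frames = []
    for f in range(config.n_frames):
        builder = _SlitFrameBuilder(lay, rng)
        builder.place_scaffold()
        draws, sites = builder.place_analytes()
        engagements = builder.engage_partners(sites)
        builder.place_background(sites)
        pos = builder.pos.copy()
        pos[:, 0] %= builder.box[0]
        pos[:, 1] %= builder.box[1]
        frames.append(
            SlitPoreFrame(
                time=f * config.frame_dt,
                box=builder.box,
                site_names=np.array(lay.site_names),
                roles=np.array(lay.roles),
                molecule_ids=np.array(lay.molecule_ids),
                positions=pos,
                surface_planes=config.surface_planes,
            )
        )
        draws.insert(0, "frame", f)
        engagements.insert(0, "frame", f)
        analyte_frames.append(draws)
        engage_frames.append(engagements)
    truth = GroundTruth(
        config=config,
        analyte_draws=pd.concat(analyte_frames, ignore_index=True),
        engagement_draws=pd.concat(engage_frames, ignore_index=True),
    )
    return frames, topology, truth


@dataclass
class BulkConfig:
    """Neat-water bulk box for the HB_solute-W,max reference measurement."""

    box_edge: float = 3.0
    seed: int = 0
    n_frames: int = 100
    frame_dt: float = 0.1
    compound: str = "phenol"
    n_analyte: int = 10
    n_water: int = 200
    hb_prob: float = 0.6

    def __post_init__(self) -> None:
        if self.n_analyte < 1:
            raise ConfigError("need at least one analyte molecule")
        if not 0.0 <= self.hb_prob <= 1.0:
            raise ConfigError(f"hb_prob must be in [0, 1], got {self.hb_prob}")
        if self.compound not in ANALYTE_TEMPLATES:
            raise ConfigError(f"unknown compound {self.compound!r}")


def generate_bulk_box(config: BulkConfig) -> tuple[list[SlitPoreFrame], Topology, GroundTruth]:
    """Homogeneous neat-water box with per-site engagement probability."""
    tpl = ANALYTE_TEMPLATES[config.compound]
    lay = _Layout(config=None)  # type: ignore[arg-type]
    n_pool = config.n_analyte * tpl.n_sites
    for _ in range(n_pool):
        lay.w_partner_slices.append(lay.add_molecule("W", "water", ["OW", "HW"]))
    for _ in range(max(config.n_water - n_pool, 0)):
        lay.w_background_idx.extend(lay.add_molecule("W", "water", ["OW"]))
    for _ in range(config.n_analyte):
        ids = lay.add_molecule(tpl.compound, "analyte", list(tpl.site_names))
        rec = lay.records[lay.molecule_ids[ids[0]]]
        rec.aromatic_rings = [[ids[i] for i in ring] for ring in tpl.rings]
        rec.donor_ids = [ids[i] for i in tpl.donor_idx]
        rec.acceptor_ids = [ids[i] for i in tpl.acceptor_idx]
        if tpl.vector_tail is not None:
            rec.vector_tail_id = ids[tpl.vector_tail]
            rec.vector_head_id = ids[tpl.vector_head]
        lay.analyte_slices.append(ids)
    topology = Topology(molecules=lay.records)
    rng = np.random.default_rng(config.seed)
    box = np.full(3, config.box_edge)
    frames = []
    engage_frames = []
    n_part = len(lay.site_names)
    for f in range(config.n_frames):
        pos = np.zeros((n_part, 3))
        sites: list[dict] = []
        local = np.asarray(tpl.coords)
        placed_sites: list[np.ndarray] = []
        for ids in lay.analyte_slices:
            u = _unit_vectors(rng, 1)[0]
            helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            e2 = np.cross(u, helper)
            e2 /= np.linalg.norm(e2)
            for _try in range(200):  # molecules keep HB-site clearance
                com = rng.random(3) * box
                atoms = com + local[:, :1] * u + local[:, 1:2] * e2
                mol_sites = _template_site_positions(tpl, atoms)
                if not placed_sites or _min_bulk_site_distance(
                    mol_sites, np.array(placed_sites), box
                ) > 0.75:
                    break
            placed_sites.extend(mol_sites)
            pos[ids] = atoms
            mid = lay.molecule_ids[ids[0]]
            for j in tpl.donor_idx:
                sites.append({"mol": mid, "kind": "donor_H", "pos": atoms[j], "z": 0.0})
            for j in tpl.acceptor_idx:
                sites.append({"mol": mid, "kind": "acceptor", "pos": atoms[j], "z": 0.0})
            for ring in tpl.rings:
                sites.append({"mol": mid, "kind": "pi", "pos": atoms[list(ring)].mean(axis=0), "z": 0.0})
        engaged = rng.random(len(sites)) < config.hb_prob
        rows = []
        w_used = 0
        helper_builder = _BulkPartnerHelper(rng, box)
        for j, site in enumerate(sites):
            if engaged[j]:
                for _try in range(200):
                    atoms = helper_builder.partner_atoms(site)
                    if not helper_builder.violates(atoms, sites, skip=j):
                        break
                else:  # pragma: no cover
                    raise ConfigError("bulk partner placement failed")
                ids = lay.w_partner_slices[w_used]
                w_used += 1
                pos[ids] = atoms
            rows.append(
                {
                    "frame": f,
                    "mol": site["mol"],
                    "kind": site["kind"],
                    "z": np.nan,
                    "engaged": bool(engaged[j]),
                    "species": "W" if engaged[j] else None,
                }
            )
        site_pos = np.array([s["pos"] for s in sites]) if sites else np.empty((0, 3))
        # parked pool + background water, clear of all solute sites
        for ids in lay.w_partner_slices[w_used:]:
            base = _bulk_clear_position(rng, box, site_pos, 0.45)
            pos[ids[0]] = base
            pos[ids[1]] = base + _OH * _unit_vectors(rng, 1)[0]
        for idx in lay.w_background_idx:
            pos[idx] = _bulk_clear_position(rng, box, site_pos, 0.27)
        pos %= box
        frames.append(
            SlitPoreFrame(
                time=f * config.frame_dt,
                box=box,
                site_names=np.array(lay.site_names),
                roles=np.array(lay.roles),
                molecule_ids=np.array(lay.molecule_ids),
                positions=pos,
                surface_planes=None,
            )
        )
        engage_frames.append(pd.DataFrame(rows, columns=["frame", "mol", "kind", "z", "engaged", "species"]))
    truth = GroundTruth(
        config=config,  # type: ignore[arg-type]
        analyte_draws=pd.DataFrame(),
        engagement_draws=pd.concat(engage_frames, ignore_index=True),
    )
    return frames, topology, truth


class _BulkPartnerHelper:
    def __init__(self, rng: np.random.Generator, box: np.ndarray):
        self.rng = rng
        self.box = box

    def partner_atoms(self, site: dict) -> np.ndarray:
        rng = self.rng
        kind = site["kind"]
        pos = site["pos"]
        if kind == "donor_H":
            cutoff = DEFAULT_CUTOFFS[("donor_H", "O_W")]
            d = cutoff * (1.0 - rng.random())
            u = _unit_vectors(rng, 1)[0]
            a = pos + d * u
            return np.array([a, a + _OH * _unit_vectors(rng, 1)[0]])
        cutoff = DEFAULT_CUTOFFS[("acceptor", "H_W") if kind == "acceptor" else ("pi", "H_W")]
        d = cutoff * (1.0 - rng.random())
        u = _unit_vectors(rng, 1)[0]
        h = pos + d * u
        return np.array([h + _OH * u, h])

    def violates(self, atoms: np.ndarray, sites: list[dict], skip: int) -> bool:
        heavy, h = atoms[0], atoms[1]
        for j, site in enumerate(sites):
            if j == skip:
                continue
            p = site["pos"]
            if site["kind"] == "donor_H":
                if _bulk_dist(heavy, p, self.box) <= DEFAULT_CUTOFFS[("donor_H", "O_W")]:
                    return True
            elif site["kind"] == "acceptor":
                if _bulk_dist(h, p, self.box) <= DEFAULT_CUTOFFS[("acceptor", "H_W")]:
                    return True
            else:
                if _bulk_dist(h, p, self.box) <= DEFAULT_CUTOFFS[("pi", "H_W")]:
                    return True
        return False


def _min_bulk_site_distance(sites_a, sites_b: np.ndarray, box: np.ndarray) -> float:
    a = np.asarray(sites_a, float)
    d = a[:, None, :] - sites_b[None, :, :]
    d -= box * np.round(d / box)
    return float(np.sqrt(np.sum(d * d, axis=-1)).min())


def _bulk_dist(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> float:
    d = q - p
    d -= box * np.round(d / box)
    return float(np.sqrt(d @ d))


def _bulk_clear_position(
    rng: np.random.Generator, box: np.ndarray, site_pos: np.ndarray, clearance: float
) -> np.ndarray:
    for _ in range(1000):
        p = rng.random(3) * box
        if len(site_pos) == 0:
            return p
        d = site_pos - p
        d -= box * np.round(d / box)
        if np.min(np.sqrt(np.sum(d * d, axis=1))) > clearance:
            return p
    raise ConfigError("bulk background placement failed")  # pragma: no cover
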