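"""End-to-end orchestration: generate → profiles → contacts → hbonds →
orientation → report.

A run either generates a synthetic ensemble from a compound preset or
loads frames + topology from disk, then executes every analysis stage in
order, writing each intermediate artifact (TSV/JSON) next to the final
``report.json``.  Runs are deterministic given the seed; the report embeds
a hash of the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .contacts import (
    contact_profile,
    reference_rbp,
    stationary_phase_limit,
    stationary_phase_summary,
)
from .descriptors import compound_descriptors
from .errors import ConfigError, RplcPoreError, UndefinedAverageError
from .hbonds import (
    HBondCriteria,
    detect_hbonds_ensemble,
    hbond_profile,
    hbond_summary,
    partner_density,
)
from .model import RegionSpec, read_frames, read_topology, write_frames, write_topology
from .orientation import orientation_profile, preferred_orientation
from .profiles import decompose_peaks, density_profile, find_peak_boundary
from .synth import ANALYTE_TEMPLATES, GeneratorConfig, generate_slitpore


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    compound: str = "phenol"
    os_type: str = "MeOH"
    vol_pct: float = 50.0
    seed: int = 0
    out_dir: str = "rplcpore_run"
    n_frames: int = 60
    frames_path: Optional[str] = None  # load instead of generate
    topology_path: Optional[str] = None
    hb_bulk: Optional[float] = None  # bulk-liquid HB reference; derived if None
    window_ns: float = 24.0  # contact observation window (scaled-down default)
    regions: RegionSpec = field(default_factory=RegionSpec)
    generator_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.vol_pct <= 100.0:
            raise ConfigError(f"vol_pct must be in [0, 100], got {self.vol_pct}")
        if self.os_type not in ("MeOH", "ACN"):
            raise ConfigError(f"os_type must be MeOH or ACN, got {self.os_type!r}")
        if self.compound not in ANALYTE_TEMPLATES:
            raise ConfigError(f"unknown compound {self.compound!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = {
            "z_bp_end": self.regions.z_bp_end,
            "z_bulk_start": self.regions.z_bulk_start,
            "bin_width": self.regions.bin_width,
        }
        d["generator_overrides"] = {k: repr(v) for k, v in self.generator_overrides.items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_generator_config(run: RunConfig) -> GeneratorConfig:
    """Scaled-down generator settings for a pipeline run."""
    kwargs = dict(
        seed=run.seed,
        n_frames=run.n_frames,
        compound=run.compound,
        os_type=run.os_type,
        n_bp_per_surface=300,
        n_water=2000,
        n_os=1000,
    )
    kwargs.update(run.generator_overrides)
    return GeneratorConfig(**kwargs)


@dataclass
class RunReport:
    """Machine-readable result bundle of one pipeline run."""

    config: RunConfig
    stationary_phase: dict
    peak_decomposition: dict
    hbonds: Optional[dict]
    orientation: Optional[dict]
    descriptors: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "stationary_phase": self.stationary_phase,
            "peak_decomposition": self.peak_decomposition,
            "hbonds": self.hbonds,
            "orientation": self.orientation,
            "descriptors": self.descriptors,
            "provenance": self.provenance,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _stage(name: str, artifact: Path):
    """Context-style error wrapper that names the failing stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, RplcPoreError):
                raise type(exc)(f"stage {name!r} (artifact {artifact}): {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(run: RunConfig) -> RunReport:
    """Execute the full analysis chain and write all artifacts."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = run.regions

    if run.frames_path is not None:
        if run.topology_path is None:
            raise ConfigError("frames_path given without topology_path")
        topology = read_topology(run.topology_path)
        frames = read_frames(run.frames_path, topology)
        truth = None
    else:
        gen = default_generator_config(run)
        frames, topology, truth = generate_slitpore(gen)
        write_frames(frames, out / "frames.xyz")
        write_topology(topology, out / "topology.tsv")

    with _stage("profiles", out / "analyte_density.tsv"):
        analyte_rho = density_profile(frames, topology, compound=run.compound, site="com", regions=regions)
        analyte_rho.write_tsv(out / "analyte_density.tsv")
        water_rho = density_profile(frames, topology, role="water", site="OW", regions=regions, label="W")
        water_rho.write_tsv(out / "water_density.tsv")

    with _stage("contacts", out / "contact_profile.tsv"):
        r_bp = reference_rbp(run.compound, run.os_type)
        times = [f.time for f in frames]
        dt = (times[1] - times[0]) if len(times) > 1 else run.window_ns
        span = max(times) - min(times) + dt
        # tile the span exactly so no trailing frames are dropped and the
        # contact and density profiles see the same ensemble
        n_windows = max(1, int(span // run.window_ns))
        window_ns = span / n_windows + 1e-9
        cprof = contact_profile(
            frames, r_bp, topology, regions=regions, window_ns=window_ns, compound=run.compound
        )
        cprof.write_tsv(out / "contact_profile.tsv")
        z_sp = stationary_phase_limit(cprof)
        regions.z_sp = z_sp
        sp = stationary_phase_summary(cprof, analyte_rho, z_sp)
        sp_dict = sp.to_dict() | {"r_bp": r_bp.r_bp, "r_bp_provenance": r_bp.provenance}
        (out / "stationary_phase.json").write_text(json.dumps(sp_dict, indent=2, sort_keys=True))

    with _stage("peak_decomposition", out / "peaks.json"):
        decomp = decompose_peaks(analyte_rho, regions)
        decomp_dict = {
            "boundary_z": decomp.boundary_z,
            "surface_peak_z_max": decomp.surface_peak_z_max,
            "z_sp": decomp.z_sp,
            "fraction_surface": decomp.fractions[0],
            "fraction_partitioning": decomp.fractions[1],
            "fraction_adsorption": decomp.fractions[2],
            "partitioning_fraction_two_way": decomp.partitioning_fraction_two_way,
        }
        (out / "peaks.json").write_text(json.dumps(decomp_dict, indent=2, sort_keys=True))

    template = ANALYTE_TEMPLATES[run.compound]
    hb_dict = None
    if template.n_sites > 0:
        with _stage("hbonds", out / "hbond_table.tsv"):
            criteria = HBondCriteria()
            table = detect_hbonds_ensemble(frames, topology, criteria)
            table.to_csv(out / "hbond_table.tsv", sep="\t", index=False, float_format="%.6f")
            hprof = hbond_profile(table, analyte_rho, regions)
            hb_bulk = run.hb_bulk
            if hb_bulk is None and truth is not None:
                # expected bulk engagement of the synthetic model
                hb_bulk = float(truth.expected_hb_per_molecule(np.array([regions.z_bulk_start + 1.0]))[0])
            if hb_bulk is None:
                raise ConfigError("hb_bulk required when analysing imported trajectories")
            try:
                summ = hbond_summary(hprof, analyte_rho, z_sp, hb_bulk, table, regions)
                hb_dict = dataclasses.asdict(summ)
            except UndefinedAverageError:
                hb_dict = {"hb_sp": None, "note": "no hydrogen bonds in the stationary phase"}
            pdens = partner_density(
                table, decomp.boundary_z, z_sp, frames[0].box, len(frames), regions
            )
            hb_dict["n_excluded_rows"] = pdens.n_excluded
            hb_dict["partner_share"] = {f"{p}/{s}": v for (p, s), v in pdens.species_share.items()}
            (out / "hbond_summary.json").write_text(json.dumps(hb_dict, indent=2, sort_keys=True))

    orient_dict = None
    if template.vector_tail is not None:
        with _stage("orientation", out / "orientation.tsv"):
            oprof = orientation_profile(frames, topology, compound=run.compound, regions=regions)
            oprof.to_frame().to_csv(out / "orientation.tsv", sep="\t", index=False, float_format="%.6f")
            boundary = decomp.boundary_z
            orient_dict = {}
            for label, interval in (
                ("partitioning", (0.0, boundary)),
                ("adsorption", (boundary, z_sp)),
            ):
                try:
                    pref = preferred_orientation(oprof, analyte_rho, interval)
                    orient_dict[label] = {
                        "mean_cos_phi": pref.mean_cos,
                        "interpretation": pref.interpretation,
                    }
                except UndefinedAverageError:
                    orient_dict[label] = None

    desc = compound_descriptors(run.compound).to_dict()
    report = RunReport(
        config=run,
        stationary_phase=sp_dict,
        peak_decomposition=decomp_dict,
        hbonds=hb_dict,
        orientation=orient_dict,
        descriptors=desc,
        provenance={
            "config_hash": run.config_hash(),
            "seed": run.seed,
            "version": __version__,
            "n_frames": len(frames),
        },
    )
    report.write(out / "report.json")
    return report
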