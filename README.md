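# rplcpore

Trajectory analysis for solvated reversed-phase liquid chromatography
(RPLC) interfaces in slit-pore geometry.

## The problem

In RPLC, small neutral analytes are separated on a hydrophobic C18
("bonded phase") layer grafted to silica, eluted with a water–organic
solvent (W–OS) mobile phase.  Molecular simulation of a silica/C18 slit
pore resolves *where* analyte molecules reside relative to the surface
and *why* retention differs between compounds.  This package implements
the analysis layer of that workflow for people who run (or emulate) such
simulations:

- **Density profiles** ρ(z) of any species versus distance z from the
  silica surface (0.05 nm bins, both pore halves folded and pooled).
- **Bonded-phase contacts**: the number of bonded-phase united-atom
  sites within a compound-specific radius r_BP of an analyte's centre of
  mass (boundary inclusive, r ≤ r_BP), the contact profile C_BP(z), the
  stationary-phase limit z_SP (where a molecule averages fewer than one
  contact per observation window), and the density-weighted retention
  statistics ⟨C_BP⟩_SP and ⟨z⟩_SP.
- **Hydrogen bonds** by a pure distance criterion r ≤ r_HB, including π
  hydrogen bonds to aromatic ring centres (W 0.30 nm, MeOH 0.32 nm),
  per-z bond profiles, the bulk-recovery fraction, water-partner
  contributions and partner-density profiles conditioned on the analyte
  peak (partitioning vs adsorption).
- **Orientation**: cos φ of a compound-specific molecular vector against
  the surface normal, with density-weighted preferred orientations.
- **Solute descriptors**: group-contribution van der Waals volumes
  (V = Σ atoms − 5.92·N_B − 14.7·R_A − 3.8·R_NR), hydrophobic CH_x
  counts, and the retention arithmetic k = t_r/t_0 − 1 and
  α = k₂/k₁ ≥ 1.

Because no public trajectories exist for this system, the package ships
a **synthetic slit-pore generator** (`rplcpore.synth`) that draws frame
ensembles from a fully specified statistical model of the interface —
bonded-phase bead density near the surface, sigmoidal water onset, an
organic-solvent "ditch", a three-component analyte mixture (surface /
partitioning / adsorption peaks), planted hydrogen-bond partners and a
z-dependent orientation law — and records every draw it makes, so each
estimator can be validated against exact ground truth.

## Worked example

```python
from rplcpore import RunConfig, run_pipeline

report = run_pipeline(RunConfig(compound="phenol", seed=7, n_frames=30,
                                out_dir="phenol_run"))
print(report.stationary_phase)
print(report.orientation)
```

prints (seed 7):

```
{'z_sp': 1.447, 'mean_contacts': 1.405, 'mean_position': 1.172,
 'sd_contacts': 1.090, 'r_bp': 0.79, 'r_bp_provenance': 'reference-table'}
{'partitioning': {'mean_cos_phi': -0.180, 'interpretation': 'surface-oriented'},
 'adsorption': {'mean_cos_phi': 0.332, 'interpretation': 'bulk-oriented'}}
```

Reading: the stationary phase of this synthetic phenol run extends to
z_SP ≈ 1.45 nm; a phenol molecule there averages 1.4 bonded-phase
contacts at a mean distance of 1.17 nm from the surface.  Molecules in
the partitioning peak point their OH group at the silica surface,
molecules in the adsorption peak point it at the bulk liquid — the
hydrogen-bonding geometry expected at a poorly solvated hydrophobic
layer.  All intermediate artifacts (density/contact/orientation TSVs,
hydrogen-bond table, JSON summaries) are written to `phenol_run/`.

The same stages are available on the command line:

```sh
rplcpore run --compound phenol --seed 7 --out phenol_run
rplcpore descriptors --compound benzene
```

## Acceptance script

`scripts/acceptance.py` rebuilds the molecular graphs of the six analyte
compounds (benzene, ethylbenzene, naphthalene, acetophenone, benzyl
alcohol, phenol) and recomputes their group-contribution van der Waals
volumes and hydrophobic CH_x counts from scratch:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/rplcpore/
  model.py        frames, topology, regions, extended-XYZ + TSV I/O
  synth.py        synthetic slit-pore / bulk-box generator + ground truth
  profiles.py     density profiles, peak decomposition
  contacts.py     contact counting, z_SP, ⟨C_BP⟩_SP, RDF-derived r_BP
  hbonds.py       distance-criterion H-bond detection and statistics
  orientation.py  cos φ profiles and preferred orientations
  descriptors.py  molecular-graph descriptors, k and α arithmetic
  pipeline.py     end-to-end orchestration with a JSON run report
  cli.py          click CLI (generate/profile/contacts/hbonds/orient/…)
```

See `docs/methods.md` for the underlying models, conventions, parameter
defaults and known limitations.
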