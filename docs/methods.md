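# Methods

This note records the models, conventions and numerical choices behind
rplcpore, in the order the pipeline applies them.

## Geometry and conventions

The system is a slit pore: a silica slab with two equivalent surfaces,
C18 chains, trimethylsilane endcaps and residual silanols grafted on
both, solvent and analytes in between.  Coordinates are nm throughout.
The box is periodic in x and y only (minimum-image convention in those
two dimensions); z is interrupted by the slab.  Bulk boxes (used for the
neat-water hydrogen-bond reference) are periodic in all three
dimensions; routines pick the right convention from the frame's
`surface_planes` field (absent = bulk).

All profiles use the distance z from the *nearest* silica surface plane.
The two pore halves are statistically equivalent, so they are folded
onto one z axis and pooled, which doubles the statistics; per-bin
volumes carry a factor of two (`n_surfaces = 2`).  How a two-surface
model maps onto a one-surface analysis axis is a convention choice, not
something the physics dictates; folding + pooling is ours.  Bins start
at z = 0 at the surface plane, default width 0.05 nm, values reported at
bin centres.

Distances (contacts, hydrogen bonds) are always evaluated in the
laboratory frame; folding only assigns bin labels.  Folding coordinates
first and then measuring distances would spuriously bring the two
surfaces' environments together.

Region defaults: bonded-phase region z ≤ 1.05 nm, bulk liquid
z > 2.55 nm.  The stationary-phase limit z_SP is *computed* (below), not
assumed.

## Synthetic ensembles

The generator draws independent frames from a stated statistical model;
it is a sampling device, not dynamics.  Time stamps (`frame_dt`,
default 0.4 ns) exist so that window-based estimators can be exercised;
nothing moves between frames.  What it emulates and what it does not:

- **Bonded phase**: single united-atom beads drawn from a truncated
  Gaussian mixture concentrated at z ≲ 1.05 nm.  No chain connectivity,
  no conformational response to the solvent — contact statistics only.
- **Water**: a sigmoidal rise to a bulk plateau (default amplitude
  9.2 atoms nm⁻³, the literature interfacial water density at the
  50 vol % MeOH reference point).  **Organic solvent**: sigmoid plateau
  (6.8 atoms nm⁻³) plus a Gaussian "ditch" maximum in the interfacial
  region (centre 1.45 nm).  Background solvent is represented by its
  heavy key atom only (O of W/MeOH, N of ACN).
- **Analytes**: rigid planar templates (aromatic ring, optional
  substituent, donor/acceptor sites) with the ring centre at a z drawn
  from a three-component truncated-Gaussian mixture — surface peak
  (0.5 nm), partitioning peak (0.8 nm), adsorption peak (1.6 nm),
  default weights 0.03/0.07/0.90 (a polar, adsorption-dominated analyte;
  published adsorption contributions for polar analytes are ~90 %).
  x,y uniform; pore side fair-coin.  No intramolecular flexibility.
- **Hydrogen bonds are planted, not emergent.**  With probability
  `hb_engage_prob(z)` per site, a partner molecule is placed so the
  distance criterion is met with margin uniform in (0, r_HB]; partner
  species is W with probability `w_share(z)`, otherwise the configured
  organic solvent (falling back to W for sites acetonitrile cannot
  donate to).  Placements are rejected and redrawn if they would satisfy
  a criterion with any *unintended* site; all other solvent keeps an
  exclusion distance from solute sites; analyte molecules keep 0.75 nm
  between their hydrogen-bond sites (only x,y are redrawn for this, so
  the configured z marginal is exact).  Consequently the detector's
  expected count *equals* the configured engagement probability — a
  green recovery test certifies the estimator chain, and deliberately
  says nothing about real solvent structure.
- **Orientation**: cos φ is drawn from a linear-in-cos-φ density
  truncated at zero, parameterised by its mean (attainable range
  |mean| < 2/3); the mean is a function of z, by default −0.3 in the
  bonded-phase region, +0.4 in the adsorption region, 0 beyond
  (functional group toward the surface when partitioned, toward the bulk
  when adsorbed).

Every draw (component labels, com z, engagement flags, partner species,
cos φ) is recorded in the returned `GroundTruth`, which is the oracle
for the recovery tests.  Scaled-down bead/solvent counts are the test
default; the box (12.14 × 13.20 × 10.93 nm, 10 nm pore) and the 10
analyte molecules per box follow the published system.

## Contacts and the stationary-phase limit

A contact is a bonded-phase united-atom site within r ≤ r_BP of the
analyte com — boundary inclusive.  Endcap and residual-silanol sites are
excluded by default ("bonded-phase groups"); a flag pulls endcaps in
since their status is genuinely ambiguous.  Published r_BP values for
the six analytes × two solvents ship as a provenance-tagged reference
table; `derive_rbp` reproduces the construction (first minimum after the
first maximum of the 3-bin-smoothed, averaged analyte-com/bead RDF,
rounded to 0.01 nm) for novel systems.  RDF normalisation in a strongly
inhomogeneous slab is not well defined; we normalise by the mean bead
density in the bonded-phase region and rely only on the minimum's
*location*.

C_BP(z): per-bin mean of the per-molecule contact count, formed within
non-overlapping observation windows (default 40 ns, assigned by
timestamp, partial trailing window dropped) and then averaged across
windows.  The average runs over both molecules and windows.

z_SP: scanning outward, the crossing of C_BP(z) through 1 after the last
bin with C_BP ≥ 1 such that every non-missing bin beyond stays < 1.  The
crossing is interpolated linearly between the bracketing bin centres;
if the outer bracketing bin is exactly zero the crossing is degenerate
and z_SP is the shared bin edge.  Plateaus at exactly 1.0 resolve
outward (conservative: larger stationary phase).

⟨C_BP⟩_SP and ⟨z⟩_SP are analyte-density-weighted averages over bins
with centre ≤ z_SP.  Bins carrying density but no contact statistics
raise instead of skewing the average; the pipeline therefore sizes its
windows to tile the frame span exactly so both estimators see the same
ensemble.

## Peak decomposition

The analyte density at z ≤ z_SP is split empirically (no Gaussian
deconvolution) at the inter-peak minimum of the 3-bin-smoothed profile,
searched in (z_bp_end − 0.15, z_bp_end + 0.25); if no interior local
minimum exists the region border (1.05 nm) is the fallback.  Three
shares are reported — silica-surface peak (z ≤ 0.55 nm, from the
published phenol surface peak at 0.5 nm), partitioning, adsorption —
normalised to the total stationary-phase density (so the denominator
includes the surface peak; the alternative of excluding it is a
documented configuration away).  For the conventional two-way split the
surface share is folded into partitioning.

## Hydrogen bonds

A pure distance criterion r ≤ r_HB, no angle term — deliberately
simpler than common geometric definitions.  π bonds use the ring-carbon
centre of mass with published cutoffs (W-H 0.30 nm, MeOH-H 0.32 nm; two
ring centres for naphthalene, each tested).  The site–site cutoffs
(default 0.245 nm solute-O–H_W/H_MeOH and solute-H–O_W/O_MeOH,
0.255 nm solute-H–N_ACN) are package defaults, *not* validated against
any published per-pair table, and are user-replaceable.  One row per
satisfying (site, partner) pair: a site can bind several partners, so
per-molecule bond numbers may exceed one; a partner bound to two sites
contributes two rows and its key atom is counted once per row.

hb_SP uses the same density-weighting rule as ⟨C_BP⟩_SP; the recovery
fraction divides by a bulk-liquid reference (supplied, or taken from the
generator's own bulk engagement when analysing synthetic data).  Partner
densities bin the partner key atom by *its own* z while conditioning on
the peak containing the *analyte's* com; rows with the analyte beyond
z_SP are excluded and tallied.  The default integration window
1.5–2.25 nm is where the bulk of adsorption-peak partners reside.
Where a published table lists two values per OH-bearing analyte, they
are stored split by *solvent role* (donor vs acceptor solvents), per the
table's footnotes.

## Orientation

cos φ = (unit molecular vector) · (unit surface normal pointing into the
pore); the normal flips sign for molecules in the upper pore half, so
cos φ < 0 always means "functional group toward silica".  Default
vectors run from the para ring carbon to the substituent terminus
(phenol/benzyl alcohol: O; acetophenone: carbonyl O; ethylbenzene:
CH3) — the exact endpoint atoms are package conventions, overridable in
the topology.  Benzene and naphthalene carry no vector and are skipped
(nothing to orient).  Histograms use 0.05 nm × 0.1 (cos φ) bins; mean
orientations are computed from exact per-bin accumulators rather than
bin centres, so extreme orientations are representable and mirror
symmetry is exact.

## Descriptors

Molecular graphs use heavy atoms with implicit hydrogens; bond counts
include C–H bonds and rings enter through an Euler-relation-checked
census.  Atom contributions (C 20.58, H 7.24, O 14.71, N 15.60 Å³),
5.92 Å³ per bond, 14.7 Å³ per aromatic and 3.8 Å³ per nonaromatic ring.
The six-analyte volumes are reproduced to ±0.02 Å³ (rounding of the
published contributions).  N(CH_x) counts every carbon (CH_0 included:
aromatic junctions, carbonyl C) unless it is bonded exclusively to
heteroatoms and bears no hydrogen; this is the minimal rule consistent
with all six published counts, and the carbonyl carbon's inclusion is
the calibration it pins down.  k = t_r/t_0 − 1 (negative k returns with
a warning); α is ordered so α ≥ 1.

## Numerical choices

- Neighbour searches: scipy cKDTree with a toroidal box; the
  non-periodic z dimension uses an effectively infinite box length.
  Cutoff queries add a 1e-12 relative margin and then filter exactly, so
  boundary cases at r = cutoff are inclusive without float surprises.
- Molecule centres are unweighted site means (united-atom sites carry no
  masses in the interchange format), minimum-image-anchored so molecules
  straddling the x/y boundary fold correctly.
- Empty selections, all-zero profiles, missing criteria, zero-weight
  averages and geometry mismatches raise typed exceptions
  (`rplcpore.errors`) rather than returning silent zeros.
- Determinism: one `numpy.random.Generator` seeded from the config;
  identical configs give byte-identical trajectories.

## Limitations

- Frames are i.i.d.: nothing kinetic (residence times, diffusivity,
  window-to-window correlation) can be studied on synthetic data.
- Planted hydrogen bonds mean solvent–solvent structure, cooperative
  effects and accidental close approaches are absent by construction.
- The published trajectory-derived numbers (⟨C_BP⟩_SP curves, r_BP
  values, neat-water hydrogen-bond requirements, adsorption
  contributions) required a cluster-scale MD campaign; they ship here
  only as provenance-tagged reference tables and are never claimed as
  recomputed results.
- The default site–site hydrogen-bond cutoffs are plausible but
  unvalidated placeholders.
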