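# Methods

This note records the models, conventions, and design choices behind
`ligandpath`, and what the synthetic test systems do and do not establish
about real data.

## Coordinate and selection conventions

All coordinates are Angstrom; residue numbering is 1-based PDB numbering
and is never rewritten on read.  All distance-cutoff comparisons are
inclusive (`d <= cutoff`) so that planted-count tests are exact.  No
periodic-boundary handling is performed anywhere: trajectories are assumed
imaged and whole, which holds for a solvated receptor whose ligand path
never wraps; documenting the assumption was preferred over silently
re-imaging.  Heavy atoms are all atoms whose element is not hydrogen;
elements missing from the file are inferred from PDB atom-name
conventions.  Waters are residues named HOH/WAT/TIP3 (configurable via
structure metadata).

## Site mapping and distance tracking

The binding-site point is the center of mass of a reference ligand (e.g. a
ligand resolved in a homolog structure) carried into the target frame by
Kabsch superposition of user-paired C-alpha anchors.  Automatic structural
pairing was deliberately left out: a user-supplied residue pairing keeps
the mapping deterministic and testable, at the cost of requiring the
pairing as input.  Centers of mass are mass-weighted by default (standard
atomic masses), with an unweighted `geometric` option, since conventions
differ between analysis tools.

With `align_each_frame`, each frame's receptor selection is superposed
onto the first frame before measuring, so a site point expressed in
first-frame coordinates stays valid under global drift or rotation; the
superposition is the same SVD Kabsch solver with the reflection branch
corrected (`det R = +1`).

## State segmentation and event counting

Two segmentation methods serve the two distinct uses of the distance
curve:

* **changepoint** (default for describing a prototypical binding
  trajectory): least-squares piecewise-constant fit with `n_states − 1`
  breakpoints found by binary segmentation; segments are named by
  mean-distance rank, outermost first.  Binary segmentation is implemented
  in-package (cumulative-sum gains, exact on plateau data).
* **threshold** (default for event counting): frames are labeled by the
  innermost undercut threshold and runs shorter than `min_dwell` are
  absorbed into their predecessor (hysteresis).

Default thresholds are `d_contact=25`, `d_entry=15`, `d_vestibule=9`,
`d_binding=4` Å with `min_dwell=5` frames.  No numeric state boundaries
exist in the field for this readout — curves are traditionally divided by
eye — so the defaults are calibrated to the synthetic receptor family
(planted plateaus at 40/25/15/8/2 Å) and are explicit configuration for
real systems.  Entry/binding events require the distance to stay below the
state threshold for `min_dwell` consecutive frames, which makes event
detection monotone in the thresholds and immune to single-frame noise
spikes.

Representative frames per state are chosen by k-means (k = 4, k-means++
initialization, 10 restarts, fixed seed) on either the flattened ligand
coordinates or the ligand–residue contact fingerprint — both offered
because field practice varies — with the representative being the frame
nearest the centroid of the most populated cluster (medoid rule), ties
broken toward the lowest frame index for determinism.

## Contacts

A residue is in contact when at least one heavy atom lies within 4.0 Å of
a ligand heavy atom.  This transparent single-distance criterion stands in
for interaction-type-specific rules (hydrogen bond, pi-stacking
geometries) used by some tools; the cutoff is configurable.  The
per-trajectory frequency denominator defaults to the frames after the
first receptor contact, because ingress frequencies would otherwise be
diluted arbitrarily by the length of the preceding bulk-diffusion stretch;
a whole-trajectory or explicit window is available.  Cohort averaging is
the unweighted mean over entry trajectories, on the outer join of residue
universes with zero fill.

## Solvation

The first shell counts distinct water residues with any atom within 3.0 Å
of any ligand heavy atom (the shell cutoff is a knob; 3.0 Å follows the
usual first-shell convention for heavy-atom distances).  Normalization
divides by the mean shell count of a bulk source — either a dedicated
ligand-in-water box or the pre-contact frames of the trajectory itself —
and the resulting fraction is not clipped: values slightly above 1 are
real fluctuations of a count ratio.

## Pocket detection

fpocket-style alpha-sphere methods were replaced by a deterministic grid
method that can be validated against analytic cavity volumes: a grid point
is *empty* if farther than `vdW + probe` (probe 1.4 Å) from every atom,
*buried* if at least 9 of 14 fixed rays (6 axial + 8 diagonal — cheap
isotropy) hit protein within 12 Å, and pockets are 26-connected components
of ≥ 30 buried empty points at 1.0 Å spacing.  Volume is
`n_points × spacing³`.  On the planted 5 Å spherical cavity this lands
within a few percent of 4/3·π·5³ = 523.6 Å³ and is stable to < 5% under
rigid rotation.  The "pocket of interest" — historically chosen by visual
inspection — is selected automatically as the pocket nearest a guide point
(e.g. the mapped reference-ligand site), falling back to largest.

Pocket polarity is the mean lining-residue value under a residue scale.
The default is Kyte–Doolittle hydropathy sign-flipped so that *higher =
more polar*; Wimley–White interface free energies are bundled as an
alternative because literature citations of "hydrophobicity scale" are
frequently ambiguous.  Lining residues are those with a heavy atom within
4.5 Å of any pocket grid point; an explicit residue list can override
this when a study defines its pocket by enumeration.

## Complementarity

Published complementarity scorers for this task are proprietary, so the
scores here are first-principles correlates defined for sign and ordering
behavior, not absolute-value compatibility:

* the ligand surface is sampled with deterministic Fibonacci lattices on
  probe-expanded atom spheres (1 point/Å², buried points removed);
* the molecular hydrophobicity potential is `Σ f_i · exp(−d/λ)` with decay
  λ = 2.0 Å and a bundled element-level constant table (aromatic C >
  aliphatic C > S > halogens > N > O; charged N/O most hydrophilic;
  per-atom overrides accepted) — hydrophobic match is the Pearson
  correlation of ligand- vs environment-sourced MHP over the surface;
* electrostatic complementarity is minus the Pearson correlation of the
  two Coulomb potentials `Σ q/d` (a constant dielectric folds out of a
  correlation); charges are input data (PQR), no charge assignment is
  implemented.

Both scores are exactly invariant under rigid motion when the surface is
transported with the complex; re-sampling the lattice in a rotated frame
perturbs them only at the quadrature level (~1e-4 at default density).
The 180°-flip utility rotates a pose about a chosen axis through its
center of mass for "reverted"-pose comparisons.

## Conservation

Pairwise pocket identity is `matches/compared × 100` over designated
alignment columns; similarity uses configurable physicochemical groups
(default {AVLIMC}, {FWY}, {ST}, {KRH}, {DE}, {NQ}, {G}, {P}), with
identical residues counting as within-group, so identity ≤ similarity
always.  Columns gapped in either sequence are excluded from the
denominator (pocket positions are structurally defined and rarely gapped).
Because "similarity" has no universal convention, the grouping is recorded
with the output and planted tests use whatever grouping is configured.
Logo matrices give per-column probabilities or `p · (log2 20 − H)` bits.

## The synthetic-data generator

The generator emulates the study conditions, not the physics:

* **Receptor**: a closed shell of single-carbon pseudo-residues around a
  spherical cavity.  A dense Fibonacci wall layer at
  `cavity_radius + 3.1 Å` makes the probe-accessible empty region a crisp
  sphere; the remaining residues fill the shell body at 0.125 atoms/Å³
  (enough that spurious interstitial voids are vanishingly rare and in any
  case below the 30-point pocket threshold).  A 3 Å-radius cylinder along
  the channel axis is kept free of atoms.
* **Trajectories**: the rigid all-carbon ligand's center of mass is placed
  on the channel axis at `planted_distance[state] + N(0, noise_sd)`;
  default plateaus 40/25/15/8/2 Å and noise 0.3–0.5 Å.  Ligand atom
  density is molecule-like (scale ∝ n^{1/3}), so a 30-atom ligand has a
  drug-sized first shell.
* **Waters** are single-particle oxygens (hydrogens add nothing to a
  distance count at this scale) at bulk density 0.0334 /Å³.  Per frame,
  exactly `round(plan[state] · B)` waters are planted inside the first
  shell — `B` being the density-expected bulk shell count — with the
  default plan 1.0/0.8/0.5/0.5/0.2 along bulk→binding, reproducing the
  staged-desolvation profile (~50% at entry/vestibule, ~20% bound);
  remaining waters are background kept off the shell.
* **Cohorts** plant exact entry/binding counts by truncating schedules;
  dwell lengths are jittered ±25%.
* **Ground truth** for contacts and shell counts is recomputed from the
  emitted coordinates by a direct numpy distance pass, independent of the
  k-d-tree analysis path, so analyses are tested against geometry rather
  than sampling intent.  All generators are deterministic under a fixed
  seed.
* **Alignments** realize planted pairwise identity/similarity
  *constructively* (exact column counts, same-group substitutions drawn
  from multi-member groups), so percentage recovery tests are exact, not
  statistical.
* **Complementarity cases** are two-atom dipole ligands inside 8-atom
  rings of matched or conjugated charge/hydrophobicity, with the score
  sign known from the construction.

What passing these tests does **not** show: real trajectories have
flexible ligands and receptors, anisotropic diffusion, waters with
structure and residence times, contact criteria confounded by hydrogens
and interaction geometry, and cavities that breathe.  The synthetic suite
validates the *measurement machinery* — that distances, counts, volumes,
correlations, and percentages are computed correctly — not the biology.

## Problem sizes and numerical choices

Synthetic receptors use 900 single-atom residues (553 wall + 347 body),
trajectories 150–250 frames, cohorts up to 88 trajectories, grids at
1.0 Å spacing — sizes chosen so the full suite and the acceptance script
each run in well under a minute-scale budget on one core while keeping
every statistic at its intended granularity.  Ties are broken
deterministically throughout (alphabetical consensus, lowest frame index,
mergesort in pose ranking).  Degenerate inputs raise rather than guess:
collinear Kabsch anchors, zero-variance complementarity fields, empty
selections, all-gap columns (flagged, never dropped silently).

## Known limitations

* DCD input requires MDAnalysis; only multi-model PDB is parsed natively.
* The threshold defaults encode the synthetic geometry; real receptors
  need their own calibration, and the changepoint method should be
  preferred when no thresholds are defensible.
* Complementarity scores are correlates suitable for ranking poses within
  one system; absolute values are not comparable across scorers.
* Contact typing (hydrogen bond vs pi-stacking vs van der Waals) is out of
  scope; the single-distance criterion cannot distinguish them.
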