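# Methods

## Model

A trimerbody is represented as a coarse-grained bead assembly with three
kinds of parts:

* a **rigid trimerization core** with three chains, three N-terminal anchor
  points (where the payload-side linkers attach) and three C-terminal anchor
  points (where the tandem format's extra linkers originate);
* three **rigid payload domains** (the antigen-binding VHH role), each with
  an N-terminal and a C-terminal attachment anchor;
* **flexible linkers** modelled as freely jointed chains (FJC): fixed virtual
  bond b = 3.8 Å between consecutive Cα-like beads, step directions uniform
  on the sphere, no angular potential. Glycine-serine linkers are maximally
  flexible, so the FJC is the natural null model; its RMS end-to-end distance
  is b√n and an n-residue linker can never extend past its contour length.

In the constructs being modelled each payload *precedes* its trimerization
domain in sequence (VHH–linker–TIE), so the primary linker runs from the
payload's C-terminal anchor to the core's N-terminal anchor. In the tandem
(single-chain) format, modules k = 1, 2 are additionally joined to module
k+1 by an extra linker from core C-anchor k to the N-terminal anchor of
payload k+1. Internal and C-terminal payloads are therefore doubly tethered:
position *and* orientation are restricted, because their two anchors sit on
opposite sides of the domain.

## Configuration sampling

Configurations are drawn by rejection. For each arm in order (N-terminal,
internal, C-terminal):

1. the primary linker grows step by step from the core N-anchor; the first
   bead sits one bond from the anchor;
2. the payload is posed rigidly: orientation uniform on SO(3) via unit
   quaternions, C-terminal anchor translated onto the linker end;
3. (tandem arms 2 and 3) the posed N-terminal anchor must lie within the
   extra tether's contour length, (n_t + 1)·b, of the donor C-anchor —
   otherwise the pose is rejected — and a bridging tether is then grown
   between the two points (below);
4. any steric clash rejects the attempt: two beads clash when their center
   distance is below `clash_scale` × (sum of radii), with `clash_scale` =
   0.9. Beads adjacent in a chain are exempt, as are payload beads within
   two bonds of a junction anchor against that junction's own linker — where
   a chain enters a domain, contact with the terminal residues is chain
   connectivity, not sterics. Without this exemption essentially every
   bridged tether is rejected, because the approach corridor to an anchor on
   the payload surface is always brushed by surface beads.

Acceptance is whole-configuration by default (any failure discards all
arms); the pipeline enables per-arm retry instead, which resamples only the
failed arm up to a budget. Both explore the same sterically allowed support;
per-arm retry changes the sampling density across arms but makes
150-configuration tandem ensembles tractable (the double-tether acceptance
is low). Ensembles are pure functions of (architecture, seed, parameters).

### Bridged tether growth

A tandem extra tether has both endpoints fixed. Growing it with unconditioned
uniform steps and rejecting misses is exact but hopeless in practice: at the
donor–payload separations this geometry produces (30–55 Å for a 17-mer whose
RMS end-to-end distance is only 15.7 Å), the probability that a free chain
ends within one bond of the target is ~1e-4 or less. The tether is instead
grown as a *conditioned* chain: each step direction is drawn uniformly over
the spherical cap of directions from which the target remains reachable
within the remaining contour length, and the final step from the cap that
lands the last bead within one bond of the target. The support is identical
to the naive rule — every fixed-bond chain whose partial chains can all still
reach the target — but the density over that support is biased toward
extended (taut) chains relative to the true end-conditioned FJC. The
consequence for the headline comparison is conservative: a density-faithful
tether would concentrate the doubly-tethered payloads even closer to their
donors, so the tandem-vs-multi-chain restriction measured here is a lower
bound on what stricter tether statistics would give. Candidate chains are
grown in vectorized batches and the first clash-free candidate is used.

## Superposition

Every configuration is aligned onto the architecture's core template frame
(not the first sample) by the Kabsch algorithm: SVD of the cross-covariance
of the corresponding core bead sets, with the reflection corrected to keep
the rotation proper (chirality preserved). Alignment is a rigid motion, so
no internal distance changes; per-configuration core RMSDs are recorded (they
are numerically zero here, since the sampler never moves the core, but the
operation is general and is exercised against scrambled inputs in the tests).

## Envelopes and their metrics

The aligned ensemble's payload beads are rasterized onto a boolean voxel
grid: a voxel is occupied when its center lies within (bead radius + probe
radius) of any bead. Defaults: spacing 2 Å, probe radius 1.4 Å (water-probe
convention), padding 10 Å; at the ~130 Å envelopes studied here that is
≤ ~80³ voxels. Within one comparison both architectures share a single
lattice — ratios across different grids are not meaningful.

* **Volume** = occupied voxels × spacing³.
* **Surface area** = area of the 0.5-level isosurface triangulated by
  marching cubes. Marching cubes applied directly to a binary field
  overestimates smooth areas by ~9% (measured on a voxelized ball), so the
  field is smoothed with a Gaussian of σ = 0.8 voxel before triangulation;
  this brings a radius-20 Å ball to within ~1% and a 40×40×20 Å box to within
  ~5% of their analytic areas, and converges under grid refinement. Counting
  exposed voxel faces instead would overestimate by ~1.5×.
* **Axes**: eigenvectors of the occupied-voxel-center covariance give the
  principal directions; each reported extent is the full span (max − min,
  plus one spacing) of the voxel centers along that direction, matching the
  "approximately 125 and 110 Å axes" semantics of reporting an envelope's
  dimensions. A covariance-ellipsoid fit was considered and rejected: span is
  what a figure caliper measures.
* **Per-domain areas**: one envelope per payload label (N/I/C) across all
  configurations — linkers and core excluded — plus the all-label merged
  envelope. The merged area can never exceed the sum of the individual areas
  (the union's boundary is a subset of the boundaries' union); the ratio
  merged/sum is reported as an overlap diagnostic.
* **Symmetry statistics**: areas of symmetry-equivalent domains (all three in
  the multi-chain format) are summarized as mean ± standard error
  (sample SD/√n).

## Synthetic templates

The synthetic-structure generators define the default study conditions so the
whole analysis runs without any structure download:

* **core**: three 10-bead chains (bead radius 2.5 Å), exactly C3-symmetric by
  construction (chains B and C are 120°/240° copies of chain A), N- and
  C-anchor circles of radius 8 Å separated axially by 25 Å, approximating a
  compact ~50-residue-per-chain trimerization domain. Anchors are recessed
  one bead radius from the terminal beads so a freshly grown linker bead is
  not automatically in steric conflict.
* **payload**: 200 beads (radius 2.5 Å) uniformly filling a ball of radius
  14 Å — an idealized Ig-domain-sized module; the N-anchor sits at the +z
  pole, the C-anchor antipodal. The true VHH dimensions assumed in the
  original modelling are not published; 14 Å is this package's documented
  choice, not a literature value.
* **linkers**: 7-residue primary linkers and 17-residue extra tethers (the
  lengths of the constructs being modelled), bead radius 1.0 Å. The thin
  linker bead reflects the glycine-serine backbone: it prevents linkers from
  threading through domains while leaving the virtual bond angles essentially
  unrestrained (a 1.9 Å bead would impose a ≥53° minimum virtual angle and
  silently rigidify the chains — and it rejects essentially all conditioned
  bridges).

What the synthetic data do *not* emulate: real Ig-fold shape and surface
ruggedness, the actual TIE-domain dimensions and terminus positions,
sequence-specific linker stiffness, and any energetics beyond hard sterics.
Passing tests on this geometry therefore validate the machinery and the
qualitative double-tether restriction, not the absolute areas or axis lengths
of any particular real construct.

## What a run reports, and the statistics of the comparison

A comparison run (150 accepted configurations per architecture, the study's
ensemble size) reports per-architecture envelope area, volume and axes,
per-domain areas with symmetry statistics, the tandem/multi-chain area ratio,
and per-arm ratios, together with acceptance rates, the seed, and a config
hash. Two relations are asserted at runtime because they hold by
construction: merged area ≤ sum of per-domain areas, and every
double-tethered payload anchor inside both of its contour balls. The area
ratio itself is *expected* below 1 — the tandem support is a subset of the
multi-chain support arm by arm — but it is not a theorem at finite ensemble
size: a 150-member union envelope has ~6% sampling noise per domain, and a
sparser ensemble can transiently produce a patchier, larger-area envelope.
On the default synthetic geometry the ratio comes out 0.92–0.96 across seeds
(restriction robust); the per-domain orderings (N-terminal largest, internal
≈ C-terminal) hold in the fixed study run asserted by the test suite but are
at noise scale on this geometry, so the acceptance script reports their
values rather than guaranteeing their sign for every seed.

## Degenerate inputs and numerical choices

* Zero-residue linkers are legal: the chain is empty and the attachment point
  is the anchor itself; a zero-residue tether pins the payload within one
  bond of its donor.
* Kabsch refuses point sets that are collinear or coincident (second singular
  value below 1e-9 of the first) and point sets of fewer than 3 points.
* Altloc handling on PDB input keeps the highest-occupancy conformer (ties:
  first encountered); HETATM records are ignored; only the first MODEL is
  read. Bead models round-trip through multi-model PDB to the format's 1e-3 Å
  coordinate precision.
* Occupancy grids store the voxel-center origin; CCP4/MRC export records the
  spacing in the unit cell and the origin in the MRC-2014 header words.
* The ensemble writer stashes each bead's radius in the B-factor column;
  labels map to residue names (ALA/GLY/ASN/ILE/CYS for
  core/linker/N/I/C-payload) so domains are selectable in molecular viewers.

## Known limitations

* The sampler explores sterically allowed space with documented density
  approximations; it is not a Boltzmann ensemble, and no statistical-weight
  (Rosenbluth) correction is applied.
* Whole-configuration vs per-arm acceptance give the same support but not the
  same density; per-arm retry (the pipeline default) slightly biases later
  arms toward placements compatible with earlier ones.
* Areas are isosurface areas of a probe-inflated occupancy field, not
  solvent-excluded molecular surfaces; absolute values depend on spacing and
  probe radius, which is why cross-architecture ratios are only computed on a
  shared lattice.
* Anchor points for PDB-derived templates are taken from chain termini
  (first/last Cα), which may differ from the exact fusion points of a real
  construct.
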