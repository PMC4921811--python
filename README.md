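# trimerbody

Conformational-envelope analysis and assembly stoichiometry for trimeric
antibody ("trimerbody") architectures.

## The problem

A trimerbody is an engineered trivalent antibody: three antigen-binding
domains (typically camelid VHH single domains, ~12–15 kDa) fused through
flexible glycine-serine linkers to the N-terminal trimerization region of
collagen XVIII (the TIE domain), which drives assembly into a trimer. Two
formats exist:

* **multi-chain** — three separate VHH–linker–TIE chains trimerize
  intermolecularly; all three binding domains are identical copies;
* **tandem (single-chain)** — three VHH–TIE modules are joined on one
  polypeptide by two extra linkers, enforcing intramolecular trimerization
  with a defined domain order (N-terminal, internal, C-terminal) and allowing
  three *different* specificities with fixed 1:1:1 stoichiometry.

Two questions about these formats are quantitative and purely geometric:

1. **How much space can each binding domain explore?** Each VHH is tethered
   to a rigid core by a flexible linker; the union of all positions it can
   reach — its *active surface* — determines what it can bind. In the tandem
   format the internal and C-terminal domains are *doubly tethered* (their
   own linker plus the extra linker from the preceding module), which
   restricts their reach.
2. **If instead you co-express three monospecific chains, what fraction of
   random trimers is trispecific?** Counting distinct trimer species of 3
   chain types, 1 of the 10 possible compositions carries all three
   specificities — 10% — which is the argument for building the tandem
   format rather than purifying a statistical mixture.

## The method

* **Linkers** are freely jointed chains of Cα-like beads: fixed virtual bond
  b = 3.8 Å, directions uniform on the sphere, so the RMS end-to-end distance
  is b√n and the reachable set of an n-residue linker is bounded by its
  contour length.
* **Configurations** are built by rejection sampling: linkers grow from the
  core's three N-terminal anchors, rigid payload domains are posed with
  uniformly random orientation at the linker ends, and any steric clash
  (center distance < 0.9 × sum of bead radii) discards the attempt. Tandem
  extra tethers must additionally bridge from the preceding module's
  C-terminus to the payload, which removes configurations.
* **Alignment**: every accepted configuration is superposed onto the core
  reference frame with the Kabsch algorithm (proper rotations only).
* **Envelopes**: the aligned ensemble's payload beads are merged on a boolean
  voxel grid (2 Å spacing, 1.4 Å probe); surface area comes from a
  marching-cubes triangulation, volume from voxel counting, and the envelope
  shape from the principal-axis extents of the occupied voxels. Per-domain
  envelopes decompose the total by payload label.
* **Stoichiometry**: exact enumeration of trimer compositions, either one
  count per distinct species (multiset-uniform) or multinomial random
  assembly at given chain abundances.

Both architectures are always sampled in one run, on identical geometry and
one shared voxel lattice, so the reported ratios are meaningful.

## Worked example

```python
from trimerbody import RunConfig, run_comparison

config = RunConfig()          # synthetic core + VHH-sized payloads,
config.seed = 1               # 7-mer linkers, 17-mer tandem tethers,
config.sampler.n_accepted = 150   # 150 configurations per architecture
report = run_comparison(config)

m = report.metrics
print(f"multi-chain area {m['multi_chain'].surface_area:.0f} A^2, "
      f"axes {[f'{a:.0f}' for a in m['multi_chain'].axes]}")
print(f"tandem      area {m['tandem'].surface_area:.0f} A^2, "
      f"axes {[f'{a:.0f}' for a in m['tandem'].axes]}")
print(f"tandem/multi area ratio {report.area_ratio_tandem_over_multi:.2f}")
```

prints (seed 1):

```
multi-chain area 31004 A^2, axes ['104', '100', '88']
tandem      area 29429 A^2, axes ['108', '102', '85']
tandem/multi area ratio 0.95
```

Both envelopes are oblate (the extent along the core's symmetry axis is the
short one), and the tandem envelope is smaller: the two extra tethers
restrict where the internal and C-terminal domains can go, so merging 150
configurations covers less surface than in the multi-chain format. Per-domain
areas are in `report.metrics[...].per_domain_area`; for the C3-symmetric
multi-chain architecture the three domains explore statistically equal areas
(reported as mean ± SE).

The stoichiometry module is a one-liner:

```python
from trimerbody import enumerate_trimer_species, trispecific_fraction
trispecific_fraction(enumerate_trimer_species(3, "multiset_uniform"))  # 0.10
trispecific_fraction(enumerate_trimer_species(3, "sequence_random"))   # 0.222
```

Counting distinct species gives 10% trispecific trimers; physically random
assembly at equal synthesis rates gives 6/27 ≈ 22%. Both are reported because
they answer subtly different questions.

## Command line

```bash
trimerbody compare --seed 1 --out results/        # full comparison
trimerbody species --n-types 3 --mode multiset_uniform
trimerbody sample --topology tandem --n 50 --seed 2 --out tandem.pdb
trimerbody metrics --ensemble tandem.pdb --spacing 2.0
```

`compare` writes the JSON/CSV report, both ensembles as multi-model PDB, and
both merged envelopes as CCP4 maps viewable in PyMOL/ChimeraX.

## Working from crystal structures

The library reads coarse-grained bead models from PDB files
(`read_pdb_coarse`, one bead per residue at the Cα position). To run the
comparison on a real trimerization domain and antibody domain, download the
entries yourself (e.g. 3HSH for the collagen XVIII trimerization domain and a
Fab fragment such as 2VXS for the VHH template) and point
`RunConfig.core.pdb_path` / `RunConfig.payload.pdb_path` at them; chain
termini are used as anchor points. The package never fetches structures over
the network; the bundled synthetic templates (an ideal C3-symmetric core and
a uniform-ball payload) make every analysis runnable offline.

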