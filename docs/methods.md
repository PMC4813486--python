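# Methods

`oligomodel` reconstructs low-resolution structures of small protein
oligomers by combining three kinds of mass-spectrometry-adjacent restraints
— ion-mobility collision cross-sections (IM-MS), chemical cross-links
(CX-MS) and an electron-microscopy density segment — into one scoring
function that drives rigid-body Monte Carlo assembly, followed by
top-fraction clustering. This note records the model, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Collision cross-sections

The projection approximation (PA) treats the CCS as the orientation-averaged
area of the molecule's shadow: atoms are hard spheres, and for a uniformly
random viewing direction the shadow is the union of the projected disks.
The estimator draws uniform random orientations (normalized quaternions) and
estimates each orientation's union area by uniform ray sampling over the
projected bounding box; the reported standard error is the between-
orientation standard error of the mean, which absorbs both shape anisotropy
and ray-sampling noise.

Two conventions matter and are explicit in the API:

* **Radius table.** The default per-element radii (H 2.2, C/N/O 2.7, S/P
  3.5 Å) are helium *collision* radii in the MOBCAL tradition — the probe
  is folded in, so `probe_radius` must be 0 with this table
  (`atomic_ccs_params()`). Sphere models use bare geometric radii plus an
  explicit probe (1.0 Å for He). The inversion used for coarse graining,
  r = sqrt(CCS/π) − probe, is the exact convex-body relation.
* **Scaling.** PA underestimates the measured CCS of rugged atomic
  surfaces; the standard empirical correction multiplies the PA value by
  1.14, predicting helium CCS of protein complexes to about ±3%. The
  correction is applied to atomic models only: PA is exact for convex
  bodies, so coarse-grained sphere models are reported unscaled.
* Structures lacking hydrogens get united-atom radii (heavy atoms +0.1 Å),
  applied only when the structure looks all-atom (≥ 4 atoms in some
  residue); Cα traces and toy fixtures keep their purpose-built radii.

Default budget is 300 orientations × 5 000 rays (relative standard error
well under 0.5% for protein-sized structures). Inside samplers a smaller
budget (48–64 orientations × ~1 000 rays) with one fixed seed is used:
identical orientations and ray offsets across candidate models act as
common random numbers, so score *differences* between similar models are
far more precise than each absolute value. The ray test runs through a
numba kernel with per-ray early exit; a pure-numpy fallback produces the
same stream.

## Cross-link restraints

BS3 bridges lysine ε-amines (and protein N-termini); a link is geometrically
satisfiable when the Cα–Cα distance is at most 35 Å. The bound is treated
as inclusive. Scoring uses a flat-bottom penalty per link — zero inside the
bound, ((d − d₀)/d₀)² beyond it — averaged over links, because BS3 provides
only an upper bound, not a target distance. Links are assigned to the
chain pair that minimizes the distance among pairs eligible for their
class: "inter" links over inter-subunit pairs only, "intra" within
subunits, "unknown" over all pairs. Homotypic links (residue i to residue
i) are never measured onto the same chain copy. Ambiguous loop-links
(e.g. "110/113" rows, where the linked residue cannot be localized) are
parsed and reported but never used as restraints.

Intra/inter classification against a rigid reference unit (e.g. a
domain-swapped dimer) measures the minimum distance over *distinct* chain
pairs of the reference and compares it with the 35 Å bound; links that
cannot be satisfied within the unit must arise between units.

The isotopic peak-pair check compares the measured light/heavy neutral-mass
difference with the d4 − d0 shift (default 4.02511 Da = 4 × (²H − ¹H)) at a
ppm tolerance referred to the light species' neutral mass, inclusive.

## Density restraint

Maps are regular isotropic grids. Models are rasterized by placing an
isotropic Gaussian on each atom (amplitude ∝ atomic mass) or sphere
(amplitude ∝ volume) with FWHM equal to the nominal resolution
(σ = resolution/2.355); fit quality is the Pearson correlation over the
segment's voxels (mean-subtracted, no envelope thresholding). The score is
1 − CCC ∈ [0, 2]. An optional matched Gaussian low-pass of both maps before
correlation is available (`em_lowpass`); it suppresses voxel-scale noise at
the price of halving effective resolution, and benchmarking showed the
trade is not worth it at 20 Å, so it is off by default.

## The scoring function

S = W_IM-MS · S_IM-MS + W_CX-MS · S_CX-MS + W_EM · S_EM, weights 1:2:2.
S_IM-MS is harmonic in the CCS deviation normalized by tolerance × target
with tolerance 0.03 — the predictive accuracy of scaled PA — so one
"experimental error" of deviation scores 1 and the three terms are
commensurate. Absent restraints contribute zero (the trimer workflow uses
IM-MS + CX-MS only; the EM segment enters for the tetramer). All terms are
dimensionless and non-negative; lower is better.

## Samplers

**Coarse-grained stepwise builder.** The monomer is a single sphere whose
radius reproduces the measured monomer CCS. Each next subunit is placed on
a deterministic grid — distances 1.2 r to 4 r from the current model's
centroid in 0.1 r steps, directions on a 15° angular grid — with
overlapping placements rejected (centers closer than 1.2 r, i.e. > 40%
overlap), and the candidate whose sphere-model CCS best matches the n-mer
target is kept. The fourth subunit is sampled by Monte Carlo around the
fixed trimer. CCS evaluations share one seed, so the grid argmin is
deterministic and comparisons are common-random-number precise.

**Atomic rigid-body sampler.** A mobile unit (monomer or dimer) is placed
against fixed units by a uniformly random rotation and an anchor-atom
construction: a random mobile atom is set a random 3–10 Å gap from a random
fixed atom along a random direction, which guarantees contact without
biasing orientation. Placements with any inter-unit atom pair closer than
2.5 Å are rejected. Every accepted model is scored; the ensemble is
reproducible from one seed.

**Refinement.** Pure generate-and-score cannot place a model closer than
its sampling density allows (~10 Å at 2 000 models for these systems), so
the pipeline refines the lowest-scoring few percent with a two-phase
Monte Carlo search in the rigid-pose space of the mobile unit: an
exploration phase (fixed temperature 0.25 in score units, 20° / 4.5 Å
proposals) followed by an annealed quench (temperature and proposal sizes
ramped to zero; restarts from the best pose found). The best-visited pose
is returned. Clustering then operates on the best-scoring models after
refinement.

**Selection and clustering.** The lowest-scoring 1% of models (ties broken
by generation order) are clustered by single-pass leader clustering in
ascending score order at a 5 Å assembly-RMSD threshold: a model joins the
first cluster whose leader is within the threshold, else founds one. The
representative of a cluster is its lowest-scoring member, and the final
model is the representative of the largest cluster. Assembly RMSD is the
minimum Cα RMSD after optimal (Kabsch) superposition over all permutations
of identical-sequence chains (exhaustive; assemblies here have ≤ 6 chains).

## Synthetic benchmark

The generator fabricates all experimental ingredients from a known planted
assembly so the whole pipeline can be validated by recovery:

* **Subunits** are compact self-avoiding Cα traces (3.8 Å bonds, 3.2 Å
  united-residue collision radius, 40 residues by default) with
  pseudo-lysines every 7 residues, roughly β2-microglobulin's lysine
  density. They reproduce chain connectivity and packing scale but not
  secondary structure, side chains or chemistry.
* **Assemblies** are clash-free contacting rigid placements; the tetramer
  benchmark stacks two copies of a rigid dimer, mirroring a dimer-of-dimers
  build. Ground-truth transforms are recorded.
* **Observables**: the CCS target is the truth's scaled PA CCS times
  (1 + ε), ε ~ N(0, 3%) — the same estimator convention used in scoring, so
  noise enters only through ε; cross-links are all inter-subunit lysine
  pairs within 35 Å (plus unsatisfiable decoy pairs at a 20% rate,
  emulating validation false discoveries); the map is the truth rasterized
  at 20 Å on 5 Å voxels plus white voxel noise of sd 10% of the maximum.

What recovery under these conditions shows: that the scoring function
ranks near-native poses ahead of wrong topologies and that the
sample-select-refine-cluster pipeline concentrates on the global basin.
What it cannot show: performance on real detergent/buffer artifacts,
conformational flexibility (subunits here are perfectly rigid and
identical to the starting units), or map segmentation error.

**Identifiability at these conditions.** At 20 Å resolution the density
term is nearly blind to ~5–10 Å rigid displacements of one dimer
(measured: against a noise-free map, poses 4–11 Å from the truth all reach
S_EM ≤ 0.15 after refinement), the CCS term constrains only overall
compactness, and the 35 Å upper-bound links are loose for subunits of this
size. The data therefore admit a shell of quasi-degenerate solutions
roughly 5–10 Å from the truth; recovery of the compact topology is robust,
while the final representative's RMSD to truth fluctuates around that
shell from seed to seed. This is a property of the restraint information
content, not of the optimizer.

## Numerical and degenerate-input conventions

* Superposition uses scipy's Kabsch implementation; degenerate (< 3 points
  or collinear) inputs are rejected.
* Leader-cluster visit order, top-fraction tie-breaks, and all random
  streams are fixed by explicit seeds; identical config + seed reproduces
  ensembles bit-for-bit.
* PDB output is fixed-width wwPDB v3.3 ATOM records at 3 decimals; chains
  are relabeled A, B, … when units are merged. Collision radii are not
  representable in PDB, so re-scoring a written pseudo-atom model requires
  restating the fixture radius table.
* The plain-text grid dialect stores dims/origin/voxel/resolution plus
  voxel values in C order, so density fixtures remain diff-able text.

## Problem sizes

Default analysis runs use 2 000-model ensembles per seed with 40-residue
subunits, refinement of the top 3%, and clustering of the best 20 refined
models; one such run takes a few minutes on one CPU core. The same code
scales to the 10 000-model ensembles of larger studies by changing
`SamplerConfig.n_models`.
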