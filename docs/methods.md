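# Methods

## Model representation

An atomic model is represented as a Gaussian mixture with one isotropic 3D
Gaussian per non-hydrogen atom, parameterised by five numbers: amplitude,
width, and the center coordinates. Centers are the atom positions, so
optimising the mixture optimises the model directly and the atom↔Gaussian
bijection is preserved through refinement. Amplitudes default to atomic
number (electron count) and the width is shared across atoms, derived from
the target resolution as σ = d/(π√2) for a target of d Å. Because the
similarity score below normalises every spatial-frequency ring
independently, the exact width only shapes a radial envelope and is not a
sensitive parameter.

## Map–model similarity

Training compares 2D projections, not 3D volumes. Projections of the
reconstruction are line integrals along quasi-uniform viewing directions
(scrambled Sobol points mapped to rotations through Shoemake's quaternion
construction, seeded); the mixture has an analytic projection — each 3D
Gaussian projects to a 2D Gaussian of the same width and integrated
amplitude a·σ·√(2π) — evaluated by separable matrix products so the cost is
O(N·S²) per image with exact gradients.

The loss is the negative Fourier ring correlation (FRC), averaged over
rings from the first non-DC ring up to a hard cutoff at the target
resolution, and over a seeded batch of projections per iteration. Ring
width is one Fourier pixel. Ring-wise normalisation makes the score
invariant to any radial filtering or B-factor-style sharpening of either
image; rings whose reference power is at numerical-noise level (below
10⁻¹⁴ of total power) are excluded. Pixel size must satisfy Nyquist
(pixel ≤ target/2); violations are rejected before training.

## Stereochemical terms

Every validation metric is written twice over the same precompiled index
tables: a smooth, differentiable loss for training and a hard-threshold
report that mirrors how validation counts are defined. Smooth hinges use
softplus; thresholds below are validation conventions.

- **Bonds and angles.** Ideal values are measured from the Chemical
  Component Dictionary ideal coordinates (via biotite) at template-build
  time; standard deviations come from shipped restraint-class tables
  (≈0.015–0.025 Å for bonds by element pair, ≈1.9° for angles, with named
  backbone overrides such as N-CA-C at 2.7°). The loss is the Gaussian
  negative log-likelihood ½z̄² plus a hinge activating at 4.5σ
  (softplus(10·(|z|−4.5))); outliers are *reported* at 5σ. The tighter
  training threshold keeps refined bonds clearly inside the reporting
  threshold.
- **Planarity.** Quad deviations are angular distances of the dihedral to
  0°/180°. Peptide ω planes use a 30° threshold; all other planar groups
  (sp2 impropers and multiple-bond ring torsions, auto-detected from CCD
  geometry and bond orders) use 10°. A weak quadratic (weight 0.05,
  normalised by threshold) provides gradient inside the hinge.
- **Ramachandran.** Six residue classes: General, Gly, trans-Pro, cis-Pro
  (|ω| < 30°), pre-Pro, and Ile (which also covers Val, as the class is
  defined by β-branching). Class precedence: Pro → pre-Pro → Gly → Ile →
  General. Scores come from periodic Gaussian-mixture surfaces fitted to
  log-histograms (below); the outlier level is 0.0005 and the allowed
  level 0.02 on the max-1 scale. Only the allowed and outlier fractions
  act on the loss: the hinges are sharp (factor 3 inside softplus), so
  favored residues sit on a flat plateau. This is deliberate — an earlier
  softer hinge left a residual pull toward basin centers that slowly
  unwound genuine backbone motion during geometry-only training.
- **Rotamers.** Per-residue χ vectors scored against per-type surfaces
  (1–4 χ; PHE/TYR/ASP/GLU have a 180°-periodic terminal χ). The loss
  combines a weak likelihood (−0.05·logS) with an outlier hinge at the
  0.002 level; reports use the hard threshold. Residues with incomplete
  sidechains are skipped with a warning.
- **Clashes.** Candidate pairs are the 128 nearest neighbours per atom
  (KD-tree), excluding pairs within 3 covalent bonds (graph BFS), over
  heavy atoms plus placed hydrogens; lists are refreshed every 100
  iterations and on demand. A pair clashes when d < rᵢ + rⱼ − 0.4 Å; H
  paired with O/N (not covalently linked) gets an extra 0.4 Å allowance
  for potential hydrogen bonds. The training hinge adds a 0.05 Å margin
  (softplus(20·(overlap+0.05))) so contacts settle clearly below the
  reporting threshold instead of hovering at zero overlap. The clash score
  is 1000·count/atoms with hydrogens included.
- **RNA suites.** Seven backbone dihedrals (δ₋₁, ε₋₁, ζ₋₁, α, β, γ, δ)
  span each base and its predecessor. Each base is assigned to the nearest
  of 46 cluster centers in the 7D torsion space under per-angle scaled
  distance d = √(mean((Δθ/w)²)); the suiteness-style score is
  ((cos(π·min(d,1))+1)/2)³, with the 0.001 assignment threshold. The
  reported mean excludes unassigned bases (score < 0.001), as validation
  does, but the loss penalises d² for *all* bases so outliers cannot hide.

## Hydrogens

Hydrogens are never part of the mixture; they are placed deterministically
from heavy atoms via internal coordinates (length, angle, torsion in a
parent/reference frame) recorded in the templates, using electron-cloud
bond lengths (C–H 0.97, N–H 0.86, O–H 0.84, S–H 1.20 Å). Rotatable groups
(methyl, hydroxyl, thiol, ammonium) are pinned at the dictionary's
staggered default torsion — the torsional freedom is deliberately frozen,
mirroring how validation re-places hydrogens at fixed default rotations —
so H positions are a pure function of the heavy atoms and transform
rigidly with them. Backbone amide H is placed in the peptide plane anti to
the carbonyl O; N-termini carry three (Pro: two) staggered hydrogens.

## Reference surfaces

Ramachandran and rotamer histograms are synthetic: wrapped-Gaussian basins
and peak lists encode the canonical α/β/PII/αL structure and the standard
m/t/p rotamer wells. They are realistic in topology but are not the
top8000 data; an importer accepts user-provided gridded histograms in the
same form.

Fitting to a continuous surface happens in log space, ln(R + C) with
C = e⁻¹⁰, so the tiny outlier level stays resolvable. Components are
initialised by seeded k-means over density-weighted bins with widths from
the bin spacing; amplitudes (the linear parameters) are solved by
iteratively reweighted ridge least squares, where bins below the outlier
level that evaluate above the outlier threshold are re-targeted and
up-weighted until every histogram-outlier bin classifies as an outlier on
the surface. For component counts up to ~64 a joint nonlinear
least-squares polish (analytic Jacobian) refines centers, widths and
amplitudes; the boundary condition is re-tightened afterwards. Component
counts follow the standard choices: 4/25/64/160 components for 1/2/3/4 χ;
the 3- and 4-χ surfaces are built directly at the library peaks (the
reference density is itself a sparse mixture, so grid fitting is
wasteful). Default Ramachandran surfaces use 324 components on a 64×64
grid — enough for exact boundary classification at desk scale; the 2500-
component setting remains available for imported full-resolution
histograms.

The RNA suite library shipped in `data/rna_suites_synthetic.json` is a
synthetic stand-in: 46 distinct centers composed from canonical torsion
classes with the A-form suite placed at its literature values. The
published consensus table can be dropped in with the same schema.

## Decoder hierarchy and single-model refinement

Three four-layer densely connected decoders (hidden width 64, ReLU)
output, respectively, per-patch rigid transforms (rotation vector +
translation about the patch center), per-residue rigid transforms, and
per-atom offsets. Output heads are zero-initialised so each decoder starts
exactly at its baseline model; hidden weights start with small seeded
random values. Patches come from seeded K-means over residue centers, so
atoms of one residue always share a patch. In single-model mode the
decoder input is the constant vector [1,1,1,1].

Refinement proceeds in five steps, each baking its output coordinates into
the next step's baseline (weights never need saving in this mode):

1. Topology and restraint tables are precompiled.
2. The patch decoder trains against the map term alone (large-scale
   morphing).
3. Patch + residue decoders train together with the basic restraints
   (bonds, angles, clashes).
4. Optionally, rotamers are rebuilt: every library peak is instantiated
   geometrically and scored by mean map density over the moved sidechain
   atoms; the best peak is kept (ties keep the input), then all χ angles
   are refined jointly by Adam against map density, rotamer surfaces and
   clashes, linearised about the current rotation axes. The χ result is
   baked into the step-5 baseline; further sidechain motion is carried by
   the per-atom decoder.
5. All three decoders train with every stereochemical term. This step can
   run alone without a map (geometry-only refinement).

The geometry weight is calibrated from the data: a two-iteration map-only
probe measures the gain in mean FRC and the degradation of the unweighted
geometry score, and the weight is their ratio Δmap/Δgeo (probe state
discarded, decoders re-initialised). A probe that cannot gain map score —
e.g. a model already fitting its map — falls back to weight 1.0 with a
warning. Recovery on the desk fixtures is insensitive to this weight over
three orders of magnitude (10⁻³–1), because the hinge penalties dominate
whenever actual violations appear.

Optimisation is Adam (lr 2·10⁻³) with seeded batch sampling; all
randomness flows from one seed, so repeat runs are bit-identical.

## Series refinement

For a stack of reconstructions with latent conformation coordinates
(d ≤ 4, padded with ones to the 4-vector input so single-model mode is the
degenerate case), the same three phases run but all decoders keep their
weights — the weights are the artifact, mapping latent → model. Each
training iteration draws one map (cycled round-robin), a batch of its
projections, and feeds the map's latent plus a small seeded Gaussian
perturbation (σ = 0.05 of the latent range per dimension), which forces
the learned mapping to be smooth between sampled latents. Maps are
weighted equally. The balance probe runs against the worst-fitting map,
since the input model (pre-refined against the neutral map) leaves no map
gain to measure on its own reconstruction.

A final geometry-only polish trains on latents drawn uniformly over the
trajectory (default: bounding box of the input latents), so frames never
covered by a reconstruction also satisfy the constraints. A quadratic
anchor to the pre-polish model at each sampled latent (weight 1.0 Å⁻² on
the mean squared displacement) keeps the map-facing frames in place:
residual violations need only ~0.1 Å local moves, which the anchor barely
resists, while large-scale drift — which could otherwise relax patch-seam
strain by unwinding the learned motion — is strongly suppressed. The
anchor weight was chosen by this separation of scales, not tuned against
any benchmark.

Sampling the refiner is deterministic (no latent noise at inference), and
refiner weights serialise to a `.npz` container with a config snapshot;
reloading reproduces sampled models bit-identically.

## Synthetic fixtures

The generator builds everything the tests need from first principles:

- **Toy structures.** Protein backbones grow by natural-extension (NeRF)
  placement at recipe (φ, ψ) — helix (−60, −45), strand (−120, 135) — with
  ideal lengths/angles taken from the same templates that define the
  restraints, so fixtures are exactly at the restraint minima. Sidechains
  are placed rigidly from CCD ideal coordinates in the N/CA/C frame and
  set to library peak rotamers, with a greedy clash-avoiding pass over
  alternative peaks. RNA chains grow 5'→3' with near-A-form junction
  torsions (ε −148, ζ −90, α −80, β 174, γ 54 — displaced slightly from
  textbook A-form so that, combined with the CCD sugar conformation, the
  chain is sterically clean while staying firmly assigned to the A-form
  suite); free phosphate oxygens are re-placed to straddle the incoming
  O3'.
- **Maps.** Gaussian-blurred atom densities (amplitude = atomic number,
  σ from the resolution), optional white noise (default off so tests
  isolate algorithmic behaviour), writable as MRC.
- **Perturbations.** The hinge is a torsion rotation: the carbonyl O of
  the hinge residue and everything after it rotates rigidly about that
  residue's CA–C bond, changing only ψ. Internal geometry therefore stays
  exactly ideal and no junction re-idealisation is needed; the positive
  rotation direction keeps intermediate states clash-free, which a φ-axis
  hinge does not (it drives the classic O(i−1)···C contact). Jitter is
  seeded isotropic Gaussian noise.
- **Motion series.** n states interpolate the hinge angle uniformly;
  latents are the normalised state index in [0, 1]; all maps share one
  box/origin. Ground-truth models are returned for recovery scoring.

What the fixtures do *not* emulate: experimental noise spectra, CTF,
solvent, B-factor variation, partial occupancy, or real conformational
ensembles. Passing tests demonstrate the algorithmic machinery (losses,
gradients, recovery of planted motion at the stated resolutions), not
performance on experimental reconstructions.

## Desk-scale problem sizes

The benchmark experiments use a 40-residue poly-Ala helix (~200 heavy
atoms), 8 Å maps in 40³ boxes at 2.5 Å voxels, 24 projections per map
(16 per map for the 5-map series), batch 4, 6 patches, and iteration
budgets 400/250/350 (single) and 400/300/400 + 400 polish (series).
Patch count matters: step-2 morphing needs patches that span domains, so
for small fixtures the 64-patch default is reduced — at one patch per
residue the map term alone can be satisfied by geometrically wrong
configurations.

## Known limitations

- Restraint ideals derive from CCD ideal coordinates plus class-level
  sigmas, not a curated refinement dictionary; absolute agreement with any
  particular validation server is not expected beyond the shared
  thresholds.
- The suite library and the reference histograms are synthetic stand-ins;
  scores are self-consistent within the package rather than comparable to
  external tools in absolute value.
- Chained χ optimisation is linearised about fixed rotation axes per
  iteration; adequate for local polish, not for large sidechain
  rearrangements (those go through the peak-enumeration rebuild).
- Alternate conformations are collapsed to the highest-occupancy
  conformer; occupancies and B-factors are not refined; DNA bases and
  ligands carry only bond/angle restraints through their CCD entries if
  supplied, and are otherwise out of scope.
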