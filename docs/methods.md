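# Methods

## Scope and model

`oxbilayer` implements the model-construction and analysis layer for
united-atom bilayer simulations of POPC, cholesterol and POPC peroxidation
products.  It does not integrate equations of motion: energies,
thermostats, barostats and electrostatics belong to an external MD engine.
The package builds initial configurations, reads the engine's trajectories
and computes the standard bilayer observables with error estimates, and it
ships a synthetic-trajectory generator whose ground truth exercises every
analysis path.

## United-atom templates

Each species is a fixed particle table (name, element, merged-hydrogen
count, mass) plus bonds.  Aliphatic hydrogens are merged into their carbon
(CH, CH2, CH3 are single particles of combined mass); polar hydrogens
(cholesterol hydroxyl, the OX1 hydroperoxide) stay explicit.  POPC
(C42H82NO8P) therefore reduces to 52 particles representing 134 atoms.
The oxidized species are derived from POPC's oleoyl chain:

| species | sn-2 chain | extra particles | polar markers |
|---------|------------|-----------------|---------------|
| OX1 | 9-hydroperoxy-octadecenoyl | −O−O−H on C9 | the two peroxide O |
| OX2 | 9-oxononanoyl (aldehyde) | aldehyde O | aldehyde O |
| OX3A | as OX2 | aldehyde O | aldehyde O |
| OX3B | nonanal-type C9 aldehyde (free fragment) | — | aldehyde O |

An OX3A/OX3B pair originates from one POPC molecule and counts as **one
lipid** in every per-lipid quantity; in coordinate files the fragments are
consecutive residues and the reader re-links each OX3B to the OX3A
immediately before it.  Particle ordering within a residue is a documented
package convention (names are element + serial); template masses equal the
all-atom molecular masses by construction, which the tests verify against
independently computed formula masses.

Since the particle tables carry no coordinates, each species also has a
schematic reference conformation (head up, tails down, anchor at the
origin) used for packing and synthesis.  Only the sn-1 chain geometry is
exact — an ideal all-trans tetrahedral zig-zag — because the order
parameter's ground truth depends on it; the rest is a compact, plausible
arrangement.

## Deuterium reconstruction and S_CD

United-atom chains have no deuteriums, so for every interior sn-1 carbon
(two heavy neighbours A, B) the two C–D unit directions are built from
a, b (unit vectors to A and B) as u cos(δ/2) ± v sin(δ/2), with
u = −(a+b)/|a+b|, v = (a×b)/|a×b| and δ the D–C–D angle.  "Ideal
tetragonal symmetry" is implemented as tetrahedral: δ = 109.471°, C–D
length 0.1 nm (the length never enters the analysis — only directions do).
The construction is exactly equivariant under rotations, makes equal
angles with both neighbours, and is skipped with a warning when A, C, B
are collinear.

The ester carbonyl (position 1) and terminal methyl (position 16) have no
CD2 frame and are excluded; positions 2–15 enter the profile.  Whether the
carbon adjacent to the carbonyl (position 2) belongs in the chain average
is ambiguous in common usage, so it is a switch (`include_c2`, default
on).  S_CD = ⟨(3cos²θ−1)/2⟩ is averaged over both bonds, all lipids of all
sn-1-bearing species and all production frames; the chain mean is the
unweighted mean over carbon positions.  Note that the formula's value is a
*bond* order parameter: vertical all-trans chains give −1/2 (bonds
perpendicular to the normal), not +1.

## Compositions and packing

Fractions become integers by half-to-even rounding on 72 lipids —
cholesterol from the total pool, the oxidation fraction from the
non-cholesterol (POPC) pool — with POPC absorbing the remainder; realized
fractions are reported beside the requests.  The study-grid enumerator is
configurable (species × oxidation levels × cholesterol levels) and
deduplicates coincident integer compositions rather than hard-coding a
particular grid.

Packing is grid-accelerated rejection sampling, chosen over an external
packing tool so the constraint is testable in-repo: lipids are split
evenly between leaflets (head groups toward the water slabs), placed at
random lateral positions and z-rotations, and re-drawn until no particle
of a different lipid lies within 2 Å (periodic minimum image; an attempt
cap converts overcrowding into a diagnostic error naming the density).
OX3B fragments start in the core below their parent.  Water is a rigid
3-site model (O–H 0.9572 Å, 104.52°, molecule mass 18.015 amu) on a
jittered lattice in the two outer slabs; only its mass density matters
downstream.

## Analysis conventions

* **Equilibration**: frames with time strictly greater than `equil_time`
  are used; the default keeps the second half of the recorded span
  (mirroring production runs that discard the first 80 of 160 ns).  Frames
  are used at native cadence, no interpolation.
* **Profiles**: each frame is recentred on its instantaneous phosphate
  midplane and binned fractionally against its instantaneous box height
  (100 bins default), so NPT box fluctuations and drift do not smear
  peaks.  The reported density is ⟨bin mass⟩/⟨bin volume⟩ (numerator and
  denominator time-averaged separately), which conserves the selected mass
  exactly; the tests require 0.1%.  Densities are mass densities in
  kg m⁻³.
* **Thickness**: argmax bin centre on each side of the midplane, ties
  broken toward larger |z|; error bar one *full* bin width (the binning,
  not statistics, limits the peak position).  Merged or missing peaks
  raise instead of returning a number.
* **Area per lipid**: time-mean lateral area over lipids per leaflet, so
  APL × n_per_leaflet reproduces the mean area exactly.  Whether
  cholesterol-rich systems should use a different per-leaflet count is
  left to the caller via `n_per_leaflet`.
* **Block errors**: the series is blocked at sizes 2^k (at least four
  blocks).  For exponentially correlated data the blocked SE² is exactly
  s²/n·[(1+c)/(1−c) − 2c(1−c^m)/(m(1−c)²)]; the two parameters (marginal
  variance s², per-sample correlation c) are fit over all block sizes with
  χ²-based weights, and the fitted plateau is reported; the maximum
  blocked SE is the fallback when the fit degenerates.  Calibration: ~2%
  of σ/√n on iid data and of the correlated closed form on AR(1) data at
  the sizes the tests use (tolerances 10% and 15%).
* **Core water density**: water mass in |z − z_mid| ≤ 0.5 nm over the slab
  volume, block error over the frame series.
* **Pore detection**: water oxygens strictly between the two phosphate
  peak planes are clustered by single linkage at 0.35 nm (periodic KD-tree
  + connected components); a pore spans when a cluster reaches within one
  cutoff of both planes.  Slabs of 0.1 nm get an effective radius
  r = √(n·v_w/(π·0.1 nm)) with v_w = 0.030 nm³ per molecule, using the
  cluster occupancy *averaged over spanning frames* (a single frame's
  per-slab count is a ~5-molecule Poisson draw whose maximum would bias
  the diameter upward).  Reported diameters are twice the largest and
  smallest slab radii; the onset is the first spanning production frame.
  The construction (clustering + slab effective radius) is this package's
  definition — the upstream literature reports pore diameters without
  specifying one.

## Synthetic bilayers and what they do (and do not) show

The generator emulates the *statistical structure* the analysis assumes:
phosphate anchors on two jittered planes a known distance apart (thickness
truth), rigid all-trans sn-1 chains tilted α from the normal with a fresh
uniform azimuth per lipid per frame (S_CD truth −0.5·P2(cos α), exact
because the C–D directions of an ideal zig-zag are perpendicular to the
chain axis), AR(1) lateral-area fluctuations around apl·n_per_leaflet
(APL and block-error truth), stratified-uniform water in the outer slabs,
and optionally a bulk-density (33.4 nm⁻³ ≈ 997 kg m⁻³) water cylinder
through the core, resampled every frame, whose radius fixes the pore
truth and whose cross-section fixes the core-density truth ρ·πr²/A.
Polar marker oxygens are placed at the core (straight mode, the freshly
oxidized state) or just below the phosphate planes (bent mode, the
equilibrated state), reproducing the qualitative density signature of
aldehyde migration.

Chains are rigid and azimuthally re-randomized each frame: truth values
are exact and every sample is independent, at the price of physical
dynamics.  Closed-loop recovery on these systems therefore validates the
*estimators* — binning, recentring, reconstruction geometry, clustering,
error propagation — not force-field realism; trends in real membranes
(condensation by cholesterol, thinning by oxidation, the oxidation level
at which pores appear) still require MD trajectories, which the pipeline
ingests through GRO/PDB + XTC/TRR.

Defaults are the study conditions (72 lipids, 4000 waters, ~5.5 × 5.5 ×
11 nm box, 100 ps cadence, 1600 frames, half-trajectory equilibration).
The test suite and validation runs use the same construction at reduced
frame counts (24–64 frames) and water counts, chosen so each randomized
recovery check completes in seconds while leaving the statistical
tolerances (3 SE for S_CD, 10% for slab densities, 2 Å for pore
diameters) comfortably resolvable.

## Numerical and degenerate-input choices

* Collinear sn-1 neighbours (|a×b| < 1e−8): carbon skipped, warning.
* Empty density selection: all-zero profile plus warning, not an error.
* Systems without phosphorus: profiles recentre on the box centre with a
  warning; pore detection reports the span as unresolved (`spanning =
  None`) rather than guessing.
* Thickness peak ties break toward larger |z|; equal-maximum bins are
  resolved before floating-point comparison noise by exact equality.
* GRO round-trips are exact to the format's 3-decimal nm precision;
  PDB to 3-decimal Å.  Frame times come from the trajectory file when
  strictly increasing, otherwise synthesized at a stated cadence.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical inputs give bit-identical packed
  frames, synthetic trajectories and pipeline artifacts.

## Known limitations

* Reference conformations are schematic; packed configurations are
  starting points for minimization/MD, not equilibrated structures.
* The pore-diameter definition is occupancy-based and resolution-limited
  by the 0.1 nm slab; bottleneck diameters on noisy small pores are
  conservative (biased low).
* Cholesterol's template has correct composition and mass but a
  simplified ring geometry; analyses that would depend on ring
  orientation (none in the battery) are out of scope.
* The block-error fit assumes a single dominant correlation time; series
  with strongly multi-scale correlations fall back toward the maximum
  blocked SE.
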