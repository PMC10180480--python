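# Methods

This note documents the models, conventions, and numerical choices behind
`sheetkit`, and what passing its tests does and does not establish.

## System

The package models a minimal DNA nanosheet assembly unit, the **F-unit**:
three strands (A, B, C) forming one **core** duplex (21 bp), four **arm**
duplexes (16 bp, each an A- or B-strand segment hybridized to a copy of
strand C), and four 10-nt **sticky ends** (SE1/SE1\*, SE2/SE2\*) left
single-stranded on the A/B strand termini. Sticky-end cohesion tiles
F-units into a porous two-dimensional lattice; cholesterol moieties on the
3′ ends of the C strands anchor the sheet to a liquid/liquid interface.

The canonical strand layout used throughout (I/O, pairing maps, the
synthetic generator) is, 5′→3′:

```
A: SE1(10) | arm(16) | core(21) | arm(16) | SE2(10)      (73 nt)
B: SE2*(10) | arm(16) | core*(21) | arm(16) | SE1*(10)   (73 nt)
C: arm-complement (16 nt), four copies per unit
```

All four arm segments read identically on A/B (every arm is complementary
to the single C sequence), the B core is the reverse complement of the A
core, and the F-unit is strand order `[A, B, C1..C4]` with 0-based
nucleotide indices.

## Junction geometry and the planarity metric

Each of the two junctions joins three duplexes (two arms plus the core).
Arm directions are unit vectors **e**₁…**e**₆ estimated by
total-least-squares (principal axis of the base-pair midpoints, sign-fixed
proximal→distal; no end-trimming by default — a trim count can be applied
by shortening the index lists). The junction point is the centroid of the
three proximal base-pair midpoints; there is no standard definition of a
junction point for this motif, and the midpoint of the core-terminal base
pair is an equivalent configurable alternative.

The planarity metric **d_p** is the distance from the junction to the
plane through the tips of the three unit arm vectors anchored at it. It is
intrinsically dimensionless (the arm vectors are unit length): 0 for
coplanar arms, and exactly sin φ when all three arms share a uniform
out-of-plane inclination φ — the identity the synthetic generator and the
property tests exploit.

A geometric fact worth stating explicitly: a tripod of three unit vectors
is coplanar **iff** its pairwise angles sum to 360° (or degenerate to one
angle equal to the sum of the others). The equilibrium angle set measured
for the F-unit, (α₁₂, α₁₃, α₂₃) = (80°, 150°, 120°), sums to 350° and is
therefore *not* realizable in a plane. `build_ideal_funit` realizes the
requested pairwise angles exactly in 3-D — core and one arm in the z = 0
plane, the second arm taking the minimal out-of-plane lift — so angle
recovery is exact and the per-junction sum is 350°; the implied junction
d_p is ≈ 0.159, consistent with the near-planar (d_p ≈ 0.2) equilibrium
this angle set comes from. An angle set summing to 360° produces an
exactly planar build with d_p = 0.

## Pore lattice closed forms

From the segment lengths, a lattice pore is a parallelogram with side
contour lengths 63 bp (arm + SE + core + arm) and 42 bp (arm + SE + arm),
converted to nm at the B-form rise of 0.34 nm/bp. At junction angle θ
(default 80°, the equilibrium arm–arm angle) the diagonals are
d± = √(a² + b² ± 2ab·cos θ), giving 27.73 and 23.59 nm at the defaults.

**Porosity** uses a strip-ownership approximation: each unit cell owns one
long-side and one short-side duplex strip of width w (2 nm, one duplex
diameter) minus their corner overlap,

φ = 1 − (a + b − w)·w / (a·b·sin θ),

which is 77.6 % at the defaults. The approximation ignores the sticky-end
single-strand width difference and junction crowding; it is the package's
own choice of closed form and is stated explicitly for that reason.

**Cholesterol spacings** are computed on an ideal collinear-segment
neighborhood: one junction pair plus its four sticky-end-bridged neighbor
arms. Arms aligned with the core (e₁/e₄ type) carry their cholesterol at
the distal arm terminus, the short-side arms (e₂/e₅ type) at the
junction-proximal terminus; like arms bridge like. The minimum spacing is
then the sticky-end span, 10 bp ≈ 3.4 nm, and the maximum a full
arm–SE–arm path, 42 bp ≈ 14.3 nm. Which pair realizes the ~3 nm minimum
is a convention: the sticky-end-bridge interpretation is adopted here and
the exact attachment indices are configurable.

## Melting thermodynamics and assembly order

Domain melting temperatures use unified nearest-neighbor parameters
(SantaLucia-2004 table via Biopython's `Tm_NN`), equal strand
concentrations (default 1 µM each), an entropy-based monovalent salt
correction, and divalent cations folded in as an equivalent monovalent
concentration (120·√[Mg²⁺] in mM). The experimentally used oligo
sequences are not bundled; defaults are GC-balanced random placeholder domains drawn at the
design lengths from a caller-supplied seed, for which the hierarchy
Tm(core) > Tm(arm) > Tm(SE) holds by length in all 100 seeded draws the
suite checks.

Hybridization is modeled as a sharp threshold — a domain binds at the
first schedule time its temperature falls to or below its Tm — with no
kinetics, since only the ordering (core, then arms, then sticky ends) is
used. The five named annealing schedules (FAP-A/B/C, SAP-A/B) are built
in; "−1 °C/5 min" ramps are expanded to stepwise 1 °C holds of 5 min
between, but excluding, the explicit endpoint holds. The slow protocols
end with a direct jump to their 4 °C hold.

## Pore metrics

Pore corners X, Y, Z, W (cyclic) are junction positions; diagonals are
|X−Z| and |Y−W| in nm. Internal angles are arccos of the dot product of
the two pore-internal arm axes at each corner. Corner-plane planarity
takes, for each corner, the plane through it and its two cyclic neighbors
(the neighbor-triple reading of the ambiguous "plane passing through each
corner"), and reports the six pairwise angles between plane normals using
|cos| (unsigned, 0–90°), so a perfectly planar quadrilateral gives 0°
for every pair; a signed variant would only differ by reflection choices.

## AFM height profiles

Pores appear as dips in a 1-D height trace, so "peak" detection runs on
the pore-depth signal max(h) − h via `scipy.signal.find_peaks` with a
prominence threshold of half a duplex layer (1 nm) by default — the
threshold is the package's own convention, stated here for that reason. Pore spacing is the mean gap between consecutive dip centers.
Segments between dips are quantized to discrete duplex layers by rounding
the median of the central half of each segment (avoiding dip shoulders)
to the nearest multiple of the 2 nm layer height, floored at zero.

## Interfacial mechanics

Sweeps are segmented by explicit boundary times or by crossings of a
temperature trigger; each phase is summarized by the mean of its trailing
25 % of samples (the package's plateau rule). The bulk extrapolation is

E = 2(1 + ν)·G′/t,

the standard isotropic shear→Young relation applied across the sheet
thickness; ν = 0.5 (incompressible) and t = 2 nm (one duplex layer, the
AFM single-layer thickness) are the defaults — this is the unique
standard relation that maps the 300 mN/m annealed-sheet plateau to
450 MPa at one-duplex thickness. The porosity correction E/(1−φ) treats the
sheet as load-bearing only over its DNA area fraction and is reported as
a lower bound ("at least" semantics). The storage/loss gap is
log₁₀(G′/G″) in decades.

## Synthetic data generators

Every generator is a pure function of (parameters, seed) with one RNG
stream per artifact, and writes a JSON ground-truth sidecar.

* **F-unit snapshots** place base-pair midpoints along straight segment
  center-lines, with the two strand beads offset ±0.5 nm perpendicular to
  the axis (the base interaction site; the rendered duplex width stays
  2 nm) and `a1` pointing at the partner. A uniform tilt φ inclines the
  arms by φ and renders the core as a shallow tent so that *all three*
  duplex directions at *both* junctions have out-of-plane inclination φ,
  making d_p = sin φ exact. Sticky ends are unpaired beads continuing the
  arm line. No helical twist is applied — every consumer works on
  base-pair midpoints, which are twist-invariant.
* **Pore snapshots** render the four sides as straight duplexes whose
  terminal base-pair midpoints sit exactly on the corner junctions (bead
  spacing side/(n−1) rather than exactly 0.34 nm), so measured corner
  positions, diagonals, and internal angles reproduce the closed forms to
  1e-6. The tilt parameter folds the quadrilateral about the X–Z diagonal
  by a known dihedral.
* **Relaxation trajectories** give frame k the tilt
  φ_k = φ_eq + (φ₀ − φ_eq)·exp(−t_k/τ) + ε_k, ε_k ~ N(0, noise²),
  defaulting to φ₀ = 60°, φ_eq = arcsin 0.2 ≈ 11.5°, τ = 10 τ_B, 1° noise,
  200 frames — conditions under which the analysis pipeline recovers an
  equilibrium d_p of 0.20 ± 0.02 across seeds.
* **Height profiles** superpose Gaussian pore dips (FWHM 2 nm) every
  25 nm by default on plateaus at integer multiples of the 2 nm layer
  height, with 0.1 nm height noise at 0.5 nm pixels.
* **Rheology sweeps** hold plateau phases (default staging: 0.1 mN/m
  baseline, 10 mN/m after strand addition, 100 mN/m at 45 °C, 300 mN/m
  after cooling) joined by logistic transitions centered 60 s inside each
  new phase and sharp enough (τ = 10 s) that trailing windows are
  plateau-pure; noise is multiplicative with CV 5 %.

What these emulations deliberately lack: thermal fluctuation structure
beyond per-bead Gaussian noise, helical geometry, sequence-dependent
mechanics, fraying, instrument drift, and 2-D AFM artifacts. Passing the
recovery tests therefore shows that the *analysis* is correct and
well-conditioned at realistic noise scales — not that the generators
reproduce real trajectories or instruments.

## Numerical conventions

* 0-based nucleotide indices; oxDNA simulation units in files
  (0.8518 nm each); nm, degrees, seconds, N/m, Pa in all public outputs.
* Versors must be unit length within 1e-6 on read; numeric round trips
  preserve values to ≤1e-9 relative (`%.12g` formatting).
* Geometric base pairing: complementary bases within 1.2 nm, `a1`
  anti-aligned within 30°, displacement along `a1` within 10°; all three
  thresholds configurable. An ambiguous candidate set is an error, not a
  guess.
* Equilibrium statistics default to the trailing 50 % of frames (the
  source says only "at late times"); window fraction configurable, at
  least 4 frames required.
* Degenerate inputs raise: collinear tripod tips, coincident arm
  midpoints, empty phases, porosity width ≥ side, tilt ≥ 90°.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
fixtures sized for a laptop: single F-units (210 nucleotides), single
four-sided pores (420 nucleotides), 200-frame pseudo-trajectories, ~10
seeds per recovery study. These sizes were chosen because every quantity
checked is either a closed form (size-independent) or a recovery whose
error is already far inside tolerance at this scale.

## Known limitations

* The porosity strip formula and the ν/t values in the modulus chain are
  reconstructions (documented above), not measured quantities.
* Placeholder sequences mean absolute Tm values are not comparable to
  measurements on the real construct; only the ordering is asserted.
* Geometric pairing is tuned for idealized fixtures; on real oxDNA
  trajectories the thresholds may need loosening, and design-mode pairing
  assumes the canonical strand layout.
* No 2-D image processing, no MD, no sequence optimization, no kinetic
  hybridization model.
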