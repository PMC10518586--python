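# Methods

This note records the models implemented in `membrane-probe`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## The coarse bead model

The generator builds a hydrated two-leaflet bilayer of point beads in an
orthorhombic box (nm everywhere; electron densities in e/nm³).  Each lipid
is a straight chain of 11 equal-mass beads: the head bead on the leaflet
head plane (default ±1.85 nm) and ten tail beads spaced 0.12 nm toward the
midplane.  With equal masses the lipid centre of mass sits
(11−1)·0.12/2 = 0.6 nm below the head bead, so the centre-of-mass planes of
a default bilayer are at ±1.25 nm and the inter-leaflet COM distance is
2.5 nm.  This offset is deliberate: thickness analyses based on centres of
mass measure a derived quantity, not an echo of the input head plane.

Electron counts per bead are fixed per species in `species_map.yaml`
(editable): the head bead lumps the phosphocholine/glycerol region (164 e),
each tail bead roughly two CH₂/CH units (27 e), water is O (8 e) + 2 H,
DDA beads are CH₂-sized carbons and carboxyl O/H, and a flavonoid is one
150-electron bead.  These values make the trajectory-derived
electron-density profile show the canonical two head-group maxima and
central minimum.

Planted features, realised exactly and recorded in a ground-truth manifest
(molecule ids, planted bond pairs, patch parameters) carried on the
trajectory and written as JSON next to generated files:

- **Thinned patch** — lipids whose head xy falls inside a circle use a
  smaller head-plane offset (default 1.35 vs 1.85 nm), producing a local
  COM-distance of 1.5 vs 2.5 nm (a ~1 nm thinning).
- **DDA aggregate** — vertical 18-bead dicarboxylic chains (two carboxyl
  groups bridged by ten chain carbons) spanning a configurable z-range,
  laterally Gaussian around a centre.  A configurable fraction of molecules
  is placed in pairs whose hydroxyl-H → carbonyl-O geometry is planted at an
  exact O···O distance (0.28 nm) and D–H···A angle (175°).
- **Water wire** — a chain of water molecules with exactly equal O–O
  spacing (0.28 nm) centred on the midpoint of the requested z-endpoints.
  Note that a chain of n waters covers (n−1)·spacing; to span a ±1.0 nm
  hydrophobic slab the default fixtures use 9 waters (extent ±1.12 nm).
- **Bulk water** — uniform slabs mirrored at ±|z| outside the head planes.
- **Flavonoids** — single beads at |z| = head-plane − 0.3 nm, alternating
  leaflets, uniform laterally.

Randomness: one `numpy` Generator per trajectory seed with a documented
draw order (aggregate sites, bulk water, flavonoids, then per-frame lipid
z-jitter).  Jitter is independent N(0, σ) on the z coordinate of every
lipid bead, each frame; planted DDA/water/flavonoid coordinates are static
across frames.  Same spec + seed ⇒ bitwise-identical output.

What the generator does **not** emulate: force-field energetics, bead
dynamics and diffusion, chain disorder and tilt, membrane undulations,
curvature, and realistic water structure.  Passing tests therefore
demonstrate that the *estimators* are correct on data whose ground truth is
known — not that any physical claim about real membranes is reproduced at
molecular-dynamics scale.  Desk-scale systems default to 128 lipids and a
few hundred waters.

## Trajectory statistics

- **Midplane and leaflets**: midplane = mean z of lipid head beads,
  recomputed per frame; a lipid joins the upper leaflet if its head bead is
  above it.  Translation invariant; a one-sided split warns rather than
  fails.
- **Density profiles**: per-frame z-histograms (recentred on the midplane,
  folded by minimum image), divided by bin volume and frame-averaged.
  Conservation is exact: Σ value·bin volume = mean selected count.  The
  electron-density variant weights particles by their electron counts.
- **RDFs**: centre-of-mass pair distances under minimum image, via a
  periodic KD-tree, normalised by the ideal-gas expectation (3D shells or
  lateral annuli).  r_max may not exceed half the smallest box edge.
- **Density maps**: 3D voxel histograms averaged over a frame window
  (default: the last quarter of the trajectory, the convention for
  equilibrated lateral maps), projected parallel (xy) or perpendicular (xz)
  to the membrane plane.  Actual cell sizes are reported because the box
  rarely divides evenly by the requested voxel.
- **Thickness map**: per lateral cell and frame, mean upper-leaflet lipid
  COM z minus mean lower-leaflet COM z, averaged over frames where both
  leaflets populate the cell; cells never populated on both sides are NaN
  and flagged, never zero.
- **Hydrogen bonds**: geometric criterion, donor–acceptor distance
  ≤ 0.35 nm and D–H···A angle ≥ 150° — standard values, both configurable;
  hydrogens are associated to the nearest same-molecule donor oxygen within
  0.115 nm.  The bond graph is simple (best-angle route per O–O pair).
  Intramolecular bonds are recorded but excluded from intermolecular
  counts and cluster edges.  Bond statistics over a frame window (default:
  last three quarters) report mean ± population standard deviation.
- **Clusters**: connected components (networkx) of the molecule graph under
  either the H-bond edge rule or a COM-distance cutoff; the largest
  cluster's z-span measures whether an aggregate crosses the membrane.
- **Water analysis**: penetrating waters are oxygens within |z−z₀| < z_cut
  (default 1.0 nm); a wire is a connected component of the O–O adjacency
  graph (cutoff 0.35 nm) whose z-extent covers the whole slab.  z_cut at or
  beyond the head planes triggers a warning.

File formats: PDB (Å, CRYST1 mandatory; MDAnalysis backend, with a fallback
that applies a file-level CRYST1 record to all models of a multi-model
file), GRO (nm, fixed-width, multi-frame by concatenation; parsed
in-package because the MDAnalysis GRO reader is single-frame), and an
extended-XYZ dialect native to this package (comment line `box="Lx Ly Lz"`,
atom lines `species x y z molecule_id`).  Species and electron counts come
from an editable YAML mapping; unknown residue/atom names are an error that
lists the offenders.

## SAXS

`edp_evaluate` implements the three-step erf profile exactly as written
above; each term is a rectangle of half-width Rᵢ convolved with a Gaussian,
giving the closed-form form factor used everywhere (validated against
quadrature to ≤1e-6 relative).  The modified Caillé structure factor is

    S(q) = N + 2 Σ_{k=1}^{N−1} (N−k) cos(kqd) e^{−(dq/2π)² η γ_E} (πk)^{−(dq/2π)² η},

which at η = 0 reduces exactly to the ideal finite-lattice interference
function (value N² at the Bragg condition).  N is a small fixed integer
chosen by the user (default 10), never fitted; d and η can be refined.  The
intensity combines the Lorentz factor 1/q² with a diffuse (unilamellar)
fraction: I = scale/q² |F|² [f_d + (1−f_d) S].  No beam smearing is applied
by default.

**Fitting.**  Weighted least squares (weights 1/σ_I; where σ_I is absent a
relative 1/I fallback with a floor so exact zeros cannot acquire unbounded
weight), with R-ordering enforced by fitting R₁ and positive increments,
widths and scale bounded positive (σ ≤ 0.6 nm — smearing widths beyond that
are unphysical for a lipid bilayer).  The χ² landscape contains
broadened-step local minima, so the optimiser runs a deterministic seeded
multistart with growing jitter and stops once χ² reaches the level implied
by the stated uncertainties.  Non-convergence is reported through
`success`/`message`.

Two identifiability facts shape the defaults:

1. *Scale degeneracy.*  Rescaling every contrast (ρᵢ−ρ₀) by λ while
   dividing the intensity scale by λ² leaves I(q) unchanged — with
   arbitrary intensity units the profile amplitude is defined only up to
   that factor.  `vary_scale=False` (with a known scale) pins it; the
   parameter-recovery study uses this mode.
2. *Sloppiness.*  Overlapping smooth steps make some parameter combinations
   nearly flat.  The generator's default planted profile
   (ρ = 334, 275, 185, 260 e/nm³; R = 0.55, 1.35, 2.35 nm;
   σ = 0.22, 0.40, 0.45 nm on a 1200-point q-grid over 0.05–6 nm⁻¹) was
   chosen by Fisher-information analysis so that all nine shape parameters
   are identifiable at 1 % relative noise (CRLB ≤ 2.2 %); it corresponds to
   a plausible fluid-phase PC bilayer (head maxima ≈ 409, methylene
   ≈ 319, centre ≈ 260 e/nm³ against 334 e/nm³ water).

The default fit window for measured curves is 0.5–2.5 nm⁻¹ (the standard
analysis range for such instruments); recovery studies on simulated curves
use the full simulated range, where the high-q damping pins the σᵢ.
`edp_report` tabulates profiles on a common grid and derives descriptors
(head-peak position/height, centre density, head width at half prominence);
the head region is a near-plateau, so position changes below 0.02 nm are
reported as "unchanged".

## EPR

Order parameters use the polarity-corrected formula quoted in the README
with the doxyl stearate tensor A_xx = A_yy = 6.1 G, A_zz = 32.9 G — the
standard literature values, which reproduce the bundled reference S values
to ≤ 0.005.  Since S depends on the tensor only through the ratio
a₀/(A_zz − (A_xx+A_yy)/2), `calibrate_tensor` fits exactly that ratio
(linear least squares) and reports an axial tensor with a₀ held at the
nominal doxyl value; the two tensor constants are not separately
identifiable from (splitting, S) pairs.  No additive polarity correction is
applied to A⊥ by default.  τ_c = 1/(6·(D_xD_yD_z)^⅓) requires the
rotational diffusion tensor from a lineshape simulation, which is outside
this package's scope; τ_c is computed only when D values are supplied.

## AFM

Breakthrough detection finds the largest contiguous force drop of at least
50 pN occurring within 0.5 nm of separation (both configurable); the yield
force is the force just before the drop and the thickness is the
separation travelled until the force recovers to the yield level on the
substrate.  Detection is invariant to force offsets.  The synthetic curve
generator places the exact breakpoints on the separation grid, so planted
(force, width) pairs are recovered exactly at zero noise.

The modulus fit is linear least squares of F against δ^{3/2} through the
origin on the pre-breakthrough contact segment (Hertz sphere, ν = 0.5,
optional constant adhesion offset as a DMT-style correction).  Units:
forces in pN, lengths in nm, modulus in Pa (conversion factor 10⁻⁶).

Roughness follows the instrument protocol: random square regions (default
four), each first-order plane-flattened, then R_a = mean|z−z̄| and
RMS = √mean(z−z̄)²; summaries are mean ± standard error over regions (SE is
NaN, never zero, for a single value).  For a sinusoid of amplitude A over
whole periods the discrete RMS equals A/√2 exactly on a uniform grid, and
R_a converges to 2A/π at second order in the pixel size — the closed-form
checks sample one period at 2048 pixel centres, where the discretisation
error is below 10⁻⁶.

## Pipeline

A single YAML file drives simulate → traj-analyze → saxs-fit → epr → afm.
Unknown keys anywhere in the configuration are rejected by name.  One
global seed fans out to per-stage seeds via
`SeedSequence([seed, stage_index])` (indices in `STAGE_ORDER`), all below
2³¹; a rerun with the same configuration is byte-identical up to the
embedded output paths.  Stage failures are isolated, recorded in the
combined JSON report, and raised at the end.

## Problem sizes and limitations

Default study sizes — 128 lipids, a few hundred waters, 1–5 frames, one
SAXS curve of 1200 points, 20-seed recovery ensembles — are desk-scale
choices that keep any single analysis in seconds.  Known limitations:
orthorhombic boxes only; no bond-topology perception from geometry (the
generator's manifest and species tags carry the topology); no triclinic
SAXS smearing or vesicle polydispersity; no acyl-chain order parameters;
EPR lineshape simulation and absolute SAXS calibration are out of scope.
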