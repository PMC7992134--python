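# Methods

## Scope and units

The package analyses labelled molecular geometry: atoms with coordinates,
van der Waals radii, monomer/residue membership, an aromatic/peptide region
tag and optional marker roles. All internal lengths are nanometres; PDB
files (Ångström) are converted exactly once, at the I/O boundary. XYZ files
are read and written in nm. Annotations that exceed the PDB vocabulary live
in a sidecar key/value config (`*.annot`) keyed on atom id; writers always
emit the companion config, so structure + config round-trips preserve every
label exactly and coordinates to PDB precision (1e-4 nm).

Atom radii default to the Bondi van der Waals set (H 0.120, C 0.170,
N 0.155, O 0.152 nm, …) and can be overridden per element in the config.
Hydrogens are retained when present — the hydrogen-bond angle needs them —
and are included in SASA by default.

## SASA (Shrake–Rupley)

Each atom's sphere is expanded by the probe radius (default 0.14 nm, the
common water-probe convention) and sampled with a deterministic Fibonacci
(golden-spiral) lattice, default 960 points; a point is accessible when it
lies outside every other expanded sphere. Occluder candidates are
prefiltered with a k-d tree on centre distances — a correctness-neutral
speedup. Determinism is exact: the same input always gives the same areas.

Numerical properties worth knowing:

- The per-atom area is quantised in units of `4π(r+p)²/n_points`
  (~0.0013 nm² at 960 points for carbon). Per-atom accuracy on nearly
  buried atoms is limited by this quantum; totals over several atoms are
  accurate to a fraction of a percent.
- The lattice is fixed in the **lab frame** by default. This makes
  occlusion monotone point by point when two rigid bodies separate along an
  axis that strictly orders their atoms — the property behind the exact
  monotonicity of covered area along separation paths. The price is that a
  rigid rotation of the whole system can change individual point
  classifications (areas move by a few quanta), as in other sphere-point
  implementations. `orientation="canonical"` instead aligns the lattice
  with the occluder cloud's inertia frame (sign-fixed by third moments),
  making all areas exactly rotation invariant; it is not the default
  because the inertia frame drifts as geometry changes, which would break
  the point-level monotonicity above.
- `monte_carlo_sasa` is a deliberately independent estimator — uniform
  random directions, brute-force occlusion checks, no shared code path —
  used by the tests as an oracle. Its standard error scales as
  `4πR²·sqrt(f(1−f)/n_samples)` per atom.

## Covered area and its decomposition

"In direct contact with the other monomer" is operationalised per atom as
the SASA the partner occludes:

    covered(atom) = SASA(atom | partner deleted) − SASA(atom | full dimer)

summed over a monomer's atoms for CA_i and over region subsets for CA_i,a
and CA_i,p. This definition makes three contracts hold to machine
precision, and the tests assert them at 1e-6 nm²:

- CA_T = CA_1 + CA_2 (definitional),
- CA_i = CA_i,a + CA_i,p + CA_i,other (regions partition atoms; cap atoms
  tagged `other` occlude and count in CA_i but in neither named region),
- CA_T = 0 exactly on dissociated frames: with no cross-monomer sphere
  overlap the two SASA evaluations classify every sample point identically,
  so the difference is exactly zero, not merely small.

Negative per-region sums beyond −1e-6 nm² raise an error (they would
indicate inconsistent inputs); within tolerance they clamp to zero.

## Ring angles

The two ring planes of each monomer (Phe ring; appended aryl ring) are fit
by SVD; each normal's sign is fixed by the Newell polygon normal of the
ring atoms *in their configured order*. Angles are therefore oriented and
live in [0°, 180°]: an angle of 120° is distinguishable from 60°, which an
unsigned plane-plane angle (range [0°, 90°]) could not represent. Two
coplanar rings with the same atom-ordering orientation give 0°. The
reported θ1/θ2 are the intra-monomer inter-ring angles — a conformational
coordinate invariant under rigid motion of either monomer, matching the
observation that the seed-forming dimer has both monomers in the same
conformation with both angles near 120°.

## Population maps

2D histograms over any two record coordinates (default bin width 0.1 nm²;
the nonlinear colour increments seen in published maps are treated as
plotting cosmetics). Frames with CA_T = 0 are excluded and reported as
`excluded_zero_fraction` (percent of all frames); cell values are percent
of included frames and sum to 100 exactly. Degenerate inputs (no included
frames) raise rather than returning an empty map.

## Seed classification

Nested filters in fixed order: (1) D1 < 0.6 nm ∧ D2 < 0.6 nm ∧
CA_T,a > 2.5 nm²; (2) + D3 < 0.8 nm; (3) + both ring angles within
120° ± 20°. Thresholds are strict inequalities, stored in nm (0.8 nm, not
8 Å, per the unit rule). All three occupancies use the total-frame
denominator — dissociated frames included — so that a seed occupancy reads
as a share of total simulation time; a contact-only denominator is
available as an option for workflows that report occupancies among
associated frames only.

The ring-angle plane shows four modes; they are partitioned by one
configurable boundary per axis (default 90°), region 4 (both angles high)
containing the (120°, 120°) seed mode. Boundary ties go to the
lower-indexed region. The regions are configured rectangles, not learned
modes.

## Screw transform and fiber construction

For a two-monomer seed with identical atom ordering, the optimal rotation
mapping monomer 1 onto monomer 2 comes from Kabsch superposition; rotation
plus residual translation decompose into twist about, rise along, and a
point on, the screw axis (the axis point solves `(I−R)c = t⊥` in the plane
normal to the axis). The twist sign is chosen to make the rise positive.
Pure translation degenerates to twist 0 with the axis along the
translation; rotation with near-zero rise (a closed ring) and the identity
transform are rejected as degenerate. `build_fiber` applies the fitted
transform k−1 times to monomer 1, so every sequential pair reproduces the
seed geometry to floating-point precision; any interatomic distance below
0.05 nm raises a steric error naming the pair.

## Helix measurement

Monomer centroids initialise the axis by PCA; because the PCA direction of
a helix sampled over incomplete turns is biased (~0.2% here), the axis is
refined by a cylinder fit that equalises centroid radii
(Levenberg–Marquardt over two axis-tilt and two axis-offset parameters).
Unwrapped centroid azimuths and axial positions are then regressed on
monomer index: `monomers_per_turn = 360°/|slope_φ|`,
`pitch = monomers_per_turn · |slope_z|`. On noise-free constructions the
planted parameters are recovered to ~1e-9; under 0.02 nm coordinate noise
the pitch error stays well inside 5%. Collinear centroids (a twist-free
stack) and fibers of fewer than 6 monomers are rejected.

## Hydrogen bonds

A bond is reported when the donor–acceptor distance is ≤ 0.35 nm and the
deviation of D–H···A from linearity is ≤ 25°. The published cutoff does not
name its angle; the convention here is the angle between the D→H and D→A
vectors, common in trajectory-analysis tools, and configurable. Donors,
hydrogens and acceptors are marker-driven; each donor is paired with its
nearest marked hydrogen of the same monomer (must be within bonding range,
0.15 nm). Intra-monomer pairs are excluded by default. The census splits
counts into the Val-backbone-N → adjacent-monomer Phe-terminal-O class and
everything else. Counts are per structure; published averages over time
come from ensembles, which the generator can supply.

## Exposure fractions

For each residue group (appended aromatic unit, Phe, Val, Asp):
`100 × mean per-monomer group SASA in the fiber / group SASA in the free
reference monomer`. Only interior monomers are averaged (first and last 4
excluded by default, clipped for short fibers) since fiber ends are
artificially exposed; the exact normalisation of the published per-residue
percentages is not printed, so this ratio is the package's documented
definition. Values may exceed 100% by discretisation tolerance only;
larger values raise an error (they indicate a mismatched reference).

## Synthetic data

The generator produces toy monomers, association trajectories and fibers
that are pure functions of their seed (regeneration is bit-identical).

The ~37-atom toy monomer is geometry, not chemistry: an appended two-ring
aromatic unit (`ARO`, 12 C), a Phe ring joined at a planted ~120° biaryl
plane angle (6 C), a 17-atom peptide-region backbone (Phe/Val/Asp with
N, H, O heteroatoms) and 2 cap atoms tagged `other`. All markers are
assigned: D1/D2 on para carbons of the outer appended ring, D3 on a Phe
ring carbon (which specific carbons serve as the D markers is
config-driven; these defaults are the package's documented choice),
donor/acceptor on the Val N/H and Phe terminal O. A seeded 0.004 nm jitter breaks exact symmetry.

Association frames are **constructed, not simulated** — place, orient,
verify — so planted labels are exact counts, not samples:

- *aromatic-stack*: the partner is flipped 180° about an in-plane axis and
  stacked ring-face to ring-face at 0.30 nm. By construction D1 ≈ 0.30 nm,
  D2 ≈ 0.38 nm, D3 ≈ 0.30 nm, CA_T,a ≈ 2.8 nm², both ring angles ≈ 120°:
  every seed filter passes, with margins of several noise standard
  deviations at the default per-atom noise of 0.01 nm.
- *peptide-contact*: the partner is rotated so the backbones run
  antiparallel 0.5 nm apart while the ring systems stay > 0.7 nm from any
  partner atom: CA_T,p > 0 with CA_T,a = 0 exactly, and no filter passes.
- *dissociated*: 2.5 nm centre offset (≥ 1.5 nm surface-to-surface, the
  initial-placement scale of the emulated simulations): CA_T = 0 exactly.
- *mixed* alternates the two contact geometries over the contact frames.

Defaults emulate the conditions of the all-atom study this pipeline
targets, at toy scale: 10 ps frame-spacing metadata, contact fraction
0.681 (the associated share of simulation time observed for the coupled
tripeptide), and 500 frames — the original dimer runs span 300 ns each,
but desk-scale analysis does not need more frames to exercise every code
path.

Fibers are built by applying a planted screw transform directly —
independently of the fitting/building code under test — with default rise
0.3667 nm and twist 60°, i.e. the characteristic regime of 2.2 nm pitch
and 6 monomers per turn. The monomer sits with its aromatic unit near the axis
and Asp outermost, giving an aromatic core whose exposure is measurably
below Asp's. When H-bond planting is on, the template's Val N and H are
repositioned so each monomer donates exactly one ideal-geometry bond
(0.30 nm, 0° deviation) to the previous monomer's Phe terminal O: planted
count n−1 exactly.

What passing tests on this data do **not** show: anything about force
fields, water, kinetics, or the trajectory statistics of real simulations
(dissociated-time fractions, seed occupancies, time-averaged H-bond counts
and exposure percentages of the original 300 ns explicit-solvent ensembles
are properties of those ensembles and are not reproducible from
constructed geometry). The tests show that, given geometry with known
ground truth, every stage measures it correctly. One consequence of the
toy scale worth noting: the helical pair geometry buries ~1.9 nm² of toy
aromatic area per sequential pair — less than the face-to-face dimer stack
(~2.8 nm²) — so consistency checks on fiber pairs use criteria the seed
pair itself satisfies rather than the dimer-screen default of 2.5 nm².

## Pipeline

`run_pipeline` (and `peptifiber run`) reads one TOML config, runs
synth/analyze/popmap/seed-scan/fiber stages (each skippable), and writes
TSVs whose header comments record the generating parameters, plus a JSON
manifest (config hash, input digests, package version, seeds). All
randomness flows from the config's single seed; repeated runs produce
byte-identical TSV and PDB outputs. A failing stage leaves partial outputs
plus a `FAILED` marker naming the stage.

## Known limitations

- Sphere-point SASA only; no analytic surfaces, no solvent-excluded
  surface, no per-point Voronoi weighting.
- Lab-frame lattice: areas are exactly reproducible but not exactly
  rotation invariant unless canonical orientation is requested.
- The screw fit assumes both monomers share atom ordering and conformation;
  strongly deformed pairs will fit poorly (the residual is not currently
  reported).
- PDB chain ids cycle beyond 62 monomers; the sidecar config remains the
  authority on monomer identity. Structures beyond the PDB serial limit
  use hybrid-36 numbering.
- Binary trajectory formats (DCD/XTC), topology files and solvent atoms
  are out of scope.
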