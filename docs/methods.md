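# Methods

## Model and assumptions

The package treats the final binding step of a 1:2 cytokine-receptor
complex as rigid-body association: the cytokine + first receptor (the 1:1
complex) is fixed in space, the second receptor ectodomain R2 is mobile,
and both keep the internal conformation of the deposited 1:2 structure.
This is justified for the systems the method targets, whose isolated
1:1-complex and apo-receptor structures superpose on the 1:2 complexes
within ~1.3 Å Cα RMSD. The transient complex — the late on-pathway
intermediate at the rim of the native energy well — is located purely from
interface shape: no force field, no electrostatics, no membrane model. How
the subunits arrive at the transient complex (3-D or membrane 2-D
diffusion) is deliberately outside the model.

## Structure preparation

PDB files are read with gemmi. Hydrogens and deuteriums are dropped;
alternate locations resolve to the highest-occupancy conformer (ties to the
first encountered); residue numbering follows the file as-is. All
downstream rules operate on heavy atoms of the deposited coordinates:
hydrogen addition and force-field minimization are intentionally not
reproduced, since contacts and axes are heavy-atom quantities and
minimization perturbs them by less than the rule tolerances. This is a
known deviation when comparing printed contact counts for the reference
systems (a few units of N_c). Flexible cytokine N-terminal tails are
handled through a configuration hook: a list of `tail_contact_residues`
whose cross-interface pairs are admitted up to a separate `tail_cutoff`
(default 8 Å — the prepared structure keeps the 1:1-complex tail
orientation, so the contacts formed only in the 1:2 complex lie beyond the
5 Å rule; the exact rule used historically is not recorded, so the cutoff
is exposed as an option). Tail handling is unused by the synthetic system.

## Interface, interaction loci, contact count

* Interface: every cross-subunit heavy-atom pair with native distance
  strictly < 5 Å, sorted ascending (ties broken by atom indices for
  determinism).
* Locus thinning: greedy scan in ascending native distance; a pair is
  retained unless its fixed-side atom lies within 3.5 Å of an already
  *retained* pair's fixed-side atom, or its mobile-side atom within 3.5 Å
  of a retained pair's mobile-side atom. "Preceding pair" is read as
  previously retained pair — standard greedy thinning, which yields a
  maximal set of well-separated loci. Should an atom appear in two retained
  pairs, its contact radius uses the smaller native distance
  (conservative).
* N_c: retained native pairs count while the current distance is ≤ native
  distance + 3.5 Å (inclusive); every other fixed-locus/mobile-locus pair
  counts as nonnative while closer than the sum of the two contact radii
  (half each atom's retained native distance) + 2.5 Å (exclusive).
  Nonnative candidates are restricted to locus atoms. The native
  configuration's retained-pair count and its N_c (which may include
  nonnative contacts formed natively) are both reported rather than
  conflated.

## Configuration sampling

Six coordinates: displacement **r** between binding-surface centroids
(per-side centroids of the unique interface atoms), body axis **e** (unit
normal of the least-squares plane of all interface atoms, both sides,
signed toward the mobile side), spin χ about **e** (χ = 0 at native). The
plane fit uses both sides' atoms; using only the mobile side would tilt
**e** by a few degrees but leaves N_c and the ensemble definition
unchanged. Sampling is uniform — |**r**| by the ball law r_cut·u^{1/3},
**e** by normalized Gaussians, χ uniform on (−180°, 180°] — which makes the
composed rotation (minimal rotation carrying native **e** to the sample,
then spin) exactly Haar-uniform on SO(3); this is asserted against the
(1 − cos θ)/π angle law in the tests.

Clash = any cross-subunit heavy-atom pair closer than `clash_distance`,
checked exhaustively (an early-exit numba kernel, verified against the
O(n²) oracle). The default 2.8 Å lies below the shortest credible native
heavy-atom contact (~3.0 Å), so the native well is never self-rejected; the
value is configurable and the pipeline can report sensitivity to ±0.3 Å.
r_cut is auto-determined as the smallest value on a 1 Å grid (ascending
from 2 Å, ceiling 30 Å) whose pilot-estimated clash-free fraction reaches
1e-4; the pilot size defaults to 1e6 draws per grid value and is
configurable (the historical pilot protocol is unrecorded). Sampling is
streamed in seeded batches; only (r, e, χ, N_c) tuples are stored
(plain-TSV store with a JSON header; floats at 17 significant digits for
bit-exact round trips), transforms being recomposed on demand.

## Transition and transient ensemble

σ_χ is computed per integer N_c bin as the RMS of χ about the native value
0 — the natural width of a well centered on native by construction, robust
to asymmetric distributions; the ordinary standard deviation about the bin
mean is available for comparison. Bins with fewer than 50 configurations
(configurable) are excluded from the fit, and at least 4 usable bins are
required. The two-state form with constant baselines is the default
denaturation-style curve; linear baselines are an option since the exact
historical functional form is unrecorded. Fits use `scipy.curve_fit` with
data-driven initialization (baselines from the bin extremes, midpoint from
the half-height bin), bounds w > 0, and are rejected when they do not
converge, place the midpoint outside the observed N_c range, or invert the
baselines (σ_u ≤ σ_n would mean rotational freedom shrinking as contacts
are lost). N_c\* is rounded to the nearest integer with ties toward the
unbound side (down), erring toward looser configurations for a late
on-pathway intermediate. The transient ensemble is the exact filter
N_c == round(N_c\*).

## Dimer frame and activation angles

Subdomain long axes are the largest-eigenvalue eigenvector of the unit-mass
positional covariance (gyration) tensor — the direction of greatest spatial
extent. Descriptions of this axis in inertia language ("largest moment of
inertia") name the *short* axis of an elongated body; both options are
implemented (`method="gyration"|"inertia"`, default gyration) and the
discrepancy is documented rather than silently resolved. The axis sign
points from the C-terminal-residue centroid to the N-terminal-residue
centroid, so C1/C2 axes point "up", away from the membrane-proximal
C-terminal ends.

The frame: z = C1 long axis; x = component of the native N2 long axis
orthogonal to z (positive along N2); y = z × x; origin at the C1 centroid.
The frame is built once from the native configuration and held fixed while
scoring ensemble members (rotations of R2 are reported relative to R1). γ
is the azimuth of the N2-axis projection minus that of the N1-axis
projection in the x-y plane (counterclockwise about +z), mapped to
[0, 360); φ is the signed angle from the C1- to the C2-axis projection in
the y-z plane (measured from z toward y), in (−180°, 180°]. These
orientation conventions were chosen so that the clockwise (top-view)
self-rotation of R2 on the way to the native complex *decreases* γ and the
scissor closure of the membrane-proximal C-subdomain ends *decreases* φ;
they are locked by regression tests on the synthetic system (including the
y-flip ⇒ φ-sign-flip assertion). Verifying the printed native angles of
the five deposited complexes requires the structures themselves and is
provided as the network-dependent `examples/native_angles_pdb.py`; the
subdomain residue ranges there are plausible fibronectin-III splits, since
the exact historical ranges are unrecorded.

Histograms default to 5° bins; "fraction above native" is computed on the
wrapped difference to the native angle so distributions straddling the
0/360 seam are handled consistently.

## Helical wheel

One TMH residue spans 360/3.5 ≈ 102.86° of helical wheel (103° only in
display rounding); n indels rotate the downstream intracellular machinery
by −n·(360/3.5), counterclockwise-positive in top view, reduced to
(−180°, 180°]. Effects repeat with period 7 (two full turns). Each
receptor's JAK2 is a single azimuth measured from facing its partner;
proximity requires both azimuths within a 30° tolerance of facing. The
baseline (loosely bound, pre-rotation) offset defaults to one half-step,
180/3.5 ≈ 51.4°, counterclockwise of facing on each receptor: under the
exact 102.86° step this is the unique class of offsets for which a
three-residue deletion and a four-residue insertion (identical rotations
mod 360) land the kinases exactly face to face while zero indels stays
outside the tolerance — a diametrically-opposed (180°) baseline would
instead single out −2/+5. Offsets and tolerance are configurable;
symmetric indels are the default and asymmetric ones are supported.

## The synthetic complex: what it emulates and what it does not

The toy system is a rigid two-subunit assembly whose interface is a field
of contact *studs*: ~12 short pegs on each side, facing each other across
3.0–3.8 Å gaps, placed aperiodically (golden-angle azimuths; radii 5–24 Å;
depths varying over 9 Å) with ≥ 7 Å lateral spacing. The aperiodicity and
depth ruggedness are essential: any spin or tilt moves each stud by a
different amount, so the contact set cannot re-form away from the native
registration (a periodic tooth pattern, by contrast, re-registers every
tooth period and shows no rotational-freedom transition). The outer studs
lose contact beyond |χ| ≈ 25–30°, deep studs clash with the partner side's
studs under larger rotations while engaged, and pulling the subunits apart
releases the clash lock before the contacts fully decay — reproducing the
sharp σ_χ rise as N_c falls. Receptor subdomains are helix-like pseudo-atom
rods (carbons at ~1.9 Å spacing, one residue per atom) whose directions
encode the requested native γ and φ; an optional obstruction wall flanks
the C2 rod on its low-φ side across the pull-out range, biasing the
transient ensemble to φ > native exactly as loop-wrapping does in real
interfaces. A polar sector is reserved (stud-free) for the C2 swing path
and the wall.

What the toy does *not* emulate: real cytokine fold topology, side-chain
packing, the gradual contact-count plateau of large protein interfaces
(native N_c ≈ 11 here vs 31–81 for the deposited systems), flexible tails,
or solvent. Passing tests on the toy therefore demonstrate the machinery —
sampling laws, counting rules, transition location, angle conventions,
asymmetry detection — not the numerical values of any real system.

One deliberate difference from production runs: the toy's native well is
made wide (loose stud spacing) so that desk-scale samples populate the
high-N_c bins; its clash-free fraction is consequently above the 1e-4
auto-r_cut floor already at the 2 Å grid start, so toy pipelines fix
r_cut = 8 Å explicitly instead of invoking the auto rule (which is designed
for the tight, low-acceptance interfaces of real complexes and is tested
against closed-form hard-sphere cases).

## Problem sizes and numerical choices

Default scales: production runs collect 8×10⁶ clash-free configurations;
toy pipelines 10⁵ (about a minute on one core; the full test suite and the
acceptance script each run end-to-end toy analyses at this scale). The
two-state fit's parameter-recovery check uses 26 integer bins, 20
replicates, Gaussian noise σ = 2°. Seeds: one root seed per run; grid
pilots and sub-analyses derive child seeds deterministically from it.
Degenerate inputs fail loudly: < 4 heavy atoms or collinear subunits,
near-isotropic subdomains (leading gyration-eigenvalue ratio < 1.2),
axes within 5° of parallel when building the frame, projections shorter
than 1e-8, empty interfaces, native clashes, midpoints outside the
observed range.

## Known limitations

Rigid subunits throughout; no association rate constants (the basal-rate +
electrostatic machinery of the transient-complex rate theory is out of
scope); no structural model of the TMH or JAK2 beyond the wheel arithmetic;
printed reference values for the deposited systems are reproducible only in
network-enabled runs and depend on subdomain-range choices documented in
the example script.
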