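# Methods

## The system and the quantity of interest

GPCR-catalysed nucleotide exchange hinges on the repositioning of the Gα α5
helix inside the cytoplasmic crevice of the active receptor. The far
C-terminus of α5 (GαCT, an 11–19-mer that forms a continuous helix capped by
a C-terminal reverse turn) binds the conserved R³·⁵⁰ arginine and the TM3
capping region around position 3.54. Two successive binding modes exist: a
GDP-intermediate register and the nucleotide-free register, related by a
screw motion of roughly 60° about the helix axis with ~1.5 Å of axial
translation, which shifts every probe contact by one residue toward the
peptide C-terminus. This package quantifies that motion and its interfacial
correlates from structures, pose ensembles and trajectories.

## Geometric core

**Superposition.** `kabsch_superpose` is the weighted SVD Kabsch solution
with the determinant sign correction, so reflections are excluded by
construction. Collinear point sets (second singular value of the
cross-covariance ≈ 0) are rejected rather than silently resolved: the
rotation is not unique there. The implementation is cross-checked in the
tests against `scipy.spatial.transform.Rotation.align_vectors` and against a
brute-force minimum over 10⁶ uniformly sampled rotations.

**Helix axis.** The axis is the total-least-squares line through centroids
of sliding windows of four consecutive Cα atoms. Four is one helical turn
(≈3.6 residues), which cancels the helical wobble of individual Cα positions;
it is the shortest window that makes the centroids nearly collinear for an
ideal helix. The direction is oriented N→C; rise is the mean axial spacing
of consecutive Cα, twist the mean signed angular advance of their
axis-perpendicular projections (right-hand rule about N→C, so a right-handed
α-helix has twist ≈ +100°/residue). A fit RMSD above 1 Å (configurable) sets
a warning flag but does not raise — bent helices are data, not errors.

**Restricted screw fit.** Rotation "about the helix axis" is defined
operationally as the best fit within the two-parameter family
{rotate θ about the axis, translate d along it}. Both parameters are closed
form: d is the mean axial displacement; θ = atan2(Σ û·(pᵢ×p′ᵢ), Σ pᵢ·p′ᵢ)
over the axis-perpendicular components. The residual RMSD of the restricted
fit is reported and is by construction never smaller than the free Kabsch
RMSD (the family is a subset of the rigid motions) — an inequality asserted
in the tests. The free Chasles decomposition (`chasles_decompose`) of an
arbitrary proper transform is provided as an independent cross-check;
below 0.1° of rotation it degrades gracefully to pure-translation form.

For trajectory analysis the axis is fitted once on the reference pose and
held fixed, so the per-frame rotation remains well defined even if the helix
bends slightly; a per-frame-axis variant is exposed as a flag. Angles are
degrees in (−180°, 180°].

## Pose analysis

"Single linkage with a cut-off" is implemented as connected components of
the graph with an edge wherever the pose–pose RMSD is at most the cut height
(1.5 Å default) — the fixed-cut-height behaviour of the classic trajectory
clustering tools; no dendrogram is built because none is consumed. Pairwise
RMSD is computed without re-superposition by default: docking poses share
the receptor frame, so position inside the crevice is part of the distance.
Backbone atoms are the default selection (the choice between backbone and
all-atom clustering is exposed). Cluster ranks are by descending occupancy,
ties broken by lowest member index; the representative is the member with
the smallest summed distance to its cluster mates.

State assignment is contact-register based. A fingerprint records every
(peptide residue, receptor probe position, interaction class) triple; a
state definition maps probe positions (Ballesteros–Weinstein labels) to
expected peptide offsets counted from the C-terminus, which makes Gs- and
Gt-derived peptides commensurable. The defaults are
`empty = {3.50: −1, 3.54: −8}` and `gdp_intermediate = {3.50: 0, 3.54: −7}`;
the register shift is reported relative to the `empty` register (0 or +1).
Contradictory offsets at a single probe, or offsets matching no state,
classify as `other` with diagnostics — never a silent pick.

## Interface analysis

Hydrogen bonds use the common crystallographic heavy-atom criterion:
donor–acceptor ≤ 3.5 Å, plus D–H⋯A ≥ 120° when explicit hydrogens are
present, or the antecedent–donor⋯acceptor ≥ 90° proxy when (as in most
crystal structures) they are not. Donor/acceptor chemistry is a per-residue
name table (backbone N/O plus the standard side-chain sets). Cation-π
contacts require the ring centroid within 6 Å of the cation carbon/nitrogen
(Arg CZ, Lys NZ) and a face-on approach: ≤ 45° between the ring normal and
the centroid→cation direction.

Surface areas are Shrake–Rupley with a deterministic Fibonacci point set
(960 points, probe 1.4 Å, Bondi-style element radii — all configurable),
computed through biotite; buried interface area is the per-complex half loss
(SASA(a)+SASA(b)−SASA(ab))/2, with an apolar variant restricted to C and S
atoms (the hydrophobic-patch contribution). Total burial is the half-burial
doubled; the half-burial is the headline field. Note a numerical property of
any point-count quadrature: the total SASA is orientation-dependent at the
~0.5 % level with 960 points and reaches < 0.1 % invariance only around 10⁴
points; the tests pin both levels. Interface waters are residues named
HOH/WAT/SOL (configurable) whose O lies within 3.5 Å of heavy atoms of
*both* partners — a bridging definition, so bulk and one-sided waters never
count.

## Trajectory metrics and the switch call

Frames are first Kabsch-aligned on the receptor selection, making all
peptide metrics receptor-frame quantities. The RMSD trace to the target
(X-ray-like) pose is computed *without* re-superposing the peptide —
translation within the crevice is the signal. Running averages are centred
moving means with shrunken edge windows (no invented padding). A switch is
called when the smoothed RMSD-to-target drops below 2.0 Å and stays below
for at least 80 % of the remaining frames; the onset is the first such
frame. This persistence rule operationalises "a conformation maintained for
the remainder of the simulation"; the thresholds live in the run
configuration and are echoed into every report. Helix tilt is the angle
between the fitted axis and the membrane plane, the normal defaulting to the
z-axis (the usual MD box convention).

## Synthetic data: what it emulates, and what it does not

The generators replace docking output and MD trajectories that cannot be
redistributed.

* **Ideal helix.** Backbone (+CB) built by internal-coordinate chaining
  (NeRF). Bond lengths are the textbook peptide values (N–CA 1.458, CA–C
  1.525, C–N 1.329, C=O 1.231 Å); the backbone angle N–CA–C is 110.0° with
  φ/ψ defaults −57.7°/−47.5°. This triple was chosen (once, numerically) so
  that the default helix reproduces canonical α-helix geometry essentially
  exactly — rise 1.500 Å and twist 99.6°/residue — because with the
  frequently quoted Engh–Huber value of 111.2° for N–CA–C no φ/ψ pair in the
  helical region yields a rise below ≈1.55 Å. All values are overridable
  through the `HelixSpec` fields and its internal-coordinate table. The
  builder's dihedral conventions are validated against Biopython's
  `calc_dihedral` (IUPAC signs; the default helix is right-handed).
* **Two-register interface scene.** A deliberately minimal receptor
  scaffold — an arginine probe pinned to 3.50 and a main-chain carbonyl
  probe at 3.54, generic numbering supplied by an anchor table — plus a
  GsαCT-like 11-mer (residues 382–392) carrying only the side-chain atoms
  the registers need: the cap tyrosine ring, the Gln amide, and glutamate/
  arginine pseudo-atoms placed *through the planted screw* so that one and
  the same receptor satisfies the `empty` contacts in one placement and the
  `gdp_intermediate` contacts after the inverse 60°/1.5 Å screw. The scene
  tests detector and register logic, not chemistry: side-chain geometry is
  schematic, there is no 7-TM bundle, no membrane, and no claim of realistic
  packing. Bridging waters are placed (seeded, with rejection) within 3.5 Å
  of both partners near the register's hydrogen-bond pair; bulk waters ≥ 10 Å
  beyond the scene radius.
* **Switch trajectory.** The peptide starts in the intermediate register
  and follows θ(t) = 60°·logistic((t−t₀)/w), d(t) = 1.5 Å·(same), with
  i.i.d. Gaussian coordinate noise (σ 0.3 Å default) on the peptide and an
  optional random per-frame global rigid motion to exercise the alignment.
  Defaults: 200 frames at 1 ns, onset 50 ns, ramp width 1 ns — a switch-like
  (fast, then stable) transition. A per-frame ground-truth table always
  accompanies the trajectory; tests compare against it, never against
  re-derived truths.
* **Pose sets.** Cluster centres are distinct screw placements (40° steps
  combined with one `center_spacing` of axial slide, guaranteeing at least
  that RMSD between centres); members add coordinate jitter of σ 0.05 Å —
  tight replicates, small against the 1.5 Å cut height and the ≈2.4 Å
  inter-register separation, so that cluster representatives stay within a
  fraction of a degree of the planted screw. The two-register set uses
  occupancies 11 and 6.

Consequently, a green test suite shows that the *measurements* are correct
on data whose ground truth is known exactly. It does not show robustness to
force-field artefacts, helix fraying, side-chain rearrangement or
partial-occupancy density — none of which the generators emulate.

## Numerical choices and degenerate inputs

Noise-free screw recovery is exact to ~1e-13 and asserted at 1e-6; under
0.3 Å noise the angle estimator's statistical floor on a 44-atom backbone is
σ_θ ≈ 0.3 Å / (r_rms √N) ≈ 1.3°, so noisy recovery is asserted as an RMS
error over 100 seeds (≤ 2° / ≤ 0.1 Å) rather than a per-seed maximum.
Altloc records keep the highest-occupancy conformer (ties by letter order,
logged). Coordinates that do not fit PDB fixed width raise on write instead
of truncating. Empty selections are legal but flagged and warned. The
switch detector requires the series to be at least one smoothing window
long; a constant-zero RMSD trace detects at frame 0 by construction.

## Problem sizes

The default study conditions are desk scale by design: 11-mer peptides
(~60 atoms with scene side chains), 200-frame trajectories, pose sets of
17–20, 100-seed noise ensembles, 10⁶-rotation brute-force grids. The full
test suite runs in about two minutes on one CPU; the acceptance script in
about the same.

## Known limitations

* PDB only; mmCIF, binary MD formats and topology files are out of scope
  (convert upstream).
* BW numbering is anchor-propagated arithmetic, not alignment-derived; it is
  exactly as good as the anchor table.
* The H-bond detector is geometric, not energetic, and trusts atom names for
  chemistry.
* Interface areas depend on the radius set and quadrature; absolute values
  from other radius conventions will differ by a few Å².
* `classify_pose` knows only the registers it is given; novel binding modes
  land in `other` by design.
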