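# Methods

`tfx` re-implements, as a tested library, the computational analysis used to
reconstruct a membrane-embedded complex between a homopentameric nicotinic
acetylcholine receptor (α7 type) and a non-conventional three-finger toxin
(WTX-class): rescoring of ensemble-docking poses against a cryo-EM density
map, interface analytics, binding-curve fits, umbrella-sampling free
energies, channel pore profiling and a sequence charge scan.  The expensive
upstream computations — the FFT docking search, molecular-dynamics
integration, cryo-EM image processing — are inputs, not parts of this
package.

## Structures, units and conventions

Atomic structures are ordered atom lists with Bondi van der Waals radii and
atomic hydrophobicity constants assigned from packaged tables on read
(unknown elements fall back to 1.7 Å / 0 with a warning).  All internal
lengths are Å (GRO nm are converted on read), energies kcal/mol, reaction
coordinates nm, force constants kJ mol⁻¹ nm⁻² (the GROMACS convention the
umbrella inputs use).  PDB parsing resolves altlocs to the highest occupancy
(ties: first in file) and carries insertion codes in the atom key.  Residue
numbering follows the file; toxin literature sometimes numbers from 0, so
selections take a user-supplied numbering offset rather than guessing.

Superposition is the closed-form Kabsch solution with a proper-rotation
correction.  GROMOS conformer clustering is the iterative neighbour-count
rule: the frame with the most neighbours within an RMSD cutoff (default
0.25 nm, computed after superposition on the selection) seeds a cluster;
ties resolve to the lowest frame index for reproducibility.

## Contact taxonomy

Six kinds of intermolecular contact are detected from heavy-atom geometry
(hydrogens are not required — deposited models often lack them):

| kind        | rule (defaults)                                                        |
|-------------|------------------------------------------------------------------------|
| hbond       | donor–acceptor ≤ 3.5 Å, angle at donor (via its bonded heavy neighbour) ≥ 120° |
| ionic       | Arg/Lys/His⁺ N to Asp/Glu/C-term O ≤ 4.0 Å                              |
| ion–dipole  | charged-group atom to uncharged polar O/N ≤ 4.0 Å                       |
| hydrophobic | apolar C to apolar C ≤ 4.5 Å                                            |
| stacking    | ring centroids ≤ 5.5 Å, inter-plane angle ≤ 30° or 60–90°               |
| cation–π    | cation N ≤ 6.0 Å from ring centroid, ≤ 45° off the ring normal          |

These thresholds are artifact choices (the software used in the original
analysis does not publish its cutoffs); all are configurable.  "Specific"
(good) contacts are hydrogen bonds, ionic bridges, stacking and cation–π;
counting deduplicates to residue-pair × kind, so one arginine forming an
ionic bridge, a hydrogen bond and a cation–π interaction contributes three.
A salt bridge whose atoms also satisfy the H-bond geometry is counted under
both kinds, consistently with per-interaction summaries in the field.
Contact lifetimes over a trajectory report per-(pair, kind) occupancy and
the mean maximal run length in ps.

## Surface area and hydrophobicity complementarity

SASA is Shrake–Rupley sampling on a Fibonacci lattice (default 960 points,
probe 1.4 Å).  Interface burial uses the ligand-side convention:
SASA(free ligand) − SASA(ligand in complex).  The molecular hydrophobicity
potential at a surface point is MHP(p) = Σᵢ fᵢ·exp(−dᵢ/α) with α = 2.0 Å and
per-atom-type constants fᵢ from a coarse Ghose–Crippen-style table (apolar
carbons +0.36, carbonyl/carboxylate/guanidinium carbons −0.24, N −0.60,
O −0.45, S +0.40).  Complementarity is an area-fraction score: over the
ligand surface points buried by the receptor, compare the sign of the
ligand-side MHP with the receptor's MHP at its nearest receptor surface
point; score = (matching area − mismatching area) / buried area ∈ [−1, 1].
Whether the original 0.55 threshold used an area-fraction or a correlation
form is not published; the area-fraction form is this package's documented
choice.  Surface-point lattices are generated in a body frame derived from
the structure (principal axes with skewness-fixed signs), which makes the
point-sampled scores exactly invariant under rigid motions of the input.

## Simulated maps, correlation, rigid fitting

Simulated maps are sums of per-atom isotropic Gaussians with
σ = 0.225 × resolution and amplitude equal to the atomic number, on a grid
with default spacing resolution/3, padded and truncated at 3σ (≤ 0.8%
integral loss, within the 2% closed-form check).  Correlation between two
maps resamples both trilinearly onto a common grid over the union footprint
and evaluates either the plain normalised inner product or the Pearson
("correlation about mean") form over a mask.  The mask is the union of the
two maps' own footprints (each thresholded at 0.1 × its maximum by
default) — the union, rather than one-sided masking, makes the metric
symmetric in its arguments.

Rigid fitting is a deterministic steepest-ascent hill climb with step
halving over the six rigid degrees of freedom (initial steps 2 Å / 4°,
convergence at 0.05 Å / 0.1°, bounded iterations), mirroring a bounded
local "fitmap"-style refinement rather than a global search; the metric
never drops below its starting value, and the result reports the net
centroid shift and net rotation angle (from the rotation-matrix trace).
Numerically, each trial transform is evaluated by resampling the *target*
map at the rigidly moved grid points of the once-simulated model map —
identical to re-simulating the model map and correlating, at a fraction of
the cost.

## The post-scoring funnel

Docking poses (rigid transforms placing a ligand conformer onto a receptor
conformer; 14 × 26 conformer combinations × 100 solutions in the original
accounting) pass through five gates in fixed order, each configurable and
individually switchable:

1. **map correlation** — the pose is expanded to the C5 pentamer and its
   simulated 8 Å map must correlate > 0.83 with the experimental map;
2. **required contacts** — the two functionally critical arginines of the
   toxin's central loop must each form at least one specific contact with
   the receptor;
3. **packing** — buried toxin surface ≥ 350 Å², MHP complementarity ≥ 0.55,
   and ≥ 10 good contacts;
4. **refit** — a local rigid refit against the experimental map under the
   correlation-about-mean metric must reach ≥ 0.29 without moving the model
   (shift < 5 Å, rotation < 5°);
5. **filling** — the visual density-filling inspection of the original
   procedure is made computable: *fill* is the fraction of toxin sub-density
   voxels (experimental map above mask, not covered by the receptor
   scaffold's simulated density) lying within 2σ of a toxin atom, and
   *protrusion* is the fraction of toxin atoms outside the experimental
   mask; defaults fill ≥ 0.5 and protrusion ≤ 0.2.

Pentamer reconstruction applies C5 symmetry to the ligand about the
receptor's symmetry axis while keeping the (pre-oriented) receptor pentamer
fixed; rotating the whole two-subunit site complex would double-count
receptor density in the simulated maps.  The receptor's pre-orientation in
the experimental map (via its glycan bulges in the original work) is an
input transform, not computed here.  Metric failures (e.g. a pose with no
interface) fail that pose without aborting the run.  A final orientation
filter implements the NMR-derived restraint: poses are kept only when the
centroid of toxin loop I is strictly nearer the membrane plane than that of
loop III (ties are discarded and logged).

Survivor counts are logged per stage and are non-increasing by
construction.  The survivor counts of the original study (426 → 21 → 4)
depend on its docking output and are not reproduced here; the funnel is
validated instead on a seeded synthetic benchmark (below) where its
verdicts must equal a brute-force evaluation of every criterion for every
pose and exactly the planted pose survives.

## Binding-curve fits

*Vesicle titration*: the apparent free-toxin fraction follows a one-site
Langmuir isotherm p_free(C_L) = 1 − B·C_L/(C_L + K_app); observations are
multiplied by the cumulative dilution factor before fitting.  The exact
isotherm form of the original reference is not reproduced in the text; the
hyperbolic one-site form is the documented choice.

*Competition assays*: the Hill equation, in normalised form
y = 100%/(1 + ([T]/IC₅₀)^nH) or raw form y = A₀ + A₁/(1 + ([T]/IC₅₀)^nH).
Both fits use bounded least squares with IC₅₀ (or K) optimised on a log
scale from four deterministic log-spaced starts spanning the dose range;
fits whose IC₅₀/K land far outside the sampled range, or with vanishing
amplitude, are flagged non-converged rather than reported.  Parameter
standard errors come from the Jacobian at the optimum.

*NMR attenuation*: per-residue relative attenuation is
(1 − I_ves/I_free) normalised to the dataset maximum (reproducing the 0–1
scale of the vesicle-binding figure); residues at or above 0.5 are classed
as membrane-interacting.

## Umbrella sampling and WHAM

Window centres follow the staged scheme of the original pulling protocol:
from the trace minimum (rounded to 0.01 nm), 20 targets at 0.05 nm in
[0, 1) nm, 10 at 0.1 nm in [1, 2) nm, then 0.15 nm steps (43 targets in the
default scheme, 73 in total); for each target the trace sample closest in ξ
is selected, ties resolving to the earliest time.  The PMF is estimated by
the standard self-consistent WHAM equations at 310 K, histograms on a
common grid (default 400 bins), iterated until the per-window free-energy
shifts move < 10⁻⁶ kJ/mol; bins with fewer than 10 total samples are
reported as +∞, because near-empty far-tail bins otherwise produce spurious
minima under the min-zero convention.  The profile zero is the curve
minimum; the bootstrap standard error resamples whole windows (50
replicates, seeded).  ΔG_bind is the mean PMF over the plateau
(ξ > 4.2 nm by default) relative to the minimum, reported with the binding
sign (negative = favourable), with the plateau standard deviation as its
spread.

## Pore profile

At each position along the channel axis, the pore radius is the largest
clearance min_i(|c − xᵢ| − rᵢ) maximised over the in-plane sphere centre c,
via 16 deterministic ring starts (plus the previous slice's centre and the
axis point) each refined by Nelder–Mead — a deterministic replacement for
Monte-Carlo annealing, chosen for testability.  Slices with radius below
the 1.4 Å water probe are classed impermeable; slices that no atoms bound
are capped at 15 Å and flagged.  Open/closed comparisons against reference
channel structures are qualitative (no printed reference radii exist).

## Sequence charge scan

Counts Lys/Arg (His excluded by default, configurable) at user-supplied
alignment positions corresponding to the toxin's membrane-active site, and
summarises per toxin class the fraction of sequences with at least three
basic residues there, displayed as whole percent.  Database-wide tallies
depend on the database snapshot, so sequences are always user-supplied
FASTA; nothing is fetched.

## Synthetic benchmarks and what they do (not) show

The `synth` module generates every pipeline input with known ground truth,
as pure seeded functions (one RNG stream per generator):

* **Toy complex** — a C5 ring of five ~190-atom pseudo-subunits (radius
  25 Å, height 40 Å) with an inter-subunit pocket, and a 66-atom
  three-loop pseudo-toxin.  The pocket and the toxin's central loop carry
  complementary pseudo-residues with standard names — two arginines forming
  salt bridges, hydrogen bonds and cation–π interactions that bridge the
  two subunits, a stacking pair, a serine hydrogen bond, a lysine bridge,
  and apolar filler — so the real chemistry tables produce 11 good contacts,
  ~370 Å² burial and MHP complementarity ~0.87 for the planted pose, which
  passes the default funnel end to end.  Loop I points at the membrane
  plane (z = −5 Å), loop III away.
* **Pose ensemble** — the planted pose at a seeded-random position among
  decoys perturbed by 3–25 Å translations and 10–180° rotations (centroid
  shift ≥ 3 Å guaranteed).
* **Pseudo-experimental map** — the true complex blurred to 8 Å plus 2%
  Gaussian voxel noise.
* **Binding data** — Langmuir titration (K_app 2 mM, B 0.9, dilution
  1 + 0.02·i, noise SD 0.02) on a 0–16 mM lipid grid, and Hill competition
  series on the published dose grids (0.3–50 µM normalised %, 0.01–300 nM
  raw MFI) with the published fit values as ground truth and replicate-scale
  noise (means of 5 replicates at 3% noise).
* **Umbrella windows** — Metropolis samples (burn-in 200, thinning 10,
  proposal SD √(kT/k)) from exp(−(U + bias)/kT) for a stated closed-form U:
  a Gaussian well (depth 10 kcal/mol, width 0.8 nm; exact ΔG_bind = −10)
  under the staged centre scheme with k = 1000 kJ mol⁻¹ nm⁻², 1000 samples
  per window, or a harmonic U for curvature-recovery checks.

The toys are deliberately not physically realistic proteins: there is no
chain connectivity, no excluded-volume refinement and no force field.
Passing tests therefore demonstrate that the geometry, thresholds and
estimators behave correctly on inputs with known truth — not that the
funnel would reproduce the original survivor counts on real docking output,
nor that desk-scale WHAM matches cluster-scale MD energetics.  The problem
sizes used throughout (100-pose benchmark, 57–73 windows × 1000 samples,
960-point surfaces) were chosen as the smallest at which the estimators'
statistical error is clearly below the acceptance bands.

## Known limitations

* Hydrogen-bond geometry is heavy-atom only; explicit-H donors are not used
  even when present.
* The MHP atomic-constant table is coarse (element + functional-group
  level), adequate for sign-based complementarity, not for quantitative
  lipophilicity.
* `fit_rigid` is strictly local; a pose outside the attraction basin will
  converge to a nearby optimum or stall, which the funnel's shift/metric
  gates are designed to reject.
* WHAM assumes uncorrelated samples within windows; the bootstrap SE
  resamples whole windows and does not capture per-bin histogram noise.
* mmCIF, water-mediated bridges, energy-based contact scoring and
  conductance prediction are out of scope.
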