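# Methods

`popshift` evaluates small-molecule binding to a rigid macromolecular pocket
with a semi-empirical pairwise scoring function, turns conformational
ensembles into free-energy spectra, and quantifies ligand-induced side-chain
rotamer population shifts. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic study systems do and do
not establish.

## Scoring function

The binding free energy of a pose is a weighted sum of pairwise terms over
all receptor–ligand atom pairs plus a torsional entropy penalty:

ΔG = W_vdw Σ (A_ij/r¹² − B_ij/r⁶)
   + W_hbond Σ (C_ij/r¹² − D_ij/r¹⁰)
   + W_elec Σ q_i q_j · 332.06 / (ε(r)·r)
   + W_desolv Σ (S_i V_j + S_j V_i) e^(−r²/2σ²)
   + W_tor · N_tor

with the AutoDock4 free-energy coefficients W_vdw = 0.1662,
W_hbond = 0.1209, W_elec = 0.1406, W_desolv = 0.1322, W_tor = 0.2983 and
desolvation width σ = 3.5 Å, all overridable. Pair coefficients derive from
the per-type table (`src/popshift/data/standard.par`, the published
AutoDock4 constants for C, A, N, NA, O, OA, S, SA, H, HD, P, Mg):
r_eq,ij is the arithmetic mean of the self-pair distances, ε_ij the
geometric mean of the well depths, A = ε r_eq¹², B = 2ε r_eq⁶ (minimum −ε at
r_eq), and C = 5ε_hb r_hb¹², D = 6ε_hb r_hb¹⁰ for the 12-10 hydrogen-bond
well, whose parameters come from the acceptor's table row.

Electrostatics are screened by the Mehler–Solmajer sigmoidal
distance-dependent dielectric
ε(r) = A + (ε₀ − A)/(1 + k·e^(−λ(ε₀−A)r)) with A = −8.5525, ε₀ = 78.4,
k = 7.7839, λ = 0.003627 Å⁻¹ (ε(0) ≈ 1.347, ε(∞) = 78.4, monotone).

Deliberate simplifications, documented as such:

* **No angular hydrogen-bond attenuation.** The 12-10 term is purely radial
  between donor/acceptor type classes. Directionality complicates grid maps
  and is not needed for the package's analyses.
* **Additive 12-10 term.** Donor–acceptor pairs receive the hydrogen-bond
  well *in addition to* the 12-6 dispersion term (the original AutoDock4
  code substitutes it). The contract is simpler and the difference is
  absorbed into the configurable table for any recalibration.
* **Per-type solvation parameter.** S_i is taken from the table with no
  charge-dependent augmentation.
* **No distance cutoff** in direct rescoring; the grid box bounds range in
  grid mode. Reproducibility is preferred over speed at this scale.
* **Ligand internal energy is excluded**; the total is intermolecular energy
  plus the torsional penalty, which is the right comparison when ranking
  poses and snapshots of the same ligand.
* **Clamping.** Pair distances are floored at 0.01 Å and every term is
  clamped at +10⁵ kcal/mol, so clashed dynamics snapshots rescore to large
  finite values rather than overflowing.
* Metal ions and waters are carried with role labels and excluded from
  scoring and interaction analysis by default (switchable), matching the
  workflow's treatment of crystallographic Mg²⁺ and waters.

Ki estimation uses Ki = exp(ΔG/RT) with R = 1.9872×10⁻³ kcal/(mol·K) and
T = 298.15 K by default; this reproduces all six of the study's printed
ΔG/Ki pairs within 3%, consistent with an unstated temperature near 298 K.

## Affinity grids

`make_grid_box` tabulates, per ligand atom type, the receptor's 12-6, 12-10
and desolvation fields, plus one electrostatic-potential-per-unit-charge
map, on a regular lattice (defaults mirror the study protocol: 0.375 Å
spacing; the box is centered on the geometric center of a selection or an
explicit point). `grid_score` interpolates trilinearly
(`scipy.interpolate.RegularGridInterpolator`) and is exact at grid nodes
because each map stores the same clamped pair sums the direct route
computes. Off-node fidelity is governed by the curvature of the pair
potential: the agreement band checked in the acceptance suite (≤0.05
kcal/mol at ≥2 Å clearance) holds only where no atom sits on a steep
repulsive wall, which constrains the synthetic pocket design below.

## Pose evaluation tiers

* **rescore** — score the pose exactly as given.
* **refine** — stochastic local descent (accept-if-better perturbations of
  translation, rigid rotation and torsions, with adaptive step size)
  confined to bounds around the input pose; defaults 1 Å translation, 15°
  rotation, 15° per torsion, reflecting a "restricted space" around a
  crystallographic site. The returned score never exceeds the input score,
  and a fixed seed reproduces the trajectory bit-for-bit.
* **dock** — multi-start search over a grid box: random placements inside a
  sampling sphere (uniform position, uniform orientation, uniform
  torsions), the same descent kernel with bounds spanning the box, then a
  deterministic polish. Results are pooled, greedily clustered by pose RMSD
  (2.0 Å default, the common docking convention) in energy order, and
  cluster-best poses are ranked by ΔG.

The descent kernel mixes blockwise moves (translation, rotation or torsion
block per step) with occasional joint moves and with uniform resampling of
torsions (30% of torsion moves) and orientation (20% of rotation moves);
resampling crosses rotameric and orientational barriers that local steps
cannot. Because the trilinearly interpolated objective is piecewise linear,
a single Nelder–Mead run collapses prematurely; the polish therefore
restarts the simplex from the incumbent until no improvement remains, and
the top restarts (5 by default) get a basin-hopping deep polish: eight
random kicks (0.45 Å / 0.25 rad / 12° scale), each followed by restarted
descent, accepted only on improvement. A multi-start kernel with these
escapes was chosen over a genetic algorithm because it is simpler to make
exactly reproducible and is sufficient as a pose generator at this scale; a
GA could be added behind the same contract.

Pose RMSD is computed in the fixed receptor frame with identity atom
mapping and no superposition — the appropriate metric for comparing a
docked pose against a reference pose of the same molecule in the same
coordinate frame. Symmetry equivalences are out of scope.

## Free-energy spectra

Snapshots are selected on a time lattice anchored at the window end (a
"last n ns" phrasing implies trailing windows, and anchoring guarantees the
final frame is included); sampling every 100 ps over the last 9 ns of a
10 ns trajectory yields 90 frames, every 10 ps over the last 1 ns of a 3 ns
trajectory yields 100. Each snapshot is rescored and the scores are
histogrammed with bin centers on integer multiples of the bin width
(default 0.5 kcal/mol), so spectra of different ligands share one lattice.
A raw histogram, not a kernel density, is the default. The most probable ΔG
is the center of the maximal-density bin, ties breaking toward the more
negative bin (conservative toward stronger predicted binding); the best-tail
ΔG is the minimum sampled score. Because the mode is a bin center, the
minimum sample can exceed it by up to half a bin when both fall in the modal
bin; the container's validity check allows exactly that slack. All frames
are weighted equally — no reweighting, no block-averaged error bars.

## Rotamer analysis

Side-chain chi dihedrals (arginine: χ1 N-CA-CB-CG, χ2 CA-CB-CG-CD, χ3
CB-CG-CD-NE, χ4 CG-CD-NE-CZ; table overridable) are measured with the
standard atan2 torsion construction, IUPAC sign, range (−180°, 180°].
Circular histograms live on that range with wraparound-aware, plateau-aware
peak detection (peaks ≥25% of the global maximum by default; a flat
distribution has no peak). The distance between rotamers is the periodic
root-mean-square dihedral deviation (shorter arc per component), a metric
on the 4-torus. Frames from multiple trajectories are pooled before
clustering so cluster indices are comparable across ligand systems;
clustering is average-linkage agglomerative (`scipy.cluster.hierarchy`) cut
at a dihedral-RMSD threshold (default 40°) rather than k-means, because no
cluster count is assumed. Centroids are medoid frames — actually sampled
conformations — avoiding circular-mean pathologies. Cluster ids are dense
from 1 in order of decreasing population. Centroid-to-reference matching
reports the dihedral metric and, when coordinates are available, side-chain
heavy-atom RMSD; neither is silently preferred, since a reference quoted in
Å implies the Cartesian metric while a dihedral-space method sentence
implies the other.

## Interaction profile

Hydrogen bonds: donor–acceptor pairs across the ligand/receptor boundary
with D–A ≤ 3.5 Å and, when the donor hydrogen is explicit, D–H···A ≥ 120°;
donors are heavy atoms with an attached donor-class hydrogen (or typed as
donors), acceptors come from the type table. Contacts: cross-boundary
heavy-atom pairs within 3.9 Å, excluding pairs already reported as hydrogen
bonds, grouped by receptor residue. The geometric criteria follow common
LigPlot-style practice and are configurable; ions and waters are excluded
by default.

## Synthetic study systems

The generators are pure functions of (spec, seed) and define the conditions
under which the quantitative guarantees are tested.

**Toy pocket and ligand.** A 48-atom probe shell (AutoDock type H, r_eq
2.0 Å, alternating ±0.05 e) of radius 8 Å encloses an ion-cradle binding
site: each atom of a four-atom zig-zag probe chain (1.45 Å bonds, one
rotatable bond, charges +0.25, +0.25, −0.25, −0.25 e) rests in a
hemispherical cradle of nine Mg-type sites at 1.65 Å — the Mg/probe pair
minimum — backed by a solid two-layer Mg slab. The design is dictated by
two hard constraints that pull in opposite directions. (a) *Grid fidelity*:
trilinear interpolation error grows with pair-potential curvature, so every
receptor atom must present only its smooth well or tail to any approach at
≥2 Å; H (r_eq,ii 2.0) and Mg (pair minimum at 1.65) satisfy this, while a
carbon-sized atom at 2 Å clearance sits on the r⁻¹² wall where no 0.375 Å
grid is faithful. (b) *A deep, unique optimum*: probe–probe dispersion is
negligible and purely electrostatic confinement is impossible (Earnshaw's
theorem), so the depth and stiffness come from the dense Mg cradle, whose
contacts are simultaneously deep (−0.022·W_vdw kcal/mol each) and smooth.
The cradle-bottom sites carry charges (−0.5, −0.5, +0.5, +0.5 e)
complementary to the ligand: the equal-magnitude ++−− registry is unique —
no shift, end-to-end flip or mirror of the chain pairs the charges
attractively — and the slab removes the cradle underside as a nesting
surface. The optimum returned by the generator is certified by an
exhaustive rigid-translation scan at 0.25 Å resolution within ±2 Å of the
build position and verified to score below 200 random in-cavity
placements.

**Ensembles.** Frames are the complex coordinates plus isotropic Gaussian
noise (default 0.05 Å, a small thermal jitter that keeps per-frame score
spread below the 0.5 kcal/mol histogram bin); an optional two-state switch
makes each frame independently adopt a displaced pose with fixed
probability, producing a bimodal rescored spectrum with known modes.

**Rotamer trajectories.** Chi tuples are drawn from mixtures of von Mises
components (von Mises is the canonical peaked circular distribution; the
default has three well-separated components at κ = 50 ≈ 8° circular spread)
and realized as coordinates by natural-extension placement on an ideal
arginine-like template (fixed bond lengths/angles; only dihedrals matter to
the analyses), so re-measuring the dihedrals reproduces the drawn angles.

**Score samples.** ΔG values are i.i.d. draws from a Gaussian mixture; the
default (means −11/−6 kcal/mol, sd 0.5, weights 0.7/0.3) has a controlled
mode at −11.

What these fixtures do **not** establish: they contain no real protein or
DNA geometry, no force-field realism, no solvent, and no correlation
structure between frames. Passing tests demonstrate that the scoring,
search, spectrum and clustering machinery is internally correct and
reproducible under known ground truth — not that the scoring function is
accurate for any particular complex.

## Problem sizes and tolerances

Default analysis sizes were chosen to characterize each guarantee well at
desk scale: 61³ grid nodes at 0.375 Å; 100 random clear poses for the
grid-equivalence band; 20 docking restarts × 500 descent steps with top-5
deep polish; 500 score samples for mode recovery; 3 × 300 frames for
rotamer recovery; 50 random starts for the refine contract. Numerical
tolerances: term conservation and density normalization at 1e-9;
node-exactness of grids at 1e-9; a full 360° torsion turn restores
coordinates within 1e-9 Å; round-tripped files preserve coordinates and
charges to the three decimals the fixed-column format carries.

## Known limitations

* One ligand copy per run; a doubly-nicked complex with two drug copies is
  modeled by two independent runs.
* Rigid receptor throughout; no ensemble docking, covalent docking, or
  receptor flexibility.
* No symmetry-corrected RMSD; identity atom mapping only.
* No mmCIF or binary trajectory formats; the multi-model PDB dialect with
  `REMARK TIME_PS` stamps is the only trajectory carrier.
* The hydrogen-bond term's lack of angular weighting overestimates
  out-of-plane donor–acceptor geometries in direct rescoring.
* Whether metal ions should contribute to ensemble rescoring is exposed as
  a switch (`include_ions`), default off.
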