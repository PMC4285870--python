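# Methods

This note records the models, algorithms, conventions and deliberate design
choices behind `energyscape`, at the level of detail a user needs to judge
what a result does and does not mean.

## Units and conventions

Energies are dimensionless multiples of the pair-well depth ε and lengths
multiples of the bead diameter σ, everywhere.  Minimum indices are 1-based
in files and in all reported output.  All random operations take an
explicit integer seed and are bit-reproducible: every generator is a pure
function of its arguments, seed included.

## The bead-chain model

Each residue is a single bead labelled B (hydrophobic), L (hydrophilic) or
N (neutral).  The energy is

    U = Σ_bonds     K_r (R − R_e)²
      + Σ_angles    K_θ (θ − θ_e)²
      + Σ_torsions  A (1 + cos φ) + B (1 + cos 3φ)
      + Σ_pairs     4 ε [C (σ/R)¹² − D (σ/R)⁶]

with defaults K_r = 231.2 ε σ⁻², R_e = σ, K_θ = 20 ε rad⁻² (the ε is
implicit in the conventional parameter statement), θ_e = 1.8326 rad.
The nonbonded sum runs over pairs at least 3 bonds apart (configurable).
Coefficients are pure functions of bead labels:

* torsion: if two or more beads of the four-bead window are N, A = 0 and
  B = 0.2 (flexible); otherwise A = B = 1.2 (stiff).  Whether "the beads"
  means all four or only the two central beads is ambiguous in the
  conventional statement of the model; both are implemented
  (`torsion_window="all" | "central"`), the default is `"all"`, and
  neither is asserted as canonical.  Swapping the two outer beads of a
  window never changes (A, B) in either mode.
* nonbonded: B–B pairs attract (C = D = 1); L with L or B is repulsive
  (C = 2/3, D = −1); any pair involving N has no R⁻⁶ term (C = 1, D = 0).
  The 2/3 follows the original statement of the potential.

The sign convention (− D (σ/R)⁶ with D = −1 for L pairs) is the only one
consistent with "L pairs are repulsive, N pairs interact through excluded
volume only".

Evaluation raises an error when any pair distance falls below 10⁻⁶ σ
rather than silently overflowing.  The analytic gradient is exact; the
test suite holds it to ≤ 10⁻⁶ ε σ⁻¹ against central finite differences at
step 10⁻⁵ σ, and energies are rigid-motion invariant to ≤ 10⁻⁹ ε.

**Gō variant.** The Gō version removes the attractive R⁻⁶ term from every
B–B pair that is *not* a contact of a supplied native structure.  Only
pairs eligible as contacts — more than three beads apart along the chain —
are truncated; closer pairs keep their full interaction, so the truncation
rule and the contact definition share one exclusion window.  With a native
map containing every eligible B–B pair, the Gō energy is identical to the
plain model.

**Minimization** uses L-BFGS-B on the analytic gradient with a pure
gradient stopping criterion (function-value tolerance disabled);
convergence means the final gradient infinity-norm is at most `gtol`
(default 10⁻⁶ ε σ⁻¹), and exhausting the iteration budget is flagged,
never silent.  **Basin-hopping** perturbs all coordinates uniformly in
±`step_size`, reminimizes, applies a Metropolis test on minimized energies
at temperature T, and merges duplicate minima when energies agree within
10⁻⁶ ε *and* Kabsch RMSd within 10⁻³ σ.  Enantiomeric minima therefore
stay distinct (equal energy, nonzero proper-rotation RMSd), which is the
physically correct bookkeeping for a chiral chain.

**Interpolated barriers.** `interpolated_barrier` Kabsch-aligns one
minimum onto the other and reports the highest energy along the straight
Cartesian interpolation path.  This is an *upper-bound surrogate* for a
transition-state energy — the straight line generally passes well above
the lowest saddle — and is provided only so small self-contained databases
can be built in-repo.  True transition-state location is out of scope.

## Databases, sublevel sets, barriers

Databases are plain-text tables with the energy in column 1.  Transition-
state rows carry endpoint minimum indices either in columns 4–5 (the full
layout; columns 2–3 and 6+ are preserved opaquely through a round trip) or
in columns 2–3 (compact layout); the layout is inferred from the column
count or forced by flag.  Coordinates ride along either as XYZ-like blocks
or as one flat 3N-value row per minimum.  Floats are written with 17
significant digits, so write→load→write is byte-stable.

A transition state below one of its endpoint energies (a real artefact of
sampled databases) triggers a warning; an optional flag clamps it to the
higher endpoint energy.  Transition states connecting a minimum to itself
are kept on output but ignored for connectivity.  Ties for the global
minimum resolve to the lowest index.

The **sublevel set** at threshold U_t contains every minimum reachable
from the global minimum by a path on which all intermediate minima *and*
all transition states lie at or below U_t.  (Requiring intermediate minima
to qualify, not only transition states, is the stricter of two defensible
readings of "connected below a threshold"; since any valid transition
state lies above both its endpoints, the two readings differ only for
databases with threshold-violating rows.)

The **minimax barrier** between two minima — the smallest possible value
over connecting paths of the highest transition-state energy en route —
is computed by a union-find sweep over transition states in increasing
energy order; the barrier is the energy of the edge whose insertion first
connects the pair.  This is exact, O(m log m), and is verified in the
tests against exhaustive path enumeration.  Barriers are symmetric and
ultrametric: barrier(i,k) ≤ max(barrier(i,j), barrier(j,k)).

## Disconnectivity trees

Thresholds descend uniformly from U_t with spacing ΔU (or a level count;
default 50 levels spanning [global-minimum energy, U_t]).  At each level,
minima are lumped by union-find over transition states at or below the
level.  Internal nodes sit at the *last (lowest) level at which their
descendants are still one cluster*; their children are the sub-clusters at
the next level down.  A leaf hangs from the node where its minimum
separates and is drawn at the minimum's own energy.  A cluster still
unresolved at the bottom level becomes a node there with one leaf per
minimum.  Consequently the lowest-common-ancestor level of any two minima
brackets their minimax barrier to within one ΔU — the discretization gap,
asserted in the tests.

**Funnel coloring** cuts the tree at a reference energy (snapped down to
the level grid), orders the resulting basins by descending size then by
lowest contained minimum energy, and assigns palette colors to basins of
at least `min_basin_size` minima; smaller basins are neutral grey.  A tree
node is colored only if all its descendant minima share a basin.

**Layouts.** The standard layout packs sibling subtrees into disjoint
horizontal spans proportional to their leaf counts (a cosmetic choice;
equal-width packing would be equally valid), children ordered by lowest
descendant energy then lowest index, every node centered in its span — so
the layout is deterministic and no two leaves coincide.  The metric layout
places each leaf at its order-parameter value(s) and each internal node at
the *unweighted arithmetic mean* of its descendant minima's values (the
natural reading of "mean" absent any stated weighting).  One metric gives
a 2D graph; two give a 3D graph, rendered as a static projection with
configurable azimuth/elevation.

## Order parameters

All metrics are invariant under rigid-body motion of the stored
coordinates: contacts and RMSd exactly, PCA projections and Isomap
geodesics up to the alignment tolerance (and a global sign per component).

**Native contacts.** Contacts are bead pairs strictly within 1.167 σ,
excluding pairs within three beads along the sequence (|i − j| ≤ 3).  The
metric for minimum α is N_α/N_NC, the fraction of the reference
structure's contacts realized by α; the reference defaults to the global
minimum, which by construction scores 1.

**RMSd.** d(α, β) = √(Σᵢ‖r_α,i − R r_β,i‖²/N) minimized over proper
rotations and translations via the Kabsch algorithm (SVD with the
determinant-correction branch, so a mirror image is never matched by a
reflection).  The metric is the distance of each minimum from the global
minimum.

**Ensemble alignment.** Before Cartesian PCA or Isomap, the ensemble is
made rotation/translation-free by iterative best-fit: center every
structure, rotate each onto the running average, recompute the average,
and repeat until the drift criterion s — defined here as the mean squared
displacement of the average structure between successive iterations — is
at most 10⁻⁸ σ² (the criterion's exact formula is a documented choice; the
threshold is conventional).  Non-convergence within the iteration cap is
flagged.

**PCA.** The mean-centered configuration matrix (one column per minimum)
is decomposed by SVD; variances use the population normalization 1/N_sp
(fractions are unaffected).  Components are sign-fixed so their
largest-magnitude entry is positive, removing run-to-run ambiguity.  The
i-th metric is each minimum's projection onto component i.  A dihedral
basis — sines and cosines of the N−3 backbone torsions, periodicity-free
and alignment-free — is computed on request, but is deliberately not
offered as a layout metric by default: its variance spreads too evenly
across components to order minima usefully (a flag forces it).  Cartesian
components back-project onto structures as r(λ) = r_ref + λ Q_i; dihedral
components have no direct Cartesian back-projection and are rejected.

**Isomap.** Pairwise distances are fixed-frame conformational distances in
the aligned common frame, scaled to the full 3N space (√N × RMSd) so the
embedded axes share units with the PC metrics; this fixed-frame distance
is a true metric, while per-pair Kabsch RMSd (available via flag) is not
guaranteed to satisfy the triangle inequality.  The k-nearest-neighbour
graph (k = 15 by default; Isomap is reported to be robust to this choice)
is symmetrized by union and weighted by these distances; all-pairs
shortest paths through it approximate manifold geodesics; classical
multidimensional scaling of the geodesic matrix (double-centering,
eigendecomposition, eigenvectors scaled by √eigenvalue, negative
eigenvalues truncated) gives the embedding.  If the neighbour graph is
disconnected, the largest component is embedded with a warning.  In the
linear limit (data in a flat subspace, neighbour graph effectively
complete) the embedding reproduces PCA projections up to rotation and
per-axis sign, which the tests assert via Procrustes.

## Synthetic generators

The generators exist to make every claim testable with known ground truth;
their defaults define the study conditions used by the tests and the
acceptance script.

* **Multi-funnel landscape** (default 3 funnels × 25 minima): funnel f has
  bottom energy −100 + f ε and its other minima drawn uniformly within
  3 ε above the bottom; each funnel is connected by a random spanning tree
  with transition states 0.5–2 ε above their higher endpoint (optional
  extra edges exercise parallel-path logic); consecutive funnel bottoms
  are joined by single transition states at exactly (highest bottom +
  10 ε), so every cross-funnel minimax barrier equals that value and
  lumping just below it returns exactly the label partition.  Coordinates
  are a 48-bead template chain displaced along a planted internal axis by
  6 σ per funnel index plus isotropic noise of 0.5 σ.
* **Planted Gaussian ensemble**: template + Σᵢ √vᵢ zᵢ·axisᵢ with
  orthonormal axes and standard normal z, so the true variance fraction of
  axis i is vᵢ/Σv.
* **Curved manifold**: a circular arc of configurable total winding
  (default 4.5 rad, beyond π so no single linear direction can rank-order
  the samples) in the plane of two orthonormal internal axes, with the arc
  parameter recorded per sample.

All planted axes are projected off the six-dimensional rigid-body subspace
(translations and infinitesimal rotations of the template), and the
template chain is deliberately large (48 beads) relative to the planted
displacements: the rotational realignment that precedes PCA/Isomap is then
near-identity and couples to the planted structure only at second order in
(displacement / chain extent).  With a small template the alignment
visibly leaks planted variance into other modes — a genuine property of
alignment-based configurational PCA, not an artifact of this code — and
the same caveat applies to real data whose conformational changes are
large relative to molecular size.

What the generators do *not* emulate: realistic kinetics, transition-state
geometries (synthetic transition states carry only energies and
endpoints), anharmonic within-funnel structure, or the heavy-tailed
minima distributions of real sampled databases.  Passing the recovery
tests therefore demonstrates the correctness of the algorithms under
controlled conditions, not the scientific conclusions one would draw from
any particular real landscape.

## Problem sizes and tolerances in the shipped checks

The test suite and `scripts/acceptance.py` use deliberately modest sizes —
databases of tens of minima, ensembles of 40–500 structures, 100 random
69-bead conformations for the gradient check — chosen so the whole suite
runs in about a minute while still leaving each statistical check many
standard errors of headroom (e.g. the planted-fraction recovery at
N = 500 is asserted within three empirical standard errors across seeds;
the PC1 funnel-separation ratio comes out around 11).  Brute-force oracles
(breadth-first search, exhaustive path enumeration, Floyd–Warshall,
rotation grid search) bound their fixtures to ≤ 30, ≤ 8, ≤ 50 and 4 points
respectively, where exhaustion is exact and fast.

## Known limitations

* `interpolated_barrier` overestimates barriers by construction; database
  generation via basin-hopping + interpolation is for self-contained
  examples, not production landscape sampling.
* Tree construction discretizes barriers to the level grid; all barrier-
  derived statements carry the ±ΔU quantization.
* Classical MDS can produce negative eigenvalues for strongly non-
  Euclidean geodesic matrices; these are truncated, and strongly curved or
  noisy manifolds may need larger k or more samples for a faithful
  embedding.
* Free-energy (entropy-weighted) graphs, rate annotations, transition-
  state searching and Boltzmann weighting of minima are out of scope.
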