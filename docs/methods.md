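# Methods

`pdmsite` predicts protein–protein interaction (PPI) sites on a protein
surface from the spatial statistics of non-covalent atomic contacts in known
structures. This note documents the model, its parameters, the numerical
choices, and what the synthetic test bed does and does not establish.

## Model overview

The central assumption is physicochemical complementarity: the core of a
PPI interface is packed like a protein interior, so the kinds of atoms a
surface region "expects" to meet across an interface can be read off from
the contact statistics of protein interiors.

The pipeline has five stages:

1. **Typing and labeling.** Heavy atoms are grouped into 30 protein
   chemical classes (backbone NH, carbonyl C, aliphatic CH2, aromatic CH,
   carboxyl O, ...) plus crystal-water oxygen (class 31); each class
   carries a van der Waals radius. Per-atom solvent-accessible surface
   area (SASA) is computed by Shrake–Rupley quadrature. Given unbound and
   complexed structures of the same chain, the fractional buried area is

       dSASA_i = (SASA_u,i − SASA_c,i) / SASA_u,i   ∈ [0, 1]

   and an atom is a PPI-site atom iff dSASA_i > 0. Atoms eligible for
   prediction are surface atoms (SASA_u > 0) of classes 1–30 belonging to
   residues with both backbone dihedrals defined (chain termini and breaks
   are excluded).

2. **Knowledge base.** For every pair of atoms in a reference structure
   set satisfying the contact rule `d ≤ r_i + r_j + 1.4 Å`, not in the
   same residue, more than three covalent bonds apart, and admitted by the
   31×31 interaction filter (value < −0.1), the displacement of the partner
   is recorded in a local orthonormal frame anchored on the centre atom and
   its first two covalent neighbours. Displacements are binned on a cubic
   grid (1 Å spacing, ±8 Å) per (centre class, partner class). In
   strict-interior mode (the default) both atoms must be solvent
   inaccessible, so the statistics come from protein interiors.

3. **Probability density maps (PDMs).** Around a query protein, each
   surface atom places its class's normalized canonical histograms into a
   global grid (1 Å spacing, 6 Å margin) via its local frame, with
   trilinear mass splatting. Grids are averaged over contributing atoms so
   density levels are comparable across proteins, and cells inside the
   protein's van der Waals volume are zeroed. The result is one map per
   interacting class: the expected density of that kind of atom at each
   point of space around the protein.

4. **Feature encoding.** For surface atom *i* and interacting class *j*:
   `S(i,j)` sums map *j* over grid cells within 5 Å of the atom;
   `A(i,j)` is a distance-weighted average of `S(k,j)` over predictable
   surface atoms *k* within 10 Å, with taper `w(d) = 1 − d/10` normalized
   by `Σw`; `A(i,32)` is the fraction of the 10 Å sphere not occupied by
   protein volume (local convexity). Attributes are rescaled to [0, 1]
   by clamp-then-linear against normalization constants `M_min(j)`,
   `M_max(j)`, the medians of per-protein minima/maxima over the training
   collection.

5. **Classification and calling.** One bagged classifier per protein atom
   class: 10 bags, each holding all positive examples plus 1.5× randomly
   drawn negatives (without replacement); members are either a 32-15-1
   feed-forward network with logistic units trained by iRprop− on
   sum-of-squared error for 1000 full-batch iterations (snapshot with the
   best validation MCC, checked every 10 iterations), or an RBF-kernel SVM
   with cost/gamma grid-searched for internal-CV MCC and Platt-calibrated
   probabilities. Ensemble activity is the equal-weight mean of member
   outputs. Activities are converted to confidence levels by a per-class
   lookup table (validation activities binned at width 0.1; confidence =
   true-positive fraction per bin; empty bins linearly interpolated).
   Atoms with confidence > 0.6 seed surface patches, collecting atoms
   within 11 Å with confidence > 0.2; patches whose seeds come within
   10 Å are merged transitively (single linkage — the only
   order-independent reading of pairwise merging). A residue is called
   positive when more than 30% of its surface atoms are patch members;
   ground truth applies the same 30% rule to dSASA > 0 atoms.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| probe radius | 1.4 Å | solvent probe for SASA and the contact tolerance |
| quadrature points | 960/atom | SASA precision (256 in the desk-scale scenario) |
| contact tolerance | 1.4 Å | probe-sized slack on vdW contact distance |
| KB grid | 1 Å, ±8 Å | canonical histogram support; covers the 5 Å feature sphere |
| PDM grid | 1 Å, 6 Å margin | global map resolution |
| density radius | 5 Å | local density sum S(i,j) |
| patch radius | 10 Å | surface-patch aggregation and geometry feature |
| bags / ratio | 10 / 1.5× | class-imbalance treatment |
| ANN | 32-15-1, iRprop−, 1000 iters | per-class classifier |
| seed/member/merge | 0.6 / 0.2 / 10–11 Å | patch calling thresholds |
| residue rule | > 30% | atom-to-residue conversion, both sides |

iRprop− uses the standard constants (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1,
Δmax = 50); weights start uniform(−0.5, 0.5) from a seeded generator, so
training is bit-reproducible.

## Numerical choices

* **SASA** is Shrake–Rupley with a Fibonacci point set. Rigid-motion
  invariance holds exactly when the point set is rotated with the
  structure (`point_rotation`); otherwise agreement is at quadrature
  resolution.
* **Histogram binning** adds a 1e-9 guard before `floor` so displacements
  lying exactly on a cell edge (common in idealized geometry) bin
  identically under rigid motion.
* **Trilinear splatting** conserves each contribution's mass except for
  cells clipped by the grid edge or the occupancy mask; a nearest-cell
  mode exists for oracle tests.
* **Geometry attribute**: the 10 Å sphere may extend past the 6 Å grid
  margin; out-of-grid cells are provably free whenever the margin exceeds
  the largest vdW radius (1.87 Å), so they count as unoccupied instead of
  raising.
* **MCC** uses the zero-denominator → 0 convention. The rank-sum test uses
  the exact distribution below 10 samples per group and the tie-corrected
  normal approximation otherwise.
* **Decision thresholds** are chosen from the sorted unique validation
  activities, maximizing MCC, ties to the lowest threshold; a
  single-class validation set falls back to 0.5 with a warning.
* **Confidence tables and thresholds** are calibrated on pooled
  out-of-fold validation predictions from a 3-rotation fold scheme over
  the per-class training pool; the deployed ensemble is the rotation with
  the best validation MCC. Per-bin confidences from a single small split
  are far too noisy to support the 0.6 seeding threshold.
* **Filter matrix**: the interaction filter is loaded from a 31×31 TSV
  when available; asymmetric input is symmetrized by element-wise minimum
  with a warning. Without a table, an all-admitting matrix is used.

## The synthetic test bed

Real benchmarking requires curated complex datasets. The package instead
ships generators whose outputs exercise every code path:

* **Toy complexes** are two sheet-like chains of idealized residues
  (backbone N/CA/C/O plus one to three correctly named side-chain spheres,
  with a small zigzag so every atom anchors a local frame). A small chain
  B docks knobs-into-holes under a randomly placed footprint of the larger
  chain A, so footprint side chains bury area on binding and the interface
  location carries no positional signal. Footprint residues draw 85%
  long-hydrophobic / 15% long-polar; the background surface draws
  40% / 40% / 20% hydrophobic-long / polar-long / short, so residue type
  frequency alone is only weakly informative and the discriminative signal
  is hydrophobic *clustering*, as in real interface cores.
* **Reference globules** are stacked sheets whose interior side chains are
  mostly hydrophobic and whose surface is mostly polar, giving the
  knowledge base interior-like contact statistics.
* **The end-to-end scenario** (8 reference globules, 14 training and 8
  test complexes, sizes chosen so the whole experiment runs in minutes on
  one CPU) builds the knowledge base, featurizes every protein, trains
  per-class bagged ANNs, calls patches and residues, and pools
  residue-level confusion counts over the test proteins. A permutation
  null repeats training with the label column shuffled over the pooled
  training examples and must score near zero.

What passing shows: the implemented statistics, projections, features,
training, calibration and calling interlock correctly, and the pipeline
recovers a planted physicochemical signal that is invisible after label
permutation. What it does not show: performance on real proteins — toy
geometry has no backbone burial, no waters, no conformational variety, and
its interfaces are far cleaner than transient or polar biological
interfaces, which the underlying approach itself finds hard.

## Known limitations

* The published interaction-filter values are not bundled; the default
  admits all pairs, which only adds (filterable) noise to the maps.
* Water (class 31) appears only as a contact partner; toy fixtures contain
  no waters, so class-31 maps are empty in the scenario.
* The file-based training pipeline persists ANN ensembles only; SVM
  ensembles are available through the library API.
* Atom classes absent from the training set (or single-class after
  labeling) get no ensemble; their atoms never join patches.
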