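# Methods

`mrffit` fits the atomic structures of the subunits of a protein complex
into a cryo-EM density map simultaneously, treating every subunit as a rigid
body. This note records the model, the numerical conventions, and the design
choices where more than one reasonable implementation existed.

## The fitting model

**Per-subunit 6D search.** For each subunit, orientation space is sampled
with a near-uniform set of unit quaternions (7,416 orientations by default)
and, for every orientation, translation space is scanned exhaustively at a
one-voxel interval using FFT cross-correlation. The per-shift score is the
unweighted sum of a density-correlation term and an overlap term:

- CCC = Σ X_i Y_i / √(Σ X_i² · Σ Y_i²), used for experimental maps;
- PCCC, the mean-centered (Pearson) variant, used for simulated maps, where
  it weights surface shape rather than dense cores;
- OV = |X ∩ Y| / |Y|, the fraction of the subunit map's occupied voxels that
  fall inside the experimental map's contour (normalized by the subunit, so
  it is deliberately asymmetric).

The best shift per rotation is kept; poses with OV < 0.5 are discarded
(inclusive boundary: OV = 0.5 survives); survivors are greedily clustered so
that transformed Cα centroids stay ≥ 8 Å apart, and at most the top 100
poses per subunit are retained.

**Summation region.** The sums in CCC/PCCC run over the rotated subunit's
own density footprint — its simulated map thresholded at 3% of its maximum —
with the experimental density zeroed below the working contour (0.5× the
recommended level) and treated as zero outside the map grid. The footprint
is a fixed set per rotation, which is what makes the exact per-shift scores
computable at FFT cost: Σ X, Σ X², and the overlap count under the moving
footprint are each one cross-correlation of a fixed kernel.

**Pairwise interaction scoring.** Every cross-subunit pair of retained poses
is scored with a docking-style energy: Lennard-Jones 12-6 van der Waals with
per-element radii (repulsion capped at +10 per pair, a soft core that keeps
scores finite at overlap), Coulomb electrostatics with the distance-dependent
dielectric ε(r) = 4r and residue-level formal charges, distance-window
hydrogen-bond (N/O pairs at 2.6–3.5 Å, −1 each) and disulfide (S–S at
1.8–2.4 Å, −2 each) terms, and a contact-solvation term (carbon–carbon
contacts < 5 Å rewarded, carbon–polar burial penalized). The combined
physics energy f_ph is the unweighted sum of the four terms; the steric
clash count f_cl (heavy-atom pairs < 3 Å) is kept separate. All terms are
exactly zero beyond a 10 Å minimum-atom-distance cutoff, enforced cheaply by
a bounding-sphere test. The functional forms and parameters are this
package's own concrete choices; they follow the standard five-term structure
of protein–protein docking scores but are not calibrated against any
published docking potential.

**Markov random field and log-linear energy.** Subunits are single nodes
whose states are their retained poses; every unordered subunit pair is an
edge. A complete assignment X₁..X_N is scored by

    E(X) = Σᵢ [ w_cc·(−CC(Xᵢ)) + w_ov·(−OV(Xᵢ)) ]
         + Σ_(i,j) [ w_ph·f_ph(Xᵢ,Xⱼ) + w_cl·f_cl(Xᵢ,Xⱼ) ]

with default weights w_cc = 0.5, w_ov = 0.9, w_ph = 1.0, w_cl = 0.8. Every
term is an energy (lower is better); the model probability is ∝ exp(−E) and
the partition function is never computed because only MAP-style inference is
needed. Negating CC and OV is a deliberate orientation choice: the
log-linear exponent must *reward* good fits, so the fit scores enter with a
minus sign and the optimal conformation is the global energy minimizer.

**Inference and top-K extraction.** Max-sum (min-sum on energies) belief
propagation runs in a single pass of two phases: single nodes send their
per-pose energies to the pairwise nodes; each pairwise node (i, j) sends
back to i, for every pose of i, the minimum over j's poses of (edge energy +
j's belief); final beliefs are initial beliefs plus incoming messages. For
two subunits this is exact; on loopy graphs (N ≥ 3) single-pass beliefs are
approximate. The top-K assemblies are therefore extracted by a best-first
heap search over partial assignments: the priority of a state is the exact
energy of its assigned part plus an admissible lower bound on the remainder
(each unassigned node's best pose conditioned on the assigned neighbors,
plus the unconditioned minima of edges between unassigned pairs). Complete
assignments pop in exact energy order, so the output is the true top-K by
the exact energy, verified against exhaustive enumeration. Energy ties break
lexicographically on pose indices; the whole stage is deterministic.
Models whose total cross-subunit clash count exceeds 10% of the assembly's
heavy-atom count are discarded and the search continues; if no clash-free
model exists the stage reports that explicitly rather than emitting one.

**Evaluation.** A model is compared with the reference complex by a single
global Kabsch superposition over all Cα atoms; when chains with identical
residue sequences exist, all chain permutations within identity groups are
enumerated and the minimum RMSD is reported. The Assembly Placement Score is
computed after that global superposition: per subunit, the centroid shift
(Å) and the rotation angle (degrees, the geodesic angle of the subunit's own
optimal superposition, axis ignored); the two APS numbers are the
residue-count-weighted means of the shifts and of the angles. Averaging the
angles arithmetically (not as rotation compositions) is a stated convention.

## Numerical conventions

- Quaternions are scalar-first (w, x, y, z), unit norm, active rotations;
  coordinates transform as x ↦ R(q)x + t.
- A voxel center is at origin + index·voxel_size (grid-node convention;
  no half-voxel offset). Map I/O honors MAPC/MAPR/MAPS permutations, ORIGIN
  and N*START, and normalizes to an X-fast layout.
- Map simulation places an isotropic Gaussian on every heavy atom with
  σ = resolution / (2√(2 ln 2)) (resolution read as FWHM), weighted by
  atomic mass, normalized so the discrete density sum approximates the total
  weight (conserved to <1% for padding ≥ 2× resolution); kernels are
  truncated at 4σ. Hydrogens are ignored.
- FFT scans zero-pad to the full linear-correlation size (no wrap-around
  aliasing) and agree with a direct per-shift evaluation to ~1e-15; shifts
  whose correlation denominator falls below 1e-9 of its per-scan maximum are
  treated as undefined (the exact-zero case contaminated by FFT roundoff).
  Score ties at the scan stage break on lexicographic (z, y, x) shift order.
- The orientation sets are generated with the super-Fibonacci spiral on the
  quaternion sphere — deterministic, any requested size, exactly 7,416 by
  default — with signs canonicalized so q and −q never both appear. The
  advertised covering radius is estimated empirically (2,000 Haar-random
  probes, 1.25× safety margin).
- The "recommended" contour level of a simulated map, where no depositor
  value exists, is the level whose super-level set holds 95% of the total
  density mass; the working contour is 0.5× that.

## The synthetic benchmark

`make_toy_complex` builds deterministic pseudo-proteins: self-avoiding Cα
walks (3.8 Å steps, ≥4 Å self-distance) with directional persistence inside
a 12 Å sphere, decorated with backbone-like N/C/O atoms and cyclic residue
identities. Persistence matters: a featureless near-spherical globule fits a
10 Å density equally well in many orientations, which would make planted-pose
recovery ill-posed; bent, elongated shapes carry orientation signal.
Subunits are packed by sliding along candidate directions until docking
contact (minimum cross distance 3.4–5.0 Å) and keeping the direction that
maximizes interface contacts within 6 Å — complexes with substantial
interfaces, zero clashes, and a unique native arrangement. A duplicate-chain
mode reuses one chain's shape and sequence to exercise the permutation
metric path.

`make_benchmark` simulates the reference map (defaults 10 Å resolution,
1.0 Å voxel, 8 Å box margin) and scrambles every subunit with an independent
seeded random rigid transform (Haar-uniform rotation, translation uniform in
a cube of half the map diagonal); the exact inverse transforms are recorded
as ground truth.

What the toys do not emulate: real secondary structure and side-chain
packing, heterogeneous subunit stoichiometry, experimental map noise,
B-factor/resolution anisotropy, and partial occupancy. Passing the planted
recovery therefore demonstrates the machinery (search, scoring, inference,
extraction, metrics) under clean conditions, not accuracy on experimental
maps.

## Problem sizes

The standard end-to-end check uses 3 subunits × 40 residues (≈480 heavy
atoms), a map of ≈50–70 voxels per axis at 1.0 Å, and 576 near-uniform
rotations plus the planted orientations — a deliberate desk-scale stand-in
for the full 7,416-orientation search, which behaves identically per
rotation and is exercised for size and uniformity separately. The test suite
completes in minutes on one CPU.

## Known limitations

- The physics parameters are plausible but uncalibrated stand-ins; absolute
  energies are not comparable with any published docking score.
- Belief propagation runs for a single pass and is not iterated to
  convergence; exactness of the output is guaranteed by the heap search, and
  beliefs are not probabilities.
- Anisotropic voxels are supported in map I/O but not in the FFT search.
- No sub-voxel translational or local rotational refinement of poses.
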