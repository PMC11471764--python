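# Methods

## Model and assumptions

The toolkit treats a protein as a harmonic bead-spring network on its
C-alpha trace. Fluctuations about the native structure are Gaussian and
isotropic; the only structural input is the native contact topology
(plus native bond directions for the anisotropic Hessian). This buys
speed and determinism at a known cost: there are no side chains, no
sequence-specific interaction energies, no solvent, and no kinetics —
"thermal unfolding" is an ordering of bond ruptures by equilibrium
fluctuation amplitude, not a temperature-calibrated trajectory. Bonds
break irreversibly, one per step (the argmax of the criterion), and
never re-form; backbone springs are unbreakable.

The native geometry is kept for all mode and shear calculations even as
the topology loses bonds: the partially broken network is always
evaluated at native coordinates. This is the standard elastic-network
idealization — modes of the damaged topology about the intact geometry —
and is what makes the floppy-mode count a purely topological-geometric
order parameter.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| r_c | contact cutoff (Å) | 7.0 | standard C-alpha GNM cutoff |
| c | backbone/contact stiffness ratio | 9.3 | published CI2-family value; 2.3 for the barnase family |
| κ | contact spring constant (k_BT/Å²) | 0.493 | published CI2-family value; 0.945 for barnase; both from B-factor fits |
| floppy threshold | absolute Hessian eigenvalue below which a mode is floppy | 1e-4 | applied to H in the units where κ multiplies Γ |
| shear amplitude | displacement amplitude per unit-norm soft mode (Å) | 1.0 | shear is used comparatively (peaks, rankings, correlations); any fixed small amplitude preserves rankings, and tests verify the quadratic leading-order scaling |
| weight ramp | neighbourhood weight for the deformation gradient | 1 below 6 Å, linear to 0 at 8 Å | results are insensitive to the weight provided neighbourhoods are large enough |

`fit_bfactors` can re-derive (c, κ) for a new structure: c is scanned
over {1.0, 1.1, …, 20.0} (the κ-independent shape [Γ⁺]_ii is correlated
with the experimental B-factors) and κ follows per c from a closed-form
least-squares scale match of B_i = (8π²/3)(3k_BT/κ)[Γ⁺]_ii. The fit is
optional; the published family constants are the defaults.

## Numerical choices

- **Pseudoinverse.** Γ is always singular (≥ 1 zero mode; more after
  fragmentation). Γ⁺ is computed by symmetric eigendecomposition with
  eigenvalues below 1e-10·λ_max treated as exact zeros. A test confirms
  agreement with the ε-regularized solve (Γ + εI)⁻¹ projected off the
  null space on small networks.
- **Tie-breaking.** Criterion values within 1e-9 (relative) of the
  running maximum count as tied and the lexicographically smallest (i, j)
  breaks. Symmetric toys genuinely tie; the tolerance keeps the choice
  stable under floating-point noise, and the brute-force oracle used in
  testing applies the same rule.
- **Force balance.** Static displacements exist only if the net force on
  every connected component vanishes; otherwise the engine raises an
  explicit error (and a force-mode run ends if the pulled termini ever
  separate — impossible while the backbone is intact, but handled for
  networks built without a full backbone).
- **Deformation gradient regularization.** If the neighbourhood matrix
  D_m is (near-)singular — collinear or coplanar neighbourhoods, e.g.
  terminal residues of a straight chain — a ridge of
  1e-8·trace(D_m)/3 is added and the residue flagged.
- **Soft-mode set for shear.** All modes with λ < 1e-4 are summed. If
  that set is only the six rigid-body modes (whose shear vanishes
  identically), the field falls back to the 20 lowest non-floppy modes
  and flags the run (`fallback_lowest_nonzero`). Real 7-Å C-alpha
  networks are often genuinely under-constrained and have soft internal
  modes in the native state; compact over-constrained toys (and some
  native structures) do not, and the fallback makes the native shear
  well-defined in both regimes while reporting which path was taken.
- **Log of zero shear.** Residues with s_m below 1e-300 are excluded
  from log-shear correlations and counted in a reported exclusion tally.
- **Shear energy form.** s_m is the squared Frobenius norm of the
  deviatoric strain, Σ_ij (γ_m)²_ij.
- **Floppy counting.** Modes are counted by threshold only; degenerate
  eigenvalues need no tie-breaking. Both the absolute count and the
  fraction f_abs/3N are exposed (curves use the absolute count by
  default).

## Region schemes and pathway encoding

Secondary-structure element labels come from a per-residue TSV
annotation (residue_id, label) — deliberately decoupled from any DSSP
run. Three schemes map a residue pair to a region:

- **ci2** — the five named regions (N-terminus–β3, α–loop2, β1–β2,
  β2–β3, rest) with canonical element names `nterm, alpha, beta1, beta2,
  beta3, loop1, loop2`.
- **barnase** — all unordered pairs of the nine named elements
  (N-terminus, three helices, three strands, two loops) are enumerated,
  pairs with no native contact dropped, and the 29 most populated kept
  plus "rest", for 30 regions. This is a documented reconstruction of a
  contact-map clustering whose exact original partition is not
  recoverable from its description.
- **generic** — all unordered pairs (including self-pairs) of whatever
  distinct labels the annotation provides, plus rest; used for synthetic
  structures.

Across a family the trajectory length N_b is fixed; shorter trajectories
are padded with all-zero rows (breaking the one-hot row invariant, which
is recorded as a padding count), longer ones truncated. The family
matrix is N_p × N_b·N_r; both its covariance and correlation are emitted.

TM-score is computed on a **supplied** correspondence (identity by
position for equal-length families) with d0 = 1.24(L−15)^⅓ − 1.8 floored
at 0.5, maximized by the standard iterative-cut Kabsch refinement seeded
from the full correspondence and contiguous fragments. No alignment
search is performed. The floppy-curve "divergence" between two runs is
defined here as the root-mean-square difference of the linearly
interpolated f(⟨z⟩) curves on a common ⟨z⟩ grid — an artifact definition,
since divergence is otherwise only described qualitatively.

## Synthetic structures: what they do and do not emulate

The fixtures provide geometry with known rigidity theory: an equilateral
triangle and the Boerdijk–Coxeter tetrahelix are isostatic (exactly 6
zero modes at the 5 Å cutoff that captures only tetrahedral edges), the
shared-edge hinge has exactly 7 (one internal hinge rotation), an open
generic chain 2N+1, and the serpentine lattice fold is a compact,
contact-rich stand-in for a small folded domain. Small seeded coordinate
jitter (0.03–0.08 Å) keeps regular placements generic without crossing
any contact-distance margin.

`make_family` perturbs a template by displacing a chosen fraction of
residues (Gaussian, σ = 1.5 Å — enough to make and break 7 Å contacts),
emulating a family that shares a fold but differs in local packing. What
the toys do **not** have: realistic secondary structure, heterogeneous
contact energies, loop anisotropy, or the strongly non-uniform shear
landscape of real proteins. Passing tests on toys therefore validate the
algorithms and their invariants — argmax selection, bookkeeping, mode
counts, strain algebra, the direction of the structure/pathway
relationship — not the quantitative correlation values reported for real
structures, which require the actual PDB entries (see README).

## Problem sizes

The test-suite and acceptance-script runs use a 27-residue lattice fold
(132 native contacts), 20 random toy networks of 5–12 residues for
oracle equivalence, and a family sweep of 50 seeded 3-member families at
rewiring rates {0, 0.2, 0.5} with 25-event pathways — sizes at which the
brute-force oracles (full per-step pseudoinversion, dense rotation-grid
TM search) remain exact and cheap, so every comparison is against an
independent computation rather than a stored expectation.

## Known limitations

- One bond per step; no rupture of several bonds crossing a threshold
  simultaneously, and no bond re-formation.
- The thermal algorithm orders ruptures but carries no temperature or
  time scale; the force algorithm uses a fixed load, not a loading rate.
- Force direction is the x axis of the input frame (recorded in run
  metadata); structures are not re-oriented.
- Anharmonicity, distance-dependent spring constants and crystal-contact
  corrections to B-factors are out of scope.
- mmCIF input, multi-model ensembles (first model only) and automatic
  sequence alignment for correspondences are not provided.
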