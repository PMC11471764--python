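# enm-unfold

Elastic-network simulations of protein unfolding for structural
bioinformaticians who want coarse-grained, native-topology-driven
unfolding pathways without molecular dynamics: thermal and force-induced
bond breaking on a Gaussian Network Model (GNM), soft-mode shear fields
that localize the floppy regions of a structure, floppy-mode counting as
a global unfolding order parameter, and region-wise pathway encoding for
comparing how members of a protein family unfold.

## Model

A protein chain is reduced to one bead per residue at the C-alpha
position. Beads within a cutoff r_c = 7 Å are joined by springs of
constant κ; consecutive residues by stiffer backbone springs cκ. The
topology lives in the Kirchhoff matrix Γ:

    Γ_ij = −c  if |i−j| = 1
    Γ_ij = −1  if |i−j| > 1 and r_ij < r_c
    Γ_ij =  0  otherwise,          Γ_ii = −Σ_{j≠i} Γ_ij

**Thermal unfolding.** Distance fluctuations follow from the
pseudoinverse of Γ,

    ⟨(ΔR_ij)²⟩ = (3 k_BT / κ) ([Γ⁺]_ii + [Γ⁺]_jj − 2 [Γ⁺]_ij),

and at each step the non-covalent contact with the largest fluctuation
breaks; Γ is updated and the fluctuations recomputed. Backbone springs
never break.

**Force-induced unfolding.** Unit forces ±x at the chain termini produce
static displacements u = κ⁻¹ Γ⁺ F (per Cartesian component); the contact
with the largest stretch |u_i − u_j| breaks each step.

**Floppy modes.** The anisotropic (ANM) Hessian H_ij = κ Γ_ij n_ij n_ijᵀ
on the native bond directions is diagonalized after every event; modes
with eigenvalue < 10⁻⁴ are floppy. A connected rigid body has exactly 6
(rigid-body translations/rotations); every extra floppy mode is an
internal zero-energy motion, so the floppy count f traces the loss of
rigidity as the coordination number ⟨z⟩ = 2·bonds/N falls.

**Shear field.** Each soft mode, applied as a small displacement of the
native coordinates, defines a local deformation gradient
F_m = A_m D_m⁻¹ around every residue (weighted over neighbours within
8 Å), an Eulerian strain ε = ½[I − (FFᵀ)⁻¹], and a shear energy
s_m = Σ_ij (γ_m)²_ij from the deviatoric part γ = ε − ⅓ tr(ε) I. High
native shear marks the regions where bond breaking starts, so log s_m
anti-correlates with the mean bond-breaking order of a residue.

**Pathway comparison.** Each breaking event is assigned to a structural
region (a pair of secondary-structure elements); the one-hot N_b × N_r
encoding, flattened, gives one vector per protein, and the family-level
correlation matrix of these vectors quantifies pathway similarity, set
against the TM-score of the native structures on a supplied residue
correspondence.

## Worked example

    enm-unfold fixtures --kind lattice-fold --n 27 --seed 1 --out toy.pdb
    enm-unfold run --pdb toy.pdb --mode thermal --c 2 --kappa 1 --rc 7 \
                   --ss toy.pdb.ss.tsv --out run1

    lattice-fold toy with 27 residues written to toy.pdb
    toy: N=27 residues, 132 native non-covalent contacts
    132 bonds broken; outputs in run1

`run1/events.csv` records one row per broken bond — its residue pair, the
fluctuation that selected it, and the bookkeeping series Q (fraction of
native contacts left), ⟨z⟩ and floppy count f:

    step,i,j,criterion,Q,z,f
    1,1,18,0.576657067,0.9924242424,11.62962963,6
    2,1,6,0.6255257475,0.9848484848,11.55555556,6
    3,1,13,0.6498050111,0.9772727273,11.48148148,6

After all 132 contacts break, only the backbone remains: Q = 0,
⟨z⟩ = 2(N−1)/N ≈ 1.926, and f = 2N+1 = 55 floppy modes, the exact count
for an open generic chain. `run1/report.json` summarizes the run:

    "shear_order_pearson_r": -0.4142669006998333

i.e. residues with high native shear break their bonds early (negative
correlation between log native shear and mean breaking order). The
compact lattice toy is over-constrained in its native state (only the 6
rigid-body soft modes), so the native shear falls back to the 20
lowest-lying modes and says so
(`"native_shear_fallback_lowest_nonzero": true`).

Family comparisons take two or more completed runs:

    enm-unfold family --run run1 --run run2 --out fam

writing pathway covariance/correlation matrices, TM-scores, and the
pairwise divergence of the floppy-mode curves f(⟨z⟩).

## Layout

- `enmunfold.structure_io` — PDB C-alpha reading/writing, contact lists, tabular outputs
- `enmunfold.network` — Kirchhoff matrix, pseudoinverse fluctuations, ANM Hessian, floppy modes, B-factor fitting
- `enmunfold.unfolding` — thermal/force bond-breaking engine and trajectory bookkeeping
- `enmunfold.shear` — deformation gradients, Eulerian strain, soft-mode shear fields
- `enmunfold.pathways` — region schemes, pathway encoding/covariance, TM-score, floppy-curve divergence
- `enmunfold.fixtures` — synthetic structures with analytically known rigidity
- `enmunfold.cli` — `enm-unfold run | family | fixtures | fit-bfactors`

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
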