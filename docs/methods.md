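# Methods

## The prediction problem

An NMR spectrum assigns each magnetically active nucleus a chemical shift
δ (ppm): ¹³C shifts span roughly 0–200 ppm, ¹H shifts roughly 0–10 ppm.
For carbohydrates, small stereochemical changes (for example the anomeric
configuration) ripple through the shifts of every atom, so a useful
predictor must see the three-dimensional structure, not just the bond
graph.  The observed quantity, the isotropic shift, is a scalar: it cannot
change when the molecule is rotated, translated or mirrored.  The model is
therefore built to be exactly invariant under the Euclidean group E(3) by
construction, not by data augmentation.

## Model

Molecules are heavy-atom graphs.  Hydrogens are folded into a per-atom
attached-hydrogen count N^h; each node carries learned embeddings of its
element Z and of N^h (concatenated, 128 dimensions in the full model).
Edges connect all atom pairs within a cutoff radius r_cut = 6 Å plus all
bonded pairs, in both directions; each edge carries an invariant feature
(Emb(E_ij) ‖ d_ij) — a learned bond-category embedding (none / single /
double / other) concatenated with the raw Euclidean distance — and the real
spherical harmonics Y_ℓ(r̂_ij) of its unit direction up to ℓ = 2.

Node features are geometric tensors: concatenations of irreducible-
representation blocks (ℓ, parity) with multiplicities; the full model's
hidden layout is 64×(0,e) ⊕ 32×(1,o) ⊕ 8×(2,e).  Each of the K = 7
attention layers computes, per directed edge i←j,

    q_i  = Linear(x_i)                 (irreps-wise linear map)
    k_ij = x_j ⊗_{w_k(e_ij)} Y(r̂_ij)
    v_ij = x_j ⊗_{w_v(e_ij)} Y(r̂_ij)

where ⊗_w is the equivariant tensor product with per-edge path weights
generated by small MLPs of the invariant edge feature.  The attention logit
is the summed scalar channel of q_i ⊗ k_ij — per irrep block, the
multiplicity-mixed inner product with learned mixing weights, scaled by
1/√dim; a max-subtracted softmax over each node's neighbors yields α_ij,
and the
aggregated message is Σ_j α_ij v_ij.  The update is an equivariant
feed-forward (linear → gate → linear) plus a residual connection, followed
by equivariant layer normalization.  After the last layer an irreps-wise
linear map extracts a 128-dimensional scalar vector, and two two-layer MLP
heads (hidden width 384, SiLU) emit one value per node per nucleus.

Numerical and design choices the architecture leaves open:

* **Tensor-product connectivity.**  Path weights follow the
  one-weight-per-multiplet ("uvu") convention, with the multiplicity mixing
  delegated to the irreps-wise linear layer that follows the product.  This
  is the standard construction in equivariant interaction networks and is
  markedly cheaper than a fully connected product at equal expressivity of
  the layer pair.
* **Gate nonlinearity.**  A plain SiLU cannot act componentwise on ℓ>0
  blocks without breaking equivariance; the feed-forward therefore uses the
  gate construction: SiLU on scalar channels, and each ℓ>0 multiplet
  multiplied by the sigmoid of a dedicated scalar gate channel.
* **Layer normalization.**  Scalar channels are standardized with the
  population variance over the channel axis; each ℓ>0 block is divided by
  the root-mean-square of its multiplet norms (ε-guarded so zero blocks
  stay zero) and scaled by a learned per-multiplet gain.  Directions are
  preserved exactly.
* **Harmonic conventions.**  Real spherical harmonics with unit L2 norm per
  ℓ-block on unit input; ℓ = 1 components ordered (y, z, x); parity
  (−1)^ℓ.  Real coupling coefficients are constructed numerically at import
  as the null space of the rotation-equivariance constraint (unique up to a
  deterministically fixed sign for ℓ ≤ 2) and normalized so that coupling
  with a scalar is the identity.
* **Neighborhoods.**  Attention excludes the self-node; self-information
  flows through the residual.  A node with no neighbors (possible only for
  degenerate inputs) receives the zero message by contract.
* **Softmax** uses max-subtraction per destination node.
* **Distances are fed raw** (one scalar slot in the edge feature).  A
  Gaussian radial-basis expansion is available behind a config switch and
  is off by default.
* **Element vocabulary** is keyed by atomic number over {C, N, O, S, P, F,
  Cl} with a shared bucket for anything else; the attached-H count is
  capped at 4 (organic valence bound).  Aromatic and triple bonds share the
  "other" bond category so arbitrary organic inputs featurize without
  changing table sizes.

All arithmetic is float64 throughout; the network, its tensor-product
algebra and the reverse-mode gradient engine are implemented in NumPy
inside the package.

## Training

Targets are z-scored per nucleus with statistics computed on the training
split and stored inside the model artifact; the two heads are trained
jointly with a masked mean-absolute-error summed over nuclei, one backward
pass per batch (Adam, learning rate 3 × 10⁻⁴ in the full configuration,
batch size 32).  Two schedules exist: `single_conformer` holds out 5% of
molecules (molecule-level, so conformers never leak across the split) and
reduces the learning rate by 0.1 when the validation error plateaus for 20
epochs; `ensemble` trains a fixed three epochs with the rate decaying by
0.1 each new epoch and no validation split.  An epoch is one pass over the
expanded (molecule × conformer) sample set; batches group conformers, not
molecules.  Training raises on non-finite loss, reporting the last finite
epochs.

## Conformer ensembles

Because molecules in solution populate many conformations, both training
and prediction use an ensemble per molecule: ETKDGv3 distance-geometry
embedding of n_generate = 200 candidates (seeded), MMFF94 single-point
energies computed with explicit hydrogens (hydrogens are stripped before
graph construction), a greedy diversity filter that drops any candidate
within 0.01 Å heavy-atom RMSD of an already-kept one, and retention of the
100 lowest-energy survivors.  Design choices: the filter aligns structures
with the Kabsch algorithm (proper rotations only, so enantiomeric
conformers are not treated as duplicates) before computing RMSD, making
the threshold frame-independent; candidates are processed in
energy-ascending order, biasing retention toward low-energy basins; if
fewer than n_keep candidates survive, the ensemble is returned short with
a warning (small rigid molecules legitimately have few conformers).

The final prediction per (atom, nucleus) is the arithmetic mean over the
ensemble; the population (1/N) standard deviation is reported as an
uncertainty estimate.  By the triangle inequality the ensemble-mean MAE
never exceeds the mean per-conformer MAE, which licenses training on the
expanded conformer set; the inequality is asserted on every evaluation
run.

## Evaluation protocol

Cross-validation is stratified by saccharide class (mono/di/tri) at the
molecule level; fold tables report per-(nucleus × class) MAE and RMSE as
"mean (std)" across folds with the population-std convention.
Structure-exclusion splits (test = molecules matching a structural
predicate) probe out-of-distribution behavior.  Evaluation ensembles are
generated with a fixed recorded seed per molecule and reused across folds,
isolating model variance from conformer variance.

Diastereotopic protons: the data model stores one ¹H value per heavy atom
(the network emits one invariant scalar per node per nucleus); when a
source lists two inequivalent protons on one carbon, the loader averages
them.  This is a representation choice, not a claim about the physics.

## Synthetic oracle

The synthetic generator exists so every pipeline stage is testable without
any external data.  It samples small stereochemistry-rich polyols, cyclic
ethers and acetylated sugars (5–20 heavy atoms) from a fixed catalogue,
with pseudo-classes (mono/di/tri by size) in proportions 107 : 153 : 115
echoing a realistic mono-to-trisaccharide collection, and assigns each
atom a closed-form E(3)-invariant "shift"

    δ(i) = a(Z_i) + b Σ_{j≠i, d<r_cut} exp(−d_ij²/σ²)
                 + c Σ_{j<k bonded to i} cos θ_jik + ε_i

with a(C) = 50, a(O) = 30, a(N) = 20, a(other) = 15 ppm, b = 20,
σ = 1.8 Å, c = 8, ε ~ N(0, 0.1 ppm), drawn once per (molecule, atom,
nucleus) so the value behaves like a single experimental observation seen
across many geometries.  The proton mimic divides the same form by 10.
These constants were fixed during generator design so that the carbon
targets have a several-ppm structural spread (an early draft with a weaker
pair term left the spread near the noise level, which is not a usable
supervision signal) while the proton mimic stays inside the 0–10 ppm
window.  The dataset's target per atom is the ensemble mean of the
deterministic part plus the fixed noise.

What the oracle does and does not emulate: it reproduces the value ranges,
the per-molecule shift counts, the class structure, and the
one-value-per-ensemble observation model of experimental data; it contains
no electronic-structure physics, no solvent or temperature effects, and
its geometric terms are strictly local.  Passing the recovery study
therefore demonstrates that the pipeline and the learning machinery work
end to end — not that the model predicts real spectra at any particular
accuracy.

## Scaled-down study sizes

The self-check experiments (test suite and `scripts/acceptance.py`) run on
one CPU, so the study sizes are reduced while keeping every mechanism
intact:

* **Recovery study**: 50 molecules × 5 conformers, reduced model (2
  layers, hidden 16×0e ⊕ 8×1o ⊕ 4×2e, 32-dim node embedding), 40 epochs of
  the plateau schedule at learning rate 3 × 10⁻³ (the reduced model
  tolerates — and at these sample sizes needs — a larger step than the
  full configuration).  Success bound: held-out MAE ≤ 0.25 × the
  population std of the oracle targets, per nucleus.
* **Invariant ablation**: the same architecture with the hidden layout cut
  to its scalar block and edge harmonics truncated to ℓ = 0, so geometry
  enters only through distances — by the same ablation
  mechanism the full-scale study uses: setting the maximum hidden ℓ to zero rather than
  re-budgeting the saved parameters into extra scalar channels.  The
  comparison uses an angular-content variant of the oracle (b = 4, c = 15,
  noise 0.05) in which the three-body term dominates, evaluated on
  trisaccharide-class molecules only (the largest and most flexible of the
  catalogue, hence the richest bond-angle variation) with a single
  conformer per molecule so the target is a pure function of one geometry,
  and is scored by held-out ¹³C MAE over three training seeds.  The models
  for this comparison are three-layer with hidden 32×0e ⊕ 16×1o ⊕ 8×2e
  (scalars-only 32×0e for the ablation): in design trials, two-layer
  reduced models converged to a shared error floor on this oracle — the
  route by which a node's own bond-angle information reaches the readout
  scalars (through attention logits or a neighbor echo) needs both depth
  and l>0 width to carry weight, which parallels the
  modest mean-level gains such equivariant models show over their
  invariant versions on real spectra.
* **Symmetry audits**: 20 molecules × 10 random E(3) elements (half of
  them improper) for prediction invariance; 5 molecules × 3 rotations with
  per-layer Wigner-matrix comparison for internal equivariance.  The
  tolerances (10⁻⁴ absolute / relative) are loose for float64 — observed
  deviations are near machine precision — and would also hold for a
  float32 port.

Known limitation, recorded for honesty: on this oracle at matched
*parameter* budget (widening the ablation's scalar block until the
parameter counts match), the distance-only model is competitive with the
equivariant one — unsurprising for a strictly local target on nearly
complete graphs, where the distance set determines the geometry up to
isometry and bonded angles are largely fixed by topology.  The equivariant
advantage shows in the like-for-like ablation above, and on real spectra the
gains of equivariant over invariant models are likewise modest in the mean
but concentrated in stereochemically subtle cases.
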