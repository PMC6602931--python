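# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `nnpkit`. It is written for users who want to understand
what the package computes and what its synthetic benchmarks do and do not
demonstrate.

## The potential

A conformation is a set of atoms (species `Z_i`, Cartesian coordinates
`x_i` in Å). The molecular energy (kcal/mol) decomposes into atomic
contributions:

```
E = Σ_i ε(Z_i) + Σ_i f_{Z_i}(G_i)
```

`ε` are linear per-element self-energies fitted by least squares to the
training energies (they absorb the enormous composition-dependent baseline
so the networks only learn the chemistry of bonding and conformation).
`G_i` is the atomic environment vector (AEV) of atom `i` and `f_Z` a small
per-element feed-forward network with four hidden layers and a scalar
output head.

### Atomic environment vectors

The AEV concatenates radial and angular symmetry functions, each strictly
local (cosine-switched cutoffs) and invariant to translation, rotation,
and same-element permutation:

* radial, per element `e` and shift `R_s`:
  `Σ_{j∈e} exp(−η_R (R_ij − R_s)²) f_c(R_ij, R_cR)`
* angular, per unordered element pair and shifts `(R'_s, θ_s)`:
  `2^{1−ζ} Σ_{(j,k)} (1 + cos(θ_ijk − θ_s))^ζ
  exp(−η_A ((R_ij+R_ik)/2 − R'_s)²) f_c(R_ij) f_c(R_ik)`

with `f_c(R, R_c) = 0.5 cos(πR/R_c) + 0.5` for `R ≤ R_c`, zero beyond.

Defaults (all configurable, serialized with every model): elements
{H, C, N, O}; `R_cR = 5.2 Å`, `R_cA = 3.5 Å`; 16 radial shifts uniform on
[0.9, 5.2) Å, `η_R = 16 Å⁻²`; 4 angular radial shifts on [0.9, 3.5) Å,
`η_A = 8 Å⁻²`; 8 angle shifts uniform on [0, π), `ζ = 32`. Feature length
384 for four elements. These are conventional values for
symmetry-function potentials of small CHNO organics; treat them as
reasonable stand-ins rather than tuned optima, and override them through
`AEVSpec` when needed. Angular terms clamp `cos θ` into [−1, 1] before
`acos`, so colinear triples are finite; the angle-gradient denominator
`sin θ` is floored at 1e−8, which matters only within ~1e−8 rad of exact
colinearity.

Element pairs in the angular block are ordered lexicographically by
symbol; radial blocks follow the `supported_elements` order. The layout is
stable and stored in saved models.

### Networks, forces, precision

Hidden layers use CELU (α = 0.1), a continuously differentiable
exponential-linear unit, so the energy is C¹ and forces
`F = −∂E/∂x` are well defined everywhere. Forces are computed by exact
backpropagation through the network and the analytic derivatives of the
symmetry functions — no finite differences anywhere in the prediction
path. Everything is float64.

Inputs to the networks are standardized per feature (shift/scale frozen
from the pretraining data, scale floored at 1e−2 so features inactive in
the reference data cannot blow up out of distribution). The standardizer
is part of the model, not a trainable parameter, and is deliberately kept
fixed through transfer learning so that frozen layers keep their meaning.

Default hidden widths are (64, 48, 32, 16); the benchmark experiments use
(32, 32, 32, 32), a deliberately desk-scale network (≈18k parameters per
element at feature length 384) chosen so a full benchmark runs on one CPU
core in minutes.

## Training

Loss: mean squared error of total energies with each residual divided by
`√N_atoms`, keeping molecules of different sizes comparably weighted. The
optimizer is Adam with decoupled weight decay on weight matrices (not
biases), plateau-based learning-rate decay (×0.5 after 25 stagnant
epochs), and early stopping on a validation split; the best-validation
snapshot is returned, so the best-validation curve is non-increasing by
construction. Self-energies are fitted once by least squares and enter
training as a fixed baseline.

Validation splits can be drawn by molecule group (no conformer of a
validation molecule is ever trained on) or by conformation. The ensemble
experiments split by conformation: at desk scale the scientifically
relevant generalization axis is across conformations of known molecules,
and a six-molecule validation set measures mostly per-molecule offset
error, which the conformer-ΔE metrics cancel anyway. The by-molecule mode
remains the default of `split_dataset` for users who need leakage-free
model selection.

### Ensembles

A committee of K = 8 members (different initializations, different
90/10 data splits) predicts with the member mean; the population standard
deviation of member energies — optionally divided by `√N_atoms` to make
thresholds size-independent — is the disagreement used both as an
uncertainty proxy and as the query-by-committee acquisition score. Both
normalization modes are exposed because size normalization is a
convention, not a law.

### Transfer learning

Starting from the low-fidelity committee, each member is retrained on its
own split of the scarce high-fidelity set with two of the four hidden
layers frozen (bit-identical before and after; the package logs the
frozen/total parameter count). Which two layers to freeze is an open
design choice with two defensible answers: freeze the input-side feature
detectors (best constrained by the abundant data) or freeze the deep
combiners and adapt the features. We compared both on the synthetic
benchmark and the second wins consistently — the inter-fidelity
correction here is predominantly a function of local geometry, which the
input-side layers represent, and those layers also hold most of the
trainable capacity — so the default `FreezeSpec` freezes the two hidden
layers nearest the output; the input-side variant is one flag away.
Before gradient training,
a per-element linear offset is refitted on the high-fidelity training
split, removing the systematic shift between the fidelity levels in one
exact least-squares step; the learning rate is reduced to ×0.1 of
pretraining to avoid catastrophic forgetting on the small dataset.

### Δ-learning

The alternative trains a fresh correction committee on residuals
`E_high − E_base` and predicts `base + correction`, at the cost of two
network evaluations per inference. By construction
`combined(x) − base(x) = correction(x)` exactly.

### Query-by-committee active learning

Curation starts from a seeded uniform random draw (default 24 points),
then runs 3 iterations that each label the top-budget pool points by
committee disagreement, grow the curated set, and retrain by transfer
learning from the original low-fidelity committee. Disagreement is
recomputed with the retrained committee each iteration (a static-ranking
ablation mode exists). Selection is without replacement; ties break by
stable input order; oracle failures are logged and skipped, never
silently dropped. An optional mode labels only a random 10% of each
selection, mirroring workflows where the expensive oracle is applied to a
subsample. Per-iteration seeds derive from the master seed through
`numpy.random.SeedSequence`.

## The synthetic two-fidelity world

Real reference data at two levels of electronic-structure theory is out
of reach for a desk-scale package, so the generator builds an analytic
world with the same statistical structure:

* **Molecules**: random valence-respecting trees (optionally one ring)
  over {C, N, O} heavy atoms (2–5 by default, carbon-weighted), saturated
  with hydrogens; a greedy 3D embedding is relaxed on the low-level
  surface to give each molecule a minimum.
* **Oracles**: both fidelity levels share one functional family — Morse
  bonds, harmonic bends, 3-fold cosine torsions, and a soft exponential
  repulsion between atoms three or more bonds apart, plus per-element
  atomic baselines of realistic magnitude (−340 to −47,000 kcal/mol).
  The high level differs by (a) systematically shifted per-element
  baselines (σ = 4 kcal/mol), (b) every bonded parameter perturbed by a
  relative scale δ (default 0.05), and (c) a bond–bond coupling term
  `k_c Δr_ij Δr_jk` over bends (k_c = 200·δ kcal/mol/Å²) absent from the
  low level. This yields both a molecule-level systematic discrepancy and
  a conformation-dependent discrepancy of ≈2 kcal/mol RMS in conformer
  ΔE — comparable, deliberately, to the gap between a mid-tier and a
  high-tier quantum-chemistry method — while keeping the two levels
  correlated (Pearson r > 0.9 over conformers). Forces are analytic
  gradients, verified against finite differences.
* **Conformers**: each molecule's minimum is perturbed along its
  unit-mass normal modes (central finite-difference Hessian; the 6
  near-zero modes dropped, 5 for linear molecules) with Gaussian mode
  coefficients scaled so each mode's expected harmonic energy equals
  `scale` (default 0.6 kcal/mol ≈ kT at room temperature). 12–24
  conformers per molecule, ≈60 molecules ≈ 1,000 low-fidelity points;
  the high-fidelity budget is ≈10% of that.

Unit masses are used throughout the mode analysis: sampling needs a
displacement distribution, not spectroscopy.

What passing benchmarks on this world shows: that the learning machinery
(features, committees, transfer, curation) exploits exactly the structure
it claims to exploit — shared smooth physics plus a systematic-and-
conformation-dependent inter-fidelity discrepancy. What it does not show:
accuracy on real quantum-chemical surfaces, which are rougher, higher
dimensional, and include electronic effects (charge transfer, long-range
interactions) entirely absent here.

## Evaluation metrics

* **Conformer ΔE**: formed over all unordered conformer pairs within each
  molecule (per-molecule constants cancel), errors pooled across
  molecules; MAD and RMSD reported. A min-referenced mode and a
  per-molecule averaging mode are provided for comparison. An energy
  window (default 100 kcal/mol above each molecule's reference minimum)
  filters high-energy conformations first.
* **Atomization energy**: `E − Σ_i ε(Z_i)`; errors vs reference, with an
  optional post-hoc per-element linear refit implementing the classical
  systematic-shift correction. The error-distribution width (std) is the
  headline statistic.
* **Forces**: MAE/RMSE pooled over all atoms and Cartesian components.
* **Torsion profiles**: the dihedral is driven every 10° by a harmonic
  restraint on the wrapped angle difference while all other degrees of
  freedom relax (L-BFGS with analytic gradients); the restraint constant
  starts at 1000 kcal/mol/rad² and escalates ×10 until the achieved angle
  is within 0.5° of target. Profiles are aligned by subtracting their own
  minimum before comparison; profile MADs across molecules are summarized
  by the median with quartiles.

## The standard benchmark experiment

`nnpkit.benchmarks` fixes the canonical experiment: corpus of 55
molecules (≈1,000 low-fidelity conformers), an 8-member committee
pretrained 120 epochs, then — over 5 seeds — transfer learning,
Δ-learning, and scratch training on 108 randomly drawn high-fidelity
labels, evaluated as conformer-ΔE RMSD on ≈500 fresh high-fidelity-labeled
conformers (9 per molecule, sampled independently of training). The
active-learning comparison uses a 4-member sub-committee, 24 initial
random labels plus 3 × 24 selected labels, against a random-selection
baseline at identical total budget. Problem sizes were chosen so the
whole experiment runs in well under half an hour on one CPU core; they
are the package's definition of "desk scale".

Observed behavior (recomputed from scratch by `scripts/acceptance.py`,
not hard-coded anywhere): the transfer-learned committee beats both the
scratch-trained committee and the low-only committee on held-out
high-fidelity conformer ΔE; Δ-learning lands close to transfer learning;
the committee mean is at least as accurate as its median member;
disagreement correlates positively with true error; and
disagreement-driven curation matches or beats random selection at equal
budget.

## Numerical choices and degenerate inputs

* Geometry relaxation: L-BFGS-B on the analytic gradient, then Newton
  polish with a finite-difference Hessian until max |F| ≤ 1e−5
  kcal/mol/Å; non-convergence raises with the residual.
* Normal-mode sampling refuses saddle points (negative eigenvalue beyond
  tolerance) and unminimized inputs.
* Self-energy fitting raises on rank-deficient element-count matrices and
  names the confounded elements.
* Dihedrals use the atan2 formulation; exactly colinear backbones raise.
* Model containers carry a format version and a SHA-256 checksum;
  loading a corrupted or future-versioned file fails loudly, and a
  save/load round trip reproduces predictions bit-for-bit.
* Every stochastic step takes an explicit seed; one master seed
  reproduces the entire pipeline bit-for-bit.

## Known limitations

* Energy-only training: forces are predicted but never trained on, so
  force accuracy trails energy accuracy.
* No periodic boundary conditions, no charges or long-range
  electrostatics, no learned descriptors.
* The descriptor hyperparameters are conventional defaults, not values
  optimized for the synthetic world.
* At desk scale the networks do not generalize usefully to molecules
  absent from training; the benchmarks therefore hold out conformations,
  not compositions.
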