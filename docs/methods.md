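# Methods

## The model

`molkd` studies knowledge distillation (KD) for *regression* on 3D molecular
graphs. A teacher encoder is pretrained on several scalar properties; its
pooled latent embedding `e_T` (the fixed-width per-molecule vector after atom
pooling, before the property head) is then distilled into smaller students
via a cosine alignment loss while the student regresses its own target:

- regression loss (default MAE): `L_reg = (1/N) Σ |y_i − ŷ_i|`; MSE, Huber
  and Smooth-L1 are available for comparison.
- distillation loss: `L_KD = 1 − mean_i cos(e_T,i, e_S,i)`, the mean over the
  per-molecule rowwise cosines in a batch (range [0, 2]).
- combined objective with homoscedastic uncertainty weighting:
  `L_total = L_reg/(2σ₁²) + L_KD/(2σ₂²) + log σ₁ + log σ₂`, with σ's learned
  as `log σ` (unconstrained, initialized at 0). For fixed loss values the
  stationary point is `σ_i = √L_i`, which the optimizer demonstrably reaches.
- KD benefit metric: relative R² deviation
  `(1 − R²_without-KD / R²_with-KD) × 100`, undefined (and excluded from
  summaries) when `R²_with-KD ≤ 0`. The printed form of the coefficient of
  determination is the standard `1 − SS_res/SS_tot`.

Two setups mirror the full-scale experimental design: *domain-specific*
(teacher and students share a dataset; student targets disjoint from teacher
targets) and *cross-domain* (a frozen teacher trained on one dataset supplies
embeddings for students trained on another).

## The reference encoder

A continuous-filter convolution backbone implemented on a small numpy
reverse-mode autodiff engine (`molkd.autodiff`): atom-type embedding table
(`z_max+1 × H`), K Gaussian radial basis functions with centers evenly spaced
on [0, cutoff] and width equal to the spacing, and T interaction layers. Each
layer generates a width-F filter from the distance expansion through a
two-layer perceptron (shifted-softplus nonlinearity), multiplies it
elementwise with a linear map of the neighbor state, sums over neighbors
within the cutoff, and maps back to width H with a residual update. Sum
pooling over atoms yields the molecular embedding; per-property affine heads
sit on top. Because only interatomic distances enter, embeddings are exactly
permutation- and rigid-motion-invariant, and atoms beyond the cutoff cannot
affect the result; the tests assert all three at 1e-6.

Students shrink capacity along one axis only — the number of filters F
(mirroring the published 128 → {8, 16, 32, 64} sweep) or the number of
interaction blocks T (4 → {1, 2, 3}) — keeping the embedding width H fixed so
teacher/student cosines never need a projection. The distilled embedding is
the *pooled* molecular vector: it is the only per-molecule representation all
candidate backbones share, making it the portable choice. Default desk-scale
teacher: H=64, F=64, T=3, K=32, cutoff 6 Å. Weights use seeded uniform
fan-in initialization with zero biases; with the atom-table entries at
fan-in scale the trained teacher's embedding is dominated by learned,
property-relevant directions rather than by the random type vectors, which
makes the cosine a meaningful alignment target. `z_max = 100` so cross-domain
molecules containing elements the teacher never saw (S, Cl, …) still embed —
their table rows are simply untrained.

Geometry enters the computation graph as constants (distances are never
differentiated), so batch featurization — the radial expansion and the
sparse gather/scatter/pooling operators — is precomputed once per batch and
reused across epochs.

## Training protocol

Adam throughout. The library defaults follow the published tuned values
(learning rate 5e-5, batch size 64); the desk-scale studies use 3e-3 with up
to 40 epochs and patience 12, the budget at which teacher and baseline
students reach their validation plateau at n = 2,000. Targets are z-scored
per property with train-split statistics only; predictions are de-normalized
before any R²/RMSE so metrics live on the physical scale. The teacher trains
multi-output with equally weighted per-property losses. Students train one
property each (per-property attribution of the deviation metric).

Matched budgets are enforced structurally: for a given seed the KD run and
the baseline run share the parameter initialization, the (static) batch
partition, the per-epoch batch order, and the stopping rule (validation
*regression* loss in both modes, best checkpoint restored); the pipeline
asserts equal initial-parameter checksums and equal batch-schedule hashes.
The desk studies run fixed-length budgets (patience equal to the epoch
budget): distilled runs traverse an early alignment transient during which
the validation regression loss stalls, so a short patience truncates them
asymmetrically and the comparison stops being budget-fair. The σ parameters are updated jointly with the model,
using the analytic gradient `∂L_total/∂log σ_i = 1 − L_i/σ_i²`; treating the
current σ's as constants inside the batch graph is exact because the chain
rule separates the model and σ gradients.

## The synthetic generator

Molecules are compact random clusters: each new atom is placed uniformly in
the shell [d_min, 2·d_min] (d_min = 0.9 Å) around a uniformly chosen
existing atom, rejected until all pairwise distances are ≥ d_min and the
cluster stays within 6 Å of the first atom. Elements are drawn from a
QM9-like palette {H, C, N, O, F} with roughly organic abundances; an
extended palette adds S and Cl for cross-domain and QM9-like/non-QM9-like
partition studies. These are geometric fixtures, not chemicals — no bonds,
valence, or force-field realism.

Properties are linear forms in five permutation- and rigid-motion-invariant
descriptors (pairwise Gaussian overlap, inverse-distance sum — both over
pairs within 6 Å — atomic-number sum, radius of gyration, heavy-atom
count). Features are standardized with population statistics before the
seeded unit weight vectors are applied; without this the atomic-number sum
(an order of magnitude larger than the geometric descriptors) would dominate
every property and geometry would be irrelevant to the learning problem.
Teacher property k is `a_k (w_k·f̃) + ε`; transfer property m is
`b_m (ρ (w̄·f̃) + (1−ρ)(v_m·f̃)) + ε` where w̄ is the mean teacher direction
and ρ ∈ [0, 1] sets the shared signal between teacher and transfer tasks
(default 0.8). Noise ε is drawn per (molecule index, property index) from a
counter-based stream, so adding properties never perturbs existing columns
and property values are invariant to rigid motions of the coordinates.
Defaults — 2,000 molecules, 12 atoms, ρ = 0.8, noise sd 0.05 — are the
study conditions of the flagship desk-scale experiment.

What the generator does *not* emulate: chemically valid structures,
conformational ensembles, heavy-tailed property distributions, and the deep
underfitting of real large-scale benchmarks. Passing desk-scale tests shows
the machinery is correct and the distillation dynamics behave as designed;
it does not certify effect sizes on real data.

## Alignment diagnostics

The teacher–student cosine profile is summarized by the mode of a Gaussian
KDE evaluated on a fixed 1e-3 grid over [−1, 1] (Silverman bandwidth by
default, ties broken toward the larger value, zero-spread samples returning
their common value); the peak shift is the difference of modes between
distilled and baseline students and is exactly antisymmetric. Note the
automatic bandwidth depends on sample size, so only a fixed explicit
bandwidth is exactly invariant under duplicating a sample. Heatmaps show
`cos(e_T,i, e_S,j)` over a seeded, id-sorted subsample (default 100 test
molecules); the diagonal is the matched-molecule alignment.

## Observed desk-scale behavior

In the flagship study the distillation signal is unambiguous on the
alignment side: distilled students' mean cosine to the teacher exceeds the
baseline students' by ≈ 0.9–1.2 (baselines sit near 0, distilled near
0.95). On the accuracy side the margins are thin by construction: the noise
ceiling at these conditions is R² ≈ 0.985, a linear probe of the frozen
teacher embedding reaches ≈ 0.980, and baseline students reach ≈ 0.94–0.975
— so the relative R² deviation lives in the sub-percent range (consistently
positive under fixed-length budgets, but an order of magnitude below the
full-scale benchmark effects, where baselines underfit deeply). The linear-
in-descriptors property family is representable even by an F=8 student, so
capacity is never the binding constraint the way it is on real data.

## Numerical choices and degenerate inputs

- Zero-norm embedding rows are an error in every cosine computation (no
  silent ε-fudging), naming the molecule.
- `relative_r2_deviation` and `rmse_improvement` return NaN as an explicit
  undefined flag; reports carry the row but exclude it from summaries.
- Split sizes use round-half-away-from-zero for val and test with the
  remainder to train, reproducing 70/20/10 exactly when n is divisible by 10.
- Target z-scoring uses the sample standard deviation (ddof 1); constant
  train columns are an error naming the property.
- Structure files: the XYZ writer emits 10 decimals (round-trip ≈ 1e-9 Å);
  SDF V2000 fixes 4 decimals (1e-4 Å). The canonical dataset container is
  one structures file plus a CSV of source_id/split/properties.
- SMILES-only records get one seeded ETKDG conformer with MMFF (fallback
  UFF) relaxation after explicit-hydrogen expansion; single-atom molecules
  sit at the origin; embedding failures after bounded retries are errors
  flagging the molecule for exclusion.
- QM9-likeness: every element in {H, C, N, O, F} *and* at most 9 heavy
  atoms; both thresholds configurable since published cutoffs vary.

## Known limitations

- The backprop engine supports exactly the operator set the reference
  encoder needs; plugging in external backbones goes through the
  encode/predict contract, not through the engine.
- Hard distance cutoff (no smooth cutoff function): embeddings are not
  continuously differentiable in geometry, which is irrelevant here because
  geometry is never optimized.
- Parameter counts of the published full-scale backbones are not
  reproducible from their descriptions; counts are reported for the
  reference family only.
- The acceptance study is stochastic at the ±0.5 % level in R² deviation;
  alignment-side conclusions are robust, accuracy-side margins are thin by
  construction (see above).
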