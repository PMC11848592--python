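# Methods

## The model

`msiseg` segments mass spectrometry imaging (MSI) data — a spots × ions
intensity matrix **M** ∈ R^(XY×Z) on an X×Y pixel grid — into regions of
shared metabolic phenotype. The pipeline has two learned modules trained
as a curriculum.

**Dimensionality reduction (parametric UMAP).** A two-layer fully
connected encoder f(·|θ): R^Z → R^l (hidden layer with batch
normalization and ReLU; linear output, default l = 20, hidden width 256)
is trained to minimize the UMAP fuzzy cross-entropy

L_DR = Σ_{i<j} [ p_ij log(p_ij/q_ij) + (1−p_ij) log((1−p_ij)/(1−q_ij)) ],

where p_ij are symmetrized fuzzy simplicial memberships computed from
the k-nearest-neighbor distances of the spectra (ρ_i = distance to the
nearest neighbor; σ_i calibrated by bisection so the smoothed weights
sum to log2(k); symmetrization p = p′ + p′ᵀ − p′∘p′ᵀ) and
q_ij = (1 + a‖e_i − e_j‖^{2b})⁻¹ with (a, b) fitted from
min_dist = 0.1. Because the map is parametric, unseen spectra are
embedded by a forward pass — the basis of cross-slice transfer.

**Spatial graph.** Each spot is a node; candidate edges connect a spot
to its ≤ 8 lattice (Moore) neighbors only, and an edge exists iff the
Euclidean distance between the two embedding vectors is strictly below a
cut-off. The default cut-off is the median of all candidate neighbor
distances; within-region neighbor distances are typically far below
boundary-crossing ones, so the median keeps intra-region edges and drops
most boundary edges. Edge distances are measured in embedding space by
default, consistent with the pipeline order (reduction before
clustering); `graph_space="raw"` gates edges on raw-spectrum distances
instead. The graph convolution uses the renormalized adjacency
Â = D̂^(−1/2)(A + I)D̂^(−1/2).

**Feature clustering (GCN).** Two graph convolutions
H1 = ReLU(Â E W0), H2 = Â H1 W1 (W0 ∈ R^{l×k}, W1 ∈ R^{k×k},
default k = 16 channels), followed by per-channel batch normalization
and an argmax classifier over channels (ties to the smallest index).

**Multi-task self-training loss.** With P = softmax(response):

- L_sim — cross-entropy between P and the model's own current argmax
  labels, recomputed each step and treated as constants (self-training);
- L_tv — total variation: L1 difference between each spot's response and
  its right/down neighbors (applied to P during optimization; the public
  `loss_tv` evaluates whatever response values it is given);
- L_ent — anti-collapse penalty. The literal per-pixel form
  −(1/k) Σ_i p_i log p_i is minimized by confident predictions and
  cannot by itself prevent a single-region solution, so the default is
  the *marginal* form log k − H(mean_i P_i): zero when the batch class
  marginal is uniform, log k when all spots collapse onto one class.
  The literal form remains available (`ent_form="per_pixel"`).
- L_scr — cross-entropy against scribble labels on annotated cells only
  (scribble mode);
- L_DR — the UMAP loss stays in the joint objective, so the embedding is
  not free to discard spectral structure while fitting the clustering
  terms.

All weights default to 1 (the objective is the unweighted sum); each
term is normalized per spot / per labeled cell / per sampled pair so the
terms are scale-comparable. Training is SGD with learning rate 0.01 and
momentum 0.9 for both phases; phase 1 (warm-up, default 200 epochs)
optimizes L_DR alone, phase 2 (default 500 epochs) optimizes the joint
objective for encoder and GCN together. The spatial graph is built once
from the warm-up embedding and held fixed during phase 2 (optional
refresh every R epochs); after training, the stored prediction graph is
rebuilt from the final embedding so that predicting the training slice
reproduces the training segmentation exactly. Training stops early when
the number of distinct predicted labels reaches `min_label_count`
(default 3). The UMAP loss is optimized by edge sampling (default 4096
edges per epoch drawn ∝ p_ij, 5 uniform negatives per edge, the standard
stabilized repulsive gradient with per-sample clipping at 4).

**Networks in NumPy.** The encoder and GCN are implemented directly in
NumPy with hand-derived backward passes (including batch-norm in batch
statistics mode); every backward pass is verified against central finite
differences in the test suite. Batch normalization uses batch statistics
during training and running statistics (momentum 0.1) at inference and
transfer time.

## Operating modes

**Scribble-interactive.** Fine-tuning continues joint optimization with
L_scr added for `scribble_epochs` (default 300) epochs. Annotations
accumulate across rounds (newest label wins per cell): without
accumulation, a later fine-tune on unrelated regions erases earlier
corrections because nothing in the unsupervised terms defends them —
user annotations are treated as persistent constraints. The fine-tuned
copy leaves the input model intact, and fine-tuning a fine-tuned model
is supported.

**Knowledge transfer.** The unseen slice is projected through the frozen
encoder, gets its own 8-neighbor graph (reusing the training cut-off by
default), and passes once through the frozen GCN with running
normalization statistics. No gradients, no parameter updates; cost is a
forward pass (≲ 0.1 % of training time in our phantom runs).

## The synthetic phantom

The generator emulates a centroided, peak-aligned MSI section: K spatial
regions (stripes, concentric rings, or Voronoi cells; default Voronoi,
K = 5 on a 40×40 grid), 60 ions with log-normal per-ion baselines
(log-sd 0.3), each region over-expressing 5 dedicated ions by a
fold change of 5, multiplicative mean-one log-normal spot noise
(default CV 0.1), and — for slice series — a per-slice per-ion batch
factor exp(N(0, batch_log_sd)) plus boundary-cell label morphing between
consecutive slices, emulating 3D batch effects and slice-to-slice
anatomy drift.

The *subtle-split* mode targets the known failure mode of unsupervised
segmentation: the last region is halved, and the second half
additionally expresses 6 ions at a 1.3× fold. Several weak ions rather
than one were chosen deliberately: real sub-organs differ in a broad set
of modestly discriminative ions, and a single weak ion is statistically
recoverable per spot yet un-learnable from ~25 scribble-labeled cells in
a 60-dimensional noise space (the fine-tune memorizes the labeled cells
without generalizing). With the multi-ion signature, unsupervised
training still merges the halves (sub-region ARI ≈ 0) while 2%-coverage
scribbles rescue the split.

What the phantom does **not** model: profile spectra, isotope envelopes,
mass drift, spatially correlated noise, intensity-dependent
heteroscedasticity, or partial-volume mixing at region boundaries.
Passing phantom tests therefore demonstrates the machinery is correct
and the losses act as designed, not that segmentation accuracy on real
tissue will match the phantom numbers.

## Numerical choices

- Probabilities are clipped at 1e-7 inside logs; q is clipped to
  [1e-7, 1−1e-7]; entropy uses the exact 0·log 0 = 0 convention.
- σ bisection runs to a relative interval of 1e-5 (residual ≤ 1e-4 in
  tests); points whose neighbor distances all equal ρ fall back to the
  mean neighbor distance.
- The adjacency cut-off uses strict `<`; `suggest_cutoff` warns and
  returns the smallest positive double when all candidate distances are
  zero.
- Argmax ties break to the smallest channel; the argmax is invariant to
  the softmax, so classification operates on the normalized response.
- All randomness flows from one `numpy.random.Generator` seeded by
  `TrainConfig.seed`; identical seeds reproduce training bit-for-bit on
  a fixed platform.
- Matrix CSV I/O uses shortest-round-trip float repr on write and
  round-trip parsing on read, so write→read is bit-exact.

## Problem sizes

Default test and acceptance runs use 40×40 grids (1600 spots, 60 ions)
for recovery/transfer/ablation and 32×32 for the subtle-split phantom;
one full training takes ~25 s on a single CPU core. The acceptance
script reports medians over 3 replicate seeds; the test suite runs the
5-seed versions of the same checks.

## Known limitations

- The Supporting-Information cut-off selection strategy of the original
  method is not public; the quantile heuristic is an explicit stand-in.
- Peak filtering uses a fraction-of-spots occurrence rule; the original
  vendor-side filtering criterion is unspecified.
- `score_marker_auc` reports in-sample AUC without a train/test split
  and without multiple-testing control (marker lists are ranks, not
  inference).
- Per-pixel entropy form is provided for completeness but is not an
  anti-collapse penalty; the marginal default is the mode used in all
  reported runs.
- Continuous-mode (profile) imzML is rejected by design; processed-mode
  files must share a common m/z axis (i.e. be peak-aligned upstream).
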