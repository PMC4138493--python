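# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not establish.

## Gaussian-visible RBM

The restricted Boltzmann machine models voxel vectors `v` (real-valued,
approximately Gaussian after z-scoring) and binary hidden units `h`
through a Gibbs distribution `p(v, h) ∝ exp(−E(v, h))` on a bipartite
graph.  Two energy conventions appear in the literature and both are
implemented:

* **standard** (textbook) form
  `E = −Σ_ij (v_j/σ_j) W_ij h_i + Σ_j (v_j−a_j)²/(2σ_j²) − Σ_i b_i h_i`,
  giving `v_j | h ~ N(a_j + σ_j Σ_i W_ij h_i, σ_j²)`;
* a **no-½ ("legacy") variant** used in parts of the neuroimaging RBM
  literature, which omits the ½ on the containment term.  Its normalizable
  reading implies `v_j | h ~ N(a_j + (σ_j/2) Σ_i W_ij h_i, σ_j²/2)` — a
  visible reconstruction gain of σ/2.  (`energy(form="legacy")` also
  evaluates the expression verbatim as sometimes printed, with the
  containment term subtracted; as written that expression is not
  normalizable and is provided for reference only.)

`σ` is fixed at 1 and never learned; per-voxel z-scoring during
preprocessing achieves the same standardization faster.

**Why training defaults to the no-½ convention.** With the reference
hyperparameters for voxel data (learning rate ε = 0.08, batch 5, L1
coefficient λ = 0.1) the textbook convention is numerically unstable:
at realistic visible counts (≥ ~1000 voxels) one CD-1 epoch is enough for
the weight magnitudes to enter an oscillatory runaway, because the
reconstruction drive `σ Wᵀh` grows with ‖W‖ while the step size stays
fixed.  The σ/2 reconstruction gain of the no-½ convention halves the
loop gain and the same hyperparameters train stably to convergence.  Both
conventions are exposed; `train_rbm(standard_form=True)` works if the
learning rate is dropped by roughly an order of magnitude.

**Hidden units.** `tanh` units take values in {−1, +1} with
`P(h_i = +1 | v) = (1 + tanh z_i)/2`, `z = W(v/σ) + b`; `logistic` units
take {0, 1} with sigmoid means.  The tanh choice makes the model exactly
symmetric under joint sign flips of a feature row and its hidden unit, so
one unit can represent source activity on both sides of baseline; with
logistic units the model tends to split such a source into two features
of opposite sign.  The signed-source benchmark (`generate_signed_source_data`)
measures exactly this: counting feature pairs with correlation < −0.9
yields a median of 0 for tanh and ~6 for logistic across seeds.

**CD-1 details** (where the choice was open):

* positive statistics use hidden means at the data;
* CD-1's negative phase samples hidden states and uses the *mean* visible
  reconstruction (the standard low-variance practice);
* multi-step chains (`cd_steps > 1`) sample the visibles at every step and
  take hidden means at the final *sampled* state — a mean-reconstruction
  chain is mean-field, not Gibbs, and its gradient stays measurably biased
  no matter how many steps are run (cosine with the exact gradient
  plateaus near 0.8, versus ≈ 0.99 for the sampling chain at 200 steps);
* `mean_field=True` gives a fully deterministic CD for diagnostics;
* weight init N(0, 0.01²), biases 0, no momentum, constant learning rate,
  `sgn(0) = 0` in the L1 update, reconstruction error is the MSE between
  data and the one-step mean reconstruction.

**Exact oracle.** For ≤ 12 hidden units the partition function is computed
by enumerating the 2^H hidden states and integrating the Gaussian
visibles in closed form (`log Z = logsumexp_h [b·h + a·c/σ + ‖c‖²/2] +
Σ_j ½log 2πσ_j²`, `c = Wᵀh`).  The exact gradient, used only as a test
oracle, matches centered finite differences of the exact log-likelihood to
~1e-10 relative error.

## Deep belief network

Greedy layer-wise pre-training: layer 1 is a Gaussian-visible RBM on the
z-scored voxels; deeper layers are logistic-logistic RBMs on the
feed-forward activations of the stack below.  An interleaved mode
(fine-tune the partial stack before pre-training the next layer) is
implemented as an option; the plain greedy mode is the default and is what
the tests exercise.  Fine-tuning adds a softmax head, initializes from the
pre-trained weights and backpropagates the cross-entropy with plain
mini-batch gradient descent at per-layer learning rates, stopping early
when the training loss plateaus (tolerance 1e-5, patience 10).  Dropout is
implemented in inverted form (activities zeroed with probability p and
rescaled by 1/(1−p) at training time, so inference needs no correction).

**Cohort training schedule** (`protocols.py`, chosen once for reliable
optimization and then frozen): pre-training rates (0.01, 0.1, 0.1) with
L1 (0.01, 0, 0) and epochs (15, 40, 40); fine-tuning rates
(0.05, 0.1, 0.1), head rate 0.2, up to 200 epochs.  Upper layers are
pre-trained longer, at a higher rate and without L1 because
logistic-logistic RBMs see far weaker gradients than the Gaussian-visible
first layer — with the first-layer schedule their weights stay at zero and
the stack above layer 1 is dead (constant activations), which no amount of
fine-tuning repairs.  A separate reference schedule for 50-50-100
structural models (rates 0.01/0.01/0.001, L1 0.1/0.01/0.001, fine-tune
rates 0.01/0.1/1e-8, dropout 0.7/0.5/0.5/0.75) ships as the
`smri_dbn_50_50_100` preset and `smri_*` helpers; its third-layer
fine-tuning rate of 1e-8 effectively freezes that layer and is kept purely
as the documented reference configuration.

## Divide-and-concur embedding

Each point owns one constraint — its k data-space nearest neighbors should
be its neighbors on the 2D map — and has one 2D replica per constraint it
participates in (its own plus each constraint listing it as a neighbor;
replicas are instantiated only for actual memberships, which preserves the
dynamics and keeps memory and per-iteration cost at O(kn)).  The divide
projection pulls, within each constraint independently, every neighbor
replica toward the owner's replica by `min(α·g(d), current 2D distance)`;
the concur projection moves all replicas of a point to their mean map
position.  The two are combined by the difference map

    x_c = P_c((1 + 1/β) P_d(x) − (1/β) x)
    x_d = P_d((1 − 1/β) P_c(x) + (1/β) x)
    x  ← x + β (x_c − x_d)

with β = 0.9 by default.

Open choices, resolved as follows:

* **Pull weight** `g(d) = exp(−d/τ)` with τ the median data-space neighbor
  distance: closer in data space ⇒ stronger pull, matching the
  constraint's intent; the opposite reading (`pull="far"`, step growing
  with distance) is exposed because the prose convention is ambiguous.
  The step scale defaults to α = 0.1 τ.
* **Step capping** at the current 2D distance prevents overshoot and makes
  a coincident replica a genuine fixed point; uncapped literal pulling
  never stabilizes.
* **Concur arithmetic** computes each mean as
  `owner replica + mean(deltas)`, which makes the projector bitwise
  idempotent (a plain sum/count mean re-rounds and fails exact
  idempotence by 1 ulp).
* **Initialization** is a deterministic principal-axis projection of the
  centered data (signs fixed by the largest loading), so the same call
  always yields the same map; random initialization with a seed is
  available.  Determinism is guaranteed *given the initialization*, not
  across initializations — solutions are at best unique up to rigid
  motion, so cross-initialization agreement is only checked at the level
  of neighbor structure.
* **Stopping**: converged when mean replica displacement < 1e-4 τ;
  flagged "oscillating" when the trailing 50-iteration mean displacement
  stops decreasing (relative change < 1e-3) while above tolerance — the
  difference map's signature behavior when constraints cannot all be
  satisfied; otherwise "max_iters".

Map quality is quantified by `knn_preservation` (mean fraction of
data-space k-neighbors kept on the map), `class_separation`
(between-centroid distance over mean within-class RMS spread) and
`severity_axis_correlation` (Spearman correlation of patient severity with
position along the control→patient centroid axis — this axis gives the
"patient limb" a canonical orientation, so the sign of the correlation is
meaningful).

## Synthetic data

**Functional datasets.** Sources are isotropic 2D Gaussians, unit peak,
on a jittered lattice (cells permuted by seed, centers jittered within
±cell/6); all sources share the width `base_width × spread` with
`base_width = cell/5`.  Centers never depend on spread.  The overlap
statistic z-scores each map across the grid and counts voxels where at
least two maps exceed 0.5 sd.  The default 12-setting sweep is geometric
over spread ∈ [1, 6], fixed at packaging time so overlap spans ≈ 0.03 to
≈ 0.99 across the sweep.

Designs are randomized oddball sequences: one task event every second
volume with type probabilities 0.8/0.1/0.1 (standard/target/novel), TR
2 s, 128 volumes.  Each source is modulated by a random subset of task
events with signed amplitudes in ±[0.5, 1.5]; the last two sources share
a sparse spike train (6 events, random magnitudes) whose per-source
realizations differ by 5% amplitude jitter — near-identical, not
identical.  Event trains are convolved with a double-gamma HRF (positive
lobe peaking ~5 s, undershoot ~15 s, peak-normalized); per-source unique
Gaussian noise (sd 0.25) is added.

Time courses ride on a constant baseline of 2.5 added at mixing time
(stored inside the subject's time-course matrix, so
`clean_data = tcs @ maps` holds exactly).  The baseline matters: Rician
(magnitude) noise `sqrt((clean+n1)² + n2²)` is sign-preserving only around
a positive operating point, as real scanner intensities are.  Without it
the magnitude operation rectifies signed fluctuations and time courses
become unrecoverable in principle (measured matched time-course
correlation 0.27 versus 0.97 with the baseline); the constant shift is
removed again by preprocessing and does not affect any correlation.

Noise is calibrated per subject: `σ_n = (mean temporal sd of the clean
signal over active voxels) / target CNR`, where active voxels are those
where any z-scored source exceeds 0.5 sd.  Recomputing the CNR from the
stored clean data and σ_n therefore reproduces the target exactly; the 5%
tolerance in the checks allows for any alternative calibration.

**Structural cohorts.** One nonnegative volume per subject: a shared
smooth template (1 + 0.2 × smoothed noise) plus smooth per-subject noise
(sd 0.1), with patients losing `effect_size × severity` of intensity in
two disk-shaped regions; severity ~ U(0.1, 1) for patients and exactly 0
for controls.  Volumes are 2D grids (default 32², kept 2D for speed; the
NIfTI export writes one-slice 3D volumes).  The XOR cohort adds two
regional offsets of random sign and labels each subject by the parity of
the signs — linearly inseparable by construction.  The signed-source
dataset (for the unit-type comparison) activates random source subsets at
amplitudes of either sign with additive Gaussian noise and no baseline.

**What the synthetic data does not emulate:** head motion, physiological
and scanner drift, spatial autocorrelation of fMRI noise, 3D anatomy,
registration error, site effects, class imbalance.  Passing these
benchmarks shows the algorithms do what they claim under their own
modeling assumptions, not that they will perform equally on real scans.

## Validation experiments and problem sizes

All experiments run at desk scale, with sizes chosen as the package's own
defaults: source recovery uses 20 subjects × 128 volumes on a 64×64 grid
(≈1100–2600 in-mask voxels), a 64-unit tanh RBM, ε = 0.08, λ = 0.1,
batch 5, 30 epochs (recovery is already converged there; the reference
protocol trains 75).  Matched spatial-map correlations are computed on
in-mask voxels, time courses by linear projection without the hidden
nonlinearity.  The depth and embedding experiments use 200-subject
cohorts on 32² grids with the 50-50-100 stack.  The O(kn) scaling check
times `dm_step` at n ∈ {1000, 2000, 4000}, k = 20 — large enough that
vectorization overhead does not mask the asymptotics — and accepts fitted
exponents in [0.8, 1.3].

## Known limitations

* The fine-tuned stacks optimize classification, not neighborhood
  structure; the class organization of their activation geometry (what
  the embedding experiments measure) varies across seeds, which is why
  those checks are asserted on medians.
* The exact oracle is limited to standard-form Gaussian visibles and
  ≤ 12 hidden units by design.
* CD-1's gradient is biased (by construction); only the multi-step
  sampling chain converges to the exact gradient.
* The CLI covers the common paths (simulate, train, extract, embed,
  evaluate); unusual combinations are expected to go through the Python
  API.
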