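# Methods

This note records the models implemented in `sparsebelief`, the
assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic experiments can demonstrate.

## Sparse-response RBM

An RBM over binary visible units v and hidden units h has energy
E(v, h) = −v′Wh − c′v − b′h and joint law p(v, h) ∝ exp(−E).  `c` is the
visible bias and `b` the hidden bias throughout; the update rules couple
`c` to visible statistics and `b` to hidden statistics.  Real-valued
inputs in [0, 1] are treated as Bernoulli activation probabilities, the
standard treatment for normalized image intensities; this is why every
upstream stage is required to deliver features in [0, 1].

Training is contrastive divergence: the model-expectation term of the
log-likelihood gradient is replaced by statistics after k Gibbs steps
started at the data (k = 1 by default).  The implemented chain samples
*both* layers — the hidden layer from p(h|v) and the visible layer from
p(v|h) — so its stationary law is exactly the RBM's equilibrium
distribution.  The final read-off is Rao-Blackwellized: the visible moment
uses p(v|h) probabilities given the last hidden sample, and the pair and
hidden moments use p(h|v) probabilities given the last visible sample.
Each estimator is conditionally exact in one layer, which reduces variance
without introducing bias; an alternative sometimes seen in practice —
propagating visible *probabilities* through the chain — is cheaper but
measurably biased (on a 4+3-unit model with N(0, 0.5) weights its
long-chain pair statistics deviate by ≈0.04 from the exact values, versus
≈0.004 sampling noise for the implemented chain at 20,000 chains), and
would not converge to the equilibrium expectations at all.

The sparse-response variant adds, after every CD update, a second additive
step ε·λ·g where g is the negative gradient of the L1 penalty
Σ_l ‖p(h|v^(l))‖₁:

    g_W[i,j] = −Σ_l p_j(l)(1−p_j(l)) v_i(l),   g_b[j] = −Σ_l p_j(l)(1−p_j(l)).

The gradient is summed (not averaged) over the mini-batch, so the
effective sparsity pressure scales with batch size while the CD term is a
batch average; with the default batch of 16 a nominal λ of 0.1 therefore
acts like ≈1.6 on the per-sample scale.  This asymmetry is retained
deliberately — the penalty is defined as a sum over training cases — and
documented here because it matters when comparing λ values across batch
sizes.

Defaults: ε = 0.05, λ = 0.1, k = 1, 30 epochs, batch 16, weights
initialized N(0, 0.01²), biases 0, no momentum or weight decay.  All are
exposed in `SRTrainConfig`.

### Exact oracles

`exact_model_statistics` computes equilibrium expectations for models with
at most 20 units by enumerating visible configurations and marginalizing
the hidden layer analytically (p*(v) = e^{c′v} Π_j (1+e^{b_j+v′W_:j})).
The test suite re-derives the same quantities by brute-force enumeration
of the full joint, keeping the two routes independent.

## SR-DBN

The deep belief network stacks three equal-width SR-RBMs (configurable).
Greedy pretraining propagates deterministic hidden probabilities — never
samples — so the pipeline is reproducible bit-for-bit from its seed.
Fine-tuning attaches a softmax head to the top hidden layer and runs
full-batch plain gradient descent on the training cross-entropy through
the entire stack.  The head is a scaffold: it is kept for diagnostics but
classification is always delegated to the ELM.

Fine-tuning defaults are lr = 2.0 for 2000 epochs.  These look aggressive
but are deliberate: after CD pretraining on decorrelated inputs the
network sits on a near-flat plateau of the loss (hidden activations nearly
constant, gradients tiny), and plain gradient descent needs either a large
step or many epochs to traverse it.  Full-batch epochs on post-PCA
problem sizes cost fractions of a millisecond, so the budget is cheap; the
non-finite-loss guard aborts cleanly if a configuration diverges
(empirically lr ≳ 5 on the synthetic problems).

Whether fine-tuning should be supervised is genuinely open in this family
of designs; it is implemented as supervised (`finetune: supervised | off`)
because the stage sits between feature learning and classification in a
labeled protocol, and the alternative — no fine-tuning — is one switch
away.

## Snapshot PCA

When p ≫ n the principal axes are recovered from the eigendecomposition of
the n × n Gram matrix of the centered data and mapped back to feature
space; this is exact PCA, not a sketch.  A thin SVD is used when n ≥ p.
Components carry a deterministic sign convention (largest-magnitude
loading positive).  Component count is chosen as the smallest k whose
cumulative explained-variance ratio reaches 0.90, capped at 20; both knobs
are configurable.  Eigenvalues below 10⁻¹² of the leading one are treated
as numerically null and dropped with a warning if the request exceeds the
numerical rank.  PCA is fitted per modality, inside each training fold
only.

Between PCA and the DBN the scores are divided by their per-component
training standard deviation (a fitted PCA parameter, so no extra
statistics are estimated) and squashed through a logistic.  Raw scores
squashed directly pile up near 0.5 with tiny spread, leaving the RBMs
almost no dynamic range; whitening first spreads every component across
the informative band of the sigmoid.

## Extreme learning machine

Input weights A and hidden biases d are drawn once from Uniform[−1, 1]
(the canonical "random within a given range") and never trained.  With
H = sigmoid(XA + d), the output weights solve min‖Hβ − T‖_F with minimum
norm, computed by SVD pseudoinverse with relative singular-value cutoff
10⁻¹⁰.  Targets are one-hot in {0, 1}; prediction is arg-max with ties to
the lowest class code; the positive-class score column feeds ROC analysis.
Default width L is 10× the input dimension capped at 1000.  A degenerate
H with all rows identical is fitted anyway (minimum-norm solution) and
logged.

## Evaluation protocol

Stratified folds are built per class: shuffle, then deal round-robin, so
per-fold class counts deviate from the ideal by at most one subject.
Within each fold, every stage — min-max normalization, PCA, SR-DBNs, ELM —
is fitted on the training 80 % only; out-of-range test values are clipped
into [0, 1].  Metrics: ACC/SEN/SPE in percent from the confusion counts,
AUC by trapezoidal threshold sweep whose tie handling makes it equal to
the Mann–Whitney concordance probability with half-credit for ties.
Undefined ratios (empty denominator) are reported as NaN with a warning
and ignored by the fold average.  AUC is fold-averaged, not pooled.
Aggregates are mean ± sd over repeat-level means.  The positive class is
the more impaired group of each task, which orients sensitivity toward
disease detection.  Per-repeat fold seeds derive from the master seed by
named substreams, so any configuration is reproducible bit-for-bit.

Pipeline variants: `full` (PCA → SR-DBN per modality → concatenation →
ELM), `no_sparsity` (identical with λ = 0, i.e. a plain DBN), and
`pca_elm` (PCA scores straight into the ELM).  Feature fusion across
modalities is concatenation before the single ELM — the minimal reading of
one classifier consuming several feature streams.

## Synthetic data

The generator draws, per modality and class, x = μ_c + Bz + ε with
z ~ N(0, I_r), ε ~ N(0, σ²I), then squashes through a logistic.  Class
means sit `separation` within-class standard deviations apart along a
random unit direction; modalities share labels but draw independent mixing
matrices (partially redundant signal, as with PET/GM/WM maps).  Defaults:
60 subjects per class, 3 modalities, 50 features, rank 5, σ = 0.1,
separation 4.0, latent marginal sd 0.2 per feature — sizes chosen to be
desk-scale analogues of a few-hundred-subject cohort after dimension
reduction.  Seeds split deterministically per modality and class, so
separation 0 yields exactly identical class-conditional distributions.

What this emulates: bounded, positively-valued, low-rank-correlated
features with a controllable linear class signal.  What it does not:
spatial voxel structure, scanner and site effects, intensity
non-Gaussianity, label noise, class imbalance of real cohorts.  Passing
the end-to-end checks therefore demonstrates that the machinery is
correct and leak-free and that the stack preserves a strong class signal —
not that it attains any particular accuracy on real imaging data.

Toy NIfTI volumes (one class with a central sphere attenuated by a chosen
factor) exercise the I/O path: manifest parsing, nonzero-union masking,
C-order flattening (the scan order is fixed and recorded in dataset
metadata).

## Numerical and design notes

- All randomness flows from named substreams of a master seed
  (`_utils.substream`); identical seeds give bit-identical datasets,
  models, and CV results.
- Bundle persistence is a custom single-file container (JSON header + raw
  C-order float64 bytes) because saving must be byte-deterministic for
  checksum-level reproducibility; archive formats embed timestamps.
  Corrupt or truncated files raise a typed `BundleFormatError`.
- Min-max normalization maps constant columns to 0 and clips test values
  into [0, 1]; applying it twice equals applying it once.
- Test problem sizes (e.g. 10 CV repeats, 20,000 evaluation chains,
  4+3-unit enumeration models) are desk-scale choices that keep the whole
  suite runnable in minutes while leaving Monte-Carlo noise well below the
  asserted tolerances; the 200-repeat study protocol is one config field
  away.

## Known limitations

- Bernoulli visible units only; Gaussian-visible RBMs are out of scope, so
  inputs must be rescaled to [0, 1].
- Plain CD-1 with no momentum, weight decay, or persistent chains; on
  decorrelated post-PCA inputs the unsupervised features are weak and the
  supervised fine-tuning stage carries most of the discriminative
  adaptation.
- The ELM is unregularized; with L ≥ n it interpolates its training set,
  which is intended behaviour of the closed-form solve but means noisy
  small-sample problems lean on the minimum-norm property for their
  generalization.
- No spatial preprocessing (segmentation, normalization, smoothing,
  partial-volume correction) is performed or modeled; inputs are assumed
  already preprocessed.
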