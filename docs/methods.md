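# Methods

## Data model

All computation runs on `BinaryDataset`: a samples × variables matrix of
{0, 1} with unique sample ids and variable names. Rows are haploid
chromosomes (or patients), columns are SNP minor-allele indicators.
Missing values are rejected at read time; the intended inputs are complete
haploid panels. Two on-disk formats are supported: a delimited matrix with
a header row (comma/tab, sniffed), and IMPUTE-style `.hap` panels (one SNP
per row, one chromosome per column, transposed on read so downstream code
always sees samples as rows; an optional `.legend` file supplies variant
names). Column indices are 0-based half-open in the library; the CLI's
`--locus` option takes a 1-based inclusive start for human use and
converts.

The MAF filter drops variants whose minor allele frequency
min(f, 1 − f) is *strictly below* the threshold — a variant exactly at the
threshold is kept.

## Restricted Boltzmann machine

Energy E(v, h) = −v′Wh − a′v − b′h; p(v, h) = e^{−E}/Z. Both conditionals
are products of logistic units, used for block Gibbs sampling and for the
one-step reconstruction whose mean squared Euclidean distance to the data
is the monitoring proxy for the likelihood ("reconstruction error" —
chosen as squared distance because it is smooth and comparable across
epochs).

Training is CD-k (default k = 1) plain SGD: per minibatch, the positive
phase uses hidden activation *probabilities* given the data; the negative
phase runs k Gibbs steps with sampled binary states, ending on hidden
probabilities. No momentum or weight decay; weights are initialized
N(0, 0.01²), biases at zero; default minibatch size 20, suited to the
small-sample regimes this package targets. Sampling uses one independent
chain per requested sample (default burn-in 50 — small models mix fast;
configurable). Conditional sampling resets clamped visible variables after
every visible update.

## Deep Boltzmann machine

Layered energy E(s) = −Σ_l s_{l−1}′W_l s_l − Σ_l b_l′s_l. Training:

1. **Greedy layer-wise pre-training.** RBMs are trained bottom-up, each on
   the hidden activation probabilities of the previous one (probabilities,
   not samples, for lower variance at small n). Because in the assembled
   DBM every interior layer receives input from both neighbours, the
   pre-training doubles the input on exactly the sides that will face
   another layer: the first RBM doubles its bottom-up input, the last its
   top-down input, interior RBMs both. Weights are then used unchanged at
   assembly; biases of layers shared by two RBMs are averaged.
2. **Fine-tuning.** Stochastic gradient ascent on the mean-field
   variational lower bound: the positive phase runs mean-field fixed-point
   iteration (default 10 iterations, tolerance 1e−6) with the visible
   layer clamped to the data; the negative phase advances persistent Gibbs
   chains on the full network (default 5 chains × 5 Gibbs steps per
   update). Setting `epochs=0` keeps the pre-trained stack: a
   pre-training-only model.

Gibbs sampling alternates odd and even layers (conditionally independent
blocks). `top2_latent_dims` returns the mean-field means of the top hidden
layer and deliberately requires exactly two top units — with a larger top
layer there is no canonical two-dimensional reduction, and silently
projecting would mislead; the error message names the required
architecture.

## Likelihood machinery

Internally an RBM is the one-hidden-layer special case of the layered
model. Within any layered model the odd layers are conditionally
independent given the even layers, so sums over odd layers collapse
analytically via Π(1 + e^x); exact partition functions enumerate only the
even layers. A hard cap of 24 total units guards the exact routines.
`exact_loglikelihood` additionally collapses p*(v) per sample by absorbing
vW₁ into the first hidden bias.

AIS estimates log Z along a geometric path that scales only the weights by
β ∈ [0, 1] (equally spaced; defaults: 100 temperatures × 100 particles,
accurate within seconds at ≤ 60 units). The β = 0 base model retains the
biases, so the base partition function is analytic and the path has lower
variance than annealing from the uniform distribution. The reported
standard error is the delta-method error of log-mean importance weight
from the particle variance. The per-sample DBM log-likelihood clamps v,
absorbs vW₁ into the first hidden bias, and runs a separate AIS estimate
of the clamped partition function per sample; the lower bound combines the
mean-field expected energy and entropy with the AIS log Ẑ.

## Baseline generators

**Independent marginals (IM)** stores the empirical frequency of each
variable and samples cells independently.

**Generative MICE** draws a uniformly random variable order from the seed,
stores p(v₁), and fits one logistic regression per later variable on its
predecessors. Candidate predictors are added consecutively in order; a
candidate is *collinear* (and excluded from this and all later models)
when appending its column to the design matrix — intercept included — does
not increase the matrix rank (tolerance-based rank test, tol 1e−8, a
deterministic criterion). A constant target variable is predicted by its
constant without a regression, and constants never serve as predictors.
Binary data at small n make complete separation common, so when the
unpenalized MLE produces |β| > 15 the model is refit with a weak L2 ridge
(λ = 1e−4) and all coefficients are capped at ±15. One fitted chain is
reused for all sampling. Sampling walks the chain in order and restores
the original column layout.

## Metrics

The utility distance d(x_gen, x_ref) builds both pairwise log-odds-ratio
matrices — each 2×2 table cell that is zero is replaced by 0.5 so every
log OR is finite; only zero cells are modified — and takes the RMSE over
the strictly lower triangle. The proportion of overfitting is
(d(gen, val) − d(gen, train)) / d(gen, val); it is ≤ 1 by construction,
positive when the generated data sit closer to the training panel, and
undefined (guarded) if d(gen, val) = 0.

The membership attack guesses "training member" for a probe record iff
some generated sample lies within a Hamming-distance threshold (the
absolute-value norm on binary vectors). Training probes yield TP/FN, test
probes FP/TN; the default threshold grid is 0..10. Precision with zero
positive guesses is reported as missing, never as 0, and missing values
are excluded from medians — silent zeros would bias summaries at small
thresholds where the attack makes few guesses.

## Distributed harness

`split_sites` cuts the cohort into consecutive equal shares (remainder on
the leading sites). Each site fits a clone of the generator on its share
and generates as many samples as the share holds, so the pooled synthetic
data matches the total training size. The hyperparameter search minimizes
d(x_gen, x_test) over random initializations × training epochs; DBM/RBM
candidates are checkpointed at up to 20 evenly spaced epochs (configurable
down to every epoch) rather than literally every epoch, trading selection
granularity for runtime; the evaluated grid is recorded in the selection
record. Experiment summaries use type-7 (linear-interpolation) quantiles,
noted in the output metadata. In `run_experiment` the attack's non-member
probes are the leading n_train validation samples, because the attack
wants a probe set of the training size and the test partition is smaller.
Every seed in the harness derives deterministically from the master seed
via `numpy` seed sequences with a structured spawn key, so cells are
independent and can run in any order with identical results.

## Synthetic data

`simulate_snp_sets` emulates a case/control SNP panel: background cells
are iid Bernoulli noise (default p = 0.1), and "SNP sets" — blocks of five
consecutive minor alleles standing in for jointly deleterious mutations —
are planted at evenly spaced starts (columns 0–4, 10–14, … at the
defaults). Each case activates each block independently with probability
`set_activation_p` (default 0.5, so different cases carry different block
subsets; set it to 1 for all-blocks-always); activation overwrites noise
with ones, controls get background only. Defaults: 500 samples, 50
variables, 250/250 case/control. Case rows come first; callers who need
mixed site shares should shuffle before splitting. What this generator
does *not* emulate: linkage-disequilibrium decay, allele-frequency
spectra, or diploid genotypes — passing tests show that block-structured
co-occurrence is learned and preserved, not that real LD structure would
be.

`simulate_iid_bernoulli` provides independence fixtures;
`simulate_logistic_chain` samples a sequential-logistic process whose
semantics mirror the MICE sampler exactly, giving ground-truth parameters
for recovery tests.

## Problem sizes and numerical choices

Exact-versus-AIS checks run on models of ≤ 8 units, where full enumeration
is instant; training checks use the 500 × 50 simulated panel, where a full
DBM fit (30 + 30 epochs) takes well under a second; distribution-recovery
checks use 50 000 Gibbs chains. Degenerate inputs are handled explicitly:
empty datasets are rejected at fit time, zero-variance columns
short-circuit in MICE, d(gen, val) = 0 raises rather than dividing by
zero, and clamped indices are validated against the visible layer.

## Known limitations

- Fine-tuning uses a fixed learning rate and small persistent-chain pool;
  very deep or wide DBMs would need more chains and a decaying rate.
- Mean-field inference is approximate; its means can deviate from exact
  posterior marginals for strongly coupled models (the tests document a
  0.05 tolerance on weakly coupled ones).
- AIS error bars are delta-method approximations and can understate the
  error when the importance weights are heavy-tailed (few effective
  particles).
- Partitioned layer architectures and DBN-style generative sampling are
  out of scope; continuous visible units are not supported.
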