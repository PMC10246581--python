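# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The prediction model

A field plot is a *bag* of instances: every time-stamped image in every
channel (5-band multispectral, 1-band thermal, 1-band digital elevation
model) plus, optionally, the line's SNP dosage vector. A set function over
the bag is permutation-invariant iff it decomposes as a transformation of a
summed per-instance transformation; we realise that decomposition as
*encoders → attention pooling → regressor*:

* **Image encoders.** One encoder per channel. The default `tiny` encoder
  average-pools the input down to an 8×8 grid (the synthetic imagery carries
  its signal in channel statistics, not fine texture), then applies a small
  residual CNN (widths 8 → 16, two residual blocks) with global average
  pooling and a projection to 256 dimensions. A `resnet18` option provides
  the standard 18-layer residual topology (4 stages, widths 64–512) for
  larger-scale work. Single-band channels pass through a learned 1→3
  channel-adapter convolution before the stem. No pretrained weights are
  used: the band statistics of plot imagery are unlike natural photographs.
* **Genotype encoder.** SNP dosages (centered by −1 so calls lie in
  {−1, 0, 1}) feed a fully connected net 1024 → 512 → 256 with rectifier
  nonlinearities. Missing calls must be imputed beforehand (per-marker mean,
  the genomic-prediction default).
* **Optional encodings.** A one-hot flight-date block (vocabulary fixed at
  training, plus one reserved slot for unseen dates, which new environments
  guarantee) and/or a one-hot channel block (multispectral / thermal / DEM /
  genotype) are appended to each embedding. The genotype instance has no
  date and receives an all-zero date block.
* **Gated attention pooling.** Per head, aᵢ = softmax(wᵀ tanh(V hᵢᵀ)) and
  z = Σ aᵢ hᵢ; the softmax subtracts the max logit before exponentiation.
  All channels are pooled jointly in a single bag (the architecture's fusion
  step happens inside the attention, not by concatenating per-channel
  summaries); heads are pooled independently and concatenated.
* **Regressor.** One hidden layer (128 rectified units) then a linear
  output in t/ha. At training start the output bias is set to the mean
  training yield so optimisation concerns deviations, not the overall scale.

Training minimises MSE with Adam. Bags larger than the `bag_size`
hyperparameter are uniformly subsampled *without* replacement, fresh each
iteration; inference always uses full bags, which removes evaluation
stochasticity and makes permutation invariance exact to floating point.
Validation Pearson is tracked per epoch with early stopping (patience
configurable); `plateau` (halve on stagnation) and cyclic `cosine`
learning-rate schedules are available. The random-search grid covers
learning rate {1e-5, 1e-4, 1e-3}, schedule {none, plateau, cosine}, batch
{8, 16}, bag size {8, 16, 32}, heads {1, 4, 8}, and the two encoding flags.

The attention width l defaults to 128 — a mid-sized gating layer between
the 256-dimensional embeddings and the scalar logit; it is configurable and
nothing downstream depends on the exact value.

## Evaluation protocol

Splits are **grouped by entry** (a genetically unique line never appears in
two partitions — replicates would otherwise leak) and **stratified by
trial**, at fractions 80/10/10, as repeated random splits (default 5
repeats). An entry whose replicates span several trials is stratified by its
majority trial, with a warning. Baselines that need no validation data may
fold the validation split into training; test sets are identical across
methods. Metrics: MAE, MSE, Pearson r, R² = 1 − SSres/SStot, at plot level
or after entry-level averaging of replicate plots.

For a new environment, genotypes are harmonized to the trained marker list
by name: shared markers are reordered, markers missing from the new panel
are filled with the training-set mean dosage, and an overlap below 50%
(configurable) is an error. Genotype-only fine-tuning continues MSE training
on the *original* training split presenting genotype-only bags — the new
environment's yields are never touched — with image encoders frozen, at
0.1× the original learning rate for a few epochs (default 5).

## The synthetic generator

The generator produces the statistical structure the model assumes, not
photorealistic imagery:

* **Genotypes.** Per marker, allele frequency p ~ U(maf range); a call is
  heterozygous with probability equal to the configured het rate h and
  otherwise homozygous with alternate-allele probability chosen so that
  E[dosage]/2 = p exactly (inbred-line genotypes have far less
  heterozygosity than allele-independent Hardy–Weinberg sampling would
  give; h is therefore a knob, not 2p(1−p)). Missing calls are i.i.d.
* **Genetic architecture.** A random subset of markers carries N(0,1)
  effects; breeding values g are standardized to unit variance. Yield =
  mean + g + trial effect + residual, in t/ha (mean 6 t/ha, a typical
  irrigated spring-wheat level). When a target heritability h² is given,
  the residual sd is derived from 1/h² − 1 = trial_sd² + residual_sd², so
  the nominal h² is exact by construction; setting residual_sd explicitly
  overrides this.
* **Imagery.** Each plot has a latent canopy-health trajectory
  s(d) = q · growth(d), where growth(d) is a logistic green-up curve over
  the season and q ∈ (0,1) is a sigmoid of the plot's standardized yield
  deviation — so images see genetics *and* environment, which is exactly
  why image-assisted prediction can beat genotype-only prediction. Image
  counts per plot, date and channel are Poisson (zeros allowed, emulating
  irregular flight coverage). Multispectral band means are set so that the
  image-mean NDVI equals s(d) plus noise whose sd is smallest at mid-season
  and grows toward both season edges: mid-season flights are the most
  informative about yield *by construction*, mirroring flowering/grain-fill
  being the critical window. Thermal is a single band inversely related to
  s(d) with the largest noise; DEM tracks accumulated growth and is
  informative late. Per-pixel Gaussian texture noise is added on top.
* **Defaults.** 8 flight dates spanning 18 Jan–21 Mar (so the shipped
  four-window date-group preset applies), 64×64-pixel images, 2 images per
  plot/date/channel in expectation. Real trials are one to two orders of
  magnitude larger in plots, markers and images; the defaults are sized so
  a full train/evaluate cycle runs in minutes on one CPU.

A second environment can be simulated from an existing one: fresh lines are
drawn from the same marker panel and the *same* causal effects, with new
trial and residual deviations — the cross-environment prediction setting.

What the generator does **not** emulate: spatial field trends and
neighbour effects, genotype×environment interaction in the genetic effects,
linkage disequilibrium between markers, reflectance calibration, and any
within-image spatial structure. Tests that pass on this generator therefore
demonstrate that the architecture and protocols recover the signals the
generator encodes; they do not certify performance on real trials.

## Study conditions used by the recovery tests

The end-to-end tests simulate trials of 150 lines × 2 replicates in 5
trials (300 plots), h² = 0.5, 150 markers of which 8 are causal, and
imagery at the defaults above with thermal/DEM noise raised to 0.6 so that
only multispectral images carry usable signal. The causal-marker count is
scaled down in proportion to the population: with ~100 training entries,
per-marker effects must each explain several percent of the genetic
variance to be estimable at all, just as thousands of markers are only
estimable with thousands of entries. The model under test uses the tiny
encoder, 4 heads, bag size 8, both encodings, lr 1e-3, and early stopping
on validation Pearson (12 epochs multi-modal, 40 genotype-only). Under
these conditions multi-modal test Pearson reaches ~0.9 and genotype-only
~0.3–0.6, attention concentrates on the multispectral channel and the
February (mid-growth) date group, and the genotype pathway transfers to a
freshly simulated environment with bootstrap CI excluding zero — each
asserted by `tests/test_acceptance.py`, three seeds.

## Numerical and design choices

* The NN core is reverse-mode autodiff over float64 numpy arrays; single
  threaded, fully seeded, hence bit-reproducible — re-running any training
  with the same seed yields identical weights.
* Softmax is computed with max-subtraction; convolution uses im2col.
* The *mode* of a continuous pixel distribution is the center of the most
  populated bin of a 256-bin histogram over the band's observed range, ties
  to the lowest bin: deterministic and resolution-controlled. Vegetation
  indices are computed per pixel and then summarised (not indices of band
  means); denominator-zero pixels are masked, never NaN-propagated.
* QC boundary semantics are literal: markers *strictly below* 40% missing
  and 10% heterozygosity are kept; lines with *more than* 50% missing are
  removed (exactly 50% is kept). Both thresholds are arguments.
* Date groups without images yield masked feature entries, imputed with
  training-column means at baseline fit time.
* Multi-allelic VCF records are rejected with an explicit error rather than
  split: the target genotyping pipelines emit biallelic SNPs.
* The evaluation design uses 5 repeated 80/10/10 grouped-stratified random
  splits rather than classic 5-fold partitioning, honoring both the stated
  fractions and the repeat count (a classic 5-fold would force 20% test).
* Selection-curve ties break by entry id; multi-head attention summaries
  are reported per head plus a head-mean; per-date attention masses are
  renormalized within dated instances so the genotype instance does not
  dilute the temporal picture.

## Known limitations

* Pure-numpy training is desk-scale: hundreds of plots, not tens of
  thousands; the `resnet18` encoder exists but is impractical to train here.
* Mean-dosage imputation and mean-dosage marker fill are simple; matching
  real pipelines (e.g. LD-aware imputation) is out of scope.
* The attention weights are an interpretation device, not a causal
  attribution; per-SNP saliency is not implemented.
* Orthomosaicking, geo-rectification and plot-boundary extraction are
  upstream of this package: inputs are per-plot image crops.
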