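# Methods

`subloc` classifies the subcellular localization of fluorescently tagged
proteins from two-channel 64×64 single-cell image patches (red: cytosolic
marker delineating the cell; green: the tagged protein), first per cell
with an 11-layer convolutional network, then per protein by aggregating
cell populations with a Dirichlet–multinomial posterior. A random forest on
classical hand-crafted features provides the baseline, a second forest
filters non-cell patches, and the trained network doubles as a feature
extractor for compartments never seen in training. Because real
high-content screens are large and external, the package ships a synthetic
microscopy generator that emulates the twelve compartment archetypes, so
the entire pipeline runs and is tested at desk scale.

## The classifier

The network is a VGG-style stack: eight 3×3 stride-1 convolutions with
widths 64, 64, 128, 128, 256, 256, 256, 256; 2×2 stride-2 max-pooling after
convolutions 2, 4 and 8 (so a 64×64 input flattens at 256·8·8 = 16,384);
then fully connected layers of 512, 512 and K=12 units and a softmax.
Batch normalization precedes every rectified-linear activation; dropout
(rate 0.5) acts on the first two fully connected layers during training.
This configuration carries 10,987,788 learnable parameters (weights,
biases, batch-norm scale/shift), verified against a closed-form
layer-by-layer count.

Training is stochastic gradient descent with momentum 0.9, initial learning
rate 0.1 halved every 16,250 iterations (25 epochs at the full scale of
65,000 training images and mini-batches of 100), weight decay 5·10⁻⁴ on
convolution and FC weights, Glorot-normal initialization, and per-pixel
training-set mean subtraction as the only preprocessing. Checkpoints are
evaluated every epoch and the weights with the lowest validation loss are
kept.

Implementation notes. The network — forward, backward and the optimizer —
is written directly in numpy: convolutions run channels-last as nine
shifted GEMMs (an im2col GEMM for the 2-channel input layer), and all
gradients are validated against central finite differences in the test
suite. Two choices the architecture description leaves open are resolved as
follows and treated as assumptions: pooling sits after convolutions 2, 4
and 8 (the 2–2–4 block reading that yields the 8×8×256 flatten), and
batch norm is applied to FC-1 and FC-2 but not to the softmax layer.
Convolutions use zero padding 1 so that three poolings take 64 to 8.
Batch-norm inference uses running averages with momentum 0.9; because the
averages start at zero, they are debiased by 1−0.9ᵗ after t updates — an
exact correction that matters only for short desk-scale runs and vanishes
at full scale. Ties in the class argmax resolve to the lowest class index.
The last incomplete mini-batch of an epoch is used (ceil convention).

### Desk-scale preset

The full configuration trains for days on a GPU; the package's `small`
preset keeps the depth and topology but cuts widths eightfold
(8, 8, 16, 16, 32, 32, 32, 32 / 64, 64, K; ≈173k parameters) so training
completes in minutes on one CPU core. Its dropout rate is 0: 64-unit FC
layers under dropout lose too much capacity and under-fit badly at these
sample sizes (the full-scale configuration keeps the rate-0.5 dropout of
its 512-unit layers). The standard study (below) trains it for 16 epochs at
batch 50 with initial learning rate 0.15 halved every 4 epochs, after a
2-epoch linear warm-up of the learning rate. The warm-up guards against an
initialization-dependent failure mode of narrow networks at high learning
rates — in the first epochs a class can be abandoned entirely and never
recovered — that full-scale training does not exhibit.

## Classic features and forests

The baseline mirrors the classical screening pipelines: a named,
fixed-order vector of 242 features per cell, spanning intensity statistics
(mean, median, SD, quantiles, extremes), Otsu-mask geometry (area,
perimeter, eccentricity, centroid offset, solidity, extent), 13 Haralick
co-occurrence statistics (32 gray levels by channel-wise min–max
quantization, distance 1, four directions, symmetric normalized matrices,
averaged over directions), Gabor filter-bank responses (zero-mean kernels,
2 frequencies × 4 orientations, mean magnitude and energy on the valid
interior), and Zernike moment magnitudes (orders ≤ 9 on a centered
radius-32 disk, intensity-normalized, rotation-invariant). Intensity,
geometry, Haralick and Gabor families are computed at two scales (native
and 2×2-mean-downsampled) for both channels; cross-channel features add
red–green correlation, intensity ratio, and the green mass inside the red
Otsu mask. Degenerate inputs give documented conventions instead of NaN:
constant images have co-occurrence contrast 0 and angular second moment 1,
empty masks yield all-zero geometry, zero-variance columns are skipped in
correlation analyses.

The compartment baseline is a random forest grid-searched on validation
accuracy over number of trees {50, 100, 250, 500, 1000}, features per split
and minimum node size {1, 2, 5, 10, 50}. The classical grid for features
per split assumed a fixed 435-wide table; here it is expressed as fractions
of the actual width {√p, 25%, 50%, 75%, 100%}. End-to-end desk-scale runs
use a reduced grid (100 trees × {√p, 50%} × node size {1, 5}) to stay
within minutes.

The cell/non-cell quality filter is a 100-tree forest whose features per
split ({2, 25%, 50%, 75%, 100% of width}) and majority-class downsampling
(balanced bootstrap subsampling on/off) are chosen by stratified 10-fold
cross-validation. Positive examples at desk scale are clean synthetic
renders sampled per class; the alternative double-agreement labeling
(cells classified correctly by both the network and the forest) is
available via `select_quality_positives(scheme="both_correct")`.

## Protein-level aggregation

Each cell's compartment is modeled as one draw from a protein-specific
multinomial over the K compartments. With a symmetric Dirichlet prior α₀
(default 1, the flat/uninformative reading; exposed as a knob), the
posterior concentration is α_k = α₀ + Σ_cells p_k — the prior plus the
*soft count* of cells per compartment, summing full per-cell probability
vectors rather than hard argmaxes (a `hard=True` mode does the latter for
comparison). The protein call is the MAP compartment, which under the flat
prior equals the compartment with the largest soft count; this is verified
in the tests against brute-force argmax of summed probability vectors. The
posterior mass fractions (α_k − α₀)/Σ(α − α₀) estimate the frequency of
cells in which the protein occupies compartment k, so genuinely
dual-localized proteins surface in the top-k report instead of being forced
into one class. Proteins observed in fewer than a configurable number of
cells (default 10) can be filtered before reporting.

## Evaluation

Reports contain the K×K confusion matrix (rows true, columns predicted),
accuracy, Cohen's κ = (p_o − p_e)/(1 − p_e) with expected agreement from
the marginals, and per-class precision (column-wise) and recall (row-wise).
Uncertainty comes from a class-stratified bootstrap: complete (true,
predicted) pairs are resampled with replacement within each true class —
so every replicate preserves the original class counts exactly, a property
the tests check on the replicate matrices — and the 2.5th/97.5th
percentiles of the per-replicate statistics form the 95% interval (plain
percentile method, not BCa). Replicates in which a class receives zero
predictions contribute a missing precision value and are dropped before the
percentiles; classes with zero support report missing intervals. The
default is 20,000 replicates; desk-scale tests use 2,000. A class absent
from the truth reports recall as missing, never as zero.

## Transfer and interpretability

Four additional compartments (actin, bud neck, lipid particle, microtubule)
are held out of classifier training entirely. Random forests are fit on
either the trained network's first-FC-layer activations or the classic
features, on stratified subsamples of 1, 3, 5, 10, 25, 50, 100, 250, 500
training images per class (the desk-scale study uses 1–10 with 30/15/30
cells per class per fold), model-selected on validation accuracy and scored
on the test fold; repeating with derived seeds gives the learning curve.
Convolutional-layer features are global-average-pooled per channel to keep
forest inputs tractable (flattened maps are available via a flag).

Interpretability tools: 2-D t-SNE embeddings of layer activations (1,000
randomly sampled cells by default, perplexity capped at (n−1)/3, seed
recorded); per-neuron mutual information with the class label after
equal-frequency discretization into 16 bins (constant neurons get MI 0 by
convention; MI is non-negative and bounded by min(log₂ bins, class
entropy)); the strongest |Pearson r| between each neuron and any classic
feature; and maximally activating input patches, where the receptive-field
extent of a neuron is computed from the architecture (3 px for conv-1,
5 px for conv-2, doubling jumps after each pooling; FC layers see the whole
image) and border-clipped crops are returned sorted by activation.

## The synthetic generator

The generator renders parametric cartoons, not optics: a soft-edged
elliptical cell (radius 15–25 px) with an off-center nucleus (0.34 of the
cell radius ± 15%, random orientation), a red channel filling the cell with
a 50% dip inside the nucleus, and a green-channel archetype per class —
boundary ring (cell periphery), nucleus-excluding fill (cytoplasm),
resolvable Gaussian puncta with class-specific counts, sizes and placement
(endosome 4–8, Golgi 2–5 clustered away from the nuclear rim, peroxisome
1–3, spindle pole 1–2 pinned to the nuclear rim, lipid particle 2–6),
perinuclear ring with reticular strands (ER), thick curvilinear
random-walk tubules (mitochondrion; thin straight ones for microtubule,
patch-plus-cable for actin), a ring around the nucleus (nuclear periphery),
a round off-center patch inside the nucleus (nucleolus; rendered round
rather than as the textbook crescent so that its global statistics match a
large cytoplasmic punctum and only the nuclear context identifies it), a
filled nuclear disk (nucleus), a faint-rimmed dark lumen (vacuole), and a band at the
mother–bud junction (bud neck). Confusable pairs are deliberately matched
in their global statistics — the nucleolar patch resembles a large
cytoplasmic punctum, spindle-pole and peroxisomal puncta overlap in count —
so that distinguishing them requires the spatial relation to the nucleus
and cell, which patch-global features cannot express. This reproduces the
error structure expected of the real problem (nucleus↔nucleolus,
punctate-class confusions) and is what gives the convolutional model its
edge at equal data.

The intensity model adds, on a 16-bit scale: background 1500 with a random
linear gradient (amplitude ≤ 400) and ±30% per-cell level jitter; signal
amplitude 4× background scaled per cell by a 0.5–1.5 expression jitter; a
per-cell diffuse cytosolic component carrying 5–35% of the green signal
(unincorporated protein); Gaussian blur σ = 0.8 px jittered ±20% (focus);
then Gaussian read noise (SD 150) and signal-scaled shot noise
(√(20·intensity)·N(0,1) approximation), clipped to [0, 65535]. Non-cell
artifacts are rendered as empty background, a signal-to-background ≈ 1.15
cell (below the quality regime), or red debris streaks without a
cell-shaped component. These defaults are the package's standard
conditions, calibrated once so that the classic-feature forest and the
small network land in the low-to-mid 80s with the network ahead — the
ordering the method is about — and are not adjusted per experiment.

All randomness derives from one master seed; the i-th cell of a dataset
uses seed `(master · 2654435761 + i) mod 2³¹`, so any cell is reproducible
in isolation. Datasets assign whole proteins to folds by largest-remainder
apportionment of the 72/14/14 fractions, making folds protein-disjoint by
construction; the manifest validator enforces this on every load.

What the generator does not emulate: realistic point-spread functions,
cell-cycle and morphological heterogeneity beyond size/position jitter,
segmentation errors inside the patch, protein-specific abundance
distributions, or spatial correlations between neighboring cells. Passing
tests therefore certify the pipeline's mechanics and the relative orderings
under controlled conditions, not absolute accuracy on real micrographs.

## The desk-scale study

`subloc.study` is the driver behind both the ordering tests and
`scripts/acceptance.py`. Per replicate seed it generates 12 classes × 7
proteins × 18 cells (1,512 cells; 5/1/1 proteins per class in train/val/
test), extracts features, grid-fits the baseline forest, trains the small
network (16 epochs, batch 50, lr 0.15 halved every 4 epochs, 2-epoch
warm-up), and measures:
held-out accuracy and κ for both models; protein-level accuracy before and
after the ≥10-cell filter, plus accuracy at 1/3/10/18 cells per protein by
repeated subsampling; the transfer comparison (deep FC-1 features vs
classic features, sizes 1–10, three repetitions); and median neuron-class
MI and median max-|r| to classic features for conv-1 versus the last hidden
FC layer. Five replicates take roughly 16 minutes on one CPU core; the
problem sizes above are the package's standard desk-scale conditions.
Orderings are asserted on seed means: a single 216-cell test fold carries
±3% binomial noise, which individual replicates of two models separated by
a few points can and do cross.

## Known limitations

- The 242-feature inventory stands in for the classical several-hundred-
  feature pipelines; family coverage, not feature-for-feature identity, is
  the design goal.
- The small network preset under-fits relative to the full architecture;
  absolute accuracies at desk scale are in the 80s, not the 90s, and carry
  seed-to-seed variance of a few percent.
- The Dirichlet aggregation assumes cells are independent draws; real
  populations violate this through imaging batch effects.
- The bootstrap treats cells as exchangeable within class; protein-level
  clustering of cells is not resampled.
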