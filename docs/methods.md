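# Methods

## Optimizer

RDBPSO minimizes a box-bounded objective f over ℝᵈ with a population of
N particles (default N = 30, 100 iterations — the canonical study
settings). Initialization draws two uniform positions per particle,
evaluates both, and stores the better as the primary memory y and the
other as the secondary memory y_second (a tie keeps the first draw as
y). The current position x is bookkeeping only: the update equations use
memories exclusively, so x is set to the better of the particle's two
candidates each iteration.

Each iteration:

1. **Pairing.** Particle indices are randomly permuted and taken two at a
   time. Within a pair, the particle with lower f(y) is the leader; ties
   go to the lower original index so seeded runs are reproducible. With
   an odd population the leftover particle runs the worker role with
   (gbest, gsecond) standing in for the leader's memories, keeping the
   budget at 2 evaluations per particle.
2. **Candidate generation.** The leader's four admissible guide pairs
   combine {gbest, gsecond} with {y, y_second}; the worker's combine the
   leader's memories with its own. Dropout keeps 2 of the 4 uniformly
   without replacement, independently per particle per iteration. Each
   kept pair (p₁, p₂) yields one candidate drawn coordinate-wise from
   N((p₁+p₂)/2, |p₁−p₂|) and clipped to the box. A coordinate where
   p₁ = p₂ has zero spread and is reproduced exactly; no variance floor
   is applied — stagnation at a shared coordinate is a property of the
   sampling rule, not an error.
3. **Memory update.** Hierarchical: f_new < f(y) demotes y; otherwise
   f(y) ≤ f_new < f(y_second) replaces the second layer only. A
   non-finite candidate fitness is discarded with a warning (during
   initialization it aborts, since memories would be undefined).
   The leader of a pair is processed before its worker, and the worker's
   combinations see the leader's memories as already updated this
   iteration (sequential update).
4. **Consolidation.** All 2N memories are pooled and sorted by fitness
   (ties: particle index, then layer); the two lowest entries become
   gbest/gsecond — possibly both from one particle. The sort dominates
   the per-iteration overhead, O(N log N) beyond objective calls.

The budget is exactly 2N evaluations per iteration plus 2N at
initialization — half of the exhaustive variant that would evaluate all
four combinations. The elitist memories make the best-fitness trace
non-increasing by construction.

One seeded NumPy generator per `optimize` call drives every stochastic
choice in a fixed order (initial draws, permutation, dropout indices,
Gaussian draws), so identical seeds give bit-identical traces.

**Velocity PSO baseline.** The comparison baseline is a global-best
velocity PSO with the canonical constriction-equivalent parameters
w = 0.7298, c₁ = c₂ = 1.49618. Velocities start at zero and are clamped
to ±(ub − lb); positions are clipped to the box. It spends N evaluations
per iteration. The choice of variant and parameters is a convention: only
the population size and iteration count were prescribed.

Bounds are validated as lb ≤ ub; a coordinate with lb = ub is a
legitimate degenerate box that collapses the search in that dimension.

## Feature extraction

Images are converted to single-channel luminance and resized to 256×256
(bilinear — the conventional default for intensity images). The 16
descriptors, in canonical column order:

- **GLCM (5).** Distance 1, angles 0°/45°/90°/135° averaged, 32
  quantized gray levels, symmetric and normalized. Contrast
  Σp(i,j)(i−j)²; correlation (defined as 1 for a zero-variance image);
  energy Σp² (the angular second moment); homogeneity Σp/(1+(i−j)²);
  entropy −Σp log₂p over nonzero cells. The parameter set is a declared
  convention — 32 levels keep entropy stable on 8-bit inputs — so
  absolute values are not comparable with other extractors, only
  self-consistent.
- **First-order statistics (6).** Mean, population standard deviation,
  Fisher skewness, excess kurtosis, and the 10th/90th percentiles with
  linear interpolation. Skewness and kurtosis of a constant image are
  defined as 0.
- **Wavelet energies (4).** Single-level 2-D Haar transform; per
  sub-band energy = sum of squared coefficients divided by the pixel
  count, so the features are resolution-comparable. LH/HL follow the
  filter convention in which HL (horizontal high-pass) responds to
  vertical edges; the orthogonality of the Haar basis means the four
  unnormalized energies sum to the image energy.
- **Edge density (1).** Sobel gradient magnitude thresholded at
  mean + 1·std of the magnitude map (adaptive, avoiding a dataset-tuned
  constant); density = flagged fraction ∈ [0, 1].

Standardization is a per-column z-transform with population std fitted
on the training table; a constant column maps to zeros rather than
dividing by zero. Feature tables round-trip through CSV at full float
precision (`float_precision="round_trip"` on read).

## Purity classifier

A solution is the row-major flattening of k cluster centers (k = 2:
healthy/tumor). Samples go to the Euclidean-nearest center, ties to the
lowest index. Purity is the majority-class overlap of the partition;
the optimizer minimizes 1 − purity, bounded by [0, 1 − max class
fraction] since purity never falls below the majority fraction. Empty
clusters contribute zero. Search bounds per dimension are the observed
min/max of the standardized features, tiled across the k centers — the
tightest box certain to contain useful centers. Fitting uses the whole
labeled table without a train/test split, mirroring the benchmark
protocol; the reported purity is therefore a training quantity, and
because purity is also the evaluation metric, accuracy = purity for the
fitted model by construction. Cluster-to-class mapping is by majority
label; an exact tie maps to healthy, the conservative screening default.

## Evaluation metrics

All five metrics derive from the k×l cluster-by-class contingency table:
accuracy and purity as the majority overlap (algebraically identical —
both are reported because both names are conventional); ARI in the
pair-counting form with combinatorial sums over cells and marginals;
NMI = 2·I(C,L)/(H(C)+H(L)) with natural logarithms (the base cancels);
FMI = TP/√((TP+FP)(TP+FN)) over co-clustered pairs — the standard
geometric-mean definition, which reproduces the published values.
Degenerate cases: ARI with a zero denominator is 1 for perfectly
agreeing trivial partitions and 0 otherwise; NMI of two trivial
partitions is 1; FMI with no co-clustered pairs is 0.

The bundled confusion matrices of the 800-image MRI benchmark are stored
in cluster-by-class orientation as published in the per-class counts;
re-deriving every metric from them reproduces the published table at 4
decimal places, which the test suite asserts cell by cell.

## Synthetic data

The **feature simulator** draws class-conditional isotropic Gaussians
over the 16 feature columns. `separation` is the Euclidean distance
between the class means in units of the noise std, spread evenly over
`n_informative` leading dimensions (default 6, reflecting that a subset
of the descriptors carries most of the real data's signal); this makes
the difficulty independent of how many dimensions are informative. At
separation 6 the Bayes error is ≈ 0.13% (half-distance 3σ), so a correct
fit reaches purity ≥ 0.99; at separation 3 the optimum is ≈ 0.93,
a regime where optimizer quality matters.

The **phantom simulator** emulates the discriminative structure of the
MRI benchmark at pixel level, not its anatomy: healthy phantoms are
bright (mean 180) with strong fine-scale band-limited texture (amplitude
45, Gaussian-smoothed white noise at σ = 1.5 px); tumor phantoms are
dimmer (mean 120), smoother (amplitude 12), and carry a dark Gaussian
blob (radius 40 px, depth −45) near the field center; both get pixel
noise (σ = 5) and are clipped to 0–255. These defaults put the
class-averaged intensity mean and GLCM contrast higher for healthy
images — the direction observed on the real data — with a margin that
desk-scale runs separate cleanly. What passing phantom tests shows is
that the pipeline recovers a *planted* contrast/intensity signal; it
says nothing about skull geometry, acquisition artifacts, or the much
weaker signal of real MRI.

## Benchmark harness

`run_benchmark` executes each requested algorithm over a seed list on
one labeled table and reports all five metrics per run plus mean and
sample (n−1) standard deviation per algorithm. The k-means (10
restarts), Gaussian-mixture (full covariance), and agglomerative (Ward
linkage) baselines delegate to scikit-learn — they are comparators, not
contributions; the linkage and covariance choices are exposed as
configuration with those conventional defaults. Swarm traces are kept
for convergence plots and record per-iteration evaluation counts so the
2N budget is auditable from logs.

## Problem sizes

Tests and the acceptance script use desk-scale problems chosen to keep a
full run in minutes while leaving the claims non-trivial: 200-sample
tables for recovery and paired-comparison runs (10 and 3×20 seeded
fits), 40 phantom images for the end-to-end pipeline, 200 random
partitions of n ≤ 40 for exhaustive pair-counting oracles. The published
headline accuracies on the real Kaggle dataset are exercised only
through the bundled confusion matrices, since the original images and
the authors' exact extractor parameters are external to the package.

## Known limitations

- Purity is both objective and metric; like the original protocol this
  couples optimization to evaluation and inflates purity relative to
  methods optimized for other criteria.
- The GLCM/wavelet/edge parameter choices are conventions; absolute
  feature values will differ from other extractors even on identical
  images.
- k > 2 is supported structurally (the encoding and purity generalize)
  but untuned; no cross-validation or held-out protocol is provided.
- The dropout ratio (2 of 4) is fixed, as in the original design.
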