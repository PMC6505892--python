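# Methods

## Problem and model

Activation tagging inserts a T-DNA carrying a tetramer of CaMV 35S
enhancers into a plant genome. Whether a flanking gene is up-regulated
depends on its promoter sequence and on the genomic distance between the
enhancer and the gene. `flankact` models the binary outcome (activated,
Ac, vs not, NAc) for one (gene, insertion) pair from sequence alone, in
two layers: per-encoding kernel classifiers over three sequence regions,
integrated by a naive-Bayes combiner, with a distance logistic both as a
prior model and as a feature weight.

### Coordinates and regions

All coordinates are 1-based inclusive (the GFF3 convention of the inputs).
The translation start site (TLS) is the first base of the start codon:
minimum CDS start for plus-strand genes, maximum CDS end for minus-strand
genes. Three regions per record, always reported 5'→3' on the gene's
coding strand:

- **UPS1K**: the 1000 bases immediately 5' of the TLS, excluding the TLS
  base; truncated with a warning at a chromosome end.
- **DISTANCE**: the sequence between the TLS and the insertion junction,
  both endpoints included (length x+1 for distance x). The junction
  coordinate stands in for the enhancer position; the offset of the
  enhancer tetramer within the T-DNA construct is rarely known, so it
  defaults to zero and is configurable.
- **MIDDLE**: the window of up to 301 nt centred on the central nucleotide
  of DISTANCE, at 1-based index ceil(L/2). For even L the centre is biased
  at most one base leftward — a deterministic convention. When DISTANCE is
  shorter than 301 nt, MIDDLE is the whole of it.

An insertion is classed US / DS / IG (upstream / downstream / intragenic)
relative to the gene span on the coding strand.

## Feature encodings

**N-gram** — raw overlapping k-mer counts for k = 3,4,5,6, concatenated
(5440 columns). Counts are not length-normalised; for DISTANCE this means
the encoding carries sequence length, which is distance information — a
deliberate property, not a leak. Windows containing N are skipped.

**Motif** — a both-strand PWM scan against a motif library. Scores are
log₂ odds against a 0-order background; per-position p-values come from
the exact distribution of the score under that background, computed by
dynamic programming over score-quantized PWM columns (1000 bins per
motif; the observed score is quantized with the same grid, so p-values
are exact for the quantized matrix). Occurrences at p ≤ 1e-4 (the
conventional scan threshold) are summarised per motif by six channels:
occurrence count; conservation (mean log-odds score); plus- and
minus-strand fractions; density = width × count / span of occurrences
(span = width for a single occurrence, so density 1); and mean distance
from occurrence start to the TLS. The distance channel is anchored at the
TLS because the encoding is computed on UPS1K, where the insertion site
lies outside the scanned sequence; anchoring at the insertion junction is
available via `motif.dis_mode = insertion`. PWMs are smoothed with a 1e-4
pseudocount at load so log-odds stay finite.

**NPC** — a 16-dinucleotide × P physicochemical property table is
column-standardised and reduced to 15 principal components (signs fixed
so each component's largest-magnitude loading is positive; with 16 rows
the centred table has rank ≤ 15, so 15 components always exist for a
full-rank table). The encoding is count(di) × component(di, j) / number
of valid dinucleotide windows, 240 values.

**CGI** — CpG islands are detected with 100-nt windows at 1-nt shift
passing GC% ≥ 50 and observed/expected CpG ≥ 0.6 (O/E = #CpG × window /
(#C × #G)); overlapping or adjacent passing windows merge, and merged
segments shorter than 200 nt are discarded — the standard windowed
island definition. The five encoded channels are island count, total
island length / promoter length, distance from the TLS to the nearest
island start, mean CpG percentage (100 × #CpG/(length−1) per island),
and a pooled raw count ratio #CpG/(#C × #G). The encoded ratio
deliberately omits the length factor used at detection time: the two
statistics are different definitions serving different roles, and both
are reported on detected islands.

**Pattern filter** — per-column Welch two-sample t-tests between Ac and
NAc records select N-gram columns (per region) and motifs (on the
occurrence-count channel; a selected motif keeps all six channels) at
P < 0.05, uncorrected. Zero-variance columns get p = 1. Welch rather than
pooled variance because class sizes and dispersions differ in realistic
data. Masks are fitted on training data only and frozen into the model
bundle.

## Distance model and feature weighting

pi(x) = logistic(b0 + b1 x) with frozen defaults b0 = 1.448,
b1 = −7.099e−5 (per-bp slope; half-activation near 20.4 kb). Training
refits the coefficients on the training records by maximum likelihood
(statsmodels); if the fit degenerates the frozen defaults are used.
Each record's feature vectors are multiplied elementwise by pi(distance)
before standardisation, so repeated observations of one promoter at
different insertion distances become distinct points; appending pi as an
extra column (`distance.weighting = append`) or disabling weighting are
configuration options.

## Two-layer classifier

Layer 1: for each admissible (region, feature) pair — UPS1K × {N-gram,
Motif, NPC, CGI}, DISTANCE × {N-gram, NPC}, MIDDLE × {N-gram, NPC} —
mask, weight, z-standardise, and train an RBF-kernel SVM with Platt
probability calibration. Hyperparameters come from a seeded 3-fold grid
search over C ∈ 2^{−3..7}, γ ∈ 2^{−7..3} in exponent steps of 2 (36
points; a finer grid changed selections negligibly on synthetic studies
at many times the cost). Constant feature columns are dropped; a pair
whose matrix is entirely constant is skipped and contributes a fixed 0.5
probability.

Stacking inputs are leakage-free: the out-of-fold layer-1 probabilities
that drive layer-2 work are produced by 5-fold refits in which the
pattern mask is refitted on each fold's training records. Fitting the
mask once on all records inflated the N-gram model's apparent CV AUC by
~0.25 relative to fresh-study performance and misled combination
selection.

Layer 2: Gaussian naive Bayes over the layer-1 probabilities of one
feature combination. All 15 non-empty combinations are scored by
stratified 5-fold CV on the out-of-fold outputs and the highest AUC wins
(ties: higher accuracy, then the smaller combination). The deployed
integrator is trained on the *final* layer-1 models' training outputs, so
its per-column orientation always matches deployment; its class-1 vs
class-0 log-likelihood difference is then recalibrated by a 1-D logistic
fitted on the out-of-fold scores. This separation matters: an integrator
trained purely on out-of-fold inputs can invert rankings when fed the
more extreme outputs the trained models produce on memorized records
(breaking self-consistency and exchange protocols), while one trained
purely on memorized outputs is badly miscalibrated on unseen data. The
integrator uses variance smoothing of 0.01 (fraction of the largest
input variance) — with probability-scale inputs, unsmoothed class
variances can be small enough that posteriors saturate to exactly 1.0
and destroy ranking.

### Subset protocol and model selection

Positives are ranked by similarity — the mean pairwise local-alignment
score (match +1, mismatch −1, gap −2) of each UPS1K promoter against all
other positives — and split into two equal groups; each group joins the
shared negatives (subsampled to a 1:1 P/N ratio, configurable) to form
one balanced training subset, extras dropped by lowest score with ids
logged. Each subset trains a full two-layer model. The models are
compared by the overfitting-aware score

    total = Σ over Eva ∈ {AUC, Sn, Sp} of cv_Eva × exchange_Eva / self_Eva

(cross-validation; exchange-testing = evaluating on the other subset;
self-consistency = evaluating on own training data). Lower totals flag
overfitting; the higher total wins, ties broken by CV AUC.

## Evaluation

Accuracy is a percentage, 100 (TP+TN)/n; Sn = TP/(TP+FN);
Sp = TN/(TN+FP); F1 = 2TP/(2TP+FN+FP), computed in closed form so
empty precision/recall denominators cannot propagate; AUC is the
trapezoidal/rank-statistic area. Undefined ratios are NaN, never 0.
Cross-validation is stratified, seeded, with metrics pooled over the
concatenated out-of-fold predictions (stabler than fold-averaging at
small n); when record keys are supplied, folds are assigned in a
canonical (label, key) order, making reports invariant to input row
order. A class smaller than the fold count triggers a warning and plain
k-fold.

## Synthetic studies

The generator builds what the method assumes: an i.i.d.-base genome at a
configurable GC fraction (default 0.45), non-overlapping genes on random
strands, one insertion per gene at a distance drawn log-uniformly from
100 bp–30 kb, and labels drawn Bernoulli(pi(distance)) with the frozen
logistic defaults. Log-uniform distances put mass at short range, giving
roughly a 2:1 Ac:NAc balance, matching the composition such studies
report. Class signal is then planted: with probability q_Ac = 0.8 (Ac)
or q_NAc = 0.2 (NAc) per record, two 10-nt consensus motifs are written
into UPS1K and MIDDLE at recorded, non-overlapping positions; a CpG-rich
block is planted in UPS1K at a per-class rate (default 0.15 for both
classes, i.e. CGI features vary but are uninformative). A manifest
records each plant and the true pi per record, so tests verify plants by
direct string comparison. Under these conditions the Bayes-optimal AUC
(plant indicator + distance, computed by simulation at n = 4×10⁵) is
≈ 0.84; labels are irreducibly noisy by construction, so no classifier
can approach 1.

What the generator does not emulate: real base composition, repeats,
gene density, splice structure, multi-copy insertions, or biologically
meaningful motif/property content. Passing tests therefore demonstrate
the machinery recovers signal it is designed for under the assumed noise
model — not field performance on rice data.

Problem sizes used by the test suite and the acceptance script — a
360-record training study, a 120-record fresh test study, n = 2000 for
logistic parameter recovery, 200 permutations for the null inclusion
rate — were chosen so each check has comfortable statistical resolution
at desk scale.

## Numerical choices and degenerate inputs

- PWM pseudocount 1e-4; scan quantization 1000 bins per motif.
- PCA sign convention: largest-magnitude loading positive.
- Even-length DISTANCE centre: ceil(L/2).
- Subset ties at the score boundary: record-id lexicographic order.
- GaussianNB variance floor 1e-12 on top of 0.01 smoothing (degenerate
  constant inputs reduce to class priors).
- Records whose DISTANCE/MIDDLE region is absent (< 2 nt) get 0.5 from
  the affected layer-1 models, flagged.
- Seeds: every stochastic step (genome generation, fold assignment, grid
  search, SVM training, subsampling) derives from the run seed; two runs
  with identical configuration are bit-identical.

## Known limitations

- Reproducing performance on real rice activation-tagging data would
  require the rice genome, curated insertion lines with validated
  expression calls, and a curated plant motif library, none of which ship
  here; synthetic studies characterise the machinery, not the biology.
- The RBF SVM on 5440 raw count columns can latch onto study-specific
  background at small n; the fold-internal masking controls the estimate
  of that overfitting but not the overfitting itself.
- Local alignment similarity is exact O(n²L²) dynamic programming — fine
  for hundreds of promoters, not for thousands.
- The model bundle stores fitted scikit-learn estimators via joblib and
  is not portable across major scikit-learn versions.
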