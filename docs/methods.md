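# Methods

## Data model

A genotype panel is an *n* × *m* matrix of codes {0, 1, 2, ?}: the two
homozygotes, the heterozygote, and missing. For letter-coded (HapMap-style)
input the mapping to codes is frequency-based: the more frequent allele's
homozygote becomes code 0, ties broken alphabetically. Any consistent
bijection would do — every imputer in the package is label-symmetric up to
its deterministic tie-break — but a fixed convention makes files
re-readable and results reproducible. Inbred, effectively haploid panels
are represented with codes {0, 2} only; nothing in the imputers assumes a
heterozygote exists.

Loci unsorted in the input are stably sorted by (chromosome, position) on
load with a logged warning rather than rejected. Duplicate positions on a
chromosome are rejected.

## Genetic coordinates

Windows are defined in genetic distance, so each locus needs a cumulative
cM position. From a map file (columns bp, rate, cumulative cM) positions
are linearly interpolated between anchors — the standard treatment of
HapMap-style maps; outside the anchored range the nearest interval's slope
extrapolates, clamped to be non-decreasing. Without a file, the rough
fallback of one centi-Morgan per million basepairs is used. Loci sharing a
bp position under a file map receive equal cM; consumers must therefore
tolerate zero genetic distance inside a window (see the WNN cap rule).

## Covering windows and encoding

The covering window of target locus *i* is every locus *i′ ≠ i* on the same
chromosome with |cM(*i′*) − cM(*i*)| ≤ δ. Windows never span chromosomes. A
side with fewer than 3 loci logs a warning: below that, local inference has
little support and any reasonable threshold should be widened.

Each window locus contributes a 3-bit one-hot block — 0 → (1,0,0),
1 → (0,1,0), 2 → (0,0,1), missing → (0,0,0) — concatenated left block then
right block. Under this encoding the bitwise Hamming distance between two
samples contributes, per locus, 2 for two different known genotypes, 1 for
known-vs-missing, and 0 for missing-vs-missing; treating two missing values
as agreeing (0, not 1) is deliberate, since shared missingness carries no
evidence of ancestral difference. An additive {0, 1, 2, ?} encoding is
provided for experimentation but is not used by the imputers, which treat
imputation as 3-class classification.

## The imputers

**BaseLine** votes the most frequent known genotype at the locus; ties
resolve to the lowest code. It is excluded only when no other sample has a
known value.

**NN** ranks training samples (those with a known genotype at the target
locus) by Hamming distance over the window and groups them into tiers of
equal distance. Starting from the nearest tier, the majority genotype among
all recruited samples wins; a tied vote recruits the next tier; a tie that
survives every tier resolves to the lowest code. Resolving the final tie
deterministically (rather than at random) keeps runs reproducible.

**WNN** weights window locus *i′* by 1/d(*i′*, *i*) in cM and scales the
window's weights so the maximum is 100, preserving ratios. A co-located
locus (d = 0) receives ten times the largest finite reciprocal weight in
the window — dominant but finite. Tiers of equal weighted distance are
formed under a relative tolerance of 1e-9 (absolute 1e-12 near zero),
because exact floating equality is fragile. Weights are computed per
window, i.e. per target locus. When every window locus is equidistant from
the target the weights are uniform and WNN reduces exactly to NN; with
wider windows the reciprocal weights differ across loci and the two
methods can legitimately disagree.

**MC** fits two first-order chains on the training samples with add-one
(Laplace) smoothing: the upstream chain over loci *i−L, …, i−1, i* and the
downstream chain over *i+R, …, i+1, i*, both estimated in the
running-toward-*i* direction. The initial distribution at a chain's first
locus is (count_g + 1)/(N + 3); each transition row is
(count(a→b) + 1)/(count(a→·) + 3), counted over samples with both adjacent
genotypes known. For the target sample, known in-window genotypes pin the
chain state; missing ones are marginalised by a forward sum, each candidate
value weighted by its smoothed training frequency at that locus (a weighted
sum, not a max). The candidate genotype's score is upstream × downstream;
a side with no loci contributes the smoothed marginal frequency at the
target locus. Ties resolve to the lowest code. The forward recursion equals
explicit enumeration over all completions, which the test suite checks
directly.

**SVM** trains a soft-margin RBF-kernel SVM (one-vs-one multi-class, via
scikit-learn's SVC) on the encoded training vectors, labels being their
genotypes at the target locus. (c, γ) is selected once per dataset: a
configurable number of target windows (default 20) is sampled, and each
point of the grid {2⁻⁵, 2⁻³, …, 2¹⁵} × {2⁻¹⁵, …, 2³} is scored by mean
10-fold cross-validated accuracy over those window panels. Searching per
target locus would multiply cost by the locus count for little benefit,
since neighboring windows are highly correlated. With a single class among
the training labels the decision falls back to that class.

**NeuralNet** is a three-layer feed-forward network: 3(L+R) inputs, a
hidden layer of exactly L+R logistic units, and 3 outputs mapped through a
softmax to class probabilities. Training minimises the cross-entropy
between the softmax outputs and one-hot labels by full-batch gradient
descent with momentum for exactly 20 epochs — a deliberate early stop
against over-fitting the small local panels — from weights drawn uniformly
in (−0.1, 0.1) under a caller-supplied seed. Defaults η = 0.1 and μ = 0.5
are conventional mid-range values; both are configurable. The hidden layer
uses the logistic activation and the output layer a true softmax, and the
loss is the standard softmax cross-entropy −Σ y log p. Prediction takes the
largest output, ties to the lowest code.

Throughout, imputation never feeds back: every decision is computed from
the originally observed values, and previously imputed entries remain
missing as inputs to other targets, so each missing entry is imputed
independently and order-invariantly.

## Evaluation protocol

`decimate(matrix, k)` retains loci 0, k, 2k, … (always keeping the first
marker, hence ⌈n/k⌉ survivors) to emulate medium- and low-density arrays.
`mask` hides round(rate × known entries) known genotypes uniformly at
random without replacement; the RNG stream derives from (seed, replicate),
so masks are reproducible and independent of which methods run. The
threshold grid is {0.01, 0.02, 0.03, 0.04, 0.05}/density cM. Accuracy is
correct/imputed; entries whose covering window is empty at a given
threshold are excluded from the statistics *for every method* — so even
the threshold-free BaseLine can vary slightly across thresholds through
its exclusion set. Cells where everything was excluded have undefined
accuracy and are dropped from summary means with a logged warning.

## The fixture generator

`generate_fixture` emulates the identical-by-descent structure the local
methods exploit with a founder-mosaic model: a small set of random founder
haplotypes; each sample haplotype follows one founder and switches to a
different founder between adjacent loci with probability
recomb_prob_per_cM × interval length; two haplotypes combine into an
unphased genotype (or one is duplicated for haplotype-allele panels); each
allele flips independently with the genotyping error rate.

Defaults are chosen to resemble a high-density SNP panel of unrelated
samples: 500 loci at 2,500 bp spacing (0.0025 cM under the 1 Mbp/cM
fallback, so the density-1 thresholds cover ±4 to ±20 loci), 30 samples,
6 founders, one mosaic switch per cM on average (LD decaying over roughly
a centi-Morgan, comfortably longer than any window), and a 0.5% per-allele
error rate, at the low end of reported chip error ranges. The generator is
*not* a coalescent simulator: it has no mutation model, no allele-frequency
spectrum, uniform marker spacing, and exchangeable samples. Passing tests
on these panels demonstrate that the methods exploit IBD sharing as
designed, not what accuracy to expect on any particular real cohort.

## Numerical choices

- Weighted-distance tier equality: relative 1e-9, absolute 1e-12.
- Zero-distance weight cap: 10 × the largest finite reciprocal weight.
- Map extrapolation: nearest-interval slope, clamped non-decreasing.
- All vote and argmax ties: lowest genotype code.
- Masked-entry count: round(rate × known entries), masking only originally
  known entries.
- Per-entry network initialisation streams derive from
  (seed, replicate, threshold index, locus, sample), so results are
  bit-reproducible and insensitive to evaluation order.

The bundled `scripts/acceptance.py` runs the protocol at 5% masking with 2
replicates across the five density-1 thresholds on the default 500 × 30
panel — sizes that keep a single-CPU run around a minute while leaving
~7,500 imputed entries per method for stable means.

## Known limitations

- A first-order chain sees only the immediate flanking loci once the
  target's window genotypes are observed. At an *isolated* differentiating
  site — where haplotype groups differ at the target locus but agree at
  both adjacent loci — MC can only return the majority group's allele, so
  it mispredicts minority-group samples there and cannot reach perfect
  recovery even on noise-free two-founder panels (NN and WNN can, and do,
  via exact pattern matching). This is inherent to the model order, not an
  estimation issue.
- The SVM's shared (c, γ) assumes window panels are statistically similar
  across the chromosome; strong heterogeneity would favor per-region
  calibration.
- Windows with fewer than 3 loci per side (warned about) give all methods
  little to work with; at very low densities none of the local methods
  materially beats the baseline vote.
- Multi-allelic SNPs, phased input, and VCF/PLINK formats are out of scope.
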