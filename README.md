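# locimpute

Local imputation of missing SNP genotypes and haplotype alleles.

Genotyping assays leave a fraction of calls missing ("no-calls"), and
downstream analyses such as genome-wide association studies need complete
matrices. `locimpute` fills missing genotypes *locally*: for a target locus
*i* it uses only the SNP loci within a genetic-distance threshold δ (in
centi-Morgans) on either side — the *covering window* — and only the samples
most similar to the target over that window. The rationale is
identical-by-descent sharing: recombination is rare, so samples that agree
over a short genetic interval almost surely carry the same ancestral
haplotype and hence the same allele at the target locus. Panels of inbred
(effectively haploid) strains are handled the same way with the two
homozygous codes only, which makes the same machinery a haplotype-allele
imputer.

## Methods

A panel is an *n* × *m* matrix *M* of genotype codes {0, 1, 2, ?} (two
homozygotes, the heterozygote, missing). Over a window of L left and R right
loci each sample is encoded as a 3(L+R)-bit orthogonal (one-hot) vector with
(0,0,0) for a missing call. Six imputers share this representation:

- **BaseLine** — majority vote over the known genotypes at the target locus.
- **NN** — expanding-tier nearest neighbor: rank training samples by Hamming
  distance to the target over the window, take the majority genotype among
  all closest samples, and recruit the next-closest tier while the vote is
  tied.
- **WNN** — NN with each window locus weighted by the reciprocal of its
  genetic distance to the target, scaled into [0, 100].
- **MC** — two first-order Markov chains with add-one smoothing, one running
  from locus *i−L* toward *i*, one from *i+R* toward *i*; the product of the
  two chain probabilities scores each candidate genotype.
- **SVM** — a soft-margin SVM with RBF kernel
  K(x, x′) = exp(−γ‖x−x′‖²) on the encoded vectors, one-vs-one multi-class,
  with (c, γ) chosen once per dataset by 10-fold cross-validation over the
  grid {2⁻⁵, 2⁻³, …, 2¹⁵} × {2⁻¹⁵, 2⁻¹³, …, 2³}.
- **NeuralNet** — a three-layer feed-forward network (3(L+R) inputs, L+R
  logistic hidden units, 3 softmax outputs) trained by batch gradient
  descent with momentum on cross-entropy for exactly 20 epochs.

The evaluation protocol masks a fraction of known genotypes uniformly at
random, imputes them, and reports accuracy (correct / imputed) over a grid
of thresholds {0.01, …, 0.05}/density cM; entries with an empty covering
window are excluded from the statistics for every method. Genetic positions
come from a HapMap-style map file (linearly interpolated) or the rough
1 Mbp/cM fallback. See `docs/methods.md` for the full model description.

## Worked example

```python
import locimpute as li

# a 500-locus, 30-sample panel with founder-mosaic LD structure
matrix, gmap = li.generate_fixture(li.FixtureSpec(seed=1))

results = li.run_experiment(
    matrix, gmap,
    methods=["baseline", "nn", "wnn", "mc"],
    rates=[0.05],              # hide 5% of the known genotypes
    replicates=2,
    grid=li.threshold_grid(1.0),   # 0.01 .. 0.05 cM
    seed=1,
)
print(li.summarize(results))
```

```
     method  rate  mean_accuracy  cells  total_imputed  total_excluded
0  baseline  0.05       0.477333     10           7500               0
1        mc  0.05       0.597333     10           7500               0
2        nn  0.05       0.851867     10           7500               0
3       wnn  0.05       0.847467     10           7500               0
```

Each row averages 10 cells (2 masking replicates × 5 thresholds): local NN
recovers ~85% of the hidden genotypes on this panel, against ~48% for the
locus-wise majority vote — the gain is the linkage information in the
covering window. The same protocol is scriptable from the shell:

```bash
locimpute simulate --n-loci 500 --samples 30 --seed 1 --out panel.tsv
locimpute mask --in panel.tsv --rate 0.05 --seed 1 \
    --out masked.tsv --truth truth.tsv
locimpute impute --method nn --delta-cm 0.03 --in masked.tsv \
    --out imputed.tsv --sidecar decisions.tsv
```

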