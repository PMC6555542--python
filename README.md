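# archaid

Reference-free inference of archaic local ancestry along phased haplotypes.

Modern human genomes outside Africa carry short tracts inherited from
archaic hominins such as Neanderthals.  Most methods that locate these
tracts need a sequenced archaic genome to compare against; for several
admixture events (deep-African archaic gene flow, the unknown ancestor in
the Denisovan genome) no such reference exists.  `archaid` is for
population geneticists who want per-haplotype, per-window archaic-ancestry
probabilities using **only** present-day genomes: a target (admixed)
panel and an unadmixed reference panel.

## Method

A binary logistic regression predicts the archaic state of a 50 kb window
on a focal haplotype from summary statistics computed on the target panel
(n haplotypes) and reference panel:

- the individual frequency spectrum: X_i = number of derived alleles on
  the focal haplotype whose derived count in the target panel is i
  (i = 1..n);
- the sorted vector of Euclidean distances from the focal haplotype to all
  n target haplotypes, plus its mean, variance, skew and kurtosis;
- the minimum distance to the reference panel;
- the number of SNPs private to the focal haplotype relative to the
  reference;
- S*, the classic chain statistic over those private sites
  (S(j) = max(0, max_{i<j} S(i) + s(i,j)), s(i,j) = bp + 5000 for gaps
  >= 10 bp, else -10000);
- the focal derived-allele count (208 features in all at n = 100).

Training data come from coalescent simulations (msprime) of a
split-and-pulse demography — ancestral population splits into archaic and
modern branches 12,000 generations ago, modern branch splits into
reference and target 2,500 generations ago, archaic pulse of m = 2% into
the target 2,000 generations ago, all diploid sizes 10,000 — with the true
archaic tract of every haplotype recorded exactly.  Windows with >= 70%
archaic bases are labeled archaic, <= 30% non-archaic, the rest discarded.
At scan time the model slides 50 kb windows 10 kb at a time and each SNP
receives the mean probability of the windows covering it; calling at
probability 0.62 corresponds to a 20% false discovery rate in simulation.

See `docs/methods.md` for assumptions, parameter meanings, numerical
choices and limitations.

## Worked example

Train a small model and score fresh data (a scaled-down run; a production
model uses thousands of training replicates):

```python
import numpy as np
from archaid import DemographyScenario, pr_roc
from archaid.pipeline import (
    train_on_scenario, simulate_test_regions, snp_scores_and_truth,
)

scenario = DemographyScenario()          # the human-Neanderthal defaults
model, ts = train_on_scenario(scenario, n_replicates=1000, seed=21)
print(f"retained {ts.n_retained} training examples, "
      f"{int(ts.y.sum())} archaic")

regions = simulate_test_regions(scenario, 10, seed=99)   # 10 x 1 Mb
scores, truth = zip(*(snp_scores_and_truth(model, r) for r in regions))
pr, roc = pr_roc(np.concatenate(scores), np.concatenate(truth))
print(f"per-SNP AUPR {pr.area:.2f}, AUROC {roc.area:.2f}")
```

```
retained 98645 training examples, 1361 archaic
per-SNP AUPR 0.42, AUROC 0.95
```

About 1% of candidate windows are discarded as ambiguous (30–70% archaic),
and roughly 1.3% of retained examples are true archaic windows — the class
imbalance the admixture fraction implies.  The per-SNP area under the
precision–recall curve is the headline accuracy number: at this reduced
training size and on a small 10 Mb test set it lands around 0.4; with full
training and a larger test set it reaches ≈ 0.6 (AUROC ≈ 0.95–0.97).
Individual 1 Mb replicates vary widely in archaic content, so accuracy
numbers on small test sets move with the realized class prevalence.

The same workflow is available from the shell:

```bash
archaid simulate -R 1000 -L 50000 -S 21 --out sim/
archaid featurize --ms sim/haplotypes.ms --tracts sim/tracts.tsv \
    -L 50000 --out features.tsv
archaid train --features features.tsv --out model.json -S 21
archaid evaluate --model model.json -R 10 -S 99
archaid predict --model model.json --ms test/haplotypes.ms -L 1000000 \
    --threshold 0.62 --out calls.tsv
```

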