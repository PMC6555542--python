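# Methods

`archaid` infers archaic local ancestry along phased haplotypes without an
archaic reference genome.  A binary logistic regression predicts, for a
focal haplotype in a genomic window, the probability that the window is
archaic; the model is trained entirely on coalescent simulations in which
the true ancestry of every base is known.  This note records the model, its
assumptions, the tunable parameters, and the numerical and design choices
made where more than one reasonable option existed.

## Demographic model and simulation

Three populations are sampled at the present: a *target* population that
received archaic gene flow, an unadmixed *reference* population, and the
archaic population itself.  Forward in time, an ancestral population of
diploid size `N0` splits `T0` generations ago into the archaic branch
(size `Na`) and the modern branch; the modern branch splits `Ts`
generations ago into reference (`N1`) and target (`N2`); at `Ta` the
archaic population contributes a single-generation pulse amounting to a
fraction `m` of the target's ancestry.  Defaults are the human–Neanderthal
configuration:

| parameter | meaning | default |
|---|---|---|
| `N0, N1, N2, Na` | diploid effective sizes | 10,000 |
| `m` | admixture fraction | 0.02 |
| `T0` | archaic split (generations) | 12,000 |
| `Ts` | target/reference split | 2,500 |
| `Ta` | admixture time | 2,000 |
| `mu` | mutation rate /bp/gen | 1.25e-8 |
| `r` | recombination rate /bp/gen | 1e-8 |

Simulations run in msprime with times in generations and diploid sizes, so
no coalescent-unit conversion is exposed anywhere; a closed-form check
(within-target pairwise diversity = `4 N mu L` when all sizes are equal and
`m = 0`) and an independent hand-coded structured-coalescent oracle for the
expected number of segregating sites guard the scaling.  Mutations are
infinite-sites (binary, ancestral state known); float coordinates are
floored onto the integer base-pair grid, with collided positions shifted to
the next free base (sites pushed past the region end are dropped — at
human-like densities this is vanishingly rare).

True archaic ancestry is recorded exactly: a census is placed midway
between `Ta` and `Ts`, every census lineage sitting in the archaic
population at that time is an archaic ancestor, and `link_ancestors`
projects those lineages onto the sampled target haplotypes as half-open,
0-based base-pair tracts.  The archaic haplotype is sampled at the present
like the modern samples; it is carried through the pipeline only for the
match diagnostics and never enters any feature.

One property of the pulse deserves emphasis: mass migration moves whole
ancestral lineages, so the archaic content of a finite replicate is
overdispersed relative to a binomial draw per base.  Individual 1 Mb
replicates commonly carry 0–5% archaic material around the 2% mean, and a
30-replicate test set can easily land at 1.4%.  Precision–recall summaries
are strongly prevalence-sensitive, so accuracy is always reported over many
replicates (40 x 1 Mb in the acceptance run) and jackknife standard errors
over 1 Mb blocks are the honest uncertainty measure.

Transient-structure confounder scenarios (`make_structured_scenario`)
isolate 25% of the target population during (2,001, 2,499) generations ago
("recent") or 25% of the ancestral population during (2,600, 12,000)
("ancestral"), with *no* archaic pulse (`m = 0`): the published outcome for
these scenarios is zero archaic calls, which only makes sense if structure
is the sole confounder present.  Isolation is complete (no migration during
the separation), and the fraction acts as the lineage-sampling probability
at the rejoin, looking backward.

## Features

For a focal haplotype in a window with an `n`-haplotype target panel and an
`n_ref`-haplotype reference panel, over all variant columns in the window
(union of target and reference variation; derived = 1):

1. **Individual frequency spectrum** (`ifs_1 … ifs_n`): entry `i` counts
   focal-carried derived alleles whose derived count in the target panel is
   exactly `i` (entry `n` therefore counts target-fixed derived sites).
2. **Distance vector** (`dist_1 … dist_n`): Euclidean distances from the
   focal haplotype to every target haplotype, sorted ascending; the self
   distance 0 is included so the vector has length `n` and sorting makes it
   invariant to haplotype ordering.
3. **Distance moments**: mean, variance, skew, kurtosis of that vector as
   raw population moments (`skew = m3/m2^1.5`, non-excess
   `kurt = m4/m2^2`); a zero-variance vector gets skew = kurtosis = 0.
4. **`min_ref_dist`**: minimum Euclidean distance to any reference
   haplotype.
5. **`n_private`**: focal-carried derived alleles absent from the reference
   panel.
6. **`s_star`**: the S* chain statistic over those private sites (below).
7. **`focal_derived`** (flag-controlled, default on): total derived-allele
   count on the focal haplotype.  The first six groups sum to `2n + 7`
   features (207 at `n = 100`); this redundant count is the 208th.

All features are functions of the target and reference panels only;
removing the archaic haplotype from a region changes nothing (tested), and
permuting non-focal haplotypes changes nothing (tested).

### S* dialect

Candidate sites are the focal haplotype's private derived alleles, ordered
by position.  The dynamic program is
`S(j) = max(0, max_{i<j} S(i) + s(i, j))` with pairwise score
`s(i, j) = bp(i, j) + 5000` when the gap is at least 10 bp and `-10000`
otherwise; chains may skip sites, a lone site scores 0, and `S*` is the
maximum over `j` (0 with no candidates).  The constants are the classic
chain-bonus family and are exposed in `SStarConfig` because published
descriptions do not pin them down exactly.  The DP is checked against
exhaustive subset enumeration for up to 12 candidates.

For the S* *baseline* (scoring haplotypes by S* alone), raw scores are
converted to empirical-CDF ranks.  Two readings of "rank by the empirical
CDF" exist: within each window's 100-haplotype cohort, or against the
pooled score distribution of the whole evaluation set.  Within-window
ranking destroys the statistic — in the many windows where every cohort
score is 0, ties are promoted to arbitrary high ranks, flooding false
positives (measured per-SNP AUPR 0.23) — so this package ranks against the
pooled distribution, which reproduces the published operating
characteristics of the baseline (AUPR ≈ 0.44–0.47, AUROC ≈ 0.94).  Ties
rank as the fraction of scores *strictly* below, so the zero mass shares a
low rank.

## Classifier

Training windows are labeled by the true archaic base fraction of the focal
haplotype: archaic at ≥ 70%, non-archaic at ≤ 30% (both inclusive),
discarded in between.  Under the default demography about 98.9% of
candidate examples are retained and about 1.4% of retained examples are
positive; the imbalance is left as-is.

The fit is an unpenalized maximum-likelihood binomial logit
(scikit-learn's `newton-cholesky` solver, suited to `n >> p`) on the raw,
unstandardized features; standardization enters only in weight *reporting*
(`weight x sd`, and `log10 |.|` for display).  Three numerical choices
matter:

- **Double precision always.**  Feature matrices may be stored float32 to
  halve memory at the million-example scale, but the sorted-distance block
  is highly collinear and the IRLS normal equations are ill-conditioned, so
  the design is upcast to float64 for the solve (a float32 solve measurably
  corrupts the fit).
- **Iteration cap 200, capped fits accepted.**  With rare positives the
  likelihood is near-flat around the optimum (quasi-separation); the
  gradient tolerance may never fire and coefficients keep creeping along a
  ridge of the likelihood.  Out-of-sample accuracy improves up to roughly
  this cap and plateaus; the capped fit is the standard GLM behaviour.
- **Separation fallback.**  A fitted |weight| x sd above 30 (a 30-logit
  swing per feature SD has no plausible MLE interpretation) or a non-finite
  fit triggers a flagged tiny-ridge IRLS refit (`alpha = 1e-4`, intercept
  unpenalized), so behaviour is defined on degenerate subsets.  Constant
  columns are dropped from the design and reported with weight 0.

An independently coded Newton–Raphson oracle in the test suite agrees with
the production fit to 1e-6 on small, well-conditioned data.

Feature-subset models (`skew_only`, `private_only`, `min_dist_only`,
`three_feat`, `no_reference`, `full`) refit on named column groups;
`no_reference` drops `min_ref_dist`, `n_private` and `s_star`, all of which
depend on the reference panel under this S* dialect.

## Window inference

Long haplotypes are scanned in 50 kb windows sliding 10 kb; each (window,
haplotype) gets a probability, and each SNP on a haplotype receives the
mean probability of all windows overlapping it (five for interior SNPs).
Probability averaging outperformed log-odds averaging in direct comparison
and matches the natural reading of the published procedure.  Windows are
placed fully inside the region; SNPs near the edges average over fewer
windows, and the per-SNP window count is recorded so edge effects stay
auditable.  A region shorter than one window yields a single truncated
window with a warning.  Calls threshold the mean probability at 0.62 by
default — the operating point whose precision is 0.8 (20% FDR) on
unperturbed simulated test data.  For empirical-style scans the stride can
be set equal to the window for non-overlapping tiling.

## Evaluation

PR and ROC curves enumerate all distinct score thresholds (ties grouped).
AUPR uses the Davis–Goadrich interpolation: between successive threshold
points the false-positive count is linear in the true-positive count, and
the area is accumulated at every integer TP step (implemented in closed
vectorized form; an explicit loop oracle checks it exactly on toys).  The
segment from recall 0 to the first observed point extends from (TP=0,
FP=0), giving the conventional constant-precision lead-in.  AUROC is the
trapezoid over the stepwise ROC, equal to the tie-corrected Mann–Whitney
statistic (tested).  Block-jackknife standard errors delete one contiguous
block (1 Mb for genome-wide accuracy summaries) and use the standard
`(B-1)/B` variance inflation.  The operating point is the smallest
threshold whose precision reaches the target (0.8), reported with its
recall.

The perturbation harness retrains nothing: the model fit under the default
demography is applied to test data simulated with one parameter halved or
doubled, and precision/recall at the fixed 0.62-level threshold are
reported as log10 fold changes against the unperturbed baseline.
Perturbations that break the time ordering (for example doubling `Ta` past
`Ts`) are rejected as non-sensible and skipped.  Joint mutation/
recombination heterogeneity draws (mu, r) pairs uniformly *as pairs* from a
user-supplied empirical list.

## Archaic-genome match diagnostics

When an archaic genome is available after the fact, calls are validated by
the match statistic `NMS = S / (N + H)` per focal haplotype per window: `N`
counts archaic-genome mutation sites (het or hom — the archaic genome is
unphased, so one matching allele suffices), `H` counts sites segregating in
the target sample at which the archaic genome is not variant, and `S`
counts focal derived alleles carried by the archaic genome.  The archaic/
non-archaic contrast in window `i` is normalized by the window's mean NMS
(cancelling local mutation-rate variation), averaged genome-wide, and
tested against zero by a 100 kb delete-one block jackknife; windows need
both call classes and ≥ 90% callable bases to contribute.  B-value analyses
bin call frequencies into [0–250], (250–500], (500–750], (750–1000] and
test the lowest-vs-highest contrast with a 50 kb block jackknife.  In
simulations the simulated archaic haplotype stands in for a real archaic
genome, making the whole module testable without external data; the exact
site universes for `N` and `H` are not pinned down by published
descriptions, and the definitions above are this package's choices.

## Problem sizes and what the tests show

The acceptance run trains on 6,000 replicates of 50 kb (600,000 candidate
examples; 60% of the full protocol, past the observed accuracy plateau) and
evaluates on 100 independent 1 Mb replicates; the training-retention count
uses the full 10,000 x 100 protocol (ancestry-only simulation, no
mutations).  The reduced-sample-size analysis retrains at `n = 30` target
haplotypes (reference panel unchanged at 100, matching the reading that
only the target dataset shrinks).  The pytest acceptance layer uses 5,000
training and 40 test replicates.  At these scales the per-SNP AUPR of the
full model sits in the high 0.5s with jackknife SEs of a few hundredths —
consistent with the 0.60 ± 0.05 full-scale figure — and all reported
accuracy numbers carry the Monte-Carlo tolerances stated in the tests.

The generator emulates neutral, uniform-rate, perfectly phased, fully
polarized data with known demography.  Passing tests therefore demonstrate
correctness of the method and its implementation under those conditions;
they do not demonstrate robustness to phasing error, polarization error,
selection, or mis-specified demography beyond the perturbation grid, and
real-data accuracy depends on how closely the assumed demography matches
the truth.

## Known limitations

- Fixed-size windows ignore variable-length dependence; the per-SNP
  averaging is a heuristic smoother, not a model of tract boundaries.
- The linear logit underfits interactions among features by construction.
- Unphased (diploid) feature variants are not implemented.
- The S* constants and the exact composition of the published 208-feature
  vector are not uniquely determined by published descriptions; both are
  configurable and the defaults are documented above.
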