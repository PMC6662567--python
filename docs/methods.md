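# Methods

`tetrabin` groups assembled contigs into genome bins from two signals:
tetranucleotide composition and read-depth profiles across samples. This
note records the model, the tunable parameters, the synthetic data the
package tests itself against, and the numerical and design choices made
where more than one reasonable option existed.

## Pairwise evidence

**Tetranucleotide frequency (TNF).** Each contig is summarized by the
frequencies of its 4-mers, collapsed over reverse complements onto 136
canonical tetramers (16 palindromes + 120 two-member classes; the
lexicographically smaller member represents a class). Windows containing N
are skipped. The raw pair score maps the Euclidean distance `d` between two
frequency vectors through a normalized logistic,

    tnf_raw(d, L_a, L_b) = g(d) / g(0),   g(d) = 1 / (1 + exp(k (d/d0 - 1)))

so the score is exactly 1 at distance zero and decays to 0. The midpoint
grows for short contigs, `d0^2 = A / L_h + B` with `L_h` the harmonic mean
of the two lengths, because the sampling variance of 4-mer frequencies
scales as 1/L: the same compositional distance is weaker evidence of
difference between short contigs than between long ones. The slope scales
with the midpoint (`k = K0 / d0`) so the curve keeps its shape across
lengths. The coefficients `A = 2.207`, `B = 6.969e-4`, `K0 = 5.37` were fit
once by `scripts/calibrate_tnf.py` (deterministic, seed 20240601): simulated
genomes are re-cut into fragments at 1–50 kb, `d0(L)` is placed halfway
between the median same-genome and median different-genome distance at each
length, `d0^2` is regressed on 1/L, and `K0` is set so the median
same-genome pair scores 0.9. The functional form and the calibration
procedure ship with the package; rerunning the script reproduces the frozen
constants.

**Abundance (ABD).** Per sample, a contig's depth is modelled as
N(mean, variance) with both moments taken from the depth table (variances
floored at 1e-4 to guard degenerate rows). The pair score in one sample is
the shared area of the two densities, computed analytically from the
intersection points of the log-densities; it is 1 for identical
distributions, falls with mean separation in units of the spreads, and is
invariant under common rescaling (doubling means while quadrupling
variances changes nothing). A sample is *effective* for a pair when at
least one of the two contigs has mean depth above `min_cv` (default 1);
scores combine across effective samples by geometric mean. With no
effective sample the pair carries no abundance evidence (distinct from
evidence of difference).

**Abundance correlation (COR).** With three or more samples, the Pearson
correlation of the two mean-depth profiles. It is undefined (not zero —
zero would claim anti-evidence) below three samples or when a profile has
zero variance.

## Score normalization and the composite score

Raw TNF, ABD and COR live on incomparable scales. TNF and COR are
quantile-normalized onto the empirical ABD distribution: a raw value is
replaced by the ABD quantile at its empirical rank within its own sampled
distribution (linear interpolation between order statistics; queries
outside the fitted range clamp to the endpoint quantiles). Distributions
are estimated from a seeded uniform sample of min(500·N, 2·10^6) contig
pairs rather than all O(N^2) pairs.

The composite edge score is

    S = TNF_n^(1-w) · ABD^w                     (< 3 samples)
    S = sqrt(TNF_n^(1-w) · ABD^w · COR_n)       (>= 3 samples)

with `w = nABD/(nABD+1)`: abundance earns weight as effective samples
accumulate. The three-factor form is the square root of the product as
written above; a cube-root variant is available (`cube_root_cor`) for
sensitivity analysis but is not the default.

**Correlation resolution.** A Pearson correlation over n samples cannot
resolve differences finer than its sampling precision — over three samples
it carries a single degree of freedom. Rank normalization would otherwise
amplify meaningless fourth-decimal differences among near-1 correlations
across a wide quantile range, and those phantom strata inside a single
genome are exactly the structure the Fisher-membership propagation (below)
preserves. COR values are therefore snapped to a grid of step
`1/(n_samples - 1)` before ranking, so sub-resolution differences tie and
share one normalized score. The grid tightens as samples grow and the
estimate earns resolution.

## Graph construction and partitioning

Contigs of at least `min_contig` bp (default 2500) are nodes. Each node
retains at most `max_edges` (default 200) of its offered links — exactly
its best k by (score, then neighbor id), independent of insertion order,
via a per-node priority queue; memory is O(N·k), not O(N^2). An edge is
*active* only while both endpoints retain it, which keeps the adjacency
symmetric and the partition insertion-order-independent.

Two admission stages feed one pool of candidate edges. Stage one qualifies
pairs by strong composition alone: raw TNF at or above the `max_p`-th
percentile (default 95) of the sampled TNF distribution; the edge weight is
the composite S where defined, or normalized TNF for pairs with no
effective coverage. Stage two qualifies pairs by composite score `S >=
min_s/100` (default 0.60) regardless of TNF rank. `min_s` is a global
filter: an edge below it is never kept, in either stage. The pooled edges
are admitted in decreasing score order through a threshold schedule, linear
from the `max_p`-th percentile of the sampled S distribution down to
`min_s/100` in `schedule_steps` (default 10) equal steps; after each step
labels are re-propagated to a fixed point, warm-started from the previous
step. Strong links bind contigs while labels are still forming, so a
genome's contigs coalesce transitively (including across its depth
gradient) before weaker, potentially cross-genome evidence arrives against
already consolidated labels. Schedules anchored at the top of the edge
score distribution were measured to work worse on simulated communities:
they freeze small, tight, early labels that later evidence cannot dissolve.

Label propagation is deterministic: nodes are visited in decreasing order
of their strongest active edge (ties by node id), starting from singleton
labels, updates applied immediately within a sweep, and a round ends at a
sweep with zero label changes (capped at `max_lpa_iters`, default 50,
accepting the current labels with a warning). A node joins the neighbor
label with the smallest Fisher's-method combined p-value: treating `1 - S`
as each link's p-value (floored at 1e-12 so S = 1 stays finite), the label
with scores S_1..S_m gets `X = -2 Σ ln(1 - S_i)` referred to a chi-square
with 2m degrees of freedom. Log survival values are compared directly so
very strong neighborhoods that underflow double precision still rank; exact
ties keep the node's current label when it is among the tied set, otherwise
the lexicographically smallest label wins. Fisher's method lets a few
strong links outweigh many weak ones, which protects small genuine
neighborhoods from absorption by large diffuse ones.

Clusters below `min_cls_size` bp (default 200 000) are not reported. With
three or more samples they dissolve into a free pool together with short
contigs (`min_contig_recruit` = 1000 bp up to `min_contig`), and each free
contig is offered to the bin to which its mean depth-profile correlation is
highest (argmax over all bins, ties by bin id); it is admitted only if that
correlation exceeds the bin's own mean pairwise member correlation
(computed exactly up to 400 members, then over a seeded subsample).
Decisions are made in one pass against the pre-recruitment bin state, so
the result is independent of the order of the free list, and recruiting
never removes a contig from a bin. Single-member bins have no within-bin
correlation and never recruit. With fewer than three samples the entire
step is a no-op: a 2-point correlation is meaningless.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_contig` | 2500 bp | smallest contig clustered directly |
| `max_p` | 95 | percentile defining "strong" scores for admission |
| `min_s` | 60 | minimum edge score (×100) kept anywhere |
| `max_edges` | 200 | per-node cap on retained links |
| `min_cls_size` | 200 kb | smallest reported bin |
| `min_cv` | 1.0 | depth above which a sample is effective |
| `min_contig_recruit` | 1000 bp | smallest contig eligible for recruiting |
| `schedule_steps` | 10 | admission-threshold steps |
| `max_lpa_iters` | 50 | propagation sweeps per round |

Only `max_edges`, `max_p` and `min_s` influence accuracy appreciably; the
genetic-algorithm search (`param_search`) explores exactly those, on the
grid {50,100,200,400,800} × {80,85,90,95,97} × {50,60,70,80,90}, with
population 10, binary tournament selection, one-point crossover at rate
0.01, per-gene mutation at rate 0.05, elitism of the top 3, between 3 and
10 generations, stopping after three generations without improvement. The
initial population uses distinct individuals while the space allows, so
small grids are covered instead of wasting evaluations on duplicates.
Fitness is the number of high-quality bins — at least 90% complete with at
most 5% contamination against the generating truth of a simulated
community. External marker-gene and RNA-annotation checks of bin quality
are out of scope; truth-based completeness and contamination stand in for
them.

## The synthetic communities

The simulator emulates the features of a real co-assembled metagenome that
the binner exploits, with full ground truth:

* **Composition.** Each genome is sampled from an order-3 Markov chain
  whose 64×4 transition logits are perturbed per genome by Gaussian noise
  of scale `composition_bias` (default 0.5, chosen so between-genome TNF
  distances sit in the range observed between real microbial species
  relative to within-genome fragment noise — see the calibration table
  printed by `scripts/calibrate_tnf.py`). `composition_groups` can force
  genomes to share one transition matrix, producing strain-like pairs that
  composition cannot separate.
* **Fragmentation.** Genomes (default 2 Mb) are cut into contigs by a
  mixture law: with probability `frac_small` (default 0.2) a uniform
  1–2.5 kb fragment, otherwise log-uniform 2.5–50 kb; terminal slivers are
  absorbed into the previous contig.
* **Coverage.** Per-genome per-sample coverage is lognormal (ln-scale mean
  3.0, sd 1.0 — median ≈ 20×, spanning roughly 2–150×), or an explicit
  matrix. Per-contig mean depth jitters multiplicatively around the genome
  level with a two-component scale mixture: 90% of contigs at relative sd
  0.08, 10% "depth-biased" contigs at 0.35, mirroring the heavy-tailed
  coverage outliers that repeats, conserved elements and mapping artifacts
  produce in real assemblies.
* **Reported variance.** The depth table's per-contig variance is
  `mean · var_ratio + (0.3 · mean)^2`: Poisson-like shot noise plus the
  positional overdispersion real depth summarizers measure along a contig
  (sd ≈ 0.3–0.5 of the mean at typical coverages). Reporting shot noise
  alone would understate real variances by an order of magnitude and make
  the abundance model treat same-genome contigs as many sigma apart.

Everything is deterministic given the seed: composition, fragmentation,
coverage and jitter each consume an independent child of one seed sequence.

What the simulator does **not** emulate: read-level errors and assembly
chimeras, strain mixtures within a genome, plasmids and viruses, GC-
coverage bias, and any correlation between contig length and depth noise.
Passing tests therefore show that the scoring and clustering machinery
behaves as designed under a realistic noise envelope — not that any
particular real assembly will bin at the same accuracy.

## Evaluation

A bin's **precision** is the bp share of its majority genome; a genome's
**completeness** is the bp of that genome inside the single bin holding
most of it, over all bp of the genome assigned to contigs (binned or not).
A genome is *recovered* at (c, p) when its best bin has precision ≥ p and
holds ≥ c of the genome; counts are reported on the grid
{0.5, 0.6, 0.7, 0.8, 0.9} × {0.9, 0.95}. No split credit is given: counting
recovered genomes, not per-bp F1, matches how binning results are used.

## Known limitations

* **Parallel coverage profiles.** Correlation is scale-invariant, so with
  few samples two genomes whose profiles are nearly proportional are
  indistinguishable to COR and to correlation-based recruiting; only
  composition separates them. With 20 genomes drawn from independent
  lognormals over 3 samples such near-parallel pairs occur by chance, and
  they are the dominant cause of residual merges.
* **Recruiting recall has a statistical ceiling.** The recruiting rule
  compares a candidate's mean correlation to the bin's *average* pairwise
  member correlation. For candidates statistically exchangeable with the
  members this is a comparison of one noise draw against the mean of the
  same distribution, and the mean of a chi-square-like variable sits above
  its typical value, so a clean candidate clears the bar only ~60–70% of
  the time regardless of the noise scale. Heavy-tailed member noise lowers
  the bar (the outlier minority drags the average down) and raises recall
  for typical contigs — but the same tails occasionally produce corrupted
  fragments that land in a foreign bin. Recall near 0.8 with rare wrong
  joins is the realistic operating point of the rule as defined.
* **Single-sample data.** With one sample the composite score leans on one
  abundance overlap and composition only; accuracy is substantially
  degraded and the pipeline warns accordingly.
* Serial implementation: the per-node link caps honor the O(N) memory
  contract, but no thread-level parallelism or cache blocking is attempted.
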