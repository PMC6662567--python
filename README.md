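# tetrabin

Adaptive metagenome binning: grouping assembled contigs into putative
genomes from two complementary signals — tetranucleotide composition and
read-depth profiles across samples — without manual parameter tuning.

Metagenome assemblies leave a biologist with thousands of anonymous contigs.
Contigs from one genome share a 4-mer composition signature (TNF) and rise
and fall together in abundance across samples. `tetrabin` scores every
contig pair on both channels, folds the scores onto one scale, clusters the
resulting similarity graph deterministically, and reports genome bins. A
synthetic-community simulator with ground truth and a completeness/precision
evaluator are part of the package, so the whole pipeline can be exercised
and benchmarked without external data.

## The score and the clustering

For a contig pair, three raw scores are computed:

* **TNF** — a logistic map of the Euclidean distance between the contigs'
  136-dimensional canonical tetramer frequency vectors, with a
  length-dependent midpoint (short contigs have noisier composition);
* **ABD** — per sample, the shared area of the two depth distributions
  N(mean, variance) taken from the depth table, combined across *effective*
  samples (depth > 1 for at least one contig) by geometric mean;
* **COR** — the Pearson correlation of the two depth profiles across
  samples, used when three or more samples are available.

TNF and COR are quantile-normalized onto the empirical ABD distribution, and
the composite edge score is

```
S = TNF^(1-w) * ABD^w                   with fewer than 3 samples
S = sqrt(TNF^(1-w) * ABD^w * COR)       with 3 or more samples
```

where `w = nABD/(nABD+1)` counts effective samples — more samples shift
weight from composition to abundance. Contigs (>= 2.5 kb by default) become
nodes of a sparse graph that keeps at most `maxEdges` strongest links per
node; edges are admitted from the strongest score down to `minS`, and after
each admission step a modified label propagation algorithm re-partitions the
graph: nodes are visited in decreasing order of their strongest link
(deterministic, no randomness), and each node joins the neighbor label whose
edge scores combine to the smallest Fisher's-method p-value (1 − S as the
per-link p-value), so a few strong links can outweigh many weak ones.
Finally, with three or more samples, bins under 200 kb dissolve and short
contigs (1–2.5 kb) are recruited into bins by depth correlation alone.

## Worked example

`examples/01_simulate_and_bin.py` simulates 8 genomes x 1 Mb over 3 samples
with distinct coverage profiles, bins the contigs, and scores the result
against the generating truth:

```
$ python examples/01_simulate_and_bin.py
community: 636 contigs from 8 genomes, 3 samples
binned 7,949,809 bp into 8 bins (6186 seed edges, 23069 candidate edges, 104 small contigs recruited)

genomes recovered (rows: completeness cutoff, columns: precision cutoff):
     0.90  0.95
0.5     8     8
0.6     8     8
0.7     8     8
0.8     8     8
0.9     8     8

high-quality bins (>=90% complete, <=5% contamination): 8
```

Every planted genome is recovered even at the strictest corner of the grid
(>= 90% of the genome's bp in one bin, >= 95% of that bin's bp from that
genome). The other examples walk through pairwise scoring, the recruiting
rule, and the genetic-algorithm parameter search.

## Command line

The same pipeline is exposed as a thin CLI:

```
tetrabin synth -o community --genomes 20 --samples 3 --seed 1
tetrabin bin -i community.fa -a community.depth.tsv -o bins --seed 1
tetrabin eval -m bins.membership.tsv -t community.truth.tsv
tetrabin tune -o fitness.tsv --genomes 10 --seed 1
```

`bin` accepts the familiar knobs `--minContig`, `--maxP`, `--minS`,
`--maxEdges`, `--minClsSize`; inputs are a contig FASTA and a per-contig
depth table (name, length, total depth, then per-sample mean/variance column
pairs — the dialect of the standard alignment depth summarizers; a mean-only
table is accepted with variance defaulting to the mean).

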