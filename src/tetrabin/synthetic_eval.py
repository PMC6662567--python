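"""Synthetic multi-sample communities with ground truth, and truth-based scoring.

The generator emulates the features of a real co-assembled metagenome that
the binner exploits, without read simulation or assembly:

* each genome is drawn from its own order-3 Markov chain whose transition
  logits are perturbed per genome, giving genomes distinguishable tetramer
  composition (``composition_bias`` scales the perturbation);
* genomes are fragmented into contigs by a mixture length law that includes
  a sub-2.5 kb fraction, mirroring short assembly leftovers;
* per-genome per-sample coverage levels are lognormal, so depth profiles
  across samples carry the covariance structure that the abundance and
  correlation scores use; per-contig depth means jitter around the genome
  level (``depth_noise``) and depth variances scale with the mean.

The evaluator scores a binning result against the generating truth the way
genome-recovery benchmarks count: per-bin precision is the bp share of the
bin's majority genome, per-genome completeness is the bp of the genome
inside the single bin holding most of it, and genomes are counted as
recovered on a completeness x precision threshold grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import BinSet, Contig, CoverageTable

__all__ = [
    "CommunitySpec",
    "Community",
    "EvalReport",
    "generate_community",
    "evaluate_bins",
    "write_depth_table",
    "write_truth",
    "read_truth",
]

COMPLETENESS_CUTOFFS = (0.5, 0.6, 0.7, 0.8, 0.9)
PRECISION_CUTOFFS = (0.9, 0.95)


@dataclass
class CommunitySpec:
    """Parameters of a simulated community.

    ``coverage_matrix`` (n_genomes x n_samples) overrides the lognormal
    coverage draw, and ``composition_groups`` assigns genomes to shared
    composition classes (same group -> same Markov transitions), for
    constructing communities where composition alone cannot separate
    genomes.
    """

    n_genomes: int = 20
    genome_length: int = 2_000_000
    n_samples: int = 3
    composition_bias: float = 0.5
    coverage_mu: float = 3.0  # ln-scale; median genome coverage ~ 20x
    coverage_sigma: float = 1.0
    frac_small: float = 0.2  # fraction of contigs drawn below 2.5 kb
    min_contig_len: int = 1000
    small_max_len: int = 2500
    max_contig_len: int = 50_000
    # per-contig mean-depth jitter around the genome-sample level is a
    # two-component scale mixture: most contigs carry mild noise, while a
    # minority ("depth-biased" contigs — repeats, conserved elements, mapping
    # artifacts) deviate strongly, mirroring the heavy-tailed coverage
    # outliers of real assemblies
    depth_noise: float = 0.08  # relative sd for typical contigs
    depth_outlier_frac: float = 0.1  # fraction of depth-biased contigs
    depth_outlier_noise: float = 0.35  # relative sd for depth-biased contigs
    var_ratio: float = 1.0  # shot-noise part of the reported variance
    # positional overdispersion of read depth along a contig, as sd fraction
    # of the mean — the dominant part of the variance the standard depth
    # summarizers report from real alignments
    depth_overdispersion: float = 0.3
    seed: int = 0
    coverage_matrix: np.ndarray | None = None
    composition_groups: list[int] | None = None

    def __post_init__(self) -> None:
        if min(self.n_genomes, self.genome_length, self.n_samples) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.frac_small <= 1.0):
            raise ValueError("frac_small must lie in [0, 1]")
        if self.genome_length < self.max_contig_len:
            raise ValueError("genome shorter than the maximum contig length")
        if self.coverage_matrix is not None:
            m = np.asarray(self.coverage_matrix, float)
            if m.shape != (self.n_genomes, self.n_samples):
                raise ValueError("coverage_matrix must be (n_genomes, n_samples)")
        if self.composition_groups is not None and len(self.composition_groups) != self.n_genomes:
            raise ValueError("composition_groups must list one group per genome")


@dataclass
class Community:
    contigs: list[Contig]
    coverage: CoverageTable
    truth: dict[str, str]  # contig id -> genome id
    genome_coverage: np.ndarray  # (n_genomes, n_samples)
    spec: CommunitySpec

    @property
    def lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.contigs}

    def save(self, prefix: str | os.PathLike) -> dict[str, str]:
        """Write <prefix>.fa, <prefix>.depth.tsv and <prefix>.truth.tsv."""
        prefix = str(prefix)
        fa = prefix + ".fa"
        with open(fa, "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.id}\n")
                for k in range(0, c.length, 80):
                    fh.write(c.sequence[k : k + 80] + "\n")
        depth = prefix + ".depth.tsv"
        write_depth_table(self.coverage, self.lengths, depth)
        truth = prefix + ".truth.tsv"
        write_truth(self.truth, self.lengths, truth)
        return {"fasta": fa, "depth": depth, "truth": truth}


@njit(cache=False)
def _markov_codes(cum: np.ndarray, u: np.ndarray, state0: int) -> np.ndarray:  # pragma: no cover
    n = u.shape[0]
    out = np.empty(n, dtype=np.uint8)
    state = state0
    for i in range(n):
        ui = u[i]
        c = 0
        while c < 3 and ui > cum[state, c]:
            c += 1
        out[i] = c
        state = (state * 4 + c) % 64
    return out


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _sample_genome(length: int, cum: np.ndarray, rng: np.random.Generator) -> str:
    u = rng.random(length)
    state0 = int(rng.integers(0, 64))
    codes = _markov_codes(cum, u, state0)
    return _BASES[codes].tobytes().decode("ascii")


def _transition_cum(bias: float, rng: np.random.Generator) -> np.ndarray:
    logits = bias * rng.standard_normal((64, 4))
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    return cum


def _fragment_lengths(total: int, spec: CommunitySpec, rng: np.random.Generator) -> list[int]:
    out: list[int] = []
    remaining = total
    log_lo = np.log(float(spec.small_max_len))
    log_hi = np.log(float(spec.max_contig_len))
    while remaining >= spec.min_contig_len:
        if rng.random() < spec.frac_small:
            ln = int(rng.integers(spec.min_contig_len, spec.small_max_len))
        else:
            ln = int(round(np.exp(rng.uniform(log_lo, log_hi))))
        ln = min(ln, remaining)
        if remaining - ln < spec.min_contig_len:
            ln = remaining  # absorb the tail instead of leaving a sliver
        out.append(ln)
        remaining -= ln
    if remaining and out:
        out[-1] += remaining
    return out


def generate_community(spec: CommunitySpec) -> Community:
    """Generate contigs, a noisy depth table, and the contig->genome truth.

    Fully deterministic for a fixed ``spec.seed``: genome composition,
    fragmentation, coverage levels and depth noise each consume an
    independent child of the same seed sequence.
    """
    ss = np.random.SeedSequence(spec.seed)
    comp_ss, seq_ss, frag_ss, cov_ss, noise_ss = ss.spawn(5)

    groups = (
        list(spec.composition_groups)
        if spec.composition_groups is not None
        else list(range(spec.n_genomes))
    )
    group_ids = sorted(set(groups))
    comp_children = comp_ss.spawn(len(group_ids))
    cum_by_group = {
        g: _transition_cum(spec.composition_bias, np.random.default_rng(child))
        for g, child in zip(group_ids, comp_children)
    }

    seq_children = seq_ss.spawn(spec.n_genomes)
    frag_rng = np.random.default_rng(frag_ss)
    cov_rng = np.random.default_rng(cov_ss)
    noise_rng = np.random.default_rng(noise_ss)

    if spec.coverage_matrix is not None:
        genome_cov = np.asarray(spec.coverage_matrix, float).copy()
    else:
        genome_cov = cov_rng.lognormal(
            spec.coverage_mu, spec.coverage_sigma, (spec.n_genomes, spec.n_samples)
        )

    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    means: list[np.ndarray] = []
    for g in range(spec.n_genomes):
        genome_id = f"genome_{g:03d}"
        seq = _sample_genome(
            spec.genome_length, cum_by_group[groups[g]], np.random.default_rng(seq_children[g])
        )
        pos = 0
        for k, ln in enumerate(_fragment_lengths(spec.genome_length, spec, frag_rng)):
            cid = f"g{g:03d}_c{k:04d}"
            contigs.append(Contig(id=cid, sequence=seq[pos : pos + ln]))
            truth[cid] = genome_id
            pos += ln
            sd = (
                spec.depth_outlier_noise
                if noise_rng.random() < spec.depth_outlier_frac
                else spec.depth_noise
            )
            jitter = 1.0 + sd * noise_rng.standard_normal(spec.n_samples)
            means.append(genome_cov[g] * np.maximum(jitter, 0.01))

    mean = np.vstack(means)
    # reported per-contig depth variance: Poisson-like shot noise plus the
    # positional overdispersion real depth summarizers measure along a contig
    var = mean * spec.var_ratio + (spec.depth_overdispersion * mean) ** 2
    coverage = CoverageTable(
        contig_ids=[c.id for c in contigs], mean_depth=mean, depth_variance=var
    )
    return Community(
        contigs=contigs,
        coverage=coverage,
        truth=truth,
        genome_coverage=genome_cov,
        spec=spec,
    )


def write_depth_table(
    coverage: CoverageTable,
    lengths: dict[str, int],
    path: str | os.PathLike,
    sample_names: list[str] | None = None,
) -> None:
    """Write the standard depth-table dialect (mean/variance column pairs)."""
    s = coverage.n_samples
    names = sample_names or [f"sample{k + 1}" for k in range(s)]
    cols = ["contigName", "contigLen", "totalAvgDepth"]
    for nm in names:
        cols += [nm, f"{nm}-var"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, cid in enumerate(coverage.contig_ids):
            row = [cid, str(lengths[cid]), f"{coverage.mean_depth[i].sum():.6f}"]
            for k in range(s):
                row.append(f"{coverage.mean_depth[i, k]:.6f}")
                row.append(f"{coverage.depth_variance[i, k]:.6f}")
            fh.write("\t".join(row) + "\n")


def write_truth(
    truth: dict[str, str], lengths: dict[str, int], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tgenome_id\tcontig_bp\n")
        for cid, gid in truth.items():
            fh.write(f"{cid}\t{gid}\t{lengths[cid]}\n")


def read_truth(path: str | os.PathLike) -> tuple[dict[str, str], dict[str, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "genome_id": str})
    truth = dict(zip(df["contig_id"], df["genome_id"]))
    lengths = dict(zip(df["contig_id"], df["contig_bp"].astype(int)))
    return truth, lengths


@dataclass
class EvalReport:
    """Truth-based score of one binning result."""

    bin_precision: dict[str, float]
    bin_majority: dict[str, str]
    genome_completeness: dict[str, float]
    genome_best_bin: dict[str, str | None]
    recovered: dict[tuple[float, float], int] = field(default_factory=dict)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                p: [self.recovered[(c, p)] for c in COMPLETENESS_CUTOFFS]
                for p in PRECISION_CUTOFFS
            },
            index=list(COMPLETENESS_CUTOFFS),
        )

    def n_recovered(self, completeness: float = 0.9, precision: float = 0.95) -> int:
        return self.recovered[(completeness, precision)]

    def hq_bins(self, completeness: float = 0.9, precision: float = 0.95) -> int:
        """Bins whose majority genome is at least ``completeness`` complete
        in that bin and whose precision is at least ``precision``."""
        n = 0
        for b, prec in self.bin_precision.items():
            g = self.bin_majority[b]
            if prec >= precision and self.genome_best_bin.get(g) == b:
                if self.genome_completeness[g] >= completeness:
                    n += 1
        return n


def evaluate_bins(
    bins: BinSet, truth: dict[str, str], lengths: dict[str, int]
) -> EvalReport:
    """Score bins against the generating truth.

    Completeness is measured against all bp of the genome assigned to
    contigs (binned or not); a genome gets credit in its single best bin
    only (no split credit). A genome counts as recovered at (c, p) iff its
    best bin has precision >= p and holds >= c of the genome's bp.
    """
    missing = [c for m in bins.bins.values() for c in m if c not in truth]
    if missing:
        raise ValueError(f"binned contig {missing[0]!r} absent from the truth")

    genome_bp: dict[str, int] = {}
    for cid, gid in truth.items():
        genome_bp[gid] = genome_bp.get(gid, 0) + lengths[cid]

    bin_precision: dict[str, float] = {}
    bin_majority: dict[str, str] = {}
    genome_in_bin: dict[str, dict[str, int]] = {g: {} for g in genome_bp}
    for b in sorted(bins.bins):
        per_genome: dict[str, int] = {}
        for cid in bins.bins[b]:
            g = truth[cid]
            per_genome[g] = per_genome.get(g, 0) + lengths[cid]
            genome_in_bin[g][b] = genome_in_bin[g].get(b, 0) + lengths[cid]
        total = sum(per_genome.values())
        best_g = max(sorted(per_genome), key=lambda g: per_genome[g])
        bin_majority[b] = best_g
        bin_precision[b] = per_genome[best_g] / total if total else 0.0

    genome_completeness: dict[str, float] = {}
    genome_best_bin: dict[str, str | None] = {}
    for g in sorted(genome_bp):
        holdings = genome_in_bin[g]
        if not holdings:
            genome_best_bin[g] = None
            genome_completeness[g] = 0.0
            continue
        best_b = max(sorted(holdings), key=lambda b: holdings[b])
        genome_best_bin[g] = best_b
        genome_completeness[g] = holdings[best_b] / genome_bp[g]

    recovered: dict[tuple[float, float], int] = {}
    for c in COMPLETENESS_CUTOFFS:
        for p in PRECISION_CUTOFFS:
            n = 0
            for g in genome_bp:
                b = genome_best_bin[g]
                if b is None:
                    continue
                if genome_completeness[g] >= c and bin_precision[b] >= p:
                    n += 1
            recovered[(c, p)] = n

    return EvalReport(
        bin_precision=bin_precision,
        bin_majority=bin_majority,
        genome_completeness=genome_completeness,
        genome_best_bin=genome_best_bin,
        recovered=recovered,
    )
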