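"""End-to-end binning pipeline: evidence -> normalization -> graph -> bins.

`run_binning` is the library entry point (in-memory contigs + coverage);
`run_binning_files` wraps it with file I/O for the command line.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np

from . import features, recruit, scoring
from .graph_cluster import BinningParams, build_seed_graph, iterative_partition
from .io_formats import (
    BinSet,
    Contig,
    CoverageTable,
    align_coverage,
    read_depth_table,
    read_fasta,
    write_bins,
)

logger = logging.getLogger(__name__)

__all__ = ["run_binning", "run_binning_files"]


def _rename_bins(raw: dict[str, list[str]], lengths: dict[str, int]) -> BinSet:
    """Deterministic bin ids: bin.1, bin.2, ... by decreasing size."""
    sized = sorted(
        raw.items(),
        key=lambda kv: (-sum(lengths[c] for c in kv[1]), min(kv[1])),
    )
    renamed = {f"bin.{i + 1}": sorted(members) for i, (_, members) in enumerate(sized)}
    return BinSet.from_bins(renamed, lengths)


def run_binning(
    contigs: list[Contig],
    coverage: CoverageTable,
    params: BinningParams | None = None,
) -> tuple[BinSet, dict]:
    """Bin contigs from composition and multi-sample coverage.

    Contigs of at least ``min_contig`` bp are clustered on the two-stage
    similarity graph; clusters below ``min_cls_size`` bp are dissolved and,
    when three or more samples are available, their members plus short
    contigs (>= ``min_contig_recruit`` bp) are recruited back by coverage
    correlation. Returns the bins and a summary dict of run statistics.
    """
    params = params or BinningParams()
    coverage, missing = align_coverage(contigs, coverage)
    lengths = {c.id: c.length for c in contigs}
    n_samples = coverage.n_samples
    if n_samples == 1:
        logger.warning(
            "single-sample input: binning accuracy is substantially degraded "
            "without coverage covariance across multiple samples"
        )

    summary: dict = {
        "n_contigs": len(contigs),
        "n_samples": n_samples,
        "params": asdict(params),
        "contigs_missing_depth": len(missing),
    }

    large = [c for c in contigs if c.length >= params.min_contig]
    summary["n_clustered_contigs"] = len(large)
    if not large:
        logger.warning("no contigs reach min_contig=%d bp", params.min_contig)
        summary.update(n_bins=0, binned_bp=0, n_seed_edges=0, n_candidate_edges=0)
        return BinSet(), summary

    ids = [c.id for c in large]
    freq, kmers = features.tnf_matrix([c.sequence for c in large])
    lens = np.array([c.length for c in large], dtype=float)
    cov = coverage.subset(ids)

    tnf = features.tnf_score_matrix(freq, lens)
    # contigs without a single valid tetramer window carry no composition
    # evidence; sever their TNF links
    dead = kmers == 0
    if dead.any():
        tnf[dead, :] = np.nan
        tnf[:, dead] = np.nan

    abd, n_abd = features.abd_matrix(cov.mean_depth, cov.depth_variance, params.min_cv)
    cor = features.cor_matrix(cov.mean_depth)

    rng = np.random.default_rng(params.seed)
    si, sj = scoring.sample_pair_indices(len(ids), rng)
    # COR from n samples cannot resolve differences finer than ~1/(n-1);
    # snap to that grid so rank normalization does not amplify noise
    cor_res = 1.0 / (n_samples - 1) if n_samples >= 3 else 0.0
    norms = scoring.ScoreDistributions.from_samples(
        tnf[si, sj], abd[si, sj], cor[si, sj], cor_resolution=cor_res
    )
    s_mat = scoring.composite_matrix(
        tnf, abd, n_abd, cor, norms, cube_root_cor=params.cube_root_cor
    )

    # seed-graph edge weights: composite S where defined, normalized TNF for
    # pairs with no effective coverage (TNF-only evidence, stage one only)
    tnf_n = norms.tnf_to_norm(tnf)
    weights = np.where(np.isfinite(s_mat), s_mat, tnf_n)
    weights = np.where(np.isfinite(tnf), weights, np.nan)
    # min_s is the minimum score of an edge kept for binning anywhere,
    # including stage one
    weights = np.where(weights >= params.min_s / 100.0, weights, np.nan)

    tnf_sample = tnf[si, sj]
    tnf_cutoff = float(np.nanpercentile(tnf_sample, params.max_p))
    graph = build_seed_graph(ids, np.nan_to_num(tnf, nan=-1.0), weights, tnf_cutoff, params)
    summary["n_seed_edges"] = graph.n_active_edges()
    summary["tnf_cutoff"] = tnf_cutoff

    floor = params.min_s / 100.0
    iu, ju = np.triu_indices(len(ids), k=1)
    s_up = s_mat[iu, ju]
    cand = np.isfinite(s_up) & (s_up >= floor)
    candidate_edges = [
        (float(s_up[k]), ids[iu[k]], ids[ju[k]]) for k in np.flatnonzero(cand)
    ]
    summary["n_candidate_edges"] = len(candidate_edges)

    s_sample = s_mat[si, sj]
    s_sample = s_sample[np.isfinite(s_sample)]
    s_start = float(np.percentile(s_sample, params.max_p)) if s_sample.size else floor

    labeling = iterative_partition(ids, graph, candidate_edges, params, s_start=s_start)

    raw_bins: dict[str, list[str]] = {}
    for node, lab in labeling.label.items():
        raw_bins.setdefault(str(lab), []).append(node)
    bins = BinSet.from_bins(raw_bins, lengths)

    if n_samples >= 3:
        bins, freed = recruit.dissolve_small_bins(bins, params.min_cls_size, n_samples)
        small = [
            c.id
            for c in contigs
            if params.min_contig_recruit <= c.length < params.min_contig
        ]
        free = sorted(set(freed) | set(small))
        summary["n_free_contigs"] = len(free)
        bins, decisions = recruit.recruit_free_contigs(
            bins, free, coverage, lengths, seed=params.seed
        )
        summary["n_recruited"] = sum(1 for d in decisions if d.target_bin)
    else:
        kept = {
            b: m for b, m in bins.bins.items() if bins.bin_bp[b] >= params.min_cls_size
        }
        bins = BinSet.from_bins(kept, lengths)
        summary["n_free_contigs"] = 0
        summary["n_recruited"] = 0

    bins = _rename_bins(bins.bins, lengths)
    summary["n_bins"] = bins.n_bins
    summary["binned_bp"] = sum(bins.bin_bp.values())
    logger.info(
        "binned %d contigs into %d bins (%d bp)",
        sum(len(m) for m in bins.bins.values()),
        bins.n_bins,
        summary["binned_bp"],
    )
    return bins, summary


def run_binning_files(
    fasta: str,
    depth: str,
    out_prefix: str,
    params: BinningParams | None = None,
) -> tuple[BinSet, dict]:
    """File-based pipeline: read inputs, bin, write bin FASTAs + membership."""
    contigs = read_fasta(fasta)
    coverage = read_depth_table(depth)
    bins, summary = run_binning(contigs, coverage, params)
    written = write_bins(bins, contigs, out_prefix)
    summary["files"] = written
    return bins, summary
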