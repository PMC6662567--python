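"""Post-clustering recruiting of small contigs and dissolution of small bins.

Clustering only sees contigs above the minimum length, and some resulting
bins are too small to be credible genomes. With three or more samples the
depth profile of a contig across samples carries enough signal on its own,
so a second chance is given by coverage correlation: bins under the size
threshold are dissolved into a free pool together with the short contigs
(1-2.5 kb by default), and a free contig joins the bin to whose members its
mean Pearson correlation is higher than the bin's own mean within-member
correlation. With fewer than three samples the whole step is a no-op —
3-point correlations are meaningless and the evidence is too weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import BinSet, CoverageTable

logger = logging.getLogger(__name__)

__all__ = ["RecruitDecision", "dissolve_small_bins", "recruit_free_contigs"]

# bins larger than this subsample their members for the O(m^2) within-bin
# mean pairwise correlation; the correlation matrix is vectorised, so the
# cap only guards pathological bin sizes
_WITHIN_CAP = 400


@dataclass
class RecruitDecision:
    contig_id: str
    target_bin: str | None
    free_to_bin_corr: float
    within_bin_corr: float


def dissolve_small_bins(
    bins: BinSet, min_cls_size: int, n_samples: int
) -> tuple[BinSet, list[str]]:
    """Remove bins below ``min_cls_size`` bp; members join the free pool.

    Skipped entirely (input returned unchanged) with fewer than 3 samples.
    """
    if n_samples < 3:
        return bins, []
    keep = {b: m for b, m in bins.bins.items() if bins.bin_bp[b] >= min_cls_size}
    freed = sorted(
        c for b, m in bins.bins.items() if b not in keep for c in m
    )
    kept = BinSet(
        bins={b: list(m) for b, m in keep.items()},
        bin_bp={b: bins.bin_bp[b] for b in keep},
    )
    return kept, freed


def _profile_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of a and every row of b; NaN where a
    profile has zero variance."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1)
    bn = np.linalg.norm(bz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az @ bz.T) / an[:, None] / bn[None, :]
    return r


def recruit_free_contigs(
    bins: BinSet,
    free: list[str],
    coverage: CoverageTable,
    lengths: dict[str, int],
    seed: int = 0,
) -> tuple[BinSet, list[RecruitDecision]]:
    """Assign free contigs to bins by coverage correlation.

    A free contig is recruited into the bin where its mean correlation to
    the member contigs exceeds the mean pairwise correlation among the
    members themselves, taking the best such bin (ties by bin id). All
    decisions are made against the pre-recruitment bin state, so the result
    is independent of the order of the free list. Single-member bins have no
    within-bin correlation and never recruit. No-op with < 3 samples.
    """
    if coverage.n_samples < 3 or not free or not bins.bins:
        return bins, []

    rng = np.random.default_rng(seed)
    bin_ids = sorted(bins.bins)
    within: dict[str, float] = {}
    member_rows: dict[str, np.ndarray] = {}
    for b in bin_ids:
        members = bins.bins[b]
        rows = np.array([coverage.row(c) for c in members])
        member_rows[b] = rows
        if len(members) < 2:
            logger.info("bin %s has a single member; it cannot recruit", b)
            within[b] = np.nan
            continue
        sub = rows
        if len(rows) > _WITHIN_CAP:
            sub = rng.choice(rows, size=_WITHIN_CAP, replace=False)
        prof = coverage.mean_depth[sub]
        r = _profile_corr(prof, prof)
        iu = np.triu_indices(len(sub), k=1)
        within[b] = float(np.nanmean(r[iu]))

    free = sorted(set(free))
    free_rows = np.array([coverage.row(c) for c in free])
    free_prof = coverage.mean_depth[free_rows]

    decisions: list[RecruitDecision] = []
    new_members: dict[str, list[str]] = {b: [] for b in bin_ids}
    for k, cid in enumerate(free):
        # the candidate bin is the argmax of mean correlation over all bins
        # (ties by bin id); the contig is assigned only if that correlation
        # also beats the bin's own within-member average
        best_bin = None
        best_r = -np.inf
        for b in bin_ids:
            r = _profile_corr(
                free_prof[k : k + 1], coverage.mean_depth[member_rows[b]]
            )
            mean_r = float(np.nanmean(r)) if np.isfinite(r).any() else np.nan
            if np.isfinite(mean_r) and mean_r > best_r:
                best_r = mean_r
                best_bin = b
        qualifies = (
            best_bin is not None
            and np.isfinite(within[best_bin])
            and best_r > within[best_bin]
        )
        decisions.append(
            RecruitDecision(
                contig_id=cid,
                target_bin=best_bin if qualifies else None,
                free_to_bin_corr=best_r if best_bin is not None else float("nan"),
                within_bin_corr=(
                    within[best_bin] if best_bin is not None else float("nan")
                ),
            )
        )
        if qualifies:
            new_members[best_bin].append(cid)

    out_bins = {b: list(m) + new_members[b] for b, m in bins.bins.items()}
    out = BinSet.from_bins(out_bins, lengths)
    n_rec = sum(1 for d in decisions if d.target_bin)
    logger.info("recruited %d of %d free contigs", n_rec, len(free))
    return out, decisions
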