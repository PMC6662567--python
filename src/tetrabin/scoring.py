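"""Score normalization and the composite edge score.

TNF, ABD and COR scores live on very different scales, so TNF and COR are
quantile-normalized onto the empirical ABD distribution: a raw value is
replaced by the ABD quantile at its rank within its own sampled
distribution. After normalization the composite score is

    S = TNF_n^(1-w) * ABD^w                      (fewer than 3 samples)
    S = sqrt(TNF_n^(1-w) * ABD^w * COR_n)        (3 or more samples)

with w = nABD/(nABD+1): the more effective samples a pair has, the more
weight abundance carries relative to composition.

Normalizers are fitted on a uniform random sample of contig pairs rather
than the full O(N^2) pair set; distribution estimation only needs a sample
and the subsampling is seeded, so runs stay deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import PairEvidence

__all__ = [
    "ScoreDistributions",
    "CompositeScore",
    "fit_normalizers",
    "composite_score",
    "composite_matrix",
    "sample_pair_indices",
]


def _rank_map(query, sorted_raw: np.ndarray, sorted_target: np.ndarray):
    """Quantile-normalize ``query``: empirical rank within ``sorted_raw``,
    then the ``sorted_target`` quantile at that rank (linear interpolation
    between order statistics; queries outside the fitted range clamp to the
    endpoint quantiles)."""
    n = sorted_raw.size
    m = sorted_target.size
    ranks = np.interp(query, sorted_raw, np.linspace(0.0, 1.0, n))
    return np.interp(ranks, np.linspace(0.0, 1.0, m), sorted_target)


@dataclass
class ScoreDistributions:
    """Monotone raw->normalized mappings fitted from sampled pairs.

    ``cor_resolution`` > 0 snaps correlation values to a grid of that step
    (both the fitted sample and queries) before ranking. A Pearson
    correlation estimated from a handful of samples cannot resolve fine
    differences — over three samples it carries a single degree of freedom —
    and rank normalization would otherwise amplify sub-resolution noise
    across a wide quantile range. Tied values share one rank, hence one
    normalized score.
    """

    abd_sample: np.ndarray  # sorted
    tnf_sample: np.ndarray  # sorted
    cor_sample: np.ndarray | None  # sorted, None when COR was never defined
    cor_resolution: float = 0.0

    def _snap(self, cor):
        if self.cor_resolution > 0:
            return np.round(np.asarray(cor, float) / self.cor_resolution) * self.cor_resolution
        return cor

    def tnf_to_norm(self, tnf_raw):
        return _rank_map(tnf_raw, self.tnf_sample, self.abd_sample)

    def cor_to_norm(self, cor):
        if self.cor_sample is None or self.cor_sample.size < 2:
            raise ValueError("no COR distribution was fitted")
        return _rank_map(self._snap(cor), self.cor_sample, self.abd_sample)

    @property
    def has_cor(self) -> bool:
        return self.cor_sample is not None and self.cor_sample.size >= 2

    @classmethod
    def from_samples(
        cls,
        tnf: np.ndarray,
        abd: np.ndarray,
        cor: np.ndarray | None,
        cor_resolution: float = 0.0,
    ) -> "ScoreDistributions":
        abd = np.asarray(abd, float)
        abd = abd[np.isfinite(abd)]
        if abd.size < 2:
            raise ValueError(
                "fewer than 2 pairs with a defined ABD score; check that the "
                "depth table has coverage above the effective threshold"
            )
        tnf = np.asarray(tnf, float)
        tnf = np.sort(tnf[np.isfinite(tnf)])
        cor_sorted = None
        if cor is not None:
            cor = np.asarray(cor, float)
            cor = cor[np.isfinite(cor)]
            if cor.size >= 2:
                # negative correlations rank into the low tail (no truncation
                # before ranking: rank normalization is order-based)
                if cor_resolution > 0:
                    cor = np.round(cor / cor_resolution) * cor_resolution
                cor_sorted = np.sort(cor)
        return cls(
            abd_sample=np.sort(abd),
            tnf_sample=tnf,
            cor_sample=cor_sorted,
            cor_resolution=cor_resolution,
        )


def fit_normalizers(
    pairs: list[PairEvidence], cor_resolution: float = 0.0
) -> ScoreDistributions:
    """Fit the TNF->ABD and COR->ABD quantile maps from sampled pairs."""
    tnf = np.array([p.tnf_raw for p in pairs], float)
    abd = np.array([p.abd for p in pairs], float)
    cor = np.array([p.cor for p in pairs], float)
    return ScoreDistributions.from_samples(tnf, abd, cor, cor_resolution=cor_resolution)


@dataclass
class CompositeScore:
    S: float
    w: float


def composite_score(
    evidence: PairEvidence,
    norms: ScoreDistributions,
    cube_root_cor: bool = False,
) -> CompositeScore:
    """Composite edge score for one pair.

    Undefined ABD (no effective sample) leaves S undefined (NaN): such a
    pair carries TNF-only evidence and can enter the seed graph only.
    ``cube_root_cor`` switches the three-factor combination from the printed
    square root to a true cube root, for sensitivity analysis.
    """
    w = evidence.n_abd / (evidence.n_abd + 1)
    if not np.isfinite(evidence.tnf_raw):
        return CompositeScore(S=float("nan"), w=w)
    if not np.isfinite(evidence.abd) or evidence.n_abd == 0:
        return CompositeScore(S=float("nan"), w=w)
    tnf_n = float(norms.tnf_to_norm(evidence.tnf_raw))
    s = tnf_n ** (1.0 - w) * evidence.abd**w
    if np.isfinite(evidence.cor) and norms.has_cor:
        cor_n = float(norms.cor_to_norm(evidence.cor))
        prod = s * cor_n
        s = prod ** (1.0 / 3.0) if cube_root_cor else np.sqrt(prod)
    return CompositeScore(S=float(np.clip(s, 0.0, 1.0)), w=w)


def composite_matrix(
    tnf_raw: np.ndarray,
    abd: np.ndarray,
    n_abd: np.ndarray,
    cor: np.ndarray,
    norms: ScoreDistributions,
    cube_root_cor: bool = False,
) -> np.ndarray:
    """Vectorised composite_score over pair matrices; NaN where undefined."""
    w = n_abd / (n_abd + 1.0)
    tnf_n = norms.tnf_to_norm(tnf_raw)
    with np.errstate(invalid="ignore"):
        s = tnf_n ** (1.0 - w) * abd**w
        if norms.has_cor:
            cor_n = norms.cor_to_norm(cor)
            prod = s * cor_n
            with_cor = prod ** (1.0 / 3.0) if cube_root_cor else np.sqrt(prod)
            s = np.where(np.isfinite(cor), with_cor, s)
    s = np.where(np.isfinite(abd) & (n_abd > 0), s, np.nan)
    return np.clip(s, 0.0, 1.0)


def sample_pair_indices(
    n: int,
    rng: np.random.Generator,
    per_node: int = 500,
    cap: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random sample of distinct-contig pairs (i < j) for fitting.

    Uses all pairs when there are fewer than the budget min(per_node*n, cap);
    duplicates in the sampled regime are harmless for quantile estimation.
    """
    total = n * (n - 1) // 2
    budget = min(per_node * n, cap)
    if total <= budget:
        i, j = np.triu_indices(n, k=1)
        return i, j
    i = rng.integers(0, n, size=budget)
    j = rng.integers(0, n - 1, size=budget)
    j = np.where(j >= i, j + 1, j)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return lo, hi
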