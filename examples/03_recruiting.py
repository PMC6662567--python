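"""Correlation-based recruiting of short contigs, decision by decision.

Clustering only sees contigs of at least 2.5 kb. With three or more samples,
shorter contigs (1-2.5 kb) get a second chance: one joins a bin when its
mean depth-profile correlation to the bin members beats the bin's own mean
within-member correlation.
"""

import numpy as np

from tetrabin.io_formats import BinSet, CoverageTable
from tetrabin.recruit import recruit_free_contigs

profiles = {
    # bin A members track coverage (30, 5, 20) across three samples
    "A1": [30.0, 5.0, 20.0], "A2": [32.0, 4.5, 19.0], "A3": [28.5, 5.5, 21.5],
    # bin B members track (5, 40, 10)
    "B1": [5.0, 40.0, 10.0], "B2": [5.5, 38.0, 10.5], "B3": [4.5, 42.0, 9.0],
    # free short contigs: one from each community, one corrupted profile
    "short_a": [29.0, 5.2, 20.5],
    "short_b": [5.2, 41.0, 9.8],
    "corrupt": [20.0, 16.0, 23.0],
}
ids = list(profiles)
mean = np.array([profiles[c] for c in ids])
coverage = CoverageTable(ids, mean, mean.copy())
lengths = {c: (50_000 if c[0] in "AB" else 1800) for c in ids}

bins = BinSet.from_bins({"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]}, lengths)
out, decisions = recruit_free_contigs(
    bins, ["short_a", "short_b", "corrupt"], coverage, lengths
)
for d in decisions:
    print(f"{d.contig_id:8s} -> {d.target_bin or 'unbinned':9s} "
          f"(r to bin = {d.free_to_bin_corr:.4f}, within-bin bar = {d.within_bin_corr:.4f})")
print("\nfinal bins:", {b: sorted(m) for b, m in out.bins.items()})
# short_a and short_b clear their bins' bars; the corrupted profile
# correlates with neither community well enough and stays unbinned.
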