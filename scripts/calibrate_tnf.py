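"""Calibrate the TNF logistic coefficients on simulated communities.

Run from the repository root:

    python scripts/calibrate_tnf.py

Fragments of simulated genomes are paired within and between genomes at a
range of lengths. For each length the midpoint distance d0(L) is placed
halfway between the median same-genome and median different-genome
Euclidean TNF distance; d0(L)^2 is then regressed on 1/L (4-mer frequency
sampling variance scales as 1/L), giving TNF_A and TNF_B. The slope
constant TNF_K0 is set so the median same-genome pair scores 0.9.

The resulting coefficients are frozen in tetrabin.features (TNF_A, TNF_B,
TNF_K0). The procedure is deterministic: seed 20240601.
"""

from __future__ import annotations

import numpy as np

from tetrabin.features import tnf_matrix
from tetrabin.synthetic_eval import CommunitySpec, generate_community

SEED = 20240601
LENGTHS = [1000, 1750, 2500, 5000, 10000, 20000, 50000]
N_GENOMES = 12
GENOME_LENGTH = 1_000_000
FRAGMENTS_PER_GENOME = 30


def main() -> None:
    spec = CommunitySpec(
        n_genomes=N_GENOMES,
        genome_length=GENOME_LENGTH,
        n_samples=1,
        seed=SEED,
    )
    community = generate_community(spec)
    # reassemble each genome from its contigs so fragments can be re-cut at
    # controlled lengths
    genomes: dict[str, str] = {}
    for c in community.contigs:
        g = community.truth[c.id]
        genomes[g] = genomes.get(g, "") + c.sequence

    rng = np.random.default_rng(SEED)
    rows = []
    for L in LENGTHS:
        frags: list[str] = []
        owner: list[int] = []
        for gi, (g, seq) in enumerate(sorted(genomes.items())):
            starts = rng.integers(0, len(seq) - L, size=FRAGMENTS_PER_GENOME)
            for s in starts:
                frags.append(seq[s : s + L])
                owner.append(gi)
        freq, _ = tnf_matrix(frags)
        owner_arr = np.array(owner)
        sq = np.einsum("ij,ij->i", freq, freq)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * freq @ freq.T, 0)
        d = np.sqrt(d2)
        iu, ju = np.triu_indices(len(frags), k=1)
        same = owner_arr[iu] == owner_arr[ju]
        d_same = np.median(d[iu[same], ju[same]])
        d_diff = np.median(d[iu[~same], ju[~same]])
        d0 = 0.5 * (d_same + d_diff)
        rows.append((L, d_same, d_diff, d0))
        print(f"L={L:6d}  median same={d_same:.5f}  diff={d_diff:.5f}  d0={d0:.5f}")

    L_arr = np.array([r[0] for r in rows], float)
    d0_arr = np.array([r[3] for r in rows])
    X = np.column_stack([1.0 / L_arr, np.ones_like(L_arr)])
    (a, b), *_ = np.linalg.lstsq(X, d0_arr**2, rcond=None)

    # slope: median same-genome pair should score ~0.9 => k0*(d/d0 - 1) = -ln 9
    d_same_arr = np.array([r[1] for r in rows])
    d0_fit = np.sqrt(a / L_arr + b)
    k0 = float(np.median(np.log(9.0) / (1.0 - d_same_arr / d0_fit)))
    print(f"\nTNF_A = {a:.4g}\nTNF_B = {b:.4g}\nTNF_K0 = {k0:.4g}")


if __name__ == "__main__":
    main()
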