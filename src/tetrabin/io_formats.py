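"""Readers and writers for the binner's on-disk formats.

Three plain-text formats are handled here: contig FASTA, the per-contig
depth table produced by the usual alignment depth summarizers (one row per
contig: name, length, total average depth, then per-sample mean/variance
column pairs), and the bin outputs (one FASTA per bin plus a contig->bin
membership TSV).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID = set("ACGT")


@dataclass
class Contig:
    """A contiguous assembled sequence, the unit of binning."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CoverageTable:
    """Per-contig, per-sample read-depth means and variances.

    Rows align with ``contig_ids``; both matrices have shape
    (n_contigs, n_samples).
    """

    contig_ids: list[str]
    mean_depth: np.ndarray
    depth_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        self.depth_variance = np.asarray(self.depth_variance, dtype=float)
        if self.mean_depth.shape != self.depth_variance.shape:
            raise ValueError("mean and variance matrices must share a shape")
        if self.mean_depth.shape[0] != len(self.contig_ids):
            raise ValueError("row count must equal the number of contigs")
        if np.any(self.depth_variance < 0):
            raise ValueError("negative depth variance")
        self._index = {c: i for i, c in enumerate(self.contig_ids)}

    @property
    def n_samples(self) -> int:
        return self.mean_depth.shape[1]

    def row(self, contig_id: str) -> int:
        return self._index[contig_id]

    def subset(self, contig_ids: list[str]) -> "CoverageTable":
        idx = [self._index[c] for c in contig_ids]
        return CoverageTable(
            list(contig_ids), self.mean_depth[idx], self.depth_variance[idx]
        )


@dataclass
class BinSet:
    """A partial partition of contigs into genome bins."""

    bins: dict[str, list[str]] = field(default_factory=dict)
    bin_bp: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_bins(cls, bins: dict[str, list[str]], lengths: dict[str, int]) -> "BinSet":
        seen: set[str] = set()
        for members in bins.values():
            for c in members:
                if c in seen:
                    raise ValueError(f"contig {c!r} assigned to two bins")
                seen.add(c)
        bp = {b: sum(lengths[c] for c in members) for b, members in bins.items()}
        return cls(bins={b: list(m) for b, m in bins.items()}, bin_bp=bp)

    def membership(self) -> dict[str, str]:
        return {c: b for b, members in self.bins.items() for c in members}

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read contigs from FASTA.

    Sequences are uppercased and any character outside A/C/G/T is mapped to
    N, so downstream tetramer counting only ever has to treat N specially.
    Duplicate record ids and empty files are fatal.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        seq = "".join(c if c in _VALID else "N" for c in seq)
        if not seq:
            raise ValueError(f"FASTA record {name!r} has an empty sequence")
        contigs.append(Contig(id=name, sequence=seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                if name in seen:
                    raise ValueError(f"duplicate contig id {name!r} in {path}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path} does not start with a FASTA header")
                chunks.append(line)
    _flush()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def read_depth_table(path: str | os.PathLike) -> CoverageTable:
    """Read a depth table: contigName, contigLen, totalAvgDepth, then either
    <sample>/<sample>-var column pairs or mean-only sample columns.

    In mean-only mode the variance defaults to the mean (Poisson-like), which
    is logged prominently since it weakens the abundance-overlap evidence.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: depth table needs at least 3 columns")
    sample_cols = list(df.columns[3:])
    names = df.iloc[:, 0].astype(str).tolist()

    paired = len(sample_cols) % 2 == 0 and all(
        str(sample_cols[i + 1]).endswith("-var") for i in range(0, len(sample_cols), 2)
    )
    if paired:
        mean_cols = sample_cols[0::2]
        var_cols = sample_cols[1::2]
        mean = df[mean_cols].to_numpy(dtype=float)
        var = df[var_cols].to_numpy(dtype=float)
    elif any(str(c).endswith("-var") for c in sample_cols):
        raise ValueError(
            f"{path}: *-var columns present but not in mean/variance pairs"
        )
    else:
        logger.warning(
            "%s: mean-only depth table (no *-var columns); assuming "
            "variance = mean for all %d samples",
            path,
            len(sample_cols),
        )
        mean = df[sample_cols].to_numpy(dtype=float)
        var = mean.copy()

    if np.any(var < 0):
        bad = names[int(np.argwhere(np.any(var < 0, axis=1))[0, 0])]
        raise ValueError(f"{path}: negative depth variance at contig {bad!r}")
    return CoverageTable(contig_ids=names, mean_depth=mean, depth_variance=var)


def align_coverage(
    contigs: list[Contig], coverage: CoverageTable
) -> tuple[CoverageTable, list[str]]:
    """Reorder a coverage table to the contig list.

    Contigs missing from the depth table get zero coverage in every sample
    and are returned as a warning list; depth rows with no matching contig
    are dropped (also warned about).
    """
    n = len(contigs)
    s = coverage.n_samples
    mean = np.zeros((n, s))
    var = np.zeros((n, s))
    missing: list[str] = []
    for i, c in enumerate(contigs):
        try:
            j = coverage.row(c.id)
        except KeyError:
            missing.append(c.id)
            continue
        mean[i] = coverage.mean_depth[j]
        var[i] = coverage.depth_variance[j]
    if missing:
        logger.warning(
            "%d contigs absent from the depth table; assuming zero coverage "
            "(first: %s)",
            len(missing),
            missing[0],
        )
    fasta_ids = {c.id for c in contigs}
    orphans = [c for c in coverage.contig_ids if c not in fasta_ids]
    if orphans:
        logger.warning(
            "%d depth-table rows have no contig in the FASTA (first: %s)",
            len(orphans),
            orphans[0],
        )
    return CoverageTable([c.id for c in contigs], mean, var), missing


def write_bins(
    bins: BinSet, contigs: list[Contig], out_prefix: str | os.PathLike
) -> list[str]:
    """Write one FASTA per bin (<prefix>.<bin>.fa) and a membership TSV
    (<prefix>.membership.tsv) listing every contig, with "unbinned" for
    contigs outside all bins. Returns the paths written."""
    out_prefix = str(out_prefix)
    parent = os.path.dirname(out_prefix) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"output directory {parent!r} does not exist")
    by_id = {c.id: c for c in contigs}
    member = bins.membership()
    for cid in member:
        if cid not in by_id:
            raise ValueError(f"binned contig {cid!r} not among the input contigs")

    written: list[str] = []
    for bin_id in sorted(bins.bins):
        fa = f"{out_prefix}.{bin_id}.fa"
        with open(fa, "w") as fh:
            for cid in bins.bins[bin_id]:
                seq = by_id[cid].sequence
                fh.write(f">{cid}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k : k + 80] + "\n")
        written.append(fa)

    tsv = f"{out_prefix}.membership.tsv"
    with open(tsv, "w") as fh:
        fh.write("contig_id\tbin_id\n")
        for c in contigs:
            fh.write(f"{c.id}\t{member.get(c.id, 'unbinned')}\n")
    written.append(tsv)
    return written


def read_membership(path: str | os.PathLike, lengths: dict[str, int]) -> BinSet:
    """Rebuild a BinSet from a membership TSV (inverse of write_bins)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bins: dict[str, list[str]] = {}
    for cid, bid in zip(df["contig_id"], df["bin_id"]):
        if bid == "unbinned":
            continue
        bins.setdefault(bid, []).append(cid)
    return BinSet.from_bins(bins, lengths)
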