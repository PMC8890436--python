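"""Split-read junction counts and per-base coverage profiles.

A split read aligns across two exons through an intron-sized gap (an N
operation in its CIGAR); each gap is direct evidence for one splice
junction.  Junctions are keyed by their exact genomic gap, 0-based
half-open, with no fuzzy merging, because latent-donor detection needs
exact donor positions.  Usage of a latent donor is the ratio of split reads
supporting the latent junction to split reads supporting the canonical
junction of the same intron; the ratio is self-normalizing, so sequencing
depth cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam


class QuantError(ValueError):
    pass


JunctionKey = tuple[str, int, int]  # (chrom, gap_start, gap_end), 0-based half-open


@dataclass
class JunctionCounts:
    sample_id: str
    condition: str = ""  # "case" | "control"
    replicate: int = 0
    counts: dict[JunctionKey, int] = field(default_factory=dict)
    total_mapped_reads: int = 0

    def get(self, key: JunctionKey) -> int:
        return self.counts.get(key, 0)

    def scaled(self, key: JunctionKey) -> float:
        """Reads per million mapped for one junction."""
        if self.total_mapped_reads <= 0:
            raise QuantError("total_mapped_reads must be positive to normalize")
        return self.counts.get(key, 0) * 1e6 / self.total_mapped_reads

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_mapped={self.total_mapped_reads}\n")
            fh.write(f"#sample={self.sample_id}\n")
            fh.write(f"#condition={self.condition}\n")
            fh.write(f"#replicate={self.replicate}\n")
            fh.write("chrom\tdonor\tacceptor\tstrand\tcount\n")
            for (chrom, start, end), count in sorted(self.counts.items()):
                fh.write(f"{chrom}\t{start}\t{end}\t.\t{count}\n")

    @classmethod
    def from_tsv(cls, path) -> "JunctionCounts":
        meta = {"total_mapped": "0", "sample": Path(str(path)).stem, "condition": "", "replicate": "0"}
        counts: dict[JunctionKey, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                elif line and not line.startswith("chrom\t"):
                    chrom, start, end, _strand, count = line.split("\t")
                    counts[(chrom, int(start), int(end))] = int(count)
        return cls(
            sample_id=meta["sample"],
            condition=meta["condition"],
            replicate=int(meta["replicate"]),
            counts=counts,
            total_mapped_reads=int(meta["total_mapped"]),
        )


def extract_junctions_from_sam(
    sam_path, sample_id: str | None = None, condition: str = "", replicate: int = 0
) -> JunctionCounts:
    """Tally junction gaps from N CIGAR operations of primary alignments.

    Secondary, supplementary, and unmapped records are skipped;
    ``total_mapped_reads`` counts every primary mapped record, gapped or not.
    """
    counts: dict[JunctionKey, int] = {}
    total = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
            if read.cigartuples is None:
                continue
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D advance the reference
                    pos += length
                elif op == 3:  # N: the junction gap
                    key = (read.reference_name, pos, pos + length)
                    counts[key] = counts.get(key, 0) + 1
                    pos += length
                elif op not in (1, 4, 5, 6):  # I, S, H, P do not advance
                    raise QuantError(f"unsupported CIGAR op {op} in read {read.query_name}")
    return JunctionCounts(
        sample_id=sample_id or Path(str(sam_path)).stem,
        condition=condition,
        replicate=replicate,
        counts=counts,
        total_mapped_reads=total,
    )


@dataclass
class UsageRecord:
    """Normalized latent usage for one site in one sample."""

    site_key: tuple
    sample_id: str
    lss_reads: int
    canonical_reads: int

    def __post_init__(self) -> None:
        if self.lss_reads < 0 or self.canonical_reads < 0:
            raise QuantError("read counts must be nonnegative")

    @property
    def defined(self) -> bool:
        return self.canonical_reads > 0

    @property
    def usage(self) -> float:
        if not self.defined:
            return float("nan")
        return self.lss_reads / self.canonical_reads


def usage_ratio(lss_reads: int, canonical_reads: int, site_key: tuple = (), sample_id: str = "") -> UsageRecord:
    """Latent usage = split-reads(latent) / split-reads(canonical); undefined at 0 canonical."""
    return UsageRecord(site_key=site_key, sample_id=sample_id, lss_reads=lss_reads, canonical_reads=canonical_reads)


def depth_normalize(counts: JunctionCounts) -> dict[JunctionKey, float]:
    """All junction counts scaled to reads per million mapped.

    Used only for cross-sample tallies of supported sites; usage ratios are
    self-normalizing and never depth-scaled.
    """
    if counts.total_mapped_reads <= 0:
        raise QuantError("total_mapped_reads must be positive")
    factor = 1e6 / counts.total_mapped_reads
    return {k: v * factor for k, v in counts.counts.items()}


@dataclass
class CoverageProfile:
    """Per-nucleotide read depth over one exon-extension interval."""

    site_key: tuple
    sample_id: str
    depths: np.ndarray
    normalization: float = 1.0  # split reads supporting the annotated donor

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise QuantError("negative depths in coverage profile")

    @property
    def normalized(self) -> np.ndarray:
        return self.depths / max(self.normalization, 1.0)

    def __len__(self) -> int:
        return len(self.depths)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": int, "end": int, "depth": float},
    )
    return df


def profile_from_bedgraph(
    bedgraph: pd.DataFrame | str | Path,
    chrom: str,
    start: int,
    end: int,
    site_key: tuple = (),
    sample_id: str = "",
    normalization: float = 1.0,
) -> CoverageProfile:
    """Per-base depth vector over [start, end); uncovered bases are 0.

    Intervals are 0-based half-open and must not overlap.
    """
    if not isinstance(bedgraph, pd.DataFrame):
        bedgraph = read_bedgraph(bedgraph)
    sub = bedgraph[bedgraph["chrom"] == chrom].sort_values("start")
    prev_end = None
    depths = np.zeros(end - start)
    for iv in sub.itertuples(index=False):
        if prev_end is not None and iv.start < prev_end:
            raise QuantError(f"overlapping bedGraph intervals on {chrom} at {iv.start}")
        prev_end = iv.end
        lo, hi = max(iv.start, start), min(iv.end, end)
        if lo < hi:
            depths[lo - start : hi - start] = iv.depth
    return CoverageProfile(site_key=site_key, sample_id=sample_id, depths=depths, normalization=normalization)
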