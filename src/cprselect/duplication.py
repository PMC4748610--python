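"""Read-depth screening for allele-specific duplications over CPRs.

Expression differences attributed to promoter variants could instead come
from a duplicated promoter copy in some lines.  A per-line read-depth track
is compared over the CPR +/- 200 bp against the average of per-gene mean
depths on the same chromosome; a ratio >= 2 flags a candidate duplication.
A read-quality prefilter (3' trimming below Q10; dropping reads mostly
below Q20) mirrors the filtering applied before depth calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrack",
    "DuplicationCall",
    "filter_reads",
    "filter_fastq",
    "detect_duplication",
]


def filter_reads(reads, trim_q: int = 10, low_q: int = 20, low_frac: float = 0.8):
    """Quality-filter reads (Biopython SeqRecords with phred qualities).

    A read is dropped when at least ``low_frac`` of its (pre-trim) sites have
    quality < ``low_q``.  Surviving reads have the maximal 3' suffix of bases
    with quality < ``trim_q`` removed (truncation at the last base with
    quality >= ``trim_q``); reads empty after trimming are dropped.  The two
    criteria are evaluated independently on the original read.
    """
    out = []
    for rec in reads:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(rec.seq):
            continue  # malformed record
        n = len(quals)
        if n == 0:
            continue
        if sum(q < low_q for q in quals) / n >= low_frac:
            continue
        end = n
        while end > 0 and quals[end - 1] < trim_q:
            end -= 1
        if end == 0:
            continue
        out.append(rec[:end])
    return out


def filter_fastq(path_in, path_out, trim_q: int = 10, low_q: int = 20, low_frac: float = 0.8) -> int:
    """Filter a FASTQ file (Sanger Phred+33); returns the retained count."""
    from Bio import SeqIO

    kept = filter_reads(SeqIO.parse(path_in, "fastq"), trim_q, low_q, low_frac)
    SeqIO.write(kept, path_out, "fastq")
    return len(kept)


@dataclass
class DepthTrack:
    """Per-base depth for one line on one chromosome, plus gene intervals.

    ``depth`` is indexed by 1-based position.  ``genes`` is a frame with
    columns ``gene``, ``start``, ``end`` (0-based half-open intervals).
    """

    line_id: str
    chrom: str
    depth: pd.Series = field(repr=False)
    genes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.depth < 0).any():
            raise ValueError("depths must be >= 0")

    def mean_depth(self, start: int, end: int) -> float:
        """Mean depth over a 0-based half-open interval (absent bases = 0)."""
        if end <= start:
            raise ValueError("empty interval")
        pos = np.arange(start + 1, end + 1)
        vals = self.depth.reindex(pos, fill_value=0).to_numpy(dtype=float)
        return float(vals.mean())

    def gene_average(self) -> float:
        """Unweighted mean of per-gene mean depths on this chromosome."""
        if self.genes.empty:
            raise ValueError("no genes on chromosome")
        means = [self.mean_depth(int(r.start), int(r.end)) for r in self.genes.itertuples()]
        return float(np.mean(means))


@dataclass
class DuplicationCall:
    cpr_id: str
    line_id: str
    region_depth: float
    gene_average_depth: float
    ratio: float
    flagged: bool


def detect_duplication(
    track: DepthTrack,
    cpr_id: str,
    cpr_start: int,
    cpr_end: int,
    flank: int = 200,
    ratio_threshold: float = 2.0,
) -> DuplicationCall:
    """Flag a (line, CPR) whose depth over CPR +/- flank is >= 2x the norm.

    The normalizer is the unweighted average of per-gene mean depths on the
    same chromosome for the same line; a zero normalizer is an error.
    """
    region = track.mean_depth(max(cpr_start - flank, 0), cpr_end + flank)
    norm = track.gene_average()
    if norm <= 0:
        raise ValueError("zero chromosome-average depth")
    ratio = region / norm
    return DuplicationCall(
        cpr_id=cpr_id,
        line_id=track.line_id,
        region_depth=region,
        gene_average_depth=norm,
        ratio=ratio,
        flagged=ratio >= ratio_threshold,
    )
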