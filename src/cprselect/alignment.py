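"""Aligned per-line haplotypes for a single core promoter region (CPR).

Inbred lines are homozygous, so each line contributes one haplotype.
Sequences are stored as a character matrix over the alphabet {A, C, G, T, N};
``N`` marks an undetermined nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = ("A", "C", "G", "T")
MISSING = "N"


@dataclass
class CprAlignment:
    """Equal-length haplotype alignment for one CPR.

    Parameters
    ----------
    cpr_id : str
        Identifier of the core promoter region.
    chrom : str
        Chromosome / chromosome-arm name.
    start, end : int
        Genomic interval, 0-based half-open.
    strand : str
        ``"+"`` or ``"-"``.
    line_ids : list of str
        One identifier per inbred line; unique.
    seqs : ndarray of shape (n_lines, length), dtype ``<U1``
        Haplotype matrix over {A, C, G, T, N}.
    """

    cpr_id: str
    chrom: str
    start: int
    end: int
    strand: str
    line_ids: list[str]
    seqs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="<U1")
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D character matrix")
        if len(self.line_ids) != self.seqs.shape[0]:
            raise ValueError("one sequence per line required")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        bad = ~np.isin(self.seqs, list(ALPHABET) + [MISSING])
        if bad.any():
            raise ValueError("sequences must be over {A,C,G,T,N}")

    @classmethod
    def from_strings(
        cls,
        seqs: dict[str, str] | list[tuple[str, str]],
        cpr_id: str = "cpr",
        chrom: str = "chr",
        start: int = 0,
        end: int | None = None,
        strand: str = "+",
    ) -> "CprAlignment":
        items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
        if not items:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        L = lengths.pop()
        mat = np.array([list(s.upper()) for _, s in items], dtype="<U1")
        return cls(
            cpr_id=cpr_id,
            chrom=chrom,
            start=start,
            end=end if end is not None else start + L,
            strand=strand,
            line_ids=[lid for lid, _ in items],
            seqs=mat,
        )

    @property
    def n(self) -> int:
        """Number of lines (haplotypes)."""
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        """Alignment length in bp."""
        return self.seqs.shape[1]

    def sequence(self, line_id: str) -> str:
        i = self.line_ids.index(line_id)
        return "".join(self.seqs[i])

    def haplotypes(self) -> dict[str, str]:
        """Mapping line_id -> haplotype string."""
        return {lid: "".join(row) for lid, row in zip(self.line_ids, self.seqs)}

    def subset_lines(self, keep: list[str]) -> "CprAlignment":
        idx = [self.line_ids.index(lid) for lid in keep]
        return replace(self, line_ids=list(keep), seqs=self.seqs[idx].copy())

    def copy(self) -> "CprAlignment":
        return replace(self, line_ids=list(self.line_ids), seqs=self.seqs.copy())

    def segregating_mask(self) -> np.ndarray:
        """Boolean mask of columns with >= 2 distinct non-N bases."""
        out = np.zeros(self.length, dtype=bool)
        for j in range(self.length):
            col = self.seqs[:, j]
            bases = set(col[col != MISSING])
            out[j] = len(bases) >= 2
        return out
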