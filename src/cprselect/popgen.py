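"""Per-CPR data cleaning and diversity statistics.

Implements the cohort cleaning rules for inbred-line promoter alignments
(minor-allele masking, heterozygous-line removal, undetermined-nucleotide
handling, minimum usable-line rule) and the classical diversity statistics:
segregating sites S, nucleotide diversity pi, Watterson's theta_w, and
Tajima's D with its normalizing constants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import math

import numpy as np

from .alignment import MISSING, CprAlignment

__all__ = [
    "DiversitySummary",
    "PreprocessResult",
    "preprocess_alignment",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "tajima_constants",
    "diversity_summary",
]


@dataclass
class DiversitySummary:
    """Diversity statistics for one cleaned CPR alignment.

    ``pi`` and ``theta_w`` are per-site values; ``tajima_d`` is ``nan`` when
    undefined (monomorphic alignment or n < 4).  The a/b/c/e constants are the
    usual Tajima normalization terms for sample size ``n``.
    """

    cpr_id: str
    n: int
    S: int
    pi: float
    theta_w: float
    tajima_d: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass
class PreprocessResult:
    """Outcome of cleaning one CPR: either a usable alignment or a verdict."""

    alignment: CprAlignment | None
    excluded: bool
    reason: str | None = None
    dropped_lines: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # usable?
        return not self.excluded


def _column_counts(col: np.ndarray) -> Counter:
    return Counter(b for b in col if b != MISSING)


def preprocess_alignment(
    raw: CprAlignment,
    maf_threshold: float = 0.01,
    min_lines: int = 20,
    het_sites: dict[str, set[int]] | None = None,
) -> PreprocessResult:
    """Apply the cohort cleaning rules to one CPR alignment.

    Rules, applied to a fixed point:

    1. lines with any heterozygous call inside the CPR are removed entirely
       (``het_sites`` maps line_id -> set of 0-based het positions);
    2. alleles with frequency below ``maf_threshold`` among non-missing calls
       are masked to N in the carrying lines (sites are kept);
    3. at a site where some lines are N and every determined line carries one
       base, the site is treated as fixed for that base (Ns filled in);
    4. lines that are N at a site that remains polymorphic are excluded from
       this CPR;
    5. if fewer than ``min_lines`` usable lines remain, the CPR is excluded.

    Masking (2) can expose new fixed sites and line exclusions (4) can push
    further alleles below the frequency threshold, so steps 2-4 are iterated
    until nothing changes; this also makes the operation idempotent.
    """
    if raw.n == 0 or raw.length == 0:
        return PreprocessResult(None, True, "no data")

    dropped: list[str] = []
    keep = list(raw.line_ids)
    if het_sites:
        keep = [lid for lid in keep if not het_sites.get(lid)]
        dropped = [lid for lid in raw.line_ids if lid not in keep]
    if len(keep) < min_lines:
        return PreprocessResult(None, True, f"fewer than {min_lines} usable lines", tuple(dropped))

    aln = raw.subset_lines(keep)
    seqs = aln.seqs.copy()

    for _ in range(raw.length * raw.n + 2):  # fixed-point loop, bounded
        changed = False
        n_now = seqs.shape[0]
        # 2. minor-allele masking
        for j in range(seqs.shape[1]):
            counts = _column_counts(seqs[:, j])
            total = sum(counts.values())
            if total == 0 or len(counts) < 2:
                continue
            for base, c in counts.items():
                if c / total < maf_threshold:
                    mask = seqs[:, j] == base
                    if mask.any():
                        seqs[mask, j] = MISSING
                        changed = True
        # 3./4. undetermined-nucleotide rules
        exclude_rows: set[int] = set()
        for j in range(seqs.shape[1]):
            col = seqs[:, j]
            missing = col == MISSING
            if not missing.any():
                continue
            counts = _column_counts(col)
            if len(counts) == 1:
                # fixed among determined lines -> site considered fixed
                seqs[missing, j] = next(iter(counts))
                changed = True
            elif len(counts) >= 2:
                exclude_rows.update(np.flatnonzero(missing).tolist())
            # len(counts) == 0: all-N column, left as is (uninformative)
        if exclude_rows:
            keep_rows = [i for i in range(n_now) if i not in exclude_rows]
            dropped.extend(aln.line_ids[i] for i in sorted(exclude_rows))
            aln = aln.subset_lines([aln.line_ids[i] for i in keep_rows])
            seqs = seqs[keep_rows]
            changed = True
        aln.seqs = seqs
        if not changed:
            break

    if aln.n < min_lines:
        return PreprocessResult(None, True, f"fewer than {min_lines} usable lines", tuple(dropped))
    return PreprocessResult(aln, False, None, tuple(dropped))


def _site_counts(aln: CprAlignment) -> np.ndarray:
    """4 x L matrix of per-site base counts (A, C, G, T rows), N excluded."""
    from .alignment import ALPHABET

    return np.stack([(aln.seqs == b).sum(axis=0) for b in ALPHABET])


def _pairwise_diff_total(aln: CprAlignment) -> float:
    """Mean pairwise difference summed over sites (pairwise deletion per site)."""
    counts = _site_counts(aln)
    m = counts.sum(axis=0)
    ok = m >= 2
    if not ok.any():
        return 0.0
    same = (counts * (counts - 1)).sum(axis=0)[ok]
    pairs = m[ok] * (m[ok] - 1)
    # per-site value is the expected difference for a random pair; summed
    # over sites it is the mean number of pairwise differences
    return float((1.0 - same / pairs).sum())


def _effective_length(aln: CprAlignment) -> int:
    return int((_site_counts(aln).sum(axis=0) >= 2).sum())


def segregating_sites(aln: CprAlignment) -> int:
    """Number of sites with >= 2 distinct determined bases."""
    return int(((_site_counts(aln) > 0).sum(axis=0) >= 2).sum())


def nucleotide_diversity(aln: CprAlignment) -> float:
    """Per-site nucleotide diversity pi.

    Average pairwise per-site difference over all unordered sequence pairs;
    sites where either member of a pair is N are dropped for that pair
    (pairwise deletion), with the per-site denominator adjusted accordingly.
    Returns ``nan`` for n < 2.
    """
    if aln.n < 2:
        return float("nan")
    L = _effective_length(aln)
    if L == 0:
        return float("nan")
    return _pairwise_diff_total(aln) / L


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's normalizing constants a1, a2, b1, b2, c1, c2, e1, e2."""
    if n < 2:
        raise ValueError("n >= 2 required")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def watterson_theta(aln: CprAlignment) -> float:
    """Per-site Watterson estimator theta_w = S / (a1 * L)."""
    if aln.n < 2:
        return float("nan")
    L = _effective_length(aln)
    if L == 0:
        return float("nan")
    a1 = tajima_constants(aln.n)["a1"]
    return segregating_sites(aln) / (a1 * L)


def tajimas_d(aln: CprAlignment) -> float:
    """Tajima's D; ``nan`` when undefined (S = 0 or n < 4).

    D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1)), with k the mean number of
    pairwise differences (pi * L).
    """
    if aln.n < 4:
        return float("nan")
    S = segregating_sites(aln)
    if S == 0:
        return float("nan")
    c = tajima_constants(aln.n)
    k = _pairwise_diff_total(aln)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (k - S / c["a1"]) / math.sqrt(var)


def diversity_summary(aln: CprAlignment) -> DiversitySummary:
    """Compute the full per-CPR diversity record."""
    c = tajima_constants(max(aln.n, 2))
    return DiversitySummary(
        cpr_id=aln.cpr_id,
        n=aln.n,
        S=segregating_sites(aln),
        pi=nucleotide_diversity(aln),
        theta_w=watterson_theta(aln),
        tajima_d=tajimas_d(aln),
        **c,
    )
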