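"""Linkage disambiguation for CPR expression associations.

An expression difference attributed to promoter variants could instead be
driven by linked SNPs in the flanking regions (+/- 5000 bp by default).
This module computes pairwise LD (D, D', r^2) from phase-known inbred-line
haplotypes, builds Gabriel-style D'-confidence-interval haplotype blocks,
runs per-SNP Wald regressions of line-mean expression on flanking alleles
with BH control at FDR 1%, and issues the per-CPR verdict: Y when some
significant flanking SNP is linked to a CPR SNP (same block, or r^2 >= 0.8),
N otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .expression import bh_adjust

__all__ = [
    "HaplotypeMatrix",
    "LdPair",
    "HaplotypeBlock",
    "pairwise_ld",
    "dprime_ci",
    "haplotype_blocks",
    "flank_association",
    "linkage_verdict",
]

MISSING_CODE = -1


@dataclass
class HaplotypeMatrix:
    """Biallelic SNP haplotypes for homozygous inbred lines.

    ``codes`` is lines x SNPs over {0 (ref), 1 (alt), -1 (missing)}; phase is
    known because every line carries a single haplotype.
    """

    chrom: str
    positions: np.ndarray  # 1-based, sorted
    ref: list[str]
    alt: list[str]
    line_ids: list[str]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if not np.all(np.diff(self.positions) >= 0):
            raise ValueError("positions must be sorted")
        if self.codes.shape != (len(self.line_ids), len(self.positions)):
            raise ValueError("codes shape mismatch")
        if not np.isin(self.codes, [-1, 0, 1]).all():
            raise ValueError("codes must be 0, 1 or -1")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def in_interval(self, start: int, end: int) -> np.ndarray:
        """Indices of SNPs with 1-based position in [start, end]."""
        return np.flatnonzero((self.positions >= start) & (self.positions <= end))


@dataclass
class LdPair:
    i: int
    j: int
    D: float
    Dprime: float
    r2: float


def _pair_freqs(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, int] | None:
    ok = (a != MISSING_CODE) & (b != MISSING_CODE)
    n = int(ok.sum())
    if n == 0:
        return None
    pA = float(a[ok].mean())
    pB = float(b[ok].mean())
    pAB = float((a[ok] & b[ok]).mean())
    return pA, pB, pAB, n


def pairwise_ld(h: HaplotypeMatrix, i: int, j: int) -> LdPair | None:
    """D, D' and r^2 between SNPs i and j; None when either is monomorphic.

    Haplotype frequencies are counted directly over lines with both calls.
    D = p_AB - p_A p_B; D' = D / Dmax; r^2 = D^2 / (p_A p_a p_B p_b).
    """
    f = _pair_freqs(h.codes[:, i], h.codes[:, j])
    if f is None:
        return None
    pA, pB, pAB, _ = f
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = D / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LdPair(i, j, D, dprime, r2)


def dprime_ci(
    h: HaplotypeMatrix,
    i: int,
    j: int,
    n_boot: int = 1000,
    alpha: float = 0.10,
    rng: np.random.Generator | None = None,
) -> tuple[float, float] | None:
    """Nonparametric bootstrap confidence interval for |D'|.

    Lines are resampled with replacement; monomorphic resamples are skipped.
    Returns (lower, upper) percentile bounds at levels alpha/2 and
    1 - alpha/2, or None if the pair is uninformative.
    """
    if pairwise_ld(h, i, j) is None:
        return None
    rng = rng or np.random.default_rng()
    a, b = h.codes[:, i], h.codes[:, j]
    ok = (a != MISSING_CODE) & (b != MISSING_CODE)
    a, b = a[ok], b[ok]
    n = len(a)
    idx = rng.integers(0, n, size=(n_boot, n))
    ra, rb = a[idx], b[idx]
    pA, pB = ra.mean(axis=1), rb.mean(axis=1)
    ok = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    if not ok.any():
        return None
    pA, pB = pA[ok], pB[ok]
    pAB = (ra[ok] & rb[ok]).mean(axis=1)
    D = pAB - pA * pB
    dmax = np.where(
        D >= 0,
        np.minimum(pA * (1 - pB), (1 - pA) * pB),
        np.minimum(pA * pB, (1 - pA) * (1 - pB)),
    )
    vals = np.where(dmax > 0, np.abs(D / np.where(dmax > 0, dmax, 1.0)), 0.0)
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class HaplotypeBlock:
    """Maximal run of SNP indices with little evidence of recombination."""

    start_index: int
    end_index: int  # inclusive
    positions: tuple[int, ...]

    def __contains__(self, snp_index: int) -> bool:
        return self.start_index <= snp_index <= self.end_index


def _classify_pairs(
    h: HaplotypeMatrix,
    n_boot: int,
    rng: np.random.Generator,
    ci_strong: tuple[float, float] = (0.70, 0.98),
    ci_recomb_high: float = 0.90,
) -> dict[tuple[int, int], str]:
    out: dict[tuple[int, int], str] = {}
    m = h.n_snps
    for i in range(m):
        for j in range(i + 1, m):
            ci = dprime_ci(h, i, j, n_boot=n_boot, rng=rng)
            if ci is None:
                out[(i, j)] = "uninformative"
            elif ci[0] >= ci_strong[0] and ci[1] >= ci_strong[1]:
                out[(i, j)] = "strong"
            elif ci[1] < ci_recomb_high:
                out[(i, j)] = "recomb"
            else:
                out[(i, j)] = "other"
    return out


def haplotype_blocks(
    h: HaplotypeMatrix,
    n_boot: int = 1000,
    seed: int | None = None,
    min_ratio: float = 19.0,
) -> list[HaplotypeBlock]:
    """Gabriel-style haplotype blocks from D' confidence intervals.

    A pair is "strong LD" when its |D'| CI has lower bound >= 0.70 and upper
    bound >= 0.98, and shows "evidence of recombination" when the upper bound
    is < 0.90.  A candidate run [i..j] is a block when its strong pairs
    outnumber recombination pairs by at least ``min_ratio`` : 1 (and there is
    at least one strong pair).  Longest valid runs are accepted greedily,
    non-overlapping.
    """
    if h.n_snps < 2:
        return []
    rng = np.random.default_rng(seed)
    kinds = _classify_pairs(h, n_boot, rng)
    candidates = []
    for i in range(h.n_snps):
        for j in range(i + 1, h.n_snps):
            strong = recomb = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    k = kinds[(a, b)]
                    strong += k == "strong"
                    recomb += k == "recomb"
            if strong >= 1 and strong >= min_ratio * recomb:
                candidates.append((j - i, i, j))
    blocks: list[HaplotypeBlock] = []
    taken = np.zeros(h.n_snps, dtype=bool)
    for _, i, j in sorted(candidates, key=lambda t: (-t[0], t[1])):
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(HaplotypeBlock(i, j, tuple(int(p) for p in h.positions[i : j + 1])))
    blocks.sort(key=lambda b: b.start_index)
    return blocks


def line_means(expr: pd.DataFrame) -> pd.Series:
    """Collapse replicated, sexed expression to one value per line.

    Mean within each line x sex cell first, then mean of the sex means, so
    unbalanced replication does not tilt a line toward one sex.
    """
    cell = expr.groupby(["line", "sex"])["value"].mean()
    return cell.groupby("line").mean()


def flank_association(
    expr: pd.DataFrame,
    h: HaplotypeMatrix,
    cpr_start: int,
    cpr_end: int,
    flank: int = 5000,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP Wald test of line-mean expression on flanking alleles.

    SNPs within ``flank`` bp of the CPR interval (1-based positions against
    the 0-based half-open CPR interval) but outside the CPR itself are
    tested with a single-predictor regression; Wald statistic =
    slope / SE(slope), p from the t distribution; BH-adjusted at ``fdr``
    across the window's SNPs.  Returns a frame indexed by SNP index with
    columns position, wald, p, q, significant (monomorphic SNPs -> NaN).
    """
    from scipy import stats

    means = line_means(expr)
    window = h.in_interval(cpr_start + 1 - flank, cpr_end + flank)
    inside = set(h.in_interval(cpr_start + 1, cpr_end).tolist())
    rows = []
    for s in window:
        if int(s) in inside:
            continue
        codes = h.codes[:, s]
        wald = p = float("nan")
        lines = [lid for lid, c in zip(h.line_ids, codes) if c != MISSING_CODE and lid in means.index]
        x = np.array([codes[h.line_ids.index(lid)] for lid in lines], dtype=float)
        y = means.loc[lines].to_numpy()
        if len(x) >= 3 and len(np.unique(x)) == 2:
            res = stats.linregress(x, y)
            if res.stderr > 0:
                wald = res.slope / res.stderr
                p = 2 * stats.t.sf(abs(wald), df=len(x) - 2)
        rows.append(dict(snp=int(s), position=int(h.positions[s]), wald=wald, p=p))
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[], significant=[])
    q, rej = bh_adjust(df["p"].to_numpy(), q=fdr)
    df["q"] = q
    df["significant"] = rej
    return df


def linkage_verdict(
    cpr_snp_indices,
    flank_results: pd.DataFrame,
    blocks: list[HaplotypeBlock],
    h: HaplotypeMatrix,
    r2_threshold: float = 0.8,
) -> str:
    """"Y" when a significant flanking SNP could explain the CPR association.

    That is the case when some BH-significant flanking SNP shares a haplotype
    block with a CPR SNP or has r^2 >= ``r2_threshold`` with one; otherwise
    "N" (including the no-significant-flanking-SNPs case).
    """
    cpr_snp_indices = [int(i) for i in cpr_snp_indices]
    if flank_results.empty:
        return "N"
    sig = flank_results[flank_results["significant"].fillna(False)]
    for s in sig["snp"].astype(int):
        for c in cpr_snp_indices:
            if any(s in b and c in b for b in blocks):
                return "Y"
            pair = pairwise_ld(h, min(s, c), max(s, c))
            if pair is not None and pair.r2 >= r2_threshold:
                return "Y"
    return "N"
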