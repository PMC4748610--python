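"""Expression ~ CPR haplotype x sex association.

For each transcript, expression is modelled as

    Y = mu + Seq + Sex + Seq x Sex + eps

where Seq is the full-CPR haplotype class of the line (lines with identical
cleaned promoter sequence share an allele label) and Sex removes sex-biased
expression.  Per-term F tests use Type II sums of squares; p-values are
adjusted across transcripts per term with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CprAlignment

__all__ = [
    "AssociationResult",
    "call_alleles",
    "fit_expression_model",
    "bh_adjust",
    "associate_transcripts",
]

TERMS = ("seq", "sex", "seq_sex")


def call_alleles(aln: CprAlignment) -> dict[str, str]:
    """Group lines by identical full-CPR haplotype.

    Labels are ``a``, ``b``, ... ordered by descending class frequency, ties
    broken by lexicographic haplotype string (so the majority haplotype is
    always allele ``a``).
    """
    haps = aln.haplotypes()
    freq = Counter(haps.values())
    ordered = sorted(freq, key=lambda h: (-freq[h], h))
    if len(ordered) > 26:
        labels = {h: f"h{i:03d}" for i, h in enumerate(ordered)}
    else:
        labels = {h: chr(ord("a") + i) for i, h in enumerate(ordered)}
    return {lid: labels[h] for lid, h in haps.items()}


@dataclass
class AssociationResult:
    """Per-term F statistics, p-values and (once adjusted) q-values."""

    transcript_id: str
    cpr_id: str
    alleles: dict[str, str]
    f_stats: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    q_values: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)
    diagnostic: str | None = None


def fit_expression_model(
    expr: pd.DataFrame, alleles: dict[str, str], transcript_id: str = "", cpr_id: str = ""
) -> AssociationResult:
    """Fit Y = mu + Seq + Sex + Seq x Sex + eps for one transcript.

    ``expr`` needs columns ``line``, ``sex`` (F/M) and ``value``; lines
    absent from ``alleles`` (excluded during preprocessing) are dropped.
    Returns NaN statistics with a diagnostic for degenerate designs (a single
    allele class, one sex, or zero residual variance).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    res = AssociationResult(transcript_id, cpr_id, dict(alleles))
    nan = {t: float("nan") for t in TERMS}
    df = expr[expr["line"].isin(alleles)].copy()
    df["allele"] = df["line"].map(alleles)
    if df.empty:
        res.f_stats, res.p_values, res.diagnostic = dict(nan), dict(nan), "no data"
        return res
    n_alleles = df["allele"].nunique()
    n_sexes = df["sex"].nunique()
    if n_alleles < 2 or n_sexes < 2:
        res.f_stats, res.p_values = dict(nan), dict(nan)
        res.diagnostic = "single allele class" if n_alleles < 2 else "single sex"
        return res
    fit = smf.ols("value ~ C(allele) * C(sex)", data=df).fit()
    if fit.df_resid < 1 or fit.ssr <= 1e-12 * max(1.0, float(np.var(df["value"])) * len(df)):
        res.f_stats, res.p_values = dict(nan), dict(nan)
        res.diagnostic = "zero residual variance"
        return res
    table = anova_lm(fit, typ=2)
    key = {"seq": "C(allele)", "sex": "C(sex)", "seq_sex": "C(allele):C(sex)"}
    for term, row in key.items():
        res.f_stats[term] = float(table.loc[row, "F"])
        res.p_values[term] = float(table.loc[row, "PR(>F)"])
    return res


def bh_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q-values, rejection flags at level ``q``).  NaN p-values pass
    through as NaN / not-rejected and do not count toward the family size.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    qvals = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        qvals[ok] = adj
        reject[ok] = rej
    return qvals, reject


def associate_transcripts(
    expr: pd.DataFrame,
    allele_maps: dict[str, dict[str, str]],
    transcript_to_cpr: dict[str, str],
    fdr: float = 0.05,
    heritability_range: tuple[float, float] = (0.3, 1.0),
) -> list[AssociationResult]:
    """Fit the model for every transcript and BH-adjust per term.

    ``expr`` columns: transcript, line, sex, replicate, value and optionally
    ``heritability`` (transcripts outside ``heritability_range`` are dropped
    before modelling).  BH is applied separately within each of the three
    term families (Seq, Sex, Seq x Sex) across transcripts.
    """
    df = expr
    if "heritability" in df.columns:
        lo, hi = heritability_range
        df = df[(df["heritability"] >= lo) & (df["heritability"] <= hi)]
    results: list[AssociationResult] = []
    for tid, sub in df.groupby("transcript", sort=True):
        cpr = transcript_to_cpr.get(tid)
        if cpr is None or cpr not in allele_maps:
            continue
        results.append(fit_expression_model(sub, allele_maps[cpr], tid, cpr))
    for term in TERMS:
        pvals = [r.p_values.get(term, float("nan")) for r in results]
        qvals, rej = bh_adjust(pvals, q=fdr)
        for r, qv, rj in zip(results, qvals, rej):
            r.q_values[term] = float(qv)
            r.significant[term] = bool(rj)
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format table: one row per transcript x term."""
    rows = []
    for r in results:
        for term in TERMS:
            rows.append(
                dict(
                    transcript=r.transcript_id,
                    cpr=r.cpr_id,
                    term=term,
                    F=r.f_stats.get(term, float("nan")),
                    p=r.p_values.get(term, float("nan")),
                    q=r.q_values.get(term, float("nan")),
                    significant=r.significant.get(term, False),
                )
            )
    return pd.DataFrame(rows)
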