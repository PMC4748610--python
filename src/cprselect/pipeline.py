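"""Orchestration: run every stage over a cohort and emit the selection report.

Stage order: preprocessing -> diversity -> expression association ->
coalescent null / outlier calling -> TFBS change events -> linkage
disambiguation -> duplication screen -> allele phylogenies.  A CPR enters
the final report only when (a) its Seq term is significant at the
association FDR, (b) its Tajima's D is a two-tailed outlier against the
simulated null, and (c) at least one TFBS change separates alleles whose
expression actually differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging
import math

import numpy as np
import pandas as pd

from .alignment import CprAlignment
from .coalescent import (
    DemographicModel,
    NullDistribution,
    build_null,
    constant_model,
    outlier_pvalue,
)
from .expression import associate_transcripts, call_alleles
from .duplication import detect_duplication
from .linkage import (
    HaplotypeMatrix,
    flank_association,
    haplotype_blocks,
    linkage_verdict,
)
from .motifs import MotifModel, count_changed_motifs, scan_sequence, tfbs_change_events
from .phylo import bootstrap_support
from .popgen import diversity_summary, preprocess_alignment
from .synthetic import SyntheticCohort

logger = logging.getLogger("cprselect")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Global thresholds and sizes for one pipeline run."""

    assoc_fdr: float = 0.05
    flank_fdr: float = 0.01
    selection_p: float = 0.01
    maf_threshold: float = 0.01
    min_lines: int = 20
    heritability_range: tuple[float, float] = (0.3, 1.0)
    flank: int = 5000
    depth_flank: int = 200
    depth_ratio: float = 2.0
    r2_linked: float = 0.8
    null_reps: int = 10_000
    block_bootstrap: int = 1000
    tree_bootstrap: int = 1000
    effect_test_p: float = 0.05  # criterion (c): bound-vs-unbound expression test
    seed: int = 0
    null_model: DemographicModel | None = None

    def __post_init__(self) -> None:
        for frac in (self.assoc_fdr, self.flank_fdr, self.selection_p, self.maf_threshold):
            if not 0 < frac < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.null_reps < 1 or self.depth_ratio <= 0:
            raise ValueError("invalid config")


@dataclass
class PipelineResult:
    report: pd.DataFrame
    null: NullDistribution
    diversity: pd.DataFrame
    association: pd.DataFrame
    artifacts: dict = field(default_factory=dict)


def _event_explains_expression(
    event, alleles: dict[str, str], expr: pd.DataFrame, p_max: float
) -> bool:
    """Does the bound/unbound partition of an event split expression?

    Lines are grouped by whether their allele class is bound or unbound at
    the event; the groups' line-mean expression levels are compared with a
    Welch t-test.
    """
    from scipy import stats

    from .linkage import line_means

    means = line_means(expr)
    bound = [l for l, a in alleles.items() if a in event.bound_alleles and l in means.index]
    unbound = [l for l, a in alleles.items() if a in event.unbound_alleles and l in means.index]
    if len(bound) < 2 or len(unbound) < 2:
        return False
    t, p = stats.ttest_ind(means.loc[bound], means.loc[unbound], equal_var=False)
    return bool(p < p_max)


def _cpr_snp_table(aln: CprAlignment) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Positions (1-based) and 0/1 codes of the CPR's segregating sites."""
    mask = aln.segregating_mask()
    sites = np.flatnonzero(mask)
    codes = np.zeros((aln.n, len(sites)), dtype=np.int8)
    ref, alt = [], []
    for k, j in enumerate(sites):
        col = aln.seqs[:, j]
        bases, counts = np.unique(col[col != "N"], return_counts=True)
        order = np.argsort(-counts, kind="stable")
        major = bases[order[0]]
        ref.append(str(major))
        alt.append(str(bases[order[1]]) if len(bases) > 1 else str(major))
        codes[:, k] = np.where(col == major, 0, 1)
        codes[col == "N", k] = -1
    positions = aln.start + sites + 1
    return positions, codes, ref, alt


def _combined_haplotypes(aln: CprAlignment, flank: HaplotypeMatrix) -> tuple[HaplotypeMatrix, set[int]]:
    """Merge CPR SNPs into the flank matrix; returns (matrix, CPR SNP indices)."""
    pos_c, codes_c, ref_c, alt_c = _cpr_snp_table(aln)
    order_lines = [flank.line_ids.index(l) for l in aln.line_ids]
    if sorted(flank.line_ids) != sorted(aln.line_ids):
        raise ValueError("flank matrix and alignment cover different lines")
    pos = np.concatenate([flank.positions, pos_c])
    codes = np.concatenate([flank.codes[order_lines], codes_c], axis=1)
    ref = list(flank.ref) + ref_c
    alt = list(flank.alt) + alt_c
    srt = np.argsort(pos, kind="stable")
    h = HaplotypeMatrix(
        chrom=flank.chrom,
        positions=pos[srt],
        ref=[ref[i] for i in srt],
        alt=[alt[i] for i in srt],
        line_ids=list(aln.line_ids),
        codes=codes[:, srt],
    )
    n_flank = flank.n_snps
    cpr_idx = {int(np.flatnonzero(srt == (n_flank + k))[0]) for k in range(len(pos_c))}
    return h, cpr_idx


def run_pipeline(cohort: SyntheticCohort, config: PipelineConfig) -> PipelineResult:
    """Run every stage over a cohort and build the Table-1-style report."""
    rng = np.random.default_rng(config.seed)

    # ---- stage 1: preprocessing -------------------------------------------------
    usable: dict[str, CprAlignment] = {}
    for cpr_id, aln in sorted(cohort.cpr_alignments.items()):
        res = preprocess_alignment(aln, config.maf_threshold, config.min_lines)
        if res:
            usable[cpr_id] = res.alignment
    logger.info("preprocessing: %d/%d CPRs usable", len(usable), len(cohort.cpr_alignments))

    # ---- stage 2: diversity -----------------------------------------------------
    div = {cpr_id: diversity_summary(aln) for cpr_id, aln in usable.items()}
    div_df = pd.DataFrame(
        [
            dict(cpr=k, n=d.n, S=d.S, pi=d.pi, theta_w=d.theta_w, tajima_d=d.tajima_d)
            for k, d in div.items()
        ]
    )

    # ---- stage 3: expression association ---------------------------------------
    allele_maps = {cpr_id: call_alleles(aln) for cpr_id, aln in usable.items()}
    transcript_to_cpr = {
        tid: tid[2:] for tid in cohort.expression["transcript"].unique() if tid.startswith("t_")
    }
    assoc = associate_transcripts(
        cohort.expression,
        allele_maps,
        transcript_to_cpr,
        fdr=config.assoc_fdr,
        heritability_range=config.heritability_range,
    )
    assoc_by_cpr = {r.cpr_id: r for r in assoc}
    n_sig = sum(r.significant.get("seq", False) for r in assoc)
    logger.info("association: %d/%d transcripts with significant Seq term", n_sig, len(assoc))

    # ---- stage 4: coalescent null + outliers -----------------------------------
    model = config.null_model or constant_model(
        N=cohort.config.theta_per_site / (4 * 1.45e-9)
    )
    null = build_null(
        model,
        n=cohort.config.n_lines,
        L=cohort.config.cpr_length,
        reps=config.null_reps,
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    selection: dict[str, tuple[float, str]] = {}
    for cpr_id, d in div.items():
        if math.isnan(d.tajima_d):
            selection[cpr_id] = (float("nan"), "not significant")
        else:
            selection[cpr_id] = outlier_pvalue(d.tajima_d, null)
    n_out = sum(v[1] != "not significant" for v in selection.values())
    logger.info("selection: %d/%d CPRs are Tajima's D outliers", n_out, len(selection))

    # ---- stage 5: TFBS change events -------------------------------------------
    events_by_cpr: dict[str, list] = {}
    for cpr_id, aln in usable.items():
        amap = allele_maps[cpr_id]
        rep_seq: dict[str, str] = {}
        for lid, allele in amap.items():
            rep_seq.setdefault(allele, aln.sequence(lid))
        if len(rep_seq) < 2:
            events_by_cpr[cpr_id] = []
            continue
        profiles = {
            allele: {m.motif_id: scan_sequence(m, seq, cpr_id, allele) for m in cohort.motifs}
            for allele, seq in rep_seq.items()
        }
        events_by_cpr[cpr_id] = tfbs_change_events(profiles)
    logger.info(
        "motifs: %d CPRs with >= 1 TFBS change event",
        sum(bool(v) for v in events_by_cpr.values()),
    )

    # ---- candidate filter + per-candidate stages -------------------------------
    rows = []
    artifacts: dict = dict(events=events_by_cpr, selection=selection)
    for cpr_id, aln in usable.items():
        res = assoc_by_cpr.get(cpr_id)
        if res is None or not res.significant.get("seq", False):
            continue
        p_sel, verdict = selection[cpr_id]
        if not (p_sel < config.selection_p):
            continue
        expr_t = cohort.expression[cohort.expression["transcript"] == res.transcript_id]
        amap = allele_maps[cpr_id]
        explained = [
            e
            for e in events_by_cpr[cpr_id]
            if _event_explains_expression(e, amap, expr_t, config.effect_test_p)
        ]
        if not explained:
            continue

        # linkage disambiguation
        h, cpr_idx = _combined_haplotypes(aln, cohort.flank_haplotypes[cpr_id])
        flank_res = flank_association(
            expr_t, h, aln.start, aln.end, flank=config.flank, fdr=config.flank_fdr
        )
        blocks = haplotype_blocks(
            h,
            n_boot=config.block_bootstrap,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        link = linkage_verdict(cpr_idx, flank_res, blocks, h, config.r2_linked)

        # duplication screen (any line flagged)
        dup_flag = False
        for lid in aln.line_ids:
            tr = cohort.depth_tracks.get((lid, cpr_id))
            if tr is None:
                continue
            call = detect_duplication(
                tr, cpr_id, aln.start, aln.end, config.depth_flank, config.depth_ratio
            )
            dup_flag = dup_flag or call.flagged

        # allele phylogeny (only with >= 3 allele classes)
        rep_seq = {}
        for lid, allele in amap.items():
            rep_seq.setdefault(allele, aln.sequence(lid))
        newick = None
        if len(rep_seq) >= 3:
            tree = bootstrap_support(
                rep_seq,
                reps=config.tree_bootstrap,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
            newick = tree.newick(support_min=60)

        d = div[cpr_id]
        rows.append(
            dict(
                cpr=cpr_id,
                transcript=res.transcript_id,
                fdr_q=res.q_values.get("seq", float("nan")),
                pi=d.pi,
                tajima_d=d.tajima_d,
                selection_p=p_sel,
                selection_verdict=verdict,
                n_tfbs_changed=count_changed_motifs(explained),
                linkage_with_neighbor=link,
                duplication=dup_flag,
                n_alleles=len(set(amap.values())),
                tree=newick,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "cpr",
            "transcript",
            "fdr_q",
            "pi",
            "tajima_d",
            "selection_p",
            "selection_verdict",
            "n_tfbs_changed",
            "linkage_with_neighbor",
            "duplication",
            "n_alleles",
            "tree",
        ],
    )
    logger.info("report: %d candidate CPRs", len(report))
    from .expression import results_frame

    return PipelineResult(
        report=report,
        null=null,
        diversity=div_df,
        association=results_frame(assoc),
        artifacts=artifacts,
    )
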