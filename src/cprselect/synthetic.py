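"""Synthetic inbred-line cohorts with the statistical structure the
pipeline assumes.

The generator emulates a panel of ~29 fully homozygous inbred lines: per-CPR
haplotype alignments drawn from a neutral coalescent at a promoter-like
diversity (theta per site ~ 0.006), sexed and replicated expression with a
controllable broad-sense heritability, flanking SNPs with tunable LD to the
promoter haplotypes, planted TFBS-flipping SNPs with expression effects, and
per-line read-depth tracks with optional 2x duplications.  A truth record of
everything planted is kept alongside the data so downstream calls can be
scored automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import math

import numpy as np
import pandas as pd

from .alignment import CprAlignment
from .coalescent import DEFAULT_MU, constant_model, simulate_sample
from .duplication import DepthTrack
from .linkage import HaplotypeMatrix
from .motifs import MotifModel, minimal_mutation_sets, scan_sequence, toy_motif_set

__all__ = [
    "CohortConfig",
    "PlantSpec",
    "TruthRecord",
    "SyntheticCohort",
    "generate_cohort",
    "plant_selection_signal",
    "plant_tfbs_effect",
]

_BASES = np.array(list("ACGT"), dtype="<U1")


@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the cohort the analysis is designed for: 29 homozygous
    lines, 160-bp promoters at theta ~ 0.006 per site (a handful of
    segregating sites each), broad-sense heritability 0.6, two replicates
    per line x sex, +/- 5000 bp of flank.
    """

    n_lines: int = 29
    cpr_length: int = 160
    n_cprs: int = 10
    theta_per_site: float = 0.006
    heritability: float = 0.6
    sex_effect: float = 1.0
    interaction_effect: float = 0.0
    n_replicates: int = 2
    flank_length: int = 5000
    ld_decay: float = 1e-4
    n_flank_snps: int = 8
    base_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines >= 2 required")
        if self.cpr_length < 1 or self.n_cprs < 0:
            raise ValueError("non-positive sizes rejected")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if self.theta_per_site < 0 or self.ld_decay < 0 or self.n_replicates < 1:
            raise ValueError("invalid config")


@dataclass
class PlantSpec:
    """What to plant into one CPR (everything defaults to 'nothing')."""

    cpr_id: str
    selection: str = "neutral"  # balancing | sweep | neutral
    selection_strength: int = 8
    tfbs_pattern: str | None = None  # I | II | III
    tfbs_motif: str | None = None  # motif_id; default picked per pattern
    expression_effect: float = 0.0  # haplogroup shift, residual-SD units
    flank_mode: str = "independent"  # linked | independent
    duplicated_lines: tuple[str, ...] = ()


@dataclass
class TruthRecord:
    """Ground truth of planted structure, for end-to-end scoring."""

    selection_mode: dict[str, str] = field(default_factory=dict)
    tfbs_snps: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    tfbs_pattern: dict[str, str] = field(default_factory=dict)
    expression_effects: dict[str, float] = field(default_factory=dict)
    flank_mode: dict[str, str] = field(default_factory=dict)
    duplications: list[tuple[str, str]] = field(default_factory=list)  # (line, cpr)
    heritability: dict[str, float] = field(default_factory=dict)
    derived_lines: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    cpr_alignments: dict[str, CprAlignment]
    cpr_intervals: dict[str, tuple[str, int, int]]  # cpr -> (chrom, start, end)
    expression: pd.DataFrame
    flank_haplotypes: dict[str, HaplotypeMatrix]
    depth_tracks: dict[tuple[str, str], DepthTrack]  # (line, cpr chrom) -> track
    motifs: list[MotifModel]
    truth: TruthRecord

    @property
    def line_ids(self) -> list[str]:
        first = next(iter(self.cpr_alignments.values()), None)
        return list(first.line_ids) if first is not None else []


def plant_selection_signal(
    alignment: CprAlignment,
    mode: str,
    strength: int,
    rng: np.random.Generator | None = None,
    derived_lines: list[str] | None = None,
) -> CprAlignment:
    """Overwrite columns to emulate a selection signature.

    ``balancing`` splits the lines into two intermediate-frequency
    haplogroups differing at ``strength`` sites (intermediate-frequency
    excess, D > 0); ``sweep`` plants ``strength`` singleton sites on
    distinct lines (rare-variant excess, D < 0); ``neutral`` returns the
    input unchanged.
    """
    if mode not in ("balancing", "sweep", "neutral"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "neutral":
        return alignment.copy()
    if strength > alignment.length:
        raise ValueError("strength exceeds alignment length")
    rng = rng or np.random.default_rng()
    aln = alignment.copy()
    sites = rng.choice(alignment.length, size=strength, replace=False)
    if mode == "balancing":
        if derived_lines is None:
            half = alignment.n // 2
            derived_lines = list(alignment.line_ids[:half])
        rows = [aln.line_ids.index(l) for l in derived_lines]
        other = [i for i in range(aln.n) if i not in rows]
        for s in sites:
            b1, b2 = _BASES[rng.choice(4, size=2, replace=False)]
            aln.seqs[other, s] = b1
            aln.seqs[rows, s] = b2
    else:  # sweep
        if strength > alignment.n:
            raise ValueError("need at least one distinct line per singleton site")
        carriers = rng.choice(alignment.n, size=strength, replace=False)
        for s, row in zip(sites, carriers):
            base = aln.seqs[:, s][0]
            aln.seqs[:, s] = base  # make the column otherwise monomorphic
            alt = _BASES[(int(np.flatnonzero(_BASES == base)[0]) + 1 + rng.integers(0, 3)) % 4]
            aln.seqs[row, s] = alt
    return aln


def _window_is_clean(
    motif: MotifModel, anc: str, der: str, snps, pattern: str, motifs: list[MotifModel]
) -> bool:
    """Round-trip check: planted SNPs must reproduce exactly the declared pattern."""
    try:
        results = minimal_mutation_sets(anc, snps, motifs)
    except ValueError:
        return False
    if not results:
        return False
    patterns = {r.pattern for r in results}
    return patterns == {pattern}


def plant_tfbs_effect(
    alignment: CprAlignment,
    motif: MotifModel,
    pattern: str,
    rng: np.random.Generator | None = None,
    derived_lines: list[str] | None = None,
    motifs: list[MotifModel] | None = None,
    max_tries: int = 50,
) -> tuple[CprAlignment, list[tuple[int, str, str]]]:
    """Plant SNPs that flip a binding call in the declared pattern.

    The derived haplogroup carries the motif consensus (bound); the
    ancestral haplogroup carries it broken at 1 (patterns I/II) or 2
    (pattern III) positions, chosen so that binding flips exactly as the
    pattern declares (verified by re-scanning; construction failure after
    ``max_tries`` placements raises).  Pattern II requires a motif whose
    consensus is bound on both strands (e.g. a palindrome).  Returns the
    modified alignment and the planted SNP records (site, ancestral base,
    derived base).
    """
    if pattern not in ("I", "II", "III"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if motif.threshold is None:
        raise ValueError("motif needs a balanced threshold")
    w = motif.width
    if w > alignment.length:
        raise ValueError("motif wider than alignment")
    rng = rng or np.random.default_rng()
    motifs = motifs or [motif]
    cons = motif.consensus
    prof = scan_sequence(motif, cons)
    if prof.calls["+"][0] != 1:
        raise ValueError(f"consensus of {motif.motif_id} does not reach its threshold")
    if pattern == "II" and prof.calls["-"][0] != 1:
        raise ValueError(
            f"pattern II needs a both-strand binder; consensus of {motif.motif_id} "
            "is not bound on the reverse strand"
        )
    if derived_lines is None:
        derived_lines = list(alignment.line_ids[: alignment.n // 2])
    rows = [alignment.line_ids.index(l) for l in derived_lines]

    n_breaks = 2 if pattern == "III" else 1
    for _ in range(max_tries):
        start = int(rng.integers(0, alignment.length - w + 1))
        break_pos = sorted(rng.choice(w, size=n_breaks, replace=False).tolist())
        anc_window = list(cons)
        snps: list[tuple[int, str, str]] = []
        ok = True
        for bp in break_pos:
            alts = [b for b in "ACGT" if b != cons[bp]]
            alt = alts[int(rng.integers(0, 3))]
            anc_window[bp] = alt
            snps.append((start + bp, alt, cons[bp]))
        aln = alignment.copy()
        # background outside the window: keep whatever is there, but the
        # window columns are overwritten for all lines
        for k in range(w):
            aln.seqs[:, start + k] = anc_window[k]
            if k in break_pos:
                aln.seqs[rows, start + k] = cons[k]
            else:
                aln.seqs[rows, start + k] = cons[k]
        anc_seq = "".join(aln.seqs[[i for i in range(aln.n) if i not in rows][0]])
        if not _window_is_clean(motif, anc_seq, None, snps, pattern, motifs):
            ok = False
        if ok:
            return aln, snps
    raise ValueError(
        f"could not construct pattern {pattern} for motif {motif.motif_id} "
        f"in {max_tries} placements"
    )


def _flank_positions(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """1-based SNP positions in the two flanks of a CPR at [flank, flank+L)."""
    F, L = cfg.flank_length, cfg.cpr_length
    left = rng.choice(np.arange(1, F + 1), size=cfg.n_flank_snps // 2, replace=False)
    right = rng.choice(
        np.arange(F + L + 1, 2 * F + L + 1),
        size=cfg.n_flank_snps - cfg.n_flank_snps // 2,
        replace=False,
    )
    return np.sort(np.concatenate([left, right]))


def _linked_flank_codes(
    cfg: CohortConfig,
    positions: np.ndarray,
    haplogroup: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy haplogroup labels outward with a per-bp switch probability.

    Each line's flank allele follows a two-state chain started at the line's
    CPR haplogroup label at the CPR boundary, flipping with probability
    ``ld_decay`` per bp; with ld_decay = 0 flanks are in perfect LD with the
    promoter haplogroups.
    """
    F, L = cfg.flank_length, cfg.cpr_length
    n = len(haplogroup)
    codes = np.zeros((n, len(positions)), dtype=np.int8)
    # distance of each SNP from the nearest CPR boundary
    dist = np.where(positions <= F, F - positions + 1, positions - (F + L))
    for j, d in enumerate(dist):
        p_flip = 0.5 * (1.0 - (1.0 - 2.0 * min(cfg.ld_decay, 0.5)) ** int(d))
        flips = rng.random(n) < p_flip
        codes[:, j] = np.where(flips, 1 - haplogroup, haplogroup)
    return codes


def generate_cohort(
    config: CohortConfig, plants: list[PlantSpec] | None = None
) -> SyntheticCohort:
    """Generate a full cohort; identical config + seed => identical cohort.

    Expression for the transcript of CPR ``c`` decomposes as
    line effect + sex effect + interaction + N(0, 1) residual, with the
    between-line variance fraction equal to the configured broad-sense
    heritability; planted expression effects shift the derived haplogroup by
    the requested number of residual standard deviations.
    """
    rng = np.random.default_rng(config.seed)
    plant_by_cpr = {p.cpr_id: p for p in (plants or [])}
    motifs = toy_motif_set()
    truth = TruthRecord()
    model = (
        constant_model(N=config.theta_per_site / (4 * DEFAULT_MU))
        if config.theta_per_site > 0
        else None
    )

    alignments: dict[str, CprAlignment] = {}
    intervals: dict[str, tuple[str, int, int]] = {}
    flanks: dict[str, HaplotypeMatrix] = {}
    depth: dict[tuple[str, str], DepthTrack] = {}
    expr_rows: list[dict] = []
    line_ids = [f"line{i:03d}" for i in range(config.n_lines)]

    h2 = config.heritability
    sd_line = math.sqrt(h2 / (1 - h2)) if h2 < 1 else 10.0

    for c in range(config.n_cprs):
        cpr_id = f"cpr{c:03d}"
        chrom = f"chr_{cpr_id}"
        start = config.flank_length
        end = start + config.cpr_length
        plant = plant_by_cpr.get(cpr_id, PlantSpec(cpr_id))

        # CPRs carrying a planted selection signature are fully constructed:
        # the signature is planted on a monomorphic background so the
        # diversity pattern is exactly the planted one, while neutral CPRs
        # carry coalescent background variation
        if model is not None and plant.selection == "neutral":
            aln = simulate_sample(
                model,
                config.n_lines,
                config.cpr_length,
                seed=int(rng.integers(1, 2**31 - 1)),
                cpr_id=cpr_id,
            )
        else:
            ref = _BASES[rng.integers(0, 4, size=config.cpr_length)]
            aln = CprAlignment(
                cpr_id=cpr_id,
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                line_ids=list(line_ids),
                seqs=np.tile(ref, (config.n_lines, 1)),
            )
        aln.line_ids = list(line_ids)
        aln.chrom, aln.start, aln.end = chrom, start, end

        derived = list(line_ids[: config.n_lines // 2])
        aln = plant_selection_signal(
            aln, plant.selection, plant.selection_strength, rng, derived_lines=derived
        )
        truth.selection_mode[cpr_id] = plant.selection
        if plant.tfbs_pattern:
            motif = next(
                (
                    m
                    for m in motifs
                    if m.motif_id == (plant.tfbs_motif or ("PAL_toy" if plant.tfbs_pattern == "II" else "TATA_toy"))
                ),
            )
            aln, snps = plant_tfbs_effect(
                aln, motif, plant.tfbs_pattern, rng, derived_lines=derived, motifs=motifs
            )
            truth.tfbs_snps[cpr_id] = snps
            truth.tfbs_pattern[cpr_id] = plant.tfbs_pattern
        alignments[cpr_id] = aln
        intervals[cpr_id] = (chrom, start, end)
        truth.derived_lines[cpr_id] = tuple(derived)

        # ----- expression -----
        # for a transcript with a planted promoter effect, the allele class
        # IS the genetic (between-line) cause: no extra per-line noise is
        # layered on top, so the planted contrast is the line effect
        tid = f"t_{cpr_id}"
        shift = plant.expression_effect
        if shift != 0.0:
            line_effect = np.zeros(config.n_lines)
        else:
            line_effect = rng.normal(0.0, sd_line, size=config.n_lines)
        is_derived = np.isin(line_ids, derived)
        truth.expression_effects[tid] = shift
        truth.heritability[tid] = h2
        for li, lid in enumerate(line_ids):
            for sex in ("F", "M"):
                base = (
                    line_effect[li]
                    + (config.sex_effect if sex == "M" else 0.0)
                    + (shift if is_derived[li] else 0.0)
                    + (
                        config.interaction_effect
                        if sex == "M" and is_derived[li]
                        else 0.0
                    )
                )
                for rep in range(config.n_replicates):
                    expr_rows.append(
                        dict(
                            transcript=tid,
                            line=lid,
                            sex=sex,
                            replicate=rep,
                            value=base + rng.normal(0.0, 1.0),
                            heritability=h2,
                        )
                    )

        # ----- flanking haplotypes -----
        # linked flanks track the derived/ancestral haplogroup partition
        # (the partition carrying any planted selection/TFBS/expression signal)
        positions = _flank_positions(config, rng)
        haplogroup = np.isin(line_ids, derived).astype(np.int8)
        if plant.flank_mode == "linked":
            codes = _linked_flank_codes(config, positions, haplogroup, rng)
        else:
            codes = np.zeros((config.n_lines, len(positions)), dtype=np.int8)
            for j in range(len(positions)):
                maf = rng.uniform(0.2, 0.5)
                codes[:, j] = (rng.random(config.n_lines) < maf).astype(np.int8)
        truth.flank_mode[cpr_id] = plant.flank_mode
        flanks[cpr_id] = HaplotypeMatrix(
            chrom=chrom,
            positions=positions,
            ref=["A"] * len(positions),
            alt=["T"] * len(positions),
            line_ids=list(line_ids),
            codes=codes,
        )

        # ----- depth tracks -----
        # gene intervals lie outside CPR +/- 250 so a planted duplication over
        # CPR +/- 200 does not inflate the per-gene normalizer
        track_start = max(start - 400, 0)
        track_end = end + 400
        pos = np.arange(track_start + 1, track_end + 1)
        genes = pd.DataFrame(
            dict(
                gene=[f"{cpr_id}_gA", f"{cpr_id}_gB"],
                start=[track_start, end + 250],
                end=[start - 250, track_end],
            )
        )
        dup_region = (start - 200, end + 200)  # 0-based half-open
        # depth at expected coverage without sampling noise: a duplicated
        # segment then sits at exactly 2x and the depth-ratio rule is exact
        for lid in line_ids:
            vals = np.full(len(pos), config.base_depth)
            if lid in plant.duplicated_lines:
                in_dup = (pos >= dup_region[0] + 1) & (pos <= dup_region[1])
                vals[in_dup] *= 2.0
            depth[(lid, cpr_id)] = DepthTrack(
                line_id=lid, chrom=chrom, depth=pd.Series(vals, index=pos), genes=genes
            )
        for lid in plant.duplicated_lines:
            truth.duplications.append((lid, cpr_id))

    expression = pd.DataFrame(
        expr_rows,
        columns=["transcript", "line", "sex", "replicate", "value", "heritability"],
    )
    return SyntheticCohort(
        config=config,
        cpr_alignments=alignments,
        cpr_intervals=intervals,
        expression=expression,
        flank_haplotypes=flanks,
        depth_tracks=depth,
        motifs=motifs,
        truth=truth,
    )
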