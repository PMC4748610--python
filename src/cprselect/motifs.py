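"""PSSM-based TFBS analysis of core promoter alleles.

Core-promoter motifs (TATA, Inr, DPE, ... supplied as JASPAR count
matrices) are turned into log-odds position-specific scoring matrices
against a uniform background, a *balanced* score threshold is chosen so
that the false-negative/false-positive rate ratio approximates a target
(1000 by default), alleles are scanned on both strands, and binding-call
differences between alleles are enumerated.  For a set of SNPs
distinguishing two alleles, all mutation combinations are scored to find
the minimal SNP subsets that flip a binding call, classified into three
patterns: one SNP flipping one TFBS (I), one SNP flipping several TFBSs
(II), and flips requiring two or more SNPs jointly (III).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import math

import numpy as np

__all__ = [
    "MotifModel",
    "BindingProfile",
    "TfbsChangeEvent",
    "MutationSetResult",
    "build_pssm",
    "balanced_threshold",
    "scan_sequence",
    "tfbs_change_events",
    "count_changed_motifs",
    "minimal_mutation_sets",
    "read_jaspar",
    "write_jaspar",
    "toy_motif_set",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
UNIFORM = np.full(4, 0.25)

#: widths up to which the score-distribution DP keeps exact score keys
EXACT_WIDTH = 10


@dataclass
class MotifModel:
    """A count matrix with its log-odds PSSM and balanced threshold.

    ``counts`` has rows A, C, G, T and one column per motif position.
    ``log_odds`` cells are log2 of the pseudocount-smoothed motif base
    probability over the background probability.  ``threshold`` is set by
    :func:`balanced_threshold`; ``fpr``/``fnr`` are the rates achieved there.
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = 0.5
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    log_odds: np.ndarray | None = None
    threshold: float | None = None
    rate_ratio: float = 1000.0
    fpr: float | None = None
    fnr: float | None = None

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Pseudocount-smoothed per-position base probabilities (4 x width)."""
        colsum = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount) / (colsum + 4 * self.pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


def build_pssm(
    counts: np.ndarray,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    motif_id: str = "motif",
) -> MotifModel:
    """Construct the log-odds PSSM from a 4 x width count matrix.

    cell(b, j) = log2( ((count(b,j) + pc) / (colsum(j) + 4 pc)) / bg(b) ).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ValueError("counts must be a 4 x width matrix")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    colsum = counts.sum(axis=0)
    if pseudocount == 0 and (colsum == 0).any():
        raise ValueError("all-zero column with zero pseudocount")
    bg = UNIFORM.copy() if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-6) or (bg <= 0).any():
        raise ValueError("background must be a positive length-4 distribution")
    probs = (counts + pseudocount) / (colsum + 4 * pseudocount)
    model = MotifModel(
        motif_id=motif_id, counts=counts, pseudocount=pseudocount, background=bg
    )
    model.log_odds = np.log2(probs / bg[:, None])
    return model


def score_distributions(
    model: MotifModel, precision: float = 0.01
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint score distribution under background and motif models.

    Position-wise convolution (dynamic programming) over the per-position
    score contributions; exact score keys for widths <= EXACT_WIDTH, scores
    binned to ``precision`` bits otherwise.  Returns (scores descending,
    P_background mass per score, P_motif mass per score).
    """
    lo = model.log_odds
    if lo is None:
        raise ValueError("build_pssm first")
    q = model.probabilities
    bg = model.background
    exact = model.width <= EXACT_WIDTH
    dist: dict[float, tuple[float, float]] = {0.0: (1.0, 1.0)}
    for j in range(model.width):
        new: dict[float, tuple[float, float]] = {}
        for s, (pb, pm) in dist.items():
            for b in range(4):
                s2 = s + lo[b, j]
                if not exact:
                    s2 = round(s2 / precision) * precision
                pb2, pm2 = pb * bg[b], pm * q[b, j]
                if s2 in new:
                    ob, om = new[s2]
                    new[s2] = (ob + pb2, om + pm2)
                else:
                    new[s2] = (pb2, pm2)
        dist = new
    scores = np.array(sorted(dist, reverse=True))
    p_bg = np.array([dist[s][0] for s in scores])
    p_mot = np.array([dist[s][1] for s in scores])
    return scores, p_bg, p_mot


def balanced_threshold(
    model: MotifModel, rate_ratio: float = 1000.0, precision: float = 0.01
) -> float:
    """Choose the threshold where FNR/FPR is closest to ``rate_ratio``.

    With the window call defined as score >= t, FPR(t) is the background
    mass at or above t and FNR(t) the motif mass below t.  Candidate
    thresholds are the achievable scores; the one minimizing the log-scale
    distance of FNR/FPR from ``rate_ratio`` is chosen (ties -> higher
    threshold).  Sets ``model.threshold``, ``model.fpr``, ``model.fnr``.
    """
    scores, p_bg, p_mot = score_distributions(model, precision)
    if len(scores) < 2:
        raise ValueError(
            f"degenerate score distribution for {model.motif_id}: single achievable score"
        )
    fpr = np.cumsum(p_bg)  # P_bg(score >= scores[i])
    fnr = np.clip(1.0 - np.cumsum(p_mot), 0.0, 1.0)  # P_motif(score < scores[i])
    tiny = 1e-300
    dist = np.abs(np.log((fnr + tiny) / (fpr + tiny)) - math.log(rate_ratio))
    best = int(np.argmin(dist))  # argmin returns the first (highest) score on ties
    model.threshold = float(scores[best])
    model.rate_ratio = rate_ratio
    model.fpr = float(fpr[best])
    model.fnr = float(fnr[best])
    return model.threshold


@dataclass
class BindingProfile:
    """Per-window, per-strand PSSM scores and binding calls for one allele.

    Window positions are 0-based offsets of the window start on the template
    strand; the minus-strand score at offset i is the score of the reverse
    complement of the window starting at i.  Calls: 1 bound, 0 unbound,
    -1 missing (window contains N).
    """

    cpr_id: str
    allele: str
    motif_id: str
    width: int
    scores: dict[str, np.ndarray]  # strand -> float scores (nan = missing)
    calls: dict[str, np.ndarray]  # strand -> int8 calls

    @property
    def n_windows(self) -> int:
        return len(self.scores["+"])


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8)


def scan_sequence(
    model: MotifModel, sequence: str, cpr_id: str = "", allele: str = ""
) -> BindingProfile:
    """Score every window of ``sequence`` on both strands.

    Windows containing N score NaN (missing call); a sequence shorter than
    the motif yields an empty profile.
    """
    if model.log_odds is None:
        raise ValueError("build_pssm first")
    w = model.width
    codes = _encode(sequence)
    L = len(codes)
    nwin = max(L - w + 1, 0)
    lo_fwd = model.log_odds
    # minus strand: reverse complement of the window, i.e. complemented rows
    # in reversed column order
    lo_rev = lo_fwd[::-1, ::-1]
    scores = {"+": np.full(nwin, np.nan), "-": np.full(nwin, np.nan)}
    calls = {"+": np.full(nwin, -1, dtype=np.int8), "-": np.full(nwin, -1, dtype=np.int8)}
    thr = model.threshold
    for i in range(nwin):
        win = codes[i : i + w]
        if (win < 0).any():
            continue
        idx = (win, np.arange(w))
        scores["+"][i] = lo_fwd[idx].sum()
        scores["-"][i] = lo_rev[idx].sum()
        if thr is not None:
            # small tolerance: the threshold is itself an achievable score and
            # float summation order must not break the >= comparison
            calls["+"][i] = 1 if scores["+"][i] >= thr - 1e-9 else 0
            calls["-"][i] = 1 if scores["-"][i] >= thr - 1e-9 else 0
    return BindingProfile(cpr_id, allele, model.motif_id, w, scores, calls)


@dataclass
class TfbsChangeEvent:
    """A (motif, window, strand) whose binding call differs among alleles."""

    cpr_id: str
    motif_id: str
    position: int
    strand: str
    bound_alleles: tuple[str, ...]
    unbound_alleles: tuple[str, ...]
    direction: str | None = None  # gain/loss relative to a designated ancestral allele

    def __post_init__(self) -> None:
        if not self.bound_alleles or not self.unbound_alleles:
            raise ValueError("event needs at least one bound and one unbound allele")


def tfbs_change_events(
    profiles: dict[str, dict[str, BindingProfile]],
    ancestral: str | None = None,
) -> list[TfbsChangeEvent]:
    """Binding-call differences across alleles of one CPR.

    ``profiles`` maps allele label -> {motif_id -> BindingProfile}; alleles
    must be profiled over the same motif set and sequence length.  One event
    is emitted per (motif, window position, strand) at which at least one
    allele is bound and one unbound (missing calls ignored).  If
    ``ancestral`` names an allele with a determined call, the event carries a
    gain/loss direction relative to it.
    """
    alleles = sorted(profiles)
    if len(alleles) < 2:
        raise ValueError("need >= 2 alleles")
    motif_ids = sorted(profiles[alleles[0]])
    for a in alleles[1:]:
        if sorted(profiles[a]) != motif_ids:
            raise ValueError("alleles profiled with different motif sets")
    events: list[TfbsChangeEvent] = []
    for mid in motif_ids:
        nwins = {profiles[a][mid].n_windows for a in alleles}
        if len(nwins) != 1:
            raise ValueError("allele sequence lengths differ")
        cpr_id = profiles[alleles[0]][mid].cpr_id
        for strand in "+-":
            callmat = np.stack([profiles[a][mid].calls[strand] for a in alleles])
            diff = (callmat == 1).any(axis=0) & (callmat == 0).any(axis=0)
            for pos in np.flatnonzero(diff):
                bound = tuple(a for a, c in zip(alleles, callmat[:, pos]) if c == 1)
                unbound = tuple(a for a, c in zip(alleles, callmat[:, pos]) if c == 0)
                direction = None
                if ancestral in bound:
                    direction = "loss"
                elif ancestral in unbound:
                    direction = "gain"
                events.append(
                    TfbsChangeEvent(cpr_id, mid, int(pos), strand, bound, unbound, direction)
                )
    return events


def count_changed_motifs(events: list[TfbsChangeEvent]) -> int:
    """Number of distinct motifs with >= 1 change event (the "# TFBSs" count)."""
    return len({e.motif_id for e in events})


@dataclass
class MutationSetResult:
    """Minimal SNP subsets flipping one binding event, with pattern class."""

    motif_id: str
    position: int
    strand: str
    sites: tuple[int, ...]  # all candidate SNP sites (sequence offsets)
    minimal_subsets: list[frozenset[int]]  # indices into ``sites``
    pattern: str  # "I", "II" or "III"


def _apply_snps(seq: str, snps, subset) -> str:
    s = list(seq)
    for i in subset:
        pos, anc, der = snps[i]
        if s[pos].upper() != anc.upper():
            raise ValueError(f"ancestral base mismatch at {pos}")
        s[pos] = der.upper()
    return "".join(s)


def minimal_mutation_sets(
    ancestral: str,
    snps: list[tuple[int, str, str]],
    motifs: list[MotifModel],
    cap: int = 12,
) -> list[MutationSetResult]:
    """Enumerate minimal SNP subsets that flip each binding call.

    All 2^k artificial sequences carrying each combination of the derived
    SNPs are scored; for every (motif, window, strand) whose call differs
    between the ancestral sequence and some combination, the minimal subsets
    (no proper subset also flips) are reported.  Pattern: "I" when a single
    SNP flips exactly this one event, "II" when a flipping single SNP flips
    two or more events, "III" when every minimal subset needs >= 2 SNPs.
    """
    k = len(snps)
    if k > cap:
        raise ValueError(f"{k} SNPs exceeds the enumeration cap of {cap}")
    for m in motifs:
        if m.threshold is None:
            raise ValueError(f"motif {m.motif_id} has no threshold")
    subsets = [frozenset(c) for r in range(k + 1) for c in combinations(range(k), r)]
    # call matrix per subset: {(motif, pos, strand): call}
    calls: list[dict[tuple[str, int, str], int]] = []
    for sub in subsets:
        seq = _apply_snps(ancestral, snps, sub)
        d: dict[tuple[str, int, str], int] = {}
        for m in motifs:
            prof = scan_sequence(m, seq)
            for strand in "+-":
                for pos, c in enumerate(prof.calls[strand]):
                    d[(m.motif_id, pos, strand)] = int(c)
        calls.append(d)
    base = calls[0]  # empty subset = ancestral
    # events: keys where some subset's determined call differs from ancestral's
    events: dict[tuple[str, int, str], list[frozenset[int]]] = {}
    for sub, d in zip(subsets, calls):
        if not sub:
            continue
        for key, c in d.items():
            if c >= 0 and base.get(key, -1) >= 0 and c != base[key]:
                events.setdefault(key, []).append(sub)
    # events flipped by each singleton, for pattern I vs II
    singleton_events: dict[int, int] = {}
    for key, subs in events.items():
        for sub in subs:
            if len(sub) == 1:
                (i,) = sub
                singleton_events[i] = singleton_events.get(i, 0) + 1
    results: list[MutationSetResult] = []
    for key in sorted(events):
        flipping = events[key]
        flipset = set(flipping)
        minimal = [
            s
            for s in flipping
            if not any(t < s for t in flipset)
        ]
        minimal.sort(key=lambda s: (len(s), sorted(s)))
        singles = [next(iter(s)) for s in minimal if len(s) == 1]
        if not singles:
            pattern = "III"
        elif max(singleton_events[i] for i in singles) >= 2:
            pattern = "II"
        else:
            pattern = "I"
        mid, pos, strand = key
        results.append(
            MutationSetResult(
                motif_id=mid,
                position=pos,
                strand=strand,
                sites=tuple(p for p, _, _ in snps),
                minimal_subsets=minimal,
                pattern=pattern,
            )
        )
    return results


# --- JASPAR io (both count-matrix dialects, via Bio.motifs) ---------------


def read_jaspar(path) -> list[MotifModel]:
    """Read JASPAR count matrices (">ID name" with labelled or bracketed rows)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        name = m.matrix_id or m.name
        if m.name and m.matrix_id and m.name != m.matrix_id:
            name = f"{m.matrix_id}"
        out.append(build_pssm(counts, motif_id=name))
    return out


def write_jaspar(models: list[MotifModel], path) -> None:
    """Write count matrices in JASPAR format."""
    from Bio import motifs as bio_motifs
    from Bio.motifs import jaspar

    bio = []
    for m in models:
        counts = {b: [float(x) for x in m.counts[i]] for i, b in enumerate(BASES)}
        mot = jaspar.Motif(matrix_id=m.motif_id, name=m.motif_id, counts=counts)
        bio.append(mot)
    with open(path, "w") as fh:
        fh.write(bio_motifs.write(bio, "jaspar"))


def _peaked(consensus: str, major: int = 18, minor: int = 1) -> np.ndarray:
    counts = np.full((4, len(consensus)), minor, dtype=float)
    for j, b in enumerate(consensus):
        counts[_CODE[b], j] = major
    return counts


def toy_motif_set(rate_ratio: float = 1000.0) -> list[MotifModel]:
    """Small bundled stand-in motif set for synthetic cohorts.

    Sharply peaked toy matrices shaped after core-promoter element
    consensi (TATA-box-like, initiator-like, DPE-like) plus one palindromic
    motif so that both-strand flips are constructible.  Real analyses should
    load the JASPAR POLII matrices instead.
    """
    specs = {
        "TATA_toy": "TATAAA",
        "INR_toy": "TCAGTT",
        "DPE_toy": "AGACGT",
        "PAL_toy": "TGCGCA",  # its own reverse complement
    }
    out = []
    for mid, cons in specs.items():
        m = build_pssm(_peaked(cons), motif_id=mid)
        balanced_threshold(m, rate_ratio=rate_ratio)
        out.append(m)
    return out
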