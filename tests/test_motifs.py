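"""PSSM construction, balanced threshold, scanning, and mutation-set search."""

import itertools
import math

import numpy as np
import pytest

from cprselect.motifs import (
    BASES,
    balanced_threshold,
    build_pssm,
    minimal_mutation_sets,
    read_jaspar,
    scan_sequence,
    score_distributions,
    tfbs_change_events,
    toy_motif_set,
    write_jaspar,
)


def random_counts(rng, width, total=20):
    """Random integer count matrix with positive column sums."""
    c = rng.integers(0, total, size=(4, width)).astype(float)
    c[:, c.sum(axis=0) == 0] = 1.0
    return c


# ---- PSSM construction -------------------------------------------------------

def test_uniform_counts_give_zero_log_odds():
    m = build_pssm(np.full((4, 5), 3.0))
    assert np.allclose(m.log_odds, 0.0)


def test_log_odds_hand_arithmetic():
    counts = np.zeros((4, 1))
    counts[0, 0] = 8  # A column (8,0,0,0)
    m = build_pssm(counts, pseudocount=0.5)
    assert m.log_odds[0, 0] == pytest.approx(math.log2((8.5 / 10) / 0.25))
    assert m.log_odds[1, 0] == pytest.approx(math.log2((0.5 / 10) / 0.25))


def test_all_zero_counts_without_pseudocount_rejected():
    with pytest.raises(ValueError):
        build_pssm(np.zeros((4, 3)), pseudocount=0.0)


# ---- balanced threshold vs exhaustive enumeration ---------------------------

def enumerate_threshold(model, rate_ratio):
    """Oracle: exact rates from all 4^w k-mers, same selection rule."""
    w = model.width
    lo, q = model.log_odds, model.probabilities
    dist = {}
    for kmer in itertools.product(range(4), repeat=w):
        s = 0.0
        pb = pm = 1.0
        for j, b in enumerate(kmer):
            s = s + lo[b, j]
            pb *= 0.25
            pm *= q[b, j]
        if s in dist:
            dist[s] = (dist[s][0] + pb, dist[s][1] + pm)
        else:
            dist[s] = (pb, pm)
    scores = sorted(dist, reverse=True)
    fpr = np.cumsum([dist[s][0] for s in scores])
    fnr = np.clip(1.0 - np.cumsum([dist[s][1] for s in scores]), 0.0, 1.0)
    d = np.abs(np.log((fnr + 1e-300) / (fpr + 1e-300)) - math.log(rate_ratio))
    k = int(np.argmin(d))
    return scores[k], fpr[k], fnr[k]


@pytest.mark.parametrize("width", [4, 6])
@pytest.mark.parametrize("rate_ratio", [1.0, 1000.0])
def test_threshold_matches_enumeration(width, rate_ratio):
    rng = np.random.default_rng(width * 100 + int(rate_ratio))
    for _ in range(3):
        m = build_pssm(random_counts(rng, width))
        t = balanced_threshold(m, rate_ratio=rate_ratio)
        t_ref, fpr_ref, fnr_ref = enumerate_threshold(m, rate_ratio)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert m.fpr == pytest.approx(fpr_ref, abs=1e-12)
        assert m.fnr == pytest.approx(fnr_ref, abs=1e-12)


def test_distribution_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    m = build_pssm(random_counts(rng, 7))
    _, p_bg, p_mot = score_distributions(m)
    assert p_bg.sum() == pytest.approx(1.0)
    assert p_mot.sum() == pytest.approx(1.0)


def test_degenerate_distribution_rejected():
    m = build_pssm(np.full((4, 3), 5.0))  # all log-odds zero -> single score
    with pytest.raises(ValueError, match="degenerate"):
        balanced_threshold(m)


# ---- scanning ----------------------------------------------------------------

def test_zero_motif_scores_zero_everywhere():
    m = build_pssm(np.full((4, 4), 2.0))
    m.threshold = 1.0
    prof = scan_sequence(m, "ACGTACGTAC")
    assert np.allclose(prof.scores["+"], 0.0)
    assert np.allclose(prof.scores["-"], 0.0)


def test_short_sequence_empty_profile(motifs):
    prof = scan_sequence(motifs[0], "ACG")
    assert prof.n_windows == 0


def test_n_windows_score_missing(motifs):
    m = motifs[0]
    prof = scan_sequence(m, "N" * m.width + "ACGTACGT")
    assert np.isnan(prof.scores["+"][0]) and prof.calls["+"][0] == -1
    assert not np.isnan(prof.scores["+"][m.width])


def test_reverse_complement_symmetry(rng, motifs):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    m = motifs[1]
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        rc = "".join(comp[c] for c in reversed(seq))
        minus = scan_sequence(m, seq).scores["-"]
        plus_rc = scan_sequence(m, rc).scores["+"]
        assert np.allclose(minus, plus_rc[::-1])


def test_scores_are_additive_sums(rng, motifs):
    m = motifs[0]
    seq = "".join(rng.choice(list("ACGT"), size=25))
    prof = scan_sequence(m, seq)
    for i in range(prof.n_windows):
        expected = sum(
            m.log_odds[BASES.index(seq[i + j]), j] for j in range(m.width)
        )
        assert prof.scores["+"][i] == pytest.approx(expected)


# ---- change events -----------------------------------------------------------

def _profiles(motifs, seqs):
    return {
        a: {m.motif_id: scan_sequence(m, s, "cpr", a) for m in motifs}
        for a, s in seqs.items()
    }


def test_identical_alleles_no_events(motifs):
    seqs = {"a": "ACGTACGTACGTACG", "b": "ACGTACGTACGTACG"}
    assert tfbs_change_events(_profiles(motifs, seqs)) == []


def test_single_threshold_crossing_yields_one_event(motifs):
    tata = motifs[0]
    bound = "GGG" + tata.consensus + "GGG"
    broken = "GGG" + "C" + tata.consensus[1:] + "GGG"
    events = tfbs_change_events(_profiles([tata], {"a": bound, "b": broken}))
    assert len(events) == 1
    e = events[0]
    assert e.position == 3 and e.bound_alleles == ("a",) and e.unbound_alleles == ("b",)


def test_event_direction_relative_to_ancestral(motifs):
    tata = motifs[0]
    bound = "GGG" + tata.consensus + "GGG"
    broken = "GGG" + "C" + tata.consensus[1:] + "GGG"
    (e,) = tfbs_change_events(
        _profiles([tata], {"anc": broken, "der": bound}), ancestral="anc"
    )
    assert e.direction == "gain"


def test_event_detection_invariant_to_allele_order(motifs):
    tata = motifs[0]
    seqs = {"a": "GGG" + tata.consensus + "GGG", "b": "GGGC" + tata.consensus[1:] + "GGG"}
    ev1 = tfbs_change_events(_profiles([tata], seqs))
    ev2 = tfbs_change_events(_profiles([tata], dict(reversed(seqs.items()))))
    assert [(e.motif_id, e.position, e.strand) for e in ev1] == [
        (e.motif_id, e.position, e.strand) for e in ev2
    ]


# ---- minimal mutation sets ---------------------------------------------------

def test_single_snp_single_flip_is_pattern_I(motifs):
    tata = motifs[0]
    anc = "GG" + "CATAAA" + "GGGG"  # consensus TATAAA broken at first base
    res = minimal_mutation_sets(anc, [(2, "C", "T")], [tata])
    assert len(res) == 1
    assert res[0].pattern == "I"
    assert res[0].minimal_subsets == [frozenset({0})]


def test_palindromic_motif_gives_pattern_II(motifs):
    pal = next(m for m in motifs if m.motif_id == "PAL_toy")
    anc = "GG" + "AGCGCA" + "GGGG"  # TGCGCA broken at first base
    res = minimal_mutation_sets(anc, [(2, "A", "T")], [pal])
    assert {r.pattern for r in res} == {"II"}
    assert {r.strand for r in res} == {"+", "-"}


def test_joint_requirement_is_pattern_III(motifs):
    tata = motifs[0]
    anc = "GG" + "CAGAAA" + "GGGG"  # two breaks of TATAAA
    res = minimal_mutation_sets(anc, [(2, "C", "T"), (4, "G", "T")], [tata])
    assert len(res) == 1
    assert res[0].pattern == "III"
    assert res[0].minimal_subsets == [frozenset({0, 1})]


def test_minimal_subsets_match_subset_oracle(motifs):
    """k=4 random SNPs: minimality verified by direct proper-subset testing."""
    rng = np.random.default_rng(17)
    tata = motifs[0]
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=20))
        sites = rng.choice(20, size=4, replace=False)
        snps = []
        for p in sorted(sites):
            anc = seq[p]
            der = rng.choice([b for b in "ACGT" if b != anc])
            snps.append((int(p), anc, str(der)))
        res = minimal_mutation_sets(seq, snps, [tata])
        # oracle: all 2^4 subsets scanned independently
        def call_at(sub, key):
            s = list(seq)
            for i in sub:
                s[snps[i][0]] = snps[i][2]
            prof = scan_sequence(tata, "".join(s))
            mid, pos, strand = key
            return int(prof.calls[strand][pos])

        for r in res:
            key = (r.motif_id, r.position, r.strand)
            base = call_at(frozenset(), key)
            flips = [
                frozenset(sub)
                for k in range(1, 5)
                for sub in itertools.combinations(range(4), k)
                if call_at(frozenset(sub), key) != base
            ]
            minimal = [f for f in flips if not any(g < f for g in flips)]
            assert sorted(map(sorted, r.minimal_subsets)) == sorted(map(sorted, minimal))


def test_enumeration_cap_enforced(motifs):
    snps = [(i, "A", "C") for i in range(13)]
    with pytest.raises(ValueError, match="cap"):
        minimal_mutation_sets("A" * 20, snps, [motifs[0]])


# ---- JASPAR io ---------------------------------------------------------------

def test_jaspar_round_trip(tmp_path, motifs):
    path = tmp_path / "motifs.jaspar"
    write_jaspar(motifs, path)
    back = read_jaspar(path)
    assert [m.motif_id for m in back] == [m.motif_id for m in motifs]
    for a, b in zip(motifs, back):
        assert np.allclose(a.counts, b.counts)


def test_jaspar_labelled_row_dialect(tmp_path):
    text = """>M0001 test
A [ 10  0  2 ]
C [  0  8  2 ]
G [  0  2  8 ]
T [  2  2  0 ]
"""
    p = tmp_path / "m.jaspar"
    p.write_text(text)
    (m,) = read_jaspar(p)
    assert m.width == 3
    assert m.counts[0, 0] == 10
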