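"""Diversity statistics and alignment-cleaning rules."""

import math
from itertools import combinations

import numpy as np
import pytest

from cprselect.alignment import CprAlignment
from cprselect.popgen import (
    diversity_summary,
    nucleotide_diversity,
    preprocess_alignment,
    segregating_sites,
    tajima_constants,
    tajimas_d,
    watterson_theta,
)

from conftest import random_alignment


# ---- independent oracles -----------------------------------------------------

def brute_force_pi(aln):
    """Average pairwise per-site difference via explicit pair enumeration."""
    haps = list(aln.haplotypes().values())
    diffs = []
    L_eff = sum(
        1
        for j in range(aln.length)
        if sum(1 for h in haps if h[j] != "N") >= 2
    )
    total = 0.0
    for a, b in combinations(haps, 2):
        for x, y in zip(a, b):
            if x != "N" and y != "N" and x != y:
                total += 1
    # per-site pi with per-site pairwise deletion must be computed per site:
    per_site = []
    for j in range(aln.length):
        col = [h[j] for h in haps if h[j] != "N"]
        if len(col) < 2:
            continue
        d = sum(1 for x, y in combinations(col, 2) if x != y)
        per_site.append(d / (len(col) * (len(col) - 1) / 2))
    return sum(per_site) / L_eff if L_eff else float("nan")


def brute_force_tajima(aln):
    """Direct evaluation of D from first principles."""
    haps = [h for h in aln.haplotypes().values()]
    n = len(haps)
    L = len(haps[0])
    S = 0
    for j in range(L):
        col = {h[j] for h in haps if h[j] != "N"}
        if len(col) >= 2:
            S += 1
    if S == 0 or n < 4:
        return float("nan")
    # mean number of pairwise differences (no missing data in these inputs)
    npairs = n * (n - 1) / 2
    k = (
        sum(
            sum(1 for x, y in zip(a, b) if x != y)
            for a, b in combinations(haps, 2)
        )
        / npairs
    )
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ---- nucleotide diversity ----------------------------------------------------

def test_pi_trivial_cases(make_alignment):
    identical = make_alignment({"a": "ACGT" * 25, "b": "ACGT" * 25})
    assert nucleotide_diversity(identical) == 0.0
    two = make_alignment({"a": "A" * 100, "b": "A" * 99 + "C"})
    assert nucleotide_diversity(two) == pytest.approx(0.01)


def test_pi_matches_brute_force(rng):
    for _ in range(10):
        aln = random_alignment(rng, n=4, L=20)
        assert nucleotide_diversity(aln) == pytest.approx(brute_force_pi(aln), abs=1e-12)


def test_pi_theta_invariant_under_sequence_permutation(rng):
    aln = random_alignment(rng, n=6, L=30)
    perm = rng.permutation(6)
    shuffled = CprAlignment(
        cpr_id=aln.cpr_id, chrom=aln.chrom, start=aln.start, end=aln.end,
        strand="+", line_ids=[aln.line_ids[i] for i in perm], seqs=aln.seqs[perm],
    )
    assert nucleotide_diversity(shuffled) == pytest.approx(nucleotide_diversity(aln))
    assert watterson_theta(shuffled) == pytest.approx(watterson_theta(aln))


# ---- Watterson's theta -------------------------------------------------------

def test_watterson_trivial_and_harmonic(make_alignment):
    mono = make_alignment({"a": "A" * 10, "b": "A" * 10})
    assert watterson_theta(mono) == 0.0
    pair = make_alignment({"a": "A" * 10, "b": "C" + "A" * 9})
    assert watterson_theta(pair) == pytest.approx(0.1)  # a1 = 1 forces S/L


def test_watterson_n29(make_alignment):
    seqs = {f"l{i:02d}": "A" * 160 for i in range(29)}
    seqs["l00"] = "C" + "A" * 159
    seqs["l01"] = "A" * 159 + "G"
    aln = make_alignment(seqs)
    h28 = sum(1 / i for i in range(1, 29))
    assert watterson_theta(aln) == pytest.approx(2 / (h28 * 160), abs=1e-12)


# ---- Tajima's D --------------------------------------------------------------

def test_tajima_undefined_cases(make_alignment):
    mono = make_alignment({c: "ACGT" * 5 for c in "abcd"})
    assert math.isnan(tajimas_d(mono))
    small = make_alignment({"a": "AAAA", "b": "AAAC", "c": "AAAA"})
    assert math.isnan(tajimas_d(small))


def test_tajima_singletons_negative_and_matches_oracle(make_alignment):
    base = "A" * 50
    aln = make_alignment(
        {
            "a": "C" + base[1:],
            "b": base[:10] + "G" + base[11:],
            "c": base[:20] + "T" + base[21:],
            "d": base,
        }
    )
    d = tajimas_d(aln)
    assert d < 0
    assert d == pytest.approx(brute_force_tajima(aln), abs=1e-10)


def test_tajima_haplogroups_positive_and_matches_oracle(make_alignment):
    base = "A" * 50
    grp = "CCC" + base[3:]
    aln = make_alignment({"a": base, "b": base, "c": grp, "d": grp})
    d = tajimas_d(aln)
    assert d > 0
    assert d == pytest.approx(brute_force_tajima(aln), abs=1e-10)


def test_tajima_sign_matches_pi_vs_watterson(rng):
    for _ in range(20):
        aln = random_alignment(rng, n=6, L=40)
        d = tajimas_d(aln)
        if math.isnan(d):
            continue
        a1 = tajima_constants(6)["a1"]
        lhs = nucleotide_diversity(aln) * aln.length - segregating_sites(aln) / a1
        if abs(lhs) > 1e-12:
            assert math.copysign(1, d) == math.copysign(1, lhs)


# ---- preprocessing -----------------------------------------------------------

def _clean29(pattern_col, L=30):
    """29-line alignment whose first column follows `pattern_col`."""
    seqs = {}
    for i in range(29):
        seqs[f"l{i:02d}"] = pattern_col[i] + "A" * (L - 1)
    return CprAlignment.from_strings(seqs)


def test_preprocess_identity_for_clean_alignment():
    aln = _clean29("C" * 15 + "G" * 14)
    res = preprocess_alignment(aln)
    assert res
    assert res.alignment.haplotypes() == aln.haplotypes()


def test_preprocess_fills_fixed_sites_with_missing():
    aln = _clean29("N" * 3 + "A" * 26)
    res = preprocess_alignment(aln)
    assert res
    assert res.alignment.n == 29  # lines retained
    assert all(h[0] == "A" for h in res.alignment.haplotypes().values())


def test_preprocess_excludes_lines_missing_at_polymorphic_site():
    aln = _clean29("N" + "C" * 14 + "G" * 14)
    res = preprocess_alignment(aln)
    assert res
    assert res.alignment.n == 28
    assert "l00" in res.dropped_lines


def test_preprocess_min_line_verdict():
    # 10 lines N at a polymorphic site -> 19 usable -> excluded
    aln = _clean29("N" * 10 + "C" * 10 + "G" * 9)
    res = preprocess_alignment(aln)
    assert not res
    assert "fewer than 20" in res.reason


def test_preprocess_heterozygous_lines_removed():
    aln = _clean29("C" * 15 + "G" * 14)
    res = preprocess_alignment(aln, het_sites={"l00": {5}})
    assert res
    assert "l00" not in res.alignment.line_ids
    assert res.alignment.n == 28


def test_preprocess_maf_masking_with_168_like_minor_allele():
    # one carrier of a sub-threshold allele at 1/29 = 3.4% > 1%: kept;
    # with a stricter threshold the carrier's site is masked then fixed
    aln = _clean29("T" + "C" * 28)
    res = preprocess_alignment(aln, maf_threshold=0.05)
    assert res
    assert all(h[0] == "C" for h in res.alignment.haplotypes().values())


def test_preprocess_idempotent(rng):
    for _ in range(5):
        aln = random_alignment(rng, n=25, L=15)
        # add some Ns
        aln.seqs[rng.integers(0, 25, 5), rng.integers(0, 15, 5)] = "N"
        res = preprocess_alignment(aln, min_lines=10)
        if not res:
            continue
        again = preprocess_alignment(res.alignment, min_lines=10)
        assert again
        assert again.alignment.haplotypes() == res.alignment.haplotypes()


def test_preprocess_empty_alignment_verdict():
    with pytest.raises(ValueError):
        CprAlignment.from_strings({})
    aln = CprAlignment(
        cpr_id="x", chrom="c", start=0, end=0, strand="+",
        line_ids=["a"], seqs=np.zeros((1, 0), dtype="<U1"),
    )
    assert preprocess_alignment(aln).reason == "no data"


def test_diversity_summary_record(make_alignment):
    seqs = {f"l{i:02d}": ("A" if i else "C") + "G" * 9 for i in range(21)}
    d = diversity_summary(make_alignment(seqs))
    assert d.n == 21 and d.S == 1
    assert d.a1 == pytest.approx(sum(1 / i for i in range(1, 21)))
    assert d.pi > 0 and d.theta_w > 0
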