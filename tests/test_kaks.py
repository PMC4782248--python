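"""Nei-Gojobori pathway counting against enumeration oracles, haplotype CDS
reconstruction, and the ratio test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from introscan import kaks as K

from conftest import toy_panel

CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
SENSE = [c for c in CODONS if not K.is_stop(c)]


# ---------------------------------------------------------------------------
# Oracles (written independently of the implementation)
# ---------------------------------------------------------------------------

def site_oracle(codon):
    """Per-position enumeration of synonymous fractions."""
    syn = 0.0
    for i, base in enumerate(codon):
        alts = [codon[:i] + b + codon[i + 1:] for b in "ACGT" if b != base]
        alts = [a for a in alts]
        n_syn = sum(
            1 for a in alts
            if not K.is_stop(a) and K.translate_codon(a) == K.translate_codon(codon)
        )
        syn += n_syn / 3
    return 3 - syn, syn


def path_oracle(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, nd, sd, blocked = c1, 0, 0, False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if K.is_stop(nxt) and nxt != c2:
                blocked = True
            if K.translate_codon(cur) == K.translate_codon(nxt) and \
                    not K.is_stop(cur) and not K.is_stop(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((nd, sd, blocked))
    keep = [(nd, sd) for nd, sd, bl in results if not bl] or \
        [(nd, sd) for nd, sd, _ in results]
    return (sum(r[0] for r in keep) / len(keep),
            sum(r[1] for r in keep) / len(keep))


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

def test_site_fractions_sum_to_three_for_every_sense_codon():
    for codon in SENSE:
        n, s = K.codon_site_counts(codon)
        assert n + s == pytest.approx(3.0)
        assert (n, s) == pytest.approx(site_oracle(codon))


def test_all_single_difference_codon_pairs_match_oracle():
    for c1 in SENSE:
        for i in range(3):
            for b in "ACGT":
                c2 = c1[:i] + b + c1[i + 1:]
                if c2 == c1 or K.is_stop(c2):
                    continue
                assert K.codon_path_differences(c1, c2) == \
                    pytest.approx(path_oracle(c1, c2))


def test_all_two_difference_codon_pairs_match_oracle():
    rng = np.random.default_rng(0)
    for c1 in SENSE:
        for i, j in itertools.combinations(range(3), 2):
            c2 = list(c1)
            c2[i] = "ACGT"[(("ACGT".index(c1[i])) + 1 + int(rng.integers(3))) % 4]
            c2[j] = "ACGT"[(("ACGT".index(c1[j])) + 1 + int(rng.integers(3))) % 4]
            c2 = "".join(c2)
            if c2[i] == c1[i] or c2[j] == c1[j] or K.is_stop(c2):
                continue
            assert K.codon_path_differences(c1, c2) == \
                pytest.approx(path_oracle(c1, c2)), (c1, c2)


def test_phenylalanine_synonymous_change():
    nd, sd = K.codon_path_differences("TTT", "TTC")
    assert (nd, sd) == (0.0, 1.0)


def test_identical_haplotypes_give_zero_rates():
    cds = K.HaplotypeCDS("g", "ATGGCTAAA", "ATGGCTAAA")
    res = K.nei_gojobori(cds)
    assert res.ka == res.ks == 0.0
    assert res.ratio == 0.0
    assert res.N + res.S == pytest.approx(9.0)


def test_thirty_codon_toy_gene_matches_full_oracle():
    rng = np.random.default_rng(5)
    codons1 = [SENSE[i] for i in rng.integers(0, len(SENSE), size=30)]
    codons2 = list(codons1)
    for k in (2, 7, 11, 19, 23, 28):  # plant differences, keep sense codons
        while True:
            cand = SENSE[int(rng.integers(0, len(SENSE)))]
            if cand != codons2[k]:
                codons2[k] = cand
                break
    cds = K.HaplotypeCDS("toy", "".join(codons1), "".join(codons2))
    res = K.nei_gojobori(cds)
    N = S = Nd = Sd = 0.0
    for c1, c2 in zip(codons1, codons2):
        n, s = site_oracle(c1)
        N += n
        S += s
        nd, sd = path_oracle(c1, c2)
        Nd += nd
        Sd += sd
    assert (res.N, res.S) == pytest.approx((N, S))
    assert (res.Nd, res.Sd) == pytest.approx((Nd, Sd))
    # and the corrections follow Jukes-Cantor exactly
    assert res.ka == pytest.approx(-0.75 * math.log(1 - 4 * (Nd / N) / 3))


def test_thirty_codon_gene_matches_biopython_ng86():
    try:
        from Bio.Align import PairwiseAligner  # noqa: F401
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    except ImportError:
        pytest.skip("Bio.codonalign unavailable")
    rng = np.random.default_rng(9)
    codons1 = [SENSE[i] for i in rng.integers(0, len(SENSE), size=30)]
    codons2 = list(codons1)
    for k in (1, 8, 15, 22):
        while True:
            cand = SENSE[int(rng.integers(0, len(SENSE)))]
            if cand != codons2[k]:
                codons2[k] = cand
                break
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dn, ds = cal_dn_ds(CodonSeq("".join(codons1)), CodonSeq("".join(codons2)),
                           method="NG86")
    res = K.nei_gojobori(K.HaplotypeCDS("g", "".join(codons1), "".join(codons2)),
                         site_average=True)
    assert res.ka == pytest.approx(dn, abs=5e-3)
    assert res.ks == pytest.approx(ds, abs=5e-3)


def test_swapping_haplotypes_leaves_results_unchanged():
    rng = np.random.default_rng(3)
    c1 = [SENSE[i] for i in rng.integers(0, len(SENSE), size=20)]
    c2 = [SENSE[i] for i in rng.integers(0, len(SENSE), size=20)]
    r12 = K.nei_gojobori(K.HaplotypeCDS("g", "".join(c1), "".join(c2)),
                         site_average=True)
    r21 = K.nei_gojobori(K.HaplotypeCDS("g", "".join(c2), "".join(c1)),
                         site_average=True)
    assert (r12.Nd, r12.Sd) == pytest.approx((r21.Nd, r21.Sd))
    assert (r12.N, r12.S) == pytest.approx((r21.N, r21.S))


def test_ks_zero_with_ka_positive_reports_infinite_ratio():
    # GAC->GAT is synonymous-free? use AAA->AGA (Lys->Arg, nonsynonymous)
    cds = K.HaplotypeCDS("g", "AAA" * 20, "AGA" + "AAA" * 19)
    res = K.nei_gojobori(cds)
    assert res.ks == 0.0 and res.ka > 0.0
    assert math.isinf(res.ratio)
    assert res.as_row()["ratio"] == "inf"


# ---------------------------------------------------------------------------
# Ratio test
# ---------------------------------------------------------------------------

def test_ratio_test_no_differences_gives_one():
    res = K.KaKsResult("g", 40, 20, 0, 0, 0.0, 0.0, 0.0)
    assert K.kaks_ratio_test(res) == 1.0


def test_ratio_test_equal_proportions_gives_half():
    res = K.KaKsResult("g", 40, 20, 4.0, 2.0, 0.1, 0.1, 1.0)
    assert K.kaks_ratio_test(res) == pytest.approx(0.5)


def test_ratio_test_level_and_power_by_monte_carlo():
    """Under p_N = p_S the one-sided test rejects ~5%; under a strong excess
    it rejects nearly always (counts at the scale of a short gene)."""
    rng = np.random.default_rng(7)
    N, S = 600.0, 300.0
    null_rej = alt_rej = 0
    n_rep = 400
    for _ in range(n_rep):
        p = 0.02
        nd = rng.binomial(int(N), p)
        sd = rng.binomial(int(S), p)
        r = K.KaKsResult("g", N, S, nd, sd, 0, 0, 0)
        null_rej += K.kaks_ratio_test(r) < 0.05
        nd = rng.binomial(int(N), 0.06)
        sd = rng.binomial(int(S), 0.005)
        r = K.KaKsResult("g", N, S, nd, sd, 0, 0, 0)
        alt_rej += K.kaks_ratio_test(r) < 0.05
    assert null_rej / n_rep < 0.1
    assert alt_rej / n_rep > 0.95


# ---------------------------------------------------------------------------
# CDS reconstruction
# ---------------------------------------------------------------------------

def _one_sample_panel(gt_rows, alleles, pos, vtype=None, phased=True):
    return toy_panel([[g] for g in gt_rows], alleles=alleles, pos=pos,
                     vtype=vtype, phased=phased)


def _cds_iv(start, end, strand="+"):
    return pd.DataFrame({"chrom": ["chrI"], "start": [start], "end": [end],
                         "strand": [strand]})


def test_reconstruction_without_variants_returns_reference():
    ref = {"chrI": "ATGGCTAAATAG"}
    panel = _one_sample_panel([(0, 0)], [("A", "C")], [3])
    cds = K.reconstruct_haplotype_cds(ref, _cds_iv(0, 9), panel, "S1", "g")
    assert cds.seq1 == cds.seq2 == "ATGGCTAAA"


def test_single_het_snp_changes_exactly_one_codon():
    ref = {"chrI": "ATGGCTAAA"}
    panel = _one_sample_panel([(0, 1)], [("G", "T")], [3])
    cds = K.reconstruct_haplotype_cds(ref, _cds_iv(0, 9), panel, "S1", "g")
    assert cds.seq1 == "ATGGCTAAA"
    assert cds.seq2 == "ATGTCTAAA"
    diffs = sum(a != b for a, b in zip(cds.seq1, cds.seq2))
    assert diffs == 1


def test_cis_and_trans_phasings_reconstruct_differently():
    ref = {"chrI": "ATGGCTAAA"}
    cis = _one_sample_panel([(0, 1), (0, 1)], [("G", "T"), ("C", "A")], [3, 4])
    got = K.reconstruct_haplotype_cds(ref, _cds_iv(0, 9), cis, "S1", "g")
    assert (got.seq1, got.seq2) == ("ATGGCTAAA", "ATGTATAAA")
    trans = _one_sample_panel([(0, 1), (1, 0)], [("G", "T"), ("C", "A")], [3, 4])
    got = K.reconstruct_haplotype_cds(ref, _cds_iv(0, 9), trans, "S1", "g")
    assert (got.seq1, got.seq2) == ("ATGGATAAA", "ATGTCTAAA")


def test_unphased_multi_het_codon_is_an_error():
    ref = {"chrI": "ATGGCTAAA"}
    panel = _one_sample_panel([(0, 1), (0, 1)], [("G", "T"), ("C", "A")],
                              [3, 4], phased=False)
    with pytest.raises(ValueError, match="phase"):
        K.reconstruct_haplotype_cds(ref, _cds_iv(0, 9), panel, "S1", "g")


def test_indel_masks_overlapping_codon():
    ref = {"chrI": "ATGGCTAAATTT"}
    panel = _one_sample_panel([(0, 1)], [("GC", "G")], [3], vtype=["DEL"])
    cds = K.reconstruct_haplotype_cds(ref, _cds_iv(0, 12), panel, "S1", "g")
    assert cds.masked_codons == {1}
    res = K.nei_gojobori(cds)
    assert res.N + res.S == pytest.approx(9.0)  # 3 of 4 codons counted


def test_minus_strand_cds_is_reverse_complemented():
    #                      0123456789
    ref = {"chrI": "TTTAGCCAT" + "AAA"}  # revcomp of first 9 = ATGGCTAAA
    panel = _one_sample_panel([(0, 1)], [("C", "A")], [5])
    cds = K.reconstruct_haplotype_cds(ref, _cds_iv(0, 9, strand="-"), panel,
                                      "S1", "g")
    assert cds.seq1 == "ATGGCTAAA"
    assert cds.seq2 == "ATGTCTAAA"  # C->A at pos 5 is G->T on the CDS strand
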