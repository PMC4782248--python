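"""SNP filtering, exact HWE, D', genetic distance and LD-decay fits."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from introscan import ld as L
from introscan.simulate import simulate_ld_panel

from conftest import toy_panel


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_brute_force(n_aa, n_ab, n_bb):
    """Exact-fraction enumeration over all heterozygote counts compatible
    with the conditioned allele count."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)

    def weight(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return Fraction(2**h, 1) / (
            Fraction(factorial(h)) * factorial(hom_r) * factorial(hom_c)
        )

    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def test_monomorphic_counts_give_p_one():
    assert L.hwe_exact(48, 0, 0) == 1.0


def test_extreme_heterozygote_excess_is_significant():
    assert L.hwe_exact(0, 48, 0) < 0.05


def test_hwe_matches_brute_force_for_all_small_tables():
    for n_aa in range(0, 6):
        for n_ab in range(0, 6):
            for n_bb in range(0, 6):
                if n_aa + n_ab + n_bb == 0:
                    continue
                assert L.hwe_exact(n_aa, n_ab, n_bb) == pytest.approx(
                    hwe_brute_force(n_aa, n_ab, n_bb), rel=1e-9
                ), (n_aa, n_ab, n_bb)


def test_hwe_invariant_to_allele_swap():
    assert L.hwe_exact(30, 10, 2) == pytest.approx(L.hwe_exact(2, 10, 30))


# ---------------------------------------------------------------------------
# SNP filter
# ---------------------------------------------------------------------------

def _filter_panel():
    # 6 individuals; sites exercising every rule in turn
    gt = [
        [(0, 1)] + [(0, 0)] * 5,              # singleton -> removed
        [(0, 1), (0, 1)] + [(0, 0)] * 4,      # kept
        [(0, 1), (0, 2)] + [(0, 0)] * 4,      # triallelic -> removed
        [(0, 1), (1, 1)] + [(0, 0)] * 4,      # kept (3 carriers? no: 2) kept
        [(0, 0)] * 6,                          # monomorphic -> removed
        [(0, 1)] * 6,                          # all-het, HWE p<0.05? n=6: check
    ]
    vtype = ["SNP"] * 6
    depths = np.full((6, 6), 50)
    panel = toy_panel(gt, alleles=[("A", "C", "G")] * 6, depths=depths,
                      vtype=vtype, pos=[10, 20, 30, 40, 50, 60])
    return panel


def test_filter_removes_singletons_triallelics_and_monomorphics():
    panel = _filter_panel()
    kept, report = L.filter_snps(panel)
    reasons = dict(zip(report["pos"], report["reason"]))
    assert reasons[10] == "singleton"
    assert reasons[30] == "multiallelic"
    assert reasons[50] == "monomorphic"
    assert reasons[20] == "pass"
    assert reasons[40] == "pass"


def test_filter_depth_is_strictly_greater_than_twenty():
    panel = _filter_panel()
    panel.dp[1, 0] = 20  # not > 20 -> fails
    _, report = L.filter_snps(panel)
    assert report.loc[report["pos"] == 20, "reason"].item() == "low_depth"


def test_filter_drops_indels_and_mnps():
    panel = toy_panel([[(0, 1), (0, 1), (0, 0)]] * 3,
                      alleles=[("A", "AT"), ("AT", "A"), ("AC", "GT")],
                      vtype=["INS", "DEL", "MNP"], pos=[5, 15, 25])
    kept, report = L.filter_snps(panel)
    assert kept.n_sites == 0
    assert set(report["reason"]) == {"not_snp"}


def test_filter_hwe_exclusion():
    # 24 het / 24 homA / 0 homB among 48: strong heterozygote pattern is fine;
    # all-48-het deviates
    gt_dev = [[(0, 1)] * 48]
    panel = toy_panel(gt_dev, alleles=[("A", "C")], pos=[10])
    _, report = L.filter_snps(panel)
    assert report.loc[0, "reason"] == "hwe"


def test_synthetic_marker_set_counts_mirror_amplicon_filtering():
    """169 markers with 23 planted singletons and 13 HWE failures leave 133."""
    rng = np.random.default_rng(2)
    n_ind, n_clean = 48, 133
    gts, pos = [], []
    p = 100
    for _ in range(n_clean):  # balanced HW genotypes, several carriers
        q = rng.uniform(0.2, 0.8)
        g = [(int(rng.random() < q), int(rng.random() < q)) for _ in range(n_ind)]
        while len({a for pair in g for a in pair}) < 2 or \
                sum(1 for a, b in g if a or b) < 2 or \
                L.hwe_exact(*_counts(g)) < 0.05:
            g = [(int(rng.random() < q), int(rng.random() < q)) for _ in range(n_ind)]
        gts.append(g)
        pos.append(p := p + 100)
    for _ in range(23):  # singletons
        g = [(0, 0)] * n_ind
        g[int(rng.integers(n_ind))] = (0, 1)
        gts.append(g)
        pos.append(p := p + 100)
    for _ in range(13):  # HWE failures: every individual heterozygous
        gts.append([(0, 1)] * n_ind)
        pos.append(p := p + 100)
    panel = toy_panel(gts, alleles=[("A", "C")] * len(gts), pos=pos)
    kept, report = L.filter_snps(panel)
    assert kept.n_sites == 133
    assert (report["reason"] == "singleton").sum() == 23
    assert (report["reason"] == "hwe").sum() == 13


def _counts(g):
    n_aa = sum(1 for a, b in g if a == b == 0)
    n_bb = sum(1 for a, b in g if a == b == 1)
    return n_aa, len(g) - n_aa - n_bb, n_bb


# ---------------------------------------------------------------------------
# Diagnostic allele frequency
# ---------------------------------------------------------------------------

def _freq_setup(gt_row):
    panel = toy_panel([gt_row], alleles=[("A", "C")], pos=[100])
    diag = pd.DataFrame({"chrom": ["chrI"], "pos": [100], "allele_A": ["A"],
                         "allele_B": ["C"], "b_specific": [True]})
    amp = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [1000]})
    return L.diag_allele_freq(panel, diag, amp)


def test_allele_frequency_all_homA_is_zero():
    df = _freq_setup([(0, 0)] * 48)
    assert df.loc[0, "b_freq"] == 0.0


def test_allele_frequency_half_het_half_homA_is_quarter():
    df = _freq_setup([(0, 1)] * 24 + [(0, 0)] * 24)
    assert df.loc[0, "b_freq"] == pytest.approx(0.25)


def test_amplicon_without_diagnostic_sites_is_undefined():
    panel = toy_panel([[(0, 0)]], alleles=[("A", "C")], pos=[100])
    diag = pd.DataFrame({"chrom": [], "pos": [], "allele_A": [], "allele_B": [],
                         "b_specific": []})
    amp = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [1000]})
    out = L.diag_allele_freq(panel, diag, amp)
    assert np.isnan(out.loc[0, "b_freq"])


# ---------------------------------------------------------------------------
# D'
# ---------------------------------------------------------------------------

def _haps_from_counts(n_ab_counts):
    """Build haplotype vectors from 2x2 haplotype counts (n11,n10,n01,n00)."""
    n11, n10, n01, n00 = n_ab_counts
    a = np.array([1] * (n11 + n10) + [0] * (n01 + n00))
    b = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00)
    return a, b


def dprime_oracle(n11, n10, n01, n00):
    n = n11 + n10 + n01 + n00
    pa, pb = (n11 + n10) / n, (n11 + n01) / n
    d = n11 / n - pa * pb
    if d == 0:
        return 0.0
    dmax = min(pa * (1 - pb), (1 - pa) * pb) if d > 0 else \
        min(pa * pb, (1 - pa) * (1 - pb))
    return abs(d) / dmax


def test_perfect_coupling_gives_dprime_one():
    a, b = _haps_from_counts((50, 0, 0, 50))
    assert L.dprime(a, b)[1] == pytest.approx(1.0)


def test_independent_equifrequent_table_gives_zero():
    a, b = _haps_from_counts((25, 25, 25, 25))
    assert L.dprime(a, b) == (0.0, 0.0)


def test_hand_computed_table_40_10_10_40():
    a, b = _haps_from_counts((40, 10, 10, 40))
    d, dp = L.dprime(a, b)
    assert dp == pytest.approx(dprime_oracle(40, 10, 10, 40))
    assert dp == pytest.approx(0.6)  # D=0.15, Dmax=0.25


@pytest.mark.parametrize("seed", range(20))
def test_dprime_matches_table_oracle_on_random_configs(seed):
    rng = np.random.default_rng(seed)
    counts = tuple(rng.integers(1, 30, size=4))
    a, b = _haps_from_counts(counts)
    assert L.dprime(a, b)[1] == pytest.approx(dprime_oracle(*counts), abs=1e-12)


def test_dprime_invariant_to_allele_relabeling():
    rng = np.random.default_rng(1)
    a = rng.integers(0, 2, size=60)
    b = rng.integers(0, 2, size=60)
    if len(set(a)) < 2 or len(set(b)) < 2:
        pytest.skip("degenerate draw")
    base = L.dprime(a, b)[1]
    assert L.dprime(1 - a, b)[1] == pytest.approx(base)
    assert L.dprime(a, 1 - b)[1] == pytest.approx(base)


def test_monomorphic_marker_is_undefined():
    d, dp = L.dprime(np.zeros(10), np.array([0, 1] * 5))
    assert np.isnan(dp)


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

def test_constant_rate_integrates_to_closed_form():
    pos = np.arange(0, 2_000_001, 50_000)
    m = L.RecombinationMap.from_observations(pos, np.full(len(pos), 3.0))
    assert m.genetic_distance(0, 1_000_000) == pytest.approx(3.0, rel=1e-3)
    assert m.genetic_distance(500_000, 500_000) == 0.0


def test_piecewise_linear_map_matches_trapezoid_oracle():
    pos = np.linspace(0, 1_000_000, 201)
    rate = 1.0 + 4.0 * pos / 1_000_000  # linear ramp, lowess-reproducible
    m = L.RecombinationMap.from_observations(pos, rate, span=0.2)
    a, b = 200_000, 800_000
    grid = np.linspace(a, b, 2_001)
    oracle = np.trapezoid(m.rate(grid) * 1e-6, grid)
    assert m.genetic_distance(a, b) == pytest.approx(oracle, rel=1e-6)


def test_genetic_distance_additive_and_symmetric():
    rng = np.random.default_rng(0)
    pos = np.arange(0, 1_000_001, 20_000)
    rate = np.abs(rng.normal(3, 1, size=len(pos)))
    m = L.RecombinationMap.from_observations(pos, rate)
    d_ac = m.genetic_distance(100_000, 900_000)
    d_ab = m.genetic_distance(100_000, 400_000)
    d_bc = m.genetic_distance(400_000, 900_000)
    assert d_ab + d_bc == pytest.approx(d_ac, abs=1e-9)
    assert m.genetic_distance(900_000, 100_000) == pytest.approx(d_ac)


def test_positions_outside_map_rejected():
    m = L.RecombinationMap.from_observations([0, 1_000_000], [1.0, 1.0])
    with pytest.raises(ValueError):
        m.genetic_distance(0, 2_000_000)


def test_smoothed_rate_is_floored_at_zero():
    pos = np.arange(0, 500_001, 10_000)
    rate = np.where(pos < 250_000, 0.05, 3.0)
    m = L.RecombinationMap.from_observations(pos, rate)
    assert (m.grid_rate >= 0).all()
    assert np.all(np.diff(m.cumulative_cM) >= 0)


# ---------------------------------------------------------------------------
# Decay fit
# ---------------------------------------------------------------------------

def _decay_pairs(rng, t, n_pairs=100, noise=0.05, max_cM=5.0):
    d = rng.uniform(0.05, max_cM, size=n_pairs)
    y = (1 - d / 100) ** t + rng.normal(0, noise, size=n_pairs)
    return pd.DataFrame({"d_cM": d, "Dprime": y, "category": "all"})


def test_fit_recovers_generating_parameter():
    rng = np.random.default_rng(4)
    pairs = _decay_pairs(rng, t=50)
    fit = L.fit_decay(pairs)["all"]
    assert fit.ci_low <= 50 <= fit.ci_high
    assert fit.t_hat == pytest.approx(50, rel=0.2)


def test_all_pairs_at_complete_ld_is_degenerate_t_zero():
    pairs = pd.DataFrame({"d_cM": [0.5, 1.0, 2.0], "Dprime": [1.0, 1.0, 1.0],
                          "category": "all"})
    fit = L.fit_decay(pairs)["all"]
    assert fit.t_hat == 0.0
    assert fit.degenerate


def test_decay_model_limits():
    fit = L.DecayFit(0.0, 0, 0, 0, 3)
    assert np.allclose(fit.curve([0.1, 2.0, 5.0]), 1.0)  # t=0: no decay
    fit50 = L.DecayFit(50.0, 0, 0, 0, 3)
    assert fit50.curve([0.0]) == pytest.approx(1.0)       # theta=0: D'=1


def test_pairs_beyond_max_distance_are_excluded():
    rng = np.random.default_rng(8)
    near = _decay_pairs(rng, t=20, n_pairs=50)
    far = pd.DataFrame({"d_cM": [8.0, 9.0], "Dprime": [0.9, 0.95],
                        "category": "all"})
    fit = L.fit_decay(pd.concat([near, far], ignore_index=True))["all"]
    assert fit.n_pairs == 50


def test_recent_introgression_decays_slower_inside_than_outside():
    pos_cM, haps, zone = simulate_ld_panel(seed=3, generations=12)
    pairs = L.pair_ld_table(haps, pos_cM, zone)
    fits = L.fit_decay(pairs, max_cM=5.0)
    assert fits[L.CATEGORY_WITHIN].t_hat < fits[L.CATEGORY_OUTSIDE].t_hat
    # within-category decay is on the order of the simulated age
    assert fits[L.CATEGORY_WITHIN].t_hat < 60


def test_haldane_theta_is_smaller_and_capped():
    d = np.array([1.0, 5.0, 80.0])
    plain = L.theta_from_cM(d)
    hald = L.theta_from_cM(d, haldane=True)
    assert (hald <= plain + 1e-12).all()
    assert plain[-1] == 0.5
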