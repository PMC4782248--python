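"""Amplicon SNP filtering, exact HWE test, D', map-based genetic distance
and LD-decay curve fitting.

The decay model is the classic single-parameter recurrence for gametic
disequilibrium: D'(d) = (1 - theta)^t with theta the recombination
fraction between a marker pair and t the number of generations since the
haplotypes were in complete association (D' = 1).  theta is taken as map
distance in Morgans (d_cM / 100, capped at 0.5); at the <= 5 cM range the
fit uses, the Haldane correction changes theta by under 5% and is off by
default (flag-switchable).  Genetic distances come from the definite
integral of a lowess-smoothed recombination-rate curve (cM/Mb floored at
zero), evaluated on a 1-kb grid so distances are deterministic and
additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .panelio import HaplotypePanel, coverage_mask

CATEGORY_WITHIN = "within"
CATEGORY_OUTSIDE = "outside"
CATEGORY_ACROSS = "across"


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg p-value, conditional on the observed allele count.

    Sums the probabilities of every heterozygote count (with the same
    parity as observed, forced by the fixed allele count) whose conditional
    probability does not exceed the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab  # minor/major labelling is irrelevant
    rare = min(n_a, 2 * n - n_a)
    # log P(n_het | n, rare) up to a shared constant
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([_log_hwe_weight(n, rare, int(h)) for h in hets])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.flatnonzero(hets == n_ab)[0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _log_hwe_weight(n: int, rare: int, n_het: int) -> float:
    n_rare_hom = (rare - n_het) // 2
    n_common_hom = n - n_het - n_rare_hom
    return (
        n_het * math.log(2.0)
        - math.lgamma(n_het + 1)
        - math.lgamma(n_rare_hom + 1)
        - math.lgamma(n_common_hom + 1)
    )


# ---------------------------------------------------------------------------
# Amplicon-style SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(
    panel: HaplotypePanel,
    min_depth: int = 20,
    hwe_alpha: float = 0.05,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Marker-panel filter for amplicon genotypes.

    Retains sites that (1) have depth strictly above `min_depth` in every
    individual, (2) are SNPs, not indels or multi-nucleotide polymorphisms,
    (3) are biallelic among the genotyped individuals, (4) have the minor
    allele in at least two individuals (no singletons), and (5) do not
    deviate from Hardy-Weinberg equilibrium (exact test, p >= `hwe_alpha`).

    Returns the filtered panel and a per-site report with the reason each
    dropped site failed (first failing rule wins).
    """
    reasons = np.array(["pass"] * panel.n_sites, dtype=object)
    depth_ok = (panel.dp > min_depth).all(axis=1)
    reasons[~depth_ok] = "low_depth"
    is_snp = panel.vtype == "SNP"
    reasons[depth_ok & ~is_snp] = "not_snp"

    keep = depth_ok & is_snp
    for i in np.flatnonzero(keep):
        g = panel.gt[i]
        called = g[g >= 0]
        alleles, counts = np.unique(called, return_counts=True)
        if len(alleles) > 2:
            reasons[i] = "multiallelic"
            continue
        if len(alleles) < 2:
            reasons[i] = "monomorphic"
            continue
        minor = alleles[np.argmin(counts)]
        carriers = int(((g == minor).any(axis=1) & (g >= 0).all(axis=1)).sum())
        if carriers < 2:
            reasons[i] = "singleton"
            continue
        a, b = alleles
        n_aa = int(((g[:, 0] == a) & (g[:, 1] == a)).sum())
        n_bb = int(((g[:, 0] == b) & (g[:, 1] == b)).sum())
        n_ab = int((((g[:, 0] == a) & (g[:, 1] == b))
                    | ((g[:, 0] == b) & (g[:, 1] == a))).sum())
        if hwe_exact(n_aa, n_ab, n_bb) < hwe_alpha:
            reasons[i] = "hwe"
    report = pd.DataFrame(
        {"chrom": panel.chrom, "pos": panel.pos, "reason": reasons}
    )
    return panel.subset_sites(reasons == "pass"), report


def diag_allele_freq(
    panel: HaplotypePanel,
    diagnostic_sites: pd.DataFrame,
    amplicons: pd.DataFrame,
) -> pd.DataFrame:
    """Mean species-B diagnostic allele frequency per amplicon interval.

    Frequency at a site is the B-allele count over 2 x genotyped
    individuals, averaged across the diagnostic sites inside the amplicon.
    Amplicons containing no diagnostic site are flagged undefined (NaN).
    """
    diag = diagnostic_sites[diagnostic_sites["b_specific"].astype(bool)]
    rows = []
    for amp in amplicons.itertuples(index=False):
        sel = diag[(diag["chrom"] == amp.chrom)
                   & (diag["pos"] >= amp.start) & (diag["pos"] < amp.end)]
        freqs = []
        for site in sel.itertuples():
            idx = panel.sites_in_region(site.chrom, site.pos, site.pos + 1)
            if len(idx) == 0:
                continue
            i = idx[0]
            try:
                ib = panel.alleles[i].index(site.allele_B)
            except ValueError:
                freqs.append(0.0)
                continue
            g = panel.gt[i]
            called = (g >= 0).all(axis=1)
            if called.sum() == 0:
                continue
            freqs.append(float((g[called] == ib).sum()) / (2 * int(called.sum())))
        rows.append(
            (amp.chrom, amp.start, amp.end, len(freqs),
             float(np.mean(freqs)) if freqs else float("nan"))
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "b_freq"])


# ---------------------------------------------------------------------------
# D'
# ---------------------------------------------------------------------------

@dataclass
class PairLD:
    marker1: int
    marker2: int
    D: float
    Dprime: float
    d_cM: float = float("nan")
    category: str = ""


def dprime(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[float, float]:
    """(D, |D'|) between two biallelic markers from phased haplotype vectors.

    D = p_AB - p_A p_B; D' normalises by the maximum |D| attainable at the
    observed allele frequencies.  The absolute-value convention makes the
    result invariant to allele relabelling at either marker.  Monomorphic
    input is undefined (NaN).
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    a = (a == a[0]).astype(float)  # code relative to first observed allele
    b = (b == b[0]).astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan"), float("nan")
    pab = (a * b).mean()
    d = pab - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return 0.0, 0.0
    return float(d), float(abs(d) / dmax)


def pair_ld_table(
    haplotypes: np.ndarray,
    positions_cM: np.ndarray,
    zone: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """All-pairs D' with genetic distances and zone categories.

    `haplotypes` is (n_haplotypes, n_markers); `positions_cM` gives each
    marker's cumulative map position; `zone` is a marker-index interval
    defining "within" (both markers inside), "outside" (both outside) and
    "across" pairs.
    """
    m = haplotypes.shape[1]
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            d, dp = dprime(haplotypes[:, i], haplotypes[:, j])
            if np.isnan(dp):
                continue
            cat = ""
            if zone is not None:
                ini = zone[0] <= i < zone[1]
                inj = zone[0] <= j < zone[1]
                cat = (CATEGORY_WITHIN if ini and inj
                       else CATEGORY_OUTSIDE if not ini and not inj
                       else CATEGORY_ACROSS)
            rows.append((i, j, d, dp, abs(positions_cM[j] - positions_cM[i]), cat))
    return pd.DataFrame(
        rows, columns=["marker1", "marker2", "D", "Dprime", "d_cM", "category"]
    )


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

@dataclass
class RecombinationMap:
    """Smoothed recombination-rate function and its cumulative map.

    Built from (position bp, rate cM/Mb) observations by lowess smoothing
    (default span 0.3), flooring the smoothed rate at zero and integrating
    on a 1-kb grid by the trapezoid rule.  ``genetic_distance`` is then an
    interpolation into the cumulative map, which makes it symmetric and
    additive over adjacent intervals by construction.
    """

    grid_pos: np.ndarray        # bp
    grid_rate: np.ndarray       # cM/Mb, floored at 0
    cumulative_cM: np.ndarray   # definite integral from grid start

    @classmethod
    def from_observations(
        cls, positions, rates, span: float = 0.3, grid_step: int = 1_000
    ) -> "RecombinationMap":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        positions = np.asarray(positions, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if len(positions) < 2:
            raise ValueError("need at least two rate observations")
        sm = lowess(rates, positions, frac=span, return_sorted=True)
        grid = np.arange(positions.min(), positions.max() + grid_step, grid_step, dtype=float)
        grid = np.minimum(grid, positions.max())
        rate = np.maximum(np.interp(grid, sm[:, 0], sm[:, 1]), 0.0)
        # cM/Mb x bp -> cM requires the 1e-6 bp->Mb conversion
        from scipy.integrate import cumulative_trapezoid

        cum = np.concatenate([[0.0], cumulative_trapezoid(rate * 1e-6, grid)])
        return cls(grid_pos=grid, grid_rate=rate, cumulative_cM=cum)

    @classmethod
    def from_table(cls, table: pd.DataFrame, chrom: str | None = None, **kw) -> "RecombinationMap":
        if chrom is not None:
            table = table[table["chrom"] == chrom]
        return cls.from_observations(table["pos"], table["rate_cM_Mb"], **kw)

    def rate(self, pos) -> np.ndarray:
        return np.interp(pos, self.grid_pos, self.grid_rate)

    def cumulative(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        if (pos < self.grid_pos[0]).any() or (pos > self.grid_pos[-1]).any():
            raise ValueError("position outside the fitted map range")
        return np.interp(pos, self.grid_pos, self.cumulative_cM)

    def genetic_distance(self, pos1, pos2) -> float:
        """Map distance in cM between two physical positions (symmetric)."""
        c1, c2 = self.cumulative([pos1, pos2])
        return float(abs(c2 - c1))


# ---------------------------------------------------------------------------
# Decay fit
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    t_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int
    category: str = ""
    degenerate: bool = False

    def curve(self, d_cM, theta_cap: float = 0.5) -> np.ndarray:
        theta = np.minimum(np.asarray(d_cM, dtype=float) / 100.0, theta_cap)
        return (1.0 - theta) ** self.t_hat


def theta_from_cM(d_cM, cap: float = 0.5, haldane: bool = False) -> np.ndarray:
    """Recombination fraction from map distance; optional Haldane inverse."""
    d = np.asarray(d_cM, dtype=float) / 100.0
    if haldane:
        theta = 0.5 * (1.0 - np.exp(-2.0 * d))
    else:
        theta = d
    return np.minimum(theta, cap)


def fit_decay(
    pairs: pd.DataFrame,
    max_cM: float = 5.0,
    theta_cap: float = 0.5,
    haldane: bool = False,
    by_category: bool = True,
) -> dict[str, DecayFit]:
    """Least-squares fit of D' = (1 - theta)^t per marker-pair category.

    Only pairs with map distance <= `max_cM` enter the fit.  The 95%
    confidence band is asymptotic, from the parameter covariance of the
    nonlinear fit.  A category where every D' is 1 is degenerate (t = 0,
    flagged).
    """
    pairs = pairs[pairs["d_cM"] <= max_cM]
    groups = pairs.groupby("category") if by_category else [("all", pairs)]
    out: dict[str, DecayFit] = {}
    for cat, grp in groups:
        if len(grp) < 3:
            continue
        theta = theta_from_cM(grp["d_cM"].to_numpy(), theta_cap, haldane)
        y = grp["Dprime"].to_numpy(dtype=float)
        if np.allclose(y, 1.0):
            out[cat] = DecayFit(0.0, 0.0, 0.0, 0.0, len(grp), cat, degenerate=True)
            continue

        def model(th, t):
            return (1.0 - th) ** t

        popt, pcov = curve_fit(model, theta, y, p0=[10.0],
                               bounds=(0.0, np.inf), maxfev=10_000)
        t_hat = float(popt[0])
        se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("inf")
        out[cat] = DecayFit(
            t_hat=t_hat,
            se=se,
            ci_low=max(0.0, t_hat - 1.96 * se),
            ci_high=t_hat + 1.96 * se,
            n_pairs=len(grp),
            category=str(cat),
        )
    return out
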