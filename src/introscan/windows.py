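"""Sliding-window population-genetic statistics and the exact rank test.

Average heterozygosity follows the small-sample unbiased estimator

    h-hat = sum over segregating sites of  n (1 - sum_j x_j^2) / (n - 1)

with n the number of chromosomes sampled at the site and x_j the sample
frequency of the j-th allele, normalised per validated nucleotide site so
that window values land on the per-bp scale (~1e-3 for a typical fish
population).  The per-site term equals the mean number of differences over
all chromosome pairs at that site, which the test-suite asserts exactly.

Windows are anchored at position 0 of each chromosome; terminal partial
windows keep their actual valid-site denominators.  Windows whose
denominator is zero are flagged undefined (NaN) rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .diagnostics import GenotypeClassTrack, HET, HOM_A, HOM_B
from .panelio import CallableTrack, HaplotypePanel


@dataclass
class WindowSpec:
    size: int
    step: int

    def __post_init__(self):
        if not (self.size >= self.step >= 1):
            raise ValueError("window size must be >= step >= 1")


def window_starts(chrom_len: int, spec: WindowSpec) -> np.ndarray:
    return np.arange(0, max(chrom_len, 1), spec.step, dtype=np.int64)


@dataclass
class HetWindow:
    chrom: str
    start: int
    end: int
    S: int                # segregating sites
    h_sum: float          # sum of per-site unbiased heterozygosity terms
    valid_sites: int      # validated nucleotide positions in the window
    @property
    def h(self) -> float:
        return self.h_sum / self.valid_sites if self.valid_sites else float("nan")


def _site_het_terms(panel: HaplotypePanel, idx: np.ndarray):
    """Unbiased per-site heterozygosity terms n(1-sum x^2)/(n-1).

    Returns (terms, segregating) aligned to `idx`.  Sites with fewer than
    two sampled chromosomes contribute nothing.
    """
    flat = panel.gt[idx].reshape(len(idx), -1)
    n = (flat >= 0).sum(axis=1).astype(float)
    max_allele = int(flat.max(initial=0))
    sumsq = np.zeros(len(idx))
    top = np.zeros(len(idx))
    for a in range(max_allele + 1):
        c = (flat == a).sum(axis=1).astype(float)
        sumsq += c**2
        top = np.maximum(top, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n * (1.0 - sumsq / n**2) / (n - 1.0)
    terms = np.where(n >= 2, terms, 0.0)
    segregating = (top < n) & (n >= 2)
    return np.where(segregating, terms, 0.0), segregating


def average_heterozygosity(
    panel: HaplotypePanel,
    mask: np.ndarray,
    track: CallableTrack,
    chrom: str,
    start: int = 0,
    end: int | None = None,
) -> HetWindow:
    """h-hat over one region, normalised by validated sites in the region."""
    if end is None:
        end = track.chrom_length(chrom)
    idx = panel.sites_in_region(chrom, start, end)
    idx = idx[mask[idx] & (panel.vtype[idx] == "SNP")]
    terms, seg = _site_het_terms(panel, idx)
    return HetWindow(
        chrom=chrom,
        start=start,
        end=end,
        S=int(seg.sum()),
        h_sum=float(terms.sum()),
        valid_sites=track.count(chrom, start, end),
    )


def _window_table(chrom, chrom_len, spec, starts_values):
    rows = []
    for s, vals in starts_values:
        rows.append((chrom, int(s), int(min(s + spec.size, chrom_len))) + vals)
    return rows


def average_heterozygosity_windows(
    panel: HaplotypePanel,
    mask: np.ndarray,
    track: CallableTrack,
    spec: WindowSpec,
    chroms=None,
) -> pd.DataFrame:
    """Sliding-window h-hat; columns chrom, start, end, S, valid_sites, h."""
    rows = []
    for chrom in chroms or track.arrays:
        L = track.chrom_length(chrom)
        idx = panel.sites_in_region(chrom)
        idx = idx[mask[idx] & (panel.vtype[idx] == "SNP")]
        terms, seg = _site_het_terms(panel, idx)
        pos = panel.pos[idx]
        valid = np.concatenate([[0], np.cumsum(track.arrays[chrom])])
        for s in window_starts(L, spec):
            e = min(s + spec.size, L)
            lo, hi = np.searchsorted(pos, [s, e])
            vs = int(valid[e] - valid[s])
            h_sum = float(terms[lo:hi].sum())
            rows.append(
                (chrom, int(s), int(e), int(seg[lo:hi].sum()), vs,
                 h_sum / vs if vs else float("nan"))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "S", "valid_sites", "h"])


def observed_het_proportion(
    panel: HaplotypePanel,
    mask: np.ndarray,
    track: CallableTrack,
    individual: str,
    chrom: str | None = None,
    start: int = 0,
    end: int | None = None,
) -> float:
    """Heterozygous-site count / validated-site count for one individual.

    NaN (undefined) when the region holds zero validated sites.
    """
    j = panel.sample_index(individual)
    if chrom is None:
        chroms = list(track.arrays)
    else:
        chroms = [chrom]
    het = 0
    denom = 0
    for c in chroms:
        e = end if (chrom is not None and end is not None) else track.chrom_length(c)
        idx = panel.sites_in_region(c, start if chrom else 0, e)
        idx = idx[mask[idx] & (panel.vtype[idx] == "SNP")]
        g = panel.gt[idx, j]
        het += int(((g[:, 0] != g[:, 1]) & (g >= 0).all(axis=1)).sum())
        denom += track.count(c, start if chrom else 0, e)
    return het / denom if denom else float("nan")


def het_site_proportion_windows(
    panel: HaplotypePanel,
    mask: np.ndarray,
    track: CallableTrack,
    spec: WindowSpec,
    individual: str,
    chroms=None,
) -> pd.DataFrame:
    """Per-window heterozygous-site proportion for one individual."""
    j = panel.sample_index(individual)
    rows = []
    for chrom in chroms or track.arrays:
        L = track.chrom_length(chrom)
        idx = panel.sites_in_region(chrom)
        idx = idx[mask[idx] & (panel.vtype[idx] == "SNP")]
        g = panel.gt[idx, j]
        is_het = (g[:, 0] != g[:, 1]) & (g >= 0).all(axis=1)
        hpos = panel.pos[idx][is_het]
        valid = np.concatenate([[0], np.cumsum(track.arrays[chrom])])
        for s in window_starts(L, spec):
            e = min(s + spec.size, L)
            vs = int(valid[e] - valid[s])
            nh = int(np.searchsorted(hpos, e) - np.searchsorted(hpos, s))
            rows.append((chrom, int(s), int(e), individual, nh, vs,
                         nh / vs if vs else float("nan")))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "individual", "n_het",
                       "valid_sites", "proportion"]
    )


def genotype_class_proportion_windows(
    track: GenotypeClassTrack,
    spec: WindowSpec,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-individual window fractions of homA / het / homB classes.

    Fractions are over B-specific diagnostic sites in the window; the three
    fractions plus the missing fraction sum to one.  Windows containing no
    B-specific site are flagged undefined (NaN fractions).
    """
    rows = []
    sites = track.sites
    for chrom, L in chrom_lengths.items():
        on = (sites["chrom"] == chrom).to_numpy()
        pos = sites["pos"].to_numpy()[on]
        cls = track.classes[on]
        order = np.argsort(pos, kind="stable")
        pos, cls = pos[order], cls[order]
        for s in window_starts(L, spec):
            e = min(s + spec.size, L)
            lo, hi = np.searchsorted(pos, [s, e])
            block = cls[lo:hi]
            n = hi - lo
            for j, ind in enumerate(track.samples):
                if n == 0:
                    fa = fh = fb = float("nan")
                else:
                    col = block[:, j]
                    fa = float((col == HOM_A).sum()) / n
                    fh = float((col == HET).sum()) / n
                    fb = float((col == HOM_B).sum()) / n
                rows.append((chrom, int(s), int(e), ind, int(n), fa, fh, fb))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "individual", "n_sites",
                       "frac_homA", "frac_het", "frac_homB"]
    )


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U test
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j < len(sv) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    return ranks


def mwu_exact(sample1, sample2) -> float:
    """Two-sided exact Mann-Whitney U p-value by complete enumeration.

    Ties are handled with mid-ranks, and the null distribution is built by
    enumerating every assignment of the pooled values to the two group
    labels, so the test stays exact in the small-sample regime where the
    normal approximation is unreliable (n1 + n2 <= 20 enforced).

    p = #{assignments with |U - E[U]| >= |U_obs - E[U]|} / C(n1+n2, n1).
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 + n2 > 20:
        raise ValueError("exact enumeration limited to n1 + n2 <= 20")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    mean_u = n1 * n2 / 2.0
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0
    obs_dev = abs(u_obs - mean_u)

    total = comb(n1 + n2, n1)
    count = 0
    offset = n1 * (n1 + 1) / 2.0 + mean_u
    for combo in combinations(range(n1 + n2), n1):
        dev = abs(ranks[list(combo)].sum() - offset)
        if dev >= obs_dev - 1e-9:
            count += 1
    return count / total
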