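"""Candidate screening, 1-kb refinement and border calling of introgression
tracts.

The scan has two resolutions.  A coarse 500-kb / 100-kb genotype-class
window screen flags regions where more than a threshold fraction (default
2%) of B-specific diagnostic sites carry the donor allele in at least one
individual of the population.  Inside each candidate region a 1-kb tiling
window labels each kilobase by its dominant genotype class (>50% of the
individual's informative diagnostic sites); maximal runs of donor-dominant
windows become tracts, with borders at the window edges where dominance
flips.  Emitted tracts must exceed 10 kb and rest on at least five
donor-carrying segregating sites.

Uninformative kilobases (no diagnostic site, or an exact 50/50 tie) carry
no label; runs are bridged across them up to a configurable gap, because
at interspecies divergence ~0.0144 the expected diagnostic-site spacing
(~70 bp) still leaves occasional empty kilobases inside real tracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import GenotypeClassTrack, HET, HOM_A, HOM_B


@dataclass
class IntrogressionTract:
    chrom: str
    start: int
    end: int
    individual: str
    n_sites: int          # supporting donor-carrying segregating sites
    dominant_state: str   # "het" or "hom"

    @property
    def length(self) -> int:
        return self.end - self.start


def screen_candidates(geno_windows: pd.DataFrame, threshold: float = 0.02) -> pd.DataFrame:
    """Merge 500-kb windows whose donor-genotype fraction exceeds `threshold`.

    A window qualifies when frac_het + frac_homB > threshold in at least
    one individual.  Overlapping qualifying windows are merged into maximal
    candidate regions; returns columns chrom, start, end.
    """
    gw = geno_windows
    donor = gw["frac_het"].fillna(0.0) + gw["frac_homB"].fillna(0.0)
    hits = gw[donor > threshold]
    regions = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        cur_s, cur_e = None, None
        for s, e in iv:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                regions.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            regions.append((chrom, int(cur_s), int(cur_e)))
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def _dominant_labels(pos, cls, region_start, region_end, window):
    """Label each 1-kb bin in the region: +1 donor-dominant, -1 recipient-
    dominant, 0 uninformative.  Bins are anchored on the absolute grid."""
    first_bin = region_start // window
    last_bin = (region_end - 1) // window
    n_bins = last_bin - first_bin + 1
    donor = np.zeros(n_bins, dtype=np.int64)
    recip = np.zeros(n_bins, dtype=np.int64)
    bins = pos // window - first_bin
    informative = (cls == HOM_A) | (cls == HET) | (cls == HOM_B)
    np.add.at(donor, bins[informative & ((cls == HET) | (cls == HOM_B))], 1)
    np.add.at(recip, bins[informative & (cls == HOM_A)], 1)
    lab = np.zeros(n_bins, dtype=np.int8)
    lab[donor > recip] = 1
    lab[recip > donor] = -1   # exact ties stay 0 (>50% required)
    return first_bin, lab, donor


def refine_and_call(
    candidates: pd.DataFrame,
    track: GenotypeClassTrack,
    window: int = 1_000,
    min_length: int = 10_000,
    min_sites: int = 5,
    max_gap: int = 5_000,
    per_window_sites: bool = False,
) -> pd.DataFrame:
    """1-kb dominant-genotype refinement of candidate regions, per individual.

    Tracts are maximal runs of donor-dominant kilobase windows (bridged
    across uninformative windows up to `max_gap`), kept when strictly longer
    than `min_length` with at least `min_sites` supporting donor-carrying
    sites.  With ``per_window_sites=True`` the site-count requirement is
    applied to every informative window instead of the whole region.

    Returns columns chrom, start, end, individual, n_sites, n_het, n_homB,
    dominant_state.
    """
    out = []
    sites = track.sites
    gap_bins = max_gap // window
    for cand in candidates.itertuples():
        on = (sites["chrom"] == cand.chrom).to_numpy()
        pos_all = sites["pos"].to_numpy()[on]
        sel = (pos_all >= cand.start) & (pos_all < cand.end)
        pos = pos_all[sel]
        if len(pos) == 0:
            continue
        cls_all = track.classes[on][sel]
        for j, ind in enumerate(track.samples):
            cls = cls_all[:, j]
            first_bin, lab, donor_counts = _dominant_labels(
                pos, cls, cand.start, cand.end, window
            )
            for b0, b1 in _donor_runs(lab, gap_bins):
                start = (first_bin + b0) * window
                end = (first_bin + b1 + 1) * window
                in_run = (pos >= start) & (pos < end)
                run_cls = cls[in_run]
                n_het = int((run_cls == HET).sum())
                n_homb = int((run_cls == HOM_B).sum())
                n_donor = n_het + n_homb
                if end - start <= min_length or n_donor < min_sites:
                    continue
                if per_window_sites:
                    seg = donor_counts[b0:b1 + 1]
                    if (seg[lab[b0:b1 + 1] == 1] < min_sites).any():
                        continue
                out.append(
                    (cand.chrom, start, end, ind, n_donor, n_het, n_homb,
                     "het" if n_het >= n_homb else "hom")
                )
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "individual", "n_sites",
                      "n_het", "n_homB", "dominant_state"]
    )


def _donor_runs(lab: np.ndarray, gap_bins: int):
    """Maximal runs of +1 bins, bridging runs of 0 bins up to gap_bins."""
    runs = []
    start = None
    last_donor = None
    for i, v in enumerate(lab):
        if v == 1:
            if start is None:
                start = i
            elif last_donor is not None and i - last_donor - 1 > gap_bins:
                runs.append((start, last_donor))
                start = i
            last_donor = i
        elif v == -1:
            if start is not None:
                runs.append((start, last_donor))
                start, last_donor = None, None
    if start is not None:
        runs.append((start, last_donor))
    return runs


def merge_population_sites(tracts: pd.DataFrame) -> pd.DataFrame:
    """Union of individual tracts into population-level introgression sites."""
    regions = []
    for chrom, grp in tracts.groupby("chrom", sort=False):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        cur_s = cur_e = None
        for s, e in iv:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                regions.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            regions.append((chrom, int(cur_s), int(cur_e)))
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def overlap_tracts(set1: pd.DataFrame, set2: pd.DataFrame):
    """Shared / private split of `set1` sites against `set2` (>= 1 bp overlap).

    Returns ``(shared, private, fraction)`` with fraction = shared / |set1|.
    """
    shared_rows, private_rows = [], []
    for row in set1.itertuples(index=False):
        other = set2[(set2["chrom"] == row.chrom)
                     & (set2["start"] < row.end) & (set2["end"] > row.start)]
        (shared_rows if len(other) else private_rows).append(tuple(row))
    shared = pd.DataFrame(shared_rows, columns=set1.columns)
    private = pd.DataFrame(private_rows, columns=set1.columns)
    fraction = len(shared) / len(set1) if len(set1) else float("nan")
    return shared, private, fraction
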