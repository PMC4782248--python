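"""In silico RAD and ddRAD capture of diagnostic SNPs.

Reduced-representation designs only interrogate sequence near restriction
sites, so small introgression tracts can be invisible to them.  This
module answers, for a set of called tracts: how many of the tract's
species-diagnostic SNPs would land on a RAD or ddRAD read?

Geometry follows 2 x 100 bp paired-end sequencing of a single-digest RAD
library (reads flanking each conserved restriction site, plus the mate
footprints whose near edge sits 400 bp from the site) and a double-digest
library size-selected to 300 +/- 36 bp fragments bounded by two different
enzymes, sequenced 100 bp in from both fragment ends.  Restriction sites
containing an interspecies fixed difference are discarded first, since
only sites conserved between the species are recovered in both genomes.
Sequencing is assumed perfect: every conserved site/fragment is captured.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str          # IUPAC recognition sequence (palindromic defaults)
    cut_offset: int = 0  # unused for interval arithmetic; kept for reference

    def __post_init__(self):
        if len(self.site) < 4:
            raise ValueError("recognition sequence must be >= 4 bp")

    @property
    def length(self) -> int:
        return len(self.site)

    def regex(self) -> re.Pattern:
        pat = "".join(c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]" for c in self.site.upper())
        return re.compile(f"(?=({pat}))")  # lookahead: overlapping matches


SBFI = Enzyme("SbfI", "CCTGCAGG", 6)
ECORI = Enzyme("EcoRI", "GAATTC", 1)
MSPI = Enzyme("MspI", "CCGG", 1)
SPHI = Enzyme("SphI", "GCATGC", 5)

ENZYMES = {e.name: e for e in (SBFI, ECORI, MSPI, SPHI)}


def find_sites(sequence: str, enzyme: Enzyme, start: int = 0, end: int | None = None) -> np.ndarray:
    """Forward-strand recognition-site start positions within [start, end).

    Palindromic recognition sequences make the forward scan strand
    complete; the site footprint is [p, p + len(site)).
    """
    region = sequence[start:end]
    return np.array(
        [m.start() + start for m in enzyme.regex().finditer(region.upper())],
        dtype=np.int64,
    )


def find_conserved_sites(
    sequence: str,
    fixed_diff_positions,
    enzyme: Enzyme,
    start: int = 0,
    end: int | None = None,
) -> np.ndarray:
    """Recognition sites whose footprint overlaps no interspecies fixed
    difference (a fixed difference inside the site means one species loses
    the site and the locus drops out of the library)."""
    sites = find_sites(sequence, enzyme, start, end)
    if len(sites) == 0:
        return sites
    fd = np.sort(np.asarray(fixed_diff_positions, dtype=np.int64))
    lo = np.searchsorted(fd, sites)
    hi = np.searchsorted(fd, sites + enzyme.length)
    return sites[lo == hi]


def rad_capture_intervals(
    site_start: int,
    site_length: int,
    chrom_length: int,
    read_length: int = 100,
    far_offset: int = 400,
    far_edge: str = "near",
) -> list[tuple[int, int]]:
    """Read footprints for one conserved RAD site (paired-end 2 x read_length).

    Four intervals: read_length immediately upstream and downstream of the
    site footprint, plus the two mate fragments located `far_offset` away on
    either flank.  With ``far_edge="near"`` (default) the mate's near edge
    is `far_offset` from the site; ``"far"`` places its far edge there.
    Intervals are clipped to [0, chrom_length).
    """
    s, e = site_start, site_start + site_length
    if far_edge == "near":
        far_left = (s - far_offset - read_length, s - far_offset)
        far_right = (e + far_offset, e + far_offset + read_length)
    elif far_edge == "far":
        far_left = (s - far_offset, s - far_offset + read_length)
        far_right = (e + far_offset - read_length, e + far_offset)
    else:
        raise ValueError("far_edge must be 'near' or 'far'")
    raw = [(s - read_length, s), (e, e + read_length), far_left, far_right]
    return [
        (max(0, a), min(chrom_length, b))
        for a, b in raw
        if min(chrom_length, b) > max(0, a)
    ]


def rad_design_intervals(
    sequence: str,
    fixed_diff_positions,
    enzyme: Enzyme = SBFI,
    read_length: int = 100,
    far_offset: int = 400,
    region: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """All capture intervals of a single-digest RAD design over a region."""
    start, end = region or (0, len(sequence))
    out = []
    for p in find_conserved_sites(sequence, fixed_diff_positions, enzyme, start, end):
        out.extend(
            rad_capture_intervals(int(p), enzyme.length, len(sequence),
                                  read_length, far_offset)
        )
    return out


def ddrad_fragments(
    sequence: str,
    enz_a: Enzyme,
    enz_b: Enzyme,
    fixed_diff_positions=(),
    size: int = 300,
    tol: int = 36,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Size-selected double-digest fragments bounded by the two enzymes.

    A fragment runs from the start of one conserved recognition site to the
    end of the next conserved site downstream, requires the two bounding
    enzymes to differ, contains no internal cut site of either enzyme (a
    size-selected library cannot contain such molecules), and has length
    within ``size +/- tol``.  Returns columns start, end, left_enzyme,
    right_enzyme.
    """
    if enz_a.name == enz_b.name:
        raise ValueError("double digest requires two different enzymes")
    start, end = region or (0, len(sequence))
    sites = []
    for enz in (enz_a, enz_b):
        for p in find_conserved_sites(sequence, fixed_diff_positions, enz, start, end):
            sites.append((int(p), int(p) + enz.length, enz.name))
    sites.sort()
    rows = []
    for (s1, e1, n1), (s2, e2, n2) in zip(sites, sites[1:]):
        if n1 == n2:
            continue
        if e1 > s2:  # overlapping recognition sites: no clean fragment
            continue
        length = e2 - s1
        if abs(length - size) <= tol:
            rows.append((s1, e2, n1, n2))
    return pd.DataFrame(rows, columns=["start", "end", "left_enzyme", "right_enzyme"])


def ddrad_capture_intervals(fragments: pd.DataFrame, read_length: int = 100) -> list[tuple[int, int]]:
    """Sequenced footprints: read_length inward from both fragment ends."""
    out = []
    for row in fragments.itertuples():
        if row.end - row.start <= 2 * read_length:
            out.append((row.start, row.end))
        else:
            out.append((row.start, row.start + read_length))
            out.append((row.end - read_length, row.end))
    return out


def merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def count_in_intervals(positions, intervals) -> int:
    """Distinct positions covered by >= 1 interval."""
    pos = np.unique(np.asarray(positions, dtype=np.int64))
    if len(pos) == 0:
        return 0
    merged = merge_intervals(intervals)
    if not merged:
        return 0
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    k = np.searchsorted(starts, pos, side="right") - 1
    ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
    return int(ok.sum())


def count_captured(
    tracts: pd.DataFrame,
    reference: dict[str, str],
    diagnostic_sites: pd.DataFrame,
    designs: dict | None = None,
    read_length: int = 100,
    far_offset: int = 400,
    size: int = 300,
    tol: int = 36,
) -> pd.DataFrame:
    """Capture report: diagnostic-SNP counts per tract for each design.

    `designs` maps a column name to either a single enzyme (RAD) or an
    enzyme pair (ddRAD); defaults to the classic SbfI RAD plus EcoRI-MspI
    and SphI-MspI ddRAD designs.  The whole-genome-sequencing column counts
    every B-specific diagnostic SNP in the tract, an upper bound that the
    reduced designs can only stay below.
    """
    if designs is None:
        designs = {
            "RAD_SbfI": SBFI,
            "ddRAD_EcoRI_MspI": (ECORI, MSPI),
            "ddRAD_SphI_MspI": (SPHI, MSPI),
        }
    diag = diagnostic_sites[diagnostic_sites.get("b_specific", True) == True]  # noqa: E712
    rows = []
    for t in tracts.itertuples(index=False):
        seq = reference[t.chrom]
        on = diag[diag["chrom"] == t.chrom]
        fd_all = on["pos"].to_numpy()
        in_tract = fd_all[(fd_all >= t.start) & (fd_all < t.end)]
        row = {"chrom": t.chrom, "start": t.start, "end": t.end, "WGS": len(in_tract)}
        # pad the scanned region so sites just outside still contribute reads
        pad = max(far_offset + read_length, size + tol)
        region = (max(0, t.start - pad), min(len(seq), t.end + pad))
        all_fd = diagnostic_sites[diagnostic_sites["chrom"] == t.chrom]["pos"].to_numpy()
        for name, design in designs.items():
            if isinstance(design, Enzyme):
                ivs = rad_design_intervals(seq, all_fd, design, read_length,
                                           far_offset, region)
            else:
                frags = ddrad_fragments(seq, design[0], design[1], all_fd,
                                        size, tol, region)
                ivs = ddrad_capture_intervals(frags, read_length)
            row[name] = count_in_intervals(in_tract, ivs)
        rows.append(row)
    return pd.DataFrame(rows)
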