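"""Interallelic Ka/Ks by the Nei-Gojobori pathway-counting method.

For a heterozygous individual the two phased haplotype coding sequences of
a gene are compared codon by codon.  Synonymous and nonsynonymous site
counts come from the standard genetic code (per position, the fraction of
the three possible changes that preserve the amino acid; changes creating
a stop count as nonsynonymous).  Codons differing at more than one
position are scored by averaging the synonymous/nonsynonymous step counts
over every shortest mutational pathway, excluding pathways that pass
through a stop codon.  Proportions p = Nd/N and Sd/S receive the
Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

The ratio test for Ka/Ks = 1 is a one-sided codon-based Z-test on
p_N - p_S with binomial variances — an explicit large-sample approximation
of the exact tests found in dedicated phylogenetics suites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import norm

from .panelio import HaplotypePanel

_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def translate_codon(codon: str) -> str:
    return "*" if codon in _STOPS else _CODE[codon]


def is_stop(codon: str) -> bool:
    return codon in _STOPS


@dataclass
class HaplotypeCDS:
    """Two in-frame haplotype coding sequences plus an indel mask."""

    gene_id: str
    seq1: str
    seq2: str
    masked_codons: set = field(default_factory=set)

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2):
            raise ValueError("haplotype sequences differ in length")
        if len(self.seq1) % 3:
            raise ValueError("coding sequence length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codon_pairs(self):
        """(codon1, codon2) for every unmasked codon."""
        for k in range(self.n_codons):
            if k in self.masked_codons:
                continue
            yield self.seq1[3 * k:3 * k + 3], self.seq2[3 * k:3 * k + 3]


@dataclass
class KaKsResult:
    gene_id: str
    N: float
    S: float
    Nd: float
    Sd: float
    ka: float
    ks: float
    ratio: float    # inf when Ks == 0 and Ka > 0
    flagged: bool = False  # JC correction undefined (p >= 3/4)

    def as_row(self) -> dict:
        row = {
            "gene": self.gene_id, "N": self.N, "S": self.S,
            "Nd": self.Nd, "Sd": self.Sd, "Ka": self.ka, "Ks": self.ks,
            "ratio": "inf" if math.isinf(self.ratio) else self.ratio,
        }
        return row


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site fractions of one codon.

    Per position, the three possible single-base changes are classified;
    the synonymous fraction at the position is (# synonymous)/3.  Changes
    producing a stop codon are nonsynonymous.  Totals sum to 3.
    """
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} in coding sequence")
    aa = translate_codon(codon)
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if not is_stop(alt) and translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) substitution counts between two codons.

    Averages over all orderings of the differing positions, dropping
    pathways whose intermediate codons are stops; if every pathway is
    blocked, all are used (so counts are always defined).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        nd = sd = 0.0
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if is_stop(nxt) and nxt != c2:
                blocked = True
            if is_stop(cur) or is_stop(nxt):
                step_syn = False
            else:
                step_syn = translate_codon(cur) == translate_codon(nxt)
            if step_syn:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((nd, sd, blocked))
    open_paths = [(nd, sd) for nd, sd, blocked in paths if not blocked]
    if not open_paths:
        open_paths = [(nd, sd) for nd, sd, _ in paths]
    nd = sum(p[0] for p in open_paths) / len(open_paths)
    sd = sum(p[1] for p in open_paths) / len(open_paths)
    return nd, sd


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 distance; flagged True when the correction is undefined."""
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def nei_gojobori(cds: HaplotypeCDS, site_average: bool = False) -> KaKsResult:
    """Nei-Gojobori Ka/Ks between the two haplotype sequences.

    Site counts N and S are taken on the first haplotype by default (at
    interallelic divergence ~1% the choice is immaterial);
    ``site_average=True`` averages the two.  Identical haplotypes give
    Ka = Ks = 0; Ks = 0 with Ka > 0 reports an infinite ratio.
    """
    N = S = Nd = Sd = 0.0
    for c1, c2 in cds.codon_pairs():
        n1, s1 = codon_site_counts(c1)
        if site_average:
            n2, s2 = codon_site_counts(c2)
            N += (n1 + n2) / 2.0
            S += (s1 + s2) / 2.0
        else:
            N += n1
            S += s1
        nd, sd = codon_path_differences(c1, c2)
        Nd += nd
        Sd += sd
    pn = Nd / N if N else 0.0
    ps = Sd / S if S else 0.0
    ka, flag_n = jukes_cantor(pn)
    ks, flag_s = jukes_cantor(ps)
    if ks == 0.0:
        ratio = 0.0 if ka == 0.0 else float("inf")
    else:
        ratio = ka / ks
    return KaKsResult(cds.gene_id, N, S, Nd, Sd, ka, ks, ratio,
                      flagged=flag_n or flag_s)


def kaks_ratio_test(result: KaKsResult) -> float:
    """One-sided p-value for Ka/Ks > 1 via a codon-based Z-test.

    Z = (p_N - p_S) / sqrt(Var p_N + Var p_S) with binomial variances
    p(1-p)/sites.  Returns 1 when there are no differences at all; 0.5 at
    exact equality of the proportions.
    """
    if result.Nd == 0 and result.Sd == 0:
        return 1.0
    pn = result.Nd / result.N if result.N else 0.0
    ps = result.Sd / result.S if result.S else 0.0
    var = pn * (1 - pn) / result.N + ps * (1 - ps) / result.S
    if var == 0.0:
        return 0.5 if pn == ps else (0.0 if pn > ps else 1.0)
    z = (pn - ps) / math.sqrt(var)
    return float(1.0 - norm.cdf(z))


# ---------------------------------------------------------------------------
# Haplotype CDS reconstruction from phased variants
# ---------------------------------------------------------------------------

def reconstruct_haplotype_cds(
    reference: dict[str, str],
    cds_intervals: pd.DataFrame,
    panel: HaplotypePanel,
    individual: str,
    gene_id: str = "",
) -> HaplotypeCDS:
    """Build the two haplotype coding sequences of one individual.

    `cds_intervals` has columns chrom, start, end, strand (0-based
    half-open; exons of one gene, genomic order).  Phased SNP/MNP alleles
    are substituted per haplotype; codons overlapping an indel allele
    carried by the individual are masked.  A codon containing two or more
    unphased heterozygous SNPs is an error: phase must be supplied, never
    guessed, because the amino-acid outcome depends on it.
    """
    iv = cds_intervals.sort_values("start").reset_index(drop=True)
    chrom = iv.loc[0, "chrom"]
    strand = iv.loc[0, "strand"] if "strand" in iv.columns else "+"
    gpos = np.concatenate([
        np.arange(int(r.start), int(r.end), dtype=np.int64) for r in iv.itertuples()
    ])
    seq = "".join(reference[chrom][int(r.start):int(r.end)] for r in iv.itertuples())
    if strand == "-":
        gpos = gpos[::-1]
        seq = seq.translate(_COMP)[::-1]
    if len(seq) % 3:
        raise ValueError("CDS length not divisible by 3")
    cds_index = {int(p): i for i, p in enumerate(gpos)}

    j = panel.sample_index(individual)
    hap = [list(seq), list(seq)]
    masked: set[int] = set()
    het_codon_positions: dict[int, list[int]] = {}

    lo, hi = int(gpos.min()), int(gpos.max()) + 1
    for i in panel.sites_in_region(chrom, lo, hi):
        a, b = panel.gt[i, j]
        if a < 0 or b < 0 or (a == 0 and b == 0):
            continue
        alleles = panel.alleles[i]
        vt = panel.vtype[i]
        p0 = int(panel.pos[i])
        if vt in ("INS", "DEL"):
            span = max(len(alleles[0]), 1)
            for off in range(span):
                ci = cds_index.get(p0 + off)
                if ci is not None:
                    masked.add(ci // 3)
            continue
        ref_len = len(alleles[0])
        for h, al in ((0, a), (1, b)):
            allele_seq = alleles[al]
            for off in range(ref_len):
                ci = cds_index.get(p0 + off)
                if ci is None:
                    continue
                base = allele_seq[off]
                hap[h][ci] = base.translate(_COMP) if strand == "-" else base
        if a != b and vt == "SNP":
            ci = cds_index.get(p0)
            if ci is not None:
                codon = ci // 3
                het_codon_positions.setdefault(codon, []).append(i)

    for codon, site_rows in het_codon_positions.items():
        if len(site_rows) >= 2 and not all(panel.phased[i, j] for i in site_rows):
            raise ValueError(
                f"codon {codon} holds multiple heterozygous SNPs without phase; "
                "supply phased genotypes"
            )

    return HaplotypeCDS(
        gene_id=gene_id,
        seq1="".join(hap[0]),
        seq2="".join(hap[1]),
        masked_codons=masked,
    )


def kaks_table(results, pvalues=None) -> pd.DataFrame:
    rows = [r.as_row() for r in results]
    df = pd.DataFrame(rows)
    if pvalues is not None:
        df["p_value"] = pvalues
    return df
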