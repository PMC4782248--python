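"""Genotype-panel containers and VCF / FASTA / BED / table I/O.

All internal coordinates are 0-based half-open.  Conversion to the 1-based
VCF convention (and back) happens only inside the readers and writers in
this module, so the rest of the package never has to think about it.

The central container is :class:`HaplotypePanel`: a site-by-individual
matrix of (possibly phased) diploid genotypes with per-site read depth and
a population label per individual.  It deliberately mirrors how the data
arrive from a joint-genotyped VCF rather than any particular analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

MISSING = -1

# variant type codes used in the VT INFO field
VTYPES = ("SNP", "INS", "DEL", "MNP")


@dataclass
class HaplotypePanel:
    """Diploid genotypes for a set of individuals at a set of sites.

    Attributes
    ----------
    samples : list of str
        Ordered individual identifiers (column order of the matrices).
    populations : dict
        Maps individual id to a population/species label.
    chrom : ndarray of str, shape (S,)
    pos : ndarray of int, shape (S,)
        0-based site positions (left-most reference base for indels/MNPs).
    alleles : list of tuple of str
        Per site, ``(ref, alt1, ...)``; genotype codes index into this.
    gt : ndarray of int8, shape (S, N, 2)
        Allele indices, ``-1`` for missing.
    phased : ndarray of bool, shape (S, N)
    dp : ndarray of int32, shape (S, N)
        Per-site per-individual read depth.
    vtype : ndarray of str, shape (S,)
        One of ``SNP``, ``INS``, ``DEL``, ``MNP``.
    """

    samples: list[str]
    populations: dict[str, str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: list[tuple[str, ...]]
    gt: np.ndarray
    phased: np.ndarray
    dp: np.ndarray
    vtype: np.ndarray = None

    def __post_init__(self):
        if self.vtype is None:
            self.vtype = np.array(["SNP"] * self.n_sites, dtype=object)
        if self.gt.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, individual: str) -> int:
        try:
            return self.samples.index(individual)
        except ValueError:
            raise KeyError(f"individual {individual!r} not in panel") from None

    def population_samples(self, label: str) -> list[str]:
        return [s for s in self.samples if self.populations.get(s) == label]

    def subset_samples(self, ids) -> "HaplotypePanel":
        idx = [self.sample_index(s) for s in ids]
        return HaplotypePanel(
            samples=list(ids),
            populations={s: self.populations.get(s, "") for s in ids},
            chrom=self.chrom,
            pos=self.pos,
            alleles=self.alleles,
            gt=self.gt[:, idx, :],
            phased=self.phased[:, idx],
            dp=self.dp[:, idx],
            vtype=self.vtype,
        )

    def subset_sites(self, index) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            samples=self.samples,
            populations=self.populations,
            chrom=self.chrom[index],
            pos=self.pos[index],
            alleles=[self.alleles[i] for i in index],
            gt=self.gt[index],
            phased=self.phased[index],
            dp=self.dp[index],
            vtype=self.vtype[index],
        )

    def sites_in_region(self, chrom: str, start: int = 0, end: int | None = None) -> np.ndarray:
        """Indices of sites on `chrom` with start <= pos < end."""
        sel = self.chrom == chrom
        sel &= self.pos >= start
        if end is not None:
            sel &= self.pos < end
        return np.flatnonzero(sel)


def coverage_mask(panel: HaplotypePanel, low: int = 20, high: int = 200) -> np.ndarray:
    """Validated-site mask: True where every individual has depth in [low, high].

    Both bounds are inclusive.  Returns a boolean array aligned to
    ``panel.pos``.
    """
    dp = panel.dp
    return np.logical_and(dp >= low, dp <= high).all(axis=1)


@dataclass
class CallableTrack:
    """Genome-wide per-position validated-site indicator.

    One boolean array per chromosome: True where all analysed individuals
    hold read depth inside the coverage band.  Variant-site masks from the
    VCF DP fields agree with this track by construction in the simulator;
    for real data the track would come from per-position depth extraction.
    """

    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def count(self, chrom: str, start: int = 0, end: int | None = None) -> int:
        a = self.arrays[chrom]
        return int(a[start:end].sum())

    def fraction(self, chrom: str, start: int = 0, end: int | None = None) -> float:
        a = self.arrays[chrom][start:end]
        return float(a.mean()) if len(a) else float("nan")

    def chrom_length(self, chrom: str) -> int:
        return len(self.arrays[chrom])

    def to_bed(self, path) -> None:
        """Write callable runs as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom, a in self.arrays.items():
                # run-length encode
                padded = np.concatenate([[False], a, [False]])
                flips = np.flatnonzero(padded[1:] != padded[:-1])
                for s, e in zip(flips[::2], flips[1::2]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    @classmethod
    def from_bed(cls, path, chrom_lengths: dict[str, int]) -> "CallableTrack":
        arrays = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, s, e = line.split()[:3]
                arrays[chrom][int(s):int(e)] = True
        return cls(arrays)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(panel: HaplotypePanel, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the panel as a VCF 4.2 text file with GT and DP per sample.

    Output ordering is deterministic: sites are emitted in stored order,
    samples in panel order.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, n in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={n}>\n")
        else:
            for c in dict.fromkeys(panel.chrom.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for i in range(panel.n_sites):
            ref = panel.alleles[i][0]
            alts = panel.alleles[i][1:]
            alt_field = ",".join(alts) if alts else "."
            cols = [
                str(panel.chrom[i]),
                str(int(panel.pos[i]) + 1),
                ".",
                ref,
                alt_field,
                ".",
                "PASS",
                f"VT={panel.vtype[i]}",
                "GT:DP",
            ]
            for j in range(panel.n_samples):
                a, b = panel.gt[i, j]
                sep = "|" if panel.phased[i, j] else "/"
                g = "./." if a < 0 or b < 0 else f"{a}{sep}{b}"
                cols.append(f"{g}:{panel.dp[i, j]}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path, populations: dict[str, str] | None = None) -> HaplotypePanel:
    """Read a VCF (GT, optionally DP) into a :class:`HaplotypePanel`.

    VCF 1-based positions become 0-based internally.  Missing genotypes
    become ``-1``; missing DP becomes 0.  Multiallelic records are kept
    with their full allele lists.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chroms, poss, alleles, vtypes = [], [], [], []
    gts, phs, dps = [], [], []
    for rec in vf.fetch() if vf.index is not None else vf:
        chroms.append(rec.chrom)
        poss.append(rec.pos - 1)
        alts = tuple(a for a in (rec.alts or ()) if a is not None)
        alleles.append((rec.ref,) + alts)
        vtypes.append(rec.info.get("VT", _infer_vtype(rec.ref, alts)))
        grow, prow, drow = [], [], []
        for s in samples:
            call = rec.samples[s]
            g = call.get("GT")
            if g is None or len(g) != 2 or g[0] is None or g[1] is None:
                grow.append((MISSING, MISSING))
            else:
                grow.append((g[0], g[1]))
            prow.append(bool(call.phased))
            d = call.get("DP")
            drow.append(0 if d is None else int(d))
        gts.append(grow)
        phs.append(prow)
        dps.append(drow)
    vf.close()
    n = len(poss)
    return HaplotypePanel(
        samples=samples,
        populations=populations or {s: "" for s in samples},
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        alleles=alleles,
        gt=np.array(gts, dtype=np.int8).reshape(n, len(samples), 2),
        phased=np.array(phs, dtype=bool).reshape(n, len(samples)),
        dp=np.array(dps, dtype=np.int32).reshape(n, len(samples)),
        vtype=np.array(vtypes, dtype=object),
    )


def _infer_vtype(ref: str, alts) -> str:
    if all(len(a) == len(ref) == 1 for a in alts):
        return "SNP"
    if all(len(a) == len(ref) for a in alts):
        return "MNP" if len(ref) > 1 else "SNP"
    if any(len(a) > len(ref) for a in alts):
        return "INS"
    return "DEL"


# ---------------------------------------------------------------------------
# FASTA / tables / BED
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_samples_table(populations: dict[str, str], path) -> None:
    pd.DataFrame(
        {"individual": list(populations), "population": list(populations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_samples_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["individual"].astype(str), df["population"].astype(str)))


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end")) -> None:
    """Write interval table as headerless BED (0-based half-open)."""
    extra = [c for c in df.columns if c not in columns]
    df[list(columns) + extra].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, names=("chrom", "start", "end"), extra_names=()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = list(names) + list(extra_names)
    df.columns = cols[: df.shape[1]] + [f"col{i}" for i in range(df.shape[1] - len(cols))] \
        if df.shape[1] > len(cols) else cols[: df.shape[1]]
    return df
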