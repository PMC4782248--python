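"""Species-diagnostic site discovery, outgroup polarization and genotype
classification.

The detection logic is deliberately rule based.  A site is diagnostic when
it is fixed for different alleles in the two species reference panels; it
is *B-specific* when the outgroup carries the species-A allele, i.e. the
mutation arose on the species-B lineage.  Each focal individual is then
classified at every B-specific site as homozygous-A, heterozygous, or
homozygous-B — the raw material for the sliding-window tract scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panelio import HaplotypePanel

# genotype class codes
HOM_A, HET, HOM_B, MISS = 0, 1, 2, 3
CLASS_NAMES = {HOM_A: "homA", HET: "het", HOM_B: "homB", MISS: "missing"}

POLARITY_B = "B"          # mutation on species-B lineage (B-specific allele)
POLARITY_A = "A"          # mutation on species-A lineage
POLARITY_NONE = "uninformative"


def _fixed_allele(panel: HaplotypePanel) -> np.ndarray:
    """Per site: the single allele index fixed across the panel, else -1.

    Sites with any missing genotype or more than one allele are -1.
    """
    flat = panel.gt.reshape(panel.n_sites, 2 * panel.n_samples)
    first = flat[:, 0]
    fixed = (flat == first[:, None]).all(axis=1) & (first >= 0)
    return np.where(fixed, first, -1).astype(np.int64)


def find_fixed_differences(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    mask: np.ndarray | None = None,
    exclude_chroms=(),
) -> pd.DataFrame:
    """Sites fixed for different alleles in the two species panels.

    The two panels must be row-aligned on the same site list (the usual
    case: both are sample subsets of one joint-genotyped panel).  Only
    SNP-type sites are eligible.  Sites on `exclude_chroms` (e.g. sex
    chromosomes, where intraspecies X/Y divergence confounds fixity) are
    dropped.

    Returns a DiagnosticSiteTable-shaped frame with columns
    chrom, pos, allele_A, allele_B, plus empty polarity columns to be
    filled by :func:`polarize`.
    """
    if panel_a.n_samples == 0 or panel_b.n_samples == 0:
        raise ValueError("species panels must contain at least one individual")
    if panel_a.n_sites != panel_b.n_sites or not np.array_equal(panel_a.pos, panel_b.pos):
        raise ValueError("panels must share one site coordinate space")

    fa = _fixed_allele(panel_a)
    fb = _fixed_allele(panel_b)
    keep = (fa >= 0) & (fb >= 0) & (fa != fb)
    keep &= panel_a.vtype == "SNP"
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if exclude_chroms:
        keep &= ~np.isin(panel_a.chrom, list(exclude_chroms))

    idx = np.flatnonzero(keep)
    table = pd.DataFrame(
        {
            "chrom": panel_a.chrom[idx],
            "pos": panel_a.pos[idx],
            "allele_A": [panel_a.alleles[i][fa[i]] for i in idx],
            "allele_B": [panel_a.alleles[i][fb[i]] for i in idx],
            "site_index": idx,
        }
    )
    table["allele_out"] = ""
    table["polarity"] = POLARITY_NONE
    table["b_specific"] = False
    return table.reset_index(drop=True)


def polarize(table: pd.DataFrame, outgroup: HaplotypePanel) -> pd.DataFrame:
    """Assign each fixed difference to the lineage on which it arose.

    The outgroup panel must be site-aligned with the panels used for
    discovery (``site_index`` indexes into it).  A site is B-specific iff
    the outgroup is monomorphic for the species-A allele; if the outgroup
    matches the species-B allele the mutation is on the A lineage; missing,
    polymorphic or third-allele outgroup states identify neither lineage
    and stay uninformative.
    """
    table = table.copy()
    fo = _fixed_allele(outgroup)
    out_allele = []
    polarity = []
    for row in table.itertuples():
        i = row.site_index
        if fo[i] < 0:
            out_allele.append("")
            polarity.append(POLARITY_NONE)
            continue
        allele = outgroup.alleles[i][fo[i]]
        out_allele.append(allele)
        if allele == row.allele_A:
            polarity.append(POLARITY_B)
        elif allele == row.allele_B:
            polarity.append(POLARITY_A)
        else:
            polarity.append(POLARITY_NONE)
    table["allele_out"] = out_allele
    table["polarity"] = polarity
    table["b_specific"] = [p == POLARITY_B for p in polarity]
    return table


@dataclass
class GenotypeClassTrack:
    """Per-individual genotype classes at B-specific diagnostic sites."""

    sites: pd.DataFrame          # chrom, pos, allele_A, allele_B (B-specific only)
    samples: list[str]
    classes: np.ndarray          # (n_sites, n_samples) int8 codes

    def for_individual(self, individual: str) -> np.ndarray:
        return self.classes[:, self.samples.index(individual)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: chrom, pos, individual, class (BED-graph-like)."""
        rows = []
        for j, s in enumerate(self.samples):
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": self.sites["chrom"].to_numpy(),
                        "pos": self.sites["pos"].to_numpy(),
                        "individual": s,
                        "class": [CLASS_NAMES[c] for c in self.classes[:, j]],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def classify(panel: HaplotypePanel, table: pd.DataFrame) -> GenotypeClassTrack:
    """Classify each panel individual at every B-specific diagnostic site.

    homA iff both alleles equal allele_A; homB iff both equal allele_B;
    het iff one of each; anything else (missing or a third allele) is
    recorded as missing.
    """
    bsites = table[table["b_specific"].astype(bool)].reset_index(drop=True)
    n_sites = len(bsites)
    classes = np.full((n_sites, panel.n_samples), MISS, dtype=np.int8)
    for k, row in enumerate(bsites.itertuples()):
        i = row.site_index
        alleles = panel.alleles[i]
        try:
            ia = alleles.index(row.allele_A)
            ib = alleles.index(row.allele_B)
        except ValueError:
            continue
        g = panel.gt[i]
        is_a = g == ia
        is_b = g == ib
        classes[k, is_a.all(axis=1)] = HOM_A
        classes[k, is_b.all(axis=1)] = HOM_B
        classes[k, (is_a.any(axis=1) & is_b.any(axis=1))] = HET
    return GenotypeClassTrack(
        sites=bsites[["chrom", "pos", "allele_A", "allele_B"]].copy(),
        samples=list(panel.samples),
        classes=classes,
    )


def write_diagnostic_table(table: pd.DataFrame, path) -> None:
    cols = ["chrom", "pos", "allele_A", "allele_B", "allele_out", "polarity", "b_specific"]
    table[cols].to_csv(path, sep="\t", index=False)
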