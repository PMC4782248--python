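import numpy as np
import pytest

from introscan.panelio import HaplotypePanel
from introscan.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def megabase_bundle():
    """1 Mb two-chromosome bundle with one planted heterozygous tract."""
    cfg = SimulationConfig(
        seed=11,
        chrom_lengths=[("chrI", 1_000_000), ("chrW", 200_000)],
        tracts=[("chrI", 400_000, 480_000, ("T1", "T2", "T3"), "het")],
        excluded_chroms=("chrW",),
    )
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free 500 kb bundle: no dropout, no indels, planted het tract."""
    cfg = SimulationConfig(
        seed=5,
        chrom_lengths=[("chrI", 500_000)],
        tracts=[("chrI", 150_000, 230_000, ("T1",), "het")],
        dropout_rate=0.0,
        indel_rate=0.0,
        mnp_rate=0.0,
    )
    return simulate_bundle(cfg)


def toy_panel(genotypes, alleles=None, pops=None, depths=None, pos=None,
              chrom="chrI", phased=True, vtype=None):
    """Hand-rolled panel: `genotypes` is a list (site) of lists (sample) of
    (a, b) allele-index pairs."""
    gt = np.array(genotypes, dtype=np.int8)
    n_sites, n_samples = gt.shape[:2]
    samples = [f"S{i + 1}" for i in range(n_samples)]
    if alleles is None:
        alleles = [("G", "T", "C", "A")[:4]] * n_sites
    if depths is None:
        depths = np.full((n_sites, n_samples), 50, dtype=np.int32)
    if pos is None:
        pos = np.arange(n_sites, dtype=np.int64) * 100
    return HaplotypePanel(
        samples=samples,
        populations=pops or {s: "" for s in samples},
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        alleles=[tuple(a) for a in alleles],
        gt=gt,
        phased=np.full((n_sites, n_samples), phased, dtype=bool),
        dp=np.asarray(depths, dtype=np.int32),
        vtype=np.array(vtype or ["SNP"] * n_sites, dtype=object),
    )
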