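"""Synthetic two-species resequencing panels with planted introgression.

The generator emulates the statistical structure a rule-based introgression
scan consumes, without coalescent machinery:

* a reference genome belonging to species A;
* species B diverged by a configurable per-bp substitution probability
  (default 0.0144, the interspecies scale typical of a few-My-old
  stickleback species pair), under an infinite-sites model on uniformly
  drawn positions;
* an outgroup lineage carrying its own branch substitutions, so that the
  lineage on which each fixed difference arose is well defined;
* a focal freshwater-like population and an anadromous-like comparison
  population with per-bp heterozygous-site proportions near 1.5e-3 and
  3.1e-3 respectively;
* planted introgression tracts (10 kb - 500 kb) carried by chosen focal or
  comparison individuals in heterozygous or homozygous state;
* per-site per-individual read depth ~ round(Normal(mean, sd)) with a
  dropout fraction forced below the coverage band, plus a genome-wide
  callable track consistent with the same depth model;
* a spatially varying recombination map emitted as noisy rate observations
  around piecewise-linear knots.

Everything flows from one seed through `numpy.random.default_rng`
substreams, so identical configs give byte-identical output bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panelio import (
    CallableTrack,
    HaplotypePanel,
    write_bed,
    write_fasta,
    write_samples_table,
    write_vcf,
)

BASES = np.array(["A", "C", "G", "T"])

POP_SPECIES_A = "species_a"
POP_SPECIES_B = "species_b"
POP_OUTGROUP = "outgroup"
POP_FOCAL = "focal"
POP_COMPARISON = "comparison"

# mean of 2q(1-q) for q ~ Uniform(0.1, 0.9); converts a target per-bp
# heterozygous-site proportion into a per-bp polymorphic-site rate
_MEAN_HET_PER_POLY = 2 * (0.5 - (0.9**3 - 0.1**3) / (3 * 0.8))


@dataclass
class TractSpec:
    """A planted introgression tract carried by named individuals."""

    chrom: str
    start: int
    end: int
    carriers: tuple[str, ...]
    zygosity: str  # "het" or "hom"

    def __post_init__(self):
        self.carriers = tuple(self.carriers)
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be 'het' or 'hom', got {self.zygosity!r}")
        if self.end <= self.start:
            raise ValueError("tract end must exceed start")


@dataclass
class PanelSizes:
    species_a: int = 10
    species_b: int = 10
    outgroup: int = 2
    focal: int = 4
    comparison: int = 4


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: list = field(default_factory=lambda: [("chrI", 1_000_000)])
    interspecies_div: float = 0.0144
    outgroup_extra_div: float = 0.01
    b_lineage_fraction: float = 0.5
    pi_focal: float = 1.5e-3
    pi_anadromous: float = 3.1e-3
    panel_sizes: PanelSizes = field(default_factory=PanelSizes)
    tracts: list = field(default_factory=list)
    coverage_mean: float = 50.0
    coverage_sd: float = 10.0
    dropout_rate: float = 0.01
    diag_leak_rate: float = 0.0
    indel_rate: float = 5e-6
    mnp_rate: float = 5e-6
    recomb_profile: list | None = None
    map_obs_spacing: int = 100_000
    map_noise_sd: float = 0.3
    excluded_chroms: tuple = ()

    def __post_init__(self):
        self.chrom_lengths = [(str(c), int(n)) for c, n in self.chrom_lengths]
        self.tracts = [t if isinstance(t, TractSpec) else TractSpec(*t) for t in self.tracts]
        if isinstance(self.panel_sizes, dict):
            self.panel_sizes = PanelSizes(**self.panel_sizes)
        self.excluded_chroms = tuple(self.excluded_chroms)
        self.validate()

    def validate(self) -> None:
        lens = dict(self.chrom_lengths)
        for p in (self.interspecies_div, self.outgroup_extra_div, self.b_lineage_fraction,
                  self.dropout_rate, self.diag_leak_rate, self.pi_focal, self.pi_anadromous,
                  self.indel_rate, self.mnp_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability parameter out of [0,1]: {p}")
        for k, v in dataclasses.asdict(self.panel_sizes).items():
            if v < 1:
                raise ValueError(f"panel size {k} must be >= 1")
        for t in self.tracts:
            if t.chrom not in lens:
                raise ValueError(f"tract chromosome {t.chrom!r} not in chrom_lengths")
            if not (0 <= t.start < t.end <= lens[t.chrom]):
                raise ValueError(f"tract {t} outside chromosome bounds")
        # conflicting zygosity for overlapping tracts on the same carrier
        by_carrier: dict[tuple, list[TractSpec]] = {}
        for t in self.tracts:
            for c in t.carriers:
                by_carrier.setdefault((t.chrom, c), []).append(t)
        for (_, carrier), ts in by_carrier.items():
            ts = sorted(ts, key=lambda t: t.start)
            for a, b in zip(ts, ts[1:]):
                if b.start < a.end and a.zygosity != b.zygosity:
                    raise ValueError(
                        f"overlapping tracts with conflicting zygosity for carrier {carrier!r}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def sample_names(self) -> dict[str, str]:
        """Ordered individual id -> population label mapping."""
        ps = self.panel_sizes
        names: dict[str, str] = {}
        for i in range(ps.species_a):
            names[f"A{i + 1}"] = POP_SPECIES_A
        for i in range(ps.species_b):
            names[f"B{i + 1}"] = POP_SPECIES_B
        for i in range(ps.outgroup):
            names[f"OUT{i + 1}"] = POP_OUTGROUP
        for i in range(ps.focal):
            names[f"T{i + 1}"] = POP_FOCAL
        for i in range(ps.comparison):
            names[f"C{i + 1}"] = POP_COMPARISON
        return names


@dataclass
class TruthSet:
    """Machine-readable ground truth for parameter-recovery tests."""

    tracts: pd.DataFrame          # chrom, start, end, carriers, zygosity
    diagnostic_sites: pd.DataFrame  # chrom, pos, allele_A, allele_B, allele_out, b_specific
    panel: HaplotypePanel         # truth-phased genotypes


@dataclass
class Bundle:
    config: SimulationConfig
    reference: dict[str, str]
    panel: HaplotypePanel
    callable_track: CallableTrack
    recomb_map: pd.DataFrame      # chrom, pos, rate_cM_Mb
    truth: TruthSet

    def write(self, outdir, callable_bed: bool = False) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, out / "reference.fa")
        write_vcf(self.panel, out / "panel.vcf", dict(self.config.chrom_lengths))
        write_samples_table(self.panel.populations, out / "samples.tsv")
        self.recomb_map.to_csv(out / "recomb_map.tsv", sep="\t", index=False)
        truth = self.truth.tracts.copy()
        truth["carriers"] = truth["carriers"].map(",".join)
        write_bed(truth, out / "truth_tracts.bed")
        self.truth.diagnostic_sites.to_csv(out / "truth_diagnostic_sites.tsv",
                                           sep="\t", index=False)
        if callable_bed:
            self.callable_track.to_bed(out / "callable.bed")
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config": _config_dict(self.config)}, fh, indent=2, default=str)


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tracts"] = [dataclasses.asdict(t) for t in config.tracts]
    return d


def _draw_positions(rng, n, length, used):
    """Draw n unused positions uniformly (infinite-sites: no collisions)."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    free = np.flatnonzero(~used)
    n = min(n, len(free))
    pos = rng.choice(free, size=n, replace=False)
    used[pos] = True
    return np.sort(pos)


def _other_base(rng, current):
    """For each current base index, draw a different base index."""
    shift = rng.integers(1, 4, size=len(current))
    return (current + shift) % 4


class _SiteBuffer:
    """Accumulates per-chromosome variant sites before matrix assembly."""

    def __init__(self):
        self.pos: list[int] = []
        self.alleles: list[tuple[str, ...]] = []
        self.vtype: list[str] = []
        self.geno: list[dict[int, tuple[int, int]]] = []  # sample idx -> (a, b)

    def add(self, pos, alleles, vtype, geno):
        self.pos.append(int(pos))
        self.alleles.append(tuple(alleles))
        self.vtype.append(vtype)
        self.geno.append(geno)


def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Generate reference, joint panel, coverage, recombination map and truth."""
    rng_master = np.random.default_rng(config.seed)
    streams = {
        name: np.random.default_rng(seed)
        for name, seed in zip(
            ["ref", "div", "poly", "cov", "map", "extra"],
            rng_master.integers(0, 2**31 - 1, size=6),
        )
    }
    names = config.sample_names()
    samples = list(names)
    n_samples = len(samples)
    sidx = {s: i for i, s in enumerate(samples)}
    pop_members = {}
    for s, p in names.items():
        pop_members.setdefault(p, []).append(sidx[s])

    pi_by_pop = {
        POP_FOCAL: config.pi_focal,
        POP_COMPARISON: config.pi_anadromous,
    }

    reference: dict[str, str] = {}
    callable_arrays: dict[str, np.ndarray] = {}
    map_rows = []
    all_chrom, all_pos, all_alleles, all_vtype = [], [], [], []
    gt_blocks, diag_rows = [], []

    # per-site probability that one individual's depth is inside the band,
    # used for the callable state of invariant positions
    from scipy.stats import norm

    band = norm.cdf((200.5 - config.coverage_mean) / config.coverage_sd) - \
        norm.cdf((19.5 - config.coverage_mean) / config.coverage_sd)
    p_pass_site = ((1.0 - config.dropout_rate) * band) ** n_samples

    for chrom, length in config.chrom_lengths:
        ref_idx = streams["ref"].integers(0, 4, size=length, dtype=np.int8)
        reference[chrom] = "".join(BASES[ref_idx])
        used = np.zeros(length, dtype=bool)
        buf = _SiteBuffer()

        # --- interspecies fixed differences -------------------------------
        rng = streams["div"]
        n_div = rng.binomial(length, config.interspecies_div)
        dpos = _draw_positions(rng, n_div, length, used)
        a_idx = ref_idx[dpos].astype(np.int64)
        b_idx = _other_base(rng, a_idx)
        on_b = rng.random(len(dpos)) < config.b_lineage_fraction
        # mutation on B branch: outgroup retains the A allele; on A branch the
        # reference (A) allele is derived and B shares the ancestral state
        # with the outgroup
        out_idx = np.where(on_b, a_idx, b_idx)
        out_extra = rng.random(len(dpos)) < config.outgroup_extra_div
        out_idx[out_extra] = _other_base(rng, out_idx[out_extra])

        leak = config.diag_leak_rate
        n_chrom_panels = 2 * (config.panel_sizes.species_a + config.panel_sizes.species_b)
        for k in range(len(dpos)):
            a, b, o = BASES[a_idx[k]], BASES[b_idx[k]], BASES[out_idx[k]]
            alleles = [a, b] if o in (a, b) else [a, b, o]
            geno: dict[int, tuple[int, int]] = {}
            for j in pop_members.get(POP_SPECIES_B, []):
                geno[j] = (1, 1)
            oi = alleles.index(o)
            for j in pop_members.get(POP_OUTGROUP, []):
                geno[j] = (oi, oi)
            if leak > 0.0:
                n_leak = rng.binomial(n_chrom_panels, leak)
                for _ in range(n_leak):
                    c = int(rng.integers(0, n_chrom_panels))
                    na = config.panel_sizes.species_a * 2
                    if c < na:  # species-A chromosome picks up the B allele
                        j = pop_members[POP_SPECIES_A][c // 2]
                        g = list(geno.get(j, (0, 0)))
                        g[c % 2] = 1
                    else:
                        j = pop_members[POP_SPECIES_B][(c - na) // 2]
                        g = list(geno.get(j, (1, 1)))
                        g[(c - na) % 2] = 0
                    geno[j] = tuple(g)
            buf.add(dpos[k], alleles, "SNP", geno)
            diag_rows.append((chrom, int(dpos[k]), a, b, o, bool(o == a)))

        diag_pos_set = dpos
        diag_b_allele_index = np.ones(len(dpos), dtype=np.int8)  # allele 1 is B

        # --- outgroup-private substitutions --------------------------------
        rng = streams["extra"]
        n_out = rng.binomial(length, config.outgroup_extra_div)
        opos = _draw_positions(rng, n_out, length, used)
        o_der = _other_base(rng, ref_idx[opos].astype(np.int64))
        for k in range(len(opos)):
            geno = {j: (1, 1) for j in pop_members.get(POP_OUTGROUP, [])}
            buf.add(opos[k], [BASES[ref_idx[opos[k]]], BASES[o_der[k]]], "SNP", geno)

        # --- within-population polymorphism --------------------------------
        rng = streams["poly"]
        for pop, pi in pi_by_pop.items():
            members = pop_members.get(pop, [])
            if not members or pi == 0.0:
                continue
            rate = pi / _MEAN_HET_PER_POLY
            n_poly = rng.binomial(length, min(rate, 1.0))
            ppos = _draw_positions(rng, n_poly, length, used)
            der = _other_base(rng, ref_idx[ppos].astype(np.int64))
            q = rng.uniform(0.1, 0.9, size=len(ppos))
            hap = rng.random((len(ppos), len(members), 2)) < q[:, None, None]
            seg = hap.any(axis=(1, 2))  # drop sites with no derived copy drawn
            for k in np.flatnonzero(seg):
                geno = {
                    j: (int(hap[k, m, 0]), int(hap[k, m, 1]))
                    for m, j in enumerate(members)
                }
                buf.add(ppos[k], [BASES[ref_idx[ppos[k]]], BASES[der[k]]], "SNP", geno)

        # --- indels and MNPs (exercise the amplicon SNP filters) ------------
        rng = streams["extra"]
        targets = pop_members.get(POP_FOCAL, []) + pop_members.get(POP_COMPARISON, [])
        for vt, rate in (("INS", config.indel_rate), ("DEL", config.indel_rate),
                         ("MNP", config.mnp_rate)):
            n_v = rng.binomial(length, rate)
            for _ in range(n_v):
                span = 1 if vt == "INS" else int(rng.integers(2, 4))
                start = int(rng.integers(0, length - span))
                if used[start:start + span].any():
                    continue
                used[start:start + span] = True
                refseq = reference[chrom][start:start + span]
                if vt == "INS":
                    alt = refseq + "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
                elif vt == "DEL":
                    alt = refseq[0]
                else:
                    alt = "".join(
                        BASES[(np.array([BASES.tolist().index(c) for c in refseq])
                               + rng.integers(1, 4, size=span)) % 4]
                    )
                q = rng.uniform(0.1, 0.5)
                geno = {}
                for j in targets:
                    g = (int(rng.random() < q), int(rng.random() < q))
                    if g != (0, 0):
                        geno[j] = g
                if geno:
                    buf.add(start, [refseq, alt], vt, geno)

        # --- assemble per-chromosome matrices -------------------------------
        order = np.argsort(np.array(buf.pos, dtype=np.int64), kind="stable")
        pos_arr = np.array(buf.pos, dtype=np.int64)[order]
        gt = np.zeros((len(order), n_samples, 2), dtype=np.int8)
        for row, k in enumerate(order):
            for j, (a, b) in buf.geno[k].items():
                gt[row, j] = (a, b)
        all_chrom.append(np.array([chrom] * len(order), dtype=object))
        all_pos.append(pos_arr)
        all_alleles.extend(buf.alleles[k] for k in order)
        all_vtype.append(np.array(buf.vtype, dtype=object)[order])
        gt_blocks.append(gt)

        # --- planted tracts -------------------------------------------------
        for t in config.tracts:
            if t.chrom != chrom:
                continue
            in_tract = np.flatnonzero(
                (pos_arr >= t.start) & (pos_arr < t.end)
                & np.isin(pos_arr, diag_pos_set)
            )
            for carrier in t.carriers:
                j = sidx[carrier]
                for row in in_tract:
                    if t.zygosity == "hom":
                        gt[row, j] = (1, 1)
                    else:
                        gt[row, j] = (1, 0)  # B allele on the first haplotype

        # --- callable state for invariant positions -------------------------
        rng = streams["cov"]
        callable_arrays[chrom] = rng.random(length) < p_pass_site

        # --- recombination map observations ---------------------------------
        rng = streams["map"]
        profile = config.recomb_profile or [
            (0, 3.0), (length // 2, 1.0), (length - 1, 5.0)
        ]
        knots_x = np.array([p for p, _ in profile], dtype=float)
        knots_y = np.array([r for _, r in profile], dtype=float)
        obs_x = np.arange(0, length, config.map_obs_spacing, dtype=float)
        obs_y = np.interp(obs_x, knots_x, knots_y)
        obs_y = np.maximum(obs_y + rng.normal(0, config.map_noise_sd, size=len(obs_x)), 0.0)
        for x, y in zip(obs_x, obs_y):
            map_rows.append((chrom, int(x), float(y)))

    chrom_arr = np.concatenate(all_chrom) if all_chrom else np.empty(0, dtype=object)
    pos_arr = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
    gt = np.concatenate(gt_blocks) if gt_blocks else np.zeros((0, n_samples, 2), np.int8)
    vtype_arr = np.concatenate(all_vtype) if all_vtype else np.empty(0, dtype=object)

    # depth: normal draws, rounded, with dropout forced below the band
    rng = streams["cov"]
    dp = np.rint(
        rng.normal(config.coverage_mean, config.coverage_sd, size=gt.shape[:2])
    ).astype(np.int32)
    np.clip(dp, 0, None, out=dp)
    drop = rng.random(gt.shape[:2]) < config.dropout_rate
    dp[drop] = rng.integers(0, 20, size=int(drop.sum()), dtype=np.int32)

    panel = HaplotypePanel(
        samples=samples,
        populations=names,
        chrom=chrom_arr,
        pos=pos_arr,
        alleles=all_alleles,
        gt=gt,
        phased=np.ones(gt.shape[:2], dtype=bool),
        dp=dp,
        vtype=vtype_arr,
    )

    # reconcile the callable track with the emitted depths at variant sites
    in_band = np.logical_and(dp >= 20, dp <= 200).all(axis=1)
    for chrom, _ in config.chrom_lengths:
        on = chrom_arr == chrom
        callable_arrays[chrom][pos_arr[on]] = in_band[on]

    truth_tracts = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.carriers, t.zygosity) for t in config.tracts],
        columns=["chrom", "start", "end", "carriers", "zygosity"],
    )
    diag = pd.DataFrame(
        diag_rows,
        columns=["chrom", "pos", "allele_A", "allele_B", "allele_out", "b_specific"],
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    return Bundle(
        config=config,
        reference=reference,
        panel=panel,
        callable_track=CallableTrack(callable_arrays),
        recomb_map=pd.DataFrame(map_rows, columns=["chrom", "pos", "rate_cM_Mb"]),
        truth=TruthSet(tracts=truth_tracts, diagnostic_sites=diag, panel=panel),
    )


# ---------------------------------------------------------------------------
# Haplotype panel for LD-decay studies
# ---------------------------------------------------------------------------

def simulate_ld_panel(
    seed: int,
    n_markers_inside: int = 10,
    n_markers_outside: int = 14,
    n_individuals: int = 48,
    generations: int = 10,
    pop_size: int = 200,
    intro_freq: float = 0.3,
    spacing_cM: float = 0.4,
):
    """Forward-simulate phased marker haplotypes around a recent introgression.

    Markers inside the introgressed zone start on a single donor haplotype at
    frequency `intro_freq` (complete LD, the state right after the
    introgression event); markers outside start at linkage equilibrium.
    `generations` rounds of Wright-Fisher random mating with recombination at
    the map distance between adjacent markers then erode LD, so pairwise D'
    inside the zone decays like (1-theta)^t while outside pairs show only
    drift-level association.

    Returns ``(positions_cM, haplotypes, zone)`` where `haplotypes` has shape
    (2*n_individuals, n_markers) and `zone` is the (start, end) marker-index
    interval of the introgressed region.
    """
    rng = np.random.default_rng(seed)
    m = n_markers_inside + n_markers_outside
    pos_cM = np.arange(m) * spacing_cM
    zone = (0, n_markers_inside)

    n_hap = 2 * pop_size
    hap = np.zeros((n_hap, m), dtype=np.int8)
    n_intro = int(round(intro_freq * n_hap))
    hap[:n_intro, zone[0]:zone[1]] = 1
    q = rng.uniform(0.3, 0.7, size=m - n_markers_inside)
    hap[:, zone[1]:] = rng.random((n_hap, m - n_markers_inside)) < q

    theta = np.minimum(np.diff(pos_cM) / 100.0, 0.5)
    for _ in range(generations):
        parents = rng.integers(0, n_hap, size=(n_hap, 2))
        cross = rng.random((n_hap, m - 1)) < theta
        which = np.zeros((n_hap, m), dtype=np.int64)
        which[:, 0] = rng.integers(0, 2, size=n_hap)
        which[:, 1:] = cross
        which = np.cumsum(which, axis=1) % 2
        pa = hap[parents[:, 0]]
        pb = hap[parents[:, 1]]
        hap = np.where(which == 0, pa, pb).astype(np.int8)

    pick = rng.choice(n_hap, size=2 * n_individuals, replace=False)
    return pos_cM, hap[pick], zone
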