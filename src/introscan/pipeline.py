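"""End-to-end orchestration of the introgression scan.

`run_scan` wires the stages together on in-memory objects: coverage
masking, diagnostic-site discovery, outgroup polarization, genotype
classification, 500-kb screening and 1-kb tract refinement for each study
population, and the cross-population overlap summary.  `run_pipeline`
wraps it with file input/output and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diagnostics, tracts, windows
from .panelio import CallableTrack, HaplotypePanel, coverage_mask, write_bed
from .simulate import (
    POP_COMPARISON,
    POP_FOCAL,
    POP_OUTGROUP,
    POP_SPECIES_A,
    POP_SPECIES_B,
    Bundle,
)

log = logging.getLogger("introscan")


@dataclass
class ScanParams:
    """Thresholds of the detection procedure with their published defaults."""

    coverage_low: int = 20
    coverage_high: int = 200
    screen_window: int = 500_000
    screen_step: int = 100_000
    screen_threshold: float = 0.02
    refine_window: int = 1_000
    min_tract_length: int = 10_000
    min_tract_sites: int = 5
    max_gap: int = 5_000
    exclude_chroms: tuple = ()


@dataclass
class ScanResult:
    diagnostic_sites: pd.DataFrame
    mask: np.ndarray
    tracts_by_population: dict[str, pd.DataFrame]
    sites_by_population: dict[str, pd.DataFrame]
    candidates_by_population: dict[str, pd.DataFrame]
    overlap: dict


def run_scan(
    panel: HaplotypePanel,
    track: CallableTrack,
    params: ScanParams | None = None,
    scan_populations=(POP_FOCAL, POP_COMPARISON),
) -> ScanResult:
    params = params or ScanParams()
    chrom_lengths = {c: track.chrom_length(c) for c in track.arrays
                     if c not in params.exclude_chroms}

    mask = coverage_mask(panel, params.coverage_low, params.coverage_high)
    panel_a = panel.subset_samples(panel.population_samples(POP_SPECIES_A))
    panel_b = panel.subset_samples(panel.population_samples(POP_SPECIES_B))
    outgrp = panel.subset_samples(panel.population_samples(POP_OUTGROUP))

    table = diagnostics.find_fixed_differences(
        panel_a, panel_b, mask=mask, exclude_chroms=params.exclude_chroms
    )
    table = diagnostics.polarize(table, outgrp)
    log.info("diagnostic sites: %d total, %d B-specific",
             len(table), int(table["b_specific"].sum()))

    spec = windows.WindowSpec(params.screen_window, params.screen_step)
    tract_sets, site_sets, cand_sets = {}, {}, {}
    for pop in scan_populations:
        members = panel.population_samples(pop)
        if not members:
            continue
        sub = panel.subset_samples(members)
        cls = diagnostics.classify(sub, table)
        gw = windows.genotype_class_proportion_windows(cls, spec, chrom_lengths)
        cands = tracts.screen_candidates(gw, params.screen_threshold)
        called = tracts.refine_and_call(
            cands, cls,
            window=params.refine_window,
            min_length=params.min_tract_length,
            min_sites=params.min_tract_sites,
            max_gap=params.max_gap,
        )
        tract_sets[pop] = called
        site_sets[pop] = tracts.merge_population_sites(called)
        cand_sets[pop] = cands
        log.info("%s: %d candidate regions -> %d tracts (%d merged sites)",
                 pop, len(cands), len(called), len(site_sets[pop]))

    overlap = {}
    pops = [p for p in scan_populations if p in site_sets]
    if len(pops) == 2:
        shared, private, frac = tracts.overlap_tracts(site_sets[pops[0]], site_sets[pops[1]])
        overlap = {
            "populations": pops,
            "n_shared": len(shared),
            "n_private": len(private),
            "fraction_shared": frac,
        }
    return ScanResult(
        diagnostic_sites=table,
        mask=mask,
        tracts_by_population=tract_sets,
        sites_by_population=site_sets,
        candidates_by_population=cand_sets,
        overlap=overlap,
    )


def run_pipeline(bundle: Bundle, outdir, params: ScanParams | None = None,
                 rrs_report: bool = True) -> ScanResult:
    """Scan a simulated bundle and write the result files and manifest."""
    from . import rrs

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or ScanParams(exclude_chroms=tuple(bundle.config.excluded_chroms))
    result = run_scan(bundle.panel, bundle.callable_track, params)

    diagnostics.write_diagnostic_table(result.diagnostic_sites, out / "diagnostic_sites.tsv")
    for pop, df in result.tracts_by_population.items():
        write_bed(df, out / f"tracts_{pop}.bed",
                  columns=("chrom", "start", "end"))
    for pop, df in result.sites_by_population.items():
        write_bed(df, out / f"introgression_sites_{pop}.bed")
    if rrs_report and POP_FOCAL in result.sites_by_population:
        report = rrs.count_captured(
            result.sites_by_population[POP_FOCAL],
            bundle.reference,
            result.diagnostic_sites,
        )
        report.to_csv(out / "capture_report.tsv", sep="\t", index=False)

    manifest = {
        "params": dataclasses.asdict(params),
        "seed": bundle.config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(params), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "overlap": result.overlap,
        "n_diagnostic_sites": len(result.diagnostic_sites),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result
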