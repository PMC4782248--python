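"""Sliding-window heterozygosity and the exact population comparison.

A planted heterozygous introgression tract raises both the unbiased
average heterozygosity (h-hat) and the per-individual heterozygous-site
proportion of carriers to the interspecies divergence scale (~1.4e-2),
an order of magnitude above the population background (~1.5e-3).  The
exact Mann-Whitney U test then compares genomewide per-individual
proportions between the low-diversity focal population and the
anadromous-like comparison population: four vs four with complete
separation gives the smallest attainable two-sided p, 2/70 = 0.02857.
"""

from introscan.panelio import coverage_mask
from introscan.simulate import SimulationConfig, simulate_bundle
from introscan.windows import (
    WindowSpec,
    average_heterozygosity_windows,
    mwu_exact,
    observed_het_proportion,
)

cfg = SimulationConfig(
    seed=2,
    chrom_lengths=[("chrI", 1_000_000)],
    tracts=[("chrI", 400_000, 520_000, ("T1", "T2"), "het")],
)
bundle = simulate_bundle(cfg)
mask = coverage_mask(bundle.panel)  # all individuals at 20-200x

focal = bundle.panel.subset_samples(bundle.panel.population_samples("focal"))
hw = average_heterozygosity_windows(
    focal, mask, bundle.callable_track, WindowSpec(100_000, 100_000)
)
print("focal-population h-hat per 100-kb window:")
print(hw[["start", "end", "S", "h"]].to_string(index=False,
                                               float_format="%.2e"))

props = {
    ind: observed_het_proportion(bundle.panel, mask, bundle.callable_track, ind)
    for ind in ("T1", "T2", "T3", "T4", "C1", "C2", "C3", "C4")
}
print("\nper-individual genomewide heterozygous-site proportions:")
for ind, p in props.items():
    print(f"  {ind}: {p:.2e}")

# Compare background diversity on the tract-free region: a planted tract
# inflates its carriers' genomewide proportions toward the divergence scale.
bg = {
    ind: observed_het_proportion(bundle.panel, mask, bundle.callable_track,
                                 ind, "chrI", 600_000, 1_000_000)
    for ind in props
}
p = mwu_exact([bg[i] for i in ("T1", "T2", "T3", "T4")],
              [bg[i] for i in ("C1", "C2", "C3", "C4")])
print(f"\nexact Mann-Whitney U on the tract-free region "
      f"(focal vs comparison, two-sided): P = {p:.5f}")
# The windows overlapping 400-520 kb stand out an order of magnitude above
# the background; with the quartets completely separated the exact
# two-sided p reaches its 4-vs-4 floor, 2/70 = 0.02857.
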