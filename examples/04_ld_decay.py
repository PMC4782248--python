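"""LD decay around a recent introgression event.

Forward-simulates phased haplotypes where markers inside an introgressed
zone start on one donor haplotype (complete LD) and outside markers start
at equilibrium, then lets twelve generations of random mating with
recombination erode the association.  Pairwise |D'| is fitted per category
to D' = (1 - theta)^t, theta from the map distance: the fitted "age" t is
small inside the zone (slow decay, recent event) and large outside —
the signature used to argue an introgressed haplotype rose recently.
"""

from introscan.ld import fit_decay, pair_ld_table
from introscan.simulate import simulate_ld_panel

positions_cM, haplotypes, zone = simulate_ld_panel(
    seed=4, generations=12, n_individuals=48
)
pairs = pair_ld_table(haplotypes, positions_cM, zone)
print(f"{len(pairs)} marker pairs; mean |D'| by category:")
print(pairs.groupby("category")["Dprime"].mean().round(3).to_string())

fits = fit_decay(pairs, max_cM=5.0)
print("\nfitted decay age t (generations since D' = 1):")
for cat in ("within", "across", "outside"):
    f = fits[cat]
    print(f"  {cat:8s} t = {f.t_hat:6.1f}  (95% CI {f.ci_low:.1f}-{f.ci_high:.1f},"
          f" {f.n_pairs} pairs)")
# Slower decay (smaller t) within and across the zone than outside is the
# expected pattern when the introgressed segment spread recently.
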