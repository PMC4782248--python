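# Methods

## The problem and the model

`introscan` targets a specific population-genomic situation: a recipient
population of a species (call it A) that carries short genomic segments
derived from a closely related donor species (B), introduced by past
hybridization and backcrossing. With only a handful of resequenced
individuals per panel, probabilistic local-ancestry inference is fragile;
the package instead reproduces a transparent rule-based procedure whose
every threshold is explicit and testable.

The detection logic assumes:

* a species-A reference genome and joint-genotyped diploid panels for
  both species, an outgroup, and the study populations;
* interspecies divergence high enough (order 1% per bp) that fixed
  differences are dense relative to the tract sizes of interest — at
  1.44% divergence the expected diagnostic-site spacing is ~70 bp, so a
  10-kb tract holds ~140 informative sites;
* introgressed segments are long runs of donor alleles, either
  heterozygous (one donor haplotype) or homozygous.

A site is *diagnostic* when both species panels are monomorphic for
different alleles; it is *donor-diagnostic (B-specific)* when the
outgroup carries the species-A allele, placing the mutation on the donor
lineage. Outgroup states equal to the B allele assign the mutation to the
A lineage; third alleles, missing or polymorphic outgroup states identify
neither lineage and are dropped from the B-specific set — they cannot
attribute the mutation to either branch.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| coverage band | 20–200× inclusive | a position is validated only when **every** analysed individual's depth lies in the band; guards against both low-confidence and collapsed-repeat genotypes |
| screen window / step | 500 kb / 100 kb | coarse genotype-class windows |
| screen threshold | > 2% | donor-genotype (het + homB) fraction, in ≥ 1 individual of a population, marking a candidate region |
| refinement window | 1 kb, tiling | dominant-genotype labels; tiling (step = size) because border calling by dominance flips is only well-posed for non-overlapping windows |
| dominance | > 50% | strict majority of an individual's informative diagnostic sites in the kilobase; an exact tie is uninformative |
| gap bridging | ≤ 5 kb | a donor run persists across uninformative kilobases up to this gap — at ~70 bp site spacing, empty kilobases occur inside genuine tracts |
| tract filters | length > 10 kb, ≥ 5 donor sites | the site count is per emitted region (the per-kilobase reading would contradict the coarse screen); a flag switches to per-window |
| amplicon SNP filter | depth > 20 (strict), biallelic SNP, ≥ 2 carriers, HWE p ≥ 0.05 | the strict `>` contrasts deliberately with the inclusive WGS band |
| ddRAD size selection | 300 ± 36 bp | fragment bounded by two *different* enzymes, no internal cut of either |
| RAD geometry | 100-bp reads, mates 400 bp away (near edge) | 2 × 100 bp paired-end model; the far-edge reading differs by 100 bp and is flag-switchable |
| decay fit | θ = d_cM/100 capped at 0.5, pairs ≤ 5 cM, unweighted least squares | at ≤ 5 cM the Haldane correction is < 5% and off by default (flag available) |
| lowess span | 0.3 | smoothing of (position, cM/Mb) observations; smoothed rate floored at 0 before integration so distances are never negative |

Sex chromosomes (or any chromosome where intraspecies X/Y divergence
confounds fixity) are handled as a configurable blocklist.

## Coordinates

Internally everything is 0-based half-open; conversions to 1-based VCF
happen only in `panelio` readers/writers. BED outputs are 0-based
half-open.

## The synthetic-data generator

`simulate.simulate_bundle` emulates the statistical structure the
analysis consumes, not sequence evolution in general:

* **Mutation model**: infinite-sites substitutions at uniformly drawn
  positions, no back-mutation. The analysis only uses biallelic fixed
  differences, so a substitution-rate-matched model suffices; no
  coalescent machinery is involved.
* **Lineage structure**: each fixed difference is assigned to the donor
  or recipient branch (default 50/50); the outgroup retains the
  ancestral allele and additionally accumulates private substitutions on
  its own branch (default 1% per bp), which occasionally overwrite the
  ancestral state at a diagnostic site and render it uninformative —
  exercising the polarization rules.
* **Within-population polymorphism**: per-population private sites at a
  rate converting the target per-bp heterozygous-site proportion
  (defaults 1.5 × 10⁻³ focal, 3.1 × 10⁻³ anadromous-like) through the
  mean heterozygosity of a Uniform(0.1, 0.9) allele frequency; genotypes
  are Hardy–Weinberg draws. Species reference panels default to zero
  internal polymorphism: the scan only consumes their fixity, and
  near-fixity noise is modelled directly by `diag_leak_rate`, a
  per-chromosome probability of carrying the other species' allele at a
  diagnostic site (expected diagnostic-site survival is then
  (1 − p)^chromosomes, which the tests verify).
* **Tracts**: planted intervals overwrite carrier genotypes at the
  diagnostic sites inside, on one haplotype (het) or both (hom).
  Overlapping tracts with conflicting zygosity for the same carrier are
  rejected at config validation.
* **Coverage**: per-site per-individual depth is a rounded
  Normal(50, 10), with a dropout fraction (default 1%) forced below the
  20× floor. Because per-bp denominators need *all* positions, not just
  variant ones, the bundle carries a genome-wide `CallableTrack`: at
  variant sites it is derived from the emitted DP values; at invariant
  positions it is a Bernoulli draw with the same model's analytic
  all-individuals pass probability. This is the in-package analog of
  per-position depth extraction from alignments, which is out of scope.
* **Recombination map**: noisy rate observations every 100 kb around
  piecewise-linear knots (default 3 → 1 → 5 cM/Mb across a chromosome).
* **Indels/MNPs**: optional low-rate (5 × 10⁻⁶/bp) events, polymorphic
  in the study populations, present solely to exercise the amplicon SNP
  filters.
* **Determinism**: all randomness flows from one seed through named
  `default_rng` substreams; identical configs give byte-identical
  bundles.

The LD study uses a separate forward simulator
(`simulate.simulate_ld_panel`): a Wright–Fisher population of haplotypes
where markers inside an introgressed zone start on a single donor
haplotype at configurable frequency (complete LD — the state right after
the event) and outside markers start at linkage equilibrium; random
mating with recombination at the map distances then erodes association
for a configurable number of generations.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: read-level errors and mapping artefacts,
genotype-likelihood uncertainty, spatially correlated coverage
(mappability), linked selection, realistic coalescent genealogies and
incomplete lineage sorting, and reference misassembly. In particular,
distinguishing introgression from shared ancestral polymorphism is an
argument the scan itself does not make.

## Statistics

* **Average heterozygosity** uses the unbiased per-site term
  n(1 − Σx²)/(n − 1), which equals the mean pairwise difference over all
  chromosome pairs at the site — the test suite asserts the identity
  exactly. Windows are anchored at 0; terminal windows keep their true
  denominators; zero-denominator windows are NaN, never 0. n is per-site
  (2 × non-missing individuals).
* **Exact Mann–Whitney** enumerates all C(n₁+n₂, n₁) label assignments
  with mid-ranks; two-sided p is the fraction of assignments with
  |U − E[U]| at least the observed. No normal approximation: the
  four-vs-four regime the package targets is exactly enumerable (the
  completely separated case gives p = 2/70 ≈ 0.02857).
* **Exact HWE** conditions on the allele count and sums probabilities of
  heterozygote counts no more likely than observed (computed in log
  space; verified against exact-fraction enumeration).
* **D′** uses the standard 2 × 2 normalisation with the absolute-value
  convention (the decay model needs D′ ∈ [0, 1]; whether the original
  analysis used signed D′ is unstated, and absolute is the only choice
  compatible with the model).
* **Decay fit**: `scipy.optimize.curve_fit` on D′ = (1 − θ)^t with t ≥ 0;
  the 95% band is asymptotic from the parameter covariance (bootstrap is
  a one-liner on top, not built in). All-D′ = 1 input is degenerate:
  t = 0, flagged. Monte-Carlo tests confirm ≥ 90% CI coverage at
  n_pairs = 100, noise sd 0.05.
* **Nei–Gojobori**: site fractions per codon from the standard code with
  changes-to-stop counted nonsynonymous; multi-difference codons
  averaged over all orderings of the differing positions, excluding
  pathways through stop codons (all-blocked codons fall back to all
  pathways so counts stay defined). Site counts are taken on the first
  haplotype by default — at interallelic divergence ~1% the haplotype
  choice is immaterial; `site_average=True` averages both (and is used
  when cross-checking against an independent NG86 implementation).
  Jukes–Cantor correction is undefined at p ≥ 3/4 and flagged. Ks = 0
  with Ka > 0 is reported as the literal string `inf` in tables. The
  ratio test is a one-sided codon-based Z-test on p_N − p_S with
  binomial variances — a documented large-sample approximation of the
  exact tests in dedicated phylogenetics tools, which are deliberately
  not wrapped.

## Problem sizes

The shipped tests run the full scan on a noise-free 10-Mb two-chromosome
genome with six planted tracts of 15–450 kb (recall 1, precision 1,
borders within 1 kb), and lighter 0.3–1 Mb bundles elsewhere; these sizes
put hundreds to thousands of diagnostic sites in every tract while
keeping the whole suite around half a minute. The acceptance script uses
a 1-Mb genome with the default four-plus-four study populations.

## Known limitations

* Tract borders snap to kilobase window edges, not to diagnostic-site
  positions; border error is bounded by the refinement window.
* The callable track treats coverage dropout as independent across
  positions and individuals; real mappability is spatially correlated,
  so real joint-callable fractions will be lower and blockier.
* `filter_snps` applies rules in a fixed order and reports the first
  failure; the retained set is order-independent, the report labels are
  not.
* The HWE and MWU exact tests enumerate; they are for small panels
  (MWU capped at n₁ + n₂ = 20 by design).
* Phasing is taken as given (the simulator emits truth phase);
  computational phasing is out of scope, and unphased multi-het codons
  in Ka/Ks raise rather than guess.
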