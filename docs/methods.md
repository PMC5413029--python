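# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that a user extending the package needs to know.

## Data model and conventions

All stages share one in-memory `Cohort`: an individuals × SNPs dosage
matrix counting copies of the cohort-wide minor allele (0/1/2, −1 for
missing), a SNP table sorted by (chromosome, bp) with optional genetic
positions, breed labels, and an optional pedigree. Physical coordinates are
1-based inclusive; every interval downstream (`[start_bp, end_bp]`) is
closed, and conversion to 0-based half-open happens only in BED export.
The counted allele is fixed at read time (cohort-wide minor allele,
lexicographic tie-break; the minor allele of a monomorphic SNP is the
absent one, dosage 0) and never relabelled afterwards — F_ST and r² are
invariant to labelling, and freezing it prevents per-breed relabelling
inconsistencies. MAF is computed from integer allele counts so it is
exactly symmetric under relabelling, which matters for SNPs sitting
precisely on a filter boundary.

Unmapped SNPs get genetic positions by linear interpolation on bp between
the flanking mapped SNPs, with constant extrapolation beyond the mapped
span; chromosomes with fewer than two mapped SNPs keep their positions
absent. Interpolation is this package's choice — array studies rarely state
how off-map SNPs were placed — and it preserves monotonicity of cM with bp
by construction.

## Quality control

Filters run in a fixed order: individual call rate ≥ 0.95, then SNP call
rate ≥ 0.95 on the retained individuals; non-autosomal SNPs out, then
MAF < 0.01 (strict) across all retained individuals; then the within-breed
exact Hardy–Weinberg test at p < 1e−7, removing a SNP that fails in *any*
single breed. The chain is a no-op on its own output. The HWE test is the
exact conditional (hypergeometric) test, two-sided by probability ordering
without a mid-p correction — the default of the standard QC tools — and is
computed from normalised log-probabilities with an LRU cache over count
triples.

LD pruning slides a 50-SNP window one SNP at a time over the *kept* set:
each candidate is compared against the previous 49 kept SNPs on its
chromosome and dropped at the first pair with genotype r² > 0.1, so the
lower-bp SNP of a violating pair always survives, the procedure is
deterministic, and no within-window pair of the output exceeds the
threshold. Missing genotypes are pairwise-deleted in r².

## Runs of homozygosity

The scan classifies every 50-SNP window as compliant (≤1 heterozygote,
≤2 missing); a SNP qualifies when at least 5 % of the windows overlapping
it are compliant (the scanning-software default; the window hit threshold
is configurable). Maximal runs of qualifying SNPs are split at inter-SNP
gaps above 250 kb *before* the run-level checks: at least `l` SNPs from the
false-positive formula (α = 0.05, mean SNP heterozygosity of the analysed
cohort), at least 1 Mb, and on average at least one SNP per 100 kb. No
run-level heterozygote cap is applied beyond what window compliance
implies. Chromosomes with fewer than 50 SNPs are scanned with the window
shrunk to the chromosome (down to 20 SNPs), below which they are skipped
with a warning. Length classes are left-closed/right-open, so a 5.0-Mb run
belongs to 5–10 Mb.

Hotspots take SNPs at or above the top-1 % incidence quantile (a SNP with
zero incidence is never a member), merging map-adjacent selected SNPs; the
mean recombination rate of a hotspot or of a 500-kb tile is
Δ cM / Δ Mb between its outermost mapped SNPs, absent for fewer than two.
TMRCA bins sum ROH *genetic* length (cM) per animal: since a run of length
`l` cM reflects an ancestor ~`g = 100/(2l)` generations back, bin edges sit
at 10, 5 and 2.5 cM, left-closed.

## Inbreeding coefficients

`F_ROH` divides the summed physical length of runs above the threshold
(1, 5, 10 Mb) by the autosome length; the default denominator is the SNP
map span (Σ per-chromosome last − first bp), with a fixed override (e.g.
2.44 × 10⁹ bp for the ovine 50K panel) available when comparability with a
published constant matters. `F_PED` uses the Meuwissen–Luo ancestor-tracing
recursion with Mendelian-sampling variances of 1, 0.75 − F/4 or
0.5 − (F_s + F_d)/4 according to how many parents are known; unknown
parents are founders with F = 0. CGE counts known ancestor *slots*, each at
(1/2)^generation, so a repeated ancestor contributes once per pedigree
path. `F_GRM` and `F_HOM` use allele frequencies of the analysed scope
(pooled by default, per-breed selectable), per-individual sums over typed
SNPs only; SNPs fixed in the scope are excluded from `F_GRM`, and `F_HOM`
is flagged undefined when every typed SNP is fixed. The comparison report
computes Pearson correlations among all measures and OLS of each F_ROH on
F_PED, pooled and within breed, over animals with CGE ≥ 6.

## F_ST and signatures

Per SNP, the Weir–Cockerham (1984) variance components are computed from
per-breed sample sizes, allele frequencies and *observed* heterozygote
frequencies; θ = a/(a+b+c), undefined (and excluded from ranking and
means) when the SNP is monomorphic across the included breeds. Negative θ
values are kept in the 5-SNP window means — clamping would bias them
upward. Windows never span chromosome ends; the two edge SNPs per
chromosome carry no windowed value and rank as below-threshold during
extension. Signature seeds are windowed values at or above the
(1 − 0.001) empirical quantile; extension in each direction stops at the
second of two consecutive SNPs below the (1 − 0.05) quantile, keeping the
first and dropping the second; overlapping or adjacent regions merge, which
makes the result independent of seed processing order. Pairwise F_ST reuses
the same machinery on each of the breed pairs.

## Effective population size

Within a breed (MAF > 0.05), genotype r² is computed for same-chromosome
pairs up to 10 Mb apart (fast standardized-matrix path without missing
data, pairwise-complete path otherwise), adjusted by −1/n (genotypes are
unphased; −1/(2n) available for phased input), and averaged in 30
equal-width bins of the recombination fraction with at least 100 pairs per
bin. The inversion `N_T(t) = (4c)⁻¹(E[r²_adj]⁻¹ − α)`, `t = (2c)⁻¹`, is
applied per bin; bins with non-positive adjusted r² or N are flagged
invalid rather than dropped silently. The default mutation correction is
α = 2; α = 1 gives the drift-only form. Three distance-to-recombination
mappings are provided; the default is the Sved–Feldman-style saturating map
`c = m/(1 + 2m)` (m in Morgans at 1 cM/Mb). Its exact historical functional
form is not uniquely documented, so the mapping is a named, pluggable
choice; the linear and Haldane maps bracket it. Recovery tests use the
Haldane map because the package's forward simulator implements an
interference-free (Markov) crossover process for which Haldane is the exact
distance→recombination relation — a model-consistency choice.

## Synthetic data: what it does and does not emulate

The generators mirror a multi-breed 50K-style cohort at roughly 1/10 scale
(defaults: 26 autosomes, evenly spaced SNPs, uniform 1 cM/Mb map, ~5,000
SNPs, tens of individuals per breed) so the whole pipeline runs at desk
scale with stable statistics.

* **Balding–Nichols breeds** draw each breed's allele frequency from
  Beta(p(1−c)/c, (1−p)(1−c)/c) around a shared ancestral p ~ U(0.05, 0.95)
  and genotypes binomially — Hardy–Weinberg within breed, E[F_ST] ≈ c.
  There is no LD, no shared demographic history and no site-frequency
  realism, so it validates the F_ST estimator and QC filters, not
  haplotype-based statistics.
* **Gene dropping** transmits founder-labelled haplotypes through a
  pedigree with Poisson crossovers placed uniformly in genetic distance
  (no interference) and no mutation, so identity-by-descent is exactly the
  identity of founder labels and true autozygous tracts are recorded at
  marker resolution. Passing the ROH recovery test shows the scan finds
  IBD tracts under these idealised maps; it does not probe
  identity-by-state ROH from ancient haplotype sharing, genotyping error,
  or uneven marker spacing.
* **Wright–Fisher** simulates 2N haplotypes forward with the same
  crossover model and recurrent mutation (default 1e−5/site/transmission),
  from linkage-equilibrium starting frequencies. Runs of 2–3× N
  generations are enough for the large-c (recent-time) bins used in the
  recovery tests; deeper-time bins may not have equilibrated and real
  populations are not constant-sized.
* **Sweeps** are injected post hoc by resampling genotypes toward a
  near-fixed frequency (0.98) in target breeds — a positive control with a
  known interval, not a model of selection dynamics.

All generators are deterministic given a seed.

## Problem sizes and numerical choices

Validation runs use 6 breeds × 100 individuals × 5,000 SNPs for F_ST drift
recovery; ~160 pedigree members over 8,000 SNPs at 50-kb spacing for ROH
recovery (endpoint tolerance: one 50-SNP window span); N ∈ {100, 200, 400}
with 400–600 generations and 2,000 SNPs for Ne recovery, judged on bins
with t ≤ N/10; 200 random ≤3-population cases for the component oracle
(agreement to 1e−12); all ≤30-allele configurations for the HWE oracle.
These sizes were chosen as the smallest at which the stochastic recoveries
are statistically stable.

Ties in empirical quantiles share the maximum rank; seed selection uses ≥
the quantile. Degenerate inputs (all-missing SNP in a breed, zero-variance
correlation inputs, chromosomes without a usable genetic map) are skipped
and logged or flagged NaN rather than raised, except where the result would
be meaningless (no individuals surviving QC, fewer than two breeds for
F_ST, cyclic pedigrees).

## Known limitations

Only biallelic autosomal array genotypes are supported (no VCF, no sex
chromosomes, no phasing). The QC chain reproduces filter *rules*, not any
specific published cohort's retained counts. The ROH window hit threshold
(0.05) and the exact Sved–Feldman mapping are conventions inherited from
widely used tools rather than uniquely determined by the literature; both
are parameters. Haplotype-cluster statistics (e.g. hapFLK), ancestry
models, and annotation of called regions are out of scope — signature and
hotspot tables are exported for external annotation.
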