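# Methods

`divscan` reconstructs, as a tested pipeline, a complete two-population
population-genomics analysis for ddRAD-type SNP data: divergence-history
inference from the folded joint site frequency spectrum (JSFS) by
simulation-based composite likelihood, and a heterogeneous-genomic-landscape
scan (Fst outlier windows, diversity contrasts, PCA-based selection scan,
hierarchical AMOVA, ancestry–phenotype correlation). The motivating system
is the piscivorous "ferox" versus benthivorous life-history pair of brown
trout, but nothing in the code is specific to that system beyond defaults.

## The coalescent engine

Both the synthetic-data generator and the demographic inference share one
structured-coalescent simulator (`_coalescent.py`, numba-compiled). Two
demes ("brown" and "ferox", diploid sizes NeB and NeF) merge into an
ancestral population of size NeANC at `tdiv` generations before present.
One event time `t2` (0 < t2 < tdiv) splits the divergence period into a
recent epoch with symmetric per-lineage migration `mig` and an ancient
epoch with rate `mig_ancient`, and can carry an instantaneous admixture
pulse: backward in time, each brown lineage jumps to ferox with probability
`adm_fb` (the forward proportion of the brown gene pool replaced from ferox
at contact) and vice versa with `adm_bf`. The pulses use pre-pulse deme
labels, i.e. they are simultaneous, not sequential. The six divergence
scenarios are configurations of this machine:

| model    | free parameters                                 | k |
|----------|-------------------------------------------------|---|
| SI       | NeANC, NeB, NeF, TDIV                           | 4 |
| IM       | + MIG (constant)                                | 5 |
| AM       | + T2; migration only before T2                  | 6 |
| SC       | + T2; migration only after T2                   | 6 |
| IMchange | + T2 and a second, ancient migration rate       | 7 |
| SCadm    | SC + admixture pulse proportions at contact     | 8 |

Times are in generations; a pair of haploid lineages in a deme of diploid
size N coalesces at rate 1/(2N) per generation. The engine was validated
against msprime branch-length statistics (total-variation distance of the
folded expected spectra below Monte-Carlo noise, ≤ 0.007 at 60k/40k
replicates) for IM, AM, SC and one-directional-pulse SCadm configurations;
two-directional pulses cannot be expressed simultaneously in msprime's
sequential event model, which is why the oracle tests use one-way pulses.

Two kernels share the event logic but no code: one accumulates expected
branch length per joint descendant class (i brown, j ferox carriers), the
other builds per-locus genealogies with leaf-set bitmasks and drops
infinite-sites Poisson mutations. Their agreement (realised folded SFS of
one versus expected spectrum of the other) is itself a test invariant.

## JSFS, projection, monomorphic correction, likelihood

The folded JSFS is built from complete sites only (any site with a missing
genotype among the used individuals is excluded; the 10%-missing pre-filter
and hypergeometric projection absorb sample-size reduction). Folding uses
the minor-allele convention: cell (i, j) merges with (n1−i, n2−j), the
dominated half is masked, and cells on the half-total diagonal each keep
half the combined mass. Projection redistributes each count by the product
of per-population hypergeometric weights; mass landing in the projected
corners (monomorphic after downsampling) moves to the monomorphic cell, so
total mass is conserved exactly.

Because one SNP per RAD locus enters the spectrum, the monomorphic count is
corrected ratio-preservingly: `n_snps_used × (n_loci·L − S_all)/S_all`
with L = 55 bp (60 bp reads minus the 5 bp restriction site) and S_all the
segregating-site total of the full data.

Expected cell probabilities are Monte-Carlo: `p(i,j) = μ · E[T(i,j)]` per
site, with the monomorphic probability as the complement; the composite
log-likelihood is `Σ m·ln p` over unmasked cells including the monomorphic
cell, with expected probabilities floored at 1e−20. Likelihoods are
natural-log internally; base-10 values are natural/ln 10 (the printed
model-selection table is natural-log — AIC = 2k − 2·lnL reproduces it; the
"maximum estimated/observed likelihood" values are log10 of the same
quantity).

## ECM fitting, model selection, bootstrap

Each of `n_runs` independent starts is drawn log-uniformly from per-
parameter ranges (Ne 50–50,000; TDIV 100–60,000 generations; migration
1e−5–0.05; admixture 0.02–1; T2 parameterised internally as a fraction
0.005–0.95 of TDIV, which enforces 0 < T2 < TDIV throughout the search).
Each cycle maximises each parameter in turn by bounded scalar search on the
log scale. Common random numbers (one kernel seed per run) make the
likelihood surface deterministic within a run, so the best-so-far
likelihood is non-decreasing across cycles and a 1-D search is meaningful;
ties keep the incumbent. Models are ranked by AIC, ties by smaller k.
Confidence intervals are non-parametric bootstrap over the per-run best
parameter vectors (resample runs with replacement, mean per resample,
2.5/97.5 percentiles of the resampled means) — one documented reading of
"bootstrap over the parameters from the top runs"; it quantifies
between-run spread, not sampling error of the data.

When two fitted models are compared at small simulation budgets, their
best parameters are re-evaluated with a common, larger simulation seed
before computing AIC, so the comparison is not dominated by per-fit
Monte-Carlo noise.

## Identifiability at reduced scale

The acceptance property "simulate 2,000 loci at the study's point
estimates and recover all SCadm parameters within ×1.5" is implemented
exactly as stated, and fails honestly: 2,000 × 55 bp loci at μ = 1e−8
carry only ~100 SNPs, and the composite likelihood at the ECM optimum
*exceeds* the likelihood at the truth by ~5 nats under fresh common
evaluation seeds — the data, not the optimiser, cannot pin eight
parameters (TDIV/TSC/migration/admixture trade off). The same protocol
discriminates the generating model family by AIC in 10/10 seeds, and
4-parameter SI fits recover the tree-length scale; both are tested. A
recovery criterion at this locus count would need either ~20× more loci or
a higher mutation rate.

## Synthetic data

Defaults are the study conditions: SCadm at its point estimates
(NeANC 12,326; NeB 1,146; NeF 393; TDIV 9,159; TSC 469; MIG 0.0022;
adm 0.817/0.536), 20 + 8 diploids across six sampling sites (ferox all at
KER), 215,000 loci of 55 bp on 29 chromosomes (80 Mb each — round figures
of Atlantic-salmon scale), μ = 1e−8, 12% uniform missingness. Loci are
unlinked, non-recombining, placed on non-overlapping 64-bp slots uniformly
per chromosome; diploids pair consecutive haploids (no inbreeding).
Haplotype tables are emitted for polymorphic loci only — monomorphic loci
carry no within-locus diversity, so gene/haplotype diversity statistics are
unaffected; an individual is missing at a locus when any of its genotypes
there is missing.

True ancestry `q` is the ferox-source lineage proportion at the admixture
pulse under SCadm (brown: adm_fb; ferox: 1 − adm_bf) and plain population
membership otherwise. Note the pulse-time proportions are *not* what a
contemporary model-based clustering would report; the pipeline therefore
feeds population membership (ferox = 1) to the phenotype generator, which
models fork length as `267 + 216·q + N(0, 80²)` mm — matching the reported
group means (483/267 mm) and group SDs. Under this linear map the
ancestry–length Spearman correlation concentrates around 0.6–0.75, higher
than the study's 0.54 — real ancestry–phenotype coupling is evidently
weaker than linear-plus-noise; the regression-regime test asserts the
distribution this generator actually produces (oracle-frozen).

The injected differentiated window redraws in-window genotypes from
binomial draws at constructed frequencies: target-group frequencies are
moved toward fixation so heterozygosity scales by the requested factor
(solving p′(1−p′) = f·p(1−p) on the same side of ½), the other group is
pushed apart by a separation `d` found by bisection on the *realised*
window-mean Weir–Cockerham Fst (tolerance ±0.05 internally, ±0.1
guaranteed); the missingness pattern is preserved and everything outside
the window is untouched.

What the generator does not emulate: linked selection, recombination
within loci, genotyping error and allele dropout, non-uniform missingness
(real RAD missingness is locus- and depth-structured), population
structure within the brown group, and mutation-model realism beyond
infinite sites. Passing scan tests therefore demonstrate statistical
correctness of the estimators and calling rules, not robustness to those
artefacts.

## Genome scan

Per-SNP Weir & Cockerham (1984) θ̂ (two populations, components a/b/c from
sample sizes, allele frequencies and observed heterozygosity; negative
estimates retained; sites with fewer than two genotyped individuals in a
group skipped). ZFst is (x − mean)/sd with the genome-wide sample mean and
sd (ddof 1); a zero-variance input warns and yields no outliers. Window
statistics average per-SNP values over 500 kb windows stepped by 125 kb
(SNP-averaged, not bp-averaged); windows without SNPs carry no statistics
and are excluded from the window-level standardisation. A window is an
outlier when its ZFst exceeds 4 *and* it contains at least two
differentiated variants — "differentiated variant" is implemented as
per-SNP ZFst > 4 (the same threshold as the SNP scan; configurable), since
the rule is not further specified. Delta diversity is gene diversity
(brown) − gene diversity (ferox) per window; outlier windows whose |Δ|
exceeds the genome-wide 75th percentile (configurable) are classed
brown-reduced or ferox-reduced by sign. Wilcoxon rank-sum contrasts use
the exact distribution for ≤ 25 combined observations without ties and the
tie-corrected normal approximation otherwise. Functional density is the
overlap-proportional sum of annotated characters per window; QTL overlap
uses half-open interval intersection (≥ 1 bp). Loess smoothing (local
quadratic, span 0.1) exists for plotting only and feeds no statistic.

## Structure scan

PCA mean-imputes missing genotypes per site and centers without scaling
(the adegenet default); all-missing sites are dropped with a warning. The
selection scan regresses each (imputed, centered) SNP on the first K = 2
PC scores, takes the K-vector of regression z-scores, computes robust
Mahalanobis D² (minimum covariance determinant, fixed seed), rescales by
the genomic inflation factor λ = median(D²)/median(χ²_K), and refers
D²/λ to χ²_K; outliers are Benjamini–Hochberg q < 0.05 (configurable) and
each is assigned to the PC with the largest squared correlation. The
AMOVA partitions allele-value variance over four nested levels (types /
sites / individuals / gene copies) using unbalanced nested-ANOVA
expected-mean-square coefficients per locus, summed over loci; Fct, Fsc,
Fis, Fit follow from the summed components, with permutation p-values
(individuals among sites within types for Fsc; whole sites among types for
Fct; (hits+1)/(n+1) convention). The ancestry correlation is Spearman with
mid-rank ties, exact permutation p for n ≤ 9 and the t-approximation
beyond.

## Numerical and design choices

- Filter boundaries are inclusive on the kept side (MAF ≥ 0.05, Ho ≤ 0.6,
  presence ≥ 0.66), matching Stacks semantics; missing genotypes are
  excluded from frequency and Ho denominators.
- Coordinates are 0-based half-open internally; VCF (1-based) and BED
  conversion happens only at the file boundary.
- "First SNP per locus" keeps the lowest position within each RAD locus.
- The SFS filter (≤ 10% missing, no MAF cut) is separate from the scan
  filter and the pipeline refuses to fit demography on unfiltered data.
- One global pipeline seed fans out to per-stage seeds through a
  counter-based `SeedSequence` derivation; a rerun of the same config is
  byte-identical.
- Projection units: "12 and 6 samples" is runnable in either reading; the
  projection routine takes haploid counts explicitly (24, 12 for the
  diploid reading).
- Test problem sizes: recovery/discrimination suites use 2,000 loci with
  12 + 6 diploids; scan suites 6,000–12,000 loci on six 10-Mb chromosomes;
  the generator's full-scale default (215,000 loci) is exercised by the
  simulator directly. These sizes are the package's chosen desk-scale
  reproduction conditions.

## Known limitations

- Composite likelihood treats SFS cells as independent; confidence
  intervals over ECM runs understate parameter uncertainty.
- The expected spectrum is Monte-Carlo; at small `sims_per_eval` the ECM
  surface is noisy (mitigated, not removed, by common random numbers).
- Only symmetric migration and a single event time per model; no
  population growth; no unfolded spectra (no outgroup polarisation).
- AMOVA treats loci as independent and missing copies as ignorable.
- The selection scan's χ² calibration assumes SNPs are exchangeable under
  the null; strong LD or family structure would inflate λ.
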