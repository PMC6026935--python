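# divscan

Two-population divergence-history inference and genomic-landscape scans
for ddRAD-like SNP data.

`divscan` is built for the situation faced by studies of recently diverged
life-history pairs — here, the rare piscivorous "ferox" versus the common
benthivorous form of brown trout (*Salmo trutta*): a few thousand to a few
tens of thousands of RAD SNPs on two small, admixed population samples, and
two questions. *How did the pair diverge?* — answered by comparing six
two-population coalescent scenarios (strict isolation SI; isolation with
migration IM, also with a rate change, IMchange; ancient migration AM;
secondary contact SC, also with an admixture pulse at contact, SCadm) on
the folded joint site frequency spectrum (JSFS) by simulation-based
composite likelihood and AIC. *Which genomic regions stand out?* — answered
by a Weir–Cockerham Fst sliding-window scan (ZFst > 4 outlier windows with
≥ 2 differentiated variants), within-group diversity contrasts (π, gene and
haplotype diversity, delta diversity), a PCA-based (eigen-GWAS) selection
scan with robust Mahalanobis distances, hierarchical AMOVA, and
ancestry–phenotype correlation.

Every stage is verifiable without the original reads: a coalescent
synthetic-data generator (the same simulation engine the inference uses)
produces ddRAD-like datasets with known demography, injectable
differentiated windows, phenotypes and annotation tracks.

## The model in brief

Backward in time, lineages sampled from the brown (NeB) and ferox (NeF)
demes coalesce at rate 1/(2Ne) per pair per generation, migrate
symmetrically at rate MIG per lineage, optionally jump demes at the
secondary-contact time TSC with probabilities (adm_FB, adm_BF) — the
forward admixture proportions — and merge into an ancestral deme (NeANC)
at TDIV. The expected folded JSFS is μ·E[branch length subtending each
joint carrier class], with the monomorphic mass as complement; the
composite log-likelihood is Σ m·ln p over folded cells including the
monomorphic cell, whose count is corrected for one-SNP-per-locus thinning
by `n_used · (n_loci·55 − S_all)/S_all`. Parameters are maximised by ECM
(cyclic bounded 1-D search, common random numbers per run) and models
ranked by AIC = 2k − 2·lnL.

## Worked example

```python
from divscan import *

# simulate a study-scale dataset under secondary contact with admixture
cfg = SimConfig(model="SCadm", params=ParameterSet.point_estimates(),
                n_brown=12, n_ferox=6, n_loci=2000, missingness=0.0,
                chrom_lengths=tuple((f"chr{i}", 10_000_000) for i in range(1, 30)),
                seed=11)
gm, radloci, popmap, q_true = simulate_dataset(cfg)

# SFS filter -> folded JSFS -> monomorphic correction
filt = demographic_site_filter(gm)
jsfs = compute_folded_jsfs(filt, popmap)
jsfs = jsfs.with_monomorphic(
    correct_monomorphic(cfg.n_loci, 55, gm.n_sites, jsfs.n_snps_used))

fit = fit_model("SCadm", jsfs, cycles=10, sims_per_eval=20_000, n_runs=5, seed=1)
print(round(fit.params.tdiv), round(generations_to_years(fit.params.tdiv)))
```

On this seed the dataset carries 105 SNPs (99 after per-site
completeness), the fitted divergence time is ≈ 1.5–9 thousand generations
depending on run, and the same protocol in `scripts/acceptance.py` (seed 1)
prints, among others:

```
delta_aic_si_minus_scadm : 36.35   # AIC prefers the generating SCadm model
tdiv_generations_estimate: 8737    # truth 9159
ne_brown_estimate        : 1563    # truth 1146
scan_sensitivity         : 1.0     # injected outlier windows recovered
selection_scan_lambda    : 1.02    # null calibration of the eigen-GWAS scan
```

A generating-versus-alternative AIC gap of ~36 means model *choice* is
solid at this scale, while single-parameter estimates from ~100 SNPs carry
wide error — the methods note (docs/methods.md) quantifies this
identifiability limit.

The same stages are scriptable from the shell:

```
divscan simulate --seed 3 --out sim_out
divscan demog-fit --vcf sim_out/genotypes.vcf --popmap sim_out/popmap.tsv \
    --phenotypes sim_out/phenotypes.tsv --model SI --model SCadm --out fit_out
divscan scan --vcf ... --out scan_out
divscan run --config pipeline.yaml
```

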