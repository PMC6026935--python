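"""End-to-end orchestration: simulate -> filter -> demography -> scans.

A single :class:`PipelineConfig` drives the full reproduction pipeline.
The global seed fans out to per-stage seeds through a counter-based
derivation, so each stage is individually reproducible and a rerun of the
same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    DataError,
    FilterConfig,
    build_windows,
    demographic_site_filter,
    filter_snps,
    load_tables,
    read_chrom_lengths,
    read_vcf,
    write_vcf,
)
from .demography import (
    DemographicModel,
    bootstrap_ci,
    compute_folded_jsfs,
    correct_monomorphic,
    fit_model,
    generations_to_years,
    project_jsfs,
    select_model,
)
from .scan import (
    ScanConfig,
    delta_classify,
    functional_density_analysis,
    locus_haplotype_stats,
    outlier_background_compare,
    qtl_overlap,
    site_pi,
    wc_fst_sites,
    window_scan,
)
from .simulate import (
    SimConfig,
    simulate_annotation_track,
    simulate_dataset,
    simulate_phenotypes,
    write_phenotypes,
    write_popmap,
    write_track,
)
from .structure import amova3, ancestry_phenotype_correlation, pca_impute, selection_scan

logger = logging.getLogger("divscan")

_STAGES = ("simulate", "filter", "demography", "scan", "structure")


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (stable across runs)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0]
               % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and per-stage options of one pipeline run."""

    outdir: str = "divscan_out"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES

    # either a simulation config ...
    sim: SimConfig | None = None
    # ... or input paths
    vcf: str | None = None
    popmap: str | None = None
    phenotypes: str | None = None
    chrom_lengths: str | None = None
    annotation_track: str | None = None
    qtl_track: str | None = None

    # stage options
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    demog_models: tuple[str, ...] = ("SI", "SCadm")
    demog_projection: tuple[int, int] | None = None
    demog_cycles: int = 10
    demog_sims: int = 20_000
    demog_runs: int = 5
    generation_time: float = 4.0
    window_size: int = 500_000
    window_step: int = 125_000
    scan_cfg: ScanConfig = field(default_factory=ScanConfig)
    pca_k: int = 2
    fdr: float = 0.05
    amova_permutations: int = 199
    plots: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise DataError(f"unknown stages: {sorted(unknown)}")
        if self.sim is None and "simulate" in self.stages:
            raise DataError("simulate stage requested but no sim config given")
        if self.sim is None and self.vcf is None:
            raise DataError("either a sim config or a VCF path is required")
        if "demography" in self.stages and "filter" not in self.stages:
            raise DataError(
                "demography stage requires the demographic site filter: add "
                "'filter' to stages so the SFS is built from <=10%-missing, "
                "one-SNP-per-locus sites")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stages": list(cfg.stages), "outputs": []}
    summary: dict = {}

    def _emit(name: str):
        manifest["outputs"].append(name)

    log_lines = [f"divscan {__version__} pipeline, seed {cfg.seed}",
                 f"stages: {', '.join(cfg.stages)}"]

    stage = "init"
    try:
        # ------------------------------------------------------------- data
        radloci = None
        pheno = None
        annot = None
        qtl = None
        q_true = None
        if cfg.sim is not None and "simulate" in cfg.stages:
            stage = "simulate"
            sim = SimConfig(**{**vars(cfg.sim), "seed": stage_seed(cfg.seed, "simulate")})
            gm, radloci, popmap, q_true = simulate_dataset(sim)
            chrom_lengths = sim.chrom_lengths
            pheno = simulate_phenotypes(
                {i: (1.0 if popmap.life_history[i] == "ferox" else 0.0)
                 for i in gm.individuals},
                seed=stage_seed(cfg.seed, "simulate") + 1)
            write_vcf(gm, out / "genotypes.vcf", chrom_lengths)
            write_popmap(popmap, out / "popmap.tsv")
            write_phenotypes(pheno, out / "phenotypes.tsv")
            with open(out / "ancestry_true.tsv", "w") as fh:
                fh.write("individual\tq_true\n")
                for i, v in q_true.items():
                    fh.write(f"{i}\t{v}\n")
            _emit("genotypes.vcf")
            _emit("popmap.tsv")
            _emit("phenotypes.tsv")
            _emit("ancestry_true.tsv")
            log_lines.append(f"simulate: {gm.n_sites} SNPs, "
                             f"{gm.n_individuals} individuals ({sim.model})")
            summary["n_snps_raw"] = gm.n_sites
            s_all = gm.n_sites
            n_loci_total = sim.n_loci
            locus_len = sim.locus_length
        else:
            stage = "load"
            gm = read_vcf(cfg.vcf)
            popmap, pheno, *tracks = load_tables(
                cfg.popmap, cfg.phenotypes,
                [p for p in (cfg.annotation_track, cfg.qtl_track) if p], gm)
            chrom_lengths = (read_chrom_lengths(cfg.chrom_lengths)
                             if cfg.chrom_lengths else ())
            s_all = gm.n_sites
            n_loci_total = None
            locus_len = 55
            if cfg.annotation_track:
                annot = tracks[0]
            if cfg.qtl_track:
                qtl = tracks[-1]
            summary["n_snps_raw"] = gm.n_sites

        grid = build_windows(chrom_lengths, cfg.window_size, cfg.window_step) \
            if chrom_lengths else None
        if cfg.sim is not None and grid is not None and annot is None:
            annot = simulate_annotation_track(grid, lam=1000.0,
                                              seed=stage_seed(cfg.seed, "simulate") + 2)
            write_track(annot, out / "annotation.bed")
            _emit("annotation.bed")

        # ----------------------------------------------------------- filter
        gm_scan = gm
        gm_demog = gm
        if "filter" in cfg.stages:
            stage = "filter"
            gm_scan = filter_snps(gm, popmap, cfg.filter_cfg)
            gm_demog = demographic_site_filter(gm)
            log_lines.append(f"filter: scan set {gm_scan.n_sites} SNPs, "
                             f"demographic set {gm_demog.n_sites} SNPs")
            summary["n_snps_scan"] = gm_scan.n_sites
            summary["n_snps_demographic"] = gm_demog.n_sites

        # ------------------------------------------------------- demography
        if "demography" in cfg.stages:
            stage = "demography"
            jsfs = compute_folded_jsfs(gm_demog, popmap)
            if cfg.demog_projection:
                jsfs = project_jsfs(jsfs, cfg.demog_projection)
            if n_loci_total is not None:
                mono = correct_monomorphic(n_loci_total, locus_len, s_all,
                                           jsfs.n_snps_used)
                jsfs = jsfs.with_monomorphic(mono)
            jsfs.to_dadi_text(out / "jsfs.sfs")
            _emit("jsfs.sfs")
            fits = []
            for model_id in cfg.demog_models:
                fit = fit_model(DemographicModel(model_id), jsfs,
                                cycles=cfg.demog_cycles,
                                sims_per_eval=cfg.demog_sims,
                                n_runs=cfg.demog_runs,
                                seed=stage_seed(cfg.seed, "demography"))
                fits.append(fit)
                log_lines.append(f"demography: {model_id} lnL={fit.lnl_natural:.2f} "
                                 f"AIC={fit.aic:.2f}")
            if len(fits) >= 2:
                ranking = select_model(fits)
            else:
                ranking = pd.DataFrame({
                    "model": [fits[0].model_id], "lnL": [fits[0].lnl_natural],
                    "k": [fits[0].k], "AIC": [fits[0].aic], "dAIC": [0.0]})
            ranking.to_csv(out / "model_selection.tsv", sep="\t", index=False)
            _emit("model_selection.tsv")
            best = max(fits, key=lambda f: -f.aic)
            top = best.run_params[:10]
            ci = bootstrap_ci(top, n_resamples=10_000,
                              seed=stage_seed(cfg.seed, "demography") + 1)
            ci.to_csv(out / "parameter_ci.tsv", sep="\t")
            _emit("parameter_ci.tsv")
            summary["best_model"] = best.model_id
            summary["best_params"] = {k: float(v)
                                      for k, v in vars(best.params).items()}
            summary["tdiv_years"] = generations_to_years(
                best.params.tdiv, cfg.generation_time)
            summary["model_ranking"] = ranking.to_dict(orient="records")

        # ------------------------------------------------------------- scan
        if "scan" in cfg.stages and grid is not None:
            stage = "scan"
            brown = popmap.individuals_of_type("benthivorous")
            ferox = popmap.individuals_of_type("ferox")
            sstats = wc_fst_sites(gm_scan, brown, ferox)
            sstats.to_csv(out / "site_fst.tsv", sep="\t", index=False)
            _emit("site_fst.tsv")
            pi_tabs = {"benthivorous": site_pi(gm_scan, brown),
                       "ferox": site_pi(gm_scan, ferox)}
            hap_tabs = None
            if radloci is not None:
                hap_tabs = {"benthivorous": locus_haplotype_stats(radloci, brown),
                            "ferox": locus_haplotype_stats(radloci, ferox)}
            wstats = window_scan(sstats, grid, pi_tabs, hap_tabs, cfg.scan_cfg)
            if hap_tabs is not None and wstats["outlier"].any():
                wstats = delta_classify(wstats, cfg.scan_cfg)
            wstats.to_csv(out / "window_stats.tsv", sep="\t", index=False)
            _emit("window_stats.tsv")
            outliers = wstats[wstats["outlier"]]
            with open(out / "outlier_windows.bed", "w") as fh:
                if len(outliers) == 0:
                    fh.write("# no outlier windows\n")
                for w in outliers.itertuples(index=False):
                    fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")
            _emit("outlier_windows.bed")
            summary["n_outlier_windows"] = int(wstats["outlier"].sum())
            if cfg.plots:
                from .scan import plot_genome_scan
                plot_genome_scan(wstats, out / "zfst_scan.png")
                _emit("zfst_scan.png")
            if wstats["outlier"].any() and (~wstats["outlier"]).any():
                for group in ("benthivorous", "ferox"):
                    col = f"pi_{group}"
                    vals = wstats[col]
                    if vals.notna().sum() > 2:
                        _, pval = outlier_background_compare(
                            vals, wstats["outlier"])
                        summary[f"pi_outlier_vs_background_p_{group}"] = pval
            if annot is not None:
                dens, wil, spear = functional_density_analysis(annot, grid, wstats)
                if spear is not None:
                    summary["density_fst_spearman"] = {"rho": spear[0],
                                                      "p": spear[1]}
                if wil is not None:
                    summary["density_outlier_wilcoxon_p"] = wil[1]
            if qtl is not None:
                overlaps = qtl_overlap(outliers, qtl)
                overlaps.to_csv(out / "qtl_overlap.tsv", sep="\t", index=False)
                _emit("qtl_overlap.tsv")
                summary["n_qtl_overlaps"] = len(overlaps)
            log_lines.append(f"scan: {summary.get('n_outlier_windows', 0)} "
                             "outlier windows")

        # -------------------------------------------------------- structure
        if "structure" in cfg.stages:
            stage = "structure"
            pca = pca_impute(gm_scan, cfg.pca_k)
            pd.DataFrame(pca.scores, index=gm_scan.individuals).to_csv(
                out / "pca_scores.tsv", sep="\t", header=False)
            _emit("pca_scores.tsv")
            summary["pca_var_frac"] = [float(v) for v in pca.var_frac]
            sel = selection_scan(gm_scan, cfg.pca_k, cfg.fdr,
                                 seed=stage_seed(cfg.seed, "structure"))
            sel.table.to_csv(out / "selection_scan.tsv", sep="\t", index=False)
            _emit("selection_scan.tsv")
            summary["selection_scan_lambda"] = sel.inflation_lambda
            summary["n_selection_outliers"] = int(sel.table["outlier"].sum())
            amova = amova3(gm_scan, popmap, n_perm=cfg.amova_permutations,
                           seed=stage_seed(cfg.seed, "structure") + 1)
            amova.components.to_csv(out / "amova.tsv", sep="\t", index=False)
            _emit("amova.tsv")
            summary["amova_f"] = amova.f_stats
            summary["amova_p"] = amova.p_values
            if pheno is not None:
                rho, pval = ancestry_phenotype_correlation(pheno)
                summary["ancestry_length_spearman"] = {"rho": rho, "p": pval}
            log_lines.append("structure: lambda="
                             f"{summary['selection_scan_lambda']:.3f}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    _emit("summary.json")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    _emit("run.log")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    for name in manifest["outputs"]:
        path = out / name
        if not path.exists() or path.stat().st_size == 0:
            raise RuntimeError(f"declared output {name} missing or empty")
    return manifest
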