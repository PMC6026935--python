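"""Population structure: PCA, PCA-based selection scan, AMOVA, ancestry.

- :func:`pca_impute` — PCA of the genotype matrix with per-site mean
  imputation of missing calls and centering only (no unit-variance
  scaling, the adegenet default).
- :func:`selection_scan` — eigen-GWAS outlier scan: per-SNP z-scores of
  the genotype regression on the leading K principal components, robust
  Mahalanobis distance, genomic-inflation correction and
  Benjamini–Hochberg q-values.
- :func:`amova3` — three-level hierarchical analysis of molecular
  variance (individuals within sampling sites within life-history types)
  with permutation p-values.
- :func:`ancestry_phenotype_correlation` — Spearman rank correlation of
  ancestry coefficient and fork length.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    MISSING,
    DataError,
    GenotypeMatrix,
    PhenotypeTable,
    PopulationMap,
)

logger = logging.getLogger("divscan")


@dataclass
class PcaResult:
    scores: np.ndarray       # individuals x K
    loadings: np.ndarray     # sites x K
    var_frac: np.ndarray     # fraction of total variance per axis
    kept_sites: np.ndarray   # indices of sites used (all-missing dropped)


@dataclass
class SelectionScanResult:
    table: pd.DataFrame      # per-SNP: d2, p, q, assigned_pc, outlier
    inflation_lambda: float
    k: int
    fdr: float


@dataclass
class AmovaResult:
    components: pd.DataFrame  # variance components table
    f_stats: dict[str, float]
    p_values: dict[str, float | None]


def _impute_mean(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    all_missing = np.isnan(col_mean)
    if all_missing.any():
        logger.warning("pca: dropping %d all-missing sites", all_missing.sum())
    kept = np.flatnonzero(~all_missing)
    g = g[:, kept]
    col_mean = col_mean[kept]
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]
    return g, kept


def pca_impute(gm: GenotypeMatrix, k: int = 2) -> PcaResult:
    """PCA with per-site mean imputation; centering only, no scaling."""
    if gm.n_individuals < 2 or gm.n_sites < 2:
        raise DataError("PCA needs at least 2 individuals and 2 sites")
    g, kept = _impute_mean(gm)
    g = g - g.mean(axis=0)
    u, s, vt = np.linalg.svd(g, full_matrices=False)
    k = min(k, len(s))
    var = s**2
    return PcaResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        var_frac=var[:k] / var.sum(),
        kept_sites=kept,
    )


def selection_scan(gm: GenotypeMatrix, k: int = 2, fdr: float = 0.05,
                   seed: int = 0) -> SelectionScanResult:
    """PCA-based (eigen-GWAS) per-SNP selection scan.

    For each SNP, the z-scores of the multiple regression of (imputed,
    centered) genotype on the first ``k`` PC scores form a K-vector; robust
    Mahalanobis D^2 over SNPs (minimum-covariance-determinant estimate) is
    rescaled by the genomic inflation factor lambda = median(D^2) /
    median(chi^2_K) and referred to chi^2_K.  Outliers are SNPs with
    Benjamini–Hochberg q < ``fdr``, each assigned to the PC with the
    largest squared correlation.
    """
    if k >= gm.n_individuals - 1:
        raise DataError("k must be < n_individuals - 1")
    pca = pca_impute(gm, k)
    g, kept = _impute_mean(gm)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0, ddof=1)
    informative = sd > 0
    if (~informative).any():
        logger.info("selection_scan: %d constant SNPs excluded",
                    (~informative).sum())

    X = pca.scores  # n x K, orthogonal columns
    n = X.shape[0]
    # per-SNP OLS z-scores: beta = (X'X)^-1 X'y computed for all SNPs at once
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ g)  # K x n_snps
    resid = g - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se, np.nan)  # K x n_snps
    zt = z.T[informative]

    mcd = MinCovDet(random_state=seed).fit(zt)
    d2 = mcd.mahalanobis(zt)
    lam = float(np.median(d2) / stats.chi2.median(df=k))
    if lam <= 0 or not np.isfinite(lam):
        raise DataError("degenerate genomic inflation factor")
    p = stats.chi2.sf(d2 / lam, df=k)
    p = np.maximum(p, np.finfo(float).tiny)  # p in (0, 1]
    _, q, *_ = multipletests(p, method="fdr_bh")

    # assign each SNP to the PC it correlates with most strongly
    gc = g[:, informative]
    corr = np.empty((k, gc.shape[1]))
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    gs = (gc - gc.mean(axis=0)) / gc.std(axis=0, ddof=1)
    corr = (xs.T @ gs) / (n - 1)
    assigned = np.argmax(corr**2, axis=0) + 1

    full = pd.DataFrame({
        "chrom": gm.sites["chrom"].to_numpy()[kept],
        "pos": gm.sites["pos"].to_numpy()[kept],
    })
    for name, vals in (("d2", d2), ("p", p), ("q", q),
                       ("assigned_pc", assigned)):
        col = np.full(len(kept), np.nan)
        col[informative] = vals
        full[name] = col
    full["outlier"] = full["q"] < fdr
    return SelectionScanResult(full, lam, k, fdr)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _copies(g: np.ndarray) -> np.ndarray:
    """Expand genotypes to gene copies, shape (2 n_ind, n_loci).

    Heterozygotes contribute copies (0, 1); homozygotes (g/2, g/2); missing
    genotypes become NaN copies.  Which copy of a heterozygote carries the
    alternate allele is arbitrary and cancels in all sums of squares.
    """
    n_ind, n_loci = g.shape
    c = np.empty((2 * n_ind, n_loci))
    gf = g.astype(float)
    het = g == 1
    miss = g == MISSING
    c[0::2] = np.where(het, 0.0, gf / 2.0)
    c[1::2] = np.where(het, 1.0, gf / 2.0)
    c[0::2][miss] = np.nan
    c[1::2][miss] = np.nan
    return c


def _amova_components(copies: np.ndarray, site_idx: np.ndarray,
                      type_idx: np.ndarray, type_of_site: np.ndarray):
    """Variance components from allele-based sums of squares, summed over loci.

    ``copies`` is the (2 n_ind, n_loci) gene-copy matrix; ``site_idx`` /
    ``type_idx`` give each individual's site and type (integer codes) and
    ``type_of_site`` each site's type.  Per-locus unbalanced nested-ANOVA
    expected-mean-square coefficients convert the four sums of squares
    (among types a, among sites within types b, among individuals within
    sites c, within individuals d) into variance components, which are
    additive across loci.
    """
    n_ind = copies.shape[0] // 2
    S = int(type_of_site.size)
    T = int(type_idx.max()) + 1

    w = (~np.isnan(copies[0::2])).astype(float) + (~np.isnan(copies[1::2]))
    ind_sum = np.nan_to_num(copies[0::2]) + np.nan_to_num(copies[1::2])
    with np.errstate(invalid="ignore", divide="ignore"):
        ind_mean = np.where(w > 0, ind_sum / np.maximum(w, 1), 0.0)

    A_site = np.zeros((S, n_ind))
    A_site[site_idx, np.arange(n_ind)] = 1.0
    A_type = np.zeros((T, n_ind))
    A_type[type_idx, np.arange(n_ind)] = 1.0
    A_ts = np.zeros((T, S))
    A_ts[type_of_site, np.arange(S)] = 1.0

    N = w.sum(axis=0)
    grand = ind_sum.sum(axis=0) / np.maximum(N, 1)

    # sums of squares per locus
    dev = copies - np.repeat(ind_mean, 2, axis=0)
    ssd = np.nansum(dev**2, axis=0)

    n_site = A_site @ w
    site_sum = A_site @ ind_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        site_mean = np.where(n_site > 0, site_sum / np.maximum(n_site, 1), 0.0)
    sm_of_ind = site_mean[site_idx]
    ssc = (w * (ind_mean - sm_of_ind) ** 2).sum(axis=0)

    n_type = A_type @ w
    type_sum = A_type @ ind_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        type_mean = np.where(n_type > 0, type_sum / np.maximum(n_type, 1), 0.0)
    tm_of_site = type_mean[type_of_site]
    ssb = (n_site * (site_mean - tm_of_site) ** 2).sum(axis=0)
    ssa = (n_type * (type_mean - grand[None, :]) ** 2).sum(axis=0)

    # degrees of freedom per locus
    I = (w > 0).sum(axis=0).astype(float)
    S_pres = (n_site > 0).sum(axis=0).astype(float)
    T_pres = (n_type > 0).sum(axis=0).astype(float)
    df_d = N - I
    df_c = I - S_pres
    df_b = S_pres - T_pres
    df_a = T_pres - 1

    # unbalanced nested-ANOVA EMS coefficients per locus
    w2 = w**2
    sw2_site = A_site @ w2
    sw2_type = A_type @ w2
    with np.errstate(invalid="ignore", divide="ignore"):
        term1 = np.where(n_site > 0, sw2_site / np.maximum(n_site, 1), 0.0).sum(axis=0)
        term2 = np.where(n_type > 0, sw2_type / np.maximum(n_type, 1), 0.0).sum(axis=0)
        sn2_by_type = A_ts @ n_site**2
        sn2t = np.where(n_type > 0, sn2_by_type / np.maximum(n_type, 1), 0.0).sum(axis=0)
    sw2_all = w2.sum(axis=0)
    sn2_all = (n_site**2).sum(axis=0)
    nt2_all = (n_type**2).sum(axis=0)

    def _safe(num, den):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    n1c = _safe(N - term1, df_c)
    n2c = _safe(term1 - term2, df_b)
    n3b = _safe(N - sn2t, df_b)
    n4c = _safe(term2 - _safe(sw2_all, N), df_a)
    n5b = _safe(sn2t - _safe(sn2_all, N), df_a)
    n6a = _safe(N - _safe(nt2_all, N), df_a)

    sd2 = _safe(ssd, df_d)
    sc2 = _safe(_safe(ssc, df_c) - sd2, n1c)
    sc2 = np.where(df_c > 0, sc2, 0.0)
    sb2 = _safe(_safe(ssb, df_b) - sd2 - n2c * sc2, n3b)
    sb2 = np.where(df_b > 0, sb2, 0.0)
    sa2 = _safe(_safe(ssa, df_a) - sd2 - n4c * sc2 - n5b * sb2, n6a)
    sa2 = np.where(df_a > 0, sa2, 0.0)

    comp = np.array([sa2.sum(), sb2.sum(), sc2.sum(), sd2.sum()])
    ss_sum = np.array([ssa.sum(), ssb.sum(), ssc.sum(), ssd.sum()])
    df_sum = np.array([df_a.sum(), df_b.sum(), df_c.sum(), df_d.sum()])
    return comp, ss_sum, df_sum


def amova3(gm: GenotypeMatrix, popmap: PopulationMap, n_perm: int = 999,
           seed: int = 0) -> AmovaResult:
    """Three-level hierarchical AMOVA: sites nested within life-history types.

    F-statistics: Fct = sa/(sa+sb+sc+sd), Fsc = sb/(sb+sc+sd),
    Fis = sc/(sc+sd), Fit = (sa+sb+sc)/(sa+sb+sc+sd).  Permutation
    p-values: individuals among sites within types (Fsc), whole sites among
    types (Fct).
    """
    popmap.validate_against(gm)
    site_lab = np.array([popmap.site[i] for i in gm.individuals])
    type_lab = np.array([popmap.life_history[i] for i in gm.individuals])
    site_names, site_idx = np.unique(site_lab, return_inverse=True)
    if site_names.size < 2:
        raise DataError("AMOVA needs at least two sampling sites")
    # each site belongs to one type (nested design)
    type_of_site_lab = np.array([type_lab[site_idx == s][0]
                                 for s in range(site_names.size)])
    for s in range(site_names.size):
        if len(set(type_lab[site_idx == s])) > 1:
            raise DataError(f"site {site_names[s]} spans multiple life-history "
                            "types; hierarchy must be nested")
    type_names, type_of_site = np.unique(type_of_site_lab, return_inverse=True)
    type_idx = type_of_site[site_idx]
    copies = _copies(gm.genotypes)

    comp, ss, df = _amova_components(copies, site_idx, type_idx, type_of_site)
    sa, sb, sc_, sd = comp
    tot = comp.sum()

    def _ratio(num, den):
        return float(num / den) if den > 0 else float("nan")

    f = {
        "Fct": _ratio(sa, tot),
        "Fsc": _ratio(sb, sb + sc_ + sd),
        "Fis": _ratio(sc_, sc_ + sd),
        "Fit": _ratio(sa + sb + sc_, tot),
    }

    rng = np.random.default_rng(seed)
    p: dict[str, float | None] = {"Fct": None, "Fsc": None}
    single_type = type_names.size < 2
    if single_type:
        logger.warning("amova3: single life-history type, Fct p undefined")

    if n_perm > 0:
        # Fsc: permute individuals among sites within their type
        count = 0
        for _ in range(n_perm):
            perm_site = site_idx.copy()
            for t in range(type_names.size):
                sel = np.flatnonzero(type_idx == t)
                perm_site[sel] = site_idx[sel][rng.permutation(sel.size)]
            c, *_ = _amova_components(copies, perm_site, type_idx, type_of_site)
            if _ratio(c[1], c[1] + c[2] + c[3]) >= f["Fsc"]:
                count += 1
        p["Fsc"] = (count + 1) / (n_perm + 1)
        # Fct: permute whole sites among types
        if not single_type:
            count = 0
            for _ in range(n_perm):
                perm_ts = type_of_site[rng.permutation(type_of_site.size)]
                perm_type = perm_ts[site_idx]
                c, *_ = _amova_components(copies, site_idx, perm_type, perm_ts)
                if _ratio(c[0], c.sum()) >= f["Fct"]:
                    count += 1
            p["Fct"] = (count + 1) / (n_perm + 1)

    pct = 100 * comp / tot if tot > 0 else np.zeros(4)
    table = pd.DataFrame({
        "source": ["Among types", "Among sites", "Among ind.", "Within ind."],
        "nested_in": ["-", "Type", "Site", "-"],
        "sigma2": comp,
        "pct_var": pct,
        "SS": ss,
        "df": df,
    })
    return AmovaResult(table, f, p)


def ancestry_phenotype_correlation(pheno: PhenotypeTable):
    """Spearman rank correlation of ancestry coefficient q and fork length.

    Mid-rank ties; exact permutation p for n <= 9, t-approximation beyond.
    """
    inds = [i for i in pheno.ancestry_q if i in pheno.fork_length]
    if len(inds) < 3:
        raise DataError("need at least 3 paired observations")
    q = np.array([pheno.ancestry_q[i] for i in inds])
    fl = np.array([pheno.fork_length[i] for i in inds])
    if np.unique(q).size < 2 or np.unique(fl).size < 2:
        raise DataError("constant vector: correlation undefined")
    rho, p_t = stats.spearmanr(q, fl)
    n = len(inds)
    if n <= 9:
        rq = stats.rankdata(q)
        rf = stats.rankdata(fl)

        def _rho(a, b):
            return float(np.corrcoef(a, b)[0, 1])

        obs = abs(_rho(rq, rf))
        hits = total = 0
        for perm in itertools.permutations(rf):
            total += 1
            if abs(_rho(rq, np.array(perm))) >= obs - 1e-12:
                hits += 1
        return float(rho), hits / total
    return float(rho), float(p_t)
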