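"""Differentiation and diversity scans across the genome.

Per-SNP Weir & Cockerham (1984) Fst between the two life-history groups,
z-transformed genome-wide (ZFst); SNP-based nucleotide diversity;
haplotype-based gene diversity and haplotype diversity per RAD locus;
sliding-window aggregation with outlier-window calling (window mean ZFst > 4
and at least two differentiated variants); delta-diversity classification
of outlier windows (which group lost diversity); Wilcoxon outlier-versus-
background contrasts; functional-density and QTL-overlap analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    MISSING,
    DataError,
    GenotypeMatrix,
    IntervalTrack,
    RadLocusHaplotypes,
    WindowGrid,
)

logger = logging.getLogger("divscan")


@dataclass(frozen=True)
class ScanConfig:
    """Outlier-window thresholds."""

    zfst_threshold: float = 4.0
    min_diff_variants: int = 2
    delta_quantile: float = 0.75

    def __post_init__(self):
        if self.zfst_threshold <= 0:
            raise DataError("zfst_threshold must be positive")
        if not (0.0 <= self.delta_quantile <= 1.0):
            raise DataError("delta_quantile must be in [0, 1]")


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def _group_rows(gm: GenotypeMatrix, group) -> list[int]:
    return [gm.individuals.index(i) for i in group if i in gm.individuals]


def wc_fst_sites(gm: GenotypeMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-site Weir & Cockerham (1984) theta-hat between two groups.

    Variance components: among populations (a), among individuals within
    populations (b), within individuals (c); theta = a / (a + b + c).
    Negative estimates are retained.  Sites with fewer than two genotyped
    individuals in either group get NaN.
    """
    rows_a, rows_b = _group_rows(gm, group_a), _group_rows(gm, group_b)
    if not rows_a or not rows_b:
        raise DataError("both groups must be non-empty")
    out = {"chrom": gm.sites["chrom"], "pos": gm.sites["pos"]}
    n_i, p_i, h_i = [], [], []
    for rows in (rows_a, rows_b):
        g = gm.genotypes[rows]
        called = g != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, g, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, (g == 1).sum(axis=0) / n, np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n1, n2 = n_i
    p1, p2 = p_i
    h1, h2 = h_i

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    valid = (n1 >= 2) & (n2 >= 2)
    fst = np.where(valid, fst, np.nan)
    out.update({"fst": fst, "p_a": p1, "p_b": p2, "n_a": n1, "n_b": n2})
    return pd.DataFrame(out)


def zfst(values) -> np.ndarray:
    """Z-transform against the genome-wide sample mean and sd.

    A constant vector (sd = 0) yields all-NaN with a warning — no outliers.
    NaN inputs propagate and are excluded from mean/sd.
    """
    x = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(x)) < 2:
        raise DataError("need at least two finite values to z-transform")
    mean = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        warnings.warn("zero variance: ZFst undefined, no outliers callable")
        return np.full_like(x, np.nan)
    return (x - mean) / sd


def site_pi(gm: GenotypeMatrix, group) -> pd.DataFrame:
    """Per-site nucleotide diversity within a group.

    pi = c_ref * c_alt / C(n, 2) over non-missing allele counts n; SNP-based
    (window averages are means over SNPs, not per bp).
    """
    rows = _group_rows(gm, group)
    g = gm.genotypes[rows]
    called = g != MISSING
    n = 2 * called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0).astype(float)
    ref = n - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, ref * alt / (n * (n - 1) / 2), np.nan)
    return pd.DataFrame({"chrom": gm.sites["chrom"], "pos": gm.sites["pos"],
                         "pi": pi})


def locus_haplotype_stats(radloci: RadLocusHaplotypes, group) -> pd.DataFrame:
    """Per-RAD-locus gene diversity and haplotype diversity within a group.

    Gene diversity: (n/(n-1)) (1 - sum p_i^2) over haplotype frequencies.
    Haplotype diversity: sum_{i != j} p_i p_j d_ij with d_ij the substitution
    count between haplotypes i and j (gene diversity scaled to distance).
    """
    group = set(group)
    rows = []
    for locus_id, per_ind in radloci.haplotypes.items():
        haps = []
        for ind, pair in per_ind.items():
            if ind in group and pair is not None:
                haps.extend(pair)
        if len(haps) < 2:
            continue
        lengths = {len(h) for h in haps}
        if len(lengths) != 1:
            raise DataError(f"locus {locus_id}: unequal haplotype lengths")
        uniq, counts = np.unique(haps, return_counts=True)
        n = counts.sum()
        p = counts / n
        gene_div = (n / (n - 1)) * (1.0 - np.sum(p**2))
        arr = np.frombuffer("".join(uniq).encode(), dtype="S1").reshape(len(uniq), -1)
        d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        hap_div = float(p @ d @ p)
        chrom, start = radloci.location[locus_id]
        rows.append((locus_id, chrom, start, n, gene_div, hap_div))
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "n_haps",
                                       "gene_diversity", "haplotype_diversity"])


# ---------------------------------------------------------------------------
# sliding-window aggregation
# ---------------------------------------------------------------------------


def _assign_windows(windows: pd.DataFrame, chrom, pos) -> list[np.ndarray]:
    """Indices of points (chrom, pos) falling in each half-open window."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    by_chrom = {}
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = np.argsort(pos[idx], kind="stable")
        by_chrom[c] = (idx[order], pos[idx][order])
    empty = np.empty(0, dtype=int)
    out = []
    for w in windows.itertuples(index=False):
        if w.chrom not in by_chrom:
            out.append(empty)
            continue
        idx, ps = by_chrom[w.chrom]
        lo = np.searchsorted(ps, w.start, side="left")
        hi = np.searchsorted(ps, w.end, side="left")
        out.append(idx[lo:hi])
    return out


def window_scan(site_stats: pd.DataFrame, grid: WindowGrid,
                pi_tables: dict[str, pd.DataFrame] | None = None,
                hap_tables: dict[str, pd.DataFrame] | None = None,
                cfg: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Aggregate per-SNP statistics into sliding windows and flag outliers.

    A window is an outlier when its mean-Fst z-score (taken across windows
    holding >= 1 SNP) exceeds ``cfg.zfst_threshold`` and it contains at
    least ``cfg.min_diff_variants`` differentiated variants (per-SNP ZFst
    above the same threshold).  Windows without SNPs carry NaN statistics
    and are excluded from the standardisation.
    """
    windows = grid.windows.copy()
    snp_z = zfst(site_stats["fst"].to_numpy())
    members = _assign_windows(windows, site_stats["chrom"], site_stats["pos"])

    fst = site_stats["fst"].to_numpy()
    n_snps = np.array([m.size for m in members])
    mean_fst = np.array([np.nanmean(fst[m]) if m.size else np.nan for m in members])
    n_diff = np.array([int(np.nansum(snp_z[m] > cfg.zfst_threshold)) if m.size else 0
                       for m in members])

    has = np.isfinite(mean_fst)
    win_z = np.full(len(windows), np.nan)
    if has.sum() >= 2:
        win_z[has] = zfst(mean_fst[has])
    windows["n_snps"] = n_snps
    windows["mean_fst"] = mean_fst
    windows["zfst"] = win_z
    windows["n_diff_variants"] = n_diff
    windows["outlier"] = (win_z > cfg.zfst_threshold) & (n_diff >= cfg.min_diff_variants)

    for label, tables in (("pi", pi_tables), ("", hap_tables)):
        if not tables:
            continue
        for group, tab in tables.items():
            if label == "pi":
                mem = _assign_windows(windows, tab["chrom"], tab["pos"])
                vals = tab["pi"].to_numpy()
                windows[f"pi_{group}"] = [
                    np.nanmean(vals[m]) if m.size else np.nan for m in mem]
            else:
                mem = _assign_windows(windows, tab["chrom"], tab["start"])
                for stat in ("gene_diversity", "haplotype_diversity"):
                    vals = tab[stat].to_numpy()
                    windows[f"{stat}_{group}"] = [
                        np.nanmean(vals[m]) if m.size else np.nan for m in mem]
    return windows


def delta_classify(window_stats: pd.DataFrame,
                   cfg: ScanConfig = ScanConfig(),
                   brown: str = "benthivorous",
                   ferox: str = "ferox",
                   stat: str = "gene_diversity") -> pd.DataFrame:
    """Classify outlier windows by which group lost diversity.

    Delta = diversity(brown) - diversity(ferox).  Outlier windows whose
    |delta| exceeds the genome-wide |delta| quantile are classed
    ``brown-reduced`` (delta < 0) or ``ferox-reduced`` (delta > 0); the rest
    are ``unclassified``.
    """
    df = window_stats.copy()
    col_b, col_f = f"{stat}_{brown}", f"{stat}_{ferox}"
    if col_b not in df or col_f not in df:
        raise DataError(f"window stats lack {col_b}/{col_f} columns")
    delta = df[col_b] - df[col_f]
    df["delta_diversity"] = delta
    abs_delta = delta.abs()
    thresh = abs_delta.quantile(cfg.delta_quantile)
    cls = np.where(~df["outlier"] | delta.isna(), "unclassified",
                   np.where(abs_delta <= thresh, "unclassified",
                            np.where(delta < 0, "brown-reduced", "ferox-reduced")))
    df["delta_class"] = cls
    return df


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


def outlier_background_compare(values, outlier_flags):
    """Wilcoxon rank-sum of a per-window statistic, outlier vs background.

    Exact two-sided p for small samples (combined n <= 25, no ties), normal
    approximation with tie correction otherwise.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(outlier_flags, dtype=bool)
    keep = np.isfinite(values)
    x = values[keep & flags]
    y = values[keep & ~flags]
    if x.size == 0 or y.size == 0:
        raise DataError("both outlier and background groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def functional_density_analysis(track: IntervalTrack, grid: WindowGrid,
                                window_stats: pd.DataFrame):
    """Annotated-character density per window, with outlier contrasts.

    Density is the overlap-proportional sum of track values over each
    window.  Returns ``(densities, wilcoxon (stat, p) or None,
    spearman (rho, p) or None)``; correlations are flagged ``None`` when
    undefined (empty track or constant input).
    """
    windows = grid.windows
    dens = np.zeros(len(windows))
    rec = track.records
    for k, w in enumerate(windows.itertuples(index=False)):
        on = rec[rec["chrom"] == w.chrom] if len(rec) else rec
        if not len(on):
            continue
        ov = (np.minimum(on["end"], w.end) - np.maximum(on["start"], w.start)).clip(lower=0)
        frac = ov / (on["end"] - on["start"])
        dens[k] = float((frac * on["value"]).sum())

    if len(rec) == 0:
        logger.warning("functional_density_analysis: empty track, "
                       "correlation undefined")
        return dens, None, None
    flags = window_stats["outlier"].to_numpy(dtype=bool)
    wilcox = (outlier_background_compare(dens, flags)
              if flags.any() and (~flags).any() else None)
    fst = window_stats["mean_fst"].to_numpy(dtype=float)
    ok = np.isfinite(fst)
    if ok.sum() >= 3 and np.unique(dens[ok]).size > 1 and np.unique(fst[ok]).size > 1:
        rho, p = stats.spearmanr(dens[ok], fst[ok])
        spear = (float(rho), float(p))
    else:
        spear = None
    return dens, wilcox, spear


def qtl_overlap(outlier_windows: pd.DataFrame, qtl_track: IntervalTrack) -> pd.DataFrame:
    """(window, QTL trait) pairs with >= 1 bp overlap (half-open intervals)."""
    rows = []
    rec = qtl_track.records
    for w in outlier_windows.itertuples(index=False):
        if len(rec) == 0:
            break
        hits = rec[(rec["chrom"] == w.chrom) & (rec["start"] < w.end)
                   & (rec["end"] > w.start)]
        for q in hits.itertuples(index=False):
            rows.append((w.chrom, w.start, w.end, q.start, q.end, q.value))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                       "qtl_start", "qtl_end", "trait"])


def plot_genome_scan(window_stats: pd.DataFrame, path,
                     span: float = 0.1) -> None:
    """Window ZFst along the genome with outlier windows highlighted.

    Negative ZFst values are clipped to zero for display; a loess curve
    (plotting aid only) is overlaid per chromosome.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ws = window_stats.dropna(subset=["zfst"]).copy()
    chroms = list(dict.fromkeys(ws["chrom"]))
    fig, ax = plt.subplots(figsize=(12, 3))
    offset = 0
    ticks = []
    for ci, chrom in enumerate(chroms):
        sub = ws[ws["chrom"] == chrom]
        x = sub["start"].to_numpy() + offset
        y = np.clip(sub["zfst"].to_numpy(), 0, None)
        ax.scatter(x, y, s=6, color=["#7a5230", "#c8a165"][ci % 2])
        if len(sub) >= 5:
            ax.plot(x, np.clip(loess_smooth(sub["start"], sub["zfst"], span),
                               0, None), lw=0.8, color="#333333")
        out = sub[sub["outlier"]]
        ax.scatter(out["start"] + offset, np.clip(out["zfst"], 0, None),
                   s=14, color="#c02020", zorder=3)
        ticks.append(offset + (sub["start"].max() if len(sub) else 0) / 2)
        offset += (sub["start"].max() + 500_000) if len(sub) else 500_000
    ax.axhline(4, ls="--", lw=0.8, color="#c02020")
    ax.set_xticks(ticks)
    ax.set_xticklabels(chroms, rotation=90, fontsize=6)
    ax.set_ylabel("ZFst")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def loess_smooth(x, y, span: float = 0.1) -> np.ndarray:
    """Local quadratic smoothing for plotting only (excluded from statistics)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(3, int(np.ceil(span * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        w = (1 - (d[idx] / max(d[idx].max(), 1e-12)) ** 3) ** 3
        X = np.vander(x[idx] - x[i], 3)
        W = np.diag(w)
        beta, *_ = np.linalg.lstsq(W @ X, W @ y[idx], rcond=None)
        out[i] = beta[-1]
    return out
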