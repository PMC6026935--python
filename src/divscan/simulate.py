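"""Synthetic ddRAD-like dataset generation with known ground truth.

Datasets are simulated under the same two-population coalescent engine used
for demographic inference: independent non-recombining RAD loci (free
recombination between loci, none within), infinite-sites mutation at rate
mu per bp per generation, diploids formed by pairing consecutive simulated
haplotypes.  Defaults emulate the study conditions: 55 bp loci on 29
chromosomes, 20 benthivorous ("brown") + 8 ferox diploids, ~12% missing
genotypes, and the secondary-contact-with-admixture demography at its
point estimates.

Ground-truth extras for testing downstream scans: an injectable
differentiated window (:func:`inject_differentiated_region`), phenotypes
linearly coupled to ancestry (:func:`simulate_phenotypes`) and Poisson
annotation-density tracks (:func:`simulate_annotation_track`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coalescent import MAX_HAPLOIDS, simulate_mutation_masks
from .datamodel import (
    MISSING,
    DataError,
    GenotypeMatrix,
    IntervalTrack,
    PhenotypeTable,
    PopulationMap,
    RadLocusHaplotypes,
    WindowGrid,
)
from .demography import ParameterSet, kernel_args

_BASES = np.array(list("ACGT"))

#: default chromosome layout: 29 chromosomes of 80 Mb
DEFAULT_CHROMS = tuple((f"chr{i}", 80_000_000) for i in range(1, 30))

#: default brown sampling-site codes (ferox always spawn at KER)
BROWN_SITES = ("LNF", "GRU", "MCF", "SLA", "TAG")


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset."""

    model: str = "SCadm"
    params: ParameterSet = field(default_factory=ParameterSet.point_estimates)
    n_brown: int = 20
    n_ferox: int = 8
    n_loci: int = 215_000
    locus_length: int = 55
    mu: float = 1e-8
    missingness: float = 0.12
    chrom_lengths: tuple = DEFAULT_CHROMS
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missingness <= 1.0):
            raise DataError("missingness must be in [0, 1]")
        if self.mu <= 0:
            raise DataError("mu must be positive")
        if self.locus_length < 1:
            raise DataError("locus_length must be >= 1")
        if 2 * (self.n_brown + self.n_ferox) > MAX_HAPLOIDS:
            raise DataError(f"at most {MAX_HAPLOIDS} haploid samples supported")
        kernel_args(self.model, self.params)  # validates model/parameter combo


@dataclass(frozen=True)
class SweepSpec:
    """Ground truth for one injected differentiated window."""

    chrom: str
    start: int
    end: int
    target_group: str = "benthivorous"  # group whose diversity is reduced
    fst_level: float = 0.6
    reduction_factor: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.fst_level <= 1.0):
            raise DataError("fst_level must be in [0, 1]")
        if not (0.0 <= self.reduction_factor <= 1.0):
            raise DataError("reduction_factor must be in [0, 1]")


def _locus_positions(cfg: SimConfig, rng: np.random.Generator):
    """Place loci uniformly on non-overlapping 64 bp slots across chromosomes."""
    lengths = np.array([l for _, l in cfg.chrom_lengths], dtype=float)
    n_per = rng.multinomial(cfg.n_loci, lengths / lengths.sum())
    chroms, starts = [], []
    for (chrom, length), n_c in zip(cfg.chrom_lengths, n_per):
        slots = length // 64
        if n_c > slots:
            raise DataError(f"{chrom}: too many loci for chromosome length")
        picked = np.sort(rng.choice(slots, size=n_c, replace=False)) * 64
        chroms.extend([chrom] * n_c)
        starts.append(picked)
    return np.array(chroms), np.concatenate(starts) if starts else np.array([], int)


def simulate_dataset(cfg: SimConfig):
    """Simulate a dataset under ``cfg``.

    Returns ``(GenotypeMatrix, RadLocusHaplotypes, PopulationMap, q)`` where
    ``q`` maps individual -> true ferox-source ancestry proportion: under
    SCadm the post-pulse lineage proportions (brown: adm_fb, ferox:
    1 - adm_bf); under all other models plain population membership (0/1).
    Haplotypes are reported for polymorphic loci (monomorphic loci carry no
    within-locus diversity).
    """
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = 2 * cfg.n_brown, 2 * cfg.n_ferox
    ka = kernel_args(cfg.model, cfg.params)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    mut_locus, mut_mask, n_mut = simulate_mutation_masks(
        n1, n2, *ka, cfg.n_loci, cfg.mu * cfg.locus_length, kernel_seed)

    individuals = ([f"B{i:03d}" for i in range(cfg.n_brown)]
                   + [f"F{i:03d}" for i in range(cfg.n_ferox)])
    n_ind = len(individuals)

    chrom_of, start_of = _locus_positions(cfg, rng)

    # derived-allele carrier matrix: haploid bits -> diploid dosage
    bits = ((mut_mask[:, None] >> np.arange(n1 + n2)) & 1).astype(np.int8)
    dosage = bits[:, 0::2] + bits[:, 1::2]  # (n_mut, n_ind)

    # per-locus site offsets (distinct, sorted: infinite sites within locus)
    order = np.argsort(mut_locus, kind="stable")
    rows, genos = [], []
    hap_alleles: dict[str, list] = {}
    i = 0
    while i < n_mut:
        j = i
        loc = mut_locus[order[i]]
        while j < n_mut and mut_locus[order[j]] == loc:
            j += 1
        nm = j - i
        if nm > cfg.locus_length:  # infinite-sites overflow guard
            nm = cfg.locus_length
            j = i + nm
        offsets = np.sort(rng.choice(cfg.locus_length, size=nm, replace=False))
        anc = rng.integers(0, 4, size=nm)
        der = (anc + rng.integers(1, 4, size=nm)) % 4
        locus_id = f"L{loc:06d}"
        site_bits = []
        for s in range(nm):
            m = order[i + s]
            rows.append((chrom_of[loc], int(start_of[loc] + offsets[s]),
                         _BASES[anc[s]], _BASES[der[s]], locus_id, s))
            genos.append(dosage[m])
            site_bits.append(bits[m])
        hap_alleles[locus_id] = (loc, offsets, anc, der, np.array(site_bits))
        i = j

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                        "locus_id", "snp_idx"])
    g = (np.array(genos, dtype=np.int8).T if genos
         else np.zeros((n_ind, 0), dtype=np.int8))
    if len(sites):
        order_s = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        sites = sites.iloc[order_s].reset_index(drop=True)
        g = g[:, order_s]

    # uniform missingness on genotype cells
    if cfg.missingness > 0 and g.size:
        miss = rng.random(g.shape) < cfg.missingness
        g = np.where(miss, np.int8(MISSING), g)
    gm = GenotypeMatrix(individuals, sites, g)

    # haplotype strings for polymorphic loci; an individual is missing at a
    # locus when any of its genotypes there is missing
    site_lookup = {(r.locus_id, r.snp_idx): k
                   for k, r in enumerate(gm.sites.itertuples(index=False))}
    locus_length, location, haplotypes = {}, {}, {}
    for locus_id, (loc, offsets, anc, der, site_bits) in hap_alleles.items():
        locus_length[locus_id] = cfg.locus_length
        location[locus_id] = (str(chrom_of[loc]), int(start_of[loc]))
        backbone = rng.integers(0, 4, size=cfg.locus_length)
        backbone[offsets] = anc
        base_str = "".join(_BASES[backbone])
        cols = [site_lookup[(locus_id, s)] for s in range(len(offsets))]
        per_ind: dict[str, tuple[str, str] | None] = {}
        for ix, ind in enumerate(individuals):
            if (gm.genotypes[ix, cols] == MISSING).any():
                per_ind[ind] = None
                continue
            pair = []
            for h in (2 * ix, 2 * ix + 1):
                seq = list(base_str)
                for s, off in enumerate(offsets):
                    if site_bits[s, h]:
                        seq[off] = _BASES[der[s]]
                pair.append("".join(seq))
            per_ind[ind] = (pair[0], pair[1])
        haplotypes[locus_id] = per_ind
    radloci = RadLocusHaplotypes(locus_length, location, haplotypes)

    site_codes = {ind: BROWN_SITES[i % len(BROWN_SITES)]
                  for i, ind in enumerate(individuals[:cfg.n_brown])}
    site_codes.update({ind: "KER" for ind in individuals[cfg.n_brown:]})
    life = {ind: ("benthivorous" if ind.startswith("B") else "ferox")
            for ind in individuals}
    popmap = PopulationMap(site=site_codes, life_history=life)

    if cfg.model == "SCadm":
        q = {ind: (cfg.params.adm_fb if ind.startswith("B")
                   else 1.0 - cfg.params.adm_bf) for ind in individuals}
    else:
        q = {ind: (0.0 if ind.startswith("B") else 1.0) for ind in individuals}
    return gm, radloci, popmap, q


# ---------------------------------------------------------------------------
# injected differentiated window
# ---------------------------------------------------------------------------


def inject_differentiated_region(gm: GenotypeMatrix, popmap: PopulationMap,
                                 spec: SweepSpec, seed: int = 0,
                                 fst_tol: float = 0.1) -> GenotypeMatrix:
    """Re-draw genotypes inside one window to a requested differentiation.

    Allele frequencies inside ``spec``'s window are re-drawn so the realised
    window-mean Weir–Cockerham Fst is within ``fst_tol`` of the requested
    level and within-window heterozygosity in the target group is scaled by
    ``reduction_factor``; everything outside the window is untouched, and
    the original missingness pattern is kept.
    """
    from .scan import wc_fst_sites  # deferred: scan depends on datamodel only

    if spec.fst_level == 0.0 and spec.reduction_factor == 1.0:
        return GenotypeMatrix(list(gm.individuals), gm.sites.copy(),
                              gm.genotypes.copy())
    in_win = ((gm.sites["chrom"] == spec.chrom)
              & (gm.sites["pos"] >= spec.start)
              & (gm.sites["pos"] < spec.end)).to_numpy()
    cols = np.flatnonzero(in_win)
    if cols.size == 0:
        raise DataError("window contains no sites")

    groups = sorted(set(popmap.life_history.values()))
    if spec.target_group not in groups:
        raise DataError(f"unknown target group {spec.target_group!r}")
    other_group = next(gr for gr in groups if gr != spec.target_group) \
        if len(groups) > 1 else spec.target_group
    rows_t = [gm.individuals.index(i)
              for i in popmap.individuals_of_type(spec.target_group)]
    rows_o = [gm.individuals.index(i)
              for i in popmap.individuals_of_type(other_group)]

    rng = np.random.default_rng(seed)
    g = gm.genotypes
    called_t = g[np.ix_(rows_t, cols)] != MISSING
    alt_t = np.where(called_t, g[np.ix_(rows_t, cols)], 0).sum(axis=0)
    p_t = np.divide(alt_t, 2 * called_t.sum(axis=0),
                    out=np.full(cols.size, 0.5), where=called_t.sum(axis=0) > 0)

    # scale target-group heterozygosity: solve p'(1-p') = factor * p(1-p),
    # taking the root on the same side of 1/2 as p
    het = spec.reduction_factor * p_t * (1 - p_t)
    disc = np.sqrt(np.maximum(0.0, 0.25 - het))
    p_t_new = np.where(p_t <= 0.5, 0.5 - disc, 0.5 + disc)

    push = np.where(p_t_new <= 0.5, 1.0, -1.0)  # direction separating the groups
    u = rng.random((gm.n_individuals, cols.size, 2))
    miss_mask = g[:, cols] == MISSING

    def realized(d: float):
        p = np.empty((gm.n_individuals, cols.size))
        p[rows_t] = p_t_new
        p[rows_o] = np.clip(p_t_new + push * d, 0.0, 1.0)
        drawn = ((u[..., 0] < p).astype(np.int8) + (u[..., 1] < p).astype(np.int8))
        drawn = np.where(miss_mask, np.int8(MISSING), drawn)
        trial = g.copy()
        trial[:, cols] = drawn
        tgm = GenotypeMatrix(list(gm.individuals), gm.sites.copy(), trial)
        stats = wc_fst_sites(tgm, popmap.individuals_of_type(groups[0]),
                             popmap.individuals_of_type(groups[-1]))
        fst = stats["fst"].to_numpy()[cols]
        return float(np.nanmean(fst)), tgm

    if spec.fst_level == 0.0:
        return realized(0.0)[1]
    lo, hi = 0.0, 1.0
    best = None
    for _ in range(25):
        d = 0.5 * (lo + hi)
        f, tgm = realized(d)
        if best is None or abs(f - spec.fst_level) < abs(best[0] - spec.fst_level):
            best = (f, tgm)
        if abs(f - spec.fst_level) <= 0.5 * fst_tol:
            return tgm
        if f < spec.fst_level:
            lo = d
        else:
            hi = d
    return best[1]


# ---------------------------------------------------------------------------
# phenotypes and annotation tracks
# ---------------------------------------------------------------------------


def simulate_phenotypes(q: dict[str, float], intercept: float = 267.0,
                        slope: float = 216.0, noise_sd: float = 80.0,
                        seed: int = 0) -> PhenotypeTable:
    """Fork length = intercept + slope * q + Gaussian noise.

    Defaults put a q ~ 1 (ferox-like) group mean near 483 mm and a q ~ 0
    (benthivorous-like) group mean near 267 mm.
    """
    if noise_sd < 0:
        raise DataError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    inds = list(q)
    qv = np.array([q[i] for i in inds], dtype=float)
    if ((qv < 0) | (qv > 1)).any():
        raise DataError("ancestry q outside [0, 1]")
    fl = intercept + slope * qv + rng.normal(0.0, noise_sd, size=len(inds))
    fl = np.maximum(fl, 1.0)  # fork length must stay positive
    return PhenotypeTable(fork_length=dict(zip(inds, fl)),
                          ancestry_q=dict(zip(inds, qv)))


def simulate_annotation_track(grid: WindowGrid, lam: float,
                              seed: int = 0) -> IntervalTrack:
    """Per-window annotated-character counts drawn Poisson(lam)."""
    if lam < 0:
        raise DataError("lambda must be >= 0")
    rng = np.random.default_rng(seed)
    win = grid.windows.copy()
    win["value"] = rng.poisson(lam, size=len(win))
    return IntervalTrack(win)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    df = pd.DataFrame({
        "individual": list(pheno.fork_length),
        "fork_length": [pheno.fork_length[i] for i in pheno.fork_length],
        "ancestry_q": [pheno.ancestry_q[i] for i in pheno.fork_length],
    })
    df.to_csv(path, sep="\t", index=False)


def write_popmap(popmap: PopulationMap, path) -> None:
    df = pd.DataFrame({
        "individual": list(popmap.site),
        "site": [popmap.site[i] for i in popmap.site],
        "type": [popmap.life_history[i] for i in popmap.site],
    })
    df.to_csv(path, sep="\t", index=False)


def write_track(track: IntervalTrack, path) -> None:
    track.records.to_csv(path, sep="\t", index=False, header=False)
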