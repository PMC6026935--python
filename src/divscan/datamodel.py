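"""Core data containers, file I/O and SNP-filtering rules.

The central container is :class:`GenotypeMatrix`: diploid individuals by
biallelic SNP sites, genotypes coded as the number of alternate alleles
(0/1/2) with ``MISSING = -1``.  Coordinates are 0-based half-open
internally; conversion to/from the 1-based VCF convention happens only at
the file boundary.

Two filtering regimes are provided, matching common ddRAD practice:

- :func:`filter_snps` — the genome-scan filter: global minor-allele
  frequency >= 0.05, observed heterozygosity <= 0.6 (paralog guard),
  per-population presence (genotyped in >= 66% of individuals in >= 4 of 6
  sampling sites), and one SNP per RAD locus.
- :func:`demographic_site_filter` — the site-frequency-spectrum filter: no
  MAF cut (low-frequency variants are informative for demography), at most
  10% missing genotypes, one SNP per locus.

Threshold boundaries are inclusive on the "kept" side (MAF >= maf_min kept,
Ho <= ho_max kept), matching Stacks populations semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("divscan")

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "locus_id", "snp_idx"]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites with missingness.

    Parameters
    ----------
    individuals
        Ordered individual IDs.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, locus_id, snp_idx``;
        ``pos`` is the 0-based position of the SNP.
    genotypes
        ``(n_individuals, n_sites)`` int8 array of alt-allele counts in
        {0, 1, 2} or ``MISSING``.
    """

    individuals: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_ind, n_sites = self.genotypes.shape
        if n_ind != len(self.individuals):
            raise DataError(
                f"genotype rows ({n_ind}) != individuals ({len(self.individuals)})"
            )
        if n_sites != len(self.sites):
            raise DataError(
                f"genotype cols ({n_sites}) != sites ({len(self.sites)})"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("genotype codes outside {0,1,2,MISSING}")
        if n_sites:
            key = self.sites[["chrom", "pos"]]
            if key.duplicated().any():
                raise DataError("duplicate (chrom, pos) sites")
            srt = self.sites.sort_values(["chrom", "pos"], kind="mergesort")
            if not np.array_equal(srt.index.to_numpy(), self.sites.index.to_numpy()):
                raise DataError("sites not sorted by (chrom, pos)")

    # -- convenience --------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, mask_or_idx) -> "GenotypeMatrix":
        """Subset sites (order preserved)."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.individuals),
            self.sites.iloc[idx].reset_index(drop=True),
            self.genotypes[:, idx],
        )

    def take_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        pos = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(list(ids), self.sites.copy(), self.genotypes[pos])

    def alt_counts(self, rows=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over ``rows``."""
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt, 2 * called.sum(axis=0)


@dataclass
class PopulationMap:
    """Individual -> sampling-site code and life-history label."""

    site: dict[str, str]
    life_history: dict[str, str]

    def __post_init__(self):
        if set(self.site) != set(self.life_history):
            raise DataError("site and life-history maps cover different individuals")

    def validate_against(self, gm: GenotypeMatrix) -> None:
        unmapped = [i for i in gm.individuals if i not in self.site]
        if unmapped:
            raise DataError(f"individuals missing from population map: {unmapped}")

    def individuals_of_site(self, code: str) -> list[str]:
        return [i for i, s in self.site.items() if s == code]

    def individuals_of_type(self, label: str) -> list[str]:
        return [i for i, t in self.life_history.items() if t == label]

    @property
    def sites_codes(self) -> list[str]:
        return sorted(set(self.site.values()))


@dataclass
class RadLocusHaplotypes:
    """Per-RAD-locus phased haplotype pairs.

    ``haplotypes[locus_id][individual]`` is a pair of equal-length strings
    over {A, C, G, T}, or ``None`` when the individual is missing.
    """

    locus_length: dict[str, int]
    location: dict[str, tuple[str, int]]  # locus -> (chrom, start)
    haplotypes: dict[str, dict[str, tuple[str, str] | None]]

    def __post_init__(self):
        for loc, per_ind in self.haplotypes.items():
            length = self.locus_length[loc]
            for ind, pair in per_ind.items():
                if pair is None:
                    continue
                for h in pair:
                    if len(h) != length:
                        raise DataError(
                            f"locus {loc}: haplotype length {len(h)} != {length}"
                        )
                    if set(h) - set("ACGT"):
                        raise DataError(f"locus {loc}: non-ACGT haplotype")


@dataclass
class PhenotypeTable:
    """Individual -> fork length (mm) and genetic ancestry coefficient q."""

    fork_length: dict[str, float]
    ancestry_q: dict[str, float]

    def __post_init__(self):
        for ind, q in self.ancestry_q.items():
            if not (0.0 <= q <= 1.0):
                raise DataError(f"{ind}: ancestry q={q} outside [0, 1]")
        for ind, fl in self.fork_length.items():
            if not fl > 0:
                raise DataError(f"{ind}: fork length {fl} must be positive")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the two SNP-filtering regimes."""

    maf_min: float | None = 0.05
    ho_max: float = 0.6
    within_pop_presence: float = 0.66
    min_pops: int = 4
    n_pops: int = 6
    first_snp_only: bool = True
    max_missing: float | None = None  # demographic regime: 0.10

    def __post_init__(self):
        for name in ("maf_min", "ho_max", "within_pop_presence", "max_missing"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise DataError(f"{name}={v} outside [0, 1]")

    @classmethod
    def demographic(cls) -> "FilterConfig":
        return cls(maf_min=None, ho_max=1.0, within_pop_presence=0.0,
                   min_pops=0, max_missing=0.10)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding windows over chromosomes, 0-based half-open."""

    chrom_lengths: tuple[tuple[str, int], ...]
    size: int = 500_000
    step: int = 125_000

    @property
    def windows(self) -> pd.DataFrame:
        rows = []
        for chrom, length in self.chrom_lengths:
            start = 0
            while start < length:
                rows.append((chrom, start, min(start + self.size, length)))
                start += self.step
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class IntervalTrack:
    """(chrom, start, end, value) records; BED-like, half-open."""

    records: pd.DataFrame  # columns chrom, start, end, value

    def __post_init__(self):
        df = self.records
        if len(df) and (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise DataError(
                f"interval {row['chrom']}:{row['start']}-{row['end']}: start must be < end"
            )

    def __len__(self):
        return len(self.records)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Biallelic SNP records only; multiallelic and indel records are dropped
    (with a logged count).  ``./.`` genotypes become ``MISSING``.  The RAD
    locus ID and within-locus SNP index are taken from the ID column when it
    has the form ``<locus>_<idx>``, else each site is its own locus.
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise DataError(f"malformed VCF {path}: {exc}") from exc

    individuals = list(vcf.samples)
    rows, genos = [], []
    n_dropped = 0
    for rec_no, rec in enumerate(vcf, start=1):
        try:
            alts = rec.ALT
            if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
                n_dropped += 1
                continue
            ident = rec.ID or f"s{rec_no}"
            if "_" in ident and ident.rsplit("_", 1)[1].isdigit():
                locus, idx = ident.rsplit("_", 1)
                idx = int(idx)
            else:
                locus, idx = ident, 0
            rows.append((rec.CHROM, rec.POS - 1, rec.REF, alts[0], locus, idx))
            g = rec.genotype.array()[:, :2]
            code = np.where((g < 0).any(axis=1), MISSING, (g > 0).sum(axis=1))
            genos.append(code.astype(np.int8))
        except DataError:
            raise
        except Exception as exc:
            raise DataError(f"malformed VCF record at {path} record {rec_no}: {exc}") from exc
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    g = (np.array(genos, dtype=np.int8).T if genos
         else np.zeros((len(individuals), 0), dtype=np.int8))
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return GenotypeMatrix(individuals, sites.iloc[order].reset_index(drop=True),
                          g[:, order])


def write_vcf(gm: GenotypeMatrix, path, chrom_lengths=None) -> None:
    """Write a minimal VCF 4.2 (GT only, 1-based positions)."""
    path = Path(path)
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscan\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individuals) + "\n")
        for j, site in enumerate(gm.sites.itertuples(index=False)):
            gts = "\t".join(code_to_gt[int(c)] for c in gm.genotypes[:, j])
            fh.write(f"{site.chrom}\t{site.pos + 1}\t{site.locus_id}_{site.snp_idx}\t"
                     f"{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------


def read_popmap(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "site", "type"}
    if not required <= set(df.columns):
        raise DataError(f"population map needs columns {sorted(required)}")
    return PopulationMap(
        site=dict(zip(df["individual"], df["site"])),
        life_history=dict(zip(df["individual"], df["type"])),
    )


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "fork_length", "ancestry_q"}
    if not required <= set(df.columns):
        raise DataError(f"phenotype table needs columns {sorted(required)}")
    return PhenotypeTable(
        fork_length=dict(zip(df["individual"], df["fork_length"].astype(float))),
        ancestry_q=dict(zip(df["individual"], df["ancestry_q"].astype(float))),
    )


def read_track(path) -> IntervalTrack:
    """Read a BED3+value track (no header required)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if len(df):
        if df.shape[1] < 4:
            df[3] = 1
        df = df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "value"]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    return IntervalTrack(df.reset_index(drop=True))


def read_chrom_lengths(path) -> tuple[tuple[str, int], ...]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return tuple((str(c), int(l)) for c, l in zip(df["chrom"], df["length"]))


def load_tables(popmap_path, phenotype_path, track_paths=(), gm: GenotypeMatrix | None = None):
    """Load and cross-validate the tabular companions of a genotype matrix."""
    popmap = read_popmap(popmap_path)
    pheno = read_phenotypes(phenotype_path)
    if gm is not None:
        popmap.validate_against(gm)
    tracks = tuple(read_track(p) for p in track_paths)
    return (popmap, pheno) + tracks


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _first_snp_mask(sites: pd.DataFrame) -> np.ndarray:
    """Keep the lowest-position SNP per RAD locus."""
    pos_min = sites.groupby("locus_id")["pos"].transform("min")
    first = (sites["pos"] == pos_min).to_numpy()
    # guard against position ties within a locus: keep the first occurrence
    seen = sites["locus_id"].where(pd.Series(first, index=sites.index)).duplicated()
    return first & ~seen.to_numpy()


def filter_snps(gm: GenotypeMatrix, popmap: PopulationMap,
                cfg: FilterConfig = FilterConfig()) -> GenotypeMatrix:
    """Genome-scan SNP filter (MAF, Ho, per-population presence, 1 SNP/locus)."""
    if gm.n_sites == 0:
        raise DataError("empty genotype matrix")
    popmap.validate_against(gm)
    g = gm.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, g, 0).sum(axis=0)
        denom = np.maximum(n_called, 1)
        p_alt = np.where(n_called > 0, alt / (2 * denom), 0.0)
        maf = np.minimum(p_alt, 1 - p_alt)
        ho = np.where(n_called > 0, (g == 1).sum(axis=0) / denom, 0.0)

    keep = n_called > 0
    if cfg.maf_min is not None:
        keep &= maf >= cfg.maf_min
    keep &= ho <= cfg.ho_max

    # presence: genotyped in >= within_pop_presence of individuals in
    # >= min_pops sampling sites
    if cfg.min_pops > 0:
        pops_ok = np.zeros(gm.n_sites, dtype=int)
        for code in popmap.sites_codes:
            rows = [gm.individuals.index(i) for i in popmap.individuals_of_site(code)
                    if i in gm.individuals]
            if not rows:
                continue
            frac = called[rows].mean(axis=0)
            pops_ok += frac >= cfg.within_pop_presence
        keep &= pops_ok >= cfg.min_pops

    if cfg.first_snp_only:
        keep &= _first_snp_mask(gm.sites)

    if not keep.any():
        logger.warning("filter_snps removed every site")
    return gm.take_sites(np.flatnonzero(keep))


def demographic_site_filter(gm: GenotypeMatrix,
                            cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """SFS-building filter: no MAF cut, <= 10% missing, 1 SNP/locus."""
    if gm.n_sites == 0:
        raise DataError("empty genotype matrix")
    cfg = cfg or FilterConfig.demographic()
    max_missing = cfg.max_missing if cfg.max_missing is not None else 0.10
    missing_frac = (gm.genotypes == MISSING).mean(axis=0)
    keep = missing_frac <= max_missing
    if cfg.first_snp_only:
        keep &= _first_snp_mask(gm.sites)
    if not keep.any():
        logger.warning("demographic_site_filter removed every site")
    return gm.take_sites(np.flatnonzero(keep))


def build_windows(chrom_lengths, size: int = 500_000, step: int = 125_000) -> WindowGrid:
    """Sliding-window grid: starts at 0, step, 2*step, ... while < length."""
    if size <= 0 or step <= 0:
        raise DataError("window size and step must be positive")
    if step > size:
        raise DataError("step must not exceed window size")
    return WindowGrid(tuple((str(c), int(l)) for c, l in chrom_lengths), size, step)
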