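"""Divergence-history inference from the folded joint site frequency spectrum.

Six two-population divergence scenarios are compared by composite likelihood
on the folded joint SFS (JSFS), in the style of simulation-based SFS fitting:

========  =====================================================  ==
model     free parameters                                        k
========  =====================================================  ==
SI        NeANC, NeB, NeF, TDIV                                   4
IM        + symmetric migration MIG                               5
AM        + migration-stop time T2 (gene flow only before T2)     6
SC        + secondary-contact time T2 (gene flow only after T2)   6
IMchange  + T2 and a second (ancient) migration rate              7
SCadm     SC + admixture pulse proportions at contact             8
========  =====================================================  ==

Expected JSFS cell probabilities come from Monte-Carlo coalescent
simulation (expected branch length subtending each joint descendant class,
times the per-site mutation rate), including the monomorphic mass, so that
absolute times and sizes are identifiable once the observed monomorphic
site count is corrected for thinning to one SNP per RAD locus.  Parameters
are optimised by ECM: cyclic bounded one-dimensional search on each
parameter (log scale) with common random numbers within a run.

Times are in generations, effective sizes in diploid individuals, migration
is the per-lineage per-generation rate, and admixture proportions are the
forward-time fractions replaced at contact (implemented backward as lineage
jump probabilities).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import hypergeom

from ._coalescent import MAX_HAPLOIDS, accumulate_branch_cells
from .datamodel import MISSING, DataError, GenotypeMatrix, PopulationMap

logger = logging.getLogger("divscan")

LN10 = math.log(10.0)

#: expected-probability floor for cells with zero simulated mass
P_FLOOR = 1e-20

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "SI": ("ne_anc", "ne_b", "ne_f", "tdiv"),
    "IM": ("ne_anc", "ne_b", "ne_f", "tdiv", "mig"),
    "AM": ("ne_anc", "ne_b", "ne_f", "tdiv", "t2_frac", "mig"),
    "SC": ("ne_anc", "ne_b", "ne_f", "tdiv", "t2_frac", "mig"),
    "IMchange": ("ne_anc", "ne_b", "ne_f", "tdiv", "t2_frac", "mig", "mig_ancient"),
    "SCadm": ("ne_anc", "ne_b", "ne_f", "tdiv", "t2_frac", "mig", "adm_fb", "adm_bf"),
}

#: default log-uniform search ranges per parameter
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "ne_anc": (50.0, 50_000.0),
    "ne_b": (50.0, 50_000.0),
    "ne_f": (50.0, 50_000.0),
    "tdiv": (100.0, 60_000.0),
    "t2_frac": (0.005, 0.95),
    "mig": (1e-5, 0.05),
    "mig_ancient": (1e-5, 0.05),
    "adm_fb": (0.02, 1.0),
    "adm_bf": (0.02, 1.0),
}


@dataclass(frozen=True)
class DemographicModel:
    """One of the six divergence scenarios."""

    model_id: str
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.model_id not in MODEL_PARAMS:
            raise DataError(f"unknown model {self.model_id!r}; "
                            f"choose from {sorted(MODEL_PARAMS)}")
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise DataError(f"invalid range for {name}: ({lo}, {hi})")

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def range_of(self, name: str) -> tuple[float, float]:
        return self.ranges.get(name, DEFAULT_RANGES[name])


@dataclass
class ParameterSet:
    """Parameter vector shared by the six models.

    ``t2`` is the single event time between 0 and ``tdiv``: secondary-contact
    time for SC/SCadm, migration-stop time for AM and migration-change time
    for IMchange.  ``mig_ancient`` is the pre-``t2`` rate used only by
    IMchange.  ``adm_fb`` is the forward proportion of the brown (benthivorous)
    gene pool drawn from ferox at contact; ``adm_bf`` the reverse.
    """

    ne_anc: float
    ne_b: float
    ne_f: float
    tdiv: float
    t2: float = 0.0
    mig: float = 0.0
    mig_ancient: float = 0.0
    adm_fb: float = 0.0
    adm_bf: float = 0.0

    def __post_init__(self):
        for name in ("ne_anc", "ne_b", "ne_f"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.tdiv < 0 or self.t2 < 0:
            raise DataError("times must be non-negative")
        for name in ("adm_fb", "adm_bf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name}={v} outside [0, 1]")

    @classmethod
    def point_estimates(cls) -> "ParameterSet":
        """Secondary-contact-with-admixture point estimates of the study system."""
        return cls(ne_anc=12_326, ne_b=1146, ne_f=393, tdiv=9159, t2=469,
                   mig=0.0022, adm_fb=0.817, adm_bf=0.536)


def kernel_args(model_id: str, ps: ParameterSet) -> tuple:
    """Map (model, parameters) to the coalescent-kernel epoch arguments."""
    uses_t2 = model_id in ("AM", "SC", "IMchange", "SCadm")
    if uses_t2 and not (0.0 < ps.t2 < ps.tdiv):
        raise DataError(
            f"{model_id}: event time t2={ps.t2} must satisfy 0 < t2 < tdiv={ps.tdiv}")
    base = (ps.ne_b, ps.ne_f, ps.ne_anc, ps.tdiv)
    if model_id == "SI":
        return base + (0.0, 0.0, 0.0, 0.0, 0.0)
    if model_id == "IM":
        return base + (0.0, 0.0, ps.mig, 0.0, 0.0)
    if model_id == "AM":
        return base + (ps.t2, 0.0, ps.mig, 0.0, 0.0)
    if model_id == "SC":
        return base + (ps.t2, ps.mig, 0.0, 0.0, 0.0)
    if model_id == "IMchange":
        return base + (ps.t2, ps.mig, ps.mig_ancient, 0.0, 0.0)
    if model_id == "SCadm":
        return base + (ps.t2, ps.mig, 0.0, ps.adm_fb, ps.adm_bf)
    raise DataError(f"unknown model {model_id!r}")


# ---------------------------------------------------------------------------
# the joint SFS
# ---------------------------------------------------------------------------


def fold_array(unfolded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold a two-population spectrum on the total minor allele.

    Cell (i, j) and its mirror (n1-i, n2-j) are merged into whichever has
    the smaller total count; cells on the (n1+n2)/2 diagonal each keep half
    the combined mass.  Returns ``(folded, mask)`` where ``mask`` is True
    for the dominated (folded-away) half.
    """
    n1 = unfolded.shape[0] - 1
    n2 = unfolded.shape[1] - 1
    tot = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
    folded = unfolded + unfolded[::-1, ::-1]
    folded = np.where(2 * tot == n1 + n2, folded * 0.5, folded)
    mask = 2 * tot > n1 + n2
    folded = np.where(mask, 0.0, folded)
    return folded, mask


@dataclass
class JSFS:
    """Folded two-population SFS with monomorphic mass.

    The alternate-allele-count spectrum is kept internally (``unfolded``,
    polarisation arbitrary) so that hypergeometric projection is exact; the
    folded view is derived.  ``monomorphic`` is the (possibly corrected)
    count of non-segregating sites, reported in the folded array's (0, 0)
    cell.
    """

    unfolded: np.ndarray  # (n1+1, n2+1) counts, corners zeroed
    monomorphic: float = 0.0

    def __post_init__(self):
        self.unfolded = np.asarray(self.unfolded, dtype=float)
        if (self.unfolded < 0).any() or self.monomorphic < 0:
            raise DataError("JSFS counts must be non-negative")

    @property
    def n1(self) -> int:
        return self.unfolded.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.unfolded.shape[1] - 1

    @property
    def n_snps_used(self) -> float:
        return float(self.unfolded.sum())

    def folded(self) -> tuple[np.ndarray, np.ndarray]:
        """(folded array with monomorphic count at (0, 0), fold mask)."""
        f, mask = fold_array(self.unfolded)
        f[0, 0] += self.monomorphic
        return f, mask

    def with_monomorphic(self, count: float) -> "JSFS":
        return JSFS(self.unfolded.copy(), float(count))

    # -- serialization (dadi text SFS layout) -------------------------------
    def to_dadi_text(self, path) -> None:
        f, mask = self.folded()
        with open(path, "w") as fh:
            fh.write(f"{self.n1 + 1} {self.n2 + 1} folded\n")
            fh.write(" ".join(format(float(v), ".17g") for v in f.ravel()) + "\n")
            fh.write(" ".join("1" if m else "0" for m in mask.ravel()) + "\n")

    @classmethod
    def from_dadi_text(cls, path) -> "JSFS":
        with open(path) as fh:
            dims = fh.readline().split()
            d1, d2 = int(dims[0]), int(dims[1])
            data = np.array(fh.readline().split(), dtype=float).reshape(d1, d2)
            np.array(fh.readline().split(), dtype=int)  # mask re-derived from shape
        mono = data[0, 0]
        data[0, 0] = 0.0
        # a folded spectrum is its own alt-count spectrum with empty mirror half
        return cls(data, monomorphic=mono)


def compute_folded_jsfs(gm: GenotypeMatrix, popmap: PopulationMap,
                        group_a: str = "benthivorous",
                        group_b: str = "ferox") -> JSFS:
    """Folded JSFS over two life-history groups.

    Sites with any missing genotype among the used individuals are excluded
    (missingness is expected to have been pre-filtered; projection absorbs
    the remaining sample-size reduction).  Sites monomorphic within the
    sample count toward the monomorphic cell.
    """
    rows_a = [gm.individuals.index(i) for i in popmap.individuals_of_type(group_a)
              if i in gm.individuals]
    rows_b = [gm.individuals.index(i) for i in popmap.individuals_of_type(group_b)
              if i in gm.individuals]
    if not rows_a or not rows_b:
        raise DataError("both groups need at least one individual")
    n1, n2 = 2 * len(rows_a), 2 * len(rows_b)
    g = gm.genotypes
    complete = (g[rows_a + rows_b] != MISSING).all(axis=0)
    ga, gb = g[rows_a][:, complete], g[rows_b][:, complete]
    alt_a = ga.sum(axis=0)
    alt_b = gb.sum(axis=0)
    unfolded = np.zeros((n1 + 1, n2 + 1))
    np.add.at(unfolded, (alt_a, alt_b), 1.0)
    mono = unfolded[0, 0] + unfolded[n1, n2]
    unfolded[0, 0] = unfolded[n1, n2] = 0.0
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("compute_folded_jsfs: %d sites with missing genotypes excluded",
                    n_excluded)
    return JSFS(unfolded, monomorphic=float(mono))


def project_jsfs(jsfs: JSFS, m: tuple[int, int]) -> JSFS:
    """Hypergeometric projection to smaller haploid sample sizes (m1, m2).

    Each count at (i, j) is redistributed over (a, b) with weight
    P(a | i, n1, m1) * P(b | j, n2, m2); mass landing in the projected
    corners (monomorphic after downsampling) moves to the monomorphic cell,
    so total mass is conserved.
    """
    m1, m2 = m
    n1, n2 = jsfs.n1, jsfs.n2
    if m1 > n1 or m2 > n2:
        raise DataError(f"cannot project ({n1},{n2}) up to ({m1},{m2})")
    # P1[i, a] = P(a successes | draw m1 from n1 with i marked)
    P1 = hypergeom.pmf(np.arange(m1 + 1)[None, :], n1, np.arange(n1 + 1)[:, None], m1)
    P2 = hypergeom.pmf(np.arange(m2 + 1)[None, :], n2, np.arange(n2 + 1)[:, None], m2)
    proj = P1.T @ jsfs.unfolded @ P2
    mono_new = proj[0, 0] + proj[m1, m2]
    proj[0, 0] = proj[m1, m2] = 0.0
    return JSFS(proj, monomorphic=jsfs.monomorphic + float(mono_new))


def correct_monomorphic(n_loci: int, locus_len: int, s_all: int,
                        n_snps_used: float) -> float:
    """Ratio-preserving monomorphic-site adjustment.

    When only one SNP per RAD locus enters the spectrum, the true
    monomorphic total ``n_loci * locus_len - S_all`` must be scaled down in
    proportion, keeping the polymorphic : monomorphic ratio of the full
    data: ``n_snps_used * (n_loci * locus_len - S_all) / S_all``.
    """
    if s_all <= 0:
        raise DataError("S_all must be positive")
    total_sites = n_loci * locus_len
    if s_all > total_sites:
        raise DataError("segregating sites exceed total sites")
    return n_snps_used * (total_sites - s_all) / s_all


# ---------------------------------------------------------------------------
# expected spectrum and composite likelihood
# ---------------------------------------------------------------------------


def expected_jsfs(model, params: ParameterSet, n1: int, n2: int,
                  n_sims: int = 100_000, seed: int = 0,
                  mu: float = 1e-8) -> np.ndarray:
    """Monte-Carlo expected folded JSFS cell probabilities.

    Returns an (n1+1, n2+1) array of per-site probabilities: folded SNP
    cells plus the monomorphic probability in cell (0, 0); folded-away
    cells are zero.  The array sums to 1.
    """
    model_id = model.model_id if isinstance(model, DemographicModel) else str(model)
    if n_sims < 1:
        raise DataError("n_sims must be >= 1")
    if n1 + n2 > MAX_HAPLOIDS:
        raise DataError(f"at most {MAX_HAPLOIDS} haploid samples supported")
    args = kernel_args(model_id, params)
    T = accumulate_branch_cells(n1, n2, *args, n_sims, seed)
    p_cells = mu * T
    folded, _mask = fold_array(p_cells)
    folded[0, 0] = 0.0
    total_poly = folded.sum()
    if total_poly >= 1.0:
        raise DataError("mu * expected tree length >= 1; model outside the "
                        "infinite-sites regime")
    folded[0, 0] = 1.0 - total_poly
    return folded


@dataclass(frozen=True)
class CompositeLikelihood:
    natural: float
    saturated_natural: float

    @property
    def log10(self) -> float:
        return self.natural / LN10

    @property
    def saturated_log10(self) -> float:
        return self.saturated_natural / LN10


def composite_loglik(jsfs: JSFS | np.ndarray, p_expected: np.ndarray) -> CompositeLikelihood:
    """Multinomial composite log-likelihood of the folded spectrum.

    ``lnL = sum m_cell * ln(p_cell)`` over unmasked cells including the
    monomorphic cell; the saturated bound ``sum m * ln(m / M)`` is returned
    alongside.  Expected probabilities are floored at ``P_FLOOR``.
    """
    if isinstance(jsfs, JSFS):
        obs, _ = jsfs.folded()
    else:
        obs = np.asarray(jsfs, dtype=float)
    if obs.shape != p_expected.shape:
        raise DataError(f"shape mismatch: {obs.shape} vs {p_expected.shape}")
    if (obs < 0).any():
        raise DataError("negative observed counts")
    p = np.maximum(p_expected, P_FLOOR)
    natural = float((obs * np.log(p)).sum())
    total = obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(obs > 0, obs * np.log(np.where(obs > 0, obs, 1.0) / total), 0.0)
    return CompositeLikelihood(natural=natural, saturated_natural=float(sat.sum()))


def aic(lnl_natural: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    if k < 0:
        raise DataError("k must be >= 0")
    return 2.0 * k - 2.0 * lnl_natural


def generations_to_years(t_generations, generation_time: float = 4.0):
    """Convert generations to years (default generation time 4 y)."""
    t = np.asarray(t_generations, dtype=float)
    if (t < 0).any() or generation_time < 0:
        raise DataError("inputs must be non-negative")
    out = t * generation_time
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# ECM fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model_id: str
    params: ParameterSet
    lnl_natural: float
    aic: float
    k: int
    trace: list[float] = field(default_factory=list)
    run_params: list[ParameterSet] = field(default_factory=list)
    bootstrap: pd.DataFrame | None = None

    @property
    def lnl_log10(self) -> float:
        return self.lnl_natural / LN10


def _to_parameter_set(model: DemographicModel, values: dict[str, float]) -> ParameterSet:
    kw = dict(ne_anc=values["ne_anc"], ne_b=values["ne_b"], ne_f=values["ne_f"],
              tdiv=values["tdiv"])
    if "t2_frac" in values:
        kw["t2"] = values["t2_frac"] * values["tdiv"]
    for name in ("mig", "mig_ancient", "adm_fb", "adm_bf"):
        if name in values:
            kw[name] = min(values[name], 1.0) if name.startswith("adm") else values[name]
    return ParameterSet(**kw)


def fit_model(model, jsfs: JSFS, cycles: int = 40, sims_per_eval: int = 100_000,
              n_runs: int = 25, seed: int = 0, mu: float = 1e-8,
              search_maxiter: int = 8) -> FitResult:
    """Maximise the composite likelihood by cyclic 1-D (ECM) search.

    ``n_runs`` independent starts are drawn log-uniformly from the model's
    parameter ranges; each cycle maximises each parameter in turn by a
    bounded scalar search on the log scale, with common random numbers (one
    kernel seed per run) so the likelihood surface is deterministic within
    a run and the best-so-far likelihood is non-decreasing across cycles.
    """
    if isinstance(model, str):
        model = DemographicModel(model)
    obs, _ = jsfs.folded()
    n1, n2 = jsfs.n1, jsfs.n2
    names = model.param_names
    rng = np.random.default_rng(seed)

    best_overall = None
    all_runs: list[tuple[float, ParameterSet]] = []
    for run in range(n_runs):
        crn_seed = int(rng.integers(0, 2**31 - 1))
        cache: dict[tuple, float] = {}

        def lnl_of(values: dict[str, float]) -> float:
            key = tuple(values[n] for n in names)
            if key not in cache:
                try:
                    ps = _to_parameter_set(model, values)
                    p = expected_jsfs(model.model_id, ps, n1, n2,
                                      n_sims=sims_per_eval, seed=crn_seed, mu=mu)
                    cache[key] = composite_loglik(obs, p).natural
                except DataError:
                    cache[key] = -np.inf
            return cache[key]

        values = {n: float(np.exp(rng.uniform(*np.log(model.range_of(n)))))
                  for n in names}
        current = lnl_of(values)
        trace = [current]
        for _cycle in range(cycles):
            for name in names:
                lo, hi = model.range_of(name)

                def neg(logv, _name=name):
                    trial = dict(values)
                    trial[_name] = float(np.exp(logv))
                    return -lnl_of(trial)

                res = minimize_scalar(neg, bounds=(np.log(lo), np.log(hi)),
                                      method="bounded",
                                      options={"maxiter": search_maxiter,
                                               "xatol": 0.01})
                cand = float(np.exp(res.x))
                trial = dict(values)
                trial[name] = cand
                if lnl_of(trial) > current:  # tie-break keeps the incumbent
                    values = trial
                    current = lnl_of(trial)
            trace.append(current)
        if not np.isfinite(current):
            continue
        ps = _to_parameter_set(model, values)
        all_runs.append((current, ps))
        if best_overall is None or current > best_overall.lnl_natural:
            best_overall = FitResult(model.model_id, ps, current,
                                     aic(current, model.k), model.k, trace)
    if best_overall is None:
        raise DataError("non-finite likelihood at every start")
    # per-run best parameter vectors, best run first (bootstrap input)
    best_overall.run_params = [p for _, p in
                               sorted(all_runs, key=lambda t: -t[0])]
    return best_overall


def select_model(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending); ties broken by smaller k."""
    if len(fits) < 2:
        raise DataError("need at least two fits to rank")
    df = pd.DataFrame({
        "model": [f.model_id for f in fits],
        "lnL": [f.lnl_natural for f in fits],
        "k": [f.k for f in fits],
        "AIC": [f.aic for f in fits],
    })
    df = df.sort_values(["AIC", "k"], kind="mergesort").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df


def bootstrap_ci(param_vectors, n_resamples: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Non-parametric bootstrap over run-level parameter vectors.

    Resamples rows with replacement, takes the mean per resample, and
    reports the mean of resampled means with 2.5%/97.5% percentile CIs —
    mirroring bootstrap resampling of the parameters from the top runs.
    """
    df = pd.DataFrame([vars(p) if isinstance(p, ParameterSet) else dict(p)
                       for p in param_vectors])
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        warnings.warn("single parameter vector: zero-width confidence intervals")
        means = arr.mean(axis=0)
        return pd.DataFrame({"mean": means, "ci_2.5": means, "ci_97.5": means},
                            index=df.columns)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.shape[0], size=(n_resamples, arr.shape[0]))
    resampled_means = arr[idx].mean(axis=1)
    return pd.DataFrame({
        "mean": resampled_means.mean(axis=0),
        "ci_2.5": np.percentile(resampled_means, 2.5, axis=0),
        "ci_97.5": np.percentile(resampled_means, 97.5, axis=0),
    }, index=df.columns)
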