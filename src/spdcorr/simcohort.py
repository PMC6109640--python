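"""Two-cohort GWAS simulation for phenotypic-correlation estimators.

The generator builds a union sample laid out as
``[A-only | shared | B-only]`` so cohorts A and B are contiguous row views
that agree exactly on the shared individuals (genotypes, environmental
factors and phenotype values).  Two phenotypes are constructed from the same
genotypes plus a common bank of environmental factors:

    y_t = X_std @ b_t  +  F @ c_t,        t = 1, 2

with weight vectors scaled so each phenotype has unit variance, the genetic
part contributes ``genetic_pct`` percent of it, and the cross-trait
covariance is split genetic:environmental in the same proportion, giving
``corr(y1, y2) = rho_target`` in expectation.  Per-factor variance shares
are random (normalized squared Gaussians), i.e. the correlation is spread
over the factors at random rather than evenly.

A scenario runner performs the GWAS of phenotype 1 in cohort A and
phenotype 2 in cohort B, estimates their correlation from summary
statistics alone (bivariate LD score regression intercept, or the Pearson
correlation of the two beta vectors), and compares it with the observed
correlation in the union sample — repeated ``n_sims`` times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import ldscore as _ldscore
from .ldscore import LDScoreTable, fit_bivariate
from .sumstats import SummaryStats, harmonize_pair

logger = logging.getLogger(__name__)

ESTIMATORS = ("ldsc_intercept", "beta_pearson")


@dataclass(frozen=True)
class SimulationScenario:
    """One row of the simulation design grid."""

    n_ind_a: int
    n_ind_b: int
    n_overlap: int
    n_snps: int
    ld_blocks: int = 0
    ld_r_max: float = 0.0
    n_env_factors: int = 1000
    genetic_pct: float = 50.0
    rho_target: float = 0.5
    n_sims: int = 100
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.n_ind_a, self.n_ind_b, self.n_snps,
               self.n_env_factors, self.n_sims) <= 0:
            raise ValueError("sizes must be positive")
        if not 0 <= self.n_overlap <= min(self.n_ind_a, self.n_ind_b):
            raise ValueError("n_overlap must be in [0, min(nA, nB)]")
        if not 0 <= self.genetic_pct <= 100:
            raise ValueError("genetic_pct must be in [0, 100]")
        if not -1 < self.rho_target < 1:
            raise ValueError("rho_target must be in (-1, 1)")
        if not 0 <= self.ld_r_max <= 0.95:
            raise ValueError("ld_r_max must be in [0, 0.95]")
        if self.ld_blocks < 0:
            raise ValueError("ld_blocks must be >= 0")

    @property
    def n_union(self) -> int:
        return self.n_ind_a + self.n_ind_b - self.n_overlap

    def scaled(self, scale_factor: float) -> "SimulationScenario":
        """Multiply n_snps and n_sims by a fraction (desk-scale runs)."""
        if scale_factor == 1.0:
            return self
        return replace(self,
                       n_snps=max(1, round(self.n_snps * scale_factor)),
                       n_sims=max(1, round(self.n_sims * scale_factor)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class CohortData:
    """Realized genotypes and phenotypes for one replicate.

    Cohort matrices are row views into the union genotype matrix
    (``[A-only | shared | B-only]`` layout), so shared individuals are
    identical in both cohorts by construction.
    """

    genotypes_a: np.ndarray = field(repr=False)
    genotypes_b: np.ndarray = field(repr=False)
    pheno1_a: np.ndarray = field(repr=False)
    pheno2_a: np.ndarray = field(repr=False)
    pheno1_b: np.ndarray = field(repr=False)
    pheno2_b: np.ndarray = field(repr=False)
    overlap_index: dict = field(default_factory=dict)
    # union-level extras used by the scenario runner
    genotypes_union: np.ndarray | None = field(default=None, repr=False)
    genotypes_std: np.ndarray | None = field(default=None, repr=False)
    pheno1_union: np.ndarray | None = field(default=None, repr=False)
    pheno2_union: np.ndarray | None = field(default=None, repr=False)
    genetic1_union: np.ndarray | None = field(default=None, repr=False)
    genetic2_union: np.ndarray | None = field(default=None, repr=False)
    snp_ids: np.ndarray | None = None


@dataclass
class SimulationResult:
    """Aggregate of one scenario: observed vs estimated correlation."""

    scenario: SimulationScenario
    estimator: str
    obs_rp_mean: float
    est_rp_mean: float
    est_rp_sd: float
    deviation_pct: float
    per_sim: pd.DataFrame = field(repr=False)  # obs_rp, est_rp, rg_obs

    def to_row(self) -> dict:
        sc = self.scenario
        pct = 0.0
        if min(sc.n_ind_a, sc.n_ind_b) > 0:
            pct = 100.0 * sc.n_overlap / min(sc.n_ind_a, sc.n_ind_b)
        return {
            "Model": sc.name, "N_ind_A": sc.n_ind_a, "N_ind_B": sc.n_ind_b,
            "N_overlap": sc.n_overlap, "Overlap_pct": round(pct, 1),
            "N_SNPs": sc.n_snps, "LD_blocks": sc.ld_blocks,
            "N_EnvF": sc.n_env_factors, "Genetic_pct": sc.genetic_pct,
            "N_simu": sc.n_sims, "Estimator": self.estimator,
            "Obs_rp": round(self.obs_rp_mean, 4),
            "Est_rp": round(self.est_rp_mean, 4),
            "Est_rp_sd": round(self.est_rp_sd, 4),
            "Deviation_pct": round(self.deviation_pct, 2),
        }


def deviation_pct(obs: float, est: float) -> float:
    """Percent deviation 100*|obs - est| / |obs| of an estimate."""
    if obs == 0:
        return float("nan")
    return 100.0 * abs(obs - est) / abs(obs)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _rng_for(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    # Philox: fast, counter-based, safe to key with (seed, stream) pairs
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed_or_rng)))


def _get_buf(ws: dict | None, key: str, shape, dtype):
    if ws is None:
        return np.empty(shape, dtype=dtype)
    arr = ws.get(key)
    if arr is None or arr.shape != shape or arr.dtype != dtype:
        arr = np.empty(shape, dtype=dtype)
        ws[key] = arr
    return arr


try:  # optional fused kernel; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=False)
    def _dosage_fill(u, t1, t2, g):  # pragma: no cover - numba-compiled
        for i in range(u.shape[0]):
            for j in range(u.shape[1]):
                x = u[i, j]
                g[i, j] = np.int8(x >= t1[j]) + np.int8(x >= t2[j])

except ImportError:  # pragma: no cover
    _dosage_fill = None


def _independent_genotypes(rng, n, maf, ws=None):
    """Binomial(2, maf) dosages via one uniform and two cumulative cuts."""
    m = maf.size
    t1 = ((1.0 - maf) ** 2).astype(np.float32)
    t2 = (1.0 - maf ** 2).astype(np.float32)
    u = _get_buf(ws, "u", (n, m), np.float32)
    rng.random(out=u, dtype=np.float32)
    g = _get_buf(ws, "g8", (n, m), np.int8)
    if _dosage_fill is not None:
        _dosage_fill(u, t1, t2, g)
    else:
        np.greater_equal(u, t1, out=g.view(np.bool_))
        b2 = _get_buf(ws, "b2", (n, m), np.int8)
        np.greater_equal(u, t2, out=b2.view(np.bool_))
        g += b2
    return g


def _ld_block_genotypes(rng, n, maf, n_blocks, ld_r_max):
    """Dosages with within-block LD from a latent AR(1) Gaussian per haplotype.

    The adjacent-SNP latent correlation is sqrt(ld_r_max), so neighbouring
    latent variables have squared correlation ld_r_max (genotype-scale r2 is
    slightly lower after dichotomizing to alleles).
    """
    m = maf.size
    phi = np.sqrt(ld_r_max)
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    g = np.empty((n, m), dtype=np.int8)
    thr = _norm_ppf(maf)  # allele = 1 when latent < threshold
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        for hap in range(2):
            latent = np.empty((n, hi - lo), dtype=np.float32)
            latent[:, 0] = rng.standard_normal(n, dtype=np.float32)
            if phi > 0:
                innov_sd = np.float32(np.sqrt(1.0 - phi * phi))
                for j in range(1, hi - lo):
                    latent[:, j] = phi * latent[:, j - 1] + \
                        innov_sd * rng.standard_normal(n, dtype=np.float32)
            else:
                latent[:, 1:] = rng.standard_normal((n, hi - lo - 1),
                                                    dtype=np.float32)
            allele = (latent < thr[lo:hi].astype(np.float32)).view(np.int8)
            if hap == 0:
                g[:, lo:hi] = allele
            else:
                g[:, lo:hi] += allele
    return g


def _norm_ppf(p):
    from scipy.special import ndtri
    return ndtri(np.asarray(p, dtype=np.float64))


def _correlated_weights(rng, m, total_var, rho):
    """Two weight vectors with ||b1||^2 = ||b2||^2 = total_var and
    b1.b2 = rho * total_var (exactly), with random per-factor shares."""
    if total_var <= 0:
        z = np.zeros(m)
        return z, z.copy()
    u = rng.standard_normal(m)
    v = rng.standard_normal(m)
    # Gram-Schmidt so the in-sample correlation of the weights is exact
    v = v - u * (u @ v) / (u @ u)
    b1 = u / np.linalg.norm(u)
    b2 = rho * b1 + np.sqrt(1.0 - rho * rho) * v / np.linalg.norm(v)
    s = np.sqrt(total_var)
    return s * b1, s * b2


def simulate_cohorts(sc: SimulationScenario, rng_state=None,
                     workspace: dict | None = None) -> CohortData:
    """Draw one replicate of the two-cohort, two-phenotype design.

    ``workspace`` (an ordinary dict) lets repeated calls at the same scenario
    size recycle the large buffers; the returned arrays are then views into
    it and are overwritten by the next call.
    """
    rng = _rng_for(rng_state if rng_state is not None else sc.seed)
    n = sc.n_union
    m = sc.n_snps
    g_share = sc.genetic_pct / 100.0
    if abs(sc.rho_target) > 1:
        raise ValueError("infeasible correlation split")

    maf = rng.uniform(0.05, 0.5, m)
    if sc.ld_blocks > 0:
        G = _ld_block_genotypes(rng, n, maf, sc.ld_blocks, sc.ld_r_max)
        zbuf = None
    else:
        G = _independent_genotypes(rng, n, maf.astype(np.float32), workspace)
        # the uniform buffer is free again once dosages exist; reuse it for Z
        zbuf = workspace["u"] if workspace is not None else None

    Z, keep = _ldscore._standardize(G, out=zbuf)
    if not keep.all():
        # monomorphic columns keep zero weight; Z column is zeros already
        Z[:, ~keep] = 0.0

    b1, b2 = _correlated_weights(rng, m, g_share, sc.rho_target)
    c1, c2 = _correlated_weights(rng, sc.n_env_factors, 1.0 - g_share,
                                 sc.rho_target)
    gen1 = Z @ b1.astype(np.float32)
    gen2 = Z @ b2.astype(np.float32)
    F = _get_buf(workspace, "F", (n, sc.n_env_factors), np.float32)
    rng.standard_normal(out=F, dtype=np.float32)
    y1 = gen1.astype(np.float64) + F @ c1.astype(np.float32)
    y2 = gen2.astype(np.float64) + F @ c2.astype(np.float32)

    na, nb, nov = sc.n_ind_a, sc.n_ind_b, sc.n_overlap
    a = slice(0, na)
    b = slice(na - nov, na - nov + nb)
    snp_ids = np.array([f"snp{j}" for j in range(m)], dtype=object)
    return CohortData(
        genotypes_a=G[a], genotypes_b=G[b],
        pheno1_a=y1[a], pheno2_a=y2[a], pheno1_b=y1[b], pheno2_b=y2[b],
        overlap_index={"a": np.arange(na - nov, na),
                       "b": np.arange(0, nov)},
        genotypes_union=G, genotypes_std=Z,
        pheno1_union=y1, pheno2_union=y2,
        genetic1_union=gen1.astype(np.float64),
        genetic2_union=gen2.astype(np.float64),
        snp_ids=snp_ids,
    )


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def run_gwas(genotypes, phenotype, snp_ids=None, trait_id: str = "trait",
             n_override=None) -> SummaryStats:
    """Per-SNP simple linear regression of phenotype on dosage.

    beta = cov(x, y)/var(x); se = sqrt(RSS/(n-2) / Sxx); z = beta/se.
    Monomorphic or perfectly fitting (RSS = 0) SNPs are dropped with a
    warning.  Alleles are synthetic placeholders (A/G).
    """
    G = np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = G.shape
    if n != y.size:
        raise ValueError("genotype rows and phenotype length differ")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(m)], dtype=object)
    # float64 inputs keep full precision; integer/float32 dosage matrices
    # (the large simulated panels) run in float32 for speed
    work = np.float64 if G.dtype == np.float64 else np.float32
    Gf = G.astype(work, copy=False)
    yc = (y - y.mean()).astype(work)
    sx = Gf.sum(axis=0, dtype=np.float64)
    sxx = np.einsum("ij,ij->j", Gf, Gf, dtype=np.float64)
    Sxx = sxx - sx * sx / n
    Sxy = (Gf.T @ yc).astype(np.float64)  # y centered, so no mean term
    Syy = float(yc.astype(np.float64) @ yc.astype(np.float64))
    ok = Sxx > 0
    beta = np.divide(Sxy, Sxx, out=np.zeros(m), where=ok)
    rss = Syy - beta * Sxy
    rss = np.maximum(rss, 0.0)
    se2 = np.divide(rss / (n - 2), Sxx, out=np.zeros(m), where=ok)
    # RSS indistinguishable from 0 at working precision means se = 0
    ok &= rss > 1e-6 * max(Syy, 1e-300)
    if not ok.all():
        logger.warning("run_gwas %s: dropped %d degenerate SNPs", trait_id,
                       int((~ok).sum()))
    se = np.sqrt(se2[ok])
    beta = beta[ok]
    nvec = np.full(int(ok.sum()), float(n_override if n_override else n))
    return SummaryStats.from_arrays(
        trait_id, np.asarray(snp_ids, dtype=object)[ok],
        a1=np.full(int(ok.sum()), "A", dtype=object),
        a2=np.full(int(ok.sum()), "G", dtype=object),
        beta=beta, se=se, n=nvec)


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

def _pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom) if denom > 0 else float("nan")


def run_scenario(sc: SimulationScenario, estimator: str = "ldsc_intercept",
                 seed: int | None = None, ld_window: int = 200,
                 weights: str = "ldsc", n_blocks: int = 200,
                 min_snps: int = 200) -> SimulationResult:
    """Repeat the simulate → GWAS → estimate loop and aggregate accuracy.

    Each replicate uses an independent counter-derived RNG stream
    ``(seed, replicate)`` so results are reproducible and order-independent.
    ``ldsc_intercept`` computes LD scores from the union genotypes of the
    replicate (window in SNPs) and takes the bivariate regression intercept;
    ``beta_pearson`` correlates the two GWAS beta vectors.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    base_seed = sc.seed if seed is None else seed
    n_blocks_eff = min(n_blocks, max(2, sc.n_snps // 2))
    a_rows = slice(0, sc.n_ind_a)
    b_rows = slice(sc.n_ind_a - sc.n_overlap,
                   sc.n_ind_a - sc.n_overlap + sc.n_ind_b)
    rows = []
    ws: dict = {}
    for i in range(sc.n_sims):
        rng = _rng_for([base_seed, i])
        cohort = simulate_cohorts(sc, rng, workspace=ws)
        if estimator == "ldsc_intercept":
            # z-scores are invariant to per-SNP linear rescaling of dosages,
            # so the union-standardized matrix (already float32) serves both
            # cohorts without re-casting the raw dosages
            ss1 = run_gwas(cohort.genotypes_std[a_rows], cohort.pheno1_a,
                           cohort.snp_ids, trait_id="pheno1_A")
            ss2 = run_gwas(cohort.genotypes_std[b_rows], cohort.pheno2_b,
                           cohort.snp_ids, trait_id="pheno2_B")
        else:
            ss1 = run_gwas(cohort.genotypes_a, cohort.pheno1_a,
                           cohort.snp_ids, trait_id="pheno1_A")
            ss2 = run_gwas(cohort.genotypes_b, cohort.pheno2_b,
                           cohort.snp_ids, trait_id="pheno2_B")
        obs = _pearson(cohort.pheno1_union, cohort.pheno2_union)
        rg = _pearson(cohort.genetic1_union, cohort.genetic2_union) \
            if sc.genetic_pct > 0 else float("nan")
        if len(ss1) == len(ss2) and \
                (ss1.df["snp_id"].to_numpy() == ss2.df["snp_id"].to_numpy()).all():
            h1, h2 = ss1, ss2  # identical SNP sets and alleles by construction
        else:
            h1, h2 = harmonize_pair(ss1, ss2, drop_ambiguous=False)
        if estimator == "ldsc_intercept":
            l2 = _ldscore._ld_scores_banded(
                cohort.genotypes_std, min(ld_window, sc.n_snps - 1), False)
            ltab = LDScoreTable(pd.DataFrame({
                "snp_id": cohort.snp_ids, "chrom": np.nan, "pos": np.nan,
                "l2": l2}), m_total=sc.n_snps)
            try:
                fit = fit_bivariate(h1, h2, ltab, n_blocks=n_blocks_eff,
                                    weights=weights, min_snps=min_snps)
            except ValueError as exc:
                raise ValueError(f"scenario {sc.name or sc}: {exc}") from exc
            est = fit.intercept
        else:
            from .phenocorr import beta_pearson
            est = beta_pearson(h1, h2)
        rows.append((obs, est, rg))
    per_sim = pd.DataFrame(rows, columns=["obs_rp", "est_rp", "rg_obs"])
    obs_mean = float(per_sim["obs_rp"].mean())
    est_mean = float(per_sim["est_rp"].mean())
    return SimulationResult(
        scenario=sc, estimator=estimator, obs_rp_mean=obs_mean,
        est_rp_mean=est_mean, est_rp_sd=float(per_sim["est_rp"].std(ddof=1))
        if len(per_sim) > 1 else 0.0,
        deviation_pct=deviation_pct(obs_mean, est_mean), per_sim=per_sim)


# ---------------------------------------------------------------------------
# Published scenario grids
# ---------------------------------------------------------------------------

def _sc(name, na, nb, pct, m, gen, blocks=0, rmax=0.0) -> SimulationScenario:
    nov = round(pct / 100.0 * min(na, nb))
    return SimulationScenario(
        n_ind_a=na, n_ind_b=nb, n_overlap=nov, n_snps=m, ld_blocks=blocks,
        ld_r_max=rmax, n_env_factors=1000, genetic_pct=gen, rho_target=0.5,
        n_sims=100, name=name)


def scenario_grid(name: str, scale_factor: float = 1.0):
    """The published simulation design grids.

    ``table1`` is the genetic/environmental-share series evaluated with the
    beta-correlation estimator (1,000 SNPs, full overlap); ``table2`` is the
    43-row LDSC-intercept design (component shares, sample size, overlap,
    unbalanced cohorts, SNP count, LD structure).  ``scale_factor``
    multiplies n_snps and n_sims for desk-scale runs.
    """
    grids = {"table1": _table1_grid, "table2": _table2_grid}
    if name not in grids:
        raise ValueError(f"unknown grid {name!r}; choose from {sorted(grids)}")
    return [sc.scaled(scale_factor) for sc in grids[name]()]


def _table1_grid():
    return [
        _sc(f"Genetic_Env_components {i + 1}", 5000, 5000, 100, 1000, 10 * i)
        for i in range(11)
    ]


def _table2_grid():
    rows = []
    for i in range(11):
        rows.append(_sc(f"Genetic_Env_components {i + 1}", 5000, 5000, 100,
                        200_000, 10 * i))
    for i, n in enumerate([1000, 3000, 5000, 10_000, 50_000, 100_000]):
        rows.append(_sc(f"sample size {i + 1}", n, n, 50, 200_000, 50))
    for i in range(9):
        rows.append(_sc(f"sample overlap {i + 1}", 5000, 5000, 10 * (i + 1),
                        200_000, 50))
    # overlap percentage is authoritative for the unbalanced series
    for i, (nb, pct) in enumerate([(5000, 90), (6000, 82), (8000, 69),
                                   (10_000, 60), (13_000, 50)]):
        rows.append(_sc(f"unbalance sample {i + 1}", 5000, nb, pct, 200_000, 50))
    for i, m in enumerate([7500, 12_500, 25_000, 50_000, 100_000, 200_000]):
        rows.append(_sc(f"number of SNPs {i + 1}", 5000, 5000, 50, m, 50))
    for i, (m, blocks) in enumerate([(10_000, 1), (20_000, 2), (30_000, 3),
                                     (40_000, 4), (50_000, 5), (200_000, 0)]):
        rows.append(_sc(f"Linkage disequilibrium {i + 1}", 5000, 5000, 50, m,
                        50, blocks=blocks, rmax=0.9 if blocks else 0.0))
    return rows
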