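"""LD scores and LD score regression (univariate and cross-trait).

The LD score of SNP *j* is ``l2_j = sum_k r^2_jk`` over SNPs *k* in a local
window around *j*, including *j* itself (``r^2_jj = 1``).  Regressing per-SNP
association statistics on LD scores separates polygenic signal (the slope,
which scales with heritability or genetic covariance) from confounding and
sample-sharing effects (the intercept).  For a pair of traits the regression
is ``z1_j * z2_j ~ l2_j``: the slope scales to the genetic covariance via
``sqrt(N1*N2)/M`` and the intercept estimates ``rho * N_s / sqrt(N1*N2)``,
the phenotypic correlation attenuated by sample overlap — equal to the
phenotypic correlation itself when both GWAS were run on one sample.

Uncertainty comes from a delete-one-block jackknife over contiguous SNP
blocks, which is robust to the local LD dependence between neighbouring
regression observations.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class LDScoreTable:
    """Per-SNP LD scores plus the SNP count M used in slope scaling."""

    df: pd.DataFrame = field(repr=False)  # snp_id, chrom, pos, l2
    m_total: int = 0

    def __post_init__(self) -> None:
        if self.m_total == 0:
            self.m_total = len(self.df)
        if self.m_total <= 0:
            raise ValueError("m_total must be positive")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LdscFit:
    """Slope/intercept of one LD score regression with jackknife SEs.

    For ``kind == "univariate"`` the coheritability field ``h2`` is the SNP
    heritability ``slope * M / mean(N)``; for ``kind == "bivariate"`` it is
    the genetic covariance ``slope * M / sqrt(mean(N1) * mean(N2))``.
    """

    kind: str
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    h2: float
    h2_se: float
    n_snps_used: int
    n_blocks: int
    mean_chisq: float
    n_mean1: float = float("nan")
    n_mean2: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def report(self) -> str:
        lines = [
            f"LD score regression ({self.kind})",
            f"  SNPs used: {self.n_snps_used} (jackknife blocks: {self.n_blocks})",
            f"  mean statistic: {self.mean_chisq:.4f}",
            f"  slope: {self.slope:.6g} ({self.slope_se:.3g})",
            f"  intercept: {self.intercept:.6g} ({self.intercept_se:.3g})",
        ]
        label = "h2" if self.kind == "univariate" else "genetic covariance"
        lines.append(f"  {label}: {self.h2:.6g} ({self.h2_se:.3g})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# LD score computation
# ---------------------------------------------------------------------------

def _standardize(genotypes: np.ndarray, out: np.ndarray | None = None,
                 dtype=np.float32):
    """Column-standardize a dosage matrix in float32; return (Z, kept mask).

    ``out`` may supply a preallocated buffer of the same shape and dtype.
    """
    G = np.asarray(genotypes)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if out is None:
        Z = G.astype(dtype, copy=True)
    else:
        np.copyto(out, G, casting="unsafe")
        Z = out
        dtype = out.dtype
    mu = Z.mean(axis=0, dtype=np.float64)
    Z -= mu.astype(dtype)
    ss = np.einsum("ij,ij->j", Z, Z, dtype=np.float64)
    keep = ss > 0
    sd = np.sqrt(ss / n, where=keep, out=np.ones_like(ss))
    Z /= sd.astype(dtype)
    return Z, keep


def compute_ld_scores(genotypes, snp_ids=None, window: int = 200,
                      adjusted: bool = False, positions=None,
                      window_kb: float | None = None,
                      dtype=np.float32) -> LDScoreTable:
    """Compute per-SNP LD scores from a reference dosage panel.

    ``window`` is counted in SNPs on each side of the index SNP (input
    order); pass ``window_kb`` with ``positions`` for physical windows.
    ``window >= M`` sums over all pairs.  With ``adjusted`` each squared
    correlation is replaced by the bias-corrected
    ``r2 - (1 - r2)/(n - 2)``.  Monomorphic SNPs are dropped with a warning.
    ``dtype`` controls the working precision (float32 default; pass float64
    for reference-grade scores on small panels).
    """
    G = np.asarray(genotypes)
    n, m_all = G.shape
    if window_kb is None and not window > 0:
        raise ValueError("window must be positive")
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(m_all)], dtype=object)
    else:
        snp_ids = np.asarray(snp_ids, dtype=object)
    Z, keep = _standardize(G, dtype=dtype)
    if not keep.all():
        logger.warning("compute_ld_scores: dropped %d monomorphic SNPs",
                       int((~keep).sum()))
        Z = Z[:, keep]
        snp_ids = snp_ids[keep]
        if positions is not None:
            positions = np.asarray(positions)[keep]
    m = Z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs")

    if window_kb is not None:
        if positions is None:
            raise ValueError("window in kb requires SNP positions")
        l2 = _ld_scores_kb(Z, np.asarray(positions, float), window_kb, adjusted)
    else:
        l2 = _ld_scores_banded(Z, int(window), adjusted)

    df = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": np.nan,
        "pos": positions if positions is not None else np.nan,
        "l2": l2,
    })
    return LDScoreTable(df, m_total=m)


def _adjust_r2(r2: np.ndarray, n: int) -> np.ndarray:
    return r2 - (1.0 - r2) / (n - 2)


def _ld_scores_banded(Z: np.ndarray, window: int, adjusted: bool) -> np.ndarray:
    """Banded all-pairs-within-window sum of squared correlations.

    Works block-wise with one GEMM per block of index SNPs against the
    ``window`` following SNPs, accumulating each squared correlation to both
    partners; the self term is added analytically.
    """
    n, m = Z.shape
    w = min(window, m - 1)
    l2 = np.full(m, 1.0)  # self term, r2 = 1 (adjusted self term is also 1)
    if w == 0:
        return l2
    b = max(64, min(512, w))
    for s in range(0, m, b):
        e = min(s + b, m)
        hi = min(m, e + w)
        nb, ncol = e - s, hi - s
        R = (Z[:, s:e].T @ Z[:, s:hi]) / np.float32(n)
        R2 = (R.astype(np.float64)) ** 2
        if adjusted:
            R2 = _adjust_r2(R2, n)
        wloc = min(w, ncol - 1)
        pad = np.zeros((nb, nb + wloc), dtype=np.float64)
        pad[:, :ncol] = R2
        stride_r, stride_c = pad.strides
        band = np.lib.stride_tricks.as_strided(
            pad[:, 1:], shape=(nb, wloc), strides=(stride_r + stride_c, stride_c))
        l2[s:e] += band.sum(axis=1)
        for d in range(1, wloc + 1):
            col = band[:, d - 1]
            ke = min(e + d, m)
            lo = s + d
            l2[lo:ke] += col[: ke - lo]
    return l2


def _ld_scores_kb(Z: np.ndarray, pos: np.ndarray, window_kb: float,
                  adjusted: bool) -> np.ndarray:
    n, m = Z.shape
    order = np.argsort(pos, kind="stable")
    inv = np.argsort(order)
    Zs = Z[:, order]
    ps = pos[order]
    half = window_kb * 1000.0
    lo = np.searchsorted(ps, ps - half, side="left")
    hi = np.searchsorted(ps, ps + half, side="right")
    l2 = np.empty(m)
    for j in range(m):
        r = (Zs[:, lo[j]:hi[j]].T @ Zs[:, j]) / n
        r2 = r.astype(np.float64) ** 2
        if adjusted:
            r2 = _adjust_r2(r2, n)
            r2[j - lo[j]] = 1.0
        l2[j] = r2.sum()
    return l2[inv]


# ---------------------------------------------------------------------------
# LD score file dialect (.l2.ldscore / .l2.M)
# ---------------------------------------------------------------------------

def read_ldscore(path, m_path=None) -> LDScoreTable:
    """Read a tab-delimited LD score file (header CHR SNP BP L2; CHR/BP may
    be absent) and optionally a companion M file (one integer per line)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    if "SNP" not in cols or "L2" not in cols:
        raise ValueError(f"{path}: LD score file needs SNP and L2 columns")
    out = pd.DataFrame({
        "snp_id": df[cols["SNP"]].astype(str),
        "chrom": df[cols["CHR"]] if "CHR" in cols else np.nan,
        "pos": df[cols["BP"]] if "BP" in cols else np.nan,
        "l2": pd.to_numeric(df[cols["L2"]]),
    })
    m_total = 0
    if m_path is not None:
        with open(str(m_path)) as fh:
            m_total = int(sum(float(line.split()[0]) for line in fh if line.strip()))
    return LDScoreTable(out, m_total=m_total or len(out))


def write_ldscore(table: LDScoreTable, path, m_path=None) -> None:
    out = pd.DataFrame({
        "CHR": table.df["chrom"], "SNP": table.df["snp_id"],
        "BP": table.df["pos"], "L2": table.df["l2"],
    })
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                   lineterminator="\n")
    if m_path is not None:
        with open(str(m_path), "w", newline="\n") as fh:
            fh.write(f"{table.m_total}\n")


# ---------------------------------------------------------------------------
# Block jackknife and weighted straight-line fits
# ---------------------------------------------------------------------------

def _block_bounds(m: int, n_blocks: int) -> list[tuple[int, int]]:
    """Contiguous equal spans in input order; remainder goes to the last."""
    size = m // n_blocks
    bounds = [(i * size, (i + 1) * size) for i in range(n_blocks)]
    bounds[-1] = (bounds[-1][0], m)
    return bounds


def block_jackknife(values, estimator, n_blocks: int):
    """Delete-one-block jackknife over contiguous blocks of SNP-ordered data.

    ``values`` is an array (or tuple of arrays) indexed by SNP; ``estimator``
    maps such data to a scalar or vector.  Returns ``(estimate, se)`` where
    the SE is ``sqrt((b-1)/b * sum((theta_i - theta_bar)^2))`` over the
    leave-one-block-out estimates.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    single = not isinstance(values, (tuple, list))
    arrays = (values,) if single else tuple(values)
    m = len(arrays[0])
    if m < n_blocks:
        raise ValueError(f"only {m} observations for {n_blocks} blocks; "
                         "reduce n_blocks")

    def call(arrs):
        return np.atleast_1d(np.asarray(
            estimator(arrs[0] if single else arrs), dtype=float))

    full = call(arrays)
    thetas = np.empty((n_blocks, full.size))
    for i, (lo, hi) in enumerate(_block_bounds(m, n_blocks)):
        sub = tuple(np.concatenate([a[:lo], a[hi:]]) for a in arrays)
        thetas[i] = call(sub)
    bar = thetas.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((thetas - bar) ** 2).sum(axis=0))
    if full.size == 1:
        return float(full[0]), float(se[0])
    return full, se


def _wls_line_jackknife(x, y, w, n_blocks, fix_slope_zero: bool = False):
    """Weighted least squares of y on (1, x) with delete-one-block jackknife.

    Uses per-block sufficient statistics so the b leave-one-out fits cost
    O(b).  With ``fix_slope_zero`` (or a degenerate regressor) the slope is
    pinned at 0 and the intercept is the weighted mean of y, jackknifed the
    same way.  Returns (slope, slope_se, intercept, intercept_se).
    """
    m = len(x)
    stats = np.empty((n_blocks, 5))
    for i, (lo, hi) in enumerate(_block_bounds(m, n_blocks)):
        wi, xi, yi = w[lo:hi], x[lo:hi], y[lo:hi]
        wx = wi * xi
        stats[i] = (wi.sum(), wx.sum(), (wi * yi).sum(),
                    (wx * xi).sum(), (wx * yi).sum())

    def solve(s):
        sw, swx, swy, swxx, swxy = s
        if fix_slope_zero:
            return np.array([0.0, swy / sw])
        det = sw * swxx - swx * swx
        if det <= 0 or not np.isfinite(det) or det < 1e-12 * sw * max(swxx, 1e-30):
            return np.array([0.0, swy / sw])
        slope = (sw * swxy - swx * swy) / det
        inter = (swxx * swy - swx * swxy) / det
        return np.array([slope, inter])

    total = stats.sum(axis=0)
    full = solve(total)
    thetas = np.array([solve(total - stats[i]) for i in range(n_blocks)])
    bar = thetas.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((thetas - bar) ** 2).sum(axis=0))
    return full[0], se[0], full[1], se[1]


def _l2_degenerate(l2: np.ndarray, w: np.ndarray, min_l2_cv: float) -> bool:
    """True when the LD scores are too close to constant to identify a slope.

    With (near-)constant LD scores — e.g. a panel of independent SNPs, where
    l2 departs from 1 only through chance-LD sampling noise — slope and
    intercept are not separately identified and the OLS intercept inherits
    the slope's noise amplified by the lever arm mean(l2)/sd(l2).  The guard
    compares the weighted coefficient of variation of l2 against
    ``min_l2_cv`` (conceptually an rcond threshold for the design matrix).
    """
    sw = w.sum()
    mu = (w * l2).sum() / sw
    var = (w * (l2 - mu) ** 2).sum() / sw
    if mu <= 0:
        return True
    return np.sqrt(var) / mu < min_l2_cv


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def _merge(s: SummaryStats, l: LDScoreTable):
    merged = s.df.merge(l.df[["snp_id", "l2"]], on="snp_id", how="inner")
    return merged


def _check_floor(m: int, n_blocks: int, min_snps: int):
    if m < n_blocks:
        raise ValueError(
            f"{m} SNPs is fewer than {n_blocks} jackknife blocks; "
            "reduce n_blocks")
    if m < min_snps:
        raise ValueError(f"need at least {min_snps} SNPs, got {m}")


def fit_univariate(s: SummaryStats, l: LDScoreTable, n_blocks: int = 200,
                   weights: str = "ldsc", min_snps: int = 200,
                   min_l2_cv: float = 0.05) -> LdscFit:
    """Heritability fit: regress chi^2 = z^2 on l2.

    ``h2 = slope * M / mean(N)``; the intercept estimates the confounding
    inflation (1 under the null).  With ``weights="ldsc"`` a two-step scheme
    is used: an unweighted first pass estimates h2, then weights
    ``1 / (max(l2, 1) * (1 + N*h2*l2/M)^2)`` are applied.  When the LD
    scores are effectively constant (CV below ``min_l2_cv``) the slope is
    not identified and is pinned at 0 (see :func:`_l2_degenerate`).
    """
    merged = _merge(s, l)
    m = len(merged)
    _check_floor(m, n_blocks, max(n_blocks, min_snps))
    l2 = merged["l2"].to_numpy(float)
    chi2 = merged["z"].to_numpy(float) ** 2
    nbar = float(merged["n"].mean())
    M = l.m_total

    wvec = np.ones(m)
    degen = _l2_degenerate(l2, wvec, min_l2_cv)
    if degen:
        logger.warning("fit_univariate %s: LD scores are near-constant; "
                       "slope is unidentified and pinned at 0", s.trait_id)
    if weights == "ldsc":
        slope0, _, _, _ = _wls_line_jackknife(l2, chi2, wvec, n_blocks,
                                              fix_slope_zero=degen)
        h2_0 = np.clip(slope0 * M / nbar, 0.0, 1.0)
        wvec = 1.0 / (np.maximum(l2, 1.0) * (1.0 + nbar * h2_0 * l2 / M) ** 2)
    elif weights != "none":
        raise ValueError(f"unknown weights {weights!r}")

    slope, slope_se, inter, inter_se = _wls_line_jackknife(
        l2, chi2, wvec, n_blocks, fix_slope_zero=degen)
    scale = M / nbar
    return LdscFit("univariate", slope, slope_se, inter, inter_se,
                   slope * scale, slope_se * scale, m, n_blocks,
                   float(chi2.mean()), n_mean1=nbar, n_mean2=nbar)


def fit_bivariate(s1: SummaryStats, s2: SummaryStats, l: LDScoreTable,
                  n_blocks: int = 200, weights: str = "ldsc",
                  min_snps: int = 200, min_l2_cv: float = 0.05) -> LdscFit:
    """Cross-trait fit: regress z1*z2 on l2.

    The slope scales to the genetic covariance by ``M / sqrt(N1*N2)``; the
    raw intercept estimates ``rho * N_s / sqrt(N1*N2)`` — the phenotypic
    correlation under the one-sample assumption (see
    :func:`spdcorr.phenocorr.rp_from_ldsc` for overlap conversions).
    Inputs must be harmonized: same SNP ids in the same order.
    """
    if len(s1) != len(s2) or not (s1.df["snp_id"].to_numpy() ==
                                  s2.df["snp_id"].to_numpy()).all():
        raise ValueError("inputs are not harmonized (SNP ids differ); "
                         "run harmonize_pair first")
    merged1 = _merge(s1, l)
    merged2 = _merge(s2, l)
    m = len(merged1)
    _check_floor(m, n_blocks, max(n_blocks, min_snps))
    l2 = merged1["l2"].to_numpy(float)
    z1 = merged1["z"].to_numpy(float)
    z2 = merged2["z"].to_numpy(float)
    y = z1 * z2
    if np.ptp(y) == 0 and len(y) > 1 and y.std() == 0:
        raise ValueError("zero-variance z1*z2 product")
    n1 = float(merged1["n"].mean())
    n2 = float(merged2["n"].mean())
    M = l.m_total
    root = np.sqrt(n1 * n2)

    wvec = np.ones(m)
    degen = _l2_degenerate(l2, wvec, min_l2_cv)
    if degen:
        logger.warning("fit_bivariate %s/%s: LD scores are near-constant; "
                       "slope is unidentified and pinned at 0",
                       s1.trait_id, s2.trait_id)
    if weights == "ldsc":
        s1a, _, _, _ = _wls_line_jackknife(l2, z1 ** 2, wvec, n_blocks,
                                           fix_slope_zero=degen)
        s2a, _, _, _ = _wls_line_jackknife(l2, z2 ** 2, wvec, n_blocks,
                                           fix_slope_zero=degen)
        sb, _, ib, _ = _wls_line_jackknife(l2, y, wvec, n_blocks,
                                           fix_slope_zero=degen)
        h1 = np.clip(s1a * M / n1, 0.0, 1.0)
        h2_ = np.clip(s2a * M / n2, 0.0, 1.0)
        covg = np.clip(sb * M / root, -1.0, 1.0)
        a = (1.0 + n1 * h1 * l2 / M) * (1.0 + n2 * h2_ * l2 / M)
        b = root * covg * l2 / M + ib
        wvec = 1.0 / (np.maximum(l2, 1.0) * (a + b ** 2))
    elif weights != "none":
        raise ValueError(f"unknown weights {weights!r}")

    slope, slope_se, inter, inter_se = _wls_line_jackknife(
        l2, y, wvec, n_blocks, fix_slope_zero=degen)
    scale = M / root
    return LdscFit("bivariate", slope, slope_se, inter, inter_se,
                   slope * scale, slope_se * scale, m, n_blocks,
                   float(y.mean()), n_mean1=n1, n_mean2=n2)
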