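"""Trait-by-trait phenotypic correlation matrices from summary statistics.

Two estimators are supported:

* ``ldsc_intercept`` — the bivariate LD score regression intercept, which
  estimates ``rho * N_s / sqrt(N1 * N2)`` and equals the phenotypic
  correlation rho when both GWAS come from one sample (the default
  assumption; a known overlap count can be supplied to undo the
  attenuation).
* ``beta_pearson`` — the Pearson correlation of the two univariate GWAS
  effect-size vectors.  This tracks the genetic, not the phenotypic,
  correlation unless the two coincide, and carries no standard error.

Raw pairwise estimates can fall outside [-1, 1] because the regression
intercept is noisy; ``condition_matrix`` symmetrizes, clips and fixes the
diagonal so the matrix is a valid input for spectral decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .ldscore import LDScoreTable, LdscFit, fit_bivariate, fit_univariate
from .sumstats import SummaryStats, harmonize_pair, trait_qc

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Trait x trait correlation estimates with provenance flags."""

    trait_ids: list[str]
    values: np.ndarray = field(repr=False)
    se: np.ndarray | None = field(default=None, repr=False)
    estimator: str = "ldsc_intercept"
    conditioned: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.trait_ids)
        if self.values.shape != (k, k):
            raise ValueError(f"matrix shape {self.values.shape} does not "
                             f"match {k} trait ids")

    @property
    def na_count(self) -> int:
        """Missing off-diagonal pairs (upper triangle count)."""
        iu = np.triu_indices(len(self.trait_ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.trait_ids,
                            columns=self.trait_ids)

    def long_format(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.trait_ids)), 2):
            rp = self.values[i, j]
            rows.append({
                "trait1": self.trait_ids[i], "trait2": self.trait_ids[j],
                "rp": rp,
                "se": self.se[i, j] if self.se is not None else np.nan,
                "estimator": self.estimator,
                "status": "ok" if np.isfinite(rp) else "missing",
            })
        return pd.DataFrame(rows)


def read_matrix(path) -> CorrelationMatrix:
    """Read a delimited square matrix with a header row and id column
    (delimiter auto-detected among tab/comma/whitespace)."""
    with open(str(path)) as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ("," if "," in head else r"\s+")
    df = pd.read_csv(str(path), sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square "
                         f"(shape {df.shape[0]}x{df.shape[1]})")
    return CorrelationMatrix(list(df.index.astype(str)), df.to_numpy(float))


def write_matrix(m: CorrelationMatrix, path, sep: str = "\t") -> None:
    with open(str(path), "w", newline="\n") as fh:
        m.to_dataframe().to_csv(fh, sep=sep, float_format="%.6f",
                                lineterminator="\n")


# ---------------------------------------------------------------------------
# Pairwise estimators
# ---------------------------------------------------------------------------

def rp_from_ldsc(fit: LdscFit, n1: float, n2: float,
                 n_overlap: float | None = None) -> tuple[float, float]:
    """Convert a bivariate-fit intercept to a phenotypic correlation.

    With the overlap count known, ``rp = intercept * sqrt(n1*n2) /
    n_overlap``; by default the one-sample assumption ``n_overlap =
    sqrt(n1*n2)`` applies and the intercept is returned as is.  The SE
    scales identically.
    """
    if fit.kind != "bivariate":
        raise ValueError("rp_from_ldsc needs a bivariate fit")
    if n_overlap is None:
        return float(fit.intercept), float(fit.intercept_se)
    if n_overlap <= 0:
        raise ValueError("phenotypic correlation is undefined without "
                         "sample overlap (n_overlap = 0)")
    scale = np.sqrt(n1 * n2) / n_overlap
    return float(fit.intercept * scale), float(fit.intercept_se * scale)


def beta_pearson(s1: SummaryStats, s2: SummaryStats) -> float:
    """Pearson correlation of two aligned GWAS beta vectors (no SE)."""
    if len(s1) != len(s2) or not (s1.df["snp_id"].to_numpy() ==
                                  s2.df["snp_id"].to_numpy()).all():
        raise ValueError("inputs are not harmonized; run harmonize_pair first")
    if len(s1) < 3:
        raise ValueError("need at least 3 SNPs")
    b1 = s1.df["beta"].to_numpy(float)
    b2 = s2.df["beta"].to_numpy(float)
    if np.isnan(b1).any() or np.isnan(b2).any():
        raise ValueError("beta column required for the beta-correlation "
                         "estimator")
    if np.ptp(b1) == 0 or np.ptp(b2) == 0:
        raise ValueError("constant beta vector: correlation undefined")
    c1 = b1 - b1.mean()
    c2 = b2 - b2.mean()
    return float(c1 @ c2 / np.sqrt((c1 @ c1) * (c2 @ c2)))


# ---------------------------------------------------------------------------
# Matrix construction and conditioning
# ---------------------------------------------------------------------------

def build_matrix(traits: list[SummaryStats], l: LDScoreTable | None = None,
                 estimator: str = "ldsc_intercept",
                 pair_policy: str = "all_pairs", groups: dict | None = None,
                 qc: bool = True, force: bool = False, n_blocks: int = 200,
                 min_snps: int = 200, qc_min_n: float = 5000,
                 qc_min_snps: int = 200_000,
                 qc_min_h2_z: float = 2.0) -> tuple[CorrelationMatrix, list]:
    """Fill a trait x trait matrix pairwise with the chosen estimator.

    Traits failing the QC gate are excluded (kept with ``force=True``);
    pairs whose regression fails become missing values.  With
    ``pair_policy="within_group"`` only pairs sharing a group label (from
    ``groups``: trait_id -> label) are estimated — the grouping strategy for
    overlap-sensitive estimators.  Returns the matrix plus the QC reports.
    """
    if estimator not in ("ldsc_intercept", "beta_pearson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if pair_policy not in ("all_pairs", "within_group"):
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    if pair_policy == "within_group" and groups is None:
        raise ValueError("within_group policy needs a groups mapping")

    reports = []
    usable = []
    for s in traits:
        if qc and estimator == "ldsc_intercept" and l is not None:
            fit = fit_univariate(s, l, n_blocks=min(n_blocks, max(2, len(s) // 2)),
                                 min_snps=min_snps)
            rep = trait_qc(s, fit, min_n=qc_min_n, min_snps=qc_min_snps,
                           min_h2_z=qc_min_h2_z)
            reports.append(rep)
            if not rep.passed and not force:
                logger.warning("build_matrix: excluding %s (%s)", s.trait_id,
                               "; ".join(rep.reasons))
                continue
        usable.append(s)
    if len(usable) < 2:
        detail = "; ".join(f"{r.trait_id}: {', '.join(r.reasons)}"
                           for r in reports if not r.passed)
        raise ValueError("fewer than 2 usable traits after QC"
                         + (f" ({detail})" if detail else ""))

    ids = [s.trait_id for s in usable]
    k = len(ids)
    vals = np.full((k, k), np.nan)
    ses = np.full((k, k), np.nan)
    np.fill_diagonal(vals, 1.0)
    np.fill_diagonal(ses, 0.0)
    for i, j in combinations(range(k), 2):
        if pair_policy == "within_group" and \
                groups.get(ids[i]) != groups.get(ids[j]):
            continue
        try:
            h1, h2 = harmonize_pair(usable[i], usable[j])
            if estimator == "ldsc_intercept":
                fit = fit_bivariate(h1, h2, l,
                                    n_blocks=min(n_blocks, max(2, len(h1) // 2)),
                                    min_snps=min_snps)
                rp, se = rp_from_ldsc(fit, fit.n_mean1, fit.n_mean2)
            else:
                rp, se = beta_pearson(h1, h2), np.nan
            vals[i, j] = vals[j, i] = rp
            ses[i, j] = ses[j, i] = se
            if abs(rp) >= 1:
                logger.warning("build_matrix: |rp| >= 1 for %s/%s (%.3f); "
                               "conditioning will clip it", ids[i], ids[j], rp)
        except ValueError as exc:
            logger.warning("build_matrix: pair %s/%s failed: %s",
                           ids[i], ids[j], exc)
    out = CorrelationMatrix(ids, vals, se=ses, estimator=estimator)
    logger.info("build_matrix: %d traits, %d missing pairs", k, out.na_count)
    return out, reports


def condition_matrix(m: CorrelationMatrix,
                     na_action: str = "fail") -> CorrelationMatrix:
    """Make a raw pairwise matrix a valid correlation-matrix input for SpD.

    Symmetrizes via (M + M')/2, clips to [-1, 1], forces a unit diagonal,
    and resolves missing cells: ``fail`` errors listing the offending pairs,
    ``drop_trait`` iteratively removes the trait with the most missing cells
    (lexicographically last id on ties), ``zero`` substitutes 0 with a loud
    log message.  Idempotent.
    """
    if na_action not in ("fail", "drop_trait", "zero"):
        raise ValueError(f"unknown na_action {na_action!r}")
    ids = list(m.trait_ids)
    vals = m.values.copy()
    se = m.se.copy() if m.se is not None else None

    if na_action == "drop_trait":
        while True:
            off = np.isnan(vals)
            np.fill_diagonal(off, False)
            counts = off.sum(axis=1)
            if counts.sum() == 0:
                break
            worst = counts.max()
            cand = [i for i, c in enumerate(counts) if c == worst]
            drop = max(cand, key=lambda i: ids[i])
            logger.warning("condition_matrix: dropping %s (%d missing pairs)",
                           ids[drop], int(worst))
            keep = np.arange(len(ids)) != drop
            vals = vals[np.ix_(keep, keep)]
            if se is not None:
                se = se[np.ix_(keep, keep)]
            ids = [t for i, t in enumerate(ids) if keep[i]]
        if len(ids) < 2:
            raise ValueError("fewer than 2 traits left after dropping "
                             "missing rows")
    else:
        off = np.isnan(vals)
        np.fill_diagonal(off, False)
        if off.any():
            pairs = [(ids[i], ids[j]) for i, j in zip(*np.where(np.triu(off)))]
            if na_action == "fail":
                raise ValueError(f"missing correlations for pairs: {pairs}")
            logger.warning("condition_matrix: substituting 0 for %d missing "
                           "pairs: %s", len(pairs), pairs[:10])
            vals[off] = 0.0

    vals = (vals + vals.T) / 2.0
    vals = np.clip(vals, -1.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return CorrelationMatrix(ids, vals, se=se, estimator=m.estimator,
                             conditioned=True)


def nearest_psd(m: CorrelationMatrix) -> CorrelationMatrix:
    """Project a conditioned matrix onto the PSD cone (eigenvalue clipping).

    Not applied by default: the SpD effective-test count tolerates negative
    eigenvalues, and clipping changes the spectrum it summarizes.  Offered
    for downstream consumers that require a proper correlation matrix.
    """
    if not m.conditioned:
        raise ValueError("condition the matrix first")
    lam, vec = np.linalg.eigh(m.values)
    if lam.min() >= 0:
        return m
    vals = (vec * np.maximum(lam, 0.0)) @ vec.T
    d = np.sqrt(np.clip(np.diag(vals), 1e-12, None))
    vals = vals / np.outer(d, d)
    vals = np.clip((vals + vals.T) / 2, -1.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return CorrelationMatrix(m.trait_ids, vals, se=m.se,
                             estimator=m.estimator, conditioned=True)


def observed_matrix(phenotypes: pd.DataFrame) -> CorrelationMatrix:
    """Direct Pearson correlation matrix of individual-level phenotypes
    (columns = traits); the benchmark the summary-level estimators target."""
    vals = phenotypes.corr(method="pearson").to_numpy()
    return CorrelationMatrix(list(phenotypes.columns.astype(str)), vals,
                             estimator="observed", conditioned=False)
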