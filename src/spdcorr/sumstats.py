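"""GWAS summary-statistic tables: I/O, harmonization, filtering, trait QC.

A summary-statistic table holds one trait's per-SNP association results
(SNP id, effect/other allele, signed Z score, per-SNP sample size, and
optionally beta/SE).  Two on-disk dialects are supported:

* ``generic_tsv`` — tab-delimited with case-insensitive column aliases
  (SNP|rsid, A1, A2, Z, BETA|b, SE, N); gzip transparent.
* ``ldsc_sumstats`` — the de-facto ``.sumstats`` standard: exactly
  SNP, A1, A2, Z, N.

Harmonization aligns two tables to a common SNP set and effect-allele
orientation, flipping Z (and beta) signs where the effect/other alleles
are swapped, optionally after strand complementation; strand-ambiguous
(A/T, C/G) variants can be dropped because their orientation cannot be
resolved from alleles alone.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: canonical column order of the in-memory table
COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "z", "n", "beta", "se"]

_ALIASES = {
    "snp": "snp_id", "rsid": "snp_id", "snp_id": "snp_id", "markername": "snp_id",
    "chr": "chrom", "chrom": "chrom",
    "bp": "pos", "pos": "pos",
    "a1": "a1", "effect_allele": "a1",
    "a2": "a2", "other_allele": "a2",
    "z": "z", "zscore": "z",
    "beta": "beta", "b": "beta",
    "se": "se",
    "n": "n",
}


class SumstatsFormatError(ValueError):
    """Raised when a summary-statistics file cannot be interpreted."""


@dataclass
class SummaryStats:
    """Per-SNP association results for one trait.

    ``df`` columns: snp_id, chrom, pos, a1, a2, z, n, beta, se
    (chrom/pos/beta/se may be all-NaN — simulated data has no coordinates).
    """

    trait_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SumstatsFormatError(f"missing columns: {missing}")
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].head(3).tolist()
            raise SumstatsFormatError(f"duplicate snp_id values, e.g. {dups}")
        if len(df) and not (df["n"] > 0).all():
            raise SumstatsFormatError("non-positive sample size N")
        for col in ("a1", "a2"):
            bad = ~df[col].map(lambda a: set(str(a)) <= _VALID_ALLELES)
            if bad.any():
                raise SumstatsFormatError(
                    f"invalid alleles in {col}: {df.loc[bad, col].unique()[:3]}"
                )
        has_bse = df["beta"].notna() & df["se"].notna()
        if has_bse.any():
            z = df.loc[has_bse, "z"].to_numpy(float)
            zb = (df.loc[has_bse, "beta"] / df.loc[has_bse, "se"]).to_numpy(float)
            rel = np.abs(z - zb) / np.maximum(1.0, np.abs(z))
            if (rel > 1e-6).any():
                # beta/se is the primary statistic; a conflicting Z column loses
                logger.warning(
                    "%s: %d records where Z disagrees with beta/se; using beta/se",
                    self.trait_id, int((rel > 1e-6).sum()),
                )
                self.df.loc[has_bse, "z"] = df.loc[has_bse, "beta"] / df.loc[has_bse, "se"]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_median(self) -> float:
        return float(self.df["n"].median())

    @classmethod
    def from_arrays(cls, trait_id, snp_id, a1, a2, z=None, n=None,
                    beta=None, se=None, chrom=None, pos=None) -> "SummaryStats":
        m = len(snp_id)
        if z is None:
            if beta is None or se is None:
                raise ValueError("need z or beta+se")
            z = np.asarray(beta, float) / np.asarray(se, float)
        df = pd.DataFrame({
            "snp_id": np.asarray(snp_id, dtype=object),
            "chrom": chrom if chrom is not None else np.full(m, np.nan),
            "pos": pos if pos is not None else np.full(m, np.nan),
            "a1": np.asarray(a1, dtype=object),
            "a2": np.asarray(a2, dtype=object),
            "z": np.asarray(z, float),
            "n": np.asarray(n, float),
            "beta": np.asarray(beta, float) if beta is not None else np.full(m, np.nan),
            "se": np.asarray(se, float) if se is not None else np.full(m, np.nan),
        })
        return cls(trait_id, df)


@dataclass
class TraitQCReport:
    """Outcome of the minimum-parameter gate for LD score regression."""

    trait_id: str
    n_median: float
    n_snps: int
    h2: float
    h2_se: float
    h2_z: float
    passed: bool
    reasons: list[str]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(path, dialect: str = "generic_tsv", trait_id: str | None = None) -> SummaryStats:
    """Read a summary-statistics table.

    Rows with neither a usable Z nor beta+se are dropped (and counted in the
    log).  A scalar ``N`` given only in the header comment line ``# N=<val>``
    is broadcast to every record.
    """
    if dialect not in ("generic_tsv", "ldsc_sumstats"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header_n = None
    with _open_text(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            if "N=" in first:
                header_n = float(first.split("N=")[1].split()[0])
            first = fh.readline()
        cols = first.rstrip("\n").split("\t")
        if dialect == "ldsc_sumstats":
            if cols != ["SNP", "A1", "A2", "Z", "N"]:
                raise SumstatsFormatError(
                    f"ldsc_sumstats dialect requires columns SNP A1 A2 Z N, got {cols}"
                )
            renames = {"SNP": "snp_id", "A1": "a1", "A2": "a2", "Z": "z", "N": "n"}
        else:
            renames = {}
            for c in cols:
                key = c.strip().lower()
                if key in _ALIASES:
                    renames[c] = _ALIASES[key]
        try:
            df = pd.read_csv(fh, sep="\t", names=cols, dtype={c: str for c in cols})
        except Exception as exc:  # pragma: no cover - pandas error passthrough
            raise SumstatsFormatError(f"cannot parse {path}: {exc}") from exc
    df = df.rename(columns=renames)
    have = set(df.columns)
    need = {"snp_id", "a1", "a2"}
    if not need <= have:
        raise SumstatsFormatError(
            f"{path}: unrecognized header; missing {sorted(need - have)}"
        )
    if "z" not in have and not {"beta", "se"} <= have:
        raise SumstatsFormatError(f"{path}: need a Z column or BETA+SE columns")
    if "n" not in have and header_n is None:
        raise SumstatsFormatError(f"{path}: no N column and no header N")

    out = pd.DataFrame({"snp_id": df["snp_id"].astype(str),
                        "a1": df["a1"].str.upper(), "a2": df["a2"].str.upper()})
    for col in ("chrom",):
        out[col] = df[col] if col in have else np.nan
    for col in ("pos", "z", "n", "beta", "se"):
        if col in have:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
            if col in ("z", "n") and bad.any():
                line = int(bad.idxmax()) + 2  # 1-based + header
                raise SumstatsFormatError(
                    f"{path}: non-numeric {col.upper()} at line {line}"
                )
            out[col] = vals
        else:
            out[col] = np.nan
    if "n" not in have:
        out["n"] = header_n
    no_assoc = out["z"].isna() & (out["beta"].isna() | out["se"].isna())
    if no_assoc.any():
        logger.info("%s: dropped %d/%d records without Z or beta/se",
                    path, int(no_assoc.sum()), len(out))
        out = out[~no_assoc]
    miss_z = out["z"].isna()
    if miss_z.any():
        out.loc[miss_z, "z"] = out.loc[miss_z, "beta"] / out.loc[miss_z, "se"]
    tid = trait_id if trait_id is not None else _infer_trait_id(path)
    return SummaryStats(tid, out[COLUMNS])


def _infer_trait_id(path) -> str:
    import os
    name = os.path.basename(str(path))
    for suf in (".gz", ".sumstats", ".tsv", ".txt"):
        if name.endswith(suf):
            name = name[: -len(suf)]
    return name


def write_sumstats(s: SummaryStats, path, dialect: str = "generic_tsv") -> None:
    """Write a table in the given dialect (LF endings, %.6g numbers)."""
    df = s.df
    if dialect == "ldsc_sumstats":
        out = df[["snp_id", "a1", "a2", "z", "n"]].copy()
        out.columns = ["SNP", "A1", "A2", "Z", "N"]
    elif dialect == "generic_tsv":
        out = df[COLUMNS].copy()
        out.columns = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "BETA", "SE"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def _orientation(a1a, a2a, a1b, a2b):
    """Return +1 (same), -1 (swapped, flip sign), 0 (no match), trying the
    reverse strand as well."""
    if (a1b, a2b) == (a1a, a2a):
        return 1
    if (a1b, a2b) == (a2a, a1a):
        return -1
    c1 = _COMPLEMENT.get(a1b)
    c2 = _COMPLEMENT.get(a2b)
    if (c1, c2) == (a1a, a2a):
        return 1
    if (c1, c2) == (a2a, a1a):
        return -1
    return 0


def harmonize_pair(a: SummaryStats, b: SummaryStats,
                   drop_ambiguous: bool = True) -> tuple[SummaryStats, SummaryStats]:
    """Align two tables to common SNPs and a common effect-allele orientation.

    ``b``'s Z (and beta) signs are flipped wherever its allele pair is the
    reverse of ``a``'s, allele matching is retried on the complementary strand,
    and SNPs matching neither orientation are dropped.  With
    ``drop_ambiguous`` (default), A/T and C/G variants are removed from both
    outputs since strand cannot be resolved.  Output row order is identical
    in both tables (a's input order restricted to the kept intersection).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot harmonize an empty table")
    da = a.df.set_index("snp_id", drop=False)
    db = b.df.set_index("snp_id", drop=False)
    common = [s for s in da.index if s in db.index]
    if not common:
        raise ValueError("no overlapping SNPs")
    da = da.loc[common]
    db = db.loc[common]
    if drop_ambiguous:
        amb = [
            (x, y) in _AMBIGUOUS_PAIRS
            for x, y in zip(da["a1"], da["a2"])
        ]
        amb = np.asarray(amb)
        if amb.any():
            logger.info("harmonize %s/%s: dropped %d strand-ambiguous SNPs",
                        a.trait_id, b.trait_id, int(amb.sum()))
            da, db = da[~amb], db[~amb]
    orient = np.fromiter(
        (_orientation(x1, x2, y1, y2)
         for x1, x2, y1, y2 in zip(da["a1"], da["a2"], db["a1"], db["a2"])),
        dtype=int, count=len(da),
    )
    keep = orient != 0
    if not keep.all():
        logger.info("harmonize %s/%s: dropped %d allele-mismatch SNPs",
                    a.trait_id, b.trait_id, int((~keep).sum()))
    da, db, orient = da[keep], db[keep], orient[keep]
    if len(da) == 0:
        raise ValueError("no overlapping SNPs after allele matching")
    db = db.copy()
    db["z"] = db["z"].to_numpy(float) * orient
    db["beta"] = db["beta"].to_numpy(float) * orient
    db["a1"] = da["a1"].to_numpy()
    db["a2"] = da["a2"].to_numpy()
    logger.info("harmonize %s/%s: kept %d SNPs (%d sign flips)",
                a.trait_id, b.trait_id, len(da), int((orient == -1).sum()))
    return (SummaryStats(a.trait_id, da.reset_index(drop=True)),
            SummaryStats(b.trait_id, db.reset_index(drop=True)))


def chisq_filter(s: SummaryStats, max_chisq: float) -> SummaryStats:
    """Keep records with z² strictly below ``max_chisq`` (inf keeps all)."""
    if not max_chisq > 0:
        raise ValueError("max_chisq must be positive")
    if np.isinf(max_chisq):
        return SummaryStats(s.trait_id, s.df.copy())
    keep = s.df["z"].to_numpy(float) ** 2 < max_chisq
    logger.info("chisq_filter %s < %g: kept %d/%d", s.trait_id, max_chisq,
                int(keep.sum()), len(s))
    return SummaryStats(s.trait_id, s.df[keep].reset_index(drop=True))


def trait_qc(s: SummaryStats, h2_fit, min_n: float = 5000,
             min_snps: int = 200_000, min_h2_z: float = 2.0) -> TraitQCReport:
    """Gate a trait on sample size, SNP coverage and heritability evidence.

    The defaults are the usual minimum parameters for LD score regression:
    median N above 5,000, more than 200,000 SNPs, and a SNP-heritability
    Z score above 2.
    """
    h2 = float(h2_fit.h2)
    h2_se = float(h2_fit.h2_se)
    h2_z = h2 / h2_se if h2_se > 0 else np.inf * np.sign(h2) if h2 else 0.0
    reasons = []
    if not s.n_median > min_n:
        reasons.append(f"median N {s.n_median:g} <= {min_n:g}")
    if not len(s) > min_snps:
        reasons.append(f"SNP count {len(s)} <= {min_snps}")
    if not h2_z > min_h2_z:
        reasons.append(f"h2 Z score {h2_z:.3g} <= {min_h2_z:g}")
    return TraitQCReport(s.trait_id, s.n_median, len(s), h2, h2_se,
                         float(h2_z), not reasons, reasons)
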