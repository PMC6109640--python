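"""Effective number of independent tests by spectral decomposition (SpD).

Correlated phenotypes do not contribute independent hypotheses, so a
Bonferroni correction by the raw trait count over-corrects.  The SpD
approach eigendecomposes the trait correlation matrix and summarizes how
far its spectrum departs from the identity:

    Veff = 1 + (M - 1) * (1 - Var(lambda) / M)

with ``Var`` the sample variance (denominator M - 1) over the M
eigenvalues.  Identity input gives Veff = M (Bonferroni); a rank-one
all-ones matrix gives Veff = 1.  The Li & Ji variant
``sum_i [I(lambda_i >= 1) + frac(lambda_i)]`` is provided as a
cross-check.  The adjusted per-test significance threshold is
``alpha / Veff`` (no rounding of Veff to an integer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phenocorr import CorrelationMatrix


@dataclass
class SpDResult:
    """Eigenvalue spectrum and effective-test counts of a trait matrix."""

    m: int
    eigenvalues: np.ndarray = field(repr=False)
    veff_nyholt: float = 0.0
    veff_liji: float | None = None
    alpha_adjusted: float = 0.0
    method: str = "nyholt"

    @property
    def veff(self) -> float:
        return self.veff_nyholt if self.method == "nyholt" else self.veff_liji

    def report(self, alpha: float = 0.05) -> str:
        lines = [
            f"Traits (M): {self.m}",
            f"Effective number of independent tests (Nyholt): "
            f"{self.veff_nyholt:.1f}",
        ]
        if self.veff_liji is not None:
            lines.append(f"Effective number of independent tests (Li & Ji): "
                         f"{self.veff_liji:.1f}")
        lines.append(f"Selected method: {self.method}")
        lines.append(f"Adjusted significance threshold: "
                     f"{self.alpha_adjusted:.6g} (alpha = {alpha:g})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "veff_nyholt": self.veff_nyholt,
            "veff_liji": self.veff_liji,
            "alpha_adjusted": self.alpha_adjusted,
            "method": self.method,
        }


def _check_conditioned(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.isnan(values).any():
        raise ValueError("matrix has missing values; run condition_matrix")
    if np.abs(values - values.T).max() > 1e-8:
        raise ValueError("matrix is asymmetric; run condition_matrix")
    if np.abs(np.diag(values) - 1.0).max() > 1e-8:
        raise ValueError("diagonal is not 1; run condition_matrix")
    if np.abs(values).max() > 1.0 + 1e-12:
        raise ValueError("entries outside [-1, 1]; run condition_matrix")


def effective_tests(m: CorrelationMatrix | np.ndarray,
                    method: str = "nyholt", alpha: float = 0.05) -> SpDResult:
    """Effective number of independent tests from a conditioned matrix.

    Negative eigenvalues (possible for non-PSD pairwise-estimated matrices)
    enter the Nyholt variance as they are but are floored at 0 for the
    Li & Ji count.
    """
    if method not in ("nyholt", "liji"):
        raise ValueError(f"unknown method {method!r}")
    values = m.values if isinstance(m, CorrelationMatrix) else np.asarray(m, float)
    _check_conditioned(values)
    M = values.shape[0]
    lam = np.linalg.eigvalsh(values)[::-1]  # symmetric -> real, descending
    if M > 1:
        veff_n = 1.0 + (M - 1) * (1.0 - np.var(lam, ddof=1) / M)
    else:
        veff_n = 1.0
    lam_pos = np.maximum(lam, 0.0)
    # snap eigenvalues to nearby integers before taking the fractional part
    # (frac() is discontinuous there and 3 - 1e-15 must count as 3, not 2.99..)
    near = np.abs(lam_pos - np.round(lam_pos)) < 1e-9
    lam_pos = np.where(near, np.round(lam_pos), lam_pos)
    veff_l = float(np.sum((lam_pos >= 1).astype(float) +
                          (lam_pos - np.floor(lam_pos))))
    res = SpDResult(m=M, eigenvalues=lam, veff_nyholt=float(veff_n),
                    veff_liji=veff_l, method=method)
    res.alpha_adjusted = adjusted_alpha(res, alpha)
    return res


def adjusted_alpha(r: SpDResult, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / Veff for the selected method."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / r.veff
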