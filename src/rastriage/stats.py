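"""Cohort statistics: germline-vs-somatic ΔΔG comparison and
rate-perturbation / energy correlation.

The headline comparison asks whether somatic (cancer) mutations carry
larger predicted energy changes than germline (RASopathy) mutations.  It
is a two-sided two-sample t-test implemented from the closed form —
Welch's unequal-variance statistic with Welch–Satterthwaite degrees of
freedom by default, the pooled-variance variant behind a flag.

The second analysis correlates measured mutant rate-constant fold
changes with predicted ΔΔG values.  Energies are additive while rate
ratios are multiplicative, so the default Pearson coefficient is taken
against log10(fold change); the untransformed coefficient is reported
alongside.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .catalog import ValidationError

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "two_sample_t",
    "rate_energy_correlation",
    "two_sample_t_power",
]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float

    @property
    def direction(self) -> str:
        """Which group mean is larger ('a', 'b' or 'equal')."""
        if self.mean_a > self.mean_b:
            return "a"
        if self.mean_b > self.mean_a:
            return "b"
        return "equal"


@dataclass(frozen=True)
class CorrelationResult:
    r: float          # Pearson r of ΔΔG vs log10(fold change)
    r_raw: float      # Pearson r of ΔΔG vs raw fold change
    n: int


def _as_group(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(f"group {name!r} needs at least 2 observations")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"group {name!r} contains non-finite values")
    return arr


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pooled: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test from its closed form.

    Welch's variant by default: t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b)
    with Welch–Satterthwaite degrees of freedom.  ``pooled=True`` uses the
    classical equal-variance statistic with n_a + n_b − 2 df.  Group means
    are reported so the direction of the effect (e.g. somatic > germline)
    can be stated alongside the p-value.  Two identical constant groups
    return t = 0, p = 1.
    """
    a = _as_group(group_a, "a")
    b = _as_group(group_b, "b")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
    else:
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = float(na + nb - 2)
    if se2 == 0.0:
        # Zero spread in both groups: identical means -> no evidence.
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, float(a.mean()), float(b.mean()))
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, float(a.mean()), float(b.mean()))
    t = diff / math.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(a.mean()), float(b.mean()))


def rate_energy_correlation(
    fold_changes: Sequence[float],
    ddg: Sequence[float],
) -> CorrelationResult:
    """Pearson correlation of predicted ΔΔG against measured fold changes.

    The primary coefficient pairs ΔΔG with log10(fold change); the raw
    (untransformed) coefficient is reported as well.  Requires n ≥ 3 pairs,
    strictly positive fold changes, and non-zero variance in both margins.
    """
    fc = np.asarray(fold_changes, dtype=float)
    dg = np.asarray(ddg, dtype=float)
    if fc.shape != dg.shape or fc.ndim != 1 or fc.size < 3:
        raise ValidationError("need at least 3 (fold change, ΔΔG) pairs of equal length")
    if not (np.all(np.isfinite(fc)) and np.all(np.isfinite(dg))):
        raise ValidationError("non-finite values in the correlation input")
    if np.any(fc <= 0):
        raise ValidationError("fold changes must be > 0 for the log transform")
    log_fc = np.log10(fc)
    for margin, name in ((log_fc, "fold change"), (dg, "ΔΔG")):
        if np.allclose(margin, margin[0]):
            raise ValidationError(f"zero variance in the {name} margin")
    r_log = sps.pearsonr(dg, log_fc).statistic
    r_raw = sps.pearsonr(dg, fc).statistic
    return CorrelationResult(float(r_log), float(r_raw), int(fc.size))


def two_sample_t_power(
    effect_sd: float,
    n_per_group: int,
    alpha: float = 0.05,
) -> float:
    """Closed-form power of the two-sided two-sample t-test.

    For a true mean difference of ``effect_sd`` standard deviations and
    ``n_per_group`` observations per group, the statistic follows a
    noncentral t distribution with ncp = d·√(n/2) and 2n − 2 df.
    """
    if n_per_group < 2:
        raise ValidationError("need n >= 2 per group")
    df = 2 * n_per_group - 2
    ncp = effect_sd * math.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))
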