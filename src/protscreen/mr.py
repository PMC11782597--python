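"""Causal-effect estimators and directionality tests for two-sample MR.

With a single instrument the causal effect of exposure on outcome is the
Wald ratio beta_y / beta_x, with a first-order delta-method standard error
se_y / |beta_x| — adequate here because instruments are strong (F in the
hundreds).  With two or more instruments, per-SNP ratios are pooled by
inverse-variance-weighted regression through the origin with a
multiplicative random-effects (IVW-MRE) variance inflation: the fixed-effect
SE is scaled by max(1, sqrt(Q/(k−1))) where Q is Cochran's heterogeneity
statistic.

The Steiger directionality test compares the variance the instrument
explains in the exposure against the outcome; explaining more outcome than
exposure variance suggests the assumed causal direction is wrong.  For
binary outcomes the observed-scale variance explained is first mapped to
the liability scale using the population prevalence (Lee et al.
transformation), so case-control sampling does not distort the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedRow
from .instruments import compute_r2

Z_95 = 1.959964  # two-sided 95% normal multiplier


@dataclass
class MrResult:
    exposure_id: str
    outcome_id: str
    method: str            # wald | ivw_mre
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    q_stat: float | None = None
    q_pval: float | None = None
    relaxed_threshold: bool = False

    @property
    def ci_excludes_null(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_true: bool
    pval: float
    single_snp: bool = False


@dataclass(frozen=True)
class LiabilityParams:
    """Population prevalence K and sample case fraction P for a binary GWAS."""

    prevalence_k: float
    case_fraction_p: float

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_k < 1 or not 0 < self.case_fraction_p < 1:
            raise ValueError("prevalence_k and case_fraction_p must be in (0, 1)")


def _finish(
    beta: float, se: float, exposure_id: str, outcome_id: str, method: str,
    n_snp: int, binary_outcome: bool, q: float | None = None,
    q_pval: float | None = None,
) -> MrResult:
    ci_low, ci_high = beta - Z_95 * se, beta + Z_95 * se
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")
    res = MrResult(
        exposure_id=exposure_id, outcome_id=outcome_id, method=method,
        beta=beta, se=se, ci_low=ci_low, ci_high=ci_high, pval=pval,
        n_snp=n_snp, q_stat=q, q_pval=q_pval,
    )
    if binary_outcome:
        res.or_ = math.exp(beta)
        res.or_low = math.exp(ci_low)
        res.or_high = math.exp(ci_high)
    return res


def wald_ratio(
    row: HarmonizedRow,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    binary_outcome: bool = True,
) -> MrResult:
    """Single-instrument causal estimate beta_y/beta_x with delta-method SE."""
    if row.beta_x == 0:
        raise ZeroDivisionError("degenerate instrument: beta_x is 0")
    beta = row.beta_y / row.beta_x
    se = row.se_y / abs(row.beta_x)
    return _finish(beta, se, exposure_id, outcome_id, "wald", 1, binary_outcome)


def ivw_mre(
    rows: list[HarmonizedRow],
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    binary_outcome: bool = True,
) -> MrResult:
    """IVW with multiplicative random effects over >= 2 instruments.

    Weighted regression of beta_y on beta_x through the origin, weights
    1/se_y²; heterogeneity inflates the SE by max(1, sqrt(Q/(k−1))).
    """
    if len(rows) < 2:
        raise ValueError("ivw_mre needs >= 2 rows; use wald_ratio for one")
    bx = np.array([r.beta_x for r in rows])
    by = np.array([r.beta_y for r in rows])
    w = np.array([1.0 / r.se_y**2 for r in rows])
    swx2 = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / swx2
    se_fixed = 1.0 / math.sqrt(swx2)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    k = len(rows)
    phi = max(1.0, math.sqrt(q / (k - 1)))
    q_pval = float(stats.chi2.sf(q, k - 1))
    return _finish(
        beta, phi * se_fixed, exposure_id, outcome_id, "ivw_mre", k,
        binary_outcome, q, q_pval,
    )


def estimate(
    rows: list[HarmonizedRow], **kw
) -> MrResult:
    """Wald ratio for one instrument, IVW-MRE for two or more."""
    kept = [r for r in rows if r.kept]
    if not kept:
        raise ValueError("no harmonized instruments available")
    if len(kept) == 1:
        return wald_ratio(kept[0], **kw)
    return ivw_mre(kept, **kw)


def observed_to_liability_r2(r2_obs: float, lp: LiabilityParams) -> float:
    """Map observed-scale variance explained to the liability scale.

    Uses the threshold-model transformation
    r2_liab = r2_obs * K²(1−K)² / (z² * P(1−P)), with K the population
    prevalence, P the sample case fraction, and z the standard normal
    density at the threshold Φ⁻¹(1−K).
    """
    k, p = lp.prevalence_k, lp.case_fraction_p
    z = stats.norm.pdf(stats.norm.isf(k))
    return r2_obs * k**2 * (1 - k) ** 2 / (z**2 * p * (1 - p))


def weighted_prevalence(prevalences: list[tuple[float, float]]) -> float:
    """Pool prevalences on the logit scale with the given weights.

    Fixed-effect weighted mean of logit(prevalence), back-transformed;
    weights are typically the contributing GWAS sample sizes.
    """
    if not prevalences:
        raise ValueError("need at least one prevalence")
    for _, w in prevalences:
        if w <= 0:
            raise ValueError("weights must be > 0")
    logits = np.array([math.log(p / (1 - p)) for p, _ in prevalences])
    weights = np.array([w for _, w in prevalences])
    pooled = float(np.average(logits, weights=weights))
    return 1.0 / (1.0 + math.exp(-pooled))


def steiger(
    rows: list[HarmonizedRow],
    binary_outcome: bool = False,
    lp: LiabilityParams | None = None,
) -> SteigerResult:
    """Steiger directionality test on the instrument SNPs.

    Variance explained is summed per SNP on each side from the summary-data
    R² formula; for binary outcomes it is converted to the liability scale
    (``lp`` required).  The p-value compares Fisher-transformed correlations
    sqrt(R²) at the two sample sizes.  Ties in R² resolve to
    direction_true = False.
    """
    kept = [r for r in rows if r.kept]
    if not kept:
        raise ValueError("no harmonized instruments available")
    if binary_outcome and lp is None:
        raise ValueError("liability parameters required for a binary outcome")
    r2_exp = sum(compute_r2(r.beta_x, r.eaf, r.se_x, r.n_x) for r in kept)
    r2_out = 0.0
    for r in kept:
        eaf_y = r.eaf_y if not math.isnan(r.eaf_y) else r.eaf
        r2 = compute_r2(r.beta_y, eaf_y, r.se_y, r.n_y)
        if binary_outcome:
            r2 = observed_to_liability_r2(r2, lp)
        r2_out += r2
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    n_exp = min(r.n_x for r in kept)
    n_out = min(r.n_y for r in kept)
    z_exp = math.atanh(math.sqrt(r2_exp))
    z_out = math.atanh(math.sqrt(r2_out))
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / denom
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction_true=r2_exp > r2_out,
        pval=pval,
        single_snp=len(kept) == 1,
    )
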