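"""Fixed-effect GWAS meta-analysis with genomic control and heterogeneity
filtering, following the METAL standard-error-weighted scheme.

Genomic control estimates the inflation factor λ as the median association
chi-square divided by 0.4549 (the median of a 1-df chi-square); when λ > 1
every SE is inflated by sqrt(λ) and p-values are recomputed, correcting for
residual population stratification before pooling.  Studies are combined
per variant by inverse-variance weighting, and variants whose cross-study
heterogeneity p-value is <= 0.05 (inclusive) are removed from the pooled
set.  The SE-weighted scheme is used (rather than sample-size z-weighting)
because the pooled betas and SEs feed directly into MR as outcome
associations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import COMPLEMENT, HarmonizeConfig
from .sumstats import AssociationRecord, SummaryStatSet

CHI2_1_MEDIAN = 0.4549


@dataclass
class MetaRecord:
    rsid: str
    beta_meta: float
    se_meta: float
    pval_meta: float
    q_stat: float
    het_pval: float
    n_studies: int
    lambda_applied: tuple[float, ...] = ()


def genomic_control(sset: SummaryStatSet) -> tuple[SummaryStatSet, float]:
    """Apply METAL-style genomic control to one study's summary statistics.

    Returns the (possibly) adjusted set and the raw λ estimate.  λ is only
    applied when > 1; with fewer than 100 variants the estimate is
    unreliable, a warning is emitted and λ is forced to 1.
    """
    z2 = np.array([rec.z**2 for rec in sset])
    if len(z2) == 0:
        return sset, 1.0
    lam = float(np.median(z2) / CHI2_1_MEDIAN)
    if len(z2) < 100:
        warnings.warn(
            f"{sset.trait_id}: only {len(z2)} variants; lambda unreliable, forcing 1",
            stacklevel=2,
        )
        return sset, 1.0
    if lam <= 1.0:
        return sset, lam
    scale = math.sqrt(lam)
    adjusted = SummaryStatSet(sset.trait_id, sset.trait_type, sset.platform, sset.build)
    for rec in sset:
        se = rec.se * scale
        pval = float(min(1.0, 2.0 * stats.norm.sf(abs(rec.beta) / se)))
        pval = max(pval, 5e-324)
        adjusted.add(rec.replace(se=se, pval=pval))
    return adjusted, lam


def _align_to(ref: AssociationRecord, other: AssociationRecord,
              cfg: HarmonizeConfig) -> AssociationRecord | None:
    """Align ``other``'s effect allele to ``ref``'s, or None if impossible.

    Reuses the harmonization allele rules, including the palindromic
    frequency-inference with its MAF <= bound.
    """
    ea_r, oa_r = ref.variant.effect_allele, ref.variant.other_allele
    ea, oa = other.variant.effect_allele, other.variant.other_allele
    if ref.variant.is_palindromic or other.variant.is_palindromic:
        if {ea, oa} != {ea_r, oa_r}:
            return None
        if ref.maf >= cfg.palindrome_maf_max or other.maf >= cfg.palindrome_maf_max:
            return None
        label_swapped = ea == oa_r
        eaf = 1 - other.eaf if label_swapped else other.eaf
        beta = -other.beta if label_swapped else other.beta
        if (ref.eaf < 0.5) != (eaf < 0.5):
            beta, eaf = -beta, 1 - eaf
        return other.replace(variant=ref.variant, beta=beta, eaf=eaf)
    if (ea, oa) == (ea_r, oa_r) or (COMPLEMENT[ea], COMPLEMENT[oa]) == (ea_r, oa_r):
        return other.replace(variant=ref.variant)
    if (ea, oa) == (oa_r, ea_r) or (COMPLEMENT[ea], COMPLEMENT[oa]) == (oa_r, ea_r):
        return other.replace(variant=ref.variant, beta=-other.beta, eaf=1 - other.eaf)
    return None


def meta_fixed(records: list[AssociationRecord],
               cfg: HarmonizeConfig | None = None,
               lambdas: tuple[float, ...] = ()) -> MetaRecord:
    """Inverse-variance fixed-effect meta-analysis of one variant.

    Records after the first are allele-aligned to the first; incompatible
    alleles raise.  Q and the heterogeneity p-value use n_studies − 1 df.
    """
    if len(records) < 2:
        raise ValueError("meta_fixed needs >= 2 studies")
    cfg = cfg or HarmonizeConfig()
    ref = records[0]
    aligned = [ref]
    for rec in records[1:]:
        adj = _align_to(ref, rec, cfg)
        if adj is None:
            raise ValueError(f"{rec.rsid}: alleles incompatible across studies")
        aligned.append(adj)
    betas = np.array([r.beta for r in aligned])
    w = np.array([1.0 / r.se**2 for r in aligned])
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(1.0 / math.sqrt(np.sum(w)))
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(beta_meta) / se_meta)))
    q = float(np.sum(w * (betas - beta_meta) ** 2))
    het_pval = float(stats.chi2.sf(q, len(aligned) - 1))
    return MetaRecord(
        rsid=ref.rsid, beta_meta=beta_meta, se_meta=se_meta, pval_meta=pval,
        q_stat=q, het_pval=max(het_pval, 5e-324), n_studies=len(aligned),
        lambda_applied=lambdas,
    )


def filter_heterogeneity(
    meta_records: list[MetaRecord], threshold: float = 0.05
) -> tuple[list[MetaRecord], dict[str, int]]:
    """Remove variants with heterogeneity p <= threshold (inclusive bound)."""
    kept = [m for m in meta_records if m.het_pval > threshold]
    report = {"n_input": len(meta_records), "n_removed": len(meta_records) - len(kept),
              "n_kept": len(kept)}
    return kept, report


def meta_analyse(
    study1: SummaryStatSet,
    study2: SummaryStatSet,
    apply_gc: bool = True,
    het_threshold: float = 0.05,
    cfg: HarmonizeConfig | None = None,
) -> tuple[SummaryStatSet, list[MetaRecord], dict]:
    """Meta-analyse two disease GWAS into a pooled SummaryStatSet.

    Genomic control is applied per study before pooling; variants present in
    only one study are dropped (heterogeneity is undefined for them), as are
    variants failing the heterogeneity filter.  The pooled set keeps the
    first study's allele orientation and sums sample sizes.
    """
    lam1 = lam2 = 1.0
    if apply_gc:
        study1, lam1 = genomic_control(study1)
        study2, lam2 = genomic_control(study2)
    shared = [rs for rs in study1.records if rs in study2]
    metas: list[MetaRecord] = []
    pooled = SummaryStatSet(
        trait_id=f"meta({study1.trait_id},{study2.trait_id})",
        trait_type=study1.trait_type,
        platform="meta",
        build=study1.build,
    )
    failed_alignment = 0
    for rs in shared:
        r1, r2 = study1.get(rs), study2.get(rs)
        try:
            m = meta_fixed([r1, r2], cfg, lambdas=(lam1, lam2))
        except ValueError:
            failed_alignment += 1
            continue
        metas.append(m)
    kept, het_report = filter_heterogeneity(metas, het_threshold)
    by_id = {m.rsid: m for m in kept}
    for rs in shared:
        m = by_id.get(rs)
        if m is None:
            continue
        r1, r2 = study1.get(rs), study2.get(rs)
        kwargs = {}
        if r1.n_case is not None and r2.n_case is not None:
            kwargs = {"n_case": r1.n_case + r2.n_case,
                      "n_control": r1.n_control + r2.n_control}
        pooled.add(
            r1.replace(
                beta=m.beta_meta, se=m.se_meta, pval=m.pval_meta,
                n=r1.n + r2.n, **kwargs,
            )
        )
    report = {
        "lambda_study1": lam1, "lambda_study2": lam2,
        "n_shared": len(shared), "n_failed_alignment": failed_alignment,
        **het_report,
    }
    return pooled, metas, report
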