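"""Allele harmonization of exposure/outcome record pairs, with LD proxies.

Exposure and outcome associations must refer to the same allele before a
ratio estimate means anything.  Matching allele pairs pass through; swapped
pairs flip the outcome beta and frequency; complementary pairs are read as
strand differences and flipped back.  Palindromic SNPs (A/T, C/G) carry no
strand information in their alleles, so alignment is inferred from allele
frequency: if both sides' minor-allele frequency is below the configured
bound (0.3), frequencies on the same side of 0.5 mean same strand
orientation; otherwise the pair is dropped as ambiguous.  Finally every
retained row is oriented so the exposure beta is non-negative — estimates
are then "per exposure-increasing allele".

When the exposure SNP is absent from the outcome study, a proxy in LD
r² >= 0.8 may stand in for it; the sign of r maps the proxy's alleles onto
the target's.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .sumstats import AssociationRecord, LDMatrix, SummaryStatSet

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizeConfig:
    proxy_min_r2: float = 0.8
    palindrome_maf_max: float = 0.3
    allow_palindromes: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.proxy_min_r2 <= 1:
            raise ValueError("proxy_min_r2 must be in (0, 1]")
        if not 0 < self.palindrome_maf_max <= 0.5:
            raise ValueError("palindrome_maf_max must be in (0, 0.5]")


@dataclass
class HarmonizedRow:
    """An exposure/outcome pair aligned to the exposure-increasing allele."""

    rsid_exposure: str
    rsid_outcome: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float            # exposure-side EAF after orientation
    eaf_y: float          # outcome-side EAF after orientation
    n_x: float
    n_y: float
    action: str           # direct | flipped | strand_inferred | proxied | dropped
    drop_reason: str | None = None
    n_case_y: float | None = None
    n_control_y: float | None = None

    @property
    def kept(self) -> bool:
        return self.action != "dropped"


ACTIONS = ("direct", "flipped", "strand_inferred", "proxied", "dropped")


def _dropped(exp: AssociationRecord, out: AssociationRecord, reason: str) -> HarmonizedRow:
    return HarmonizedRow(
        rsid_exposure=exp.rsid, rsid_outcome=out.rsid,
        beta_x=exp.beta, se_x=exp.se, beta_y=out.beta, se_y=out.se,
        eaf=exp.eaf, eaf_y=out.eaf, n_x=exp.n, n_y=out.n,
        action="dropped", drop_reason=reason,
        n_case_y=out.n_case, n_control_y=out.n_control,
    )


def harmonize_pair(
    exp: AssociationRecord,
    out: AssociationRecord,
    cfg: HarmonizeConfig | None = None,
    action_label: str | None = None,
) -> HarmonizedRow:
    """Harmonize one exposure/outcome record pair sharing an rsID.

    ``action_label`` overrides the recorded action (used by the proxy path,
    which performs the same alignment but reports ``proxied``).
    """
    cfg = cfg or HarmonizeConfig()
    if exp.rsid != out.rsid and action_label != "proxied":
        raise ValueError(f"rsid mismatch: {exp.rsid} vs {out.rsid}")

    ea_x, oa_x = exp.variant.effect_allele, exp.variant.other_allele
    ea_y, oa_y = out.variant.effect_allele, out.variant.other_allele

    beta_y, eaf_y = out.beta, out.eaf
    if exp.variant.is_palindromic or out.variant.is_palindromic:
        same_pair = {ea_y, oa_y} == {ea_x, oa_x}
        if not same_pair:
            return _dropped(exp, out, "incompatible_alleles")
        if not cfg.allow_palindromes:
            return _dropped(exp, out, "palindromic_disallowed")
        if exp.maf >= cfg.palindrome_maf_max or out.maf >= cfg.palindrome_maf_max:
            return _dropped(exp, out, "ambiguous_palindrome")
        # labels may agree or be swapped; frequency decides true orientation
        label_swapped = ea_y == oa_x  # outcome's effect label is exposure's other
        freq_same_side = (exp.eaf < 0.5) == ((1 - eaf_y if label_swapped else eaf_y) < 0.5)
        aligned_eaf = 1 - eaf_y if label_swapped else eaf_y
        aligned_beta = -beta_y if label_swapped else beta_y
        if not freq_same_side:
            # opposite strand: the labelled alignment is inverted
            aligned_beta, aligned_eaf = -aligned_beta, 1 - aligned_eaf
        beta_y, eaf_y = aligned_beta, aligned_eaf
        action = "strand_inferred"
    elif (ea_y, oa_y) == (ea_x, oa_x):
        action = "direct"
    elif (ea_y, oa_y) == (oa_x, ea_x):
        beta_y, eaf_y = -beta_y, 1 - eaf_y
        action = "flipped"
    elif (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (ea_x, oa_x):
        action = "direct"  # strand flip only; effect direction unchanged
    elif (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (oa_x, ea_x):
        beta_y, eaf_y = -beta_y, 1 - eaf_y
        action = "flipped"
    else:
        return _dropped(exp, out, "incompatible_alleles")

    beta_x, eaf_x = exp.beta, exp.eaf
    if beta_x < 0:  # orient to the exposure-increasing allele
        beta_x, beta_y = -beta_x, -beta_y
        eaf_x, eaf_y = 1 - eaf_x, 1 - eaf_y

    return HarmonizedRow(
        rsid_exposure=exp.rsid, rsid_outcome=out.rsid,
        beta_x=beta_x, se_x=exp.se, beta_y=beta_y, se_y=out.se,
        eaf=eaf_x, eaf_y=eaf_y, n_x=exp.n, n_y=out.n,
        action=action_label or action,
        n_case_y=out.n_case, n_control_y=out.n_control,
    )


@dataclass(frozen=True)
class ProxyMatch:
    proxy_rsid: str
    r: float
    r2: float

    @property
    def same_orientation(self) -> bool:
        """True when the proxy's effect allele tracks the target's."""
        return self.r >= 0


def find_proxy(
    target_rsid: str,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    cfg: HarmonizeConfig | None = None,
) -> ProxyMatch | None:
    """Best outcome-present LD proxy for a target SNP, or None.

    Candidates need r² >= ``proxy_min_r2`` with the target; the highest r²
    wins, ties resolved by genomic proximity to the target.  If the target
    itself is present in the outcome set, it is returned with an identity
    mapping.
    """
    cfg = cfg or HarmonizeConfig()
    if target_rsid not in ld:
        raise KeyError(f"{target_rsid} absent from LD matrix")
    if target_rsid in outcome:
        return ProxyMatch(target_rsid, 1.0, 1.0)
    t_idx = ld._index[target_rsid]
    t_pos = ld.positions[t_idx]
    best: tuple[float, float, str] | None = None  # (-r2, distance, rsid)
    best_r = 0.0
    for rsid in ld.rsids:
        if rsid == target_rsid or rsid not in outcome:
            continue
        r = ld.r_between(target_rsid, rsid)
        r2 = r * r
        if r2 < cfg.proxy_min_r2:
            continue
        dist = abs(ld.positions[ld._index[rsid]] - t_pos)
        key = (-r2, dist, rsid)
        if best is None or key < best:
            best, best_r = key, r
    if best is None:
        return None
    return ProxyMatch(best[2], float(best_r), float(best_r**2))


def harmonize_instrument(
    exposure_snps: list[AssociationRecord],
    outcome: SummaryStatSet,
    ld: LDMatrix | None = None,
    cfg: HarmonizeConfig | None = None,
) -> list[HarmonizedRow]:
    """Harmonize each instrument SNP against the outcome set, proxying
    missing SNPs through LD when possible.

    The exposure statistics always remain the original sentinel's; when a
    proxy stands in, the outcome record is the proxy's and the sign of LD r
    maps its alleles onto the target's.  SNPs with no outcome record and no
    qualifying proxy yield dropped rows with reason ``no_outcome_record``.
    """
    cfg = cfg or HarmonizeConfig()
    rows: list[HarmonizedRow] = []
    for exp in exposure_snps:
        out = outcome.get(exp.rsid)
        if out is not None:
            rows.append(harmonize_pair(exp, out, cfg))
            continue
        match = None
        if ld is not None and exp.rsid in ld:
            match = find_proxy(exp.rsid, outcome, ld, cfg)
        if match is None:
            rows.append(
                HarmonizedRow(
                    rsid_exposure=exp.rsid, rsid_outcome="",
                    beta_x=exp.beta, se_x=exp.se, beta_y=float("nan"), se_y=float("nan"),
                    eaf=exp.eaf, eaf_y=float("nan"), n_x=exp.n, n_y=float("nan"),
                    action="dropped", drop_reason="no_outcome_record",
                )
            )
            continue
        proxy_out = outcome.get(match.proxy_rsid)
        # re-label the exposure record at the proxy locus: the proxy allele
        # correlated with the exposure effect allele plays the effect role
        pv = proxy_out.variant
        if match.same_orientation:
            ea, oa, eaf = pv.effect_allele, pv.other_allele, exp.eaf
        else:
            ea, oa, eaf = pv.other_allele, pv.effect_allele, 1 - exp.eaf
        pseudo_exp = exp.replace(
            variant=replace(exp.variant, rsid=pv.rsid, chrom=pv.chrom, pos=pv.pos,
                            effect_allele=ea, other_allele=oa),
            eaf=eaf,
        )
        row = harmonize_pair(pseudo_exp, proxy_out, cfg, action_label="proxied")
        row.rsid_exposure = exp.rsid
        rows.append(row)
    return rows
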