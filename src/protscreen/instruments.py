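"""Instrument selection: cis-pQTL sentinels, LD clumping, and strength metrics.

Proteins are instrumented by a single sentinel cis-SNP: genome-wide
significant SNPs within 1 Mb of the gene's transcription start site are
grouped into regions (overlapping flanks merge, as do SNP pairs in high LD),
and the lowest-p SNP of the region containing the global minimum is the
sentinel.  Disease instruments come from standard greedy p-value clumping
(r² > 0.001 within a 10 kb window by default).

Instrument strength uses the conventional summary-data formulas

    R² = 2b²·EAF·(1−EAF) / (2b²·EAF·(1−EAF) + SE²·2N·EAF·(1−EAF))
    F  = R²·(N − 1 − k) / ((1 − R²)·k)

with F > 10 the usual bar for a strong instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .sumstats import (
    AssociationRecord,
    GeneAnnotation,
    LDMatrix,
    SummaryStatSet,
)


class LookupError_(Exception):
    """A gene or variant required for selection is missing."""


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    Defaults follow the screen's study conditions: a deCODE-style exposure
    threshold, genome-wide significance for disease instruments with a
    relaxed preset, plink-style clumping parameters, and r² >= 0.8 region
    merging.  ``region_flank_bp`` is the per-SNP flank used when testing
    region overlap (half of the nominal 1 Mb region width).
    """

    cis_window_bp: int = 1_000_000
    pthreshold_exposure: float = 1.8e-9
    pthreshold_outcome: float = 5e-8
    pthreshold_outcome_relaxed: float = 5e-7
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000
    merge_r2: float = 0.8
    region_flank_bp: int = 500_000
    mhc_interval: tuple[str, int, int] | None = None

    #: preset exposure thresholds per platform
    EXPOSURE_PRESETS = {"decode": 1.8e-9, "ukb_ppp": 1.7e-11}

    def __post_init__(self) -> None:
        for name in ("pthreshold_exposure", "pthreshold_outcome", "pthreshold_outcome_relaxed"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.clump_r2 <= 1 or not 0 < self.merge_r2 <= 1:
            raise ValueError("r2 thresholds must lie in [0, 1]")
        if self.cis_window_bp <= 0 or self.clump_window_bp <= 0 or self.region_flank_bp <= 0:
            raise ValueError("window sizes must be > 0")


@dataclass
class Instrument:
    """Sentinel SNP(s) proxying an exposure, with strength metrics."""

    exposure_id: str
    snps: list[AssociationRecord]
    r2_per_snp: list[float]
    r2_total: float
    f_stat: float
    is_cis: bool
    region: tuple[str, int, int] | None = None  # chrom, start, end (closed)

    @property
    def sentinel(self) -> AssociationRecord:
        return self.snps[0]

    @property
    def n_snp(self) -> int:
        return len(self.snps)


def compute_r2(beta: float, eaf: float, se: float, n: float) -> float:
    """Variance in the exposure explained by one SNP, from summary data."""
    num = 2.0 * beta * beta * eaf * (1.0 - eaf)
    den = num + se * se * 2.0 * n * eaf * (1.0 - eaf)
    if den == 0.0:
        return 0.0
    return num / den


def compute_f_stat(r2: float, n: float, k: int = 1) -> float:
    """Instrument F-statistic from total variance explained, N and SNP count."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return r2 * (n - 1 - k) / ((1.0 - r2) * k)


def record_r2(rec: AssociationRecord) -> float:
    return compute_r2(rec.beta, rec.eaf, rec.se, rec.n)


def _sorted_by_p(records: list[AssociationRecord]) -> list[AssociationRecord]:
    # ties on p broken by lower genomic position, then rsid, for determinism
    return sorted(records, key=lambda r: (r.pval, r.variant.pos, r.rsid))


def _pair_r2(ld: LDMatrix, a: str, b: str) -> float:
    r2 = ld.r2_between(a, b)
    if r2 is None:
        warnings.warn(
            f"LD unavailable for pair ({a}, {b}); treating r2 as 0", stacklevel=3
        )
        return 0.0
    return r2


def _in_mhc(rec: AssociationRecord, mhc: tuple[str, int, int] | None) -> bool:
    if mhc is None:
        return False
    chrom, start, end = mhc
    return rec.variant.chrom == chrom and start <= rec.variant.pos <= end


def select_cis_instrument(
    protein_sumstats: SummaryStatSet,
    gene: GeneAnnotation,
    ld: LDMatrix | None,
    cfg: SelectionConfig | None = None,
) -> Instrument | None:
    """Select the sentinel cis-SNP instrumenting a protein, or None.

    Candidates are SNPs with p below the exposure threshold within
    ``cis_window_bp`` of the TSS (closed interval, same chromosome).  Regions
    of ``±region_flank_bp`` around candidates are merged iteratively starting
    from the lowest-p SNP; SNP pairs with r² >= ``merge_r2`` merge regardless
    of distance; an MHC interval, if configured, acts as one region.  The
    sentinel is the lowest-p SNP of the region containing the global
    lowest-p candidate.
    """
    cfg = cfg or SelectionConfig()
    candidates = [
        rec for rec in protein_sumstats
        if rec.pval < cfg.pthreshold_exposure
        and rec.variant.chrom == gene.chrom
        and abs(rec.variant.pos - gene.tss) <= cfg.cis_window_bp
    ]
    if not candidates:
        return None
    ordered = _sorted_by_p(candidates)

    # regions as (interval_start, interval_end, members); built lowest-p first
    regions: list[dict] = []
    for rec in ordered:
        lo = max(1, rec.variant.pos - cfg.region_flank_bp)
        hi = rec.variant.pos + cfg.region_flank_bp
        if _in_mhc(rec, cfg.mhc_interval):
            lo = min(lo, cfg.mhc_interval[1])
            hi = max(hi, cfg.mhc_interval[2])
        merged_into = None
        for reg in regions:
            overlap = not (hi < reg["lo"] or lo > reg["hi"])
            high_ld = ld is not None and any(
                _pair_r2(ld, rec.rsid, m.rsid) >= cfg.merge_r2 for m in reg["members"]
            )
            if overlap or high_ld:
                if merged_into is None:
                    reg["lo"] = min(reg["lo"], lo)
                    reg["hi"] = max(reg["hi"], hi)
                    reg["members"].append(rec)
                    merged_into = reg
                else:
                    # this SNP bridges two regions: merge them
                    merged_into["lo"] = min(merged_into["lo"], reg["lo"])
                    merged_into["hi"] = max(merged_into["hi"], reg["hi"])
                    merged_into["members"].extend(reg["members"])
                    reg["members"] = []
        regions = [r for r in regions if r["members"]]
        if merged_into is None:
            regions.append({"lo": lo, "hi": hi, "members": [rec]})

    top = ordered[0]
    home = next(reg for reg in regions if top in reg["members"])
    sentinel = _sorted_by_p(home["members"])[0]
    r2 = record_r2(sentinel)
    f = compute_f_stat(r2, sentinel.n, 1)
    return Instrument(
        exposure_id=protein_sumstats.trait_id,
        snps=[sentinel],
        r2_per_snp=[r2],
        r2_total=r2,
        f_stat=f,
        is_cis=True,
        region=(gene.chrom, int(home["lo"]), int(home["hi"])),
    )


def clump(
    sumstats: SummaryStatSet,
    ld: LDMatrix | None,
    cfg: SelectionConfig | None = None,
    pthreshold: float | None = None,
) -> list[AssociationRecord]:
    """Greedy p-value clumping of disease instruments.

    Repeatedly retain the lowest-p SNP passing ``pthreshold`` (default
    ``cfg.pthreshold_outcome``) and discard SNPs on the same chromosome with
    r² > ``clump_r2`` within ``clump_window_bp`` of it.  The result is
    independent of input row order.
    """
    cfg = cfg or SelectionConfig()
    thresh = cfg.pthreshold_outcome if pthreshold is None else pthreshold
    pool = _sorted_by_p([rec for rec in sumstats if rec.pval < thresh])
    kept: list[AssociationRecord] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        survivors = []
        for rec in pool:
            same_chrom = rec.variant.chrom == index.variant.chrom
            near = same_chrom and abs(rec.variant.pos - index.variant.pos) <= cfg.clump_window_bp
            if near and ld is not None and _pair_r2(ld, index.rsid, rec.rsid) > cfg.clump_r2:
                continue
            survivors.append(rec)
        pool = survivors
    return kept


def instrument_from_snps(
    exposure_id: str, snps: list[AssociationRecord], is_cis: bool = False
) -> Instrument:
    """Bundle pre-selected SNPs into an Instrument with joint strength metrics."""
    if not snps:
        raise ValueError("need at least one SNP")
    r2s = [record_r2(s) for s in snps]
    r2_total = min(sum(r2s), 1.0 - 1e-12)
    n = min(s.n for s in snps)
    f = compute_f_stat(r2_total, n, len(snps))
    return Instrument(exposure_id, list(snps), r2s, r2_total, f, is_cis)
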