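"""Synthetic GWAS summary statistics with known causal architecture.

The generator emulates the statistical structure the screen assumes: a cis
region of LD-correlated SNPs, an additive pQTL effect on a standardised
plasma protein, a low-prevalence binary disease arising from a liability
threshold, two independent protein "platforms" (independent cohorts), and
two independent disease cohorts for meta-analysis.  Five scenario types
cover the causal configurations the decision engine must distinguish:
``shared_causal``, ``distinct_causal``, ``pleiotropy``,
``reverse_causation`` and ``null``.

Haplotypes come from a latent Gaussian AR(1) process thresholded at
MAF-matching quantiles.  Thresholding attenuates correlation, so the latent
per-step correlation is calibrated per adjacent pair by inverting the
tetrachoric relation (bivariate-normal orthant probability via Owen's T):
the realised 0/1-scale adjacent-SNP correlation then concentrates near the
requested ``ld_rho``, capped at the maximum attainable for the pair's
allele frequencies.

The liability gets a standard-logistic error term, so the protein's causal
effect ``gamma`` is exactly the conditional log-odds effect that a
logistic-regression GWAS estimates — the Wald ratio then recovers ``gamma``
on its own scale.  The threshold is solved per cohort so the marginal
prevalence matches ``prevalence_k``.

Per-SNP association statistics are computed by closed-form simple linear
regression (quantitative traits) and a vectorised Newton–Raphson logistic
regression fitting every SNP jointly (binary traits); the logistic fit is
cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .sumstats import (
    AssociationRecord,
    GeneAnnotation,
    LDMatrix,
    SummaryStatSet,
    VariantKey,
    ld_from_haplotypes,
)

SCENARIOS = ("shared_causal", "distinct_causal", "pleiotropy", "reverse_causation", "null")

#: default per-scenario parameters (a: SNP->protein SD effect; gamma:
#: protein->liability log-odds effect; delta: direct SNP->liability effect;
#: K: disease prevalence).  Chosen once to give desk-scale cohorts (n=20,000)
#: realistic pQTL strength and detectable case counts; see docs/methods.md.
SCENARIO_DEFAULTS: dict[str, dict[str, float]] = {
    "shared_causal": {"a": 0.3, "gamma": 0.3, "delta": 0.0, "prevalence_k": 0.01},
    "distinct_causal": {"a": 0.5, "gamma": 0.0, "delta": 0.5, "prevalence_k": 0.05},
    "pleiotropy": {"a": 0.3, "gamma": 0.3, "delta": 0.15, "prevalence_k": 0.01},
    "reverse_causation": {"a": 0.6, "gamma": 0.3, "delta": 0.0, "prevalence_k": 0.02},
    "null": {"a": 0.0, "gamma": 0.0, "delta": 0.0, "prevalence_k": 0.01},
}

_ALLELES = ("A", "G")  # non-palindromic pair used for all simulated SNPs


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of one simulated scenario."""

    scenario: str = "shared_causal"
    causal_snp_idx: int | None = None    # default: region centre
    distinct_snp_idx: int | None = None  # disease causal SNP in distinct_causal
    a: float = 0.3
    gamma: float = 0.3
    delta: float = 0.0
    prevalence_k: float = 0.01
    n_protein: int = 20_000
    n_disease_1: int = 20_000
    n_disease_2: int = 20_000
    ld_rho: float = 0.8
    m_snps: int = 21
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_ref: int = 10_000
    spacing_bp: int = 5_000
    chrom: str = "1"
    region_start: int = 1_000_000
    gene_symbol: str = "GENE1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.causal_snp_idx is None:
            # distinct_causal separates the two causal SNPs for low LD
            self.causal_snp_idx = min(3, self.m_snps - 1) \
                if self.scenario == "distinct_causal" else self.m_snps // 2
        if self.distinct_snp_idx is None:
            self.distinct_snp_idx = max(self.causal_snp_idx + 1,
                                        min(self.m_snps - 4, self.m_snps - 1))
        if not 0 <= self.causal_snp_idx < self.m_snps:
            raise ValueError("causal_snp_idx out of range")
        if not 0 <= self.distinct_snp_idx < self.m_snps:
            raise ValueError("distinct_snp_idx out of range")
        if min(self.n_protein, self.n_disease_1, self.n_disease_2) <= 0:
            raise ValueError("cohort sizes must be > 0")
        if not 0 < self.prevalence_k < 0.5:
            raise ValueError("prevalence_k must be in (0, 0.5)")

    @classmethod
    def for_scenario(cls, scenario: str, seed: int = 0, **overrides) -> "SyntheticTruth":
        """Truth with the documented default parameters of a scenario."""
        params = dict(SCENARIO_DEFAULTS[scenario])
        params.update(overrides)
        return cls(scenario=scenario, seed=seed, **params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)


@dataclass
class ScenarioBundle:
    """Everything one scenario produces: sumstats, LD, annotation, truth."""

    protein_sets: dict[str, SummaryStatSet]
    disease_sets: dict[str, SummaryStatSet]
    ld: LDMatrix
    gene: GeneAnnotation
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# haplotypes and genotypes
# ---------------------------------------------------------------------------

def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Standard bivariate normal CDF P(X<h, Y<k; rho) via Owen's T."""
    from scipy.special import owens_t

    h = np.where(h == 0.0, 1e-12, np.asarray(h, dtype=float))
    k = np.where(k == 0.0, 1e-12, np.asarray(k, dtype=float))
    rho = np.clip(np.asarray(rho, dtype=float), -1 + 1e-12, 1 - 1e-12)
    denom = np.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * denom)
    a2 = (h - rho * k) / (k * denom)
    c = np.where(h * k > 0, 0.0, np.where(h + k >= 0, 0.0, 0.5))
    return (0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
            - owens_t(h, a1) - owens_t(k, a2) - c)


def _latent_rho_for(target_r: float, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Latent Gaussian correlation whose thresholded 0/1 correlation is
    ``target_r`` (tetrachoric inversion), capped at the margin-attainable
    maximum.  Vectorised bisection over SNP pairs."""
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    scale = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def binary_r(rho: np.ndarray) -> np.ndarray:
        return (_bvn_cdf(t1, t2, rho) - p1 * p2) / scale

    lo = np.zeros_like(t1)
    hi = np.full_like(t1, 1.0 - 1e-9)
    capped = binary_r(hi) <= target_r
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        too_low = binary_r(mid) < target_r
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return np.where(capped, 1.0 - 1e-9, 0.5 * (lo + hi))


def simulate_ld_panel(
    m_snps: int,
    rho: float,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    n_ref: int = 10_000,
    seed: int | np.random.Generator = 0,
    rsids: list[str] | None = None,
    positions: list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, LDMatrix]:
    """Simulate a 0/1 haplotype panel with AR(1)-decaying LD.

    Returns ``(panel, mafs, ld)`` where ``panel`` is n_ref x m_snps.  The
    latent Gaussian chain's per-step correlations are solved from the
    tetrachoric relation so the realised adjacent-SNP correlation of the
    thresholded haplotypes lands at ``rho`` (or at the maximum attainable
    for the pair's frequencies, whichever is smaller).
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # MAFs vary smoothly along the region (Gaussian-copula AR(1), uniform
    # marginals): tightly linked SNPs share genealogy, hence similar
    # frequencies — and r near rho is only attainable between binary
    # variables with similar margins
    lam = math.sin(math.pi * rho / 2.0)
    w = rng.standard_normal(m_snps)
    for j in range(1, m_snps):
        w[j] = lam * w[j - 1] + math.sqrt(1 - lam * lam) * w[j]
    mafs = maf_low + (maf_high - maf_low) * stats.norm.cdf(w)
    z = rng.standard_normal((n_ref, m_snps))
    if m_snps > 1 and rho > 0:
        rho_latent = _latent_rho_for(rho, mafs[:-1], mafs[1:])
        for j in range(1, m_snps):
            rl = rho_latent[j - 1]
            z[:, j] = rl * z[:, j - 1] + math.sqrt(1 - rl * rl) * z[:, j]
    panel = (z < stats.norm.ppf(mafs)).astype(np.int8)
    if rsids is None:
        rsids = [f"rs{j + 1}" for j in range(m_snps)]
    if positions is None:
        positions = list(range(1, m_snps + 1))
    ld = ld_from_haplotypes(panel, rsids, positions)
    return panel, mafs, ld


def _draw_genotypes(panel: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Diploid dosages: sum of two haplotypes drawn with replacement."""
    idx = rng.integers(0, panel.shape[0], size=(2, n))
    return (panel[idx[0]] + panel[idx[1]]).astype(np.float64)


# ---------------------------------------------------------------------------
# per-SNP association scans
# ---------------------------------------------------------------------------

def linear_gwas(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form simple linear regression of y on each genotype column.

    Returns (beta, se, pval) arrays of length m.
    """
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = yc @ gc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
        t = beta / se
    pval = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return beta, se, np.maximum(pval, 5e-324)


def logistic_gwas(
    d: np.ndarray, g: np.ndarray, max_iter: int = 30, tol: float = 1e-10,
    block: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression (intercept + dosage), fitted jointly.

    A vectorised Newton–Raphson over all SNPs; returns (beta, se, pval) on
    the log-odds scale.
    """
    d = np.asarray(d, dtype=np.float64)
    n, m = g.shape
    beta = np.empty(m)
    se = np.empty(m)
    base = math.log(d.mean() / (1.0 - d.mean()))
    for lo in range(0, m, block):
        gb = g[:, lo:lo + block]
        mb = gb.shape[1]
        a = np.full(mb, base)
        b = np.zeros(mb)
        for _ in range(max_iter):
            eta = a[None, :] + gb * b[None, :]
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            resid = d[:, None] - p
            s0 = resid.sum(axis=0)
            s1 = np.einsum("ij,ij->j", gb, resid)
            h00 = w.sum(axis=0)
            h01 = np.einsum("ij,ij->j", gb, w)
            h11 = np.einsum("ij,ij,ij->j", gb, gb, w)
            det = h00 * h11 - h01 * h01
            da = (h11 * s0 - h01 * s1) / det
            db = (h00 * s1 - h01 * s0) / det
            a += da
            b += db
            if max(np.abs(da).max(initial=0.0), np.abs(db).max(initial=0.0)) < tol:
                break
        eta = a[None, :] + gb * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", gb, w)
        h11 = np.einsum("ij,ij,ij->j", gb, gb, w)
        det = h00 * h11 - h01 * h01
        beta[lo:lo + mb] = b
        se[lo:lo + mb] = np.sqrt(h00 / det)
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, np.maximum(pval, 5e-324)


def _solve_threshold(eta: np.ndarray, k: float) -> float:
    """Threshold c such that mean sigmoid(eta - c) equals the prevalence k."""

    def f(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(eta - c))))) - k

    lo, hi = float(eta.min()) - 40.0, float(eta.max()) + 40.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# scenario simulation
# ---------------------------------------------------------------------------

def _records_from_arrays(
    trait_id: str, trait_type: str, platform: str,
    rsids: list[str], chrom: str, positions: list[int],
    eaf: np.ndarray, beta: np.ndarray, se: np.ndarray, pval: np.ndarray,
    n: int, n_case: float | None = None,
) -> SummaryStatSet:
    sset = SummaryStatSet(trait_id, trait_type, platform, build="synthetic")
    for j, rs in enumerate(rsids):
        if not 0 < eaf[j] < 1 or not np.isfinite(se[j]) or se[j] <= 0:
            continue  # monomorphic or degenerate SNP
        v = VariantKey(rs, chrom, positions[j], _ALLELES[0], _ALLELES[1])
        kwargs = {}
        if n_case is not None:
            kwargs = {"n_case": float(n_case), "n_control": float(n - n_case)}
        sset.add(AssociationRecord(v, float(beta[j]), float(se[j]),
                                   float(pval[j]), float(eaf[j]), float(n), **kwargs))
    return sset


def _protein_signal(g: np.ndarray, truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    """Standardised protein X = a·g_causal + N(0,1), scaled to unit variance."""
    x = truth.a * g[:, truth.causal_snp_idx] + rng.standard_normal(g.shape[0])
    return x / x.std()


def _liability_and_disease(
    x: np.ndarray | None, g: np.ndarray, truth: SyntheticTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Disease indicator from a logistic-error liability threshold model."""
    eta = np.zeros(g.shape[0])
    if truth.scenario in ("shared_causal", "pleiotropy", "null"):
        eta = truth.gamma * x + truth.delta * g[:, truth.causal_snp_idx]
    elif truth.scenario == "distinct_causal":
        eta = truth.delta * g[:, truth.distinct_snp_idx]
    elif truth.scenario == "reverse_causation":
        eta = truth.a * g[:, truth.causal_snp_idx]
    c = _solve_threshold(eta, truth.prevalence_k)
    p = 1.0 / (1.0 + np.exp(-(eta - c)))
    d = (rng.random(g.shape[0]) < p).astype(np.float64)
    expected_cases = truth.prevalence_k * g.shape[0]
    if expected_cases < 50:
        warnings.warn(
            f"expected case count {expected_cases:.0f} < 50; logistic estimates unstable",
            stacklevel=3,
        )
    return d


def simulate_scenario(truth: SyntheticTruth) -> ScenarioBundle:
    """Simulate one scenario bundle: two protein platforms, two disease
    cohorts, an LD matrix and a gene annotation.

    All randomness flows from ``truth.seed``; identical truth gives an
    identical bundle.
    """
    rng = np.random.default_rng(truth.seed)
    positions = [truth.region_start + j * truth.spacing_bp for j in range(truth.m_snps)]
    rsids = [f"rs{j + 1}" for j in range(truth.m_snps)]
    panel, _, ld = simulate_ld_panel(
        truth.m_snps, truth.ld_rho, truth.maf_low, truth.maf_high,
        truth.n_ref, rng, rsids=rsids, positions=positions,
    )
    tss = positions[truth.m_snps // 2]
    gene = GeneAnnotation(truth.gene_symbol, truth.chrom, tss)

    protein_sets: dict[str, SummaryStatSet] = {}
    for platform, n in (("platform_a", truth.n_protein), ("platform_b", truth.n_protein)):
        g = _draw_genotypes(panel, n, rng)
        if truth.scenario == "reverse_causation":
            # protein is downstream of disease liability
            u = rng.logistic(size=n)
            liab = truth.a * g[:, truth.causal_snp_idx] + u
            x = truth.gamma * liab + rng.standard_normal(n)
            x = (x - x.mean()) / x.std()
        else:
            x = _protein_signal(g, truth, rng)
        beta, se, pval = linear_gwas(x, g)
        protein_sets[platform] = _records_from_arrays(
            f"{truth.gene_symbol}:{platform}", "quantitative", platform,
            rsids, truth.chrom, positions, g.mean(axis=0) / 2.0, beta, se, pval, n,
        )

    disease_sets: dict[str, SummaryStatSet] = {}
    for cohort, n in (("cohort1", truth.n_disease_1), ("cohort2", truth.n_disease_2)):
        g = _draw_genotypes(panel, n, rng)
        if truth.scenario == "reverse_causation":
            x = None
        else:
            x = _protein_signal(g, truth, rng)
        d = _liability_and_disease(x, g, truth, rng)
        beta, se, pval = logistic_gwas(d, g)
        disease_sets[cohort] = _records_from_arrays(
            f"disease:{cohort}", "binary", cohort,
            rsids, truth.chrom, positions, g.mean(axis=0) / 2.0, beta, se, pval,
            n, n_case=float(d.sum()),
        )
    return ScenarioBundle(protein_sets, disease_sets, ld, gene, truth)


def make_test_suite(seed: int = 0, **overrides) -> dict[str, ScenarioBundle]:
    """One bundle per scenario type at the documented default parameters."""
    return {
        sc: simulate_scenario(SyntheticTruth.for_scenario(sc, seed=seed + i, **overrides))
        for i, sc in enumerate(SCENARIOS)
    }


def coloc_calibration_truth(kind: str, seed: int = 0) -> SyntheticTruth:
    """Scenario presets for colocalization calibration.

    Signals are made strong (per-trait sentinel |z| well above 6) so that
    the posterior reflects the region's causal configuration rather than
    GWAS power: a larger pQTL effect, a larger protein->disease effect and
    a commoner disease than the estimation presets.
    """
    if kind == "shared":
        return SyntheticTruth.for_scenario(
            "shared_causal", seed=seed, a=0.5, gamma=1.0, prevalence_k=0.05,
        )
    if kind == "distinct":
        return SyntheticTruth.for_scenario("distinct_causal", seed=seed)
    raise ValueError("kind must be shared|distinct")


# ---------------------------------------------------------------------------
# multi-protein screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Ground truth for a multi-protein screen simulation."""

    n_proteins: int = 20
    causal_idx: tuple[int, ...] = (0, 1)   # indices of causal proteins
    a: float = 0.4
    gamma: float = 1.0
    n_disease_loci: int = 2
    delta: float = 0.45
    prevalence_k: float = 0.02
    n_protein: int = 20_000
    n_disease_1: int = 20_000
    n_disease_2: int = 20_000
    ld_rho: float = 0.8
    m_snps: int = 21
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_ref: int = 10_000
    spacing_bp: int = 5_000
    seed: int = 0

    @property
    def protein_ids(self) -> list[str]:
        return [f"G{k + 1:02d}" for k in range(self.n_proteins)]

    @property
    def causal_proteins(self) -> list[str]:
        return [self.protein_ids[k] for k in self.causal_idx]

    @property
    def locus_ids(self) -> list[str]:
        return [f"L{k + 1:02d}" for k in range(self.n_disease_loci)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScreenBundle:
    """A full synthetic screen: per-protein sumstats on two platforms,
    two disease cohorts covering every region, LD per region, annotations."""

    protein_sets: dict[str, dict[str, SummaryStatSet]]  # platform -> protein -> set
    disease_sets: dict[str, SummaryStatSet]
    ld: dict[str, LDMatrix]            # region id (gene or locus) -> LD
    genes: dict[str, GeneAnnotation]
    truth: ScreenTruth


def simulate_screen(truth: ScreenTruth | None = None) -> ScreenBundle:
    """Simulate a joint multi-protein screen with planted causal proteins.

    Each protein has its own cis region on its own chromosome; the disease
    additionally has ``n_disease_loci`` direct-effect loci (no protein),
    mirroring genome-wide disease hits outside any cis region.  Disease
    liability is gamma * sum of causal proteins + delta * direct-locus
    dosages + logistic noise.  Protein sumstats cover the protein's cis
    region plus the disease loci (so reverse MR has outcome records at the
    disease instruments); disease sumstats cover every region.
    """
    truth = truth or ScreenTruth()
    rng = np.random.default_rng(truth.seed)
    m = truth.m_snps
    cidx = m // 2  # causal SNP at the region centre

    region_ids = truth.protein_ids + truth.locus_ids
    panels: dict[str, np.ndarray] = {}
    lds: dict[str, LDMatrix] = {}
    genes: dict[str, GeneAnnotation] = {}
    positions = [1_000_000 + j * truth.spacing_bp for j in range(m)]
    rsids_by_region = {}
    for i, rid in enumerate(region_ids):
        chrom = str(i + 1)
        rsids = [f"rs{i + 1}_{j + 1}" for j in range(m)]
        rsids_by_region[rid] = (chrom, rsids)
        panel, _, ld = simulate_ld_panel(
            m, truth.ld_rho, truth.maf_low, truth.maf_high, truth.n_ref, rng,
            rsids=rsids, positions=positions,
        )
        panels[rid] = panel
        lds[rid] = ld
        if rid in truth.protein_ids:
            genes[rid] = GeneAnnotation(rid, chrom, positions[cidx])

    causal_set = set(truth.causal_proteins)

    def protein_value(g_region: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = truth.a * g_region[:, cidx] + rng.standard_normal(g_region.shape[0])
        return x / x.std()

    # protein platform cohorts: per-protein GWAS over cis region + disease loci
    protein_sets: dict[str, dict[str, SummaryStatSet]] = {}
    for platform in ("platform_a", "platform_b"):
        n = truth.n_protein
        g_loci = {lid: _draw_genotypes(panels[lid], n, rng) for lid in truth.locus_ids}
        per_protein: dict[str, SummaryStatSet] = {}
        for pid in truth.protein_ids:
            g = _draw_genotypes(panels[pid], n, rng)
            x = protein_value(g, rng)
            chrom, rsids = rsids_by_region[pid]
            beta, se, pval = linear_gwas(x, g)
            sset = _records_from_arrays(
                f"{pid}:{platform}", "quantitative", platform,
                rsids, chrom, positions, g.mean(axis=0) / 2.0, beta, se, pval, n,
            )
            for lid in truth.locus_ids:
                lchrom, lrsids = rsids_by_region[lid]
                lb, ls, lp = linear_gwas(x, g_loci[lid])
                for rec in _records_from_arrays(
                    f"{pid}:{platform}", "quantitative", platform,
                    lrsids, lchrom, positions, g_loci[lid].mean(axis=0) / 2.0,
                    lb, ls, lp, n,
                ):
                    sset.add(rec)
            per_protein[pid] = sset
        protein_sets[platform] = per_protein

    # disease cohorts: genotypes at every region, liability over causal
    # proteins and direct loci, logistic GWAS genome-wide
    disease_sets: dict[str, SummaryStatSet] = {}
    for cohort, n in (("cohort1", truth.n_disease_1), ("cohort2", truth.n_disease_2)):
        g_all = {rid: _draw_genotypes(panels[rid], n, rng) for rid in region_ids}
        eta = np.zeros(n)
        for pid in truth.protein_ids:
            x = protein_value(g_all[pid], rng)
            if pid in causal_set:
                eta += truth.gamma * x
        for lid in truth.locus_ids:
            eta += truth.delta * g_all[lid][:, cidx]
        c = _solve_threshold(eta, truth.prevalence_k)
        p = 1.0 / (1.0 + np.exp(-(eta - c)))
        d = (rng.random(n) < p).astype(np.float64)
        sset = SummaryStatSet(f"disease:{cohort}", "binary", cohort, build="synthetic")
        for rid in region_ids:
            chrom, rsids = rsids_by_region[rid]
            beta, se, pval = logistic_gwas(d, g_all[rid])
            for rec in _records_from_arrays(
                f"disease:{cohort}", "binary", cohort,
                rsids, chrom, positions, g_all[rid].mean(axis=0) / 2.0,
                beta, se, pval, n, n_case=float(d.sum()),
            ):
                sset.add(rec)
        disease_sets[cohort] = sset

    return ScreenBundle(protein_sets, disease_sets, lds, genes, truth)
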