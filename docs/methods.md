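# Methods

This note records the statistical model behind `protscreen`, the design
choices made where the problem was genuinely open, and what the synthetic
data generator does and does not emulate.

## Model and estimators

**Forward MR.** Each protein is instrumented by a single sentinel cis-SNP.
With summary associations (β_gx, se_x) on the standardized protein and
(β_gy, se_y) on disease log-odds, the Wald ratio β̂ = β_gy/β_gx estimates
the log-odds effect of one SD of protein on disease. The SE uses the
first-order delta method, se_y/|β_gx|; the second-order term is omitted
because instruments in this setting are very strong (median F in the
hundreds), making the correction negligible relative to se_y. 95% CIs use
the multiplier 1.959964 throughout.

**Reverse MR.** Disease instruments come from greedy clumping (p < 5e-8,
falling back to 5e-7 when nothing reaches genome-wide significance; the
relaxed origin is carried on the result as a caveat flag). One instrument
uses the Wald ratio; two or more use IVW through the origin with weights
1/se_y² and a multiplicative random-effects SE inflation φ = max(1,
√(Q/(k−1))). The floor φ ≥ 1 is the standard convention: heterogeneity can
only widen, never tighten, the interval.

Reverse instruments are Steiger-filtered by default: an instrument that
explains more variance in the tested protein than in the disease
(liability scale) is the protein's own cis variant acting in the forward
direction, not a disease instrument — without this filter every truly
causal protein would veto itself, because its cis-SNP is necessarily a
genome-wide disease hit. The filter can be disabled
(`steiger_filter=False` / `PipelineConfig.reverse_steiger_filter`).

**Meta-analysis.** The two disease GWAS are pooled per variant by
SE-weighted fixed-effect meta-analysis (the METAL "STDERR" scheme), chosen
over sample-size z-weighting because the pooled β/SE feed directly into MR
as outcome associations. Genomic control is applied per study before
pooling: λ = median((β/se)²)/0.4549, SEs inflated by √λ only when λ > 1,
and λ forced to 1 (with a warning) below 100 variants where the median is
unstable. Variants present in a single study are dropped — heterogeneity
is undefined for them — and variants with heterogeneity p ≤ 0.05
(inclusive) are removed.

**Steiger directionality.** Per-SNP variance explained is computed from
summary data as R² = 2b²·EAF(1−EAF)/(2b²·EAF(1−EAF) + SE²·2N·EAF(1−EAF))
and summed over instrument SNPs on each side. For binary outcomes the
observed-scale value is mapped to the liability scale by
r²_liab = r²_obs·K²(1−K)²/(z²·P(1−P)), with K the population prevalence, P
the sample case fraction and z the standard normal density at Φ⁻¹(1−K) —
the standard threshold-model transformation, verified here against direct
simulation of a probit liability model (it is first-order accurate and
drifts for latent r² above ~5%). The test p-value compares
Fisher-transformed √R² at the two sample sizes; ties resolve to
direction_true = False, and single-SNP results carry a `single_snp` flag
because one variant cannot distinguish causal from pleiotropic models —
the decision rule therefore uses Steiger only jointly with bidirectional
consistency. Prevalences for a meta-analysed outcome are pooled on the
logit scale weighted by study sample size (defaults 1.4e-5 and 1.1e-5,
the UK and Finland figures).

**Colocalization.** Wakefield log approximate Bayes factors,
lABF = ½[ln(V/(V+W)) + z²W/(V+W)], with prior effect SD 0.15 for
quantitative and 0.2 for binary traits, the conventional defaults of the
ABF colocalization framework. Posteriors over
H0–H4 are accumulated entirely in log space (log-sum-exp), so |z| of
several hundred cannot overflow; the H3 term uses
log(S1·S2 − S12) = logS1+logS2 + log1p(−exp(logS12−logS1−logS2)). Window
widths are read as total spans centred on the sentinel (±width/2); a
flank mode is available because "window around" is ambiguous. Windows with
no shared variants are reported empty rather than failing, and a
consistency flag records whether all non-empty windows agree on the top
hypothesis.

**Decision rule.** Tier assignment is a pure function of the four criteria
booleans and the h4 flag, tested exhaustively: all four true and
max h4 > 0.8 → colocalized_candidate; all four true → consistent_candidate;
direction discordant → inconsistent; otherwise suggestive; a protein
missing either platform's forward result → not_shared. No multiple-testing
correction enters the rule (a Bonferroni column is emitted for information
only). Criterion (4), "no evidence of a reverse effect", is operationalised
as every available reverse 95% CI overlapping zero.

## Numerical and I/O choices

- Coordinates are 1-based with fully closed intervals everywhere (a SNP
  exactly 1 Mb from the TSS is cis).
- Alleles are restricted to single-nucleotide A/C/G/T; indels are dropped
  by validation. Validation is total: every input row is either kept,
  satisfying all invariants, or counted in a drop report.
- Ties on p-value (sentinel choice, clump ordering) break to the lower
  genomic position, then rsID, for determinism.
- A missing LD entry during clumping is treated as r² = 0 with a warning —
  permissive, so instruments are not silently discarded.
- Region merging runs per chromosome; the MHC can be supplied as a single
  merge interval (no default coordinates are assumed).
- Palindrome handling applies uniformly to proxies and direct matches: any
  alignment requiring frequency inference with MAF ≥ 0.3 on either side is
  dropped as ambiguous.
- Sumstats TSVs are written with shortest-round-trip float formatting, so
  write→read→write is byte-identical; reports are timestamp-free and
  deterministically ordered for the same reason.

## The synthetic generator

`simulate_scenario` builds one cis region: a 0/1 haplotype panel from a
latent Gaussian AR(1) process thresholded at MAF quantiles; diploid
genotypes as sums of two panel haplotypes; a standardized protein
X = a·g + ε; and disease from a liability threshold with **standard
logistic noise**, L = γX + δg + ε_L, D = 1{L > c}, with c solved so the
marginal prevalence equals K. Two design points matter:

1. **Logistic, not Gaussian, liability noise.** With logistic noise γ *is*
   the conditional log-odds effect per SD of protein, which is the scale a
   logistic-regression GWAS estimates and the Wald ratio recovers. With
   Gaussian noise the rare-disease marginal log-OR is the probit effect
   times the inverse-Mills factor (~2.7 at K = 0.01), and no estimator on
   the log-odds scale could recover γ as specified. The remaining
   marginal-vs-conditional attenuation is ≈ 1/√(1+0.346·γ²σ²_resid): about
   1.5% at the estimation preset γ = 0.3, visible (~13%) only at the
   deliberately strong coloc preset γ = 1.
2. **LD calibration.** Thresholding attenuates latent correlation, and two
   binary variants can only reach r near 1 when their frequencies match.
   The generator therefore (a) gives the MAF sequence AR(1) Gaussian-copula
   correlation along the region — mirroring the fact that tightly linked
   real SNPs share genealogy and hence similar frequencies — and (b) solves
   the tetrachoric equation (bivariate-normal CDF via Owen's T, vectorised
   bisection) for each adjacent pair's latent correlation so the realised
   adjacent haplotype r lands on the requested ld_rho, capped at the
   margin-attainable maximum.

Per-SNP GWAS are closed-form simple linear regression (protein) and a
vectorised Newton–Raphson logistic regression fitting all SNPs jointly
(disease), cross-checked against statsmodels; the vectorisation is what
makes 500-replicate studies take ~a minute.

Scenario presets (chosen once as the study conditions; all cohorts
n = 20,000, m = 21 SNPs at 5 kb spacing, ld_rho = 0.8, MAF ~ U(0.1, 0.5)):

| scenario          | a    | γ   | δ    | K    | purpose |
|-------------------|------|-----|------|------|---------|
| shared_causal     | 0.3  | 0.3 | 0    | 0.01 | estimator recovery/coverage |
| pleiotropy        | 0.3  | 0.3 | 0.15 | 0.01 | documents Wald bias ≈ δ/a |
| distinct_causal   | 0.5  | 0   | 0.5  | 0.05 | coloc H3; causal SNPs at r² ≈ 0.1 |
| reverse_causation | 0.6* | 0.3†| 0    | 0.02 | Steiger flags wrong direction |
| null              | 0    | 0   | 0    | 0.01 | type-I calibration |

\* SNP→liability log-odds; † liability→protein coupling. The reverse preset
uses K = 0.02 and a large SNP effect so the disease hit clears the relaxed
instrument threshold and case counts stay stable at n = 20,000.
`coloc_calibration_truth` strengthens the shared preset (a = 0.5, γ = 1,
K = 0.05) so sentinel |z| ≥ 6 on both traits and the posterior reflects the
causal configuration rather than GWAS power. K defaults to 0.01 for
testing — rare enough to exercise the liability machinery while keeping a
few hundred cases; a K = 1e-4 stress value mirrors the real disease's
rarity but needs biobank-scale n to be estimable.

The 20-protein screen (`simulate_screen`) places each protein's cis region
on its own chromosome, adds two direct-effect disease loci outside any cis
region (the genome-wide disease hits that reverse MR instruments), and
generates disease liability jointly from the causal proteins (γ = 1,
a = 0.4, δ = 0.45, K = 0.02). Protein sumstats cover the cis region plus
the disease loci so reverse MR has outcome records where it needs them.

**What the generator does not emulate:** genome-wide polygenic background,
imputation noise, sample overlap between exposure and outcome GWAS,
ancestry structure, assay-specific measurement artefacts (aptamer
cross-reactivity, binding-site variants), case misclassification, and
MGUS-style precursor states. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under its own assumptions,
not that those assumptions hold in any particular real cohort.

## Operating characteristics and problem sizes

The simulation studies use 500 replicates for estimator recovery and null
calibration, 200 each for coloc and reverse-direction Steiger, and three
20-protein screens — sizes at which Monte-Carlo error is well below every
acceptance band and the whole suite runs in minutes on one CPU.

Two finite-sample behaviours are documented rather than hidden. Logistic
Wald tests are *conservative* below ~200 cases, so the generator's p-value
uniformity is checked in a configuration with a few hundred cases; at the
rare-disease presets the conservatism only lowers false-positive rates.
And the reverse-MR veto in the decision rule is a nominal 5%-level test
applied to genuinely null instrument–protein pairs, so each true candidate
survives it with probability ≈ 0.95 per reverse analysis; end-to-end
recovery is asserted against that designed survival rate (within two
binomial SDs across screens), with any loss of a planted causal protein
required to be attributable to the reverse veto alone.

## Known limitations

- Single-causal-variant colocalization only; no SuSiE-style multi-signal
  decomposition and no LD-aware fine-mapping.
- No MR-Egger / weighted-median / mode estimators: with a single cis-SNP
  per protein there is nothing for them to work with.
- rsID-based variant matching (position+allele matching exists behind a
  flag); no liftover between genome builds — build is opaque metadata and
  the caller must keep it consistent.
- The liability transformation is first-order and drifts for latent
  r² ≳ 5%.
- Weighted prevalence uses fixed-effect logit pooling with sample-size
  weights; other weightings are the caller's choice.
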