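# Methods

`mregulome` re-implements, as a tested library, an integrative workflow for
connecting GWAS risk loci to the regulatory genome of myeloid cells
(monocytes, macrophages, microglia): classify histone-mark peaks into
chromatin states, call risk enhancers, map them to target genes through
promoter-capture Hi-C gated on eQTL evidence, test the causal chain
chromatin activity → gene expression → disease risk with summary-data
Mendelian randomization (SMR), quantify heritability enrichment of
annotations, fine-map loci with annotation-informed priors, and score
variant effects on transcription-factor binding and allele-specific read
counts. Everything runs on synthetic loci with known ground truth, generated
by the package itself.

## The synthetic-data model

All association data are generated at the summary-statistic level (the
standard RSS model). For a locus with LD matrix `R` and a single causal
variant `c` with per-SD effect `b` in a study of `n` individuals,

    z = sqrt(n) · b · R[:, c] + ε,   ε ~ MVN(0, R),

with `beta = z/sqrt(n)` and `se = 1/sqrt(n)`. The causal chain composes
multiplicatively: the chromatin dataset sees `b_vh`, the expression dataset
`b_vh·b_he`, and the disease GWAS `b_vh·b_he·b_ed`. Defaults are
`b_vh = b_he = b_ed = 0.3` per SD with sample sizes 10k (hQTL), 10k (eQTL)
and 50k (GWAS) — effect sizes chosen for test power at desk scale, not as a
biological calibration; real hQTL effect-size distributions are not well
characterized.

Genotype panels are diploid dosages built from latent AR(1) Gaussian
haplotypes thresholded at the `1−maf` quantile (default MAF 0.3). Because
thresholding attenuates correlation, the latent AR(1) parameter is
tetrachorically calibrated (bisection on the bivariate-normal orthant mass)
so the empirical adjacent dosage `r` matches the configured `ld_rho`
(default 0.8) to within sampling error. `simulate_block_panel` concatenates
several independent AR(1) blocks of different strength to create LD-score
variation (needed by the heritability regression; see below).

The regulatory landscape plants one enhancer (distal H3K4me1 ∩ H3K27ac
interval containing the causal variant), one promoter at the target gene's
TSS, one Hi-C interaction linking them, decoy peaks far from the causal
variant, a consensus-embedded transcription-factor motif with the causal
allele at a chosen motif position (default 7 of a CTCF-like site), and
per-individual allele counts (total ~ truncated Poisson(depth), alt ~
Binomial(total, ase_prob), default ase_prob 0.7).

What the generator does *not* emulate: realistic allele-frequency spectra,
population structure, genotyping error, multi-causal architecture per
dataset, trans effects, overdispersed read counts, or empirical human LD
(AR(1) blocks are far more regular). Passing tests therefore demonstrate
correctness of the statistical machinery under a known model, not robustness
to every property of real data.

## Chromatin states

A peak is *proximal* iff it overlaps (≥ 1 bp) a strand-oriented window
[TSS−500, TSS+1000] around any TSS, mirrored on the minus strand; *active*
iff it overlaps any H3K27ac peak. Proximal H3K4me2/3 peaks are promoters
(AP with H3K27ac, else PP); distal H3K4me1/2 peaks are enhancers (AE with
H3K27ac, else PE). Proximal H3K4me1-only peaks cannot become promoters; they
are reported as PE with `proximal=True` so enhancer-flank analyses can
exclude them — this avoids misclassifying promoter-adjacent H3K4me1. Any
overlap with the TSS window counts as proximal, the simplest testable
reading. Each input peak yields exactly one element (states partition the
input); overlapping H3K4me1/me2 peaks are emitted per source mark.

## Risk enhancers and target genes

A risk enhancer is an AE whose interval, extended ±500 bp, contains ≥ 1 GWAS
variant with p ≤ 1e-6. A target-gene link requires the enhancer ±3000 bp to
overlap a promoter-capture Hi-C other-end whose bait gene has eQTL support:
at least one of the enhancer's own risk variants must be a significant eQTL
(BH q ≤ 0.05) for that gene in the same cell type — the literal "risk
variant is itself the eQTL" reading; LD-proxy expansion is deliberately not
the default. No interaction-score threshold is applied. Epigenome, Hi-C and
eQTL layers never mix across cell types.

## Colocalization

Wakefield approximate Bayes factors per variant:
`log ABF = ½·log(1−r) + z²r/2` with `r = W/(se²+W)`; prior effect SD 0.15
for quantitative traits, 0.2 (log-odds) for case-control — disease GWAS
default to case-control. Single-causal-per-trait posteriors over H0–H4 use
priors p1 = p2 = 1e-4, p12 = 1e-5, computed entirely in log space
(log-sum-exp; the H3 term uses `expm1` of the log-difference). Regions are
retained for downstream SMR when PP.H3 + PP.H4 ≥ 0.8 — evidence that the
QTL signal either shares or co-locates with the GWAS signal.

## SMR causal chain and conditional z-scores

For an instrument SNP, `T_SMR = z_zx²·z_zy²/(z_zx²+z_zy²)` with p from
χ²(1); `b_xy = b_zy/b_zx`. The instrument is the exposure's top cis variant
with p < 5e-8 (ties broken by position) unless a target SNP is named. The
chain runs stage 1 (chromatin → expression) over all peak–gene pairs
sharing a cis window, BH-corrects, then stage 2 (expression → disease) for
surviving genes, BH-corrects again; `--independent-stages` disables the
gating (the default gates, since stage 2 is motivated by stage-1 hits). The
HEIDI heterogeneity test is not computed and results carry an explicit
not-computed flag. `T_SMR` is exactly χ²(1) under the outcome null only in
the strong-instrument limit; at marginal instruments the test is mildly
conservative, so null-calibration checks are run in the strong-instrument
regime (|z_zx| ≈ 30).

Conditional z-scores use the standardized-genotype approximation
`z_{i|C} = (z_i − R_iC R_CC⁻¹ z_C)/sqrt(1 − R_iC R_CC⁻¹ R_Ci)` with a ridge
(1e-4) on `R_CC`; conditioning a variant on itself returns 0, and
collinearity (denominator ≤ 0) is an error rather than a silent NaN. This
replaces full joint conditional machinery (effective sample sizes,
allele-frequency adjustment), which the workflow only needs qualitatively.

## Partitioned heritability

Per-variant LD scores `ℓ(j,c) = Σ_{k∈c, |pos_k−pos_j| ≤ window} r²_jk`
(window 1 Mb, self term included) feed a single-pass weighted regression of
χ² on `{N·ℓ(j,c)}` with a free intercept and weights `1/max(1, ℓ_total)`.
There is no iterative weight refinement — a documented divergence from
reference implementations that matters at high non-centrality (see below).
`h²_c` sums member SNPs' total per-SNP heritability; enrichment is
`(h²_c/h²)/(M_c/M)`; a category covering every retained SNP has enrichment
exactly 1 by definition. Standard errors come from a 20-block
position-contiguous jackknife; confidence intervals on enrichment should
use the t(19) quantile, not the normal. Variants in the APOE
(chr19:45,000,000–45,800,000) and MHC (chr6:28,477,797–33,448,354) regions
are excluded before fitting. Negative enrichment estimates are reported,
never clamped.

Two structural cautions established while validating at desk scale:

- **Identifiability requires LD-score variation.** On a homogeneous AR(1)
  locus `ℓ_total` is nearly constant, making the all-SNPs column collinear
  with the free intercept; the fit is then unidentifiable and the
  enrichment ratio meaningless. Recovery experiments therefore use
  `simulate_block_panel` (blocks of ρ = 0.1/0.4/0.7/0.9, ℓ spanning ~1.4–47).
- **Keep per-SNP non-centrality moderate.** With single-pass weights, member
  SNPs with χ² in the hundreds-to-thousands have residual variance
  ∝ (N·τ·ℓ)² that the weights ignore, destroying intercept/coefficient
  separation. The recovery experiment uses N = 20k with h² = 0.1
  concentrated in 10% of 2000 SNPs (per-SNP NCP ≈ 10, typical of a strongly
  enriched GWAS annotation); there the jackknife t-CI covers the true
  10-fold enrichment in ≥ 80% of replicates, while the ratio's median
  retains a modest upward bias (~20–30%) inherent to a ratio of correlated
  noisy estimates at this scale.

## Fine-mapping

Exact enumeration of causal configurations up to size K (default 1, max 3;
≤ 25 variants — larger loci are pre-thinned, in the pipeline by proximity to
the lead variant). `BF(C)` is the MVN density ratio of `z` under
`N(0, R + σ²·R[:,C]R[C,:])` versus `N(0, R)` with σ² = 25 on the
non-centrality scale (typical GWAS; configurable). Per-variant priors default
to 1/M; the null configuration is included so PIPs are calibrated on
no-signal loci. Annotations enter through a per-locus two-pass empirical
prior: flat-prior PIPs give each annotation a relative causal probability
(mean member PIP / mean locus PIP); annotations with ratio > 1 multiply
member prior odds by the ratio, renormalized to preserve the expected number
of causal variants. This replaces cross-locus EM estimation of annotation
weights — the selection rule (ratio > 1) is preserved, the weight estimation
is deliberately simpler and noisier.

Candidate prioritization applies, in order: LD r² ≥ 0.8 to the lead
variant; a coding-variant screen from a user-supplied annotation table
(coding candidates are reported directly with the lead variant's residual
conditional z, bypassing regulatory filters); residence in an active
enhancer (skipped for loci flagged as distal-regulation); a strong motif
disruption/creation for a TF with TPM ≥ 1; significant eQTL support
(q ≤ 0.05); and PIP ≥ 0.1 when fine-mapping ran. Each missing input layer
skips its filter with an explicit log line; output ranks by PIP then eQTL q.

## Motif scoring

PWMs are 4×L probability matrices; scores are Σ log2(p/bg) over a window,
maximized over offsets and both strands. Match p-values are computed exactly
by dynamic programming over the discretized score distribution under the
background (bins of 1e-3 log-odds units), which agrees bin-for-bin with
enumeration over all 4^L sequences. Both alleles are scored on the same
placement (the window/strand maximizing the better allele). A hit requires
the better allele's match p ≤ 5e-5 and an expressed TF (TPM ≥ 1 in ≥ 1 cell
type); *disruption* means the reference matches at threshold and the
alternate does not, *creation* the converse — when both alleles match, the
hit is reported with direction `neutral` and only the score delta speaks.
The strong/weak boundary is |Δscore| ≥ 0.7 × the mean per-position log-odds
range of the PWM — a pinned, configurable choice; the reference tools do not
publish a numeric boundary.

## Allelic imbalance

Individuals are kept when the variant's read depth reaches the assay minimum
(RNA 10, ATAC 5). Each allele's count is normalized per individual to
reads-per-million on the variant's own chromosome (generalizing
fixed-chromosome normalization; override available), then a paired one-sided
t-test is applied in a direction declared before testing. Zero-variance
differences return p = 0.5 when all differences are zero, else the exact
sign result. Per-allele CPM (rather than pooled-count normalization) is the
pinned reading of an ambiguous normalization description. Overdispersion
(beta-binomial) is out of scope.

## Pipeline

`run_locus` executes states → risk enhancers → Hi-C mapping → coloc gate →
SMR chain → fine-mapping → prioritization → variant function on one
synthetic locus. A gene's evidence class is `hic` (risk-enhancer link),
`smr` (significant stage-1 chromatin → expression association), or `both`;
risk direction is the sign of the significant stage-2 `b_xy`
(`not_inferred` otherwise). Ablations behave predictably: removing the Hi-C
link demotes `both` to `smr`; zeroing the expression → disease effect
nullifies the GWAS, so the coloc gate closes and nothing is nominated.
Re-running with the same config and seed reproduces identical output.

## Problem sizes and numerical choices

Default locus: 40 variants at 500-bp spacing, panel of 2000 individuals;
replicate counts in the validation suite are 100–2000 per check, chosen so
the whole suite runs on one CPU in minutes. Ridge 1e-4 is added to LD
diagonals before any inversion or Cholesky. Strand-ambiguous (A/T, C/G)
allele pairs are dropped during harmonization unless both frequencies are
informative (< 0.4 or > 0.6) and concordant after orientation — a stand-in
rule; the source datasets' harmonization is not described anywhere
authoritative. BH q-values are computed within whatever table is supplied.
LD-block clustering is greedy seed-extension at r² ≥ 0.5 — a stand-in for
clique-based blocking, adequate because blocks only delimit candidate sets.

## Known limitations

- The heritability module is a desk-scale teaching implementation: no
  baseline annotation set, no iterative weighting, no liability-scale
  conversion; its enrichment ratio is median-biased upward at small M.
- Coloc assumes one causal variant per trait; SMR uses a single instrument
  (no HEIDI, no multi-SNP or sensitivity estimators).
- The two-pass fine-mapping prior is per-locus and empirical; it preserves
  the enriched/not-enriched decision rule but not cross-locus shrinkage.
- The per-base oracles and enumeration guards cap exact computations
  (≤ 25 variants, motif length ≤ ~20 for the DP lattice) by design.
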