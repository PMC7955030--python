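"""Synthetic loci with known ground truth.

Generates everything the downstream stages consume: an LD-structured genotype
panel, chained chromatin -> expression -> disease summary statistics, a peak
landscape with a planted enhancer/promoter pair, a promoter-capture Hi-C link,
a PWM with a planted motif-disrupting allele, and per-individual allele-specific
read counts. Every generator is a pure function of its config (seeds are
mandatory, never wall-clock).

The association model is the standard summary-statistic (RSS) model: with LD
matrix R and a single causal variant c with per-SD effect b in a study of n
individuals, marginal z-scores are drawn as

    z = sqrt(n) * b * R[:, c] + eps,   eps ~ MVN(0, R)

and beta/se are back-filled as z/sqrt(n) and 1/sqrt(n). Chain effects compose
multiplicatively: the GWAS causal effect is b_vh * b_he * b_ed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_io import (
    GenomicInterval,
    GenotypePanel,
    InteractionRecord,
    QTLRecord,
    SummaryStatRecord,
    compute_ld_matrix,
)

from scipy import stats


@dataclass
class PWMSpec:
    """A planted transcription-factor motif: consensus sequence + SNP position.

    ``snp_motif_pos`` is 1-based within the motif; the alt allele at that
    position is the consensus-minimum base, i.e. maximally disruptive.
    """

    tf_name: str = "CTCF"
    consensus: str = "CCGCGNGGNGGCAG".replace("N", "A")
    snp_motif_pos: int = 7
    consensus_weight: float = 0.85


@dataclass
class SimConfig:
    """Study conditions for one synthetic locus."""

    n_variants: int = 40
    ld_rho: float = 0.8  # AR(1) adjacent correlation of latent haplotypes
    maf: float = 0.3
    n_panel: int = 2000  # individuals in the LD reference panel
    n_gwas: int = 50000
    n_eqtl: int = 10000
    n_hqtl: int = 10000
    b_vh: float = 0.3  # variant -> chromatin, per SD
    b_he: float = 0.3  # chromatin -> expression
    b_ed: float = 0.3  # expression -> disease
    causal_index: int = 20
    seed: int = 0
    # locus geometry (1-based variant positions laid out on a grid)
    chrom: str = "chr11"
    locus_start: int = 60_000_000
    variant_spacing: int = 500
    tss_pos: int = 60_060_000
    gene: str = "MS4A6A"
    peak_id: str = "peak_1"
    enhancer_halfwidth: int = 750
    hic_score: float = 7.0
    n_decoy_enhancers: int = 3
    n_decoy_promoters: int = 1
    ase_prob: float = 0.7
    pwm_spec: PWMSpec = field(default_factory=PWMSpec)

    def __post_init__(self):
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 <= self.causal_index < self.n_variants):
            raise ValueError("causal_index out of range")
        if not (0 < self.maf < 0.5):
            raise ValueError("maf must be in (0, 0.5)")

    @property
    def positions(self) -> np.ndarray:
        """1-based positions of the locus variants."""
        return self.locus_start + self.variant_spacing * np.arange(self.n_variants)

    @property
    def variant_ids(self) -> list[str]:
        return [f"rs{i + 1}" for i in range(self.n_variants)]

    @property
    def causal_pos(self) -> int:
        return int(self.positions[self.causal_index])


@dataclass
class SimTruth:
    """Ground truth co-emitted with every synthetic locus."""

    causal_variant: str
    causal_pos: int
    marginal_effects: dict  # dataset -> per-SD causal effect
    coloc_shared: bool  # GWAS and hQTL share the causal variant
    enhancer: GenomicInterval | None = None
    promoter: GenomicInterval | None = None
    target_gene: str | None = None
    ase_prob: float | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "causal_variant": self.causal_variant,
            "causal_pos": self.causal_pos,
            "marginal_effects": self.marginal_effects,
            "coloc_shared": self.coloc_shared,
            "target_gene": self.target_gene,
            "ase_prob": self.ase_prob,
        }
        if self.enhancer is not None:
            d["enhancer"] = [self.enhancer.chrom, self.enhancer.start, self.enhancer.end]
        if self.promoter is not None:
            d["promoter"] = [self.promoter.chrom, self.promoter.start, self.promoter.end]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _tetrachoric_latent_rho(target_r: float, maf: float) -> float:
    """Latent normal correlation whose thresholded binary correlation is target_r.

    Thresholding attenuates correlation, so the latent AR(1) parameter is
    inflated (tetrachoric calibration) to make adjacent haplotype r match the
    configured value. Solved by bisection on the bivariate normal orthant mass.
    """
    if target_r <= 0:
        return target_r
    t = stats.norm.ppf(1 - maf)
    denom = maf * (1 - maf)

    def binary_r(rho: float) -> float:
        p11 = 1 - 2 * stats.norm.cdf(t) + stats.multivariate_normal.cdf(
            [t, t], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        return (p11 - maf**2) / denom

    lo, hi = target_r, 1 - 1e-9
    if binary_r(hi) < target_r:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if binary_r(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_ld_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Diploid dosages from AR(1)-correlated latent haplotypes.

    Each haplotype is a latent MVN with AR(1) structure thresholded at the
    ``1 - maf`` normal quantile; dosage = sum of two haplotypes. The latent
    adjacent correlation is tetrachorically calibrated so the empirical
    adjacent dosage r approximates ``ld_rho``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, m = cfg.n_panel, cfg.n_variants
    rho = _tetrachoric_latent_rho(cfg.ld_rho, cfg.maf)
    thresh = stats.norm.ppf(1 - cfg.maf)

    def haplotypes() -> np.ndarray:
        eps = rng.standard_normal((n, m))
        lat = np.empty((n, m))
        lat[:, 0] = eps[:, 0]
        scale = np.sqrt(1 - rho**2)
        for j in range(1, m):
            lat[:, j] = rho * lat[:, j - 1] + scale * eps[:, j]
        return (lat > thresh).astype(float)

    dosages = haplotypes() + haplotypes()
    # guard: resample any monomorphic column (possible at small n)
    for j in range(m):
        while dosages[:, j].std() == 0:
            flip = rng.integers(0, n)
            dosages[flip, j] = 2 - dosages[flip, j] if dosages[flip, j] in (0, 2) else 1
    return GenotypePanel(
        sample_ids=[f"ind{i + 1}" for i in range(n)],
        variant_ids=cfg.variant_ids,
        positions=cfg.positions,
        dosages=dosages,
        chrom=cfg.chrom,
    )


# ---------------------------------------------------------------------------
# chained summary statistics
# ---------------------------------------------------------------------------


def _marginal_z(
    rng: np.random.Generator,
    chol: np.ndarray,
    r_causal: np.ndarray,
    b: float,
    n: float,
) -> np.ndarray:
    mean = np.sqrt(n) * b * r_causal
    return mean + chol @ rng.standard_normal(len(r_causal))


def _records(cfg: SimConfig, z: np.ndarray, n: float) -> list[SummaryStatRecord]:
    se = 1.0 / np.sqrt(n)
    pos = cfg.positions
    pvals = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    recs = []
    for j, vid in enumerate(cfg.variant_ids):
        p = float(pvals[j])
        recs.append(
            SummaryStatRecord(
                variant_id=vid, chrom=cfg.chrom, pos=int(pos[j]),
                effect_allele="A", other_allele="G",
                beta=float(z[j] * se), se=float(se), p=p, n=n, eaf=cfg.maf,
            )
        )
    return recs


def simulate_summary_chain(
    cfg: SimConfig,
    panel: GenotypePanel,
    rng: np.random.Generator | None = None,
    gwas_causal_index: int | None = None,
) -> tuple[list[QTLRecord], list[QTLRecord], list[SummaryStatRecord], SimTruth]:
    """hQTL, eQTL and GWAS summary statistics for the planted causal chain.

    ``gwas_causal_index`` moves the GWAS causal variant away from the
    molecular one (distinct-causal loci for colocalization tests); by default
    all three datasets share ``cfg.causal_index``.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    ld = compute_ld_matrix(panel)
    chol = np.linalg.cholesky(ld.regularized(1e-4))
    r_c = ld.r[:, cfg.causal_index]

    b_h = cfg.b_vh
    b_e = cfg.b_vh * cfg.b_he
    b_g = cfg.b_vh * cfg.b_he * cfg.b_ed

    z_h = _marginal_z(rng, chol, r_c, b_h, cfg.n_hqtl)
    z_e = _marginal_z(rng, chol, r_c, b_e, cfg.n_eqtl)
    gidx = cfg.causal_index if gwas_causal_index is None else gwas_causal_index
    z_g = _marginal_z(rng, chol, ld.r[:, gidx], b_g, cfg.n_gwas)

    hqtl = [
        QTLRecord(s, feature_id=cfg.peak_id, feature_type="chromatin")
        for s in _records(cfg, z_h, cfg.n_hqtl)
    ]
    eqtl = [
        QTLRecord(s, feature_id=cfg.gene, feature_type="expression")
        for s in _records(cfg, z_e, cfg.n_eqtl)
    ]
    gwas = _records(cfg, z_g, cfg.n_gwas)
    truth = SimTruth(
        causal_variant=cfg.variant_ids[cfg.causal_index],
        causal_pos=cfg.causal_pos,
        marginal_effects={"hqtl": b_h, "eqtl": b_e, "gwas": b_g},
        coloc_shared=gidx == cfg.causal_index,
        target_gene=cfg.gene,
        ase_prob=cfg.ase_prob,
    )
    return hqtl, eqtl, gwas, truth


@dataclass
class BlockPanel:
    """A multi-block panel of independent AR(1) LD blocks of varying strength.

    LD-score regression needs LD-score variation to separate the slope from
    the intercept; a homogeneous AR(1) locus has near-constant LD scores and
    is a degenerate design for it. Blocks are placed far apart (beyond any
    LD-score window) and are truly independent, so z-score generation is
    block-diagonal.
    """

    panel: GenotypePanel
    block_r: list[np.ndarray]
    block_chol: list[np.ndarray]
    block_slices: list[slice]

    def draw_z(self, rng: np.random.Generator, beta: np.ndarray | None = None,
               n: float = 1.0) -> np.ndarray:
        """Marginal z under the standard summary-statistic model, per block."""
        out = []
        for R, chol, sl in zip(self.block_r, self.block_chol, self.block_slices):
            mean = 0.0 if beta is None else np.sqrt(n) * (R @ beta[sl])
            out.append(mean + chol @ rng.standard_normal(R.shape[0]))
        return np.concatenate(out)


def simulate_block_panel(
    n_variants: int = 2000,
    block_rhos: tuple[float, ...] = (0.1, 0.4, 0.7, 0.9),
    n_panel: int = 1000,
    seed: int = 0,
    maf: float = 0.3,
    variant_spacing: int = 500,
    chrom: str = "chr11",
    ridge: float = 1e-4,
) -> BlockPanel:
    """Concatenate independent AR(1) blocks with heterogeneous LD strength."""
    per = n_variants // len(block_rhos)
    panels = []
    for k, rho in enumerate(block_rhos):
        cfg = SimConfig(
            seed=seed + k, n_variants=per, ld_rho=rho, n_panel=n_panel,
            maf=maf, causal_index=0, variant_spacing=variant_spacing,
            chrom=chrom, locus_start=60_000_000 + k * 2_000_000,
            tss_pos=60_000_000 + k * 2_000_000 + 1_500_000,
        )
        panels.append(simulate_ld_genotypes(cfg))
    X = np.hstack([p.dosages for p in panels])
    panel = GenotypePanel(
        sample_ids=[f"ind{j + 1}" for j in range(n_panel)],
        variant_ids=[f"rs{j + 1}" for j in range(per * len(block_rhos))],
        positions=np.concatenate([p.positions for p in panels]),
        dosages=X,
        chrom=chrom,
    )
    block_r, block_chol, slices = [], [], []
    for b, p in enumerate(panels):
        Xs = p.dosages
        Xc = (Xs - Xs.mean(0)) / Xs.std(0)
        R = (Xc.T @ Xc) / Xs.shape[0]
        block_r.append(R)
        block_chol.append(np.linalg.cholesky(R + ridge * np.eye(per)))
        slices.append(slice(b * per, (b + 1) * per))
    return BlockPanel(panel, block_r, block_chol, slices)


def simulate_marginal_stats(
    cfg: SimConfig,
    panel: GenotypePanel,
    b: float,
    n: float,
    causal_index: int | None = None,
    rng: np.random.Generator | None = None,
    ld=None,
) -> list[SummaryStatRecord]:
    """One dataset's marginal summary statistics for a single causal variant.

    Same generator as the chain (z = sqrt(n) * b * r_causal + MVN(0, R) noise)
    but for one trait with an arbitrary causal position; ``ld`` may be passed
    to avoid recomputing panel correlations across replicates.
    """
    rng = np.random.default_rng(cfg.seed + 4) if rng is None else rng
    if ld is None:
        ld = compute_ld_matrix(panel)
    chol = np.linalg.cholesky(ld.regularized(1e-4))
    cidx = cfg.causal_index if causal_index is None else causal_index
    z = _marginal_z(rng, chol, ld.r[:, cidx], b, n)
    return _records(cfg, z, n)


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryLandscape:
    peaks: dict  # mark -> list[GenomicInterval]
    tss: list[GenomicInterval]
    interactions: list[InteractionRecord]
    enhancer: GenomicInterval
    promoter: GenomicInterval


def simulate_regulatory_landscape(
    cfg: SimConfig, include_k27ac_on_enhancer: bool = True
) -> RegulatoryLandscape:
    """Peak sets, TSS table and a Hi-C link around the planted causal variant.

    The planted enhancer is a distal H3K4me1 + H3K27ac interval containing
    the causal variant; the planted promoter sits on the target
    gene's TSS (H3K4me3 & H3K27ac); one interaction links them with the
    configured score. Decoy peaks are placed away from the causal variant.
    """
    c = cfg.causal_pos - 1  # 0-based
    hw = cfg.enhancer_halfwidth
    enhancer = GenomicInterval(cfg.chrom, c - hw, c + hw, name="planted_enhancer")
    tss0 = cfg.tss_pos - 1
    if enhancer.end > tss0 - 2000 and enhancer.start < tss0 + 2000:
        raise ValueError("geometry collision: planted enhancer overlaps the TSS window")
    promoter = GenomicInterval(cfg.chrom, tss0 - 400, tss0 + 800, name="planted_promoter")

    # the planted enhancer is emitted under H3K4me1 only, so active-enhancer
    # counts stay exact bookkeeping (decoys + 1)
    peaks = {"H3K4me1": [enhancer], "H3K4me2": [], "H3K4me3": [promoter],
             "H3K27ac": [], "ATAC": [enhancer]}
    if include_k27ac_on_enhancer:
        peaks["H3K27ac"].append(enhancer)
    peaks["H3K27ac"].append(promoter)

    # decoys: distal AE-like peaks upstream of the locus, far from the causal variant
    decoy_anchor = cfg.locus_start - 200_000
    for d in range(cfg.n_decoy_enhancers):
        s = decoy_anchor + 5000 * d
        iv = GenomicInterval(cfg.chrom, s, s + 1000, name=f"decoy_enh_{d + 1}")
        peaks["H3K4me1"].append(iv)
        peaks["H3K27ac"].append(iv)
    for d in range(cfg.n_decoy_promoters):
        s = decoy_anchor - 50_000 - 10_000 * d
        iv = GenomicInterval(cfg.chrom, s, s + 800, name=f"decoy_prom_{d + 1}")
        peaks["H3K4me3"].append(iv)

    tss = [GenomicInterval(cfg.chrom, tss0, tss0 + 1, strand="+", name=cfg.gene)]
    for d in range(cfg.n_decoy_promoters):
        s = decoy_anchor - 50_000 - 10_000 * d + 100
        tss.append(GenomicInterval(cfg.chrom, s, s + 1, strand="+", name=f"DECOY{d + 1}"))

    interactions = [
        InteractionRecord(bait=promoter, other_end=enhancer,
                          bait_gene=cfg.gene, score=cfg.hic_score)
    ]
    return RegulatoryLandscape(peaks, tss, interactions, enhancer, promoter)


# ---------------------------------------------------------------------------
# allele-specific counts
# ---------------------------------------------------------------------------


def simulate_allele_counts(
    cfg: SimConfig,
    n_individuals: int = 30,
    depth: float = 50,
    rng: np.random.Generator | None = None,
    chrom_background: int = 1_000_000,
) -> list[tuple[int, int, int]]:
    """Per-individual (ref_count, alt_count, chrom_total) triples.

    Total reads per individual are Poisson(depth) truncated to >= 1; alt reads
    are Binomial(total, ase_prob); chrom_total adds a Poisson library-size
    background so normalization has something to normalize.
    """
    if not (0 < cfg.ase_prob <= 1):
        raise ValueError("ase_prob must be in (0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    out = []
    for _ in range(n_individuals):
        total = 0
        while total < 1:
            total = int(rng.poisson(depth))
        alt = int(rng.binomial(total, cfg.ase_prob))
        chrom_total = total + int(rng.poisson(chrom_background))
        out.append((total - alt, alt, chrom_total))
    return out


# ---------------------------------------------------------------------------
# sequence context for the planted motif
# ---------------------------------------------------------------------------


def simulate_motif_context(
    cfg: SimConfig, rng: np.random.Generator | None = None, flank: int = 20
) -> tuple[str, str, str]:
    """(sequence, ref_allele, alt_allele) around the planted motif site.

    The motif consensus is embedded so the causal variant falls at
    ``pwm_spec.snp_motif_pos`` (1-based within the motif). The ref allele is
    the consensus base at that position; the alt allele is maximally
    disruptive (any other base; 'T' unless consensus is 'T').
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    spec = cfg.pwm_spec
    cons = spec.consensus.upper()
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    seq = left + cons + right
    ref = cons[spec.snp_motif_pos - 1]
    alt = "T" if ref != "T" else "G"
    return seq, ref, alt


def pwm_from_consensus(spec: PWMSpec) -> np.ndarray:
    """4 x L probability matrix putting ``consensus_weight`` on the consensus base."""
    order = "ACGT"
    L = len(spec.consensus)
    w = spec.consensus_weight
    mat = np.full((4, L), (1 - w) / 3)
    for j, base in enumerate(spec.consensus.upper()):
        mat[order.index(base), j] = w
    return mat
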