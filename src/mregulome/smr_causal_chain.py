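"""Summary-data Mendelian randomization (SMR) and the chromatin -> expression
-> disease causal chain, plus approximate conditional z-scores.

For an instrument SNP with exposure effect b_zx (z_zx = b_zx / se_zx) and
outcome effect b_zy, the mediated effect is b_xy = b_zy / b_zx and the SMR
statistic is

    T_SMR = z_zx^2 * z_zy^2 / (z_zx^2 + z_zy^2),   p_SMR = P(chi^2_1 > T_SMR).

The chain runs SMR twice: chromatin activity (hQTL) as exposure against gene
expression (eQTL) as outcome, then expression as exposure against disease
(GWAS) as outcome, BH-correcting within each stage. HEIDI heterogeneity
filtering is not computed (flagged as such in results).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import LDMatrix, QTLRecord, SummaryStatRecord, bh_fdr, harmonize_alleles

logger = logging.getLogger(__name__)

INSTRUMENT_P_DEFAULT = 5e-8


@dataclass
class SMRResult:
    exposure_id: str
    outcome_id: str
    instrument: str
    b_zx: float
    se_zx: float
    b_zy: float
    se_zy: float
    b_xy: float
    t_smr: float
    p_smr: float
    q: float | None = None
    heidi: None = None  # heterogeneity test not computed


@dataclass
class ChainResult:
    stage1: list[SMRResult]  # chromatin -> expression
    stage2: list[SMRResult]  # expression -> disease
    genes_both_stages: list[str]


def smr_test(
    exposure: list[QTLRecord],
    outcome: list[SummaryStatRecord],
    instrument: str | None = None,
    instrument_p: float = INSTRUMENT_P_DEFAULT,
    outcome_id: str = "outcome",
) -> SMRResult | None:
    """SMR test for one exposure feature against one outcome.

    The instrument is the named variant if given, else the exposure's top cis
    variant with p < ``instrument_p`` (ties broken by smaller position).
    Returns None (with a log line) when no variant qualifies or the
    instrument is absent from the outcome.
    """
    if not exposure:
        raise ValueError("empty exposure set")
    feature = exposure[0].feature_id
    outcome_by_id = {r.variant_id: r for r in outcome}

    if instrument is None:
        candidates = [
            q for q in exposure
            if q.stat.p < instrument_p and q.stat.variant_id in outcome_by_id
        ]
        if not candidates:
            logger.info("SMR %s: no instrument passes p < %g; feature skipped",
                        feature, instrument_p)
            return None
        top = min(candidates, key=lambda q: (q.stat.p, q.stat.pos))
    else:
        matches = [q for q in exposure if q.stat.variant_id == instrument]
        if not matches or instrument not in outcome_by_id:
            logger.info("SMR %s: instrument %s missing from exposure or outcome",
                        feature, instrument)
            return None
        top = matches[0]

    out_rec, _ = harmonize_alleles(top.stat, outcome_by_id[top.stat.variant_id])
    if out_rec is None:
        logger.info("SMR %s: instrument %s alleles irreconcilable", feature,
                    top.stat.variant_id)
        return None

    b_zx, se_zx = top.stat.beta, top.stat.se
    b_zy, se_zy = out_rec.beta, out_rec.se
    if b_zx == 0:
        raise ValueError(f"exposure effect exactly 0 at instrument {top.stat.variant_id}")
    z_zx, z_zy = b_zx / se_zx, b_zy / se_zy
    denom = z_zx**2 + z_zy**2
    t = 0.0 if denom == 0 else (z_zx**2 * z_zy**2) / denom
    p = float(stats.chi2.sf(t, df=1))
    return SMRResult(
        exposure_id=feature, outcome_id=outcome_id,
        instrument=top.stat.variant_id,
        b_zx=b_zx, se_zx=se_zx, b_zy=b_zy, se_zy=se_zy,
        b_xy=b_zy / b_zx, t_smr=t, p_smr=p,
    )


def _group_by_feature(qtls: list[QTLRecord]) -> dict[str, list[QTLRecord]]:
    groups: dict[str, list[QTLRecord]] = {}
    for q in qtls:
        groups.setdefault(q.feature_id, []).append(q)
    return groups


def _cis_overlap(a: list[QTLRecord], b: list[QTLRecord]) -> bool:
    """Two features share a cis window iff they share >= 1 variant id."""
    ids_a = {q.stat.variant_id for q in a}
    return any(q.stat.variant_id in ids_a for q in b)


def run_smr_chain(
    hqtls: list[QTLRecord],
    eqtls: list[QTLRecord],
    gwas: list[SummaryStatRecord],
    fdr: float = 0.05,
    instrument_p: float = INSTRUMENT_P_DEFAULT,
    independent_stages: bool = False,
) -> ChainResult:
    """Two-stage SMR chain with BH correction within each stage.

    Stage 1 tests every (chromatin peak, gene) pair sharing a cis window;
    stage 2 tests genes surviving stage 1 (all genes when
    ``independent_stages``). ``genes_both_stages`` lists genes significant at
    ``fdr`` in both.
    """
    peaks = _group_by_feature(hqtls)
    genes = _group_by_feature(eqtls)

    stage1: list[SMRResult] = []
    for peak_id, peak_qtls in sorted(peaks.items()):
        for gene_id, gene_qtls in sorted(genes.items()):
            if not _cis_overlap(peak_qtls, gene_qtls):
                continue
            res = smr_test(
                peak_qtls, [q.stat for q in gene_qtls],
                instrument_p=instrument_p, outcome_id=gene_id,
            )
            if res is not None:
                stage1.append(res)
    if not stage1:
        logger.info("SMR chain: no testable (peak, gene) pairs")
        if not independent_stages:
            return ChainResult([], [], [])
    qs = bh_fdr([r.p_smr for r in stage1])
    for r, q in zip(stage1, qs):
        r.q = float(q)
    stage1_genes = sorted({r.outcome_id for r in stage1 if r.q <= fdr})

    eligible = sorted(genes) if independent_stages else stage1_genes
    stage2: list[SMRResult] = []
    for gene_id in eligible:
        res = smr_test(genes[gene_id], gwas, instrument_p=instrument_p,
                       outcome_id="disease")
        if res is not None:
            stage2.append(res)
    if stage2:
        qs2 = bh_fdr([r.p_smr for r in stage2])
        for r, q in zip(stage2, qs2):
            r.q = float(q)
    stage2_genes = {r.exposure_id for r in stage2 if r.q is not None and r.q <= fdr}

    both = sorted(set(stage1_genes) & stage2_genes)
    return ChainResult(stage1, stage2, both)


def conditional_z(
    z_target: float,
    target_id: str,
    conditioning: dict[str, float],
    ld: LDMatrix,
    ridge: float = 1e-4,
) -> float:
    """Approximate conditional (residual) z-score of one variant.

    z_{i|C} = (z_i - R_iC R_CC^{-1} z_C) / sqrt(1 - R_iC R_CC^{-1} R_Ci),
    the standardized-genotype approximation to joint conditional analysis.
    Conditioning a variant on itself returns 0.
    """
    if target_id in conditioning:
        return 0.0
    cond_ids = list(conditioning)
    i = ld.index_of(target_id)
    c_idx = [ld.index_of(v) for v in cond_ids]
    r_ic = ld.r[i, c_idx]
    r_cc = ld.r[np.ix_(c_idx, c_idx)] + ridge * np.eye(len(c_idx))
    z_c = np.array([conditioning[v] for v in cond_ids])
    w = np.linalg.solve(r_cc, z_c)
    quad = float(r_ic @ np.linalg.solve(r_cc, r_ic))
    denom = 1.0 - quad
    if denom <= 0:
        raise np.linalg.LinAlgError(
            f"variant {target_id} collinear with conditioning set (1 - R_iC R_CC^-1 R_Ci <= 0)"
        )
    return float((z_target - r_ic @ w) / np.sqrt(denom))
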