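"""Risk-enhancer identification and Hi-C target-gene assignment.

A risk enhancer is an active enhancer (state AE) whose 500-bp-flanked
interval contains at least one GWAS variant with p <= 1e-6. A target-gene
link is emitted when the enhancer's 3000-bp-flanked interval overlaps a
promoter-capture Hi-C other-end whose bait gene has eQTL support: at least
one of the enhancer's risk variants is a significant eQTL (BH q <= 0.05) for
that gene in the same cell type. The risk variant itself must be the eQTL
(no LD-proxy expansion by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chromatin_states import RegulatoryElement
from .core_io import InteractionRecord, QTLRecord, SummaryStatRecord, bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class RiskEnhancer:
    element: RegulatoryElement
    flank_bp: int
    risk_variants: list[str]
    risk_pvalues: list[float]
    cell_type: str


@dataclass
class EnhancerGeneLink:
    enhancer: RiskEnhancer
    gene: str
    interaction: InteractionRecord
    supporting_variants: list[str]
    supporting_q: list[float]
    cell_type: str


def find_risk_enhancers(
    elements: list[RegulatoryElement],
    gwas: list[SummaryStatRecord],
    p_threshold: float = 1e-6,
    flank: int = 500,
) -> list[RiskEnhancer]:
    """Active enhancers whose flank-extended interval holds a risk variant."""
    non_ae = sum(1 for el in elements if el.state != "AE")
    if non_ae:
        logger.info("find_risk_enhancers: ignoring %d non-AE elements", non_ae)
    out = []
    for el in elements:
        if el.state != "AE":
            continue
        ext = el.interval.expanded(flank)
        hits = [
            (r.variant_id, r.p)
            for r in gwas
            if r.p <= p_threshold and ext.contains_pos(r.chrom, r.pos)
        ]
        if hits:
            out.append(
                RiskEnhancer(
                    element=el, flank_bp=flank,
                    risk_variants=[h[0] for h in hits],
                    risk_pvalues=[h[1] for h in hits],
                    cell_type=el.cell_type,
                )
            )
    out.sort(key=lambda e: (e.element.interval.chrom, e.element.interval.start))
    return out


def _ensure_q(eqtls: list[QTLRecord]) -> None:
    """Fill missing BH q-values, per-gene across the supplied table."""
    if all(q.fdr is not None for q in eqtls):
        return
    by_gene: dict[str, list[QTLRecord]] = {}
    for q in eqtls:
        by_gene.setdefault(q.feature_id, []).append(q)
    for recs in by_gene.values():
        qs = bh_fdr([r.stat.p for r in recs])
        for r, qv in zip(recs, qs):
            r.fdr = float(qv)


def map_targets(
    risk_enhancers: list[RiskEnhancer],
    interactions: list[InteractionRecord],
    eqtls: list[QTLRecord],
    fdr: float = 0.05,
    flank: int = 3000,
) -> list[EnhancerGeneLink]:
    """Assign target genes to risk enhancers via Hi-C, gated on eQTL support."""
    _ensure_q(eqtls)
    # (gene, cell_type, variant) -> q
    eqtl_q: dict[tuple[str, str, str], float] = {}
    for q in eqtls:
        key = (q.feature_id, q.cell_type, q.stat.variant_id)
        if key not in eqtl_q or q.fdr < eqtl_q[key]:
            eqtl_q[key] = q.fdr

    links = []
    for enh in risk_enhancers:
        ext = enh.element.interval.expanded(flank)
        for ia in interactions:
            if not ia.bait_gene:
                logger.warning("map_targets: interaction without bait gene skipped")
                continue
            if ia.cell_type != enh.cell_type:
                continue
            if not ext.overlaps(ia.other_end):
                continue
            support = [
                (v, eqtl_q[(ia.bait_gene, enh.cell_type, v)])
                for v in enh.risk_variants
                if (ia.bait_gene, enh.cell_type, v) in eqtl_q
                and eqtl_q[(ia.bait_gene, enh.cell_type, v)] <= fdr
            ]
            if support:
                links.append(
                    EnhancerGeneLink(
                        enhancer=enh, gene=ia.bait_gene, interaction=ia,
                        supporting_variants=[s[0] for s in support],
                        supporting_q=[s[1] for s in support],
                        cell_type=enh.cell_type,
                    )
                )
    links.sort(
        key=lambda l: (l.enhancer.element.interval.chrom,
                       l.enhancer.element.interval.start, l.gene)
    )
    return links
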