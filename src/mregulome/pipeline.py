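"""End-to-end locus workflow.

Runs, in dependency order: chromatin-state classification -> risk-enhancer
calling -> Hi-C/eQTL target mapping -> GWAS/hQTL colocalization gate -> the
two-stage SMR chain -> fine-mapping -> candidate-variant prioritization ->
variant-function checks (motif disruption, allelic imbalance). Each nominated
gene carries an evidence class (hic / smr / both) and a direction-of-risk
label derived from the sign of the significant stage-2 SMR effect
(``not_inferred`` when expression -> disease is not significant).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import chromatin_states, coloc_abf, enhancer_gene_map, finemap_annot
from . import smr_causal_chain as smr
from . import synthetic_data as synth
from . import variant_function as vf
from .core_io import compute_ld_matrix, cluster_ld_blocks

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "states", "risk_enhancers", "hic_map", "coloc", "smr_chain",
    "finemap", "prioritize", "variant_function",
)


@dataclass
class PipelineConfig:
    """One synthetic-locus run: study conditions plus stage toggles."""

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    include_hic: bool = True
    gwas_p_threshold: float = 1e-6
    coloc_threshold: float = 0.8
    smr_fdr: float = 0.05
    pip_threshold: float = 0.1
    out_dir: str | Path | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synth.SimConfig(**raw.pop("sim", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=sim, **raw)


@dataclass
class LocusReport:
    config: PipelineConfig
    truth: synth.SimTruth | None = None
    elements: list = field(default_factory=list)
    state_counts: dict = field(default_factory=dict)
    risk_enhancers: list = field(default_factory=list)
    links: list = field(default_factory=list)
    coloc: coloc_abf.ColocResult | None = None
    coloc_pass: bool = False
    chain: smr.ChainResult | None = None
    finemap: finemap_annot.FineMapResult | None = None
    candidates: object = None  # pandas DataFrame from prioritize_variants
    motif_hits: list = field(default_factory=list)
    ase: vf.ASEResult | None = None
    genes: dict = field(default_factory=dict)  # gene -> {evidence_class, direction}

    def summary(self) -> dict:
        return {
            "seed": self.config.sim.seed,
            "n_elements": len(self.elements),
            "state_counts": self.state_counts,
            "n_risk_enhancers": len(self.risk_enhancers),
            "hic_genes": sorted({l.gene for l in self.links}),
            "coloc_pp": None if self.coloc is None else self.coloc.pp,
            "coloc_pass": self.coloc_pass,
            "smr_genes": [] if self.chain is None else self.chain.genes_both_stages,
            "max_pip_variant": None if self.finemap is None else
                self.finemap.variant_ids[int(np.argmax(self.finemap.pip))],
            "max_pip": None if self.finemap is None else float(self.finemap.pip.max()),
            "candidates": [] if self.candidates is None else
                list(self.candidates["variant"]),
            "ase_p": None if self.ase is None else self.ase.p,
            "genes": self.genes,
        }


def _evidence_classes(report: LocusReport, cfg: PipelineConfig) -> dict:
    """Gene -> evidence class and risk direction.

    A gene earns 'smr' evidence from a significant chromatin -> expression
    association (stage 1); direction is inferred only when the expression ->
    disease stage is also significant.
    """
    hic_genes = {l.gene for l in report.links}
    smr_genes = set()
    if report.chain is not None:
        smr_genes = {
            r.outcome_id for r in report.chain.stage1
            if r.q is not None and r.q <= cfg.smr_fdr
        }
    directions = {}
    if report.chain is not None:
        for res in report.chain.stage2:
            if res.q is not None and res.q <= cfg.smr_fdr:
                directions[res.exposure_id] = (
                    "risk_increasing" if res.b_xy > 0 else "risk_decreasing"
                )
    out = {}
    for gene in sorted(hic_genes | smr_genes):
        if gene in hic_genes and gene in smr_genes:
            cls = "both"
        elif gene in hic_genes:
            cls = "hic"
        else:
            cls = "smr"
        out[gene] = {
            "evidence_class": cls,
            "direction": directions.get(gene, "not_inferred"),
        }
    return out


def run_locus(cfg: PipelineConfig) -> LocusReport:
    """Execute the enabled stages on one synthetic locus."""
    report = LocusReport(config=cfg)
    stages = set(cfg.stages)
    if not stages:
        logger.info("all stages disabled; empty report")
        return report

    sim = cfg.sim
    panel = synth.simulate_ld_genotypes(sim)
    ld = compute_ld_matrix(panel)
    hqtl, eqtl, gwas, truth = synth.simulate_summary_chain(sim, panel)
    landscape = synth.simulate_regulatory_landscape(sim)
    report.truth = truth

    def log_stage(name, msg):
        logger.info("stage %-16s %s", name, msg)

    if "states" in stages:
        h3k4 = {m: landscape.peaks[m] for m in ("H3K4me1", "H3K4me2", "H3K4me3")
                if m in landscape.peaks}
        report.elements = chromatin_states.classify_elements(
            h3k4, landscape.peaks.get("H3K27ac", []), landscape.tss
        )
        report.state_counts = chromatin_states.count_states(report.elements)
        log_stage("states", f"{len(report.elements)} elements")

    if "risk_enhancers" in stages and report.elements:
        report.risk_enhancers = enhancer_gene_map.find_risk_enhancers(
            report.elements, gwas, p_threshold=cfg.gwas_p_threshold
        )
        log_stage("risk_enhancers", f"{len(report.risk_enhancers)} retained")

    if "hic_map" in stages and report.risk_enhancers:
        interactions = landscape.interactions if cfg.include_hic else []
        report.links = enhancer_gene_map.map_targets(
            report.risk_enhancers, interactions, eqtl
        )
        log_stage("hic_map", f"{len(report.links)} links")

    if "coloc" in stages:
        report.coloc = coloc_abf.coloc_posteriors(
            gwas, [q.stat for q in hqtl], trait1_type="cc", trait2_type="quant"
        )
        report.coloc_pass = report.coloc.pp_h3_plus_h4 >= cfg.coloc_threshold
        log_stage("coloc", f"PP.H3+PP.H4={report.coloc.pp_h3_plus_h4:.3f}")

    if "smr_chain" in stages:
        gate_open = "coloc" not in stages or report.coloc_pass
        if gate_open:
            report.chain = smr.run_smr_chain(hqtl, eqtl, gwas, fdr=cfg.smr_fdr)
            log_stage("smr_chain",
                      f"{len(report.chain.genes_both_stages)} genes pass both stages")
        else:
            log_stage("smr_chain", "skipped: coloc gate not passed")

    if "finemap" in stages:
        # pre-thin to the enumeration guard by proximity to the lead variant
        z = np.array([r.z for r in gwas])
        tag_idx = int(np.argmax(np.abs(z)))
        order = np.argsort(np.abs(np.arange(len(z)) - tag_idx), kind="stable")
        keep = np.sort(order[: finemap_annot.MAX_ENUM_VARIANTS])
        sub_ids = [ld.variant_ids[i] for i in keep]
        sub_ld = ld.subset(sub_ids)
        ae_ivs = [el.interval for el in report.elements if el.state == "AE"]
        annot = np.array([
            1 if any(iv.contains_pos(gwas[i].chrom, gwas[i].pos) for iv in ae_ivs)
            else 0
            for i in keep
        ])
        if annot.any():
            _, report.finemap = finemap_annot.finemap_with_annotations(
                z[keep], sub_ld, annot, names=["AE"]
            )
        else:
            report.finemap = finemap_annot.enumerate_posteriors(z[keep], sub_ld)
        log_stage("finemap", f"max PIP {report.finemap.pip.max():.3f}")

    motif_hits_by_variant = {}
    if "variant_function" in stages or "prioritize" in stages:
        seq, ref, alt = synth.simulate_motif_context(sim)
        pwm = vf.PWM(sim.pwm_spec.tf_name, synth.pwm_from_consensus(sim.pwm_spec))
        L = pwm.length
        pos_in_seq = 20 + sim.pwm_spec.snp_motif_pos - 1  # flank=20 in the generator
        hits = vf.motif_break_effect(
            ref, alt,
            seq[:pos_in_seq], seq[pos_in_seq + 1:],
            [pwm], tf_tpm={pwm.tf_name: {"microglia": 30.0}},
        )
        report.motif_hits = hits
        motif_hits_by_variant = {truth.causal_variant: hits}

    if "prioritize" in stages:
        blocks = cluster_ld_blocks(ld)
        report.candidates = finemap_annot.prioritize_variants(
            gwas, ld,
            elements=report.elements or None,
            eqtls=eqtl,
            motif_hits=motif_hits_by_variant,
            variant_annotations={v: "noncoding" for v in ld.variant_ids},
            finemap=report.finemap,
            pip_threshold=cfg.pip_threshold,
        )
        n = 0 if report.candidates is None else len(report.candidates)
        log_stage("prioritize", f"{n} candidates (blocks: {blocks.max() + 1})")

    if "variant_function" in stages:
        counts = synth.simulate_allele_counts(sim)
        records = [
            vf.AlleleCountRecord(f"ind{i + 1}", truth.causal_variant, ref_c, alt_c,
                                 chrom_total, "ATAC")
            for i, (ref_c, alt_c, chrom_total) in enumerate(counts)
        ]
        direction = "alt" if sim.ase_prob > 0.5 else "ref"
        report.ase = vf.allelic_imbalance_test(records, direction=direction)
        log_stage("variant_function",
                  f"{len(report.motif_hits)} motif hits, ASE p={report.ase.p:.4g}")

    report.genes = _evidence_classes(report, cfg)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "locus_summary.json", "w") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)
        if report.candidates is not None and len(report.candidates):
            report.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False,
                                     float_format="%.6g")
    return report


def ablate_hic(cfg: PipelineConfig) -> PipelineConfig:
    """The same locus without its Hi-C link."""
    return replace(cfg, include_hic=False)


def ablate_expression_to_disease(cfg: PipelineConfig) -> PipelineConfig:
    """The same locus with the expression -> disease effect zeroed."""
    return replace(cfg, sim=replace(cfg.sim, b_ed=0.0))
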