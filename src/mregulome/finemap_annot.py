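"""Annotation-informed Bayesian fine-mapping by exact enumeration.

For a locus with marginal z-scores z and LD matrix R, a causal configuration
C (|C| <= K) with per-causal prior effect variance sigma^2 on the
non-centrality scale has Bayes factor

    BF(C) = N(z; 0, R + sigma^2 * R[:, C] R[C, :]) / N(z; 0, R)

against the null configuration. With independent per-variant prior causal
probabilities p_i, posterior(C) is proportional to BF(C) * prod_i p_i^{c_i}
(1 - p_i)^{1 - c_i} (the null configuration included), and per-variant PIPs
marginalize over configurations. Annotation information enters through a
two-pass empirical prior: flat-prior PIPs give each annotation a relative
causal probability; annotations with ratio > 1 multiply the prior odds of
their member variants by that ratio on a second pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .chromatin_states import RegulatoryElement
from .core_io import LDMatrix, QTLRecord, SummaryStatRecord
from .smr_causal_chain import conditional_z
from .variant_function import MotifHit

logger = logging.getLogger(__name__)

MAX_ENUM_VARIANTS = 25
MAX_K = 3


@dataclass
class FineMapResult:
    variant_ids: list[str]
    pip: np.ndarray
    configurations: list[tuple[int, ...]]
    log_posterior: np.ndarray  # aligned with configurations, normalized
    sigma2: float
    k_max: int
    prior: np.ndarray
    annotation_ratios: dict[str, float] = field(default_factory=dict)

    def pip_of(self, variant_id: str) -> float:
        return float(self.pip[self.variant_ids.index(variant_id)])


def _log_mvn(z: np.ndarray, cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    sol = np.linalg.solve(cov, z)
    return -0.5 * (logdet + z @ sol + len(z) * np.log(2 * np.pi))


def enumerate_posteriors(
    z: np.ndarray,
    ld: LDMatrix,
    prior: np.ndarray | None = None,
    sigma2: float = 25.0,
    k_max: int = 1,
    ridge: float = 1e-4,
) -> FineMapResult:
    """Exact posterior over causal configurations of size <= k_max."""
    z = np.asarray(z, dtype=float)
    m = len(z)
    if m != len(ld.variant_ids):
        raise ValueError("z and LD dimensions differ")
    if m > MAX_ENUM_VARIANTS:
        raise ValueError(
            f"{m} variants exceeds the exact-enumeration guard "
            f"({MAX_ENUM_VARIANTS}); pre-thin by LD blocks"
        )
    if not (1 <= k_max <= MAX_K):
        raise ValueError(f"k_max must be in [1, {MAX_K}]")
    if prior is None:
        prior = np.full(m, 1.0 / m)
    prior = np.asarray(prior, dtype=float)
    if np.any((prior <= 0) | (prior >= 1)):
        raise ValueError("per-variant priors must be in (0, 1)")

    R = ld.regularized(ridge)
    log_null = _log_mvn(z, R)
    log1m = np.log1p(-prior)
    base_prior = log1m.sum()

    configs: list[tuple[int, ...]] = [()]
    log_post = [base_prior]  # BF(null) = 1
    for k in range(1, k_max + 1):
        for C in combinations(range(m), k):
            idx = list(C)
            cov = R + sigma2 * (ld.r[:, idx] @ ld.r[idx, :])
            log_bf = _log_mvn(z, cov) - log_null
            lp = base_prior + sum(np.log(prior[i]) - log1m[i] for i in idx)
            configs.append(C)
            log_post.append(log_bf + lp)
    log_post = np.asarray(log_post)
    log_post -= logsumexp(log_post)

    pip = np.zeros(m)
    for C, lp in zip(configs, log_post):
        for i in C:
            pip[i] += np.exp(lp)
    return FineMapResult(
        variant_ids=list(ld.variant_ids), pip=pip, configurations=configs,
        log_posterior=log_post, sigma2=sigma2, k_max=k_max, prior=prior,
    )


def annotation_enrichment(
    finemap_flat: FineMapResult, annotations: np.ndarray,
    names: list[str] | None = None,
) -> dict[str, float]:
    """Relative causal probability of each annotation under flat-prior PIPs.

    ratio_c = (mean PIP inside annotation c) / (mean PIP across the locus);
    an annotation is enriched iff ratio > 1. Zero-member annotations are
    skipped with a warning.
    """
    A = np.asarray(annotations)
    if A.ndim == 1:
        A = A[:, None]
    names = names or [f"annot{j + 1}" for j in range(A.shape[1])]
    pip = finemap_flat.pip
    overall = pip.mean()
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        members = A[:, j] == 1
        if not members.any():
            logger.warning("annotation %s has no members in locus; skipped", name)
            continue
        out[name] = float(pip[members].mean() / overall) if overall > 0 else np.nan
    return out


def enriched_prior(
    base_prior: np.ndarray,
    annotations: np.ndarray,
    ratios: dict[str, float],
    names: list[str] | None = None,
) -> np.ndarray:
    """Convert enrichment ratios (> 1 only) into per-variant prior odds.

    Each enriched annotation multiplies the prior odds of its member variants
    by its ratio; the result is renormalized so the locus-wide expected number
    of causal variants matches the base prior's.
    """
    A = np.asarray(annotations)
    if A.ndim == 1:
        A = A[:, None]
    names = names or [f"annot{j + 1}" for j in range(A.shape[1])]
    odds = base_prior / (1 - base_prior)
    for j, name in enumerate(names):
        ratio = ratios.get(name)
        if ratio is not None and ratio > 1:
            odds = odds * np.where(A[:, j] == 1, ratio, 1.0)
    p = odds / (1 + odds)
    scale = base_prior.sum() / p.sum()
    return np.clip(p * scale, 1e-12, 0.99)


def finemap_with_annotations(
    z: np.ndarray,
    ld: LDMatrix,
    annotations: np.ndarray,
    names: list[str] | None = None,
    sigma2: float = 25.0,
    k_max: int = 1,
) -> tuple[FineMapResult, FineMapResult]:
    """Two-pass fine-mapping: flat prior, then annotation-informed prior."""
    flat = enumerate_posteriors(z, ld, sigma2=sigma2, k_max=k_max)
    ratios = annotation_enrichment(flat, annotations, names)
    prior = enriched_prior(flat.prior, annotations, ratios, names)
    informed = enumerate_posteriors(z, ld, prior=prior, sigma2=sigma2, k_max=k_max)
    informed.annotation_ratios = ratios
    return flat, informed


# ---------------------------------------------------------------------------
# composite prioritization filter
# ---------------------------------------------------------------------------


def prioritize_variants(
    gwas: list[SummaryStatRecord],
    ld: LDMatrix,
    elements: list[RegulatoryElement] | None = None,
    eqtls: list[QTLRecord] | None = None,
    motif_hits: dict[str, list[MotifHit]] | None = None,
    variant_annotations: dict[str, str] | None = None,
    finemap: FineMapResult | None = None,
    pip_threshold: float = 0.1,
    r2_tag: float = 0.8,
    distal_regulation: bool = False,
) -> pd.DataFrame:
    """Composite candidate-causal-variant filter for one locus.

    Steps: (1) restrict to variants in LD r^2 >= ``r2_tag`` with the locus tag
    (lead GWAS) variant; (2) if any candidate is coding per
    ``variant_annotations``, report the coding branch (with the residual
    conditional z of the tag after conditioning on it) and stop; (3) else
    require residence in an active enhancer (skipped for distal-regulation
    loci); (4) require a strong motif disruption/creation for an expressed TF;
    (5) require significant eQTL support (q <= 0.05); (6) require PIP >=
    ``pip_threshold`` when fine-mapping was run. Missing input layers skip
    their filter with a log line. Output ranked by PIP, then eQTL q.
    """
    by_id = {r.variant_id: r for r in gwas}
    tag = min(gwas, key=lambda r: (r.p, r.pos))
    tag_idx = ld.index_of(tag.variant_id)
    r2 = ld.r[tag_idx] ** 2
    candidates = [
        vid for vid in ld.variant_ids
        if vid in by_id and r2[ld.index_of(vid)] >= r2_tag
    ]

    rows = []

    def row(vid: str, branch: str, **extra) -> dict:
        rec = by_id[vid]
        return {
            "variant": vid, "pos": rec.pos, "gwas_p": rec.p,
            "r2_tag": float(r2[ld.index_of(vid)]), "branch": branch, **extra,
        }

    # coding branch
    if variant_annotations is None:
        logger.info("prioritize: no variant annotation table; coding screen skipped")
    else:
        coding = [v for v in candidates if variant_annotations.get(v) == "coding"]
        if coding:
            for vid in coding:
                resid = conditional_z(tag.z, tag.variant_id, {vid: by_id[vid].z}, ld) \
                    if vid != tag.variant_id else 0.0
                rows.append(row(vid, "coding", tag_conditional_z=resid))
            return pd.DataFrame(rows).sort_values("gwas_p").reset_index(drop=True)

    kept = list(candidates)

    if distal_regulation:
        logger.info("prioritize: locus flagged distal-regulation; enhancer filter skipped")
    elif elements is None:
        logger.info("prioritize: no chromatin states supplied; enhancer filter skipped")
    else:
        aes = [el.interval for el in elements if el.state == "AE"]
        kept = [
            v for v in kept
            if any(iv.contains_pos(by_id[v].chrom, by_id[v].pos) for iv in aes)
        ]

    if motif_hits is None:
        logger.info("prioritize: no motif results supplied; motif filter skipped")
    else:
        kept = [
            v for v in kept
            if any(h.effect == "strong" for h in motif_hits.get(v, []))
        ]

    eqtl_q: dict[str, float] = {}
    if eqtls is None:
        logger.info("prioritize: no eQTL table supplied; eQTL filter skipped")
    else:
        from .enhancer_gene_map import _ensure_q

        _ensure_q(eqtls)
        for q in eqtls:
            if q.fdr is not None and (q.stat.variant_id not in eqtl_q
                                      or q.fdr < eqtl_q[q.stat.variant_id]):
                eqtl_q[q.stat.variant_id] = q.fdr
        kept = [v for v in kept if eqtl_q.get(v, 1.0) <= 0.05]

    if finemap is None:
        logger.info("prioritize: no fine-mapping result supplied; PIP filter skipped")
    else:
        kept = [v for v in kept if finemap.pip_of(v) >= pip_threshold]

    for vid in kept:
        rows.append(
            row(
                vid, "regulatory",
                pip=np.nan if finemap is None else finemap.pip_of(vid),
                eqtl_q=eqtl_q.get(vid, np.nan),
            )
        )
    df = pd.DataFrame(
        rows, columns=["variant", "pos", "gwas_p", "r2_tag", "branch", "pip", "eqtl_q"]
    )
    if len(df):
        df = df.sort_values(
            ["pip", "eqtl_q"], ascending=[False, True], na_position="last"
        ).reset_index(drop=True)
    return df
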