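"""Bayesian colocalization of two association datasets via Wakefield ABFs.

For one variant with z-score z and standard error se, under a N(0, W) effect
prior with W = W_sd^2, the approximate Bayes factor against the null is

    log ABF = 0.5 * log(1 - r) + z^2 * r / 2,   r = W / (se^2 + W).

Assuming at most one causal variant per trait in the region, posterior
probabilities of the five hypotheses (H0 none, H1 trait-1 only, H2 trait-2
only, H3 two distinct variants, H4 one shared variant) follow from summing
per-variant ABFs over the causal configurations with priors p1, p2, p12.
All sums run in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core_io import SummaryStatRecord, harmonize_alleles

#: per-trait effect-sd priors (coloc defaults): quantitative traits 0.15 per SD,
#: case-control 0.2 on the log-odds scale
DEFAULT_W_SD = {"quant": 0.15, "cc": 0.2}


@dataclass
class ABFParams:
    """Effect-size prior for one trait."""

    w_sd: float = 0.15

    def __post_init__(self):
        if self.w_sd <= 0:
            raise ValueError("prior effect sd must be > 0")

    @property
    def w(self) -> float:
        return self.w_sd**2

    @classmethod
    def for_trait(cls, trait_type: str) -> "ABFParams":
        return cls(DEFAULT_W_SD[trait_type])


@dataclass
class ColocResult:
    priors: tuple[float, float, float]
    pp: dict[str, float]  # PP.H0 .. PP.H4
    log_bf1: np.ndarray
    log_bf2: np.ndarray
    variant_ids: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.log_bf1)

    @property
    def pp_h3_plus_h4(self) -> float:
        return self.pp["PP.H3"] + self.pp["PP.H4"]


def wakefield_log_abf(z: float, se: float, params: ABFParams) -> float:
    """Log approximate Bayes factor for a single variant."""
    if se <= 0:
        raise ValueError("se must be > 0")
    r = params.w / (se**2 + params.w)
    return 0.5 * np.log1p(-r) + (z**2) * r / 2


def coloc_posteriors(
    trait1: list[SummaryStatRecord],
    trait2: list[SummaryStatRecord],
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    trait1_type: str = "cc",
    trait2_type: str = "quant",
    harmonize: bool = True,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Records are intersected on variant_id; trait-2 records are allele-oriented
    onto trait 1 (drops, e.g. strand-ambiguous pairs, are excluded from the
    shared set). The magnitude of z is all that matters downstream, so
    orientation affects only which records survive harmonization.
    """
    t2_by_id = {r.variant_id: r for r in trait2}
    shared1, shared2 = [], []
    for r1 in trait1:
        r2 = t2_by_id.get(r1.variant_id)
        if r2 is None:
            continue
        if harmonize:
            r2h, _reason = harmonize_alleles(r1, r2)
            if r2h is None:
                continue
            r2 = r2h
        if not (np.isfinite(r1.z) and np.isfinite(r2.z)):
            continue
        shared1.append(r1)
        shared2.append(r2)
    if len(shared1) < 2:
        raise ValueError(f"need >= 2 shared SNPs, got {len(shared1)}")

    pars1 = ABFParams.for_trait(trait1_type)
    pars2 = ABFParams.for_trait(trait2_type)
    l1 = np.array([wakefield_log_abf(r.z, r.se, pars1) for r in shared1])
    l2 = np.array([wakefield_log_abf(r.z, r.se, pars2) for r in shared2])

    pp = posteriors_from_log_bfs(l1, l2, p1, p2, p12)
    return ColocResult(
        priors=(p1, p2, p12),
        pp=pp,
        log_bf1=l1,
        log_bf2=l2,
        variant_ids=[r.variant_id for r in shared1],
    )


def posteriors_from_log_bfs(
    log_bf1: np.ndarray,
    log_bf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> dict[str, float]:
    """Hypothesis posteriors from per-variant log Bayes factors (log-sum-exp)."""
    l1 = np.asarray(log_bf1, dtype=float)
    l2 = np.asarray(log_bf2, dtype=float)
    s1 = logsumexp(l1)  # log sum BF1_i
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)  # log sum BF1_i * BF2_i

    log_l = np.empty(5)
    log_l[0] = 0.0
    log_l[1] = np.log(p1) + s1
    log_l[2] = np.log(p2) + s2
    # sum_{i != j} BF1_i BF2_j = (sum BF1)(sum BF2) - sum BF1_i BF2_i
    d = s1 + s2 - s12
    if d <= 0:  # only possible at m=1 / degenerate cancellation
        log_l[3] = -np.inf
    else:
        log_l[3] = np.log(p1) + np.log(p2) + s12 + np.log(np.expm1(d))
    log_l[4] = np.log(p12) + s12

    denom = logsumexp(log_l)
    pp = np.exp(log_l - denom)
    return {f"PP.H{k}": float(pp[k]) for k in range(5)}


def select_qtl_regions(
    results: dict[str, ColocResult], threshold: float = 0.8
) -> list[str]:
    """Regions with evidence of independent or colocalized signals.

    Retains a region iff PP.H3 + PP.H4 >= threshold (the filter used to pick
    chromatin regions whose QTL signal overlaps the GWAS signal, whether
    shared or merely co-located).
    """
    return [rid for rid, res in results.items() if res.pp_h3_plus_h4 >= threshold]
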