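"""PWM-based motif disruption/creation scoring and allelic-imbalance testing.

Motif scores are sums of per-position log2 odds log2(p_base / bg_base). The
match p-value of a score is computed exactly under the background model by
dynamic programming over the discretized score distribution (1e-3 log-odds
bins), so it agrees bin-for-bin with brute-force enumeration over all 4^L
background sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

BASES = "ACGT"
SCORE_BIN = 1e-3  # log-odds discretization for the match-p DP

RC = str.maketrans("ACGT", "TGCA")

#: minimum reads on the variant per assay for allelic-imbalance inclusion
MIN_READS_DEFAULT = {"RNA": 10, "ATAC": 5}


def revcomp(seq: str) -> str:
    return seq.translate(RC)[::-1]


@dataclass
class PWM:
    """Position probability matrix (4 x L, rows A/C/G/T) with background."""

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix, pseudocount-smoothed."""
        p = (self.matrix + self.pseudocount) / (1 + 4 * self.pseudocount)
        return np.log2(p / self.background[:, None])

    @property
    def score_bins(self) -> np.ndarray:
        """log_odds discretized to integer SCORE_BIN units (the DP lattice)."""
        return np.round(self.log_odds / SCORE_BIN).astype(np.int64)

    @classmethod
    def from_counts(cls, tf_name: str, counts: np.ndarray, pseudocount: float = 0.8,
                    background: np.ndarray | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        prob = (counts + pseudocount / 4) / (counts.sum(axis=0) + pseudocount)
        kwargs = {} if background is None else {"background": background}
        return cls(tf_name, prob, **kwargs)


@dataclass
class MotifHit:
    tf_name: str
    strand: str
    offset: int  # 0-based window start in the supplied sequence
    ref_score: float
    alt_score: float
    score_delta: float  # alt - ref
    match_p_ref: float
    match_p_alt: float
    effect: str  # strong / weak / none
    change: str  # disruption / creation / neutral
    snp_position_in_motif: int  # 1-based


def _score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact background distribution of the discretized motif score.

    Returns (probabilities, bin offset of index 0). Probabilities index the
    score lattice: score_bin = index + offset.
    """
    bins = pwm.score_bins
    bg = pwm.background
    lo = int(bins.min(axis=0).sum())
    hi = int(bins.max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    # start before position 0: point mass at score 0, tracked via running range
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.length):
        col = bins[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        nxt = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(col[b]) - new_lo
            nxt[shift:shift + len(cur)] += bg[b] * cur
        cur, cur_lo = nxt, new_lo
    dist[cur_lo - lo: cur_lo - lo + len(cur)] = cur
    return dist, lo


def score_pvalue(pwm: PWM, score: float) -> float:
    """P(motif score >= score) for one background window (exact on the lattice)."""
    dist, lo = _score_distribution(pwm)
    b = int(np.round(score / SCORE_BIN))
    idx = b - lo
    if idx <= 0:
        return 1.0
    if idx >= len(dist):
        return 0.0
    return float(dist[idx:].sum())


def _window_scores(seq: str, pwm: PWM) -> list[tuple[float, int, str]]:
    """(score, offset, strand) for every clean ACGT window on both strands."""
    L = pwm.length
    lo = pwm.log_odds
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for off in range(n - L + 1):
            window = s[off:off + L]
            if any(c not in BASES for c in window):
                continue
            score = sum(lo[BASES.index(c), j] for j, c in enumerate(window))
            # report offsets on the forward strand
            fwd_off = off if strand == "+" else n - L - off
            out.append((score, fwd_off, strand))
    return out


def pwm_best_scores(sequence: str, pwm: PWM) -> tuple[float, int, str, float]:
    """Best log-odds score over all offsets and strands, with its match p.

    Returns (score, forward-strand offset, strand, match_p). The match p is
    the exact background tail probability of the best score for a single
    motif-length window (uniform backgrounds make it strand-symmetric).
    """
    sequence = sequence.upper()
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than motif")
    scored = _window_scores(sequence, pwm)
    if not scored:
        raise ValueError("no scorable window (non-ACGT characters throughout)")
    best = max(scored, key=lambda t: t[0])
    return best[0], best[1], best[2], score_pvalue(pwm, best[0])


def default_strong_delta(pwm: PWM) -> float:
    """Strong/weak boundary: 0.7 x mean per-position log-odds range."""
    lo = pwm.log_odds
    return 0.7 * float((lo.max(axis=0) - lo.min(axis=0)).mean())


def motif_break_effect(
    ref_allele: str,
    alt_allele: str,
    flank_left: str,
    flank_right: str,
    pwms: list[PWM],
    tf_tpm: dict[str, dict[str, float]] | None = None,
    p_threshold: float = 5e-5,
    tpm_min: float = 1.0,
    strong_delta: float | None = None,
) -> list[MotifHit]:
    """Score ref vs alt alleles against each expressed TF's motif.

    ``tf_tpm`` maps tf_name -> {cell_type: TPM}; a PWM is considered only if
    the TF reaches ``tpm_min`` in at least one cell type (absent TFs are
    skipped with a warning). A hit is reported iff the better allele's match
    p <= ``p_threshold``. Both alleles are scored on the same motif placement
    (the window/strand maximizing the better allele's score over windows
    covering the variant).
    """
    if ref_allele == alt_allele:
        return []
    hits: list[MotifHit] = []
    for pwm in pwms:
        if tf_tpm is not None:
            tpms = tf_tpm.get(pwm.tf_name)
            if tpms is None:
                logger.warning("TF %s absent from TPM table; skipped", pwm.tf_name)
                continue
            if max(tpms.values(), default=0.0) < tpm_min:
                continue
        L = pwm.length
        left = flank_left[-(L - 1):].upper() if L > 1 else ""
        right = flank_right[: L - 1].upper() if L > 1 else ""
        snp_idx = len(left)
        ref_seq = left + ref_allele.upper() + right
        alt_seq = left + alt_allele.upper() + right

        # every window of these trimmed sequences covers the variant
        ref_windows = {(off, strand): s for s, off, strand in _window_scores(ref_seq, pwm)}
        alt_windows = {(off, strand): s for s, off, strand in _window_scores(alt_seq, pwm)}
        common = set(ref_windows) & set(alt_windows)
        if not common:
            continue
        off, strand = max(common, key=lambda k: max(ref_windows[k], alt_windows[k]))
        ref_score, alt_score = ref_windows[(off, strand)], alt_windows[(off, strand)]
        p_ref = score_pvalue(pwm, ref_score)
        p_alt = score_pvalue(pwm, alt_score)
        if min(p_ref, p_alt) > p_threshold:
            continue
        delta = alt_score - ref_score
        cut = default_strong_delta(pwm) if strong_delta is None else strong_delta
        effect = "strong" if abs(delta) >= cut else "weak"
        if p_alt <= p_threshold < p_ref:
            change = "creation"
        elif p_ref <= p_threshold < p_alt:
            change = "disruption"
        else:
            change = "neutral"
        if strand == "+":
            motif_pos = snp_idx - off + 1
        else:
            motif_pos = off + L - snp_idx
        hits.append(
            MotifHit(
                tf_name=pwm.tf_name, strand=strand, offset=off,
                ref_score=ref_score, alt_score=alt_score, score_delta=delta,
                match_p_ref=p_ref, match_p_alt=p_alt, effect=effect,
                change=change, snp_position_in_motif=motif_pos,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# allelic imbalance
# ---------------------------------------------------------------------------


@dataclass
class AlleleCountRecord:
    individual: str
    variant_id: str
    ref_count: int
    alt_count: int
    chrom_total: int
    assay: str  # ATAC or RNA

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("counts must be >= 0")
        if self.chrom_total < self.ref_count + self.alt_count:
            raise ValueError("chrom_total must cover the variant's reads")
        if self.assay not in ("ATAC", "RNA"):
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass
class ASEResult:
    n: int
    mean_ref_norm: float
    mean_alt_norm: float
    t: float
    p: float
    direction: str


def allelic_imbalance_test(
    records: list[AlleleCountRecord],
    direction: str = "ref",
    min_reads: dict[str, int] | None = None,
) -> ASEResult:
    """Paired one-sided t-test of normalized allele counts across individuals.

    Individuals are kept when ref + alt reads reach the assay's minimum
    (RNA 10, ATAC 5 by default). Counts are normalized per individual to
    reads-per-million on the variant's chromosome. ``direction`` declares
    which allele is expected higher ('ref' or 'alt') before testing.
    """
    if direction not in ("ref", "alt"):
        raise ValueError("direction must be 'ref' or 'alt'")
    min_reads = MIN_READS_DEFAULT if min_reads is None else min_reads
    kept = [
        r for r in records
        if r.ref_count + r.alt_count >= min_reads[r.assay]
    ]
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} individuals pass the read filter; need >= 2")
    ref = np.array([r.ref_count / r.chrom_total * 1e6 for r in kept])
    alt = np.array([r.alt_count / r.chrom_total * 1e6 for r in kept])
    hi, lo = (ref, alt) if direction == "ref" else (alt, ref)
    diffs = hi - lo
    if np.allclose(diffs.std(), 0):
        if np.allclose(diffs, 0):
            t, p = 0.0, 0.5
        else:
            t = np.inf if diffs.mean() > 0 else -np.inf
            p = 0.0 if diffs.mean() > 0 else 1.0
    else:
        t, p = stats.ttest_rel(hi, lo, alternative="greater")
    return ASEResult(
        n=len(kept), mean_ref_norm=float(ref.mean()), mean_alt_norm=float(alt.mean()),
        t=float(t), p=float(p), direction=direction,
    )
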