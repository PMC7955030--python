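"""Shared domain types, file I/O, LD computation and small statistical utilities.

Coordinate conventions: intervals are 0-based half-open (BED native);
summary-statistic positions are 1-based and kept 1-based in
:class:`SummaryStatRecord` (they are point coordinates, compared against
intervals with the usual ``start <= pos-1 < end`` rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: column order of the tab-delimited summary-statistic exchange format
SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "FRQ"]


class ParseError(ValueError):
    """Raised when an input file line cannot be interpreted."""


class MonomorphicVariantError(ValueError):
    """Raised when a constant dosage column reaches LD computation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least one shared base (bedtools default semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos_1based: int) -> bool:
        return self.chrom == chrom and self.start <= pos_1based - 1 < self.end

    def expanded(self, flank: int) -> "GenomicInterval":
        return replace(self, start=max(0, self.start - flank), end=self.end + flank)


@dataclass
class SummaryStatRecord:
    """One variant's association evidence in one dataset.

    ``pos`` is 1-based. ``z`` is derived from beta/se when not supplied.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    n: float
    z: float | None = None
    eaf: float | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.variant_id}: p must be in (0,1], got {self.p}")
        if self.z is None:
            self.z = self.beta / self.se
        elif abs(self.z - self.beta / self.se) >= 1e-6:
            raise ValueError(
                f"{self.variant_id}: inconsistent z={self.z} vs beta/se={self.beta / self.se}"
            )
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf outside [0,1]")


@dataclass
class QTLRecord:
    """A summary-stat record tied to a molecular feature (gene or peak)."""

    stat: SummaryStatRecord
    feature_id: str
    feature_type: str = "expression"  # or "chromatin"
    cell_type: str = "monocyte"
    fdr: float | None = None

    def __post_init__(self):
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")
        if self.feature_type not in ("expression", "chromatin"):
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.fdr is not None and not (0 <= self.fdr <= 1):
            raise ValueError("fdr outside [0,1]")


@dataclass
class InteractionRecord:
    """A promoter-capture Hi-C bait(gene) <-> other-end pair."""

    bait: GenomicInterval
    other_end: GenomicInterval
    bait_gene: str
    score: float
    cell_type: str = "monocyte"

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("interaction score must be >= 0")


@dataclass
class LDMatrix:
    """Pairwise Pearson correlations of allele dosages for an ordered variant set."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("r must be square and match variant_ids")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def regularized(self, ridge: float = 1e-4) -> np.ndarray:
        """R with a small ridge on the diagonal, for downstream inversion."""
        return self.r + ridge * np.eye(len(self.variant_ids))

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


@dataclass
class GenotypePanel:
    """Individuals x variants dosage matrix (values in [0, 2])."""

    sample_ids: list[str]
    variant_ids: list[str]
    positions: np.ndarray  # 1-based, parallel to variant_ids
    dosages: np.ndarray  # n_samples x n_variants
    chrom: str = "chr1"

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("dosage matrix dimensions inconsistent with ids")
        if len(self.positions) != m:
            raise ValueError("positions inconsistent with variants")


# ---------------------------------------------------------------------------
# BED / table I/O
# ---------------------------------------------------------------------------


def parse_bed_intervals(path: str | Path, flank: int = 0) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file into intervals, optionally flank-extended.

    Records with start >= end are rejected with a warning; malformed lines
    raise :class:`ParseError` naming the line number.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                warnings.warn(
                    f"{path}:{lineno}: rejected interval with start >= end "
                    f"({start} >= {end})"
                )
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            out.append(
                GenomicInterval(
                    chrom, max(0, start - flank), end + flank, strand, name, score
                )
            )
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else format(iv.score, ".6g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_sumstats(path: str | Path) -> list[SummaryStatRecord]:
    """Read a tab-delimited summary-statistic table (SNP CHR BP A1 A2 BETA SE P N [FRQ])."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTAT_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        eaf = getattr(row, "FRQ", None)
        if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
            eaf = None
        records.append(
            SummaryStatRecord(
                variant_id=str(row.SNP),
                chrom=str(row.CHR),
                pos=int(row.BP),
                effect_allele=str(row.A1),
                other_allele=str(row.A2),
                beta=float(row.BETA),
                se=float(row.SE),
                p=float(row.P),
                n=float(row.N),
                eaf=None if eaf is None else float(eaf),
            )
        )
    return records


def sumstats_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": [r.variant_id for r in records],
            "CHR": [r.chrom for r in records],
            "BP": [r.pos for r in records],
            "A1": [r.effect_allele for r in records],
            "A2": [r.other_allele for r in records],
            "BETA": [float(f"{r.beta:.6g}") for r in records],
            "SE": [float(f"{r.se:.6g}") for r in records],
            "P": [float(f"{r.p:.6g}") for r in records],
            "N": [r.n for r in records],
            "FRQ": [np.nan if r.eaf is None else float(f"{r.eaf:.6g}") for r in records],
        }
    )


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    sumstats_to_frame(records).to_csv(path, sep="\t", index=False)


def read_qtl_table(path: str | Path, feature_type: str = "expression",
                   cell_type: str = "monocyte") -> list[QTLRecord]:
    """QTL table = sumstat columns plus FEATURE (gene or peak id)."""
    df = pd.read_csv(path, sep="\t")
    if "FEATURE" not in df.columns:
        raise ParseError(f"{path}: QTL table requires a FEATURE column")
    out = []
    for row in df.itertuples(index=False):
        eaf = getattr(row, "FRQ", None)
        if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
            eaf = None
        stat = SummaryStatRecord(
            variant_id=str(row.SNP), chrom=str(row.CHR), pos=int(row.BP),
            effect_allele=str(row.A1), other_allele=str(row.A2),
            beta=float(row.BETA), se=float(row.SE), p=float(row.P),
            n=float(row.N), eaf=None if eaf is None else float(eaf),
        )
        out.append(QTLRecord(stat, feature_id=str(row.FEATURE),
                             feature_type=feature_type, cell_type=cell_type))
    return out


def write_qtl_table(records: Sequence[QTLRecord], path: str | Path) -> None:
    df = sumstats_to_frame([q.stat for q in records])
    df.insert(0, "FEATURE", [q.feature_id for q in records])
    df.to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path, cell_type: str = "monocyte") -> list[InteractionRecord]:
    """BEDPE-like file: chrom1 start1 end1 chrom2 start2 end2 gene score."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ParseError(f"{path}:{lineno}: expected 8 BEDPE-like columns")
            bait = GenomicInterval(f[0], int(f[1]), int(f[2]))
            other = GenomicInterval(f[3], int(f[4]), int(f[5]))
            out.append(InteractionRecord(bait, other, f[6], float(f[7]), cell_type))
    return out


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.bait.chrom}\t{r.bait.start}\t{r.bait.end}"
                f"\t{r.other_end.chrom}\t{r.other_end.start}\t{r.other_end.end}"
                f"\t{r.bait_gene}\t{format(r.score, '.6g')}\n"
            )


def read_panel(path: str | Path) -> GenotypePanel:
    """Plain dosage table: first columns SNP, CHR, BP; remaining columns = samples."""
    df = pd.read_csv(path, sep="\t")
    meta = ["SNP", "CHR", "BP"]
    samples = [c for c in df.columns if c not in meta]
    return GenotypePanel(
        sample_ids=samples,
        variant_ids=[str(v) for v in df["SNP"]],
        positions=df["BP"].to_numpy(),
        dosages=df[samples].to_numpy(dtype=float).T,
        chrom=str(df["CHR"].iloc[0]),
    )


def write_panel(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.dosages.T, columns=panel.sample_ids)
    df.insert(0, "BP", panel.positions)
    df.insert(0, "CHR", panel.chrom)
    df.insert(0, "SNP", panel.variant_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize_alleles(
    a: SummaryStatRecord, b: SummaryStatRecord
) -> tuple[SummaryStatRecord | None, str]:
    """Orient record ``b`` onto record ``a``'s effect/other alleles.

    Returns ``(harmonized_b, reason)``; ``harmonized_b`` is None when the pair
    must be dropped, with ``reason`` one of ``ambiguous_palindromic`` or
    ``irreconcilable``. Strand-ambiguous (A/T, C/G) pairs are kept only when
    both allele frequencies are informative (< 0.4 or > 0.6) and concordant
    after orientation.
    """
    ea_a, oa_a = a.effect_allele.upper(), a.other_allele.upper()
    ea_b, oa_b = b.effect_allele.upper(), b.other_allele.upper()

    def flipped(rec: SummaryStatRecord) -> SummaryStatRecord:
        return replace(
            rec,
            effect_allele=ea_a,
            other_allele=oa_a,
            beta=-rec.beta,
            z=None if rec.z is None else -rec.z,
            eaf=None if rec.eaf is None else 1 - rec.eaf,
        )

    def relabelled(rec: SummaryStatRecord) -> SummaryStatRecord:
        return replace(rec, effect_allele=ea_a, other_allele=oa_a)

    if _is_palindromic(ea_a, oa_a) or _is_palindromic(ea_b, oa_b):
        if {ea_a, oa_a} != {ea_b, oa_b}:
            return None, "irreconcilable"
        if a.eaf is None or b.eaf is None:
            return None, "ambiguous_palindromic"

        def informative(f: float) -> bool:
            return f < 0.4 or f > 0.6

        if not (informative(a.eaf) and informative(b.eaf)):
            return None, "ambiguous_palindromic"
        same_labels = ea_b == ea_a
        eaf_b = b.eaf if same_labels else 1 - b.eaf
        if (a.eaf < 0.5) == (eaf_b < 0.5):
            return (relabelled(b) if same_labels else flipped(b)), "ok"
        # frequencies disagree: the labels are strand-swapped relative to a
        return (flipped(b) if same_labels else relabelled(b)), "ok"

    if (ea_b, oa_b) == (ea_a, oa_a):
        return b, "ok"
    if (ea_b, oa_b) == (oa_a, ea_a):
        return flipped(b), "ok"
    cb = (COMPLEMENT.get(ea_b, "?"), COMPLEMENT.get(oa_b, "?"))
    if cb == (ea_a, oa_a):
        return relabelled(b), "ok"
    if cb == (oa_a, ea_a):
        return flipped(b), "ok"
    return None, "irreconcilable"


# ---------------------------------------------------------------------------
# LD, FDR, LD blocks
# ---------------------------------------------------------------------------


def compute_ld_matrix(
    panel: GenotypePanel, variant_ids: Sequence[str] | None = None
) -> LDMatrix:
    """Pearson correlation of dosages; monomorphic variants are an error."""
    if panel.dosages.shape[0] < 2:
        raise ValueError("LD computation requires >= 2 individuals")
    ids = list(variant_ids) if variant_ids is not None else list(panel.variant_ids)
    idx = [panel.variant_ids.index(v) for v in ids]
    X = panel.dosages[:, idx]
    sd = X.std(axis=0)
    mono = [ids[j] for j in range(len(ids)) if sd[j] == 0]
    if mono:
        raise MonomorphicVariantError(f"monomorphic variants: {mono}")
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(ids, np.clip(r, -1.0, 1.0))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_ld_blocks(ld: LDMatrix, r2_cut: float = 0.5) -> np.ndarray:
    """Greedy position-ordered LD-block assignment.

    Walk variants in order; extend the current block while the next variant
    has r^2 >= r2_cut with the block's seed (first) variant, else start a new
    block. A coarse stand-in for clique-based haplotype blocking: blocks are
    used only to delimit candidate variant sets.
    """
    m = len(ld.variant_ids)
    blocks = np.zeros(m, dtype=int)
    if m == 0:
        return blocks
    block, seed = 0, 0
    for j in range(1, m):
        if ld.r[seed, j] ** 2 >= r2_cut:
            blocks[j] = block
        else:
            block += 1
            seed = j
            blocks[j] = block
    return blocks
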