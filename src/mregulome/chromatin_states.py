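"""Chromatin-state classification of H3K4 peaks.

Rule table (per-peak, one state each):

========  ============  ==========  ======
position  mark          H3K27ac     state
========  ============  ==========  ======
proximal  H3K4me2/3     yes         AP (active promoter)
proximal  H3K4me2/3     no          PP (primed promoter)
distal    H3K4me1/2     yes         AE (active enhancer)
distal    H3K4me1/2     no          PE (primed enhancer)
========  ============  ==========  ======

"Proximal" means >= 1 bp overlap with a strand-oriented TSS window
[TSS-500, TSS+1000] (mirrored on the minus strand). Proximal H3K4me1 peaks
cannot become promoters; they are reported as PE with ``proximal=True`` so
downstream enhancer analyses can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .core_io import GenomicInterval

VALID_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3")
PROMOTER_MARKS = ("H3K4me2", "H3K4me3")
ENHANCER_MARKS = ("H3K4me1", "H3K4me2")

TSS_WINDOW = (-500, 1000)


@dataclass
class RegulatoryElement:
    """A classified H3K4 peak."""

    interval: GenomicInterval
    state: str  # AE / AP / PE / PP
    source_mark: str
    k27ac_overlap: bool
    tss_distance: int  # signed, strand-aware bp to the nearest TSS
    proximal: bool
    cell_type: str = "monocyte"


def tss_window(tss: GenomicInterval, window: tuple[int, int] = TSS_WINDOW) -> GenomicInterval:
    """Strand-oriented promoter window around a TSS (coordinates mirrored on '-')."""
    lo, hi = window
    t = tss.start  # TSS point, 0-based
    if tss.strand == "-":
        start, end = t - hi, t - lo + 1
    else:
        start, end = t + lo, t + hi + 1
    return GenomicInterval(tss.chrom, max(0, start), end, strand=tss.strand, name=tss.name)


def _tree(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    by_chrom: dict[str, IntervalTree] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return by_chrom

def _any_overlap(trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    t = trees.get(iv.chrom)
    return bool(t is not None and t.overlap(iv.start, iv.end))


def _signed_tss_distance(peak: GenomicInterval, tss_list: list[GenomicInterval]) -> int:
    """Distance from peak midpoint to nearest TSS, signed downstream-positive."""
    mid = (peak.start + peak.end) // 2
    best, best_abs = 0, None
    for tss in tss_list:
        if tss.chrom != peak.chrom:
            continue
        d = mid - tss.start
        if tss.strand == "-":
            d = -d
        if best_abs is None or abs(d) < best_abs:
            best, best_abs = d, abs(d)
    return best


def classify_elements(
    h3k4_peaks: dict[str, list[GenomicInterval]],
    h3k27ac_peaks: list[GenomicInterval],
    tss_table: list[GenomicInterval],
    window: tuple[int, int] = TSS_WINDOW,
    cell_type: str = "monocyte",
) -> list[RegulatoryElement]:
    """Classify every H3K4 peak into exactly one of AE/AP/PE/PP."""
    for mark in h3k4_peaks:
        if mark not in VALID_MARKS:
            raise ValueError(f"unknown H3K4 mark {mark!r}; expected one of {VALID_MARKS}")
    windows = _tree([tss_window(t, window) for t in tss_table])
    k27 = _tree(h3k27ac_peaks)

    elements: list[RegulatoryElement] = []
    for mark, peaks in h3k4_peaks.items():
        for peak in peaks:
            proximal = _any_overlap(windows, peak)
            active = _any_overlap(k27, peak)
            if proximal and mark in PROMOTER_MARKS:
                state = "AP" if active else "PP"
            else:
                # distal peaks, and proximal H3K4me1 (cannot become a promoter)
                state = "AE" if active else "PE"
            if proximal and mark == "H3K4me1":
                state = "PE"  # flagged proximal; excluded from enhancer flank work
            elements.append(
                RegulatoryElement(
                    interval=peak,
                    state=state,
                    source_mark=mark,
                    k27ac_overlap=active,
                    tss_distance=_signed_tss_distance(peak, tss_table),
                    proximal=proximal,
                    cell_type=cell_type,
                )
            )
    return elements


def count_states(
    elements: list[RegulatoryElement], merge: bool = False
) -> dict[str, dict[str, int]]:
    """Per-cell-type, per-state tabulation; states partition the input.

    With ``merge``, elements sharing (interval, state) within a cell type —
    the same region emitted under both H3K4me1 and H3K4me2 — count once.
    """
    out: dict[str, dict[str, int]] = {}
    seen: set[tuple] = set()
    for el in elements:
        if merge:
            key = (el.cell_type, el.interval.chrom, el.interval.start,
                   el.interval.end, el.state)
            if key in seen:
                continue
            seen.add(key)
        cell = out.setdefault(el.cell_type, {"AE": 0, "AP": 0, "PE": 0, "PP": 0})
        cell[el.state] += 1
    return out
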