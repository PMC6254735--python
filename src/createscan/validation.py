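"""Genomic-edit validation from amplicon sequencing of targeted windows.

For each sequenced genomic window, a database of expected sequences is
enumerated — the wild-type window plus, for every design whose edit falls
inside it, the window with that design's codon edit and PAM-kill applied.
Trimmed merged reads are matched at 100% identity.  Two summary numbers
follow the deep-sequencing bookkeeping of the experiment:

    fraction covered = 100 * (distinct designs observed) / (designs in window)
    Eff = (edit reads / total reads) / (w / library size), as a percent

where Eff estimates the per-locus editing efficiency by normalizing the
edited-read fraction by the window's share w/library_size of the library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .design import ARM_LEFT, Cassette

WT_KEY = "WT"
DEFAULT_LIBRARY_SIZE = 16300


@dataclass
class GenomicWindow:
    """One sequenced genomic region (1-based inclusive coordinates,
    primer binding sites excluded) and its expected-variant database."""

    gene_id: str
    start: int
    end: int
    wt_seq: str
    expected_variants: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.wt_seq) != self.end - self.start + 1:
            raise ValueError("wt_seq length does not match window coordinates")

    @property
    def w(self) -> int:
        """Number of designs whose edits fall in this window."""
        return len(self.expected_variants)


def enumerate_expected(
    gene_id: str,
    genome: str,
    start: int,
    end: int,
    cassettes: Sequence[Cassette],
) -> GenomicWindow:
    """Build the expected-variant database for a window.

    ``start``/``end`` are 1-based inclusive genome coordinates.  Every
    cassette's codon edit and PAM-kill must lie inside the window; each
    design contributes one full-window sequence, all of which must be
    unique and differ from wild type.
    """
    lo, hi = start - 1, end  # 0-based half-open
    wt = genome[lo:hi]
    variants: dict[str, str] = {}
    for cas in sorted(cassettes, key=lambda c: c.design.design_id):
        design = cas.design
        codon_pos = cas.arm_start + ARM_LEFT
        if not (lo <= codon_pos and codon_pos + 3 <= hi):
            raise ValueError(
                f"design {design.design_id} codon edit outside window"
            )
        if not (lo <= cas.pam_kill.pos < hi):
            raise ValueError(
                f"design {design.design_id} PAM kill outside window"
            )
        seq = wt[: codon_pos - lo] + design.target_codon + wt[codon_pos - lo + 3 :]
        seq = cas.pam_kill.apply(seq, offset=lo)
        if seq == wt:
            raise ValueError(f"design {design.design_id} identical to wild type")
        variants[design.design_id] = seq
    if len(set(variants.values())) != len(variants):
        raise ValueError("ambiguous variant database")
    return GenomicWindow(
        gene_id=gene_id, start=start, end=end, wt_seq=wt,
        expected_variants=variants,
    )


def match_window_reads(
    reads: Iterable[str], window: GenomicWindow
) -> tuple[dict[str, int], int]:
    """Exact-match trimmed reads against the variant database.

    Returns (per-variant counts keyed by design_id plus ``'WT'``, total
    reads considered).  Reads of the wrong length are skipped with a
    warning; reads matching nothing count toward the total only.
    """
    lookup = {seq: d for d, seq in window.expected_variants.items()}
    lookup[window.wt_seq] = WT_KEY
    counts = {d: 0 for d in window.expected_variants}
    counts[WT_KEY] = 0
    total = 0
    skipped = 0
    for read in reads:
        read = read.upper()
        if len(read) != len(window.wt_seq):
            skipped += 1
            continue
        total += 1
        key = lookup.get(read)
        if key is not None:
            counts[key] += 1
    if skipped:
        warnings.warn(f"{skipped} read(s) of wrong length skipped")
    return counts, total


def fraction_covered(edits_observed: int, w: int) -> float:
    """Percent of a window's designed edits observed, one-decimal rounded."""
    if w <= 0:
        raise ValueError("window has no designed edits")
    if not (0 <= edits_observed <= w):
        raise ValueError("edits_observed out of range")
    return round(100.0 * edits_observed / w, 1)


def editing_efficiency(
    edit_reads: int,
    total_reads: int,
    w: int,
    library_size: int = DEFAULT_LIBRARY_SIZE,
) -> float:
    """Estimated editing efficiency Eff = (edits/total)/(w/library_size), %.

    Normalizes the edited-read fraction of a window by the fraction of the
    design library the window represents.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if w <= 0:
        raise ValueError("window has no designed edits")
    if w > library_size:
        raise ValueError("window larger than library")
    return 100.0 * (edit_reads / total_reads) / (w / library_size)


@dataclass(frozen=True)
class EditObservation:
    """Summary of one window's amplicon sequencing."""

    gene_id: str
    w: int
    edits_observed: int
    edit_reads: int
    total_reads: int
    fraction_covered: float
    eff: float


def observe_window(
    window: GenomicWindow,
    reads: Iterable[str],
    library_size: int = DEFAULT_LIBRARY_SIZE,
) -> EditObservation:
    """Match reads and compute coverage/efficiency for one window.

    A design counts as observed with >= 1 exact-match read (no read-count
    floor is applied).
    """
    counts, total = match_window_reads(reads, window)
    edit_reads = sum(c for d, c in counts.items() if d != WT_KEY)
    observed = sum(1 for d, c in counts.items() if d != WT_KEY and c > 0)
    return EditObservation(
        gene_id=window.gene_id,
        w=window.w,
        edits_observed=observed,
        edit_reads=edit_reads,
        total_reads=total,
        fraction_covered=fraction_covered(observed, window.w),
        eff=round(editing_efficiency(edit_reads, total, window.w, library_size), 1),
    )
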