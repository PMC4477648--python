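"""Long-loop extraction, the stem-loop screen, and SLQS classification.

A long-loop candidate hit becomes an SLQS only if *every* loop longer than
the short-loop cutoff (7 nt) folds into a stable duplex stem-loop covering at
least half of the loop in base pairs.  Before folding, each long loop is
extended on both sides with the guanines in excess of three from its two
flanking G-tracts (a flanking tract of G5 contributes 2 G's), so screened
sequences range from 8 to 26 nt under the default scan parameters.  The
pair-fraction denominator is the extended loop length, i.e. the sequence the
screen actually folds.

Rejected candidates are kept with their failing loop and reasons so that a
scan output is a complete audit trail: every PQS hit is exactly one of
PQS_L7, SLQS or rejected candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .folding import (
    DEFAULT_FOLD_PARAMS,
    FoldParams,
    StemLoopPrediction,
    fold_stem_loop,
    passes_screen,
)
from .scanner import (
    DEFAULT_SCAN_PARAMS,
    LONG_LOOP_CANDIDATE,
    PQS_L7,
    PQSHit,
    ScanParams,
    revcomp,
)

__all__ = [
    "LoopRecord",
    "SLQSRecord",
    "Rejection",
    "extract_long_loops",
    "classify_slqs",
    "classify_hits",
    "stemloop_length_distribution",
    "SLQS",
    "REJECTED",
]

SLQS = "SLQS"
REJECTED = "REJECTED"

#: per-side cap on flanking-G extension (a tract is at most max_tract = 6 G,
#: i.e. at most 3 G in excess of three)
_MAX_EXT = 3


@dataclass(frozen=True)
class LoopRecord:
    """One extracted long loop with its flanking-G extension."""

    loop_index: int  # 1..3
    raw_seq: str  # inter-tract gap, 5'->3' on the hit strand
    ext5: int
    ext3: int

    @property
    def raw_len(self) -> int:
        return len(self.raw_seq)

    @property
    def ext_seq(self) -> str:
        return "G" * self.ext5 + self.raw_seq + "G" * self.ext3

    @property
    def ext_len(self) -> int:
        return self.raw_len + self.ext5 + self.ext3


@dataclass(frozen=True)
class SLQSRecord:
    """A long-loop candidate whose every long loop passed the screen."""

    hit: PQSHit
    loops: tuple[LoopRecord, ...]
    predictions: tuple[StemLoopPrediction, ...]

    @property
    def n_stemloops(self) -> int:
        return len(self.loops)

    @property
    def dot_brackets(self) -> tuple[str, ...]:
        return tuple(p.dot_bracket for p in self.predictions)

    @property
    def min_dG37(self) -> float:
        return min(p.dG37 for p in self.predictions)


@dataclass(frozen=True)
class Rejection:
    """A long-loop candidate that failed the screen, with the first failing loop."""

    hit: PQSHit
    loop_index: int
    reasons: tuple[str, ...]


def _extension(tract_len: int) -> int:
    return min(max(tract_len - 3, 0), _MAX_EXT)


def extract_long_loops(
    hit: PQSHit, record, params: ScanParams | None = None
) -> list[LoopRecord]:
    """LoopRecords for every loop of `hit` longer than the short-loop cutoff.

    Loop sequences are read 5'->3' on the hit's own strand; the extension
    guanines come from the placed flanking tracts (min(tract length - 3, 3)
    per side).
    """
    params = params or DEFAULT_SCAN_PARAMS
    out = []
    minus = hit.strand == "-"
    for idx in range(3):
        if hit.loop_lengths[idx] <= params.short_loop_cutoff:
            continue
        a, b = hit.loops[idx]
        raw = record.seq[a:b]
        if minus:
            raw = revcomp(raw)
        t5 = hit.tracts[idx]
        t3 = hit.tracts[idx + 1]
        out.append(
            LoopRecord(
                loop_index=idx + 1,
                raw_seq=raw,
                ext5=_extension(t5[1] - t5[0]),
                ext3=_extension(t3[1] - t3[0]),
            )
        )
    return out


def classify_slqs(
    hit: PQSHit,
    record,
    fold_params: FoldParams | None = None,
    scan_params: ScanParams | None = None,
    cache: dict | None = None,
) -> SLQSRecord | Rejection:
    """Apply the stem-loop screen to a long-loop candidate.

    Returns an :class:`SLQSRecord` iff every long loop passes, otherwise a
    :class:`Rejection` carrying the first failing loop and its reasons.
    `cache` (extended sequence -> prediction) may be shared across calls.
    """
    if hit.class_label != LONG_LOOP_CANDIDATE:
        raise ValueError("classify_slqs expects a LONG_LOOP_CANDIDATE hit")
    fold_params = fold_params or DEFAULT_FOLD_PARAMS
    loops = extract_long_loops(hit, record, scan_params)
    preds = []
    for loop in loops:
        if cache is not None and loop.ext_seq in cache:
            pred = cache[loop.ext_seq]
        else:
            pred = fold_stem_loop(loop.ext_seq, fold_params)
            if cache is not None:
                cache[loop.ext_seq] = pred
        verdict = passes_screen(pred, fold_params)
        if not verdict.passed:
            return Rejection(hit=hit, loop_index=loop.loop_index, reasons=verdict.reasons)
        preds.append(pred)
    return SLQSRecord(hit=hit, loops=tuple(loops), predictions=tuple(preds))


def classify_hits(
    hits,
    record,
    fold_params: FoldParams | None = None,
    scan_params: ScanParams | None = None,
):
    """Partition scan hits into (pqs7, slqs, rejected).

    Every input hit lands in exactly one of the three lists; a shared fold
    cache makes overlapping candidates cheap.
    """
    cache: dict = {}
    pqs7, slqs, rejected = [], [], []
    for hit in hits:
        if hit.class_label == PQS_L7:
            pqs7.append(hit)
            continue
        res = classify_slqs(hit, record, fold_params, scan_params, cache)
        (slqs if isinstance(res, SLQSRecord) else rejected).append(res)
    return pqs7, slqs, rejected


def stemloop_length_distribution(slqs_records, max_len: int = 26):
    """Histogram of stem-loop (extended loop) lengths over all SLQS stem-loops.

    Returns (lengths, counts, cumulative_fraction) for lengths 8..max_len.
    The cumulative fraction is over the counted range and ends at 1 whenever
    any stem-loop falls inside it.
    """
    if max_len < 8:
        raise ValueError("max_len must be >= 8")
    lengths = np.arange(8, max_len + 1)
    counts = np.zeros(lengths.size, dtype=int)
    for rec in slqs_records:
        for loop in rec.loops:
            if 8 <= loop.ext_len <= max_len:
                counts[loop.ext_len - 8] += 1
    total = counts.sum()
    cum = np.cumsum(counts) / total if total else np.zeros(lengths.size)
    return lengths, counts, cum
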