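"""Enumeration of putative quadruplex sequences (PQS) on both strands.

The grammar is G_3-6 N_1-20 G_3-6 N_1-20 G_3-6 N_1-20 G_3-6: four G-tracts of
3-6 consecutive guanines separated by three loops of 1-20 nt, loops inclusive
of guanines.  Hits whose loops are all <= 7 nt are sub-classified PQS_L7; the
rest are long-loop candidates handed to the stem-loop screen.

Tract placement: :func:`find_g_runs` reports *maximal* runs of G (runs longer
than ``max_tract`` are flagged), and :func:`enumerate_pqs` then enumerates
every admissible tract placement of ``min_tract``..``max_tract`` consecutive
guanines within those runs.  Guanines of a run not covered by the chosen
tract fall into the adjacent loop, and two tracts may come from one long run.
Hits are therefore permitted to overlap and may share up to three identical
G-tracts; a connected component of tract-sharing hits forms one cluster (see
:mod:`slqscan.annotation`).

Coordinates are 0-based half-open on the forward reference throughout; minus
strand hits are found on the reverse complement and mapped back, with tracts
and loops listed in the motif's own 5'->3' order.
"""

from __future__ import annotations

import bisect
import re
import warnings
from dataclasses import dataclass

__all__ = [
    "ScanParams",
    "GRun",
    "PQSHit",
    "HitList",
    "find_g_runs",
    "enumerate_pqs",
    "scan_both_strands",
    "make_id",
    "chromosome_code",
    "revcomp",
    "PQS_L7",
    "LONG_LOOP_CANDIDATE",
]

PQS_L7 = "PQS_L7"
LONG_LOOP_CANDIDATE = "LONG_LOOP_CANDIDATE"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScanParams:
    min_tract: int = 3
    max_tract: int = 6
    min_loop: int = 1
    max_loop: int = 20
    short_loop_cutoff: int = 7
    max_quadruples_per_window: int = 10_000
    window_size: int = 10_000

    def __post_init__(self) -> None:
        if not (1 <= self.min_loop <= self.max_loop):
            raise ValueError("need 1 <= min_loop <= max_loop")
        if self.min_tract < 3:
            raise ValueError("min_tract must be >= 3")
        if self.max_tract < self.min_tract:
            raise ValueError("max_tract must be >= min_tract")
        if not (self.short_loop_cutoff < self.max_loop):
            raise ValueError("short_loop_cutoff must be < max_loop")


DEFAULT_SCAN_PARAMS = ScanParams()


@dataclass(frozen=True)
class GRun:
    """A maximal run of >= min_tract guanines on one strand (forward coords)."""

    seq_name: str
    strand: str
    start: int
    end: int
    flagged: bool = False  # run longer than max_tract

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PQSHit:
    seq_name: str
    strand: str
    tracts: tuple[tuple[int, int], ...]  # forward coords, motif 5'->3' order
    loops: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, int, int]
    span: tuple[int, int]
    class_label: str
    id: str = ""

    @property
    def tract_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.tracts)

    def sequence(self, seq: str) -> str:
        """Hit sequence 5'->3' on its own strand."""
        sub = seq[self.span[0]: self.span[1]]
        return sub if self.strand == "+" else revcomp(sub)


class HitList(list):
    """List of PQSHit with a truncation flag for capped windows."""

    def __init__(self, hits=(), truncated_windows=()):  # noqa: D107
        super().__init__(hits)
        self.truncated_windows: set[int] = set(truncated_windows)

    @property
    def truncated(self) -> bool:
        return bool(self.truncated_windows)


def find_g_runs(record, strand: str = "+", params: ScanParams | None = None) -> list[GRun]:
    """Maximal runs of G on the given strand, in forward-coordinate order.

    On the minus strand, G-runs correspond to C-runs of the forward sequence.
    """
    params = params or DEFAULT_SCAN_PARAMS
    base = "G" if strand == "+" else "C"
    pat = re.compile(base + "{%d,}" % params.min_tract)
    runs = []
    for m in pat.finditer(record.seq):
        runs.append(
            GRun(
                seq_name=record.name,
                strand=strand,
                start=m.start(),
                end=m.end(),
                flagged=(m.end() - m.start()) > params.max_tract,
            )
        )
    return runs


def _placements(run_local: tuple[int, int], params: ScanParams) -> list[tuple[int, int]]:
    """All tract placements of min_tract..max_tract G within one maximal run."""
    s, e = run_local
    out = []
    for i in range(s, e - params.min_tract + 1):
        for j in range(i + params.min_tract, min(e, i + params.max_tract) + 1):
            out.append((i, j))
    return out


def _enumerate_local(
    seq: str,
    runs_local: list[tuple[int, int]],
    params: ScanParams,
) -> tuple[list[tuple[tuple[int, int], ...]], set[int]]:
    """Enumerate tract quadruples in local coordinates.

    Returns (list of 4-tuples of tract intervals, set of truncated windows).
    Quadruples are capped per window of the first tract's start position.
    """
    cands: list[tuple[int, int]] = []
    for run in runs_local:
        cands.extend(_placements(run, params))
    cands.sort()
    n = len(cands)
    starts = [c[0] for c in cands]  # successor lookup: candidates sorted by start

    quads: list[tuple[tuple[int, int], ...]] = []
    window_counts: dict[int, int] = {}
    truncated: set[int] = set()
    cap = params.max_quadruples_per_window
    wsize = params.window_size

    def successors(end: int):
        lo = bisect.bisect_left(starts, end + params.min_loop)
        hi = bisect.bisect_right(starts, end + params.max_loop)
        return range(lo, hi)

    for a in range(n):
        w = cands[a][0] // wsize
        if window_counts.get(w, 0) >= cap:
            truncated.add(w)
            continue
        full = False
        for b in successors(cands[a][1]):
            if full:
                break
            for c in successors(cands[b][1]):
                if full:
                    break
                for d in successors(cands[c][1]):
                    cnt = window_counts.get(w, 0)
                    if cnt >= cap:
                        truncated.add(w)
                        full = True
                        break
                    window_counts[w] = cnt + 1
                    quads.append((cands[a], cands[b], cands[c], cands[d]))
    return quads, truncated


def _hit_from_local(
    quad: tuple[tuple[int, int], ...],
    seq_local: str,
    seq_len: int,
    strand: str,
    seq_name: str,
    params: ScanParams,
) -> PQSHit | None:
    span_local = (quad[0][0], quad[3][1])
    sub = seq_local[span_local[0]: span_local[1]]
    if any(ch not in "ACGT" for ch in sub):
        return None
    loops_local = tuple((quad[i][1], quad[i + 1][0]) for i in range(3))
    loop_lengths = tuple(b - a for a, b in loops_local)
    label = PQS_L7 if max(loop_lengths) <= params.short_loop_cutoff else LONG_LOOP_CANDIDATE

    if strand == "+":
        tracts, loops, span = quad, loops_local, span_local
    else:
        conv = lambda iv: (seq_len - iv[1], seq_len - iv[0])  # noqa: E731
        tracts = tuple(conv(t) for t in quad)
        loops = tuple(conv(l) for l in loops_local)
        span = conv(span_local)
    return PQSHit(
        seq_name=seq_name,
        strand=strand,
        tracts=tracts,
        loops=loops,
        loop_lengths=loop_lengths,  # type: ignore[arg-type]
        span=span,
        class_label=label,
    )


def enumerate_pqs(runs: list[GRun], record, params: ScanParams | None = None) -> HitList:
    """All PQS hits for the maximal runs of one strand of one record.

    Output is sorted by (span start, span end, tract coordinates).  If the
    per-window quadruple cap is hit, surplus quadruples are dropped, the
    affected windows are recorded on ``HitList.truncated_windows`` and a
    warning is emitted (never silent).
    """
    params = params or DEFAULT_SCAN_PARAMS
    if not runs:
        return HitList()
    strand = runs[0].strand
    if any(r.strand != strand for r in runs):
        raise ValueError("enumerate_pqs expects runs from a single strand")
    seq_len = len(record.seq)
    if strand == "+":
        seq_local = record.seq
        runs_local = [(r.start, r.end) for r in runs]
    else:
        seq_local = revcomp(record.seq)
        runs_local = sorted((seq_len - r.end, seq_len - r.start) for r in runs)

    quads, truncated = _enumerate_local(seq_local, runs_local, params)
    hits = []
    for quad in quads:
        hit = _hit_from_local(quad, seq_local, seq_len, strand, record.name, params)
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (h.span, h.tracts))
    if truncated:
        warnings.warn(
            f"{record.name} ({strand}): quadruple cap of "
            f"{params.max_quadruples_per_window} reached in {len(truncated)} window(s); "
            "output truncated",
            stacklevel=2,
        )
    return HitList(hits, truncated)


def scan_both_strands(record, params: ScanParams | None = None) -> HitList:
    """Union of plus-strand hits and minus-strand hits mapped back to forward
    coordinates, sorted by (span start, span end, strand with '+' first)."""
    params = params or DEFAULT_SCAN_PARAMS
    plus = enumerate_pqs(find_g_runs(record, "+", params), record, params)
    minus = enumerate_pqs(find_g_runs(record, "-", params), record, params)
    merged = sorted(list(plus) + list(minus), key=lambda h: (h.span, h.strand, h.tracts))
    return HitList(merged, plus.truncated_windows | minus.truncated_windows)


_CHROM_CODES = {**{f"chr{i}": f"{i:02d}" for i in range(1, 23)},
                "chrX": "23", "chrY": "24", "chrM": "25"}


def chromosome_code(seq_name: str) -> str:
    """UCSC chromosome name -> 2-digit ID code (chr1-22 -> 01-22, X 23, Y 24, M 25)."""
    try:
        return _CHROM_CODES[seq_name]
    except KeyError:
        raise ValueError(f"no chromosome code for sequence name {seq_name!r}") from None


def make_id(hit: PQSHit | None, chrom_code: str, position: int) -> str:
    """Hit ID of the form G4ST + 2-digit chromosome code + 9-digit 1-based position.

    `position` is the 1-based start of the hit's first tract on the forward
    strand (pass ``hit.span[0] + 1``; `hit` itself is accepted for signature
    symmetry and may be None).
    """
    if not (len(chrom_code) == 2 and chrom_code.isdigit() and 1 <= int(chrom_code) <= 25):
        raise ValueError(f"chromosome code must be '01'..'25', got {chrom_code!r}")
    if not (1 <= position < 10**9):
        raise ValueError(f"position {position} out of range for a 9-digit ID")
    return f"G4ST{chrom_code}{position:09d}"
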