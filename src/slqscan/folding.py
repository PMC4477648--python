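"""Minimum-free-energy single stem-loop prediction for short DNA sequences.

This module predicts the most stable *single hairpin* a short DNA sequence can
form -- one helix, possibly interrupted by bulges and internal loops, closed
by one hairpin loop; no multibranch loops -- and scores it with the unified
DNA nearest-neighbor model at 37 degC (see :mod:`slqscan.nn`).  It also
implements the screen used to decide whether an extracted quadruplex long loop
harbours a duplex stem-loop: the structure must be stable (dG37 below a
threshold, default 0) and its paired bases must cover at least half of the
screened sequence.

A brute-force enumerator over all nested single-hairpin pairings
(:func:`brute_force_fold`) serves as an independent oracle for the
dynamic-programming search; both use the identical energy tables, so for
sequences short enough to enumerate they must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nn

__all__ = [
    "FoldParams",
    "StemLoopPrediction",
    "ScreenVerdict",
    "fold_stem_loop",
    "brute_force_fold",
    "passes_screen",
]

_OPEN_CENTS = 0  # free energy of the unfolded chain (reference state)


@dataclass(frozen=True)
class FoldParams:
    """Folding and screening parameters.

    temperature is fixed at 37 degC: the energy tables are dG37 tables and no
    dH/dS rescaling is performed.
    """

    temperature: float = 37.0
    allow_gt: bool = False  # admit G.T wobble pairs
    min_hairpin_loop: int = 3
    stability_threshold: float = 0.0  # pass requires dG37 strictly below this
    min_pair_fraction: float = 0.5  # paired-base fraction of the screened loop
    max_interior_loop: int = 30  # cap on total unpaired nt in a bulge/internal loop
    max_length: int = 110

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")

    def _key(self) -> tuple:
        return (self.allow_gt, self.min_hairpin_loop, self.max_interior_loop)


DEFAULT_FOLD_PARAMS = FoldParams()


@dataclass(frozen=True)
class StemLoopPrediction:
    """A predicted (possibly empty) single stem-loop structure."""

    seq: str
    pairs: tuple[tuple[int, int], ...]  # 0-based (i, j), i < j, outermost first
    dG37: float  # kcal/mol; 0.0 for the open chain
    dot_bracket: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_fraction(self) -> float:
        return 2.0 * self.n_pairs / len(self.seq) if self.seq else 0.0

    @property
    def stable(self) -> bool:
        return self.dG37 < 0.0


@dataclass(frozen=True)
class ScreenVerdict:
    passed: bool
    reasons: tuple[str, ...] = field(default=())


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return seq


def _candidate_pairs(seq: str, params: FoldParams) -> list[tuple[int, int]]:
    n = len(seq)
    out = []
    for i in range(n):
        for j in range(i + params.min_hairpin_loop + 1, n):
            if nn.pair_allowed(seq[i], seq[j], params.allow_gt):
                out.append((i, j))
    return out


def _loop_cents(seq: str, outer: tuple[int, int], inner: tuple[int, int]) -> int:
    """Energy of the loop closed by `outer` with `inner` as its only branch."""
    i, j = outer
    k, l = inner
    n1 = k - i - 1
    n2 = j - l - 1
    if n1 == 0 and n2 == 0:
        return nn.stack_cents(seq, i, k, j, l)
    if n1 == 0 or n2 == 0:
        size = n1 + n2
        e = nn.bulge_cents(size)
        if size == 1:
            # single-nt bulges retain the stack across the bulge
            e += nn.stack_cents(seq, i, k, j, l)
        return e
    return nn.internal_cents(n1, n2)


def _terminal_cents(seq: str, pair: tuple[int, int]) -> int:
    d = seq[pair[0]] + seq[pair[1]]
    return nn.TERMINAL_AT_CENTS if d in ("AT", "TA") else 0


def _open_chain(seq: str) -> StemLoopPrediction:
    return StemLoopPrediction(seq=seq, pairs=(), dG37=0.0, dot_bracket="." * len(seq))


def _to_prediction(seq: str, cents: int, pairs: tuple[tuple[int, int], ...]) -> StemLoopPrediction:
    db = ["."] * len(seq)
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return StemLoopPrediction(seq=seq, pairs=pairs, dG37=cents / 100.0, dot_bracket="".join(db))


def fold_stem_loop(seq: str, params: FoldParams | None = None) -> StemLoopPrediction:
    """MFE single-hairpin structure of `seq`, or the open chain if nothing folds.

    Ties are broken deterministically: lower energy, then more base pairs,
    then the lexicographically smallest pair set.
    """
    params = params or DEFAULT_FOLD_PARAMS
    seq = _validate_seq(seq)
    if len(seq) > params.max_length:
        raise ValueError(f"sequence of {len(seq)} nt exceeds max_length={params.max_length}")
    if len(seq) < params.min_hairpin_loop + 2:
        return _open_chain(seq)

    cands = _candidate_pairs(seq, params)
    if not cands:
        return _open_chain(seq)
    # best structure closed by each candidate pair, keyed for tie-breaking:
    # (energy_cents, -n_pairs, pairs_tuple)
    best: dict[tuple[int, int], tuple[int, int, tuple[tuple[int, int], ...]]] = {}
    cap = params.max_interior_loop
    for outer in sorted(cands, key=lambda p: p[1] - p[0]):
        i, j = outer
        entry = (nn.hairpin_cents(j - i - 1), -1, (outer,))
        for inner in cands:
            k, l = inner
            if not (i < k and l < j and (k, l) != (i, j)):
                continue
            if (k - i - 1) + (j - l - 1) > cap:
                continue
            sub = best.get(inner)
            if sub is None:
                continue
            cand = (_loop_cents(seq, outer, inner) + sub[0], sub[1] - 1, (outer,) + sub[2])
            if cand < entry:
                entry = cand
        best[outer] = entry

    overall = (_OPEN_CENTS, 0, ())
    for outer, (cents, negn, pairs) in best.items():
        total = (cents + _terminal_cents(seq, outer), negn, pairs)
        if total < overall:
            overall = total
    if overall[0] >= _OPEN_CENTS:
        return _open_chain(seq)
    return _to_prediction(seq, overall[0], overall[2])


_BRUTE_MAX = 15


def brute_force_fold(seq: str, params: FoldParams | None = None) -> StemLoopPrediction:
    """Exhaustive enumeration of every nested single-hairpin pairing.

    Refuses sequences longer than 15 nt (combinatorial guard).  Uses the same
    energy function as :func:`fold_stem_loop`, so agreement must be exact.
    """
    params = params or DEFAULT_FOLD_PARAMS
    seq = _validate_seq(seq)
    if len(seq) > _BRUTE_MAX:
        raise ValueError(f"brute_force_fold refuses sequences longer than {_BRUTE_MAX} nt")
    cands = _candidate_pairs(seq, params)
    cap = params.max_interior_loop

    overall = [(_OPEN_CENTS, 0, ())]

    def extend(chain: list[tuple[int, int]], cents: int) -> None:
        outer = chain[-1]
        total = cents + nn.hairpin_cents(outer[1] - outer[0] - 1) + _terminal_cents(seq, chain[0])
        overall.append((total, -len(chain), tuple(chain)))
        i, j = outer
        for inner in cands:
            k, l = inner
            if i < k and l < j and (k - i - 1) + (j - l - 1) <= cap:
                chain.append(inner)
                extend(chain, cents + _loop_cents(seq, outer, inner))
                chain.pop()

    for first in cands:
        extend([first], 0)

    best = min(overall)
    if best[0] >= _OPEN_CENTS:
        return _open_chain(seq)
    return _to_prediction(seq, best[0], best[2])


def passes_screen(pred: StemLoopPrediction, params: FoldParams | None = None) -> ScreenVerdict:
    """Stability + base-pair-composition screen for one extracted loop.

    Pass requires dG37 strictly below the stability threshold *and* paired
    bases covering >= min_pair_fraction (default 50%, boundary inclusive) of
    the screened sequence.
    """
    params = params or DEFAULT_FOLD_PARAMS
    reasons = []
    if not (pred.dG37 < params.stability_threshold):
        reasons.append("no stable stem-loop")
    if pred.pair_fraction < params.min_pair_fraction:
        reasons.append(
            f"base-pair composition {pred.pair_fraction:.3f} below {params.min_pair_fraction:g}"
        )
    return ScreenVerdict(passed=not reasons, reasons=tuple(reasons))
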