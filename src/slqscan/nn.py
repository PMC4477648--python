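"""Unified DNA nearest-neighbor free-energy parameters (37 degC, 1 M Na+).

The tables below are the standard unified oligonucleotide DNA parameters:
Watson-Crick stack free energies, a per-helix-end terminal A.T penalty, and
hairpin / bulge / internal-loop initiation penalties with Jacobson-Stockmayer
extrapolation beyond the tabulated sizes.

All energies are handled internally as integer centi-kcal/mol so that the
dynamic-programming folder and the brute-force enumeration oracle produce
bit-identical sums regardless of summation order.
"""

from __future__ import annotations

import math

# -- Watson-Crick stacks, kcal/mol.  Key: 5'-XY-3' top strand paired with
#    3'-ZW-5' bottom strand, written "XY/ZW".
_STACK_DG = {
    "AA/TT": -1.00,
    "AT/AT": -0.88,
    "TA/TA": -0.58,
    "CA/GT": -1.45,
    "GT/CA": -1.44,
    "CT/GA": -1.28,
    "GA/CT": -1.30,
    "CG/GC": -2.17,
    "GC/CG": -2.24,
    "GG/CC": -1.84,
}

# A stack read from the other strand is the same physical stack:
# value("XY/ZW") == value("WZ/YX").
STACK_CENTS: dict[str, int] = {}
for _k, _v in _STACK_DG.items():
    _top, _bot = _k.split("/")
    _cents = round(_v * 100)
    STACK_CENTS[_k] = _cents
    STACK_CENTS[_bot[::-1] + "/" + _top[::-1]] = _cents

#: Penalty for a helix terminated by an A.T pair, kcal/mol (applied once at
#: the outermost pair of the single hairpin stem).
TERMINAL_AT_CENTS = round(0.05 * 100)

# -- Loop initiation free energies, kcal/mol, tabulated by loop size.
_HAIRPIN_ANCHORS = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.4,
    12: 4.3, 14: 4.1, 16: 4.5, 18: 4.8, 20: 4.5, 25: 4.7, 30: 4.9,
}
_BULGE_ANCHORS = {
    1: 4.0, 2: 2.9, 3: 3.1, 4: 3.2, 5: 3.3, 6: 3.5, 7: 3.7, 8: 3.9,
    9: 4.1, 10: 4.3, 12: 4.5, 14: 4.8, 16: 5.0, 18: 5.2, 20: 5.3,
    25: 5.6, 30: 5.9,
}
_INTERNAL_ANCHORS = {
    2: 3.2, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4, 7: 4.6, 8: 4.8, 9: 4.9,
    10: 4.9, 12: 5.2, 14: 5.4, 16: 5.6, 18: 5.8, 20: 5.9, 25: 6.3, 30: 6.6,
}

#: Asymmetry penalty for internal loops, kcal/mol per unpaired-side difference,
#: capped at 3.0 kcal/mol.
_ASYMMETRY_PER_NT = 0.48
_ASYMMETRY_CAP = 3.0

# Gas constant * 310.15 K, kcal/mol; Jacobson-Stockmayer coefficient 2.44.
_RT = 1.9872e-3 * 310.15
_JS_COEFF = 2.44


def _interp_table(anchors: dict[int, float], lo: int, hi: int) -> dict[int, int]:
    """Linear interpolation between anchor sizes, in centi-kcal."""
    sizes = sorted(anchors)
    out: dict[int, int] = {}
    for n in range(lo, hi + 1):
        if n in anchors:
            out[n] = round(anchors[n] * 100)
            continue
        left = max(s for s in sizes if s < n)
        right = min(s for s in sizes if s > n)
        frac = (n - left) / (right - left)
        out[n] = round((anchors[left] + frac * (anchors[right] - anchors[left])) * 100)
    return out


HAIRPIN_CENTS = _interp_table(_HAIRPIN_ANCHORS, 3, 30)
BULGE_CENTS = _interp_table(_BULGE_ANCHORS, 1, 30)
INTERNAL_CENTS = _interp_table(_INTERNAL_ANCHORS, 2, 30)

_MAX_TABULATED = 30


def _js_extrapolate(table: dict[int, int], n: int) -> int:
    """Jacobson-Stockmayer size extrapolation beyond the tabulated range."""
    base = table[_MAX_TABULATED]
    return base + round(_JS_COEFF * _RT * math.log(n / _MAX_TABULATED) * 100)


def hairpin_cents(size: int) -> int:
    if size < 3:
        raise ValueError(f"hairpin loop of {size} nt is not allowed (minimum 3)")
    if size <= _MAX_TABULATED:
        return HAIRPIN_CENTS[size]
    return _js_extrapolate(HAIRPIN_CENTS, size)


def bulge_cents(size: int) -> int:
    if size <= _MAX_TABULATED:
        return BULGE_CENTS[size]
    return _js_extrapolate(BULGE_CENTS, size)


def internal_cents(n1: int, n2: int) -> int:
    total = n1 + n2
    base = INTERNAL_CENTS[total] if total <= _MAX_TABULATED else _js_extrapolate(INTERNAL_CENTS, total)
    asym = min(_ASYMMETRY_CAP, _ASYMMETRY_PER_NT * abs(n1 - n2))
    return base + round(asym * 100)


_WC = {"AT", "TA", "GC", "CG"}
_WOBBLE = {"GT", "TG"}


def pair_allowed(x: str, y: str, allow_gt: bool = False) -> bool:
    """Canonical A.T / G.C pairing, with an optional G.T wobble toggle."""
    d = x + y
    return d in _WC or (allow_gt and d in _WOBBLE)


def stack_cents(seq: str, i: int, k: int, j: int, l: int) -> int:
    """Stack term between pair (i, j) and the next pair (k, l), i < k <= l < j.

    The same lookup serves plain stacks (k = i+1, l = j-1) and the retained
    stack across a single-nucleotide bulge.  Stacks involving a non-WC pair
    (wobble toggle) are not tabulated and contribute 0.
    """
    key = seq[i] + seq[k] + "/" + seq[j] + seq[l]
    return STACK_CENTS.get(key, 0)
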