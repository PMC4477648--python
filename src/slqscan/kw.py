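"""The Kolmogorov-Waring distribution for per-gene SLQS counts.

The family is defined by the recursion

    p_{m+1} = theta * (a + m) / (b + m + 1) * p_m,       m = 0, 1, 2, ...

with shape parameters b > a > 0 and 0 < theta <= 1.  Equivalently
p_m = p_0 * theta^m * (a)_m / (b+1)_m (a Beta-function ratio), so the
normalizing constant is the Gauss hypergeometric series 2F1(a, 1; b+1; theta)
and the normalized p_0 is its reciprocal.  For theta = 1 (the Waring special
case) this reduces exactly to the closed form p_0 = 1 - a/b, and the tail
decays like m^-(b-a+1) -- the heavy right tail seen in per-gene motif counts.

Observed per-gene count tables typically miss both zero counts (genes with no
hits are not in the hit table) and counts beyond the largest observed value
J, so fitting uses the doubly truncated pmf

    p_m^T = p_m / sum_{s=1..J} p_s,        1 <= m <= J.

Fitting maximizes the multinomial log-likelihood by a derivative-free simplex
search over (logit theta, log a, log(b-a)) from five deterministic starting
points; the reparametrization enforces the constraints by construction.
Because (theta, a, b) trade off along a ridge, fits are judged on pmf
distance, not parameter equality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "KWParams",
    "KWFitResult",
    "kw_p0",
    "kw_pmf",
    "kw_pmf_vector",
    "kw_truncated_pmf",
    "kw_sample",
    "kw_fit",
    "read_histogram",
    "write_histogram",
]

_SERIES_TOL = 1e-12
_SERIES_CAP = 1_000_000


@dataclass(frozen=True)
class KWParams:
    theta: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if not (self.b > self.a > 0.0):
            raise ValueError(f"need b > a > 0, got a={self.a}, b={self.b}")


def _series_p0(params: KWParams) -> float:
    """Fallback: direct series summation, tail truncated at increment < 1e-12."""
    total, term, m = 1.0, 1.0, 0
    while m < _SERIES_CAP:
        term *= params.theta * (params.a + m) / (params.b + m + 1)
        total += term
        if term < _SERIES_TOL * total:
            break
        m += 1
    return 1.0 / total

def kw_p0(params: KWParams, mode: str = "normalized") -> float:
    """Probability of the zero class.

    `normalized`: p_0 = 1 / 2F1(a, 1; b+1; theta), making the pmf sum to 1.
    `closed_form`: p_0 = 1 - a/b (exact for theta = 1).
    """
    if mode == "closed_form":
        return 1.0 - params.a / params.b
    if mode != "normalized":
        raise ValueError(f"unknown p0 mode {mode!r}")
    s = special.hyp2f1(params.a, 1.0, params.b + 1.0, params.theta)
    if not np.isfinite(s) or s <= 0:
        return _series_p0(params)
    return 1.0 / s


def kw_pmf_vector(params: KWParams, m_max: int, p0_mode: str = "normalized") -> np.ndarray:
    """p_0 .. p_{m_max} generated by the recursion from p_0."""
    p = np.empty(m_max + 1)
    p[0] = kw_p0(params, p0_mode)
    m = np.arange(m_max)
    ratios = params.theta * (params.a + m) / (params.b + m + 1)
    p[1:] = p[0] * np.cumprod(ratios)
    return p


def kw_pmf(m, params: KWParams, p0_mode: str = "normalized"):
    """P(X = m); `m` may be a scalar or an array of non-negative counts."""
    arr = np.asarray(m)
    if np.any(arr < 0):
        raise ValueError("m must be >= 0")
    vec = kw_pmf_vector(params, int(arr.max()) if arr.size else 0, p0_mode)
    out = vec[arr]
    return float(out) if np.isscalar(m) else out


def kw_truncated_pmf(m, params: KWParams, J: int) -> np.ndarray | float:
    """Doubly truncated pmf p_m^T = p_m / sum_{s=1..J} p_s on 1 <= m <= J."""
    if J < 1:
        raise ValueError("J must be >= 1")
    arr = np.asarray(m)
    if np.any((arr < 1) | (arr > J)):
        raise ValueError(f"m must lie in 1..J={J}")
    vec = kw_pmf_vector(params, J)
    out = vec[arr] / vec[1:].sum()
    return float(out) if np.isscalar(m) else out


def _untruncated_table(params: KWParams) -> np.ndarray:
    """pmf table covering all but <= 1e-12 of the mass (for sampling)."""
    chunks = [kw_pmf_vector(params, 255)]
    covered = chunks[0].sum()
    m_max = 255
    while 1.0 - covered > 1e-12 and m_max < _SERIES_CAP:
        last = chunks[-1][-1]
        m = np.arange(m_max, 2 * m_max)
        ratios = params.theta * (params.a + m) / (params.b + m + 1)
        nxt = last * np.cumprod(ratios)
        chunks.append(nxt)
        covered += nxt.sum()
        m_max *= 2
    return np.concatenate(chunks)


def kw_sample(
    n: int, params: KWParams, J: int | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """n i.i.d. draws by inverse-CDF lookup; truncated to 1..J when J is given."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if J is None:
        table = _untruncated_table(params)
        offset = 0
    else:
        vec = kw_pmf_vector(params, J)
        table = vec[1:] / vec[1:].sum()
        offset = 1
    cdf = np.cumsum(table)
    cdf[-1] = 1.0
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right") + offset


@dataclass(frozen=True)
class KWFitResult:
    params: KWParams
    log_likelihood: float
    p0: float
    truncated: bool
    J: int
    table: pd.DataFrame  # m, observed, expected
    converged: bool


def _hist_arrays(hist: dict[int, float], truncated: bool) -> tuple[np.ndarray, np.ndarray]:
    items = sorted((int(m), float(c)) for m, c in hist.items() if c > 0)
    if truncated:
        items = [(m, c) for m, c in items if m >= 1]
    if any(m < 0 for m, _ in items):
        raise ValueError("counts m must be >= 0")
    m = np.array([m for m, _ in items], dtype=int)
    c = np.array([c for _, c in items])
    return m, c


def kw_fit(hist: dict[int, float], truncated: bool = True) -> KWFitResult:
    """Constrained maximum-likelihood fit of the (truncated) KW pmf.

    `hist` maps per-gene count m to the number of genes observed with that
    count.  Raises ValueError("unidentifiable ...") for degenerate histograms
    with fewer than three distinct support points.
    """
    m_obs, n_obs = _hist_arrays(hist, truncated)
    if m_obs.size < 3:
        raise ValueError("unidentifiable: histogram needs >= 3 distinct observed counts")
    J = int(m_obs.max())
    total = n_obs.sum()

    def unpack(x: np.ndarray) -> KWParams:
        theta = 1.0 / (1.0 + np.exp(-x[0]))
        a = np.exp(x[1])
        b = a + np.exp(x[2])
        return KWParams(theta=min(theta, 1.0), a=a, b=b)

    def nll(x: np.ndarray) -> float:
        try:
            params = unpack(x)
            if truncated:
                probs = kw_truncated_pmf(m_obs, params, J)
            else:
                vec = kw_pmf_vector(params, J)
                probs = vec[m_obs]
        except (ValueError, FloatingPointError, OverflowError):
            return np.inf
        probs = np.asarray(probs)
        if not np.all(np.isfinite(probs)) or np.any(probs <= 0):
            return np.inf
        return -float(np.sum(n_obs * np.log(probs)))

    starts = [
        np.array([4.0, 0.0, 0.5]),    # theta ~ 0.98, a = 1, b - a ~ 1.6
        np.array([2.0, 1.0, 1.0]),
        np.array([6.0, 1.5, 0.0]),
        np.array([3.0, -0.5, 1.5]),
        np.array([5.0, 0.5, -0.5]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)
    if truncated:
        expected = np.asarray(kw_truncated_pmf(m_obs, params, J)) * total
    else:
        expected = kw_pmf_vector(params, J)[m_obs] * total
    table = pd.DataFrame({"m": m_obs, "observed": n_obs, "expected": expected})
    return KWFitResult(
        params=params,
        log_likelihood=-best.fun,
        p0=kw_p0(params),
        truncated=truncated,
        J=J,
        table=table,
        converged=bool(best.success),
    )


def read_histogram(path) -> dict[int, float]:
    """Count-histogram TSV with columns m, frequency ('#' comments allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:2])
    return {int(m): float(f) for m, f in zip(df[cols[0]], df[cols[1]])}


def write_histogram(hist: dict[int, float], path) -> None:
    pd.DataFrame(
        {"m": sorted(hist), "frequency": [hist[m] for m in sorted(hist)]}
    ).to_csv(path, sep="\t", index=False)
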