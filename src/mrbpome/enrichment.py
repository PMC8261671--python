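"""Hypergeometric overlap significance and gene-set over-representation.

The upper tail P(X >= k) is summed in log space with log-gamma binomial
coefficients, so probabilities far below the float underflow limit remain
representable as log10 p.  Over-representation applies a minimum-overlap
filter before Benjamini-Hochberg adjustment across the emitted categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core_io import GeneSetCollection
from .errors import ValidationError

LOG10E = np.log10(np.e)


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_hypergeom_args(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(
            f"need 0 <= K <= N and 0 <= n <= N; got N={N}, K={K}, n={n}"
        )
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValidationError(
            f"overlap k={k} outside [{max(0, K + n - N)}, {min(K, n)}] "
            f"for N={N}, K={K}, n={n}"
        )


def log_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Natural-log P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _validate_hypergeom_args(N, K, n, k)
    hi = min(K, n)
    i = np.arange(k, hi + 1)
    log_terms = (
        _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    )
    return float(min(logsumexp(log_terms), 0.0))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail probability P(X >= k); underflows to 0 below ~1e-308
    (use :func:`log_hypergeom_upper_tail` for the log-space value)."""
    return float(np.exp(log_hypergeom_upper_tail(N, K, n, k)))


@dataclass
class OverlapTest:
    universe_size: int
    set1_size: int
    set2_size: int
    overlap: int
    p_value: float
    log10_p: float


def overlap_test(
    set1: set[str], set2: set[str], universe: set[str]
) -> OverlapTest:
    """Hypergeometric significance of the overlap between two sets drawn from
    one universe."""
    set1, set2, universe = set(set1), set(set2), set(universe)
    outside = sorted((set1 | set2) - universe)
    if outside:
        raise ValidationError(
            f"members outside the universe: {outside[:10]}"
        )
    N, K, n = len(universe), len(set1), len(set2)
    k = len(set1 & set2)
    logp = log_hypergeom_upper_tail(N, K, n, k)
    return OverlapTest(
        universe_size=N,
        set1_size=K,
        set2_size=n,
        overlap=k,
        p_value=float(np.exp(logp)),
        log10_p=logp * LOG10E,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjustment with monotonicity enforcement; input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def ora(
    foreground: set[str],
    collection: GeneSetCollection,
    background: set[str],
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Over-representation of each category in *foreground* against
    *background*; categories are intersected with the background first and
    rows with overlap < *min_overlap* are dropped before BH adjustment.

    Columns: set, category_size, foreground_size, overlap, p, log10_p,
    adjusted_p.
    """
    foreground, background = set(foreground), set(background)
    if not foreground:
        raise ValidationError("foreground is empty")
    stray = sorted(foreground - background)
    if stray:
        raise ValidationError(
            f"foreground members outside the background: {stray[:10]}"
        )
    N, n = len(background), len(foreground)
    rows = []
    for name, (_desc, members) in collection.sets.items():
        category = set(members) & background
        k = len(category & foreground)
        if k < min_overlap:
            continue
        logp = log_hypergeom_upper_tail(N, len(category), n, k)
        rows.append(
            {
                "set": name,
                "category_size": len(category),
                "foreground_size": n,
                "overlap": k,
                "p": float(np.exp(logp)),
                "log10_p": logp * LOG10E,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "set", "category_size", "foreground_size", "overlap", "p", "log10_p",
        ],
    )
    df["adjusted_p"] = benjamini_hochberg(df["p"].to_numpy()) if len(df) else []
    return df
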