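"""Conversions from real-valued series to finite-alphabet symbol sequences.

Everything downstream (effort-to-compress complexity, the causality
statistics, the plug-in entropies) operates on integer symbol sequences.
This module holds the four ways a real-valued series becomes one:

* time-delay embedding (:func:`delay_embed`) followed by ordinal-pattern
  encoding (:func:`ordinal_encode`), the Bandt-Pompe scheme that labels the
  m values of each delay vector by their rank;
* equidistant amplitude binning (:func:`equidistant_bin`), equal-width bins
  over the observed range;
* equiquantal amplitude binning (:func:`equiquantal_bin`), marginal
  equiprobable bins at empirical quantiles.

It also implements embedding-delay selection as the first local minimum of
the auto mutual information function (:func:`select_delay_auto_mi`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "EmbeddedSeries",
    "SymbolSequence",
    "DelaySelection",
    "delay_embed",
    "select_delay_auto_mi",
    "ordinal_encode",
    "equidistant_bin",
    "equiquantal_bin",
]


@dataclass(frozen=True)
class SymbolSequence:
    """A finite-alphabet sequence of non-negative integer symbols.

    Parameters
    ----------
    symbols
        Integer array; every entry must lie in ``[0, alphabet_size)``.
    alphabet_size
        Number of admissible symbols (>= 1).
    """

    symbols: np.ndarray
    alphabet_size: int

    def __post_init__(self) -> None:
        sym = np.ascontiguousarray(self.symbols, dtype=np.int64)
        object.__setattr__(self, "symbols", sym)
        if sym.ndim != 1 or sym.size < 1:
            raise ValueError("symbols must be a non-empty 1-d sequence")
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        if sym.min() < 0 or sym.max() >= self.alphabet_size:
            raise ValueError("symbols must lie in [0, alphabet_size)")

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass(frozen=True)
class EmbeddedSeries:
    """Matrix of delay vectors with the metadata needed for alignment.

    ``vectors[i]`` is the delay vector attached to time index ``t0 + i`` of
    the source series.  In ``forward`` mode that vector is
    ``(x(t), x(t+eta), ..., x(t+(m-1)eta))`` with ``t0 = 0``; in
    ``backward`` mode it is ``(x(t), x(t-eta), ..., x(t-(m-1)eta))`` with
    ``t0 = (m-1)*eta``.  A partner series can therefore be co-truncated to
    indices ``t0 ... t0 + len(vectors) - 1``.
    """

    vectors: np.ndarray
    m: int
    eta: int
    direction: str
    t0: int

    def __len__(self) -> int:
        return int(self.vectors.shape[0])


class DelaySelection(NamedTuple):
    """Outcome of auto-MI delay selection."""

    lag: int
    is_local_minimum: bool
    mi_curve: np.ndarray


def _as_float_array(series: Sequence[float], name: str = "series") -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def delay_embed(
    series: Sequence[float],
    m: int,
    eta: int,
    direction: str = "forward",
) -> EmbeddedSeries:
    """Time-delay embed a series into m-dimensional vectors with delay eta.

    Returns ``N - (m-1)*eta`` vectors for an input of length ``N``.  The
    ``direction`` controls whether each vector looks forward
    (``x(t), x(t+eta), ...``) or backward (``x(t), x(t-eta), ...``) in time.
    """
    arr = np.asarray(series)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if eta < 1:
        raise ValueError("embedding delay eta must be >= 1")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    n = arr.size
    span = (m - 1) * eta
    n_vec = n - span
    if n_vec < 1:
        raise ValueError(
            f"insufficient length: need more than (m-1)*eta = {span} samples, got {n}"
        )
    base = np.arange(n_vec)[:, None]
    if direction == "forward":
        idx = base + np.arange(m)[None, :] * eta
        t0 = 0
    else:
        idx = span + base - np.arange(m)[None, :] * eta
        t0 = span
    return EmbeddedSeries(vectors=arr[idx], m=m, eta=eta, direction=direction, t0=t0)


def _plugin_entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def _binned_auto_mi(sym: np.ndarray, q: int, lag: int) -> float:
    a = sym[: sym.size - lag] if lag else sym
    b = sym[lag:] if lag else sym
    ha = _plugin_entropy_from_counts(np.bincount(a, minlength=q))
    hb = _plugin_entropy_from_counts(np.bincount(b, minlength=q))
    hab = _plugin_entropy_from_counts(np.bincount(a * q + b, minlength=q * q))
    return ha + hb - hab


def select_delay_auto_mi(
    series: Sequence[float],
    max_lag: int = 50,
    bins: int = 16,
) -> DelaySelection:
    """Choose the embedding delay as the first local minimum of auto-MI.

    The series is binned into ``bins`` equiprobable symbols once, and the
    mutual information between the series and its lagged copy is evaluated
    for lags ``0 ... max_lag``.  The selected delay is the smallest lag
    ``k >= 1`` with ``MI(k) < MI(k-1)`` and ``MI(k) < MI(k+1)``.  If no such
    local minimum exists, the lag of the global minimum over ``1..max_lag``
    is returned with ``is_local_minimum=False`` and a warning.
    """
    arr = _as_float_array(series)
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2 to bracket a local minimum")
    if arr.size <= max_lag + 1:
        raise ValueError("series too short for the requested max_lag")
    if np.unique(arr).size < 2:
        raise ValueError("constant series has zero entropy; cannot select a delay")
    q = min(bins, np.unique(arr).size)
    sym = equiquantal_bin(arr, q).symbols
    mi = np.array([_binned_auto_mi(sym, q, k) for k in range(max_lag + 1)])
    for k in range(1, max_lag):
        if mi[k] < mi[k - 1] and mi[k] < mi[k + 1]:
            return DelaySelection(lag=k, is_local_minimum=True, mi_curve=mi)
    k = int(np.argmin(mi[1:]) + 1)
    warnings.warn(
        f"no local minimum of auto-MI within max_lag={max_lag}; "
        f"falling back to the global minimum at lag {k}",
        stacklevel=2,
    )
    return DelaySelection(lag=k, is_local_minimum=False, mi_curve=mi)


def _rank_patterns(vectors: np.ndarray) -> np.ndarray:
    # stable argsort: exact ties keep occurrence order, so the earlier
    # occurrence of a tied value receives the smaller rank label
    order = np.argsort(vectors, axis=1, kind="stable")
    n, m = vectors.shape
    ranks = np.empty((n, m), dtype=np.int64)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(m)[None, :]
    return ranks


def _lehmer_index(ranks: np.ndarray) -> np.ndarray:
    """Lexicographic index of each rank pattern among the m! permutations."""
    n, m = ranks.shape
    idx = np.zeros(n, dtype=np.int64)
    for j in range(m - 1):
        smaller_after = np.zeros(n, dtype=np.int64)
        for k in range(j + 1, m):
            smaller_after += ranks[:, k] < ranks[:, j]
        idx += smaller_after * math.factorial(m - 1 - j)
    return idx


def ordinal_encode(embedded: EmbeddedSeries) -> SymbolSequence:
    """Encode each delay vector as its ordinal (permutation) pattern.

    Values are labelled 0..m-1 in ascending order (0 = lowest); exact ties
    are labelled by order of occurrence, the earlier occurrence taking the
    smaller label.  The rank pattern is mapped to a single integer in
    ``[0, m!)`` via its lexicographic index, so the alphabet size is ``m!``.
    """
    if len(embedded) < 1:
        raise ValueError("embedded series is empty")
    ranks = _rank_patterns(np.asarray(embedded.vectors, dtype=float))
    return SymbolSequence(
        symbols=_lehmer_index(ranks),
        alphabet_size=math.factorial(embedded.m),
    )


def equidistant_bin(series: Sequence[float], B: int) -> SymbolSequence:
    """Symbolize with B equal-width bins spanning [min, max].

    The top bin is right-closed (the maximum maps to symbol ``B-1``); a
    constant series maps entirely to symbol 0.
    """
    arr = _as_float_array(series)
    if B < 1:
        raise ValueError("number of bins B must be >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return SymbolSequence(symbols=np.zeros(arr.size, dtype=np.int64), alphabet_size=B)
    sym = np.minimum((B * (arr - lo) / (hi - lo)).astype(np.int64), B - 1)
    return SymbolSequence(symbols=sym, alphabet_size=B)


def equiquantal_bin(series: Sequence[float], Q: int) -> SymbolSequence:
    """Symbolize with Q marginal-equiprobable bins (quantile edges).

    Bin edges sit at the empirical ``k/Q`` quantiles, so each symbol
    receives ``N/Q`` samples up to ties and interpolation.
    """
    arr = _as_float_array(series)
    if Q < 2:
        raise ValueError("number of quantile bins Q must be >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    if np.unique(arr).size < Q:
        raise ValueError(
            f"need at least Q={Q} distinct values for equiquantal binning, "
            f"got {np.unique(arr).size}"
        )
    edges = np.quantile(arr, np.arange(1, Q) / Q)
    sym = np.searchsorted(edges, arr, side="right").astype(np.int64)
    return SymbolSequence(symbols=sym, alphabet_size=Q)
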