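"""Effort-To-Compress (ETC) complexity via Non-Sequential Recursive Pair
Substitution (NSRPS).

NSRPS repeatedly replaces the most frequent adjacent symbol pair with a
fresh symbol; ETC is the number of substitution passes needed to reduce a
sequence to a constant (or length-1) sequence.  Conventions frozen here:

* pair occurrences are counted non-overlapping, greedily left to right
  ("aaa" contains one (a,a) pair);
* ties in the pair count are broken in favour of the pair whose first
  occurrence comes earliest in the sequence (``tiebreak="first"``, the
  default).  This rule depends only on positions, never on symbol values,
  which makes ETC exactly invariant under bijective relabeling of the
  alphabet — the property the causality statistics rely on (the
  self-causality CCC(x->x) vanishes identically because the joint coding of
  a pair with itself is a relabeling).  A lexicographic tie-break
  (``tiebreak="lex"``, smallest pair wins) is available for comparison with
  implementations that use it; it is *not* relabeling-invariant;
* the fresh symbol is the current alphabet size, which then grows by one.

The joint (two-sequence) variant codes contemporaneous symbol pairs into a
product alphabet (fresh codes assigned in first-appearance order) and
compresses the coded sequence.

The substitution loop is jitted with numba when available; the identical
source runs un-jitted otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .symbolize import SymbolSequence

__all__ = ["EtcResult", "nsrps_step", "etc", "joint_etc"]

SequenceLike = Union[SymbolSequence, Sequence[int], np.ndarray]


def _maybe_jit(func):
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return func
    return njit(cache=True)(func)


TIEBREAK_FIRST = 0  # earliest first occurrence wins (relabeling-invariant)
TIEBREAK_LEX = 1  # lexicographically smallest pair wins


@_maybe_jit
def _best_pair(s: np.ndarray, alphabet: int, tiebreak: int) -> int:
    """Code a*alphabet+b of the most frequent adjacent pair.

    Counting is non-overlapping greedy left-to-right.  Ties in the count go
    to the pair with the earliest first occurrence (tiebreak=0) or the
    smallest code (tiebreak=1).
    """
    n = s.size
    keys = np.empty(n - 1, np.int64)
    for i in range(n - 1):
        keys[i] = (s[i] * alphabet + s[i + 1]) * n + i
    keys.sort()
    best_code = np.int64(-1)
    best_count = 0
    best_first = np.int64(n)
    cur_code = np.int64(-1)
    cur_count = 0
    cur_first = np.int64(n)
    last_pos = np.int64(-2)
    for key in keys:
        code = key // n
        pos = key % n
        if code != cur_code:
            if cur_count > best_count or (
                cur_count == best_count
                and tiebreak == TIEBREAK_FIRST
                and cur_first < best_first
            ):
                best_count = cur_count
                best_code = cur_code
                best_first = cur_first
            cur_code = code
            cur_count = 0
            cur_first = pos  # positions ascend within a code group
            last_pos = np.int64(-2)
        if pos != last_pos + 1:
            cur_count += 1
            last_pos = pos
    if cur_count > best_count or (
        cur_count == best_count
        and tiebreak == TIEBREAK_FIRST
        and cur_first < best_first
    ):
        best_code = cur_code
    return int(best_code)


@_maybe_jit
def _substitute_pair(s: np.ndarray, a: int, b: int, fresh: int) -> np.ndarray:
    out = np.empty(s.size, np.int64)
    i = 0
    j = 0
    n = s.size
    while i < n:
        if i < n - 1 and s[i] == a and s[i + 1] == b:
            out[j] = fresh
            i += 2
        else:
            out[j] = s[i]
            i += 1
        j += 1
    return out[:j]


@_maybe_jit
def _is_constant(s: np.ndarray) -> bool:
    for i in range(1, s.size):
        if s[i] != s[0]:
            return False
    return True


@_maybe_jit
def _etc_steps(s: np.ndarray, alphabet: int, tiebreak: int = 0) -> int:
    steps = 0
    while s.size > 1 and not _is_constant(s):
        code = _best_pair(s, alphabet, tiebreak)
        s = _substitute_pair(s, code // alphabet, code % alphabet, alphabet)
        alphabet += 1
        steps += 1
    return steps


@_maybe_jit
def _first_appearance_pair_code(
    a: np.ndarray, b: np.ndarray, alpha_b: int, n_codes: int
) -> np.ndarray:
    """Product-alphabet coding of contemporaneous pairs, fresh codes in
    first-appearance order."""
    table = np.full(n_codes, -1, np.int64)
    out = np.empty(a.size, np.int64)
    nxt = 0
    for i in range(a.size):
        c = a[i] * alpha_b + b[i]
        if table[c] < 0:
            table[c] = nxt
            nxt += 1
        out[i] = table[c]
    return out


def _coerce(seq: SequenceLike) -> SymbolSequence:
    if isinstance(seq, SymbolSequence):
        return seq
    arr = np.ascontiguousarray(seq, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty sequence")
    if arr.min() < 0:
        raise ValueError("symbols must be non-negative integers")
    return SymbolSequence(symbols=arr, alphabet_size=int(arr.max()) + 1)


@dataclass(frozen=True)
class EtcResult:
    """ETC of a symbol sequence of original length ``length``.

    ``steps`` is the number of NSRPS substitution passes; ``normalized`` is
    ``steps / (length - 1)`` (defined as 0 for length 1), which lies in
    [0, 1] because each pass shortens the sequence by at least one symbol.
    """

    steps: int
    length: int

    @property
    def normalized(self) -> float:
        if self.length <= 1:
            return 0.0
        return self.steps / (self.length - 1)


def _tiebreak_code(tiebreak: str) -> int:
    if tiebreak == "first":
        return TIEBREAK_FIRST
    if tiebreak == "lex":
        return TIEBREAK_LEX
    raise ValueError("tiebreak must be 'first' or 'lex'")


def nsrps_step(seq: SequenceLike, tiebreak: str = "first") -> SymbolSequence:
    """One NSRPS pass: replace the most frequent adjacent pair.

    The fresh symbol is the input ``alphabet_size``; the output alphabet is
    one symbol larger.  Length-1 input is already irreducible and raises.
    """
    sq = _coerce(seq)
    if len(sq) < 2:
        raise ValueError("already irreducible: sequence of length < 2")
    code = _best_pair(sq.symbols, sq.alphabet_size, _tiebreak_code(tiebreak))
    a, b = divmod(code, sq.alphabet_size)
    out = _substitute_pair(sq.symbols, a, b, sq.alphabet_size)
    return SymbolSequence(symbols=out, alphabet_size=sq.alphabet_size + 1)


def etc(seq: SequenceLike, tiebreak: str = "first") -> EtcResult:
    """Effort-to-compress: NSRPS passes until constant or length 1."""
    sq = _coerce(seq)
    steps = _etc_steps(sq.symbols, sq.alphabet_size, _tiebreak_code(tiebreak))
    return EtcResult(steps=int(steps), length=len(sq))


def joint_etc(a: SequenceLike, b: SequenceLike, tiebreak: str = "first") -> EtcResult:
    """ETC of the product-alphabet coding of two equal-length sequences."""
    sa, sb = _coerce(a), _coerce(b)
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    coded = _first_appearance_pair_code(
        sa.symbols, sb.symbols, sb.alphabet_size, sa.alphabet_size * sb.alphabet_size
    )
    steps = _etc_steps(coded, int(coded.max()) + 1, _tiebreak_code(tiebreak))
    return EtcResult(steps=int(steps), length=len(sa))
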