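"""Independent brute-force reference implementations used as oracles.

Deliberately written in plain Python (lists, dicts, itertools) with no
shared code with the package internals, so agreement is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_nsrps_pass(seq: list[int], alphabet: int) -> list[int]:
    """One pair-substitution pass on a plain list.

    Per pair type, occurrences are counted by an independent left-to-right
    scan that skips overlaps; the winner is the most frequent pair, ties
    resolved by the earliest first occurrence.
    """
    pair_types = {(seq[i], seq[i + 1]) for i in range(len(seq) - 1)}
    counts: dict[tuple[int, int], int] = {}
    first: dict[tuple[int, int], int] = {}
    for p in pair_types:
        n = 0
        i = 0
        while i < len(seq) - 1:
            if (seq[i], seq[i + 1]) == p:
                if p not in first:
                    first[p] = i
                n += 1
                i += 2
            else:
                i += 1
        counts[p] = n
    best = max(pair_types, key=lambda p: (counts[p], -first[p]))
    out: list[int] = []
    i = 0
    while i < len(seq):
        if i < len(seq) - 1 and (seq[i], seq[i + 1]) == best:
            out.append(alphabet)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def brute_etc(seq) -> int:
    """Brute-force effort-to-compress (substitution passes to constancy)."""
    s = [int(v) for v in seq]
    alphabet = max(s) + 1
    steps = 0
    while len(s) > 1 and len(set(s)) > 1:
        s = brute_nsrps_pass(s, alphabet)
        alphabet += 1
        steps += 1
    return steps


def brute_joint_etc(a, b) -> int:
    """Brute-force joint ETC: code observed pairs in first-appearance order."""
    codebook: dict[tuple[int, int], int] = {}
    coded = []
    for pair in zip(a, b):
        if pair not in codebook:
            codebook[pair] = len(codebook)
        coded.append(codebook[pair])
    return brute_etc(coded)


def brute_joint_entropy(*columns) -> float:
    """Plug-in joint entropy from a Counter over row tuples (nats)."""
    rows = list(zip(*columns))
    n = len(rows)
    return -sum(
        (c / n) * math.log(c / n) for c in Counter(rows).values()
    )


def brute_cmi(x, y, zs) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z) from raw counts."""
    zs = [list(z) for z in zs]
    return (
        brute_joint_entropy(list(x), *zs)
        + brute_joint_entropy(list(y), *zs)
        - brute_joint_entropy(list(x), list(y), *zs)
        - brute_joint_entropy(*zs)
    )


def brute_auto_mi_curve(series, max_lag: int, q: int) -> list[float]:
    """Auto-MI at lags 0..max_lag from quantile-binned symbols."""
    n = len(series)
    order = sorted(range(n), key=lambda i: (series[i], i))
    ranks = [0] * n
    for r, i in enumerate(order):
        ranks[i] = r
    # rank-based quantile binning keeps this oracle independent of the
    # package's edge conventions; the tests compare minimum LOCATIONS
    sym = [min(q - 1, r * q // n) for r in ranks]
    curve = []
    for lag in range(max_lag + 1):
        a = sym[: n - lag] if lag else sym
        b = sym[lag:] if lag else sym
        curve.append(
            brute_joint_entropy(a)
            + brute_joint_entropy(b)
            - brute_joint_entropy(a, b)
        )
    return curve
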