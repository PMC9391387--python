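"""Compression-Complexity Causality (CCC) and its permutation variant (PCCC).

CCC asks whether the future of the putative effect ``y`` compresses better
when the past of the putative cause ``x`` is supplied jointly.  For each
window anchored at ``k*delta`` the two dynamical compression-complexity
terms are

    CC(dy | y_past)          = ETC(y_past + dy) - ETC(y_past)
    CC(dy | y_past, x_past)  = ETC(y_past + dy, x_past + dy) - ETC(x_past, y_past)

with ``y_past``/``x_past`` of length ``L``, ``dy`` the following ``w``
samples of ``y``, ``+`` denoting concatenation and the two-argument ETC the
joint (product-alphabet) variant.  The averaged causality is

    CCC(x -> y) = mean CC(dy | y_past) - mean CC(dy | y_past, x_past)

which can be positive or negative; its magnitude measures strength, and
significance is judged against surrogates.  PCCC applies CCC after
delay-embedding the *driver only* and encoding it with ordinal patterns
(alphabet m!), while the target is equidistantly binned with m! bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .etc import _etc_steps, _first_appearance_pair_code, etc, joint_etc
from .symbolize import SymbolSequence, delay_embed, equidistant_bin, ordinal_encode

__all__ = ["CCCParams", "CCCResult", "window_cc_self", "window_cc_joint", "ccc", "pccc"]


@dataclass(frozen=True)
class CCCParams:
    """Window geometry and binning for CCC.

    Defaults are the coupled-Rossler PCCC setting (L=25, w=15, delta=20);
    ``B`` only applies when the caller bins raw data for scalar CCC (the
    Rossler scalar-CCC setting uses L=300, w=30, delta=30, B=8).  With
    ``normalized=True`` each ETC is divided by (length-1) before the
    differences are taken; the default uses raw substitution counts.
    """

    L: int = 25
    w: int = 15
    delta: int = 20
    B: int = 8
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("past-window length L must be >= 2")
        if self.w < 1:
            raise ValueError("future-window length w must be >= 1")
        if self.delta < 1:
            raise ValueError("window step delta must be >= 1")
        if self.B < 2:
            raise ValueError("number of bins B must be >= 2")


@dataclass(frozen=True)
class CCCResult:
    """Per-window CC terms and their averaged difference."""

    per_window_cc_self: np.ndarray
    per_window_cc_joint: np.ndarray
    ccc: float
    n_windows: int


def _etc_value(result, normalized: bool) -> float:
    return result.normalized if normalized else float(result.steps)


def window_cc_self(
    y_past: SymbolSequence, dy: SymbolSequence, normalized: bool = False
) -> float:
    """CC(dy | y_past): extra compression effort contributed by dy."""
    alpha = max(y_past.alphabet_size, dy.alphabet_size)
    joined = SymbolSequence(
        symbols=np.concatenate([y_past.symbols, dy.symbols]), alphabet_size=alpha
    )
    return _etc_value(etc(joined), normalized) - _etc_value(etc(y_past), normalized)


def window_cc_joint(
    y_past: SymbolSequence,
    x_past: SymbolSequence,
    dy: SymbolSequence,
    normalized: bool = False,
) -> float:
    """CC(dy | y_past, x_past): as above, with the cause's past supplied."""
    if len(y_past) != len(x_past):
        raise ValueError("y_past and x_past must have equal length L")
    y_ext = np.concatenate([y_past.symbols, dy.symbols])
    x_ext = np.concatenate([x_past.symbols, dy.symbols])
    return _etc_value(joint_etc(y_ext, x_ext), normalized) - _etc_value(
        joint_etc(x_past.symbols, y_past.symbols), normalized
    )


def ccc(x: SymbolSequence, y: SymbolSequence, params: CCCParams) -> CCCResult:
    """Averaged compression-complexity causality from x to y.

    Both inputs must already be symbolized and of equal length
    ``N >= L + w``; windows are anchored at ``k*delta`` and trailing samples
    that do not fill a full window are dropped.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(y)
    L, w, delta = params.L, params.w, params.delta
    if n < L + w:
        raise ValueError(
            f"series too short for window geometry: need >= L+w = {L + w}, got {n}"
        )
    # same primitives as window_cc_self / window_cc_joint, but calling the
    # compiled kernels directly: this loop dominates the benchmark runtime
    xs = np.ascontiguousarray(x.symbols)
    ys = np.ascontiguousarray(y.symbols)
    ax, ay = x.alphabet_size, y.alphabet_size

    def _val(steps: int, length: int) -> float:
        if params.normalized:
            return steps / (length - 1) if length > 1 else 0.0
        return float(steps)

    cc_self = []
    cc_joint = []
    start = 0
    while start + L + w <= n:
        y_past = ys[start : start + L]
        x_past = xs[start : start + L]
        y_ext = ys[start : start + L + w]
        x_ext = np.concatenate([x_past, ys[start + L : start + L + w]])
        cc_self.append(
            _val(_etc_steps(y_ext, ay), L + w) - _val(_etc_steps(y_past, ay), L)
        )
        joint_ext = _first_appearance_pair_code(y_ext, x_ext, max(ax, ay), ay * max(ax, ay))
        joint_past = _first_appearance_pair_code(x_past, y_past, ay, ax * ay)
        cc_joint.append(
            _val(_etc_steps(joint_ext, int(joint_ext.max()) + 1), L + w)
            - _val(_etc_steps(joint_past, int(joint_past.max()) + 1), L)
        )
        start += delta
    cc_self = np.asarray(cc_self)
    cc_joint = np.asarray(cc_joint)
    return CCCResult(
        per_window_cc_self=cc_self,
        per_window_cc_joint=cc_joint,
        ccc=float(cc_self.mean() - cc_joint.mean()),
        n_windows=len(cc_self),
    )


def pccc(
    x_raw: Sequence[float],
    y_raw: Sequence[float],
    m: int,
    eta_x: int,
    params: CCCParams,
) -> CCCResult:
    """Permutation CCC from x to y: embed and ordinal-encode the driver only.

    The driver ``x`` is forward-embedded with dimension ``m`` and delay
    ``eta_x`` and encoded into ordinal patterns (alphabet m!); the target
    ``y`` is truncated to the same contemporaneous index range and
    equidistantly binned with m! bins.  For the reverse direction call
    ``pccc(y_raw, x_raw, m, eta_y, params)``.
    """
    x_arr = np.asarray(x_raw, dtype=float)
    y_arr = np.asarray(y_raw, dtype=float)
    if x_arr.size != y_arr.size:
        raise ValueError("x and y must have equal length")
    embedded = delay_embed(x_arr, m=m, eta=eta_x, direction="forward")
    x_hat = ordinal_encode(embedded)
    y_aligned = y_arr[embedded.t0 : embedded.t0 + len(embedded)]
    y_hat = equidistant_bin(y_aligned, x_hat.alphabet_size)
    return ccc(x_hat, y_hat, params)
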