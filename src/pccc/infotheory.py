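"""Plug-in entropy and conditional-mutual-information coupling measures.

The conditional mutual information

    I(X; Y | Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)

evaluated with Y = y(t+tau) and Z the past of y measures the net
information the process x carries about the tau-step future of y beyond
what y's own past supplies — the transfer-entropy formulation of directed
coupling.  Three estimators are provided, all plug-in (empirical counts,
natural log):

* :func:`cmi1` — scalar conditioning on y(t) alone;
* :func:`cmi3` — conditioning on the m backward-embedded coordinates
  (y(t), y(t-eta), ..., y(t-(m-1)eta));
* :func:`pcmi` — permutation CMI: both series are forward-embedded and
  ordinal-encoded, and the horizon is shifted to tau + (m-1)*eta so the
  symbolized past and future do not overlap.

Continuous inputs to cmi1/cmi3 are discretized with Q equiprobable bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .symbolize import (
    SymbolSequence,
    delay_embed,
    equiquantal_bin,
    ordinal_encode,
)

__all__ = ["CmiParams", "joint_entropy", "cmi", "cmi1", "cmi3", "pcmi"]


@dataclass(frozen=True)
class CmiParams:
    """Horizon, embedding and binning for the CMI family.

    ``tau`` is the prediction horizon in samples (coupled-Rossler default
    20), ``m`` and ``eta`` the embedding dimension and delay used by cmi3
    and pcmi, and ``Q`` the number of equiprobable bins for continuous
    inputs.  All entropies are in nats.
    """

    tau: int = 20
    m: int = 3
    eta: int = 5
    Q: int = 8

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("prediction horizon tau must be >= 1")
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.eta < 1:
            raise ValueError("embedding delay eta must be >= 1")
        if self.Q < 2:
            raise ValueError("number of bins Q must be >= 2")


def _columns_to_codes(columns: Sequence[SymbolSequence]) -> np.ndarray:
    """Mixed-radix code of the column tuples (one integer per row)."""
    if not columns:
        raise ValueError("need at least one column")
    n = len(columns[0])
    codes = np.zeros(n, dtype=np.int64)
    for col in columns:
        if len(col) != n:
            raise ValueError("columns must have equal length")
        codes = codes * col.alphabet_size + col.symbols
    return codes


def joint_entropy(*columns: SymbolSequence) -> float:
    """Plug-in joint Shannon entropy (nats) of the column tuples."""
    codes = _columns_to_codes(columns)
    if codes.size < 1:
        raise ValueError("empty input")
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    return float(-(p * np.log(p)).sum())


def cmi(
    x: SymbolSequence,
    y: SymbolSequence,
    z: SymbolSequence | Sequence[SymbolSequence],
) -> float:
    """Plug-in conditional mutual information I(X; Y | Z) in nats.

    ``z`` may be a single symbol sequence or a list of them (joint
    conditioning).  Non-negative up to floating-point rounding.
    """
    zs = [z] if isinstance(z, SymbolSequence) else list(z)
    h_xz = joint_entropy(x, *zs)
    h_yz = joint_entropy(y, *zs)
    h_xyz = joint_entropy(x, y, *zs)
    h_z = joint_entropy(*zs)
    return h_xz + h_yz - h_xyz - h_z


def _binned(series: Sequence[float], Q: int) -> SymbolSequence:
    return equiquantal_bin(np.asarray(series, dtype=float), Q)


def _slice(sym: SymbolSequence, start: int, stop: int) -> SymbolSequence:
    return SymbolSequence(sym.symbols[start:stop], sym.alphabet_size)


def cmi1(
    x_raw: Sequence[float], y_raw: Sequence[float], params: CmiParams
) -> float:
    """Scalar CMI: I(x(t); y(t+tau) | y(t)) on Q-binned series."""
    x_arr = np.asarray(x_raw, dtype=float)
    y_arr = np.asarray(y_raw, dtype=float)
    n = x_arr.size
    if y_arr.size != n:
        raise ValueError("x and y must have equal length")
    if n <= params.tau + 1:
        raise ValueError("series too short for the prediction horizon")
    xs = _binned(x_arr, params.Q)
    ys = _binned(y_arr, params.Q)
    tau = params.tau
    return cmi(
        _slice(xs, 0, n - tau),
        _slice(ys, tau, n),
        _slice(ys, 0, n - tau),
    )


def cmi3(
    x_raw: Sequence[float], y_raw: Sequence[float], params: CmiParams
) -> float:
    """Condition-embedded CMI: the conditioning set is the m backward-embedded
    coordinates (y(t), y(t-eta), ..., y(t-(m-1)eta))."""
    x_arr = np.asarray(x_raw, dtype=float)
    y_arr = np.asarray(y_raw, dtype=float)
    n = x_arr.size
    if y_arr.size != n:
        raise ValueError("x and y must have equal length")
    m, eta, tau = params.m, params.eta, params.tau
    span = (m - 1) * eta
    if n <= tau + span:
        raise ValueError("series too short for the horizon and embedding")
    xs = _binned(x_arr, params.Q)
    ys = _binned(y_arr, params.Q)
    # valid anchors t = span ... n-1-tau
    t_lo, t_hi = span, n - tau
    cond = [
        _slice(ys, t_lo - k * eta, t_hi - k * eta) for k in range(m)
    ]
    return cmi(
        _slice(xs, t_lo, t_hi),
        _slice(ys, t_lo + tau, t_hi + tau),
        cond,
    )


def pcmi(
    x_raw: Sequence[float],
    y_raw: Sequence[float],
    params: CmiParams,
    eta_x: int | None = None,
    eta_y: int | None = None,
) -> float:
    """Permutation CMI: I(x_hat(t); y_hat(t+tau') | y_hat(t)), tau' = tau + (m-1)*eta_y.

    Both series are forward-embedded and ordinal-encoded (alphabet m!); the
    shifted horizon keeps the symbolized past and future of y disjoint.
    Per-series delays default to ``params.eta``.
    """
    eta_x = params.eta if eta_x is None else eta_x
    eta_y = params.eta if eta_y is None else eta_y
    x_arr = np.asarray(x_raw, dtype=float)
    y_arr = np.asarray(y_raw, dtype=float)
    if x_arr.size != y_arr.size:
        raise ValueError("x and y must have equal length")
    m, tau = params.m, params.tau
    x_hat = ordinal_encode(delay_embed(x_arr, m=m, eta=eta_x, direction="forward"))
    y_hat = ordinal_encode(delay_embed(y_arr, m=m, eta=eta_y, direction="forward"))
    n = min(len(x_hat), len(y_hat))
    tau_eff = tau + (m - 1) * eta_y
    if n <= tau_eff:
        raise ValueError("series too short for the shifted horizon tau + (m-1)*eta")
    return cmi(
        _slice(x_hat, 0, n - tau_eff),
        _slice(y_hat, tau_eff, n),
        _slice(y_hat, 0, n - tau_eff),
    )
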