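"""Plug-in entropy/MI machinery, time-lag mutual information, transfer entropy.

All estimators are *plug-in*: probabilities are empirical frequencies from
joint histograms and entropies are in bits (base-2 logs).  Time-lag mutual
information (TLMI) between series U and V is

    I(U, V, dt) = sum P(u_{t+dt}, v_t) log2[ P(u_{t+dt}, v_t)
                                             / (P(u_{t+dt}) P(v_t)) ],

evaluated on the truncated overlap of the shifted series (no wraparound).  A
peak at positive lag means V is leading U.  Transfer entropy from U to V with
history length h is the Schreiber reduction

    T_{U->V}(h) = H(V_t | V_hist) - H(V_t | V_hist, U_hist),

with both conditional entropies plug-in over the length-h joint embeddings.
No bias correction is applied; see :func:`permissible_states` for the
finite-sample guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    InsufficientDataError,
    LagRangeError,
    ParameterError,
)
from .trajectory_io import SymbolSeries

__all__ = [
    "TLMICurve",
    "PeakSummary",
    "TEResult",
    "entropy_bits",
    "mutual_information",
    "tlmi",
    "tlmi_curve",
    "peak_summary",
    "half_decay_time",
    "transfer_entropy",
    "permissible_states",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class TLMICurve:
    """Lag-resolved mutual information between two symbol series."""

    lag_steps: np.ndarray
    lag_s: np.ndarray
    values_bits: np.ndarray
    kind: str  # "auto" | "cross"

    def __post_init__(self) -> None:
        self.lag_steps = np.asarray(self.lag_steps, dtype=np.int64)
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.values_bits = np.asarray(self.values_bits, dtype=float)

    def value_at(self, lag_step: int) -> float:
        idx = np.flatnonzero(self.lag_steps == lag_step)
        if idx.size == 0:
            raise LagRangeError(f"lag {lag_step} not on the curve grid")
        return float(self.values_bits[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag_s, "bits": self.values_bits})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PeakSummary:
    """Peak location/height of a cross-TLMI curve plus auto-decay time.

    ``normalized_height`` is the cross peak divided by the mean of the two
    auto-TLMI zero-lag values, making it independent of the bit depth used in
    the discretization.  ``half_decay_s`` is the first nonnegative lag at
    which the agent-0 auto curve falls below half its zero-lag value.
    """

    peak_lag_s: float
    peak_height_bits: float
    normalized_height: float
    half_decay_s: float


@dataclass
class TEResult:
    """Bidirectional transfer entropy at one history length."""

    h: int
    te_fwd_bits: float
    te_rev_bits: float
    delta_bits: float
    bits: int


# ---------------------------------------------------------------------------
# plug-in estimators


def _joint_entropy_bits(columns: list[np.ndarray], n_states: int) -> float:
    """Plug-in joint entropy (bits) of aligned integer columns.

    Rows are encoded as a single integer when the code space fits in int64;
    otherwise falls back to row-wise uniquing.
    """
    m = len(columns[0])
    k = len(columns)
    if n_states**k < 2**62:
        code = columns[0].astype(np.int64)
        for col in columns[1:]:
            code = code * n_states + col
        _, counts = np.unique(code, return_counts=True)
    else:
        mat = np.stack(columns, axis=1)
        _, counts = np.unique(mat, axis=0, return_counts=True)
    p = counts / m
    return float(-(p * np.log2(p)).sum())


def entropy_bits(series: SymbolSeries) -> float:
    """Plug-in entropy H of a symbol series, in bits."""
    return _joint_entropy_bits([series.symbols], series.n_states)


def _mi_bits(a: np.ndarray, na: int, b: np.ndarray, nb: int) -> float:
    """Plug-in MI between aligned integer arrays with alphabet sizes na, nb."""
    m = len(a)
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    pj = joint[nz] / m
    # outer product of marginals restricted to occupied joint cells
    pm = (pa[:, None] * pb[None, :])[nz] / (m * m)
    return float((pj * np.log2(pj / pm)).sum())


def mutual_information(a: SymbolSeries, b: SymbolSeries) -> float:
    """Plug-in mutual information between two aligned symbol series, in bits."""
    if len(a) != len(b):
        raise AlignmentError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise InsufficientDataError("need at least 2 aligned samples")
    return _mi_bits(a.symbols, a.n_states, b.symbols, b.n_states)


def tlmi(u: SymbolSeries, v: SymbolSeries, lag_steps: int) -> float:
    """TLMI of U against V at an integer lag (in samples).

    Pairs ``u[t + lag]`` with ``v[t]`` over the valid overlap; a maximum at
    positive lag means V is leading U.
    """
    if len(u) != len(v):
        raise AlignmentError(f"length mismatch: {len(u)} vs {len(v)}")
    n = len(u)
    j = int(lag_steps)
    if abs(j) >= n - 1:
        raise LagRangeError(f"|lag|={abs(j)} too large for n={n}")
    if j >= 0:
        a, b = u.symbols[j:], v.symbols[: n - j]
    else:
        a, b = u.symbols[: n + j], v.symbols[-j:]
    return _mi_bits(a, u.n_states, b, v.n_states)


def tlmi_curve(u: SymbolSeries, v: SymbolSeries, max_lag_s: float) -> TLMICurve:
    """Evaluate the TLMI on every integer lag in ``[-max_lag_s, +max_lag_s]``."""
    dt = u.time_step_s
    if max_lag_s < dt:
        raise LagRangeError(f"max_lag_s={max_lag_s} below one time step {dt}")
    jmax = int(np.floor(max_lag_s / dt + 1e-9))
    jmax = min(jmax, len(u) - 2)
    lags = np.arange(-jmax, jmax + 1)
    kind = "auto" if u.symbols is v.symbols or np.array_equal(u.symbols, v.symbols) else "cross"
    values = np.array([tlmi(u, v, j) for j in lags])
    return TLMICurve(lag_steps=lags, lag_s=lags * dt, values_bits=values, kind=kind)


def _peak_index(curve: TLMICurve) -> int:
    """Index of the curve maximum; ties go to smallest |lag|, then negative lag."""
    vmax = curve.values_bits.max()
    cand = np.flatnonzero(curve.values_bits == vmax)
    order = sorted(cand, key=lambda i: (abs(int(curve.lag_steps[i])), int(curve.lag_steps[i])))
    return order[0]


def half_decay_time(auto: TLMICurve) -> float:
    """First nonnegative lag (s) where an auto curve drops below half its
    zero-lag value; NaN if it never does within the curve's window."""
    nn = auto.lag_steps >= 0
    lags = auto.lag_s[nn]
    vals = auto.values_bits[nn]
    order = np.argsort(lags)
    lags, vals = lags[order], vals[order]
    v0 = vals[0]
    below = np.flatnonzero(vals < 0.5 * v0)
    return float(lags[below[0]]) if below.size else float("nan")


def peak_summary(cross: TLMICurve, auto0: TLMICurve, auto1: TLMICurve) -> PeakSummary:
    """Summarize a cross curve against the two agents' auto curves."""
    for c in (cross, auto0, auto1):
        if c.values_bits.size == 0:
            raise InsufficientDataError("empty TLMI curve")
    i = _peak_index(cross)
    peak_lag_s = float(cross.lag_s[i])
    peak = float(cross.values_bits[i])
    ref = 0.5 * (auto0.value_at(0) + auto1.value_at(0))
    norm = peak / ref if ref > 0 else float("nan")
    return PeakSummary(
        peak_lag_s=peak_lag_s,
        peak_height_bits=peak,
        normalized_height=norm,
        half_decay_s=half_decay_time(auto0),
    )


# ---------------------------------------------------------------------------
# transfer entropy


def permissible_states(bits: int, h: int) -> int:
    """Number of joint embedding states, ``(2**bits)**(h+1)``.

    This is the count that must stay well below the sample size for the
    plug-in TE to be reliable; e.g. 4 states at h=8 gives 262,144.
    """
    return (2**bits) ** (h + 1)


def _te_one_direction(src: np.ndarray, tgt: np.ndarray, h: int, n_states: int) -> float:
    """T_{src->tgt}(h) in bits via four joint entropies of the embedding."""
    n = len(tgt)
    m = n - h
    tgt_now = tgt[h:]
    tgt_hist = [tgt[h - k - 1 : n - k - 1] for k in range(h)]
    src_hist = [src[h - k - 1 : n - k - 1] for k in range(h)]
    h_vh = _joint_entropy_bits(tgt_hist, n_states)
    h_v_vh = _joint_entropy_bits([tgt_now] + tgt_hist, n_states)
    h_vh_uh = _joint_entropy_bits(tgt_hist + src_hist, n_states)
    h_v_vh_uh = _joint_entropy_bits([tgt_now] + tgt_hist + src_hist, n_states)
    # H(V_t|V_hist) - H(V_t|V_hist,U_hist)
    return (h_v_vh - h_vh) - (h_v_vh_uh - h_vh_uh)


def transfer_entropy(src: SymbolSeries, tgt: SymbolSeries, h: int) -> TEResult:
    """Bidirectional plug-in transfer entropy with equal history lengths.

    Warns (does not fail) when the joint state count exceeds the sample
    size, where the plug-in estimate is known to be strongly biased.
    """
    if h < 1:
        raise ParameterError(f"history length must be >= 1, got {h}")
    if len(src) != len(tgt):
        raise AlignmentError(f"length mismatch: {len(src)} vs {len(tgt)}")
    if src.bits != tgt.bits:
        raise AlignmentError("source and target must share a bit depth")
    n = len(src)
    if n < h + 2:
        raise InsufficientDataError(f"n={n} too short for history h={h}")
    n_perm = permissible_states(src.bits, h)
    if n <= n_perm:
        warnings.warn(
            f"sample size {n} <= permissible state count {n_perm}; "
            f"plug-in TE at h={h} will be biased",
            stacklevel=2,
        )
    ns = src.n_states
    fwd = _te_one_direction(src.symbols, tgt.symbols, h, ns)
    rev = _te_one_direction(tgt.symbols, src.symbols, h, ns)
    return TEResult(h=h, te_fwd_bits=fwd, te_rev_bits=rev, delta_bits=fwd - rev, bits=src.bits)
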