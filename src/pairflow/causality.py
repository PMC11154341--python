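"""Bivariate Granger causality and Liang's covariance information flow.

Granger causality compares, per direction, a restricted autoregression of the
target on its own p lags against an unrestricted regression that adds the
other series' p lags, both fit by OLS on the same sample window with no
intercept (inputs are mean-centered).  The statistic is the log residual
variance ratio

    F_{U->V} = ln( var(eps) / var(eta) )  >= 0,

and the direction call is the larger F.  Asymptotic p-values use the
large-sample equivalence n*F ~ chi2(p) under the null.

Liang's T is a closed-form information-flow rate built from sample
covariances of the two series and their finite-difference derivatives:

    T_{V->U} = (C_UU C_UV C_{V,dU} - C_UV^2 C_{U,dU})
               / (C_UU^2 C_VV - C_UU C_UV^2),

in units of inverse time.  Direction is read off by magnitude comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

__all__ = [
    "GCResult",
    "LiangTResult",
    "OrderSelection",
    "select_var_order",
    "granger_f",
    "gc_pvalue",
    "liang_t",
]


@dataclass
class GCResult:
    """Bidirectional Granger F statistics (nats) with asymptotic p-values."""

    order: int
    f_fwd: float  # F_{0->1}: series 0's lags improve prediction of series 1
    f_rev: float  # F_{1->0}
    p_fwd: float
    p_rev: float
    n_effective: int

    @property
    def direction(self) -> int:
        """0 if information flows 0->1 (f_fwd larger), else 1."""
        return 0 if self.f_fwd >= self.f_rev else 1


@dataclass
class LiangTResult:
    """Bidirectional Liang information-flow rates, per time step."""

    t_fwd: float  # T_{0->1}
    t_rev: float  # T_{1->0}

    @property
    def direction(self) -> int:
        return 0 if abs(self.t_fwd) >= abs(self.t_rev) else 1


@dataclass
class OrderSelection:
    """Outcome of information-criterion VAR order selection.

    ``saturated`` is set when the criterion is strictly decreasing all the
    way to ``p_max`` (no interior minimum, only saturation), in which case
    ``order == p_max``.
    """

    order: int
    criterion: str
    values: np.ndarray = field(repr=False)
    saturated: bool = False


def _as_centered(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("series must be 1-D")
    if np.std(x) == 0:
        raise DegenerateInputError("constant series")
    return x - x.mean()


def _lag_matrix(x: np.ndarray, p: int, start: int) -> np.ndarray:
    """Columns [x_{t-1}, ..., x_{t-p}] for t = start..n-1."""
    n = len(x)
    return np.column_stack([x[start - k : n - k] for k in range(1, p + 1)])


def select_var_order(
    u, v, p_max: int = 20, criterion: str = "bic"
) -> OrderSelection:
    """Select the VAR order for a bivariate pair by AIC or BIC.

    Fits the unrestricted bivariate VAR(p) for p = 1..p_max on a common
    sample window and returns the argmin of

        IC(p) = ln det(Sigma_p) + c * (4p + 2) / n,

    with c = 2 (AIC) or ln n (BIC) and Sigma_p the 2x2 residual covariance.
    """
    if p_max < 1:
        raise ParameterError(f"p_max must be >= 1, got {p_max}")
    crit = criterion.lower()
    if crit not in ("aic", "bic"):
        raise ParameterError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    u = _as_centered(u)
    v = _as_centered(v)
    n = len(u)
    if n != len(v):
        raise ParameterError("series must share a length")
    if n <= 10 * p_max:
        raise InsufficientDataError(f"need n > {10 * p_max} samples for p_max={p_max}")

    n_eff = n - p_max
    y = np.column_stack([u[p_max:], v[p_max:]])
    penalty = 2.0 if crit == "aic" else np.log(n_eff)
    values = np.empty(p_max)
    for p in range(1, p_max + 1):
        x = np.hstack([_lag_matrix(u, p, p_max), _lag_matrix(v, p, p_max)])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sigma = resid.T @ resid / n_eff
        values[p - 1] = np.log(np.linalg.det(sigma)) + penalty * (4 * p + 2) / n_eff
    order = int(np.argmin(values)) + 1
    saturated = bool(np.all(np.diff(values) < 0))
    if saturated:
        order = p_max
    return OrderSelection(order=order, criterion=crit, values=values, saturated=saturated)


def _f_one_direction(src: np.ndarray, tgt: np.ndarray, p: int) -> float:
    """ln(restricted/unrestricted residual variance) for src -> tgt."""
    n = len(tgt)
    y = tgt[p:]
    x_own = _lag_matrix(tgt, p, p)
    x_full = np.hstack([x_own, _lag_matrix(src, p, p)])
    rss_r = _rss(x_own, y)
    rss_u = _rss(x_full, y)
    if rss_u <= 0:
        return float("inf")
    return float(np.log(rss_r / rss_u))


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def granger_f(u, v, p: int) -> GCResult:
    """Bidirectional Granger log-variance-ratio F at order p.

    ``f_fwd`` measures series 0 (u) causing series 1 (v).  p-values are the
    chi-square upper tails of n*F with p degrees of freedom.
    """
    if p < 1:
        raise ParameterError(f"order must be >= 1, got {p}")
    u = _as_centered(u)
    v = _as_centered(v)
    n = len(u)
    if n != len(v):
        raise ParameterError("series must share a length")
    if n <= 2 * p + 10:
        raise InsufficientDataError(f"n={n} too short for order p={p}")
    n_eff = n - p
    f_fwd = _f_one_direction(u, v, p)
    f_rev = _f_one_direction(v, u, p)
    return GCResult(
        order=p,
        f_fwd=f_fwd,
        f_rev=f_rev,
        p_fwd=gc_pvalue(max(f_fwd, 0.0), p, n_eff),
        p_rev=gc_pvalue(max(f_rev, 0.0), p, n_eff),
        n_effective=n_eff,
    )


def gc_pvalue(f: float, p: int, n: int) -> float:
    """Asymptotic p-value of a Granger F: upper chi2(p) tail at n*f."""
    if f < 0 or p < 1 or n <= p:
        raise ParameterError("need f >= 0, p >= 1, n > p")
    return float(stats.chi2.sf(n * f, df=p))


def liang_t(u, v, dt: float = 1.0) -> LiangTResult:
    """Liang's information-flow rates between two real-valued series.

    Derivatives are forward differences ``(x_{i+1} - x_i)/dt`` and all series
    are truncated to the common length n-1; covariances use 1/(n-2)
    normalization (ddof=1).  The result is invariant under separate linear
    rescaling of either input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) != len(v):
        raise ParameterError("series must share a length")
    if len(u) < 3:
        raise InsufficientDataError("need at least 3 samples")
    du = np.diff(u) / dt
    dv = np.diff(v) / dt
    u, v = u[:-1], v[:-1]

    def one_direction(a, b, da):
        # T_{B->A}: flow from b into the target a; da is the target's derivative
        c_aa = _cov(a, a)
        c_ab = _cov(a, b)
        c_bb = _cov(b, b)
        c_b_da = _cov(b, da)
        c_a_da = _cov(a, da)
        denom = c_aa**2 * c_bb - c_aa * c_ab**2
        if denom == 0:
            raise DegenerateInputError("vanishing covariance denominator")
        return (c_aa * c_ab * c_b_da - c_ab**2 * c_a_da) / denom

    t_rev = one_direction(u, v, du)  # T_{1->0}: flow from v into u
    t_fwd = one_direction(v, u, dv)  # T_{0->1}
    return LiangTResult(t_fwd=float(t_fwd), t_rev=float(t_rev))


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1])
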