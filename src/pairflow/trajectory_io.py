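"""Paired-trajectory data model, CSV I/O, and trajectory discretization.

Recordings are two agents swimming in a two-channel tank: ``x`` runs along the
channel length, ``y`` across the two channels, which are separated by a
divider wall pierced by one or more doors.  Two discretizations feed the
information-theoretic analysis:

* the x position is binned into ``2**bits`` equal-width states anchored at
  the physical tank span, and
* the y position is reduced to a 1-bit *channel state* (which side of the
  divider the agent occupies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InsufficientDataError,
    ResolutionError,
    TimingError,
)

logger = logging.getLogger(__name__)

#: Columns a trajectory CSV must carry, in canonical order.
CSV_COLUMNS = ("t", "x0", "y0", "x1", "y1")

#: Default channel length, mm.
DEFAULT_X_SPAN_MM = 216.0
#: Default divider (wall) position across the channels, mm.
DEFAULT_WALL_Y_MM = 70.0

MAX_BITS = 16


@dataclass
class TrajectoryPair:
    """Timestamped (x, y) tracks of two agents plus the tank geometry.

    Coordinates are millimetres; ``x0/y0`` belong to the agent carrying
    ``labels[0]``.  Positions are validated (and x clamped to the tank span)
    by :func:`read_trajectory_pair`; direct construction does not clamp.
    """

    time_step_s: float
    x0: np.ndarray
    y0: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    x_span_mm: float = DEFAULT_X_SPAN_MM
    wall_y_mm: float = DEFAULT_WALL_Y_MM
    door_x_mm: tuple[float, ...] = (DEFAULT_X_SPAN_MM / 2.0,)
    labels: tuple[str, str] = ("fish0", "fish1")

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        self.y0 = np.asarray(self.y0, dtype=float)
        self.x1 = np.asarray(self.x1, dtype=float)
        self.y1 = np.asarray(self.y1, dtype=float)
        n = len(self.x0)
        if not (len(self.y0) == len(self.x1) == len(self.y1) == n):
            raise FormatError("coordinate series must share one length")
        if self.time_step_s <= 0:
            raise TimingError(f"time_step_s must be positive, got {self.time_step_s}")
        self.door_x_mm = tuple(float(d) for d in self.door_x_mm)
        for d in self.door_x_mm:
            if not 0.0 <= d <= self.x_span_mm:
                raise FormatError(f"door position {d} outside [0, {self.x_span_mm}]")

    @property
    def n_samples(self) -> int:
        return len(self.x0)

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.time_step_s

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.time_step_s

    def swapped(self) -> "TrajectoryPair":
        """Return a copy with the two agents' columns (and labels) exchanged."""
        return TrajectoryPair(
            time_step_s=self.time_step_s,
            x0=self.x1.copy(),
            y0=self.y1.copy(),
            x1=self.x0.copy(),
            y1=self.y0.copy(),
            x_span_mm=self.x_span_mm,
            wall_y_mm=self.wall_y_mm,
            door_x_mm=self.door_x_mm,
            labels=(self.labels[1], self.labels[0]),
        )


@dataclass
class SymbolSeries:
    """A discretized integer-state series with its bit depth.

    Every symbol lies in ``[0, 2**bits)``.
    """

    symbols: np.ndarray
    bits: int
    time_step_s: float

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1 or self.symbols.size < 1:
            raise InsufficientDataError("symbol series must be 1-D and non-empty")
        if self.bits < 1:
            raise ResolutionError(f"bits must be >= 1, got {self.bits}")
        lo, hi = self.symbols.min(), self.symbols.max()
        if lo < 0 or hi >= 2**self.bits:
            raise ResolutionError(
                f"symbols [{lo}, {hi}] outside alphabet [0, {2**self.bits})"
            )

    @property
    def n_states(self) -> int:
        return 2**self.bits

    def __len__(self) -> int:
        return len(self.symbols)


def read_trajectory_pair(
    path,
    x_span_mm: float = DEFAULT_X_SPAN_MM,
    wall_y_mm: float = DEFAULT_WALL_Y_MM,
    door_x_mm: tuple[float, ...] = (DEFAULT_X_SPAN_MM / 2.0,),
    labels: tuple[str, str] = ("fish0", "fish1"),
    dt_tolerance: float = 0.01,
) -> TrajectoryPair:
    """Read a paired-trajectory CSV (columns t, x0, y0, x1, y1).

    The time step is inferred from the median increment of ``t``; ``t`` must
    be strictly increasing and uniform within ``dt_tolerance`` (relative).
    Out-of-range x values are clamped to the tank span and the count logged.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InsufficientDataError(f"{path}: empty file") from exc
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 rows, got {len(df)}")

    t = df["t"].to_numpy(dtype=float)
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise TimingError(f"{path}: time column not strictly increasing")
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > dt_tolerance * dt):
        raise TimingError(f"{path}: non-uniform sampling (tolerance {dt_tolerance:.0%})")

    coords = {c: df[c].to_numpy(dtype=float) for c in CSV_COLUMNS[1:]}
    n_clamped = 0
    for c in ("x0", "x1"):
        out = (coords[c] < 0.0) | (coords[c] > x_span_mm)
        n_clamped += int(out.sum())
        coords[c] = np.clip(coords[c], 0.0, x_span_mm)
    if n_clamped:
        logger.info("%s: clamped %d out-of-span x samples", path, n_clamped)

    return TrajectoryPair(
        time_step_s=dt,
        x0=coords["x0"],
        y0=coords["y0"],
        x1=coords["x1"],
        y1=coords["y1"],
        x_span_mm=x_span_mm,
        wall_y_mm=wall_y_mm,
        door_x_mm=door_x_mm,
        labels=labels,
    )


def write_trajectory_pair(pair: TrajectoryPair, path) -> None:
    """Write a pair to CSV so that a read round-trips all coordinates."""
    if pair.n_samples < 2:
        raise InsufficientDataError("cannot write a pair with fewer than 2 samples")
    df = pd.DataFrame(
        {
            "t": pair.time_s,
            "x0": pair.x0,
            "y0": pair.y0,
            "x1": pair.x1,
            "y1": pair.y1,
        }
    )
    # %.12g keeps round-trip error far below the 1e-9 mm contract
    df.to_csv(path, index=False, float_format="%.12g")


def discretize_x(
    x: np.ndarray,
    bits: int,
    x_span_mm: float = DEFAULT_X_SPAN_MM,
    time_step_s: float = 1.0 / 30.0,
) -> SymbolSeries:
    """Bin x positions into ``2**bits`` equal-width states over the tank span.

    ``symbol = floor(x / (x_span_mm / 2**bits))``; ``x == x_span_mm`` maps to
    the top state and out-of-range values clamp to the edge bins.
    """
    if bits < 1:
        raise ResolutionError(f"bits must be >= 1, got {bits}")
    if bits > MAX_BITS:
        raise ResolutionError(f"bits={bits} exceeds maximum {MAX_BITS}")
    if x_span_mm <= 0:
        raise ResolutionError(f"x_span_mm must be positive, got {x_span_mm}")
    x = np.asarray(x, dtype=float)
    n_states = 2**bits
    sym = np.floor(x / (x_span_mm / n_states)).astype(np.int64)
    np.clip(sym, 0, n_states - 1, out=sym)
    return SymbolSeries(symbols=sym, bits=bits, time_step_s=time_step_s)


def discretize_uniform(
    x: np.ndarray,
    bits: int,
    time_step_s: float = 1.0 / 30.0,
) -> SymbolSeries:
    """Bin a real-valued series into ``2**bits`` equal-width states over its
    own [min, max] range (for dimensionless signals with no physical span)."""
    if bits < 1:
        raise ResolutionError(f"bits must be >= 1, got {bits}")
    if bits > MAX_BITS:
        raise ResolutionError(f"bits={bits} exceeds maximum {MAX_BITS}")
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    n_states = 2**bits
    if hi == lo:
        sym = np.zeros(len(x), dtype=np.int64)
    else:
        sym = np.floor((x - lo) / (hi - lo) * n_states).astype(np.int64)
        np.clip(sym, 0, n_states - 1, out=sym)
    return SymbolSeries(symbols=sym, bits=bits, time_step_s=time_step_s)


def channel_state(
    y: np.ndarray,
    wall_y_mm: float = DEFAULT_WALL_Y_MM,
    time_step_s: float = 1.0 / 30.0,
) -> SymbolSeries:
    """Reduce y positions to the 1-bit channel state.

    State 0 is the upper channel (``y > wall_y_mm``); a point exactly on the
    divider counts as lower (state 1).  The labelling is arbitrary but fixed;
    mutual-information results do not depend on it.
    """
    y = np.asarray(y, dtype=float)
    sym = np.where(y > wall_y_mm, 0, 1).astype(np.int64)
    return SymbolSeries(symbols=sym, bits=1, time_step_s=time_step_s)
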