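"""Deterministic summaries of small wet-lab tables.

Two quantities are covered: the intraspecific lethal rate of a phage from a
host-range (spot-assay) matrix — the percentage of tested conspecific
strains it lyses — and the burst size from a one-step growth curve — the
mean plaque titer over the growth plateau divided by the number of
initially infected cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SENSITIVE = "S"
INSENSITIVE = "I"
UNTESTED = "U"

_VALID_CELLS = {SENSITIVE, INSENSITIVE, UNTESTED}


@dataclass
class HostRangeMatrix:
    """Phages × strains grid of spot-assay outcomes (S/I/U).

    Untested cells never enter a denominator.
    """

    table: pd.DataFrame  # index: phage ids, columns: strain ids

    def __post_init__(self) -> None:
        if self.table.columns.duplicated().any():
            raise ValueError("duplicate strain ids in host-range matrix")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate phage ids in host-range matrix")
        bad = set(np.unique(self.table.values)) - _VALID_CELLS
        if bad:
            raise ValueError(f"invalid host-range codes: {sorted(bad)}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HostRangeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df.apply(lambda col: col.str.strip().str.upper()))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def lethal_rate(matrix: HostRangeMatrix, phage: str) -> float:
    """Percentage of tested strains the phage lyses, to 1 decimal.

    100 · sensitive / (sensitive + insensitive); untested strains are
    excluded from the denominator.
    """
    if phage not in matrix.table.index:
        raise KeyError(f"phage {phage!r} not in host-range matrix")
    row = matrix.table.loc[phage]
    sensitive = int((row == SENSITIVE).sum())
    insensitive = int((row == INSENSITIVE).sum())
    tested = sensitive + insensitive
    if tested == 0:
        raise ValueError(f"phage {phage!r}: all strains untested, rate undefined")
    return round(100.0 * sensitive / tested, 1)


@dataclass
class GrowthCurve:
    """One-step growth curve: phage titer over time after infection."""

    minutes: np.ndarray
    pfu_per_ml: np.ndarray
    initial_infected: float  # infected cells per mL at time zero

    def __post_init__(self) -> None:
        t = np.asarray(self.minutes, dtype=float)
        y = np.asarray(self.pfu_per_ml, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or len(t) < 2:
            raise ValueError("curve needs matched 1-D time and titer arrays (>= 2 points)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("titers must be non-negative")
        if self.initial_infected <= 0:
            raise ValueError("initial_infected must be positive")
        self.minutes = t
        self.pfu_per_ml = y

    @classmethod
    def read_tsv(cls, path: str | Path, initial_infected: float) -> "GrowthCurve":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected minutes<TAB>pfu_per_ml")
        return cls(
            minutes=df.iloc[:, 0].to_numpy(float),
            pfu_per_ml=df.iloc[:, 1].to_numpy(float),
            initial_infected=initial_infected,
        )


def detect_plateau(
    curve: GrowthCurve, ratio_tolerance: float = 0.2, min_points: int = 2
) -> tuple[float, float]:
    """Automatic plateau window: the longest suffix of time points whose
    titers agree pairwise within ``ratio_tolerance`` (max/min ≤ 1+tol)."""
    y = curve.pfu_per_ml
    t = curve.minutes
    end = len(y)
    start = end - 1
    while start > 0:
        window = y[start - 1 : end]
        if window.min() <= 0:
            break
        if window.max() / window.min() > 1.0 + ratio_tolerance:
            break
        start -= 1
    if end - start < min_points:
        raise ValueError(
            "no plateau found: fewer than "
            f"{min_points} terminal points agree within {ratio_tolerance:.0%}"
        )
    return float(t[start]), float(t[end - 1])


def burst_size(
    curve: GrowthCurve, plateau_window: Optional[tuple[float, float]] = None
) -> float:
    """Mean plateau titer divided by initially infected cells.

    ``plateau_window`` is an inclusive (start, end) time range in minutes;
    when omitted the plateau is detected automatically (see
    :func:`detect_plateau`).
    """
    if plateau_window is None:
        plateau_window = detect_plateau(curve)
    lo, hi = plateau_window
    if lo > hi:
        raise ValueError(f"empty plateau window ({lo}, {hi})")
    if lo < curve.minutes[0] or hi > curve.minutes[-1]:
        raise ValueError(
            f"plateau window ({lo}, {hi}) outside observed range "
            f"({curve.minutes[0]}, {curve.minutes[-1]})"
        )
    mask = (curve.minutes >= lo) & (curve.minutes <= hi)
    if not mask.any():
        raise ValueError(f"no time points inside plateau window ({lo}, {hi})")
    plateau_mean = float(curve.pfu_per_ml[mask].mean())
    return plateau_mean / curve.initial_infected
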