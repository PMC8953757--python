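"""Direct-terminal-repeat (DTR) inference from a per-base coverage profile.

A linear phage genome packaged with a direct terminal repeat carries the
repeat at both ends, so reads from both copies pile onto the single copy in
the assembly: the repeat shows roughly twice the depth of the rest of the
genome.  This module formalises that reasoning as a two-segment least-squares
changepoint fit: the boundary is the split of the profile into a terminal
segment and a remainder that minimises the pooled within-segment sum of
squared deviations (equivalently maximises the between-means separation).
The ratio of segment means estimates the per-packaged-genome copy number of
the repeat.

This is a deliberately simple detector for the coverage argument alone; it
does not model read termini or packaging mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

MIN_PROFILE_LEN = 100
DEFAULT_MIN_LEN = 500
DEFAULT_MAX_FRAC = 0.25
DEFAULT_FOLD_THRESHOLD = 1.5


@dataclass
class CoverageProfile:
    """Per-base sequencing depth along a genome."""

    depths: np.ndarray
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        arr = np.asarray(self.depths, dtype=float)
        if arr.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if len(arr) < MIN_PROFILE_LEN:
            raise ValueError(
                f"profile of {len(arr)} positions is below the detector "
                f"minimum of {MIN_PROFILE_LEN}"
            )
        if np.any(arr < 0):
            raise ValueError("depths must be non-negative")
        self.depths = arr

    def __len__(self) -> int:
        return len(self.depths)


@dataclass(frozen=True)
class DTRCall:
    """A detected terminal repeat.

    ``boundary`` is the 0-based position where the elevated terminal segment
    ends; for ``terminus == "start"`` the repeat covers [0, boundary).
    ``copies`` is the rounded fold change — the repeat's copy number in one
    completely packaged genome.
    """

    boundary: int
    mean_high: float
    mean_rest: float
    fold_change: float
    copies: int
    terminus: str = "start"

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError("boundary must be positive")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if self.copies != round(self.fold_change) or self.copies < 1:
            raise ValueError("copies must equal round(fold_change) and be >= 1")

    def to_dict(self) -> dict:
        return {
            "boundary": self.boundary,
            "mean_high": self.mean_high,
            "mean_rest": self.mean_rest,
            "fold_change": self.fold_change,
            "copies": self.copies,
            "terminus": self.terminus,
        }


def _best_prefix_boundary(
    depths: np.ndarray, min_len: int, max_len: int
) -> tuple[int, float]:
    """Boundary in [min_len, max_len] minimising within-segment SSE.

    O(L) via cumulative sums: SSE(b) = (S2_pre − S1_pre²/b) + (S2_suf − S1_suf²/(L−b)).
    Minimising SSE is the same as maximising the between-segment separation
    b·(L−b)/L·(mean_pre − mean_suf)² since total SS is constant.
    """
    L = len(depths)
    c1 = np.concatenate(([0.0], np.cumsum(depths)))
    c2 = np.concatenate(([0.0], np.cumsum(depths**2)))
    bs = np.arange(min_len, max_len + 1)
    s1_pre, s2_pre = c1[bs], c2[bs]
    s1_suf, s2_suf = c1[L] - s1_pre, c2[L] - s2_pre
    sse = (s2_pre - s1_pre**2 / bs) + (s2_suf - s1_suf**2 / (L - bs))
    i = int(np.argmin(sse))
    return int(bs[i]), float(sse[i])


def detect_dtr(
    coverage: CoverageProfile,
    min_len: int = DEFAULT_MIN_LEN,
    max_frac: float = DEFAULT_MAX_FRAC,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    both_ends: bool = False,
) -> Optional[DTRCall]:
    """Locate a terminal repeat as a coverage step, or report no-call.

    The candidate boundary ranges over ``[min_len, max_frac·L]`` at the
    genome start (packaged-genome convention: the repeat sits at the physical
    end the assembly begins with); with ``both_ends`` a mirror window at the
    genome end is also scanned and the better-separating end wins.  A call is
    only emitted when the fitted fold change reaches ``fold_threshold`` —
    below that the profile is treated as repeat-free (a one-copy terminus is
    indistinguishable from no repeat).
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    if not (0 < max_frac <= 0.5):
        raise ValueError("max_frac must be in (0, 0.5]")
    depths = coverage.depths
    L = len(depths)
    if L < 2 * min_len:
        raise ValueError(
            f"profile length {L} is shorter than 2×min_len ({2 * min_len})"
        )
    max_len = int(max_frac * L)
    if max_len < min_len:
        raise ValueError("max_frac·L below min_len: search window is empty")

    candidates: list[tuple[float, int, str]] = []
    b, sse = _best_prefix_boundary(depths, min_len, max_len)
    candidates.append((sse, b, "start"))
    if both_ends:
        b_rev, sse_rev = _best_prefix_boundary(depths[::-1], min_len, max_len)
        candidates.append((sse_rev, b_rev, "end"))
    sse_best, boundary, terminus = min(candidates)

    if terminus == "start":
        high, rest = depths[:boundary], depths[boundary:]
    else:
        high, rest = depths[L - boundary:], depths[: L - boundary]
        boundary = L - boundary  # report as a genome coordinate
    mean_high = float(high.mean())
    mean_rest = float(rest.mean())
    if mean_rest == 0.0:
        return None
    fold = mean_high / mean_rest
    if fold < fold_threshold:
        return None
    if terminus == "end":
        # For a suffix repeat the elevated segment is [boundary, L).
        return DTRCall(
            boundary=boundary,
            mean_high=mean_high,
            mean_rest=mean_rest,
            fold_change=fold,
            copies=int(round(fold)),
            terminus="end",
        )
    return DTRCall(
        boundary=boundary,
        mean_high=mean_high,
        mean_rest=mean_rest,
        fold_change=fold,
        copies=int(round(fold)),
        terminus="start",
    )


def summarize_segments(coverage: CoverageProfile, boundary: int) -> dict:
    """Mean and sample standard deviation of depth on each side of a boundary."""
    L = len(coverage)
    if not (0 < boundary < L):
        raise ValueError(f"boundary must lie strictly inside (0, {L})")
    high = coverage.depths[:boundary]
    rest = coverage.depths[boundary:]
    return {
        "mean_high": float(high.mean()),
        "sd_high": float(high.std(ddof=1)) if len(high) > 1 else 0.0,
        "mean_rest": float(rest.mean()),
        "sd_rest": float(rest.std(ddof=1)) if len(rest) > 1 else 0.0,
    }


def read_depths(path: str | Path, genome_id: str = "genome") -> CoverageProfile:
    """Read a depth profile from TSV.

    Two-column ``pos<TAB>depth`` (1-based positions; gaps imply depth 0) or a
    plain one-column depth file (one value per line, position implicit).
    """
    path = Path(path)
    positions: list[int] = []
    values: list[float] = []
    two_col = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if two_col is None:
                two_col = len(parts) >= 2
            if two_col:
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected pos<TAB>depth")
                positions.append(int(parts[0]))
                values.append(float(parts[1]))
            else:
                values.append(float(parts[0]))
    if two_col:
        if not positions:
            raise ValueError(f"{path}: empty depth table")
        length = max(positions)
        depths = np.zeros(length, dtype=float)
        for pos, d in zip(positions, values):
            if pos < 1:
                raise ValueError(f"{path}: positions are 1-based, got {pos}")
            depths[pos - 1] = d
    else:
        depths = np.asarray(values, dtype=float)
    return CoverageProfile(depths=depths, genome_id=genome_id)
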