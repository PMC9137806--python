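"""The Displacement Index: per-sample distance, per-second index, trial mean.

The vibration-intensity statistic works on raw tri-axial acceleration. For
consecutive readings :math:`p_m = (x_m, y_m, z_m)` and :math:`p_n`, the
displacement is the Euclidean distance

.. math:: D = \\sqrt{(x_n - x_m)^2 + (y_n - y_m)^2 + (z_n - z_m)^2},

combining all three axes because any movement, independent of direction,
shakes the transported semen doses. The Displacement Index for second *k*
averages the *f* distances of that second (sampling frequency *f*), and the
trial mean D̄x averages the per-second indices over the trial.

Because D is a difference norm, the whole family is translation-invariant
(gravity or any constant offset cancels) and positively scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from roadvib.logio import AccelSample, LoggerTrace


class InsufficientDataError(ValueError):
    """Raised when an operation needs more samples than the input holds."""


#: Table-style D_i bin boundaries: first bin closed at 1 ("<=1"), later bins
#: left-open (">1-2", ...), last bin unbounded.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, float("inf"))

#: Road-quality classes from D_i: good (<= 1), moderate (1, 1.5), bad (>= 1.5).
QUALITY_BOUNDS: dict[str, tuple[float, float]] = {
    "good": (0.0, 1.0),
    "moderate": (1.0, 1.5),
    "bad": (1.5, float("inf")),
}

QUALITY_LABELS = ("good", "moderate", "bad")


def _as_vector(p: AccelSample | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(p, AccelSample):
        return p.vector()
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def sample_distance(p_m: AccelSample | Sequence[float], p_n: AccelSample | Sequence[float]) -> float:
    """Euclidean distance between two tri-axial acceleration readings."""
    a, b = _as_vector(p_m), _as_vector(p_n)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("acceleration readings must be finite")
    return float(np.linalg.norm(b - a))


def consecutive_distances(accel: np.ndarray) -> np.ndarray:
    """Distances between each pair of consecutive samples; length n-1."""
    accel = np.asarray(accel, dtype=float).reshape(-1, 3)
    return np.linalg.norm(np.diff(accel, axis=0), axis=1)


@dataclass
class DisplacementSeries:
    """Per-second Displacement Index values derived from one trace."""

    f: int
    values: np.ndarray
    source_duration: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size and self.values.min() < 0:
            raise ValueError("Displacement Index values must be >= 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Covered time in seconds (one value per second)."""
        return float(len(self))


@dataclass(frozen=True)
class TrialResult:
    """Mean Displacement Index and D_i extremes of one standardized trial."""

    surface: str
    speed: float
    dbar: float
    min_di: float
    max_di: float
    seconds: float

    def __post_init__(self) -> None:
        if self.seconds <= 0:
            raise ValueError("trial duration must be positive")
        if not self.min_di <= self.dbar <= self.max_di:
            raise ValueError("trial mean must lie between the D_i extremes")


def displacement_series(trace: LoggerTrace) -> DisplacementSeries:
    """Compute the per-second Displacement Index series of a trace.

    The n-1 consecutive-sample distances are averaged in non-overlapping
    blocks of *f* distances aligned to the first distance; a trailing block
    with fewer than *f* distances is dropped (the index divides by *f*, so a
    partial block would be biased low). A 60 s trace at 50 Hz therefore
    yields 59 full windows from its 2999 distances.
    """
    if trace.n_samples < 2:
        raise InsufficientDataError("need at least 2 samples to compute distances")
    d = consecutive_distances(trace.accel)
    f = trace.f
    n_win = d.size // f
    values = d[: n_win * f].reshape(n_win, f).mean(axis=1) if n_win else np.empty(0)
    return DisplacementSeries(f=f, values=values, source_duration=trace.duration)


def trial_mean(series: DisplacementSeries) -> float:
    """Mean Displacement Index D̄x over a series (Eq. 3 style average)."""
    if len(series) == 0:
        raise InsufficientDataError("cannot average an empty Displacement-Index series")
    return float(series.values.mean())


def trial_summary(series: DisplacementSeries, surface: str, speed: float) -> TrialResult:
    """Summarize one trial: D̄x plus the minimum and maximum per-second D_i."""
    if len(series) == 0:
        raise InsufficientDataError("cannot summarize an empty Displacement-Index series")
    return TrialResult(
        surface=surface,
        speed=float(speed),
        dbar=trial_mean(series),
        min_di=float(series.values.min()),
        max_di=float(series.values.max()),
        seconds=series.duration,
    )


def classify_quality(di: float) -> str:
    """Road-quality class of a D_i value: good / moderate / bad.

    good iff D_i <= 1; moderate iff 1 < D_i < 1.5; bad iff D_i >= 1.5.
    """
    if not np.isfinite(di) or di < 0:
        raise ValueError(f"D_i must be finite and >= 0, got {di}")
    if di <= 1.0:
        return "good"
    if di < 1.5:
        return "moderate"
    return "bad"


def quality_proportions(series: DisplacementSeries) -> dict[str, float]:
    """Percentage of seconds per quality class (sums to 100)."""
    if len(series) == 0:
        raise InsufficientDataError("cannot classify an empty series")
    v = series.values
    n = v.size
    good = int(np.count_nonzero(v <= 1.0))
    bad = int(np.count_nonzero(v >= 1.5))
    return {
        "good": 100.0 * good / n,
        "moderate": 100.0 * (n - good - bad) / n,
        "bad": 100.0 * bad / n,
    }


@dataclass
class BinnedDistribution:
    """Relative frequency and absolute time of D_i levels."""

    edges: tuple[float, ...]
    counts: np.ndarray
    freq_pct: np.ndarray
    abs_time_s: np.ndarray

    def labels(self) -> list[str]:
        out = [f"<={_short(self.edges[1])}"]
        for lo, hi in zip(self.edges[1:-1], self.edges[2:]):
            out.append(f">{_short(lo)}" if np.isinf(hi) else f">{_short(lo)}-{_short(hi)}")
        return out

    @property
    def abs_time_min(self) -> np.ndarray:
        return self.abs_time_s / 60.0


def _short(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def bin_distribution(
    series: DisplacementSeries, edges: Iterable[float] = DEFAULT_BIN_EDGES
) -> BinnedDistribution:
    """Bin per-second D_i values into intensity levels.

    The first bin is closed at its upper edge and every later bin is
    left-open, so with the default edges the levels read ``<=1``, ``>1-2``,
    ..., ``>5``. Absolute time per bin is the second count; frequencies are
    percentages of the series length.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing with at least two entries")
    if len(series) == 0:
        raise InsufficientDataError("cannot bin an empty series")
    v = series.values
    if v.min() < edges[0] or (np.isfinite(edges[-1]) and v.max() > edges[-1]):
        raise ValueError("series contains values outside the binning range")
    inner = np.asarray(edges[1:-1])
    idx = np.digitize(v, inner, right=True)  # (edges[i], edges[i+1]] per bin
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(int)
    total = v.size
    return BinnedDistribution(
        edges=edges,
        counts=counts,
        freq_pct=100.0 * counts / total,
        abs_time_s=counts.astype(float),
    )
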