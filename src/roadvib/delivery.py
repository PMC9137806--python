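"""Field-delivery analysis: trip summary, binning, high-vibration segments.

A delivery trace is summarized by its overall mean Displacement Index, the
relative frequency / absolute time spent at each D_i level, and the share of
seconds per road-quality class. Sections with markedly increased vibrations
(e.g. unpaved access roads to sow farms) are extracted as maximal runs of
seconds strictly above a threshold and geolocated from the GNSS track.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from roadvib.displacement import (
    BinnedDistribution,
    DisplacementSeries,
    DEFAULT_BIN_EDGES,
    bin_distribution,
    quality_proportions,
    trial_mean,
)
from roadvib.logio import GnssFix, LoggerTrace


@dataclass(frozen=True)
class VibrationSegment:
    """A contiguous run of seconds with D_i above a threshold."""

    start_s: float
    end_s: float  # exclusive
    threshold: float
    mean_di: float
    peak_di: float
    start_fix: GnssFix | None = None
    end_fix: GnssFix | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("segment end must be after its start")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class DeliveryReport:
    """Summary of one delivery: overall D̄x, D_i distribution, quality mix."""

    duration_s: float
    dbar: float
    distribution: BinnedDistribution
    quality_pct: dict[str, float]
    segments: list[VibrationSegment] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "duration_min": self.duration_s / 60.0,
            "dbar": self.dbar,
            "distribution": [
                {
                    "level": label,
                    "frequency_pct": float(f),
                    "absolute_time_min": float(t) / 60.0,
                }
                for label, f, t in zip(
                    self.distribution.labels(),
                    self.distribution.freq_pct,
                    self.distribution.abs_time_s,
                )
            ],
            "quality_pct": dict(self.quality_pct),
            "segments": [
                {
                    "start_s": s.start_s,
                    "end_s": s.end_s,
                    "duration_s": s.duration,
                    "threshold": s.threshold,
                    "mean_di": s.mean_di,
                    "peak_di": s.peak_di,
                    "start_fix": None
                    if s.start_fix is None
                    else {"lat": s.start_fix.lat, "lon": s.start_fix.lon, "time": s.start_fix.time},
                    "end_fix": None
                    if s.end_fix is None
                    else {"lat": s.end_fix.lat, "lon": s.end_fix.lon, "time": s.end_fix.time},
                }
                for s in self.segments
            ],
        }

    def to_json(self, path: str | Path, **extra) -> None:
        payload = self.to_dict()
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def delivery_summary(
    series: DisplacementSeries, edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> DeliveryReport:
    """Trip-level summary (without segment detection)."""
    return DeliveryReport(
        duration_s=series.duration,
        dbar=trial_mean(series),
        distribution=bin_distribution(series, edges),
        quality_pct=quality_proportions(series),
    )


def detect_segments(
    series: DisplacementSeries,
    threshold: float = 3.0,
    min_duration: float = 1.0,
    gap_tolerance: float = 0.0,
) -> list[VibrationSegment]:
    """Maximal runs of consecutive seconds with D_i strictly above *threshold*.

    Runs shorter than *min_duration* seconds are discarded. With a positive
    *gap_tolerance*, runs separated by at most that many below-threshold
    seconds are merged (the merged segment's mean may then dip below the
    threshold).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_duration < 1:
        raise ValueError("min_duration must be at least 1 second")
    v = series.values
    above = v > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    runs = list(zip(edges[::2], edges[1::2]))  # half-open [start, end)
    if gap_tolerance > 0:
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= gap_tolerance:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [tuple(r) for r in merged]
    out = []
    for s, e in runs:
        if e - s >= min_duration:
            window = v[s:e]
            out.append(
                VibrationSegment(
                    start_s=float(s),
                    end_s=float(e),
                    threshold=threshold,
                    mean_di=float(window.mean()),
                    peak_di=float(window.max()),
                )
            )
    return out


def _nearest_fix(fixes: list[GnssFix], t: float) -> GnssFix:
    times = np.array([f.time for f in fixes])
    return fixes[int(np.argmin(np.abs(times - t)))]


def locate_segments(
    segments: list[VibrationSegment], trace: LoggerTrace
) -> list[VibrationSegment]:
    """Annotate segments with the nearest-in-time GNSS fixes of their endpoints.

    With no fixes available the segments are returned unannotated and a
    warning is emitted.
    """
    if not trace.gnss:
        if segments:
            warnings.warn("trace has no GNSS fixes; segments left unlocated", stacklevel=2)
        return list(segments)
    return [
        replace(
            seg,
            start_fix=_nearest_fix(trace.gnss, seg.start_s),
            end_fix=_nearest_fix(trace.gnss, seg.end_s),
        )
        for seg in segments
    ]


def analyze_delivery(
    trace: LoggerTrace,
    threshold: float = 3.0,
    min_duration: float = 30.0,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    gap_tolerance: float = 0.0,
) -> DeliveryReport:
    """Full delivery analysis of a trace: summary plus located segments."""
    from roadvib.displacement import displacement_series

    series = displacement_series(trace)
    report = delivery_summary(series, edges)
    segments = detect_segments(series, threshold, min_duration, gap_tolerance)
    report.segments = locate_segments(segments, trace)
    return report
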