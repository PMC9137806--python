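"""Synthetic accelerometer traces with the study's statistical structure.

The generator draws each sample i.i.d. Gaussian per axis around a constant
gravity vector. Consecutive differences per axis are then Gaussian with
standard deviation :math:`\\sigma_a\\sqrt{2}`, so the consecutive-sample
distance follows a 3-d chi distribution with mean

.. math:: E[D] = \\sigma_a \\sqrt{2} \\cdot \\sqrt{2}\\,
          \\frac{\\Gamma(2)}{\\Gamma(3/2)} = \\frac{4}{\\sqrt{\\pi}}\\sigma_a .

Inverting that expectation calibrates the per-axis noise scale to any target
mean Displacement Index exactly (the MA(1) correlation of differences of
i.i.d. samples affects only the variance of the per-second average, not its
mean). Per-category intensities are taken from a packaged reference table of
standardized road-trial summaries (surfaces A smooth asphalt, B rough
asphalt, C cobblestone, D dirt road; speeds 30-150 km/h); short Poisson
impulse bursts mimic the irregular single impacts of rough and unpaved
roads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from roadvib.logio import Annotation, GnssFix, LoggerTrace

#: Mean of ||N(0, I_3)|| differences scale: E[D] = CHI3_DIFF_MEAN * sigma_a.
CHI3_DIFF_MEAN = 4.0 / math.sqrt(math.pi)

DEFAULT_GRAVITY = (0.0, 0.0, 1.0)  # logger units (g); cancels in all D math

SURFACES = ("A", "B", "C", "D")


def calibrate_sigma(target_di: float) -> float:
    """Per-axis noise scale whose expected consecutive distance is *target_di*.

    Linear in the target: ``calibrate_sigma(c * x) == c * calibrate_sigma(x)``.
    """
    if not np.isfinite(target_di) or target_di < 0:
        raise ValueError(f"target D_i must be finite and >= 0, got {target_di}")
    return target_di / CHI3_DIFF_MEAN


@dataclass(frozen=True)
class SurfaceModel:
    """Vibration model of one road-surface x speed category."""

    surface: str
    speed: float
    target_dbar: float
    between_trial_sd: float = 0.0
    impulse_rate: float = 0.0  # bursts per minute
    impulse_scale: float = 8.0  # burst amplitude as multiple of base sigma_a

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ValueError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        if self.target_dbar < 0 or self.between_trial_sd < 0:
            raise ValueError("target_dbar and between_trial_sd must be >= 0")
        if self.impulse_rate < 0 or self.impulse_scale < 0:
            raise ValueError("impulse parameters must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.surface}-{int(self.speed)}"


def _rng(seed: int, counter: int = 0) -> np.random.Generator:
    # single seed stream split per trial by counter; portable across runs
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(counter),)))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return max(0.0, mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0  # pathological mean << -sd; effectively the truncation mass point


def _simulate_samples(
    model: SurfaceModel,
    duration: float,
    f: int,
    rng: np.random.Generator,
    gravity: tuple[float, float, float],
) -> tuple[np.ndarray, list[float]]:
    """Raw (n, 3) samples plus impulse start times."""
    n = int(round(duration * f))
    intensity = _truncated_normal(rng, model.target_dbar, model.between_trial_sd)
    sigma = calibrate_sigma(intensity)
    accel = np.asarray(gravity, dtype=float) + rng.normal(0.0, sigma, size=(n, 3))
    impulse_times: list[float] = []
    if model.impulse_rate > 0 and sigma > 0:
        k = rng.poisson(model.impulse_rate * duration / 60.0)
        starts = np.sort(rng.uniform(0.0, duration, size=k))
        for t0 in starts:
            burst = rng.uniform(0.04, 0.2)  # bursts stay below 0.2 s
            i0 = int(t0 * f)
            i1 = min(n, i0 + max(1, int(burst * f)))
            accel[i0:i1] += rng.normal(0.0, model.impulse_scale * sigma, size=(i1 - i0, 3))
            impulse_times.append(float(t0))
    return accel, impulse_times


def simulate_trial(
    model: SurfaceModel,
    duration: float = 60.0,
    f: int = 50,
    seed: int = 0,
    gravity: tuple[float, float, float] = DEFAULT_GRAVITY,
) -> LoggerTrace:
    """Simulate one standardized road trial (default 60 s at 50 Hz).

    The per-trial intensity is drawn from Normal(target_dbar,
    between_trial_sd) truncated at zero and converted to a per-axis noise
    scale via :func:`calibrate_sigma`. The same seed always reproduces the
    identical trace. Annotations record the surface, the speed, and every
    impulse burst.
    """
    if duration <= 0 or f <= 0:
        raise ValueError("duration and sampling frequency must be positive")
    rng = _rng(seed)
    accel, impulses = _simulate_samples(model, duration, f, rng, gravity)
    annotations = [
        Annotation(time=0.0, kind="road_surface", value=model.surface),
        Annotation(time=0.0, kind="speed", value=float(model.speed)),
    ]
    annotations += [Annotation(time=t, kind="event", value="impulse") for t in impulses]
    return LoggerTrace(
        f=int(f),
        accel=accel,
        annotations=annotations,
        meta={"device": "roadvib-synth", "seed": str(seed), "category": model.label},
    )


def reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """Per-category road-trial reference parameters (packaged CSV by default)."""
    if path is None:
        with resources.files("roadvib.data").joinpath("road_trial_reference.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def default_trial_design(path: str | Path | None = None) -> list[tuple[SurfaceModel, int]]:
    """The standardized 12-category design: 10 replicates per observed cell.

    Cells: A at 30/60/90/120/150 km/h, B at 30-120, C at 30/60, D at 30 —
    120 trials in total.
    """
    table = reference_table(path)
    design: list[tuple[SurfaceModel, int]] = []
    for row in table.itertuples(index=False):
        model = SurfaceModel(
            surface=str(row.surface),
            speed=float(row.speed),
            target_dbar=float(row.mean_dbar),
            between_trial_sd=float(row.sd_dbar),
            impulse_rate=float(row.impulse_rate_per_min),
            impulse_scale=float(row.impulse_scale),
        )
        design.append((model, 10))
    return design


def simulate_design(
    design: list[tuple[SurfaceModel, int]] | None = None,
    duration: float = 60.0,
    f: int = 50,
    seed: int = 0,
) -> list[tuple[SurfaceModel, int, LoggerTrace]]:
    """Simulate every replicate of a trial design with per-trial sub-seeds."""
    if design is None:
        design = default_trial_design()
    out: list[tuple[SurfaceModel, int, LoggerTrace]] = []
    counter = 0
    for model, reps in design:
        for rep in range(reps):
            rng = _rng(seed, counter)
            accel, impulses = _simulate_samples(model, duration, f, rng, DEFAULT_GRAVITY)
            annotations = [
                Annotation(time=0.0, kind="road_surface", value=model.surface),
                Annotation(time=0.0, kind="speed", value=float(model.speed)),
            ] + [Annotation(time=t, kind="event", value="impulse") for t in impulses]
            trace = LoggerTrace(
                f=int(f),
                accel=accel,
                annotations=annotations,
                meta={
                    "device": "roadvib-synth",
                    "seed": str(seed),
                    "trial": str(counter),
                    "category": model.label,
                },
            )
            out.append((model, rep, trace))
            counter += 1
    return out


@dataclass(frozen=True)
class RouteSegment:
    """One leg of a delivery: a surface model driven for a fixed duration."""

    model: SurfaceModel
    duration: float
    start: tuple[float, float]  # (lat, lon)
    end: tuple[float, float]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass
class RoutePlan:
    """Ordered route segments forming one delivery."""

    segments: list[RouteSegment] = field(default_factory=list)

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RoutePlan":
        ref = reference_table()
        segments = []
        for seg in cfg["segments"]:
            surface, speed = str(seg["surface"]), float(seg["speed"])
            row = ref[(ref.surface == surface) & (ref.speed == speed)]
            defaults = row.iloc[0] if len(row) else None
            model = SurfaceModel(
                surface=surface,
                speed=speed,
                target_dbar=float(
                    seg.get("target_dbar", defaults.mean_dbar if defaults is not None else 0.0)
                ),
                between_trial_sd=float(
                    seg.get("between_trial_sd", defaults.sd_dbar if defaults is not None else 0.0)
                ),
                impulse_rate=float(
                    seg.get(
                        "impulse_rate",
                        defaults.impulse_rate_per_min if defaults is not None else 0.0,
                    )
                ),
                impulse_scale=float(
                    seg.get("impulse_scale", defaults.impulse_scale if defaults is not None else 8.0)
                ),
            )
            segments.append(
                RouteSegment(
                    model=model,
                    duration=float(seg["duration"]),
                    start=tuple(float(x) for x in seg["start"]),
                    end=tuple(float(x) for x in seg["end"]),
                )
            )
        return cls(segments=segments)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoutePlan":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_delivery(
    plan: RoutePlan,
    f: int = 50,
    seed: int = 0,
    gravity: tuple[float, float, float] = DEFAULT_GRAVITY,
) -> LoggerTrace:
    """Simulate a multi-segment delivery with a 1 Hz interpolated GNSS track.

    Per-segment samples are concatenated in plan order; each segment gets a
    road-surface and a speed annotation at its start plus an event marker,
    and GNSS fixes interpolate linearly between its endpoints.
    """
    if not plan.segments:
        raise ValueError("route plan has no segments")
    accel_parts: list[np.ndarray] = []
    annotations: list[Annotation] = []
    gnss: list[GnssFix] = []
    t0 = 0.0
    for i, seg in enumerate(plan.segments):
        rng = _rng(seed, i)
        accel, impulses = _simulate_samples(seg.model, seg.duration, f, rng, gravity)
        accel_parts.append(accel)
        annotations.append(Annotation(time=t0, kind="event", value=f"segment_{i}"))
        annotations.append(Annotation(time=t0, kind="road_surface", value=seg.model.surface))
        annotations.append(Annotation(time=t0, kind="speed", value=float(seg.model.speed)))
        annotations += [Annotation(time=t0 + t, kind="event", value="impulse") for t in impulses]
        n_fix = int(seg.duration)  # 1 Hz within the segment
        for k in range(n_fix + (1 if i == len(plan.segments) - 1 else 0)):
            w = k / seg.duration
            gnss.append(
                GnssFix(
                    time=t0 + k,
                    lat=seg.start[0] + w * (seg.end[0] - seg.start[0]),
                    lon=seg.start[1] + w * (seg.end[1] - seg.start[1]),
                )
            )
        t0 += seg.duration
    annotations.sort(key=lambda a: a.time)
    return LoggerTrace(
        f=int(f),
        accel=np.vstack(accel_parts),
        gnss=gnss,
        annotations=annotations,
        meta={"device": "roadvib-synth", "seed": str(seed), "kind": "delivery"},
    )
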