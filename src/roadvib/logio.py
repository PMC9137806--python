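"""Data-logger text format and export of derived series.

The logger stores one record per line as ``key=value`` pairs separated by
``;``, with the record type first::

    rec=hdr;f=50;date=2022-05-23T08:00:00;device=nano33ble
    rec=acc;i=0;ax=0.0123;ay=-0.981;az=0.0502
    rec=aux;t=0.0;ch=temperature;v=17.2
    rec=gnss;t=12.0;lat=52.6701;lon=13.5803;ele=62.0
    rec=ann;t=30.0;k=road_surface;v=C

Acceleration values are unit-agnostic (interpreted as g by default) and are
serialized with 6 significant digits; all timestamps are seconds from trace
start. Absolute date/time lives only in the header.
"""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from roadvib.displacement import DisplacementSeries


class LogFormatError(ValueError):
    """A structural problem in a log file (e.g. a missing header key)."""


class LogParseError(ValueError):
    """A field that could not be parsed, reported with its line number."""


class LogIntegrityError(ValueError):
    """Parsed records that violate a trace invariant."""


ANNOTATION_KINDS = ("speed", "road_surface", "event")

# characters that would break the key=value;... line structure
_FORBIDDEN = set(";=\n\r")


@dataclass(frozen=True)
class AccelSample:
    """One tri-axial acceleration reading (logger units, default g)."""

    index: int
    ax: float
    ay: float
    az: float

    def vector(self) -> np.ndarray:
        return np.array([self.ax, self.ay, self.az], dtype=float)


@dataclass(frozen=True)
class GnssFix:
    """A GNSS position fix, timed in seconds from trace start."""

    time: float
    lat: float
    lon: float
    elevation: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")


@dataclass(frozen=True)
class Annotation:
    """A timed note: vehicle speed (km/h), road-surface label, or free event."""

    time: float
    kind: str
    value: float | str

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(
                f"annotation kind must be one of {ANNOTATION_KINDS}, got {self.kind!r}"
            )
        if self.kind == "speed" and float(self.value) < 0:
            raise ValueError("speed annotations must be >= 0")


@dataclass
class LoggerTrace:
    """One recording: sampled tri-axial acceleration plus auxiliary channels.

    Parameters
    ----------
    f
        Sampling frequency in Hz (positive integer).
    accel
        Array of shape ``(n, 3)`` with per-sample ``(ax, ay, az)``.
    aux
        Optional auxiliary channels (temperature, pressure, light,
        humidity, ...), each a list of ``(time_s, value)`` pairs.
    gnss
        GNSS fixes with non-decreasing times.
    annotations
        Speed / road-surface / event annotations.
    meta
        Header strings (date, device, ...).
    """

    f: int
    accel: np.ndarray
    aux: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    gnss: list[GnssFix] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        if int(self.f) != self.f or self.f <= 0:
            raise ValueError(f"sampling frequency must be a positive integer, got {self.f}")
        self.f = int(self.f)
        if not np.all(np.isfinite(self.accel)):
            raise ValueError("acceleration samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration(self) -> float:
        """Trace duration in seconds (sample count over sampling rate)."""
        return self.n_samples / self.f

    def samples(self) -> Iterator[AccelSample]:
        for i, (ax, ay, az) in enumerate(self.accel):
            yield AccelSample(i, float(ax), float(ay), float(az))

    def validate(self) -> None:
        """Raise :class:`LogIntegrityError` if timed records exceed duration."""
        d = self.duration
        for fix in self.gnss:
            if fix.time > d + 1e-9:
                raise LogIntegrityError(f"GNSS fix at t={fix.time} exceeds duration {d}")
        times = [fix.time for fix in self.gnss]
        if any(b < a for a, b in zip(times, times[1:])):
            raise LogIntegrityError("GNSS fix times must be non-decreasing")
        for ann in self.annotations:
            if ann.time > d + 1e-9:
                raise LogIntegrityError(f"annotation at t={ann.time} exceeds duration {d}")


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def _check_text(value: str) -> str:
    if _FORBIDDEN & set(value):
        raise ValueError(f"value contains reserved characters (';', '=' or newline): {value!r}")
    return value


def _parse_line(line: str, lineno: int) -> dict[str, str]:
    fields: dict[str, str] = {}
    for chunk in line.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise LogParseError(f"line {lineno}: malformed field {chunk!r}")
        k, v = chunk.split("=", 1)
        fields[k] = v
    return fields


def _parse_float(fields: dict[str, str], key: str, lineno: int) -> float:
    try:
        return float(fields[key])
    except KeyError:
        raise LogParseError(f"line {lineno}: missing field {key!r}") from None
    except ValueError:
        raise LogParseError(
            f"line {lineno}: non-numeric value {fields[key]!r} for field {key!r}"
        ) from None


def read_log(path: str | Path) -> LoggerTrace:
    """Read a logger text file into a :class:`LoggerTrace`.

    Raises
    ------
    LogFormatError
        If the header is absent or misses a required key.
    LogParseError
        If a field cannot be parsed (message carries the line number).
    LogIntegrityError
        If acceleration sample indices are not strictly increasing.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    f_hz: int | None = None
    accel_rows: list[tuple[float, float, float]] = []
    indices: list[int] = []
    aux: dict[str, list[tuple[float, float]]] = {}
    gnss: list[GnssFix] = []
    annotations: list[Annotation] = []
    saw_header = False

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _parse_line(line, lineno)
            rec = fields.pop("rec", None)
            if rec is None:
                raise LogFormatError(f"line {lineno}: record without 'rec' key")
            if rec == "hdr":
                saw_header = True
                if "f" not in fields:
                    raise LogFormatError("header is missing required key 'f'")
                f_val = _parse_float(fields, "f", lineno)
                if f_val <= 0 or int(f_val) != f_val:
                    raise LogFormatError(f"header key 'f' must be a positive integer, got {fields['f']}")
                f_hz = int(f_val)
                meta.update({k: v for k, v in fields.items() if k != "f"})
            elif rec == "acc":
                idx = int(_parse_float(fields, "i", lineno))
                indices.append(idx)
                accel_rows.append(
                    (
                        _parse_float(fields, "ax", lineno),
                        _parse_float(fields, "ay", lineno),
                        _parse_float(fields, "az", lineno),
                    )
                )
            elif rec == "aux":
                ch = fields.get("ch")
                if ch is None:
                    raise LogParseError(f"line {lineno}: aux record without 'ch'")
                aux.setdefault(ch, []).append(
                    (_parse_float(fields, "t", lineno), _parse_float(fields, "v", lineno))
                )
            elif rec == "gnss":
                ele = _parse_float(fields, "ele", lineno) if "ele" in fields else None
                gnss.append(
                    GnssFix(
                        time=_parse_float(fields, "t", lineno),
                        lat=_parse_float(fields, "lat", lineno),
                        lon=_parse_float(fields, "lon", lineno),
                        elevation=ele,
                    )
                )
            elif rec == "ann":
                kind = fields.get("k")
                if kind is None:
                    raise LogParseError(f"line {lineno}: ann record without 'k'")
                value: float | str = fields.get("v", "")
                if kind == "speed":
                    value = _parse_float(fields, "v", lineno)
                annotations.append(Annotation(time=_parse_float(fields, "t", lineno), kind=kind, value=value))
            else:
                raise LogFormatError(f"line {lineno}: unknown record type {rec!r}")

    if not saw_header or f_hz is None:
        raise LogFormatError("log file has no 'hdr' record")
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise LogIntegrityError("acceleration sample indices are not strictly increasing")

    accel = np.array(accel_rows, dtype=float).reshape(-1, 3)
    trace = LoggerTrace(f=f_hz, accel=accel, aux=aux, gnss=gnss, annotations=annotations, meta=meta)
    trace.validate()
    return trace


def write_log(trace: LoggerTrace, path: str | Path) -> None:
    """Write a trace in the logger text format (lossless round trip at 6
    significant digits for floats)."""
    path = Path(path)
    lines: list[str] = []
    hdr = [f"rec=hdr", f"f={trace.f}"]
    for k, v in trace.meta.items():
        hdr.append(f"{_check_text(str(k))}={_check_text(str(v))}")
    lines.append(";".join(hdr))
    for i, (ax, ay, az) in enumerate(trace.accel):
        lines.append(f"rec=acc;i={i};ax={_fmt(ax)};ay={_fmt(ay)};az={_fmt(az)}")
    for ch, series in trace.aux.items():
        _check_text(ch)
        for t, v in series:
            lines.append(f"rec=aux;t={_fmt(t)};ch={ch};v={_fmt(v)}")
    for fix in trace.gnss:
        line = f"rec=gnss;t={_fmt(fix.time)};lat={_fmt(fix.lat)};lon={_fmt(fix.lon)}"
        if fix.elevation is not None:
            line += f";ele={_fmt(fix.elevation)}"
        lines.append(line)
    for ann in trace.annotations:
        v = _fmt(ann.value) if ann.kind == "speed" else _check_text(str(ann.value))
        lines.append(f"rec=ann;t={_fmt(ann.time)};k={ann.kind};v={v}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_series_csv(series: "DisplacementSeries", path: str | Path) -> None:
    """Write a Displacement-Index series as CSV with one row per second."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["second_index", "d_i"])
        for k, di in enumerate(series.values):
            writer.writerow([k, format(float(di), ".9g")])


_GPX_NS = "http://www.topografix.com/GPX/1/1"


def _gpx_root() -> ET.Element:
    root = ET.Element("gpx", attrib={"version": "1.1", "creator": "roadvib", "xmlns": _GPX_NS})
    return root


def _write_gpx(root: ET.Element, path: str | Path) -> None:
    ET.indent(ET.ElementTree(root))
    ET.ElementTree(root).write(Path(path), encoding="unicode", xml_declaration=True)


def export_track_gpx(trace: LoggerTrace, path: str | Path) -> None:
    """Export a trace's GNSS fixes as a single GPX 1.1 track."""
    root = _gpx_root()
    trk = ET.SubElement(root, "trk")
    ET.SubElement(trk, "name").text = trace.meta.get("device", "roadvib trace")
    seg = ET.SubElement(trk, "trkseg")
    for fix in trace.gnss:
        pt = ET.SubElement(seg, "trkpt", attrib={"lat": _fmt(fix.lat), "lon": _fmt(fix.lon)})
        if fix.elevation is not None:
            ET.SubElement(pt, "ele").text = _fmt(fix.elevation)
    _write_gpx(root, path)


def export_waypoints_gpx(fixes: list[tuple[str, GnssFix]], path: str | Path) -> None:
    """Export named fixes (e.g. segment endpoints) as GPX 1.1 waypoints."""
    root = _gpx_root()
    for name, fix in fixes:
        wpt = ET.SubElement(root, "wpt", attrib={"lat": _fmt(fix.lat), "lon": _fmt(fix.lon)})
        if fix.elevation is not None:
            ET.SubElement(wpt, "ele").text = _fmt(fix.elevation)
        ET.SubElement(wpt, "name").text = name
    _write_gpx(root, path)


def traces_equal(a: LoggerTrace, b: LoggerTrace, rel: float = 1e-5) -> bool:
    """Field-for-field equality at the serialization precision (6 sig digits)."""
    if a.f != b.f or a.meta != b.meta or a.n_samples != b.n_samples:
        return False
    if a.n_samples and not np.allclose(a.accel, b.accel, rtol=rel, atol=1e-12):
        return False
    if set(a.aux) != set(b.aux):
        return False
    for ch in a.aux:
        pa, pb = np.array(a.aux[ch], dtype=float), np.array(b.aux[ch], dtype=float)
        if pa.shape != pb.shape or (pa.size and not np.allclose(pa, pb, rtol=rel, atol=1e-12)):
            return False
    if len(a.gnss) != len(b.gnss) or len(a.annotations) != len(b.annotations):
        return False
    for fa, fb in zip(a.gnss, b.gnss):
        ea = -1.0 if fa.elevation is None else fa.elevation
        eb = -1.0 if fb.elevation is None else fb.elevation
        if (fa.elevation is None) != (fb.elevation is None):
            return False
        if not np.allclose([fa.time, fa.lat, fa.lon, ea], [fb.time, fb.lat, fb.lon, eb], rtol=rel, atol=1e-9):
            return False
    for xa, xb in zip(a.annotations, b.annotations):
        if xa.kind != xb.kind:
            return False
        if not math.isclose(xa.time, xb.time, rel_tol=rel, abs_tol=1e-9):
            return False
        if xa.kind == "speed":
            if not math.isclose(float(xa.value), float(xb.value), rel_tol=rel, abs_tol=1e-9):
                return False
        elif str(xa.value) != str(xb.value):
            return False
    return True
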