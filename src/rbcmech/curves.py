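"""Force-curve containers, file I/O, protocol segmentation and substrate masking.

A force curve is an ordered set of named segments, each carrying time ``t``,
piezo extension ``Z`` (positive toward the sample) and cantilever deflection
``d``.  Everything in memory is strictly SI (seconds, metres, newtons);
unit conversion happens only at the file boundary.

Two plain-text dialects are supported:

``generic-tsv``
    The package's canonical format.  Comment lines start with ``#`` and carry
    ``key: value`` metadata; the data table has columns
    ``segment  t[s]  Z[m]  d[m]`` separated by tabs.

``jpk-text``
    A vendor-flavoured variant with columns
    ``segment  seriesTime[s]  height[nm]  vDeflection[nm]`` (lengths in nm).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    ParameterError,
    SegmentationError,
    ValidationError,
)

SEGMENT_NAMES = ("approach", "dwell1", "step", "dwell2", "retract")

#: Column layout per dialect: (time, Z, d) column names and length unit in metres.
_DIALECTS = {
    "generic-tsv": {"cols": ("t[s]", "Z[m]", "d[m]"), "length_unit": 1.0},
    "jpk-text": {
        "cols": ("seriesTime[s]", "height[nm]", "vDeflection[nm]"),
        "length_unit": 1e-9,
    },
}


@dataclass(frozen=True)
class CantileverSpec:
    """Cantilever calibration: spring constant and tip half-opening angle.

    Parameters
    ----------
    kc : float
        Spring constant in N/m (thermal calibration value).
    alpha : float
        Conical tip half-opening angle in radians.
    label : str
        Free-text probe identifier.
    """

    kc: float
    alpha: float = math.radians(20.0)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.kc > 0:
            raise ValidationError(f"spring constant must be positive, got {self.kc}")
        if not 0 < self.alpha < math.pi / 2:
            raise ValidationError(
                f"tip half-angle must lie in (0, pi/2), got {self.alpha}"
            )


@dataclass
class ForceSegment:
    """One protocol phase: arrays of time, piezo extension and deflection."""

    name: str
    t: np.ndarray
    Z: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        n = self.t.size
        if not (self.Z.size == n and self.d.size == n and n >= 2):
            raise ValidationError(
                f"segment '{self.name}': arrays must share a length >= 2"
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(f"segment '{self.name}': time must strictly increase")
        if self.name.startswith("dwell"):
            span = float(np.ptp(self.Z))
            scale = max(abs(float(np.mean(self.Z))), 1e-9)
            if span > 1e-6 * scale + 1e-12:
                raise ValidationError(
                    f"segment '{self.name}': Z must be constant during a dwell "
                    f"(peak-to-peak {span:.3g} m)"
                )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ForceCurve:
    """A segmented force curve with cantilever metadata.

    ``segments`` preserve acquisition order and carry unique names; time is
    non-decreasing across segment boundaries.
    """

    segments: list[ForceSegment]
    cantilever: CantileverSpec
    speed: float = 0.0
    position: tuple[float, float] = (0.0, 0.0)
    cell_id: str = ""
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("a force curve needs at least one segment")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValidationError(f"segment names must be unique, got {names}")
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if nxt.t[0] < prev.t[-1] - 1e-15:
                raise ValidationError(
                    f"time runs backwards between '{prev.name}' and '{nxt.name}'"
                )

    def segment(self, name: str) -> ForceSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(f"curve has no segment named '{name}'")

    def has_segment(self, name: str) -> bool:
        return any(seg.name == name for seg in self.segments)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_FIELDS = ("kc", "alpha", "label", "speed", "x", "y", "cell_id", "subject_id")


def write_force_curve(curve: ForceCurve, path: str | Path, dialect: str = "generic-tsv") -> Path:
    """Write ``curve`` to ``path`` in the given dialect.

    The inverse of :func:`read_force_curve`: a write/read round trip
    reproduces the curve to float-repr precision.
    """
    spec = _dialect_spec(dialect)
    unit = spec["length_unit"]
    tcol, zcol, dcol = spec["cols"]
    lines = [f"# rbcmech force curve, dialect: {dialect}"]
    meta = {
        "kc": repr(curve.cantilever.kc),
        "alpha": repr(curve.cantilever.alpha),
        "label": curve.cantilever.label,
        "speed": repr(curve.speed),
        "x": repr(curve.position[0]),
        "y": repr(curve.position[1]),
        "cell_id": curve.cell_id,
        "subject_id": curve.subject_id,
    }
    for key, value in meta.items():
        lines.append(f"# {key}: {value}")
    lines.append("\t".join(("segment", tcol, zcol, dcol)))
    for seg in curve.segments:
        for ti, zi, di in zip(seg.t, seg.Z / unit, seg.d / unit):
            lines.append(
                f"{seg.name}\t{float(ti)!r}\t{float(zi)!r}\t{float(di)!r}"
            )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_force_curve(path: str | Path, dialect: str = "generic-tsv") -> ForceCurve:
    """Read a force curve file, converting file-native units to SI."""
    spec = _dialect_spec(dialect)
    unit = spec["length_unit"]
    tcol, zcol, dcol = spec["cols"]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path}: no data rows")
    table = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
    for col in ("segment", tcol, zcol, dcol):
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    segments = []
    for name in table["segment"].unique():
        rows = table[table["segment"] == name]
        t = rows[tcol].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{path}: non-monotone time in segment '{name}'")
        segments.append(
            ForceSegment(
                name=str(name),
                t=t,
                Z=rows[zcol].to_numpy(dtype=float) * unit,
                d=rows[dcol].to_numpy(dtype=float) * unit,
            )
        )
    cantilever = CantileverSpec(
        kc=float(meta.get("kc", "nan")),
        alpha=float(meta.get("alpha", repr(math.radians(20.0)))),
        label=meta.get("label", ""),
    )
    return ForceCurve(
        segments=segments,
        cantilever=cantilever,
        speed=float(meta.get("speed", "0.0")),
        position=(float(meta.get("x", "0.0")), float(meta.get("y", "0.0"))),
        cell_id=meta.get("cell_id", ""),
        subject_id=meta.get("subject_id", ""),
    )


def _dialect_spec(dialect: str) -> dict:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise FormatError(
            f"unknown dialect '{dialect}'; expected one of {sorted(_DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# Protocol segmentation
# ---------------------------------------------------------------------------


def segment_protocol(
    t: np.ndarray,
    Z: np.ndarray,
    d: np.ndarray | None = None,
    markers: Sequence[int] | None = None,
    nominal_speed: float | None = None,
) -> list[ForceSegment]:
    """Split a (t, Z) trace into named protocol segments.

    When ``markers`` (segment start indices, excluding 0) are given the trace
    is split exactly there.  Otherwise boundaries are detected from the piezo
    velocity: a sample belongs to a ramp regime when ``|dZ/dt|`` exceeds 10%
    of the nominal ramp speed (``nominal_speed``, defaulting to a robust
    maximum of the observed velocity).  Detected segments are named in the
    relaxation-protocol order approach, dwell1, step, dwell2 (then retract).
    """
    t = np.asarray(t, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if t.size != Z.size:
        raise ValidationError("t and Z must have the same length")
    if d is None:
        d = np.zeros_like(Z)
    d = np.asarray(d, dtype=float)

    if markers is not None:
        bounds = [0, *sorted(int(m) for m in markers), t.size]
        ramp_like = None
    else:
        dZdt = np.gradient(Z, t)
        if nominal_speed is None:
            nominal_speed = float(np.percentile(np.abs(dZdt), 98))
        if nominal_speed <= 0 or np.max(np.abs(dZdt)) < 1e-15:
            # Entirely constant trace: one long dwell.
            return [ForceSegment("dwell1", t, Z, d)]
        is_ramp = np.abs(dZdt) > 0.1 * nominal_speed
        change = np.flatnonzero(np.diff(is_ramp.astype(int)))
        bounds = [0, *(int(c) + 1 for c in change), t.size]
        ramp_like = [bool(is_ramp[b]) for b in bounds[:-1]]

    segments: list[ForceSegment] = []
    n_dwell = 0
    for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        if hi - lo < 2:
            # One-sample runs (the instantaneous step) are merged forward so
            # every emitted segment satisfies the length invariant.
            hi = min(hi + 1, t.size)
            if hi - lo < 2:
                continue
        zc = Z[lo:hi]
        is_constant = (
            ramp_like is not None and not ramp_like[k]
            if markers is None
            else np.ptp(zc) <= 1e-6 * max(abs(float(np.mean(zc))), 1e-9) + 1e-12
        )
        if is_constant:
            n_dwell += 1
            name = f"dwell{n_dwell}"
        else:
            slope = (zc[-1] - zc[0]) / (t[hi - 1] - t[lo])
            if not segments:
                name = "approach"
            elif slope < 0:
                name = "step" if n_dwell == 1 else "retract"
            else:
                name = f"ramp{k}"
        segments.append(ForceSegment(name, t[lo:hi], zc, d[lo:hi]))
    if not segments:
        raise SegmentationError("no segments of length >= 2 detected")
    return segments


def require_relaxation_segments(segments: Sequence[ForceSegment]) -> None:
    """Check that a segmented trace carries the two-dwell relaxation protocol."""
    names = {s.name for s in segments}
    missing = {"dwell1", "dwell2"} - names
    if missing:
        raise SegmentationError(
            f"relaxation protocol requires segments {sorted(missing)}; found {sorted(names)}"
        )


# ---------------------------------------------------------------------------
# Substrate masking
# ---------------------------------------------------------------------------


def mask_substrate(
    curves: Sequence[ForceCurve],
    height_threshold: float = 200e-9,
    heights: np.ndarray | None = None,
) -> tuple[list[ForceCurve], list[ForceCurve]]:
    """Split a force map into on-cell and substrate curves by local height.

    A position is substrate when its sample height (contact extension relative
    to the substrate plane, see :func:`rbcmech.sneddon.cell_height`) falls
    below ``height_threshold``.  Pass precomputed ``heights`` (one per curve,
    e.g. against an externally known substrate plane) to skip detection.
    """
    from .sneddon import map_heights  # local import to avoid a cycle

    if height_threshold <= 0:
        raise ParameterError(
            f"height threshold must be positive, got {height_threshold}"
        )
    if heights is None:
        heights = map_heights(curves)
    heights = np.asarray(heights, dtype=float)
    cell = [c for c, h in zip(curves, heights) if h >= height_threshold]
    substrate = [c for c, h in zip(curves, heights) if h < height_threshold]
    return cell, substrate


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

COHORT_GROUPS = ("control", "AD")
HEMATOLOGICAL_FIELDS = (
    "ESR", "RBC", "MCV", "MCH", "MCHC", "Hb", "TBIL", "ALP", "Fe", "ROS",
)
MECHANICAL_FIELDS = ("E", "k1", "k2", "f", "tau_c")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject-level cohort table (one row per subject).

    Required columns: ``subject_id``, ``group``, ``age``.  Hematological and
    mechanical columns are optional but, when present, mechanical means must
    be non-negative.
    """
    for col in ("subject_id", "group", "age"):
        if col not in table.columns:
            raise ValidationError(f"cohort table missing required column '{col}'")
    if table["subject_id"].duplicated().any():
        raise ValidationError("cohort table subject ids must be unique")
    bad = set(table["group"].unique()) - set(COHORT_GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels {sorted(bad)}")
    for col in MECHANICAL_FIELDS:
        if col in table.columns and (table[col].dropna() < 0).any():
            raise ValidationError(f"mechanical mean '{col}' must be non-negative")
    return table


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_cohort_table(table)
    path = Path(path)
    table.to_csv(path, index=False)
    return path
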