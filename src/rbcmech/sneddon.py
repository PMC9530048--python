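"""Conventional force–distance analysis with the Sneddon cone contact model.

For a rigid cone of half-opening angle ``alpha`` indenting an incompressible
elastic half-space, the force–indentation relation is

    F(delta) = 2 E tan(alpha) / (pi (1 - nu**2)) * delta**2

with ``E`` the apparent Young's modulus and ``nu`` the Poisson ratio (0.5 for
an incompressible cell).  Indentation follows from the piezo extension and
the measured deflection through ``dZ = d + delta``.  On viscoelastic samples
``E`` depends on indentation speed; the speed dependence is summarised with a
four-parameter sigmoid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .curves import ForceCurve, ForceSegment
from .exceptions import (
    AggregationError,
    ContactDetectionError,
    FitError,
    ValidationError,
)

__all__ = [
    "SneddonFit",
    "SpeedSweepFit",
    "sneddon_force",
    "compute_indentation",
    "detect_contact_point",
    "fit_sneddon",
    "cell_height",
    "map_heights",
    "fit_speed_sweep",
]


@dataclass(frozen=True)
class SneddonFit:
    """Result of fitting the cone contact model to one approach curve."""

    E: float                 # apparent Young's modulus, Pa
    nu: float                # Poisson ratio
    alpha: float             # tip half-angle, rad
    contact_index: int       # sample index of the contact point
    delta_max: float         # indentation range used in the fit, m
    rms_residual: float      # force residual, N
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValidationError(f"E must be non-negative, got {self.E}")
        if not 0 <= self.nu <= 0.5:
            raise ValidationError(f"nu must lie in [0, 0.5], got {self.nu}")
        if not self.delta_max > 0:
            raise ValidationError("delta_max must be positive")


@dataclass(frozen=True)
class SpeedSweepFit:
    """Sigmoid summary of apparent modulus versus indentation speed."""

    E_low: float    # low-speed asymptote, Pa
    E_high: float   # high-speed plateau, Pa
    v_half: float   # speed at half rise, m/s
    width: float    # transition width, m/s

    def __post_init__(self) -> None:
        if not self.E_high >= self.E_low >= 0:
            raise ValidationError("sigmoid requires E_high >= E_low >= 0")
        if not self.v_half > 0:
            raise ValidationError("v_half must be positive")

    def __call__(self, v: np.ndarray | float) -> np.ndarray | float:
        return _sigmoid(np.asarray(v, dtype=float), self.E_low, self.E_high,
                        self.v_half, self.width)


def sneddon_prefactor(alpha: float, nu: float = 0.5) -> float:
    """Geometric prefactor 2 tan(alpha) / (pi (1 - nu^2)) of the cone model."""
    return 2.0 * math.tan(alpha) / (math.pi * (1.0 - nu**2))


def sneddon_force(delta: np.ndarray, E: float, alpha: float, nu: float = 0.5) -> np.ndarray:
    """Cone-contact force for indentation ``delta`` (m), in newtons."""
    delta = np.asarray(delta, dtype=float)
    return sneddon_prefactor(alpha, nu) * E * delta**2


def compute_indentation(
    curve: ForceCurve, contact_index: int, segment: str = "approach"
) -> tuple[np.ndarray, np.ndarray]:
    """Convert an approach segment to (indentation, force) past contact.

    Piezo travel past contact splits into deflection and indentation,
    ``dZ = d + delta``; the deflection is offset-corrected to zero at the
    contact point and force is ``kc * d``.
    """
    seg = curve.segment(segment)
    if not 0 <= contact_index < len(seg) - 1:
        raise IndexError(
            f"contact index {contact_index} outside segment of {len(seg)} samples"
        )
    dZ = seg.Z[contact_index:] - seg.Z[contact_index]
    d = seg.d[contact_index:] - seg.d[contact_index]
    delta = dZ - d
    F = curve.cantilever.kc * d
    return delta, F


def detect_contact_point(
    approach: ForceSegment,
    kc: float | None = None,
    min_baseline: int = 5,
) -> int:
    """Locate the contact point on an approach segment.

    Scans candidate indices and scores a two-regime model — flat baseline
    before contact, quadratic force growth after — by total squared residual.
    The candidate with minimal residual wins; ties break to the earliest
    index.  A segment that a single straight line explains at least as well
    as the best two-regime split carries no contact signature and raises
    :class:`ContactDetectionError`.

    The scan is restricted to the shallow-contact region (deflection below a
    quarter of its rise) where the quadratic growth model holds; deep
    indentation bends away from the parabola and would bias the estimate.
    """
    d = np.asarray(approach.d, dtype=float)
    Z = np.asarray(approach.Z, dtype=float)
    # Truncate past shallow contact; keep enough points either way.
    d_lo = float(np.percentile(d, 5))
    d_hi = float(np.max(d))
    if d_hi > d_lo:
        deep = np.flatnonzero(d > d_lo + 0.25 * (d_hi - d_lo))
        cut = int(deep[0]) if deep.size else d.size
        cut = max(cut, 2 * min_baseline + 2)
        d, Z = d[:cut], Z[:cut]
    n = d.size
    if n < 2 * min_baseline + 2:
        raise ContactDetectionError(f"approach too short ({n} samples)")

    # Cumulative sums give O(1) baseline residuals per candidate.
    cs, cs2 = np.cumsum(d), np.cumsum(d**2)
    best_idx, best_ssr = -1, np.inf
    for i in range(min_baseline, n - min_baseline):
        base_mean = cs[i - 1] / i
        ssr_base = cs2[i - 1] - i * base_mean**2
        x = Z[i:] - Z[i]
        y = d[i:] - base_mean
        x4 = float(np.dot(x**2, x**2))
        if x4 <= 0:
            continue
        c = float(np.dot(y, x**2)) / x4
        if c < 0:
            c = 0.0
        resid = y - c * x**2
        ssr = ssr_base + float(np.dot(resid, resid))
        if ssr < best_ssr - 1e-30:
            best_idx, best_ssr = i, ssr

    if best_idx < 0:
        raise ContactDetectionError("no admissible contact candidate")

    # Straight-line comparison model: if a line does as well, there is no
    # baseline-plus-parabola signature to detect.
    A = np.vstack([Z, np.ones_like(Z)]).T
    coef, *_ = np.linalg.lstsq(A, d, rcond=None)
    ssr_line = float(np.sum((d - A @ coef) ** 2))
    if best_ssr >= ssr_line * (1.0 - 1e-9):
        raise ContactDetectionError(
            "no contact signature: straight line fits as well as the "
            "baseline + contact model"
        )
    return best_idx


def fit_sneddon(
    delta: np.ndarray,
    F: np.ndarray,
    alpha: float,
    nu: float = 0.5,
    delta_max: float = 0.5e-6,
    contact_index: int = 0,
    local_height: float | None = None,
) -> SneddonFit:
    """Least-squares apparent modulus over indentations in [0, delta_max].

    The model is linear in ``E`` so the estimate is the closed-form projection
    ``E = sum(F delta^2) / (C sum(delta^4))`` with ``C`` the cone prefactor.
    Data beyond ``delta_max`` never enter the estimate.
    """
    delta = np.asarray(delta, dtype=float)
    F = np.asarray(F, dtype=float)
    if delta.size != F.size:
        raise ValidationError("delta and F must have equal length")
    mask = (delta >= 0) & (delta <= delta_max)
    if int(mask.sum()) < 5:
        raise FitError(
            f"only {int(mask.sum())} points with indentation in [0, {delta_max}]"
        )
    dm, Fm = delta[mask], F[mask]
    C = sneddon_prefactor(alpha, nu)
    denom = C * float(np.dot(dm**2, dm**2))
    E = max(float(np.dot(Fm, dm**2)) / denom, 0.0)
    resid = Fm - C * E * dm**2
    if local_height is not None and delta_max > 0.1 * local_height:
        warnings.warn(
            f"fit range {delta_max:.2e} m exceeds 10% of local sample height "
            f"{local_height:.2e} m; apparent E may be overestimated",
            stacklevel=2,
        )
    return SneddonFit(
        E=E,
        nu=nu,
        alpha=alpha,
        contact_index=contact_index,
        delta_max=delta_max,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=int(mask.sum()),
    )


def map_heights(curves: Sequence[ForceCurve]) -> np.ndarray:
    """Sample height at each map position, relative to the substrate plane.

    The contact extension is detected per curve; the substrate plane is the
    mean of the lowest decile of surface heights (deepest contacts), and each
    height is the contact extension deficit relative to that plane.
    """
    contact_z = np.empty(len(curves))
    for k, curve in enumerate(curves):
        seg = curve.segment("approach")
        idx = detect_contact_point(seg, curve.cantilever.kc)
        contact_z[k] = seg.Z[idx]
    # Larger extension at contact = lower surface; substrate = deepest decile.
    surface = -contact_z
    q10 = np.quantile(surface, 0.10)
    plane = float(np.mean(surface[surface <= q10]))
    return surface - plane


def cell_height(
    curves: Sequence[ForceCurve], height_threshold: float = 200e-9
) -> tuple[np.ndarray, float, float]:
    """Per-position heights plus mean ± SEM over cell-masked positions."""
    heights = map_heights(curves)
    cell = heights[heights >= height_threshold]
    if cell.size == 0:
        raise AggregationError("no positions above the substrate threshold")
    mean = float(np.mean(cell))
    sem = float(np.std(cell, ddof=1) / np.sqrt(cell.size)) if cell.size > 1 else 0.0
    return heights, mean, sem


def _sigmoid(v, E_low, E_high, v_half, width):
    return E_low + (E_high - E_low) / (1.0 + np.exp(-(v - v_half) / width))


def fit_speed_sweep(points: Sequence[tuple[float, float]]) -> SpeedSweepFit:
    """Fit the E(v) sigmoid to (speed, apparent modulus) pairs.

    Initialised from data quantiles and bounded so the plateau is at least
    the low-speed asymptote.  Speeds are used on a linear axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValidationError("need >= 4 (v, E) points")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite values in speed-sweep input")
    v, E = pts[:, 0], pts[:, 1]
    order = np.argsort(v)
    v, E = v[order], E[order]
    E_lo0 = float(np.quantile(E, 0.05))
    E_hi0 = float(np.quantile(E, 0.95))
    dE0 = max(E_hi0 - E_lo0, 1e-12 * max(abs(E_hi0), 1.0))
    # Half-rise initial guess: first speed where E crosses the midpoint.
    mid = E_lo0 + 0.5 * dE0
    above = np.flatnonzero(E >= mid)
    v_half0 = float(v[above[0]]) if above.size else float(np.median(v))
    v_half0 = max(v_half0, float(np.min(v[v > 0], initial=1e-9)))
    width0 = max((float(v[-1]) - float(v[0])) / 10.0, v_half0 / 10.0)

    def model(v, E_low, dE, v_half, width):
        return _sigmoid(v, E_low, E_low + dE, v_half, width)

    span = float(v[-1] - v[0])
    E_span = max(float(np.max(E) - np.min(E)), 1e-12 * max(abs(E_hi0), 1.0))
    p0 = (E_lo0, dE0, min(v_half0, float(v[-1])), min(width0, span))
    # Bounds keep the asymptotes and transition inside the observed ranges;
    # an unconstrained linear-v sigmoid diverges on log-spaced speed data.
    bounds = (
        [0.0, 0.0, float(v[0]) / 10.0 + 1e-15, span * 1e-4],
        [float(np.max(E)) * 1.5, 2.0 * E_span, float(v[-1]), span],
    )
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        popt, _ = curve_fit(model, v, E, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    E_low, dE, v_half, width = (float(x) for x in popt)
    return SpeedSweepFit(E_low=E_low, E_high=E_low + dE, v_half=v_half, width=width)
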