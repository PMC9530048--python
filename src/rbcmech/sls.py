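"""Standard-linear-solid analysis of two-step force–relaxation curves.

The cell is modelled as an equilibrium spring ``k2`` in parallel with a
Maxwell arm (spring ``k1`` in series with a dashpot ``f``); the cantilever
adds a series spring ``kc``.  During a constant-height dwell the deflection
relaxes as a single exponential

    d(t) = A exp(-t / tau_c) + db,
    tau_c = f (k1 + k2 + kc) / (k1 (kc + k2)),
    db    = k2 dZ / (kc + k2),
    A     = da - db,

where ``da`` and ``db`` are the deflections at the start (point a) and the
asymptote (point b) of the dwell and ``dZ`` is the total piezo travel past
contact.  Because ``dZ`` and ``da`` carry large experimental error, the tip
is retracted by a known step ``J`` after the first relaxation; the new
equilibrium (point c) satisfies ``kc dc = k2 (dZ - J - dc)``.  Eliminating
``dZ`` and ``da`` yields closed-form estimates

    k2 = kc (db - dc) / (J + dc - db)
    k1 = A (kc + k2) k2 / (kc db - k2 A)
    f  = tau_c k1 (kc + k2) / (k1 + k2 + kc)

which this module evaluates after fitting the dwell exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .curves import ForceCurve, ForceSegment, require_relaxation_segments
from .exceptions import (
    AggregationError,
    FitError,
    InvalidAmplitudeError,
    InvalidGeometryError,
    ProtocolError,
)

__all__ = [
    "RelaxFit",
    "CellSummary",
    "fit_dwell_exponential",
    "extract_dc",
    "solve_sls",
    "tau_c_from_params",
    "analyze_relaxation_curve",
    "aggregate",
]


@dataclass
class RelaxFit:
    """All intermediates and SLS parameters extracted from one curve."""

    A: float          # exponential amplitude, m
    tau_c: float      # relaxation time, s
    db: float         # first-dwell asymptotic deflection, m
    dc: float         # post-step equilibrium deflection, m
    J: float          # retraction step, m
    kc: float         # cantilever spring constant, N/m
    k1: float         # Maxwell-arm spring, N/m
    k2: float         # equilibrium spring, N/m
    f: float          # damping coefficient, N s/m
    da: float = float("nan")   # deflection at point a (informational), m
    fit_rms: float = float("nan")  # dwell-fit residual, m
    flags: list[str] = field(default_factory=list)
    curve_id: str = ""

    @property
    def valid(self) -> bool:
        return not self.flags and min(self.k1, self.k2, self.f) > 0


@dataclass
class CellSummary:
    """Per-cell means and standard errors over valid curve fits."""

    cell_id: str
    n_curves_used: int
    mean: dict[str, float]
    sem: dict[str, float]
    height: float = float("nan")
    flags: list[str] = field(default_factory=list)


def _exp_model(t, A, tau, db):
    return A * np.exp(-t / tau) + db


def fit_dwell_exponential(
    t: np.ndarray, d: np.ndarray
) -> tuple[float, float, float, float, list[str]]:
    """Fit ``d(t) = A exp(-t/tau_c) + db`` to a dwell segment.

    Returns ``(A, tau_c, db, rms, flags)``.  Initialisation is deterministic:
    ``db0`` is the mean of the final 10% of samples, ``A0 = d(0) - db0`` and
    ``tau0`` the first time the residual decays to ``A0/e``.  ``tau_c`` is
    bounded to [2 samples, 10 dwell lengths]; a fit pinned at a bound or with
    amplitude indistinguishable from noise is flagged rather than rejected.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if t.size != d.size or t.size < 10:
        raise FitError(f"dwell fit needs >= 10 samples, got {t.size}")
    t = t - t[0]
    span = float(t[-1])
    dt = float(np.median(np.diff(t)))
    tail = d[-max(t.size // 10, 2):]
    db0 = float(np.mean(tail))
    A0 = float(d[0] - db0)
    noise_scale = float(np.std(tail, ddof=1)) if tail.size > 1 else 0.0

    if abs(A0) <= max(3.0 * noise_scale / np.sqrt(tail.size), 1e-15):
        # No resolvable decay: amplitude at noise floor, tau unidentifiable.
        rms = float(np.std(d - db0))
        return 0.0, float("nan"), db0, rms, ["degenerate-amplitude"]

    decayed = np.flatnonzero(np.abs(d - db0) <= abs(A0) / np.e)
    tau0 = float(t[decayed[0]]) if decayed.size else span / 5.0
    tau0 = min(max(tau0, 2.0 * dt), 10.0 * span)
    lo, hi = 2.0 * dt, 10.0 * span
    # Normalise deflection to O(1): metre-scale residuals leave the cost
    # gradient below the optimiser's tolerance and stall the fit.
    scale = max(abs(A0), float(np.ptp(d)), 1e-30)
    try:
        popt, _ = curve_fit(
            _exp_model,
            t,
            d / scale,
            p0=(A0 / scale, tau0, db0 / scale),
            bounds=([-np.inf, lo, -np.inf], [np.inf, hi, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"dwell exponential fit did not converge: {exc}") from exc
    A, tau, db = float(popt[0]) * scale, float(popt[1]), float(popt[2]) * scale
    rms = float(np.sqrt(np.mean((_exp_model(t, A, tau, db) - d) ** 2)))
    flags = []
    if tau <= lo * (1 + 1e-6) or tau >= hi * (1 - 1e-6):
        flags.append("tau-at-bound")
    return A, tau, db, rms, flags


def extract_dc(dwell2: ForceSegment) -> float:
    """Post-step equilibrium deflection: asymptote of the second dwell.

    Falls back to the mean of the final 10% of samples when the exponential
    is degenerate (already at equilibrium).
    """
    if len(dwell2) < 10:
        raise FitError(f"dwell2 too short ({len(dwell2)} samples) to extract dc")
    A, tau, db, rms, flags = fit_dwell_exponential(dwell2.t, dwell2.d)
    if "degenerate-amplitude" in flags:
        n_tail = max(len(dwell2) // 10, 2)
        return float(np.mean(dwell2.d[-n_tail:]))
    return db


def solve_sls(
    A: float, tau_c: float, db: float, dc: float, J: float, kc: float
) -> tuple[float, float, float]:
    """Closed-form inversion of the two-step relaxation to (k1, k2, f)."""
    if J <= 0:
        raise InvalidGeometryError(f"retraction step J must be positive, got {J}")
    if tau_c <= 0 or not np.isfinite(tau_c):
        raise FitError(f"relaxation time must be positive and finite, got {tau_c}")
    geom = J + dc - db
    if geom <= 0:
        raise InvalidGeometryError(
            f"J + dc - db = {geom:.3g} <= 0: step geometry inconsistent with fit"
        )
    k2 = kc * (db - dc) / geom
    if k2 <= 0:
        raise InvalidGeometryError(
            f"db - dc = {db - dc:.3g} <= 0 gives k2 <= 0: no equilibrium spring"
        )
    amp = kc * db - k2 * A
    if amp <= 0:
        raise InvalidAmplitudeError(
            f"kc*db - k2*A = {amp:.3g} <= 0: amplitude inconsistent with equilibria"
        )
    k1 = A * (kc + k2) * k2 / amp
    f = tau_c * k1 * (kc + k2) / (k1 + k2 + kc)
    return k1, k2, f


def tau_c_from_params(k1: float, k2: float, f: float, kc: float) -> float:
    """Dwell relaxation time implied by SLS parameters and the cantilever."""
    return f * (k1 + k2 + kc) / (k1 * (kc + k2))


def estimate_step(curve: ForceCurve) -> float:
    """Retraction step J measured from the piezo trace between the dwells."""
    z1 = float(np.median(curve.segment("dwell1").Z))
    z2 = float(np.median(curve.segment("dwell2").Z))
    J = z1 - z2
    if J <= 0:
        raise ProtocolError(f"non-positive measured step J = {J:.3g} m")
    return J


def ramp_amplitude_factor(t_ramp: float, tau_c: float) -> float:
    """Finite-ramp correction mapping the fitted dwell amplitude to point a.

    The inversion assumes an abrupt indentation, but the sample relaxes a
    little already during the constant-speed ramp of duration ``t_ramp``.
    For a linear ramp the exact dwell amplitude is attenuated by
    ``(1 - exp(-x)) / x`` with ``x = t_ramp / tau_c``; multiplying the fitted
    amplitude by the inverse restores the instantaneous-indentation value.
    """
    if t_ramp <= 0:
        return 1.0
    x = t_ramp / tau_c
    return x / -np.expm1(-x)


def analyze_relaxation_curve(curve: ForceCurve, ramp_correction: bool = True) -> RelaxFit:
    """Full per-curve analysis: dwell fit, dc extraction and SLS inversion.

    The step size ``J`` is always measured from the Z trace (median dwell
    levels) rather than trusted from configuration.  When the curve carries
    an approach segment and ``ramp_correction`` is on, the fitted amplitude
    is corrected for relaxation during the in-contact ramp (see
    :func:`ramp_amplitude_factor`).
    """
    try:
        require_relaxation_segments(curve.segments)
        dwell1 = curve.segment("dwell1")
        dwell2 = curve.segment("dwell2")
        J = estimate_step(curve)
        A, tau_c, db, rms, flags = fit_dwell_exponential(dwell1.t, dwell1.d)
        if flags:
            raise FitError(f"dwell1 fit flagged: {flags}")
        if ramp_correction and curve.has_segment("approach"):
            seg = curve.segment("approach")
            t_ramp = float(seg.t[-1] - seg.t[0])
            A *= ramp_amplitude_factor(t_ramp, tau_c)
        dc = extract_dc(dwell2)
        kc = curve.cantilever.kc
        k1, k2, f = solve_sls(A, tau_c, db, dc, J, kc)
    except Exception as exc:
        raise type(exc)(
            f"curve '{curve.subject_id}/{curve.cell_id}': {exc}"
        ) from exc
    return RelaxFit(
        A=A, tau_c=tau_c, db=db, dc=dc, J=J, kc=kc,
        k1=k1, k2=k2, f=f, da=float(dwell1.d[0]), fit_rms=rms,
        curve_id=f"{curve.subject_id}/{curve.cell_id}",
    )


_AGG_FIELDS = ("E", "k1", "k2", "f", "tau_c")


def aggregate(
    results: pd.DataFrame, by: str, fields: Sequence[str] = _AGG_FIELDS
) -> pd.DataFrame:
    """Mean and SEM of mechanical parameters grouped by ``by``.

    ``results`` is a tidy per-curve (or per-cell) table.  Rows with any
    non-finite value in ``fields`` are excluded and counted.  A group with a
    single valid entry reports SEM 0 and the flag ``single-entry``.  Subject
    level aggregation should be fed cell means, not pooled curves.
    """
    present = [f for f in fields if f in results.columns]
    if not present:
        raise AggregationError(f"none of {fields} present in results")
    valid = results.dropna(subset=present)
    if valid.empty:
        raise AggregationError("no valid results to aggregate")
    rows = []
    for key, grp in valid.groupby(by, sort=True):
        rec: dict = {by: key, "n_used": len(grp),
                     "n_excluded": int((results[by] == key).sum()) - len(grp)}
        for f in present:
            vals = grp[f].to_numpy(dtype=float)
            rec[f] = float(np.mean(vals))
            if vals.size > 1:
                rec[f"{f}_sem"] = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
            else:
                rec[f"{f}_sem"] = 0.0
        rec["flags"] = "single-entry" if len(grp) == 1 else ""
        rows.append(rec)
    return pd.DataFrame(rows)
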