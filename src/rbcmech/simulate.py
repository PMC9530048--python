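"""Forward simulation of the cantilever-coupled standard linear solid.

During contact, force balance between the cantilever spring ``kc`` and the
SLS sample (equilibrium spring ``k2`` parallel to a Maxwell arm ``k1``–``f``)
gives a first-order linear ODE for the deflection ``d`` driven by the piezo
trajectory ``dZ(t)``:

    d' = k1 [ k2 dZ - (k2 + kc) d + (f (k1 + k2) / k1) dZ' ]
         / ( f (k1 + k2 + kc) )

For a piecewise-linear trajectory the exact solution on each piece is a
linear-in-time particular solution plus an exponential transient with the
dwell time constant ``tau_c = f (k1+k2+kc) / (k1 (kc+k2))``; the integrator
propagates that closed form, so simulated dwells equal the analytic
exponential to float accumulation error.

The module also builds the two-dwell relaxation protocol (indent at constant
speed to a target force, hold, retract by a step ``J``, hold), adds
deflection noise, composes speed sweeps of apparent Sneddon modulus, and
generates hierarchical synthetic cohorts with correlated hematological
covariates standing in for unavailable patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import (
    CantileverSpec,
    ForceCurve,
    ForceSegment,
    write_cohort_table,
    write_force_curve,
)
from .exceptions import ProtocolError, SpecError, ValidationError
from . import sneddon

__all__ = [
    "SLSParams",
    "ProtocolSpec",
    "CohortSpec",
    "dwell_deflection",
    "simulate_sls_response",
    "make_protocol",
    "simulate_relaxation_curve",
    "add_noise",
    "simulate_speed_sweep",
    "simulate_cohort_table",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SLSParams:
    """Ground-truth mechanical parameters for simulation."""

    k1: float          # Maxwell-arm spring, N/m
    k2: float          # equilibrium spring, N/m
    f: float           # damping coefficient, N s/m
    kc: float = 0.03   # cantilever spring, N/m

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.f, self.kc) <= 0:
            raise ValidationError("all SLS parameters must be positive")

    @property
    def tau_c(self) -> float:
        """Dwell relaxation time with the cantilever attached."""
        return self.f * (self.k1 + self.k2 + self.kc) / (self.k1 * (self.kc + self.k2))

    def db(self, dZ: float) -> float:
        """Equilibrium deflection at constant extension ``dZ`` (point b)."""
        return self.k2 * dZ / (self.kc + self.k2)

    def da(self, dZ: float) -> float:
        """Instantaneous deflection after an abrupt indentation to ``dZ``."""
        return (self.k1 + self.k2) * dZ / (self.k1 + self.k2 + self.kc)

    def dc(self, dZ: float, J: float) -> float:
        """Equilibrium deflection after retracting by ``J`` (point c)."""
        return self.k2 * (dZ - J) / (self.kc + self.k2)


@dataclass(frozen=True)
class ProtocolSpec:
    """Two-dwell force–relaxation protocol settings.

    Defaults follow the acquisition described for the relaxation maps: a fast
    35 um/s indentation to a 2 nN trigger force, a first constant-height
    dwell, a one-sample retraction step ``J`` and a second dwell.
    """

    approach_speed: float = 35e-6   # m/s
    target_force: float = 2e-9      # N
    dwell1_duration: float = 1.5    # s
    J: float = 50e-9                # m
    dwell2_duration: float = 1.5    # s
    sample_rate: float = 2000.0     # Hz

    def __post_init__(self) -> None:
        for name in ("approach_speed", "target_force", "dwell1_duration",
                     "dwell2_duration", "sample_rate"):
            if getattr(self, name) <= 0:
                raise SpecError(f"protocol field '{name}' must be positive")
        if self.J < 0:
            raise SpecError("retraction step J must be non-negative")


def dwell_deflection(params: SLSParams, dZ: float, d0: float, t: np.ndarray) -> np.ndarray:
    """Analytic dwell solution ``(d0 - db) exp(-t/tau_c) + db``."""
    db = params.db(dZ)
    return (d0 - db) * np.exp(-np.asarray(t, dtype=float) / params.tau_c) + db


def _propagate_linear_piece(
    params: SLSParams, z0: float, v: float, d0: float, t_local: np.ndarray
) -> np.ndarray:
    """Exact ODE solution on one linear piece dZ(t) = z0 + v t."""
    k1, k2, f, kc = params.k1, params.k2, params.f, params.kc
    K = k1 + k2 + kc
    tau = params.tau_c
    b = 1.0 / tau
    a0 = (k1 * k2 * z0 + f * (k1 + k2) * v) / (f * K)
    p1 = v * k2 / (k2 + kc)
    p0 = (a0 - p1) / b
    return p0 + p1 * t_local + (d0 - p0) * np.exp(-t_local / tau)


def simulate_sls_response(
    params: SLSParams,
    t_knots: Sequence[float],
    Z_knots: Sequence[float],
    sample_rate: float,
    d0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the deflection ODE along a piecewise-linear Z trajectory.

    ``(t_knots, Z_knots)`` define extension past contact versus time
    (``dZ(t)``, starting at contact).  Returns sampled ``(t, Z, d)`` arrays on
    a uniform grid at ``sample_rate``.  The solution is the closed-form
    exponential on each linear piece, so accuracy is limited only by float
    accumulation.
    """
    t_knots = np.asarray(t_knots, dtype=float)
    Z_knots = np.asarray(Z_knots, dtype=float)
    if t_knots.ndim != 1 or t_knots.size != Z_knots.size or t_knots.size < 2:
        raise ValidationError("trajectory needs matching 1-D knot arrays, >= 2 knots")
    if np.any(np.diff(t_knots) <= 0):
        raise ValidationError("trajectory knot times must strictly increase")

    dt = 1.0 / sample_rate
    n = int(round((t_knots[-1] - t_knots[0]) / dt)) + 1
    t = t_knots[0] + dt * np.arange(n)
    Z = np.interp(t, t_knots, Z_knots)
    d = np.empty(n)
    d_state = d0
    t_state = t_knots[0]
    pos = 0
    for k in range(t_knots.size - 1):
        t0, t1 = t_knots[k], t_knots[k + 1]
        v = (Z_knots[k + 1] - Z_knots[k]) / (t1 - t0)
        hi = int(np.searchsorted(t, t1, side="right")) if k < t_knots.size - 2 else n
        idx = np.arange(pos, hi)
        if idx.size:
            z_at_state = Z_knots[k] + v * (t_state - t0)
            d[idx] = _propagate_linear_piece(
                params, z_at_state, v, d_state, t[idx] - t_state
            )
            d_state = d[idx[-1]]
            t_state = t[idx[-1]]
            pos = hi
        # advance the state to the knot time exactly
        z_at_state = Z_knots[k] + v * (t_state - t0)
        d_state = float(
            _propagate_linear_piece(
                params, z_at_state, v, d_state, np.array([t1 - t_state])
            )[0]
        )
        t_state = t1
    return t, Z, d


def make_protocol(
    spec: ProtocolSpec, params: SLSParams, max_extension: float = 20e-6
) -> dict:
    """Build the relaxation-protocol Z trajectory for given sample parameters.

    The indentation ramp runs at ``approach_speed`` until the simulated force
    ``kc d`` reaches ``target_force`` (point a); the extension then holds for
    ``dwell1_duration``, drops by ``J`` over one sample, and holds for
    ``dwell2_duration``.  Returns knots, ground-truth segment boundaries (in
    samples) and the extension past contact ``dZ``.
    """
    dt = 1.0 / spec.sample_rate
    # Fast-limit deflection underestimates ramp time; extend until trigger.
    # Solve on a fine analytic grid: d(t) on the ramp from the exact piece.
    d_target = spec.target_force / params.kc
    t_hi = max_extension / spec.approach_speed
    t_grid = np.arange(0.0, t_hi, dt / 4.0)
    d_ramp = _propagate_linear_piece(params, 0.0, spec.approach_speed, 0.0, t_grid)
    reached = np.flatnonzero(d_ramp >= d_target)
    if reached.size == 0:
        raise ProtocolError(
            f"target force {spec.target_force} N unreachable within "
            f"{max_extension} m extension: sample too soft"
        )
    # Snap the contact-to-trigger time onto the sampling grid (next sample).
    t_a = math.ceil(t_grid[reached[0]] / dt - 1e-9) * dt
    t_a = max(t_a, 2 * dt)
    dZ = spec.approach_speed * t_a
    if spec.J > 0 and spec.J >= dZ:
        raise ProtocolError(f"step J={spec.J} exceeds extension past contact {dZ}")
    t1 = t_a + spec.dwell1_duration
    t_step = t1 + dt
    t2 = t_step + spec.dwell2_duration
    t_knots = [0.0, t_a, t1, t_step, t2]
    Z_knots = [0.0, dZ, dZ, dZ - spec.J, dZ - spec.J]
    n_a = int(round(t_a / dt))
    n_d1 = int(round(spec.dwell1_duration / dt))
    boundaries = {
        "approach_end": n_a,
        "dwell1_end": n_a + n_d1,
        "step_end": n_a + n_d1 + 1,
    }
    return {
        "t_knots": np.array(t_knots),
        "Z_knots": np.array(Z_knots),
        "boundaries": boundaries,
        "dZ": dZ,
        "t_a": t_a,
    }


def simulate_relaxation_curve(
    params: SLSParams,
    spec: ProtocolSpec | None = None,
    cantilever: CantileverSpec | None = None,
    cell_id: str = "",
    subject_id: str = "",
) -> tuple[ForceCurve, dict]:
    """Simulate one full relaxation curve; returns (curve, truth record)."""
    spec = spec or ProtocolSpec()
    cantilever = cantilever or CantileverSpec(kc=params.kc)
    if abs(cantilever.kc - params.kc) > 1e-12:
        raise SpecError("cantilever spring constant disagrees with SLSParams.kc")
    proto = make_protocol(spec, params)
    t, Z, d = simulate_sls_response(
        params, proto["t_knots"], proto["Z_knots"], spec.sample_rate
    )
    b = proto["boundaries"]
    dZ = proto["dZ"]
    slices = {
        "approach": slice(0, b["approach_end"] + 1),
        "dwell1": slice(b["approach_end"], b["dwell1_end"] + 1),
        "step": slice(b["dwell1_end"], b["step_end"] + 1),
        "dwell2": slice(b["step_end"], t.size),
    }
    segments = []
    for name, sl in slices.items():
        zseg = Z[sl]
        if name.startswith("dwell"):
            zseg = np.full_like(zseg, zseg[-1])  # clamp float interp jitter
        segments.append(ForceSegment(name, t[sl], zseg, d[sl]))
    curve = ForceCurve(
        segments=segments,
        cantilever=cantilever,
        speed=spec.approach_speed,
        cell_id=cell_id,
        subject_id=subject_id,
    )
    truth = {
        "k1": params.k1, "k2": params.k2, "f": params.f, "kc": params.kc,
        "tau_c": params.tau_c, "dZ": dZ, "J": spec.J,
        "da": params.da(dZ), "db": params.db(dZ),
        "dc": params.dc(dZ, spec.J),
        "A": params.da(dZ) - params.db(dZ),
        "boundaries": b,
    }
    return curve, truth


def add_noise(
    curve: ForceCurve, sigma_d: float, drift_rate: float = 0.0, seed: int | None = 0
) -> ForceCurve:
    """Add i.i.d. Gaussian deflection noise and linear drift, reproducibly."""
    if sigma_d < 0 or drift_rate < 0:
        raise ValidationError("noise parameters must be non-negative")
    if sigma_d == 0 and drift_rate == 0:
        return curve
    rng = np.random.default_rng(seed)
    t0 = curve.segments[0].t[0]
    new_segments = []
    for seg in curve.segments:
        noise = rng.normal(0.0, sigma_d, size=len(seg)) if sigma_d > 0 else 0.0
        drift = drift_rate * (seg.t - t0)
        new_segments.append(
            ForceSegment(seg.name, seg.t.copy(), seg.Z.copy(), seg.d + noise + drift)
        )
    return ForceCurve(
        segments=new_segments,
        cantilever=curve.cantilever,
        speed=curve.speed,
        position=curve.position,
        cell_id=curve.cell_id,
        subject_id=curve.subject_id,
    )


# ---------------------------------------------------------------------------
# Speed sweep: apparent Sneddon modulus of the linear SLS element
# ---------------------------------------------------------------------------


def apparent_stiffness(params: SLSParams, speed: float, depth: float = 0.5e-6,
                       n_samples: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an FD ramp at ``speed`` and return (indentation, force).

    The ramp extends dZ until the indentation reaches ``depth``; force is
    ``kc d`` and indentation ``dZ - d``.
    """
    # Extension needed: delta = dZ - d <= dZ, overshoot then trim.
    z_end = depth * (1.0 + params.kc / params.k2) * 1.2
    t_end = z_end / speed
    t = np.linspace(0.0, t_end, n_samples)
    rate = (n_samples - 1) / t_end
    tt, Z, d = simulate_sls_response(
        params, [0.0, t_end], [0.0, z_end], rate
    )
    delta = Z - d
    F = params.kc * d
    keep = delta <= depth
    return delta[keep], F[keep]


def simulate_speed_sweep(
    params: SLSParams,
    speeds: Sequence[float],
    alpha: float = math.radians(20.0),
    nu: float = 0.5,
    depth: float = 0.5e-6,
) -> list[tuple[float, float]]:
    """Apparent Sneddon modulus at each indentation speed.

    Composes the linear SLS contact force with the cone-model fit: the tip is
    ramped at each speed to ``depth`` of indentation and the resulting
    (indentation, force) record is fitted by the Sneddon parabola, mirroring
    how measured moduli acquire speed dependence on a viscoelastic sample.
    """
    out = []
    for v in speeds:
        if v <= 0:
            raise ValidationError("speeds must be positive")
        delta, F = apparent_stiffness(params, v, depth=depth)
        fit = sneddon.fit_sneddon(delta, F, alpha=alpha, nu=nu, delta_max=depth)
        out.append((float(v), fit.E))
    return out


# ---------------------------------------------------------------------------
# Elastic force–distance maps (Sneddon forward model)
# ---------------------------------------------------------------------------


def sneddon_approach_curve(
    E: float,
    z_contact: float,
    z_max: float,
    cantilever: CantileverSpec,
    nu: float = 0.5,
    speed: float = 5e-6,
    sample_rate: float = 20000.0,
    position: tuple[float, float] = (0.0, 0.0),
) -> ForceCurve:
    """Elastic approach curve over a Sneddon half-space.

    The piezo extends from 0 to ``z_max``; the surface sits at extension
    ``z_contact``.  Past contact the deflection solves the force balance
    ``kc d = C E delta^2`` with ``delta = (Z - z_contact) - d``, i.e. the
    positive root of the quadratic ``C E delta^2 + kc delta - kc dZ = 0``.
    """
    n = max(int(round(z_max / speed * sample_rate)) + 1, 8)
    t = np.arange(n) / sample_rate
    Z = speed * t
    C = sneddon.sneddon_prefactor(cantilever.alpha, nu)
    kc = cantilever.kc
    dZ = np.clip(Z - z_contact, 0.0, None)
    delta = (-kc + np.sqrt(kc**2 + 4.0 * C * E * kc * dZ)) / (2.0 * C * E)
    d = dZ - delta
    seg = ForceSegment("approach", t, Z, d)
    return ForceCurve(
        segments=[seg], cantilever=cantilever, speed=speed, position=position
    )


def spherical_cap_heights(n: int = 8, cap_radius: float = 3.5e-6,
                          cap_height: float = 2.0e-6,
                          pitch: float = 1.0e-6) -> np.ndarray:
    """Height field of a spherical cap centred on an n x n map, in metres.

    The cap has footprint radius ``cap_radius`` and apex height
    ``cap_height``; positions outside the footprint are substrate (0).
    """
    R = (cap_radius**2 + cap_height**2) / (2.0 * cap_height)  # sphere radius
    ax = (np.arange(n) - (n - 1) / 2.0) * pitch
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    h = np.sqrt(np.clip(R**2 - r2, 0.0, None)) - (R - cap_height)
    return np.clip(h, 0.0, None)


def simulate_fd_map(
    heights: np.ndarray,
    E: float = 2300.0,
    cantilever: CantileverSpec | None = None,
    baseline: float = 1.0e-6,
    indent_past_contact: float = 1.0e-6,
    pitch: float = 1.0e-6,
    sigma_d: float = 0.0,
    seed: int = 0,
) -> tuple[list[ForceCurve], np.ndarray]:
    """Force–distance map over a height field; returns (curves, truth heights).

    Each position gets an elastic approach curve whose contact extension is
    ``baseline + (max height - local height)``: taller sample, earlier
    contact.  ``truth`` is the flattened height per curve, in map order.
    """
    cantilever = cantilever or CantileverSpec(kc=0.03)
    heights = np.asarray(heights, dtype=float)
    h_flat = heights.ravel()
    rng = np.random.default_rng(seed)
    curves = []
    for k, h in enumerate(h_flat):
        i, j = divmod(k, heights.shape[1])
        z_c = baseline + (h_flat.max() - h)
        curve = sneddon_approach_curve(
            E, z_c, z_c + indent_past_contact, cantilever,
            position=(j * pitch, i * pitch),
        )
        if sigma_d > 0:
            curve = add_noise(curve, sigma_d, seed=int(rng.integers(2**31 - 1)))
        curves.append(curve)
    return curves, h_flat


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Default hematological covariate marginals (clinically plausible adult
#: ranges): mean and SD per variable, shared across groups.
DEFAULT_COVARIATES = {
    "ESR": (18.0, 9.0),      # mm/h
    "RBC": (4.7, 0.45),      # 10^6 / uL
    "MCV": (90.0, 4.5),      # fL
    "MCH": (30.0, 1.8),      # pg
    "MCHC": (33.5, 1.1),     # g/dL
    "Hb": (14.0, 1.3),       # g/dL
    "TBIL": (0.7, 0.25),     # mg/dL
    "ALP": (75.0, 20.0),     # U/L
    "Fe": (95.0, 30.0),      # ug/dL
    "ROS": (1.0, 0.3),       # arbitrary units
}

#: Default Spearman targets between covariates and latent mechanics, by group.
DEFAULT_RANK_CORR = {
    "control": {("MCV", "k1"): -0.7, ("Hb", "k1"): -0.4, ("MCHC", "f"): -0.5,
                ("TBIL", "k2"): -0.58, ("ALP", "k1"): -0.35},
    "AD": {("Fe", "k2"): -0.7, ("ROS", "E"): 0.66},
}


@dataclass(frozen=True)
class CohortSpec:
    """Hierarchical synthetic-cohort settings.

    Group sizes, map geometry and acquisition settings default to the study
    layout (20 controls + 16 patients, ~10 cells/subject, 64 curves per map);
    mechanical group means are the package's own calibration chosen so that
    the SLS parameters separate the groups while apparent E at 5 um/s does
    not (the AD geometry factor is auto-calibrated to equalise group-mean E).
    """

    n_control: int = 20
    n_AD: int = 16
    cells_per_subject: int = 10
    curves_per_cell: int = 64
    kc: float = 0.03
    # group-level means of (k1, k2, f) in N/m, N/m, N s/m
    control_means: tuple[float, float, float] = (0.015, 0.010, 0.0015)
    ad_shift: tuple[float, float, float] = (1.48, 1.34, 1.50)
    subject_cv: float = 0.25
    cell_cv: float = 0.12
    geometry_cv: float = 0.20
    sigma_d: float = 0.5e-9
    age_control: tuple[float, float] = (66.0, 8.0)
    age_ad: tuple[float, float] = (75.0, 7.0)
    e_speed: float = 5e-6        # speed at which cohort apparent E is taken
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    rank_corr: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_RANK_CORR.items()
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_AD, self.cells_per_subject,
               self.curves_per_cell) < 1:
            raise SpecError("all counts must be >= 1")
        if min(self.subject_cv, self.cell_cv, self.geometry_cv, self.sigma_d) < 0:
            raise SpecError("CVs and noise must be non-negative")

    def group_means(self, group: str) -> tuple[float, float, float]:
        if group == "control":
            return self.control_means
        return tuple(m * s for m, s in zip(self.control_means, self.ad_shift))


def _lognormal_around(rng, mean: float, cv: float, size=None, z=None):
    """Lognormal with the requested arithmetic mean and CV; optional z input."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma = math.sqrt(math.log(1.0 + cv**2))
    mu = math.log(mean) - 0.5 * sigma**2
    if z is None:
        z = rng.standard_normal(size)
    return np.exp(mu + sigma * z)


_MECH_LATENTS = ("k1", "k2", "f", "E")


def _copula_matrix(spec: CohortSpec, group: str) -> tuple[list[str], np.ndarray]:
    """Joint Gaussian-copula correlation over mech latents + covariates."""
    cov_names = list(spec.covariates)
    names = list(_MECH_LATENTS) + cov_names
    k = len(names)
    R = np.eye(k)
    # Mechanical latents are conditionally independent within a group: the
    # group effect alone induces their pooled correlation, mirroring the
    # absence of significant within-group mechanical cross-correlations.
    for (cov, mech), rho_s in spec.rank_corr.get(group, {}).items():
        if cov not in cov_names or mech not in _MECH_LATENTS:
            raise SpecError(f"unknown rank-correlation target ({cov}, {mech})")
        r = 2.0 * math.sin(math.pi * rho_s / 6.0)  # Spearman -> Pearson (copula)
        i, j = names.index(mech), names.index(cov)
        R[i, j] = R[j, i] = r
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 1e-10:
        raise SpecError(
            f"rank-correlation targets give a non-positive-definite copula "
            f"(min eigenvalue {eig.min():.3g})"
        )
    return names, R


def _reference_apparent_E(spec: CohortSpec) -> float:
    """Apparent Sneddon modulus of the control-mean SLS element at ``e_speed``."""
    k1, k2, f = spec.group_means("control")
    pts = simulate_speed_sweep(
        SLSParams(k1=k1, k2=k2, f=f, kc=spec.kc), [spec.e_speed]
    )
    return pts[0][1]


def simulate_cohort_table(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a subject-level cohort table directly from the hierarchical model.

    Subject mechanical means are the latent subject-level parameters (the
    quantity curve-level fitting estimates with error much smaller than the
    between-subject spread); hematological covariates come from the Gaussian
    copula.  Used for replicate-heavy statistical studies where simulating
    and refitting every raw curve would add nothing but fitting noise.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    E_ref = _reference_apparent_E(spec)
    rows = []
    sid = 0
    for group, n, age_ms in (
        ("control", spec.n_control, spec.age_control),
        ("AD", spec.n_AD, spec.age_ad),
    ):
        names, R = _copula_matrix(spec, group)
        L = np.linalg.cholesky(R)
        means = dict(zip(("k1", "k2", "f"), spec.group_means(group)))
        for _ in range(n):
            z = L @ rng.standard_normal(len(names))
            zmap = dict(zip(names, z))
            rec = {"subject_id": f"S{sid:03d}", "group": group,
                   "age": float(rng.normal(*age_ms))}
            for p in ("k1", "k2", "f"):
                rec[p] = float(
                    _lognormal_around(rng, means[p], spec.subject_cv, z=zmap[p])
                )
            # Apparent E at the acquisition speed: dominated by tip-placement
            # and contact-geometry variability rather than the cell's SLS
            # shift, so both groups share the reference modulus and the
            # entire spread comes from the lognormal geometry factor (whose
            # copula component carries covariate correlations with E).
            geo = _lognormal_around(rng, 1.0, spec.geometry_cv, z=zmap["E"])
            rec["E"] = float(E_ref * geo)
            rec["tau_c"] = SLSParams(
                k1=rec["k1"], k2=rec["k2"], f=rec["f"], kc=spec.kc
            ).tau_c
            for cov in spec.covariates:
                m, s = spec.covariates[cov]
                rec[cov] = float(m + s * zmap[cov])
            rows.append(rec)
            sid += 1
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[list[ForceCurve], pd.DataFrame, pd.DataFrame]:
    """Generate raw relaxation curves plus cohort and truth tables.

    Hierarchy: subject parameters are lognormal around group means
    (``subject_cv``), cell parameters lognormal around the subject
    (``cell_cv``); ``curves_per_cell`` noisy relaxation curves are simulated
    per cell.  Returns ``(curves, cohort_table, truth_table)``; when
    ``out_dir`` is given, curves are written as a subject/cell directory tree
    of TSVs along with ``cohort.csv`` and ``truth.csv``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subject_table = simulate_cohort_table(spec, seed=int(rng.integers(2**31 - 1)))
    cantilever = CantileverSpec(kc=spec.kc)
    curves: list[ForceCurve] = []
    truth_rows = []
    for _, srow in subject_table.iterrows():
        for c in range(spec.cells_per_subject):
            cell_id = f"{srow.subject_id}_c{c:02d}"
            cell_params = SLSParams(
                k1=float(_lognormal_around(rng, srow.k1, spec.cell_cv)),
                k2=float(_lognormal_around(rng, srow.k2, spec.cell_cv)),
                f=float(_lognormal_around(rng, srow.f, spec.cell_cv)),
                kc=spec.kc,
            )
            clean, truth = simulate_relaxation_curve(
                cell_params, spec.protocol, cantilever,
                cell_id=cell_id, subject_id=str(srow.subject_id),
            )
            for q in range(spec.curves_per_cell):
                noisy = add_noise(
                    clean, spec.sigma_d, seed=int(rng.integers(2**31 - 1))
                )
                noisy.cell_id = cell_id
                curves.append(noisy)
            truth_rows.append({
                "subject_id": srow.subject_id, "cell_id": cell_id,
                "group": srow.group,
                **{k: truth[k] for k in ("k1", "k2", "f", "tau_c", "dZ", "J",
                                          "da", "db", "dc", "A")},
            })
    truth_table = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for curve in curves:
            d = out_dir / curve.subject_id / curve.cell_id
            d.mkdir(parents=True, exist_ok=True)
            idx = sum(1 for _ in d.glob("curve_*.tsv"))
            write_force_curve(curve, d / f"curve_{idx:03d}.tsv")
        write_cohort_table(subject_table, out_dir / "cohort.csv")
        truth_table.to_csv(out_dir / "truth.csv", index=False)
    return curves, subject_table, truth_table
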