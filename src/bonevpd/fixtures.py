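"""Deterministic generators for every input the tests and demos need.

All generators are pure functions of their arguments and an integer seed:
parameter presets transcribed from the calibration tables, ramp/hold strain
programs, synthetic relaxation series with known power-law ground truth,
and orientation point clouds sampled from analytic frame fields (so that
assigned axes can be checked against exact ground truth).  Nothing is
downloaded; the whole test suite runs from these generators.
"""

from __future__ import annotations

import numpy as np

from .drivers import LoadingProgram
from .octree import OrientationCloud
from .parameters import MaterialParameters, ParameterError, load_preset
from .relaxation import RelaxationSeries

__all__ = [
    "preset_parameters",
    "make_relaxation_series",
    "make_orientation_cloud",
    "analytic_triads",
    "make_strain_program",
    "REDUCED_YIELD_STRAINS",
]

# Equilibrium (reduced) uniaxial yield strains per tissue: the calibrated
# strains scaled by the 24% mean relaxation reduction, as published.
REDUCED_YIELD_STRAINS = {
    "cortical": (0.00044, 0.0036),
    "trabecular": (0.0012, 0.0018),
}


def preset_parameters(tissue: str, reduced: bool = False) -> MaterialParameters:
    """Calibrated parameter preset for ``cortical`` or ``trabecular`` bone.

    With ``reduced=True`` the uniaxial yield strains are swapped for the
    equilibrium (relaxation-reduced) values used for viscoplastic runs.
    """
    params = load_preset(tissue)
    if reduced:
        eps0p, eps0m = REDUCED_YIELD_STRAINS[tissue]
        from dataclasses import replace

        params = params.with_yield(replace(params.yield_, eps0p=eps0p, eps0m=eps0m))
    return params


def make_relaxation_series(
    a: float, b: float, n: int = 50, noise_sd: float = 0.0, seed: int = 0,
    label: str = "",
) -> RelaxationSeries:
    """Synthetic relaxation series s = a t^-b (1 + eps) on log-spaced times.

    Times are log-spaced on [1, 1e3] s; ``eps`` is i.i.d. Normal(0, noise_sd)
    multiplicative noise from a seeded generator, so the same arguments
    always produce the identical series.
    """
    if a <= 0 or b < 0:
        raise ParameterError("need a > 0 and b >= 0")
    if n < 3:
        raise ParameterError("need n >= 3 samples")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    t = np.logspace(0.0, 3.0, n)
    rng = np.random.default_rng(seed)
    s = a * t ** (-b) * (1.0 + rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else a * t ** (-b)
    if np.any(s <= 0):
        raise ParameterError("noise drove the series non-positive; lower noise_sd")
    import warnings

    with warnings.catch_warnings():
        # noisy series are legitimately non-monotone; the type itself warns
        warnings.simplefilter("ignore")
        return RelaxationSeries(t=t, s=s, label=label or f"synthetic(a={a},b={b})")


# ---------------------------------------------------------------------------
# Orientation clouds with analytic frame fields

_FIELDS = ("uniform", "cylindrical", "torus_like")

# cylindrical shell: radii and height in mm (mandible-scale specimen)
_CYL_R = (8.0, 10.0)
_CYL_H = 10.0
# torus segment: centre-circle radius, tube radius, toroidal angle span
_TOR_R0 = 10.0
_TOR_RHO = 2.0
_TOR_SPAN = 1.5 * np.pi


def analytic_triads(field: str, points: np.ndarray) -> np.ndarray:
    """Ground-truth triads of the analytic frame field at given points.

    uniform: identity everywhere.  cylindrical and torus_like: axis 1
    tangential (circumferential), axis 2 radial in-plane, axis 3 = z,
    right-handed.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    if field == "uniform":
        return np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    if field not in _FIELDS:
        raise ParameterError(f"unknown field {field!r}")
    theta = np.arctan2(points[:, 1], points[:, 0])
    triads = np.zeros((n, 3, 3))
    triads[:, 0, 0] = np.sin(theta)
    triads[:, 0, 1] = -np.cos(theta)
    triads[:, 1, 0] = np.cos(theta)
    triads[:, 1, 1] = np.sin(theta)
    triads[:, 2, 2] = 1.0
    return triads


def make_orientation_cloud(field: str, n: int, seed: int = 0) -> OrientationCloud:
    """Sample an orientation cloud from an analytic frame field.

    ``uniform``: points in a 10 mm cube with identical identity triads.
    ``cylindrical``: shell r in [8, 10] mm, z in [0, 10] mm, full circle.
    ``torus_like``: tube of radius 2 mm around a 10 mm centre circle over a
    270 degree span.  Triads come from :func:`analytic_triads`.
    """
    if n < 1:
        raise ParameterError("need n >= 1")
    if field not in _FIELDS:
        raise ParameterError(f"unknown field {field!r}")
    rng = np.random.default_rng(seed)
    if field == "uniform":
        pts = rng.uniform(0.0, 10.0, size=(n, 3))
    elif field == "cylindrical":
        r = np.sqrt(rng.uniform(_CYL_R[0] ** 2, _CYL_R[1] ** 2, n))
        th = rng.uniform(0.0, 2.0 * np.pi, n)
        z = rng.uniform(0.0, _CYL_H, n)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
    else:  # torus_like
        phi = rng.uniform(0.0, _TOR_SPAN, n)
        rho = _TOR_RHO * np.sqrt(rng.uniform(0.0, 1.0, n))
        psi = rng.uniform(0.0, 2.0 * np.pi, n)
        rad = _TOR_R0 + rho * np.cos(psi)
        pts = np.column_stack([rad * np.cos(phi), rad * np.sin(phi), rho * np.sin(psi)])
    return OrientationCloud(points=pts, triads=analytic_triads(field, pts))


# ---------------------------------------------------------------------------
# Strain programs

_HOLD_SCHEDULE = ((100.0, 10.0), (1000.0, 50.0), (3000.0, 100.0), (1e4, 500.0))


def make_strain_program(
    kind: str,
    amplitude: float,
    n_steps: int = 100,
    rate: float | None = None,
    axis: int = 1,
    t_hold: float = 1e4,
) -> LoadingProgram:
    """Build a loading program with exact step times.

    ``kind``: ``ramp`` (uniaxial monotone ramp), ``sawtooth`` (strain path up
    and back down) or ``ramp_hold`` (relaxation: ramp then hold with the
    growing 10 s -> 500 s time-step schedule).  By default the ramp spans
    1 s in ``n_steps`` uniform increments (dt = 0.01 s at the default 100);
    passing ``rate`` (1/s) sets the ramp duration to |amplitude|/rate.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    t_ramp = abs(amplitude) / rate if rate else 1.0
    if t_ramp <= 0:
        t_ramp = 1.0  # null program: keep a valid 1 s window of zero strain
    dt = t_ramp / n_steps
    if kind == "ramp":
        return LoadingProgram(
            kind="uniaxial", axis=axis, amplitude=amplitude,
            t_ramp=t_ramp, dt_schedule=[(t_ramp, dt)], shape="ramp",
        )
    if kind == "sawtooth":
        return LoadingProgram(
            kind="strain_path", axis=axis, amplitude=amplitude,
            t_ramp=t_ramp, dt_schedule=[(t_ramp, dt)], shape="sawtooth",
        )
    if kind == "ramp_hold":
        sched = [(t_ramp, dt)]
        for until, hdt in _HOLD_SCHEDULE:
            if until >= t_hold:
                sched.append((t_ramp + t_hold, hdt))
                break
            sched.append((t_ramp + until, hdt))
        if sched[-1][0] < t_ramp + t_hold:
            sched.append((t_ramp + t_hold, _HOLD_SCHEDULE[-1][1]))
        return LoadingProgram(
            kind="relaxation", axis=axis, amplitude=amplitude,
            t_ramp=t_ramp, t_hold=t_hold, dt_schedule=sched, shape="ramp",
        )
    raise ParameterError(f"unknown program kind {kind!r}")
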