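"""Material-point experiment drivers.

Three drivers mirror the standard calibration and characterization tests:

* :func:`run_strain_path` — fully strain-controlled histories (all six
  components imposed);
* :func:`run_uniaxial` — mixed-control uniaxial tests: the axial strain is
  imposed while the two lateral normal strains are solved at every step so
  the transverse normal stresses vanish (free lateral surfaces), shear
  components identically zero;
* :func:`run_relaxation` — uniaxial ramp to a target strain followed by a
  hold phase in which the full strain vector is frozen and the viscous
  overstress relaxes.

All drivers produce a :class:`ResponseRecord` — a time-stamped table of
strain, stress, accumulated plastic strain kappa, damage D, yield value Y
and regime — exportable to CSV.  On a Newton failure inside a step the
driver bisects the strain increment (up to 10 levels) before giving up.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import constitutive as con
from .parameters import MaterialParameters, MaterialState, ParameterError
from .return_mapping import ConvergenceError, SolverSettings, StepResult, integrate_step

__all__ = [
    "LoadingProgram",
    "ResponseRecord",
    "run_strain_path",
    "run_uniaxial",
    "run_relaxation",
    "simulate_strain_history",
    "program_from_yaml",
    "program_to_yaml",
]

log = logging.getLogger(__name__)

MAX_BISECT_LEVELS = 10

_COLUMNS = (
    ["t"]
    + [f"eps_{c}" for c in ("11", "22", "33", "12", "23", "31")]
    + [f"sig_{c}" for c in ("11", "22", "33", "12", "23", "31")]
    + ["kappa", "D", "Y", "regime"]
)


@dataclass
class LoadingProgram:
    """Description of one material-point loading experiment.

    ``kind`` selects the driver (``strain_path``/``uniaxial``/``relaxation``);
    ``axis`` is the loaded material direction (1-3); ``amplitude`` the signed
    target strain; ``t_ramp``/``t_hold`` the phase durations in seconds.
    ``dt_schedule`` is an ordered list of (until_time, dt) pairs covering the
    whole program, e.g. ``[(1.0, 0.01)]`` for 100 uniform steps over 1 s or a
    growing schedule for long relaxation holds.  ``shape`` distinguishes
    monotone ramps from sawtooth (ramp up then back down) strain paths.
    """

    kind: str
    axis: int = 1
    amplitude: float = 0.0
    t_ramp: float = 1.0
    t_hold: float = 0.0
    dt_schedule: list[tuple[float, float]] | None = None
    shape: str = "ramp"

    def __post_init__(self) -> None:
        if self.kind not in ("strain_path", "uniaxial", "relaxation"):
            raise ParameterError(f"unknown program kind {self.kind!r}")
        if self.axis not in (1, 2, 3):
            raise ParameterError("axis must be 1, 2 or 3")
        if self.t_ramp <= 0 or self.t_hold < 0:
            raise ParameterError("durations must be positive")
        if self.shape not in ("ramp", "sawtooth"):
            raise ParameterError(f"unknown shape {self.shape!r}")
        if self.dt_schedule is None:
            self.dt_schedule = [(self.total_time, self.t_ramp / 100.0)]
        self.dt_schedule = [(float(u), float(d)) for u, d in self.dt_schedule]
        if any(d <= 0 for _, d in self.dt_schedule):
            raise ParameterError("dt values must be positive")
        if self.dt_schedule[-1][0] < self.total_time - 1e-12:
            raise ParameterError("dt_schedule does not cover the full program")

    @property
    def total_time(self) -> float:
        return self.t_ramp + self.t_hold

    def step_times(self) -> np.ndarray:
        """Step-end times implied by the dt schedule, starting after t=0."""
        times = [0.0]
        t = 0.0
        for until, dt in self.dt_schedule:
            while t < min(until, self.total_time) - 1e-9 * max(dt, 1.0):
                t = min(t + dt, until, self.total_time)
                times.append(t)
            if t >= self.total_time - 1e-12:
                break
        return np.array(times)

    def axial_strain(self, t: float) -> float:
        """Imposed axial strain at time t for ramp/sawtooth shapes."""
        if self.shape == "ramp":
            return self.amplitude * min(t / self.t_ramp, 1.0)
        # sawtooth: up and back down within t_ramp, zero afterwards
        x = t / self.t_ramp
        if x >= 1.0:
            return 0.0
        return self.amplitude * (1.0 - abs(1.0 - 2.0 * x))


def program_to_yaml(program: LoadingProgram, path) -> None:
    d = {
        "kind": program.kind,
        "axis": program.axis,
        "amplitude": program.amplitude,
        "t_ramp": program.t_ramp,
        "t_hold": program.t_hold,
        "dt_schedule": [list(p) for p in program.dt_schedule],
        "shape": program.shape,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def program_from_yaml(path) -> LoadingProgram:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("dt_schedule") is not None:
        d["dt_schedule"] = [tuple(p) for p in d["dt_schedule"]]
    return LoadingProgram(**d)


@dataclass
class ResponseRecord:
    """Per-step response table; row 0 is the initial state at t[0].

    Rows hold time, the six Voigt strain and stress components, kappa, D,
    the yield value Y and the step regime.  ``steps`` keeps the per-step
    solver diagnostics (iterations, residuals) for auditing.
    """

    t: np.ndarray
    strain: np.ndarray
    stress: np.ndarray
    kappa: np.ndarray
    D: np.ndarray
    Y: np.ndarray
    regime: list[str]
    steps: list[StepResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("record times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        data = np.column_stack([self.t, self.strain, self.stress, self.kappa, self.D, self.Y])
        df = pd.DataFrame(data, columns=_COLUMNS[:-1])
        df["regime"] = self.regime
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Recorder:
    def __init__(self, params: MaterialParameters, mode: str | None):
        self.params = params
        self.mode = mode
        self.rows: list[tuple] = []
        self.regimes: list[str] = []
        self.steps: list[StepResult] = []

    def add(self, t: float, eps: np.ndarray, state: MaterialState, regime: str,
            step: StepResult | None = None) -> None:
        y = con.yield_value(
            state.sigma, state.kappa, self.params.yield_tensors, self.params.hardening, self.mode
        )
        self.rows.append((t, eps.copy(), state.sigma.copy(), state.kappa, state.D, y))
        self.regimes.append(regime)
        if step is not None:
            self.steps.append(step)

    def record(self) -> ResponseRecord:
        t, eps, sig, kap, dam, yy = zip(*self.rows)
        return ResponseRecord(
            t=np.array(t),
            strain=np.array(eps),
            stress=np.array(sig),
            kappa=np.array(kap),
            D=np.array(dam),
            Y=np.array(yy),
            regime=self.regimes,
            steps=self.steps,
        )


def _advance(
    state: MaterialState,
    eps0: np.ndarray,
    eps1: np.ndarray,
    dt: float,
    params: MaterialParameters,
    settings: SolverSettings,
    mode: str | None,
    level: int = MAX_BISECT_LEVELS,
) -> StepResult:
    """integrate_step with recursive strain-increment bisection on failure."""
    try:
        return integrate_step(state, eps1, dt, params, settings, mode)
    except ConvergenceError:
        if level <= 0:
            raise
        mid = 0.5 * (eps0 + eps1)
        r1 = _advance(state, eps0, mid, 0.5 * dt, params, settings, mode, level - 1)
        r2 = _advance(r1.state, mid, eps1, 0.5 * dt, params, settings, mode, level - 1)
        regime = "plastic" if "plastic" in (r1.regime, r2.regime) else "elastic"
        return StepResult(
            r2.state,
            regime,
            r1.iterations + r2.iterations,
            r2.residual_norm,
            r2.gamma,
            ybar=r2.ybar,
        )


def simulate_strain_history(
    times: np.ndarray,
    strains: np.ndarray,
    params: MaterialParameters,
    settings: SolverSettings | None = None,
    mode: str | None = None,
    initial_state: MaterialState | None = None,
) -> ResponseRecord:
    """Integrate a fully prescribed strain history.

    ``times`` (n+1,) must start at the initial time; ``strains`` (n+1, 6)
    holds the Voigt strain at each time, row 0 being the initial strain
    consistent with ``initial_state`` (virgin zero state by default).
    """
    settings = settings or SolverSettings()
    times = np.asarray(times, dtype=float)
    strains = np.asarray(strains, dtype=float).reshape(len(times), 6)
    state = (initial_state or MaterialState()).copy()
    rec = _Recorder(params, mode)
    rec.add(times[0], strains[0], state, "elastic")
    for k in range(1, len(times)):
        dt = times[k] - times[k - 1]
        try:
            step = _advance(state, strains[k - 1], strains[k], dt, params, settings, mode)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"step {k} (t={times[k]:.6g} s) failed: {err}",
                residual=err.residual,
                iterations=err.iterations,
            ) from err
        state = step.state
        rec.add(times[k], strains[k], state, step.regime, step)
        log.debug(
            "step %d t=%.6g regime=%s iters=%d res=%.3e gamma=%.3e",
            k, times[k], step.regime, step.iterations, step.residual_norm, step.gamma,
        )
    return rec.record()


def run_strain_path(
    program: LoadingProgram,
    params: MaterialParameters,
    settings: SolverSettings | None = None,
    mode: str | None = None,
) -> ResponseRecord:
    """Strain-controlled run: only the program's axial component is imposed."""
    if program.kind != "strain_path":
        raise ParameterError("run_strain_path requires a strain_path program")
    times = program.step_times()
    strains = np.zeros((len(times), 6))
    strains[:, program.axis - 1] = [program.axial_strain(t) for t in times]
    return simulate_strain_history(times, strains, params, settings, mode)


def _solve_lateral(
    state: MaterialState,
    eps_prev: np.ndarray,
    e_axial: float,
    lat_guess: np.ndarray,
    ax: int,
    lat: tuple[int, int],
    dt: float,
    params: MaterialParameters,
    settings: SolverSettings,
    mode: str | None,
    tol: float = 1e-6,
    max_iter: int = 30,
) -> tuple[StepResult, np.ndarray]:
    """Inner Newton on the two lateral strains zeroing transverse stresses."""

    def attempt(lv: np.ndarray) -> tuple[StepResult, np.ndarray]:
        eps = np.zeros(6)
        eps[ax] = e_axial
        eps[lat[0]], eps[lat[1]] = lv
        step = _advance(state, eps_prev, eps, dt, params, settings, mode)
        return step, step.state.sigma[list(lat)]

    lv = lat_guess.astype(float).copy()
    step, f = attempt(lv)
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tol:
            return step, lv
        J = np.empty((2, 2))
        for j in range(2):
            h = 1e-8 + 1e-6 * abs(lv[j])
            lp = lv.copy()
            lp[j] += h
            _, fp = attempt(lp)
            J[:, j] = (fp - f) / h
        try:
            dlv = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular lateral-strain Jacobian in uniaxial driver")
        lv = lv - dlv
        step, f = attempt(lv)
    raise ConvergenceError(
        f"lateral-strain iteration did not converge (|sigma_t| = {np.max(np.abs(f)):.3e} MPa)"
    )


def run_uniaxial(
    program: LoadingProgram,
    params: MaterialParameters,
    settings: SolverSettings | None = None,
    mode: str | None = None,
) -> ResponseRecord:
    """Mixed-control uniaxial test along the program axis.

    The axial strain follows the ramp; at every step the two lateral normal
    strains are found so that the transverse normal stresses vanish within
    1e-6 MPa (inner two-unknown Newton).  Shear components remain zero.
    """
    if program.kind != "uniaxial":
        raise ParameterError("run_uniaxial requires a uniaxial program")
    settings = settings or SolverSettings()
    ax = program.axis - 1
    lat = tuple(i for i in range(3) if i != ax)
    C = params.compliance
    lat_ratio = C[list(lat), ax] / C[ax, ax]  # elastic lateral/axial strain ratio

    times = program.step_times()
    state = MaterialState()
    rec = _Recorder(params, mode)
    eps_prev = np.zeros(6)
    rec.add(times[0], eps_prev, state, "elastic")
    lv = np.zeros(2)
    lv_prev = np.zeros(2)
    first = True
    for k in range(1, len(times)):
        e_ax = program.axial_strain(times[k])
        dt = times[k] - times[k - 1]
        if first:
            guess = lat_ratio * e_ax
            first = False
        else:
            guess = 2.0 * lv - lv_prev  # linear extrapolation of lateral strains
        try:
            step, lv_new = _solve_lateral(
                state, eps_prev, e_ax, guess, ax, lat, dt, params, settings, mode
            )
        except ConvergenceError as err:
            raise ConvergenceError(f"step {k} (t={times[k]:.6g} s) failed: {err}") from err
        lv_prev, lv = lv, lv_new
        state = step.state
        eps_prev = np.zeros(6)
        eps_prev[ax] = e_ax
        eps_prev[lat[0]], eps_prev[lat[1]] = lv
        rec.add(times[k], eps_prev, state, step.regime, step)
    return rec.record()


def run_relaxation(
    program: LoadingProgram,
    params: MaterialParameters,
    settings: SolverSettings | None = None,
    mode: str | None = None,
) -> ResponseRecord:
    """Uniaxial ramp to the target strain, then hold the full strain vector.

    During the ramp the test is mixed-control (transverse stresses free);
    during the hold every strain component is frozen at its end-of-ramp
    value and the overstress relaxes towards the rate-independent state.
    Warns when the ramp never leaves the elastic domain (an elastic hold
    carries no overstress and the stress stays exactly constant).
    """
    if program.kind != "relaxation":
        raise ParameterError("run_relaxation requires a relaxation program")
    if program.t_hold <= 0:
        raise ParameterError("relaxation program needs t_hold > 0")
    settings = settings or SolverSettings()

    ramp = LoadingProgram(
        kind="uniaxial",
        axis=program.axis,
        amplitude=program.amplitude,
        t_ramp=program.t_ramp,
        dt_schedule=[(u, d) for u, d in program.dt_schedule if u <= program.t_ramp + 1e-12]
        or [(program.t_ramp, program.dt_schedule[0][1])],
        shape="ramp",
    )
    rec_ramp = run_uniaxial(ramp, params, settings, mode)
    if not any(r == "plastic" for r in rec_ramp.regime):
        warnings.warn(
            "relaxation ramp stayed elastic: no overstress develops during the hold",
            stacklevel=2,
        )

    state = MaterialState(
        rec_ramp.stress[-1],
        rec_ramp.steps[-1].state.eps_p if rec_ramp.steps else np.zeros(6),
        rec_ramp.kappa[-1],
        rec_ramp.D[-1],
    )
    eps_hold = rec_ramp.strain[-1].copy()

    rec = _Recorder(params, mode)
    rec.rows = list(zip(rec_ramp.t, rec_ramp.strain, rec_ramp.stress,
                        rec_ramp.kappa, rec_ramp.D, rec_ramp.Y))
    rec.regimes = list(rec_ramp.regime)
    rec.steps = list(rec_ramp.steps)

    t = program.t_ramp
    for until, dt in program.dt_schedule:
        if until <= program.t_ramp + 1e-12:
            continue
        while t < min(until, program.total_time) - 1e-9 * max(dt, 1.0):
            t_next = min(t + dt, until, program.total_time)
            step = _advance(state, eps_hold, eps_hold, t_next - t, params, settings, mode)
            state = step.state
            rec.add(t_next, eps_hold, state, step.regime, step)
            t = t_next
        if t >= program.total_time - 1e-12:
            break
    return rec.record()
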