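"""Firing-rate / neuromodulator dynamics of the basal-ganglia-thalamo-cortical loop.

The model couples six neural populations — primary motor cortex (M1),
thalamus (Thal), dorsal raphe nucleus (DRN), substantia nigra pars compacta
(SNc), and the striatal direct (DP) and indirect (IP) pathways — with the
striatal concentrations of serotonin (5-HT) and dopamine (DA).  Eight coupled
first-order ODEs describe the loop; every variable carries a linear decay
term, inter-area influences are linear except for DA release (a product of
5-HT concentration and SNc rate) and the pathological oscillatory drive on
the indirect pathway, whose amplitude is inversely modulated by DA:

    dM1/dt   = a1Thal*Thal - tauM1*M1
    dThal/dt = a2Ex + a2DP*DP - a2IP*IP - tauThal*Thal
    dDRN/dt  = a3Ex - a3M1*M1 + a3SNc*SNc - tauDRN*DRN
    d5HT/dt  = a4DRN*DRN - tau5HT*5HT
    dSNc/dt  = a5Ex - a5DRN*DRN - tauSNc*SNc
    dDA/dt   = G*5HT*SNc - tauDA*DA
    dDP/dt   = a7Ex + a7DA*DA - tauDP*DP
    dIP/dt   = a8Ex - tauIP*IP + alphaIP*sin(fIP*t)/max(DA, EPSILON_DA)

The inverse-DA reading of the oscillatory term makes dopamine loss amplify
the indirect-pathway (GPe-STN) oscillation, which is the mechanism by which
lesions produce tremor in this model; ``EPSILON_DA`` guards the denominator.

Lesions and drug doses are timed multiplicative changes of single
parameters (:class:`Intervention`), applied to the running parameter value
just before the first integration step at or after the intervention time.
Integration is fixed-step explicit Euler by default (dt = 0.1 s), with a
classical RK4 stepper available through :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "EPSILON_DA",
    "OVERFLOW_GUARD",
    "CircuitParameters",
    "CircuitState",
    "Intervention",
    "InterventionSchedule",
    "SimulationConfig",
    "Trajectory",
    "CircuitError",
    "IntegrationError",
    "SteadyStateError",
    "circuit_derivatives",
    "integrate_circuit",
    "integrate_batch",
    "steady_state",
    "mean_abs_percentage_error",
    "DEFAULT_PARAMS",
    "REFERENCE_STATE",
]

# Floor for DA wherever it appears in a denominator (nM).
EPSILON_DA = 1e-3
# Any |state| above this aborts integration with a diagnostic.
OVERFLOW_GUARD = 1e9

PARAM_NAMES: tuple[str, ...] = (
    "a1Thal", "tauM1",
    "a2Ex", "a2DP", "a2IP", "tauThal",
    "a3Ex", "a3M1", "a3SNc", "tauDRN",
    "a4DRN", "tau5HT",
    "a5Ex", "a5DRN", "tauSNc",
    "G", "tauDA",
    "a7Ex", "a7DA", "tauDP",
    "a8Ex", "fIP", "alphaIP", "tauIP",
)

STATE_NAMES: tuple[str, ...] = (
    "M1", "Thal", "DRN", "fiveHT", "SNc", "DA", "DP", "IP",
)

_P = {name: i for i, name in enumerate(PARAM_NAMES)}
_S = {name: i for i, name in enumerate(STATE_NAMES)}


class CircuitError(Exception):
    """Base class for circuit-model failures."""


class IntegrationError(CircuitError):
    """Raised when a state variable blows up or becomes non-finite.

    Attributes ``time`` and ``variable`` identify where the failure
    occurred.
    """

    def __init__(self, time: float, variable: str):
        self.time = float(time)
        self.variable = variable
        super().__init__(
            f"integration failure at t={time:.4g} s: variable {variable!r} "
            f"non-finite or beyond the overflow guard ({OVERFLOW_GUARD:g})"
        )


class SteadyStateError(CircuitError):
    """Raised when the windowed mean fails to converge within the horizon.

    ``last_mean`` holds the mean over the final complete window so callers
    (e.g. the calibration fitness) can still penalise the candidate.
    """

    def __init__(self, message: str, last_mean: "CircuitState | None" = None):
        self.last_mean = last_mean
        super().__init__(message)


@dataclass(frozen=True)
class CircuitParameters:
    """The 24 coefficients of the loop equations.

    Defaults are the published parameter table.  ``a*`` coefficients are
    inter-area gains or constant external drives (Hz or drive units);
    ``tau*`` are the decay coefficients, used multiplicatively exactly as
    they appear in the equations; ``G`` converts 5-HT (nM) x SNc (Hz) into
    DA release; ``fIP``/``alphaIP`` set the angular frequency (rad/s) and
    gain of the indirect-pathway oscillation.
    """

    a1Thal: float = 1.3655
    tauM1: float = 0.9330
    a2Ex: float = 1.5985
    a2DP: float = 3.7502
    a2IP: float = 2.1032
    tauThal: float = 0.2547
    a3Ex: float = 6.6911
    a3M1: float = 0.1671
    a3SNc: float = 0.010
    tauDRN: float = 1.6829
    a4DRN: float = 1.1951
    tau5HT: float = 1.9949
    a5Ex: float = 60.4428
    a5DRN: float = 13.6055
    tauSNc: float = 9.2357
    G: float = 0.8083
    tauDA: float = 1.1173
    a7Ex: float = 2.4290
    a7DA: float = 0.1544
    tauDP: float = 1.0648
    a8Ex: float = 1.1229
    fIP: float = 6.1493
    alphaIP: float = 7.3801
    tauIP: float = 1.0283

    def __post_init__(self) -> None:
        # zero is allowed so that degenerate configurations (zero drives,
        # silenced oscillator, frozen couplings) remain expressible;
        # negative coefficients would flip the sign structure of the loop.
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"parameter {name!r} must be non-negative and finite, "
                    f"got {value!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CircuitParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected shape ({len(PARAM_NAMES)},), got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def replace(self, **changes: float) -> "CircuitParameters":
        return dataclasses.replace(self, **changes)

    def scaled(self, name: str, multiplier: float) -> "CircuitParameters":
        """Return a copy with ``name`` multiplied by ``multiplier``."""
        if name not in _P:
            raise KeyError(f"unknown parameter {name!r}")
        return self.replace(**{name: getattr(self, name) * multiplier})

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class CircuitState:
    """One point of the eight-dimensional state.

    Firing rates in Hz (M1, Thal, DRN, SNc, DP, IP); striatal concentrations
    in nM (fiveHT, DA).  Defaults are the experimentally observed reference
    steady state that calibration targets.
    """

    M1: float = 23.6
    Thal: float = 17.5
    DRN: float = 1.41
    fiveHT: float = 0.846
    SNc: float = 4.47
    DA: float = 2.72
    DP: float = 1.85
    IP: float = 1.88

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CircuitState":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(STATE_NAMES),):
            raise ValueError(f"expected shape ({len(STATE_NAMES)},), got {values.shape}")
        return cls(**dict(zip(STATE_NAMES, values.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in STATE_NAMES}


DEFAULT_PARAMS = CircuitParameters()
REFERENCE_STATE = CircuitState()


@dataclass(frozen=True)
class Intervention:
    """A timed multiplicative change of one parameter.

    A +X% lesion is ``multiplier = 1 + X/100``; a -X% dose is
    ``1 - X/100``.  Multipliers compose on the running value of the
    parameter, so two interventions on the same parameter accumulate.
    """

    time: float
    parameter: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.parameter not in _P:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not np.isfinite(self.multiplier) or self.multiplier <= 0:
            raise ValueError(f"multiplier must be > 0, got {self.multiplier!r}")
        if self.time < 0:
            raise ValueError(f"intervention time must be >= 0, got {self.time!r}")


@dataclass(frozen=True)
class InterventionSchedule:
    """Time-ordered list of interventions."""

    interventions: tuple[Intervention, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.interventions, key=lambda iv: iv.time))
        object.__setattr__(self, "interventions", ordered)

    def __iter__(self):
        return iter(self.interventions)

    def __len__(self) -> int:
        return len(self.interventions)

    @classmethod
    def from_dicts(cls, entries: Iterable[dict]) -> "InterventionSchedule":
        return cls(tuple(
            Intervention(float(e["time"]), str(e["parameter"]), float(e["multiplier"]))
            for e in entries
        ))

    def to_dicts(self) -> list[dict]:
        return [
            {"time": iv.time, "parameter": iv.parameter, "multiplier": iv.multiplier}
            for iv in self.interventions
        ]


@dataclass(frozen=True)
class SimulationConfig:
    """Horizon, step and integration options for the circuit.

    ``method`` is ``"euler"`` (the published fixed step, default) or
    ``"rk4"``.  ``clamp_nonnegative`` optionally floors every state variable
    at zero after each step; off by default since the equations themselves
    do not prescribe it.
    """

    duration: float = 300.0
    dt: float = 0.1
    initial_state: CircuitState = field(default_factory=CircuitState)
    seed: int = 0
    method: str = "euler"
    clamp_nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration!r}")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration ({self.duration}) must be an integer multiple of dt ({self.dt})"
            )
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"method must be 'euler' or 'rk4', got {self.method!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class Trajectory:
    """A recorded run: time grid plus one series per state variable."""

    time: np.ndarray          # (n+1,)
    states: np.ndarray        # (n+1, 8)

    def series(self, name: str) -> np.ndarray:
        return self.states[:, _S[name]]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        frame.insert(0, "time", self.time)
        return frame

    def write_csv(self, path) -> None:
        # >= 9 significant digits so runs round-trip through text exactly
        # enough for downstream analysis.
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def window_mean(self, start: float, stop: float) -> CircuitState:
        """Mean state over ``start <= t <= stop``."""
        mask = (self.time >= start - 1e-9) & (self.time <= stop + 1e-9)
        if not mask.any():
            raise ValueError(f"window [{start}, {stop}] contains no samples")
        return CircuitState.from_array(self.states[mask].mean(axis=0))


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def _derivatives_array(y: np.ndarray, p: np.ndarray, t: float) -> np.ndarray:
    """Vectorised right-hand side.  ``y``: (..., 8), ``p``: (..., 24)."""
    M1 = y[..., 0]; Thal = y[..., 1]; DRN = y[..., 2]; HT = y[..., 3]
    SNc = y[..., 4]; DA = y[..., 5]; DP = y[..., 6]; IP = y[..., 7]

    da_safe = np.maximum(DA, EPSILON_DA)
    osc = p[..., 22] * np.sin(p[..., 21] * t) / da_safe

    out = np.empty_like(y)
    out[..., 0] = p[..., 0] * Thal - p[..., 1] * M1
    out[..., 1] = p[..., 2] + p[..., 3] * DP - p[..., 4] * IP - p[..., 5] * Thal
    out[..., 2] = p[..., 6] - p[..., 7] * M1 + p[..., 8] * SNc - p[..., 9] * DRN
    out[..., 3] = p[..., 10] * DRN - p[..., 11] * HT
    out[..., 4] = p[..., 12] - p[..., 13] * DRN - p[..., 14] * SNc
    out[..., 5] = p[..., 15] * HT * SNc - p[..., 16] * DA
    out[..., 6] = p[..., 17] + p[..., 18] * DA - p[..., 19] * DP
    out[..., 7] = p[..., 20] - p[..., 23] * IP + osc
    return out


def circuit_derivatives(
    state: CircuitState, params: CircuitParameters, t: float = 0.0
) -> CircuitState:
    """Instantaneous derivative of each state variable at time ``t``.

    Raises :class:`IntegrationError` naming the first offending variable if
    the state is non-finite.
    """
    y = state.to_array()
    bad = ~np.isfinite(y)
    if bad.any():
        raise IntegrationError(t, STATE_NAMES[int(np.argmax(bad))])
    rates = _derivatives_array(y, params.to_array(), float(t))
    return CircuitState.from_array(rates)


# ---------------------------------------------------------------------------
# fixed-step integration
# ---------------------------------------------------------------------------

def _euler_step(y, p, t, dt):
    return y + dt * _derivatives_array(y, p, t)


def _rk4_step(y, p, t, dt):
    k1 = _derivatives_array(y, p, t)
    k2 = _derivatives_array(y + 0.5 * dt * k1, p, t + 0.5 * dt)
    k3 = _derivatives_array(y + 0.5 * dt * k2, p, t + 0.5 * dt)
    k4 = _derivatives_array(y + dt * k3, p, t + dt)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_batch(
    param_array: np.ndarray,
    initial_array: np.ndarray,
    config: SimulationConfig,
    schedule: InterventionSchedule | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a batch of circuits sharing one intervention schedule.

    Parameters
    ----------
    param_array:
        Shape (B, 24); modified copies are used internally, the input is
        left untouched.
    initial_array:
        Shape (B, 8) initial states.
    config, schedule:
        As for :func:`integrate_circuit`; the schedule multiplies the
        running parameter value of every batch member.

    Returns
    -------
    states : (n_steps + 1, B, 8) array.  Rows of failed members are NaN
        from the failing step onward.
    fail_time : (B,) first failure time, NaN where the run succeeded.
    fail_var : (B,) index into ``STATE_NAMES`` of the failing variable,
        -1 where the run succeeded.
    """
    p = np.array(param_array, dtype=float)
    if p.ndim != 2 or p.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"param_array must be (B, 24), got {p.shape}")
    y = np.array(initial_array, dtype=float)
    if y.shape != (p.shape[0], len(STATE_NAMES)):
        raise ValueError(f"initial_array must be (B, 8), got {y.shape}")

    n = config.n_steps
    dt = config.dt
    step = _euler_step if config.method == "euler" else _rk4_step
    events = sorted(schedule or (), key=lambda iv: iv.time)
    n_batch = p.shape[0]

    out = np.empty((n + 1, n_batch, len(STATE_NAMES)), dtype=float)
    out[0] = y
    fail_time = np.full(n_batch, np.nan)
    fail_var = np.full(n_batch, -1, dtype=int)
    alive = np.ones(n_batch, dtype=bool)

    next_event = 0
    for i in range(n):
        t = i * dt
        while next_event < len(events) and events[next_event].time <= t + 1e-9:
            iv = events[next_event]
            p[:, _P[iv.parameter]] *= iv.multiplier
            next_event += 1
        y = step(y, p, t, dt)
        if config.clamp_nonnegative:
            np.maximum(y, 0.0, out=y)
        with np.errstate(invalid="ignore"):
            ok = np.all(np.abs(y) < OVERFLOW_GUARD, axis=-1)
        if not ok.all():
            newly_dead = alive & ~ok
            if newly_dead.any():
                for b in np.flatnonzero(newly_dead):
                    with np.errstate(invalid="ignore"):
                        bad = ~(np.abs(y[b]) < OVERFLOW_GUARD)
                    fail_time[b] = (i + 1) * dt
                    fail_var[b] = int(np.argmax(bad))
                alive &= ok
            y[~alive] = np.nan
        out[i + 1] = y
    return out, fail_time, fail_var


def integrate_circuit(
    config: SimulationConfig,
    params: CircuitParameters,
    schedule: InterventionSchedule | None = None,
) -> Trajectory:
    """Fixed-step integration of the full loop over the horizon.

    Interventions multiply the named parameter just before the first step
    at or after their time, so the trajectory up to that time is identical
    to the unlesioned run.  Raises :class:`IntegrationError` on blow-up.
    """
    states, fail_time, fail_var = integrate_batch(
        params.to_array()[None, :],
        config.initial_state.to_array()[None, :],
        config,
        schedule,
    )
    if fail_var[0] >= 0:
        raise IntegrationError(fail_time[0], STATE_NAMES[fail_var[0]])
    time = np.arange(config.n_steps + 1) * config.dt
    return Trajectory(time=time, states=states[:, 0, :])


# ---------------------------------------------------------------------------
# steady state and calibration metric
# ---------------------------------------------------------------------------

def convergence_window_samples(dt: float, n_min: int, fip: float) -> int:
    """Window length (samples) covering a near-integer number of forcing periods.

    The indirect-pathway forcing sin(fIP*t) only averages out of a window
    mean when the window spans (almost exactly) whole oscillation periods;
    this picks the sample count in [n_min, 2*n_min] whose span comes
    closest to a multiple of the period, which shrinks the oscillatory
    residue of the mean by several orders of magnitude.
    """
    if not np.isfinite(fip) or fip <= 0:
        return n_min
    best, best_err = n_min, np.inf
    two_pi = 2.0 * np.pi
    for n in range(n_min, 2 * n_min + 1):
        phase = (fip * n * dt) % two_pi
        err = min(phase, two_pi - phase)
        if err < best_err - 1e-12:
            best, best_err = n, err
    return best


def steady_state(
    params: CircuitParameters,
    config: SimulationConfig | None = None,
    window: float = 10.0,
    tol: float = 1e-4,
) -> CircuitState:
    """Converged windowed-mean state of the unlesioned model.

    Means are taken over consecutive non-overlapping windows of at least
    ``window`` seconds (default 10 s, longer than the oscillation period),
    stretched to a near-integer number of forcing periods so the
    sinusoidal indirect-pathway component averages out (see
    :func:`convergence_window_samples`).  Convergence is declared when the
    relative change of every variable between successive window means
    drops below ``tol``; the mean over the later window is returned.
    """
    if config is None:
        config = SimulationConfig()
    traj = integrate_circuit(config, params)
    n_min = int(round(window / config.dt))
    if n_min < 1:
        raise ValueError("window shorter than one step")
    k = convergence_window_samples(config.dt, n_min, params.fIP)
    n_windows = traj.states.shape[0] // k
    if n_windows < 2:
        raise ValueError("horizon holds fewer than two convergence windows")
    # trailing alignment: the last window ends at the final sample
    tail = traj.states[traj.states.shape[0] - n_windows * k:]
    means = tail.reshape(n_windows, k, -1).mean(axis=1)
    prev = means[:-1]
    curr = means[1:]
    denom = np.maximum(np.abs(prev), 1e-12)
    rel = np.max(np.abs(curr - prev) / denom, axis=1)
    converged = np.flatnonzero(rel < tol)
    if converged.size == 0:
        raise SteadyStateError(
            f"windowed mean did not converge within {config.duration} s "
            f"(last relative change {rel[-1]:.3g})",
            last_mean=CircuitState.from_array(means[-1]),
        )
    return CircuitState.from_array(means[converged[0] + 1])


def mean_abs_percentage_error(
    estimate: CircuitState, reference: CircuitState
) -> float:
    """Mean over the 8 variables of |estimate - reference| / |reference|."""
    est = estimate.to_array()
    ref = reference.to_array()
    if np.any(ref == 0):
        zero = STATE_NAMES[int(np.argmax(ref == 0))]
        raise ValueError(f"reference value for {zero!r} is zero; APE undefined")
    return float(np.mean(np.abs(est - ref) / np.abs(ref)))
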