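"""Two-link planar arm driven by motor-cortex activity through a PD controller.

The arm is an anthropomorphic shoulder-elbow linkage moving in a horizontal
(gravity-free) plane, anchored at the origin.  Rigid-body dynamics are

    M(q) q'' + C(q, q') q' = T

with the standard two-link inertia matrix and Coriolis/centripetal terms,
integrated with a classical fourth-order Runge-Kutta scheme at dt = 0.01 s.
Joint torques come from a proportional-derivative controller,

    T = Kp (A_des - A_cur) - Kd dA_cur/dt,

which stands in for the visco-elastic behaviour of arm muscles.  Desired
angles are an affine image of the scalar M1 firing-rate trace: the minimum
of the trace over the whole experiment maps to the lower joint limits
(shoulder -60 deg, elbow 0 deg) and the maximum to the upper limits
(150 deg, 180 deg), so pathological M1 oscillations become joint
oscillations and, through the forward kinematics, endpoint tremor.

Tremor is quantified as the mean half peak-to-peak excursion of the
endpoint along its dominant oscillation axis, cycle by cycle (see
:func:`tremor_amplitude`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArmParameters",
    "ControllerGains",
    "ArmState",
    "ArmTrace",
    "ArmConfigurationError",
    "DEFAULT_ARM",
    "DEFAULT_GAINS",
    "pd_torque",
    "forward_kinematics",
    "step_arm",
    "m1_to_desired_angles",
    "resample_zero_order_hold",
    "simulate_arm_from_m1",
    "tremor_amplitude",
    "tremor_cycles",
]

_DEG = np.pi / 180.0


class ArmConfigurationError(Exception):
    """Degenerate arm parameters (singular inertia matrix)."""


@dataclass(frozen=True)
class ArmParameters:
    """Physical constants of the two links and the joint limits.

    Canonical human-arm values: upper arm 0.30 m / 1.9 kg, forearm
    0.35 m / 1.1 kg, centre of mass at mid-link, slender-rod moments of
    inertia about the centre of mass.  Angles are radians internally;
    joint limits are shoulder in [-60 deg, 150 deg] and elbow in
    [0 deg, 180 deg], the shoulder anchored at (0, 0).
    """

    l1: float = 0.30        # upper-arm length (m)
    l2: float = 0.35        # forearm length (m)
    m1: float = 1.9         # upper-arm mass (kg)
    m2: float = 1.1         # forearm mass (kg)
    lc1: float = 0.15       # shoulder -> upper-arm COM (m)
    lc2: float = 0.175      # elbow -> forearm COM (m)
    I1: float = 1.9 * 0.30**2 / 12.0    # about COM (kg m^2)
    I2: float = 1.1 * 0.35**2 / 12.0
    shoulder_limits: tuple[float, float] = (-60.0 * _DEG, 150.0 * _DEG)
    elbow_limits: tuple[float, float] = (0.0, 180.0 * _DEG)

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "m1", "m2", "lc1", "lc2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"arm parameter {name!r} must be positive")
        # inertia matrix must be positive definite over the whole workspace;
        # the worst case for the determinant is the fully folded elbow.
        for q2 in (0.0, np.pi):
            m11, m12, m22 = self._inertia_entries(np.array(q2))
            det = m11 * m22 - m12 * m12
            if det <= 1e-12 or m22 <= 1e-12:
                raise ArmConfigurationError(
                    "inertia matrix is singular for these link parameters"
                )

    def _inertia_entries(self, q2: np.ndarray):
        c2 = np.cos(q2)
        m22 = self.I2 + self.m2 * self.lc2**2
        m12 = m22 + self.m2 * self.l1 * self.lc2 * c2
        m11 = (
            self.I1 + self.m1 * self.lc1**2
            + m22 + self.m2 * (self.l1**2 + 2.0 * self.l1 * self.lc2 * c2)
        )
        return m11, m12, m22


@dataclass(frozen=True)
class ControllerGains:
    """PD gains, (shoulder, elbow): Kp in Nm/rad, Kd in Nm s/rad."""

    kp: tuple[float, float] = (20.0, 10.0)
    kd: tuple[float, float] = (1.5, 1.0)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (*self.kp, *self.kd)):
            raise ValueError("controller gains must be positive")


DEFAULT_ARM = ArmParameters()
DEFAULT_GAINS = ControllerGains()


@dataclass(frozen=True)
class ArmState:
    """Joint angles and angular velocities, (shoulder, elbow), radians."""

    angles: tuple[float, float] = (0.0, 0.0)
    velocities: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class ArmTrace:
    """Recorded arm run: joint angles plus the endpoint path."""

    time: np.ndarray        # (n,)
    angles: np.ndarray      # (n, 2) shoulder, elbow
    endpoint: np.ndarray    # (n, 2) x, y in metres

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time,
            "shoulder_angle": self.angles[:, 0],
            "elbow_angle": self.angles[:, 1],
            "x": self.endpoint[:, 0],
            "y": self.endpoint[:, 1],
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def pd_torque(desired, current, velocity, gains: ControllerGains = DEFAULT_GAINS):
    """Element-wise PD law ``T = Kp (desired - current) - Kd velocity``."""
    desired = np.asarray(desired, dtype=float)
    current = np.asarray(current, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if not (np.isfinite(desired).all() and np.isfinite(current).all()
            and np.isfinite(velocity).all()):
        raise ValueError("pd_torque requires finite inputs")
    kp = np.asarray(gains.kp)
    kd = np.asarray(gains.kd)
    return kp * (desired - current) - kd * velocity


def forward_kinematics(angles, params: ArmParameters = DEFAULT_ARM):
    """Endpoint (x, y) for shoulder/elbow angles; works on (..., 2) arrays."""
    angles = np.asarray(angles, dtype=float)
    beta = angles[..., 0]
    alpha = angles[..., 1]
    x = params.l1 * np.cos(beta) + params.l2 * np.cos(beta + alpha)
    y = params.l1 * np.sin(beta) + params.l2 * np.sin(beta + alpha)
    return np.stack([x, y], axis=-1)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _accelerations(q, qd, torque, params: ArmParameters):
    """Solve M(q) qdd = torque - C(q, qd) qd.  Shapes (..., 2)."""
    q2 = q[..., 1]
    m11, m12, m22 = params._inertia_entries(q2)
    h = params.m2 * params.l1 * params.lc2 * np.sin(q2)
    qd1 = qd[..., 0]
    qd2 = qd[..., 1]
    c1 = -h * (2.0 * qd1 * qd2 + qd2 * qd2)
    c2 = h * qd1 * qd1
    rhs1 = torque[..., 0] - c1
    rhs2 = torque[..., 1] - c2
    det = m11 * m22 - m12 * m12
    qdd1 = (m22 * rhs1 - m12 * rhs2) / det
    qdd2 = (m11 * rhs2 - m12 * rhs1) / det
    return np.stack([qdd1, qdd2], axis=-1)


def _arm_rhs(q, qd, torque, params):
    return qd, _accelerations(q, qd, torque, params)


def _rk4_arm_step(q, qd, torque, params, dt):
    """One RK4 step with torque held constant over the step."""
    return _rk4_closed_loop_step(q, qd, lambda qq, vv: torque, params, dt)


def _rk4_closed_loop_step(q, qd, torque_fn, params, dt):
    """One RK4 step with the torque re-evaluated at every stage state.

    ``torque_fn(q, qd)`` closes the feedback loop inside the step, which
    preserves the fourth-order accuracy of the scheme for state-dependent
    (PD-controlled) torques.
    """
    k1q, k1v = _arm_rhs(q, qd, torque_fn(q, qd), params)
    q2, v2 = q + 0.5 * dt * k1q, qd + 0.5 * dt * k1v
    k2q, k2v = _arm_rhs(q2, v2, torque_fn(q2, v2), params)
    q3, v3 = q + 0.5 * dt * k2q, qd + 0.5 * dt * k2v
    k3q, k3v = _arm_rhs(q3, v3, torque_fn(q3, v3), params)
    q4, v4 = q + dt * k3q, qd + dt * k3v
    k4q, k4v = _arm_rhs(q4, v4, torque_fn(q4, v4), params)
    q_new = q + (dt / 6.0) * (k1q + 2 * k2q + 2 * k3q + k4q)
    qd_new = qd + (dt / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
    return q_new, qd_new


def _apply_joint_limits(q, qd, params: ArmParameters):
    """Clamp angles to the joint ranges, zeroing the offending velocity."""
    lims = np.array([params.shoulder_limits, params.elbow_limits])  # (2, 2)
    low = lims[:, 0]
    high = lims[:, 1]
    below = q < low
    above = q > high
    q = np.clip(q, low, high)
    qd = np.where(below & (qd < 0), 0.0, qd)
    qd = np.where(above & (qd > 0), 0.0, qd)
    return q, qd


def step_arm(
    state: ArmState,
    torque,
    params: ArmParameters = DEFAULT_ARM,
    dt: float = 0.01,
) -> ArmState:
    """Advance the rigid-body dynamics one RK4 step under a constant torque."""
    q = np.asarray(state.angles, dtype=float)
    qd = np.asarray(state.velocities, dtype=float)
    torque = np.asarray(torque, dtype=float)
    q, qd = _rk4_arm_step(q, qd, torque, params, dt)
    q, qd = _apply_joint_limits(q, qd, params)
    return ArmState(angles=tuple(q.tolist()), velocities=tuple(qd.tolist()))


# ---------------------------------------------------------------------------
# M1 drive
# ---------------------------------------------------------------------------

def m1_to_desired_angles(
    m1_series: np.ndarray, params: ArmParameters = DEFAULT_ARM
) -> np.ndarray:
    """Affine map from the scalar M1 trace to (shoulder, elbow) targets.

    The minimum of the full trace maps to the lower joint limits and the
    maximum to the upper limits; the same scalar signal drives both joints.
    Raises ``ValueError`` for a (numerically) constant trace, for which the
    scaling is undefined.
    """
    m1 = np.asarray(m1_series, dtype=float)
    lo = float(np.min(m1))
    hi = float(np.max(m1))
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        raise ValueError("M1 series is constant; angle scaling is undefined")
    u = (m1 - lo) / (hi - lo)
    sh = params.shoulder_limits[0] + u * (params.shoulder_limits[1] - params.shoulder_limits[0])
    el = params.elbow_limits[0] + u * (params.elbow_limits[1] - params.elbow_limits[0])
    return np.stack([sh, el], axis=-1)


def resample_zero_order_hold(
    series: np.ndarray, dt_src: float, dt_dst: float, n_out: int
) -> np.ndarray:
    """Sample-and-hold resampling from a coarse grid onto a finer one."""
    series = np.asarray(series)
    t = np.arange(n_out) * dt_dst
    idx = np.minimum((t / dt_src + 1e-9).astype(int), len(series) - 1)
    return series[idx]


def simulate_arm_from_m1(
    m1_series: np.ndarray,
    circuit_dt: float = 0.1,
    params: ArmParameters = DEFAULT_ARM,
    gains: ControllerGains = DEFAULT_GAINS,
    dt: float = 0.01,
    initial: ArmState | None = None,
) -> ArmTrace:
    """Drive the arm over the full experiment from an M1 firing-rate trace.

    The M1 trace (on the circuit grid, step ``circuit_dt``) is mapped to
    desired joint angles, held piecewise-constant on the arm grid, and
    tracked by the PD controller.  The arm starts at rest with both angles
    at zero unless ``initial`` is given.
    """
    traces = simulate_arm_from_m1_batch(
        np.asarray(m1_series, dtype=float)[:, None],
        circuit_dt=circuit_dt, params=params, gains=gains, dt=dt,
        initial=initial,
    )
    return traces[0]


def simulate_arm_from_m1_batch(
    m1_series: np.ndarray,
    circuit_dt: float = 0.1,
    params: ArmParameters = DEFAULT_ARM,
    gains: ControllerGains = DEFAULT_GAINS,
    dt: float = 0.01,
    initial: ArmState | None = None,
) -> list[ArmTrace]:
    """Vectorised form of :func:`simulate_arm_from_m1`.

    ``m1_series`` has shape (n_circuit_samples, B); one trace per column is
    returned.  All columns share the arm constants and controller gains but
    each is scaled by its own trace extrema.
    """
    m1 = np.asarray(m1_series, dtype=float)
    if m1.ndim != 2:
        raise ValueError("m1_series must be (n_samples, B)")
    n_src, n_batch = m1.shape
    horizon = (n_src - 1) * circuit_dt
    n_steps = int(round(horizon / dt))

    desired = np.empty((n_steps + 1, n_batch, 2))
    for b in range(n_batch):
        tgt = m1_to_desired_angles(m1[:, b], params)
        desired[:, b, 0] = resample_zero_order_hold(tgt[:, 0], circuit_dt, dt, n_steps + 1)
        desired[:, b, 1] = resample_zero_order_hold(tgt[:, 1], circuit_dt, dt, n_steps + 1)

    if initial is None:
        q = np.zeros((n_batch, 2))
        qd = np.zeros((n_batch, 2))
    else:
        q = np.tile(np.asarray(initial.angles, dtype=float), (n_batch, 1))
        qd = np.tile(np.asarray(initial.velocities, dtype=float), (n_batch, 1))

    kp = np.asarray(gains.kp)
    kd = np.asarray(gains.kd)
    angles = np.empty((n_steps + 1, n_batch, 2))
    angles[0] = q
    for i in range(n_steps):
        target = desired[i]
        q, qd = _rk4_closed_loop_step(
            q, qd, lambda qq, vv: kp * (target - qq) - kd * vv, params, dt
        )
        q, qd = _apply_joint_limits(q, qd, params)
        angles[i + 1] = q

    time = np.arange(n_steps + 1) * dt
    endpoint = forward_kinematics(angles, params)
    return [
        ArmTrace(time=time, angles=angles[:, b], endpoint=endpoint[:, b])
        for b in range(n_batch)
    ]


# ---------------------------------------------------------------------------
# tremor metric
# ---------------------------------------------------------------------------

def _principal_displacement(endpoint: np.ndarray) -> np.ndarray:
    """Signed displacement of the endpoint along its dominant axis.

    The endpoint cloud is centred on its mean and projected onto the first
    principal axis, giving a scalar series whose sign distinguishes the two
    half-cycles of an oscillation.  Rigid translations of the trace leave
    the result unchanged and uniform scalings scale it linearly.
    """
    centred = endpoint - endpoint.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    return centred @ axis


def tremor_cycles(trace: ArmTrace, window: tuple[float, float]):
    """Per-cycle peak-to-peak excursions of the endpoint within ``window``.

    Cycles are delimited by every second zero-crossing of the detrended
    (mean-subtracted) displacement along the dominant oscillation axis.
    Returns the array of peak-to-peak values (possibly empty).
    """
    t0, t1 = window
    mask = (trace.time >= t0 - 1e-9) & (trace.time <= t1 + 1e-9)
    if not mask.any():
        raise ValueError(f"window [{t0}, {t1}] lies outside the trace")
    s = _principal_displacement(trace.endpoint[mask])
    s = s - s.mean()
    sign = np.sign(s)
    sign[sign == 0] = 1
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if crossings.size < 3:
        return np.empty(0)
    p2p = []
    for a, b in zip(crossings[:-2:2], crossings[2::2]):
        seg = s[a:b + 1]
        p2p.append(seg.max() - seg.min())
    return np.asarray(p2p)


def tremor_amplitude(trace: ArmTrace, window: tuple[float, float]) -> float:
    """Mean endpoint oscillation amplitude (metres) over a time window.

    Defined as half the mean per-cycle peak-to-peak excursion (see
    :func:`tremor_cycles`).  If fewer than two full cycles are detected the
    amplitude is reported as 0.0 with a warning.
    """
    p2p = tremor_cycles(trace, window)
    if p2p.size < 2:
        warnings.warn(
            f"fewer than 2 oscillation cycles in window {window}; "
            "tremor amplitude reported as 0",
            stacklevel=2,
        )
        return 0.0
    return float(p2p.mean() / 2.0)
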