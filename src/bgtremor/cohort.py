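"""Simulated-subject cohorts and the three in-silico experiments.

A cohort of simulated subjects is built by perturbing every model
parameter and every initial state value with additive zero-mean Gaussian
noise whose standard deviation is a subject-specific fraction of the base
value: the fraction grows linearly from 0.01 (subject 1) to 0.02 (subject
``n``), so later subjects are noisier.  Draws that would turn a quantity
non-positive are resampled.

Three scenario presets reproduce the experiments the model was built for,
all on a 300-s horizon with condition windows bounded at 75/125/175/225 s:

* ``snc-lesion`` — mild dopaminergic lesion at 75 s (SNc decay +25%,
  oscillation gain +11%); exercises the serotonergic compensation chain.
* ``drn-damage`` — progressive serotonergic damage (DRN decay +40/60/80%
  of baseline at 75/125/175 s); dopamine falls and tremor grows with the
  damage level.
* ``ssri`` — strong dopaminergic lesion at 75 s (SNc decay +70%,
  oscillation gain +333%) followed by three escalating SSRI doses
  (serotonin decay -20/-30/-40% of baseline at 125/175/225 s); dopamine
  recovers and tremor shrinks with the dose.

Per condition the cohort summary reports the windowed dopamine mean
(first 10 s of each window dropped as transient, so the value reflects
quasi-steady behaviour) and the endpoint tremor amplitude of the arm
driven by each subject's M1 trace over the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arm import (
    ArmParameters,
    ControllerGains,
    DEFAULT_ARM,
    DEFAULT_GAINS,
    simulate_arm_from_m1_batch,
    tremor_amplitude,
)
from .circuit import (
    PARAM_NAMES,
    STATE_NAMES,
    CircuitParameters,
    CircuitState,
    REFERENCE_STATE,
    Intervention,
    InterventionSchedule,
    SimulationConfig,
    integrate_batch,
)

__all__ = [
    "CohortSpec",
    "Subject",
    "Condition",
    "ScenarioResult",
    "make_subject",
    "run_scenario",
    "run_snc_lesion_scenario",
    "run_drn_damage_scenario",
    "run_ssri_scenario",
    "condition_summary",
    "repeated_measures_anova",
    "SCENARIO_NAMES",
]

TRANSIENT_SKIP = 10.0   # seconds dropped at the start of each condition window


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, subject-noise range and master seed."""

    n_subjects: int = 20
    noise_low: float = 0.01
    noise_high: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.noise_low <= self.noise_high):
            raise ValueError("need 0 <= noise_low <= noise_high")

    def noise_scale(self, index: int) -> float:
        """Noise fraction for subject ``index`` (1-based), evenly spaced."""
        if not 1 <= index <= self.n_subjects:
            raise ValueError(f"subject index {index} outside 1..{self.n_subjects}")
        if self.n_subjects == 1:
            return self.noise_low
        frac = (index - 1) / (self.n_subjects - 1)
        return self.noise_low + frac * (self.noise_high - self.noise_low)


@dataclass(frozen=True)
class Subject:
    """One simulated subject: perturbed parameters and initial state."""

    index: int
    params: CircuitParameters
    initial_state: CircuitState
    seed: int


@dataclass(frozen=True)
class Condition:
    """A named scenario window [start, stop)."""

    name: str
    start: float
    stop: float


@dataclass(frozen=True)
class ScenarioResult:
    """Cohort outcome of one scenario.

    ``per_subject`` has one row per (subject, condition) with the windowed
    DA mean (nM) and endpoint tremor amplitude (m); ``summary`` aggregates
    over subjects.  ``failures`` lists subjects whose integration blew up
    (their rows are NaN).
    """

    scenario: str
    conditions: tuple[Condition, ...]
    per_subject: pd.DataFrame
    summary: pd.DataFrame
    seed: int
    m1_traces: np.ndarray | None = None     # (n_samples, n_subjects)
    failures: tuple[int, ...] = ()

    def to_report(self) -> dict:
        """Machine-readable summary used by the CLI JSON output."""
        def num(value):
            value = float(value)
            return None if np.isnan(value) else value

        conditions = []
        for cond in self.conditions:
            row = self.summary.loc[self.summary["condition"] == cond.name].iloc[0]
            conditions.append({
                "name": cond.name,
                "window": [cond.start, cond.stop],
                "da_mean": num(row["da_mean"]),
                "da_sd": num(row["da_sd"]),
                "tremor_mean": num(row["tremor_mean"]),
                "tremor_sd": num(row["tremor_sd"]),
            })
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "n_subjects": int(self.per_subject["subject"].nunique()),
            "conditions": conditions,
        }


def _resample_positive(rng: np.random.Generator, base: float, sd: float) -> float:
    """Additive Gaussian perturbation of ``base``, resampled until positive."""
    if sd == 0.0:
        return base
    for _ in range(1000):
        value = base + rng.normal(0.0, sd)
        if value > 0:
            return value
    raise RuntimeError("could not draw a positive perturbation")  # pragma: no cover


def make_subject(
    base_params: CircuitParameters,
    base_state: CircuitState,
    index: int,
    spec: CohortSpec,
) -> Subject:
    """Build subject ``index`` (1-based) of the cohort.

    Every parameter and initial value receives additive Gaussian noise
    with SD = noise_scale(index) x its base value; deterministic given the
    master seed and the index.
    """
    scale = spec.noise_scale(index)
    rng = np.random.default_rng((spec.seed, index))
    params = {
        name: _resample_positive(rng, getattr(base_params, name),
                                 scale * getattr(base_params, name))
        for name in PARAM_NAMES
    }
    state = {
        name: _resample_positive(rng, getattr(base_state, name),
                                 scale * getattr(base_state, name))
        for name in STATE_NAMES
    }
    return Subject(
        index=index,
        params=CircuitParameters(**params),
        initial_state=CircuitState(**state),
        seed=int(np.random.default_rng((spec.seed, index, 0)).integers(2**31)),
    )


# ---------------------------------------------------------------------------
# scenario definitions
# ---------------------------------------------------------------------------

def _snc_lesion_schedule() -> InterventionSchedule:
    return InterventionSchedule((
        Intervention(75.0, "tauSNc", 1.25),
        Intervention(75.0, "alphaIP", 1.11),
    ))


def _drn_damage_schedule(damages: tuple[float, ...]) -> InterventionSchedule:
    """Damage multipliers are relative to baseline; interventions compose
    on the running value, so each step multiplies by the ratio."""
    times = (75.0, 125.0, 175.0)
    if len(damages) > len(times):
        raise ValueError("at most three damage levels are supported")
    if any(d < 1.0 for d in damages):
        raise ValueError("damage multipliers must be >= 1")
    events = []
    previous = 1.0
    for time, level in zip(times, damages):
        events.append(Intervention(time, "tauDRN", level / previous))
        previous = level
    return InterventionSchedule(tuple(events))


def _ssri_schedule(doses: tuple[float, ...] = (0.8, 0.7, 0.6)) -> InterventionSchedule:
    """Strong lesion at 75 s, then baseline-relative SSRI doses."""
    events = [
        Intervention(75.0, "tauSNc", 1.70),
        Intervention(75.0, "alphaIP", 4.33),
    ]
    previous = 1.0
    for time, dose in zip((125.0, 175.0, 225.0), doses):
        events.append(Intervention(time, "tau5HT", dose / previous))
        previous = dose
    return InterventionSchedule(tuple(events))


def _drn_conditions(n_damage: int) -> tuple[Condition, ...]:
    names = ["HEALTH", "DAMAGE1", "DAMAGE2", "DAMAGE3"][: n_damage + 1]
    bounds = [0.0, 75.0, 125.0, 175.0, 300.0][: n_damage + 2]
    bounds[-1] = 300.0
    return tuple(
        Condition(name, start, stop)
        for name, start, stop in zip(names, bounds[:-1], bounds[1:])
    )


_SSRI_CONDITIONS = (
    Condition("HEALTH", 0.0, 75.0),
    Condition("SNC_DAMAGE", 75.0, 125.0),
    Condition("TRMT1", 125.0, 175.0),
    Condition("TRMT2", 175.0, 225.0),
    Condition("TRMT3", 225.0, 300.0),
)

_LESION_CONDITIONS = (
    Condition("HEALTH", 0.0, 75.0),
    Condition("LESION", 75.0, 300.0),
)

SCENARIO_NAMES = ("snc-lesion", "drn-damage", "ssri")


# ---------------------------------------------------------------------------
# scenario engine
# ---------------------------------------------------------------------------

def _default_base_params() -> CircuitParameters:
    from .calibration import CALIBRATED_PARAMS
    return CALIBRATED_PARAMS


def run_scenario(
    scenario: str,
    cohort: CohortSpec | None = None,
    base_params: CircuitParameters | None = None,
    base_state: CircuitState = REFERENCE_STATE,
    damages: tuple[float, ...] = (1.4, 1.6, 1.8),
    doses: tuple[float, ...] = (0.8, 0.7, 0.6),
    duration: float = 300.0,
    dt: float = 0.1,
    arm_dt: float = 0.01,
    include_arm: bool = True,
    arm_params: ArmParameters = DEFAULT_ARM,
    gains: ControllerGains = DEFAULT_GAINS,
    keep_m1: bool = False,
) -> ScenarioResult:
    """Run one scenario preset over the whole cohort.

    Each subject's circuit is integrated once over the full horizon with
    the scenario's intervention schedule; the arm is then driven
    continuously by the subject's M1 trace and both the DA mean and the
    tremor amplitude are evaluated per condition window (skipping the
    first ``TRANSIENT_SKIP`` seconds of each window).  Integration
    failures are recorded per subject without aborting the cohort.
    """
    if cohort is None:
        cohort = CohortSpec()
    if base_params is None:
        base_params = _default_base_params()

    if scenario == "snc-lesion":
        schedule = _snc_lesion_schedule()
        conditions = _LESION_CONDITIONS
    elif scenario == "drn-damage":
        schedule = _drn_damage_schedule(tuple(damages))
        conditions = _drn_conditions(len(tuple(damages)))
    elif scenario == "ssri":
        schedule = _ssri_schedule(tuple(doses))
        conditions = _SSRI_CONDITIONS
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIO_NAMES}")

    subjects = [
        make_subject(base_params, base_state, i, cohort)
        for i in range(1, cohort.n_subjects + 1)
    ]
    pop = np.stack([s.params.to_array() for s in subjects])
    y0 = np.stack([s.initial_state.to_array() for s in subjects])
    sim = SimulationConfig(duration=duration, dt=dt)
    states, fail_time, fail_var = integrate_batch(pop, y0, sim, schedule)
    time = np.arange(sim.n_steps + 1) * dt
    failures = tuple(
        s.index for s, fv in zip(subjects, fail_var) if fv >= 0
    )

    i_da = STATE_NAMES.index("DA")
    i_m1 = STATE_NAMES.index("M1")
    m1_all = states[:, :, i_m1]

    traces = [None] * len(subjects)
    if include_arm:
        ok_cols = [b for b in range(len(subjects)) if fail_var[b] < 0]
        if ok_cols:
            ok_traces = simulate_arm_from_m1_batch(
                m1_all[:, ok_cols], circuit_dt=dt,
                params=arm_params, gains=gains, dt=arm_dt,
            )
            for col, trace in zip(ok_cols, ok_traces):
                traces[col] = trace

    rows = []
    for b, subject in enumerate(subjects):
        failed = fail_var[b] >= 0
        for cond in conditions:
            t0 = cond.start + TRANSIENT_SKIP
            t1 = cond.stop
            if failed:
                da_mean = np.nan
                amp = np.nan
            else:
                mask = (time >= t0 - 1e-9) & (time <= t1 + 1e-9)
                da_mean = float(states[mask, b, i_da].mean())
                if include_arm and traces[b] is not None:
                    amp = tremor_amplitude(traces[b], (t0, t1))
                else:
                    amp = np.nan
            rows.append({
                "subject": subject.index,
                "condition": cond.name,
                "da_mean": da_mean,
                "tremor_amplitude": amp,
            })
    per_subject = pd.DataFrame(rows)

    result = ScenarioResult(
        scenario=scenario,
        conditions=conditions,
        per_subject=per_subject,
        summary=_summarise(per_subject, conditions),
        seed=cohort.seed,
        m1_traces=m1_all if keep_m1 else None,
        failures=failures,
    )
    return result


def _summarise(per_subject: pd.DataFrame, conditions) -> pd.DataFrame:
    rows = []
    for cond in conditions:
        sub = per_subject.loc[per_subject["condition"] == cond.name]
        rows.append({
            "condition": cond.name,
            "window_start": cond.start,
            "window_stop": cond.stop,
            "da_mean": sub["da_mean"].mean(),
            "da_sd": sub["da_mean"].std(ddof=1) if len(sub) > 1 else 0.0,
            "tremor_mean": sub["tremor_amplitude"].mean(),
            "tremor_sd": sub["tremor_amplitude"].std(ddof=1) if len(sub) > 1 else 0.0,
            "n": int(sub["da_mean"].notna().sum()),
        })
    return pd.DataFrame(rows)


def run_snc_lesion_scenario(
    cohort: CohortSpec | None = None, **kwargs
) -> ScenarioResult:
    """Mild dopaminergic lesion at 75 s; serotonergic compensation chain."""
    return run_scenario("snc-lesion", cohort, **kwargs)


def run_drn_damage_scenario(
    cohort: CohortSpec | None = None,
    damages: tuple[float, ...] = (1.4, 1.6, 1.8),
    **kwargs,
) -> ScenarioResult:
    """Progressive serotonergic damage; DA falls and tremor grows."""
    return run_scenario("drn-damage", cohort, damages=damages, **kwargs)


def run_ssri_scenario(
    cohort: CohortSpec | None = None,
    doses: tuple[float, ...] = (0.8, 0.7, 0.6),
    **kwargs,
) -> ScenarioResult:
    """Strong lesion then SSRI dose escalation; DA recovers, tremor shrinks."""
    return run_scenario("ssri", cohort, doses=doses, **kwargs)


def condition_summary(result: ScenarioResult) -> pd.DataFrame:
    """Condition x {DA mean/SD, tremor mean/SD, n} table."""
    return _summarise(result.per_subject, result.conditions)


def repeated_measures_anova(result: ScenarioResult, metric: str = "da_mean"):
    """Repeated-measures ANOVA over conditions (delegated to pingouin).

    ``metric`` is ``"da_mean"`` or ``"tremor_amplitude"``.  Returns the
    pingouin ANOVA table; requires the optional ``stats`` extra.
    """
    try:
        import pingouin  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "repeated_measures_anova requires pingouin (the 'stats' extra)"
        ) from exc
    data = result.per_subject.dropna(subset=[metric])
    return pingouin.rm_anova(
        data=data, dv=metric, within="condition", subject="subject"
    )
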