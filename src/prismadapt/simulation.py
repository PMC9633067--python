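"""Synthetic prism-adaptation cohorts.

The generator is a single-state linear error-correction (state-space)
learner.  An internal compensation state ``x`` (degrees) tracks how far
the visuomotor mapping has been shifted away from its baseline.  On each
trial the recorded pointing error is

    error = prism_shift * [prism on] + baseline_bias - x + noise

and the state evolves as

    x <- retention * x + learning_rate * error      (terminal feedback seen)
    x <- nofeedback_retention * x                   (no feedback)

Motor/visual noise is Gaussian with a standard deviation that grows
linearly with the observer's log-acuity deficit relative to a reference
cutoff frequency, which couples poor contrast sensitivity to noisier
pointing.  The canonical design is 12 pre-prism, 48 prism (with terminal
feedback) and 48 post-prism trials, balanced over three targets at
-25/0/+25 degrees, with a +11.31 degree (20 prism diopter) rightward
shift during the prism phase only.

Group presets:

``control``
    fast learner; the aftereffect decays trial by trial in the
    feedback-free post phase (nofeedback_retention < 1).
``control_blur``
    sighted observer viewing through blur matched to the cataract group's
    acuity; reduced learning rate and mildly elevated noise.
``cataract``
    slow learner with strongly elevated motor noise; the aftereffect does
    not decay (nofeedback_retention ~ 1), mirroring the absence of
    proprioception-driven return to the original mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recal_metrics import PRISM_SHIFT_DEG

__all__ = [
    "PHASES",
    "GROUPS",
    "REFERENCE_ACUITY_CPD",
    "ExperimentDesign",
    "ObserverParams",
    "JitterSpec",
    "CohortSpec",
    "GROUP_PRESETS",
    "DEVELOPMENT_L_MAX",
    "make_target_sequence",
    "simulate_participant",
    "simulate_group",
    "simulate_longitudinal_cohort",
    "derive_seeds",
]

PHASES = ("pre", "prism", "post")
GROUPS = ("cataract", "control", "control_blur")

#: Cutoff frequency (cpd) treated as normal acuity; observers at or above
#: it incur no acuity-coupled noise.  Top rung of the CSF ladder.
REFERENCE_ACUITY_CPD = 10.75

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "phase",
    "trial",
    "target_deg",
    "error_deg",
    "feedback",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Three-phase pointing design with balanced target presentation."""

    n_pre: int = 12
    n_prism: int = 48
    n_post: int = 48
    targets: tuple[float, ...] = (-25.0, 0.0, 25.0)
    prism_shift_deg: float = PRISM_SHIFT_DEG
    feedback_phases: frozenset = frozenset({"prism"})

    def __post_init__(self):
        if len(self.targets) == 0:
            raise ValueError("design needs at least one target position")
        for name, n in (("n_pre", self.n_pre), ("n_prism", self.n_prism), ("n_post", self.n_post)):
            if n <= 0:
                raise ValueError(f"{name} must be positive, got {n}")
            if n % len(self.targets):
                raise ValueError(
                    f"{name}={n} is not divisible by {len(self.targets)} targets"
                )
        if not np.isfinite(self.prism_shift_deg):
            raise ValueError("prism_shift_deg must be finite")
        unknown = set(self.feedback_phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown feedback phases: {sorted(unknown)}")

    def n_trials(self, phase: str) -> int:
        return {"pre": self.n_pre, "prism": self.n_prism, "post": self.n_post}[phase]

    @property
    def total_trials(self) -> int:
        return self.n_pre + self.n_prism + self.n_post


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant."""

    learning_rate: float
    retention: float = 1.0
    nofeedback_retention: float = 1.0
    motor_noise_sd: float = 0.0
    acuity_cpd: float = REFERENCE_ACUITY_CPD
    noise_acuity_coupling: float = 0.0
    baseline_bias: float = 0.0

    def __post_init__(self):
        for name in (
            "learning_rate",
            "retention",
            "nofeedback_retention",
            "motor_noise_sd",
            "acuity_cpd",
            "noise_acuity_coupling",
            "baseline_bias",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ("learning_rate", "retention", "nofeedback_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.motor_noise_sd < 0 or self.noise_acuity_coupling < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.acuity_cpd <= 0:
            raise ValueError(f"acuity_cpd must be positive, got {self.acuity_cpd}")

    @property
    def noise_sd(self) -> float:
        """Effective trial noise SD: motor noise plus acuity-coupled noise."""
        deficit = max(0.0, math.log2(REFERENCE_ACUITY_CPD / self.acuity_cpd))
        return self.motor_noise_sd + self.noise_acuity_coupling * deficit


# Preset means.  Steady-state algebra of the learner
# (x* = lr*shift/(1-retention+lr)) places the groups near the observed
# i_recal ordering while keeping the qualitative signatures: residual
# prism error cataract > blur > control, aftereffect decay only in the
# sighted presets, baseline noise largest after cataract surgery.
GROUP_PRESETS: dict[str, ObserverParams] = {
    "control": ObserverParams(
        learning_rate=0.30,
        retention=0.878,
        nofeedback_retention=0.95,
        motor_noise_sd=1.0,
        acuity_cpd=REFERENCE_ACUITY_CPD,
        noise_acuity_coupling=0.0,
    ),
    "control_blur": ObserverParams(
        learning_rate=0.18,
        retention=0.874,
        nofeedback_retention=0.95,
        motor_noise_sd=1.2,
        acuity_cpd=5.0,
        noise_acuity_coupling=0.4,
    ),
    "cataract": ObserverParams(
        learning_rate=0.05,
        retention=0.883,
        nofeedback_retention=0.995,
        motor_noise_sd=2.6,
        acuity_cpd=5.0,
        noise_acuity_coupling=0.8,
    ),
}

#: Asymptotic learning rate reached long after surgery in the
#: longitudinal model (chosen so that the asymptotic i_recal of a
#: developed cataract observer sits near the blur-control level).
DEVELOPMENT_L_MAX = 0.16


@dataclass(frozen=True)
class JitterSpec:
    """Log-normal between-participant dispersion, truncated to valid ranges.

    Acuity is drawn first; the learning rate then scales with the drawn
    acuity as ``(acuity / preset_acuity) ** lr_acuity_exponent`` before
    its own log-normal jitter.  Observers with poorer vision therefore
    both point more noisily (through the noise-acuity coupling) and learn
    more slowly, which is what links baseline variance and acuity to the
    recalibration index at the individual level.
    """

    learning_rate_sigma: float = 0.25
    noise_sigma: float = 0.20
    acuity_sigma: float = 0.35
    lr_acuity_exponent: float = 0.5

    def apply(self, params: ObserverParams, rng: np.random.Generator) -> ObserverParams:
        ac = float(np.clip(params.acuity_cpd * rng.lognormal(0.0, self.acuity_sigma), 0.5, 20.0))
        acuity_factor = (ac / params.acuity_cpd) ** self.lr_acuity_exponent
        lr = params.learning_rate * acuity_factor * rng.lognormal(0.0, self.learning_rate_sigma)
        sd = params.motor_noise_sd * rng.lognormal(0.0, self.noise_sigma)
        return replace(
            params,
            learning_rate=float(np.clip(lr, 0.0, 1.0)),
            motor_noise_sd=float(max(sd, 0.0)),
            acuity_cpd=ac,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal cataract cohort: one time-since-surgery per observer."""

    times_years: tuple[float, ...]
    development_rate: float = 1.5
    seed: int = 0
    l_max: float = DEVELOPMENT_L_MAX
    base_params: ObserverParams | None = None
    jitter: JitterSpec | None = None

    def __post_init__(self):
        if len(self.times_years) < 1:
            raise ValueError("cohort needs at least one participant")
        times = np.asarray(self.times_years, dtype=float)
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("times since surgery must be finite and >= 0")
        if self.development_rate <= 0:
            raise ValueError("development_rate must be positive")
        if not 0 < self.l_max <= 1:
            raise ValueError("l_max must lie in (0, 1]")

    @property
    def n(self) -> int:
        return len(self.times_years)


def make_target_sequence(design: ExperimentDesign, phase: str, seed) -> np.ndarray:
    """Balanced pseudorandom target order for one phase (seeded shuffle)."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    n = design.n_trials(phase)
    reps = n // len(design.targets)
    seq = np.repeat(np.asarray(design.targets, dtype=float), reps)
    rng = np.random.default_rng(seed)
    rng.shuffle(seq)
    return seq


def simulate_participant(
    design: ExperimentDesign,
    params: ObserverParams,
    seed,
    participant_id: str = "sim",
    group: str = "control",
    return_state: bool = False,
):
    """Simulate one participant's full three-phase session.

    Returns a trial table (one row per trial; columns ``participant_id,
    group, phase, trial, target_deg, error_deg, feedback``).  With
    ``return_state=True`` the table carries an extra ``state_pre`` column
    holding the compensation state before each trial, for diagnostics.
    """
    ss = np.random.SeedSequence(seed)
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    target_seeds = ss.generate_state(len(PHASES))
    sigma = params.noise_sd

    records = []
    x = 0.0
    for phase, tseed in zip(PHASES, target_seeds):
        targets = make_target_sequence(design, phase, tseed)
        prism_on = phase == "prism"
        feedback = phase in design.feedback_phases
        shift = design.prism_shift_deg if prism_on else 0.0
        n = design.n_trials(phase)
        eps = noise_rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
        for t in range(n):
            state_pre = x
            error = shift + params.baseline_bias - x + eps[t]
            if feedback:
                x = params.retention * x + params.learning_rate * error
            else:
                x = params.nofeedback_retention * x
            records.append(
                (
                    participant_id,
                    group,
                    phase,
                    t + 1,
                    targets[t],
                    error,
                    feedback,
                    state_pre,
                )
            )
    df = pd.DataFrame(records, columns=TRIAL_COLUMNS + ["state_pre"])
    if not return_state:
        df = df.drop(columns="state_pre")
    return df


def derive_seeds(seed, n: int) -> list[int]:
    """Deterministic per-participant seeds from a master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def simulate_group(
    design: ExperimentDesign,
    preset: str,
    n: int,
    seed,
    jitter: JitterSpec | None = JitterSpec(),
    id_prefix: str | None = None,
    return_params: bool = False,
):
    """Simulate ``n`` participants of one group preset.

    Per-participant seeds are derived deterministically from the master
    seed and parameters are jittered log-normally (truncated to valid
    ranges) around the preset means; pass ``jitter=None`` to disable.
    With ``return_params=True`` also returns a per-participant table of
    the realised generative parameters.
    """
    if preset not in GROUP_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(GROUP_PRESETS)}"
        )
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    base = GROUP_PRESETS[preset]
    prefix = preset if id_prefix is None else id_prefix
    seeds = derive_seeds(seed, n)
    jitter_rng = np.random.default_rng(np.random.SeedSequence([int(seed) & (2**63 - 1), 1]))
    tables, param_rows = [], []
    for i in range(n):
        params = jitter.apply(base, jitter_rng) if jitter is not None else base
        pid = f"{prefix}_{i + 1:02d}"
        tables.append(
            simulate_participant(design, params, seeds[i], participant_id=pid, group=preset)
        )
        param_rows.append({"participant_id": pid, "group": preset, "seed": seeds[i], **vars(params)})
    table = pd.concat(tables, ignore_index=True)
    if return_params:
        return table, pd.DataFrame(param_rows)
    return table


def developed_learning_rate(t_years: float, rate: float, l_max: float = DEVELOPMENT_L_MAX) -> float:
    """Learning rate as a saturating function of time since surgery."""
    return l_max * (1.0 - math.exp(-rate * t_years))


def simulate_longitudinal_cohort(
    spec: CohortSpec, design: ExperimentDesign
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a cataract cohort whose learning rate grows with time
    since surgery as ``l_max * (1 - exp(-development_rate * t))``.

    Returns the concatenated trial table and a participant -> years map.
    """
    base = spec.base_params if spec.base_params is not None else GROUP_PRESETS["cataract"]
    seeds = derive_seeds(spec.seed, spec.n)
    jitter_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & (2**63 - 1), 2]))
    tables = []
    times: dict[str, float] = {}
    for i, t in enumerate(spec.times_years):
        params = spec.jitter.apply(base, jitter_rng) if spec.jitter is not None else base
        params = replace(
            params,
            learning_rate=developed_learning_rate(float(t), spec.development_rate, spec.l_max),
        )
        pid = f"cataract_t{i + 1:02d}"
        times[pid] = float(t)
        tables.append(
            simulate_participant(design, params, seeds[i], participant_id=pid, group="cataract")
        )
    return pd.concat(tables, ignore_index=True), times
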