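"""Contrast-sensitivity-function measurement by adaptive staircases.

The procedure mirrors a two-block orientation-discrimination (2AFC) test:

Block 1 (frequency staircase, 100% contrast)
    Gratings ascend a 9-rung frequency ladder (0.042 .. 10.75 cpd,
    doubling each step) while responses are correct; the first error
    starts a 3-up-1-down staircase (3 consecutive correct -> next higher
    frequency, 1 error -> next lower).  The run stops after 6 reversals
    and the threshold frequency is the geometric mean of the reversal
    frequencies.  A 3-up-1-down rule converges where the probability of a
    correct response is 0.5**(1/3) ~ 0.794.

Block 2 (contrast staircases)
    At each frequency from the lowest rung up to one ladder step above
    the block-1 threshold, contrast descends an 8-rung ladder (100% ..
    0.78%, halving) while correct; the first error starts the analogous
    3-correct-down / 1-wrong-up rule.  The contrast threshold is the
    geometric mean of the last six reversal contrasts.

Sensitivity S = 100 / threshold% is fitted in log-log coordinates with a
downward (inverse) parabola; the CSF cutoff is the larger root of
log10 S = 0, i.e. the highest frequency still visible at full contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "FREQUENCIES_CPD",
    "CONTRASTS_PCT",
    "STAIRCASE_P_TARGET",
    "make_frequency_ladder",
    "make_contrast_ladder",
    "StaircaseTrace",
    "run_staircase",
    "run_frequency_staircase",
    "run_contrast_staircase",
    "CSFModel",
    "fit_csf",
    "match_csf",
    "CSFObserver",
    "simulate_csf_observer",
    "measure_csf",
]

#: The 9 spatial frequencies (cpd), evenly spaced on a log scale (factor 2).
FREQUENCIES_CPD = (0.042, 0.084, 0.168, 0.336, 0.672, 1.344, 2.688, 5.375, 10.75)

#: The 8 contrast levels (%), halving from 100 down to 0.78.
CONTRASTS_PCT = (100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 1.5625, 0.78125)

#: Convergence point of a 3-up-1-down rule: p_correct = 0.5**(1/3).
STAIRCASE_P_TARGET = 0.5 ** (1.0 / 3.0)


def make_frequency_ladder() -> np.ndarray:
    """Spatial-frequency ladder, lowest (easiest) first."""
    return np.asarray(FREQUENCIES_CPD, dtype=float)


def make_contrast_ladder() -> np.ndarray:
    """Contrast ladder, highest (easiest) first."""
    return np.asarray(CONTRASTS_PCT, dtype=float)


@dataclass(frozen=True)
class StaircaseTrace:
    """Trial-by-trial record of one staircase run.

    ``levels``/``values`` hold the ladder index and stimulus value per
    trial; ``reversals`` flags trials on which the step direction
    reversed.  ``termination`` is ``"reversals"`` (reached the reversal
    quota), ``"boundary"`` (pinned against a ladder end with no further
    reversals possible) or ``"max_trials"``.
    """

    levels: tuple[int, ...]
    values: tuple[float, ...]
    correct: tuple[bool, ...]
    reversals: tuple[bool, ...]
    termination: str

    @property
    def n_reversals(self) -> int:
        return sum(self.reversals)

    def reversal_values(self) -> np.ndarray:
        return np.asarray(
            [v for v, r in zip(self.values, self.reversals) if r], dtype=float
        )


def run_staircase(
    respond,
    levels,
    start_index: int = 0,
    n_reversals: int = 6,
    up_rule: int = 3,
    max_trials: int = 1000,
    boundary_patience: int = 2,
) -> StaircaseTrace:
    """Generic initial-sweep + 3-up-1-down staircase on an ordered ladder.

    ``levels`` is ordered easiest (index 0) to hardest; ``respond(value)``
    returns True for a correct response.  During the initial sweep every
    correct response steps harder; the first error switches to the
    staircase rule (``up_rule`` consecutive correct -> harder, one error
    -> easier).  Ladder ends are absorbing: a step past an end keeps the
    current rung, and after ``boundary_patience`` consecutive clamped
    steps in the same outward direction the run terminates with reason
    ``"boundary"`` (an observer who is always correct can never reverse).
    Reversals are counted as changes in the intended step direction.
    """
    values = np.asarray(levels, dtype=float)
    n_lv = values.size
    if n_lv < 2:
        raise ValueError("ladder needs at least two levels")
    if not 0 <= start_index < n_lv:
        raise ValueError(f"start_index {start_index} outside ladder of {n_lv}")

    idx = start_index
    sweep = True
    run_correct = 0
    prev_dir = 0  # +1 harder, -1 easier
    clamped_in_a_row = 0
    n_rev = 0
    trace_levels, trace_values, trace_correct, trace_rev = [], [], [], []
    termination = "max_trials"

    for _ in range(max_trials):
        correct = bool(respond(values[idx]))
        if sweep:
            if correct:
                step = +1
            else:
                step = -1
                sweep = False
                run_correct = 0
        else:
            if correct:
                run_correct += 1
                if run_correct >= up_rule:
                    step = +1
                    run_correct = 0
                else:
                    step = 0
            else:
                step = -1
                run_correct = 0

        reversal = step != 0 and prev_dir != 0 and step != prev_dir
        trace_levels.append(idx)
        trace_values.append(float(values[idx]))
        trace_correct.append(correct)
        trace_rev.append(reversal)
        if reversal:
            n_rev += 1
        if step != 0:
            prev_dir = step
            new_idx = idx + step
            if 0 <= new_idx < n_lv:
                idx = new_idx
                clamped_in_a_row = 0
            else:
                clamped_in_a_row += 1
                if clamped_in_a_row >= boundary_patience and n_rev == 0:
                    termination = "boundary"
                    break
                if clamped_in_a_row >= max(boundary_patience, 6):
                    termination = "boundary"
                    break
        if n_rev >= n_reversals:
            termination = "reversals"
            break

    return StaircaseTrace(
        levels=tuple(trace_levels),
        values=tuple(trace_values),
        correct=tuple(trace_correct),
        reversals=tuple(trace_rev),
        termination=termination,
    )


def run_frequency_staircase(
    observer, ladder=None, n_reversals: int = 6
) -> tuple[float, StaircaseTrace]:
    """Block-1 staircase over spatial frequency at 100% contrast.

    ``observer(frequency_cpd, contrast_pct)`` returns correct/incorrect.
    Starts at the lowest frequency and ascends while correct; the first
    error begins the 3-up-1-down rule.  The threshold frequency is the
    geometric mean of the reversal frequencies (log-scale mean, matching
    the ladder's geometry); a run terminated at a ladder boundary returns
    that boundary frequency.
    """
    lad = make_frequency_ladder() if ladder is None else np.asarray(ladder, dtype=float)
    trace = run_staircase(lambda f: observer(f, 100.0), lad, start_index=0, n_reversals=n_reversals)
    rev = trace.reversal_values()
    if rev.size == 0:
        threshold = float(trace.values[-1])
    else:
        threshold = float(np.exp(np.mean(np.log(rev))))
    return threshold, trace


def run_contrast_staircase(
    observer, frequency_cpd: float, ladder=None, n_reversals: int = 6
) -> tuple[float, StaircaseTrace]:
    """Block-2 staircase over contrast at a fixed spatial frequency.

    Contrast descends from 100% while responses are correct; after the
    first error, 3 consecutive correct lower the contrast and one error
    raises it.  The threshold is the geometric mean of the last six
    reversal contrasts (floor 0.78%); a run pinned at 100% (stimulus
    never seen) returns 100.
    """
    lad = make_contrast_ladder() if ladder is None else np.asarray(ladder, dtype=float)
    trace = run_staircase(
        lambda c: observer(frequency_cpd, c), lad, start_index=0, n_reversals=n_reversals
    )
    rev = trace.reversal_values()
    if rev.size == 0:
        threshold = float(trace.values[-1])
    else:
        last = rev[-min(6, rev.size):]
        threshold = float(np.exp(np.mean(np.log(last))))
    return threshold, trace


@dataclass(frozen=True)
class CSFModel:
    """Log-parabola contrast sensitivity curve.

    ``log10 S(f) = peak_log_sensitivity - curvature * (log10 f -
    log10 peak_frequency)**2``.  The cutoff is the upper root of
    ``log10 S = 0`` (sensitivity 1, i.e. threshold at 100% contrast);
    bandwidth is the full width (octaves) at half the peak
    log-sensitivity.  ``degenerate`` marks fits that were collinear,
    upward-curving or entirely below sensitivity 1; their cutoff is the
    highest tested frequency.
    """

    peak_log_sensitivity: float
    peak_frequency_cpd: float
    curvature: float
    cutoff_cpd: float = field(default=float("nan"))
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            if self.curvature <= 0:
                raise ValueError("curvature must be positive for a downward parabola")
            if self.peak_frequency_cpd <= 0:
                raise ValueError("peak frequency must be positive")
            if math.isnan(self.cutoff_cpd):
                root = math.sqrt(self.peak_log_sensitivity / self.curvature)
                object.__setattr__(
                    self,
                    "cutoff_cpd",
                    10 ** (math.log10(self.peak_frequency_cpd) + root),
                )

    @classmethod
    def from_cutoff(
        cls, peak_log_sensitivity: float, peak_frequency_cpd: float, cutoff_cpd: float
    ) -> "CSFModel":
        """Build a model from its peak and cutoff (curvature derived)."""
        if cutoff_cpd <= peak_frequency_cpd:
            raise ValueError("cutoff must exceed the peak frequency")
        span = math.log10(cutoff_cpd) - math.log10(peak_frequency_cpd)
        return cls(
            peak_log_sensitivity=peak_log_sensitivity,
            peak_frequency_cpd=peak_frequency_cpd,
            curvature=peak_log_sensitivity / span**2,
        )

    @property
    def bandwidth_octaves(self) -> float:
        """Full width at half the peak log-sensitivity, in octaves."""
        half_width_dec = math.sqrt(self.peak_log_sensitivity / (2.0 * self.curvature))
        return 2.0 * half_width_dec / math.log10(2.0)

    def log_sensitivity(self, frequency_cpd) -> np.ndarray:
        f = np.asarray(frequency_cpd, dtype=float)
        return self.peak_log_sensitivity - self.curvature * (
            np.log10(f) - math.log10(self.peak_frequency_cpd)
        ) ** 2

    def threshold_pct(self, frequency_cpd) -> np.ndarray:
        """Contrast threshold (%) implied by the curve; may exceed 100."""
        return 100.0 / 10 ** self.log_sensitivity(frequency_cpd)


_CENSOR_PCT = 100.0 * (1.0 - 1e-9)


def fit_csf(points) -> CSFModel:
    """Least-squares log-parabola fit of (frequency, contrast threshold) data.

    ``points`` is an iterable of ``(frequency_cpd, threshold_pct)`` pairs.
    Thresholds at or above 100% are censored (the grating was invisible at
    full contrast) and excluded from the fit.  Degenerate data — fewer
    than three usable distinct frequencies, an upward-curving or collinear
    fit, or a curve that never rises above sensitivity 1 — yield a model
    flagged ``degenerate`` whose cutoff is the highest tested frequency.
    """
    pts = [(float(f), float(th)) for f, th in points]
    if len({f for f, _ in pts}) < 3:
        raise ValueError("need >=3 points with distinct frequencies")
    if any(f <= 0 or th <= 0 for f, th in pts):
        raise ValueError("frequencies and thresholds must be positive")
    max_tested = max(f for f, _ in pts)
    usable = [(f, th) for f, th in pts if th < _CENSOR_PCT]

    def _degenerate() -> CSFModel:
        return CSFModel(
            peak_log_sensitivity=float("nan"),
            peak_frequency_cpd=float("nan"),
            curvature=float("nan"),
            cutoff_cpd=max_tested,
            degenerate=True,
        )

    if len({f for f, _ in usable}) < 3:
        return _degenerate()
    logf = np.log10([f for f, _ in usable])
    logs = np.log10([100.0 / th for _, th in usable])
    c2, c1, c0 = np.polyfit(logf, logs, 2)
    if c2 >= 0:
        return _degenerate()
    peak_logf = -c1 / (2.0 * c2)
    peak = c0 - c1**2 / (4.0 * c2)
    if peak <= 0:
        return _degenerate()
    disc = c1**2 - 4.0 * c2 * c0
    if disc <= 0:  # never crosses sensitivity 1
        return _degenerate()
    upper_root = (-c1 - math.sqrt(disc)) / (2.0 * c2)  # larger root (c2 < 0)
    return CSFModel(
        peak_log_sensitivity=float(peak),
        peak_frequency_cpd=float(10**peak_logf),
        curvature=float(-c2),
        cutoff_cpd=float(10**upper_root),
    )


def match_csf(
    target: CSFModel,
    candidate: CSFModel,
    tol_cutoff_octaves: float = 0.5,
    tol_shape_log10: float = 0.2,
    n_grid: int = 50,
) -> tuple[bool, dict]:
    """Decide whether a candidate CSF matches a target in cutoff and shape.

    A match requires the cutoff ratio within ``tol_cutoff_octaves`` and
    the maximum absolute difference of the two log-sensitivity curves,
    over a log-spaced grid spanning the shared passband (between the
    curves' lower sensitivity-1 crossings and the smaller cutoff), within
    ``tol_shape_log10``.  Returns the verdict plus diagnostics.
    """
    if target.degenerate or candidate.degenerate:
        raise ValueError("both models must be non-degenerate fits")
    cutoff_diff_oct = abs(math.log2(candidate.cutoff_cpd / target.cutoff_cpd))

    def lower_crossing(m: CSFModel) -> float:
        root = math.sqrt(m.peak_log_sensitivity / m.curvature)
        return 10 ** (math.log10(m.peak_frequency_cpd) - root)

    lo = max(lower_crossing(target), lower_crossing(candidate))
    hi = min(target.cutoff_cpd, candidate.cutoff_cpd)
    if hi <= lo:
        shape_diff = float("inf")
    else:
        grid = np.logspace(math.log10(lo), math.log10(hi), n_grid)
        shape_diff = float(
            np.max(np.abs(target.log_sensitivity(grid) - candidate.log_sensitivity(grid)))
        )
    ok = cutoff_diff_oct <= tol_cutoff_octaves and shape_diff <= tol_shape_log10
    return ok, {
        "cutoff_diff_octaves": cutoff_diff_oct,
        "max_shape_diff_log10": shape_diff,
        "tol_cutoff_octaves": tol_cutoff_octaves,
        "tol_shape_log10": tol_shape_log10,
    }


class CSFObserver:
    """Simulated 2AFC observer for the orientation-discrimination task.

    The probability of a correct response follows a cumulative-Gaussian
    psychometric function in log contrast::

        p(correct | f, c) = 0.5 + (0.5 - lapse) *
                            Phi(slope * (log10 c - log10 threshold(f)))

    with ``threshold(f) = 100 / S(f)`` from the observer's true CSF, so
    that at threshold contrast (lapse 0) p = 0.75 and far below threshold
    p tends to the 0.5 chance floor.  Calling the observer draws a
    Bernoulli response from its seeded stream.
    """

    def __init__(self, model: CSFModel, slope: float = 3.0, lapse: float = 0.02, seed=0):
        if slope <= 0:
            raise ValueError(f"slope must be positive, got {slope}")
        if not 0.0 <= lapse <= 0.1:
            raise ValueError(f"lapse must lie in [0, 0.1], got {lapse}")
        self.model = model
        self.slope = float(slope)
        self.lapse = float(lapse)
        self.rng = np.random.default_rng(seed)

    def p_correct(self, frequency_cpd: float, contrast_pct: float) -> float:
        log_thr = math.log10(100.0) - float(self.model.log_sensitivity(frequency_cpd))
        z = self.slope * (math.log10(contrast_pct) - log_thr)
        return 0.5 + (0.5 - self.lapse) * float(norm.cdf(z))

    def __call__(self, frequency_cpd: float, contrast_pct: float) -> bool:
        return bool(self.rng.random() < self.p_correct(frequency_cpd, contrast_pct))


def simulate_csf_observer(
    true_model: CSFModel, slope: float = 3.0, lapse: float = 0.02, seed=0
) -> CSFObserver:
    """Construct a seeded simulated observer around a known CSF."""
    return CSFObserver(true_model, slope=slope, lapse=lapse, seed=seed)


@dataclass(frozen=True)
class CSFResult:
    """Outcome of a full two-block CSF measurement.

    ``points`` holds every measured (frequency, contrast threshold) pair;
    ``fit_points`` the subset the curve was fitted to (see
    :func:`measure_csf`).
    """

    threshold_frequency_cpd: float
    points: tuple[tuple[float, float], ...]
    fit_points: tuple[tuple[float, float], ...]
    model: CSFModel
    frequency_trace: StaircaseTrace
    contrast_traces: tuple[StaircaseTrace, ...]


#: Contrast thresholds within one ladder rung of the 100% ceiling cannot
#: be resolved by a descending staircase and are treated as censored.
CEILING_CENSOR_PCT = 50.0


def measure_csf(
    observer,
    freq_ladder=None,
    contrast_ladder=None,
    coverage: str = "one_above",
) -> CSFResult:
    """Run the full two-block procedure and fit the CSF.

    ``coverage`` controls which block-2 frequencies are tested:
    ``"one_above"`` (default) tests from the lowest rung up to one ladder
    step above the block-1 threshold frequency; ``"all"`` tests every
    rung.  At least three frequencies are always tested.

    The parabola is fitted on the rungs strictly below the block-1
    threshold frequency: block 1 already established that the observer
    fails near that frequency at full contrast, so contrast staircases at
    or above it sit against the 100% ceiling and their apparent
    thresholds are selection-biased.  Within the fitted rungs, thresholds
    at or above :data:`CEILING_CENSOR_PCT` (one rung below the ceiling)
    are likewise censored.  All measured points are returned for
    diagnostics.
    """
    lad_f = make_frequency_ladder() if freq_ladder is None else np.asarray(freq_ladder, float)
    thr_f, trace_f = run_frequency_staircase(observer, lad_f)
    if coverage == "one_above":
        at_or_above = np.nonzero(lad_f >= thr_f * (1 - 1e-12))[0]
        top = (at_or_above[0] + 1) if at_or_above.size else (lad_f.size - 1)
        # always test at least three frequencies so a curve can be fitted
        top = min(max(int(top), 2), lad_f.size - 1)
    elif coverage == "all":
        top = lad_f.size - 1
    else:
        raise ValueError(f"unknown coverage {coverage!r}")
    points, traces = [], []
    for f in lad_f[: top + 1]:
        thr_c, trace_c = run_contrast_staircase(observer, float(f), ladder=contrast_ladder)
        points.append((float(f), thr_c))
        traces.append(trace_c)
    below = [i for i, (f, _) in enumerate(points) if f < thr_f]
    n_fit = max(3, len(below))
    fit_points = [
        (f, 100.0 if th >= CEILING_CENSOR_PCT else th) for f, th in points[:n_fit]
    ]
    model = fit_csf(fit_points)
    return CSFResult(
        threshold_frequency_cpd=thr_f,
        points=tuple(points),
        fit_points=tuple(fit_points),
        model=model,
        frequency_trace=trace_f,
        contrast_traces=tuple(traces),
    )
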