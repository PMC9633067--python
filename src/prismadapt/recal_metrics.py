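"""Per-participant and group-level recalibration metrics.

A prism-adaptation session has three phases: a *pre* baseline without
distortion, a *prism* phase in which goggles shift the visual field
rightward and terminal feedback drives trial-by-trial error correction,
and a *post* phase in which the prism is removed and the negative
aftereffect is observed.  This module turns trial-level pointing errors
into the standard summary quantities:

* ``Adaptation`` — induced prism distortion minus the mean of the last
  three prism-phase errors (``End Prism``);
* ``Initial Aftereffect`` — mean of the first three post-phase errors
  (negative when recalibration occurred);
* ``i_recal`` — the recalibration index, the average of Adaptation and
  the (negative) Initial Aftereffect normalised by the prism distortion,
  so 0 means no recalibration and 1 complete recalibration;
* group-level power-law fits ``error = a * x**b`` of the prism-phase
  learning curve, where ``b < 0`` and larger ``|b|`` means faster
  adaptation;
* the whole-phase aftereffect mean and its linear trial-by-trial trend.

All errors are in degrees of visual angle, rightward positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as _stats

__all__ = [
    "DEFAULT_PRISM_DIOPTERS",
    "PRISM_SHIFT_DEG",
    "PowerFit",
    "DecayFit",
    "prism_diopters_to_degrees",
    "bin_errors",
    "compute_metrics",
    "fit_power",
    "aftereffect_summary",
]

DEFAULT_PRISM_DIOPTERS = 20.0

METRIC_COLUMNS = [
    "participant_id",
    "group",
    "prism_distortion",
    "end_prism",
    "adaptation",
    "initial_aftereffect",
    "i_recal",
    "baseline_mean",
    "baseline_variance",
    "aftereffect_mean",
]


def prism_diopters_to_degrees(pd_value: float) -> float:
    """Convert prism diopters to degrees of visual angle.

    One prism diopter deviates light by 1 cm at 1 m, so the deflection
    angle is ``atan(pd / 100)``; 20 pd is 11.31 degrees.
    """
    if not np.isfinite(pd_value):
        raise ValueError(f"prism diopter value must be finite, got {pd_value!r}")
    return math.degrees(math.atan(pd_value / 100.0))


#: Canonical rightward shift of the distorting goggles (20 pd = 11.31 deg).
PRISM_SHIFT_DEG = prism_diopters_to_degrees(DEFAULT_PRISM_DIOPTERS)


def bin_errors(errors, bin_size: int = 3) -> np.ndarray:
    """Mean pointing error over consecutive non-overlapping bins of trials.

    A trailing partial bin (trial count not divisible by ``bin_size``) is
    dropped with a warning; the canonical 12/48/48 design divides evenly.
    """
    arr = np.asarray(errors, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot bin an empty error series")
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    n_full, remainder = divmod(arr.size, bin_size)
    if remainder:
        warnings.warn(
            f"dropping trailing partial bin of {remainder} trial(s)",
            stacklevel=2,
        )
    if n_full == 0:
        raise ValueError(
            f"fewer trials ({arr.size}) than one bin of size {bin_size}"
        )
    return arr[: n_full * bin_size].reshape(n_full, bin_size).mean(axis=1)


def _phase_errors(sub: pd.DataFrame, phase: str) -> np.ndarray:
    block = sub[sub["phase"] == phase].sort_values("trial")
    return block["error_deg"].to_numpy(dtype=float)


def compute_metrics(
    trials: pd.DataFrame, prism_distortion: float = PRISM_SHIFT_DEG
) -> pd.DataFrame:
    """Compute recalibration metrics for every participant in a trial table.

    Parameters
    ----------
    trials:
        Long-format trial table with columns ``participant_id``, ``group``,
        ``phase`` (pre/prism/post), ``trial`` and ``error_deg``.
    prism_distortion:
        Size of the induced shift in degrees (default 11.31, i.e. 20 pd).

    Returns
    -------
    DataFrame with one row per participant and columns
    ``prism_distortion, end_prism, adaptation, initial_aftereffect,
    i_recal, baseline_mean, baseline_variance, aftereffect_mean``.

    Definitions (degrees, rightward positive)::

        end_prism           = mean(last 3 prism-phase errors)
        adaptation          = prism_distortion - end_prism
        initial_aftereffect = mean(first 3 post-phase errors)
        i_recal             = (adaptation - initial_aftereffect)
                              / (2 * prism_distortion)

    so complete recalibration (end_prism = 0, initial aftereffect =
    -prism_distortion) gives ``i_recal = 1`` and no recalibration gives 0.
    ``baseline_variance`` is the unbiased (n-1) variance of all pre-phase
    errors; ``aftereffect_mean`` averages over every post-phase trial.
    """
    if not np.isfinite(prism_distortion) or prism_distortion <= 0:
        raise ValueError(f"prism_distortion must be positive, got {prism_distortion}")
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        pre = _phase_errors(sub, "pre")
        prism = _phase_errors(sub, "prism")
        post = _phase_errors(sub, "post")
        if prism.size < 3 or post.size < 3:
            raise ValueError(
                f"participant {pid!r} needs >=3 prism and >=3 post trials "
                f"(got {prism.size} and {post.size})"
            )
        if pre.size == 0:
            raise ValueError(f"participant {pid!r} has no pre-phase trials")
        end_prism = float(prism[-3:].mean())
        initial_after = float(post[:3].mean())
        adaptation = prism_distortion - end_prism
        i_recal = (adaptation - initial_after) / (2.0 * prism_distortion)
        group = sub["group"].iloc[0] if "group" in sub.columns else ""
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "prism_distortion": prism_distortion,
                "end_prism": end_prism,
                "adaptation": adaptation,
                "initial_aftereffect": initial_after,
                "i_recal": i_recal,
                "baseline_mean": float(pre.mean()),
                "baseline_variance": float(pre.var(ddof=1)) if pre.size > 1 else float("nan"),
                "aftereffect_mean": float(post.mean()),
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


@dataclass(frozen=True)
class PowerFit:
    """Power-law fit ``error = a * x**b`` of a group learning curve.

    ``a`` is the modelled initial pointing error (degrees, the abscissa
    starts at x = 1 on the first prism trial) and ``b`` the adaptation
    rate; faster adaptation means a more negative ``b``.  ``ci_b`` is a
    percentile bootstrap interval over participants when participant-level
    curves are supplied, otherwise the curvature (asymptotic) interval,
    which is always reported separately as ``ci_b_curvature``.
    """

    a: float
    b: float
    ci_b: tuple[float, float]
    ci_b_curvature: tuple[float, float]
    residual_rms: float
    n_trials: int
    n_boot: int = 0

    def predict(self, x) -> np.ndarray:
        return self.a * np.power(np.asarray(x, dtype=float), self.b)


def _power_least_squares(x: np.ndarray, y: np.ndarray, p0) -> tuple[np.ndarray, np.ndarray]:
    popt, pcov = optimize.curve_fit(
        lambda xx, a, b: a * np.power(xx, b), x, y, p0=p0, maxfev=20000
    )
    return popt, pcov


def fit_power(
    mean_errors,
    x=None,
    participant_errors=None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> PowerFit:
    """Fit ``a * x**b`` to per-trial group-mean prism-phase errors.

    The fit runs on the raw (untransformed) means — post-adaptation errors
    can be zero or negative, which rules out log-log regression — using
    nonlinear least squares initialised at ``(first-trial mean, -0.3)``.

    Parameters
    ----------
    mean_errors:
        Per-trial means over participants, trial 1 first.
    x:
        Optional abscissa; defaults to ``1..n`` (x = 1 at the first prism
        trial so that ``a`` is commensurate with the induced shift).
    participant_errors:
        Optional ``(n_participants, n_trials)`` array of individual error
        curves.  When given, ``ci_b`` is a seeded percentile bootstrap
        (resample participants, recompute means, refit).
    """
    y = np.asarray(mean_errors, dtype=float).ravel()
    if y.size < 5:
        raise ValueError(f"need >=5 trials to fit a power law, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("mean errors must be finite")
    xv = np.arange(1, y.size + 1, dtype=float) if x is None else np.asarray(x, dtype=float)
    if xv.shape != y.shape:
        raise ValueError("x and mean_errors must have matching length")
    p0 = (y[0] if y[0] > 0 else max(abs(y[0]), 1.0), -0.3)
    try:
        popt, pcov = _power_least_squares(xv, y, p0)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"power fit did not converge (n={y.size}, p0={p0}): {err}"
        ) from err
    a_hat, b_hat = float(popt[0]), float(popt[1])
    resid = y - a_hat * np.power(xv, b_hat)
    rms = float(np.sqrt(np.mean(resid**2)))
    se_b = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    ci_curv = (b_hat - 1.96 * se_b, b_hat + 1.96 * se_b)

    n_boot_done = 0
    ci_b = ci_curv
    if participant_errors is not None:
        mat = np.asarray(participant_errors, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != y.size:
            raise ValueError(
                "participant_errors must be (n_participants, n_trials) "
                f"matching the {y.size} trial means"
            )
        rng = np.random.default_rng(seed)
        boots = []
        n_part = mat.shape[0]
        for _ in range(n_boot):
            draw = rng.integers(0, n_part, n_part)
            ym = mat[draw].mean(axis=0)
            try:
                popt_b, _ = _power_least_squares(xv, ym, (popt[0], popt[1]))
            except RuntimeError:
                continue
            boots.append(popt_b[1])
        if len(boots) >= max(10, n_boot // 2):
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci_b = (float(lo), float(hi))
            n_boot_done = len(boots)
    return PowerFit(
        a=a_hat,
        b=b_hat,
        ci_b=ci_b,
        ci_b_curvature=ci_curv,
        residual_rms=rms,
        n_trials=int(y.size),
        n_boot=n_boot_done,
    )


@dataclass(frozen=True)
class DecayFit:
    """Linear trend of the aftereffect across post-phase trials.

    A positive slope on a negative aftereffect series means decay toward
    the original mapping (errors shrinking back to zero).
    """

    slope: float
    intercept: float
    ci_slope: tuple[float, float]
    r: float
    p: float
    n_trials: int


def aftereffect_summary(trials: pd.DataFrame) -> tuple[float, DecayFit]:
    """Whole-phase aftereffect mean and its linear trial-by-trial trend.

    The mean pools every post-phase error of every participant in
    ``trials`` (for one group this is the group aftereffect); the trend is
    an ordinary least-squares line through the per-trial means across
    participants, with a 95% CI on the slope.
    """
    post = trials[trials["phase"] == "post"]
    if post.empty:
        raise ValueError("trial table has no post-phase trials")
    mean_after = float(post["error_deg"].mean())
    per_trial = post.groupby("trial")["error_deg"].mean().sort_index()
    xs = per_trial.index.to_numpy(dtype=float)
    ys = per_trial.to_numpy(dtype=float)
    if xs.size < 3:
        raise ValueError("need >=3 post-phase trials for a decay trend")
    res = _stats.linregress(xs, ys)
    tcrit = float(_stats.t.ppf(0.975, xs.size - 2))
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    fit = DecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_slope=(float(ci[0]), float(ci[1])),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n_trials=int(xs.size),
    )
    return mean_after, fit
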