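"""Developmental time course of the recalibration index.

After sight-restoring surgery the recalibration index improves with time
(and thus visuomotor experience).  The time course is modelled as a
saturating exponential with both ends fixed::

    i_recal(x) = (a - c) * exp(-b * x) + c

with amplitude ``a`` fixed at 0 (no visual experience -> no
recalibration), asymptote ``c`` fixed externally to the mean performance
of the CSF-matched (blurred-vision) control group, and the rate ``b``
(1/years) as the single free parameter estimated by least squares.  With
``a = 0`` the curve is ``c * (1 - exp(-b x))``.

Repeated measurements of re-tested participants enter as separate points;
the bootstrap CI resamples participants as clusters so that both
measurements of a re-tested participant move together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["DevelopmentFit", "fit_development", "time_to_fraction"]

B_BOUNDS = (1e-6, 50.0)


@dataclass(frozen=True)
class DevelopmentFit:
    """Exponential time-course fit with fixed amplitude and asymptote."""

    b: float
    ci_b: tuple[float, float]
    a: float
    c: float
    n_points: int
    sse: float
    pinned: bool
    n_boot: int = 0

    def predict(self, x) -> np.ndarray:
        xv = np.asarray(x, dtype=float)
        return (self.a - self.c) * np.exp(-self.b * xv) + self.c


def _as_frame(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.copy()
        if "time_years" not in df.columns or "i_recal" not in df.columns:
            raise ValueError("data frame needs 'time_years' and 'i_recal' columns")
        if "participant_id" not in df.columns:
            df["participant_id"] = [f"p{i}" for i in range(len(df))]
        return df[["participant_id", "time_years", "i_recal"]]
    rows = []
    for i, pt in enumerate(points):
        if len(pt) == 3:
            rows.append({"participant_id": str(pt[0]), "time_years": pt[1], "i_recal": pt[2]})
        else:
            rows.append({"participant_id": f"p{i}", "time_years": pt[0], "i_recal": pt[1]})
    return pd.DataFrame(rows)


def _fit_b(x: np.ndarray, y: np.ndarray, a: float, c: float) -> float:
    def sse(b):
        pred = (a - c) * np.exp(-b * x) + c
        return float(np.sum((y - pred) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=B_BOUNDS, method="bounded", options={"xatol": 1e-12}
    )
    return float(res.x)


def fit_development(
    points,
    c: float,
    a: float = 0.0,
    n_boot: int = 2000,
    seed: int | None = None,
) -> DevelopmentFit:
    """Fit the rate ``b`` of ``(a - c) exp(-b x) + c`` to (time, i_recal) data.

    Parameters
    ----------
    points:
        DataFrame with columns ``time_years``, ``i_recal`` and optionally
        ``participant_id`` (for the cluster bootstrap), or an iterable of
        ``(time, i_recal)`` / ``(participant_id, time, i_recal)`` tuples.
    c, a:
        Fixed asymptote and amplitude (``a`` defaults to 0).
    n_boot:
        Percentile cluster-bootstrap resamples for the 95% CI on ``b``;
        0 disables the bootstrap (CI is then (nan, nan)).

    An estimate pinned against the search bounds ``[1e-6, 50]``/year is
    flagged ``pinned`` (e.g. data with no time trend drive b to 0).
    """
    df = _as_frame(points)
    x = df["time_years"].to_numpy(dtype=float)
    y = df["i_recal"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"need >=3 points, got {x.size}")
    if np.any(x < 0) or not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("times must be finite and >= 0; indices finite")
    if np.unique(x).size == 1:
        raise ValueError("all times identical: the rate is unidentifiable")

    b_hat = _fit_b(x, y, a, c)
    pinned = b_hat <= B_BOUNDS[0] * (1 + 1e-6) or b_hat >= B_BOUNDS[1] * (1 - 1e-6)
    pred = (a - c) * np.exp(-b_hat * x) + c
    sse = float(np.sum((y - pred) ** 2))

    ci = (float("nan"), float("nan"))
    n_boot_done = 0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        clusters = df.groupby("participant_id").indices
        keys = list(clusters)
        boots = []
        for _ in range(n_boot):
            draw = rng.integers(0, len(keys), len(keys))
            idx = np.concatenate([clusters[keys[k]] for k in draw])
            xb, yb = x[idx], y[idx]
            if np.unique(xb).size < 2:
                continue
            boots.append(_fit_b(xb, yb, a, c))
        if len(boots) >= max(10, n_boot // 2):
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi))
            n_boot_done = len(boots)
    return DevelopmentFit(
        b=b_hat,
        ci_b=ci,
        a=a,
        c=c,
        n_points=int(x.size),
        sse=sse,
        pinned=bool(pinned),
        n_boot=n_boot_done,
    )


def time_to_fraction(fit, fraction: float) -> float:
    """Years until the curve covers ``fraction`` of the way to its asymptote.

    For ``c (1 - exp(-b x))`` this is ``-ln(1 - fraction) / b``; e.g. with
    b = 1.5/year the 95% point lies at ~2.0 years.  Accepts a
    :class:`DevelopmentFit` or a bare rate.
    """
    b = float(getattr(fit, "b", fit))
    if b <= 0:
        raise ValueError(f"rate must be positive, got {b}")
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    return -math.log1p(-fraction) / b
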