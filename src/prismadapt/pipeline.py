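"""End-to-end analysis pipeline and run configuration.

``run_full_pipeline`` ties the stages together: simulate (or load) a
three-group cohort, compute per-participant recalibration metrics, fit
the group power-law learning curves and aftereffect trends, simulate a
longitudinal cataract cohort and fit its developmental exponential
(asymptote fixed to the blur-control group mean), and run the
statistical battery.  Every stochastic stage derives its stream from the
single seed in the configuration, so a persisted config reproduces a run
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import development as dev
from . import recal_metrics as rm
from . import simulation as sim
from . import stats as st
from .io import write_trial_table

__all__ = ["RunConfig", "run_full_pipeline", "save_report"]

logger = logging.getLogger("prismadapt")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one synthetic-cohort analysis run."""

    n_per_group: int = 20
    seed: int = 0
    prism_diopters: float = 20.0
    bin_size: int = 3
    jitter: bool = True
    n_boot_power: int = 500
    n_boot_development: int = 500
    eta_formula: str = "eta2_h"
    # longitudinal cohort: n_first first post-surgical tests with times drawn
    # log-normally (median ~0.6 y, range clipped to [0.003, 10] y, i.e. one
    # day to ten years), plus retests of n_retest of them 4-16 months later.
    n_longitudinal: int = 20
    n_retest: int = 13
    development_rate: float = 1.5
    outlier_sd_limit: float = 3.0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _longitudinal_times(config: RunConfig, rng: np.random.Generator):
    """Times since surgery: first tests plus clustered retests."""
    t_first = np.clip(rng.lognormal(mean=np.log(0.6), sigma=1.2, size=config.n_longitudinal),
                      0.003, 10.0)
    n_re = min(config.n_retest, config.n_longitudinal)
    retest_idx = rng.choice(config.n_longitudinal, size=n_re, replace=False)
    t_retest = t_first[retest_idx] + rng.uniform(4 / 12, 16 / 12, size=n_re)
    return t_first, retest_idx, t_retest


def run_full_pipeline(config: RunConfig = RunConfig(), trials: pd.DataFrame | None = None) -> dict:
    """Execute the full synthetic pipeline; returns a report bundle (dict).

    When ``trials`` is given it replaces the simulated cohort (the
    longitudinal stage is still simulated).  Stages that are infeasible
    for a degenerate cohort (e.g. one participant per group) are skipped
    and recorded in ``report["notes"]`` instead of raising.
    """
    notes: list[str] = []
    shift = rm.prism_diopters_to_degrees(config.prism_diopters)
    design = sim.ExperimentDesign(prism_shift_deg=shift)
    seeds = sim.derive_seeds(config.seed, 8)
    jitter = sim.JitterSpec() if config.jitter else None

    stage = "simulate"
    try:
        if trials is None:
            tables, params = [], []
            for i, preset in enumerate(("cataract", "control", "control_blur")):
                tab, par = sim.simulate_group(
                    design, preset, config.n_per_group, seeds[i], jitter=jitter,
                    return_params=True,
                )
                tables.append(tab)
                params.append(par)
            trials = pd.concat(tables, ignore_index=True)
            params_df = pd.concat(params, ignore_index=True)
        else:
            params_df = None

        stage = "metrics"
        metrics = rm.compute_metrics(trials, prism_distortion=shift)

        stage = "power fits"
        power_fits: dict[str, rm.PowerFit] = {}
        aftereffects: dict[str, dict] = {}
        for group, gtab in trials.groupby("group", sort=True):
            prism = gtab[gtab["phase"] == "prism"]
            wide = prism.pivot_table(index="participant_id", columns="trial", values="error_deg")
            mat = wide.to_numpy(dtype=float)
            means = mat.mean(axis=0)
            power_fits[group] = rm.fit_power(
                means,
                participant_errors=mat if mat.shape[0] > 1 else None,
                n_boot=config.n_boot_power,
                seed=seeds[3],
            )
            mean_after, decay = rm.aftereffect_summary(gtab)
            aftereffects[group] = {"mean": mean_after, "decay": decay}

        stage = "development"
        rng = np.random.default_rng(seeds[4])
        t_first, retest_idx, t_retest = _longitudinal_times(config, rng)
        cohort1 = sim.CohortSpec(
            times_years=tuple(t_first),
            development_rate=config.development_rate,
            seed=seeds[5],
            jitter=jitter,
        )
        trials1, times1 = sim.simulate_longitudinal_cohort(cohort1, design)
        m1 = rm.compute_metrics(trials1, prism_distortion=shift)
        m1["time_years"] = m1["participant_id"].map(times1)
        parts = [m1[["participant_id", "time_years", "i_recal"]]]
        if len(t_retest):
            cohort2 = sim.CohortSpec(
                times_years=tuple(t_retest),
                development_rate=config.development_rate,
                seed=seeds[6],
                jitter=jitter,
            )
            trials2, times2 = sim.simulate_longitudinal_cohort(cohort2, design)
            m2 = rm.compute_metrics(trials2, prism_distortion=shift)
            m2["time_years"] = m2["participant_id"].map(times2)
            # a retest keeps its participant's cluster id
            retest_ids = {f"cataract_t{j + 1:02d}": f"cataract_t{int(i) + 1:02d}"
                          for j, i in enumerate(retest_idx)}
            m2["participant_id"] = m2["participant_id"].map(retest_ids)
            parts.append(m2[["participant_id", "time_years", "i_recal"]])
        longitudinal = pd.concat(parts, ignore_index=True)
        blur_mean = float(metrics.loc[metrics["group"] == "control_blur", "i_recal"].mean())
        development = None
        if len(longitudinal) >= 3 and np.isfinite(blur_mean):
            development = dev.fit_development(
                longitudinal, c=blur_mean, n_boot=config.n_boot_development, seed=seeds[7]
            )
        else:
            notes.append("development fit skipped: too few longitudinal points")

        stage = "stats"
        results: list[st.TestResult] = []
        by_group = {
            g: metrics.loc[metrics["group"] == g, "i_recal"].to_numpy()
            for g in sorted(metrics["group"].unique())
        }
        feasible = len(by_group) >= 2 and all(v.size >= 2 for v in by_group.values())
        if feasible:
            results.append(
                st.omnibus_group_test(by_group, effect=config.eta_formula, label="i_recal omnibus")
            )
            results.extend(st.pairwise_ranksum(by_group, label="i_recal"))
            base_by_group = {
                g: metrics.loc[metrics["group"] == g, "baseline_mean"].to_numpy()
                for g in by_group
            }
            results.append(
                st.omnibus_group_test(
                    base_by_group, effect=config.eta_formula, label="baseline error omnibus"
                )
            )
            import itertools

            pairs = list(itertools.combinations(sorted(base_by_group), 2))
            for g1, g2 in pairs:
                results.append(
                    st.variance_f_test(
                        base_by_group[g1], base_by_group[g2],
                        label=f"baseline precision: {g1} vs {g2}",
                    )
                )
            after_by_group = {
                g: metrics.loc[metrics["group"] == g, "aftereffect_mean"].to_numpy()
                for g in by_group
            }
            results.append(
                st.omnibus_group_test(
                    after_by_group, effect=config.eta_formula, label="aftereffect omnibus"
                )
            )
            results.extend(st.pairwise_ranksum(after_by_group, label="aftereffect"))
        else:
            notes.append("group tests skipped: need >=2 groups with >=2 participants each")

        cat = metrics[metrics["group"] == "cataract"]
        if len(cat) >= 2:
            results.append(
                st.signed_rank(cat["i_recal"].to_numpy(), tail="greater",
                               label="cataract i_recal > 0")
            )
        correlations = {}
        if len(cat) >= 3:
            correlations["variance_vs_i_recal"] = st.screened_pearson(
                cat["baseline_variance"], cat["i_recal"],
                sd_limit=config.outlier_sd_limit, ids=cat["participant_id"],
            )
            if params_df is not None:
                acuity = cat.merge(
                    params_df[["participant_id", "acuity_cpd"]], on="participant_id"
                )
                correlations["acuity_vs_i_recal"] = st.screened_pearson(
                    np.log10(acuity["acuity_cpd"]), acuity["i_recal"],
                    sd_limit=config.outlier_sd_limit, ids=acuity["participant_id"],
                )
        else:
            notes.append("cataract correlations skipped: fewer than 3 participants")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "config": config,
        "design": design,
        "trials": trials,
        "params": params_df,
        "metrics": metrics,
        "power_fits": power_fits,
        "aftereffects": aftereffects,
        "longitudinal": longitudinal,
        "development": development,
        "stats": results,
        "correlations": correlations,
        "notes": notes,
        "seeds": seeds,
    }


def _summary(report: dict) -> dict:
    metrics = report["metrics"]
    out = {
        "i_recal_mean": {
            g: float(v) for g, v in metrics.groupby("group")["i_recal"].mean().items()
        },
        "baseline_variance_mean": {
            g: float(v) for g, v in metrics.groupby("group")["baseline_variance"].mean().items()
        },
        "aftereffect_mean": {g: a["mean"] for g, a in report["aftereffects"].items()},
        "power_b": {g: f.b for g, f in report["power_fits"].items()},
        "power_ci_b": {g: list(f.ci_b) for g, f in report["power_fits"].items()},
        "notes": report["notes"],
        "seeds": report["seeds"],
    }
    fit = report["development"]
    if fit is not None:
        out["development"] = {
            "b": fit.b, "ci_b": list(fit.ci_b), "c": fit.c, "n_points": fit.n_points,
            "pinned": fit.pinned,
        }
    return out


def save_report(report: dict, outdir) -> None:
    """Persist a report bundle: tables, stats, summary and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trial_table(report["trials"], outdir / "trials.csv")
    report["metrics"].to_csv(outdir / "metrics.csv", index=False)
    report["longitudinal"].to_csv(outdir / "longitudinal.csv", index=False)
    pd.DataFrame([r.as_row() for r in report["stats"]]).to_csv(
        outdir / "stats.csv", index=False
    )
    report["config"].to_json(outdir / "config.json")
    (outdir / "summary.json").write_text(json.dumps(_summary(report), indent=2))
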