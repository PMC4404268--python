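"""End-to-end study replica: develop, externally validate, report.

``run_study`` simulates a development cohort, fits the joint frailty model
and per-landmark-time Cox models on it, simulates shifted validation
cohorts (different case mix, censoring or relapse-recording rules),
computes the three dynamic predictions on each validation cohort, and
writes prediction-error curves, calibration tables, plots and a summary.
Everything is deterministic given the root seed; all intermediate
artifacts are CSV/JSON/PNG under the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, write_cohort
from .joint_model import FitConfig, JointParams, fit_joint_model
from .landmark import LandmarkConfig, LandmarkFit, build_landmark_dataset, fit_landmark_cox
from .prediction import predict_ign, predict_lm, predict_rec, request_from_subject
from .simulate import (
    CensoringConfig,
    FRENCH_FREQUENCIES,
    NETHERLANDS_FREQUENCIES,
    SimulationConfig,
    TrueParams,
    WEST_MIDLANDS_FREQUENCIES,
    french_like,
    simulate_cohort,
)
from .validation import (
    brier_error,
    calibration_table,
    censoring_km,
    km_reference_error,
    prediction_error_curve,
    r_squared,
)

log = logging.getLogger("jointpredict")

__all__ = ["ScenarioConfig", "StudyConfig", "run_study"]


@dataclass
class ScenarioConfig:
    """One simulated population (development or validation)."""

    name: str
    n_subjects: int
    covariate_frequencies: dict = field(default_factory=lambda: dict(FRENCH_FREQUENCIES))
    censoring: CensoringConfig = field(default_factory=CensoringConfig)
    recording_truncation_time: float | None = None

    def simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_subjects=self.n_subjects,
            covariate_frequencies=self.covariate_frequencies,
            censoring=self.censoring,
            recording_truncation_time=self.recording_truncation_time,
            seed=seed,
        )


@dataclass
class StudyConfig:
    """Full study layout; defaults emulate the published design at desk scale."""

    true_params: TrueParams = field(default_factory=french_like)
    development: ScenarioConfig = field(
        default_factory=lambda: ScenarioConfig("development_french_like", 1000)
    )
    validation: list[ScenarioConfig] = field(
        default_factory=lambda: [
            ScenarioConfig(
                "west_midlands_like", 1500,
                covariate_frequencies=dict(WEST_MIDLANDS_FREQUENCIES),
            ),
            ScenarioConfig(
                "netherlands_like", 1500,
                covariate_frequencies=dict(NETHERLANDS_FREQUENCIES),
                censoring=CensoringConfig(c_admin=9.0, early_fraction=0.15,
                                          early_low=4.0, early_high=9.0),
                recording_truncation_time=5.0,
            ),
        ]
    )
    landmark_times: list[float] = field(default_factory=lambda: [2.0, 5.0])
    fix_s_grid: dict = field(
        default_factory=lambda: {"s": 5.0, "w": [1.0, 2.0, 3.5, 5.0, 7.5, 10.0]}
    )
    fix_w_grid: dict = field(
        default_factory=lambda: {"w": 2.0, "s": [1.0, 2.0, 3.0, 5.0, 7.0]}
    )
    calibration_point: tuple[float, float] = (5.0, 5.0)
    seed: int = 20150401
    fit: FitConfig = field(default_factory=FitConfig)
    landmark_fit: LandmarkConfig = field(default_factory=LandmarkConfig)

    # -- YAML round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "true_params": self.true_params.to_dict(),
            "development": _scenario_dict(self.development),
            "validation": [_scenario_dict(v) for v in self.validation],
            "landmark_times": list(self.landmark_times),
            "fix_s_grid": self.fix_s_grid,
            "fix_w_grid": self.fix_w_grid,
            "calibration_point": list(self.calibration_point),
            "seed": self.seed,
            "fit": dataclasses.asdict(self.fit),
            "landmark_fit": dataclasses.asdict(self.landmark_fit),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kw = {}
        if "true_params" in d:
            kw["true_params"] = TrueParams.from_dict(d["true_params"])
        if "development" in d:
            kw["development"] = _scenario_from_dict(d["development"])
        if "validation" in d:
            kw["validation"] = [_scenario_from_dict(v) for v in d["validation"]]
        for key in ("landmark_times", "fix_s_grid", "fix_w_grid", "seed"):
            if key in d:
                kw[key] = d[key]
        if "calibration_point" in d:
            kw["calibration_point"] = tuple(d["calibration_point"])
        if "fit" in d:
            kw["fit"] = FitConfig(**d["fit"])
        if "landmark_fit" in d:
            kw["landmark_fit"] = LandmarkConfig(**d["landmark_fit"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _scenario_dict(sc: ScenarioConfig) -> dict:
    return {
        "name": sc.name,
        "n_subjects": sc.n_subjects,
        "covariate_frequencies": sc.covariate_frequencies,
        "censoring": sc.censoring.to_dict(),
        "recording_truncation_time": sc.recording_truncation_time,
    }


def _scenario_from_dict(d: dict) -> ScenarioConfig:
    return ScenarioConfig(
        name=d["name"],
        n_subjects=d["n_subjects"],
        covariate_frequencies=d.get("covariate_frequencies", dict(FRENCH_FREQUENCIES)),
        censoring=CensoringConfig(**d["censoring"]) if "censoring" in d else CensoringConfig(),
        recording_truncation_time=d.get("recording_truncation_time"),
    )


def _landmark_for(dev_cohort: Cohort, s: float, config: LandmarkConfig,
                  cache: dict) -> LandmarkFit:
    if s not in cache:
        df = build_landmark_dataset(dev_cohort, s)
        cache[s] = fit_landmark_cox(df, s, config)
    return cache[s]


def _predictor(setting: str, joint: JointParams, dev_cohort: Cohort,
               lm_config: LandmarkConfig, lm_cache: dict):
    def f(subject, s, w):
        req = request_from_subject(subject, s, w)
        if setting == "rec":
            return predict_rec(req, joint).probability
        if setting == "ign":
            return predict_ign(req, joint).probability
        fit = _landmark_for(dev_cohort, s, lm_config, lm_cache)
        return predict_lm(req, fit).probability

    return f


def _plot_error_curves(df: pd.DataFrame, xcol: str, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for setting, sub in df.groupby("setting"):
        ax.plot(sub[xcol], 100 * sub["r_squared"], marker="o", label=setting)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel(xcol + " (years)")
    ax.set_ylabel("explained variation R2 (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_calibration(tables: dict, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(tables), figsize=(4.2 * len(tables), 4.4), squeeze=False)
    for ax, (setting, ct) in zip(axes[0], tables.items()):
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.errorbar(
            ct.mean_predicted, ct.observed,
            yerr=[ct.observed - ct.ci_low, ct.ci_high - ct.observed],
            fmt="o", ms=4, capsize=2,
        )
        centers = 0.5 * (ct.histogram_edges[:-1] + ct.histogram_edges[1:])
        hmax = ct.histogram_counts.max() or 1
        ax.bar(centers, 0.25 * ct.histogram_counts / hmax, width=0.045,
               bottom=0, alpha=0.25, color="grey")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel("mean predicted risk")
        ax.set_ylabel("observed proportion")
        ax.set_title(setting)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(config: StudyConfig, out_dir) -> dict:
    """Run the full replica; returns the summary dictionary.

    Stages: simulate development data -> fit joint + landmark models ->
    simulate each validation scenario -> prediction-error curves (s fixed
    / w fixed), calibration tables, and subgroup analyses (relapse before
    s vs not, predictions applied without refitting).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(1 + len(config.validation))]
    summary: dict = {"seed": config.seed, "scenarios": {}}
    config.to_yaml(out / "study_config.yaml")

    stage = "simulate development"
    try:
        dev = simulate_cohort(
            config.true_params, config.development.simulation_config(seeds[0])
        )
        write_cohort(dev, out / "dev_subjects.csv", out / "dev_recurrences.csv")
        log.info("development cohort: n=%d, relapses=%d, deaths=%d",
                 len(dev), dev.n_relapses, dev.n_deaths)

        stage = "fit joint model"
        joint = fit_joint_model(dev, config.fit)
        joint.save(out / "joint_model.json")
        summary["joint"] = {
            "theta": joint.theta, "alpha": joint.alpha,
            "beta_rec": joint.beta_rec.tolist(),
            "beta_death": joint.beta_death.tolist(),
            "converged": joint.converged,
        }

        stage = "fit landmark models"
        lm_cache: dict = {}
        for s in config.landmark_times:
            fit = _landmark_for(dev, s, config.landmark_fit, lm_cache)
            fit.save(out / f"landmark_s{s:g}.json")

        for scen, seed in zip(config.validation, seeds[1:]):
            stage = f"validate on {scen.name}"
            vdir = out / scen.name
            vdir.mkdir(exist_ok=True)
            val = simulate_cohort(config.true_params, scen.simulation_config(seed))
            write_cohort(val, vdir / "subjects.csv", vdir / "recurrences.csv")
            scen_summary = _validate_scenario(
                config, joint, dev, lm_cache, val, vdir
            )
            summary["scenarios"][scen.name] = scen_summary
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise RuntimeError(f"study aborted during stage {stage!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def _validate_scenario(config, joint, dev, lm_cache, val, vdir: Path) -> dict:
    scen_summary: dict = {"n": len(val)}
    curves = []
    grid_s = [(config.fix_s_grid["s"], w) for w in config.fix_s_grid["w"]]
    grid_w = [(s, config.fix_w_grid["w"]) for s in config.fix_w_grid["s"]]
    for setting in ("rec", "ign", "lm"):
        pred = _predictor(setting, joint, dev, config.landmark_fit, lm_cache)
        for mode, grid in (("fix_s_vary_w", grid_s), ("fix_w_vary_s", grid_w)):
            for res in prediction_error_curve(val, pred, grid, setting):
                curves.append(
                    {"mode": mode, "setting": setting, "s": res.s, "w": res.w,
                     "n": res.n_eval, "err": res.error, "err_km": res.reference_error,
                     "r2": res.r_squared}
                )
    cdf = pd.DataFrame(curves)
    cdf.to_csv(vdir / "brier_curves.csv", index=False, float_format="%.10g")
    _plot_error_curves(
        cdf[cdf["mode"] == "fix_s_vary_w"].rename(columns={"r2": "r_squared"}),
        "w", vdir / "r2_fix_s.png", f"s = {config.fix_s_grid['s']:g}",
    )
    _plot_error_curves(
        cdf[cdf["mode"] == "fix_w_vary_s"].rename(columns={"r2": "r_squared"}),
        "s", vdir / "r2_fix_w.png", f"w = {config.fix_w_grid['w']:g}",
    )
    scen_summary["mean_r2"] = (
        cdf.groupby("setting")["r2"].mean().to_dict()
    )

    s0, w0 = config.calibration_point
    at_risk = [subj for subj in val if subj.followup_time > s0]
    T = np.array([subj.followup_time for subj in at_risk])
    d = np.array([subj.death_indicator for subj in at_risk])
    preds = {}
    rows = []
    for setting in ("rec", "ign", "lm"):
        pred = _predictor(setting, joint, dev, config.landmark_fit, lm_cache)
        P = np.array([pred(subj, s0, w0) for subj in at_risk])
        preds[setting] = P
        for subj, p in zip(at_risk, P):
            rows.append({"id": subj.id, "s": s0, "w": w0, "setting": setting,
                         "probability": p})
    pd.DataFrame(rows).to_csv(vdir / "predictions.csv", index=False,
                              float_format="%.10g")
    tables = {}
    for setting, P in preds.items():
        ct = calibration_table(P, T, d, s0, w0)
        ct.to_frame().to_csv(vdir / f"calibration_{setting}.csv", index=False,
                             float_format="%.10g")
        tables[setting] = ct
    _plot_calibration(tables, vdir / "calibration.png",
                      f"death in ({s0:g}, {s0 + w0:g}] years")

    # subgroup analyses: prediction only, no refit
    subgroup = {}
    for label, keep in (
        ("no_relapse_before_s", lambda subj: len(subj.relapses_before(s0)) == 0),
        ("relapse_before_s", lambda subj: len(subj.relapses_before(s0)) >= 1),
    ):
        idx = np.array([keep(subj) for subj in at_risk])
        if idx.sum() < 10:
            continue
        G = censoring_km(T[idx], d[idx])
        sub = {}
        for setting, P in preds.items():
            err = brier_error(P[idx], T[idx], d[idx], s0, w0, G)
            err_km = km_reference_error(T[idx], d[idx], s0, w0, G)
            obs = calibration_table(P[idx], T[idx], d[idx], s0, w0)
            sub[setting] = {
                "n": int(idx.sum()),
                "err": err,
                "r2": r_squared(err, err_km),
                "mean_predicted": float(P[idx].mean()),
                "observed_overall": float(np.average(obs.observed, weights=obs.counts)),
            }
        subgroup[label] = sub
    scen_summary["subgroups"] = subgroup
    with open(vdir / "scenario_summary.json", "w") as fh:
        json.dump(scen_summary, fh, indent=1)
    return scen_summary
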