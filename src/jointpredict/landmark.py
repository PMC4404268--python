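"""Landmark Cox model for death with relapse-count covariates.

At a landmark time s the model keeps only subjects still alive (and
uncensored) at s, summarizes their relapse history as the count of
relapses up to s — categorized {0, 1, >=2} — and fits a proportional
hazards model for death on t >= s with a penalized M-spline baseline,
left-truncated at s.  Relapses after s never enter the fit.

A separate model is fitted per landmark time; each fit serves exactly its
own s for prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import Cohort, DESIGN_COLUMNS, design_matrix
from .joint_model import _constant_eta, _finite_diff_hessian
from .splines import BaselineHazard, SplineBasis

__all__ = ["LandmarkFit", "LandmarkConfig", "build_landmark_dataset", "fit_landmark_cox"]

#: design columns of the landmark model (baseline covariates + history)
LANDMARK_COLUMNS = (*DESIGN_COLUMNS, "rec_1", "rec_2plus")


@dataclass
class LandmarkConfig:
    n_knots: int = 7
    kappa_death: float = 1.0
    max_iter: int = 400
    compute_se: bool = True


@dataclass
class LandmarkFit:
    """Fitted landmark Cox model at landmark time s.

    The spline baseline lives on the elapsed scale t - s (so its
    cumulative hazard is 0 at the landmark time); `cumulative_hazard`
    takes calendar times t >= s.
    """

    landmark_time: float
    hazard_death_s: BaselineHazard
    beta_s: np.ndarray
    n_at_risk: int
    se: dict = field(default_factory=dict)
    converged: bool = True
    penalized_loglik: float = np.nan
    kappa_death: float = 0.0

    def __post_init__(self):
        self.beta_s = np.asarray(self.beta_s, dtype=float)

    def cumulative_hazard(self, t, z_row: np.ndarray) -> np.ndarray:
        """Lambda(t | Z) for calendar t >= s, conditional on survival to s."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.landmark_time - 1e-12):
            raise ValueError("landmark model is defined for t >= its landmark time")
        base = self.hazard_death_s.cumulative(np.maximum(t - self.landmark_time, 0.0))
        return base * np.exp(float(np.dot(self.beta_s, z_row)))

    def to_dict(self) -> dict:
        return {
            "landmark_time": self.landmark_time,
            "hazard_death_s": self.hazard_death_s.to_dict(),
            "beta_s": self.beta_s.tolist(),
            "n_at_risk": self.n_at_risk,
            "se": {k: (list(v) if np.ndim(v) else v) for k, v in self.se.items()},
            "converged": self.converged,
            "penalized_loglik": self.penalized_loglik,
            "kappa_death": self.kappa_death,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkFit":
        return cls(
            d["landmark_time"],
            BaselineHazard.from_dict(d["hazard_death_s"]),
            np.asarray(d["beta_s"]),
            d["n_at_risk"],
            se={k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.get("se", {}).items()},
            converged=d.get("converged", True),
            penalized_loglik=d.get("penalized_loglik", np.nan),
            kappa_death=d.get("kappa_death", 0.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "LandmarkFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def relapse_count_indicators(n_prev: int) -> tuple[float, float]:
    """{0, 1, >=2} dummy coding, reference 0 previous relapses."""
    return (1.0 if n_prev == 1 else 0.0, 1.0 if n_prev >= 2 else 0.0)


def build_landmark_dataset(cohort: Cohort, s: float) -> pd.DataFrame:
    """Risk set at s with relapse history summarized as count indicators.

    Keeps subjects with follow-up strictly beyond s; counts relapses with
    X_ij <= s; outcome time and death indicator are unchanged.
    """
    if s < 0:
        raise ValueError("landmark time must be >= 0")
    rows = []
    for subj in cohort:
        if subj.followup_time <= s:
            continue
        n_prev = len(subj.relapses_before(s))
        r1, r2 = relapse_count_indicators(n_prev)
        rows.append(
            {
                "id": subj.id,
                "time": subj.followup_time,
                "death": subj.death_indicator,
                "n_prev_rec": n_prev,
                "rec_1": r1,
                "rec_2plus": r2,
            }
        )
    if not rows:
        raise ValueError(f"empty risk set at landmark time s={s}")
    df = pd.DataFrame(rows)
    design = design_matrix([subj for subj in cohort if subj.followup_time > s])
    for k, col in enumerate(DESIGN_COLUMNS):
        df[col] = design[:, k]
    return df[["id", "time", "death", "n_prev_rec", *LANDMARK_COLUMNS]]


def fit_landmark_cox(
    landmark_df: pd.DataFrame, s: float, config: LandmarkConfig | None = None
) -> LandmarkFit:
    """Penalized full-likelihood proportional hazards fit on t >= s.

    The baseline is an M-spline hazard on the elapsed time t - s, so left
    truncation at s is handled by construction; the log-likelihood is
    ``sum_i delta_i [log lambda0(T_i - s) + beta'Z_i]
    - exp(beta'Z_i) Lambda0(T_i - s)`` minus the curvature penalty.
    """
    config = config or LandmarkConfig()
    T = landmark_df["time"].to_numpy(dtype=float)
    delta = landmark_df["death"].to_numpy(dtype=int)
    Z = landmark_df[list(LANDMARK_COLUMNS)].to_numpy(dtype=float)
    n, p = Z.shape
    if delta.sum() == 0:
        raise ValueError("no deaths after the landmark time: model cannot be fitted")

    elapsed = T - s
    t_max = float(elapsed.max())
    death_elapsed = elapsed[delta == 1]
    basis = SplineBasis.from_event_times(death_elapsed, config.n_knots, t_max)
    M_ev = basis.basis_matrix(death_elapsed)
    I_all = basis.integral_matrix(elapsed)
    P = basis.curvature_gram()
    m = basis.n_basis
    died = delta == 1

    def negloglik(x):
        eta = x[:m] ** 2
        beta = x[m:]
        lam = M_ev @ eta
        if np.any(lam <= 0):
            return 1e12
        lp = Z @ beta
        ll = float(np.sum(np.log(lam)) + np.sum(lp[died]) - np.sum(np.exp(lp) * (I_all @ eta)))
        ll -= config.kappa_death * float(eta @ P @ eta)
        return -ll if np.isfinite(ll) else 1e12

    rate0 = max(died.sum(), 1) / float(np.sum(elapsed))
    x0 = np.concatenate([np.sqrt(np.maximum(_constant_eta(basis, rate0), 1e-8)), np.zeros(p)])
    res = minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        options={"maxiter": config.max_iter, "ftol": 1e-10, "gtol": 1e-6, "maxcor": 25},
    )
    eta = res.x[:m] ** 2
    beta = res.x[m:]

    se: dict = {}
    if config.compute_se:
        try:
            H = _finite_diff_hessian(negloglik, res.x)
            cov = np.linalg.inv(H)
            dvar = np.diag(cov).copy()
            dvar[dvar < 0] = np.nan
            se["beta_s"] = np.sqrt(dvar[m:])
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular Hessian: landmark SEs unavailable", stacklevel=2)

    return LandmarkFit(
        landmark_time=float(s),
        hazard_death_s=BaselineHazard(basis, eta),
        beta_s=beta,
        n_at_risk=n,
        se=se,
        converged=bool(res.success),
        penalized_loglik=float(-res.fun),
        kappa_death=config.kappa_death,
    )
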