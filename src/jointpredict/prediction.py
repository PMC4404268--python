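"""Dynamic conditional probabilities of death in (s, s+w].

Three settings share one question — given survival to the prediction time
s, what is the probability of dying before s+w? — but differ in what they
condition on:

* ``predict_rec`` (joint model, relapse history used): conditions on the
  full history — J relapses observed at times up to s and no (J+1)-th
  relapse by s.  The frailty is integrated against its posterior given
  that history, so more relapses shift the posterior up and (for positive
  power link alpha) raise the predicted risk.
* ``predict_ign`` (joint model, history ignored): integrates the frailty
  against its prior; only baseline covariates enter.
* ``predict_lm`` (landmark Cox): plugs the relapse count at s into the
  landmark model fitted at that same s.

All frailty integrals reduce to ``log_frailty_integral`` and are computed
in the log domain, so large relapse counts and tiny survival probabilities
do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Subject, design_row
from .joint_model import JointParams, QuadratureRule, log_frailty_integral
from .landmark import LandmarkFit, relapse_count_indicators

__all__ = [
    "PredictionRequest",
    "PredictionResult",
    "conditional_survival_death",
    "conditional_survival_next_recurrence",
    "predict_rec",
    "predict_ign",
    "predict_lm",
    "request_from_subject",
]

_LOG_TINY = -690.0  # below exp() underflow: denominator treated as degenerate


@dataclass(frozen=True)
class PredictionRequest:
    """Snapshot of one subject at prediction time s with window w."""

    covariates: dict
    s: float
    w: float
    relapse_times: tuple[float, ...] = ()

    def __post_init__(self):
        if self.s < 0 or self.w <= 0:
            raise ValueError("need s >= 0 and w > 0")
        times = tuple(float(t) for t in self.relapse_times)
        if any(t > self.s for t in times):
            raise ValueError("history may only contain relapses at or before s")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("relapse times must be strictly increasing")
        object.__setattr__(self, "relapse_times", times)

    @property
    def n_relapses(self) -> int:
        return len(self.relapse_times)

    @property
    def last_relapse(self) -> float:
        """X_iJ, with X_i0 = 0 when no relapse has occurred."""
        return self.relapse_times[-1] if self.relapse_times else 0.0


@dataclass(frozen=True)
class PredictionResult:
    probability: float
    setting: str  # "rec" | "ign" | "lm"
    s: float
    w: float
    model_id: str = ""

    def __post_init__(self):
        if not (-1e-12 <= self.probability <= 1 + 1e-12):
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        object.__setattr__(self, "probability", float(np.clip(self.probability, 0.0, 1.0)))


def request_from_subject(subject: Subject, s: float, w: float) -> PredictionRequest:
    """Truncate a subject's relapse stream at s and build a request."""
    return PredictionRequest(
        covariates=dict(subject.covariates), s=s, w=w, relapse_times=subject.relapses_before(s)
    )


def conditional_survival_death(params: JointParams, covariates: dict, t: float, u: float):
    """S_D(t | Z, u) = exp(-u^alpha Lambda_D0(t) exp(beta_death'Z))."""
    if t < 0 or u <= 0:
        raise ValueError("need t >= 0 and u > 0")
    z = design_row(covariates)
    lam = float(params.hazard_death.cumulative(t)[0]) * np.exp(float(np.dot(params.beta_death, z)))
    return float(np.exp(-(u**params.alpha) * lam))


def conditional_survival_next_recurrence(
    params: JointParams, covariates: dict, s: float, last_relapse: float, u: float
):
    """S_R,(J+1)(s | Z, u): no (J+1)-th relapse by s, risk starting at X_iJ."""
    if last_relapse > s:
        raise ValueError("last relapse must be at or before s")
    if u <= 0:
        raise ValueError("u must be > 0")
    z = design_row(covariates)
    gap = float(
        params.hazard_rec.cumulative(s)[0] - params.hazard_rec.cumulative(last_relapse)[0]
    ) * np.exp(float(np.dot(params.beta_rec, z)))
    return float(np.exp(-u * gap))


def _joint_cumulatives(params: JointParams, request: PredictionRequest):
    z = design_row(request.covariates)
    lp_r = float(np.dot(params.beta_rec, z))
    lp_d = float(np.dot(params.beta_death, z))
    s, w = request.s, request.w
    gap = float(
        params.hazard_rec.cumulative(s)[0]
        - params.hazard_rec.cumulative(request.last_relapse)[0]
    ) * np.exp(lp_r)
    lam_d_s = float(params.hazard_death.cumulative(s)[0]) * np.exp(lp_d)
    lam_d_sw = float(params.hazard_death.cumulative(s + w)[0]) * np.exp(lp_d)
    return gap, lam_d_s, lam_d_sw


def _ratio_prediction(theta, alpha, J, gap, lam_s, lam_sw, n_nodes) -> float:
    """1 - [int u^J e^{-u gap - u^a lam_sw} g] / [same with lam_s]."""
    log_den = float(log_frailty_integral(theta, J, gap, lam_s, alpha, n_nodes))
    log_sw = float(log_frailty_integral(theta, J, gap, lam_sw, alpha, n_nodes))
    if log_den < _LOG_TINY:
        raise ValueError(
            "degenerate history: survival probability at s underflows; the "
            "requested prediction is conditioned on a near-impossible event"
        )
    return float(np.clip(1.0 - np.exp(log_sw - log_den), 0.0, 1.0))


def predict_rec(
    request: PredictionRequest, params: JointParams, rule: QuadratureRule | None = None
) -> PredictionResult:
    """Joint-model prediction using the relapse history observed by s.

    Ratio of frailty integrals: the numerator weights the prior by the
    history likelihood u^J S_R(s|u) S_D(s|u); the same weight normalizes
    the denominator.
    """
    n_nodes = rule.n_nodes if rule is not None else 128
    if rule is not None and not np.isclose(rule.theta, params.theta):
        raise ValueError("quadrature rule was built for a different theta")
    gap, lam_s, lam_sw = _joint_cumulatives(params, request)
    prob = _ratio_prediction(
        params.theta, params.alpha, float(request.n_relapses), gap, lam_s, lam_sw, n_nodes
    )
    return PredictionResult(prob, "rec", request.s, request.w)


def predict_ign(
    request: PredictionRequest, params: JointParams, rule: QuadratureRule | None = None
) -> PredictionResult:
    """Joint-model prediction ignoring the relapse history (prior frailty)."""
    n_nodes = rule.n_nodes if rule is not None else 128
    if rule is not None and not np.isclose(rule.theta, params.theta):
        raise ValueError("quadrature rule was built for a different theta")
    _, lam_s, lam_sw = _joint_cumulatives(params, request)
    prob = _ratio_prediction(params.theta, params.alpha, 0.0, 0.0, lam_s, lam_sw, n_nodes)
    return PredictionResult(prob, "ign", request.s, request.w)


def predict_lm(request: PredictionRequest, fit: LandmarkFit) -> PredictionResult:
    """Landmark Cox prediction; request.s must equal the fit's landmark time."""
    if not np.isclose(request.s, fit.landmark_time):
        raise ValueError(
            f"landmark fit is for s={fit.landmark_time}, request has s={request.s}"
        )
    z = np.concatenate(
        [design_row(request.covariates), relapse_count_indicators(request.n_relapses)]
    )
    lam_s = float(fit.cumulative_hazard(request.s, z)[0])  # 0 by construction
    lam_sw = float(fit.cumulative_hazard(request.s + request.w, z)[0])
    prob = 1.0 - np.exp(-(lam_sw - lam_s))
    return PredictionResult(float(prob), "lm", request.s, request.w)
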