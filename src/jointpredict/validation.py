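"""External-validation layer: IPCW Brier score, explained variation, calibration.

The prediction error at (s, w) is a censoring-weighted Brier score over
the N_s subjects alive and uncensored at s:

    Err = (1/N_s) sum_i [I(T_i > s+w) - (1 - P_i)]^2 * h_i

with inverse-probability-of-censoring weights built from the reverse
Kaplan-Meier estimate G of the censoring survival:

    h_i = I(T_i <= s+w) d_i / (G(T_i-)/G(s)) + I(T_i > s+w) / (G(s+w)/G(s)).

Subjects censored alive inside the window get weight 0.  Explained
variation compares Err with the error of the covariate-free conditional
Kaplan-Meier prediction: R^2 = 1 - Err / Err_KM.

Calibration groups predicted risks by deciles and compares each group's
mean predicted risk with the observed death proportion in (s, s+w],
estimated by a conditional Kaplan-Meier inside the group (the raw
proportion when nothing is censored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort

__all__ = [
    "CensoringEstimate",
    "BrierResult",
    "CalibrationTable",
    "censoring_km",
    "survival_km",
    "ipcw_weight",
    "ipcw_weights",
    "brier_error",
    "km_conditional_death",
    "km_reference_error",
    "r_squared",
    "prediction_error_curve",
    "calibration_table",
]


@dataclass(frozen=True)
class CensoringEstimate:
    """Right-continuous step estimate of the censoring survival G(t)."""

    step_times: np.ndarray
    step_values: np.ndarray

    def __call__(self, t) -> np.ndarray:
        """G(t), right-continuous."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.step_times, t, side="right") - 1
        vals = np.concatenate([[1.0], self.step_values])
        return vals[idx + 1]

    def left_limit(self, t) -> np.ndarray:
        """G(t-)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.step_times, t, side="left") - 1
        vals = np.concatenate([[1.0], self.step_values])
        return vals[idx + 1]


def _km_step(times: np.ndarray, events: np.ndarray) -> CensoringEstimate:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    v = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return CensoringEstimate(t[keep], v[keep])


def censoring_km(cohort_or_times, death=None) -> CensoringEstimate:
    """Reverse Kaplan-Meier: event = censoring, deaths censor the process.

    Ties between death and censoring times are handled by the standard
    convention that deaths precede censorings at the same instant.
    """
    if isinstance(cohort_or_times, Cohort):
        T = np.array([s.followup_time for s in cohort_or_times])
        d = np.array([s.death_indicator for s in cohort_or_times])
    else:
        T = np.asarray(cohort_or_times, dtype=float)
        d = np.asarray(death, dtype=int)
    return _km_step(T, 1 - d)


def survival_km(cohort_or_times, death=None) -> CensoringEstimate:
    """Plain Kaplan-Meier estimate of the death survival function."""
    if isinstance(cohort_or_times, Cohort):
        T = np.array([s.followup_time for s in cohort_or_times])
        d = np.array([s.death_indicator for s in cohort_or_times])
    else:
        T = np.asarray(cohort_or_times, dtype=float)
        d = np.asarray(death, dtype=int)
    return _km_step(T, d)


def ipcw_weight(T: float, delta: int, s: float, w: float, G: CensoringEstimate) -> float:
    """IPCW weight of one evaluated subject (must satisfy T > s)."""
    return float(ipcw_weights(np.array([T]), np.array([delta]), s, w, G)[0])


def ipcw_weights(T, delta, s, w, G: CensoringEstimate) -> np.ndarray:
    """Vectorized IPCW weights; deaths use G(T-), survivors G(s+w)."""
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if np.any(T <= s):
        raise ValueError("IPCW weights are defined only for subjects with T > s")
    gs = float(G(s))
    out = np.zeros(len(T))
    dead_in = (T <= s + w) & (delta == 1)
    if np.any(dead_in):
        gt = G.left_limit(T[dead_in])
        if np.any(gt <= 0):
            t_bad = T[dead_in][gt <= 0].min()
            raise ZeroDivisionError(
                f"censoring survival is 0 at t={t_bad}: IPCW positivity violated"
            )
        out[dead_in] = gs / gt
    past = T > s + w
    if np.any(past):
        gsw = float(G(s + w))
        if gsw <= 0:
            raise ZeroDivisionError(
                f"censoring survival is 0 at t={s + w}: IPCW positivity violated"
            )
        out[past] = gs / gsw
    return out


@dataclass(frozen=True)
class BrierResult:
    s: float
    w: float
    n_eval: int
    error: float
    reference_error: float = np.nan
    r_squared: float = np.nan
    setting: str = ""


def brier_error(predictions, T, delta, s: float, w: float, G: CensoringEstimate) -> float:
    """IPCW Brier score over the at-risk set (all inputs restricted to T > s)."""
    P = np.asarray(predictions, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=int)
    h = ipcw_weights(T, delta, s, w, G)
    surv_status = (T > s + w).astype(float)
    return float(np.mean((surv_status - (1.0 - P)) ** 2 * h))


def km_conditional_death(T, delta, s: float, w: float) -> float:
    """Covariate-free death probability in (s, s+w] from the overall KM."""
    S = survival_km(np.asarray(T, float), np.asarray(delta, int))
    ss = float(S(s))
    if ss <= 0:
        raise ZeroDivisionError(f"Kaplan-Meier survival is 0 at s={s}")
    return float(1.0 - S(s + w) / ss)


def km_reference_error(cohort_or_times, death, s: float, w: float, G: CensoringEstimate) -> float:
    """Brier error of the Kaplan-Meier prediction (same value for everyone)."""
    if isinstance(cohort_or_times, Cohort):
        T = np.array([subj.followup_time for subj in cohort_or_times])
        d = np.array([subj.death_indicator for subj in cohort_or_times])
    else:
        T = np.asarray(cohort_or_times, dtype=float)
        d = np.asarray(death, dtype=int)
    p_km = km_conditional_death(T, d, s, w)
    at_risk = T > s
    return brier_error(np.full(at_risk.sum(), p_km), T[at_risk], d[at_risk], s, w, G)


def r_squared(err: float, err_km: float) -> float:
    """Explained residual variation 1 - Err / Err_KM (NaN when Err_KM = 0)."""
    if err_km == 0:
        warnings.warn("reference error is 0: R^2 undefined", stacklevel=2)
        return np.nan
    return 1.0 - err / err_km


def prediction_error_curve(
    cohort: Cohort,
    predictor: Callable,
    grid: Sequence[tuple[float, float]],
    setting: str = "",
) -> list[BrierResult]:
    """Brier/R^2 at each (s, w) of the grid.

    ``predictor(subject, s, w) -> probability``; for the landmark setting
    pass a closure that refits (or looks up) the s-specific model.  Points
    with an empty at-risk set are skipped with a warning.
    """
    T = np.array([subj.followup_time for subj in cohort])
    d = np.array([subj.death_indicator for subj in cohort])
    G = censoring_km(cohort)
    results = []
    for s, w in grid:
        at_risk = [subj for subj in cohort if subj.followup_time > s]
        if not at_risk:
            warnings.warn(f"empty at-risk set at s={s}: point skipped", stacklevel=2)
            continue
        P = np.array([predictor(subj, s, w) for subj in at_risk])
        Ts = np.array([subj.followup_time for subj in at_risk])
        ds = np.array([subj.death_indicator for subj in at_risk])
        err = brier_error(P, Ts, ds, s, w, G)
        err_km = km_reference_error(T, d, s, w, G)
        results.append(
            BrierResult(s, w, len(at_risk), err, err_km, r_squared(err, err_km), setting)
        )
    return results


@dataclass
class CalibrationTable:
    """Decile-grouped observed vs predicted risks plus histogram counts."""

    mean_predicted: np.ndarray
    observed: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    counts: np.ndarray
    histogram_edges: np.ndarray = field(default_factory=lambda: np.arange(0, 1.05, 0.05))
    histogram_counts: np.ndarray = field(default_factory=lambda: np.zeros(20, dtype=int))
    s: float = 0.0
    w: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_predicted": self.mean_predicted,
                "observed": self.observed,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n": self.counts,
            }
        )


def _observed_death_ci(T, delta, s, w):
    """Observed P(death in (s, s+w]) with 95% CI inside one decile.

    Conditional Kaplan-Meier handles censoring; when no subject is
    censored inside the window this reduces to the raw proportion with a
    Wilson interval.
    """
    T = np.asarray(T, float)
    delta = np.asarray(delta, int)
    n = len(T)
    censored_in = np.any((delta == 0) & (T <= s + w))
    if not censored_in:
        k = int(np.sum((T <= s + w) & (delta == 1)))
        phat = k / n
        z = 1.959963984540054
        den = 1 + z * z / n
        centre = (phat + z * z / (2 * n)) / den
        half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / den
        return phat, max(centre - half, 0.0), min(centre + half, 1.0)
    kmf = KaplanMeierFitter()
    kmf.fit(T, delta)
    sf = kmf.survival_function_
    t_steps = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    idx = np.searchsorted(t_steps, s + w, side="right") - 1
    s_sw = surv[idx] if idx >= 0 else 1.0
    idx_s = np.searchsorted(t_steps, s, side="right") - 1
    s_s = surv[idx_s] if idx_s >= 0 else 1.0
    obs = 1.0 - s_sw / s_s
    # Greenwood variance on the conditional survival scale
    ev = kmf.event_table
    tt = ev.index.to_numpy(float)
    mask = (tt > s) & (tt <= s + w) & (ev["observed"].to_numpy() > 0)
    dA = ev["observed"].to_numpy(float)[mask]
    nA = ev["at_risk"].to_numpy(float)[mask]
    gw = np.sum(dA / (nA * np.maximum(nA - dA, 1e-12)))
    se = (s_sw / s_s) * np.sqrt(gw)
    return obs, max(obs - 1.96 * se, 0.0), min(obs + 1.96 * se, 1.0)


def calibration_table(predictions, T, delta, s: float, w: float) -> CalibrationTable:
    """Deciles of predicted risk vs observed event proportion in (s, s+w]."""
    P = np.asarray(predictions, dtype=float)
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if len(P) < 10:
        raise ValueError("need at least 10 subjects for a decile calibration table")
    edges = np.unique(np.quantile(P, np.linspace(0, 1, 11)))
    if len(edges) < 11:
        warnings.warn(
            "tied predictions collapse some deciles: returning fewer groups",
            stacklevel=2,
        )
    if len(edges) < 2:
        edges = np.array([P.min(), P.max() + 1e-12])
    group = np.clip(np.searchsorted(edges, P, side="right") - 1, 0, len(edges) - 2)
    mean_p, obs, lo, hi, cnt = [], [], [], [], []
    for g in range(len(edges) - 1):
        sel = group == g
        if not np.any(sel):
            continue
        o, a, b = _observed_death_ci(T[sel], delta[sel], s, w)
        mean_p.append(float(P[sel].mean()))
        obs.append(o)
        lo.append(a)
        hi.append(b)
        cnt.append(int(sel.sum()))
    hist_edges = np.arange(0, 1.05, 0.05)
    hist, _ = np.histogram(P, bins=hist_edges)
    return CalibrationTable(
        np.array(mean_p), np.array(obs), np.array(lo), np.array(hi),
        np.array(cnt, dtype=int), hist_edges, hist, s, w,
    )
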