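"""Penalized maximum-likelihood estimation of the joint frailty model.

Model: subject i carries a gamma frailty u_i (mean 1, variance theta).
Conditional on u_i the relapse intensity is ``u_i * lambda_R0(t) *
exp(beta_rec' Z_i)`` on the calendar clock with risk renewal at each
relapse, and the death hazard is ``u_i^alpha * lambda_D0(t) *
exp(beta_death' Z_i)``.  Both baselines are M-spline hazards; the frailty
is integrated out of the likelihood numerically and the spline
coefficients are shrunk by a squared-second-derivative penalty.

Every frailty integral in this package reduces to

    I(p, c, d) = int_0^inf u^p exp(-c u - d u^alpha) g(u; theta) du

which :func:`log_frailty_integral` evaluates in the log domain.  When the
integrand is an exact gamma kernel (d = 0, or alpha in {0, 1} after
folding) the closed form is used; otherwise the integral is computed on
the log-frailty scale, where the exponent is strictly concave, with
Gauss-Hermite nodes centred and scaled at the per-integrand Laplace mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.special import roots_hermite as _roots_hermite


@lru_cache(maxsize=16)
def roots_hermite(n: int):
    return _roots_hermite(n)

from .cohort import Cohort, DESIGN_COLUMNS, Subject, design_matrix, design_row
from .splines import BaselineHazard, SplineBasis

__all__ = [
    "QuadratureRule",
    "JointParams",
    "FitConfig",
    "gamma_frailty_density",
    "log_frailty_integral",
    "subject_conditional_loglik",
    "marginal_loglik",
    "fit_joint_model",
    "lcv",
    "posterior_frailty_mean",
]

_THETA_FLOOR = 1e-8


def gamma_frailty_density(u, theta: float):
    """Density of the mean-one gamma frailty, variance theta.

    ``g(u) = u^{1/theta-1} exp(-u/theta) / (theta^{1/theta} Gamma(1/theta))``
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("frailty values must be > 0")
    inv = 1.0 / theta
    logg = (inv - 1.0) * np.log(u) - u * inv - inv * np.log(theta) - gammaln(inv)
    return np.exp(logg)


def log_frailty_integral(theta, p, c, d, alpha, n_nodes: int = 128,
                         exact_gamma: bool = True):
    """log of  int u^p exp(-c*u - d*u^alpha) g(u; theta) du, elementwise.

    p, c, d broadcast to a common shape; c, d >= 0.  Gamma-kernel cases
    (alpha in {0, 1}, or d = 0) are closed-form when ``exact_gamma``; the
    rest use mode-adapted Gauss-Hermite on v = log u.  ``exact_gamma=False``
    forces the quadrature path everywhere — the optimizer uses it so the
    objective stays smooth in alpha across the special values.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    p, c, d = np.broadcast_arrays(
        np.asarray(p, dtype=float), np.asarray(c, dtype=float), np.asarray(d, dtype=float)
    )
    p = p.copy()
    c = c.copy()
    d = d.copy()
    extra = np.zeros_like(p)
    if alpha == 0.0:
        # u^0 = 1 exactly: fold e^{-d} out (continuous in alpha, keep always)
        extra -= d
        d = np.zeros_like(d)
    elif alpha == 1.0 and exact_gamma:
        c = c + d
        d = np.zeros_like(d)

    inv = 1.0 / theta
    shape = inv + p
    rate = inv + c
    base = -inv * np.log(theta) - gammaln(inv)
    out = np.empty_like(p)

    exact = d == 0.0
    if np.any(exact):
        out[exact] = (
            gammaln(shape[exact]) - shape[exact] * np.log(rate[exact]) + base + extra[exact]
        )
    rest = ~exact
    if np.any(rest):
        s, r, dd = shape[rest], rate[rest], d[rest]
        # mode of H(v) = s v - r e^v - d e^{alpha v}; H' strictly decreasing
        v = np.log(s / r)
        for _ in range(100):
            ev = np.exp(v)
            eav = np.exp(alpha * v)
            g1 = s - r * ev - dd * alpha * eav
            g2 = -r * ev - dd * alpha * alpha * eav
            step = g1 / g2
            v = v - np.clip(step, -2.0, 2.0)
            if np.max(np.abs(step)) < 1e-13:
                break
        sig = 1.0 / np.sqrt(r * np.exp(v) + dd * alpha * alpha * np.exp(alpha * v))
        z, w = roots_hermite(n_nodes)
        vk = v[..., None] + np.sqrt(2.0) * sig[..., None] * z
        H = s[..., None] * vk - r[..., None] * np.exp(vk) - dd[..., None] * np.exp(alpha * vk)
        ex = np.log(w) + z * z + H
        m = ex.max(axis=-1)
        out[rest] = (
            m
            + np.log(np.sum(np.exp(ex - m[..., None]), axis=-1))
            + np.log(np.sqrt(2.0) * sig)
            + base
            + extra[rest]
        )
    return out


@dataclass(frozen=True)
class QuadratureRule:
    """Fixed nodes/log-weights approximating ``int f(u) g(u; theta) du``.

    Built by Gauss-Hermite on the log-frailty scale centred at the mode of
    the gamma density.  The adaptive integrator above re-centres per
    integrand; this fixed rule is what gets passed around the public API
    and pins the node count.
    """

    theta: float
    n_nodes: int = 128
    nodes: np.ndarray = field(init=False, repr=False)
    log_weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        inv = 1.0 / self.theta
        if inv <= 150.0:
            # generalized Gauss-Laguerre on x = u/theta: exact for the
            # gamma weight, so the rule integrates 1, u, u^2 ... exactly
            from scipy.special import roots_genlaguerre

            x, w = roots_genlaguerre(self.n_nodes, inv - 1.0)
            nodes = self.theta * x
            logw = np.log(w) - gammaln(inv)
        else:
            # near-degenerate frailty: log-normal-matched Gauss-Hermite
            z, w = roots_hermite(self.n_nodes)
            sig = 1.0 / np.sqrt(inv)
            vk = np.sqrt(2.0) * sig * z
            logg_v = inv * vk - inv * np.exp(vk) - inv * np.log(self.theta) - gammaln(inv)
            logw = np.log(w) + z * z + logg_v + 0.5 * np.log(2.0) + np.log(sig)
            nodes = np.exp(vk)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "log_weights", logw)

    def integrate(self, f) -> float:
        """int f(u) g(u) du for a vectorized f."""
        vals = np.log(np.maximum(f(self.nodes), 0.0)) + self.log_weights
        m = vals.max()
        return float(np.exp(m) * np.sum(np.exp(vals - m)))


@dataclass
class FitConfig:
    """Knobs of the penalized joint fit."""

    n_knots: int = 7  # basis functions per hazard
    kappa_rec: float = 1.0
    kappa_death: float = 1.0
    n_nodes: int = 32  # quadrature nodes inside the optimizer
    init: str = "auto"  # "auto": moment-based; or "zero"
    max_iter: int = 600
    ftol: float = 1e-9
    gtol: float = 1e-5
    fix_alpha: Optional[float] = None
    fix_theta: Optional[float] = None
    compute_se: bool = True
    shared_knots: bool = True


@dataclass
class JointParams:
    """Fitted (or true) joint-model parameter vector xi."""

    hazard_rec: BaselineHazard
    hazard_death: BaselineHazard
    beta_rec: np.ndarray
    beta_death: np.ndarray
    alpha: float
    theta: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    penalized_loglik: float = np.nan
    loglik: float = np.nan
    kappa_rec: float = 0.0
    kappa_death: float = 0.0
    n_subjects: int = 0

    def __post_init__(self):
        self.beta_rec = np.asarray(self.beta_rec, dtype=float)
        self.beta_death = np.asarray(self.beta_death, dtype=float)
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    def to_dict(self) -> dict:
        return {
            "hazard_rec": self.hazard_rec.to_dict(),
            "hazard_death": self.hazard_death.to_dict(),
            "beta_rec": self.beta_rec.tolist(),
            "beta_death": self.beta_death.tolist(),
            "alpha": self.alpha,
            "theta": self.theta,
            "se": {k: (list(v) if np.ndim(v) else v) for k, v in self.se.items()},
            "converged": self.converged,
            "penalized_loglik": self.penalized_loglik,
            "loglik": self.loglik,
            "kappa_rec": self.kappa_rec,
            "kappa_death": self.kappa_death,
            "n_subjects": self.n_subjects,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointParams":
        return cls(
            BaselineHazard.from_dict(d["hazard_rec"]),
            BaselineHazard.from_dict(d["hazard_death"]),
            np.asarray(d["beta_rec"]),
            np.asarray(d["beta_death"]),
            d["alpha"],
            d["theta"],
            se={k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.get("se", {}).items()},
            converged=d.get("converged", True),
            penalized_loglik=d.get("penalized_loglik", np.nan),
            loglik=d.get("loglik", np.nan),
            kappa_rec=d.get("kappa_rec", 0.0),
            kappa_death=d.get("kappa_death", 0.0),
            n_subjects=d.get("n_subjects", 0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "JointParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------

def _subject_pieces(subject: Subject, params: JointParams):
    """(N, A, LamR, delta, B, LamD): covariate-scaled event/exposure terms."""
    z = design_row(subject.covariates)
    lp_r = float(np.dot(params.beta_rec, z))
    lp_d = float(np.dot(params.beta_death, z))
    times = np.asarray(subject.relapse_times)
    N = len(times)
    if N:
        lam = params.hazard_rec.hazard(times)
        with np.errstate(divide="ignore"):
            A = float(np.sum(np.log(lam))) + N * lp_r
    else:
        A = 0.0
    T = subject.followup_time
    LamR = float(params.hazard_rec.cumulative(T)[0]) * np.exp(lp_r)
    delta = subject.death_indicator
    if delta:
        lamD = float(params.hazard_death.hazard(T)[0])
        with np.errstate(divide="ignore"):
            B = float(np.log(lamD)) + lp_d
    else:
        B = 0.0
    LamD = float(params.hazard_death.cumulative(T)[0]) * np.exp(lp_d)
    return N, A, LamR, delta, B, LamD


def subject_conditional_loglik(subject: Subject, params: JointParams, u: float) -> float:
    """Log-likelihood contribution conditional on the frailty value u.

    ``sum_j log(u lam_R(X_ij)) - u Lam_R(T) + delta (alpha log u + log
    lam_D(T)) - u^alpha Lam_D(T)`` with covariate-scaled hazards.
    """
    if u <= 0:
        raise ValueError("u must be > 0")
    N, A, LamR, delta, B, LamD = _subject_pieces(subject, params)
    return (
        N * np.log(u)
        + A
        - u * LamR
        + delta * (params.alpha * np.log(u) + B)
        - u**params.alpha * LamD
    )


def marginal_loglik(
    cohort: Cohort, params: JointParams, rule: QuadratureRule | None = None
) -> float:
    """Sum over subjects of log int exp(conditional loglik) g(u) du."""
    n_nodes = rule.n_nodes if rule is not None else 128
    if rule is not None and not np.isclose(rule.theta, params.theta):
        raise ValueError("quadrature rule was built for a different theta")
    pieces = [_subject_pieces(s, params) for s in cohort]
    N = np.array([p[0] for p in pieces], dtype=float)
    A = np.array([p[1] for p in pieces])
    LamR = np.array([p[2] for p in pieces])
    delta = np.array([p[3] for p in pieces], dtype=float)
    B = np.array([p[4] for p in pieces])
    LamD = np.array([p[5] for p in pieces])
    if not np.all(np.isfinite(A + delta * B)):
        # baseline hazard is 0 at an observed event time
        import warnings

        bad = [s.id for s, pc in zip(cohort, pieces) if not np.isfinite(pc[1] + pc[3] * pc[4])]
        warnings.warn(f"hazard is 0 at an event time for subjects {bad[:5]}", stacklevel=2)
        return -np.inf
    logints = log_frailty_integral(
        params.theta, N + delta * params.alpha, LamR, LamD, params.alpha, n_nodes
    )
    total = A + delta * B + logints
    if not np.all(np.isfinite(total)):
        bad = [s.id for s, t in zip(cohort, total) if not np.isfinite(t)]
        raise FloatingPointError(f"non-finite marginal likelihood for subjects {bad[:5]}")
    return float(np.sum(total))


def posterior_frailty_mean(subject: Subject, params: JointParams, n_nodes: int = 128) -> float:
    """E[u | observed data] via ratio of frailty integrals."""
    N, A, LamR, delta, B, LamD = _subject_pieces(subject, params)
    p = N + delta * params.alpha
    num = log_frailty_integral(params.theta, p + 1.0, LamR, LamD, params.alpha, n_nodes)
    den = log_frailty_integral(params.theta, p, LamR, LamD, params.alpha, n_nodes)
    return float(np.exp(num - den))


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

class _Likelihood:
    """Vectorized penalized marginal log-likelihood on the working scale.

    Working vector: [psi_R (m), psi_D (m), beta_rec (p), beta_death (p),
    alpha?, log theta?] with eta = psi^2 ensuring hazard positivity.
    """

    def __init__(self, cohort: Cohort, basis_rec: SplineBasis, basis_death: SplineBasis,
                 config: FitConfig):
        self.config = config
        self.basis_rec = basis_rec
        self.basis_death = basis_death
        subjects = list(cohort)
        self.n = len(subjects)
        self.Z = design_matrix(subjects)
        self.pcov = self.Z.shape[1]
        self.N = np.array([s.n_relapses for s in subjects], dtype=float)
        self.delta = np.array([s.death_indicator for s in subjects], dtype=float)
        T = np.array([s.followup_time for s in subjects])
        rel_times = np.concatenate([np.asarray(s.relapse_times) for s in subjects]) if any(
            s.relapse_times for s in subjects
        ) else np.empty(0)
        rel_idx = np.concatenate(
            [np.full(s.n_relapses, i) for i, s in enumerate(subjects)]
        ).astype(int) if rel_times.size else np.empty(0, dtype=int)
        self.rel_idx = rel_idx
        # fixed basis matrices: likelihood evals reduce to linear algebra
        self.M_rel = basis_rec.basis_matrix(rel_times) if rel_times.size else np.empty(
            (0, basis_rec.n_basis)
        )
        self.I_rec = basis_rec.integral_matrix(T)
        died = self.delta == 1
        self.died = died
        self.M_death = basis_death.basis_matrix(T[died])
        self.I_death = basis_death.integral_matrix(T)
        self.P_rec = basis_rec.curvature_gram()
        self.P_death = basis_death.curvature_gram()
        self.mR = basis_rec.n_basis
        self.mD = basis_death.n_basis

    # -- working-vector packing --------------------------------------
    def pack(self, eta_r, eta_d, b1, b2, alpha, theta):
        x = [np.sqrt(eta_r), np.sqrt(eta_d), b1, b2]
        if self.config.fix_alpha is None:
            x.append([alpha])
        if self.config.fix_theta is None:
            x.append([np.log(theta)])
        return np.concatenate(x)

    def unpack(self, x):
        mR, mD, p = self.mR, self.mD, self.pcov
        i = 0
        psi_r = x[i : i + mR]; i += mR
        psi_d = x[i : i + mD]; i += mD
        b1 = x[i : i + p]; i += p
        b2 = x[i : i + p]; i += p
        if self.config.fix_alpha is None:
            alpha = float(x[i]); i += 1
        else:
            alpha = float(self.config.fix_alpha)
        if self.config.fix_theta is None:
            theta = float(np.exp(np.clip(x[i], -50, 50))); i += 1
        else:
            theta = float(self.config.fix_theta)
        return psi_r**2, psi_d**2, b1, b2, alpha, max(theta, _THETA_FLOOR)

    # -- objective ----------------------------------------------------
    def loglik(self, x, penalized=True) -> float:
        eta_r, eta_d, b1, b2, alpha, theta = self.unpack(x)
        lp_r = self.Z @ b1
        lp_d = self.Z @ b2
        lam_rel = self.M_rel @ eta_r
        lamD_ev = self.M_death @ eta_d
        if np.any(lam_rel <= 0) or np.any(lamD_ev <= 0):
            return -np.inf
        A = np.zeros(self.n)
        if lam_rel.size:
            np.add.at(A, self.rel_idx, np.log(lam_rel))
        A += self.N * lp_r
        B = np.zeros(self.n)
        B[self.died] = np.log(lamD_ev)
        B += self.delta * lp_d
        LamR = (self.I_rec @ eta_r) * np.exp(lp_r)
        LamD = (self.I_death @ eta_d) * np.exp(lp_d)
        logints = log_frailty_integral(
            theta, self.N + self.delta * alpha, LamR, LamD, alpha,
            self.config.n_nodes, exact_gamma=False,
        )
        ll = float(np.sum(A + self.delta * B + logints))
        if not np.isfinite(ll):
            return -np.inf
        if penalized:
            ll -= self.config.kappa_rec * float(eta_r @ self.P_rec @ eta_r)
            ll -= self.config.kappa_death * float(eta_d @ self.P_death @ eta_d)
        return ll

    def negloglik(self, x):
        v = self.loglik(x)
        return 1e12 if not np.isfinite(v) else -v


def _constant_eta(basis: SplineBasis, level: float) -> np.ndarray:
    """Coefficients reproducing a constant hazard `level` on the basis."""
    knots = basis.knots
    m = basis.n_basis
    return level * (knots[basis.order :] - knots[:m]) / basis.order


def _finite_diff_hessian(f, x, h=1e-4):
    p = len(x)
    H = np.zeros((p, p))
    f0 = f(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def fit_joint_model(cohort: Cohort, config: FitConfig | None = None) -> JointParams:
    """Penalized maximum-likelihood fit of the joint frailty model.

    Maximizes ``marginal loglik - kappa_R * pen(eta_R) - kappa_D *
    pen(eta_D)`` over spline coefficients (squared transform), covariate
    effects, alpha and log theta with L-BFGS-B.  Standard errors come from
    the finite-difference Hessian of the penalized objective on the
    working scale, mapped by the delta method.
    """
    config = config or FitConfig()
    subjects = list(cohort)
    if not subjects:
        raise ValueError("empty cohort")
    n_rel = sum(s.n_relapses for s in subjects)
    n_death = sum(s.death_indicator for s in subjects)
    if n_rel == 0 or n_death == 0:
        import warnings

        warnings.warn(
            "cohort has no relapse or no death: joint model weakly identified",
            stacklevel=2,
        )
    T = np.array([s.followup_time for s in subjects])
    t_max = float(T.max())
    rel_times = np.concatenate(
        [np.asarray(s.relapse_times) for s in subjects if s.relapse_times]
    ) if n_rel else np.array([t_max / 2])
    death_times = T[np.array([s.death_indicator for s in subjects]) == 1]
    basis_rec = SplineBasis.from_event_times(rel_times, config.n_knots, t_max)
    if config.shared_knots:
        basis_death = basis_rec
    else:
        basis_death = SplineBasis.from_event_times(
            death_times if death_times.size else T, config.n_knots, t_max
        )

    lik = _Likelihood(cohort, basis_rec, basis_death, config)

    # moment-based initialization: event totals / frailty-free exposure
    Z = lik.Z
    exposure = T
    rate_rec = max(n_rel, 1) / float(np.sum(exposure))
    rate_death = max(n_death, 1) / float(np.sum(exposure))
    eta_r0 = np.maximum(_constant_eta(basis_rec, rate_rec), 1e-8)
    eta_d0 = np.maximum(_constant_eta(basis_death, rate_death), 1e-8)
    b0 = np.zeros(lik.pcov)
    alpha0 = config.fix_alpha if config.fix_alpha is not None else 1.0
    theta0 = config.fix_theta if config.fix_theta is not None else 0.5
    x0 = lik.pack(eta_r0, eta_d0, b0, b0, alpha0, theta0)

    res = minimize(
        lik.negloglik,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iter,
            "gtol": config.gtol,
            "ftol": config.ftol,
            "maxcor": 25,
        },
    )
    x = res.x
    eta_r, eta_d, b1, b2, alpha, theta = lik.unpack(x)

    se: dict = {}
    if config.compute_se:
        try:
            H = _finite_diff_hessian(lik.negloglik, x)
            cov = np.linalg.inv(H)
            dvar = np.diag(cov).copy()
            dvar[dvar < 0] = np.nan
            sd = np.sqrt(dvar)
            i = lik.mR + lik.mD
            se["beta_rec"] = sd[i : i + lik.pcov]
            se["beta_death"] = sd[i + lik.pcov : i + 2 * lik.pcov]
            j = i + 2 * lik.pcov
            if config.fix_alpha is None:
                se["alpha"] = float(sd[j]); j += 1
            if config.fix_theta is None:
                se["theta"] = float(sd[j] * theta)  # delta method for log scale
            se["_working_hessian_ok"] = bool(np.all(np.isfinite(sd)))
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular Hessian: standard errors unavailable", stacklevel=2)

    pll = -res.fun
    params = JointParams(
        hazard_rec=BaselineHazard(basis_rec, eta_r),
        hazard_death=BaselineHazard(basis_death, eta_d),
        beta_rec=b1,
        beta_death=b2,
        alpha=alpha,
        theta=theta,
        se=se,
        converged=bool(res.success),
        penalized_loglik=float(pll),
        loglik=float(lik.loglik(x, penalized=False)),
        kappa_rec=config.kappa_rec,
        kappa_death=config.kappa_death,
        n_subjects=len(subjects),
    )
    params._working = x  # kept for LCV's information matrices
    params._likelihood = lik
    return params


def lcv(fit: JointParams, cohort: Cohort | None = None) -> float:
    """Approximate likelihood cross-validation criterion (smaller = better).

    ``(1/n) [trace(H_pen^{-1} H_unpen) - loglik]`` with the observed
    information of the penalized and unpenalized marginal log-likelihoods.
    With zero smoothing the trace equals the parameter count and the
    criterion is AIC-like.
    """
    lik = getattr(fit, "_likelihood", None)
    x = getattr(fit, "_working", None)
    if lik is None or x is None:
        if cohort is None:
            raise ValueError("need the fitting cohort to rebuild the likelihood")
        cfg = FitConfig(kappa_rec=fit.kappa_rec, kappa_death=fit.kappa_death)
        lik = _Likelihood(cohort, fit.hazard_rec.basis, fit.hazard_death.basis, cfg)
        x = lik.pack(
            fit.hazard_rec.eta, fit.hazard_death.eta, fit.beta_rec, fit.beta_death,
            fit.alpha, fit.theta,
        )
    n = lik.n
    H_pen = _finite_diff_hessian(lambda v: -lik.loglik(v, penalized=True), x)
    H_unpen = _finite_diff_hessian(lambda v: -lik.loglik(v, penalized=False), x)
    try:
        tr = float(np.trace(np.linalg.solve(H_pen, H_unpen)))
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular penalized information: LCV undefined", stacklevel=2)
        return np.nan
    return (tr - lik.loglik(x, penalized=False)) / n
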