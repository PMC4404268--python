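"""Shared fixtures: toy subjects, analytic parameter sets, simulated cohorts."""

import numpy as np
import pytest

from jointpredict.cohort import Cohort, Subject
from jointpredict.joint_model import JointParams
from jointpredict.simulate import (
    SimulationConfig,
    TrueParams,
    WeibullHazard,
    simulate_cohort,
)
from jointpredict.splines import BaselineHazard

BASE_COV = dict(age_group="gt55", pvi=0, size_gt20=0, nodal=0, grade="I")


def make_subject(sid="a", relapses=(), followup=10.0, death=0, **cov):
    covariates = {**BASE_COV, **cov}
    return Subject(sid, covariates, tuple(relapses), followup, death)


@pytest.fixture
def base_cov():
    return dict(BASE_COV)


@pytest.fixture
def toy_cohort():
    return Cohort(
        [
            make_subject("a", (2.0, 5.0), 8.0, 1),
            make_subject("b", (), 10.0, 0),
            make_subject("c", (1.5,), 6.0, 1, nodal=1),
        ]
    )


def constant_joint_params(rate_rec=0.1, rate_death=0.08, alpha=1.0, theta=1.0,
                          t_max=30.0, beta_rec=None, beta_death=None):
    """JointParams with exactly constant baselines (M-spline representation)."""
    return JointParams(
        hazard_rec=BaselineHazard.constant(rate_rec, t_max),
        hazard_death=BaselineHazard.constant(rate_death, t_max),
        beta_rec=np.zeros(7) if beta_rec is None else np.asarray(beta_rec),
        beta_death=np.zeros(7) if beta_death is None else np.asarray(beta_death),
        alpha=alpha,
        theta=theta,
    )


@pytest.fixture
def constant_params():
    return constant_joint_params()


def recovery_truth(theta=1.0, alpha=1.0):
    """Simulation truth with nonzero covariate effects for recovery checks."""
    beta = (0.0, 0.0, 0.5, 0.7, 0.6, 0.8, 1.1)
    return TrueParams(
        theta=theta,
        alpha=alpha,
        beta_rec=beta,
        beta_death=beta,
        base_rec=WeibullHazard(1.0, 12.0),
        base_death=WeibullHazard(1.0, 18.0),
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    """Medium cohort from the recovery truth (administrative censoring)."""
    return simulate_cohort(recovery_truth(), SimulationConfig(n_subjects=800, seed=42))
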