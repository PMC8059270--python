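"""Shared fixtures: compact synthetic scenarios with known latent structure."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from trajmix import data_model as dm
from trajmix import synthetic_data as sd

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

AGES5 = (11.0, 16.0, 23.0, 33.0, 42.0)
CENTER = 23.64


def make_cohort(label, n, probs, retention=0.9, ages=AGES5):
    return sd.CohortConfig(
        label=label,
        n_subjects=n,
        target_ages=ages,
        class_probabilities=tuple(probs),
        retention=(retention,) * len(ages),
    )


def linear_classes(intercepts, slopes, intercept_sds, sigma, rho, slope_sd=0.04):
    """Classes with linear mean trajectories (cubic coefficients zeroed)."""
    return tuple(
        sd.ClassTruth(
            beta=(float(b0), float(b1), 0.0, 0.0),
            intercept_sd=float(isd),
            slope_sd=slope_sd,
            int_slope_corr=0.0,
            sigma=tuple(sigma),
            rho=rho,
        )
        for b0, b1, isd in zip(intercepts, slopes, intercept_sds)
    )


def two_class_config(delta, n=400, intercept_sd=1.0, sigma=1.5, rho=0.4, retention=1.0):
    """Two classes separated by ``delta`` kg/m² in intercept, equal slopes."""
    classes = linear_classes(
        intercepts=(22.0, 22.0 + delta),
        slopes=(0.05, 0.05),
        intercept_sds=(intercept_sd, intercept_sd),
        sigma=(sigma,) * 5,
        rho=rho,
    )
    cohorts = (make_cohort("COH", n, (0.5, 0.5), retention=retention),)
    return sd.GeneratorConfig(cohorts=cohorts, classes=classes, centering_age=CENTER)


def three_class_config(n=600):
    """Well-separated 3-class scenario in the final-model structure
    (sweep-heteroskedastic AR(1) residuals, class-specific intercept SD)."""
    classes = linear_classes(
        intercepts=(19.5, 24.5, 30.0),
        slopes=(0.05, 0.14, 0.22),
        intercept_sds=(1.0, 1.2, 1.5),
        sigma=(1.0, 1.2, 1.4, 1.6, 1.8),
        rho=0.5,
    )
    cohorts = (make_cohort("COH", n, (0.5, 0.3, 0.2)),)
    return sd.GeneratorConfig(cohorts=cohorts, classes=classes, centering_age=CENTER)


def simulate_centered(config, seed, min_obs=3):
    ds, truth = sd.simulate(config, seed=seed)
    ds = dm.filter_min_observations(ds, min_obs)
    ds = dm.center_ages(ds, config.centering_age)
    kept = {s.id for s in ds.subjects}
    truth = [t for t in truth if t.id in kept]
    return ds, truth


def true_params(config):
    """ClassParams at the generating truth (pooled mixing proportions)."""
    from trajmix.gmm_core import ClassParams

    tot = sum(c.n_subjects for c in config.cohorts)
    pis = np.zeros(len(config.classes))
    for c in config.cohorts:
        pis += np.array(c.class_probabilities) * c.n_subjects / tot
    return [
        ClassParams(pi=float(pis[k]), beta=np.array(cl.beta), psi=cl.re_cov(),
                    sigma=np.array(cl.sigma), rho=cl.rho)
        for k, cl in enumerate(config.classes)
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """~120 subjects, two moderately separated classes, irregular ages."""
    cfg = two_class_config(delta=5.0, n=120, retention=0.9)
    ds, truth = simulate_centered(cfg, seed=7)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def tiny_raw_dataset():
    """20 subjects, raw (uncentered) ages, for I/O round-trips."""
    cfg = two_class_config(delta=4.0, n=20, retention=0.9)
    ds, _ = sd.simulate(cfg, seed=3)
    return ds
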