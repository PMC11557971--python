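"""Shared fixtures.

The expensive fixtures (whole-cohort MCMC fits) are session-scoped and
shared between the unit tests and the acceptance suite; every fixture is
seeded, so the suite is fully deterministic.
"""

import warnings

import numpy as np
import pytest

import ddmcompare as dc
from ddmcompare.cohort import scanner_trials
from ddmcompare.inference import NonConvergenceWarning

# reduced-but-adequate MCMC used by most fitting tests
FAST_MCMC = dict(samples=2000, burn=1000)


@pytest.fixture(autouse=True)
def _quiet_nonconvergence():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonConvergenceWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _simulate_cohort(true_fraction, task, n, seed, contaminant=0.06):
    rng = np.random.default_rng(seed)
    specs = dc.sample_cohort(n, true_fraction, rng)
    data = {}
    for spec in specs:
        trials = scanner_trials(task, 90, rng)
        data[spec.id] = dc.simulate_behavior(spec, trials, contaminant, rng)
    return specs, data


@pytest.fixture(scope="session")
def attribute_cohort():
    """35 attribute-generated participants, intertemporal scanner task."""
    return _simulate_cohort(1.0, "intertemporal", 35, 2024)


@pytest.fixture(scope="session")
def attribute_cohort_fits(attribute_cohort):
    """Both-model fits for every participant of the attribute cohort."""
    specs, data = attribute_cohort
    rng = np.random.default_rng(77)
    fits = {}
    for spec in specs:
        fits[spec.id] = {
            "attribute": dc.fit_ddm(data[spec.id], "attribute",
                                    seed=int(rng.integers(2**31)), **FAST_MCMC),
            "option": dc.fit_ddm(data[spec.id], "option",
                                 seed=int(rng.integers(2**31)), **FAST_MCMC),
        }
    return fits


@pytest.fixture(scope="session")
def option_cohort():
    """Option-generated cohort (35 participants), interpersonal scanner task.

    The social-distance design identifies the discount rate well (distances
    span 1-100 so k*d covers both tails); in the intertemporal design the
    sigmoid ceiling leaves k weakly identified for many participants (see
    the methods note), so discount-rate recovery is assessed here.
    """
    return _simulate_cohort(0.0, "interpersonal", 35, 502)


@pytest.fixture(scope="session")
def option_cohort_fits(option_cohort):
    specs, data = option_cohort
    rng = np.random.default_rng(88)
    return {spec.id: dc.fit_ddm(data[spec.id], "option", seed=int(rng.integers(2**31)),
                                **FAST_MCMC)
            for spec in specs}


@pytest.fixture(scope="session")
def single_fit(attribute_cohort, attribute_cohort_fits):
    """One converged attribute fit with its spec and records, for PPC tests."""
    specs, data = attribute_cohort
    for spec in specs:
        fit = attribute_cohort_fits[spec.id]["attribute"]
        if fit.converged:
            return spec, data[spec.id], fit
    raise RuntimeError("no converged fit in cohort")
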