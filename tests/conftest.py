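import itertools

import numpy as np
import pandas as pd
import pytest

from gutlink.fsea import CorrelationVector
from gutlink.synth import (CohortSpec, SimulationConfig, generate_cohort,
                           make_catalog)


@pytest.fixture(scope="session")
def small_config():
    """Small two-cohort configuration with one planted gene set, one planted
    species and one planted metabolite."""
    return SimulationConfig(
        seed=11,
        cohorts={
            "A": CohortSpec(n_subjects=80, srs2_intercept=43.6, srs2_noise_sd=4.8),
            "B": CohortSpec(n_subjects=50, srs2_intercept=49.9, srs2_noise_sd=8.5),
        },
        n_species=40,
        n_genefamilies=400,
        n_sets=10,
        set_size=12,
        set_delta={"set_00": 0.4},
        species_beta={"Species_0003": 0.41},
        metabolite_beta={"metabolite_00": 0.86},
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return make_catalog(small_config)


@pytest.fixture(scope="session")
def cohort_a(small_config, small_catalog):
    return generate_cohort(small_config, "A", small_catalog)


@pytest.fixture(scope="session")
def cohort_b(small_config, small_catalog):
    return generate_cohort(small_config, "B", small_catalog)


def corr_vector(values, names=None, measure="score"):
    """Build a CorrelationVector directly from correlation values."""
    names = names or [f"F{i:04d}" for i in range(len(values))]
    table = pd.DataFrame({"r": values, "prevalence": len(values)}, index=names)
    return CorrelationVector(table=table, measure=measure, n=len(values),
                             n_excluded_low_prevalence=0,
                             n_excluded_zero_variance=0)


def brute_force_mwu(r_in, r_out):
    """Exact two-sided Mann-Whitney p by enumerating every group assignment.

    Mirrors the doubled-smaller-tail convention on the enumerated null.
    """
    pooled = np.concatenate([r_in, r_out])
    n1 = len(r_in)
    u_obs = sum((a > b) + 0.5 * (a == b) for a in r_in for b in r_out)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        us.append(sum((a > b) + 0.5 * (a == b) for a in grp for b in rest))
    us = np.asarray(us)
    n_le = np.sum(us <= u_obs + 1e-9)
    n_ge = np.sum(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(n_le, n_ge) / len(us))
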