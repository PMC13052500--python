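import numpy as np
import pytest

import kerapol as kp


@pytest.fixture(scope="session")
def phenotypes():
    return kp.default_phenotypes()


@pytest.fixture(scope="session")
def small_cohort(phenotypes):
    """12/11/13 cohort with the default phenotypes (fast, session-shared)."""
    return kp.generate_cohort(12, 11, 13, 33.0 / 109.0, rng_seed=11)


@pytest.fixture(scope="session")
def separated_phenotypes(phenotypes):
    """Strongly separated variant: wide mean gaps, tiny spreads.

    Used where a pipeline must classify perfectly; group criterion boxes are
    still respected by construction.
    """
    from dataclasses import replace

    def tighten(p, pr_mean):
        idx = {
            dev: {k: (m, s * 0.05) for k, (m, s) in d.items()}
            for dev, d in p.index_means_sds.items()
        }
        return replace(
            p,
            pr_central_mean=pr_mean,
            pr_central_sd=0.3,
            epi_sd=0.2,
            bowman_sd=0.1,
            pr_noise_sd=0.1,
            epi_noise_sd=0.1,
            bowman_noise_sd=0.1,
            index_means_sds=idx,
        )

    return {
        "healthy": tighten(phenotypes["healthy"], 20.0),
        "skc": tighten(phenotypes["skc"], 35.0),
        "kc": tighten(phenotypes["kc"], 55.0),
    }


@pytest.fixture(scope="session")
def separated_cohort(separated_phenotypes):
    return kp.generate_cohort(30, 30, 30, 0.0, rng_seed=5, phenotypes=separated_phenotypes)


@pytest.fixture
def constant_map():
    return kp.CornealMap(np.full((16, 20), 45.0), (0.25, 0.25), "phase_retardation")
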