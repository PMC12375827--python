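import numpy as np
import pytest

from bilicea import (
    CEAContext,
    ModelSettings,
    ParametricFit,
    builtin_configs,
)


@pytest.fixture(scope="session")
def configs():
    return builtin_configs()


@pytest.fixture(scope="session")
def china(configs):
    return configs["China"]


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


def analytic_fits(median_os: float, median_pfs: float) -> dict[str, ParametricFit]:
    """Exponential OS/PFS fits with the given medians (rate = ln2/median)."""
    ln2 = np.log(2.0)
    return {
        "OS": ParametricFit("exponential", (ln2 / median_os,), loglik=0.0,
                            n_obs=100),
        "PFS": ParametricFit("exponential", (ln2 / median_pfs,), loglik=0.0,
                             n_obs=100),
    }


@pytest.fixture(scope="session")
def fast_context(china, settings):
    """A model context with analytic survival curves: experimental medians
    (12.7, 6.5) months vs control (10.9, 5.6), China inputs."""
    return CEAContext(
        exp_fits=analytic_fits(12.7, 6.5),
        ctl_fits=analytic_fits(10.9, 5.6),
        config=china,
        settings=settings,
    )


@pytest.fixture(scope="session")
def pipeline_result():
    """The full end-to-end China run on synthetic data (shared: ~4 s)."""
    from bilicea import builtin_config, run_pipeline

    return run_pipeline(builtin_config("China"), seed=42)
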