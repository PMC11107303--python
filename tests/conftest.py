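import numpy as np
import pytest

from ppe import synthetic, trial_model


@pytest.fixture(scope="session")
def default_cfg():
    return synthetic.default_config()


@pytest.fixture(scope="session")
def default_records(default_cfg):
    """One realization of the default synthetic trial (shared across tests)."""
    return synthetic.generate_trial(default_cfg, seed=1)


@pytest.fixture(scope="session")
def comparisons(default_cfg, default_records):
    return [
        trial_model.build_comparison(spec, default_records)
        for spec in default_cfg.treatments
    ]


@pytest.fixture(scope="session")
def record_index(default_records):
    return {r.id: r for r in default_records}


@pytest.fixture(scope="session")
def null_flat_cfg(default_cfg):
    """Null configuration: calendar drift disabled, flat base rate.

    Under this configuration the matched/nonmatched contrast has true log-OR
    exactly 0 for every comparison, so it is the right reference for
    calibration checks (with drift on, enrollment-time differences between
    groups within a window act as a real confounder of the placebo contrast).
    """
    import dataclasses

    return dataclasses.replace(
        default_cfg,
        generate_pro=False,
        logit_drift=0.0,
        logit_intercept=-2.6,
    )
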