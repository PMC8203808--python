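"""Shared fixtures: small in-memory phantoms and one generated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from neurophantom.phantoms import (PhantomConfig, ParticipantRecord, make_template,
                                   synth_cohort)


@pytest.fixture(scope="session")
def template24():
    """Template, brain mask and ROI mask on a 24^3 grid."""
    return make_template((24, 24, 24), seed=5)


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(
        shape=(24, 24, 24),
        n_internal={"AD": 12, "CN": 12, "MCIc": 5, "MCInc": 5},
        n_external={"AD": 6, "SCD": 6, "MCIc": 4, "MCInc": 4},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, tmp_path_factory):
    """A small written cohort shared by I/O-level tests."""
    out = tmp_path_factory.mktemp("cohort")
    return synth_cohort(small_config, out)


def record(group="AD", icv=1.0, site="site_int", seed=0, cohort="internal", pid=None):
    return ParticipantRecord(
        id=pid or f"{group}-{seed}", group=group, cohort=cohort,
        icv=icv, site=site, seed=seed,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
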