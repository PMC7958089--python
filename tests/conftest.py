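"""Shared fixtures: small simulated cohorts and fitted OA-vector models."""

import numpy as np
import pytest

from bscore.oa_vector import build_oa_vector
from bscore.shapes import mirror_to_reference_side
from bscore.simulate import SimulationConfig, generate_cohort, oa_group_labels


def fit_model_from_cohort(cohort):
    """Mirror lefts, split by observed KLG and fit the OA vector."""
    labels = oa_group_labels(cohort.records)
    shapes = [mirror_to_reference_side(s) for s in cohort.shapes]
    nonoa = [s for s in shapes if labels.get(s.shape_id) == 0]
    oa = [s for s in shapes if labels.get(s.shape_id) == 1]
    return build_oa_vector(nonoa, oa), shapes, nonoa, oa


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort, 80 subjects / 160 knees."""
    return generate_cohort(SimulationConfig(n_subjects=80, seed=11))


@pytest.fixture(scope="session")
def fitted(cohort):
    model, shapes, nonoa, oa = fit_model_from_cohort(cohort)
    return {"model": model, "shapes": shapes, "nonoa": nonoa, "oa": oa,
            "cohort": cohort}


@pytest.fixture(scope="session")
def noiseless_cohort():
    """No measurement noise or individual variation: B-score must be an
    exact affine function of the latent severity."""
    config = SimulationConfig(n_subjects=60, seed=5, noise_sd=0.0,
                              variation_sds=(0.0, 0.0, 0.0))
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
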