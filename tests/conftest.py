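"""Shared fixtures: desk-scale cohorts, phantoms, and one trained model.

The trained-model fixture is session-scoped because three-step training is
the expensive step; every test that needs a trained screening model shares
the same run (seeded, so the suite is reproducible end to end).
"""

import pytest

from padar import (PhantomSpec, SeriesSpec, TrainConfig, generate_cohort,
                   generate_fundus, generate_longitudinal_series,
                   train_three_step)

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_cohort():
    """5 classes x 10 eyes x 4 images at 64 px — the desk study cohort."""
    return generate_cohort({c: 10 for c in ("HC", "AMD", "DR", "CM", "PM")},
                           images_per_eye=4, seed=DESK_SEED, image_size=64)


@pytest.fixture(scope="session")
def desk_split(desk_cohort):
    return desk_cohort.grouped_split(0.2, seed=DESK_SEED)


@pytest.fixture(scope="session")
def trained_desk_model(desk_cohort, desk_split):
    train_idx, _ = desk_split
    model, log = train_three_step(desk_cohort, TrainConfig.desk(seed=DESK_SEED),
                                  train_idx=train_idx)
    return model, log


@pytest.fixture(scope="session")
def amd_phantom_512():
    return generate_fundus(PhantomSpec(image_size=512, disease_class="AMD",
                                       rng_seed=3))


@pytest.fixture(scope="session")
def registered_pair_512():
    """Two timepoints of one AMD eye, linked by a known affine motion."""
    spec = PhantomSpec(image_size=512, disease_class="AMD", rng_seed=3)
    series = SeriesSpec(n_timepoints=2, rotation_deg=15, translation_frac=0.08,
                        scale_range=(0.95, 1.05), rng_seed=7)
    return generate_longitudinal_series(spec, series)
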