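"""Shared fixtures: synthetic fixtures and trained models.

Model training is expensive relative to the rest of the suite, so trained
estimators are session-scoped and shared; tests never mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from multicellseg import CascadePatchClassifier, MultiCellSeg
from multicellseg.synth import SynthParams, generate_wound_image


WOUND_PARAMS = SynthParams(image_size=(200, 200), wound_area_fraction=0.35)


@pytest.fixture(scope="session")
def wound_params() -> SynthParams:
    return WOUND_PARAMS


#: training images span healing stages from near-closed to wide-open wounds,
#: as a manually tagged training set drawn across an assay would
TRAIN_FRACTIONS = (0.08, 0.15, 0.25, 0.35, 0.45)


@pytest.fixture(scope="session")
def training_pairs():
    """Five training fixtures with distinct seeds and wound stages."""
    return [generate_wound_image(WOUND_PARAMS.replace(rng_seed=i,
                                                      wound_area_fraction=f))
            for i, f in enumerate(TRAIN_FRACTIONS)]


@pytest.fixture(scope="session")
def test_pairs():
    """Twenty fresh evaluation fixtures at varied wound fractions."""
    return [generate_wound_image(WOUND_PARAMS.replace(
        rng_seed=1000 + i, wound_area_fraction=0.12 + 0.015 * i))
        for i in range(20)]


@pytest.fixture(scope="session")
def trained_pipeline(training_pairs) -> MultiCellSeg:
    model = MultiCellSeg(random_state=0)
    return model.fit([p.image for p in training_pairs],
                     [p.mask for p in training_pairs])


@pytest.fixture(scope="session")
def trained_cascade(trained_pipeline) -> CascadePatchClassifier:
    return trained_pipeline.cascade_


@pytest.fixture(scope="session")
def single_pair(test_pairs):
    return test_pairs[5]
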