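"""Shared fixtures.

The heavyweight desk experiments (segmenter training, CAE training, fusion
training) are session-scoped so that every test inspecting their outcome
shares one seeded run.
"""

from __future__ import annotations

import numpy as np
import pytest

from sinusct.phantoms import PhantomSpec, generate_phantom
from sinusct.pipeline import (desk_anomaly_experiment, desk_fusion_experiment,
                              desk_segmentation_experiment)

PROTOCOL_SEED = 0


@pytest.fixture(scope="session")
def seg_experiment():
    """Desk segmenter: 32 training phantoms (48^3), 8 held out."""
    return desk_segmentation_experiment(PROTOCOL_SEED)


@pytest.fixture(scope="session")
def anomaly_experiment():
    """Desk CAE: trained on 16 normal phantoms, 16 anomalous held out."""
    return desk_anomaly_experiment(PROTOCOL_SEED)


@pytest.fixture(scope="session")
def fusion_experiment(anomaly_experiment):
    """Desk fusion extractor on a 24-phantom cohort plus CAM evaluation."""
    return desk_fusion_experiment(PROTOCOL_SEED,
                                  anomaly_experiment["cae"],
                                  anomaly_experiment["cae_config"])


@pytest.fixture(scope="session")
def clean_phantom():
    """One noiseless, blur-free, anomaly-free phantom at 64^3."""
    return generate_phantom(PhantomSpec(noise_sd_hu=0.0, blur_sigma_vox=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
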