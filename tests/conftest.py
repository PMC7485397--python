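import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_disc_patches  # noqa: E402

from swe_radiomics.features import (CNNFeatureExtractor, NetworkConfig,  # noqa: E402
                                    TrainingConfig)
from swe_radiomics.synthetic import CohortSpec, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """8 benign + 8 malignant desk-scale cases, fixed seed."""
    return generate_cohort(CohortSpec(n_benign=8, n_malignant=8, seed=7))


@pytest.fixture(scope="session")
def disc_patches():
    return make_disc_patches()


@pytest.fixture(scope="session")
def toy_extractor(disc_patches):
    """CNN trained on the separable toy problem (shared across tests)."""
    X, y = disc_patches
    model = CNNFeatureExtractor(
        net_config=NetworkConfig(input_size=X.shape[1:]),
        train_config=TrainingConfig(epochs=8, seed=0),
    )
    return model.fit(X, y)
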