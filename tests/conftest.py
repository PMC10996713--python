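"""Shared fixtures: synthetic cohorts and trained models reused across tests.

Heavy artifacts (the planted-effect recovery fit) are session-scoped so the
expensive training run happens once.
"""

import numpy as np
import pytest

from demiform.model import DementiaTransformer, ModelConfig
from demiform.simulate import (
    SyntheticConfig,
    default_schema,
    generate_cohort,
    planted_effect_matrix,
    split_cohort,
)
from demiform.training import TrainConfig


@pytest.fixture(scope="session")
def strong_cohort():
    """n=2000 mixed cohort with strong planted effects (shift = 2 sd on 6
    features per label) plus person-level splits."""
    schema = default_schema(n_numerical=16, n_categorical=4)
    E = planted_effect_matrix(schema, shift=2.0, features_per_label=6, seed=11)
    cfg = SyntheticConfig(n=2000, effect_matrix=E, seed=11)
    cohort = generate_cohort(cfg, schema)
    train, val, test = split_cohort(cohort, (0.7, 0.15, 0.15), seed=11)
    return {
        "schema": schema,
        "effects": E,
        "config": cfg,
        "cohort": cohort,
        "train": train,
        "val": val,
        "test": test,
    }


@pytest.fixture(scope="session")
def recovery_fit(strong_cohort):
    """Small transformer trained until the validation weighted AUROC clears
    0.9 (or 200 epochs); the parameter-recovery experiment."""
    model = DementiaTransformer(
        strong_cohort["train"],
        config=ModelConfig(d_model=32, n_layers=2, n_heads=4, d_ff=128, seed=0),
    )
    result = model.fit(
        val_cohort=strong_cohort["val"],
        train_config=TrainConfig(epochs=200, batch_size=128, seed=0, stop_threshold=0.9),
    )
    return result


@pytest.fixture(scope="session")
def tiny_untrained_model():
    """Fresh small model over a tiny cohort, for structural checks."""
    schema = default_schema(n_numerical=6, n_categorical=2)
    E = planted_effect_matrix(schema, shift=1.5, features_per_label=3, seed=5)
    cohort = generate_cohort(SyntheticConfig(n=120, effect_matrix=E, seed=5), schema)
    model = DementiaTransformer(
        cohort, config=ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=32, seed=1)
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
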