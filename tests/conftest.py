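"""Shared fixtures: synthetic corpora and trained reference models.

The expensive session fixtures (one trained reference model; the three
bias-ensemble runs) are built once and shared across test modules; their
problem sizes are the package's desk-scale defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

from rxnlens.bias import BiasRunConfig, run_bias_experiment
from rxnlens.fc_data import PRESETS, build_datasets
from rxnlens.model import ReferenceModelConfig, train_reference_model
from rxnlens.reaction_io import source_string, tokenize_smiles


def token_pairs(labeled):
    """(source tokens, target tokens) pairs from labeled FC reactions."""
    return [
        (
            list(tokenize_smiles(source_string(r.record)).tokens),
            list(tokenize_smiles(r.record.products[0]).tokens),
        )
        for r in labeled
    ]


@pytest.fixture(scope="session")
def balanced_data():
    """(train, test) labeled corpora of the balanced FC condition."""
    return build_datasets(PRESETS["balanced"])


# the reference training setup: reaches >=0.9 held-out exact match on the
# balanced corpus in a few CPU-minutes
REFERENCE_CONFIG = ReferenceModelConfig(
    d_model=64, n_layers=1, n_heads=2, d_ff=128,
    epochs=60, batch_size=192, seed=1,
    learning_rate=2e-3, lr_decay=0.98, dtype="float64",
)


@pytest.fixture(scope="session")
def balanced_split(balanced_data):
    """Shuffled (train pairs, held-out pairs) from the balanced corpus."""
    train, _ = balanced_data
    pairs = token_pairs(train)
    order = np.random.default_rng(0).permutation(len(pairs))
    held = [pairs[i] for i in order[:50]]
    rest = [pairs[i] for i in order[50:]]
    return rest, held


@pytest.fixture(scope="session")
def trained_model(balanced_split):
    """The shared reference model trained on the balanced FC corpus."""
    rest, _ = balanced_split
    return train_reference_model(rest, REFERENCE_CONFIG)


# per-corpus ensemble setups for the bias-recovery experiment; epochs scale
# roughly inversely with corpus size so members see comparable step budgets
BIAS_ENSEMBLE_SETUPS = {
    "balanced": dict(epochs=45),
    "biased": dict(epochs=70),
    "severe": dict(epochs=40),
}
BIAS_ENSEMBLE_SEEDS = (0, 1, 2, 3)


@pytest.fixture(scope="session")
def bias_curves():
    """Final-checkpoint proportion curves for the three bias conditions."""
    curves = {}
    for name, setup in BIAS_ENSEMBLE_SETUPS.items():
        train, test = build_datasets(PRESETS[name])
        model_config = ReferenceModelConfig(
            d_model=48, n_layers=1, n_heads=2, d_ff=96,
            batch_size=128, learning_rate=2.5e-3, lr_decay=0.99,
            dtype="float32", epochs=setup["epochs"],
        )
        config = BiasRunConfig(
            dataset_name=name,
            model_config=model_config,
            seeds=BIAS_ENSEMBLE_SEEDS,
            eval_every=setup["epochs"],
        )
        curves[name] = run_bias_experiment(config, train, test)
    return curves
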