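"""The regioselectivity bias-recovery experiment.

Train an ensemble of randomly initialized reference models on each of the
synthetic Friedel–Crafts corpora (Balanced 1:1, Biased 9:1, Severely
Biased 100:1 para:meta) and track, as training progresses, the proportion
of para / meta / other / invalid predictions the models make on the fixed
balanced test set.  A model trained on balanced data converges to
predicting para and meta in equal measure; the more biased the corpus,
the smaller the meta fraction at convergence — predictions mirror dataset
statistics rather than chemistry (the Clever Hans failure mode this
benchmark exists to expose).

Fractions use the full test set as denominator, with ``invalid`` (decoded
strings that are not parseable SMILES) and ``other`` (parseable but not a
para/meta/ortho acylation of the directing ring) counted separately, so
para + meta + other + invalid = 1 per model and checkpoint while the
para/meta curves alone need not sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fc_data import LabeledReaction, classify_orientation, PARA_BENZYLS, META_BENZYLS
from .model import ReferenceModelConfig, TransformerPredictor, train_reference_model
from .reaction_io import source_string, tokenize_smiles

__all__ = [
    "BiasRunConfig",
    "ProportionCurve",
    "eval_proportions",
    "run_bias_experiment",
]

_BENZYL_SMILES = {**PARA_BENZYLS, **META_BENZYLS}


@dataclass
class BiasRunConfig:
    """One ensemble run: which corpus, how many members, when to evaluate.

    ``augment`` doubles the training corpus with random-equivalent SMILES
    spellings before training (the standard augmentation protocol for
    SMILES seq2seq models); it markedly improves validity and length
    generalization on the held-out test chains.
    """

    dataset_name: str
    model_config: ReferenceModelConfig
    seeds: tuple[int, ...] = (0, 1, 2, 3)
    eval_every: int = 10
    augment: bool = True
    augment_seed: int = 1000003

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one ensemble seed is required")
        if self.eval_every < 1 or self.eval_every > self.model_config.epochs:
            raise ValueError("eval_every must be in [1, epochs]")

    @property
    def ensemble_size(self) -> int:
        return len(self.seeds)


@dataclass
class ProportionCurve:
    """Ensemble mean/std of prediction proportions per checkpoint."""

    dataset_name: str
    frame: pd.DataFrame  # columns: epoch, para_mean, para_std, meta_mean,
    #                      meta_std, invalid_mean, other_mean

    def final(self) -> pd.Series:
        return self.frame.iloc[-1]


def eval_proportions(model: TransformerPredictor, test: list[LabeledReaction]) -> dict:
    """Greedy-decode every test source and classify the predictions.

    Returns fractions over all test reactions; the four categories sum
    to 1 exactly.  Decodes that hit the length cap count as invalid.
    """
    if not test:
        raise ValueError("empty test set")
    sources = [tokenize_smiles(source_string(r.record)).tokens for r in test]
    decodes = model.greedy_decode_batch(sources)
    tally = {"para": 0, "meta": 0, "other": 0, "invalid": 0}
    for rxn, out in zip(test, decodes):
        if not out.complete:
            cat = "invalid"
        else:
            cat = classify_orientation(out.smiles, _BENZYL_SMILES[rxn.benzyl_id])
            if cat == "ortho":
                cat = "other"
        tally[cat] += 1
    n = len(test)
    return {k: v / n for k, v in tally.items()}


def run_bias_experiment(
    config: BiasRunConfig,
    train: list[LabeledReaction],
    test: list[LabeledReaction],
) -> ProportionCurve:
    """Train the ensemble and record proportion curves.

    Every member trains on the same corpus with its own seed; evaluation
    happens every ``eval_every`` epochs and at the final epoch.  Members
    whose training raises are recorded as failures and the curve is
    computed over the survivors (with a warning).
    """
    records = [r.record for r in train]
    if config.augment:
        from .model import augment_records

        records = augment_records(records, seed=config.augment_seed)
    pairs = [
        (
            list(tokenize_smiles(source_string(r)).tokens),
            list(tokenize_smiles(".".join(r.products)).tokens),
        )
        for r in records
    ]
    epochs = config.model_config.epochs
    eval_epochs = sorted(
        set(range(config.eval_every, epochs + 1, config.eval_every)) | {epochs}
    )
    per_member: list[dict[int, dict]] = []
    for seed in config.seeds:
        member_cfg = replace(config.model_config, seed=seed)
        history: dict[int, dict] = {}

        def record(epoch, model, history=history):
            if epoch in eval_epochs:
                history[epoch] = eval_proportions(model, test)

        try:
            train_reference_model(pairs, member_cfg, epoch_callback=record)
        except FloatingPointError as exc:  # divergence: keep the survivors
            import warnings

            warnings.warn(f"ensemble member seed={seed} diverged: {exc}")
            continue
        per_member.append(history)
    if not per_member:
        raise RuntimeError("every ensemble member failed to train")

    rows = []
    for epoch in eval_epochs:
        stats = {"epoch": epoch}
        for key in ("para", "meta", "invalid", "other"):
            vals = np.array([h[epoch][key] for h in per_member])
            stats[f"{key}_mean"] = vals.mean()
            if key in ("para", "meta"):
                stats[f"{key}_std"] = vals.std(ddof=0)
        rows.append(stats)
    frame = pd.DataFrame(rows)[
        ["epoch", "para_mean", "para_std", "meta_mean", "meta_std",
         "invalid_mean", "other_mean"]
    ]
    return ProportionCurve(dataset_name=config.dataset_name, frame=frame)
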