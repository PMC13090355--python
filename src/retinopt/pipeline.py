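"""End-to-end experiment driver.

Ties the stages together at desk scale: phantom generation (or user
images) → preprocessing → stratified split → IMRFO hyperparameter search,
where each candidate's fitness is the negated validation accuracy of a
short training run → final training with the best configuration → test-set
metric report.  Every stage draws its randomness from the single
experiment seed, so a run is fully reproducible from its config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from .augment import GeoAugParams, NoiseConfig, augment_to_balance
from .evaluation import metric_report, stratified_split
from .imrfo import imrfo_run
from .model import DualStreamSpec, ModelHyperparams, build_model, train_model
from .mrfo import MRFOConfig, mrfo_run
from .opposition import OppositionConfig
from .phantom import generate_dataset
from .preprocess import PreprocessConfig, preprocess_pipeline
from .search_space import SearchSpace, default_search_space

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    n_per_class: int = 30
    phantom_size: tuple[int, int] = (256, 256)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    pop_size: int = 4
    max_iter: int = 3
    jump_probability: float = 0.3
    search_epochs: int = 2
    final_epochs: int = 5
    use_imrfo: bool = True
    model_spec: DualStreamSpec = field(default_factory=DualStreamSpec)
    seed: int = 0


def _prepare_images(cfg: ExperimentConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate phantoms and push them through the preprocessing pipeline."""
    dataset = generate_dataset(cfg.n_per_class, seed=cfg.seed, image_size=cfg.phantom_size)
    processed = []
    for img in dataset.images:
        out, _, _ = preprocess_pipeline(img, cfg.preprocess)
        processed.append(out)
    return np.stack(processed), dataset.labels


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run the full desk-scale experiment; returns (and optionally writes)
    a JSON-serializable report."""
    t0 = time.time()
    logger.info("stage=synth generating %d phantoms per class", cfg.n_per_class)
    images, labels = _prepare_images(cfg)

    logger.info("stage=split stratified %s", cfg.fractions)
    split = stratified_split(labels, cfg.fractions, seed=cfg.seed)
    x_train, y_train = images[split.train], labels[split.train]
    x_val, y_val = images[split.val], labels[split.val]
    x_test, y_test = images[split.test], labels[split.test]

    space = default_search_space()
    train_seed = cfg.seed + 1

    def fitness(values: dict[str, Any]) -> float:
        geo = GeoAugParams.from_values(values)
        hp = ModelHyperparams.from_values(values)
        rng = np.random.default_rng(train_seed)
        by_class = {
            0: [x for x, y in zip(x_train, y_train) if y == 0],
            1: [x for x, y in zip(x_train, y_train) if y == 1],
        }
        aug = augment_to_balance(by_class, geo, NoiseConfig(), rng)
        model = build_model(cfg.model_spec, hp, seed=train_seed)
        record = train_model(
            model, np.stack(aug.images), aug.labels, x_val, y_val, cfg.search_epochs, rng
        )
        return -max(record.val_accuracy)  # minimize negated validation accuracy

    mrfo_cfg = MRFOConfig(max_iter=cfg.max_iter, pop_size=cfg.pop_size, seed=cfg.seed)
    opp_cfg = OppositionConfig(jump_probability=cfg.jump_probability)
    logger.info(
        "stage=optimize %s N=%d MaxItr=%d",
        "IMRFO" if cfg.use_imrfo else "MRFO", cfg.pop_size, cfg.max_iter,
    )
    if cfg.use_imrfo:
        result = imrfo_run(space, fitness, mrfo_cfg, opp_cfg)
    else:
        result = mrfo_run(space, fitness, mrfo_cfg)

    logger.info("stage=train final training with best hyperparameters")
    best_values = result.best.typed_values
    geo = GeoAugParams.from_values(best_values)
    hp = ModelHyperparams.from_values(best_values)
    rng = np.random.default_rng(train_seed)
    by_class = {
        0: [x for x, y in zip(x_train, y_train) if y == 0],
        1: [x for x, y in zip(x_train, y_train) if y == 1],
    }
    aug = augment_to_balance(by_class, geo, NoiseConfig(), rng)
    model = build_model(cfg.model_spec, hp, seed=train_seed)
    record = train_model(
        model, np.stack(aug.images), aug.labels, x_val, y_val, cfg.final_epochs, rng
    )

    logger.info("stage=evaluate scoring the held-out test set")
    probs = model.predict_proba(x_test)
    report = metric_report(y_test, probs)

    out = {
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "search": result.to_dict(),
        "final_training": {
            "train_loss": record.train_loss,
            "val_loss": record.val_loss,
            "val_accuracy": record.val_accuracy,
        },
        "test_metrics": report.to_dict(),
        "runtime_seconds": time.time() - t0,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(out, indent=2))
        logger.info("report written to %s", out_dir / "report.json")
    return out
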