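"""End-to-end pipeline: phantom cohort → labels → split → augment → train → evaluate.

The driver wires the stages together with explicit seed derivation (one
master seed spawns every per-stage seed), per-stage slice counting, and a
machine-readable JSON run report, so the bookkeeping of a run — how many
slices went in, how many augmented pairs came out, what the test metrics
were — is a first-class output.  Augmentation is applied to the training
side only; the test side is never augmented.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .augment import AugmentationConfig, DEFAULT_AUG_CONFIG, augment_dataset, split_by_patient
from .labels import SlicePair, ThresholdRule, make_labels
from .metrics import evaluate_cohort
from .phantom import PhantomConfig, generate_cohort
from .segnet import ModelSpec, TrainSpec, build_model, predict, train
from .volumes import export_slice_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    The master ``seed`` deterministically derives all stage seeds, so one
    integer reproduces the whole run bit-for-bit.
    """

    n_patients: int = 4
    per_patient_slices: int = 6
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        ct_shape=(12, 64, 64), ct_spacing=(4.0, 2.0, 2.0)))
    threshold: ThresholdRule = field(default_factory=ThresholdRule)
    margin: int = 0
    augmentation: AugmentationConfig = DEFAULT_AUG_CONFIG
    train_fraction: float = 0.8
    families: tuple = ("fcn8s", "upsampled_resnet")
    width_scale: float = 0.125
    iterations: int = 60
    learning_rate: float = 1e-4
    train_on_augmented: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.n_patients < 2:
            raise ValueError("pipeline needs >= 2 patients for a leak-free split")

    def stage_seeds(self) -> Dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ("phantom", "split", "augment", "model")
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig, out_dir) -> Dict:
    """Execute all stages in order and write artifacts plus a JSON report.

    Writes the unaugmented training manifest, the augmented training
    manifest, the test manifest, one trained model per family and a
    ``report.json`` with per-stage counts, seeds and the evaluation metrics.
    Any stage failure aborts with the stage name and cause.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    report: Dict = {"config": _config_dict(config), "seeds": seeds, "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("phantom")
        cases = generate_cohort(config.n_patients, config.per_patient_slices,
                                config.phantom, seed=seeds["phantom"])
        report["stages"]["phantom"] = {"n_patients": len(cases)}

        stage("labels")
        pairs: List[SlicePair] = []
        for case in cases:
            pairs.extend(make_labels(case.pet, case.ct, config.threshold, margin=config.margin))
        report["stages"]["labels"] = {"n_slices": len(pairs)}

        stage("split")
        train_pairs, test_pairs = split_by_patient(pairs, config.train_fraction, seed=seeds["split"])
        report["stages"]["split"] = {
            "n_train": len(train_pairs), "n_test": len(test_pairs),
            "train_patients": sorted({p.patient_id for p in train_pairs}),
            "test_patients": sorted({p.patient_id for p in test_pairs}),
        }

        stage("augment")  # training side only; the test set is never augmented
        aug_cfg = replace(config.augmentation, rng_seed=seeds["augment"])
        augmented = augment_dataset(train_pairs, aug_cfg)
        report["stages"]["augment"] = {
            "n_in": len(train_pairs),
            "n_out": len(augmented),
            "variants_per_slice": aug_cfg.variants_per_slice,
            "magnification_factor": len(augmented) // len(train_pairs),
        }
        export_slice_dataset(train_pairs, out_dir / "train_original", overwrite=True)
        export_slice_dataset(augmented, out_dir / "train_augmented", overwrite=True)
        export_slice_dataset(test_pairs, out_dir / "test", overwrite=True)

        stage("train")
        input_size = train_pairs[0].image.shape
        fit_pairs = augmented if config.train_on_augmented else train_pairs
        report["stages"]["train"] = {}
        models = {}
        for family in config.families:
            mspec = ModelSpec(family=family, input_size=input_size, width_scale=config.width_scale)
            tspec = TrainSpec(iterations=config.iterations, learning_rate=config.learning_rate,
                              seed=seeds["model"])
            model = build_model(mspec, seed=seeds["model"])
            model, trace = train(model, fit_pairs, tspec)
            model.save(out_dir / f"model_{family}.npz", train_spec=tspec)
            np.savetxt(out_dir / f"loss_{family}.txt", np.asarray(trace))
            models[family] = model
            report["stages"]["train"][family] = {
                "iterations": len(trace),
                "loss_first": trace[0] if trace else None,
                "loss_last": trace[-1] if trace else None,
            }

        stage("evaluate")
        report["stages"]["evaluate"] = {}
        for family, model in models.items():
            preds = [(predict(model, p.image), p.mask) for p in test_pairs]
            rep = evaluate_cohort(preds)
            report["stages"]["evaluate"][family] = {
                "mean": rep.mean, "n_undefined": rep.n_undefined, "n_pairs": len(rep),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted in stage {_current_stage(report)}: {exc}") from exc

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _current_stage(report: Dict) -> str:
    order = ("phantom", "labels", "split", "augment", "train", "evaluate")
    done = set(report["stages"])
    for name in order:
        if name not in done:
            return name
    return "finalize"


def _config_dict(config: RunConfig) -> Dict:
    d = asdict(config)
    d["families"] = list(config.families)
    return d
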