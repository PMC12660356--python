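"""End-to-end orchestration of the phantom study.

Stages: simulate phantoms, split leakage-safely and augment the
training originals, enhance with the configured method, train
FCAU-Net, and evaluate on the held-out originals.  Each stage draws
its own seed from the global one, every stage is individually
skippable, and the machine-readable summary JSON carries the metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import enhance as en
from . import evaluation as ev
from . import model as mdl
from . import preprocess as pp
from . import synthetic as syn
from .config import RunConfig, config_hash, stage_seed
from .types import AugmentationSpec, LabeledSample, SplitPlan

log = logging.getLogger("fcaunet")


def _enhance_sample(s: LabeledSample, method: str, fce_p, clahe_p) -> LabeledSample:
    if method == "none":
        return s
    if method == "he":
        img = en.equalize_histogram(s.image)
    elif method == "clahe":
        img = en.clahe(s.image, clahe_p)
    elif method == "fce":
        img = en.fce(s.image, fce_p)
    elif method == "auto":
        variants = {
            "he": en.equalize_histogram(s.image),
            "clahe": en.clahe(s.image, clahe_p),
            "fce": en.fce(s.image, fce_p),
        }
        img = variants[en.select_highest_intensity(variants)]
    else:
        raise ValueError(f"unknown enhancement method {method!r}")
    return dataclasses.replace(s, image=img)


def run_pipeline(cfg: RunConfig, skip: set[str] = frozenset()) -> dict:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config_hash": config_hash(cfg)}

    # --- simulate ----------------------------------------------------
    size = int(cfg.simulate["size"])
    spec = syn.PhantomSpec(image_size=(size, size), mode=cfg.simulate["mode"])
    samples = syn.generate_dataset(int(cfg.simulate["n_per_class"]), spec,
                                   seed=stage_seed(cfg.seed, "simulate"))
    summary["simulate"] = {"n_samples": len(samples), "mode": cfg.simulate["mode"]}

    # --- preprocess --------------------------------------------------
    if "preprocess" not in skip:
        if cfg.preprocess["crop"]:
            samples = [s.with_transform(pp.crop_to_largest_contour, origin=s.origin)
                       for s in samples]
        plan = SplitPlan(test_fraction=cfg.preprocess["test_fraction"],
                         val_fraction=cfg.preprocess["val_fraction"],
                         seed=stage_seed(cfg.seed, "split"))
        train_set, val_set, test_set = pp.split_dataset(samples, plan)
        if cfg.preprocess["augment"]:
            aug = AugmentationSpec()
            train_set = train_set + [a for s in train_set for a in pp.augment_sample(s, aug)]
        summary["preprocess"] = {"train": len(train_set), "val": len(val_set),
                                 "test": len(test_set)}
    else:
        train_set, val_set, test_set = samples, [], []

    # --- enhance -----------------------------------------------------
    method = cfg.enhance["method"] if "enhance" not in skip else "none"
    fce_p = en.FCEParams(fe=cfg.enhance["fe"], fd=cfg.enhance["fd"])
    clahe_p = en.ClaheParams(tile_shape=tuple(cfg.enhance["tile"]),
                             clip_fraction=cfg.enhance["clip"])
    train_set = [_enhance_sample(s, method, fce_p, clahe_p) for s in train_set]
    val_set = [_enhance_sample(s, method, fce_p, clahe_p) for s in val_set]
    test_set = [_enhance_sample(s, method, fce_p, clahe_p) for s in test_set]
    summary["enhance"] = {"method": method}

    # --- train -------------------------------------------------------
    if "train" not in skip:
        mc = mdl.ModelConfig(input_size=(size, size),
                             base_channels=cfg.model["base_channels"],
                             depth=cfg.model["depth"],
                             dropout_rate=cfg.model["dropout_rate"],
                             attention_gate=cfg.model["attention_gate"],
                             ffcm_enabled=cfg.model["ffcm_enabled"],
                             mask_head=cfg.model["mask_head"],
                             seed=stage_seed(cfg.seed, "model"))
        model = mdl.build_fcau_net(mc)
        params = mdl.TrainParams(epochs=cfg.train["epochs"],
                                 batch_size=cfg.train["batch_size"],
                                 lr=cfg.train["lr"])
        model, history = mdl.train_model(model, train_set, val_set, params,
                                         seed=stage_seed(cfg.seed, "train"))
        mdl.save_checkpoint(model, str(out_dir / "model"))
        summary["train"] = {"epochs": len(history),
                            "final_loss": history[-1]["loss"],
                            "final_val_accuracy": history[-1].get("val_accuracy")}
    else:
        model, history = None, []

    # --- evaluate ----------------------------------------------------
    if "evaluate" not in skip and model is not None and test_set:
        y = np.array([0 if s.label == "healthy" else 1 for s in test_set])
        labels, probs, _ = mdl.predict(model, test_set)
        cm = ev.confusion(y, labels)
        curves = ev.roc_pr(y, probs[:, 1])
        summary["evaluate"] = {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "metrics": ev.classification_metrics(cm),
            "roc_auc": curves["roc"]["auc"],
            "pr_auc": curves["pr"]["auc"],
        }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
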