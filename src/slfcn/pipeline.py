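"""Desk-scale end-to-end pipeline: fixtures -> soft maps -> training -> scores.

This module wires the library stages together at sizes that train in minutes
on one CPU: 128x128 fields, a width-1/8 network, mean-reduced loss at an
ordinary learning rate.  The published full-scale recipe (512 tiles, full
width, lr 1e-10 with sum reduction) uses exactly the same code paths with
different configuration values.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import data, evaluation, synth
from .network import NetworkConfig, build_slfcn, predict, save_checkpoint
from .softlabel import KernelPair, SoftLabelParams, WeightParams, soften_dataset
from .train import DESK_PROFILE, fit

__all__ = ["desk_synth_params", "make_desk_dataset", "train_desk_model",
           "heldout_foreground_scores", "soft_vs_hard_f1", "run_demo"]

HARD_KERNELS = KernelPair(1, 1)

#: Kernel pair for desk-scale soft maps.  At 128-pixel fields the dataset
#: median diagonal is dominated by the punctate signals (~6 px), for which
#: the size rule returns identity kernels and the soft band vanishes; the
#: desk profile therefore pins the (3, 7) pair that the published parameters
#: produce at clinical object scales (median diagonal in [100, 300)).
DESK_SOFT_KERNELS = KernelPair(3, 7)


def desk_synth_params(seed: int, size: int = 128,
                      blur: float = 1.5) -> synth.SynthParams:
    """Fixture family used for desk-scale training runs.

    Nucleus radii are chosen so each nucleus spans roughly 1.5-2 output-stride
    cells of the network (diameter 40-56 px against the 32-px stride) — the
    closest a 128-px field can come to the clinical regime, where annotated
    objects cover several stride cells of a 512-px tile.
    """
    return synth.SynthParams(seed=seed, height=size, width=size,
                             nucleus_count=2, nucleus_radius=(20.0, 28.0),
                             dots_dark=3, dots_red=2, dot_radius=(1.5, 2.5),
                             boundary_blur_sigma=blur)


def make_desk_dataset(seed: int, n_train: int = 20, n_test: int = 5,
                      size: int = 128, blur: float = 1.5,
                      soft: bool = True,
                      weights: WeightParams = WeightParams(),
                      params: SoftLabelParams = SoftLabelParams(),
                      kernels: KernelPair | None = None):
    """Generate fixtures and their training tensors.

    Returns a dict with ``train`` (list of (input, labels, weight_map)),
    ``test`` (list of (key, image, reference labels)), and the derived
    ``psi_star``/``kernels``.  ``soft=False`` switches to the hard-label
    baseline: identity kernels, so weights are core/background only.
    """
    records = synth.generate_dataset(n_train, n_test, desk_synth_params(
        seed, size=size, blur=blur))
    per_image = {r["key"]: r["instances"] for r in records}
    shapes = {r["key"]: r["image"].shape[:2] for r in records}
    if kernels is None:
        kernels = DESK_SOFT_KERNELS if soft else HARD_KERNELS
    outputs, psi_star, kernels = soften_dataset(
        per_image, shapes, synth.CLASS_TABLE, params, weights,
        kernels=kernels)

    train, test = [], []
    for rec in records:
        wmap, labels = outputs[rec["key"]]
        if rec["split"] == "train":
            train.append((data.to_network_input(rec["image"]), labels, wmap))
        else:
            test.append((rec["key"], rec["image"], labels))
    return {"train": train, "test": test, "records": records,
            "outputs": outputs, "psi_star": psi_star, "kernels": kernels}


def train_desk_model(train_samples, seed: int, steps: int = 500,
                     width: float = 0.125, num_classes: int = 4,
                     lr: float | None = None):
    """Train a narrow network on prepared samples; returns (net, history).

    Dropout is disabled at desk scale: with 1/8-width feature heads the
    regularisation noise outweighs its benefit over a few hundred steps.
    """
    nc = NetworkConfig(num_classes=num_classes, width_multiplier=width,
                       dropout=0.0)
    tc = replace(DESK_PROFILE, steps=steps, seed=seed,
                 **({"lr": lr} if lr is not None else {}))
    net = build_slfcn(nc)
    return fit(net, train_samples, tc)


def heldout_foreground_scores(net, test_items) -> pd.DataFrame:
    """Foreground (any class vs background) metrics per held-out image."""
    rows = []
    for key, image, ref_labels in test_items:
        pred_labels, _ = predict(net, data.to_network_input(image))
        scored = evaluation.evaluate_pair(pred_labels, ref_labels)
        rows.append({"key": key, **{k: v for k, v in
                                    scored["foreground"].items()
                                    if k != "degenerate"}})
    return pd.DataFrame(rows)


def soft_vs_hard_f1(seed: int, n_train: int = 10, n_test: int = 3,
                    size: int = 128, blur: float = 3.0, steps: int = 250,
                    width: float = 0.125):
    """Mean held-out foreground F1 for soft-band vs hard (identity) weights.

    Both arms share the same fixtures, network width, seed, and step budget;
    only the weight maps differ.
    """
    means = {}
    for arm, soft in (("soft", True), ("hard", False)):
        ds = make_desk_dataset(seed, n_train, n_test, size=size, blur=blur,
                               soft=soft)
        net, _ = train_desk_model(ds["train"], seed, steps=steps, width=width)
        means[arm] = float(heldout_foreground_scores(net, ds["test"])
                           ["f1"].mean())
    return means["soft"], means["hard"]


def run_demo(out_dir, seed: int = 7, size: int = 128, steps: int = 200,
             n_train: int = 8, n_test: int = 3,
             compare_hard: bool = False) -> pd.DataFrame:
    """Full artifact-producing run; returns the aggregate metric report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arms = [("soft", True)] + ([("hard", False)] if compare_hard else [])
    report_rows = []
    for arm, soft in arms:
        arm_dir = out_dir / arm
        ds = make_desk_dataset(seed, n_train, n_test, size=size, soft=soft)
        data.write_dataset(ds["records"], arm_dir / "fixtures")
        maps_dir = arm_dir / "maps"
        maps_dir.mkdir(parents=True, exist_ok=True)
        for key, (wmap, labels) in ds["outputs"].items():
            data.write_weight_map(maps_dir / f"{key}_weights.tif", wmap)
            data.write_label_map(maps_dir / f"{key}_labels.png", labels)
        net, history = train_desk_model(ds["train"], seed, steps=steps)
        save_checkpoint(str(arm_dir / "checkpoint.npz"), net,
                        meta={"arm": arm, "seed": seed})
        pd.DataFrame({"step": range(len(history)), "loss": history}).to_csv(
            arm_dir / "training_log.csv", index=False)
        pred_dir = arm_dir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        scores = heldout_foreground_scores(net, ds["test"])
        for key, image, _ in ds["test"]:
            labels_pred, _ = predict(net, data.to_network_input(image))
            data.write_label_map(pred_dir / f"{key}_pred.png", labels_pred)
        scores.to_csv(arm_dir / "per_image_metrics.csv", index=False)
        agg = evaluation.aggregate(scores)
        agg.to_csv(arm_dir / "report.csv")
        report_rows.append(pd.Series(
            {m: agg.loc[m, "mean"] for m in agg.index}, name=arm))
    return pd.DataFrame(report_rows)
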