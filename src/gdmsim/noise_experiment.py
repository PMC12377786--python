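"""Noise-grid simulations and the analytic AUC mixture oracle.

Two arms over an FN-rate x FP-rate grid (defaults 0%..90% in 10% steps, so
the train arm fits 100 models):

* **train_noise** — corrupt the clean (validated) training labels per cell,
  refit preprocessing + logistic regression, and score on the untouched
  clean test set; the noisy-train-set metrics are recorded per cell too.
* **test_noise** — fit once on the clean training labels, then per cell
  corrupt the test labels and re-score the fixed predictions against them.

Both arms share the same split and base seed, so their (0, 0) cells equal
the clean pipeline exactly.

``expected_noisy_auc`` is the closed-form oracle for the test arm: a noisy
positive is a mixture of true positives and flipped negatives, so the
probability of ranking a random noisy positive above a random noisy negative
decomposes over the four true-class pairings — (true-pos, true-pos) and
(true-neg, true-neg) pairs contribute 1/2, (true-pos, true-neg) pairs the
clean AUC, and (true-neg, true-pos) pairs its complement. The same mixture
inflates prevalence to ``pi (1 - fn) + (1 - pi) fp``, which is the AP of a
random ranker on the noisy labels — the mechanism behind the counter-
intuitive AP rise at high FP noise.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .label_processes import NoiseSpec, cell_seed, corrupt_labels, grid_levels
from .modeling import (
    SplitPlan,
    _fit_arm,
    _view_labels,
    average_precision,
    predict_proba,
    roc_auc,
    split_cohort,
)

ARMS = ("train_noise", "test_noise")


def noisy_prevalence(prevalence: float, fn_rate: float, fp_rate: float) -> float:
    """Positive-class share after class-conditional flipping."""
    for name, v in (("prevalence", prevalence), ("fn_rate", fn_rate), ("fp_rate", fp_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1]")
    return prevalence * (1.0 - fn_rate) + (1.0 - prevalence) * fp_rate


def expected_noisy_auc(
    clean_auc: float, prevalence: float, fn_rate: float, fp_rate: float
) -> float | None:
    """Closed-form test-noise AUC; None when a noisy class is empty."""
    for name, v in (
        ("clean_auc", clean_auc),
        ("prevalence", prevalence),
        ("fn_rate", fn_rate),
        ("fp_rate", fp_rate),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1]")
    pi = prevalence
    w_pp = pi * (1.0 - fn_rate)          # true positives kept positive
    w_np = (1.0 - pi) * fp_rate          # true negatives flipped positive
    w_pn = pi * fn_rate                  # true positives flipped negative
    w_nn = (1.0 - pi) * (1.0 - fp_rate)  # true negatives kept negative
    mass_pos = w_pp + w_np
    mass_neg = w_pn + w_nn
    if mass_pos == 0.0 or mass_neg == 0.0:
        return None
    a = w_pp / mass_pos  # P(true positive | noisy positive)
    b = w_pn / mass_neg  # P(true positive | noisy negative)
    return (
        a * b * 0.5
        + a * (1.0 - b) * clean_auc
        + (1.0 - a) * b * (1.0 - clean_auc)
        + (1.0 - a) * (1.0 - b) * 0.5
    )


@dataclass
class GridResult:
    """Metric matrices indexed (FN level row, FP level column)."""

    arm: str
    fn_levels: list
    fp_levels: list
    auc: np.ndarray
    ap: np.ndarray
    train_auc: np.ndarray | None = None  # train arm: metrics on noisy train labels
    train_ap: np.ndarray | None = None
    cell_seeds: np.ndarray | None = None
    flip_counts: np.ndarray | None = None  # (..., 2): realized (#FN, #FP) flips
    manifest: dict = field(default_factory=dict)

    def matrix_frame(self, metric: str) -> pd.DataFrame:
        data = getattr(self, metric)
        if data is None:
            raise ValidationError(f"grid has no matrix {metric!r}")
        return pd.DataFrame(
            data,
            index=pd.Index(self.fn_levels, name="fn_level"),
            columns=pd.Index(self.fp_levels, name="fp_level"),
        )

    def to_csv_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metrics = ["auc", "ap"] + (
            ["train_auc", "train_ap"] if self.train_auc is not None else []
        )
        for metric in metrics:
            self.matrix_frame(metric).to_csv(outdir / f"{self.arm}_{metric}.csv")
        with open(outdir / f"{self.arm}_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _clean_train_test(cohort, frame, plan):
    train_idx, test_idx = split_cohort(cohort, frame, plan)
    train_rows, train_labels = _view_labels(frame, train_idx, "val")
    test_rows, test_labels = _view_labels(frame, test_idx, "val")
    return train_rows, train_labels, test_rows, test_labels


def run_train_noise_grid(
    cohort,
    frame,
    plan: SplitPlan | None = None,
    levels=None,
    config=None,
    base_seed: int = 0,
) -> GridResult:
    """Refit per corrupted-train cell; score on the untouched clean test set."""
    plan = plan or SplitPlan()
    levels = list(levels) if levels is not None else grid_levels()
    train_rows, train_labels, test_rows, test_labels = _clean_train_test(
        cohort, frame, plan
    )
    test_features = cohort.records.iloc[test_rows]
    k = len(levels)
    auc = np.full((k, k), np.nan)
    ap = np.full((k, k), np.nan)
    train_auc = np.full((k, k), np.nan)
    train_ap = np.full((k, k), np.nan)
    seeds = np.zeros((k, k), dtype=np.int64)
    flips = np.zeros((k, k, 2), dtype=np.int64)

    for i, fn_level in enumerate(levels):
        for j, fp_level in enumerate(levels):
            seed = cell_seed(base_seed, i, j)
            seeds[i, j] = seed
            noisy, flip_mask = corrupt_labels(
                train_labels, NoiseSpec(fn_level, fp_level, seed)
            )
            flips[i, j, 0] = int(np.sum(flip_mask & (train_labels == 1)))
            flips[i, j, 1] = int(np.sum(flip_mask & (train_labels == 0)))
            if np.unique(noisy).size < 2:
                continue  # undefined cell: corrupted train set is single-class
            model, pre = _fit_arm(cohort, train_rows, noisy, config)
            train_probs = predict_proba(model, pre.transform(cohort.records.iloc[train_rows]))
            test_probs = predict_proba(model, pre.transform(test_features))
            a = roc_auc(test_probs, test_labels)
            p = average_precision(test_probs, test_labels)
            auc[i, j] = np.nan if a is None else a
            ap[i, j] = np.nan if p is None else p
            ta = roc_auc(train_probs, noisy)
            tp = average_precision(train_probs, noisy)
            train_auc[i, j] = np.nan if ta is None else ta
            train_ap[i, j] = np.nan if tp is None else tp

    return GridResult(
        arm="train_noise",
        fn_levels=levels,
        fp_levels=levels,
        auc=auc,
        ap=ap,
        train_auc=train_auc,
        train_ap=train_ap,
        cell_seeds=seeds,
        flip_counts=flips,
        manifest={
            "arm": "train_noise",
            "base_seed": int(base_seed),
            "levels": levels,
            "n_train": int(len(train_rows)),
            "n_test": int(len(test_rows)),
            "split": {
                "test_fraction": plan.test_fraction,
                "seed": plan.seed,
                "exclude_years": list(plan.exclude_years),
            },
        },
    )


def run_test_noise_grid(
    cohort,
    frame,
    plan: SplitPlan | None = None,
    levels=None,
    config=None,
    base_seed: int = 0,
) -> GridResult:
    """Fit once on clean labels; per cell re-score against corrupted test labels."""
    plan = plan or SplitPlan()
    levels = list(levels) if levels is not None else grid_levels()
    train_rows, train_labels, test_rows, test_labels = _clean_train_test(
        cohort, frame, plan
    )
    model, pre = _fit_arm(cohort, train_rows, train_labels, config)
    probs = predict_proba(model, pre.transform(cohort.records.iloc[test_rows]))

    k = len(levels)
    auc = np.full((k, k), np.nan)
    ap = np.full((k, k), np.nan)
    seeds = np.zeros((k, k), dtype=np.int64)
    flips = np.zeros((k, k, 2), dtype=np.int64)
    for i, fn_level in enumerate(levels):
        for j, fp_level in enumerate(levels):
            seed = cell_seed(base_seed, i, j)
            seeds[i, j] = seed
            noisy, flip_mask = corrupt_labels(
                test_labels, NoiseSpec(fn_level, fp_level, seed)
            )
            flips[i, j, 0] = int(np.sum(flip_mask & (test_labels == 1)))
            flips[i, j, 1] = int(np.sum(flip_mask & (test_labels == 0)))
            a = roc_auc(probs, noisy)
            p = average_precision(probs, noisy)
            auc[i, j] = np.nan if a is None else a
            ap[i, j] = np.nan if p is None else p

    return GridResult(
        arm="test_noise",
        fn_levels=levels,
        fp_levels=levels,
        auc=auc,
        ap=ap,
        cell_seeds=seeds,
        flip_counts=flips,
        manifest={
            "arm": "test_noise",
            "base_seed": int(base_seed),
            "levels": levels,
            "n_train": int(len(train_rows)),
            "n_test": int(len(test_rows)),
            "split": {
                "test_fraction": plan.test_fraction,
                "seed": plan.seed,
                "exclude_years": list(plan.exclude_years),
            },
        },
    )


def plot_grid(result: GridResult, metric: str, path, title: str | None = None):
    """Annotated heatmap of one metric matrix (undefined cells hatched grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = getattr(result, metric)
    fig, ax = plt.subplots(figsize=(7, 6))
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, cmap=cmap, origin="upper", aspect="auto")
    ax.set_xticks(range(len(result.fp_levels)))
    ax.set_xticklabels([f"{v:.0%}" for v in result.fp_levels], rotation=45)
    ax.set_yticks(range(len(result.fn_levels)))
    ax.set_yticklabels([f"{v:.0%}" for v in result.fn_levels])
    ax.set_xlabel("true negatives flipped to false positives")
    ax.set_ylabel("true positives flipped to false negatives")
    ax.set_title(title or f"{result.arm}: {metric}")
    for i in range(len(result.fn_levels)):
        for j in range(len(result.fp_levels)):
            v = data[i, j]
            ax.text(
                j,
                i,
                "n/a" if np.isnan(v) else f"{v:.2f}",
                ha="center",
                va="center",
                fontsize=7,
                color="white" if not np.isnan(v) else "black",
            )
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
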