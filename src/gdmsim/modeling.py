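"""Risk-prediction pipeline: split, preprocess, fit, evaluate.

Mirrors a standard clinical tabular-ML workflow: 70/30 split stratified on
the reference label (2020 excluded by default because of the screening-
disruption year), one-hot encoding with the first category dropped plus
z-scoring fit on the training set only, ridge-penalised logistic regression
with pinned "library default" hyperparameters, and evaluation by ROC AUC
(with a stratified percentile-bootstrap CI), average precision, and logistic
recalibration (calibration slope and calibration-in-the-large intercept).

ROC AUC and average precision are computed by their definitional forms
(Mann-Whitney midranks; step-wise precision-recall sum) so their behaviour
under label noise is exactly the one analysed in
:mod:`gdmsim.noise_experiment`; scikit-learn backs the heavier machinery
(splitting, encoders, the penalised fit, curve traces).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .errors import ValidationError
from .label_processes import LabelFrame

PROB_CLIP = 1e-6  # keeps logits finite for saturated predictions

LABEL_VIEWS = ("truth", "observed", "val")


# ---------------------------------------------------------------- splitting


@dataclass(frozen=True)
class SplitPlan:
    test_fraction: float = 0.3
    seed: int = 0
    stratify_on_reference: bool = True
    exclude_years: tuple = (2020,)

    def validate(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must lie in (0, 1)")


def split_cohort(cohort, frame: LabelFrame, plan: SplitPlan):
    """Disjoint (train, test) positional indices over the included years.

    Test size is round(test_fraction * n_included); stratification uses the
    reference (ground-truth) label.
    """
    plan.validate()
    years = cohort.years
    included = ~np.isin(years, np.asarray(plan.exclude_years, dtype=int))
    idx = np.flatnonzero(included)
    if idx.size < 2:
        raise ValidationError("fewer than 2 records after year exclusion")
    n_test = int(round(plan.test_fraction * idx.size))
    n_test = min(max(n_test, 1), idx.size - 1)
    stratify = frame.truth[idx] if plan.stratify_on_reference else None
    try:
        train_idx, test_idx = train_test_split(
            idx,
            test_size=n_test,
            random_state=plan.seed,
            stratify=stratify,
            shuffle=True,
        )
    except ValueError as exc:
        raise ValidationError(
            "stratified split failed (a class has < 2 members); "
            "retry with stratify_on_reference=False"
        ) from exc
    return np.sort(train_idx), np.sort(test_idx)


# ----------------------------------------------------------- preprocessing


@dataclass
class PreprocessPlan:
    """Train-fitted one-hot (drop-first) + z-score state."""

    numeric_columns: list
    categorical_columns: list
    scaler: StandardScaler | None
    encoder: OneHotEncoder | None

    @property
    def feature_names(self) -> list:
        names = list(self.numeric_columns)
        if self.encoder is not None:
            names += list(self.encoder.get_feature_names_out(self.categorical_columns))
        return names

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        _check_no_missing(features, self.numeric_columns + self.categorical_columns)
        blocks = []
        if self.numeric_columns:
            blocks.append(self.scaler.transform(features[self.numeric_columns]))
        if self.categorical_columns:
            with warnings.catch_warnings():
                # unseen categories encoding to all-zeros is the documented
                # convention, not a surprise worth a warning per call
                warnings.filterwarnings(
                    "ignore", message="Found unknown categories"
                )
                blocks.append(self.encoder.transform(features[self.categorical_columns]))
        return np.hstack(blocks) if blocks else np.empty((len(features), 0))


def _check_no_missing(features, columns):
    sub = features[columns]
    if len(sub) and sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValidationError(f"missing values in feature columns: {bad}")


def fit_preprocessor(train_features, numeric_columns, categorical_columns):
    if len(train_features) == 0:
        raise ValidationError("train_features must be non-empty")
    _check_no_missing(train_features, list(numeric_columns) + list(categorical_columns))
    scaler = encoder = None
    if numeric_columns:
        scaler = StandardScaler().fit(train_features[list(numeric_columns)])
    if categorical_columns:
        # drop='first' drops the lexicographically smallest level; unseen
        # test categories encode as all zeros.
        encoder = OneHotEncoder(
            drop="first", handle_unknown="ignore", sparse_output=False
        ).fit(train_features[list(categorical_columns)])
    return PreprocessPlan(list(numeric_columns), list(categorical_columns), scaler, encoder)


# ------------------------------------------------------------------ model


@dataclass(frozen=True)
class LogisticConfig:
    """Pinned 'default' hyperparameters of the ridge-penalised fit."""

    C: float = 1.0
    tol: float = 1e-4
    max_iter: int = 1000
    solver: str = "lbfgs"


@dataclass
class FittedModel:
    coefficients: np.ndarray
    intercept: float
    feature_names: list
    config: LogisticConfig
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.feature_names, map(float, self.coefficients))),
            "intercept": float(self.intercept),
            "config": vars(self.config).copy()
            if not isinstance(self.config, LogisticConfig)
            else {
                "C": self.config.C,
                "tol": self.config.tol,
                "max_iter": self.config.max_iter,
                "solver": self.config.solver,
            },
            "metadata": self.metadata,
        }


def train_logistic(X, y, config: LogisticConfig | None = None) -> FittedModel:
    config = config or LogisticConfig()
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("labels contain a single class; cannot fit")
    clf = LogisticRegression(
        C=config.C, tol=config.tol, max_iter=config.max_iter, solver=config.solver
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
    names = [f"x{i}" for i in range(X.shape[1])]
    return FittedModel(
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_names=names,
        config=config,
        metadata={"n_iter": int(np.ravel(clf.n_iter_)[0]), "converged": converged,
                  "n_train": int(len(y))},
    )


def predict_proba(model: FittedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.coefficients.size:
        raise ValidationError(
            f"design width {X.shape[1]} does not match model "
            f"({model.coefficients.size} coefficients)"
        )
    return expit(X @ model.coefficients + model.intercept)


def save_model(path, model: FittedModel, preprocessor: PreprocessPlan | None = None):
    payload = model.to_dict()
    if preprocessor is not None:
        payload["preprocess"] = {
            "numeric_columns": preprocessor.numeric_columns,
            "categorical_columns": preprocessor.categorical_columns,
            "means": None
            if preprocessor.scaler is None
            else preprocessor.scaler.mean_.tolist(),
            "scales": None
            if preprocessor.scaler is None
            else preprocessor.scaler.scale_.tolist(),
            "categories": None
            if preprocessor.encoder is None
            else [c.tolist() for c in preprocessor.encoder.categories_],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    cfg = LogisticConfig(**payload["config"])
    names = list(payload["coefficients"])
    model = FittedModel(
        coefficients=np.array([payload["coefficients"][k] for k in names]),
        intercept=payload["intercept"],
        feature_names=names,
        config=cfg,
        metadata=payload.get("metadata", {}),
    )
    pre = None
    if "preprocess" in payload:
        p = payload["preprocess"]
        scaler = encoder = None
        if p["means"] is not None:
            scaler = StandardScaler()
            scaler.mean_ = np.array(p["means"])
            scaler.scale_ = np.array(p["scales"])
            scaler.var_ = scaler.scale_ ** 2
            scaler.n_features_in_ = len(p["means"])
            scaler.feature_names_in_ = np.asarray(p["numeric_columns"], dtype=object)
        if p["categories"] is not None:
            encoder = OneHotEncoder(
                drop="first", handle_unknown="ignore", sparse_output=False
            )
            cats = [list(c) for c in p["categories"]]
            # refit on a table cycling every stored level; the encoder sorts
            # levels, so the fitted state reproduces the saved one exactly
            depth = max(len(c) for c in cats)
            fit_table = pd.DataFrame(
                {
                    name: [c[i % len(c)] for i in range(depth)]
                    for name, c in zip(p["categorical_columns"], cats)
                }
            )
            encoder.fit(fit_table)
        pre = PreprocessPlan(
            p["numeric_columns"], p["categorical_columns"], scaler, encoder
        )
    return model, pre


# ---------------------------------------------------------------- metrics


def roc_auc(scores, labels) -> float | None:
    """Mann-Whitney AUC via midranks; ties credited 0.5. None if one class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(scores, labels) -> float | None:
    """Step-wise AP over descending unique thresholds; ties grouped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return None
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tie group = cumulative counts at that threshold
    boundary = np.flatnonzero(np.diff(s) != 0)
    last = np.append(boundary, s.size - 1)
    tp = np.cumsum(y)[last]
    pred_pos = last + 1
    precision = tp / pred_pos
    recall = tp / n_pos
    prev_recall = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - prev_recall) * precision))


def auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0):
    """Percentile 95% CI from a label-stratified bootstrap."""
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes required for a bootstrap CI")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    ones = np.ones(pos.size, dtype=int)
    zeros = np.zeros(neg.size, dtype=int)
    lab = np.concatenate([ones, zeros])
    for b in range(n_boot):
        sample = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        stats[b] = roc_auc(sample, lab)
    low, high = np.percentile(stats, [2.5, 97.5])
    return float(low), float(high)


def calibration_curve(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-frequency reliability bins (ties to the lower bin; empty omitted)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValidationError("probs must lie in [0, 1]")
    if n_bins > probs.size:
        raise ValidationError("n_bins exceeds the number of observations")
    edges = np.quantile(probs, np.arange(1, n_bins) / n_bins)
    bins = np.searchsorted(edges, probs, side="left")
    rows = []
    for b in np.unique(bins):
        mask = bins == b
        rows.append(
            {
                "mean_predicted": float(probs[mask].mean()),
                "observed_rate": float(labels[mask].mean()),
                "count": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def calibration_intercept_slope(probs, labels):
    """Logistic recalibration: slope from labels ~ logit(p); intercept from
    the offset model (calibration-in-the-large given slope 1)."""
    probs = np.clip(np.asarray(probs, dtype=float), PROB_CLIP, 1 - PROB_CLIP)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValidationError("both classes required for calibration")
    lp = logit(probs)
    ones = np.ones((lp.size, 1))
    intercept = float(
        sm.GLM(labels, ones, family=sm.families.Binomial(), offset=lp).fit().params[0]
    )
    if np.ptp(lp) == 0:
        return intercept, None  # slope undefined for degenerate predictions
    slope_fit = sm.GLM(
        labels, np.column_stack([np.ones_like(lp), lp]), family=sm.families.Binomial()
    ).fit()
    return intercept, float(slope_fit.params[1])


# -------------------------------------------------------------- evaluation


@dataclass
class ModelEval:
    label_view: str
    n: int
    roc_auc: float | None
    roc_auc_ci: tuple | None
    average_precision: float | None
    calibration_intercept: float | None
    calibration_slope: float | None
    roc_points: pd.DataFrame | None
    pr_points: pd.DataFrame | None
    calibration_bins: pd.DataFrame | None

    def to_dict(self) -> dict:
        return {
            "label_view": self.label_view,
            "n": self.n,
            "roc_auc": self.roc_auc,
            "roc_auc_ci": list(self.roc_auc_ci) if self.roc_auc_ci else None,
            "average_precision": self.average_precision,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
        }


def _view_labels(frame: LabelFrame, idx, view: str):
    """(kept positional indices, labels) for one label view on a subset."""
    if view not in LABEL_VIEWS:
        raise ValidationError(f"label view must be one of {LABEL_VIEWS}")
    if view == "val":
        keep = idx[frame.agreement_mask[idx]]
        return keep, frame.truth[keep]
    labels = frame.truth if view == "truth" else frame.observed
    return idx, labels[idx]


def evaluate_scores(scores, labels, view="truth", n_boot=2000, seed=0,
                    with_curves=True) -> ModelEval:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValidationError("evaluation set is empty")
    auc = roc_auc(scores, labels)
    ap = average_precision(scores, labels)
    two_class = auc is not None
    ci = auc_ci(scores, labels, n_boot, seed) if (two_class and n_boot) else None
    intercept = slope = None
    bins = roc_pts = pr_pts = None
    if two_class:
        intercept, slope = calibration_intercept_slope(scores, labels)
    if with_curves and two_class:
        fpr, tpr, thr = roc_curve(labels, scores)
        roc_pts = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        prec, rec, pthr = precision_recall_curve(labels, scores)
        pr_pts = pd.DataFrame(
            {
                "recall": rec,
                "precision": prec,
                "threshold": np.append(pthr, np.nan),
            }
        )
        bins = calibration_curve(scores, labels, min(10, labels.size))
    return ModelEval(
        label_view=view,
        n=int(labels.size),
        roc_auc=auc,
        roc_auc_ci=ci,
        average_precision=ap,
        calibration_intercept=intercept,
        calibration_slope=slope,
        roc_points=roc_pts,
        pr_points=pr_pts,
        calibration_bins=bins,
    )


def evaluate(model, preprocessor, cohort, frame: LabelFrame, test_idx,
             label_view="truth", n_boot=2000, seed=0, with_curves=True) -> ModelEval:
    keep, labels = _view_labels(frame, np.asarray(test_idx), label_view)
    if keep.size == 0:
        raise ValidationError("evaluation set is empty after masking")
    X = preprocessor.transform(cohort.records.iloc[keep])
    probs = predict_proba(model, X)
    return evaluate_scores(probs, labels, label_view, n_boot, seed, with_curves)


def _fit_arm(cohort, rows, labels, config):
    features = cohort.records.iloc[rows]
    pre = fit_preprocessor(features, cohort.numeric_columns, cohort.categorical_columns)
    model = train_logistic(pre.transform(features), labels, config)
    return model, pre


def run_label_source_experiment(
    cohort,
    frame: LabelFrame,
    plan: SplitPlan | None = None,
    config: LogisticConfig | None = None,
    n_boot: int = 2000,
    eval_seed: int = 0,
) -> dict:
    """The headline three-arm comparison on one shared split.

    Arms: EHR-style observed labels for training (all train rows) vs
    validated labels (agreement rows only), both scored on the validated
    test subset; plus the validated-trained model scored against the
    observed labels of the full test set.
    """
    plan = plan or SplitPlan()
    train_idx, test_idx = split_cohort(cohort, frame, plan)

    ehr_rows, ehr_labels = _view_labels(frame, train_idx, "observed")
    val_rows, val_labels = _view_labels(frame, train_idx, "val")
    model_ehr, pre_ehr = _fit_arm(cohort, ehr_rows, ehr_labels, config)
    model_val, pre_val = _fit_arm(cohort, val_rows, val_labels, config)

    out = {
        "train_ehr_test_val": evaluate(
            model_ehr, pre_ehr, cohort, frame, test_idx, "val", n_boot, eval_seed
        ),
        "train_val_test_val": evaluate(
            model_val, pre_val, cohort, frame, test_idx, "val", n_boot, eval_seed
        ),
        "train_val_test_ehr": evaluate(
            model_val, pre_val, cohort, frame, test_idx, "observed", n_boot, eval_seed
        ),
    }
    return {
        "arms": out,
        "split": {"train": train_idx, "test": test_idx},
        "models": {"ehr": (model_ehr, pre_ehr), "val": (model_val, pre_val)},
    }


def cross_validated_auc(cohort, labels, k: int = 5, config=None, seed: int = 0):
    """k-fold stratified CV utility (a robustness check, not a headline arm)."""
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(np.zeros(labels.size), labels):
        model, pre = _fit_arm(cohort, tr, labels[tr], config)
        probs = predict_proba(model, pre.transform(cohort.records.iloc[te]))
        aucs.append(roc_auc(probs, labels[te]))
    return aucs
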