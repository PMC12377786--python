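"""Label constructions: class-conditional noise-at-random and agreement labels.

Two label views are derived from the ground-truth (registry-style) labels:

* ``observed`` — an EHR-style view produced by flipping an exact fraction of
  each ORIGINAL class (noise at random): ``round(fn_rate * #positives)``
  positives become 0 and ``round(fp_rate * #negatives)`` negatives become 1,
  each drawn uniformly without replacement. Class membership is fixed before
  any flip, so a record can be flipped at most once and the order of the two
  flip passes is immaterial.
* ``val`` — the validated view, defined only where truth and observed agree
  (the records a chart-review validation would retain).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError, ValidationError

LABEL_FRAME_COLUMNS = ("patient_id", "truth", "observed", "agreement", "val")

# The discordance measured between the hospital EHR and the clinical team
# database: miss rate 14.3% on true positives, false-alarm rate 2.3% on
# true negatives.
DEFAULT_FN_RATE = 0.143
DEFAULT_FP_RATE = 0.023


@dataclass(frozen=True)
class NoiseSpec:
    """Class-conditional flip rates: fn_rate on positives, fp_rate on negatives."""

    fn_rate: float = DEFAULT_FN_RATE
    fp_rate: float = DEFAULT_FP_RATE
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValidationError("fn_rate must lie in [0, 1]")
        if not 0.0 <= self.fp_rate <= 1.0:
            raise ValidationError("fp_rate must lie in [0, 1]")


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    out = arr.astype(int)
    if not np.array_equal(out, arr) or not np.isin(out, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 values")
    return out


def round_half_away(x: float) -> int:
    """round(rate * class size) with halves away from zero (rates are >= 0)."""
    return int(np.floor(x + 0.5))


def corrupt_labels(truth, noise: NoiseSpec):
    """Flip exact per-class counts of labels; returns (observed, flip_mask)."""
    noise.validate()
    truth = _as_binary(truth, "truth")
    pos = np.flatnonzero(truth == 1)
    neg = np.flatnonzero(truth == 0)
    n_fn = round_half_away(noise.fn_rate * len(pos))
    n_fp = round_half_away(noise.fp_rate * len(neg))

    rng = np.random.default_rng(noise.seed)
    flip_mask = np.zeros(truth.shape, dtype=bool)
    if n_fn:
        flip_mask[rng.choice(pos, size=n_fn, replace=False)] = True
    if n_fp:
        flip_mask[rng.choice(neg, size=n_fp, replace=False)] = True
    observed = np.where(flip_mask, 1 - truth, truth)
    return observed, flip_mask


@dataclass
class LabelFrame:
    """Aligned label views for one cohort.

    ``val`` is a float vector equal to ``truth`` where the views agree and
    NaN elsewhere (undefined outside the agreement subset).
    """

    ids: np.ndarray
    truth: np.ndarray
    observed: np.ndarray
    agreement_mask: np.ndarray
    val: np.ndarray
    years: np.ndarray | None = None  # optional stratification carrier

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def val_values(self) -> np.ndarray:
        """The validated labels on the agreement subset, as ints."""
        return self.truth[self.agreement_mask]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "patient_id": self.ids,
                "truth": self.truth,
                "observed": self.observed,
                "agreement": self.agreement_mask.astype(int),
                "val": self.val,
            }
        )
        if self.years is not None:
            out["year"] = self.years
        return out


def make_label_frame(ids, truth, observed, years=None) -> LabelFrame:
    ids = np.asarray(ids, dtype=object)
    truth = _as_binary(truth, "truth")
    observed = _as_binary(observed, "observed")
    if not (len(ids) == len(truth) == len(observed)):
        raise AlignmentError(
            f"ids ({len(ids)}), truth ({len(truth)}) and observed "
            f"({len(observed)}) must have equal lengths"
        )
    if years is not None:
        years = np.asarray(years, dtype=int)
        if len(years) != len(ids):
            raise AlignmentError("years must align with ids")
    agreement = truth == observed
    val = np.where(agreement, truth.astype(float), np.nan)
    return LabelFrame(ids, truth, observed, agreement, val, years)


def corrupt_cohort(cohort, noise: NoiseSpec) -> LabelFrame:
    """Corrupt a cohort's ground-truth labels into a full LabelFrame."""
    observed, _ = corrupt_labels(cohort.truth, noise)
    return make_label_frame(cohort.ids, cohort.truth, observed, years=cohort.years)


def write_label_frame(frame: LabelFrame, path) -> None:
    frame.to_frame().to_csv(path, index=False)


def read_label_frame(path) -> LabelFrame:
    table = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(LABEL_FRAME_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(missing, source=str(path))
    years = table["year"].to_numpy(dtype=int) if "year" in table.columns else None
    return make_label_frame(
        table["patient_id"].to_numpy(dtype=object),
        table["truth"].to_numpy(),
        table["observed"].to_numpy(),
        years=years,
    )


def grid_levels(max_level: float = 0.9, step: float = 0.1) -> list:
    """Noise levels {0, step, 2*step, ..., max_level}; defaults give 10 levels."""
    if not 0.0 <= step <= 1.0 or not 0.0 <= max_level <= 1.0:
        raise ValidationError("step and max_level must lie in [0, 1]")
    if max_level == 0.0:
        return [0.0]
    if step > max_level:
        raise ValidationError("step must not exceed max_level")
    if step == 0.0:
        raise ValidationError("step must be > 0 when max_level > 0")
    n = int(np.floor(max_level / step + 1e-9))
    return [round(i * step, 10) for i in range(n + 1)]


def cell_seed(base_seed: int, fn_index: int, fp_index: int) -> int:
    """Stable per-cell seed so any grid cell is reproducible in isolation."""
    ss = np.random.SeedSequence((int(base_seed), int(fn_index), int(fp_index)))
    return int(ss.generate_state(1)[0] % (2**31))
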