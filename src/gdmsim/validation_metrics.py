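"""Agreement between an observed label source and a reference standard.

Covers the validation step of a label-accuracy study: confusion composition,
class-conditional rates (TPR/FPR/TNR/FNR), accuracy / precision / recall /
F1 / Cohen kappa, per-year stratified reports with pooled and
pooled-excluding-a-year rows, and relative prevalence reduction.

Undefined statistics (zero denominators) are reported as ``None`` — never as
silent NaN — so presentation layers must handle them explicitly.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

POOLED_LABEL = "All years"


@dataclass(frozen=True)
class ConfusionSummary:
    """The four agreement counts of a binary label comparison."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class RateSummary:
    tpr: float | None
    fpr: float | None
    tnr: float | None
    fnr: float | None
    composition: dict  # {tp,fp,tn,fn} shares of n
    prevalence_observed: float
    prevalence_reference: float


@dataclass(frozen=True)
class AgreementStats:
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    kappa: float | None


def _binary(values, name):
    arr = np.asarray(values)
    out = arr.astype(int)
    if not np.array_equal(out, arr) or not np.isin(out, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 values")
    return out


def confusion(observed, reference) -> ConfusionSummary:
    obs = _binary(observed, "observed")
    ref = _binary(reference, "reference")
    if len(obs) != len(ref):
        raise AlignmentError(
            f"observed ({len(obs)}) and reference ({len(ref)}) lengths differ"
        )
    return ConfusionSummary(
        tp=int(np.sum((obs == 1) & (ref == 1))),
        fp=int(np.sum((obs == 1) & (ref == 0))),
        tn=int(np.sum((obs == 0) & (ref == 0))),
        fn=int(np.sum((obs == 0) & (ref == 1))),
    )


def rates(cs: ConfusionSummary) -> RateSummary:
    if cs.n < 1:
        raise ValidationError("confusion summary is empty (n = 0)")
    pos = cs.tp + cs.fn  # reference positives
    neg = cs.fp + cs.tn
    return RateSummary(
        tpr=cs.tp / pos if pos else None,
        fnr=cs.fn / pos if pos else None,
        fpr=cs.fp / neg if neg else None,
        tnr=cs.tn / neg if neg else None,
        composition={
            "tp": cs.tp / cs.n,
            "fp": cs.fp / cs.n,
            "tn": cs.tn / cs.n,
            "fn": cs.fn / cs.n,
        },
        prevalence_observed=(cs.tp + cs.fp) / cs.n,
        prevalence_reference=pos / cs.n,
    )


def agreement_stats(cs: ConfusionSummary) -> AgreementStats:
    """Accuracy, precision, recall, F1 and Cohen kappa from one 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e computed from
    the marginals; when both marginals are degenerate on the same side
    (p_e = 1, forcing p_o = 1) kappa is taken as 1.
    """
    if cs.n < 1:
        raise ValidationError("confusion summary is empty (n = 0)")
    n = cs.n
    accuracy = (cs.tp + cs.tn) / n
    precision = cs.tp / (cs.tp + cs.fp) if cs.tp + cs.fp else None
    recall = cs.tp / (cs.tp + cs.fn) if cs.tp + cs.fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    p_o = accuracy
    p_e = ((cs.tp + cs.fp) * (cs.tp + cs.fn) + (cs.fn + cs.tn) * (cs.fp + cs.tn)) / (
        n * n
    )
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementStats(accuracy, precision, recall, f1, kappa)


def relative_reduction(p_baseline: float, p_dip: float) -> float:
    """Percent reduction of p_dip relative to p_baseline (both percentages)."""
    if p_baseline <= 0:
        raise ValidationError("p_baseline must be > 0")
    return 100.0 * (1.0 - p_dip / p_baseline)


@dataclass(frozen=True)
class StratumReport:
    label: str
    counts: ConfusionSummary
    rates: RateSummary
    stats: AgreementStats


@dataclass
class AgreementReport:
    """Per-stratum agreement statistics plus pooled rows."""

    strata: list  # list[StratumReport]; pooled rows carry string labels

    def row(self, label) -> StratumReport:
        for s in self.strata:
            if s.label == str(label):
                return s
        raise KeyError(label)

    def to_dataframe(self, precision: int | None = None) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            rows.append(
                {
                    "stratum": s.label,
                    "n": s.counts.n,
                    "tp": s.counts.tp,
                    "fp": s.counts.fp,
                    "tn": s.counts.tn,
                    "fn": s.counts.fn,
                    "tpr": s.rates.tpr,
                    "fpr": s.rates.fpr,
                    "tnr": s.rates.tnr,
                    "fnr": s.rates.fnr,
                    "prevalence_observed": s.rates.prevalence_observed,
                    "prevalence_reference": s.rates.prevalence_reference,
                    "kappa": s.stats.kappa,
                    "accuracy": s.stats.accuracy,
                    "precision": s.stats.precision,
                    "recall": s.stats.recall,
                    "f1": s.stats.f1,
                }
            )
        out = pd.DataFrame(rows)
        if precision is not None:
            num = out.select_dtypes("number").columns.difference(
                ["n", "tp", "fp", "tn", "fn"]
            )
            out[num] = out[num].round(precision)
        return out

    def to_csv(self, path, precision: int | None = None) -> None:
        self.to_dataframe(precision).to_csv(path, index=False)

    def to_json(self, path=None):
        payload = json.loads(self.to_dataframe().to_json(orient="records"))
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def _stratum(label, obs, ref) -> StratumReport:
    cs = confusion(obs, ref)
    return StratumReport(str(label), cs, rates(cs), agreement_stats(cs))


def stratified_report(
    years, observed, reference, exclude_years=(2020,)
) -> AgreementReport:
    """Per-year rows, a pooled row, and pooled-excluding-year rows.

    ``exclude_years`` adds an "All minus <year>" row for each listed year
    present in the data; years with no records are skipped with a log note.
    """
    years = np.asarray(years, dtype=int)
    obs = _binary(observed, "observed")
    ref = _binary(reference, "reference")
    if not (len(years) == len(obs) == len(ref)):
        raise AlignmentError("years, observed and reference must align")
    strata = []
    present = np.unique(years)
    for year in present:
        mask = years == year
        strata.append(_stratum(year, obs[mask], ref[mask]))
    strata.append(_stratum(POOLED_LABEL, obs, ref))
    for year in exclude_years or ():
        if year not in present:
            logger.info("stratum %s has no records; 'All minus' row skipped", year)
            continue
        mask = years != year
        strata.append(_stratum(f"All minus {year}", obs[mask], ref[mask]))
    return AgreementReport(strata)
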