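"""Implantation-potential framework: the 50% mosaicism cutoff and the
predictive metrics of a TE result for ICM status.

An ICM is labelled **low** implantation potential when its profile contains
any full (non-mosaic) call, or any mosaic call strictly above the 50%
cutoff; otherwise it is **high** (euploid profiles included).  The strict
inequality matters: a profile whose worst mosaic call sits exactly at 50%
retains high potential, and that reading is the only one consistent with
the clinical confusion counts this framework reproduces.

For each abnormal TE category, the TE result is scored against the ICM
label using a shared euploid-TE reference group:

* TP — abnormal TE, low-potential ICM
* FP — abnormal TE, high-potential ICM
* FN — euploid TE, low-potential ICM
* TN — euploid TE, high-potential ICM

with sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP) and
NPV TN/(TN+FN).  Because the reference FN/TN are shared, NPV is identical
across abnormal categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .classify import (
    CATEGORY_ORDER,
    Category,
    DEFAULT_PRECEDENCE,
    classify_profile,
)
from .concordance import round_half_up
from .karyo import BiopsyProfile, ClassificationThresholds, DEFAULT_THRESHOLDS
from .records import EmbryoRecord

__all__ = [
    "Potential",
    "ConfusionCounts",
    "PredictiveMetrics",
    "potential_of_profile",
    "confusion_counts",
    "predictive_metrics",
    "PotentialModel",
    "PotentialResults",
]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 50.0


class Potential(str, Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for one abnormal TE category vs the euploid-TE
    reference.  TP+FP is the abnormal-group size; FN+TN the reference size."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PredictiveMetrics:
    """The four predictive proportions; ``None`` marks an undefined ratio
    (zero denominator), which is propagated rather than raised."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_percent(self, ndigits: int = 1) -> dict[str, float | None]:
        """Display form: percent rounded half-up to ``ndigits`` decimals."""
        return {
            name: None if v is None else round_half_up(100 * v, ndigits)
            for name, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def potential_of_profile(
    icm: BiopsyProfile,
    cutoff: float = DEFAULT_CUTOFF,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> Potential:
    """Low/high implantation potential of an ICM profile.

    Low iff any call is full (level >= ``thresholds.full_min``) or any
    mosaic call exceeds ``cutoff`` strictly; otherwise high.
    """
    for call in icm.calls:
        if call.level >= thresholds.full_min or call.level > cutoff:
            return Potential.LOW
    return Potential.HIGH


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_counts(
    abnormal_icm: Iterable[BiopsyProfile],
    reference: tuple[int, int] | Iterable[BiopsyProfile],
    cutoff: float = DEFAULT_CUTOFF,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> ConfusionCounts:
    """Confusion counts for one abnormal-TE group against the euploid-TE
    reference.

    ``reference`` is either pre-tallied ``(fn, tn)`` counts (the usual case
    when only the reference row of a published table is available) or the
    euploid-TE group's ICM profiles, which are tallied here.  An empty
    reference makes every metric undefined and raises ``ValueError``.
    """
    tp = fp = 0
    for icm in abnormal_icm:
        if potential_of_profile(icm, cutoff, thresholds) is Potential.LOW:
            tp += 1
        else:
            fp += 1
    if isinstance(reference, tuple):
        fn, tn = reference
    else:
        fn = tn = 0
        for icm in reference:
            if potential_of_profile(icm, cutoff, thresholds) is Potential.LOW:
                fn += 1
            else:
                tn += 1
    if fn + tn == 0:
        raise ValueError("empty euploid-TE reference group: metrics undefined")
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def predictive_metrics(counts: ConfusionCounts) -> PredictiveMetrics:
    """Sensitivity, specificity, PPV and NPV from confusion counts."""
    return PredictiveMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


# ---------------------------------------------------------------------------
# Model / Results surface


class PotentialModel:
    """Predictive-metric analysis of TE results for ICM potential.

    Groups records by TE category; the euploid-TE records form the shared
    reference (FN/TN).  When the cohort contains no euploid-TE records —
    e.g. when only an abnormal subgroup's profiles are published —
    ``reference_counts=(fn, tn)`` supplies the reference row directly.
    """

    def __init__(
        self,
        records: Iterable[EmbryoRecord],
        reference_counts: tuple[int, int] | None = None,
        cutoff: float = DEFAULT_CUTOFF,
        thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
        use_labels: bool = False,
        precedence: Sequence[Category] = DEFAULT_PRECEDENCE,
    ) -> None:
        self.records = list(records)
        self.reference_counts = reference_counts
        self.cutoff = cutoff
        self.thresholds = thresholds
        self.use_labels = use_labels
        self.precedence = tuple(precedence)

    def _te_category(self, rec: EmbryoRecord) -> Category | None:
        if self.use_labels and rec.te_label is not None:
            return rec.te_label
        if rec.te is not None:
            return classify_profile(rec.te, self.thresholds, self.precedence)
        return rec.te_label

    def fit(self) -> "PotentialResults":
        groups: dict[Category, list[BiopsyProfile]] = {c: [] for c in CATEGORY_ORDER}
        skipped: list[str] = []
        for rec in self.records:
            cat = self._te_category(rec)
            if cat is None or rec.icm is None:
                skipped.append(rec.embryo_id)
                continue
            groups[cat].append(rec.icm)
        if groups[Category.EU]:
            fn = tn = 0
            for icm in groups[Category.EU]:
                if potential_of_profile(icm, self.cutoff, self.thresholds) is Potential.LOW:
                    fn += 1
                else:
                    tn += 1
            reference = (fn, tn)
        elif self.reference_counts is not None:
            reference = tuple(self.reference_counts)
        else:
            raise ValueError(
                "no euploid-TE records and no reference_counts: reference "
                "FN/TN unavailable"
            )
        rows: dict[str, tuple[ConfusionCounts, PredictiveMetrics]] = {}
        for cat in CATEGORY_ORDER:
            if cat is Category.EU or not groups[cat]:
                continue
            counts = confusion_counts(
                groups[cat], reference, self.cutoff, self.thresholds
            )
            rows[cat.label] = (counts, predictive_metrics(counts))
        return PotentialResults(
            model=self, reference=reference, rows=rows, skipped=tuple(skipped)
        )


@dataclass(frozen=True)
class PotentialResults:
    model: PotentialModel
    reference: tuple[int, int]  # (FN, TN)
    rows: Mapping[str, tuple[ConfusionCounts, PredictiveMetrics]]
    skipped: tuple[str, ...]

    def summary(self) -> str:
        fn, tn = self.reference
        lines = [
            "Implantation-potential predictive metrics "
            f"(cutoff: mosaicism > {self.model.cutoff:g}% -> low potential)",
            "=" * 78,
            f"{'TE result':<12}{'Low (TP)':>9}{'High (FP)':>10}"
            f"{'Sens':>8}{'Spec':>8}{'PPV':>8}{'NPV':>8}",
            f"{'Euploidy':<12}{fn:>9}{tn:>10}" + " " * 12 + "(reference: FN, TN)",
        ]
        for label, (counts, metrics) in self.rows.items():
            pct = metrics.as_percent()
            cells = "".join(
                f"{'-' if pct[k] is None else format(pct[k], '.1f') + '%':>8}"
                for k in ("sensitivity", "specificity", "ppv", "npv")
            )
            lines.append(f"{label:<12}{counts.tp:>9}{counts.fp:>10}{cells}")
        if self.skipped:
            lines.append(f"skipped (no TE category or no ICM profile): {len(self.skipped)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        fn, tn = self.reference
        return {
            "cutoff": self.model.cutoff,
            "reference": {"fn": fn, "tn": tn},
            "rows": {
                label: {
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "raw": {
                        "sensitivity": metrics.sensitivity,
                        "specificity": metrics.specificity,
                        "ppv": metrics.ppv,
                        "npv": metrics.npv,
                    },
                    "percent": metrics.as_percent(),
                }
                for label, (counts, metrics) in self.rows.items()
            },
            "skipped": list(self.skipped),
        }
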