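"""TE-ICM cross-tabulation, concordance rates and chi-square statistics.

Concordance is categorical: an embryo is concordant when its TE biopsy and
ICM sample fall in the same five-way category.  This module builds the 5x5
TE x ICM cross-tab, the per-TE-category concordance and ICM-euploidy rates,
the Pearson chi-square test of independence (no continuity correction, the
SPSS default for r x c tables), and pairwise post hoc comparisons of
concordant-vs-discordant proportions with Bonferroni correction.

The model-style surface is :class:`ConcordanceModel` /
:class:`ConcordanceResults`; the underlying operations
(:func:`build_crosstab`, :func:`rates`, :func:`chisq_independence`,
:func:`pairwise_posthoc`) are plain functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    CATEGORY_ORDER,
    Category,
    DEFAULT_PRECEDENCE,
    classify_profile,
)
from .karyo import ClassificationThresholds, DEFAULT_THRESHOLDS
from .records import EmbryoRecord

__all__ = [
    "CrossTab",
    "RateSummary",
    "Chi2Result",
    "PosthocPair",
    "ConcordanceModel",
    "ConcordanceResults",
    "build_crosstab",
    "rates",
    "overall_concordance",
    "chisq_independence",
    "pairwise_posthoc",
]

log = logging.getLogger(__name__)
_LABELS = [c.label for c in CATEGORY_ORDER]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossTab:
    """5x5 TE x ICM category counts (rows: TE, columns: ICM)."""

    counts: pd.DataFrame
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = self.counts.reindex(index=_LABELS, columns=_LABELS, fill_value=0)
        if (counts.to_numpy() < 0).any():
            raise ValueError("cross-tab counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def overall_n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __add__(self, other: "CrossTab") -> "CrossTab":
        return CrossTab(self.counts + other.counts, self.excluded + other.excluded)


@dataclass(frozen=True)
class RowRates:
    concordant: int
    icm_euploid: int
    total: int

    @property
    def concordance(self) -> float | None:
        return self.concordant / self.total if self.total else None

    @property
    def icm_euploidy(self) -> float | None:
        return self.icm_euploid / self.total if self.total else None


@dataclass(frozen=True)
class RateSummary:
    """Per-TE-category concordance and ICM-euploidy rates with counts kept."""

    rows: dict[str, RowRates]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for label, r in self.rows.items():
            recs.append(
                {
                    "te_category": label,
                    "concordant": r.concordant,
                    "icm_euploid": r.icm_euploid,
                    "total": r.total,
                    "concordance_pct": (
                        round_half_up(100 * r.concordance) if r.total else None
                    ),
                    "icm_euploidy_pct": (
                        round_half_up(100 * r.icm_euploidy) if r.total else None
                    ),
                }
            )
        return pd.DataFrame(recs).set_index("te_category")


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    table: pd.DataFrame


@dataclass(frozen=True)
class PosthocPair:
    pair: tuple[str, str]
    table: tuple[tuple[int, int], tuple[int, int]]  # [[conc_a, disc_a], [conc_b, disc_b]]
    p_raw: float
    p_adjusted: float
    significant: bool


def _category_of(
    profile,
    label,
    thresholds: ClassificationThresholds,
    precedence: Sequence[Category],
    use_labels: bool,
) -> Category | None:
    if use_labels and label is not None:
        return label
    if profile is not None:
        return classify_profile(profile, thresholds, precedence)
    return label


def build_crosstab(
    records: Iterable[EmbryoRecord],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    precedence: Sequence[Category] = DEFAULT_PRECEDENCE,
    use_labels: bool = False,
) -> CrossTab:
    """Cross-tabulate TE vs ICM categories over a cohort.

    Categories are recomputed from the profiles by default; with
    ``use_labels=True`` pre-assigned labels take priority (falling back to
    profiles where a label is missing).  Records lacking a usable category on
    either side are excluded and logged.
    """
    counts = pd.DataFrame(0, index=_LABELS, columns=_LABELS, dtype=int)
    excluded: list[str] = []
    for rec in records:
        te = _category_of(rec.te, rec.te_label, thresholds, precedence, use_labels)
        icm = _category_of(rec.icm, rec.icm_label, thresholds, precedence, use_labels)
        if te is None or icm is None:
            log.warning("excluding %s: missing category on one side", rec.embryo_id)
            excluded.append(rec.embryo_id)
            continue
        counts.loc[te.label, icm.label] += 1
    return CrossTab(counts, tuple(excluded))


def rates(crosstab: CrossTab) -> RateSummary:
    """Per-row concordance (diagonal / row total) and ICM-euploidy rates."""
    rows = {}
    for label in _LABELS:
        total = int(crosstab.counts.loc[label].sum())
        rows[label] = RowRates(
            concordant=int(crosstab.counts.loc[label, label]),
            icm_euploid=int(crosstab.counts.loc[label, Category.EU.label]),
            total=total,
        )
    return RateSummary(rows)


def overall_concordance(crosstab: CrossTab) -> tuple[int, int, float | None]:
    """(diagonal sum, grand total, rate) over the whole cross-tab."""
    diag = int(np.trace(crosstab.counts.to_numpy()))
    n = crosstab.overall_n
    return diag, n, (diag / n if n else None)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, CrossTab):
        return table.counts
    return pd.DataFrame(table)


def chisq_independence(table, drop_empty: bool = True) -> Chi2Result:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction; ``df = (r-1)(c-1)`` after optionally dropping
    all-zero rows/columns.  Degenerate tables (fewer than 2 rows or columns
    remaining) raise ``ValueError``.
    """
    frame = _as_frame(table)
    if drop_empty:
        frame = frame.loc[frame.sum(axis=1) > 0, frame.sum(axis=0) > 0]
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError(
            f"need at least a 2x2 table after dropping empty margins, got {frame.shape}"
        )
    stat, p, df, _ = stats.chi2_contingency(frame.to_numpy(), correction=False)
    return Chi2Result(float(stat), int(df), float(p), frame)


def _pair_chi2(a: tuple[int, int], b: tuple[int, int]) -> float:
    """p-value of the 2x2 concordant/discordant comparison (Pearson, no
    correction); identical proportions or empty margins give p = 1."""
    arr = np.array([a, b], dtype=float)
    if (arr.sum(axis=0) == 0).any():
        return 1.0
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p)


def pairwise_posthoc(
    crosstab: CrossTab, alpha: float = 0.05
) -> tuple[list[PosthocPair], list[tuple[str, str]]]:
    """Bonferroni-corrected pairwise comparisons of per-category concordance.

    For every unordered pair of TE categories with non-zero totals, a 2x2
    Pearson chi-square compares concordant vs discordant counts; raw
    p-values are multiplied by the number of tested pairs (capped at 1).
    Pairs involving a zero-total row are skipped and returned separately.
    """
    summary = rates(crosstab)
    nonempty = [l for l in _LABELS if summary.rows[l].total > 0]
    skipped = [
        pair
        for pair in combinations(_LABELS, 2)
        if pair[0] not in nonempty or pair[1] not in nonempty
    ]
    pairs = list(combinations(nonempty, 2))
    results = []
    for a, b in pairs:
        ra, rb = summary.rows[a], summary.rows[b]
        table = (
            (ra.concordant, ra.total - ra.concordant),
            (rb.concordant, rb.total - rb.concordant),
        )
        p_raw = _pair_chi2(*table)
        p_adj = min(1.0, p_raw * len(pairs))
        results.append(
            PosthocPair((a, b), table, p_raw, p_adj, bool(p_adj < alpha))
        )
    return results, skipped


# ---------------------------------------------------------------------------
# Model / Results surface


class ConcordanceModel:
    """Concordance analysis of a cohort of paired TE/ICM records.

    Parameters
    ----------
    records : iterable of EmbryoRecord
    thresholds : ClassificationThresholds, optional
    use_labels : bool
        Tabulate pre-assigned category labels instead of re-classifying
        profiles (labels fall back to profiles where absent).
    alpha : float
        Significance level for the post hoc comparisons.
    """

    def __init__(
        self,
        records: Iterable[EmbryoRecord],
        thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
        use_labels: bool = False,
        alpha: float = 0.05,
        precedence: Sequence[Category] = DEFAULT_PRECEDENCE,
    ) -> None:
        self.records = list(records)
        self.thresholds = thresholds
        self.use_labels = use_labels
        self.alpha = alpha
        self.precedence = tuple(precedence)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ConcordanceModel":
        from .io import records_from_frame

        records, errors = records_from_frame(frame)
        for err in errors:
            log.warning("skipping row: %s", err)
        return cls(records, **kwargs)

    def fit(self) -> "ConcordanceResults":
        crosstab = build_crosstab(
            self.records, self.thresholds, self.precedence, self.use_labels
        )
        summary = rates(crosstab)
        try:
            chi2 = chisq_independence(crosstab)
        except ValueError as exc:
            log.info("chi-square unavailable: %s", exc)
            chi2 = None
        posthoc, skipped = pairwise_posthoc(crosstab, self.alpha)
        return ConcordanceResults(
            model=self,
            crosstab=crosstab,
            rates=summary,
            chi2=chi2,
            posthoc=posthoc,
            posthoc_skipped=skipped,
        )


@dataclass(frozen=True)
class ConcordanceResults:
    model: ConcordanceModel
    crosstab: CrossTab
    rates: RateSummary
    chi2: Chi2Result | None
    posthoc: list[PosthocPair]
    posthoc_skipped: list[tuple[str, str]]

    @property
    def overall(self) -> tuple[int, int, float | None]:
        return overall_concordance(self.crosstab)

    def summary(self) -> str:
        lines = ["TE-ICM concordance analysis", "=" * 60]
        lines.append(f"n = {self.crosstab.overall_n} embryos"
                     + (f" ({len(self.crosstab.excluded)} excluded)"
                        if self.crosstab.excluded else ""))
        lines.append("")
        lines.append("Cross-tab (rows: TE, columns: ICM):")
        lines.append(self.crosstab.counts.to_string())
        lines.append("")
        lines.append("Per-TE-category rates:")
        lines.append(self.rates.to_frame().to_string())
        diag, n, rate = self.overall
        if rate is not None:
            lines.append(
                f"Overall concordance: {diag}/{n} = {round_half_up(100 * rate)}%"
            )
        if self.chi2 is not None:
            lines.append(
                f"Chi-square: stat={self.chi2.statistic:.3f}, df={self.chi2.df}, "
                f"p={self.chi2.pvalue:.3g}"
            )
        if self.posthoc:
            lines.append(f"Post hoc (Bonferroni over {len(self.posthoc)} pairs):")
            for pr in self.posthoc:
                mark = "*" if pr.significant else " "
                lines.append(
                    f"  {pr.pair[0]:>5} vs {pr.pair[1]:<5} p_adj={pr.p_adjusted:.3g} {mark}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        diag, n, rate = self.overall
        return {
            "categories": _LABELS,
            "counts": self.crosstab.counts.to_numpy().tolist(),
            "excluded": list(self.crosstab.excluded),
            "rates": {
                label: {
                    "concordant": r.concordant,
                    "icm_euploid": r.icm_euploid,
                    "total": r.total,
                    "concordance": r.concordance,
                    "concordance_pct": (
                        round_half_up(100 * r.concordance) if r.total else None
                    ),
                    "icm_euploidy": r.icm_euploidy,
                    "icm_euploidy_pct": (
                        round_half_up(100 * r.icm_euploidy) if r.total else None
                    ),
                }
                for label, r in self.rates.rows.items()
            },
            "overall": {"concordant": diag, "total": n, "rate": rate},
            "chi_square": (
                None
                if self.chi2 is None
                else {
                    "statistic": self.chi2.statistic,
                    "df": self.chi2.df,
                    "pvalue": self.chi2.pvalue,
                }
            ),
            "posthoc": [
                {
                    "pair": list(pr.pair),
                    "table": [list(row) for row in pr.table],
                    "p_raw": pr.p_raw,
                    "p_adjusted": pr.p_adjusted,
                    "significant": pr.significant,
                }
                for pr in self.posthoc
            ],
            "posthoc_skipped": [list(p) for p in self.posthoc_skipped],
        }
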