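"""Cross-tabulation, rates, chi-square and post hoc comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from segconcord.classify import Category
from segconcord.concordance import (
    ConcordanceModel,
    CrossTab,
    build_crosstab,
    chisq_independence,
    overall_concordance,
    pairwise_posthoc,
    rates,
)
from segconcord.records import EmbryoRecord

_LABELS = [c.label for c in Category.__members__.values()]


def _labelled(eid, te, icm):
    return EmbryoRecord(embryo_id=eid, te_label=te, icm_label=icm)


class TestBuildCrosstab:
    def test_fixture_published_labels_row(self, cohort):
        """Tallying the published ICM classifications of the 36 full-segmental
        TE embryos: 7 euploid, 18 segmental mosaic, 9 concordant, 2
        whole-chromosome aneuploid."""
        ct = build_crosstab(cohort, use_labels=True)
        row = ct.counts.loc["Seg-A"]
        assert row["EU"] == 7
        assert row["Seg-M"] == 18
        assert row["Seg-A"] == 9
        assert row["Who-A"] == 2
        assert row["Who-M"] == 0
        assert ct.overall_n == 36

    def test_empty_input_gives_zero_table(self):
        ct = build_crosstab([])
        assert ct.overall_n == 0
        assert (ct.counts.to_numpy() == 0).all()

    def test_duplication_doubles_counts(self, cohort):
        once = build_crosstab(cohort, use_labels=True)
        twice = build_crosstab(list(cohort) * 2, use_labels=True)
        assert (twice.counts.to_numpy() == 2 * once.counts.to_numpy()).all()

    def test_record_order_never_matters(self, cohort):
        fwd = build_crosstab(cohort, use_labels=True)
        rev = build_crosstab(list(reversed(cohort)), use_labels=True)
        assert fwd.counts.equals(rev.counts)

    def test_row_totals_match_cells(self, cohort):
        ct = build_crosstab(cohort, use_labels=True)
        assert (ct.row_totals == ct.counts.sum(axis=1)).all()
        assert ct.overall_n == ct.row_totals.sum()


class TestRates:
    def test_fixture_sega_rates(self, cohort):
        summary = rates(build_crosstab(cohort, use_labels=True))
        sega = summary.rows["Seg-A"]
        assert (sega.concordant, sega.total) == (9, 36)
        assert sega.concordance == pytest.approx(0.25)
        assert (sega.icm_euploid, sega.total) == (7, 36)
        assert round(100 * sega.icm_euploidy) == 19

    def test_identity_table_fully_concordant(self):
        counts = pd.DataFrame(
            np.diag([3, 4, 5, 6, 7]), index=_LABELS, columns=_LABELS
        )
        summary = rates(CrossTab(counts))
        assert all(r.concordance == 1.0 for r in summary.rows.values())

    def test_zero_rows_undefined(self):
        summary = rates(CrossTab(pd.DataFrame(0, index=_LABELS, columns=_LABELS)))
        assert all(r.concordance is None for r in summary.rows.values())

    def test_overall_is_weighted_mean_of_rows(self, cohort):
        ct = build_crosstab(cohort, use_labels=True)
        summary = rates(ct)
        diag, n, rate = overall_concordance(ct)
        weighted = sum(
            r.concordance * r.total for r in summary.rows.values() if r.total
        ) / n
        assert rate == pytest.approx(weighted)


class TestChiSquare:
    def test_no_association_is_zero(self):
        res = chisq_independence([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # E = 12.5 in every cell; sum of (7.5)^2/12.5 over 4 cells = 18
        res = chisq_independence([[20, 5], [5, 20]])
        assert res.statistic == pytest.approx(18.0)
        assert res.df == 1

    def test_empty_margins_dropped_reduce_df(self):
        table = pd.DataFrame(
            [[10, 5, 0], [3, 12, 0], [0, 0, 0]],
            index=["a", "b", "c"],
            columns=["x", "y", "z"],
        )
        res = chisq_independence(table)
        assert res.table.shape == (2, 2)
        assert res.df == 1

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError):
            chisq_independence([[5, 5]])

    @given(
        obs=arrays(
            np.int64,
            (5, 5),
            elements=st.integers(0, 40),
        ).filter(
            lambda a: (a.sum(axis=1) > 0).sum() >= 2 and (a.sum(axis=0) > 0).sum() >= 2
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_pearson_sum(self, obs):
        """Independent oracle: explicit sum of (O-E)^2/E over non-empty cells."""
        a = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0].astype(float)
        rowsum = a.sum(axis=1, keepdims=True)
        colsum = a.sum(axis=0, keepdims=True)
        expected = rowsum @ colsum / a.sum()
        brute = float(((a - expected) ** 2 / expected).sum())
        res = chisq_independence(pd.DataFrame(obs))
        assert res.statistic == pytest.approx(brute, rel=1e-9, abs=1e-9)
        assert res.df == (a.shape[0] - 1) * (a.shape[1] - 1)


class TestPosthoc:
    @staticmethod
    def _table(rows):
        counts = pd.DataFrame(0, index=_LABELS, columns=_LABELS)
        for label, conc, disc in rows:
            counts.loc[label, label] = conc
            other = next(l for l in _LABELS if l != label)
            counts.loc[label, other] += disc
        return CrossTab(counts)

    def test_strong_difference_survives_bonferroni(self):
        # concordance 49/52 vs 9/36: chi-square p on the 1e-9 scale, so it
        # stays significant even after correcting for 10 pairs
        ct = self._table([("Who-A", 49, 3), ("Seg-A", 9, 27)])
        results, _ = pairwise_posthoc(ct)
        (pair,) = [r for r in results if set(r.pair) == {"Who-A", "Seg-A"}]
        assert pair.p_raw < 1e-8
        assert pair.significant

    def test_identical_rows_not_significant(self):
        ct = self._table([("EU", 10, 10), ("Seg-A", 10, 10)])
        results, _ = pairwise_posthoc(ct)
        (pair,) = results
        assert pair.p_adjusted == pytest.approx(1.0)
        assert not pair.significant

    def test_single_nonempty_row_yields_nothing(self, cohort):
        ct = build_crosstab(cohort, use_labels=True)
        results, skipped = pairwise_posthoc(ct)
        assert results == []
        assert len(skipped) == 10  # all pairs involve a zero-total row

    def test_bonferroni_caps_at_one(self):
        ct = self._table([("EU", 5, 5), ("Seg-A", 5, 5), ("Seg-M", 4, 6)])
        results, _ = pairwise_posthoc(ct)
        assert all(r.p_adjusted <= 1.0 for r in results)


class TestModelSurface:
    def test_fit_bundles_everything(self, cohort):
        res = ConcordanceModel(cohort, use_labels=True).fit()
        assert res.crosstab.overall_n == 36
        assert res.chi2 is None  # single non-empty TE row: test undefined
        assert "Seg-A" in res.summary()
        d = res.to_dict()
        assert d["rates"]["Seg-A"]["concordance_pct"] == 25

    def test_label_records_without_profiles(self):
        recs = [
            _labelled("a", Category.EU, Category.EU),
            _labelled("b", Category.WHO_A, Category.WHO_A),
            _labelled("c", Category.WHO_A, Category.EU),
        ]
        res = ConcordanceModel(recs, use_labels=True).fit()
        assert res.crosstab.counts.loc["Who-A", "Who-A"] == 1
        assert res.crosstab.counts.loc["Who-A", "EU"] == 1
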