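"""Clonal-mosaicism simulator: generative structure, observation model,
reproducibility and origin-mixture limits."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from segconcord.classify import Category, classify_profile
from segconcord.concordance import ConcordanceModel
from segconcord.simdata import (
    Clone,
    OriginMixtureModel,
    SimParams,
    TrueEmbryo,
    biopsy,
    cohort_to_frame,
    fit_origin_mixture,
    generate_embryo,
    simulate_cohort,
    truth_to_frame,
)
from segconcord.karyo import Dosage, Scope, SegmentCall


def _params(**kw):
    base = dict(
        seed=11,
        n_embryos=50,
        p_meiotic_whole=0.0,
        p_meiotic_segmental=0.0,
        p_mitotic=0.0,
        p_artifact=0.0,
    )
    base.update(kw)
    return SimParams(**base)


def _aberrant_embryo(fraction):
    call = SegmentCall(
        chromosome="7",
        scope=Scope.SEGMENTAL,
        dosage=Dosage.LOSS,
        level=100.0,
        region="7q11.1~22.2",
        size_mb=40.0,
    )
    clones = (
        (Clone(1.0, (call,)),)
        if fraction == 1.0
        else (Clone(1.0 - fraction), Clone(fraction, (call,)))
    )
    return TrueEmbryo(clones=clones)


class TestGenerateEmbryo:
    def test_meiotic_whole_is_monoclonal(self):
        rng = np.random.default_rng(0)
        embryo, truth = generate_embryo(_params(p_meiotic_whole=1.0), rng)
        (clone,) = embryo.clones
        assert clone.fraction == 1.0
        (call,) = clone.karyotype
        assert call.scope is Scope.WHOLE_CHROMOSOME and call.is_full
        assert truth["origin"] == "meiotic_whole"

    def test_mitotic_first_division_clone_is_half(self):
        rng = np.random.default_rng(0)
        params = _params(p_mitotic=1.0, mitotic_division_range=(1, 1))
        embryo, truth = generate_embryo(params, rng)
        assert truth["origin"] == "mitotic"
        assert truth["clone_fraction"] == pytest.approx(0.5)
        assert any(c.karyotype and c.fraction == 0.5 for c in embryo.clones)

    def test_all_mass_zero_gives_euploid(self):
        rng = np.random.default_rng(0)
        embryo, truth = generate_embryo(_params(), rng)
        assert all(not c.karyotype for c in embryo.clones)
        assert truth["origin"] == "euploid"

    def test_division_range_respected(self):
        rng = np.random.default_rng(1)
        params = _params(p_mitotic=1.0, mitotic_division_range=(3, 3))
        _, truth = generate_embryo(params, rng)
        assert truth["division"] == 3
        assert truth["clone_fraction"] == pytest.approx(2.0 ** -3)


class TestBiopsy:
    def test_monoclonal_aberrant_reads_level_100(self):
        rng = np.random.default_rng(0)
        prof = biopsy(_aberrant_embryo(1.0), 7, rng)
        (call,) = prof.calls
        assert call.level == 100.0

    def test_euploid_embryo_reads_empty(self):
        rng = np.random.default_rng(0)
        prof = biopsy(TrueEmbryo(clones=(Clone(1.0),)), 6, rng)
        assert prof.calls == ()

    def test_levels_quantized_to_zero_are_omitted(self):
        rng = np.random.default_rng(0)
        embryo = _aberrant_embryo(0.5)
        seen = set()
        for _ in range(200):
            prof = biopsy(embryo, 6, rng)
            for c in prof.calls:
                seen.add(c.level)
        assert 0.0 not in seen
        assert seen <= {20.0, 30.0, 50.0, 70.0, 80.0, 100.0}

    def test_observed_level_follows_exact_binomial_law(self):
        """For clone fraction 1/2 in a 6-cell biopsy the reported level is
        100*Binomial(6, 0.5)/6 quantized to 10s; the empirical histogram over
        10^4 draws must match that law."""
        rng = np.random.default_rng(42)
        embryo = _aberrant_embryo(0.5)
        n, draws = 6, 10_000
        observed = np.zeros(n + 1)
        for _ in range(draws):
            prof = biopsy(embryo, n, rng)
            level = prof.calls[0].level if prof.calls else 0.0
            # invert the quantization: each k maps to a distinct level
            k = min(
                range(n + 1),
                key=lambda kk: abs(math.floor(100 * kk / n / 10 + 0.5) * 10 - level),
            )
            observed[k] += 1
        expected = stats.binom.pmf(np.arange(n + 1), n, 0.5) * draws
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        # 7 bins -> df 6; 99.9th percentile ~ 22.5
        assert chi2 < stats.chi2.ppf(0.999, df=6)

    def test_mean_level_matches_clone_fraction(self):
        rng = np.random.default_rng(3)
        embryo = _aberrant_embryo(0.5)
        levels = []
        for _ in range(4000):
            prof = biopsy(embryo, 8, rng)
            levels.append(prof.calls[0].level if prof.calls else 0.0)
        assert np.mean(levels) == pytest.approx(50.0, abs=1.5)

    def test_artifact_appends_spurious_full_segmental(self):
        rng = np.random.default_rng(0)
        params = _params()
        prof = biopsy(
            TrueEmbryo(clones=(Clone(1.0),)), 6, rng, p_artifact=1.0, params=params
        )
        (call,) = prof.calls
        assert call.scope is Scope.SEGMENTAL and call.is_full
        assert params.segment_size_range_mb[0] <= call.size_mb <= params.segment_size_range_mb[1]


class TestSimulateCohort:
    def test_pure_meiotic_whole_is_fully_concordant(self):
        params = _params(p_meiotic_whole=1.0, n_embryos=40)
        res = ConcordanceModel(simulate_cohort(params)).fit()
        assert res.crosstab.counts.loc["Who-A", "Who-A"] == 40
        assert res.overall[2] == 1.0

    def test_pure_euploid_cohort_is_all_eu(self):
        params = _params(n_embryos=30)
        res = ConcordanceModel(simulate_cohort(params)).fit()
        assert res.crosstab.counts.loc["EU", "EU"] == 30

    def test_same_seed_reproduces_identical_tsv_bytes(self):
        params = SimParams(seed=123, n_embryos=60)
        a = cohort_to_frame(simulate_cohort(params)).to_csv(sep="\t", index=False)
        b = cohort_to_frame(simulate_cohort(params)).to_csv(sep="\t", index=False)
        assert a.encode() == b.encode()
        ta = truth_to_frame(simulate_cohort(params)).to_csv(sep="\t", index=False)
        tb = truth_to_frame(simulate_cohort(params)).to_csv(sep="\t", index=False)
        assert ta == tb

    def test_different_seeds_differ(self):
        a = cohort_to_frame(simulate_cohort(SimParams(seed=1, n_embryos=60)))
        b = cohort_to_frame(simulate_cohort(SimParams(seed=2, n_embryos=60)))
        assert not a.equals(b)

    def test_truth_sidecar_covers_every_embryo(self):
        records = simulate_cohort(SimParams(seed=5, n_embryos=25))
        truth = truth_to_frame(records)
        assert list(truth["embryo_id"]) == [r.embryo_id for r in records]
        assert set(truth["origin"]) <= {
            "euploid",
            "meiotic_whole",
            "meiotic_segmental",
            "mitotic",
        }

    def test_lineage_bias_enriches_icm(self):
        """With full positive bias the aberrant clone concentrates in the ICM
        sample and is depleted from the TE biopsy."""
        params = _params(
            p_mitotic=1.0,
            mitotic_division_range=(1, 1),
            mitotic_whole_fraction=0.0,
            lineage_bias=0.8,
            n_embryos=150,
            seed=9,
        )
        records = simulate_cohort(params)

        def mean_level(profiles):
            levels = [max((c.level for c in p.calls), default=0.0) for p in profiles]
            return np.mean(levels)

        assert mean_level(r.icm for r in records) > mean_level(r.te for r in records)


class TestOriginMixture:
    def test_artifact_only_cohort_recovers_artifact_weight(self):
        params = _params(p_artifact=1.0, n_embryos=300, seed=21)
        records = simulate_cohort(params)
        res = fit_origin_mixture(records, params, n_mc=4000)
        assert res.weights["artifact"] > 0.9
        lo, hi = res.conf_ints["artifact"]
        assert hi == pytest.approx(1.0)

    def test_single_record_has_wide_intervals(self):
        params = _params(p_meiotic_segmental=1.0, seed=3)
        res = OriginMixtureModel([Category.SEG_A], params, n_mc=3000).fit()
        widths = [hi - lo for lo, hi in res.conf_ints.values()]
        assert all(w > 0.5 for w in widths)
        assert res.n == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            OriginMixtureModel([], _params())

    def test_summary_lists_components(self):
        params = _params(p_meiotic_segmental=1.0, n_embryos=80, seed=4)
        records = simulate_cohort(params)
        res = fit_origin_mixture(records, params, n_mc=3000)
        text = res.summary()
        for origin in ("meiotic_segmental", "mitotic", "artifact"):
            assert origin in text
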