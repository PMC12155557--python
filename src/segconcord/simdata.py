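"""Synthetic blastocyst cohorts under a clonal-mosaicism generative model.

The generator embodies the mechanism the concordance analysis presumes:

* **meiotic** errors arise in the gametes, so every cell of the embryo
  carries the aberration (one clone, fraction 1);
* **mitotic** errors arise at cleavage division ``d``, producing one
  aberrant clone of fraction ``2^-d`` (synchronous divisions, no selection
  by default; an optional per-division survival penalty can deplete the
  aberrant clone);
* a small TE biopsy (5-10 cells) and an ICM sample (10 cells) each draw
  cells multinomially from the clone fractions, and each aberration is
  reported at level ``100 * aberrant cells / sampled cells`` quantized to
  the platform's 10% reporting step (levels quantized to 0 vanish);
* with probability ``p_artifact`` the TE biopsy acquires one spurious full
  segmental call, mimicking an S-phase/amplification artifact.

Because a trisomic cell is simply aberrant or not, intermediate mosaicism
levels are pure sampling noise plus quantization: the observed level for a
clone of fraction *f* in an *n*-cell biopsy is ``100*Binomial(n, f)/n``
quantized.  That observation model is what makes small biopsies of mitotic
clones so often discordant with the ICM.

:class:`OriginMixtureModel` inverts the same observation model: given the
ICM categories of embryos whose TE read as full segmental aneuploid, it
estimates by grid-search maximum likelihood what fraction of those TE
results were meiotic (true in every cell), mitotic (clonal), or artifact
(spurious call on a euploid embryo), with profile-likelihood intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CATEGORY_ORDER, Category, classify_profile
from .karyo import (
    BiopsyProfile,
    ClassificationThresholds,
    DEFAULT_THRESHOLDS,
    Dosage,
    Scope,
    SegmentCall,
)
from .records import EmbryoRecord

__all__ = [
    "Clone",
    "TrueEmbryo",
    "SimParams",
    "generate_embryo",
    "biopsy",
    "simulate_cohort",
    "cohort_to_frame",
    "truth_to_frame",
    "OriginMixtureModel",
    "OriginMixtureResults",
    "fit_origin_mixture",
]

log = logging.getLogger(__name__)

ORIGINS = ("euploid", "meiotic_whole", "meiotic_segmental", "mitotic", "artifact")
_MIXTURE_COMPONENTS = ("meiotic_segmental", "mitotic", "artifact")


@dataclass(frozen=True)
class Clone:
    """A clonal subpopulation: its cell fraction and (full) karyotype calls."""

    fraction: float
    karyotype: tuple[SegmentCall, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"clone fraction must be in [0, 1], got {self.fraction}")
        for call in self.karyotype:
            if not call.is_full:
                raise ValueError(
                    "clone karyotypes are per-cell states and must be full calls"
                )


@dataclass(frozen=True)
class TrueEmbryo:
    """Ground-truth embryo: clone structure plus lineage cell counts."""

    clones: tuple[Clone, ...]
    te_cells: int = 100
    icm_cells: int = 30
    sex: str = "XX"

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation parameters.

    The origin mixture (``p_meiotic_whole + p_meiotic_segmental + p_mitotic
    <= 1``, remainder euploid) is drawn per embryo; ``p_artifact`` acts at
    the TE biopsy, not the embryo.  Defaults echo a clinical PGT-A case mix
    dominated by whole-chromosome aneuploidy and segmental mosaicism, with
    biopsy sizes of 5-10 cells and segment sizes of 10-140 Mb.
    ``seed`` is mandatory: identical params reproduce identical cohorts.
    """

    seed: int
    n_embryos: int = 175
    p_meiotic_whole: float = 0.30
    p_meiotic_segmental: float = 0.15
    p_mitotic: float = 0.40
    mitotic_whole_fraction: float = 0.5
    mitotic_division_range: tuple[int, int] = (1, 5)
    segment_size_range_mb: tuple[float, float] = (10.0, 140.0)
    biopsy_size_range: tuple[int, int] = (5, 10)
    icm_sample_size: int = 10
    p_artifact: float = 0.05
    artifact_in_icm: bool = False
    reporting_quantum: float = 10.0
    lineage_bias: float = 0.0
    mitotic_selection: float = 0.0

    def __post_init__(self) -> None:
        probs = (self.p_meiotic_whole, self.p_meiotic_segmental, self.p_mitotic)
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1 + 1e-12:
            raise ValueError("origin mixture probabilities must lie in [0,1] and sum <= 1")
        if not 0 <= self.p_artifact <= 1:
            raise ValueError("p_artifact must be in [0, 1]")
        for lo, hi in (
            self.mitotic_division_range,
            self.segment_size_range_mb,
            self.biopsy_size_range,
        ):
            if lo > hi:
                raise ValueError("ranges must be non-empty (lo <= hi)")
        if self.n_embryos < 0 or self.icm_sample_size < 1:
            raise ValueError("n_embryos must be >= 0 and icm_sample_size >= 1")
        if not 0 <= self.mitotic_selection < 1:
            raise ValueError("mitotic_selection must be in [0, 1)")
        if not -1 <= self.lineage_bias <= 1:
            raise ValueError("lineage_bias must be in [-1, 1]")


# plausible sub-band labels for synthetic segment endpoints
_SYN_BANDS = ("11.1", "12.3", "13.2", "21.1", "22.2", "24.3", "31.2", "33.1")


def _synthetic_segment(
    rng: np.random.Generator, params: SimParams, level: float = 100.0
) -> SegmentCall:
    """A grammar-valid synthetic segmental call with a drawn size."""
    chrom = str(int(rng.integers(1, 23)))
    arm = "p" if rng.random() < 0.5 else "q"
    b1, b2 = sorted(rng.choice(len(_SYN_BANDS), size=2, replace=False))
    lo, hi = params.segment_size_range_mb
    size = float(np.round(rng.uniform(lo, hi), 1))
    return SegmentCall(
        chromosome=chrom,
        scope=Scope.SEGMENTAL,
        dosage=Dosage.GAIN if rng.random() < 0.5 else Dosage.LOSS,
        level=level,
        region=f"{chrom}{arm}{_SYN_BANDS[b1]}~{arm}{_SYN_BANDS[b2]}",
        size_mb=size,
    )


def _whole_call(rng: np.random.Generator) -> SegmentCall:
    return SegmentCall(
        chromosome=str(int(rng.integers(1, 23))),
        scope=Scope.WHOLE_CHROMOSOME,
        dosage=Dosage.GAIN if rng.random() < 0.5 else Dosage.LOSS,
        level=100.0,
    )


def generate_embryo(
    params: SimParams, rng: np.random.Generator
) -> tuple[TrueEmbryo, dict]:
    """Draw one embryo and its ground-truth record.

    Meiotic errors occupy a single clone of fraction 1; mitotic errors one
    aberrant clone of fraction ``2^-d`` for a uniform division ``d`` (shrunk
    further if ``mitotic_selection`` > 0); the remainder of the mixture mass
    yields a fully euploid embryo.
    """
    sex = "XX" if rng.random() < 0.5 else "XY"
    u = rng.random()
    p1 = params.p_meiotic_whole
    p2 = p1 + params.p_meiotic_segmental
    p3 = p2 + params.p_mitotic
    truth = {"origin": "euploid", "division": None, "clone_fraction": 0.0}
    if u < p1:
        clones = (Clone(1.0, (_whole_call(rng),)),)
        truth.update(origin="meiotic_whole", clone_fraction=1.0)
    elif u < p2:
        clones = (Clone(1.0, (_synthetic_segment(rng, params),)),)
        truth.update(origin="meiotic_segmental", clone_fraction=1.0)
    elif u < p3:
        lo, hi = params.mitotic_division_range
        d = int(rng.integers(lo, hi + 1))
        f = 2.0 ** -d
        if params.mitotic_selection:
            w = f * (1 - params.mitotic_selection) ** d
            f = w / (w + (1 - f))
        call = (
            _whole_call(rng)
            if rng.random() < params.mitotic_whole_fraction
            else _synthetic_segment(rng, params)
        )
        clones = (Clone(1.0 - f), Clone(f, (call,)))
        truth.update(origin="mitotic", division=d, clone_fraction=f)
    else:
        clones = (Clone(1.0),)
    return TrueEmbryo(clones=clones, sex=sex), truth


def _quantize(level: float, quantum: float) -> float:
    return min(100.0, math.floor(level / quantum + 0.5) * quantum)


def _lineage_fractions(embryo: TrueEmbryo, bias: float) -> np.ndarray:
    """Clone fractions as seen by one lineage; ``bias`` > 0 enriches the
    aberrant clones in that lineage (well-mixed at 0)."""
    frac = np.array([c.fraction for c in embryo.clones], dtype=float)
    if bias:
        weight = np.array(
            [1.0 + bias if c.karyotype else 1.0 for c in embryo.clones]
        )
        frac = frac * weight
    return frac / frac.sum()


def biopsy(
    embryo: TrueEmbryo,
    n_cells: int,
    rng: np.random.Generator,
    quantum: float = 10.0,
    p_artifact: float = 0.0,
    params: SimParams | None = None,
    fractions: np.ndarray | None = None,
) -> BiopsyProfile:
    """Sample ``n_cells`` cells and report the quantized mosaicism levels.

    Each aberration is observed at ``100 * aberrant cells / n_cells``
    rounded to the reporting quantum; levels that quantize to 0 are omitted.
    With probability ``p_artifact`` one spurious full segmental call is
    appended (``params`` supplies its size range).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if fractions is None:
        fractions = np.array([c.fraction for c in embryo.clones], dtype=float)
    counts = rng.multinomial(n_cells, fractions / fractions.sum())
    calls: list[SegmentCall] = []
    for clone, k in zip(embryo.clones, counts):
        if k == 0 or not clone.karyotype:
            continue
        level = _quantize(100.0 * k / n_cells, quantum)
        if level <= 0:
            continue
        for template in clone.karyotype:
            calls.append(replace(template, level=level))
    if p_artifact and rng.random() < p_artifact:
        calls.append(
            _synthetic_segment(rng, params or SimParams(seed=0), level=100.0)
        )
    return BiopsyProfile(sex=embryo.sex, calls=tuple(calls))


def simulate_cohort(params: SimParams) -> list[EmbryoRecord]:
    """Simulate a full cohort of paired TE/ICM records.

    Each embryo receives one TE biopsy (uniform size in
    ``biopsy_size_range``, artifact-prone) and one ICM sample
    (``icm_sample_size`` cells, artifact-free by default).  Ground truth
    (origin, division, clone fraction) travels in each record's ``meta``.
    Identical params (including seed) produce identical cohorts.
    """
    rng = np.random.default_rng(params.seed)
    records: list[EmbryoRecord] = []
    for i in range(params.n_embryos):
        embryo, truth = generate_embryo(params, rng)
        n_te = int(rng.integers(params.biopsy_size_range[0], params.biopsy_size_range[1] + 1))
        te = biopsy(
            embryo,
            n_te,
            rng,
            quantum=params.reporting_quantum,
            p_artifact=params.p_artifact,
            params=params,
            fractions=_lineage_fractions(embryo, -params.lineage_bias),
        )
        icm = biopsy(
            embryo,
            params.icm_sample_size,
            rng,
            quantum=params.reporting_quantum,
            p_artifact=params.p_artifact if params.artifact_in_icm else 0.0,
            params=params,
            fractions=_lineage_fractions(embryo, params.lineage_bias),
        )
        records.append(
            EmbryoRecord(
                embryo_id=f"SIM{i + 1:04d}",
                te=te,
                icm=icm,
                provenance="simulated",
                meta={**truth, "te_cells_sampled": n_te},
            )
        )
    return records


def cohort_to_frame(records: Iterable[EmbryoRecord]) -> pd.DataFrame:
    """Cohort as the TSV schema the pipeline reads back."""
    from .karyo import render_profile

    rows = []
    for rec in records:
        te_sizes = ";".join(
            "" if c.size_mb is None else f"{c.size_mb:g}" for c in (rec.te.calls if rec.te else ())
        )
        rows.append(
            {
                "embryo_id": rec.embryo_id,
                "grade": rec.grade or "",
                "day": rec.day or "",
                "te_profile": render_profile(rec.te) if rec.te else "",
                "te_size_mb": te_sizes,
                "icm_profile": render_profile(rec.icm) if rec.icm else "",
            }
        )
    return pd.DataFrame(rows)


def truth_to_frame(records: Iterable[EmbryoRecord]) -> pd.DataFrame:
    """Ground-truth sidecar (embryo_id, origin, division, clone_fraction)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "embryo_id": rec.embryo_id,
                "origin": rec.meta.get("origin", ""),
                "division": rec.meta.get("division", ""),
                "clone_fraction": rec.meta.get("clone_fraction", ""),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Origin-mixture estimation


def _component_params(params: SimParams, origin: str, n_mc: int, seed: int) -> SimParams:
    base = replace(
        params,
        n_embryos=n_mc,
        seed=seed,
        p_meiotic_whole=0.0,
        p_meiotic_segmental=0.0,
        p_mitotic=0.0,
        p_artifact=0.0,
    )
    if origin == "meiotic_segmental":
        return replace(base, p_meiotic_segmental=1.0)
    if origin == "mitotic":
        return replace(base, p_mitotic=1.0)
    if origin == "artifact":
        return replace(base, p_artifact=1.0)
    raise ValueError(f"unknown origin {origin!r}")


def origin_components(
    params: SimParams,
    n_mc: int = 20000,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, tuple[float, np.ndarray]]:
    """Monte-Carlo observation-model components for the mixture fit.

    For each pure origin, simulate ``n_mc`` embryos under otherwise
    identical params and return ``(q, pi)`` where ``q`` is the probability
    that the TE biopsy reads full segmental aneuploid and ``pi`` the ICM
    category distribution conditional on that (Laplace-smoothed).
    """
    components = {}
    for idx, origin in enumerate(_MIXTURE_COMPONENTS):
        seed = (params.seed * 1_000_003 + 7919 * (idx + 1)) % (2**31 - 1)
        sub = simulate_cohort(_component_params(params, origin, n_mc, seed))
        icm_counts = np.zeros(len(CATEGORY_ORDER))
        n_sega = 0
        for rec in sub:
            if classify_profile(rec.te, thresholds) is Category.SEG_A:
                n_sega += 1
                icm = classify_profile(rec.icm, thresholds)
                icm_counts[CATEGORY_ORDER.index(icm)] += 1
        q = max(n_sega, 0.5) / n_mc
        pi = (icm_counts + 0.5) / (icm_counts.sum() + 0.5 * len(CATEGORY_ORDER))
        components[origin] = (q, pi)
    return components


@dataclass(frozen=True)
class OriginMixtureResults:
    """Grid-search MLE of the origin mixture behind full-segmental TE calls."""

    weights: Mapping[str, float]
    conf_ints: Mapping[str, tuple[float, float]]
    loglik: float
    n: int
    counts: Mapping[str, int]
    components: Mapping[str, tuple[float, Sequence[float]]]
    conf_level: float

    def summary(self) -> str:
        lines = [
            f"Origin mixture behind {self.n} full-segmental TE results",
            "=" * 60,
            f"{'origin':<20}{'weight':>8}{'{:.0f}% CI'.format(100 * self.conf_level):>18}",
        ]
        for origin in _MIXTURE_COMPONENTS:
            lo, hi = self.conf_ints[origin]
            lines.append(
                f"{origin:<20}{self.weights[origin]:>8.3f}"
                f"{f'[{lo:.2f}, {hi:.2f}]':>18}"
            )
        lines.append(f"log-likelihood: {self.loglik:.3f}")
        return "\n".join(lines)


class OriginMixtureModel:
    """MLE of (meiotic_segmental, mitotic, artifact) weights from the ICM
    categories of embryos whose TE classified as full segmental aneuploid.

    The likelihood is multinomial over ICM category counts; each origin's
    conditional category distribution and its probability of producing a
    full-segmental TE read come from Monte-Carlo runs of the simulator
    itself.  Weights are the *unconditional* origin shares (selection on the
    TE read is corrected via those probabilities) and are maximised on a
    0.01-step grid over the 2-simplex, with profile-likelihood intervals.
    """

    def __init__(
        self,
        icm_categories: Sequence[Category],
        params: SimParams,
        n_mc: int = 20000,
        grid_step: float = 0.01,
        thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    ) -> None:
        if len(icm_categories) == 0:
            raise ValueError("need at least one full-segmental TE record")
        self.icm_categories = list(icm_categories)
        self.params = params
        self.n_mc = n_mc
        self.grid_step = grid_step
        self.thresholds = thresholds

    def fit(self, conf_level: float = 0.95) -> OriginMixtureResults:
        components = origin_components(self.params, self.n_mc, self.thresholds)
        y = np.zeros(len(CATEGORY_ORDER))
        for cat in self.icm_categories:
            y[CATEGORY_ORDER.index(cat)] += 1
        q = np.array([components[o][0] for o in _MIXTURE_COMPONENTS])
        pi = np.vstack([components[o][1] for o in _MIXTURE_COMPONENTS])

        step = self.grid_step
        ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
        grid: list[tuple[float, float, float]] = []
        lls: list[float] = []
        for w1 in ticks:
            for w2 in ticks:
                w3 = 1.0 - w1 - w2
                if w3 < -1e-9:
                    continue
                w = np.array([w1, w2, max(w3, 0.0)])
                c = w * q
                tot = c.sum()
                if tot <= 0:
                    continue
                mix = (c / tot) @ pi
                with np.errstate(divide="ignore"):
                    ll = float(np.where(y > 0, y * np.log(mix), 0.0).sum())
                grid.append((w1, w2, w[2]))
                lls.append(ll)
        lls_arr = np.asarray(lls)
        best = int(np.argmax(lls_arr))
        ll_max = float(lls_arr[best])
        w_best = dict(zip(_MIXTURE_COMPONENTS, grid[best]))

        crit = stats.chi2.ppf(conf_level, df=1) / 2.0
        keep = lls_arr >= ll_max - crit
        conf_ints = {}
        for j, origin in enumerate(_MIXTURE_COMPONENTS):
            vals = np.array([g[j] for g in grid])[keep]
            conf_ints[origin] = (float(vals.min()), float(vals.max()))
        counts = {
            cat.label: int(y[i]) for i, cat in enumerate(CATEGORY_ORDER) if y[i]
        }
        return OriginMixtureResults(
            weights=w_best,
            conf_ints=conf_ints,
            loglik=ll_max,
            n=len(self.icm_categories),
            counts=counts,
            components={
                o: (components[o][0], components[o][1].tolist())
                for o in _MIXTURE_COMPONENTS
            },
            conf_level=conf_level,
        )


def fit_origin_mixture(
    records: Iterable[EmbryoRecord],
    params: SimParams,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    n_mc: int = 20000,
    grid_step: float = 0.01,
    conf_level: float = 0.95,
) -> OriginMixtureResults:
    """Fit the origin mixture from a cohort's full-segmental TE records.

    Filters the records whose TE profile classifies as full segmental
    aneuploid, takes their ICM categories, and runs
    :class:`OriginMixtureModel`.  Raises if no such record exists.
    """
    cats = []
    for rec in records:
        if rec.te is None or rec.icm is None:
            continue
        if classify_profile(rec.te, thresholds) is Category.SEG_A:
            cats.append(classify_profile(rec.icm, thresholds))
    model = OriginMixtureModel(cats, params, n_mc=n_mc, grid_step=grid_step,
                               thresholds=thresholds)
    return model.fit(conf_level)
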