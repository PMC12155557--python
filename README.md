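# segconcord

Trophectoderm–ICM chromosomal concordance analysis for PGT-A cohorts, with a
clonal-mosaicism biopsy simulator.

## What problem this addresses

In IVF, preimplantation genetic testing for aneuploidy (PGT-A) reads a 5–10
cell trophectoderm (TE) biopsy as a proxy for the whole embryo. For full
segmental aneuploidies (Seg-A) that proxy is unreliable: the inner cell mass
(ICM) — the lineage that becomes the fetus — is frequently euploid even when
the TE biopsy reads a full segmental gain or loss. `segconcord` is for
embryologists, genetic counsellors and PGT-A methodologists who want to
quantify that gap: it parses clinical call strings, assigns the five-way
blastocyst categories, cross-tabulates TE vs ICM with chi-square/post hoc
statistics, computes the predictive metrics of a TE result for ICM
implantation potential, and simulates cohorts under the meiotic/mitotic
clonal model that explains the discordance.

## The model in brief

Each call carries a mosaicism level *m* (percent aberrant cells, quantized
in 10% steps) and a scope. Categories: **EU** (all calls m < 25%), **Seg-M**
/ **Who-M** (segmental / whole-chromosome call with 25% ≤ m < 85%), **Seg-A**
/ **Who-A** (full calls, m ≥ 85%), with severity precedence
Who-A > Seg-A > Who-M > Seg-M for mixed profiles and a 10 Mb segmental
reporting floor. Concordance is categorical equality between the TE and ICM
assignments. An ICM has **low implantation potential** if it carries a full
call or a mosaic call with m > 50% (strictly); per abnormal TE category,
against the shared euploid-TE reference (FN, TN),

    sensitivity = TP/(TP+FN)   specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)           NPV = TN/(TN+FN)

The simulator draws embryo origins (meiotic errors in every cell; mitotic
errors in a clone of fraction 2⁻ᵈ), samples biopsies multinomially, and
quantizes the observed levels — so TE–ICM discordance emerges from binomial
sampling of small biopsies, plus an optional artifact rate. A grid-search
maximum-likelihood mixture model inverts this to estimate how many
full-segmental TE reads were meiotic, mitotic or artifactual. See
`docs/methods.md` for the full account.

## Worked example

The package ships a 36-embryo clinical cohort in which every TE biopsy read
full segmental aneuploid, with each embryo's published ICM profile:

```sh
segconcord concord src/segconcord/data/seg_aneuploid_cohort.tsv --labels-only
```

```
Cross-tab (rows: TE, columns: ICM):
       EU  Seg-A  Seg-M  Who-M  Who-A
Seg-A   7      9     18      0      2
...
Overall concordance: 9/36 = 25.0%
```

Only 9 of 36 ICMs confirm the TE's Seg-A call (25% concordance) and 7 of 36
ICMs are outright euploid (19%) — the central observation: a Seg-A TE result
is a weak predictor of the fetal lineage. The predictive metrics make the
same point as a diagnostic test, using the clinical series' euploid-TE
reference row (FN=1, TN=12):

```sh
segconcord metrics src/segconcord/data/seg_aneuploid_cohort.tsv \
    --reference-fn 1 --reference-tn 12
```

```
TE result    Low (TP) High (FP)    Sens    Spec     PPV     NPV
Euploidy            1        12            (reference: FN, TN)
Seg-A              17        19   94.4%   38.7%   47.2%   92.3%
```

Sensitivity is high (94.4%: a low-potential ICM is rarely missed) but
specificity is poor (38.7%) and PPV below half (47.2%): most embryos
"condemned" by a Seg-A TE result would have had usable ICMs. The same
objects are available from Python:

```python
import segconcord as sc
cohort = sc.load_fixture_cohort().records
print(sc.ConcordanceModel(cohort, use_labels=True).fit().summary())
print(sc.PotentialModel(cohort, reference_counts=(1, 12)).fit().summary())
```

Simulation and the origin-mixture estimator:

```python
params = sc.SimParams(seed=7, n_embryos=500)
records = sc.simulate_cohort(params)
print(sc.fit_origin_mixture(records, params).summary())
```

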