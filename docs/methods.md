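# Methods

## Problem and data model

Preimplantation genetic testing for aneuploidy (PGT-A) infers an embryo's
chromosomal status from a 5–10-cell trophectoderm (TE) biopsy, yet the inner
cell mass (ICM) — the lineage that forms the fetus — may differ from the TE,
particularly when the TE result is a segmental abnormality. `segconcord`
implements the categorical concordance analysis used to quantify that gap,
together with a generative simulator that reproduces the sampling mechanism
believed to cause it.

Inputs are per-embryo records pairing a TE call profile with an ICM call
profile, written in the clinical shorthand of NGS PGT-A reports
(`"loss 12p13.33~11.21"`, `"30% mosaic loss of chr6"`). Each call carries a
chromosome, a scope (segmental or whole-chromosome), a dosage (gain/loss), a
mosaicism level in percent (absent prefix = full call, level 100), and
optionally a segment size in Mb. Mosaicism levels are quantized in 10% steps
by the reporting platform; segmental calls are reportable from 10 Mb.

## Five-way classification

A profile is assigned exactly one of five categories from its calls:

| category | rule |
|---|---|
| EU | no call at or above the 25% mosaic floor |
| Seg-A | a full (non-mosaic) segmental call |
| Seg-M | a segmental call with level in [25%, 85%) |
| Who-A | a full whole-chromosome call |
| Who-M | a whole-chromosome call with level in [25%, 85%) |

Levels below 25% are background and never change the category. The boundary
at 85% is formally ambiguous in the clinical definition ("<85%" vs ">85%");
we treat level ≥ 85 as full. The 10% reporting quantum never emits 85, so the
choice is inert on clinical data but must be fixed for the simulator. Mixed
profiles are resolved by a severity precedence Who-A > Seg-A > Who-M > Seg-M,
inferred from how clinical reports label profiles that combine full
whole-chromosome with segmental findings; the order is configurable.
Segmental calls smaller than the 10 Mb floor are dropped with a warning
before classification.

On the packaged 36-embryo cohort the recomputed ICM categories agree with the
published labels in 35/36 rows. The single divergence is an ICM reported as
"30% mosaic loss of chr6" and labelled segmental mosaic in the source table;
a whole-chromosome mosaic call classifies as Who-M under the stated rules.
The fixture stores both the printed label and the recomputed one; concordance
tabulations use the printed column by default (`use_labels=True`).

## Concordance and statistics

Concordance is category-level equality between the TE and ICM assignments of
the same embryo (an optional stricter chromosome-level mode exists but feeds
no headline number). Per-TE-category concordance is the diagonal cell over
the row total of the 5×5 cross-tab; ICM euploidy is the EU-column cell over
the row total. Display rounding of these rates is half-up to integer percent.

The test of independence is the Pearson chi-square without continuity
correction (the SPSS default for r×c tables), computed via
`scipy.stats.chi2_contingency(correction=False)` after dropping all-zero
margins; a table reduced below 2×2 is reported as unavailable rather than
forced. Post hoc, every unordered pair of non-empty TE categories is compared
on concordant-vs-discordant counts in a 2×2 Pearson chi-square, with
Bonferroni adjustment by the number of tested pairs (capped at 1) at
α = 0.05. The source study does not define the pairwise contrast behind its
significance letters; comparing concordance proportions is this package's
choice and is configurable in principle via the functional API.

## Implantation potential and predictive metrics

An ICM is **low potential** if its profile contains any full call or any
mosaic call strictly above the 50% cutoff, else **high**. Two readings of
"below or above 50%" are possible; only the strict rule reproduces the
clinical confusion counts (one cohort profile's worst mosaic call sits
exactly at 50% and must count as high to give TP = 17). That derivation is
itself a test. Full calls are low potential regardless of the cutoff — the
whole-chromosome aneuploid column (TP = 52, FP = 0) forces it.

For each abnormal TE category the TE result is scored against ICM potential
with a shared euploid-TE reference: TP/FP are the abnormal group's
low/high-potential ICMs; FN/TN the reference group's. Sensitivity
TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN);
undefined ratios (zero denominator) propagate as missing, never raise.
Because FN/TN are shared, NPV is constant across abnormal categories. The
reference row may be supplied as pre-tallied counts (`reference_counts=(1,
12)` for the clinical series, whose euploid-TE profiles are not published
per embryo) or recomputed from euploid-TE records when present. Metric
display rounding is half-up to one decimal percent.

## Synthetic cohorts

The simulator generates what the analysis assumes:

* **Origin mixture** per embryo: meiotic whole-chromosome, meiotic
  segmental, mitotic, or euploid, with probabilities
  (`p_meiotic_whole`, `p_meiotic_segmental`, `p_mitotic`, remainder).
  Defaults (0.30 / 0.15 / 0.40, artifact rate 0.05, euploid remainder) were
  chosen once to echo a clinical PGT-A case mix dominated by
  whole-chromosome aneuploidy and segmental mosaicism; the artifact and
  mitotic rates are illustrative, as no clinical quantification exists, and
  reports should label them as such.
* **Meiotic** errors occupy one clone of fraction 1. **Mitotic** errors
  create one aberrant clone of fraction 2⁻ᵈ for a cleavage division d drawn
  uniformly on 1–5 — synchronous divisions, no selection. An optional
  per-division survival penalty (`mitotic_selection`) depletes the aberrant
  clone; default off. Mitotic errors are whole-chromosome or segmental with
  probability `mitotic_whole_fraction` (default 0.5).
* **Lineage allocation** is well-mixed by default; `lineage_bias` tilts the
  aberrant clone toward the ICM (positive) or TE (negative) by reweighting
  clone fractions, for what-if analyses of spatial clustering.
* **Observation**: a TE biopsy of uniform size 5–10 cells and an ICM sample
  of 10 cells (ICM cell numbers are not reported clinically; 10 is this
  package's choice) draw cells multinomially from clone fractions. Each
  aberration is reported at 100 × aberrant cells / sampled cells, rounded
  half-up to the 10% quantum; levels quantized to 0 vanish. Segment sizes
  are uniform on 10–140 Mb, dosage gain/loss equiprobable, chromosome
  uniform on 1–22, and synthetic band ranges are grammar-valid but not
  biologically mapped.
* **Artifacts**: with probability `p_artifact` the TE biopsy (only, by
  default) gains one spurious full segmental call, mimicking S-phase or
  amplification artifacts.

What the simulator does not model: sequencing reads or copy-number signal,
chromosome-specific error rates, multi-clone hierarchies, reciprocal
translocation carriers, or spatially contiguous biopsies. Passing simulator
tests therefore validate the sampling arithmetic and the pipeline's
plumbing, not clinical realism of any particular parameter set.

## Origin-mixture estimation

`OriginMixtureModel` asks: of the embryos whose TE read as full segmental
aneuploid (Seg-A), what fraction were truly meiotic, mitotic, or artifact?
The three origins imply distinct ICM-category distributions under the
simulator's own observation model: meiotic → ICM Seg-A almost surely,
artifact → ICM euploid, mitotic → a mixture reflecting binomial sampling of
the clone. Component distributions π_o and the selection probabilities
q_o = P(TE reads Seg-A | origin o) are estimated by Monte Carlo (default
20 000 embryos per pure origin, seeded deterministically from the params
seed, Laplace-smoothed). The likelihood of the observed ICM category counts
is multinomial with category probabilities Σ_o c_o(w) π_o where
c_o(w) ∝ w_o q_o corrects for selection, so the fitted weights w are
unconditional origin shares. Maximization is exhaustive over a 0.01-step
grid on the 2-simplex (exactness beats elegance at this dimension);
confidence intervals are profile-likelihood sets at the χ²₁/2 cutoff
(1.92 for 95%). Because mitotic clones rarely reach the ≥85% biopsy level,
q_mitotic is small and its interval is honestly wide at realistic cohort
sizes.

## Numerical and engineering choices

* All display rounding is decimal half-up (`Decimal`-based), matching how
  the clinical tables round; raw proportions are always retained alongside.
* Cytoband maps are read in the UCSC `cytoBand` layout and converted to
  1-based inclusive coordinates; band-range spans round half-up to integer
  Mb. Size resolution is optional plumbing — classification never needs it.
* Record order never affects any output; reports contain no timestamps, so
  identical inputs give byte-identical JSON.
* The packaged cohort stores one published anomaly as printed: a
  two-segment TE call with a single pooled 1010 Mb size, inconsistent with
  the dataset's stated 10–140 Mb per-segment range. The pooled value is
  flagged (`size_anomaly`) and excluded from per-call size attribution.
  Relatedly, two published summary figures do not recompute from the
  published per-category data (an overall concordance of 55% vs the 52%
  implied by the printed counts; a 40.2 Mb mean segment size vs 41.0 Mb
  excluding the anomalous row). The pipeline reports the recomputed values;
  tests document the divergence rather than chase it.
* Problem sizes in the test suite (10⁴ biopsy draws for the binomial-law
  check, a 2 000-embryo cohort with 20 000-draw Monte Carlo components for
  mixture recovery) were chosen as the smallest sizes at which the
  statistical assertions are stable.

## Known limitations

The classifier trusts reported levels; it does not re-derive mosaicism from
reads. The precedence rule for mixed profiles and the post hoc contrast are
inferences where the clinical definitions are silent, exposed as
configuration. The origin-mixture model conditions on the simulator's own
observation model; applied to real cohorts it is a structured sensitivity
analysis, not an assumption-free estimator.
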