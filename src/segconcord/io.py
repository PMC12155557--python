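"""Cohort file reading, the packaged fixture cohort, and report assembly.

The cohort schema is a TSV/CSV with columns ``embryo_id``, optional
``grade`` and ``day``, then per side either a profile string column
(``te_profile`` / ``icm_profile``) or a pre-assigned category label column
(``te_label`` / ``icm_label``); ``te_size_mb`` optionally carries
semicolon-separated per-call segment sizes.  Malformed rows are skipped and
reported with their line numbers rather than aborting the read.

The packaged fixture (:func:`load_fixture_cohort`) is a 36-embryo clinical
cohort in which every TE biopsy read as full segmental aneuploid, with the
published ICM re-biopsy profile and classification for each embryo.  One
row carries a single pooled size for a two-segment TE call, inconsistent
with the dataset's stated 10-140 Mb per-segment range; it is stored as
published and flagged in the ``size_anomaly`` column.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .classify import parse_category
from .concordance import ConcordanceModel
from .config import RunConfig
from .karyo import ProfileParseError, parse_profile
from .potential import PotentialModel, Potential, potential_of_profile
from .records import EmbryoRecord

__all__ = [
    "CohortReadResult",
    "read_cohort",
    "records_from_frame",
    "load_fixture_cohort",
    "fixture_path",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger(__name__)

_PROFILE_COLS = ("te_profile", "icm_profile")
_LABEL_COLS = ("te_label", "icm_label")


@dataclass(frozen=True)
class CohortReadResult:
    records: list[EmbryoRecord]
    errors: list[str]


def _parse_sizes(raw) -> list[float | None]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return []
    out: list[float | None] = []
    for tok in str(raw).split(";"):
        tok = tok.strip()
        out.append(float(tok) if tok else None)
    return out


def _row_to_record(
    row: pd.Series, line_no: int, labels_only: bool, provenance: str
) -> EmbryoRecord:
    def cell(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        s = str(v).strip()
        return s or None

    te = icm = None
    meta: dict = {}
    if not labels_only:
        te_text = cell("te_profile")
        if te_text:
            te = parse_profile(te_text)
            sizes = _parse_sizes(cell("te_size_mb"))
            if sizes:
                if len(sizes) == len(te.calls):
                    calls = tuple(
                        c if s is None else dataclasses.replace(c, size_mb=s)
                        for c, s in zip(te.calls, sizes)
                    )
                    te = dataclasses.replace(te, calls=calls)
                else:
                    # a pooled size that cannot be attributed to single calls
                    meta["te_size_pool_mb"] = sizes
                    meta["size_anomaly"] = True
        icm_text = cell("icm_profile")
        if icm_text:
            icm = parse_profile(icm_text)
    te_label = cell("te_label")
    icm_label = cell("icm_label")
    if cell("size_anomaly"):
        meta["size_anomaly"] = True
    day = cell("day")
    return EmbryoRecord(
        embryo_id=cell("embryo_id") or f"row{line_no}",
        te=te,
        icm=icm,
        te_label=parse_category(te_label) if te_label else None,
        icm_label=parse_category(icm_label) if icm_label else None,
        grade=cell("grade"),
        day=int(day) if day else None,
        provenance=provenance,
        meta=meta,
    )


def records_from_frame(
    frame: pd.DataFrame, labels_only: bool = False, provenance: str = "user"
) -> tuple[list[EmbryoRecord], list[str]]:
    """Convert a cohort dataframe to records; returns (records, error strings)."""
    if "embryo_id" not in frame.columns:
        raise ValueError("missing mandatory column: embryo_id")
    has_profile = any(c in frame.columns for c in _PROFILE_COLS)
    has_label = any(c in frame.columns for c in _LABEL_COLS)
    if labels_only and not has_label:
        raise ValueError("labels-only mode needs te_label/icm_label columns")
    if not (has_profile or has_label):
        raise ValueError(
            "need profile columns (te_profile/icm_profile) or label columns"
        )
    records, errors = [], []
    for i, (_, row) in enumerate(frame.iterrows()):
        line_no = i + 2  # header is line 1
        try:
            records.append(_row_to_record(row, line_no, labels_only, provenance))
        except (ValueError, ProfileParseError) as exc:
            msg = f"line {line_no}: {exc}"
            log.warning("skipping %s", msg)
            errors.append(msg)
    return records, errors


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_cohort(path: str | Path, labels_only: bool = False) -> CohortReadResult:
    """Read a cohort TSV/CSV; malformed rows are skipped with line numbers."""
    frame = _read_table(path)
    records, errors = records_from_frame(frame, labels_only=labels_only)
    return CohortReadResult(records, errors)


def fixture_path() -> Path:
    resource = importlib.resources.files("segconcord.data") / "seg_aneuploid_cohort.tsv"
    return Path(str(resource))


def load_fixture_cohort() -> CohortReadResult:
    """The packaged 36-embryo segmental-aneuploidy TE/ICM cohort."""
    frame = _read_table(fixture_path())
    records, errors = records_from_frame(frame, provenance="fixture")
    return CohortReadResult(records, errors)


# ---------------------------------------------------------------------------
# Full analysis report


def run_full_analysis(
    records: Iterable[EmbryoRecord], config: RunConfig | None = None
) -> dict:
    """End-to-end analysis bundle for a cohort.

    Emits the 5x5 cross-tab with per-category rates and chi-square/post hoc
    results, the predictive-metrics table (against per-embryo euploid-TE
    records when present, else ``config.reference_counts``), and a per-embryo
    audit of categories and ICM potential.  Deterministic: no timestamps, so
    identical inputs give byte-identical JSON.
    """
    config = config or RunConfig()
    records = list(records)
    conc = ConcordanceModel(
        records,
        thresholds=config.thresholds,
        use_labels=config.use_labels,
        alpha=config.alpha,
        precedence=config.precedence,
    ).fit()
    try:
        pot = PotentialModel(
            records,
            reference_counts=config.reference_counts,
            cutoff=config.cutoff,
            thresholds=config.thresholds,
            use_labels=config.use_labels,
            precedence=config.precedence,
        ).fit()
        potential_section: dict = {"available": True, **pot.to_dict()}
    except ValueError as exc:
        potential_section = {"available": False, "reason": str(exc)}

    from .classify import classify_profile

    audit = []
    for rec in records:
        te_cat = (
            rec.te_label.label
            if (config.use_labels and rec.te_label is not None)
            else (
                classify_profile(rec.te, config.thresholds, config.precedence).label
                if rec.te is not None
                else (rec.te_label.label if rec.te_label else None)
            )
        )
        icm_cat = (
            rec.icm_label.label
            if (config.use_labels and rec.icm_label is not None)
            else (
                classify_profile(rec.icm, config.thresholds, config.precedence).label
                if rec.icm is not None
                else (rec.icm_label.label if rec.icm_label else None)
            )
        )
        audit.append(
            {
                "embryo_id": rec.embryo_id,
                "te_category": te_cat,
                "icm_category": icm_cat,
                "icm_potential": (
                    potential_of_profile(rec.icm, config.cutoff, config.thresholds).value
                    if rec.icm is not None
                    else None
                ),
                "concordant": (te_cat == icm_cat) if te_cat and icm_cat else None,
            }
        )
    return {
        "version": __version__,
        "settings": {
            "thresholds": {
                "euploid_max": config.thresholds.euploid_max,
                "mosaic_min": config.thresholds.mosaic_min,
                "full_min": config.thresholds.full_min,
                "segmental_floor_mb": config.thresholds.segmental_floor_mb,
                "reporting_quantum": config.thresholds.reporting_quantum,
            },
            "cutoff": config.cutoff,
            "alpha": config.alpha,
            "use_labels": config.use_labels,
            "precedence": [c.label for c in config.precedence],
            "seed": config.simulate.seed if config.simulate else None,
        },
        "concordance": conc.to_dict(),
        "potential": potential_section,
        "audit": audit,
    }


def write_report(report: dict, path: str | Path, fmt: str = "json") -> None:
    """Write a report bundle as JSON, or its cross-tab/rates as TSV."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        conc = report["concordance"]
        counts = pd.DataFrame(
            conc["counts"], index=conc["categories"], columns=conc["categories"]
        )
        rates = pd.DataFrame(conc["rates"]).T
        with open(path, "w") as fh:
            fh.write("# TE x ICM counts\n")
            counts.to_csv(fh, sep="\t")
            fh.write("# per-TE-category rates\n")
            rates.to_csv(fh, sep="\t")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
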