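"""Domain types and parsing for PGT-A copy-number call strings.

Clinical PGT-A reports describe chromosomal gains and losses in a compact
notation such as ``"loss 12p13.33~11.21"`` (a full segmental loss of the
short arm of chromosome 12) or ``"30% mosaic loss of chr6"`` (a
whole-chromosome loss present in roughly 30% of the biopsied cells).  This
module provides typed records for single calls (:class:`SegmentCall`) and
whole biopsy profiles (:class:`BiopsyProfile`), a parser for that notation,
canonical renderers, and optional cytoband-based segment-size resolution.

The grammar is deliberately frozen to the dialects seen in clinical NGS
reports rather than full ISCN:

* an optional ``<level>% mosaic`` prefix (absent means a full, non-mosaic
  call at level 100),
* a dosage keyword ``gain`` or ``loss``, optionally followed by ``of``,
* a target that is either ``chr N`` / ``chrN`` (whole chromosome) or a
  cytoband range ``<chrom><arm><band>~[<chrom>][<arm>]<band>`` where the
  second endpoint may omit the chromosome and/or arm, and the range may
  cross the centromere (``4p14~q13.1``),
* ``~``, en-dash, em-dash or hyphen accepted as the range separator,
* trailing periods, stray closing parentheses and whitespace tolerated.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CHROMOSOMES",
    "Scope",
    "Dosage",
    "SegmentCall",
    "BiopsyProfile",
    "ClassificationThresholds",
    "CallParseError",
    "CallValidationError",
    "ProfileParseError",
    "BandLookupError",
    "CytobandMap",
    "parse_call",
    "parse_profile",
    "render_call",
    "render_profile",
    "resolve_size",
]

#: Valid chromosome labels (autosomes 1-22 plus the sex chromosomes).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class Scope(str, Enum):
    """Whether a call affects a chromosome segment or a whole chromosome."""

    SEGMENTAL = "segmental"
    WHOLE_CHROMOSOME = "whole_chromosome"


class Dosage(str, Enum):
    """Direction of the copy-number change."""

    GAIN = "gain"
    LOSS = "loss"


class CallParseError(ValueError):
    """A call string does not match the supported grammar."""


class CallValidationError(ValueError):
    """A parsed call violates a domain invariant (e.g. level out of range)."""


class ProfileParseError(CallParseError):
    """A profile string contains a malformed clause (message names its index)."""


class BandLookupError(KeyError):
    """A cytoband named in a call is absent from the supplied cytoband map."""


@dataclass(frozen=True)
class SegmentCall:
    """One chromosomal gain/loss call from a biopsy.

    Parameters
    ----------
    chromosome : str
        Chromosome label in ``1..22``, ``X`` or ``Y``.
    scope : Scope
        Segmental or whole-chromosome.
    dosage : Dosage
        Gain or loss.
    level : float
        Percent of biopsied cells carrying the aberration, in (0, 100].
        Full (non-mosaic) calls carry level 100.
    region : str or None
        Cytoband range string for segmental calls (``"p13.33~11.21"`` style
        targets are stored with their chromosome prefix, e.g.
        ``"12p13.33~11.21"``).  Whole-chromosome calls carry no region.
    size_mb : float or None
        Estimated size of the affected segment in megabases, when reported.
    """

    chromosome: str
    scope: Scope
    dosage: Dosage
    level: float = 100.0
    region: str | None = None
    size_mb: float | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise CallValidationError(f"unknown chromosome {self.chromosome!r}")
        if not 0 < self.level <= 100:
            raise CallValidationError(
                f"mosaicism level must be in (0, 100], got {self.level}"
            )
        if self.scope is Scope.WHOLE_CHROMOSOME and self.region is not None:
            raise CallValidationError("whole-chromosome calls carry no region string")
        if self.scope is Scope.SEGMENTAL and not self.region:
            raise CallValidationError("segmental calls require a region string")
        if self.size_mb is not None and self.size_mb <= 0:
            raise CallValidationError(f"size_mb must be positive, got {self.size_mb}")

    @property
    def is_full(self) -> bool:
        """True for non-mosaic (level 100) calls."""
        return self.level >= 100


@dataclass(frozen=True)
class BiopsyProfile:
    """The full set of calls reported for one biopsy (TE or ICM).

    An empty ``calls`` collection means a fully euploid profile.
    """

    sex: str | None = None
    calls: tuple[SegmentCall, ...] = ()

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("XX", "XY"):
            raise CallValidationError(f"sex must be 'XX' or 'XY', got {self.sex!r}")
        object.__setattr__(self, "calls", tuple(self.calls))

    @property
    def is_euploid(self) -> bool:
        return not self.calls


@dataclass(frozen=True)
class ClassificationThresholds:
    """Mosaicism-level and segment-size thresholds for the five-way categories.

    Attributes
    ----------
    euploid_max : float
        Exclusive upper bound (percent) for "background" mosaicism that does
        not change a profile's category.  Default 25.
    mosaic_min : float
        Inclusive lower bound for a call to count as mosaic.  Default 25.
    full_min : float
        Levels at or above this are treated as full (non-mosaic).  Default 85.
    segmental_floor_mb : float
        Minimum reportable segment size in Mb; smaller segmental calls are
        dropped before classification.  Default 10.
    reporting_quantum : float
        Granularity (percent) of reported mosaicism levels.  Default 10.
    """

    euploid_max: float = 25.0
    mosaic_min: float = 25.0
    full_min: float = 85.0
    segmental_floor_mb: float = 10.0
    reporting_quantum: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.euploid_max <= self.mosaic_min < self.full_min <= 100:
            raise ValueError(
                "thresholds must satisfy 0 < euploid_max <= mosaic_min < full_min <= 100"
            )
        if self.segmental_floor_mb < 0:
            raise ValueError("segmental_floor_mb must be non-negative")
        if not 0 < self.reporting_quantum <= 100:
            raise ValueError("reporting_quantum must be in (0, 100]")


DEFAULT_THRESHOLDS = ClassificationThresholds()

# ---------------------------------------------------------------------------
# Parsing

_CHROM = r"(?:2[0-2]|1[0-9]|[1-9]|[XY])"
_BAND = r"\d+(?:\.\d+)?"
_DASHES = re.compile(r"[–—−-]")  # en/em dash, minus, hyphen -> "~"

_CALL_RE = re.compile(
    rf"(?:(?P<level>\d+(?:\.\d+)?)\s*%\s*mosaic\s+)?"
    rf"(?P<dosage>gain|loss)\s+(?:of\s+)?(?P<target>.+)",
    re.IGNORECASE,
)
_CALL_HEAD_RE = re.compile(
    r"(?:\d+(?:\.\d+)?\s*%\s*mosaic\s+)?(?:gain|loss)\b", re.IGNORECASE
)
_WHOLE_RE = re.compile(rf"chr\s*(?P<chrom>{_CHROM})$", re.IGNORECASE)
_RANGE_RE = re.compile(
    rf"(?P<chrom>{_CHROM})(?P<arm1>[pq])(?P<band1>{_BAND})"
    rf"~(?:(?P<chrom2>{_CHROM})(?P<arm2>[pq])|(?P<arm3>[pq]))?(?P<band2>{_BAND})$"
)
_STATUS_RE = re.compile(
    r"^(?P<status>euploidy|mosaicism|aneuploidy)\b[\s,]*(?P<sex>X[XY])?\s*(?:;|$)",
    re.IGNORECASE,
)


def _clean(text: str) -> str:
    return _DASHES.sub("~", text).strip().rstrip(" .) ").strip()


def parse_call(
    text: str,
    size_mb: float | None = None,
    quantum: float = 10.0,
) -> SegmentCall:
    """Parse one call string into a :class:`SegmentCall`.

    ``size_mb`` attaches an externally reported segment size (the notation
    itself never carries one).  Mosaic levels must be a multiple of
    ``quantum`` (or exactly 100), mirroring how clinical platforms quantize
    the diploid-aneuploid intermediate signal.

    >>> parse_call("30% mosaic loss of chr6")
    SegmentCall(chromosome='6', scope=<Scope.WHOLE_CHROMOSOME: ...>, ...)
    """
    s = _clean(str(text or ""))
    if not s:
        raise CallParseError("empty call string")
    m = _CALL_RE.fullmatch(s)
    if m is None:
        raise CallParseError(f"unrecognised call syntax: {text!r}")
    level = float(m["level"]) if m["level"] else 100.0
    if not 0 < level <= 100:
        raise CallValidationError(f"mosaicism level {level}% outside (0, 100]")
    if level != 100 and quantum and level % quantum != 0:
        raise CallValidationError(
            f"mosaicism level {level}% is not a multiple of the {quantum}% "
            "reporting quantum"
        )
    dosage = Dosage(m["dosage"].lower())
    target = _clean(m["target"])

    wm = _WHOLE_RE.fullmatch(target)
    if wm is not None:
        return SegmentCall(
            chromosome=wm["chrom"].upper(),
            scope=Scope.WHOLE_CHROMOSOME,
            dosage=dosage,
            level=level,
            size_mb=size_mb,
        )
    rm = _RANGE_RE.fullmatch(target)
    if rm is None:
        raise CallParseError(f"unrecognised target {target!r} in call {text!r}")
    chrom = rm["chrom"].upper()
    if rm["chrom2"] and rm["chrom2"].upper() != chrom:
        raise CallParseError(
            f"range endpoints name different chromosomes in {target!r}"
        )
    return SegmentCall(
        chromosome=chrom,
        scope=Scope.SEGMENTAL,
        dosage=dosage,
        level=level,
        region=target,
        size_mb=size_mb,
    )


def _parse_clause(clause: str, quantum: float) -> list[SegmentCall]:
    """Parse one semicolon-delimited clause into its calls.

    A clause may list several comma- (or "and"-) separated regions that share
    one level/dosage; each region becomes its own call.  An item carrying its
    own dosage keyword starts a new call instead.
    """
    calls: list[SegmentCall] = []
    level: float | None = None
    dosage: Dosage | None = None
    for item in re.split(r",|\band\b", clause):
        item = _clean(item)
        if not item:
            continue
        if _CALL_HEAD_RE.match(item):
            call = parse_call(item, quantum=quantum)
            level, dosage = call.level, call.dosage
            calls.append(call)
        else:
            if dosage is None:
                raise CallParseError(
                    f"region {item!r} appears before any gain/loss keyword"
                )
            prefix = "" if level == 100 else f"{level:g}% mosaic "
            calls.append(parse_call(f"{prefix}{dosage.value} {item}", quantum=quantum))
    if not calls:
        raise CallParseError("clause contains no calls")
    return calls


def parse_profile(text: str, quantum: float = 10.0) -> BiopsyProfile:
    """Parse a full biopsy profile string.

    Accepted forms::

        Euploidy
        Euploidy, XX
        Mosaicism, XY; 50% mosaic loss of 6p25.3~6p21.33, 6q26~6q27; ...
        Aneuploidy, XX; gain 3q27.3~3q29, loss 8q21.11~24.3.
        loss 12p13.33~11.21            (bare call list, no status keyword)

    ``"Euploidy"`` (with or without sex) yields an empty calls collection.
    Every region in a multi-region clause inherits that clause's level and
    dosage.  Malformed clauses raise :class:`ProfileParseError` naming the
    clause index.
    """
    s = _DASHES.sub("~", str(text or "")).strip()
    if not s:
        raise ProfileParseError("empty profile string")
    sex: str | None = None
    m = _STATUS_RE.match(s)
    if m is not None:
        sex = m["sex"].upper() if m["sex"] else None
        s = s[m.end():].strip()
    if not s or not s.strip(" .;)"):
        return BiopsyProfile(sex=sex, calls=())
    calls: list[SegmentCall] = []
    for i, clause in enumerate(s.split(";")):
        clause = clause.strip()
        if not clause or not clause.strip(" .)"):
            continue
        try:
            calls.extend(_parse_clause(clause, quantum))
        except CallParseError as exc:
            raise ProfileParseError(f"clause {i}: {exc}") from exc
    return BiopsyProfile(sex=sex, calls=tuple(calls))


# ---------------------------------------------------------------------------
# Rendering (canonical form: no trailing period, "chrN" without space)


def render_call(call: SegmentCall) -> str:
    """Render a call in canonical text form; ``parse_call`` round-trips it."""
    target = (
        f"chr{call.chromosome}"
        if call.scope is Scope.WHOLE_CHROMOSOME
        else call.region
    )
    if call.is_full:
        return f"{call.dosage.value} {target}"
    return f"{call.level:g}% mosaic {call.dosage.value} of {target}"


def render_profile(profile: BiopsyProfile) -> str:
    """Render a profile in canonical form; ``parse_profile`` round-trips it."""
    sex_part = f", {profile.sex}" if profile.sex else ""
    if profile.is_euploid:
        return f"Euploidy{sex_part}"
    status = "Aneuploidy" if any(c.is_full for c in profile.calls) else "Mosaicism"
    body = "; ".join(render_call(c) for c in profile.calls)
    return f"{status}{sex_part}; {body}"


# ---------------------------------------------------------------------------
# Cytoband size resolution


@dataclass(frozen=True)
class _Band:
    start: int  # 1-based inclusive
    end: int
    name: str  # e.g. "p13.3"


@dataclass(frozen=True)
class CytobandMap:
    """Cytoband coordinates per chromosome, 1-based inclusive.

    Built from the standard UCSC ``cytoBand`` table layout (tab-separated
    ``chrom  start  end  band  stain`` with 0-based half-open coordinates,
    converted on load).
    """

    bands: dict[str, tuple[_Band, ...]] = field(default_factory=dict)

    @classmethod
    def from_ucsc(cls, path: str | Path) -> "CytobandMap":
        bands: dict[str, list[_Band]] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                chrom = row[0].removeprefix("chr")
                if chrom not in CHROMOSOMES:
                    continue
                start, end, name = int(row[1]) + 1, int(row[2]), row[3]
                bands.setdefault(chrom, []).append(_Band(start, end, name))
        return cls({c: tuple(sorted(b, key=lambda x: x.start)) for c, b in bands.items()})

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, str]]
    ) -> "CytobandMap":
        """Build from ``(chrom, start, end, band)`` rows, 1-based inclusive."""
        bands: dict[str, list[_Band]] = {}
        for chrom, start, end, name in records:
            bands.setdefault(chrom.removeprefix("chr"), []).append(
                _Band(int(start), int(end), name)
            )
        return cls({c: tuple(sorted(b, key=lambda x: x.start)) for c, b in bands.items()})

    def band_span(self, chromosome: str, band: str) -> tuple[int, int]:
        """Genomic span of a band (exact name, else its sub-bands)."""
        entries = self.bands.get(chromosome, ())
        hits = [b for b in entries if b.name == band]
        if not hits:
            hits = [b for b in entries if b.name.startswith(band + ".")]
        if not hits:
            raise BandLookupError(f"band {chromosome}{band} not in cytoband map")
        return min(b.start for b in hits), max(b.end for b in hits)

    def chrom_span(self, chromosome: str) -> tuple[int, int]:
        entries = self.bands.get(chromosome, ())
        if not entries:
            raise BandLookupError(f"chromosome {chromosome} not in cytoband map")
        return min(b.start for b in entries), max(b.end for b in entries)


def _round_mb(bases: int) -> int:
    return int(
        (Decimal(bases) / Decimal(1_000_000)).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    )


def resolve_size(
    call: SegmentCall, cytobands: CytobandMap | None = None
) -> float | None:
    """Segment size in Mb: the reported size if present, else the span the
    band range implies under ``cytobands`` (rounded half-up to whole Mb),
    else ``None`` (unknown).  Classification never requires a size.
    """
    if call.size_mb is not None:
        return float(call.size_mb)
    if cytobands is None:
        return None
    if call.scope is Scope.WHOLE_CHROMOSOME:
        start, end = cytobands.chrom_span(call.chromosome)
        return float(_round_mb(end - start + 1))
    rm = _RANGE_RE.fullmatch(call.region or "")
    if rm is None:  # pragma: no cover - regions come from the same grammar
        raise CallParseError(f"cannot interpret region {call.region!r}")
    band1 = rm["arm1"] + rm["band1"]
    arm2 = rm["arm2"] or rm["arm3"] or rm["arm1"]
    band2 = arm2 + rm["band2"]
    s1, e1 = cytobands.band_span(call.chromosome, band1)
    s2, e2 = cytobands.band_span(call.chromosome, band2)
    return float(_round_mb(max(e1, e2) - min(s1, s2) + 1))
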