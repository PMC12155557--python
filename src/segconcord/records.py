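"""Per-embryo record type pairing the TE biopsy with the ICM sample."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Mapping

from .classify import Category
from .karyo import BiopsyProfile

__all__ = ["EmbryoRecord", "PROVENANCES"]

PROVENANCES = ("fixture", "user", "simulated")
_GRADE_RE = re.compile(r"\d[A-Da-d]{2}")


@dataclass(frozen=True)
class EmbryoRecord:
    """Paired TE and ICM observations for one blastocyst.

    Each side carries a parsed :class:`~segconcord.karyo.BiopsyProfile`
    and/or a pre-assigned :class:`~segconcord.classify.Category` label (the
    label-only form supports datasets that publish classifications without
    call strings).  ``meta`` holds side-channel data such as per-call TE
    segment sizes or, for simulated embryos, the ground-truth origin.
    """

    embryo_id: str
    te: BiopsyProfile | None = None
    icm: BiopsyProfile | None = None
    te_label: Category | None = None
    icm_label: Category | None = None
    grade: str | None = None
    day: int | None = None
    provenance: str = "user"
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.te is None and self.te_label is None:
            raise ValueError(f"{self.embryo_id}: TE side needs a profile or a label")
        if self.icm is None and self.icm_label is None:
            raise ValueError(f"{self.embryo_id}: ICM side needs a profile or a label")
        if self.grade is not None and not _GRADE_RE.fullmatch(self.grade):
            raise ValueError(
                f"{self.embryo_id}: grade {self.grade!r} does not match "
                "digit+letter+letter"
            )
        if self.day is not None and self.day not in (5, 6):
            raise ValueError(f"{self.embryo_id}: biopsy day must be 5 or 6")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
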