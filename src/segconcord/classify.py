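"""Five-way blastocyst categorization from a biopsy profile.

A PGT-A biopsy is assigned exactly one of five categories from the scope
(segmental vs whole-chromosome) and mosaicism level of its calls:

* ``EU`` — euploid: no call at or above the mosaic floor (25%),
* ``Seg-A`` — full segmental aneuploid: a non-mosaic segmental call,
* ``Seg-M`` — segmental mosaic: a segmental call at 25-85%,
* ``Who-A`` — full whole-chromosome aneuploid,
* ``Who-M`` — whole-chromosome mosaic.

Mixed profiles are resolved by precedence (most severe wins):
Who-A > Seg-A > Who-M > Seg-M.  Calls below the mosaic floor are
"background" and never change the category; segmental calls smaller than
the 10 Mb reporting floor are dropped with a warning.
"""

from __future__ import annotations

import warnings
from enum import Enum
from typing import Iterable, Sequence

from .karyo import (
    BiopsyProfile,
    ClassificationThresholds,
    DEFAULT_THRESHOLDS,
    Scope,
    SegmentCall,
)

__all__ = [
    "Category",
    "CallClass",
    "CATEGORY_ORDER",
    "DEFAULT_PRECEDENCE",
    "classify_call",
    "classify_profile",
    "parse_category",
]


class Category(Enum):
    """One of the five blastocyst categories; ``value`` is the display label."""

    EU = "EU"
    SEG_A = "Seg-A"
    SEG_M = "Seg-M"
    WHO_M = "Who-M"
    WHO_A = "Who-A"

    @property
    def label(self) -> str:
        return self.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Display/tabulation order for cross-tabs and reports.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.EU,
    Category.SEG_A,
    Category.SEG_M,
    Category.WHO_M,
    Category.WHO_A,
)

#: Severity precedence for mixed profiles (first match wins).
DEFAULT_PRECEDENCE: tuple[Category, ...] = (
    Category.WHO_A,
    Category.SEG_A,
    Category.WHO_M,
    Category.SEG_M,
)


class CallClass(Enum):
    BACKGROUND = "background"
    SEGMENTAL_MOSAIC = "segmental_mosaic"
    WHOLE_MOSAIC = "whole_mosaic"
    SEGMENTAL_FULL = "segmental_full"
    WHOLE_FULL = "whole_full"


_CLASS_TO_CATEGORY = {
    CallClass.SEGMENTAL_MOSAIC: Category.SEG_M,
    CallClass.WHOLE_MOSAIC: Category.WHO_M,
    CallClass.SEGMENTAL_FULL: Category.SEG_A,
    CallClass.WHOLE_FULL: Category.WHO_A,
}

_LABEL_ALIASES = {
    "eu": Category.EU,
    "euploid": Category.EU,
    "euploidy": Category.EU,
    "sega": Category.SEG_A,
    "segm": Category.SEG_M,
    "whom": Category.WHO_M,
    "whoa": Category.WHO_A,
}


def parse_category(label: str) -> Category:
    """Parse a category label (``"Seg-A"``, ``"SegA"``, ``"EU"``, ...)."""
    key = str(label).strip().lower().replace("-", "").replace("_", "").replace(" ", "")
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown category label {label!r}") from None


def classify_call(
    call: SegmentCall,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> CallClass:
    """Classify a single call by its mosaicism level and scope.

    Levels below ``mosaic_min`` are background; levels in
    ``[mosaic_min, full_min)`` are mosaic; levels at or above ``full_min``
    are full.  (The reporting quantum never emits a level exactly at the 85%
    default boundary, so the >= convention there is inert on clinical data.)
    """
    if call.level < thresholds.mosaic_min:
        return CallClass.BACKGROUND
    segmental = call.scope is Scope.SEGMENTAL
    if call.level < thresholds.full_min:
        return CallClass.SEGMENTAL_MOSAIC if segmental else CallClass.WHOLE_MOSAIC
    return CallClass.SEGMENTAL_FULL if segmental else CallClass.WHOLE_FULL


def _effective_calls(
    profile: BiopsyProfile, thresholds: ClassificationThresholds
) -> list[SegmentCall]:
    kept = []
    for call in profile.calls:
        if (
            call.scope is Scope.SEGMENTAL
            and call.size_mb is not None
            and call.size_mb < thresholds.segmental_floor_mb
        ):
            warnings.warn(
                f"dropping sub-floor segmental call ({call.size_mb} Mb < "
                f"{thresholds.segmental_floor_mb} Mb): {call.region}",
                stacklevel=3,
            )
            continue
        kept.append(call)
    return kept


def classify_profile(
    profile: BiopsyProfile,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    precedence: Sequence[Category] = DEFAULT_PRECEDENCE,
) -> Category:
    """Assign the profile its single category.

    Classification is total and order-independent: the most severe call class
    present (under ``precedence``) determines the category, background calls
    never matter, and an empty profile is ``EU``.
    """
    classes = {
        classify_call(c, thresholds) for c in _effective_calls(profile, thresholds)
    }
    present = {
        _CLASS_TO_CATEGORY[cls] for cls in classes if cls is not CallClass.BACKGROUND
    }
    for category in precedence:
        if category in present:
            return category
    if present:  # precedence list did not cover a present category
        raise ValueError(f"precedence order omits categories: {present}")
    return Category.EU
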