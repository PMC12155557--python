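"""Run configuration: thresholds, cutoffs and simulation parameters.

Loaded from YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .classify import Category, DEFAULT_PRECEDENCE, parse_category
from .karyo import ClassificationThresholds
from .simdata import SimParams

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class RunConfig:
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    cutoff: float = 50.0
    alpha: float = 0.05
    precedence: tuple[Category, ...] = DEFAULT_PRECEDENCE
    use_labels: bool = False
    #: (FN, TN) of the euploid-TE reference row when per-embryo euploid
    #: records are not part of the cohort.
    reference_counts: tuple[int, int] | None = None
    simulate: SimParams | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.cutoff <= 100:
            raise ValueError("cutoff must be in [0, 100]")
        if set(self.precedence) != set(DEFAULT_PRECEDENCE):
            raise ValueError(
                "precedence must order exactly the four abnormal categories"
            )


def _build(cls, data: Mapping[str, Any], section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Recognised sections: top-level ``cutoff``, ``alpha``, ``use_labels``,
    ``precedence`` (list of category labels), ``reference_counts``
    (``[fn, tn]``), plus ``thresholds`` and ``simulate`` mappings mirroring
    :class:`ClassificationThresholds` and :class:`SimParams`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {
        "thresholds",
        "simulate",
        "cutoff",
        "alpha",
        "precedence",
        "use_labels",
        "reference_counts",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "thresholds" in raw:
        kwargs["thresholds"] = _build(
            ClassificationThresholds, raw["thresholds"], "thresholds"
        )
    if "simulate" in raw:
        kwargs["simulate"] = _build(SimParams, raw["simulate"], "simulate")
    if "precedence" in raw:
        kwargs["precedence"] = tuple(parse_category(x) for x in raw["precedence"])
    if "reference_counts" in raw and raw["reference_counts"] is not None:
        fn, tn = raw["reference_counts"]
        kwargs["reference_counts"] = (int(fn), int(tn))
    for key in ("cutoff", "alpha", "use_labels"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)
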