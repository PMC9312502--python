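"""Diffusive vs. advective sediment-system attribution.

The bioirrigation score set switches between diffusion-dominated (mud to
fine sand) and advection-dominated (medium sand and coarser, i.e. permeable)
sediments.  Attribution here is by median grain size against a threshold,
with per-station expert overrides taking precedence — overrides exist
because fine-sand sites with high organic content can behave diffusively
despite a borderline median.

The default threshold of 177 µm is the conventional fine/medium-sand class
boundary (2.5 φ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .datatypes import SYSTEMS, CommunitySample

#: fine/medium sand boundary, 2.5 phi, in micrometres
DEFAULT_ADVECTIVE_MIN_GRAIN_UM = 177.0


class UnclassifiableSample(ValueError):
    """Sample has no grain size, no override and no explicit label."""


@dataclass
class SystemRule:
    """Classification rule: grain-size threshold plus station overrides."""

    advective_min_grain_um: float = DEFAULT_ADVECTIVE_MIN_GRAIN_UM
    overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.advective_min_grain_um > 0:
            raise ValueError("grain-size threshold must be > 0")
        for station, system in self.overrides.items():
            if system not in SYSTEMS:
                raise ValueError(
                    f"override for station {station!r} must be one of {SYSTEMS}, "
                    f"got {system!r}"
                )


def classify(sample: CommunitySample, rule: SystemRule | None = None) -> str:
    """Return ``"diffusive"`` or ``"advective"`` for a sample.

    Precedence: per-sample explicit label, then station override, then
    median grain size (advective iff grain >= threshold).  A sample with
    none of the three raises :class:`UnclassifiableSample` — there is no
    silent default system.
    """
    rule = rule or SystemRule()
    if sample.system_override is not None:
        return sample.system_override
    if sample.station_id in rule.overrides:
        return rule.overrides[sample.station_id]
    if sample.median_grain_um is not None:
        if sample.median_grain_um >= rule.advective_min_grain_um:
            return "advective"
        return "diffusive"
    raise UnclassifiableSample(
        f"sample {sample.sample_id} has no grain size, override or label"
    )


def grain_class(median_grain_um: float) -> str:
    """Coarse sediment-class label from the median grain size (µm).

    mud < 63 ≤ fine sand < 177 ≤ medium sand < 500 ≤ coarse sand,
    following the conventional Wentworth-style boundaries used for
    per-class key-taxon summaries.
    """
    if not median_grain_um > 0:
        raise ValueError("grain size must be > 0")
    if median_grain_um < 63:
        return "mud"
    if median_grain_um < DEFAULT_ADVECTIVE_MIN_GRAIN_UM:
        return "fine sand"
    if median_grain_um < 500:
        return "medium sand"
    return "coarse sand"


def classify_grain(median_grain_um: float, rule: SystemRule | None = None) -> str:
    """Classify a bare median grain size (µm) without station context."""
    rule = rule or SystemRule()
    if not median_grain_um > 0:
        raise ValueError("grain size must be > 0")
    return "advective" if median_grain_um >= rule.advective_min_grain_um else "diffusive"
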