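"""Core domain types for trait-based benthic functioning indices.

The central objects are the per-taxon trait score table (:class:`ScoreTable`),
a macrofauna community sample (:class:`CommunitySample`) and the result of an
index computation (:class:`IndexResult`).  Scores exist in two variants per
taxon because the bioirrigation index distinguishes diffusion-dominated
(muddy to fine-sand) from advection-dominated (medium sand and coarser)
sediment systems; the bioturbation index uses a single mobility/reworking
score pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

System = Literal["diffusive", "advective"]

SYSTEMS: tuple[str, str] = ("diffusive", "advective")

#: score columns of a score table, in canonical order
SCORE_COLUMNS = (
    "ft_diff", "bt_diff", "l_diff",
    "ft_adv", "bt_adv", "l_adv",
    "m_bpc", "r_bpc",
)


class ValidationError(ValueError):
    """A table or record violates a domain invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns."""


def _norm_taxon(name: str) -> str:
    """Canonical taxon key: whitespace-normalised, case-insensitive."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class ScoreEntry:
    """Trait scores for one taxon.

    ``ft`` (feeding type), ``bt`` (burrow type) and ``l`` (depth) scores come
    in a diffusive and an advective variant; ``m`` (mobility) and ``r``
    (sediment reworking) are the single-variant bioturbation scores.  A zero
    in any factor encodes a trait that is irrelevant to solute exchange
    (e.g. epifauna) and forces a zero contribution.
    """

    taxon: str
    ft_diff: float
    bt_diff: float
    l_diff: float
    ft_adv: float
    bt_adv: float
    l_adv: float
    m_bpc: float
    r_bpc: float
    lit_depth_cm: float | None = None

    def __post_init__(self) -> None:
        for col in SCORE_COLUMNS:
            v = getattr(self, col)
            if not (v >= 0):  # also rejects NaN
                raise ValidationError(
                    f"score {col}={v!r} for taxon {self.taxon!r} must be >= 0"
                )

    def product(self, system: str) -> float:
        """FT*BT*L score product for the given sediment system."""
        if system == "diffusive":
            return self.ft_diff * self.bt_diff * self.l_diff
        if system == "advective":
            return self.ft_adv * self.bt_adv * self.l_adv
        raise ValueError(f"unknown sediment system {system!r}")


class ScoreTable:
    """Per-taxon trait scores, keyed by normalised taxon name."""

    def __init__(self, entries: Iterable[ScoreEntry]):
        self._entries: dict[str, ScoreEntry] = {}
        for e in entries:
            key = _norm_taxon(e.taxon)
            if key in self._entries:
                raise ValidationError(f"duplicate taxon in score table: {e.taxon!r}")
            self._entries[key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, taxon: str) -> bool:
        return _norm_taxon(taxon) in self._entries

    def get(self, taxon: str) -> ScoreEntry | None:
        return self._entries.get(_norm_taxon(taxon))

    @property
    def entries(self) -> list[ScoreEntry]:
        return list(self._entries.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self._entries.values():
            row = {"taxon": e.taxon, **{c: getattr(e, c) for c in SCORE_COLUMNS}}
            if e.lit_depth_cm is not None:
                row["lit_depth_cm"] = e.lit_depth_cm
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon's abundance/biomass in a sample.

    abundance in ind·m⁻², biomass as ash-free dry weight in g·m⁻²,
    optional mid-depth of the sediment slice of occurrence in cm.
    """

    taxon: str
    abundance: float
    biomass_afdw: float
    depth_measured: float | None = None

    def __post_init__(self) -> None:
        if not (self.abundance >= 0):
            raise ValidationError(
                f"abundance {self.abundance!r} for {self.taxon!r} must be >= 0"
            )
        if not (self.biomass_afdw >= 0):
            raise ValidationError(
                f"biomass {self.biomass_afdw!r} for {self.taxon!r} must be >= 0"
            )
        if self.biomass_afdw > 0 and self.abundance == 0:
            raise ValidationError(
                f"taxon {self.taxon!r} has biomass > 0 with abundance = 0"
            )


@dataclass
class CommunitySample:
    """Macrofauna community at one station and date, in m⁻² units."""

    station_id: str
    date: str
    records: list[TaxonRecord] = field(default_factory=list)
    median_grain_um: float | None = None
    system_override: System | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            key = _norm_taxon(r.taxon)
            if key in seen:
                raise ValidationError(
                    f"duplicate taxon {r.taxon!r} in sample {self.sample_id}"
                )
            seen.add(key)
        if self.median_grain_um is not None and not (self.median_grain_um > 0):
            raise ValidationError(
                f"median grain size must be > 0, got {self.median_grain_um!r}"
            )
        if self.system_override is not None and self.system_override not in SYSTEMS:
            raise ValidationError(f"unknown system {self.system_override!r}")

    @property
    def sample_id(self) -> str:
        return f"{self.station_id}/{self.date}"

    def total_abundance(self) -> float:
        return sum(r.abundance for r in self.records)

    def total_biomass(self) -> float:
        return sum(r.biomass_afdw for r in self.records)


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured quantity on one incubated core.

    Quantities are free-form names, e.g. ``br_inventory_mmol_m2``,
    ``irrigation_l_m2_d`` or ``flux_po4``; an optional depth interval in cm
    marks layer-resolved variants.
    """

    core_id: str
    quantity: str
    value: float
    layer_top_cm: float | None = None
    layer_bottom_cm: float | None = None

    def __post_init__(self) -> None:
        if (self.layer_top_cm is None) != (self.layer_bottom_cm is None):
            raise ValidationError(
                f"layer bounds must both be given or both absent ({self.core_id})"
            )
        if self.layer_top_cm is not None and not (self.layer_top_cm < self.layer_bottom_cm):
            raise ValidationError(
                f"layer top {self.layer_top_cm} must be < bottom {self.layer_bottom_cm}"
            )


@dataclass
class IndexResult:
    """BIPc / BPc for one sample, with diagnostics.

    ``contributions`` maps taxon name → its additive contribution;
    the index value is exactly the sum of contributions.  Coverage is the
    share of sample abundance / AFDW biomass carried by scored taxa, in
    percent (``None`` when the respective sample total is zero).
    """

    sample_id: str
    system: str
    bipc: float
    bpc: float
    contributions: Mapping[str, float]
    bpc_contributions: Mapping[str, float]
    coverage_abundance_pct: float | None
    coverage_biomass_pct: float | None
    unscored_taxa: Sequence[str]
    warnings: Sequence[str] = ()


@dataclass
class DepthProfile:
    """Vertical partition of a sample's BIPc into sediment-depth slices.

    ``boundaries`` are the n+1 slice edges (cm, 0 at the interface);
    ``values[i]`` is the BIPc carried by fauna in ``[boundaries[i],
    boundaries[i+1])`` (final slice closed).  Slice values sum to the
    whole-core index over the taxa with a usable depth.
    """

    boundaries: Sequence[float]
    values: Sequence[float]
    mode: Literal["measured", "theoretical"]
    excluded_taxa: Sequence[str] = ()
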