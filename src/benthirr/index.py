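"""Community bioirrigation (BIPc) and bioturbation (BPc) potential indices.

BIPc sums, over the taxa present in a sample, the mean individual biomass
(Bᵢ/Aᵢ, AFDW g·m⁻² over ind·m⁻²) weighted back by abundance and multiplied
by the feeding-type, burrow-type and depth trait scores of the sediment
system at hand::

    BIPc = Σᵢ (Bᵢ/Aᵢ) · Aᵢ · FTᵢ · BTᵢ · Lᵢ

BPc is the established bioturbation analogue with a square-root biomass
weighting and mobility/reworking scores::

    BPc  = Σᵢ √(Bᵢ/Aᵢ) · Aᵢ · Mᵢ · Rᵢ

A zero in any score factor (e.g. epifauna, whose burrow type is irrelevant
to solute exchange) forces a zero contribution.  Taxa absent from the score
table contribute nothing and are reported in the coverage diagnostics
rather than imputed.  Records with Aᵢ = 0 contribute 0 (no 0/0 division is
ever evaluated).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    SYSTEMS,
    CommunitySample,
    DepthProfile,
    IndexResult,
    ScoreTable,
)


def _match_arrays(sample: CommunitySample, scores: ScoreTable, system: str):
    """Split records into scored arrays and the unscored-taxon list."""
    if system not in SYSTEMS:
        raise ValueError(f"unknown sediment system {system!r}")
    taxa, A, B, prod_irr, prod_bio = [], [], [], [], []
    unscored = []
    for rec in sample.records:
        entry = scores.get(rec.taxon)
        if entry is None:
            unscored.append(rec.taxon)
            continue
        taxa.append(rec.taxon)
        A.append(rec.abundance)
        B.append(rec.biomass_afdw)
        prod_irr.append(entry.product(system))
        prod_bio.append(entry.m_bpc * entry.r_bpc)
    return (
        taxa,
        np.asarray(A, dtype=float),
        np.asarray(B, dtype=float),
        np.asarray(prod_irr, dtype=float),
        np.asarray(prod_bio, dtype=float),
        unscored,
    )


def _bipc_contrib(A: np.ndarray, B: np.ndarray, prod: np.ndarray) -> np.ndarray:
    out = np.zeros_like(A)
    pos = A > 0
    out[pos] = (B[pos] / A[pos]) * A[pos] * prod[pos]
    return out


def _bpc_contrib(A: np.ndarray, B: np.ndarray, prod: np.ndarray) -> np.ndarray:
    out = np.zeros_like(A)
    pos = A > 0
    out[pos] = np.sqrt(B[pos] / A[pos]) * A[pos] * prod[pos]
    return out


def compute_index(
    sample: CommunitySample, scores: ScoreTable, system: str
) -> IndexResult:
    """BIPc and BPc for one sample, with per-taxon contributions.

    ``system`` selects the diffusive or advective score columns for BIPc
    (BPc has a single score set and ignores it).
    """
    taxa, A, B, p_irr, p_bio, unscored = _match_arrays(sample, scores, system)
    c_irr = _bipc_contrib(A, B, p_irr)
    c_bio = _bpc_contrib(A, B, p_bio)

    tot_a = sample.total_abundance()
    tot_b = sample.total_biomass()
    cov_a = 100.0 * float(A.sum()) / tot_a if tot_a > 0 else None
    cov_b = 100.0 * float(B.sum()) / tot_b if tot_b > 0 else None

    warnings = []
    if sample.records and not taxa:
        warnings.append("no taxon in this sample has trait scores; index is 0")

    return IndexResult(
        sample_id=sample.sample_id,
        system=system,
        bipc=float(c_irr.sum()),
        bpc=float(c_bio.sum()),
        contributions=dict(zip(taxa, c_irr.tolist())),
        bpc_contributions=dict(zip(taxa, c_bio.tolist())),
        coverage_abundance_pct=cov_a,
        coverage_biomass_pct=cov_b,
        unscored_taxa=unscored,
        warnings=warnings,
    )


def bipc(sample: CommunitySample, scores: ScoreTable, system: str) -> IndexResult:
    """Alias of :func:`compute_index`; the BIPc value is ``result.bipc``."""
    return compute_index(sample, scores, system)


def bpc(sample: CommunitySample, scores: ScoreTable) -> tuple[float, dict[str, float]]:
    """BPc value and per-taxon contributions (system-independent)."""
    res = compute_index(sample, scores, "diffusive")
    return res.bpc, dict(res.bpc_contributions)


def coverage(
    samples: Iterable[CommunitySample], scores: ScoreTable
) -> tuple[float | None, float | None]:
    """Aggregate % of abundance and AFDW biomass carried by scored taxa.

    Percentages are computed on totals summed across all samples; a zero
    total leaves the respective coverage undefined (``None``), never 0.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("coverage requires at least one sample")
    tot_a = tot_b = sc_a = sc_b = 0.0
    for s in samples:
        for rec in s.records:
            tot_a += rec.abundance
            tot_b += rec.biomass_afdw
            if rec.taxon in scores:
                sc_a += rec.abundance
                sc_b += rec.biomass_afdw
    cov_a = 100.0 * sc_a / tot_a if tot_a > 0 else None
    cov_b = 100.0 * sc_b / tot_b if tot_b > 0 else None
    return cov_a, cov_b


def key_species(
    samples: Sequence[CommunitySample],
    scores: ScoreTable,
    systems: Sequence[str],
    classes: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Taxon shares of summed BIPc, overall and per sediment class.

    ``systems`` gives each sample's diffusive/advective attribution;
    ``classes`` optionally labels each sample with a sediment class
    (e.g. mud / fine sand / medium sand / coarse sand).  Each group maps to
    a DataFrame of columns ``taxon, contribution, share_pct`` sorted by
    descending share, ties broken alphabetically; shares sum to 100 per
    group.  A group whose summed BIPc is zero gets an empty ranking.
    """
    if len(systems) != len(samples):
        raise ValueError("one system label per sample required")
    if classes is not None and len(classes) != len(samples):
        raise ValueError("one class label per sample required")

    groups: dict[str, dict[str, float]] = {"overall": {}}
    for i, (sample, system) in enumerate(zip(samples, systems)):
        res = compute_index(sample, scores, system)
        keys = ["overall"]
        if classes is not None:
            keys.append(classes[i])
        for key in keys:
            acc = groups.setdefault(key, {})
            for taxon, c in res.contributions.items():
                acc[taxon] = acc.get(taxon, 0.0) + c

    out: dict[str, pd.DataFrame] = {}
    for key, acc in groups.items():
        total = sum(acc.values())
        if total <= 0:
            out[key] = pd.DataFrame(columns=["taxon", "contribution", "share_pct"])
            continue
        df = pd.DataFrame(
            {"taxon": list(acc.keys()), "contribution": list(acc.values())}
        )
        df["share_pct"] = 100.0 * df["contribution"] / total
        df = df.sort_values(
            ["share_pct", "taxon"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        out[key] = df
    return out


def layer_index(
    sample: CommunitySample,
    scores: ScoreTable,
    system: str,
    layer: tuple[float, float],
) -> IndexResult:
    """Index restricted to fauna found at ``layer[0] <= depth < layer[1]`` cm.

    The lower bound is closed, the upper open.  Records without a measured
    depth cannot be placed and are dropped with a warning; a sample where no
    record carries a depth raises, directing the caller to the whole-core
    index instead.
    """
    top, bottom = layer
    if not top < bottom:
        raise ValueError("layer top must be < bottom")
    if not any(r.depth_measured is not None for r in sample.records):
        raise ValueError(
            f"sample {sample.sample_id} has no measured depths; "
            "use the whole-core index"
        )
    kept, no_depth = [], []
    for rec in sample.records:
        if rec.depth_measured is None:
            no_depth.append(rec.taxon)
        elif top <= rec.depth_measured < bottom:
            kept.append(rec)
    sub = CommunitySample(
        station_id=sample.station_id,
        date=sample.date,
        records=kept,
        median_grain_um=sample.median_grain_um,
        system_override=sample.system_override,
    )
    res = compute_index(sub, scores, system)
    if no_depth:
        res.warnings = list(res.warnings) + [
            f"records without depth excluded from layer: {', '.join(no_depth)}"
        ]
    return res


def depth_profile(
    sample: CommunitySample,
    scores: ScoreTable,
    system: str,
    slice_cm: float,
    mode: str = "measured",
) -> DepthProfile:
    """Partition a sample's BIPc into vertical sediment slices.

    mode="measured"     uses each record's observed mid-depth of occurrence
    mode="theoretical"  uses the per-taxon literature burrow depth from the
                        score table (``lit_depth_cm``) — the anticipated
                        maximum penetration depth, as a point value

    Slices are ``[k·slice_cm, (k+1)·slice_cm)`` with the final slice closed;
    each record's whole contribution is assigned to the slice containing its
    depth, so slice values sum to the whole-core BIPc over included taxa.
    Taxa without a usable depth are excluded from the profile and reported
    in ``excluded_taxa`` (their whole-core contribution is unaffected).
    """
    if mode not in ("measured", "theoretical"):
        raise ValueError(f"unknown profile mode {mode!r}")
    if not slice_cm > 0:
        raise ValueError("slice thickness must be > 0")

    res = compute_index(sample, scores, system)
    depths: list[float] = []
    contribs: list[float] = []
    excluded: list[str] = []
    for rec in sample.records:
        c = res.contributions.get(rec.taxon)
        if c is None:
            continue  # unscored: not part of the index at all
        if mode == "measured":
            d = rec.depth_measured
        else:
            entry = scores.get(rec.taxon)
            d = entry.lit_depth_cm if entry is not None else None
        if d is None:
            excluded.append(rec.taxon)
            continue
        depths.append(float(d))
        contribs.append(c)

    if not depths:
        return DepthProfile(
            boundaries=[0.0, slice_cm], values=[0.0], mode=mode,
            excluded_taxa=excluded,
        )

    n_slices = max(1, math.ceil(max(depths) / slice_cm))
    boundaries = [k * slice_cm for k in range(n_slices + 1)]
    values = [0.0] * n_slices
    for d, c in zip(depths, contribs):
        k = min(int(d // slice_cm), n_slices - 1)
        values[k] += c
    return DepthProfile(
        boundaries=boundaries, values=values, mode=mode, excluded_taxa=excluded
    )
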