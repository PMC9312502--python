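"""Seeded synthetic data with the statistical structure the analysis assumes.

The study's monitoring data are not public, so every pipeline stage is
exercised on generated inputs that emulate their salient features:

- a trait-score table for a 120-taxon pool with distinct diffusive and
  advective score columns and a fraction of zero-score (epifaunal) taxa;
- lognormal, right-skewed community abundance/biomass samples whose
  *expected* bioirrigation potential is a configured multiple (default 5×)
  higher at advective than at diffusive stations, with a configured
  between-sample coefficient of variation;
- smooth Gaussian-filtered environmental predictor fields of which a
  declared subset actually drives the (log-scale) index, the rest being
  decoys;
- tracer/flux measurements monotonically linked to the true index through
  a power law with multiplicative lognormal noise.

Each generator records the ground truth it used, so downstream estimates
can be checked against known values.  A single global seed fans out to
fixed per-generator sub-streams, keeping outputs stable when new
generators are added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (
    CommunitySample,
    MeasurementRecord,
    ScoreEntry,
    ScoreTable,
    TaxonRecord,
)
from .raster import PredictorStack, Raster

# fixed sub-stream ids, one per generator
_STREAM_SCORES = 1
_STREAM_COMMUNITIES = 2
_STREAM_LANDSCAPE = 3
_STREAM_MEASUREMENTS = 4


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults mirror the emulated survey."""

    seed: int = 0
    # score table
    n_taxa: int = 120
    max_score: int = 3
    zero_score_frac: float = 0.1      # epifauna: burrow type scored 0
    adv_differ_frac: float = 0.5      # taxa whose advective scores differ
    # communities
    unscored_frac: float = 0.08       # taxa outside the scored pool
    n_stations: int = 8               # half diffusive, half advective
    years: int = 5
    occupancy_p: float = 0.4
    abundance_mu: float = 4.0         # ln ind·m⁻²
    abundance_sigma: float = 1.0
    indiv_mass_mu: float = -3.0       # ln g per individual (AFDW)
    indiv_mass_sigma: float = 1.0
    base_bipc: float = 100.0          # expected diffusive-system BIPc
    advective_multiplier: float = 5.0
    community_cv: float = 0.3         # between-sample CV of true BIPc
    # landscape
    landscape_shape: tuple[int, int] = (40, 40)
    landscape_smoothness: float = 4.0  # Gaussian-filter sigma, cells
    n_driving: int = 3
    n_decoy: int = 5
    landscape_noise_sigma: float = 0.3
    landscape_stations: int = 200
    cellsize: float = 600.0            # metres
    # measurements
    measurement_a: float = 0.05        # irrigation = a · BIPc^b · e^ε
    measurement_b: float = 1.0
    measurement_sigma: float = 0.3
    n_cores: int = 14

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not self.advective_multiplier > 0:
            raise ValueError("advective multiplier must be > 0")
        for name in ("abundance_sigma", "indiv_mass_sigma",
                     "landscape_noise_sigma", "measurement_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def loop_bipc(records: Sequence[TaxonRecord], scores: ScoreTable, system: str) -> float:
    """Literal per-taxon evaluation of the bioirrigation sum.

    Deliberately independent of the vectorised engine: a plain Python loop
    over records used as the generator's ground-truth oracle.
    """
    total = 0.0
    for rec in records:
        entry = scores.get(rec.taxon)
        if entry is None or rec.abundance == 0:
            continue
        if system == "diffusive":
            ft, bt, l = entry.ft_diff, entry.bt_diff, entry.l_diff
        elif system == "advective":
            ft, bt, l = entry.ft_adv, entry.bt_adv, entry.l_adv
        else:
            raise ValueError(f"unknown system {system!r}")
        total += (rec.biomass_afdw / rec.abundance) * rec.abundance * ft * bt * l
    return total


def loop_bpc(records: Sequence[TaxonRecord], scores: ScoreTable) -> float:
    """Loop-oracle counterpart for the bioturbation sum."""
    total = 0.0
    for rec in records:
        entry = scores.get(rec.taxon)
        if entry is None or rec.abundance == 0:
            continue
        total += (
            math.sqrt(rec.biomass_afdw / rec.abundance)
            * rec.abundance * entry.m_bpc * entry.r_bpc
        )
    return total


def gen_scores(config: GeneratorConfig) -> ScoreTable:
    """Synthetic trait-score table for the taxon pool.

    Scores are uniform integers in [1, max_score]; an exact
    ``zero_score_frac`` share of taxa are epifaunal (burrow-type score 0 in
    both systems) and an ``adv_differ_frac`` share get independently drawn
    advective scores.  Literature burrow depths (``lit_depth_cm``) are
    drawn uniformly in [2, 15] cm.
    """
    rng = config.rng(_STREAM_SCORES)
    n = config.n_taxa
    hi = config.max_score

    def draw(size):
        return rng.integers(1, hi + 1, size=size).astype(float)

    ft_d, bt_d, l_d = draw(n), draw(n), draw(n)
    ft_a, bt_a, l_a = ft_d.copy(), bt_d.copy(), l_d.copy()
    differ = rng.random(n) < config.adv_differ_frac
    ft_a[differ], bt_a[differ], l_a[differ] = (
        draw(differ.sum()), draw(differ.sum()), draw(differ.sum())
    )
    m, r = draw(n), draw(n)
    n_zero = round(config.zero_score_frac * n)
    zero_idx = rng.choice(n, size=n_zero, replace=False)
    bt_d[zero_idx] = bt_a[zero_idx] = 0.0
    depths = rng.uniform(2.0, 15.0, size=n)

    entries = [
        ScoreEntry(
            taxon=f"Taxonus synth{i:03d}",
            ft_diff=ft_d[i], bt_diff=bt_d[i], l_diff=l_d[i],
            ft_adv=ft_a[i], bt_adv=bt_a[i], l_adv=l_a[i],
            m_bpc=m[i], r_bpc=r[i],
            lit_depth_cm=float(depths[i]),
        )
        for i in range(n)
    ]
    return ScoreTable(entries)


@dataclass
class CommunityData:
    """Generated samples with their ground truth."""

    samples: list[CommunitySample]
    systems: list[str]
    true_bipc: list[float]
    stations: list[str] = field(default_factory=list)


def gen_communities(
    config: GeneratorConfig, scores: ScoreTable
) -> CommunityData:
    """Generate station × year community samples with known true BIPc.

    Occupancy is Bernoulli per taxon, abundances and per-individual masses
    are lognormal.  A community also contains rarer taxa that no score list
    covers; an extra pool of ``unscored_frac × n_taxa`` such taxa (drawn
    like the others) keeps the coverage diagnostics non-trivial.  Each sample's biomasses are then rescaled so that its
    true index equals ``base_bipc × multiplier(system) × S`` with
    S ~ lognormal(E[S] = 1, CV = community_cv), giving the configured
    expected advective/diffusive contrast exactly.  The returned truth is
    computed with the loop oracle, not the vectorised engine.
    """
    rng = config.rng(_STREAM_COMMUNITIES)
    n_adv = config.n_stations // 2
    stations = []
    station_system = {}
    grains = {}
    for i in range(config.n_stations):
        st = f"ST{i:02d}"
        stations.append(st)
        advective = i < n_adv
        station_system[st] = "advective" if advective else "diffusive"
        grains[st] = float(rng.uniform(190, 320) if advective else rng.uniform(20, 150))

    # lognormal scale factor with mean 1 and the configured CV
    cv = config.community_cv
    s_sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    s_mu = -0.5 * s_sigma * s_sigma

    entries = scores.entries
    n_unscored = round(config.unscored_frac * config.n_taxa)
    unscored_pool = [f"Nonscorus extra{i:03d}" for i in range(n_unscored)]
    samples: list[CommunitySample] = []
    systems: list[str] = []
    truths: list[float] = []
    for st in stations:
        system = station_system[st]
        mult = config.advective_multiplier if system == "advective" else 1.0
        for year in range(config.years):
            records: list[TaxonRecord] = []
            present = rng.random(len(entries)) < config.occupancy_p
            for e, here in zip(entries, present):
                if not here:
                    continue
                a = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
                mass = float(rng.lognormal(config.indiv_mass_mu, config.indiv_mass_sigma))
                records.append(
                    TaxonRecord(
                        taxon=e.taxon,
                        abundance=a,
                        biomass_afdw=a * mass,
                        depth_measured=float(
                            rng.uniform(0.0, e.lit_depth_cm or 10.0)
                        ),
                    )
                )
            extra_here = rng.random(n_unscored) < config.occupancy_p
            for name, here in zip(unscored_pool, extra_here):
                if not here:
                    continue
                a = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
                mass = float(rng.lognormal(config.indiv_mass_mu, config.indiv_mass_sigma))
                records.append(
                    TaxonRecord(taxon=name, abundance=a, biomass_afdw=a * mass,
                                depth_measured=float(rng.uniform(0.0, 10.0)))
                )
            target = config.base_bipc * mult * float(rng.lognormal(s_mu, s_sigma))
            raw = loop_bipc(records, scores, system)
            if raw > 0:
                factor = target / raw
                records = [
                    TaxonRecord(
                        taxon=r.taxon,
                        abundance=r.abundance,
                        biomass_afdw=r.biomass_afdw * factor,
                        depth_measured=r.depth_measured,
                    )
                    for r in records
                ]
            sample = CommunitySample(
                station_id=st,
                date=f"{2000 + year}-05-15",
                records=records,
                median_grain_um=grains[st],
            )
            samples.append(sample)
            systems.append(system)
            truths.append(loop_bipc(records, scores, system))
    return CommunityData(
        samples=samples, systems=systems, true_bipc=truths, stations=stations
    )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardised Gaussian-filtered white-noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


@dataclass
class LandscapeData:
    """Predictor stack plus declared spatial ground truth."""

    stack: PredictorStack
    driving: list[str]
    decoys: list[str]
    true_log_bipc: Raster
    station_x: np.ndarray
    station_y: np.ndarray
    station_log_bipc: np.ndarray       # includes noise; what a survey observes
    station_predictors: pd.DataFrame
    coefficients: dict[str, float]
    # companion bioturbation-potential response (same drivers, different
    # weights), used to exercise the bivariate overlay
    station_log_bpc: np.ndarray | None = None
    bpc_coefficients: dict[str, float] | None = None
    true_log_bpc: Raster | None = None


def gen_landscape(config: GeneratorConfig) -> LandscapeData:
    """Smooth predictor fields with a declared log-index response.

    True log-scale index = Σ βₖ·layerₖ over the driving layers (β fixed,
    declared in the result) shifted to non-negative values; stations sample
    random distinct cells and observe the truth plus Gaussian noise of the
    configured sigma.  Decoy layers do not enter the response.
    """
    rng = config.rng(_STREAM_LANDSCAPE)
    shape = tuple(config.landscape_shape)
    names_drive = [f"driver_{i}" for i in range(config.n_driving)]
    names_decoy = [f"decoy_{i}" for i in range(config.n_decoy)]
    cell = config.cellsize
    fields = {
        name: _smooth_field(rng, shape, config.landscape_smoothness)
        for name in names_drive + names_decoy
    }
    # Smooth fields have few effective degrees of freedom, so an independent
    # draw can correlate strongly with the drivers by chance; project the
    # driver subspace out of each decoy so "decoy" is true of the realised
    # field, not just of the recipe.
    drive_mat = np.column_stack(
        [np.ones(shape[0] * shape[1])] + [fields[n].ravel() for n in names_drive]
    )
    for name in names_decoy:
        flat = fields[name].ravel()
        coef, *_ = np.linalg.lstsq(drive_mat, flat, rcond=None)
        resid = (flat - drive_mat @ coef).reshape(shape)
        fields[name] = (resid - resid.mean()) / resid.std()
    layers = {
        name: Raster(
            data=np.ma.asarray(data), x0=cell / 2, y0=shape[0] * cell - cell / 2,
            dx=cell, dy=cell,
        )
        for name, data in fields.items()
    }
    betas = {name: 1.5 - 0.3 * i for i, name in enumerate(names_drive)}
    truth = sum(betas[n] * np.asarray(layers[n].data) for n in names_drive)
    truth = truth - truth.min()  # log10(x+1) scale is non-negative
    truth_raster = Raster(
        data=np.ma.asarray(truth),
        x0=cell / 2, y0=shape[0] * cell - cell / 2, dx=cell, dy=cell,
    )

    n_st = config.landscape_stations
    flat = rng.choice(shape[0] * shape[1], size=n_st, replace=False)
    rows, cols = np.unravel_index(flat, shape)
    xs = truth_raster.x0 + cols * cell
    ys = truth_raster.y0 - rows * cell
    # log10(x+1) of a non-negative index cannot go below zero
    observed = np.maximum(
        truth[rows, cols]
        + rng.normal(0.0, config.landscape_noise_sigma, size=n_st),
        0.0,
    )
    stack = PredictorStack(layers)
    pred = pd.DataFrame(stack.extract(xs, ys), columns=stack.names)

    # companion response: same drivers, reversed weights → similar but not
    # identical spatial pattern, as expected of a sibling trait index
    betas_b = {name: b for name, b in zip(names_drive, reversed(list(betas.values())))}
    truth_b = sum(betas_b[n] * np.asarray(layers[n].data) for n in names_drive)
    truth_b = truth_b - truth_b.min()
    truth_b_raster = Raster(
        data=np.ma.asarray(truth_b),
        x0=cell / 2, y0=shape[0] * cell - cell / 2, dx=cell, dy=cell,
    )
    observed_b = np.maximum(
        truth_b[rows, cols]
        + rng.normal(0.0, config.landscape_noise_sigma, size=n_st),
        0.0,
    )
    return LandscapeData(
        stack=stack,
        driving=names_drive,
        decoys=names_decoy,
        true_log_bipc=truth_raster,
        station_x=np.asarray(xs, dtype=float),
        station_y=np.asarray(ys, dtype=float),
        station_log_bipc=observed,
        station_predictors=pred,
        coefficients=betas,
        station_log_bpc=observed_b,
        bpc_coefficients=betas_b,
        true_log_bpc=truth_b_raster,
    )


def stratified_cores(samples: Sequence[CommunitySample], n: int) -> list[CommunitySample]:
    """Pick ``n`` incubation cores round-robin across stations.

    Measured cores in a tracer campaign span contrasting sites, so the
    selection cycles over stations (one sampling date per pass) rather than
    taking consecutive samples from a single station.
    """
    by_station: dict[str, list[CommunitySample]] = {}
    for s in samples:
        by_station.setdefault(s.station_id, []).append(s)
    queues = list(by_station.values())
    out: list[CommunitySample] = []
    i = 0
    while len(out) < min(n, len(samples)):
        q = queues[i % len(queues)]
        if q:
            out.append(q.pop(0))
        i += 1
    return out


def gen_measurements(
    config: GeneratorConfig,
    true_bipc_by_core: dict[str, float],
) -> list[MeasurementRecord]:
    """Tracer-irrigation measurements monotonically linked to true BIPc.

    irrigation (L·m⁻²·d⁻¹) = a · BIPc^b · exp(ε), ε ~ N(0, σ²); a bromide
    inventory proportional to irrigation is emitted alongside.  With σ = 0
    the link is exactly monotone.
    """
    rng = config.rng(_STREAM_MEASUREMENTS)
    records: list[MeasurementRecord] = []
    for core, v in true_bipc_by_core.items():
        eps = float(rng.normal(0.0, config.measurement_sigma))
        irr = config.measurement_a * (v ** config.measurement_b) * math.exp(eps)
        records.append(
            MeasurementRecord(core_id=core, quantity="irrigation_l_m2_d", value=irr)
        )
        eps2 = float(rng.normal(0.0, config.measurement_sigma))
        records.append(
            MeasurementRecord(
                core_id=core, quantity="br_inventory_mmol_m2",
                value=20.0 * irr * math.exp(eps2),
            )
        )
    return records
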