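"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised/engine code
paths: they work on plain dicts and Python loops so that agreement with the
engine is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from benthirr.datatypes import CommunitySample, ScoreEntry, ScoreTable, TaxonRecord


def oracle_bipc(sample: CommunitySample, score_rows: dict[str, dict], system: str) -> float:
    """Plain-loop evaluation of the bioirrigation sum from a dict of scores."""
    total = 0.0
    for rec in sample.records:
        row = score_rows.get(rec.taxon.strip().casefold())
        if row is None or rec.abundance == 0:
            continue
        suffix = "diff" if system == "diffusive" else "adv"
        prod = row[f"ft_{suffix}"] * row[f"bt_{suffix}"] * row[f"l_{suffix}"]
        total += (rec.biomass_afdw / rec.abundance) * rec.abundance * prod
    return total


def oracle_bpc(sample: CommunitySample, score_rows: dict[str, dict]) -> float:
    total = 0.0
    for rec in sample.records:
        row = score_rows.get(rec.taxon.strip().casefold())
        if row is None or rec.abundance == 0:
            continue
        total += (
            math.sqrt(rec.biomass_afdw / rec.abundance)
            * rec.abundance * row["m_bpc"] * row["r_bpc"]
        )
    return total


def random_scores(rng: np.random.Generator, n_taxa: int) -> tuple[ScoreTable, dict]:
    """A random score table plus its plain-dict mirror for the oracles."""
    entries = []
    rows = {}
    for i in range(n_taxa):
        name = f"Taxon sp{i:03d}"
        vals = {
            k: float(rng.integers(0, 4))
            for k in ("ft_diff", "bt_diff", "l_diff", "ft_adv", "bt_adv", "l_adv",
                      "m_bpc", "r_bpc")
        }
        entries.append(ScoreEntry(taxon=name, **vals))
        rows[name.casefold()] = vals
    return ScoreTable(entries), rows


def random_sample(
    rng: np.random.Generator,
    taxa_pool: list[str],
    n_taxa: int,
    station: str = "S1",
    date: str = "2020-01-01",
    allow_zero_abundance: bool = False,
) -> CommunitySample:
    chosen = rng.choice(len(taxa_pool), size=min(n_taxa, len(taxa_pool)), replace=False)
    records = []
    for i in chosen:
        a = float(rng.lognormal(3, 1))
        if allow_zero_abundance and rng.random() < 0.1:
            a, b = 0.0, 0.0
        else:
            b = a * float(rng.lognormal(-2, 1))
        records.append(
            TaxonRecord(taxon=taxa_pool[i], abundance=a, biomass_afdw=b,
                        depth_measured=float(rng.uniform(0, 12)))
        )
    return CommunitySample(station_id=station, date=date, records=records)


@pytest.fixture(scope="session")
def score_pair():
    """(ScoreTable, dict mirror) for a 60-taxon random pool, seeded."""
    rng = np.random.default_rng(12345)
    return random_scores(rng, 60)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_scores():
    """Two hand-written taxa with known scores."""
    return ScoreTable(
        [
            ScoreEntry("Mya arenaria", ft_diff=2, bt_diff=2, l_diff=3,
                       ft_adv=1, bt_adv=2, l_adv=2, m_bpc=3, r_bpc=3,
                       lit_depth_cm=10.0),
            ScoreEntry("Pygospio elegans", ft_diff=1, bt_diff=0, l_diff=2,
                       ft_adv=2, bt_adv=1, l_adv=1, m_bpc=2, r_bpc=1,
                       lit_depth_cm=4.0),
        ]
    )
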