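"""Index engine: worked examples, oracle equivalence and conservation laws."""

import numpy as np
import pytest

from benthirr.datatypes import CommunitySample, ScoreEntry, ScoreTable, TaxonRecord
from benthirr.index import (
    bpc,
    compute_index,
    coverage,
    depth_profile,
    key_species,
    layer_index,
)

from conftest import oracle_bipc, oracle_bpc, random_sample


def one_taxon_sample(taxon="Mya arenaria", a=100.0, b=2.0, depth=None):
    return CommunitySample(
        station_id="S1", date="2020-01-01",
        records=[TaxonRecord(taxon=taxon, abundance=a, biomass_afdw=b,
                             depth_measured=depth)],
    )


class TestBipc:
    def test_single_taxon_hand_value(self, tiny_scores):
        # (2/100)·100·2·2·3 = 24
        res = compute_index(one_taxon_sample(a=100, b=2), tiny_scores, "diffusive")
        assert res.bipc == pytest.approx(24.0)

    def test_zero_score_factor_kills_contribution(self, tiny_scores):
        # Pygospio has bt_diff = 0: epifauna-style zero regardless of biomass
        res = compute_index(
            one_taxon_sample("Pygospio elegans", a=500, b=40), tiny_scores, "diffusive"
        )
        assert res.bipc == 0.0

    def test_additivity_over_taxa(self, tiny_scores):
        both = CommunitySample(
            station_id="S1", date="d",
            records=[TaxonRecord("Mya arenaria", 100, 2),
                     TaxonRecord("Pygospio elegans", 50, 1)],
        )
        r_both = compute_index(both, tiny_scores, "advective")
        r1 = compute_index(one_taxon_sample(a=100, b=2), tiny_scores, "advective")
        r2 = compute_index(one_taxon_sample("Pygospio elegans", a=50, b=1),
                           tiny_scores, "advective")
        assert r_both.bipc == pytest.approx(r1.bipc + r2.bipc)

    def test_system_switch_changes_result_only_with_differing_scores(self, tiny_scores):
        s = one_taxon_sample(a=100, b=2)
        d = compute_index(s, tiny_scores, "diffusive").bipc
        a = compute_index(s, tiny_scores, "advective").bipc
        assert d != a  # Mya scores differ between systems: 2·2·3 vs 1·2·2

    def test_zero_abundance_record_contributes_zero(self, tiny_scores):
        s = CommunitySample(station_id="S", date="d",
                            records=[TaxonRecord("Mya arenaria", 0.0, 0.0)])
        assert compute_index(s, tiny_scores, "diffusive").bipc == 0.0

    def test_unknown_system_rejected(self, tiny_scores):
        with pytest.raises(ValueError):
            compute_index(one_taxon_sample(), tiny_scores, "sandy")

    def test_all_unscored_sample_warns_not_raises(self, tiny_scores):
        s = one_taxon_sample(taxon="Nobody knowsi")
        res = compute_index(s, tiny_scores, "diffusive")
        assert res.bipc == 0.0
        assert res.unscored_taxa == ["Nobody knowsi"]
        assert res.warnings

    def test_matches_loop_oracle_on_random_samples(self, score_pair, rng):
        table, rows = score_pair
        pool = [e.taxon for e in table.entries]
        for _ in range(50):
            s = random_sample(rng, pool, 50, allow_zero_abundance=True)
            res = compute_index(s, table, "advective")
            expected = oracle_bipc(s, rows, "advective")
            assert res.bipc == pytest.approx(expected, rel=1e-12)
            assert res.bipc == pytest.approx(sum(res.contributions.values()), rel=1e-12)

    def test_algebraic_identity_biomass_times_scores(self, score_pair, rng):
        """With all abundances > 0, Eq-style result equals Σ Bᵢ·FT·BT·L."""
        table, rows = score_pair
        pool = [e.taxon for e in table.entries]
        for _ in range(20):
            s = random_sample(rng, pool, 30)
            res = compute_index(s, table, "diffusive")
            direct = sum(
                rec.biomass_afdw
                * rows[rec.taxon.casefold()]["ft_diff"]
                * rows[rec.taxon.casefold()]["bt_diff"]
                * rows[rec.taxon.casefold()]["l_diff"]
                for rec in s.records
            )
            assert res.bipc == pytest.approx(direct, rel=1e-12)

    def test_homogeneity_in_biomass_and_abundance(self, score_pair, rng):
        table, _ = score_pair
        pool = [e.taxon for e in table.entries]
        s = random_sample(rng, pool, 30)
        base = compute_index(s, table, "diffusive")
        scaled_b = CommunitySample(
            station_id="S", date="d",
            records=[TaxonRecord(r.taxon, r.abundance, 3.0 * r.biomass_afdw)
                     for r in s.records],
        )
        res_b = compute_index(scaled_b, table, "diffusive")
        assert res_b.bipc == pytest.approx(3.0 * base.bipc, rel=1e-9)
        # BPc scales as √3 under a biomass-only rescale
        assert res_b.bpc == pytest.approx(np.sqrt(3.0) * base.bpc, rel=1e-9)
        # scaling abundance at fixed biomass leaves BIPc unchanged
        scaled_a = CommunitySample(
            station_id="S", date="d",
            records=[TaxonRecord(r.taxon, 7.0 * r.abundance, r.biomass_afdw)
                     for r in s.records],
        )
        res_a = compute_index(scaled_a, table, "diffusive")
        assert res_a.bipc == pytest.approx(base.bipc, rel=1e-9)


class TestBpc:
    def test_hand_value(self, tiny_scores):
        # √(4/100)·100·3·3 = 0.2·100·9 = 180
        val, contribs = bpc(one_taxon_sample(a=100, b=4), tiny_scores)
        assert val == pytest.approx(180.0)
        assert contribs["Mya arenaria"] == pytest.approx(180.0)

    def test_zero_mobility_score(self):
        table = ScoreTable([ScoreEntry("A a", 1, 1, 1, 1, 1, 1, m_bpc=0, r_bpc=3)])
        val, _ = bpc(one_taxon_sample("A a", 100, 4), table)
        assert val == 0.0

    def test_matches_loop_oracle(self, score_pair, rng):
        table, rows = score_pair
        pool = [e.taxon for e in table.entries]
        for _ in range(30):
            s = random_sample(rng, pool, 40, allow_zero_abundance=True)
            val, _ = bpc(s, table)
            assert val == pytest.approx(oracle_bpc(s, rows), rel=1e-12)


class TestCoverage:
    def test_all_scored(self, tiny_scores):
        s = one_taxon_sample(a=10, b=1)
        assert coverage([s], tiny_scores) == (pytest.approx(100.0), pytest.approx(100.0))

    def test_half_biomass_scored(self, tiny_scores):
        s = CommunitySample(station_id="S", date="d", records=[
            TaxonRecord("Mya arenaria", 10, 1.0),
            TaxonRecord("Unknown speciesi", 30, 1.0),
        ])
        cov_a, cov_b = coverage([s], tiny_scores)
        assert cov_b == pytest.approx(50.0)
        assert cov_a == pytest.approx(25.0)

    def test_scored_plus_unscored_is_total(self, score_pair, rng):
        table, _ = score_pair
        pool = [e.taxon for e in table.entries] + [f"Extra sp{i}" for i in range(20)]
        samples = [random_sample(rng, pool, 40) for _ in range(10)]
        cov_a, cov_b = coverage(samples, table)
        tot_a = sum(r.abundance for s in samples for r in s.records)
        sc_a = sum(r.abundance for s in samples for r in s.records if r.taxon in table)
        assert cov_a == pytest.approx(100.0 * sc_a / tot_a, rel=1e-12)
        assert 0 <= cov_a <= 100 and 0 <= cov_b <= 100

    def test_zero_total_reported_missing(self, tiny_scores):
        s = CommunitySample(station_id="S", date="d", records=[])
        assert coverage([s], tiny_scores) == (None, None)


class TestKeySpecies:
    def test_single_taxon_is_everything(self, tiny_scores):
        shares = key_species([one_taxon_sample(a=10, b=1)], tiny_scores, ["diffusive"])
        df = shares["overall"]
        assert list(df["taxon"]) == ["Mya arenaria"]
        assert df["share_pct"].iloc[0] == pytest.approx(100.0)

    def test_equal_contributions_tie_broken_alphabetically(self):
        table = ScoreTable([
            ScoreEntry("Zebra speciesi", 1, 1, 1, 1, 1, 1, 1, 1),
            ScoreEntry("Alpha speciesi", 1, 1, 1, 1, 1, 1, 1, 1),
        ])
        s = CommunitySample(station_id="S", date="d", records=[
            TaxonRecord("Zebra speciesi", 10, 2.0),
            TaxonRecord("Alpha speciesi", 10, 2.0),
        ])
        df = key_species([s], table, ["diffusive"])["overall"]
        assert list(df["taxon"]) == ["Alpha speciesi", "Zebra speciesi"]
        assert df["share_pct"].tolist() == pytest.approx([50.0, 50.0])

    def test_shares_sum_to_100_per_group_and_match_oracle(self, score_pair, rng):
        table, rows = score_pair
        pool = [e.taxon for e in table.entries]
        samples = [random_sample(rng, pool, 20) for _ in range(8)]
        systems = ["diffusive"] * 4 + ["advective"] * 4
        classes = ["mud"] * 4 + ["medium sand"] * 4
        shares = key_species(samples, table, systems, classes)
        for group, df in shares.items():
            if len(df):
                assert df["share_pct"].sum() == pytest.approx(100.0)
        # oracle: brute-force per-group contribution sums
        acc: dict[str, float] = {}
        for s, system in zip(samples[:4], systems[:4]):
            for rec in s.records:
                row = rows.get(rec.taxon.casefold())
                if row is None or rec.abundance == 0:
                    continue
                c = rec.biomass_afdw * row["ft_diff"] * row["bt_diff"] * row["l_diff"]
                acc[rec.taxon] = acc.get(rec.taxon, 0.0) + c
        total = sum(acc.values())
        df = shares["mud"].set_index("taxon")
        for taxon, c in acc.items():
            if c > 0:
                assert df.loc[taxon, "share_pct"] == pytest.approx(
                    100.0 * c / total, rel=1e-9)

    def test_zero_total_group_gets_empty_ranking(self, tiny_scores):
        s = one_taxon_sample("Pygospio elegans", a=10, b=1)  # bt_diff = 0
        shares = key_species([s], tiny_scores, ["diffusive"])
        assert len(shares["overall"]) == 0


class TestLayerIndex:
    def make(self, depth):
        return one_taxon_sample(a=100, b=2, depth=depth)

    def test_inside_layer_included(self, tiny_scores):
        res = layer_index(self.make(5.0), tiny_scores, "diffusive", (2, 10))
        assert res.bipc == pytest.approx(24.0)

    def test_above_layer_excluded(self, tiny_scores):
        res = layer_index(self.make(1.0), tiny_scores, "diffusive", (2, 10))
        assert res.bipc == 0.0

    def test_lower_bound_closed(self, tiny_scores):
        res = layer_index(self.make(2.0), tiny_scores, "diffusive", (2, 10))
        assert res.bipc == pytest.approx(24.0)

    def test_upper_bound_open(self, tiny_scores):
        res = layer_index(self.make(10.0), tiny_scores, "diffusive", (2, 10))
        assert res.bipc == 0.0

    def test_no_depths_raises_with_direction(self, tiny_scores):
        with pytest.raises(ValueError, match="whole-core"):
            layer_index(self.make(None), tiny_scores, "diffusive", (2, 10))


class TestDepthProfile:
    def test_all_fauna_in_one_slice(self, tiny_scores):
        prof = depth_profile(one_taxon_sample(a=100, b=2, depth=3.0),
                             tiny_scores, "diffusive", slice_cm=2.0)
        assert prof.boundaries == [0.0, 2.0, 4.0]
        assert prof.values == pytest.approx([0.0, 24.0])

    def test_slices_conserve_whole_core_value(self, score_pair, rng):
        table, _ = score_pair
        pool = [e.taxon for e in table.entries]
        for _ in range(10):
            s = random_sample(rng, pool, 30)
            whole = compute_index(s, table, "diffusive").bipc
            prof = depth_profile(s, table, "diffusive", slice_cm=2.0)
            assert sum(prof.values) == pytest.approx(whole, rel=1e-12)

    def test_depth_on_final_edge_stays_in_last_slice(self, tiny_scores):
        prof = depth_profile(one_taxon_sample(a=100, b=2, depth=4.0),
                             tiny_scores, "diffusive", slice_cm=2.0)
        assert prof.values[-1] == pytest.approx(24.0)

    def test_theoretical_mode_uses_literature_depths(self, tiny_scores):
        # Mya lit depth 10 cm; measured 3 cm → theoretical mass deeper
        s = one_taxon_sample(a=100, b=2, depth=3.0)
        measured = depth_profile(s, tiny_scores, "diffusive", 2.0, mode="measured")
        theo = depth_profile(s, tiny_scores, "diffusive", 2.0, mode="theoretical")
        centre = lambda p: sum(
            0.5 * (p.boundaries[i] + p.boundaries[i + 1]) * v
            for i, v in enumerate(p.values)
        ) / sum(p.values)
        assert centre(theo) > centre(measured)

    def test_missing_literature_depth_flags_taxon(self):
        table = ScoreTable([ScoreEntry("A a", 1, 1, 1, 1, 1, 1, 1, 1)])  # no lit depth
        s = one_taxon_sample("A a", a=10, b=1, depth=3.0)
        prof = depth_profile(s, table, "diffusive", 2.0, mode="theoretical")
        assert prof.excluded_taxa == ["A a"]
        assert sum(prof.values) == 0.0
        # whole-core value is unaffected
        assert compute_index(s, table, "diffusive").bipc > 0
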