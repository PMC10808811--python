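import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microhi as mh


def make_pmap(taxa, pathogenic):
    return mh.PhenotypeMap(
        pd.DataFrame(
            {
                "pathogenic": [1.0 if t in pathogenic else 0.0 for t in taxa],
                "mobile": 0.0,
                "stress": 0.0,
            },
            index=taxa,
        )
    )


class TestPhenotypeLinked:
    def test_weighted_and_present_taxon_selected(self, tiny_table):
        pmap = make_pmap(tiny_table.taxa, {"TaxA"})
        assert mh.phenotype_linked_taxa(tiny_table, pmap) == ["TaxA"]

    def test_all_zero_map_gives_empty_set(self, tiny_table):
        pmap = make_pmap(tiny_table.taxa, set())
        assert mh.phenotype_linked_taxa(tiny_table, pmap) == []

    def test_absent_taxon_excluded(self):
        frame = pd.DataFrame({"s1": [1.0, 0.0], "s2": [1.0, 0.0]}, index=["A", "Ghost"])
        table = mh.AbundanceTable(frame)
        pmap = make_pmap(["A", "Ghost"], {"A", "Ghost"})
        assert mh.phenotype_linked_taxa(table, pmap) == ["A"]


def unit_meta(n_units, gut_per_unit, water_per_unit):
    records = []
    g = w = 0
    for u in range(n_units):
        for _ in range(gut_per_unit):
            records.append(
                mh.SampleMetadata(
                    sample_id=f"g{g}", source="gut", species="Sp",
                    ecotype="carnivorous", site=f"S{u}", year=2022,
                )
            )
            g += 1
        for _ in range(water_per_unit):
            records.append(
                mh.SampleMetadata(sample_id=f"w{w}", source="water", site=f"S{u}", year=2022)
            )
            w += 1
    return mh.metadata_frame(records)


def tables_from_unit_values(gut_vals, water_vals, taxon="T"):
    """One-taxon-of-interest tables; a second filler taxon absorbs the rest."""
    def build(vals, prefix):
        cols = {f"{prefix}{i}": [v, 1 - v] for i, v in enumerate(vals)}
        return mh.AbundanceTable(pd.DataFrame(cols, index=[taxon, "filler"]))

    return build(gut_vals, "g"), build(water_vals, "w")


class TestEnvGutCorrelation:
    def test_exact_proportionality_flags_both(self):
        water = [0.05, 0.10, 0.15, 0.20]
        gut = [2 * v for v in water]
        gut_t, water_t = tables_from_unit_values(gut, water)
        meta = unit_meta(4, 1, 1)
        rec = mh.env_gut_correlation(gut_t, water_t, meta, ["T"])
        row = rec.loc["T"]
        assert row["env_gut_slope"] == pytest.approx(2.0, abs=1e-9)
        assert row["env_gut_r2"] == pytest.approx(1.0, abs=1e-9)
        assert bool(row["correlated"]) and bool(row["positive"])

    def test_constant_gut_fails_positive_flag(self):
        water = [0.05, 0.10, 0.15, 0.20]
        gut_t, water_t = tables_from_unit_values([0.3] * 4, water)
        meta = unit_meta(4, 1, 1)
        row = mh.env_gut_correlation(gut_t, water_t, meta, ["T"]).loc["T"]
        assert row["env_gut_slope"] == pytest.approx(0.0, abs=1e-12)
        assert not bool(row["positive"])

    def test_fewer_than_three_units_flagged_insufficient(self):
        gut_t, water_t = tables_from_unit_values([0.1, 0.2], [0.1, 0.2])
        meta = unit_meta(2, 1, 1)
        rec = mh.env_gut_correlation(gut_t, water_t, meta, ["T"])
        assert bool(rec.loc["T", "insufficient"])

    def test_matches_least_squares_oracle(self, rng):
        water = rng.uniform(0.05, 0.3, 5)
        gut = rng.uniform(0.05, 0.3, 5)
        gut_t, water_t = tables_from_unit_values(gut, water)
        meta = unit_meta(5, 1, 1)
        row = mh.env_gut_correlation(gut_t, water_t, meta, ["T"]).loc["T"]
        fit = stats.linregress(water, gut)
        assert row["env_gut_slope"] == pytest.approx(fit.slope, abs=1e-9)
        assert row["env_gut_r2"] == pytest.approx(fit.rvalue**2, abs=1e-9)

    def test_undetectable_in_water_cannot_be_correlated(self):
        # taxon absent from the water column: never flagged correlated
        water = [1e-7, 2e-7, 1e-7, 3e-7]
        gut = [0.1, 0.2, 0.3, 0.4]
        gut_t, water_t = tables_from_unit_values(gut, water)
        meta = unit_meta(4, 1, 1)
        row = mh.env_gut_correlation(gut_t, water_t, meta, ["T"]).loc["T"]
        assert not bool(row["correlated"]) and not bool(row["positive"])


def differential_fixture(rng, n=20, high=0.10):
    """One taxon near zero in healthy guts and ~10% in unhealthy guts."""
    taxa = ["spike", "a", "b", "c"]
    cols, labels, records = {}, {}, []
    for i in range(2 * n):
        unhealthy = i >= n
        base = np.array([high if unhealthy else 0.002, 0.4, 0.3, 0.3])
        cols[f"g{i}"] = rng.dirichlet(base / base.sum() * 100)
        labels[f"g{i}"] = "unhealthy" if unhealthy else "healthy"
        records.append(
            mh.SampleMetadata(
                sample_id=f"g{i}", source="gut", species="Sp",
                ecotype="carnivorous", site="S1", year=2022,
            )
        )
    table = mh.AbundanceTable(pd.DataFrame(cols, index=taxa))
    return table, pd.Series(labels), mh.metadata_frame(records)


class TestKwLdaDifferential:
    def test_identical_groups_not_differential(self, rng):
        table, labels, meta = differential_fixture(rng)
        # relabel so both groups are draws from the same healthy pool
        flat = pd.Series(
            ["healthy" if i % 2 else "unhealthy" for i in range(20)],
            index=[f"g{i}" for i in range(20)],
        )
        out = mh.kw_lda_differential(table.subset(list(flat.index)), flat, meta, "carnivorous")
        assert not out["differential"].any()

    def test_spiked_taxon_differential_up_in_unhealthy(self, rng):
        table, labels, meta = differential_fixture(rng)
        out = mh.kw_lda_differential(table, labels, meta, "carnivorous")
        row = out.loc["spike"]
        assert row["kw_p"] < 0.05
        assert row["lda_score"] >= 3.0
        assert row["direction"] == "up-in-unhealthy"
        assert bool(row["differential"])

    def test_single_group_ecotype_untestable(self, rng):
        table, labels, meta = differential_fixture(rng)
        labels[:] = "healthy"
        out = mh.kw_lda_differential(table, labels, meta, "carnivorous")
        assert out["untestable"].all()
        assert out["kw_p"].isna().all()

    def test_lda_scores_deterministic_for_fixed_seed(self, rng):
        table, labels, meta = differential_fixture(rng)
        a = mh.kw_lda_differential(table, labels, meta, "carnivorous", seed=3)
        b = mh.kw_lda_differential(table, labels, meta, "carnivorous", seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestCascade:
    def base_records(self):
        return pd.DataFrame(
            {
                "phenotype_linked": [True, True, True],
                "correlated": [True, True, False],
                "positive": [True, False, True],
                "differential_carnivorous": [True, True, True],
                "direction_carnivorous": ["up-in-unhealthy"] * 3,
                "differential_filter-feeding": [True, True, True],
                "direction_filter-feeding": ["up-in-unhealthy"] * 3,
                "differential_scraper-feeding": [True, True, True],
                "direction_scraper-feeding": ["up-in-unhealthy"] * 3,
            },
            index=["good", "slope_fail", "corr_fail"],
        )

    ECOTYPES = ["carnivorous", "filter-feeding", "scraper-feeding"]

    def test_failing_one_threshold_is_not_key(self):
        report = mh.key_taxa_cascade(self.base_records(), self.ECOTYPES, 3)
        assert report.key_taxa == ["good"]

    def test_survivor_counts_monotone(self):
        report = mh.key_taxa_cascade(self.base_records(), self.ECOTYPES, 3)
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_direction_must_be_up_in_unhealthy(self):
        records = self.base_records()
        records.loc["good", "direction_carnivorous"] = "up-in-healthy"
        report = mh.key_taxa_cascade(records, self.ECOTYPES, 3)
        assert report.key_taxa == []

    def test_empty_records_zeroed_report(self):
        report = mh.key_taxa_cascade(pd.DataFrame(), ["carnivorous"], 3)
        assert report.key_taxa == []
        assert all(v == 0 for v in report.stage_counts.values())
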