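"""Contaminant removal, sample-depth dropping, contamination rates, binning."""

import math

import numpy as np
import pytest

import tickdecon as td
from tickdecon.contaminants import RULE_MAIN, RULE_NONE, ContaminantCall
from tickdecon.io import SampleCategory, SampleInfo


def calls_for(table, flagged):
    totals = table.otu_totals()
    controls_max = 0
    return [
        ContaminantCall(
            otu_id=o,
            is_contaminant=o in flagged,
            rule=RULE_MAIN if o in flagged else RULE_NONE,
            category_fractions={},
            total_count=int(totals[o]),
            expected_count=0.0002 * int(totals[o]),
            upper_threshold=0,
            max_control_count=controls_max,
        )
        for o in table.otu_ids
    ]


@pytest.fixture
def toy_pipeline(toy_table, toy_metadata, toy_taxonomy):
    table = td.filter_nonprokaryotic(td.filter_rare_otus(toy_table), toy_taxonomy)
    calls = td.classify_contaminants(table, toy_metadata)
    return table, calls


class TestRemoveContaminants:
    def test_toy_hand_enumeration(self, toy_pipeline):
        table, calls = toy_pipeline
        cleaned = td.remove_contaminants(table, calls)
        assert cleaned.otu_ids == ["OTU01", "OTU02", "OTU10"]
        assert cleaned.sample_ids == table.sample_ids

    def test_study_scale_cardinalities(self):
        # synthetic table built with the motivating study's cardinalities:
        # 513 OTUs of which 160 flagged leaves 353
        rng = np.random.default_rng(0)
        table = td.CountTable.from_arrays(
            rng.integers(0, 50, size=(513, 4)),
            [f"O{i}" for i in range(513)],
            list("ABCD"),
        )
        flagged = {f"O{i}" for i in range(160)}
        cleaned = td.remove_contaminants(table, calls_for(table, flagged))
        assert cleaned.shape[0] == 353

    def test_zero_flagged_identity(self, toy_pipeline):
        table, _ = toy_pipeline
        assert td.remove_contaminants(table, calls_for(table, set())) == table

    def test_all_flagged_keeps_columns(self, toy_pipeline):
        table, _ = toy_pipeline
        cleaned = td.remove_contaminants(table, calls_for(table, set(table.otu_ids)))
        assert cleaned.shape == (0, table.shape[1])
        assert cleaned.sample_ids == table.sample_ids

    def test_missing_call_is_error(self, toy_pipeline):
        table, calls = toy_pipeline
        with pytest.raises(ValueError, match="missing"):
            td.remove_contaminants(table, calls[:-1])


class TestDropShallow:
    def test_boundary_at_500(self):
        table = td.CountTable.from_arrays(
            [[499, 500, 501]], ["O1"], ["A", "B", "C"]
        )
        assert td.drop_shallow_samples(table).sample_ids == ["B", "C"]

    def test_toy_post_filter_drop(self, toy_pipeline):
        table, calls = toy_pipeline
        cleaned = td.drop_shallow_samples(td.remove_contaminants(table, calls))
        # F1 had 2,423 reads before removal but only 292 after; controls drop too
        assert cleaned.sample_ids == ["N1", "N2"]

    def test_matches_brute_force_scan(self, sim_default):
        ds, _ = sim_default
        calls = td.classify_contaminants(ds.table, ds.metadata)
        cleaned = td.remove_contaminants(ds.table, calls)
        kept = td.drop_shallow_samples(cleaned)
        expected = [s for s in cleaned.sample_ids if cleaned.sample_totals()[s] >= 500]
        assert kept.sample_ids == expected

    def test_identity_when_all_deep(self):
        table = td.CountTable.from_arrays([[600, 700]], ["O1"], ["A", "B"])
        assert td.drop_shallow_samples(table) == table

    def test_retained_columns_unaltered(self, sim_default):
        ds, _ = sim_default
        kept = td.drop_shallow_samples(ds.table, min_depth=4000)
        for s in kept.sample_ids:
            assert (kept.data[s] == ds.table.data[s]).all()


class TestContaminationRates:
    def test_arithmetic(self):
        table = td.CountTable.from_arrays(
            [[80], [20]], ["BAD", "GOOD"], ["N1"]
        )
        meta = {"N1": SampleInfo("N1", SampleCategory.NYMPH)}
        profiles = td.contamination_rates(table, calls_for(table, {"BAD"}), meta)
        assert profiles[0].rate == pytest.approx(0.80)

    def test_zero_contaminant_reads(self):
        table = td.CountTable.from_arrays([[80], [20]], ["A", "B"], ["N1"])
        meta = {"N1": SampleInfo("N1", SampleCategory.NYMPH)}
        profiles = td.contamination_rates(table, calls_for(table, set()), meta)
        assert profiles[0].rate == 0.0

    def test_zero_total_sample_flagged_undefined(self):
        table = td.CountTable.from_arrays([[0]], ["A"], ["N1"])
        meta = {"N1": SampleInfo("N1", SampleCategory.NYMPH)}
        profiles = td.contamination_rates(table, calls_for(table, set()), meta)
        assert math.isnan(profiles[0].rate)

    def test_controls_excluded(self, toy_pipeline, toy_metadata):
        table, calls = toy_pipeline
        profiles = td.contamination_rates(table, calls, toy_metadata)
        assert [p.sample_id for p in profiles] == ["N1", "N2", "F1"]

    def test_conservation_and_pooled_rate(self, sim_default):
        ds, truth = sim_default
        calls = td.classify_contaminants(ds.table, ds.metadata)
        profiles = td.contamination_rates(ds.table, calls, ds.metadata)
        totals = ds.table.sample_totals()
        cleaned = td.remove_contaminants(ds.table, calls)
        for p in profiles:
            retained = cleaned.sample_totals()[p.sample_id]
            assert p.contaminant_count + retained == totals[p.sample_id]
        specimen_ids = [p.sample_id for p in profiles]
        pooled = sum(p.contaminant_count for p in profiles) / sum(
            p.total_count for p in profiles
        )
        flagged = sorted({c.otu_id for c in calls if c.is_contaminant})
        direct = (
            ds.table.data.loc[flagged, specimen_ids].to_numpy().sum()
            / ds.table.data[specimen_ids].to_numpy().sum()
        )
        assert pooled == pytest.approx(direct)

    def test_rates_zero_after_removal(self, sim_default):
        ds, _ = sim_default
        calls = td.classify_contaminants(ds.table, ds.metadata)
        cleaned = td.remove_contaminants(ds.table, calls)
        none_calls = [c for c in calls if not c.is_contaminant]
        profiles = td.contamination_rates(cleaned, none_calls, ds.metadata)
        assert all(p.rate == 0.0 or math.isnan(p.rate) for p in profiles)


class TestBinning:
    def test_enumeration(self):
        meta = {
            s: SampleInfo(s, SampleCategory.NYMPH) for s in ("A", "B", "C")
        }
        profiles = [
            td.ContaminationProfile("A", 100, 10),
            td.ContaminationProfile("B", 100, 30),
            td.ContaminationProfile("C", 100, 90),
        ]
        out = td.bin_contamination(profiles, meta)
        row = out.loc["nymph"]
        assert row["count_[0,0.2)"] == 1
        assert row["count_[0.2,0.5)"] == 1
        assert row["count_[0.5,1]"] == 1
        assert row["frac_above_last_break"] == pytest.approx(1 / 3)
        assert row["frac_below_first_break"] == pytest.approx(1 / 3)

    def test_all_zero_rates_in_first_bin(self):
        meta = {"A": SampleInfo("A", SampleCategory.MALE)}
        out = td.bin_contamination([td.ContaminationProfile("A", 50, 0)], meta)
        assert out.loc["male", "count_[0,0.2)"] == 1

    def test_invalid_breaks(self):
        meta = {"A": SampleInfo("A", SampleCategory.MALE)}
        profiles = [td.ContaminationProfile("A", 50, 10)]
        with pytest.raises(ValueError):
            td.bin_contamination(profiles, meta, breaks=[0.5, 0.2])

    def test_low_biomass_categories_more_contaminated(self):
        # female biomass 10x nymph: heavy-contamination fraction higher in nymphs
        n_high, f_high = [], []
        for seed in range(5):
            cfg = td.GeneratorConfig(
                seed=seed, biomass={"nymph": 1.0, "male": 1.0, "female": 10.0}
            )
            ds, _ = td.simulate_dataset(cfg)
            calls = td.classify_contaminants(ds.table, ds.metadata)
            profiles = td.contamination_rates(ds.table, calls, ds.metadata)
            out = td.bin_contamination(profiles, ds.metadata)
            n_high.append(out.loc["nymph", "frac_above_last_break"])
            f_high.append(out.loc["female", "frac_above_last_break"])
        assert np.mean(n_high) > np.mean(f_high)
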