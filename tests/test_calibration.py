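"""The four normalization schemes and the SpikeCalibration model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scml import (
    CountTable,
    DataError,
    DesignTable,
    QpcrTable,
    SpikeCalibration,
    adjust_spike_counts,
    apply_calibration,
    qpcr_calibrate,
    relative_abundance,
    size_factors,
)
from scml.calibration import calibration_counts

from conftest import random_count_table


def single_spike_table(spike_counts, bg_counts=None):
    """One spike taxon plus one background taxon over len(spike_counts) samples."""
    samples = [f"S{i}" for i in range(len(spike_counts))]
    rows = {"OTU_S.ruber": spike_counts}
    rows["BG1"] = bg_counts if bg_counts is not None else [100] * len(samples)
    frame = pd.DataFrame(rows, index=samples).T
    return CountTable(frame, {"S.ruber": "OTU_S.ruber"})


class TestRelativeAbundance:
    def test_forced_arithmetic(self):
        table = CountTable(
            pd.DataFrame({"S1": [10, 30, 60]}, index=["A", "B", "C"])
        )
        rel = relative_abundance(table)
        assert list(rel.values["S1"]) == [0.1, 0.3, 0.6]

    def test_single_taxon_sample_is_one(self):
        table = CountTable(pd.DataFrame({"S1": [17]}, index=["A"]))
        assert relative_abundance(table).values.loc["A", "S1"] == 1.0

    def test_columns_sum_to_one(self, spiked_table):
        rel = relative_abundance(spiked_table)
        assert np.allclose(rel.values.sum(axis=0), 1.0, atol=1e-9)

    def test_exclude_spikes_matches_row_deletion_oracle(self, spiked_table):
        rel = relative_abundance(spiked_table, include_spikes=False)
        # oracle: physically delete spike rows, renormalize, compare background
        pruned = CountTable(spiked_table.counts.loc[spiked_table.background_taxa])
        oracle = relative_abundance(pruned)
        bg = spiked_table.background_taxa
        assert np.allclose(rel.values.loc[bg], oracle.values.loc[bg], atol=1e-12)

    def test_zero_total_sample_named_in_error(self):
        table = CountTable(pd.DataFrame({"S1": [1], "EMPTY": [0]}, index=["A"]))
        with pytest.raises(DataError, match="EMPTY"):
            relative_abundance(table)


class TestAdjustSpikeCounts:
    def test_half_concentration_doubles_counts(self, spiked_table, dilution_design):
        # R. radiobacter designed at half the S. ruber concentration everywhere
        adjusted = adjust_spike_counts(spiked_table, dilution_design, "S.ruber")
        raw = spiked_table.counts.loc["OTU_R.radiobacter"].astype(float)
        assert np.allclose(adjusted.loc["OTU_R.radiobacter"], 2.0 * raw)

    def test_equal_concentration_unchanged(self, spiked_table, dilution_design):
        adjusted = adjust_spike_counts(spiked_table, dilution_design, "S.ruber")
        raw = spiked_table.counts.loc["OTU_S.ruber"].astype(float)
        assert np.allclose(adjusted.loc["OTU_S.ruber"], raw)

    def test_background_rows_untouched(self, spiked_table, dilution_design):
        adjusted = adjust_spike_counts(spiked_table, dilution_design, "S.ruber")
        bg = spiked_table.background_taxa
        assert np.array_equal(
            adjusted.loc[bg].to_numpy(), spiked_table.counts.loc[bg].astype(float)
        )

    def test_sample_constant_concentrations_cancel_in_ratios(
        self, spiked_table, dilution_design
    ):
        # concentration constant across samples => between-sample ratios of the
        # adjusted counts equal those of the raw counts (factor cancels)
        adjusted = adjust_spike_counts(spiked_table, dilution_design, "S.ruber")
        raw = spiked_table.counts.loc["OTU_R.radiobacter"].astype(float)
        adj = adjusted.loc["OTU_R.radiobacter"]
        s = spiked_table.sample_ids
        assert np.allclose(
            adj[s[0]] / adj[s[3]], raw[s[0]] / raw[s[3]], rtol=1e-12
        )


class TestSizeFactors:
    def test_equal_spike_counts_give_unit_factors(self):
        table = single_spike_table([250, 250, 250])
        sf = size_factors(table, reference="S.ruber")
        assert sf.reference_level == 250
        assert np.allclose(sf.factors, 1.0)

    def test_forced_by_definition(self):
        table = single_spike_table([100, 200, 300])
        sf = size_factors(table, reference="S.ruber")
        assert sf.reference_level == 200
        assert np.allclose(sf.factors, [2.0, 1.0, 2.0 / 3.0])

    def test_zero_spike_count_is_hard_error(self):
        table = single_spike_table([100, 0, 300])
        with pytest.raises(DataError, match="cannot be calibrated"):
            size_factors(table, reference="S.ruber")

    def test_combined_equals_single_when_other_spikes_empty(self, dilution_design):
        samples = [f"S{i}" for i in range(1, 7)]
        counts = pd.DataFrame(
            {
                "OTU_S.ruber": [120, 240, 360, 480, 600, 720],
                "OTU_R.radiobacter": [0] * 6,
                "OTU_A.acidiphilus": [0] * 6,
                "BG1": [50] * 6,
            },
            index=samples,
        ).T
        table = CountTable(
            counts,
            {
                "S.ruber": "OTU_S.ruber",
                "R.radiobacter": "OTU_R.radiobacter",
                "A.acidiphilus": "OTU_A.acidiphilus",
            },
        )
        single = size_factors(table, mode="single", reference="S.ruber")
        combined = size_factors(
            table, dilution_design, mode="combined", reference="S.ruber"
        )
        assert np.allclose(single.factors, combined.factors, rtol=1e-12)
        assert single.reference_level == pytest.approx(combined.reference_level)

    def test_combined_counts_match_brute_force(self, spiked_table, dilution_design):
        cal = calibration_counts(spiked_table, dilution_design, "combined", "S.ruber")
        for sample in spiked_table.sample_ids:
            total = 0.0
            c_ref = dilution_design.copies("S.ruber")[sample]
            for species, taxon in spiked_table.spike_map.items():
                c_sp = dilution_design.copies(species)[sample]
                total += spiked_table.counts.loc[taxon, sample] * c_ref / c_sp
            assert cal[sample] == pytest.approx(total, rel=1e-12)


class TestApplyCalibration:
    def test_unit_factors_identity(self):
        table = single_spike_table([250, 250], bg_counts=[10, 20])
        res = SpikeCalibration(table, reference="S.ruber").fit()
        assert np.allclose(res.calibrated.values, table.counts)

    def test_reference_row_constant_at_s_bar(self, spiked_table, dilution_design):
        res = SpikeCalibration(spiked_table, dilution_design, "single", "S.ruber").fit()
        ref_row = res.calibrated.values.loc["OTU_S.ruber"]
        assert np.allclose(ref_row, res.reference_level, rtol=1e-12)

    def test_doubling_one_sample_leaves_calibrated_values_unchanged(
        self, spiked_table
    ):
        doubled = spiked_table.counts.copy()
        target = spiked_table.sample_ids[2]
        doubled[target] = doubled[target] * 2
        res_a = SpikeCalibration(spiked_table, reference="S.ruber").fit()
        res_b = SpikeCalibration(
            CountTable(doubled, spiked_table.spike_map), reference="S.ruber"
        ).fit()
        # the doubled sample's factor halves (up to the shift in s_bar), and its
        # calibrated background values are unchanged relative to the anchor
        ratio = res_b.factors[target] / res_a.factors[target]
        anchor_shift = res_b.reference_level / res_a.reference_level
        assert ratio == pytest.approx(anchor_shift / 2.0, rel=1e-12)
        bg = spiked_table.background_taxa
        assert np.allclose(
            res_b.calibrated.values.loc[bg, target] / anchor_shift,
            res_a.calibrated.values.loc[bg, target],
            rtol=1e-12,
        )

    def test_sample_mismatch_is_error(self, spiked_table):
        table = single_spike_table([100, 200])
        sf = size_factors(table, reference="S.ruber")
        with pytest.raises(DataError, match="missing"):
            apply_calibration(spiked_table, sf)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_fixed_point_property(self, seed):
        rng = np.random.default_rng(seed)
        table = random_count_table(rng, n_taxa=int(rng.integers(2, 7)),
                                   n_samples=int(rng.integers(2, 6)))
        res = SpikeCalibration(table, reference="S.ruber").fit()
        ref = res.calibrated.values.loc["T0"]
        assert np.all(np.abs(ref / res.reference_level - 1.0) <= 1e-9)


class TestQpcrCalibrate:
    def test_values_sum_to_measured_totals(self, spiked_table, qpcr_table):
        cal = qpcr_calibrate(spiked_table, qpcr_table)
        assert np.allclose(
            cal.values.sum(axis=0),
            qpcr_table.total_copies[spiked_table.sample_ids],
            rtol=1e-12,
        )

    def test_ratios_are_relative_ratios_times_total_ratio(
        self, spiked_table, qpcr_table
    ):
        cal = qpcr_calibrate(spiked_table, qpcr_table)
        rel = relative_abundance(spiked_table)
        a, b = spiked_table.sample_ids[:2]
        t = spiked_table.background_taxa[0]
        lhs = cal.values.loc[t, a] / cal.values.loc[t, b]
        rhs = (rel.values.loc[t, a] / rel.values.loc[t, b]) * (
            qpcr_table.total_copies[a] / qpcr_table.total_copies[b]
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_missing_total_is_error(self, spiked_table):
        partial = QpcrTable(pd.Series({"S1": 1e9}))
        with pytest.raises(DataError, match="unmatched"):
            qpcr_calibrate(spiked_table, partial)

    def test_noiseless_equal_yields_matches_scml(self):
        # when every species has the same read yield and qPCR totals are exact,
        # qPCR-calibrated background ratios equal the SCML ones
        from scml.simulate import SimulationParams, simulate_experiment

        params = SimulationParams(
            seed=3,
            n_background_taxa=5,
            yields={sp: 1.0 for sp in
                    ("background", "S.ruber", "R.radiobacter", "A.acidiphilus")},
        )
        counts, design, qpcr, _ = simulate_experiment(params, expected=True)
        scml_cal = SpikeCalibration(counts, design, "single", "S.ruber").fit().calibrated
        qpcr_cal = qpcr_calibrate(counts, qpcr)
        bg = counts.background_taxa
        a, b = counts.sample_ids[0], counts.sample_ids[-1]
        scml_ratio = scml_cal.values.loc[bg, a] / scml_cal.values.loc[bg, b]
        qpcr_ratio = qpcr_cal.values.loc[bg, a] / qpcr_cal.values.loc[bg, b]
        assert np.allclose(scml_ratio, qpcr_ratio, rtol=1e-9)


class TestScaleInvariance:
    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), alpha=st.floats(0.25, 8.0))
    def test_relative_abundance_is_scale_free(self, seed, alpha):
        rng = np.random.default_rng(seed)
        table = random_count_table(rng)
        scaled = table.counts.astype(float).copy()
        target = scaled.columns[0]
        scaled[target] = scaled[target] * alpha
        scaled_table = CountTable(scaled, table.spike_map, integral=False)
        rel_a = relative_abundance(table).values[target]
        rel_b = relative_abundance(scaled_table).values[target]
        assert np.allclose(rel_a, rel_b, rtol=1e-12)
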