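"""Normalization/QC cascade: each stage's contract plus cascade invariants."""

import logging

import numpy as np
import pandas as pd
import pytest

from arsig import preprocess
from arsig.preprocess import (
    PreprocessParams,
    apply_intensity_floor,
    average_replicates,
    compute_log_ratios,
    filter_dye_swap_discordant,
    filter_low_intensity_spots,
    normalize_subarray_lowess,
    scale_to_global_median,
)
from arsig.simulate import SimulationConfig, generate_experiment

from conftest import make_single_condition_spots


def _one_array(cy3, cy5, control=None, subarray="S1"):
    n = len(cy3)
    return pd.DataFrame({
        "array_id": "A1", "subarray_id": subarray,
        "probe_id": [f"P{i}" for i in range(n)],
        "genbank_id": [f"GB{i}" for i in range(n)],
        "symbol": [f"G{i}" for i in range(n)],
        "control_flag": control if control is not None else False,
        "cy3": np.asarray(cy3, float), "cy5": np.asarray(cy5, float),
    })


class TestLowess:
    def test_equal_channels_stay_zero(self):
        rng = np.random.default_rng(0)
        inten = 2.0 ** rng.uniform(8, 12, 200)
        spots = _one_array(inten, inten)
        out = normalize_subarray_lowess(spots)
        m = np.log2(out.cy3) - np.log2(out.cy5)
        assert np.allclose(m, 0.0, atol=1e-9)

    def test_removes_planted_sinusoid_bias(self):
        # planted M = 0.5*sin(A) + N(0, 0.05): per-A-decile mean residual
        # must fall below 0.05 after normalization
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 2000)
        m = 0.5 * np.sin(a) + rng.normal(0, 0.05, 2000)
        cy3 = 2.0 ** (a + m / 2.0)
        cy5 = 2.0 ** (a - m / 2.0)
        out = normalize_subarray_lowess(_one_array(cy3, cy5))
        m_new = (np.log2(out.cy3) - np.log2(out.cy5)).to_numpy()
        deciles = np.quantile(a, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (a >= lo) & (a <= hi)
            assert abs(m_new[sel].mean()) < 0.05

    def test_preserves_a(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, 300)
        m = 0.4 * np.sin(a) + rng.normal(0, 0.1, 300)
        spots = _one_array(2.0 ** (a + m / 2), 2.0 ** (a - m / 2))
        out = normalize_subarray_lowess(spots)
        a_new = 0.5 * (np.log2(out.cy3) + np.log2(out.cy5))
        assert np.allclose(a_new, a, atol=1e-9)

    def test_small_subarray_unchanged_with_warning(self, caplog):
        spots = _one_array(np.full(10, 500.0), np.full(10, 250.0))
        with caplog.at_level(logging.WARNING):
            out = normalize_subarray_lowess(spots, min_spots=50)
        assert np.allclose(out.cy3, spots.cy3)
        assert any("unnormalized" in r.message for r in caplog.records)

    def test_controls_excluded_from_fit(self):
        # a block of control spots with huge M must not drag the fit
        rng = np.random.default_rng(3)
        a = rng.uniform(9, 11, 300)
        m = rng.normal(0, 0.05, 300)
        control = np.zeros(300, bool)
        control[:100] = True
        m[:100] = 3.0
        spots = _one_array(2.0 ** (a + m / 2), 2.0 ** (a - m / 2), control=control)
        out = normalize_subarray_lowess(spots)
        m_new = (np.log2(out.cy3) - np.log2(out.cy5)).to_numpy()
        assert abs(m_new[~control].mean()) < 0.05


class TestScaling:
    def test_median_500_doubles(self):
        vals = np.array([100.0, 500.0, 900.0])
        spots = _one_array(vals, vals)  # pooled median 500
        out = scale_to_global_median(spots, target=1000.0)
        assert np.allclose(out.cy3, vals * 2)
        pooled = np.concatenate([out.cy3, out.cy5])
        assert np.median(pooled) == pytest.approx(1000.0)

    def test_median_already_on_target_unchanged(self):
        vals = np.array([500.0, 1000.0, 1500.0])
        out = scale_to_global_median(_one_array(vals, vals))
        assert np.allclose(out.cy3, vals)

    def test_constant_array_maps_to_target(self):
        out = scale_to_global_median(_one_array(np.full(5, 42.0), np.full(5, 42.0)))
        assert np.allclose(out.cy3, 1000.0) and np.allclose(out.cy5, 1000.0)

    def test_all_zero_array_errors(self):
        with pytest.raises(ValueError):
            scale_to_global_median(_one_array(np.zeros(4), np.zeros(4)))


class TestFloor:
    @pytest.mark.parametrize("value,expected", [(150.0, 200.0), (200.0, 200.0),
                                                (1000.0, 1000.0)])
    def test_boundary(self, value, expected):
        out = apply_intensity_floor(_one_array([value], [value]), floor=200.0)
        assert out.cy3.iloc[0] == expected

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            apply_intensity_floor(_one_array([1.0], [1.0]), floor=-1.0)


class TestLowIntensityRule:
    def _course(self, n_low_arrays, one_channel_high=False):
        m = np.zeros((1, 6))
        spots, design = make_single_condition_spots(m, a=10.0)
        arrays = design.array_id.tolist()
        for aid in arrays[:n_low_arrays]:
            sel = spots.array_id == aid
            spots.loc[sel, "cy3"] = 150.0
            spots.loc[sel, "cy5"] = 1000.0 if one_channel_high else 150.0
        return spots, design

    @pytest.mark.parametrize("k,expect_excluded", [(3, False), (4, True)])
    def test_boundary_of_majority_rule(self, k, expect_excluded):
        spots, design = self._course(k)
        mask = filter_low_intensity_spots(spots, design)
        assert mask.excluded.iloc[0] is np.bool_(expect_excluded)

    def test_one_high_channel_protects(self):
        spots, design = self._course(6, one_channel_high=True)
        mask = filter_low_intensity_spots(spots, design)
        assert not mask.excluded.iloc[0]

    def test_monotone_in_floor(self):
        rng = np.random.default_rng(4)
        cfg = SimulationConfig(n_probes=300, frac_low_intensity=0.3, seed=8)
        spots, design, _ = generate_experiment(cfg)
        m_low = filter_low_intensity_spots(spots, design, floor=150.0)
        m_high = filter_low_intensity_spots(spots, design, floor=250.0)
        key = ["probe_id", "cell_line", "treatment"]
        merged = m_low.merge(m_high, on=key, suffixes=("_lo", "_hi"))
        # raising the floor never un-excludes
        assert not (merged.excluded_lo & ~merged.excluded_hi).any()

    def test_nonstandard_array_count_scales_rule(self, caplog):
        spots, design = self._course(2)
        keep = design.array_id.iloc[:4].tolist()  # 4-array course, 2 low
        spots = spots[spots.array_id.isin(keep)]
        design = design[design.array_id.isin(keep)]
        with caplog.at_level(logging.WARNING):
            mask = filter_low_intensity_spots(spots, design)
        assert any("expected 6" in r.message for r in caplog.records)
        assert not mask.excluded.iloc[0]  # 2 of 4 is not > 50%


class TestLogRatios:
    def test_examples_and_orientation_invariance(self):
        m = np.full((1, 6), 0.0)
        spots, design = make_single_condition_spots(m)
        spots["cy3"] = 2000.0
        spots["cy5"] = 1000.0
        ratios = compute_log_ratios(spots, design)
        # stim_cy3 arrays: M = +1; stim_cy5 arrays (same channels): M = -1
        by_rep = ratios.groupby("replicate")["M"].mean()
        assert by_rep[1] == pytest.approx(1.0)
        assert by_rep[2] == pytest.approx(-1.0)

    def test_swapping_channels_and_orientation_is_identity(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0, 0.5, (20, 6))
        spots, design = make_single_condition_spots(m)
        r1 = compute_log_ratios(spots, design)
        flipped = spots.copy()
        flipped[["cy3", "cy5"]] = flipped[["cy5", "cy3"]].to_numpy()
        design2 = design.copy()
        design2["dye_orientation"] = design2["dye_orientation"].map(
            {"stim_cy3": "stim_cy5", "stim_cy5": "stim_cy3"})
        r2 = compute_log_ratios(flipped, design2)
        assert np.allclose(r1.M.to_numpy(), r2.M.to_numpy())

    def test_bad_orientation_rejected(self):
        spots, design = make_single_condition_spots(np.zeros((1, 6)))
        design = design.assign(dye_orientation="sideways")
        with pytest.raises(ValueError, match="orientation"):
            compute_log_ratios(spots, design)


class TestDyeSwapDiscordance:
    def _ratios(self, rep1_mean, rep2_mean):
        rows = []
        for t in (4, 8, 16):
            rows.append({"probe_id": "P0", "cell_line": "PC346C",
                         "treatment": "R1881", "time_h": t, "replicate": 1,
                         "M": rep1_mean, "A": 10.0})
            rows.append({"probe_id": "P0", "cell_line": "PC346C",
                         "treatment": "R1881", "time_h": t, "replicate": 2,
                         "M": rep2_mean, "A": 10.0})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("r1,r2,excluded", [
        (0.6, -0.6, True),
        (0.6, 0.2, False),
        (0.5, -0.5, True),     # inclusive boundary
        (-0.5, 0.5, True),     # symmetric
        (0.49, -0.6, False),   # one side short of the bound
    ])
    def test_opposite_effect_rule(self, r1, r2, excluded):
        filtered, excl = filter_dye_swap_discordant(self._ratios(r1, r2))
        assert (len(excl) == 1) is excluded
        assert filtered.empty is excluded

    def test_single_replicate_skipped_with_warning(self, caplog):
        ratios = self._ratios(0.6, -0.6)
        ratios = ratios[ratios.replicate == 1]
        with caplog.at_level(logging.WARNING):
            filtered, excl = filter_dye_swap_discordant(ratios)
        assert excl.empty and len(filtered) == 3


class TestAverageReplicates:
    def test_mean_of_replicates(self):
        df = pd.DataFrame({
            "probe_id": "P0", "cell_line": "C", "treatment": "R",
            "time_h": [4, 4, 8, 8, 16, 16], "replicate": [1, 2] * 3,
            "M": [0.8, 0.4, 0.8, 0.4, 0.8, 0.4],
        })
        avg = average_replicates(df)
        assert np.allclose(avg.M, 0.6)
        assert avg.complete.all()

    def test_single_surviving_replicate_keeps_time_point(self):
        df = pd.DataFrame({
            "probe_id": "P0", "cell_line": "C", "treatment": "R",
            "time_h": [4, 4, 8, 8, 16], "replicate": [1, 2, 1, 2, 1],
            "M": [0.6, 0.8, 0.6, 0.8, 0.9],
        })
        avg = average_replicates(df)
        assert avg[avg.time_h == 16].M.iloc[0] == pytest.approx(0.9)
        assert avg.complete.all()

    def test_missing_time_point_marks_incomplete(self):
        df = pd.DataFrame({
            "probe_id": "P0", "cell_line": "C", "treatment": "R",
            "time_h": [4, 8], "replicate": [1, 1], "M": [0.6, 0.6],
        })
        avg = average_replicates(df)
        assert not avg.complete.any()


def test_cascade_null_simulation_mean_m_bounded():
    # zero effect, zero bias: per-class |mean M| stays under 3*sd/sqrt(n_arrays)
    cfg = SimulationConfig(n_probes=800, frac_responsive=0.0,
                           dye_bias_amplitude=0.0, frac_spot_dropout=0.0,
                           frac_low_intensity=0.3, seed=21)
    spots, design, _ = generate_experiment(cfg)
    averaged, pooled, _ = preprocess.preprocess_experiment(spots, design)
    bound = 3 * cfg.noise_sd / np.sqrt(6)
    per_probe = pooled.groupby("probe_id")["M"].mean()
    assert abs(per_probe.mean()) < bound
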