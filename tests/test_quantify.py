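"""Intensity extraction, normalization, metric arithmetic, rejection, and
rank-correlation diagnostics against direct oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctapipe.detect import SpotROI, rois_from_truth
from punctapipe.preprocess import median_filter_3d
from punctapipe.quantify import (dff_trace, extract_intensities,
                                 normalize_population,
                                 photoconversion_metrics,
                                 reject_autofluorescent,
                                 size_bias_diagnostics)
from punctapipe.volume import ImageVolume


def vol(arr, vs=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(arr, dtype=np.float32), vs)


def make_roi(voxels, rid=0):
    voxels = np.atleast_2d(np.asarray(voxels))
    pos = voxels.astype(float)
    centroid = pos.mean(axis=0)
    dev = np.abs(pos - centroid).max(axis=0)
    return SpotROI(id=rid, voxels=voxels, centroid_um=tuple(centroid),
                   semi_axes_um=tuple(np.sqrt(3) * dev + 0.5),
                   volume_voxels=len(voxels))


class TestExtraction:
    def test_single_voxel_roi_reads_that_voxel(self):
        data = np.arange(27, dtype=np.float32).reshape(3, 3, 3)
        rec = extract_intensities([make_roi([(1, 2, 0)])], {"G0": vol(data)})
        assert rec.loc[0, "G0"] == data[1, 2, 0]

    def test_matches_brute_force_max_over_member_voxels(self):
        rng = np.random.default_rng(8)
        data = rng.random((12, 12, 12)).astype(np.float32)
        voxels = rng.integers(0, 12, size=(40, 3))
        rec = extract_intensities([make_roi(voxels)], {"G0": vol(data)})
        brute = max(data[tuple(v)] for v in voxels)
        assert rec.loc[0, "G0"] == brute

    def test_out_of_volume_roi_flagged_invalid_not_dropped(self):
        data = np.ones((4, 4, 4), dtype=np.float32)
        rec = extract_intensities([make_roi([(1, 1, 1), (9, 9, 9)])],
                                  {"G0": vol(data)})
        assert len(rec) == 1 and bool(rec.loc[0, "invalid"])


class TestNormalization:
    def _records(self, rng, n=30):
        g0 = rng.lognormal(0, 0.3, n)
        return pd.DataFrame({
            "roi_id": np.arange(n),
            "G0": g0, "G1": g0 * 0.8,
            "R0": 0.4 * g0, "R1": 0.4 * g0 * (1 + rng.uniform(0, 2, n)),
            "autofluorescent": False, "invalid": False,
        })

    def test_single_record_normalizes_to_one(self):
        rec = self._records(np.random.default_rng(0), n=1)
        out = normalize_population(rec)
        assert out.loc[0, "g0"] == 1.0 and out.loc[0, "r0"] == 1.0

    def test_kept_population_means_are_exactly_one(self):
        rec = self._records(np.random.default_rng(1))
        rec.loc[3, "autofluorescent"] = True
        out = normalize_population(rec)
        kept = out[~out["autofluorescent"]]
        assert np.isclose(kept["g0"].mean(), 1.0)
        assert np.isclose(kept["r0"].mean(), 1.0)

    def test_global_gain_leaves_normalized_values_and_pc_unchanged(self):
        rec = self._records(np.random.default_rng(2))
        scaled = rec.copy()
        for col in ("G0", "G1", "R0", "R1"):
            scaled[col] = scaled[col] * 7.0
        a = photoconversion_metrics(normalize_population(rec))
        b = photoconversion_metrics(normalize_population(scaled))
        for col in ("g0", "g1", "r0", "r1", "pc"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(g_gain=st.floats(0.1, 50), r_gain=st.floats(0.1, 50))
    def test_pc_invariant_under_independent_channel_gains(self, g_gain, r_gain):
        rec = self._records(np.random.default_rng(3))
        scaled = rec.copy()
        scaled["G0"] *= g_gain
        scaled["G1"] *= g_gain
        scaled["R0"] *= r_gain
        scaled["R1"] *= r_gain
        a = photoconversion_metrics(normalize_population(rec))
        b = photoconversion_metrics(normalize_population(scaled))
        np.testing.assert_allclose(a["pc"], b["pc"], rtol=1e-9)

    def test_zero_population_mean_rejected(self):
        rec = pd.DataFrame({"roi_id": [0], "G0": [0.0], "G1": [0.0],
                            "R0": [0.0], "R1": [0.0],
                            "autofluorescent": [False], "invalid": [False]})
        with pytest.raises(ValueError):
            normalize_population(rec)


class TestMetrics:
    def _normalized(self, g0, g1, r0, r1):
        return pd.DataFrame({"g0": [g0], "g1": [g1], "r0": [r0], "r1": [r1]})

    def test_no_red_change_gives_zero(self):
        out = photoconversion_metrics(self._normalized(1.0, 1.0, 0.9, 0.9))
        assert out.loc[0, "dR"] == 0.0 and out.loc[0, "pc"] == 0.0

    def test_worked_example(self):
        out = photoconversion_metrics(self._normalized(1.2, 1.0, 1.0, 3.2))
        assert np.isclose(out.loc[0, "pc"], 1.0)
        assert np.isclose(out.loc[0, "dR"], 2.2)
        assert np.isclose(out.loc[0, "r1_over_g1"], 3.2)

    def test_degenerate_denominators_flagged_not_nan_propagated(self):
        out = photoconversion_metrics(self._normalized(0.0, 0.0, 1.0, 2.0))
        assert not out.loc[0, "pc_valid"]
        assert not out.loc[0, "ratio_valid"]


class TestRejection:
    def test_clutter_rejected_synapses_kept(self):
        from punctapipe.phantom import (ConversionModel, PhantomSpec,
                                        generate_phantom)

        n_syn = 437  # realistic density for this field of view
        spec = PhantomSpec(
            volume_shape=(24, 110, 110), n_synapses=n_syn,
            conversion_model=ConversionModel(kind="constant", median=0.5,
                                             dispersion=0.4),
            autofluorescence_volume_fraction=0.02, seed=19,
        )
        stacks, truth = generate_phantom(spec)
        rois = rois_from_truth(truth, include_clutter=True)
        kept, report = reject_autofluorescent(
            rois, median_filter_3d(stacks["R0"], 1))
        clutter_ids = set(range(n_syn, n_syn + len(truth.clutter)))
        rejected = set(report.rejected_ids)
        assert len(rejected & clutter_ids) / len(clutter_ids) >= 0.98
        assert len(rejected - clutter_ids) / n_syn <= 0.02
        assert report.n_detected == len(rois)

    def test_zero_red_baseline_rejects_nothing(self):
        data = np.zeros((6, 6, 6), dtype=np.float32)
        rois = [make_roi([(2, 2, 2)], 0), make_roi([(3, 3, 3)], 1)]
        kept, report = reject_autofluorescent(rois, vol(data))
        assert report.n_rejected == 0 and len(kept) == 2

    def test_rejection_is_pure_filtering(self):
        rng = np.random.default_rng(4)
        data = rng.random((8, 8, 8)).astype(np.float32)
        data[6, 6, 6] = 50.0  # one clutter-bright spot
        rois = [make_roi([(2, 2, 2)], 0), make_roi([(6, 6, 6)], 1)]
        before = extract_intensities(rois, {"R0": vol(data)})
        kept, report = reject_autofluorescent(rois, vol(data), k=3.0)
        after = extract_intensities(kept, {"R0": vol(data)})
        merged = before.merge(after, on="roi_id", suffixes=("_b", "_a"))
        assert np.array_equal(merged["R0_b"], merged["R0_a"])


class TestSizeBias:
    def _records(self, g0, dr, pc):
        n = len(g0)
        return pd.DataFrame({
            "g0": g0, "dR": dr, "pc": pc, "r1_over_g1": pc,
            "autofluorescent": np.zeros(n, bool),
            "invalid": np.zeros(n, bool),
        })

    def test_matches_direct_rank_computation(self):
        rng = np.random.default_rng(10)
        g0 = rng.random(20)
        dr = rng.random(20)
        rec = self._records(g0, dr, dr / g0)
        out = size_bias_diagnostics(rec).set_index("metric")

        def ranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            # average ties
            for val in np.unique(v):
                m = v == val
                r[m] = r[m].mean()
            return r

        rho_direct = np.corrcoef(ranks(g0), ranks(dr))[0, 1]
        assert abs(out.loc["dR", "rho"] - rho_direct) < 1e-12

    def test_perfectly_monotone_pairs_give_rho_one(self):
        g0 = np.arange(1.0, 16.0)
        rec = self._records(g0, g0 ** 2, g0 ** 3)
        out = size_bias_diagnostics(rec).set_index("metric")
        assert np.isclose(out.loc["dR", "rho"], 1.0)

    def test_constant_metric_reported_undefined(self):
        g0 = np.arange(1.0, 16.0)
        rec = self._records(g0, np.ones(15), np.ones(15))
        out = size_bias_diagnostics(rec).set_index("metric")
        assert not out.loc["dR", "defined"]
        assert np.isnan(out.loc["dR", "rho"])

    def test_too_few_records_rejected(self):
        rec = self._records(np.arange(5.0), np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            size_bias_diagnostics(rec)


class TestDffTrace:
    def _movie(self, trace, sigma=2.0, shape=(40, 40)):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        spot = np.exp(-((yy - 20.) ** 2 + (xx - 20.) ** 2) / (2 * sigma ** 2))
        return trace[:, None, None] * spot[None]

    def test_constant_movie_gives_zero_dff(self):
        movie = self._movie(np.full(20, 100.0))
        tr = dff_trace(movie, baseline_window=(0, 5))
        np.testing.assert_allclose(tr.dff, 0.0, atol=1e-6)
        assert tr.center_yx == (20, 20)

    def test_simple_dimming_arithmetic(self):
        movie = np.zeros((2, 8, 8))
        movie[0] = 100.0
        movie[1] = 90.0
        tr = dff_trace(movie, baseline_window=(0, 1), roi_diameter_px=4)
        assert np.isclose(tr.dff[1], -0.1)

    def test_transient_amplitude_recovered_within_5_percent(self):
        rng = np.random.default_rng(6)
        t = np.arange(50)
        amp = 0.8
        trace = 100.0 * (1 + amp * np.exp(-0.5 * ((t - 25) / 3.0) ** 2))
        movie = self._movie(trace) + rng.normal(0, 0.3, (50, 40, 40))
        tr = dff_trace(movie, baseline_window=(0, 10),
                       background_rois=[(5, 5), (35, 35)])
        assert abs(tr.dff.max() - amp) / amp < 0.05

    def test_nonpositive_baseline_flags_trace(self):
        movie = np.zeros((10, 8, 8))
        tr = dff_trace(movie, baseline_window=(0, 3))
        assert tr.flagged and np.isnan(tr.dff).all()

    def test_baseline_window_validated(self):
        with pytest.raises(ValueError):
            dff_trace(np.ones((10, 8, 8)), baseline_window=(5, 20))
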