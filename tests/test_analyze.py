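"""Active-synapse classification, Sholl-ring statistics, exponential fits
and enrichment ratios — closed forms, oracles and recovery properties."""

import numpy as np
import pandas as pd
import pytest

from punctapipe.analyze import (classify_active, enrichment_ratio,
                                fit_exponential_curve, fit_exponential_decay,
                                fit_exponential_distance, ring_analysis,
                                rings_monotone_decreasing)


def records_from(pc, distance=None, **extra):
    pc = np.asarray(pc, float)
    df = pd.DataFrame({"pc": pc, "pc_valid": np.isfinite(pc),
                       "autofluorescent": np.zeros(pc.size, bool)})
    if distance is not None:
        df["distance_um"] = distance
    for k, v in extra.items():
        df[k] = v
    return df


class TestClassifyActive:
    def test_single_outlier_above_threshold_is_flagged(self):
        rng = np.random.default_rng(0)
        pc = np.concatenate([rng.normal(0, 1, 200), [7.0]])
        out, threshold = classify_active(records_from(pc))
        assert out["active"].sum() == 1
        assert bool(out.loc[200, "active"])
        assert threshold > 3.0

    def test_all_equal_values_error(self):
        with pytest.raises(ValueError, match="spread"):
            classify_active(records_from(np.ones(50)))

    def test_too_few_records_error(self):
        with pytest.raises(ValueError, match="20"):
            classify_active(records_from(np.arange(10.0)))

    def test_robust_variant_uses_median_and_mad(self):
        rng = np.random.default_rng(1)
        pc = np.concatenate([rng.normal(0, 1, 500), np.full(20, 50.0)])
        _, thr_plain = classify_active(records_from(pc))
        _, thr_robust = classify_active(records_from(pc), robust=True)
        assert thr_robust < thr_plain  # outliers inflate mean+3*sd only

    def test_false_positive_rate_matches_gaussian_tail(self):
        """Mean+3*sigma on a Gaussian null flags ~0.13% of synapses."""
        rng = np.random.default_rng(2)
        flagged, total = 0, 0
        for _ in range(10):
            pc = rng.normal(0, 0.15, 2000)
            out, _ = classify_active(records_from(pc))
            flagged += int(out["active"].sum())
            total += 2000
        rate = flagged / total
        # binomial 3-sigma envelope around P(Z>3) = 0.00135
        assert rate <= 0.00135 + 3 * np.sqrt(0.00135 / total) + 0.001

    def test_sensitivity_on_strongly_converted_subpopulation(self):
        rng = np.random.default_rng(3)
        hits, n_conv = 0, 0
        for _ in range(10):
            null = rng.normal(0, 0.1, 1000)
            converted = 1.0 + rng.normal(0, 0.1, 10)  # 10 sigma effect
            pc = np.concatenate([null, converted])
            out, _ = classify_active(records_from(pc))
            hits += int(out["active"].to_numpy()[-10:].sum())
            n_conv += 10
        assert hits / n_conv >= 0.9


class TestRingAnalysis:
    def test_binning_convention_half_open_rings(self):
        rec = records_from([1.0], distance=[25.0])
        rings = ring_analysis(rec, ring_width_um=20.0)
        assert rings.loc[1, "n"] == 1
        assert (rings.loc[1, "inner_um"], rings.loc[1, "outer_um"]) == (20.0, 40.0)

    def test_medians_match_brute_force_table_filtering(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 100, 200)
        pc = rng.random(200)
        rings = ring_analysis(records_from(pc, distance=d), 20.0)
        for i in range(5):
            sel = pc[(d >= 20 * i) & (d < 20 * (i + 1))]
            assert rings.loc[i, "n"] == sel.size
            if sel.size:
                assert np.isclose(rings.loc[i, "median"], np.median(sel))
                assert np.isclose(rings.loc[i, "iqr"],
                                  np.percentile(sel, 75) - np.percentile(sel, 25))

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 100, 100)
        pc = rng.random(100)
        rec = records_from(pc, distance=d)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(ring_analysis(rec, 20.0),
                                      ring_analysis(shuffled, 20.0))

    def test_empty_rings_reported_with_zero_count(self):
        rec = records_from([1.0, 2.0], distance=[5.0, 90.0])
        rings = ring_analysis(rec, 20.0)
        assert rings.loc[1, "n"] == 0 and np.isnan(rings.loc[1, "median"])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ring_analysis(records_from([1.0], distance=[-5.0]), 20.0)

    def test_monotone_decrease_detected_on_exponential_conversion(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0, 200, 600)
        pc = 2.0 * np.exp(-d / 105.0) * rng.lognormal(0, 0.5, 600)
        rings = ring_analysis(records_from(pc, distance=d), 20.0)
        assert rings_monotone_decreasing(rings)


class TestDistanceFit:
    def _rings(self, centers, medians, n=50):
        return pd.DataFrame({
            "ring": np.arange(len(centers)), "center_um": centers,
            "median": medians, "n": np.full(len(centers), n),
        })

    def test_noiseless_exponential_recovered_to_machine_precision(self):
        d = np.arange(10.0, 250.0, 20.0)
        rings = self._rings(d, 2.0 * np.exp(-d / 105.0))
        fit = fit_exponential_distance(rings)
        assert abs(fit.params["lambda_um"] - 105.0) / 105.0 < 1e-6
        assert fit.r_squared > 1 - 1e-9
        assert fit.converged

    def test_constant_medians_flagged_non_convergent(self):
        d = np.arange(10.0, 130.0, 20.0)
        fit = fit_exponential_distance(self._rings(d, np.full(d.size, 0.5)))
        assert not fit.converged

    def test_too_few_rings_rejected(self):
        d = np.array([10.0, 30.0, 50.0])
        with pytest.raises(ValueError, match="4"):
            fit_exponential_distance(self._rings(d, np.exp(-d / 50)))

    def test_lambda_recovery_unbiased_at_study_scale(self):
        """Table-level: ~1800 synapses, ring medians, 10 seeds."""
        lams = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = rng.uniform(5, 240, 1800)
            pc = 2.0 * np.exp(-d / 105.0) * rng.lognormal(0, 0.5, 1800)
            rings = ring_analysis(records_from(pc, distance=d), 20.0)
            lams.append(fit_exponential_distance(rings).params["lambda_um"])
        lams = np.asarray(lams)
        assert abs(lams.mean() - 105.0) / 105.0 < 0.05
        assert lams.std() / lams.mean() <= 0.10


class TestDecayFit:
    def test_noiseless_tau_recovered_exactly(self):
        t = np.arange(0, 65, 5.0)
        v = 1.4 * np.exp(-t / 29.4) + 0.05
        fit = fit_exponential_decay(t, v)
        assert abs(fit.params["tau_min"] - 29.4) / 29.4 < 1e-6
        assert fit.selected_model == "exponential"

    def test_constant_series_selects_constant_model(self):
        t = np.arange(0, 60, 5.0)
        fit = fit_exponential_decay(t, np.full(t.size, 0.3))
        assert fit.selected_model == "constant"

    def test_noisy_constant_series_selects_constant_model(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 65, 5.0)
        fit = fit_exponential_decay(t, 0.3 + rng.normal(0, 0.01, t.size))
        assert fit.selected_model == "constant"

    def test_per_synapse_matrix_is_averaged(self):
        t = np.arange(0, 65, 5.0)
        base = np.exp(-t / 29.4)
        mat = np.stack([0.8 * base, 1.2 * base])
        fit = fit_exponential_decay(t, mat)
        assert abs(fit.params["tau_min"] - 29.4) / 29.4 < 1e-9

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_exponential_decay(np.array([0.0, 5, 10]), np.ones(3))

    def test_tau_recovery_unbiased_at_study_scale(self):
        """138 synapse traces x 13 timepoints, multiplicative noise, 10 seeds."""
        taus = []
        t = np.arange(0, 65, 5.0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            c = rng.lognormal(np.log(1.5), 0.4, 138)
            traces = c[:, None] * np.exp(-t[None, :] / 29.4) \
                * rng.lognormal(0, 0.1, (138, t.size))
            taus.append(fit_exponential_decay(t, traces).params["tau_min"])
        taus = np.asarray(taus)
        assert abs(taus.mean() - 29.4) / 29.4 < 0.05
        assert taus.std() / taus.mean() <= 0.10


class TestEnrichment:
    def test_filler_equals_target_gives_unity(self):
        rng = np.random.default_rng(8)
        comp = rng.uniform(1, 5, 30)
        shaft = rng.uniform(1, 5, 30)
        res = enrichment_ratio(comp, shaft, comp, shaft)
        np.testing.assert_allclose(res.ratios, 1.0)
        assert res.median == 1.0

    def test_constructed_fourfold_enrichment(self):
        shaft = np.full(20, 2.0)
        res = enrichment_ratio(4.0 * shaft, shaft, shaft, shaft)
        assert np.isclose(res.median, 4.0)

    def test_bouton_enrichment_with_realistic_scatter(self):
        """3.8-fold enriched boutons, flat filler, multiplicative noise."""
        rng = np.random.default_rng(9)
        n = 60
        shaft = rng.uniform(1, 3, n)
        target_bouton = 3.8 * shaft * rng.lognormal(0, 0.15, n)
        filler_shaft = rng.uniform(1, 3, n)
        filler_bouton = filler_shaft * rng.lognormal(0, 0.15, n)
        res = enrichment_ratio(target_bouton, shaft, filler_bouton, filler_shaft)
        assert abs(res.median - 3.8) / 3.8 < 0.05

    def test_zero_shaft_flagged_not_propagated(self):
        res = enrichment_ratio(np.array([4.0, 4.0]), np.array([2.0, 0.0]),
                               np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert res.flagged[1] and not res.flagged[0]
        assert np.isnan(res.ratios[1])

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(np.ones(3), np.ones(4), np.ones(3), np.ones(3))


def test_fit_exponential_curve_on_raw_points():
    rng = np.random.default_rng(10)
    d = rng.uniform(0, 250, 55)
    y = np.exp(-d / 106.0)
    fit = fit_exponential_curve(d, y)
    assert abs(fit.params["lambda_um"] - 106.0) / 106.0 < 1e-6
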