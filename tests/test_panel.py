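"""Panel filtering, subsampling sensitivity, and saturation extrapolation."""

import itertools
import math

import numpy as np
import pytest

from tumoronly import (
    CallSet,
    PanelCollection,
    PopulationModel,
    apply_panel_filter,
    build_germline_pool,
    compare_panels,
    estimate_detection_sensitivity,
    fit_carrier_spectrum,
    fit_saturation_curve,
    mean_sensitivity_exact,
    refine_with_matched_normal,
    required_panel_size,
    sensitivity_by_frequency,
    sensitivity_curve,
    simulate_panel,
)
from tumoronly.panel import CurvePoint, FitError, SaturationFit, SensitivityCurve

from conftest import vk


def panel_of(*sets, label="X"):
    return PanelCollection(
        label=label,
        members=[CallSet(sample_id=f"{label}{i}", variants=set(s)) for i, s in enumerate(sets)],
    )


class TestFilters:
    def test_panel_filter_set_oracles(self):
        v1, v2, v3, v4 = vk(1), vk(2), vk(3), vk(4)
        tumor = CallSet(sample_id="t", variants={v1, v2, v3})
        assert apply_panel_filter(tumor, panel_of()).variants == {v1, v2, v3}
        assert apply_panel_filter(tumor, panel_of({v1, v2, v3})).variants == set()
        assert apply_panel_filter(tumor, panel_of({v1}, {v4})).variants == {v2, v3}

    def test_panel_filter_never_removes_unseen_variants(self, small_cohort, small_panel):
        union = small_panel.site_union()
        for cs in small_cohort.tumor:
            kept = apply_panel_filter(cs, small_panel)
            assert kept.variants == cs.variants - union
            assert not (cs.variants - union) - kept.variants

    def test_refine_set_oracles_and_patient_check(self):
        a, b, c = vk(1), vk(2), vk(3)
        tumor = CallSet(sample_id="P1", variants={a, b})
        assert refine_with_matched_normal(
            tumor, CallSet(sample_id="P1")
        ).variants == {a, b}
        assert (
            refine_with_matched_normal(tumor, CallSet(sample_id="P1", variants={a, b})).variants
            == set()
        )
        assert refine_with_matched_normal(
            tumor, CallSet(sample_id="P1", variants={b, c})
        ).variants == {a}
        with pytest.raises(ValueError, match="mismatched"):
            refine_with_matched_normal(tumor, CallSet(sample_id="P2"))


class TestSubsamplingEstimator:
    def test_exhaustive_three_member_example(self):
        g1, g2 = vk(1), vk(2)
        truth = {"P1": {g1, g2}}
        pan = panel_of({g1}, {g1}, set())
        p1 = estimate_detection_sensitivity(truth, pan, k=1)
        assert p1.n_combos == 3
        assert p1.mean_sensitivity == pytest.approx(1 / 3)
        p3 = estimate_detection_sensitivity(truth, pan, k=3)
        assert p3.mean_sensitivity == pytest.approx(0.5)
        full = panel_of({g1, g2}, {g1, g2})
        for k in (1, 2):
            assert estimate_detection_sensitivity(truth, full, k).mean_sensitivity == 1.0

    def test_matches_brute_force_enumeration_exactly(self, rng):
        # independent oracle: plain set arithmetic over all combinations
        sites = [vk(p) for p in range(1, 30)]
        truth = {f"P{i}": set(rng.choice(len(sites), 8, replace=False)) for i in range(3)}
        truth = {p: {sites[j] for j in idx} for p, idx in truth.items()}
        members = [set(sites[j] for j in rng.choice(len(sites), 6, replace=False)) for _ in range(6)]
        pan = panel_of(*members)
        for k in (1, 2, 3, 5, 6):
            est = estimate_detection_sensitivity(truth, pan, k, max_combos=10_000)
            vals = []
            for combo in itertools.combinations(range(6), k):
                union = set().union(*(members[i] for i in combo))
                vals.append(np.mean([len(t & union) / len(t) for _, t in sorted(truth.items())]))
            assert est.n_combos == math.comb(6, k)
            assert est.mean_sensitivity == pytest.approx(np.mean(vals), abs=1e-12)
            assert est.sd == pytest.approx(np.std(vals, ddof=1) if len(vals) > 1 else 0.0, abs=1e-12)
            # and the closed-form average over all combos agrees
            assert mean_sensitivity_exact(truth, pan, k) == pytest.approx(
                np.mean(vals), abs=1e-12
            )

    def test_errors(self, small_panel):
        truth = {"P1": {vk(1)}}
        with pytest.raises(ValueError, match="k must lie"):
            estimate_detection_sensitivity(truth, small_panel, k=0)
        with pytest.raises(ValueError, match="k must lie"):
            estimate_detection_sensitivity(truth, small_panel, k=len(small_panel) + 1)
        with pytest.raises(ValueError, match="undefined sensitivity"):
            estimate_detection_sensitivity({"P1": set()}, small_panel, k=1)

    def test_mean_sensitivity_nondecreasing_in_k(self, small_cohort, small_panel):
        truth = small_cohort.germline_truth()
        vals = [mean_sensitivity_exact(truth, small_panel, k) for k in (1, 3, 6, 12, 24, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_subset_union_dominated_by_superset(self, small_cohort, small_panel, rng):
        # deterministic pointwise property S(subset) <= S(superset)
        truth = small_cohort.germline_truth()
        sets = [m.variants for m in small_panel.members]
        for _ in range(10):
            sup = rng.choice(len(sets), 5, replace=False)
            sub = sup[:3]

            def sens(ids):
                union = set().union(*(sets[i] for i in ids))
                return np.mean([len(t & union) / len(t) for t in truth.values() if t])

            assert sens(sub) <= sens(sup) + 1e-15


class TestFrequencyStratification:
    def test_single_bin_equals_unstratified(self, small_cohort, small_panel):
        truth = small_cohort.germline_truth()
        freqs = small_cohort.cohort_frequencies()
        table = sensitivity_by_frequency(truth, freqs, small_panel, k=10, bins=[1.0])
        assert table["sensitivity"].iloc[0] == pytest.approx(
            mean_sensitivity_exact(truth, small_panel, 10)
        )

    def test_empty_bin_is_nan_not_zero(self, small_cohort, small_panel):
        truth = small_cohort.germline_truth()
        freqs = {k: min(v, 0.5) for k, v in small_cohort.cohort_frequencies().items()}
        table = sensitivity_by_frequency(
            truth, freqs, small_panel, k=10, bins=[0.9999, 1.0]
        )
        assert np.isnan(table["sensitivity"].iloc[-1])
        assert table["n_instances"].iloc[-1] == 0

    def test_common_variants_detected_better_than_rare(self, small_genome):
        pop = PopulationModel(
            frequency_classes=((0.25, 0.5), (0.005, 0.5)), n_germline_sites=3000
        )
        pool = build_germline_pool(pop, small_genome, seed=61)
        panel = simulate_panel(pool, 60, seed=62)
        # truth: one pseudo-patient carrying a sample of each class
        carriers = {"T": set(pool.keys)}
        q = pool.carrier_probs
        freqs = {k: (0.6 if qq > 0.1 else 0.005) for k, qq in zip(pool.keys, q)}
        table = sensitivity_by_frequency(carriers, freqs, panel, k=50, bins=[0.05, 1.0])
        rare, common = table["sensitivity"].to_numpy()
        assert common > rare

    def test_missing_frequency_is_an_error(self, small_panel):
        truth = {"P1": {vk(1)}}
        with pytest.raises(ValueError, match="missing from the frequency map"):
            sensitivity_by_frequency(truth, {}, small_panel, k=2, bins=[1.0])


def make_curve(k, s, sd=0.0):
    return SensitivityCurve(
        points=[CurvePoint(int(kk), float(ss), sd, 100) for kk, ss in zip(k, s)]
    )


class TestSaturation:
    def test_noiseless_exponential_recovery(self):
        k = np.arange(1, 60)
        s = 0.8 * -np.expm1(-k / 10.0)
        fit = fit_saturation_curve(make_curve(k, s))
        assert fit.s_max == pytest.approx(0.8, abs=1e-6)
        assert fit.tau == pytest.approx(10.0, abs=1e-4)
        assert fit.residual_rms < 1e-8

    def test_degenerate_and_short_curves_rejected(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_saturation_curve(make_curve([1, 5, 10], [0.5, 0.5, 0.5]))
        with pytest.raises(ValueError, match="at least 3"):
            fit_saturation_curve(make_curve([1, 5], [0.1, 0.2]))

    def test_required_panel_size_closed_forms(self):
        fit = SaturationFit(model="exponential", s_max=1.0, tau=10.0)
        assert required_panel_size(fit, 1 - math.exp(-1)) == 10
        fit2 = SaturationFit(model="exponential", s_max=0.8, tau=10.0)
        with pytest.raises(ValueError, match="exceeds asymptote"):
            required_panel_size(fit2, 0.9)
        fit3 = SaturationFit(model="exponential", s_max=0.95, tau=300.0)
        expect = math.ceil(-300 * math.log1p(-0.9 / 0.95))
        assert required_panel_size(fit3, 0.9) == expect
        with pytest.raises(ValueError):
            required_panel_size(fit3, 1.5)

    def test_mixture_fit_with_known_classes(self):
        qs = np.array([0.4, 0.02, 0.001])
        w = np.array([0.3, 0.3, 0.4])
        k = np.array([1, 2, 5, 10, 20, 50, 100, 200])
        s = (w * (1 - (1 - qs) ** k[:, None])).sum(axis=1)
        fit = fit_saturation_curve(make_curve(k, s), model="mixture", q_grid=qs)
        assert np.allclose(fit.weights, w, atol=1e-6)
        assert fit.predict(1000) == pytest.approx(
            (w * (1 - (1 - qs) ** 1000)).sum(), abs=1e-6
        )

    def test_spectrum_deconvolution_recovers_single_class(self, small_genome):
        pop = PopulationModel(frequency_classes=((0.01, 1.0),), n_germline_sites=4000)
        pool = build_germline_pool(pop, small_genome, seed=71)
        panel = simulate_panel(pool, 150, seed=72)
        truth = {"T": set(pool.keys)}
        fit = fit_carrier_spectrum(truth, panel)
        q = 1 - 0.99**2
        k90_true = math.ceil(math.log(0.1) / math.log1p(-q))
        assert required_panel_size(fit, 0.9) == pytest.approx(k90_true, rel=0.15)


class TestComparePanels:
    def test_identical_panels_give_identical_curves(self, small_cohort, small_panel):
        truth = small_cohort.germline_truth()
        curves = compare_panels(truth, [small_panel, small_panel], [1, 5, 10], exact=True)
        assert np.allclose(curves[0].sensitivity, curves[1].sensitivity)

    def test_matched_population_dominates_disjoint_panel(self, small_genome, small_cohort):
        truth = small_cohort.germline_truth()
        other_pool = build_germline_pool(
            PopulationModel(n_germline_sites=4000), small_genome, seed=99
        )
        mismatched = simulate_panel(other_pool, 30, "CEU", seed=100)
        matched = simulate_panel(small_cohort.pool, 30, "JPT", seed=101)
        curves = compare_panels(truth, [matched, mismatched], [1, 5, 15, 30], exact=True)
        assert np.all(curves[0].sensitivity > curves[1].sensitivity)
        assert np.allclose(curves[1].sensitivity, 0.0, atol=1e-6)

    def test_single_panel_consistent_with_estimator(self, small_cohort, small_panel):
        truth = small_cohort.germline_truth()
        [curve] = compare_panels(truth, [small_panel], [4, 8], exact=True)
        assert curve.sensitivity[0] == pytest.approx(
            mean_sensitivity_exact(truth, small_panel, 4)
        )

    def test_empty_panel_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty"):
            compare_panels(
                small_cohort.germline_truth(),
                [PanelCollection(label="E", members=[])],
                [1],
            )

    def test_k_grid_capped_at_panel_size(self, small_cohort, small_panel):
        truth = small_cohort.germline_truth()
        curve = sensitivity_curve(truth, small_panel, [5, 10, 10_000], exact=True)
        assert list(curve.k) == [5, 10]
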