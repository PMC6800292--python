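"""Generator contracts: determinism, construction counts, closed forms."""

import numpy as np
import pytest

from neurophenotyper.synth import (
    CohortDesign,
    FiberParams,
    GroupEffects,
    GroupSpec,
    PlacementError,
    PunctaParams,
    SceneParams,
    generate_calcium_traces,
    generate_ct_table,
    generate_eb_mask,
    generate_expression_matrix,
    generate_image_scene,
    generate_mea_recording,
    simulate_measurement_cohort,
)


class TestSceneGenerator:
    def test_empty_scene(self):
        scene, gt = generate_image_scene(SceneParams(n_nuclei=0), seed=0)
        assert gt.nucleus_records == []
        # background + noise only: nothing near nucleus intensity
        assert scene.channel("hoechst").max() < 30

    def test_seed_determinism_bit_identical(self):
        p = SceneParams(n_nuclei=10, fibers=[FiberParams(n_fibers=4)])
        s1, g1 = generate_image_scene(p, seed=5)
        s2, g2 = generate_image_scene(p, seed=5)
        for ch in s1.channels:
            np.testing.assert_array_equal(s1.channels[ch], s2.channels[ch])
        assert g1.to_json() == g2.to_json()

    def test_different_seeds_differ(self):
        p = SceneParams(n_nuclei=10)
        s1, _ = generate_image_scene(p, seed=1)
        s2, _ = generate_image_scene(p, seed=2)
        assert not np.array_equal(s1.channel("hoechst"), s2.channel("hoechst"))

    def test_coloc_pairs_count_by_construction(self):
        p = SceneParams(
            pixel_size_um=0.22, n_nuclei=0,
            fibers=[FiberParams(channel="btub", n_fibers=4, length_um=(60, 90), width_um=1.2)],
            puncta=PunctaParams(n_pre=50, n_post=50, coloc_fraction=0.4),
        )
        _, gt = generate_image_scene(p, seed=3)
        assert len(gt.colocalized_pairs) == 20
        assert len(gt.puncta_lists["synapsin"]) == 50
        assert len(gt.puncta_lists["homer"]) == 50
        # every true pair's centres sit within the colocalization distance
        pre = gt.puncta_lists["synapsin"]
        post = gt.puncta_lists["homer"]
        for i, j in gt.colocalized_pairs:
            d_px = np.hypot(
                pre[i].center[0] - post[j].center[0],
                pre[i].center[1] - post[j].center[1],
            )
            assert d_px * gt.pixel_size_um <= gt.coloc_distance_um + 1e-9

    def test_ground_truth_invariants(self, nuclei_scene):
        _, gt = nuclei_scene
        normal_max = max(
            n.intensity for n in gt.nucleus_records if n.intensity_class != "pyknotic"
        )
        for n in gt.nucleus_records:
            assert n.area_um2 > 0
            if n.intensity_class == "pyknotic":
                assert n.intensity > normal_max
        for f in gt.fiber_arcs:
            assert f.arc_length_um > 0

    def test_polyline_arc_length_matches_vertices(self, fiber_scene):
        _, gt = fiber_scene
        for f in gt.fiber_arcs:
            seg = np.diff(f.vertices, axis=0)
            length_px = np.hypot(seg[:, 0], seg[:, 1]).sum()
            assert length_px * gt.pixel_size_um == pytest.approx(f.arc_length_um, rel=1e-9)

    def test_placement_failure_raises(self):
        p = SceneParams(shape=(96, 96), n_nuclei=200, max_place_tries=500)
        with pytest.raises(PlacementError):
            generate_image_scene(p, seed=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_image_scene(SceneParams(n_nuclei=-1), seed=0)


class TestEBGenerator:
    def test_circle_truth(self):
        _, truth = generate_eb_mask(area_um2=200_000, elongation=1.0)
        assert truth.form_factor == pytest.approx(1.0, abs=1e-6)

    def test_elongation_lowers_form_factor(self):
        ffs = [
            generate_eb_mask(area_um2=200_000, elongation=e)[1].form_factor
            for e in (1.0, 1.5, 2.5)
        ]
        assert ffs[0] > ffs[1] > ffs[2]


class TestMEAGenerator:
    def test_zero_rate_pure_noise(self):
        rec, gt = generate_mea_recording(np.zeros(3), duration_s=10, seed=0)
        assert all(len(t) == 0 for t in gt.spike_times)
        sd = rec.voltage.std()
        assert sd == pytest.approx(3.0, rel=0.05)

    def test_poisson_mean_counts(self):
        # 48 electrodes at 6/min for 300 s: lambda*t = 30 per electrode
        rec, gt = generate_mea_recording(
            np.full(48, 6.0), duration_s=300.0, seed=7, noise_sd_uv=3.0
        )
        counts = np.array([len(t) for t in gt.spike_times])
        se = np.sqrt(30.0 / 48)
        assert abs(counts.mean() - 30.0) < 3 * se

    def test_determinism(self):
        r1, _ = generate_mea_recording([6.0], duration_s=5, seed=3)
        r2, _ = generate_mea_recording([6.0], duration_s=5, seed=3)
        np.testing.assert_array_equal(r1.voltage, r2.voltage)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            generate_mea_recording([1.0], duration_s=0)


class TestCalciumGenerator:
    def test_flat_trace_no_events_no_bleach_no_noise(self):
        tr, _ = generate_calcium_traces(
            n_rois=1, event_rate_per_min=0, bleach_endpoint_drop=0,
            noise_sd_dff=0, n_frames=100, seed=0,
        )
        np.testing.assert_allclose(tr.raw, tr.raw[0, 0])

    def test_bleach_endpoint_by_construction(self):
        tr, _ = generate_calcium_traces(
            n_rois=1, event_rate_per_min=0, bleach_endpoint_drop=0.2,
            noise_sd_dff=0, n_frames=200, seed=0,
        )
        assert tr.raw[-1, 0] == pytest.approx(0.8 * tr.raw[0, 0])

    def test_single_event_peak_closed_form(self):
        # amplitude 0.8 with no bleach/noise: peak raw value = 1.8 x F0
        tr, gt = generate_calcium_traces(
            n_rois=1, bleach_endpoint_drop=0, noise_sd_dff=0,
            event_times=[[10.0]], event_amplitudes=[[0.8]], seed=0,
        )
        assert tr.raw.max() == pytest.approx(1.8 * gt.f0_level, rel=1e-6)

    def test_defaults_match_recording_model(self):
        tr, gt = generate_calcium_traces(n_rois=1, seed=0)
        assert gt.n_frames == 3500
        assert 0.031 <= gt.frame_interval_s <= 0.032


class TestCohort:
    def test_control_must_be_unit(self):
        design = CohortDesign(
            groups=[GroupSpec("control", effects=GroupEffects(dendrite_length_factor=0.9))]
        )
        with pytest.raises(ValueError):
            design.validate()

    def test_effect_scaling_in_measurement_cohort(self):
        design = CohortDesign(
            groups=[
                GroupSpec("control", n_replicates=2000),
                GroupSpec("patient", n_replicates=2000,
                          effects=GroupEffects(dendrite_length_factor=0.7,
                                               puncta_count_factor=0.6)),
            ],
            seed=4,
        )
        df = simulate_measurement_cohort(design, cv=0.15)
        means = df.groupby(["measure", "group"])["value"].mean()
        assert means["dendrite_length", "patient"] / means["dendrite_length", "control"] \
            == pytest.approx(0.7, abs=0.02)
        assert means["coloc_puncta", "patient"] / means["coloc_puncta", "control"] \
            == pytest.approx(0.6, abs=0.02)

    def test_null_cohort_exchangeable_means(self):
        design = CohortDesign(
            groups=[GroupSpec("control", n_replicates=3000),
                    GroupSpec("g2", n_replicates=3000)],
            seed=5,
        )
        df = simulate_measurement_cohort(design, cv=0.15)
        m = df[df.measure == "dendrite_length"].groupby("group")["value"].mean()
        assert m["g2"] / m["control"] == pytest.approx(1.0, abs=0.02)


class TestMolecular:
    def test_ct_table_known_fold_change(self):
        df = generate_ct_table(
            {"control": 3, "case": 3},
            fold_changes={"case": {"PCDH15": 0.5}},
            target_genes=["PCDH15"],
            ct_sd=0.0,
            seed=0,
        )
        # one cycle = factor two: 0.5-fold shifts delta-Ct up by exactly 1
        ref = df[df.gene == "GAPDH"].set_index("sample")["ct"]
        tgt = df[df.gene == "PCDH15"].set_index("sample")
        dct = (tgt["ct"] - ref).groupby(tgt["group"]).mean()
        assert dct["case"] - dct["control"] == pytest.approx(1.0, abs=1e-12)

    def test_expression_matrix_planted_folds(self):
        mat, groups, planted = generate_expression_matrix(
            n_genes=50, groups={"control": 3, "case": 3},
            planted={"case": {"G00001": 3.0}}, cv=0.0, seed=0,
        )
        case_cols = groups.index[groups == "case"]
        ctrl_cols = groups.index[groups == "control"]
        fold = mat.loc["G00001", case_cols].mean() / mat.loc["G00001", ctrl_cols].mean()
        assert fold == pytest.approx(3.0, rel=1e-9)
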