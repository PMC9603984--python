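"""Generator contracts: determinism, noise-free limit, configured rates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from orgaswell import (
    Condition,
    PlateLayout,
    SimulationConfig,
    areas_from_detections,
    fit_tracks,
    link_tracks,
    make_screen_layout,
    simulate_screen,
    simulate_traces,
)
from orgaswell.errors import ConfigurationError, DataError
from orgaswell.layout import well_names
from orgaswell.synthetic_data import (
    expected_well_rate_iqr,
    make_primary_screen,
    render_frame,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_frames", 1),
        ("detection_dropout_p", 1.5),
        ("detection_dropout_p", -0.1),
        ("organoids_per_well", 0.0),
        ("slope_noise_sd", -1.0),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**{field: value})


class TestSimulateScreen:
    def test_same_seed_identical_tables(self, small_layout, quiet_config):
        d1, t1 = simulate_screen(small_layout, quiet_config)
        d2, t2 = simulate_screen(small_layout, quiet_config)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1.observations, t2.observations)
        assert d1.to_csv(index=False) == d2.to_csv(index=False)

    def test_different_seed_differs(self, small_layout, quiet_config):
        d1, _ = simulate_screen(small_layout, quiet_config)
        d2, _ = simulate_screen(
            small_layout, dataclasses.replace(quiet_config, seed=99)
        )
        assert not d1.equals(d2)

    def test_noise_free_limit_exactly_linear_complete_tracks(
        self, small_layout, noise_free_config
    ):
        det, truth = simulate_screen(small_layout, noise_free_config)
        # every organoid present in all 13 frames
        counts = truth.detections_truth.groupby("organoid_id").size()
        assert (counts == 13).all()
        # areas from boxes are exactly baseline + slope * frame
        areas = areas_from_detections(det)
        truth_det = truth.detections_truth
        np.testing.assert_allclose(
            areas["area"].to_numpy(),
            truth_det["true_area"].to_numpy(),
            rtol=1e-9,
        )

    def test_adding_wells_does_not_perturb_existing_draws(self, quiet_config):
        lay1 = make_screen_layout("P1", [("a", "b"), ("c", "d")], 1, 1)
        extended = dict(lay1.wells)
        free = [w for w in sorted(well_names(384)) if w not in extended]
        extended[free[0]] = Condition("compound", ("e", "f"))
        extended[free[1]] = Condition("dmso")
        lay2 = PlateLayout("P1", 384, extended)
        d1, _ = simulate_screen(lay1, quiet_config)
        d2, _ = simulate_screen(lay2, quiet_config)
        shared = sorted(lay1.wells)
        pd.testing.assert_frame_equal(
            d1[d1["well"].isin(shared)].reset_index(drop=True),
            d2[d2["well"].isin(shared)].reset_index(drop=True),
        )

    def test_dropout_fraction_matches_binomial(self):
        layout = make_screen_layout(
            "P1", [(f"a{i}", f"b{i}") for i in range(50)], 5, 5
        )
        cfg = SimulationConfig(
            seed=3, detection_dropout_p=0.3, organoids_per_well=15.0
        )
        _, truth = simulate_screen(layout, cfg)
        obs = truth.observations
        n = len(obs)
        assert n > 10_000
        frac = obs["dropped"].mean()
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < 3 * sd

    def test_full_pipeline_recovers_true_slopes_noise_free(
        self, small_layout, noise_free_config
    ):
        det, truth = simulate_screen(small_layout, noise_free_config)
        fits = fit_tracks(link_tracks(areas_from_detections(det)))
        got = np.sort(fits["slope"].to_numpy())
        want = np.sort(truth.organoids["true_slope"].to_numpy())
        assert len(got) == len(want)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_plate_effects_applied_to_slopes(self):
        from orgaswell import PlateEffect

        lay_a = make_screen_layout("PA", [("a", "b")] , 1, 1)
        cfg = SimulationConfig(
            seed=11, organoids_per_well=40.0,
            slope_noise_sd=0.0, baseline_area_sd=0.0,
            detection_dropout_p=0.0, area_obs_noise_sd=0.0, bbox_jitter_sd=0.0,
            plate_effects={"PA": PlateEffect(shift=3.0, scale=2.0)},
        )
        _, truth = simulate_screen(lay_a, cfg)
        dmso = truth.organoids[truth.organoids["role"] == "dmso"]
        # shift + scale * basal_slope, no noise
        assert dmso["true_slope"].to_numpy() == pytest.approx(
            2.0 * cfg.basal_slope + 3.0
        )


class TestRenderFrames:
    def test_single_detection_renders_one_ring_component(self):
        from scipy import ndimage

        det = pd.DataFrame(
            [[40.0, 40.0, 80.0, 80.0]],
            columns=["x_min", "y_min", "x_max", "y_max"],
        )
        img = render_frame(det, (128, 128), rng=np.random.default_rng(0))
        bright = img > 20000
        _, n = ndimage.label(bright)
        assert n == 1

    def test_zero_detections_background_only(self):
        img = render_frame(
            pd.DataFrame(columns=["x_min", "y_min", "x_max", "y_max"]),
            (64, 64), rng=np.random.default_rng(0),
        )
        assert img.max() < 5000

    def test_out_of_bounds_box_rejected(self):
        det = pd.DataFrame(
            [[-5.0, 10.0, 30.0, 40.0]],
            columns=["x_min", "y_min", "x_max", "y_max"],
        )
        with pytest.raises(DataError):
            render_frame(det, (64, 64))


class TestTraces:
    def test_clean_step_differs_by_exactly_5(self):
        tr = simulate_traces("isc", step_uA=5.0, noise_sd=0.0)
        before = tr[tr["time_s"] < 150.0]["isc"].iloc[-1]
        after = tr[tr["time_s"] > 150.0]["isc"].iloc[0]
        assert after - before == pytest.approx(5.0, abs=1e-12)

    def test_yfp_no_decay_constant(self):
        tr = simulate_traces("yfp", segments=[(10.0, 0.0)], noise_sd=0.0)
        assert tr["fluorescence"].nunique() == 1

    def test_yfp_two_segment_steepest_is_second(self):
        tr = simulate_traces("yfp", segments=[(5.0, -0.01), (5.0, -0.08)])
        t = tr["time_s"].to_numpy()
        y = tr["fluorescence"].to_numpy()
        early = (t >= 2.0) & (t <= 7.0)
        late = (t >= 7.0) & (t <= 12.0)
        slope_early = np.polyfit(t[early], y[early], 1)[0]
        slope_late = np.polyfit(t[late], y[late], 1)[0]
        assert slope_late < slope_early < 0

    def test_event_outside_trace_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_traces("isc", duration_s=100.0, event_time_s=500.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_traces("patch_clamp")


def test_primary_screen_spikes_requested_actives():
    layouts, cfg, actives = make_primary_screen(
        seed=5, n_plates=2, n_compound_wells=30, n_actives=4
    )
    assert len(actives) == 4
    assert len(layouts) == 2
    effect = 3.0 * expected_well_rate_iqr(cfg)
    for c in actives:
        assert cfg.compound_effects[c] == pytest.approx(effect)
    # actives sit in distinct wells: no two share a well
    wells_of = [
        w for lay in layouts[:1] for w, cond in lay.wells.items()
        if set(cond.compounds) & actives
    ]
    assert len(wells_of) == 4
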