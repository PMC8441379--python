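import numpy as np
import pytest
from datetime import datetime, timedelta

from phenorhythm.synth import (
    CircadianModel,
    EnvModel,
    GrowthModel,
    LeafSpec,
    LogisticCurve,
    PlantSpec,
    default_growth_model,
    grow_spec,
    modulate_spec,
    random_plant_spec,
    sample_leaf,
    sample_plant,
    simulate_env,
    simulate_series,
)

PLANTING = datetime(2019, 3, 25)


class TestLeafSpec:
    def test_invalid_droop_rejected(self):
        with pytest.raises(ValueError, match="droop"):
            LeafSpec(length=0.5, max_width=0.1, attach_height=1.0,
                     inclination_deg=10, azimuth_deg=0, droop=0.6)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            LeafSpec(length=-1, max_width=0.1, attach_height=1.0,
                     inclination_deg=10, azimuth_deg=0)

    def test_azimuth_normalized_to_range(self):
        spec = LeafSpec(length=0.5, max_width=0.1, attach_height=1.0,
                        inclination_deg=10, azimuth_deg=370.0)
        assert spec.azimuth_deg == pytest.approx(10.0)

    def test_chord_length_matches_arc_for_straight_leaf(self):
        spec = LeafSpec(length=0.5, max_width=0.1, attach_height=1.0,
                        inclination_deg=30, azimuth_deg=45, droop=0.0)
        assert spec.chord_length == pytest.approx(0.5, abs=1e-12)

    def test_drooping_chord_shorter_than_arc(self):
        spec = LeafSpec(length=0.5, max_width=0.1, attach_height=1.0,
                        inclination_deg=30, azimuth_deg=45, droop=0.3)
        assert spec.chord_length < 0.5

    def test_midrib_numeric_arc_equals_length(self):
        spec = LeafSpec(length=0.47, max_width=0.1, attach_height=1.0,
                        inclination_deg=35, azimuth_deg=120, droop=0.25)
        s = np.linspace(0, 1, 20001)
        pts = spec.midrib_points(s)
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc == pytest.approx(spec.length, rel=1e-6)


class TestSampleLeaf:
    def test_flat_horizontal_leaf_z_constant(self, flat_leaf_spec):
        cloud = sample_leaf(flat_leaf_spec, density=2e4, noise_sd=0.0, seed=0)
        assert np.all(np.abs(cloud.z - 1.0) < 1e-12)

    def test_azimuth_of_chord(self):
        # oracle: arctangent of the horizontal displacement of generated
        # tip-end points from base-end points
        spec = LeafSpec(length=0.5, max_width=0.08, attach_height=1.0,
                        inclination_deg=20, azimuth_deg=37.0, droop=0.0)
        cloud = sample_leaf(spec, density=2e5, noise_sd=0.0, seed=1)
        d = cloud.xyz @ spec._chord_unit()
        lo, hi = np.quantile(d, [0.05, 0.95])
        base_c = cloud.xyz[d <= lo].mean(axis=0)
        tip_c = cloud.xyz[d >= hi].mean(axis=0)
        vec = tip_c - base_c
        az = np.degrees(np.arctan2(vec[0], vec[1])) % 360
        assert az == pytest.approx(37.0, abs=0.5)

    def test_poisson_point_count(self):
        # flat leaf with surface area exactly 0.02 m^2
        width = 0.08
        length = 0.02 * np.pi / (2 * width)
        spec = LeafSpec(length=length, max_width=width, attach_height=0.5,
                        inclination_deg=0, azimuth_deg=0)
        assert spec.surface_area == pytest.approx(0.02, rel=1e-9)
        counts = [len(sample_leaf(spec, 1e5, 0.0, seed)) for seed in range(5)]
        assert abs(np.mean(counts) - 2000) < 3 * np.sqrt(2000)

    def test_labels_match_requested(self, flat_leaf_spec):
        cloud = sample_leaf(flat_leaf_spec, 1e4, 0.0, 0, label=5)
        assert set(cloud.labels) == {5}

    def test_nonpositive_density_rejected(self, flat_leaf_spec):
        with pytest.raises(ValueError, match="density"):
            sample_leaf(flat_leaf_spec, 0.0, 0.0, 0)

    def test_noise_changes_points(self, flat_leaf_spec):
        c0 = sample_leaf(flat_leaf_spec, 1e4, 0.0, 0)
        c1 = sample_leaf(flat_leaf_spec, 1e4, 0.002, 0)
        assert np.std(c1.z) > 0 and np.std(c0.z) < 1e-12


class TestSamplePlant:
    def test_stem_only_plant(self):
        spec = PlantSpec(stem_height=2.0, leaves=())
        cloud = sample_plant(spec, density=5e4, noise_sd=0.0, seed=0)
        assert cloud.z.max() == pytest.approx(2.0, abs=1e-12)
        assert set(cloud.labels) == {0}

    def test_determinism_bit_identical(self, plateau_plant_spec):
        a = sample_plant(plateau_plant_spec, 2e4, 0.002, 11)
        b = sample_plant(plateau_plant_spec, 2e4, 0.002, 11)
        assert np.array_equal(a.xyz, b.xyz)
        assert np.array_equal(a.labels, b.labels)

    def test_label_set_enumerates_leaves(self):
        rng = np.random.default_rng(1)
        spec = random_plant_spec(rng, n_leaves=8)
        cloud = sample_plant(spec, 2e4, 0.0, 0)
        assert set(cloud.labels.tolist()) == set(range(9))

    def test_label_conservation(self, plateau_plant_cloud):
        total = sum(
            (plateau_plant_cloud.labels == k).sum()
            for k in np.unique(plateau_plant_cloud.labels)
        )
        assert total == len(plateau_plant_cloud)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="attach_height"):
            PlantSpec(
                stem_height=1.0,
                leaves=(LeafSpec(length=0.5, max_width=0.1, attach_height=1.5,
                                 inclination_deg=10, azimuth_deg=0),),
            )


class TestGrowSpec:
    def test_plateau_limit(self, plateau_plant_spec):
        grown = grow_spec(plateau_plant_spec, default_growth_model(), 500.0)
        assert grown.stem_height == pytest.approx(plateau_plant_spec.stem_height, rel=0.01)

    def test_midpoint_is_half_plateau(self, plateau_plant_spec):
        growth = default_growth_model()
        t_mid = growth.curves["stem_height"].t_mid
        grown = grow_spec(plateau_plant_spec, growth, t_mid)
        assert grown.stem_height == pytest.approx(plateau_plant_spec.stem_height / 2)

    def test_monotone_in_time(self, plateau_plant_spec):
        growth = default_growth_model()
        a = grow_spec(plateau_plant_spec, growth, 40.0)
        b = grow_spec(plateau_plant_spec, growth, 90.0)
        assert a.stem_height <= b.stem_height
        for la, lb in zip(a.leaves, b.leaves):
            assert la.length <= lb.length
            assert la.max_width <= lb.max_width
            assert la.attach_height <= lb.attach_height

    def test_negative_time_rejected(self, plateau_plant_spec):
        with pytest.raises(ValueError):
            grow_spec(plateau_plant_spec, default_growth_model(), -1.0)

    def test_unknown_growth_field_rejected(self):
        with pytest.raises(ValueError, match="unknown growth field"):
            GrowthModel(curves={"bogus": LogisticCurve(1, 1, 1)})


class TestModulateSpec:
    def test_zero_amplitude_identity(self, plateau_plant_spec):
        circ = CircadianModel(terms={"stem_height": (0.0, 6.0)})
        assert modulate_spec(plateau_plant_spec, circ, 12.0) == plateau_plant_spec

    def test_sine_peak_at_phase_plus_six(self, plateau_plant_spec):
        circ = CircadianModel(terms={"stem_height": (0.05, 2.0)})
        mod = modulate_spec(plateau_plant_spec, circ, 8.0)
        assert mod.stem_height == pytest.approx(plateau_plant_spec.stem_height + 0.05)

    def test_mean_over_24_hourly_samples_is_base(self, plateau_plant_spec):
        circ = CircadianModel(terms={"stem_height": (0.05, 3.7)})
        heights = [
            modulate_spec(plateau_plant_spec, circ, h).stem_height for h in range(24)
        ]
        assert np.mean(heights) == pytest.approx(plateau_plant_spec.stem_height, abs=1e-9)

    def test_clock_out_of_range_rejected(self, plateau_plant_spec):
        with pytest.raises(ValueError):
            modulate_spec(plateau_plant_spec, CircadianModel(), 24.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            CircadianModel(terms={"stem_height": (-0.1, 0.0)})


class TestSimulateSeries:
    #: the 16 printed scan times of the standard-condition circadian day
    SCAN_TIMES = [
        (0, 19, 49), (0, 21, 48), (0, 23, 48), (1, 1, 48), (1, 3, 48), (1, 4, 48),
        (1, 6, 48), (1, 8, 48), (1, 10, 48), (1, 12, 0), (1, 12, 48), (1, 14, 48),
        (1, 16, 48), (1, 18, 48), (1, 19, 48), (1, 21, 48),
    ]

    def _moments(self):
        day0 = PLANTING + timedelta(days=89)
        return [
            day0 + timedelta(days=d, hours=h, minutes=m) for d, h, m in self.SCAN_TIMES
        ]

    def test_sixteen_scan_moments_give_sixteen_clouds(self, plateau_plant_spec):
        clouds, truth = simulate_series(
            plateau_plant_spec, None, None, self._moments(), 5e3, 0.0, 0,
            planting_time=PLANTING,
        )
        assert len(clouds) == 16
        assert truth["moment"].nunique() == 16

    def test_four_stage_days_non_decreasing_heights(self, plateau_plant_spec):
        moments = [PLANTING + timedelta(days=d, hours=12) for d in (67, 78, 98, 112)]
        clouds, truth = simulate_series(
            plateau_plant_spec, default_growth_model(), None, moments, 5e3, 0.0, 0,
            planting_time=PLANTING,
        )
        assert len(clouds) == 4
        stem = truth.groupby("moment", sort=True)["stem_height"].first().to_numpy()
        assert np.all(np.diff(stem) >= 0)
        maxz = [c.z.max() for c in clouds]
        assert np.all(np.diff(maxz) >= 0)

    def test_plateau_zero_amplitude_equals_direct_sample(self, plateau_plant_spec):
        moment = [PLANTING + timedelta(days=200)]
        clouds, _ = simulate_series(
            plateau_plant_spec, None, CircadianModel(), moment, 1e4, 0.0, 9,
            planting_time=PLANTING,
        )
        direct = sample_plant(plateau_plant_spec, 1e4, 0.0, np.random.default_rng(9))
        assert np.array_equal(clouds[0].xyz, direct.xyz)

    def test_unsorted_moments_rejected(self, plateau_plant_spec):
        moments = [PLANTING + timedelta(days=d) for d in (70, 69)]
        with pytest.raises(ValueError, match="increasing"):
            simulate_series(plateau_plant_spec, None, None, moments, 1e3, 0.0, 0,
                            planting_time=PLANTING)

    def test_truth_rows_match_moments_times_leaves(self, plateau_plant_spec):
        moments = [PLANTING + timedelta(days=d, hours=6) for d in (80, 90)]
        _, truth = simulate_series(plateau_plant_spec, None, None, moments, 1e3, 0.0, 0,
                                   planting_time=PLANTING)
        assert len(truth) == 2 * len(plateau_plant_spec.leaves)


class TestSimulateEnv:
    def test_fencepost_record_count(self):
        start = datetime(2019, 6, 22, 0, 0)
        env = simulate_env(EnvModel(), start, start + timedelta(hours=24))
        assert len(env) == 49

    def test_par_zero_at_night(self):
        model = EnvModel(sunrise_h=4.77, sunset_h=19.77)
        start = datetime(2019, 6, 22, 0, 0)
        env = simulate_env(model, start, start + timedelta(hours=24))
        night = env[env["time"].dt.hour == 2]
        assert (night["PAR"] == 0.0).all()

    def test_temperature_peak_value(self):
        model = EnvModel(t_min=18.0, t_max=32.0, t_peak_hour=14.0)
        start = datetime(2019, 6, 22, 0, 0)
        env = simulate_env(model, start, start + timedelta(hours=24))
        at_peak = env[env["time"].dt.hour == 14].iloc[0]
        assert at_peak["T"] == pytest.approx(32.0)

    def test_rh_within_bounds_with_noise(self):
        start = datetime(2019, 6, 22, 0, 0)
        env = simulate_env(EnvModel(), start, start + timedelta(hours=48),
                           seed=3, noise_sd=(50.0, 1.0, 20.0))
        assert env["RH"].between(0, 100).all()
        assert (env["PAR"] >= 0).all()

    def test_invalid_span_rejected(self):
        start = datetime(2019, 6, 22)
        with pytest.raises(ValueError):
            simulate_env(EnvModel(), start, start)

    def test_nonpositive_step_rejected(self):
        start = datetime(2019, 6, 22)
        with pytest.raises(ValueError):
            simulate_env(EnvModel(), start, start + timedelta(hours=1), step_min=0)
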