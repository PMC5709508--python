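import numpy as np
import pytest
from scipy import ndimage

from rhizohair import (FixedLength, GrowthConfig, HairSeed, angle_between,
                       assign_lengths, cartesian_face, classify_bins,
                       extract_surface, generate_sphere_packing, grow_hair,
                       grow_population, grow_step, sample_transition_points,
                       spiral_points, uniform_volume, validity_tests)
from rhizohair.geometry import MINERAL, PORE, ROOT, TEXTURAL, PhaseVolume
from rhizohair.growth import build_fan

from conftest import make_sphere_volume


class TestSpiralPoints:
    def test_n2_antipodal_poles(self):
        pts = spiral_points(2)
        np.testing.assert_allclose(pts[0], [0, 0, -1])
        np.testing.assert_allclose(pts[1], [0, 0, 1])

    @pytest.mark.parametrize("n", [2, 8, 30, 100, 500])
    def test_unit_norm(self, n):
        pts = spiral_points(n)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)

    def test_min_separation_vs_ideal(self):
        # brute-force pairwise scan at n=100
        pts = spiral_points(100)
        dots = np.clip(pts @ pts.T, -1, 1)
        ang = np.arccos(dots)
        np.fill_diagonal(ang, np.inf)
        ideal = np.sqrt(8 * np.pi / (np.sqrt(3) * 100))
        # pole-adjacent pairs of this construction sit at ~0.53x the ideal
        # equal-area spacing; interior pairs clear 0.6x comfortably
        assert ang.min() >= 0.5 * ideal
        assert ang[1:-1, 1:-1].min() >= 0.6 * ideal

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            spiral_points(1)

    def test_deterministic(self):
        np.testing.assert_array_equal(spiral_points(64), spiral_points(64))


class TestAngleBetween:
    def test_parallel(self):
        assert angle_between([1, 0, 0], [2, 0, 0]) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert angle_between([1, 0, 0], [0, 1, 0]) == pytest.approx(np.pi / 2)

    def test_vs_arccos_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(100_000, 3))
        b = rng.normal(size=(100_000, 3))
        # include near-antiparallel pairs where arccos is least accurate
        b[:100] = -a[:100] + 1e-6 * rng.normal(size=(100, 3))
        for i in range(0, 100_000, 997):
            dot = np.dot(a[i], b[i]) / (np.linalg.norm(a[i]) * np.linalg.norm(b[i]))
            oracle = np.arccos(np.clip(dot, -1.0, 1.0))
            assert abs(angle_between(a[i], b[i]) - oracle) < 1e-9

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_between([0, 0, 0], [1, 0, 0])


class TestClassifyBins:
    def test_zero_angle_first_bin(self):
        assert classify_bins(0.0, 4)[0] == 1

    def test_direct_evaluation(self):
        # 0.4 rad > pi/8, so second bin when k=4
        expected = int(np.floor(0.4 / (np.pi / 8))) + 1
        assert expected == 2
        assert classify_bins(0.4, 4)[0] == 2

    def test_right_angle_out_of_range(self):
        assert classify_bins(np.pi / 2, 4)[0] == 0

    def test_bins_half_open(self):
        k = 4
        w = np.pi / (2 * k)
        assert classify_bins(w - 1e-12, k)[0] == 1
        assert classify_bins(w, k)[0] == 2

    def test_bad_k(self):
        with pytest.raises(ValueError):
            classify_bins([0.1], 0)


class TestValidityTests:
    def test_open_pore_all_angle_valid_selectable(self, empty_volume):
        cfg = GrowthConfig()
        fan = build_fan(np.array([400.0, 400, 400]), np.array([1.0, 0, 0]),
                        cfg.step_length, cfg.fan_size, cfg.bin_count)
        validity_tests(fan, empty_volume, cfg, seed_in_fluid=False)
        np.testing.assert_array_equal(fan.selectable, fan.bin_index >= 1)

    def test_f1_confines_to_textural(self):
        labels = np.full((20, 20, 20), PORE, dtype=np.uint8)
        labels[:, :, :10] = TEXTURAL
        vol = PhaseVolume(labels, 10.0)
        cfg = GrowthConfig(condition_F="F1")
        tip = np.array([100.0, 100.0, 80.0])  # in the slab, near its boundary
        fan = build_fan(tip, np.array([1.0, 0, 0]), cfg.step_length,
                        cfg.fan_size, cfg.bin_count)
        validity_tests(fan, vol, cfg, seed_in_fluid=True)
        labs = vol.label_at(fan.test_points)
        np.testing.assert_array_equal(fan.fluid_ok, labs == TEXTURAL)
        assert np.any(labs == PORE)  # some candidates do reach the pore phase
        assert not np.any(fan.fluid_ok[labs == PORE])

    def test_f0_ignores_fluid(self):
        labels = np.full((20, 20, 20), TEXTURAL, dtype=np.uint8)
        vol = PhaseVolume(labels, 10.0)
        cfg = GrowthConfig(condition_F="F0")
        fan = build_fan(np.array([100.0, 100, 100]), np.array([1.0, 0, 0]),
                        cfg.step_length, cfg.fan_size, cfg.bin_count)
        validity_tests(fan, vol, cfg, seed_in_fluid=True)
        assert fan.fluid_ok.all()

    def test_root_and_outside_invalid(self):
        labels = np.full((10, 10, 10), ROOT, dtype=np.uint8)
        labels[0, 0, 0] = PORE
        vol = PhaseVolume(labels, 10.0)
        cfg = GrowthConfig()
        fan = build_fan(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
                        cfg.step_length, cfg.fan_size, cfg.bin_count)
        validity_tests(fan, vol, cfg, seed_in_fluid=False)
        labs = vol.label_at(fan.test_points)
        assert not np.any(fan.not_mineral[labs == ROOT])


class TestGrowStep:
    def test_empty_domain_lowest_bin(self, empty_volume, rng):
        cfg = GrowthConfig()
        ref = np.array([1.0, 0, 0])
        res = grow_step(np.array([400.0, 400, 400]), ref, empty_volume, cfg,
                        rng)
        assert res is not None
        _, h = res
        assert angle_between(ref, h) < np.pi / (2 * cfg.bin_count)

    def test_two_candidate_frequency(self):
        # engineer exactly two selectable candidates and count choices
        cfg = GrowthConfig()
        fan = build_fan(np.zeros(3), np.array([1.0, 0, 0]), cfg.step_length,
                        cfg.fan_size, cfg.bin_count)
        in_bin1 = np.flatnonzero(fan.bin_index == 1)
        keep = in_bin1[:2]
        assert len(keep) == 2
        labels = np.full((40, 40, 40), MINERAL, dtype=np.uint8)
        vol = PhaseVolume(labels, 5.0, origin=np.array([-100.0, -100, -100]))
        idx = vol.voxel_index(fan.test_points[keep])
        labels[idx[:, 0], idx[:, 1], idx[:, 2]] = PORE
        tip_idx = vol.voxel_index(np.zeros(3))[0]
        labels[tuple(tip_idx)] = PORE
        rng = np.random.default_rng(99)
        counts = {tuple(np.round(fan.test_points[k], 6)): 0 for k in keep}
        for _ in range(10_000):
            res = grow_step(np.zeros(3), np.array([1.0, 0, 0]), vol, cfg, rng)
            assert res is not None
            counts[tuple(np.round(res[0], 6))] += 1
        freqs = np.array(list(counts.values())) / 10_000
        assert len(freqs) == 2
        np.testing.assert_allclose(freqs, 0.5, atol=0.02)

    def test_all_bins_empty_terminates(self, rng):
        labels = np.full((30, 30, 30), MINERAL, dtype=np.uint8)
        labels[15, 15, 15] = PORE
        vol = PhaseVolume(labels, 10.0)
        cfg = GrowthConfig(step_length=30.0)
        res = grow_step(np.array([150.0, 150, 150]), np.array([1.0, 0, 0]),
                        vol, cfg, rng)
        assert res is None


def _center_seed(vol, heading=(1.0, 0.0, 0.0)):
    c = (np.array(vol.shape) - 1) * vol.voxel_size / 2
    c[0] = 0.0
    return HairSeed(c, np.array(heading))


class TestGrowHair:
    def test_exact_length_and_segments(self, empty_volume, rng):
        # l_v = 500, r = 32: 15 full steps + one 20 µm remainder
        seed = _center_seed(empty_volume)
        cfg = GrowthConfig(condition_A="A0")
        path = grow_hair(seed, 500.0, empty_volume, cfg, rng)
        assert not path.terminated_early
        assert path.achieved_length == pytest.approx(500.0, abs=1e-9)
        assert len(path.vertices) == 17  # 16 segments
        d = np.linalg.norm(np.diff(path.vertices, axis=0), axis=1)
        np.testing.assert_allclose(d[:-1], 32.0, atol=1e-9)
        assert d[-1] == pytest.approx(20.0, abs=1e-9)

    def test_zero_length(self, empty_volume, rng):
        path = grow_hair(_center_seed(empty_volume), 0.0, empty_volume,
                         GrowthConfig(), rng)
        assert len(path.vertices) == 1
        assert path.achieved_length == 0.0

    def test_trapped(self, rng):
        labels = np.full((30, 30, 30), MINERAL, dtype=np.uint8)
        labels[15, 15, 15] = PORE
        vol = PhaseVolume(labels, 10.0)
        seed = HairSeed(np.array([150.0, 150, 150]), np.array([1.0, 0, 0]))
        path = grow_hair(seed, 100.0, vol, GrowthConfig(step_length=30.0), rng)
        assert path.terminated_early
        assert path.termination_reason == "trapped"
        assert len(path.vertices) == 1

    def test_seed_in_mineral_errors(self, rng):
        vol = make_sphere_volume(100, 4, pad_um=30)
        c = (np.array(vol.shape) - 1) * vol.voxel_size / 2
        with pytest.raises(ValueError, match="mineral"):
            grow_hair(HairSeed(c, np.array([1.0, 0, 0])), 100.0, vol,
                      GrowthConfig(), rng)

    def test_no_vertex_in_mineral_or_root(self, three_phase_volume, rng):
        surf = extract_surface(three_phase_volume, cartesian_face(0, "low"))
        seeds = sample_transition_points(surf, 60, rng,
                                         volume=three_phase_volume)
        la = assign_lengths(seeds, FixedLength(500))
        cfg = GrowthConfig(condition_A="A1", rng_seed=5)
        for p in grow_population(seeds, la, three_phase_volume, cfg):
            labs = three_phase_volume.label_at(p.vertices)
            assert not np.any((labs == MINERAL) | (labs == ROOT))

    def test_a0_max_deviation_vs_initial(self, three_phase_volume, rng):
        seed = _center_seed(three_phase_volume)
        cfg = GrowthConfig(condition_A="A0", rng_seed=2)
        path = grow_hair(seed, 400.0, three_phase_volume, cfg, rng)
        for h in path.headings:
            assert angle_between(seed.heading, h) <= np.pi / 2 + 1e-12

    def test_a1_max_deviation_consecutive(self, three_phase_volume, rng):
        seed = _center_seed(three_phase_volume)
        cfg = GrowthConfig(condition_A="A1", rng_seed=2)
        path = grow_hair(seed, 400.0, three_phase_volume, cfg, rng)
        for h_prev, h_next in zip(path.headings[:-1], path.headings[1:]):
            assert angle_between(h_prev, h_next) <= np.pi / 2 + 1e-12

    def test_a0_straightness_in_empty_domain(self, empty_volume, rng):
        cfg = GrowthConfig(condition_A="A0")
        for trial in range(5):
            path = grow_hair(_center_seed(empty_volume), 500.0, empty_volume,
                             cfg, np.random.default_rng(trial))
            assert path.chord >= 500.0 * np.cos(np.pi / (2 * cfg.bin_count))

    def test_f1_confinement_along_path(self, rng):
        # slab of textural phase; hair seeded inside must stay inside
        labels = np.full((100, 40, 40), PORE, dtype=np.uint8)
        labels[:, :, :20] = TEXTURAL
        vol = PhaseVolume(labels, 10.0)
        seed = HairSeed(np.array([5.0, 200.0, 100.0]), np.array([1.0, 0, 0]))
        cfg = GrowthConfig(condition_A="A1", condition_F="F1", rng_seed=8)
        path = grow_hair(seed, 500.0, vol, cfg, rng)
        labs = vol.label_at(path.vertices)
        first_s = np.argmax(labs == TEXTURAL)
        assert np.all(labs[first_s:] == TEXTURAL)


class TestNoTunnelling:
    def test_penetration_depth_bounded(self):
        """Endpoint-only collision tests allow shallow grazing of grain
        surfaces but never traversal through grain cores: the deepest
        mineral-phase penetration of any 1 µm path sample stays well below
        the grain radius."""
        vol = generate_sphere_packing("BCC", 90, 720, 6)
        surf = extract_surface(vol, cartesian_face(0, "low"))
        rng = np.random.default_rng(4)
        seeds = sample_transition_points(surf, 100, rng, volume=vol)
        la = assign_lengths(seeds, FixedLength(500))
        cfg = GrowthConfig(condition_A="A1", rng_seed=4)
        paths = grow_population(seeds, la, vol, cfg)
        # depth inside the mineral phase, µm
        depth = ndimage.distance_transform_edt(vol.labels == MINERAL) \
            * vol.voxel_size
        max_depth = 0.0
        for p in paths:
            v = p.vertices
            for a, b in zip(v[:-1], v[1:]):
                L = np.linalg.norm(b - a)
                n = max(1, int(np.ceil(L)))
                t = (np.arange(n) + 0.5) / n
                pts = a + t[:, None] * (b - a)
                idx = vol.voxel_index(pts)
                d = depth[idx[:, 0], idx[:, 1], idx[:, 2]]
                max_depth = max(max_depth, float(d.max()))
        assert max_depth < 45.0 / 2  # far below the 45 µm grain radius


class TestGrowPopulation:
    def test_reproducible(self, empty_volume, rng):
        surf = extract_surface(empty_volume, cartesian_face(0, "low"))
        seeds = sample_transition_points(surf, 40, np.random.default_rng(1))
        la = assign_lengths(seeds, FixedLength(200))
        cfg = GrowthConfig(condition_A="A1", rng_seed=11)
        a = grow_population(seeds, la, empty_volume, cfg)
        b = grow_population(seeds, la, empty_volume, cfg)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.vertices, pb.vertices)

    def test_control_full_growth_419_seeds(self):
        vol = uniform_volume(1860, 12)
        surf = extract_surface(vol, cartesian_face(0, "low"))
        seeds = sample_transition_points(surf, 121, np.random.default_rng(0))
        assert len(seeds) == 419
        la = assign_lengths(seeds, FixedLength(500))
        paths = grow_population(seeds, la, vol, GrowthConfig(rng_seed=1))
        assert len(paths) == 419
        assert not any(p.terminated_early for p in paths)
        assert all(abs(p.achieved_length - 500) < 1e-9 for p in paths)

    def test_replicates_distinct(self, empty_volume):
        surf = extract_surface(empty_volume, cartesian_face(0, "low"))
        seeds = sample_transition_points(surf, 20, np.random.default_rng(2))
        la = assign_lengths(seeds, FixedLength(300))
        reps = [grow_population(seeds, la, empty_volume,
                                GrowthConfig(condition_A="A1", rng_seed=s))
                for s in range(1, 11)]
        for i in range(10):
            for j in range(i + 1, 10):
                assert not np.array_equal(reps[i][0].vertices,
                                          reps[j][0].vertices)

    def test_mismatched_lengths_error(self, empty_volume, rng):
        surf = extract_surface(empty_volume, cartesian_face(0, "low"))
        seeds = sample_transition_points(surf, 20, rng)
        la = assign_lengths(seeds[:-1], FixedLength(300))
        with pytest.raises(ValueError):
            grow_population(seeds, la, empty_volume, GrowthConfig())


class TestGrowthConfig:
    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GrowthConfig(step_length=0)
        with pytest.raises(ValueError):
            GrowthConfig(fan_size=4)
        with pytest.raises(ValueError):
            GrowthConfig(condition_A="A2")

    def test_bin_width(self):
        assert GrowthConfig(bin_count=4).bin_width == pytest.approx(np.pi / 8)
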