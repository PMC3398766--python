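"""Contrast vectors, Welch t maps, clusters, voxel categorisation, foci."""

import json

import numpy as np
import pytest
from scipy import stats

from modfilt import maps


def eye_affine(scale=2.0):
    A = np.diag([scale, scale, scale, 1.0])
    return A


class TestContrasts:
    def test_published_contrast_weights(self):
        assert maps.contrast_vector("all_sound_vs_silence").tolist() == [1, 1, 1, 1, -4]
        assert maps.contrast_vector("meaningless_vs_silence").tolist() == [0, 0, 1, 1, -2]
        assert maps.contrast_vector("category_animal").tolist() == [1, -1, -1, 1, 0]

    def test_tool_contrast_is_reverse_of_animal(self):
        assert np.array_equal(
            maps.contrast_vector("category_tool"),
            -maps.contrast_vector("category_animal"),
        )

    def test_non_baseline_contrasts_sum_to_zero(self):
        for name, weights in maps.CONTRASTS.items():
            if weights[-1] == 0:  # contrasts not involving the silence baseline
                assert sum(weights) == 0, name
        # baseline contrasts are estimable too: weights always sum to zero
        assert all(sum(w) == 0 for w in maps.CONTRASTS.values())

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="unknown contrast"):
            maps.contrast_vector("novelty")

    def test_expansion_to_two_run_design(self):
        v = maps.expand_to_design(maps.contrast_vector("category_animal"))
        assert v.shape == (22,)  # 2 runs x (5 conditions + 6 motion)
        assert v.tolist() == [1, -1, -1, 1, 0] + [0] * 6 + [1, -1, -1, 1, 0] + [0] * 6


class TestWelch:
    def test_identical_constant_groups_give_zero_t(self):
        A = eye_affine()
        g = [maps.StatMap(values=np.ones((5, 5, 5)), affine=A) for _ in range(3)]
        t_map, _ = maps.welch_group_t_map(g, g)
        assert np.all(t_map.values == 0)

    def test_planted_effect_raises_t_inside_sphere(self):
        region = [{"center": (0.0, 0.0, 0.0), "radius": 8.0}]
        ga, gb = maps.simulate_group_maps(
            n_per_group=(8, 8), shape=(16, 16, 16), voxel_size=3.0,
            effect_regions=region, effect_size=2.0, seed=1,
        )
        t_map, _ = maps.welch_group_t_map(ga, gb)
        center_mm = np.stack(
            np.meshgrid(*[np.arange(16)] * 3, indexing="ij"), axis=-1
        ) * 3.0 + t_map.affine[:3, 3]
        inside = np.linalg.norm(center_mm, axis=-1) <= 8.0
        assert np.abs(t_map.values[inside]).mean() > np.abs(t_map.values[~inside]).mean()

    def test_degrees_of_freedom_between_welch_bounds(self):
        ga, gb = maps.simulate_group_maps(n_per_group=(5, 12), shape=(8, 8, 8), seed=2)
        _, df_map = maps.welch_group_t_map(ga, gb)
        assert np.all(df_map.values >= 4 - 1e-9)          # min(n)-1
        assert np.all(df_map.values <= 15 + 1e-9)         # na+nb-2

    def test_group_size_and_grid_checks(self):
        A = eye_affine()
        one = [maps.StatMap(values=np.zeros((4, 4, 4)), affine=A)]
        two = [maps.StatMap(values=np.zeros((4, 4, 4)), affine=A) for _ in range(2)]
        other = [maps.StatMap(values=np.zeros((5, 5, 5)), affine=A) for _ in range(2)]
        with pytest.raises(ValueError):
            maps.welch_group_t_map(one, two)
        with pytest.raises(ValueError):
            maps.welch_group_t_map(two, other)


class TestClusters:
    def test_empty_and_singleton(self):
        A = eye_affine()
        m = maps.StatMap(values=np.zeros((6, 6, 6)), affine=A, kind="t")
        assert maps.form_clusters(m, 1.0) == []
        v = np.zeros((6, 6, 6))
        v[2, 3, 4] = 5.0
        m = maps.StatMap(values=v, affine=A, kind="t")
        clusters = maps.form_clusters(m, 1.0)
        assert len(clusters) == 1 and clusters[0].extent == 1
        assert clusters[0].peak_voxel == (2, 3, 4)
        assert np.allclose(clusters[0].peak_mm, [4.0, 6.0, 8.0])

    def test_diagonal_neighbours_depend_on_connectivity(self):
        v = np.zeros((4, 4, 4))
        v[1, 1, 1] = v[1, 2, 2] = 3.0  # share an edge: 18-connected, not 6
        m = maps.StatMap(values=v, affine=eye_affine(), kind="t")
        assert len(maps.form_clusters(m, 1.0, connectivity=18)) == 1
        assert len(maps.form_clusters(m, 1.0, connectivity=6)) == 2

    def test_invalid_connectivity(self):
        m = maps.StatMap(values=np.zeros((4, 4, 4)), affine=eye_affine(), kind="t")
        with pytest.raises(ValueError):
            maps.form_clusters(m, 1.0, connectivity=10)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity, flood_fill_oracle):
        rng = np.random.default_rng(connectivity)
        for _ in range(3):
            grid = rng.random((16, 16, 16)) < 0.3
            m = maps.StatMap(
                values=grid.astype(float), affine=eye_affine(), kind="t"
            )
            ours = sorted(c.extent for c in maps.form_clusters(m, 0.5, connectivity))
            assert ours == flood_fill_oracle(grid, connectivity)


class TestCategorisation:
    def test_uniform_control_directions(self):
        A = eye_affine()
        mask = np.zeros((5, 5, 5))
        mask[1:4, 1:4, 1:4] = 1
        pos = maps.StatMap(values=np.ones((5, 5, 5)), affine=A)
        neg = maps.StatMap(values=-np.ones((5, 5, 5)), affine=A)
        lm_pos = maps.categorise_interaction_voxels(mask, pos)
        assert lm_pos.count("cyan") == 27 and lm_pos.count("magenta") == 0
        lm_neg = maps.categorise_interaction_voxels(mask, neg)
        assert lm_neg.count("magenta") == 27 and lm_neg.count("cyan") == 0
        assert lm_neg.count("outside") == 125 - 27

    def test_mixed_signs_match_per_voxel_sign_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((6, 6, 6))
        vals[0, 0, 0] = 0.0
        mask = rng.random((6, 6, 6)) < 0.5
        mask[0, 0, 0] = True
        ctrl = maps.StatMap(values=vals, affine=eye_affine())
        lm = maps.categorise_interaction_voxels(mask.astype(float), ctrl)
        codes = lm.codes
        expected = np.where(
            ~mask, codes["outside"],
            np.where(vals > 0, codes["cyan"],
                     np.where(vals < 0, codes["magenta"], codes["indeterminate"])),
        )
        assert np.array_equal(lm.labels, expected)

    def test_grid_mismatch_rejected(self):
        ctrl = maps.StatMap(values=np.ones((4, 4, 4)), affine=eye_affine())
        with pytest.raises(ValueError):
            maps.categorise_interaction_voxels(np.ones((5, 5, 5)), ctrl)


class TestFoci:
    def test_constant_map_returns_constant(self):
        m = maps.StatMap(values=np.full((8, 8, 8), 3.25), affine=eye_affine())
        foci = {"a": (2.0, 2.0, 2.0), "b": (10.0, 4.0, 6.0)}
        values = maps.sample_foci([m, m], foci)
        assert np.all(values.to_numpy() == 3.25)

    def test_single_voxel_effect_is_picked_up(self):
        v = np.zeros((8, 8, 8))
        v[3, 3, 3] = 7.0
        m = maps.StatMap(values=v, affine=eye_affine(2.0))
        values = maps.sample_foci([m], {"hit": (6.0, 6.0, 6.0), "miss": (0.0, 0.0, 0.0)})
        assert values.loc[0, "hit"] == 7.0
        assert values.loc[0, "miss"] == 0.0

    def test_translation_of_map_and_affine_is_invariant(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal((8, 8, 8))
        A = eye_affine(2.0)
        A2 = A.copy()
        A2[:3, 3] += [10.0, -4.0, 6.0]
        foci = {"f": (4.0, 4.0, 4.0)}
        shifted_foci = {"f": (14.0, 0.0, 10.0)}
        v1 = maps.sample_foci([maps.StatMap(values=v, affine=A)], foci)
        v2 = maps.sample_foci([maps.StatMap(values=v, affine=A2)], shifted_foci)
        assert v1.loc[0, "f"] == v2.loc[0, "f"]

    def test_out_of_bounds_focus_rejected(self):
        m = maps.StatMap(values=np.zeros((4, 4, 4)), affine=eye_affine())
        with pytest.raises(ValueError, match="outside"):
            maps.sample_foci([m], {"far": (1000.0, 0.0, 0.0)})

    def test_summary_interval_covers_sample_mean(self):
        rng = np.random.default_rng(5)
        ms = [
            maps.StatMap(values=rng.standard_normal((6, 6, 6)) + 2.0, affine=eye_affine())
            for _ in range(10)
        ]
        values = maps.sample_foci(ms, {"f": (5.0, 5.0, 5.0)})
        summary = maps.summarize_foci(values)
        assert summary.loc["f", "ci_low"] < summary.loc["f", "mean"] < summary.loc["f", "ci_high"]

    def test_foci_config_round_trip(self, tmp_path):
        # synthetic focus coordinates, stand-ins for the study's six labels
        foci = {
            "mSTG_L": [-55.0, -10.0, 0.0], "mSTG_R": [55.0, -10.0, 0.0],
            "pLaS_L": [-40.0, -30.0, 15.0], "pLaS_R": [40.0, -30.0, 15.0],
            "pMTG_L": [-58.0, -60.0, 5.0], "pMTG_R": [58.0, -60.0, 5.0],
        }
        path = tmp_path / "foci_synthetic.json"
        path.write_text(json.dumps(foci))
        loaded = maps.load_foci(path)
        assert set(loaded) == set(foci)
        assert np.allclose(loaded["pMTG_R"], [58.0, -60.0, 5.0])


class TestSimulation:
    def test_same_seed_reproduces_maps(self):
        a1, b1 = maps.simulate_group_maps(n_per_group=(3, 3), shape=(6, 6, 6), seed=9)
        a2, b2 = maps.simulate_group_maps(n_per_group=(3, 3), shape=(6, 6, 6), seed=9)
        assert np.array_equal(a1[0].values, a2[0].values)
        assert np.array_equal(b1[-1].values, b2[-1].values)

    def test_zero_effect_groups_are_exchangeable(self):
        ga, gb = maps.simulate_group_maps(
            n_per_group=(10, 10), shape=(12, 12, 12),
            effect_regions=[{"center": (0, 0, 0), "radius": 6.0}],
            effect_size=0.0, seed=10,
        )
        t_map, df_map = maps.welch_group_t_map(ga, gb)
        crit = stats.t.ppf(0.995, df_map.values)
        assert np.mean(np.abs(t_map.values) > crit) < 0.05

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            maps.simulate_group_maps(
                shape=(6, 6, 6),
                effect_regions=[{"center": (500.0, 0, 0), "radius": 2.0}],
            )


class TestNifti:
    def test_nifti_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        m = maps.StatMap(values=rng.standard_normal((5, 6, 7)), affine=eye_affine(3.0))
        path = tmp_path / "map.nii"
        maps.write_nifti(m, path)
        back = maps.read_nifti(path)
        assert np.allclose(back.values, m.values, atol=1e-6)
        assert np.allclose(back.affine, m.affine)
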