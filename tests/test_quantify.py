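"""Overlap statistic and core/outgrowth decomposition against oracles.

The independent oracle for volumes, inside/outside calls and the degree
of overlap is naive exhaustive voxel enumeration in pure Python loops.
"""

import dataclasses
import math

import numpy as np
import pytest

import spherolec as sl
from spherolec import ConfigurationError, GridMismatchError, UndefinedStatisticError

from conftest import make_ball_mask


# ---------------------------------------------------------------------------
# brute-force oracles (pure python; deliberately naive)


def brute_volume(voxels, voxel_size):
    n = 0
    nz, ny, nx = voxels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if voxels[z, y, x]:
                    n += 1
    return n * voxel_size[0] * voxel_size[1] * voxel_size[2]


def brute_degree(labels, lec, voxel_size, mode, tau, object_volumes):
    """Naive degree of overlap on undilated masks (lec_dilation=0)."""
    vv = voxel_size[0] * voxel_size[1] * voxel_size[2]
    v_lec = int(lec.sum()) * vv
    nz, ny, nx = labels.shape
    inter = {}
    counts = {}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                l = labels[z, y, x]
                if l > 0:
                    counts[l] = counts.get(l, 0) + 1
                    if lec[z, y, x]:
                        inter[l] = inter.get(l, 0) + 1
    if mode == "voxel":
        v_inside = sum(inter.values()) * vv
    else:
        v_inside = sum(
            object_volumes[l] for l in counts if inter.get(l, 0) / counts[l] >= tau
        )
    return v_inside / v_lec


class TestComputeVolume:
    def test_empty_mask_is_zero(self):
        assert sl.compute_volume(sl.BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))) == 0

    def test_solid_block_exact(self):
        vox = np.zeros((12, 12, 12), bool)
        vox[1:11, 1:11, 1:11] = True
        assert sl.compute_volume(sl.BinaryMask(vox, (1.0, 1.0, 1.0))) == 1000.0

    def test_rasterized_sphere_approaches_analytic_volume(self):
        mask = make_ball_mask((32, 32, 32), (32.0, 32.0, 32.0), 20.0, voxel_size=(2, 2, 2))
        analytic = 4 / 3 * math.pi * 20**3
        assert abs(sl.compute_volume(mask) - analytic) / analytic < 0.05

    def test_anisotropic_voxel_volume(self):
        vox = np.ones((2, 3, 4), bool)
        assert sl.compute_volume(sl.BinaryMask(vox, (2.0, 0.5, 0.25))) == pytest.approx(
            24 * 0.25, abs=1e-12
        )


class TestClassifyInside:
    def test_fully_inside_and_fully_outside(self):
        lec = np.zeros((8, 8, 8), bool)
        lec[:, :4, :] = True
        tnbc = np.zeros((8, 8, 8), bool)
        tnbc[2:4, 1:3, 1:3] = True
        labels = sl.label_objects(sl.BinaryMask(tnbc, (1, 1, 1)))
        params = sl.OverlapParams(lec_dilation=0.0, inside_fraction_tau=0.9)
        [r] = sl.classify_inside(labels, sl.BinaryMask(lec, (1, 1, 1)), params)
        assert r.overlap_fraction == 1.0 and r.inside
        [r] = sl.classify_inside(
            labels, sl.BinaryMask(~lec, (1, 1, 1)), sl.OverlapParams(lec_dilation=0.0,
                                                                     inside_fraction_tau=0.1)
        )
        assert r.overlap_fraction == 0.0 and not r.inside

    def test_toy_fixture_fraction_and_call(self, toy_overlap_masks):
        tnbc, lec = toy_overlap_masks
        labels = sl.label_objects(tnbc)
        params = sl.OverlapParams(lec_dilation=0.0, inside_fraction_tau=0.5)
        [r] = sl.classify_inside(labels, lec, params)
        assert r.overlap_fraction == pytest.approx(0.80, abs=1e-12)
        assert r.inside

    def test_grid_mismatch_rejected(self):
        labels = sl.label_objects(sl.BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))
        with pytest.raises(GridMismatchError):
            sl.classify_inside(labels, sl.BinaryMask(np.zeros((4, 4, 5), bool), (1, 1, 1)))


class TestDegreeOfOverlap:
    def test_disjoint_masks_zero_in_both_modes(self):
        tnbc = np.zeros((6, 6, 6), bool)
        tnbc[0:2, 0:2, 0:2] = True
        lec = np.zeros((6, 6, 6), bool)
        lec[4:6, 4:6, 4:6] = True
        labels = sl.label_objects(sl.BinaryMask(tnbc, (1, 1, 1)))
        for mode in ("object", "voxel"):
            res = sl.degree_of_overlap(
                labels, sl.BinaryMask(lec, (1, 1, 1)),
                sl.OverlapParams(mode=mode, lec_dilation=0.0, inside_fraction_tau=0.5),
            )
            assert res.degree == 0.0

    def test_toy_fixture_object_and_voxel_modes_exact(self, toy_overlap_masks):
        """100-voxel spheroid, 80 inside a 1000-voxel network, tau 0.5:
        object mode counts the whole spheroid (0.1), voxel mode counts
        the 80-voxel intersection (0.08)."""
        tnbc, lec = toy_overlap_masks
        labels = sl.label_objects(tnbc)
        obj = sl.degree_of_overlap(
            labels, lec, sl.OverlapParams(mode="object", lec_dilation=0.0,
                                          inside_fraction_tau=0.5)
        )
        vox = sl.degree_of_overlap(
            labels, lec, sl.OverlapParams(mode="voxel", lec_dilation=0.0,
                                          inside_fraction_tau=0.5)
        )
        assert obj.degree == pytest.approx(0.10, abs=1e-12)
        assert vox.degree == pytest.approx(0.08, abs=1e-12)
        assert obj.v_inside == 100.0 and vox.v_inside == 80.0
        assert obj.v_lec == 1000.0

    def test_empty_lec_mask_is_an_explicit_error(self, toy_overlap_masks):
        tnbc, lec = toy_overlap_masks
        labels = sl.label_objects(tnbc)
        empty = sl.BinaryMask(np.zeros(lec.shape, bool), lec.voxel_size, "LEC")
        with pytest.raises(UndefinedStatisticError):
            sl.degree_of_overlap(labels, empty)

    def test_matches_brute_force_enumeration_on_random_grids(self):
        """Randomized cross-check of the vectorized implementation
        against naive exhaustive voxel counting (both modes)."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            shape = tuple(rng.integers(4, 14, 3))
            labels_mask = rng.random(shape) > 0.6
            lec = rng.random(shape) > 0.6
            if not lec.any():
                continue
            lm = sl.label_objects(sl.BinaryMask(labels_mask, (1.0, 1.0, 1.0)))
            object_volumes = {r.label: r.volume for r in lm.objects}
            for mode in ("object", "voxel"):
                params = sl.OverlapParams(mode=mode, lec_dilation=0.0,
                                          inside_fraction_tau=0.5)
                got = sl.degree_of_overlap(lm, sl.BinaryMask(lec, (1.0, 1.0, 1.0)), params)
                want = brute_degree(lm.labels, lec, (1.0, 1.0, 1.0), mode, 0.5,
                                    object_volumes)
                assert got.degree == pytest.approx(want, abs=1e-12)
                assert sl.compute_volume(lm.foreground()) == pytest.approx(
                    brute_volume(labels_mask, (1.0, 1.0, 1.0)), abs=1e-12
                )


class TestDecomposition:
    def test_solid_sphere_is_nearly_all_core(self):
        mask = make_ball_mask((64, 64, 64), (32.0, 32.0, 32.0), 30.0)
        dec = sl.decompose_core_outgrowth(mask, sl.DecompParams(core_opening_radius=10.0))
        assert dec.outgrowth_volume / dec.total_volume <= 0.05
        assert not dec.all_outgrowth

    def test_sphere_with_cylinder_protrusion_split_near_truth(self):
        shape, vs = (64, 80, 64), (1.0, 1.0, 1.0)
        center = (32.0, 28.0, 32.0)
        sphere = make_ball_mask(shape, center, 20.0, vs)
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        z, y, x = [(g + 0.5) * v for g, v in zip(grids, vs)]
        # cylinder of radius 4 along +y from the sphere surface, length 30
        cyl = (
            (np.sqrt((z - center[0]) ** 2 + (x - center[2]) ** 2) <= 4.0)
            & (y >= center[1])
            & (y <= center[1] + 50.0)
        )
        cyl_only = cyl & ~sphere.voxels
        truth_cyl_volume = cyl_only.sum() * 1.0
        mask = sl.BinaryMask(sphere.voxels | cyl, vs)
        dec = sl.decompose_core_outgrowth(mask, sl.DecompParams(core_opening_radius=8.0))
        assert abs(dec.outgrowth_volume - truth_cyl_volume) / truth_cyl_volume < 0.25
        # exact partition
        assert not (dec.core_mask.voxels & dec.outgrowth_mask.voxels).any()
        np.testing.assert_array_equal(
            dec.core_mask.voxels | dec.outgrowth_mask.voxels, mask.voxels
        )
        assert dec.core_volume + dec.outgrowth_volume == dec.total_volume

    def test_thin_object_flagged_all_outgrowth(self):
        vox = np.zeros((8, 20, 8), bool)
        vox[3:5, 2:18, 3:5] = True  # 2 µm-thick rod
        dec = sl.decompose_core_outgrowth(
            sl.BinaryMask(vox, (1, 1, 1)), sl.DecompParams(core_opening_radius=5.0)
        )
        assert dec.all_outgrowth
        assert dec.core_volume == 0
        assert dec.outgrowth_volume == dec.total_volume

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            sl.decompose_core_outgrowth(
                sl.BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1)), sl.DecompParams()
            )

    def test_anisotropic_opening_matches_isotropic_geometry(self):
        """The same physical ball sampled on anisotropic voxels yields a
        core volume close to the isotropic rasterization's."""
        iso = make_ball_mask((48, 48, 48), (24, 24, 24), 15.0, (1.0, 1.0, 1.0))
        aniso = make_ball_mask((24, 48, 48), (24, 24, 24), 15.0, (2.0, 1.0, 1.0))
        p = sl.DecompParams(core_opening_radius=6.0)
        v_iso = sl.decompose_core_outgrowth(iso, p).core_volume
        v_aniso = sl.decompose_core_outgrowth(aniso, p).core_volume
        assert abs(v_iso - v_aniso) / v_iso < 0.1


class TestQuantifyExperiment:
    def _entries(self, seeds, condition="co", day=1.0):
        entries = []
        for i, seed in enumerate(seeds, start=1):
            cfg = dataclasses.replace(sl.PhantomConfig(seed=seed), grid_shape=(16, 64, 64),
                                      n_spheroids=1, network_node_count=4)
            stacks, _ = sl.generate_phantom(cfg)
            entries.append(((condition, day, i), stacks))
        return entries

    def test_partition_invariant_holds_in_table(self):
        volumes, overlaps = sl.quantify_experiment(self._entries([0]))
        by = volumes.set_index("compartment")["volume"]
        assert by["tnbc_core"] + by["tnbc_outgrowth"] == pytest.approx(
            by["tnbc_total"], abs=1e-9
        )

    def test_identical_replicates_differ_only_in_replicate_id(self):
        e = self._entries([3])
        twin = [(("co", 1.0, 2), e[0][1])]
        v1, _ = sl.quantify_experiment(e)
        v2, _ = sl.quantify_experiment(twin)
        np.testing.assert_allclose(v1["volume"], v2["volume"])
        assert (v2["replicate"] == 2).all()

    def test_duplicate_keys_rejected(self):
        e = self._entries([4])
        with pytest.raises(ConfigurationError):
            sl.quantify_experiment(e + e)

    def test_noiseless_timecourse_degree_nondecreasing_end_to_end(self):
        cfg = dataclasses.replace(sl.PhantomConfig(seed=6), noise_model=None)
        entries = []
        for day, stacks, _ in sl.generate_timecourse(cfg):
            entries.append((("co", day, 1), stacks))
        _, overlaps = sl.quantify_experiment(
            entries, overlap_params=sl.OverlapParams(mode="voxel")
        )
        degs = overlaps.sort_values("day")["degree"].to_numpy()
        assert all(b >= a - 1e-12 for a, b in zip(degs, degs[1:]))
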