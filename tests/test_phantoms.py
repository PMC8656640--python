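"""Determinism, truth bookkeeping and construction laws of the generator."""

import dataclasses

import numpy as np
import pytest

import spherolec as sl
from spherolec import ConfigurationError, PhantomConfig


class TestValidation:
    def test_association_strength_bounds(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(association_strength=1.5)

    def test_structure_too_large_for_grid_names_parameter(self):
        with pytest.raises(ConfigurationError, match="spheroid_radius_mean"):
            PhantomConfig(grid_shape=(8, 32, 32), voxel_size=(1, 1, 1),
                          spheroid_radius_mean=10.0)
        with pytest.raises(ConfigurationError, match="network_tube_radius"):
            PhantomConfig(grid_shape=(8, 64, 64), voxel_size=(1, 1, 1),
                          spheroid_radius_mean=3.0, outgrowth_length=3.0,
                          network_tube_radius=30.0)


class TestGeneratePhantom:
    def test_same_config_and_seed_bit_identical(self, small_phantom_config):
        s1, t1 = sl.generate_phantom(small_phantom_config)
        s2, t2 = sl.generate_phantom(small_phantom_config)
        for chan in ("TNBC", "LEC"):
            np.testing.assert_array_equal(s1[chan].intensities, s2[chan].intensities)
        np.testing.assert_array_equal(t1.tnbc_labels, t2.tnbc_labels)
        np.testing.assert_array_equal(t1.lec_truth_mask.voxels, t2.lec_truth_mask.voxels)
        assert t1.true_degree_voxel == t2.true_degree_voxel

    def test_noise_and_blur_off_gives_two_valued_channels(self, small_phantom_config):
        cfg = dataclasses.replace(small_phantom_config, psf_sigma=(0, 0, 0), noise_model=None)
        stacks, _ = sl.generate_phantom(cfg)
        for chan in ("TNBC", "LEC"):
            assert set(np.unique(stacks[chan].intensities)) == {
                cfg.background_level, cfg.signal_level
            }

    def test_truth_volume_bookkeeping_is_exact(self, small_phantom_config):
        _, truth = sl.generate_phantom(small_phantom_config)
        vv = float(np.prod(small_phantom_config.voxel_size))
        for s in truth.per_spheroid:
            # core/outgrowth voxel sets disjoint; union is the spheroid mask
            assert not set(s.core_indices) & set(s.outgrowth_indices)
            assert s.core_volume == len(s.core_indices) * vv
            assert s.outgrowth_volume == len(s.outgrowth_indices) * vv
            assert s.core_volume + s.outgrowth_volume == s.total_volume
            assert truth.spheroid_mask(s.label).volume == s.total_volume
        assert truth.tnbc_total_volume == truth.tnbc_truth_mask.volume
        assert truth.lec_total_volume == truth.lec_truth_mask.volume

    def test_association_dial_raises_true_overlap(self):
        """Mean true voxel-mode overlap over 100 seeds is strictly larger
        with spheroids placed on the network than placed uniformly."""
        overlaps = {0.0: [], 1.0: []}
        for a in overlaps:
            for seed in range(100):
                cfg = PhantomConfig(
                    grid_shape=(16, 64, 64), n_spheroids=2, network_node_count=4,
                    association_strength=a, seed=seed,
                )
                truth = sl.generate_truth(cfg)
                overlaps[a].append(truth.true_degree_voxel)
        assert np.mean(overlaps[1.0]) > np.mean(overlaps[0.0])

    def test_on_network_flag_matches_actual_contact(self):
        cfg = PhantomConfig(association_strength=1.0, seed=9)
        _, truth = sl.generate_phantom(cfg)
        assert all(s.inside_network for s in truth.per_spheroid)
        lec = truth.lec_truth_mask.voxels
        for s in truth.per_spheroid:
            sph = truth.spheroid_mask(s.label).voxels
            assert (sph & lec).any()  # centre on the skeleton → real contact


class TestTimecourse:
    def test_true_overlap_nondecreasing_across_days(self):
        cfg = PhantomConfig(seed=21)
        series = sl.generate_timecourse(cfg)
        degs = [t.true_degree_voxel for _, _, t in series]
        assert all(b >= a for a, b in zip(degs, degs[1:]))

    def test_core_growth_factor_reproduced_between_reference_days(self):
        """Truth core volume grows 3-4 fold between day 3 and day 6 with
        the default fold-change of 3.5."""
        cfg = dataclasses.replace(PhantomConfig(seed=22), timepoints=(3.0, 6.0))
        series = sl.generate_timecourse(cfg)
        core = {day: sum(s.core_volume for s in t.per_spheroid) for day, _, t in series}
        assert 3.0 <= core[6.0] / core[3.0] <= 4.0

    def test_single_timepoint_matches_generate_phantom(self):
        base = PhantomConfig(seed=23)
        cfg = dataclasses.replace(base, timepoints=(base.growth_ref_days[0],))
        [(day, stacks, truth)] = sl.generate_timecourse(cfg)
        ref_stacks, ref_truth = sl.generate_phantom(base)
        for chan in ("TNBC", "LEC"):
            np.testing.assert_array_equal(stacks[chan].intensities, ref_stacks[chan].intensities)
        np.testing.assert_array_equal(truth.tnbc_labels, ref_truth.tnbc_labels)

    def test_timepoints_must_be_strictly_increasing(self):
        cfg = dataclasses.replace(PhantomConfig(seed=1), timepoints=(2.0, 2.0))
        with pytest.raises(ConfigurationError):
            sl.generate_timecourse(cfg)
        with pytest.raises(ConfigurationError):
            sl.generate_timecourse(dataclasses.replace(PhantomConfig(seed=1), timepoints=()))

    def test_geometry_frozen_across_days(self):
        cfg = PhantomConfig(seed=24)
        series = sl.generate_timecourse(cfg)
        # the network is identical at every day
        ref = series[0][2].lec_truth_mask.voxels
        for _, _, truth in series[1:]:
            np.testing.assert_array_equal(truth.lec_truth_mask.voxels, ref)


def test_default_channel_density_ratio_near_one_to_five():
    """The default network-to-spheroid volume ratio echoes the 1:5
    tumor:endothelial seeding ratio of the emulated cocultures."""
    ratios = []
    for seed in range(10):
        truth = sl.generate_truth(PhantomConfig(seed=seed))
        ratios.append(truth.lec_total_volume / truth.tnbc_total_volume)
    assert 3.5 <= np.mean(ratios) <= 6.5
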