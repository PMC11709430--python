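"""Synthetic-data generator: design structure, behavioural slopes, BOLD
ground truth, RSFA, and determinism contracts."""

import numpy as np
import pytest

import compfmri as cf
from compfmri.simulate import (
    SimulationConfig,
    RegionSpec,
    _ar1_noise,
    _region_profiles,
    _rng,
    generate_design,
    region_layout,
    simulate_behaviour,
    simulate_rsfa,
)


def _cfg(**kw):
    defaults = dict(
        n_participants=20,
        grid_shape=(12, 8, 8),
        region_specs=[
            RegionSpec(label="mdn", n_voxels=32, base_contrast=0.8),
            RegionSpec(label="comp", n_voxels=32, unique_info_base=0.4),
        ],
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDesign:
    def test_default_block_structure(self):
        design = generate_design(SimulationConfig())
        assert len(design.onsets) == 8
        labels = design.labels
        assert labels.count("easy") == 4 and labels.count("hard") == 4
        # strict alternation
        assert all(a != b for a, b in zip(labels, labels[1:]))
        assert np.allclose(design.durations, 30.0)
        total_task = float(np.sum(design.durations))
        assert total_task == 240.0 <= design.n_scans * design.tr

    def test_single_block_pair(self):
        cfg = _cfg(n_blocks_per_condition=1)
        design = generate_design(cfg)
        assert len(design.onsets) == 2
        assert set(design.labels) == {"easy", "hard"}

    def test_blocks_exceeding_run_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            _cfg(block_length=40.0)  # 8 x 40 s = 320 s > 300 s

    @pytest.mark.parametrize("placement", ["split", "start", "end"])
    def test_gap_placement_keeps_blocks_in_run(self, placement):
        design = generate_design(_cfg(gap_placement=placement))
        assert np.all(design.onsets >= 0)
        assert np.all(design.onsets + design.durations <= 300.0 + 1e-9)


class TestBehaviour:
    def test_age_slope_recovered_by_ols(self):
        cfg = _cfg(n_participants=200, behav_age_slope=-0.7)
        rng = np.random.default_rng(2)
        ages = rng.uniform(*cfg.age_range, size=200)
        records = simulate_behaviour(ages, cfg, seed=3)
        perf = np.array([r.performance for r in records])
        z_age = (ages - ages.mean()) / ages.std()
        z_perf = (perf - perf.mean()) / perf.std()
        slope, intercept = np.polyfit(z_age, z_perf, 1)
        resid = z_perf - slope * z_age - intercept
        se = np.sqrt(resid.var() / (len(ages) * z_age.var()))
        assert abs(slope - (-0.7)) < 2 * se

    def test_noise_free_flat_cohort_scores_equal(self):
        cfg = _cfg(behav_age_slope=0.0, performance_sd=0.0)
        ages = np.linspace(20, 80, 12)
        records = simulate_behaviour(ages, cfg, seed=1)
        scores = {r.performance for r in records}
        assert len(scores) == 1

    def test_determinism(self):
        cfg = _cfg()
        ages = np.linspace(20, 80, 10)
        a = simulate_behaviour(ages, cfg, seed=9)
        b = simulate_behaviour(ages, cfg, seed=9)
        assert [(r.hard_correct, r.easy_correct) for r in a] == [
            (r.hard_correct, r.easy_correct) for r in b
        ]

    def test_counts_non_negative_and_bounded(self):
        cfg = _cfg(n_participants=50)
        ages = np.linspace(*cfg.age_range, 50)
        for r in simulate_behaviour(ages, cfg, seed=4):
            assert 0 <= r.hard_correct <= cfg.hard_trials
            assert 0 <= r.easy_correct <= cfg.easy_trials
            assert r.hard_incorrect == cfg.hard_trials - r.hard_correct

    def test_ages_outside_range_rejected(self):
        with pytest.raises(ValueError, match="age_range"):
            simulate_behaviour(np.array([5.0]), _cfg(), seed=0)


class TestBold:
    def test_noise_free_contrast_recovery(self):
        """With all noise sources off, the GLM recovers the configured
        contrast exactly in every region voxel."""
        spec = RegionSpec(
            label="roi", n_voxels=27, base_contrast=1.0,
            subject_sd=0.0, pattern_gain_sd=0.0,
        )
        cfg = _cfg(
            region_specs=[spec], noise_sd=0.0, noise_shared_sd=0.0,
            vascular_sd=0.0,
        )
        cohort = cf.simulate_cohort(cfg)
        rec = cohort.records[0]
        dataset, truth = cohort.bold_for(rec)
        from compfmri.glm import build_design, fit_prewhitened_glm

        design = build_design(cohort.design)
        result = fit_prewhitened_glm(dataset, design)
        cols = dataset.columns_in_mask(cohort.region_masks["roi"])
        assert truth.contrast["roi"] == pytest.approx(1.0)
        assert np.allclose(
            result.contrast[cols], truth.measured_contrast["roi"], atol=1e-6
        )

    def test_noise_autocorrelation_matches_config(self):
        """Pooled lag-1 autocorrelation of the generated noise is the
        configured AR coefficient."""
        cfg = _cfg(noise_ar1=0.3, n_participants=2)
        cohort = cf.simulate_cohort(cfg)
        dataset, _ = cohort.bold_for(cohort.records[0])
        region = np.zeros(cfg.grid_shape, dtype=bool)
        for mask in cohort.region_masks.values():
            region |= mask
        null_cols = np.setdiff1d(
            np.arange(dataset.n_voxels), dataset.columns_in_mask(region)
        )[:500]
        noise = dataset.data[:, null_cols] - cfg.baseline
        noise = noise - noise.mean(axis=0)
        num = np.sum(noise[:-1] * noise[1:])
        den = np.sum(noise**2)
        assert abs(num / den - 0.3) < 0.05

    def test_unique_pattern_orthogonal_to_mean_profile(self):
        cfg = _cfg()
        spec = cfg.region_specs[1]
        rec = cf.simulate_cohort(cfg).records[0]
        g, p = _region_profiles(spec, rec, cfg, seed=cfg.seed)
        assert abs(p.sum()) < 1e-9  # zero spatial mean
        assert abs(p @ g) < 1e-9  # carries no region-average signal
        assert np.sqrt(np.mean(p**2)) == pytest.approx(1.0)

    def test_determinism_bit_identical(self):
        cfg = _cfg(n_participants=3)
        c1 = cf.simulate_cohort(cfg)
        c2 = cf.simulate_cohort(cfg)
        d1, t1 = c1.bold_for(c1.records[1])
        d2, t2 = c2.bold_for(c2.records[1])
        assert np.array_equal(d1.data, d2.data)
        assert t1.contrast == t2.contrast

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec(label="bad", n_voxels=0)

    def test_regions_disjoint_and_sized(self):
        cfg = _cfg()
        masks = region_layout(cfg)
        overlap = np.zeros(cfg.grid_shape, dtype=int)
        for spec in cfg.region_specs:
            assert masks[spec.label].sum() == spec.n_voxels
            overlap += masks[spec.label]
        assert overlap.max() <= 1


class TestRSFA:
    def test_vascular_age_slope_recovered(self):
        spec = RegionSpec(label="roi", n_voxels=32, vascular_age_slope=-0.3)
        cfg = _cfg(n_participants=200, region_specs=[spec])
        cohort = cf.simulate_cohort(cfg)
        mask = cohort.region_masks["roi"]
        means, z_ages = [], []
        for rec in cohort.records:
            rsfa = simulate_rsfa([spec], rec, cfg)
            means.append(rsfa.values[mask].mean())
            z_ages.append(rec.z_age)
        means = np.array(means)
        z = np.array(z_ages)
        slope, intercept = np.polyfit(z, means, 1)
        resid = means - slope * z - intercept
        se = np.sqrt(resid.var() / (len(z) * z.var()))
        assert abs(slope - (-0.3)) < 2 * se

    def test_age_invariant_when_slope_zero(self):
        spec = RegionSpec(label="roi", n_voxels=32, vascular_age_slope=0.0)
        cfg = _cfg(n_participants=100, region_specs=[spec])
        cohort = cf.simulate_cohort(cfg)
        mask = cohort.region_masks["roi"]
        means = np.array(
            [simulate_rsfa([spec], r, cfg).values[mask].mean()
             for r in cohort.records]
        )
        z = np.array([r.z_age for r in cohort.records])
        slope = np.polyfit(z, means, 1)[0]
        assert abs(slope) < 0.02

    def test_always_positive(self):
        spec = RegionSpec(label="roi", n_voxels=16, vascular_age_slope=-5.0)
        cfg = _cfg(region_specs=[spec], rsfa_floor=0.05)
        cohort = cf.simulate_cohort(cfg)
        for rec in cohort.records[:5]:
            assert simulate_rsfa([spec], rec, cfg).values.min() > 0


def test_seed_helper_is_stable():
    a = _rng(5, "noise", "sub-001").standard_normal(4)
    b = _rng(5, "noise", "sub-001").standard_normal(4)
    c = _rng(5, "noise", "sub-002").standard_normal(4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_ar1_noise_marginal_variance():
    rng = np.random.default_rng(3)
    x = _ar1_noise(rng, 4000, 50, 0.5, 2.0)
    assert abs(x.std() - 2.0) < 0.1


class TestOnDiskInterface:
    def test_nifti_roundtrip(self, tmp_path):
        cfg = _cfg(n_participants=2)
        cohort = cf.simulate_cohort(cfg)
        dataset, _ = cohort.bold_for(cohort.records[0])
        img = dataset.to_nifti()
        back = cf.VoxelDataset.from_nifti(img)
        assert back.data.shape == dataset.data.shape
        # float32 storage: agreement to single precision
        assert np.allclose(back.data, dataset.data, atol=1e-3)
        assert back.tr == pytest.approx(dataset.tr)

    def test_write_cohort_layout(self, tmp_path):
        from compfmri.simulate import write_cohort

        cfg = _cfg(n_participants=2, grid_shape=(12, 8, 8))
        cohort = cf.simulate_cohort(cfg)
        artifacts = write_cohort(cohort, tmp_path, write_bold=True)
        assert (tmp_path / "participants.tsv").exists()
        assert (tmp_path / "task-cattell_events.tsv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        import nibabel as nib

        bold = nib.load(artifacts["bold_sub-001"])
        assert bold.shape == (12, 8, 8, cfg.n_scans)
        rsfa = nib.load(artifacts["rsfa_sub-001"])
        assert np.asarray(rsfa.get_fdata()).min() > 0

    def test_events_table_matches_design(self):
        cfg = _cfg()
        design = generate_design(cfg)
        frame = design.to_events_frame()
        assert list(frame.columns) == ["onset", "duration", "trial_type"]
        assert len(frame) == 8
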