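"""Group univariate analysis: scoring/exclusion, regressions, TFCE,
permutation inference, intersection ROIs and RSFA scaling.

TFCE and connected components are checked against independent brute-force
oracles (explicit per-threshold flood fill) written here.
"""

from collections import deque

import numpy as np
import pytest

from compfmri.core import ParticipantRecord, ROIMask, StatMap
from compfmri.group import (
    behaviour_regression,
    group_voxelwise,
    intersection_roi,
    permutation_inference,
    roi_regression,
    rsfa_scale,
    score_and_exclude,
    tfce_enhance,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

NEIGHBOURS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_components(mask: np.ndarray) -> list[np.ndarray]:
    """Exhaustive BFS flood fill with 26-connectivity."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        comp = np.zeros_like(mask)
        queue = deque([start])
        seen[start] = comp[start] = True
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in NEIGHBOURS:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(p, mask.shape)):
                    if mask[p] and not seen[p]:
                        seen[p] = comp[p] = True
                        queue.append(p)
        comps.append(comp)
    return comps


def tfce_flood_oracle(values, E=0.5, H=2.0, dh=0.1):
    """Threshold-sum TFCE built on the BFS flood fill."""
    pos = np.maximum(np.asarray(values, float), 0.0)
    out = np.zeros_like(pos)
    for i in range(1, int(np.floor(pos.max() / dh + 1e-9)) + 1):
        h = i * dh
        for comp in flood_fill_components(pos >= h - 1e-12):
            out[comp] += comp.sum() ** E * h**H * dh
    return out


def _records(n, rng, ages=None):
    ages = rng.uniform(20, 85, n) if ages is None else np.asarray(ages)
    out = []
    for i, age in enumerate(ages):
        hc = int(rng.integers(4, 16))
        ec = int(rng.integers(16, 32))
        out.append(
            ParticipantRecord(
                id=f"s{i:03d}", age=float(age),
                sex="F" if rng.random() < 0.5 else "M",
                hard_correct=hc, hard_incorrect=16 - hc,
                easy_correct=ec, easy_incorrect=32 - ec,
            )
        )
    return out


class TestScoreAndExclude:
    def test_performance_formula(self):
        r = ParticipantRecord(
            id="a", age=30, sex="F",
            hard_correct=10, hard_incorrect=2,
            easy_correct=20, easy_incorrect=0,
        )
        assert r.performance == 14.0

    def test_all_incorrect_flagged(self):
        good = ParticipantRecord(
            id="ok", age=30, sex="F", hard_correct=10, easy_correct=20
        )
        bad = ParticipantRecord(
            id="bad", age=40, sex="M",
            hard_incorrect=10, easy_incorrect=20,
        )
        report = score_and_exclude([good, bad])
        assert [r.id for r in report.excluded] == ["bad"]
        assert "chance" in report.reasons["bad"]

    def test_zero_trials_reason(self):
        good = ParticipantRecord(id="ok", age=30, sex="F", easy_correct=10)
        empty = ParticipantRecord(id="none", age=50, sex="M")
        report = score_and_exclude([good, empty])
        assert report.reasons["none"] == "no responses"

    def test_everyone_excluded_raises(self):
        bad = ParticipantRecord(id="b", age=30, sex="F", hard_incorrect=5)
        with pytest.raises(ValueError, match="all participants"):
            score_and_exclude([bad])

    def test_negative_counts_rejected(self):
        r = ParticipantRecord(id="n", age=30, sex="F", hard_correct=-1)
        with pytest.raises(ValueError):
            score_and_exclude([r])


class TestBehaviourRegression:
    def test_slope_recovery(self):
        import compfmri as cf

        cfg = cf.SimulationConfig(n_participants=200, behav_age_slope=-0.7)
        cohort = cf.simulate_cohort(cfg)
        table = behaviour_regression(cohort.records)
        row = table[table.term == "age"].iloc[0]
        se = row.estimate / row.t
        assert abs(row.estimate - (-0.7)) < 2 * abs(se)
        assert table.attrs["r_squared"] > 0.3

    def test_null_slope_type_one_rate(self, rng):
        """Flat cohorts should rarely produce |t| > 2."""
        n_rep = 200
        n_sig = 0
        for _ in range(n_rep):
            records = _records(40, rng)
            table = behaviour_regression(records)
            if abs(table[table.term == "age"].iloc[0].t) > 2:
                n_sig += 1
        # nominal ~5%; allow Monte-Carlo slack
        assert n_sig / n_rep <= 0.09

    def test_too_few_records(self, rng):
        with pytest.raises(ValueError):
            behaviour_regression(_records(2, rng))


class TestGroupVoxelwise:
    def test_noise_free_recovery(self, rng):
        """Maps built exactly from the model recover the slopes."""
        records = _records(40, rng)
        from compfmri.group import group_design

        x = group_design(records)
        true = dict(const=0.1, age=0.4, performance=-0.2, sex=0.05,
                    age_x_performance=0.3)
        shape = (4, 4, 4)
        signal = x @ np.array(list(true.values()))
        maps = [StatMap(np.full(shape, s)) for s in signal]
        out = group_voxelwise(maps, records)
        for term, value in true.items():
            est = out[term]["coefficient"].values
            assert np.allclose(est, value, atol=1e-10)

    def test_shuffled_ages_break_age_effect(self, rng):
        records = _records(60, rng)
        from compfmri.group import group_design

        x = group_design(records)
        shape = (3, 3, 3)
        maps = [
            StatMap(np.full(shape, 0.8 * x[i, 1]) )
            for i in range(len(records))
        ]
        out = group_voxelwise(maps, records)
        t_true = out["age"]["t"].values[1, 1, 1]
        perm = rng.permutation(len(records))
        maps_perm = [maps[i] for i in perm]
        out_p = group_voxelwise(maps_perm, records)
        t_perm = out_p["age"]["t"].values[1, 1, 1]
        assert t_true > 5
        assert abs(t_perm) < t_true / 2


class TestTFCE:
    def test_zero_map(self):
        assert tfce_enhance(np.zeros((5, 5, 5))).max() == 0.0

    def test_single_voxel_closed_form(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 1.7
        dh = 0.1
        got = tfce_enhance(vals, dh=dh)[2, 2, 2]
        heights = np.arange(dh, 1.7 + 1e-12, dh)
        expected = np.sum(1.0**0.5 * heights**2 * dh)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_monotone_in_height(self, rng):
        vals = np.abs(rng.standard_normal((5, 5, 5)))
        a = tfce_enhance(vals, dh=0.05)
        b = tfce_enhance(2 * vals, dh=0.05)
        nz = a > 0
        assert np.all(b[nz] > a[nz])

    @pytest.mark.parametrize("dh", [0.05, 0.13])
    def test_matches_flood_fill_oracle(self, rng, dh):
        for _ in range(5):
            vals = rng.standard_normal((5, 5, 5)) * 1.5
            assert np.allclose(
                tfce_enhance(vals, dh=dh), tfce_flood_oracle(vals, dh=dh),
                atol=1e-12,
            )

    def test_subthreshold_relabeling_invariance(self, rng):
        """Values below the first threshold never affect the output."""
        vals = np.abs(rng.standard_normal((5, 5, 5))) + 0.5
        dh = 0.2
        jitter = vals.copy()
        below = jitter < dh
        jitter[below] = rng.uniform(0, dh * 0.99, below.sum())
        assert np.allclose(
            tfce_enhance(vals, dh=dh), tfce_enhance(jitter, dh=dh)
        )


class TestPermutationInference:
    def test_strong_effect_survives_correction(self, rng):
        records = _records(30, rng)
        from compfmri.group import group_design

        x = group_design(records)
        shape = (6, 6, 6)
        maps = []
        for i in range(len(records)):
            vol = rng.standard_normal(shape) * 0.3
            vol[1:4, 1:4, 1:4] += 2.0 * x[i, 1]  # strong age effect
            maps.append(StatMap(vol))
        res = permutation_inference(
            maps, records, "age", n_perm=200,
            tfce_kwargs=dict(n_steps=25), seed=1,
        )
        assert res.sig_mask[2, 2, 2]
        assert not res.sig_mask[5, 5, 5]

    def test_too_few_participants(self, rng):
        records = _records(5, rng)
        maps = [StatMap(rng.standard_normal((3, 3, 3))) for _ in records]
        with pytest.raises(ValueError, match="participants"):
            permutation_inference(maps, records, "age", n_perm=100)

    def test_minimum_permutations_enforced(self, rng):
        records = _records(20, rng)
        maps = [StatMap(rng.standard_normal((3, 3, 3))) for _ in records]
        with pytest.raises(ValueError, match="n_perm"):
            permutation_inference(maps, records, "age", n_perm=50)


class TestIntersectionROI:
    def test_single_overlap_blob(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[1:4, 1:4, 1] = True  # 9 voxels
        b[2:5, 1:4, 1] = True
        b[1, 1, 1] = True
        a[4, 1:4, 1] = True
        rois = intersection_roi(a, b)
        assert len(rois) == 1
        assert rois[0].n_voxels == 10

    def test_disjoint_masks_empty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert intersection_roi(a, b) == []

    def test_components_match_flood_fill(self, rng):
        for _ in range(10):
            a = rng.random((6, 6, 6)) > 0.6
            b = rng.random((6, 6, 6)) > 0.4
            rois = intersection_roi(a, b)
            oracle = flood_fill_components(a & b)
            assert len(rois) == len(oracle)
            assert sorted(r.n_voxels for r in rois) == sorted(
                int(c.sum()) for c in oracle
            )


class TestRSFAScale:
    def test_constant_two_halves(self, rng):
        contrast = rng.standard_normal((4, 4, 4))
        assert np.allclose(
            rsfa_scale(contrast, np.full((4, 4, 4), 2.0)), contrast / 2
        )

    def test_unit_identity(self, rng):
        contrast = rng.standard_normal((4, 4, 4))
        assert np.allclose(rsfa_scale(contrast, np.ones((4, 4, 4))), contrast)

    def test_non_positive_voxels_dropped(self):
        contrast = np.ones((2, 2, 2))
        rsfa = np.ones((2, 2, 2))
        rsfa[0, 0, 0] = 0.0
        out = rsfa_scale(contrast, rsfa)
        assert np.isnan(out[0, 0, 0])
        assert np.isfinite(out).sum() == 7


class TestROIRegression:
    def _roi_and_maps(self, rng, interaction):
        records = _records(80, rng)
        from compfmri.group import group_design

        x = group_design(records)
        slopes = np.array([0.0, 0.3, 0.2, 0.0, interaction])
        shape = (4, 4, 4)
        mask = np.zeros(shape, bool)
        mask[1:3, 1:3, 1:3] = True
        maps = []
        for i in range(len(records)):
            vol = rng.standard_normal(shape) * 0.05
            vol[mask] += x[i] @ slopes
            maps.append(StatMap(vol))
        return ROIMask(mask=mask, label="roi"), maps, records

    def test_interaction_recovered(self, rng):
        roi, maps, records = self._roi_and_maps(rng, interaction=0.25)
        table = roi_regression(roi, maps, records)
        row = table[table.term == "age_x_performance"].iloc[0]
        assert row.estimate > 0.15 and row.p < 0.01

    def test_additive_region_null_interaction(self, rng):
        roi, maps, records = self._roi_and_maps(rng, interaction=0.0)
        table = roi_regression(roi, maps, records)
        row = table[table.term == "age_x_performance"].iloc[0]
        assert abs(row.t) < 2.5

    def test_bonferroni_attribute(self, rng):
        roi, maps, records = self._roi_and_maps(rng, interaction=0.0)
        table = roi_regression(roi, maps, records, n_comparisons=2)
        assert table.attrs["alpha_bonferroni"] == pytest.approx(0.025)
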