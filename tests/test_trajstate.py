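import dataclasses

import numpy as np
import pandas as pd
import pytest

from pharmsel import synthetic
from pharmsel.errors import DataError, ValidationError
from pharmsel.trajstate import (
    DEFAULT_RESIDUE_MAPS,
    FeatureSeries,
    ResidueMap,
    StateSeries,
    classify_active,
    classify_channel_open,
    classify_tail_vertical,
    classify_tm6_outward,
    compute_features,
    dihedral,
    distance,
    grouped_fraction,
    moving_average,
    standard_feature_defs,
    state_frequency,
)


def fs_from(time, **features):
    return FeatureSeries(
        simulation_id="s1", data=pd.DataFrame({"time_ns": time, **features})
    )


def dihedral_oracle(p0, p1, p2, p3):
    """Independent construction: atan2(|b1| b0.(b1 x b2), (b0 x b1).(b1 x b2))."""
    b0 = np.subtract(p1, p0)
    b1 = np.subtract(p2, p1)
    b2 = np.subtract(p3, p2)
    y = np.linalg.norm(b1) * np.dot(b0, np.cross(b1, b2))
    x = np.dot(np.cross(b0, b1), np.cross(b1, b2))
    return np.degrees(np.arctan2(y, x))


class TestGeometry:
    def test_distance_345(self):
        assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_dihedral_cis_trans(self):
        # coplanar points: cis -> 0, trans -> 180
        cis = [(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)]
        trans = [(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)]
        assert dihedral(*cis) == pytest.approx(0.0, abs=1e-12)
        assert abs(dihedral(*trans)) == pytest.approx(180.0, abs=1e-12)

    def test_dihedral_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            pts = rng.normal(size=(4, 3)) * 3.0
            got = float(dihedral(*pts))
            want = dihedral_oracle(*pts)
            # compare as angles (0 vs 360 equivalence at the seam)
            delta = (got - want + 180.0) % 360.0 - 180.0
            assert abs(delta) < 1e-9

    def test_dihedral_range(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ang = float(dihedral(*rng.normal(size=(4, 3))))
            assert -180.0 < ang <= 180.0


class TestComputeFeatures:
    def _coord_table(self):
        rows = []
        for frame in range(2):
            rows += [
                (frame, "191:CA", 0.0, 0.0, 0.0),
                (frame, "408:CA", 3.0, 4.0 + frame, 0.0),
            ]
        return pd.DataFrame(rows, columns=["frame", "atom", "x", "y", "z"])

    def test_distance_feature(self):
        rmap = ResidueMap(subtype="M2", mapping={"5.43": 191, "6.56": 408})
        fs = compute_features(
            self._coord_table(), standard_feature_defs(rmap), dt_ns=0.5
        )
        np.testing.assert_allclose(fs.feature("d_tm5_tm6"), [5.0, np.hypot(3, 5)])
        np.testing.assert_allclose(fs.time, [0.0, 0.5])

    def test_chi1_feature(self):
        rmap = ResidueMap(subtype="X", mapping={"6.52": 407})
        tbl = pd.DataFrame(
            [
                (0, "407:N", 1.0, 1.0, 0.0),
                (0, "407:CA", 1.0, 0.0, 0.0),
                (0, "407:CB", -1.0, 0.0, 0.0),
                (0, "407:CG", -1.0, -1.0, 0.0),
            ],
            columns=["frame", "atom", "x", "y", "z"],
        )
        fs = compute_features(tbl, standard_feature_defs(rmap), dt_ns=1.0)
        assert abs(fs.feature("chi1_n652")[0]) == pytest.approx(180.0)

    def test_missing_atom_names_atom_and_frame(self):
        tbl = self._coord_table().iloc[:-1]  # drop 408:CA of frame 1
        rmap = ResidueMap(subtype="M2", mapping={"5.43": 191, "6.56": 408})
        with pytest.raises(DataError, match=r"frame 1.*408:CA"):
            compute_features(tbl, standard_feature_defs(rmap), dt_ns=1.0)

    def test_default_m2_map_matches_printed_residues(self):
        m2 = DEFAULT_RESIDUE_MAPS["M2"]
        assert m2.resolve("5.43") == 191 and m2.resolve("6.56") == 408
        assert m2.resolve("4.57") == 155 and m2.resolve("6.55") == 407
        assert m2.ecl2_residue == 181
        assert DEFAULT_RESIDUE_MAPS["M4"].ecl2_residue == 190

    def test_residue_map_roundtrip(self, tmp_path):
        rmap = ResidueMap(
            subtype="M4", mapping={"6.52": 435}, ligand_tail_atom="LIG:C17", ecl2_residue=190
        )
        p = tmp_path / "m4.json"
        rmap.to_json(p)
        assert ResidueMap.from_json(p) == rmap


class TestClassifiers:
    def test_channel_open_thresholds(self):
        fs = fs_from([50.0, 51.0, 52.0, 53.0], chi1_n652=[0.0, 180.0, -50.0, 100.0])
        ss = classify_channel_open(fs)
        assert ss.values.tolist() == [True, False, False, False]

    def test_active_thresholds(self):
        fs = fs_from([50.0, 51.0, 52.0], d_tm3_tm6_ic=[11.0, 8.0, 10.0])
        assert classify_active(fs).values.tolist() == [True, False, False]

    def test_tm6_outward_thresholds(self):
        fs = fs_from([50.0, 51.0, 52.0], d_tm4_tm6=[21.0, 20.0, 20.7])
        assert classify_tm6_outward(fs).values.tolist() == [True, False, False]

    def test_tail_vertical_thresholds_and_mask(self):
        fs = fs_from([0.0, 99.0, 100.0, 150.0], d_tail_ecl2=[8.0, 8.0, 8.0, 9.5])
        ss = classify_tail_vertical(fs)
        assert ss.values.tolist() == [True, True, True, False]
        # first 100 ns masked regardless of value
        assert ss.mask.tolist() == [False, False, True, True]

    def test_equilibration_mask_is_time_based(self):
        # 50 ns exclusion independent of frame rate
        fs = fs_from([0.0, 25.0, 49.9, 50.0, 75.0], chi1_n652=[0.0] * 5)
        ss = classify_channel_open(fs)
        assert ss.mask.tolist() == [False, False, False, True, True]

    def test_missing_feature_rejected(self):
        fs = fs_from([0.0, 1.0], d_tm4_tm6=[20.0, 21.0])
        with pytest.raises(ValidationError, match="chi1_n652"):
            classify_channel_open(fs)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-180, 180, 50)
        fs = fs_from(np.arange(50.0, 100.0), chi1_n652=vals)
        ss = classify_channel_open(fs)
        perm = rng.permutation(50)
        fs2 = fs_from(np.arange(50.0, 100.0), chi1_n652=vals[perm])
        ss2 = classify_channel_open(fs2)
        assert (ss.values[perm] == ss2.values).all()


class TestStateFrequency:
    def test_all_open(self):
        ss = StateSeries("s", "x", np.arange(4.0), np.ones(4, bool), np.ones(4, bool))
        [est] = state_frequency([ss])
        assert est.fraction == 1.0 and est.n_frames_used == 4

    def test_markov_ground_truth_occupancy(self, markov_spec):
        fs = synthetic.generate_markov_trace(markov_spec)
        ss = classify_active(fs)  # emissions fully separable at the 10 A threshold
        [est] = state_frequency([ss])
        truth = fs.data.loc[fs.data["time_ns"] >= 50.0, "true_state"]
        assert est.fraction == pytest.approx(truth.mean(), abs=0)

    def test_active_only_halves_denominator(self):
        n = 100
        t = np.arange(50.0, 50.0 + n)
        target = StateSeries("s", "x", t, np.ones(n, bool), np.ones(n, bool))
        alternating = StateSeries(
            "s", "active", t, np.arange(n) % 2 == 0, np.ones(n, bool)
        )
        [est] = state_frequency([target], condition=[alternating])
        assert est.n_frames_used == n // 2

    def test_zero_eligible_frames_is_missing(self):
        ss = StateSeries("s", "x", np.arange(4.0), np.ones(4, bool), np.zeros(4, bool))
        [est] = state_frequency([ss])
        assert est.fraction is None and est.n_frames_used == 0

    def test_upsampling_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.random(40) < 0.3
        t = np.arange(50.0, 90.0)
        base = StateSeries("s", "x", t, vals, np.ones(40, bool))
        # duplicate every label at twice the frame rate
        t2 = np.arange(50.0, 90.0, 0.5)
        up = StateSeries("s", "x", t2, np.repeat(vals, 2), np.ones(80, bool))
        [a] = state_frequency([base])
        [b] = state_frequency([up])
        assert a.fraction == pytest.approx(b.fraction, abs=0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            state_frequency([])


class TestMovingAverage:
    def test_constant_unchanged(self):
        fs = fs_from(np.arange(100.0), d=np.full(100, 7.5))
        out = moving_average(fs, window_ns=30.0)
        np.testing.assert_allclose(out.feature("d"), 7.5)

    def test_impulse_plateau(self):
        n, k = 101, 9
        v = np.zeros(n)
        v[50] = 1.0
        fs = fs_from(np.arange(float(n)), d=v)
        out = moving_average(fs, window_ns=float(k) - 0.5)  # window covers k frames
        assert out.feature("d")[50] == pytest.approx(1.0 / k)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        t = np.arange(200.0) * 0.7
        v = rng.normal(size=200)
        fs = fs_from(t, d=v)
        out = moving_average(fs, window_ns=30.0)
        naive = np.array(
            [v[(t >= ti - 15.0) & (t <= ti + 15.0)].mean() for ti in t]
        )
        np.testing.assert_allclose(out.feature("d"), naive, atol=1e-12)

    def test_window_below_spacing_rejected(self):
        fs = fs_from(np.arange(0.0, 50.0, 5.0), d=np.zeros(10))
        with pytest.raises(ValidationError, match="window"):
            moving_average(fs, window_ns=1.0)

    def test_raw_series_untouched(self):
        fs = fs_from(np.arange(100.0), d=np.arange(100.0))
        _ = moving_average(fs, 30.0)
        np.testing.assert_allclose(fs.feature("d"), np.arange(100.0))


class TestGroupedFraction:
    def _series(self, target_vals, cond_vals):
        n = len(target_vals)
        t = np.arange(50.0, 50.0 + n)
        tgt = StateSeries("s", "t", t, np.asarray(target_vals, bool), np.ones(n, bool))
        cond = StateSeries("s", "c", t, np.asarray(cond_vals, bool), np.ones(n, bool))
        return [tgt], [cond]

    def test_condition_always_true_leaves_false_group_missing(self):
        tgt, cond = self._series([1, 0, 1, 1], [1, 1, 1, 1])
        out = grouped_fraction(tgt, cond, n_boot=100, seed=0)
        assert out["condition_false"] is None
        assert out["condition_true"]["fraction"] == pytest.approx(0.75)

    def test_perfect_coupling(self):
        vals = np.arange(100) % 2 == 0
        tgt, cond = self._series(vals, vals)
        out = grouped_fraction(tgt, cond, n_boot=200, seed=0)
        assert out["condition_true"]["fraction"] == 1.0
        assert out["condition_false"]["fraction"] == 0.0

    def test_independent_labels_agree_within_ci(self):
        rng = np.random.default_rng(6)
        tgt, cond = self._series(rng.random(4000) < 0.4, rng.random(4000) < 0.5)
        out = grouped_fraction(tgt, cond, n_boot=2000, seed=0)
        a, b = out["condition_true"], out["condition_false"]
        overlap = min(a["ci_high"], b["ci_high"]) - max(a["ci_low"], b["ci_low"])
        assert overlap > 0  # independence: group fractions agree within CIs
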