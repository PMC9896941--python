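"""Tests for interaction pairs, PCA pseudo-time, register shifts, cycle duration."""

import numpy as np
import pandas as pd
import pytest

from polqc import pseudotime, synthetic
from polqc.pseudotime import (
    build_pairs,
    circular_moving_average,
    cycle_duration,
    feature_matrix,
    order_profiles,
    phase_recovery_score,
    pseudo_time,
    register_shift_correlation,
    reliability_check,
)


def foci_table(rows):
    return pd.DataFrame(rows, columns=["nucleus_id", "gene_id", "z_nm", "y_nm", "x_nm", "gene_intensity"])


def cluster_table(rows):
    return pd.DataFrame(
        rows,
        columns=["nucleus_id", "cluster_id", "z_nm", "y_nm", "x_nm",
                 "ser5p_mean", "ser2p_mean", "elongation", "solidity"],
    )


class TestBuildPairs:
    def test_single_focus_single_cluster(self):
        foci = foci_table([[0, "g", 0.0, 0.0, 0.0, 5.0]])
        clus = cluster_table([[0, 1, 300.0, 400.0, 0.0, 1, 1, 1, 1]])
        pairs = build_pairs(foci, clus)
        assert len(pairs) == 1
        assert pairs.distance_nm.iloc[0] == pytest.approx(500.0)
        assert pairs.cluster_id.iloc[0] == 1

    def test_nearest_cluster_chosen(self):
        foci = foci_table([[0, "g", 0.0, 0.0, 0.0, 5.0]])
        clus = cluster_table(
            [[0, 1, 0.0, 0.0, 900.0, 1, 1, 1, 1], [0, 2, 0.0, 0.0, 200.0, 2, 2, 2, 1]]
        )
        pairs = build_pairs(foci, clus)
        assert pairs.cluster_id.iloc[0] == 2

    def test_equidistant_tie_breaks_to_lowest_id(self):
        foci = foci_table([[0, "g", 0.0, 0.0, 0.0, 5.0]])
        clus = cluster_table(
            [[0, 7, 0.0, 0.0, 300.0, 1, 1, 1, 1], [0, 2, 0.0, 0.0, -300.0, 2, 2, 2, 1]]
        )
        pairs = build_pairs(foci, clus)
        assert pairs.cluster_id.iloc[0] == 2

    def test_foci_without_cluster_dropped_with_count(self, caplog):
        import logging

        foci = foci_table([[0, "g", 0, 0, 0, 1.0], [1, "g", 0, 0, 0, 1.0]])
        clus = cluster_table([[0, 1, 0.0, 0.0, 100.0, 1, 1, 1, 1]])
        with caplog.at_level(logging.WARNING, logger="polqc.pseudotime"):
            pairs = build_pairs(foci, clus)
        assert len(pairs) == 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_pair_count_matches_generator(self):
        rng = np.random.default_rng(0)
        foci_rows, clus_rows = [], []
        expected = 0
        for nid in range(12):
            n_foci = rng.integers(0, 5)  # zero to four foci per nucleus
            has_cluster = rng.random() > 0.2
            if has_cluster:
                clus_rows.append([nid, 1, *rng.uniform(0, 5000, 3), 1, 1, 1, 1])
                expected += n_foci
            for _ in range(n_foci):
                foci_rows.append([nid, "g", *rng.uniform(0, 5000, 3), 1.0])
        pairs = build_pairs(foci_table(foci_rows), cluster_table(clus_rows))
        assert len(pairs) == expected


class TestFeatureMatrix:
    def test_columns_standardized(self):
        table, _ = synthetic.make_pair_table(synthetic.PairCycleParams(n_pairs=50, seed=0))
        std = feature_matrix(table, ("ser5p_mean", "ser2p_mean", "elongation"))
        np.testing.assert_allclose(std.matrix.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.matrix.std(axis=0), 1.0, atol=1e-12)

    def test_zero_variance_feature_dropped_with_warning(self):
        table, _ = synthetic.make_pair_table(synthetic.PairCycleParams(n_pairs=20, seed=0))
        table["flat"] = 3.0
        with pytest.warns(UserWarning, match="flat"):
            std = feature_matrix(table, ("ser5p_mean", "ser2p_mean", "flat"))
        assert "flat" not in std.feature_names

    def test_duplicating_a_pair_keeps_directions(self):
        table, _ = synthetic.make_pair_table(synthetic.PairCycleParams(n_pairs=30, seed=1))
        doubled = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        s1 = feature_matrix(table, ("ser5p_mean", "ser2p_mean"))
        s2 = feature_matrix(doubled, ("ser5p_mean", "ser2p_mean"))
        # standardized coordinates of shared rows stay proportional
        r1 = s1.matrix[0] / np.linalg.norm(s1.matrix[0])
        r2 = s2.matrix[0] / np.linalg.norm(s2.matrix[0])
        np.testing.assert_allclose(r1, r2, atol=5e-2)

    def test_too_few_pairs_rejected(self):
        table, _ = synthetic.make_pair_table(synthetic.PairCycleParams(n_pairs=8, seed=0))
        with pytest.raises(ValueError, match=">= 8"):
            feature_matrix(table.iloc[:5], ("ser5p_mean", "ser2p_mean"))


class TestPseudoTime:
    def axis_aligned_result(self):
        # ellipse with PC1 along the first column (larger variance)
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        X = np.column_stack([2.0 * np.cos(theta), np.sin(theta)])
        std = pseudotime.StandardizedFeatures(
            matrix=X, feature_names=["a", "b"],
            means=np.zeros(2), sds=np.ones(2),
        )
        return theta, pseudo_time(std)

    def test_s_in_unit_interval_and_ordering_permutation(self):
        theta, res = self.axis_aligned_result()
        assert np.all(res.s >= 0) and np.all(res.s < 1)
        assert sorted(res.ordering) == list(range(len(theta)))

    def test_atan2_convention(self):
        # (1, 0) -> 0; (0, 1) -> 0.25; negative angles wrap into [0, 1)
        assert pseudotime.angle_to_s(1.0, 0.0) == pytest.approx(0.0)
        assert pseudotime.angle_to_s(0.0, 1.0) == pytest.approx(0.25)
        assert pseudotime.angle_to_s(-1.0, 0.0) == pytest.approx(0.5)
        assert pseudotime.angle_to_s(0.0, -1.0) == pytest.approx(0.75)
        # pseudo_time applies exactly this convention to its own PCs
        _, res = self.axis_aligned_result()
        np.testing.assert_allclose(res.s, pseudotime.angle_to_s(res.pc1, res.pc2))

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.linspace(-1, 1, 20), np.linspace(-1, 1, 20)])
        std = pseudotime.StandardizedFeatures(
            matrix=X, feature_names=["a", "b"], means=np.zeros(2), sds=np.ones(2)
        )
        with pytest.raises(ValueError, match="cyclic plane"):
            pseudo_time(std)

    def test_noise_free_circular_cycle_recovery_is_exact(self):
        # quarter-offset features on an even phase grid: z-scoring keeps the
        # cycle a true circle, so the recovered angle equals the phase up to
        # the rotation/reflection gauge
        theta = np.linspace(0, 2 * np.pi, 96, endpoint=False)
        table = pd.DataFrame({"a": 2.0 * np.cos(theta), "b": 0.5 * np.sin(theta)})
        res = pseudo_time(feature_matrix(table, ["a", "b"]))
        assert phase_recovery_score(res.s, theta) > 1 - 1e-9

    def test_noise_free_default_features_recovery(self):
        # unevenly spread phase offsets make an ellipse, not a circle, in PC
        # space: ordering is monotone but the angle is slightly distorted
        params = synthetic.PairCycleParams(n_pairs=100, noise_sd=0.0, seed=3)
        table, theta = synthetic.make_pair_table(params)
        res = pseudo_time(feature_matrix(table, list(params.feature_amplitudes)))
        assert phase_recovery_score(res.s, theta) > 0.98

    @pytest.mark.parametrize("seed", range(10))
    def test_recovery_with_quarter_noise(self, seed):
        # noise_sd = 25% of unit amplitude
        params = synthetic.PairCycleParams(n_pairs=200, noise_sd=0.25, seed=seed)
        table, theta = synthetic.make_pair_table(params)
        res = pseudo_time(feature_matrix(table, list(params.feature_amplitudes)))
        assert phase_recovery_score(res.s, theta) >= 0.9

    def test_gauge_s_invariant_to_global_rotation(self):
        params = synthetic.PairCycleParams(n_pairs=64, noise_sd=0.0, seed=5)
        table, theta = synthetic.make_pair_table(params)
        res = pseudo_time(feature_matrix(table, list(params.feature_amplitudes)))
        # adding a constant to all true angles leaves the recovered circular
        # order equivalent: score is rotation-invariant by construction
        assert phase_recovery_score(res.s, theta + 1.234) == pytest.approx(
            phase_recovery_score(res.s, theta), abs=1e-9
        )

    def test_pc2_sign_flip_reverses_ordering(self):
        params = synthetic.PairCycleParams(n_pairs=40, noise_sd=0.0, seed=6)
        table, _ = synthetic.make_pair_table(params)
        res = pseudo_time(feature_matrix(table, list(params.feature_amplitudes)))
        s_flipped = np.mod(np.arctan2(-res.pc2, res.pc1) / (2 * np.pi), 1.0)
        # circular rank order reverses under reflection
        a = np.argsort(res.s)
        b = np.argsort(s_flipped)
        assert list(b) != list(a)
        # traversing the flipped order visits the original cycle backwards
        pos = {p: i for i, p in enumerate(a)}
        steps = np.diff([pos[p] for p in b])
        steps = np.mod(steps, len(a))
        assert np.all(steps == len(a) - 1)


class TestOrderProfiles:
    def test_window_one_is_raw_sorted(self):
        table, _ = synthetic.make_pair_table(synthetic.PairCycleParams(n_pairs=16, seed=0))
        s = np.linspace(0, 0.99, 16)[::-1]
        prof = order_profiles(table, s, ["ser5p_mean"], smoothing_window=1)
        np.testing.assert_array_equal(
            prof.ser5p_mean.to_numpy(), table.ser5p_mean.to_numpy()[np.argsort(s)]
        )

    def test_circular_smoothing_preserves_constant(self):
        assert np.allclose(circular_moving_average(np.full(20, 4.2), 5), 4.2)

    def test_smoothed_profile_keeps_phase(self):
        params = synthetic.PairCycleParams(
            n_pairs=128, noise_sd=0.0, seed=1,
            feature_amplitudes={"a": 1.0, "b": 1.0},
            feature_phase_offsets={"a": 0.0, "b": np.pi / 2},
        )
        table, theta = synthetic.make_pair_table(params)
        prof = order_profiles(table, theta / (2 * np.pi), ["a", "b"], smoothing_window=5)
        # peak of feature a sits near s = 0 (theta = 0), peak of b a quarter earlier
        s_peak_a = prof.s.iloc[prof.a.idxmax()]
        assert min(s_peak_a, 1 - s_peak_a) < 0.05


class TestRegisterShift:
    def test_anchor_self_shift_zero_is_one(self):
        table, _ = synthetic.make_pair_table(synthetic.PairCycleParams(n_pairs=32, seed=0))
        prof = order_profiles(table, table.true_phase / (2 * np.pi), ["ser5p_mean"])
        out = register_shift_correlation(
            prof, "ser5p_mean", features=["ser5p_mean"], n_bootstrap=100, seed=0
        )
        at_zero = out[out["shift"] == 0].correlation.iloc[0]
        assert at_zero == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_circular_autocorrelation(self):
        rng = np.random.default_rng(2)
        n = 24
        x = rng.standard_normal(n)
        prof = pd.DataFrame({"s": np.linspace(0, 0.99, n), "f": x})
        out = register_shift_correlation(
            prof, "f", features=["f"], max_shift=n // 2, n_bootstrap=100, seed=0
        )
        z = (x - x.mean()) / x.std()
        for _, row in out.iterrows():
            oracle = float(np.mean(z * np.roll(z, -int(row["shift"]))))
            assert row.correlation == pytest.approx(oracle, abs=1e-9)

    def test_quarter_offset_extremum_near_quarter_n(self):
        n = 120
        params = synthetic.PairCycleParams(
            n_pairs=n, noise_sd=0.0, seed=0,
            feature_amplitudes={"a": 1.0, "b": 1.0},
            feature_phase_offsets={"a": 0.0, "b": np.pi / 2},
        )
        table, theta = synthetic.make_pair_table(params)
        prof = order_profiles(table, theta / (2 * np.pi), ["a", "b"])
        out = register_shift_correlation(prof, "a", features=["b"], n_bootstrap=50, seed=0)
        b = out[out.feature == "b"]
        best = int(b.loc[b.correlation.idxmax(), "shift"])
        assert abs(abs(best) - n // 4) <= 2

    def test_shift_bound_enforced(self):
        table, _ = synthetic.make_pair_table(synthetic.PairCycleParams(n_pairs=16, seed=0))
        prof = order_profiles(table, table.true_phase / (2 * np.pi), ["ser5p_mean"])
        with pytest.raises(ValueError, match="max_shift"):
            register_shift_correlation(prof, "ser5p_mean", max_shift=20)

    def test_null_features_inside_null_band(self):
        rng = np.random.default_rng(3)
        n = 64
        prof = pd.DataFrame(
            {"s": np.linspace(0, 0.99, n), "a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        )
        out = register_shift_correlation(prof, "a", features=["b"], n_bootstrap=100, seed=0)
        # permutation null: sd of circular correlation ~ 1/sqrt(n)
        assert out.correlation.abs().max() < 4.0 / np.sqrt(n)


class TestReliability:
    def test_all_contact_passes(self):
        pairs = pd.DataFrame({"distance_nm": np.zeros(20)})
        rep = reliability_check(pairs, 100.0, 0.25)
        assert rep.passed and rep.contact_fraction == 1.0

    def test_no_contact_fails(self):
        pairs = pd.DataFrame({"distance_nm": np.full(20, 1e6)})
        rep = reliability_check(pairs, 100.0, 0.25)
        assert not rep.passed and rep.contact_fraction == 0.0

    def test_rare_vs_frequent_contact_gene(self):
        rng = np.random.default_rng(0)
        rare = pd.DataFrame({"distance_nm": np.where(rng.random(200) < 0.10, 50.0, 2000.0)})
        frequent = pd.DataFrame({"distance_nm": np.where(rng.random(200) < 0.60, 50.0, 2000.0)})
        assert not reliability_check(rare, 100.0, 0.25).passed
        assert reliability_check(frequent, 100.0, 0.25).passed


class TestCycleDuration:
    def test_worked_example(self):
        # printed inputs: pair counts 169/186/191, 50 steps corresponding to 10 s
        per_gene, mean = cycle_duration([169, 186, 191], 50, 10.0)
        np.testing.assert_allclose(per_gene, [33.8, 37.2, 38.2])
        assert mean == pytest.approx(36.4)

    def test_count_equals_steps_gives_calibration_time(self):
        per_gene, mean = cycle_duration([50], 50, 10.0)
        assert per_gene == [10.0] and mean == 10.0

    def test_linearity_in_counts(self):
        _, m1 = cycle_duration([100, 200], 50, 10.0)
        _, m2 = cycle_duration([200, 400], 50, 10.0)
        assert m2 == pytest.approx(2 * m1)

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError, match="steps"):
            cycle_duration([100], 0, 10.0)
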