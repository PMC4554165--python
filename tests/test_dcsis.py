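"""Distance correlation and DC-SIS screening: oracle equivalence,
closed-form values, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirscar import (SimulationConfig, simulate_dataset,
                     distance_covariance_sq, distance_correlation_sq,
                     model_size, dcsis_screen, DCSIS)
from mirscar.errors import InputError
from mirscar.preprocess import log2_transform


def brute_force_dcov_sq(x, y):
    """Independent O(m^2) double-loop oracle; shares no helpers with the
    implementation under test."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    m = len(x)
    a = [[abs(x[k] - x[l]) for l in range(m)] for k in range(m)]
    b = [[abs(y[k] - y[l]) for l in range(m)] for k in range(m)]
    a_row = [sum(row) / m for row in a]
    a_col = [sum(a[k][l] for k in range(m)) / m for l in range(m)]
    a_all = sum(a_row) / m
    b_row = [sum(row) / m for row in b]
    b_col = [sum(b[k][l] for k in range(m)) / m for l in range(m)]
    b_all = sum(b_row) / m
    total = 0.0
    for k in range(m):
        for l in range(m):
            A = a[k][l] - a_row[k] - a_col[l] + a_all
            B = b[k][l] - b_row[k] - b_col[l] + b_all
            total += A * B
    return total / (m * m)


class TestDistanceCovariance:
    def test_two_point_hand_value(self):
        """x = y = (0,1): A = B = [[-.5,.5],[.5,-.5]], dCov^2 = 1/4."""
        assert distance_covariance_sq([0, 1], [0, 1]) == pytest.approx(0.25)

    def test_constant_y_gives_zero(self):
        assert distance_covariance_sq([1.0, 2.0, 5.0],
                                      [3.0, 3.0, 3.0]) == 0.0

    def test_quadratic_pair_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x ** 2
        assert distance_covariance_sq(x, y) == pytest.approx(
            brute_force_dcov_sq(x, y), abs=1e-12)

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = rng.integers(2, 51)
            x = rng.normal(size=m)
            y = rng.normal(size=m)
            assert distance_covariance_sq(x, y) == pytest.approx(
                brute_force_dcov_sq(x, y), abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(InputError):
            distance_covariance_sq([1.0], [2.0])
        with pytest.raises(InputError):
            distance_covariance_sq([1.0, 2.0], [1.0, 2.0, 3.0])


class TestDistanceCorrelation:
    def test_affine_relation_gives_one(self):
        x = np.array([0.3, 1.7, 2.2, 5.0, -1.0])
        assert distance_correlation_sq(x, 2.0 * x + 3.0) == pytest.approx(
            1.0, abs=1e-10)

    def test_constant_input_gives_zero(self):
        assert distance_correlation_sq([2.0, 2.0, 2.0],
                                       [1.0, 5.0, 9.0]) == 0.0

    def test_independent_samples_small_value(self):
        """Independent N(0,1) pairs at m=1000: dCor^2 < 0.05 for at least
        95 of 100 seeds (the V-statistic carries O(1/m) bias)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            if distance_correlation_sq(x, y) < 0.05:
                hits += 1
        assert hits >= 95

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 30))
        x, y = rng.normal(size=m), rng.normal(size=m)
        v = distance_correlation_sq(x, y)
        assert 0.0 <= v <= 1.0
        assert v == distance_correlation_sq(y, x)

    def test_scale_shift_invariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = distance_correlation_sq(x, y)
        for a, b in [(3.0, 2.0), (-1.0, -0.5), (100.0, 0.01)]:
            assert distance_correlation_sq(a + b * x, y) == pytest.approx(
                base, abs=1e-10)

    def test_binary_response_recoding_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=18)
        y01 = np.repeat([0.0, 1.0], 9)
        ypm = 2.0 * y01 - 1.0
        assert distance_correlation_sq(x, y01) == pytest.approx(
            distance_correlation_sq(x, ypm), abs=1e-10)


class TestModelSize:
    @pytest.mark.parametrize("n,multiplier,expected", [
        (18, 6, 36),   # 18/ln 18 = 6.227 -> 6 -> 36
        (9, 6, 24),    # 9/ln 9 = 4.096 -> 4 -> 24
        (3, 1, 2),     # 3/ln 3 = 2.73 -> 2
    ])
    def test_natural_log_rule(self, n, multiplier, expected):
        assert model_size(n, multiplier) == expected

    def test_log_base_configurable(self):
        # base 10: 18/log10(18) = 14.34 -> 14, x6 = 84
        assert model_size(18, 6, log_base=10) == 84

    def test_small_n_rejected(self):
        with pytest.raises(InputError):
            model_size(1)


class TestScreen:
    def test_recovery_of_planted_signals(self):
        cfg = SimulationConfig(n_mirnas=500, n_patients=9, n_true_de=10,
                               effect_log2=1.5, noise_sd=0.5,
                               bias_amplitude=0.0, background_level=0.0,
                               seed=55)
        matrix, sheet, truth = simulate_dataset(cfg)
        res = dcsis_screen(log2_transform(matrix), sheet)
        assert res.d == 36 and res.n_used == 18
        assert len(truth.de_ids & res.selected_ids) >= 9

    def test_single_strong_signal_ranks_first(self):
        cfg = SimulationConfig(n_mirnas=200, n_patients=9, n_true_de=1,
                               effect_log2=4.0, noise_sd=0.3, frac_down=0.0,
                               bias_amplitude=0.0, background_level=0.0,
                               seed=56)
        matrix, sheet, truth = simulate_dataset(cfg)
        res = dcsis_screen(log2_transform(matrix), sheet)
        (planted,) = truth.de_ids
        assert res.table.iloc[0]["mirna_id"] == planted

    def test_constant_rows_fall_back_to_lexicographic(self, caplog):
        matrix = pd.DataFrame(np.ones((15, 4)),
                              index=pd.Index([f"m{i:02d}" for i in
                                              range(15)], name="mirna_id"),
                              columns=["p1_scar", "p1_normal",
                                       "p2_scar", "p2_normal"])
        sheet = pd.DataFrame({"array_id": matrix.columns,
                              "patient_id": ["p1", "p1", "p2", "p2"],
                              "condition": ["scar", "normal",
                                            "scar", "normal"]})
        import logging
        with caplog.at_level(logging.WARNING, logger="mirscar.dcsis"):
            res = DCSIS(matrix, sheet).fit()
        assert (res.table["omega"] == 0.0).all()
        d = min(res.d, 15)
        expected = sorted(matrix.index)[:d]
        assert sorted(res.selected_ids) == expected
        assert any("zero" in rec.message for rec in caplog.records)

    def test_row_order_invariance(self, small_dataset):
        matrix, sheet, _ = small_dataset
        log2 = log2_transform(matrix)
        res1 = dcsis_screen(log2, sheet)
        shuffled = log2.sample(frac=1.0, random_state=0)
        res2 = dcsis_screen(shuffled, sheet)
        assert res1.selected_ids == res2.selected_ids
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_selected_count_and_rank_permutation(self, small_dataset):
        matrix, sheet, _ = small_dataset
        res = dcsis_screen(log2_transform(matrix), sheet)
        assert int(res.table["selected"].sum()) == min(res.d,
                                                       len(res.table))
        assert sorted(res.table["rank"]) == list(range(1,
                                                       len(res.table) + 1))
        assert res.table["omega"].between(0, 1).all()

    def test_tsv_round_trip(self, small_dataset, tmp_path):
        from mirscar.dcsis import DCSISResults
        matrix, sheet, _ = small_dataset
        res = dcsis_screen(log2_transform(matrix), sheet)
        path = tmp_path / "screen.tsv"
        res.to_tsv(path)
        back = DCSISResults.from_tsv(path)
        assert back.d == res.d and back.n_used == res.n_used
        pd.testing.assert_frame_equal(res.table, back.table)
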