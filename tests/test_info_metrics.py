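import numpy as np
import pytest
from hypothesis import given, strategies as st

from _bruteforce import ais_bf, dmi_bf, ei_bf, ei_monte_carlo, entropy_bf, mi_bf, te_bf
from infoflow.info_metrics import (
    MetricParams,
    MetricResult,
    TransitionModel,
    UndersampledEmbeddingWarning,
    active_information_storage,
    delayed_mutual_information,
    effective_information,
    mutual_information,
    shannon_information,
    transfer_entropy,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

binary_seq = st.lists(st.integers(0, 1), min_size=4, max_size=12).map(
    lambda v: np.array(v, dtype=np.uint8)
)


def bernoulli_trace(p, T, seed=0):
    n_active = round(p * T)
    states = np.zeros(T, dtype=np.uint8)
    states[:n_active] = 1
    return np.random.default_rng(seed).permutation(states)


class TestShannonInformation:
    @pytest.mark.parametrize(
        "active_p, expected_2dp",
        [(0.10, 0.47), (0.90, 0.47), (0.50, 1.00)],
    )
    def test_three_reporter_scenario(self, active_p, expected_2dp):
        """Reporters active 10%, 90% and 50% of the time carry 0.47, 0.47
        and 1.00 bits: most signal is not most information."""
        value = shannon_information(bernoulli_trace(active_p, 60))
        assert round(value, 2) == expected_2dp

    def test_constant_signal_carries_no_information(self):
        assert shannon_information(np.zeros(10, dtype=np.uint8)) == 0.0
        assert shannon_information(np.ones(10, dtype=np.uint8)) == 0.0


class TestMutualInformation:
    def test_factorizing_joint_gives_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_deterministic_bijection_gives_one_bit(self):
        assert mutual_information([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(1.0)

    @given(x=binary_seq)
    def test_self_mi_is_information_content(self, x):
        assert mutual_information(x, x) == pytest.approx(
            shannon_information(x), abs=1e-12
        )

    @given(x=binary_seq, y=binary_seq)
    def test_symmetry_and_entropy_bound(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        mi = mutual_information(x, y)
        assert mi == mutual_information(y, x)
        bound = min(shannon_information(x), shannon_information(y))
        assert -1e-12 <= mi <= bound + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information([0, 1], [0, 1, 1])


class TestDelayedMutualInformation:
    @given(x=binary_seq, y=binary_seq)
    def test_lag_zero_reduces_to_plain_mi(self, x, y):
        n = min(len(x), len(y))
        assert delayed_mutual_information(x[:n], y[:n], 0) == mutual_information(
            x[:n], y[:n]
        )

    def test_shifted_copy_recovers_source_entropy(self):
        x = np.array([0, 1, 1, 0, 1, 0, 0, 1, 0], dtype=np.uint8)
        y = np.concatenate([[0], x[:-1]]).astype(np.uint8)  # right-shift by 1
        value = delayed_mutual_information(x, y, 1)
        assert value == pytest.approx(entropy_bf(x[:8]), abs=1e-12)
        assert value == pytest.approx(1.0)

    def test_in_phase_oscillators_show_spurious_lagged_correlation(self):
        """Two independent alternating signals in phase: 1 bit of lagged MI
        with no coupling at all (the segmentation-clock trap)."""
        t = np.arange(9)
        wave = (t % 2).astype(np.uint8)
        assert delayed_mutual_information(wave, wave.copy(), 1) == pytest.approx(1.0)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            delayed_mutual_information([0, 1, 0], [0, 1, 1], 3)


class TestActiveInformationStorage:
    def test_alternating_series_is_fully_self_predictable(self):
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0], dtype=np.uint8)
        assert active_information_storage(x, 1) == pytest.approx(1.0)

    def test_constant_series_stores_nothing(self):
        assert active_information_storage(np.zeros(10, dtype=np.uint8), 3) == 0.0

    def test_period_four_word_needs_two_frames_of_history(self):
        x = np.array([0, 0, 1, 1] * 4, dtype=np.uint8)
        k1 = active_information_storage(x, 1)
        k2 = active_information_storage(x, 2)
        # frozen brute-force joint-count values for this exact word
        assert k1 == pytest.approx(0.003685168498985914, abs=1e-12)
        assert k2 == pytest.approx(0.9852281360342515, abs=1e-12)
        assert k2 >= k1

    @given(x=binary_seq)
    def test_reduces_to_self_dmi_at_unit_history(self, x):
        assert active_information_storage(x, 1) == pytest.approx(
            dmi_bf(list(x), list(x), 1), abs=1e-12
        )

    def test_history_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            active_information_storage([0, 1, 0], 2)

    def test_undersampled_embedding_warns(self):
        x = np.tile([0, 1], 10).astype(np.uint8)
        with pytest.warns(UndersampledEmbeddingWarning):
            active_information_storage(x, 4)


class TestTransferEntropy:
    def test_deterministic_target_admits_no_transfer(self):
        target = np.tile([0, 1], 6).astype(np.uint8)
        source = np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1, 0], dtype=np.uint8)
        assert transfer_entropy(source, target, 1, 1) == 0.0

    def test_common_driver_shows_correlation_without_transfer(self):
        # odd length so the 12 lag-1 pairs are exactly balanced
        driver = np.resize([0, 1], 13).astype(np.uint8)
        a, b = driver.copy(), driver.copy()
        assert delayed_mutual_information(a, b, 1) == pytest.approx(1.0)
        assert transfer_entropy(a, b, 1, 1) == 0.0
        assert transfer_entropy(b, a, 1, 1) == 0.0

    def test_lagged_copy_of_balanced_word_transfers_about_one_bit(self):
        source = np.array(([0, 0, 1, 1] * 5)[:17], dtype=np.uint8)
        target = np.concatenate([[0], source[:-1]]).astype(np.uint8)
        value = transfer_entropy(source, target, 1, 1)
        assert value == pytest.approx(
            te_bf(list(source), list(target), 1, 1), abs=1e-12
        )
        assert value > 0.95

    @given(x=binary_seq, y=binary_seq)
    def test_bounded_by_target_conditional_entropy(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        te = transfer_entropy(y, x, 1, 1)
        # H(x+ | x-history) = H(x+, xh) - H(xh), from brute-force counts
        pairs = list(zip(x[:-1], x[1:]))
        h_cond = entropy_bf([2 * a + b for a, b in pairs]) - entropy_bf(x[:-1])
        assert -1e-12 <= te <= h_cond + 1e-12

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            transfer_entropy([0, 1, 0], [0, 1, 1], 2, 2)


class TestEffectiveInformation:
    def test_permutation_map_is_fully_controllable(self):
        assert effective_information(np.eye(4)) == pytest.approx(2.0)

    def test_constant_map_is_uncontrollable(self):
        m = np.tile([0.0, 1.0, 0.0], (3, 1))
        assert effective_information(m) == 0.0

    def test_noisy_two_state_switch_matches_closed_form(self):
        m = [[0.9, 0.1], [0.1, 0.9]]
        expected = 1.0 - entropy_bf([1] * 9 + [0])  # 1 - H(0.9)
        assert effective_information(m) == pytest.approx(expected, abs=1e-12)
        assert effective_information(m) == pytest.approx(ei_bf(m), abs=1e-12)

    def test_matches_monte_carlo_interventional_sampler(self, rng):
        m = [[0.7, 0.2, 0.1], [0.1, 0.1, 0.8], [0.5, 0.5, 0.0]]
        mc = ei_monte_carlo(m, 200_000, rng)
        assert effective_information(m) == pytest.approx(mc, abs=0.01)

    @given(seed=st.integers(0, 1000))
    def test_invariant_under_simultaneous_state_relabeling(self, seed):
        local = np.random.default_rng(seed)
        m = local.dirichlet(np.ones(4), size=4)
        perm = local.permutation(4)
        relabeled = m[np.ix_(perm, perm)]
        assert effective_information(relabeled) == pytest.approx(
            effective_information(m), abs=1e-12
        )

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            effective_information(np.array([[0.5, 0.4], [0.1, 0.9]]))

    def test_custom_intervention_distribution(self):
        m = np.eye(2)
        # a deterministic intervention has zero entropy to transfer
        assert effective_information(
            TransitionModel(m), intervention=np.array([1.0, 0.0])
        ) == pytest.approx(0.0)


class TestOracleEquivalence:
    """Vectorized estimators agree with explicit joint-count enumeration."""

    @given(x=binary_seq, y=binary_seq, k=st.integers(1, 2), l=st.integers(1, 2),
           lag=st.integers(0, 2))
    def test_all_metrics_match_brute_force(self, x, y, k, l, lag):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        assert shannon_information(x) == pytest.approx(entropy_bf(x), abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(mi_bf(x, y), abs=1e-12)
        assert delayed_mutual_information(x, y, lag) == pytest.approx(
            dmi_bf(list(x), list(y), lag), abs=1e-12
        )
        if n >= k + 2:
            assert active_information_storage(x, k) == pytest.approx(
                ais_bf(list(x), k), abs=1e-12
            )
        if n >= max(k, l) + 2:
            assert transfer_entropy(y, x, k, l) == pytest.approx(
                te_bf(list(y), list(x), k, l), abs=1e-12
            )


class TestParamsAndResults:
    def test_metric_params_validation(self):
        with pytest.raises(ValueError):
            MetricParams(history_k=0)
        with pytest.raises(ValueError):
            MetricParams(lag_u=-1)

    def test_metric_result_rejects_negative_values(self):
        with pytest.raises(ValueError):
            MetricResult("mi", -0.1, "a", "b")

    def test_metric_result_significance_flag(self):
        r = MetricResult("te", 0.5, "a", "b", p_value=0.01)
        assert r.significant is True
        assert MetricResult("te", 0.5, "a", "b").significant is None
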