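import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairflow.errors import AlignmentError, LagRangeError, ParameterError
from pairflow.infotheory import (
    TLMICurve,
    entropy_bits,
    half_decay_time,
    mutual_information,
    peak_summary,
    permissible_states,
    tlmi,
    tlmi_curve,
    transfer_entropy,
)
from pairflow.trajectory_io import SymbolSeries


def sym(values, bits, dt=1.0):
    return SymbolSeries(symbols=np.asarray(values), bits=bits, time_step_s=dt)


# --- independent oracles (naive enumeration; deliberately unvectorized) ----


def mi_oracle(a, b):
    """Plug-in MI by explicit double sum over the joint histogram."""
    n = len(a)
    pa, pb, pab = {}, {}, {}
    for x, y in zip(a, b):
        pa[x] = pa.get(x, 0) + 1
        pb[y] = pb.get(y, 0) + 1
        pab[(x, y)] = pab.get((x, y), 0) + 1
    total = 0.0
    for (x, y), c in pab.items():
        pj = c / n
        total += pj * np.log2(pj / ((pa[x] / n) * (pb[y] / n)))
    return total


def cond_entropy_oracle(target, given_rows):
    """H(target | given) from explicit joint counts."""
    n = len(target)
    joint, marg = {}, {}
    for i in range(n):
        g = tuple(row[i] for row in given_rows)
        joint[(target[i], g)] = joint.get((target[i], g), 0) + 1
        marg[g] = marg.get(g, 0) + 1
    return -sum(
        (c / n) * np.log2(c / marg[g]) for (t, g), c in joint.items()
    )


def te_oracle(src, tgt, h):
    """Schreiber TE by direct conditional-entropy enumeration."""
    n = len(tgt)
    tgt_now = [tgt[i] for i in range(h, n)]
    tgt_hist = [[tgt[i - k] for i in range(h, n)] for k in range(1, h + 1)]
    src_hist = [[src[i - k] for i in range(h, n)] for k in range(1, h + 1)]
    return cond_entropy_oracle(tgt_now, tgt_hist) - cond_entropy_oracle(
        tgt_now, tgt_hist + src_hist
    )


# ---------------------------------------------------------------------------


class TestMutualInformation:
    def test_uniform_cycling_series_saturates_at_two_bits(self):
        s = sym(np.tile([0, 1, 2, 3], 100), bits=2)
        assert mutual_information(s, s) == pytest.approx(2.0, abs=1e-12)

    def test_independent_uniform_sequences_near_zero(self, rng):
        a = sym(rng.integers(0, 4, 20000), bits=2)
        b = sym(rng.integers(0, 4, 20000), bits=2)
        assert mutual_information(a, b) < 0.01

    def test_matches_enumeration_oracle(self, rng):
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        got = mutual_information(sym(a, 1), sym(b, 1))
        assert got == pytest.approx(mi_oracle(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            mutual_information(sym([0, 1], 1), sym([0, 1, 0], 1))

    @given(
        st.lists(st.integers(0, 3), min_size=4, max_size=60),
        st.lists(st.integers(0, 3), min_size=4, max_size=60),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_marginal_entropies(self, a, b):
        m = min(len(a), len(b))
        sa, sb = sym(a[:m], 2), sym(b[:m], 2)
        mi = mutual_information(sa, sb)
        assert -1e-12 <= mi <= min(entropy_bits(sa), entropy_bits(sb)) + 1e-12


class TestTLMI:
    def test_delayed_copy_peaks_at_minus_delay(self, rng):
        # v_t = u_{t-3}: U leads V, so the peak sits at negative lag
        u = rng.integers(0, 4, 400)
        v = np.roll(u, 3)
        curve = tlmi_curve(sym(u, 2), sym(v, 2), max_lag_s=10.0)
        assert curve.lag_steps[np.argmax(curve.values_bits)] == -3

    def test_leading_copy_peaks_at_plus_delay(self, rng):
        # u_t = v_{t-5}: V leads U, peak at positive lag per the convention
        v = rng.integers(0, 4, 400)
        u = np.roll(v, 5)
        curve = tlmi_curve(sym(u, 2), sym(v, 2), max_lag_s=10.0)
        assert curve.lag_steps[np.argmax(curve.values_bits)] == +5

    def test_auto_curve_peaks_at_zero_with_entropy_value(self, rng):
        u = sym(rng.integers(0, 4, 300), 2)
        curve = tlmi_curve(u, u, max_lag_s=8.0)
        assert curve.lag_steps[np.argmax(curve.values_bits)] == 0
        assert curve.value_at(0) == pytest.approx(entropy_bits(u), abs=1e-12)

    def test_swap_symmetry_on_matched_windows(self, rng):
        u = sym(rng.integers(0, 4, 200), 2)
        v = sym(rng.integers(0, 4, 200), 2)
        for j in (-7, -1, 0, 2, 9):
            assert tlmi(u, v, j) == pytest.approx(tlmi(v, u, -j), abs=1e-12)

    def test_constant_series_gives_zero_curve(self):
        u = sym(np.zeros(100, dtype=int), 1)
        curve = tlmi_curve(u, u, max_lag_s=5.0)
        np.testing.assert_allclose(curve.values_bits, 0.0, atol=1e-15)

    def test_independent_series_near_flat(self, rng):
        a = sym(rng.integers(0, 4, 10000), 2)
        b = sym(rng.integers(0, 4, 10000), 2)
        curve = tlmi_curve(a, b, max_lag_s=20.0)
        assert curve.values_bits.max() < 0.01

    def test_curve_exports_two_column_csv(self, rng, tmp_path):
        u = sym(rng.integers(0, 4, 100), 2, dt=0.1)
        curve = tlmi_curve(u, u, max_lag_s=1.0)
        path = tmp_path / "curve.csv"
        curve.write_csv(path)
        header, first = path.read_text().splitlines()[:2]
        assert header == "lag_s,bits"
        assert len(first.split(",")) == 2

    def test_excessive_lag_rejected(self):
        u = sym([0, 1, 0, 1], 1)
        with pytest.raises(LagRangeError):
            tlmi(u, u, 5)


class TestPeakSummary:
    def make_curve(self, lags, values, dt=1.0, kind="cross"):
        lags = np.asarray(lags)
        return TLMICurve(lags, lags * dt, np.asarray(values, float), kind)

    def test_tie_breaks_toward_smallest_lag(self):
        cross = self.make_curve([-1, 0, 1, 2], [0.1, 0.3, 0.3, 0.1])
        auto = self.make_curve([-1, 0, 1, 2], [0.5, 1.0, 0.5, 0.2], kind="auto")
        ps = peak_summary(cross, auto, auto)
        assert ps.peak_lag_s == 0.0

    def test_tie_at_equal_magnitude_prefers_negative(self):
        cross = self.make_curve([-1, 0, 1], [0.3, 0.1, 0.3])
        auto = self.make_curve([-1, 0, 1], [0.5, 1.0, 0.5], kind="auto")
        assert peak_summary(cross, auto, auto).peak_lag_s == -1.0

    def test_half_decay_first_crossing(self):
        auto = self.make_curve([0, 1, 2], [1.0, 0.6, 0.45], kind="auto")
        assert half_decay_time(auto) == 2.0

    def test_normalization_uses_mean_auto_zero_lag(self):
        cross = self.make_curve([-1, 0, 1], [0.1, 0.4, 0.2])
        auto0 = self.make_curve([-1, 0, 1], [0.2, 1.0, 0.2], kind="auto")
        auto1 = self.make_curve([-1, 0, 1], [0.4, 3.0, 0.4], kind="auto")
        ps = peak_summary(cross, auto0, auto1)
        assert ps.normalized_height == pytest.approx(0.4 / 2.0)


class TestTransferEntropy:
    def test_copy_channel_transfers_one_bit(self, rng):
        u = rng.integers(0, 2, 8192)
        v = np.roll(u, 1)
        res = transfer_entropy(sym(u, 1), sym(v, 1), h=1)
        assert res.te_fwd_bits == pytest.approx(1.0, abs=0.01)
        assert res.te_rev_bits == pytest.approx(0.0, abs=0.01)
        assert res.delta_bits > 0.9

    def test_matches_enumeration_oracle(self, rng):
        u = rng.integers(0, 2, 200)
        v = rng.integers(0, 2, 200)
        res = transfer_entropy(sym(u, 1), sym(v, 1), h=2)
        assert res.te_fwd_bits == pytest.approx(te_oracle(u, v, 2), abs=1e-12)
        assert res.te_rev_bits == pytest.approx(te_oracle(v, u, 2), abs=1e-12)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(5):
            u = rng.integers(0, 4, 300)
            v = rng.integers(0, 4, 300)
            res = transfer_entropy(sym(u, 2), sym(v, 2), h=1)
            assert res.te_fwd_bits >= 0 and res.te_rev_bits >= 0

    def test_state_guard_warns_when_sample_starved(self, rng):
        u = sym(rng.integers(0, 4, 1000), 2)
        v = sym(rng.integers(0, 4, 1000), 2)
        with pytest.warns(UserWarning, match="permissible state count"):
            transfer_entropy(u, v, h=5)  # 4**6 = 4096 > 1000

    def test_invalid_history_rejected(self):
        u = sym([0, 1, 0, 1], 1)
        with pytest.raises(ParameterError):
            transfer_entropy(u, u, h=0)


def test_permissible_state_count_guard():
    # 4-state alphabet, history 8: 4**9 joint embedding states
    assert permissible_states(bits=2, h=8) == 262_144
    assert permissible_states(bits=1, h=1) == 4
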