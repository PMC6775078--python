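"""Unit and property tests for the contact-level model rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refutesim.model_core import (
    AgentTraits,
    EmotionBand,
    RefutationContext,
    Role,
    TransitionParams,
    apply_band_transition,
    classify_emotion,
    classify_emotions,
    compute_transmission_probability,
    expected_population_counts,
    spontaneous_activation,
    update_infected_by_spreader,
    update_same_state_pair,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestTransmissionProbability:
    @pytest.mark.parametrize(
        "w,b,a,v,expected",
        [
            (1.0, 1.0, 1.0, 1.0, 1.0),
            (0.7, 0.0, 0.9, 0.5, 0.0),
            (0.5, 0.5, 0.8, 0.8, 0.16),
        ],
    )
    def test_examples(self, w, b, a, v, expected):
        r = compute_transmission_probability(
            AgentTraits(d=1.0, w=w, b=b), RefutationContext(a=a, v=v)
        )
        assert r == pytest.approx(expected)

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            AgentTraits(d=1.0, w=1.2, b=0.5)
        with pytest.raises(ValueError):
            RefutationContext(a=-0.1, v=0.5)

    @given(w=unit, b=unit, a=unit, v=unit, bump=unit)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_in_each_factor_and_bounded(self, w, b, a, v, bump):
        base = compute_transmission_probability(
            AgentTraits(d=1.0, w=w, b=b), RefutationContext(a=a, v=v)
        )
        assert 0.0 <= base <= 1.0
        w2 = min(1.0, w + bump)
        higher = compute_transmission_probability(
            AgentTraits(d=1.0, w=w2, b=b), RefutationContext(a=a, v=v)
        )
        assert higher >= base - 1e-12
        zero = compute_transmission_probability(
            AgentTraits(d=1.0, w=0.0, b=b), RefutationContext(a=a, v=v)
        )
        assert zero == 0.0


class TestEmotionBands:
    @pytest.mark.parametrize(
        "e,band",
        [
            (0.0, EmotionBand.NEGATIVE),
            (0.33, EmotionBand.NEGATIVE),
            (0.34, EmotionBand.IMMUNE),
            (0.66, EmotionBand.IMMUNE),
            (0.661, EmotionBand.POSITIVE),
            (1.0, EmotionBand.POSITIVE),
        ],
    )
    def test_boundaries(self, e, band):
        assert classify_emotion(e) is band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_emotion(1.0001)

    def test_bands_partition_unit_interval(self):
        grid = np.linspace(0.0, 1.0, 10_000)
        codes = classify_emotions(grid)
        # every point gets exactly one band and the scalar path agrees
        assert set(np.unique(codes)) <= {0, 1, 2}
        scalar = np.array([int(classify_emotion(float(e))) for e in grid[::97]])
        np.testing.assert_array_equal(scalar, codes[::97])


class TestInfectedUpdate:
    @pytest.mark.parametrize(
        "e_r,e_s,d_r,r_sr,expected",
        [
            (0.3, 0.9, 1.0, 0.5, 0.6),
            (0.4, 0.4, 1.0, 0.7, 0.4),
            (0.4, 0.9, 1.0, 0.0, 0.4),
        ],
    )
    def test_examples(self, e_r, e_s, d_r, r_sr, expected):
        new_r, new_s = update_infected_by_spreader(e_r, e_s, d_r, r_sr)
        assert new_r == pytest.approx(expected)
        assert new_s == e_s

    @given(e_r=unit, e_s=unit, d_r=unit, r_sr=unit)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_result_clamped_and_limits(self, e_r, e_s, d_r, r_sr):
        new_r, _ = update_infected_by_spreader(e_r, e_s, d_r, r_sr)
        assert 0.0 <= new_r <= 1.0
        full, _ = update_infected_by_spreader(e_r, e_s, 1.0, 1.0)
        assert full == pytest.approx(e_s)  # full adoption limit
        decay, _ = update_infected_by_spreader(e_r, e_s, d_r, 0.0)
        assert decay == pytest.approx(d_r * e_r)  # pure self-decay limit


class TestSameStatePair:
    def test_as_printed_clamps_divergence(self):
        assert update_same_state_pair(0.8, 0.2, 1, 1, 0.5, 0.5, "as_printed") == (1.0, 0.0)

    def test_convergent_meets_halfway(self):
        e1, e2 = update_same_state_pair(0.8, 0.2, 1, 1, 0.5, 0.5, "convergent")
        assert (e1, e2) == (pytest.approx(0.5), pytest.approx(0.5))

    @pytest.mark.parametrize("variant", ["as_printed", "convergent"])
    def test_equal_pair_unchanged(self, variant):
        assert update_same_state_pair(0.4, 0.4, 1, 1, 0.9, 0.9, variant) == (0.4, 0.4)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            update_same_state_pair(0.4, 0.5, 1, 1, 0.5, 0.5, "sideways")

    @given(e1=unit, e2=unit, r=unit)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_convergent_contracts_as_printed_expands(self, e1, e2, r):
        # direct-arithmetic oracle for the gap before/after
        c1, c2 = update_same_state_pair(e1, e2, 1.0, 1.0, r, r, "convergent")
        assert abs(c1 - c2) <= abs(e1 - e2) + 1e-12
        raw1 = e1 + (e1 - e2) * r
        raw2 = e2 + (e2 - e1) * r
        assert abs(raw1 - raw2) >= abs(e1 - e2) - 1e-12  # pre-clamp expansion
        p1, p2 = update_same_state_pair(e1, e2, 1.0, 1.0, r, r, "as_printed")
        assert p1 == pytest.approx(min(1.0, max(0.0, raw1)))
        assert p2 == pytest.approx(min(1.0, max(0.0, raw2)))


class TestBandTransition:
    @pytest.mark.parametrize(
        "role,e,contacted,expected",
        [
            (Role.M, 0.70, True, Role.R),
            (Role.M, 0.50, True, Role.M),
            (Role.M, 0.20, True, Role.R),
            (Role.R, 0.50, True, Role.M),
            (Role.S, 0.50, True, Role.M),
            (Role.R, 0.80, True, Role.R),
            (Role.M, 0.70, False, Role.M),
        ],
    )
    def test_transitions(self, role, e, contacted, expected):
        assert apply_band_transition(role, e, contacted) is expected


class TestSpontaneousActivation:
    @pytest.mark.parametrize(
        "u,expected",
        [(0.05, Role.S), (0.25, Role.R), (0.95, Role.M)],
    )
    def test_interval_partition(self, u, expected):
        params = TransitionParams(f_s=0.1, f_r=0.2)
        assert spontaneous_activation(Role.M, u, params) is expected

    def test_zero_probabilities_keep_m(self):
        params = TransitionParams(f_s=0.0, f_r=0.0)
        for u in (0.0, 0.5, 0.999):
            assert spontaneous_activation(Role.M, u, params) is Role.M

    def test_non_m_pass_through(self):
        params = TransitionParams(f_s=0.5, f_r=0.5)
        assert spontaneous_activation(Role.S, 0.0, params) is Role.S

    def test_overfull_probabilities_rejected(self):
        with pytest.raises(ValueError, match="f_s"):
            TransitionParams(f_s=0.7, f_r=0.5)


class TestExpectedCounts:
    def test_examples(self):
        params = TransitionParams(f_s=0.1, f_r=0.2)
        assert expected_population_counts(10, 20, 70, params, 100) == (17, 34, 49)
        zero = TransitionParams(f_s=0.0, f_r=0.0)
        assert expected_population_counts(10, 20, 70, zero, 100) == (10, 20, 70)
        full = TransitionParams(f_s=0.5, f_r=0.5)
        assert expected_population_counts(10, 20, 70, full, 100) == (45, 55, 0)

    def test_corrupt_state_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            expected_population_counts(10, 20, 60, TransitionParams(0.1, 0.1), 100)

    @given(
        s=st.integers(0, 500),
        r=st.integers(0, 500),
        m=st.integers(0, 500),
        f_s=unit,
        f_r=unit,
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_conserves_n_and_nonnegative(self, s, r, m, f_s, f_r):
        if f_s + f_r > 1.0:
            f_s, f_r = f_s / 2, f_r / 2
        n = s + r + m
        s2, r2, m2 = expected_population_counts(
            s, r, m, TransitionParams(f_s=f_s, f_r=f_r), n
        )
        assert s2 + r2 + m2 == pytest.approx(n, abs=1e-9)
        assert m2 >= -1e-9
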