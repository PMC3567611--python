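"""Observer models: counting, expectancy, digital filters and their spectra.

The recursive filter implementations are checked against independent
direct-sum oracles that materialize the uniform ν ≤ 0 prefix explicitly
and evaluate the weighted sums with their own arithmetic.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p3dif import (DIFParams, SQUParams, amplitude_response, beta_from_gamma,
                   dif_probability, gamma_from_beta, generate_sequence,
                   long_term_schedule, mar_probability, model_trace,
                   squ_alternation_count, squ_expectancy, squ_short_count,
                   surprise)
from p3dif.observers import STIMULUS_RATE_HZ, ProbabilityTrace, _g_block, \
    dif_counts, assert_highpass
from p3dif.sequences import StimulusSequence

EVEN, BIASED = (0.5, 0.5), (0.3, 0.7)


# --------------------------------------------------------------------------
# direct-sum oracles (independent arithmetic path)
# --------------------------------------------------------------------------

def short_filter_direct(seq, k, beta_S, pad=None):
    """c_S,k(n) = (1/C_S) Σ_{ν=-pad}^{n-1} γ^{n-ν} g_k(ν), C_S = γ/(1-γ).

    The materialized prefix is sized so the truncation error γ^pad is far
    below the comparison tolerance (pad = 30 time constants)."""
    gamma = math.exp(-1.0 / beta_S)
    if pad is None:
        pad = int(30 * beta_S) + 50
    C_S = gamma / (1.0 - gamma)
    g = {nu: (1.0 / seq.K if nu <= 0 else float(seq.events[nu - 1] == k))
         for nu in range(-pad, seq.N)}
    out = []
    for n in range(1, seq.N + 1):
        out.append(sum(gamma ** (n - nu) * g[nu]
                       for nu in range(-pad, n)) / C_S)
    return np.array(out)


def long_filter_direct(seq, k, schedule):
    """Recursion-unrolled direct weights:
    c_L,k(n) = Σ_ν (1-γ_ν) Π_{u=ν+1}^{n-1} γ_u g_k(ν) + Π_{u=0}^{n-1} γ_u / K."""
    gam = schedule.gamma
    g = [1.0 / seq.K] + [float(e == k) for e in seq.events]  # index ν = 0..N
    out = []
    for n in range(1, seq.N + 1):
        total = 0.0
        for nu in range(0, n):
            w = 1.0 - gam[nu]
            for u in range(nu + 1, n):
                w *= gam[u]
            total += w * g[nu]
        prefix = 1.0 / seq.K
        for u in range(0, n):
            prefix *= gam[u]
        out.append(total + prefix)
    return np.array(out)


# --------------------------------------------------------------------------
# MAR
# --------------------------------------------------------------------------

class TestMar:
    def test_uniform_initial_prior(self, seq_even):
        assert np.allclose(mar_probability(seq_even).P[0], 0.5)

    def test_hand_count(self):
        seq = StimulusSequence(events=np.array([1, 1, 2, 1]), K=2)
        P = mar_probability(seq).P
        assert P[3, 0] == pytest.approx((2 + 1) / (3 + 2))  # P_1(4) = 0.6

    def test_exact_normalization(self, seq_biased):
        sums = mar_probability(seq_biased).P.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-12

    def test_converges_to_relative_frequency(self):
        """P_rare(n) approaches the empirical relative frequency, with the
        Laplace-smoothing gap bounded by K/(n-1+K)."""
        seq = generate_sequence(2, 2000, BIASED, seed=9)
        P = mar_probability(seq).P
        for n in (500, 1000, 2000):
            freq = np.mean(seq.events[:n - 1] == 1)
            assert abs(P[n - 1, 0] - freq) < seq.K / (n - 1 + seq.K)

    def test_observation_increases_probability(self, seq_even):
        """Seeing event k strictly raises P_k on the next trial."""
        P = mar_probability(seq_even).P
        ev = seq_even.events
        for n in range(1, seq_even.N):
            assert P[n, ev[n - 1] - 1] > P[n - 1, ev[n - 1] - 1]


# --------------------------------------------------------------------------
# SQU
# --------------------------------------------------------------------------

class TestSquShortCount:
    def test_empty_window_is_zero(self):
        seq = StimulusSequence(events=np.array([2, 2, 2, 2]), K=2)
        assert squ_short_count(seq, 1, SQUParams(P_k=EVEN)).tolist() == [0] * 4

    def test_single_and_double_lag_matches(self, squ_params):
        # s = (k, k, other): at n=2 only lag-1 match (0.6); at n=3 lags 1+2
        seq = StimulusSequence(events=np.array([1, 1, 2]), K=2)
        c = squ_short_count(seq, 1, squ_params)
        assert c[1] == pytest.approx(0.6)
        assert c[2] == pytest.approx(0.6 + 0.36)

    def test_window_limit(self, squ_params):
        # a single match beyond N_depth contributes nothing
        events = np.array([1, 2, 2, 2, 2, 2, 2])
        seq = StimulusSequence(events=events, K=2)
        assert squ_short_count(seq, 1, squ_params)[6] == 0.0


class TestSquAlternation:
    def test_first_trial_returns_zero(self, seq_even):
        assert squ_alternation_count(seq_even, 1) == 0

    def test_exhaustive_codomain_and_sign(self):
        """All binary length-6 histories: outputs lie in {-3,-2,0,2,3} with
        sign matching the repetition/alternation rule."""
        seen = set()
        for hist in itertools.product((1, 2), repeat=6):
            seq = StimulusSequence(events=np.array(hist), K=2)
            v = squ_alternation_count(seq, 6)
            seen.add(v)
            assert v in {-3, -2, 0, 2, 3}
            if v != 0:
                if hist[5] == hist[4]:
                    assert v < 0
                else:
                    assert v > 0
        assert seen == {-3, -2, 0, 2, 3}  # every level is reachable

    def test_repetition_never_positive(self):
        for hist in itertools.product((1, 2), repeat=5):
            seq = StimulusSequence(events=np.array(hist + (hist[-1],)), K=2)
            assert squ_alternation_count(seq, 6) <= 0

    def test_magnitude_grows_with_alternation_run(self):
        # runs of 2, 3 and 4 alternations before a confirming alternation
        mk = lambda ev: StimulusSequence(events=np.array(ev), K=2)
        assert squ_alternation_count(mk((1, 1, 2, 1, 2)), 5) == 2   # run 2, met
        assert squ_alternation_count(mk((1, 2, 1, 2, 1)), 5) == 3   # run 3, met
        assert squ_alternation_count(mk((1, 2, 1, 2, 1, 2)), 6) == 3
        assert squ_alternation_count(mk((1, 2, 1, 2, 2)), 5) == -3  # violated


class TestSquExpectancy:
    def test_plugin_with_zero_counts(self, squ_params):
        """First trial: E = 0.505 · 0.5 − 0.027 = 0.2255."""
        seq = StimulusSequence(events=np.array([1, 2]), K=2)
        E = squ_expectancy(seq, squ_params).P
        assert E[0, 0] == pytest.approx(0.2255)
        assert E[0, 1] == pytest.approx(0.2255)

    def test_affine_in_short_count(self, seq_even, squ_params):
        E = squ_expectancy(seq_even, squ_params).P
        for k in (1, 2):
            cS = squ_short_count(seq_even, k, squ_params)
            cA = np.array([squ_alternation_count(seq_even, n, k)
                           for n in range(1, seq_even.N + 1)], float)
            manual = 0.505 * 0.5 + 0.235 * cS - 0.033 * cA - 0.027
            assert np.allclose(E[:, k - 1], manual)

    def test_gamma_beta_mapping(self):
        assert beta_from_gamma(0.6) == pytest.approx(1.96, abs=0.005)

    def test_requires_binary_alphabet(self):
        seq = StimulusSequence(events=np.array([1, 2, 3]), K=3)
        with pytest.raises(ValueError):
            squ_expectancy(seq, SQUParams(P_k=EVEN))

    def test_missing_probabilities_rejected(self):
        with pytest.raises((TypeError, ValueError)):
            SQUParams(P_k=None)


# --------------------------------------------------------------------------
# DIF filters
# --------------------------------------------------------------------------

class TestDifShortFilter:
    def test_hand_recursion_steps(self):
        """K=2, γ_S=0.6: c(1) = 0.5 and, after observing k, c(2) = 0.7."""
        beta = beta_from_gamma(0.6)
        seq = StimulusSequence(events=np.array([1, 2]), K=2)
        cL, cS, cD = dif_counts(seq, DIFParams(beta_S=beta))
        assert cS[0, 0] == pytest.approx(0.5)
        assert cS[1, 0] == pytest.approx(0.4 * 1.0 + 0.6 * 0.5)

    @pytest.mark.parametrize("probs,seed", [(EVEN, 1), (BIASED, 2)])
    @pytest.mark.parametrize("beta_S", [1.82, 5.0])
    def test_recursion_equals_direct_sum(self, probs, seed, beta_S):
        seq = generate_sequence(2, 200, probs, seed=seed)
        _, cS, _ = dif_counts(seq, DIFParams(beta_S=beta_S))
        for k in (1, 2):
            direct = short_filter_direct(seq, k, beta_S)
            assert np.max(np.abs(cS[:, k - 1] - direct)) < 1e-10

    def test_indicator_signal_input_path(self, seq_even, dif_params):
        """Feeding a padded IndicatorSignal gives the same trace as the
        internal array path."""
        from p3dif import dif_short_filter, input_signal_g
        g = input_signal_g(seq_even, 1, pad=5)
        c = dif_short_filter(g, dif_params.beta_S)
        _, cS, _ = dif_counts(seq_even, dif_params)
        assert np.array_equal(c, cS[:, 0])
        with pytest.raises(ValueError):
            dif_short_filter(input_signal_g(seq_even, 1, pad=0), 1.82)

    def test_output_bounded_in_unit_interval(self, seq_biased, dif_params):
        _, cS, _ = dif_counts(seq_biased, dif_params)
        assert np.all(cS >= 0) and np.all(cS <= 1)

    def test_observation_increases_short_count(self, seq_even, dif_params):
        """With γ_S in (0,1), observing k raises c_S,k on the next trial."""
        _, cS, _ = dif_counts(seq_even, dif_params)
        ev = seq_even.events
        for n in range(1, seq_even.N):
            k = ev[n - 1] - 1
            assert cS[n, k] > cS[n - 1, k] or cS[n - 1, k] == 1.0


class TestLongTermSchedule:
    def test_anchor_values_as_printed(self):
        sch = long_term_schedule(33.6, 0.27, 192)
        assert round(sch.beta[1], 1) == 40.3
        assert round(sch.beta[192]) == 11787

    def test_gamma_monotone_toward_one(self):
        sch = long_term_schedule(33.6, 0.27, 192)
        assert np.all(np.diff(sch.gamma) > 0)
        assert np.all((sch.gamma > 0) & (sch.gamma < 1))

    def test_invalid_parameters(self):
        for tau1, tau2 in [(-1, 0.3), (10, 0), (0, 0.5)]:
            with pytest.raises(ValueError):
                long_term_schedule(tau1, tau2, 10)


class TestDifLongFilter:
    def test_initial_uniform_prior(self, seq_even, dif_params):
        cL, _, _ = dif_counts(seq_even, dif_params)
        assert np.allclose(cL[0], 0.5)

    def test_constant_schedule_reduces_to_short_filter(self, seq_biased):
        """γ_L,n ≡ γ_S makes the two recursions identical."""
        from p3dif.observers import LongTermSchedule
        params = DIFParams(beta_S=3.0)
        gam = np.full(seq_biased.N + 1, params.gamma_S)
        sch = LongTermSchedule(tau1=1, tau2=1, beta=-1 / np.log(gam), gamma=gam)
        cL, cS, _ = dif_counts(seq_biased, params, sch)
        assert np.max(np.abs(cL - cS)) < 1e-14

    @pytest.mark.parametrize("probs,seed", [(EVEN, 3), (BIASED, 4)])
    def test_recursion_equals_unrolled_weights(self, probs, seed):
        seq = generate_sequence(2, 200, probs, seed=seed)
        params = DIFParams()
        sch = long_term_schedule(params.tau1, params.tau2, seq.N)
        cL, _, _ = dif_counts(seq, params, sch)
        for k in (1, 2):
            direct = long_filter_direct(seq, k, sch)
            assert np.max(np.abs(cL[:, k - 1] - direct)) < 1e-10

    def test_partition_preserved(self, seq_even, dif_params):
        cL, _, _ = dif_counts(seq_even, dif_params)
        assert np.allclose(cL.sum(axis=1), 1.0)

    def test_schedule_length_mismatch(self, seq_even, dif_params):
        from p3dif.observers import dif_long_filter
        short = long_term_schedule(33.6, 0.27, 10)
        with pytest.raises(ValueError):
            dif_long_filter(_g_block(seq_even)[:-1], short)


class TestDifAlternationFilter:
    def test_zero_input_window(self, dif_params):
        from p3dif.observers import dif_alternation_filter
        x = np.zeros(8)
        assert np.allclose(dif_alternation_filter(x, dif_params.taps), 0.0)

    def test_depends_only_on_last_four_inputs(self, seq_even, dif_params):
        """Perturbing g at lag 5 leaves c_Δ unchanged."""
        from p3dif.observers import dif_alternation_filter
        x = _g_block(seq_even)[:-1, 0].copy()
        n = 100  # inspect trial n: inputs ν = n-4..n-1 matter
        before = dif_alternation_filter(x, dif_params.taps)[n - 1]
        x[n - 5] = 1.0 - x[n - 5]
        after = dif_alternation_filter(x, dif_params.taps)[n - 1]
        assert before == after

    def test_tap_count_validated(self):
        from p3dif.observers import dif_alternation_filter
        with pytest.raises(ValueError):
            dif_alternation_filter(np.zeros(5), taps=(1.0, -1.0, 1.0))


# --------------------------------------------------------------------------
# DIF probability and surprise
# --------------------------------------------------------------------------

class TestDifProbability:
    def test_uniform_first_trial(self, seq_even, seq_biased, dif_params):
        for seq in (seq_even, seq_biased):
            assert np.allclose(dif_probability(seq, dif_params).P[0], 0.5)

    def test_degenerate_weights_reduce_to_long_filter(self, seq_biased):
        params = DIFParams(alpha_L=1.0, alpha_S=0.0, alpha_Delta=0.0)
        cL, _, _ = dif_counts(seq_biased, params)
        P = dif_probability(seq_biased, params).P
        assert np.max(np.abs(P - cL)) < 1e-14

    def test_normalization_sweep(self):
        """Σ_k P_k(n) = 1 within 1e-9 on 100 random sequences per category."""
        params = DIFParams()
        worst = 0.0
        for probs in (EVEN, BIASED):
            for s in range(100):
                seq = generate_sequence(2, 192, probs, seed=s)
                sums = dif_probability(seq, params).P.sum(axis=1)
                worst = max(worst, float(np.max(np.abs(sums - 1.0))))
        assert worst < 1e-9

    def test_weight_sum_violation_rejected(self):
        with pytest.raises(ValueError):
            DIFParams(alpha_L=0.9, alpha_S=0.2, alpha_Delta=0.05)

    def test_no_clamping_under_valid_parameters(self, seq_even, dif_params):
        tr = model_trace("DIF", seq_even, dif_params)
        assert tr.clamp_events == 0


class TestSurprise:
    @pytest.mark.parametrize("p,bits", [(0.5, 1.0), (0.25, 2.0), (1.0, 0.0)])
    def test_closed_form_values(self, p, bits):
        seq = StimulusSequence(events=np.array([1]), K=2)
        tr = ProbabilityTrace(P=np.array([[p, 1 - p]]), model="DIF")
        assert surprise(tr, seq).I[0] == pytest.approx(bits)

    def test_antitone_in_probability(self, seq_even, dif_params):
        tr = model_trace("DIF", seq_even, dif_params)
        p = tr.P[np.arange(seq_even.N), seq_even.events - 1]
        order = np.argsort(p)
        assert np.all(np.diff(tr.I[order]) <= 1e-12)
        assert np.all(tr.I >= 0)

    def test_squ_has_no_surprise(self, seq_even, squ_params):
        tr = squ_expectancy(seq_even, squ_params)
        with pytest.raises(ValueError):
            surprise(tr, seq_even)


# --------------------------------------------------------------------------
# frequency responses
# --------------------------------------------------------------------------

class TestAmplitudeResponse:
    def test_unity_dc_gain(self):
        assert amplitude_response("short", 0.0, beta=1.82) == pytest.approx(1.0)

    def test_one_pole_nyquist_closed_form(self):
        """γ = 0.6 at Nyquist: (1-γ)/(1+γ) = 0.25."""
        mag = amplitude_response("short", STIMULUS_RATE_HZ / 2, gamma=0.6)
        assert mag == pytest.approx(0.25)

    def test_lowpass_characters(self, dif_params):
        f = np.linspace(0, STIMULUS_RATE_HZ / 2, 257)
        for gamma in (dif_params.gamma_S,
                      long_term_schedule(33.6, 0.27, 192).gamma[1]):
            mag = amplitude_response("short", f, gamma=gamma)
            assert np.all(np.diff(mag) <= 1e-12)

    def test_highpass_character_of_default_taps(self, dif_params):
        f = np.linspace(0, STIMULUS_RATE_HZ / 2, 257)
        mag = amplitude_response("alternation", f, taps=dif_params.taps)
        assert np.all(np.diff(mag) >= -1e-12)
        assert_highpass(dif_params)  # startup assertion agrees

    def test_long_filter_sharpens_with_trials(self):
        """The late-block long-term filter attenuates Nyquist more than the
        early-block one (the low-pass gets sharper as experience grows)."""
        sch = long_term_schedule(33.6, 0.27, 192)
        nyq = STIMULUS_RATE_HZ / 2
        late = amplitude_response("long", nyq, gamma=sch.gamma[192])
        early = amplitude_response("long", nyq, gamma=sch.gamma[1])
        assert late < early

    def test_out_of_band_rejected(self):
        with pytest.raises(ValueError):
            amplitude_response("short", STIMULUS_RATE_HZ, beta=2.0)


@settings(max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10 ** 6))
def test_dif_probability_is_a_distribution(seed):
    """Property: P is a probability distribution on every trial for random
    sequences of either category."""
    probs = EVEN if seed % 2 else BIASED
    seq = generate_sequence(2, 96, probs, seed=seed)
    P = dif_probability(seq, DIFParams()).P
    assert np.all(P >= 0) and np.all(P <= 1)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
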