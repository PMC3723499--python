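"""Mean-field layer: formulas, ODEs, pulse asymptotics, readout, lifetimes."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memsim.config import ConfigError, ModelConfig
from memsim import meanfield as mf


# ---------------------------------------------------------------------------
# homogeneous closed forms


def test_discrete_formula_values():
    assert mf.mf_homogeneous_discrete(10**4, 1.0, 0) == 10**4
    assert mf.mf_homogeneous_discrete(10**4, 1.0, 1) == 0.0
    assert mf.mf_homogeneous_discrete(10**4, 0.5, 2) == 1250.0
    with pytest.raises(ValueError):
        mf.mf_homogeneous_discrete(10, 0.5, -1)


def test_continuous_snr_values():
    N, q = 10**4, 0.2
    assert mf.mf_homogeneous_snr_continuous(N, q, 0.0) == np.sqrt(N) * q
    t1 = np.log(np.sqrt(N) * q) / q
    assert abs(mf.mf_homogeneous_snr_continuous(N, q, t1) - 1.0) < 1e-12


def test_discrete_vs_continuous_agreement():
    # deviation relative to the initial signal stays below 2% for q <= 0.1
    for q in (0.1, 0.05, 0.01):
        t = np.arange(0, int(5 / q) + 1)
        disc = (1 - q) ** t
        cont = np.exp(-q * t)
        assert np.max(np.abs(disc - cont)) < 0.02


# ---------------------------------------------------------------------------
# heterogeneous


def test_heterogeneous_reduces_to_homogeneous():
    cfg = ModelConfig.homogeneous(10**4, 0.3)
    t = np.linspace(0, 20, 50)
    curve = mf.mf_heterogeneous(cfg, t)
    expected = mf.mf_homogeneous_snr_continuous(10**4, 0.3, t)
    assert np.allclose(curve.snr_optimal, expected, rtol=1e-12)


def test_two_equal_groups_give_sqrt2_boost():
    cfg = ModelConfig(N=2 * 10**4, n=2, q1=0.2, qn=0.2)
    t = np.linspace(0, 10, 20)
    curve = mf.mf_heterogeneous(cfg, t)
    single = mf.mf_homogeneous_snr_continuous(10**4, 0.2, t)
    assert np.allclose(curve.snr_optimal, np.sqrt(2) * single, rtol=1e-12)


def test_heterogeneous_power_law_regime():
    # interior decades: log-SNR vs log-t about linear, slope stable +-20%
    cfg = ModelConfig(N=50 * 10**4, n=50, q1=1.0, qn=1e-4)
    t = np.logspace(0.5, 3.0, 60)
    curve = mf.mf_heterogeneous(cfg, t)
    logt, logs = np.log(t), np.log(curve.snr_optimal)
    slopes = np.diff(logs) / np.diff(logt)
    med = np.median(slopes)
    assert np.all(np.abs(slopes - med) < 0.2 * np.abs(med))


# ---------------------------------------------------------------------------
# transfer chain


def test_transfer_discrete_delay_line_and_silent_stage():
    cfg = ModelConfig(N=4 * 100, n=4, q1=1.0, qn=1.0)
    S = mf.mf_transfer_discrete(cfg, 8).per_stage_signal
    for k in range(1, 4):
        assert np.allclose(S[k, k:], S[0, :-k] if k else S[0])
        assert np.all(S[k, :k] == 0.0)
    tiny = ModelConfig(N=2 * 100, n=2, q1=0.5, qn=1e-300)
    S2 = mf.mf_transfer_discrete(tiny, 10).per_stage_signal
    assert np.allclose(S2[1], 0.0)


def test_transfer_ode_stage2_closed_forms():
    # distinct rates: S2 = S1(0) q2 (e^{-q2 t} - e^{-q1 t}) / (q1 - q2)
    cfg = ModelConfig(N=2 * 10**4, n=2, q1=0.5, qn=0.1)
    t = np.linspace(0, 40, 400)
    curve = mf.mf_transfer_ode(cfg, t)
    S1_0 = 10**4 * 0.5
    exact = S1_0 * 0.1 * (np.exp(-0.1 * t) - np.exp(-0.5 * t)) / (0.5 - 0.1)
    scale = exact.max()
    assert np.max(np.abs(curve.per_stage_signal[1] - exact) / scale) < 1e-6

    # confluent limit q1 = q2 = q: S2 = S1(0) q t e^{-q t}
    cfge = ModelConfig(N=2 * 10**4, n=2, q1=0.3, qn=0.3)
    curve_e = mf.mf_transfer_ode(cfge, t)
    exact_e = (10**4 * 0.3) * 0.3 * t * np.exp(-0.3 * t)
    assert np.max(np.abs(curve_e.per_stage_signal[1] - exact_e) / exact_e.max()) < 1e-6


def test_transfer_ode_matches_discrete_for_small_rates():
    cfg = ModelConfig(N=3 * 1000, n=3, q1=0.1, qn=0.01)
    T = 300
    disc = mf.mf_transfer_discrete(cfg, T).per_stage_signal
    cont = mf.mf_transfer_ode(cfg, np.arange(T + 1, dtype=float)).per_stage_signal
    scale = disc[0, 0]  # the chain's signal scale S1(0)
    assert np.max(np.abs(disc - cont)) < 0.02 * scale


def test_mean_field_positivity_and_bound():
    cfg = ModelConfig(N=10 * 1000, n=10, q1=1.0, qn=1e-3)
    t = np.concatenate([[0.0], np.logspace(-2, 4, 400)])
    S = mf.mf_transfer_ode(cfg, t).per_stage_signal
    assert np.all(S >= -1e-9 * S.max())
    assert np.all(S <= S[0, 0] * (1 + 1e-9))


# ---------------------------------------------------------------------------
# pulse asymptotics


def test_pulse_peak_monotone_and_accurate():
    cfg = ModelConfig(N=50 * 10**4, n=50, q1=1.0, qn=1e-4)
    grid = np.concatenate([[0.0], np.logspace(-1, 4.8, 900)])
    ode = mf.mf_transfer_ode(cfg, grid)
    times = [30, 100, 300, 1000, 3000, 10000]
    peaks = []
    for t in times:
        snr = mf.pulse_snr_asymptotic(cfg, t)
        k = int(np.argmax(snr))
        peaks.append(k)
        i = int(np.argmin(np.abs(grid - t)))
        ode_peak = ode.per_stage_snr[:, i].max()
        assert abs(snr[k] - ode_peak) / ode_peak < 0.10
    assert np.all(np.diff(peaks) >= 0)  # peak advances with time
    # SNR envelope decays: no spontaneous amplification
    env = [mf.pulse_snr_asymptotic(cfg, t).max() for t in times]
    assert np.all(np.diff(env) < 0)


def test_pulse_warns_outside_validity():
    cfg = ModelConfig(N=4 * 100, n=4, q1=1.0, qn=0.1)
    with pytest.warns(UserWarning):
        mf.pulse_snr_asymptotic(cfg, 5.0)


# ---------------------------------------------------------------------------
# optimal readout


def test_optimal_readout_single_and_equal_pair():
    idx, snr = mf.optimal_readout([50.0], [100])
    assert list(idx) == [0] and snr == 5.0
    idx2, snr2 = mf.optimal_readout([50.0, 50.0], [100, 100])
    assert list(idx2) == [0, 1]
    assert np.isclose(snr2, np.sqrt(2) * 5.0)
    with pytest.raises(ValueError):
        mf.optimal_readout([], [])


def _brute_force_readout(S, L):
    import itertools

    best, best_set = -np.inf, None
    m = len(S)
    for r in range(1, m + 1):
        for combo in itertools.combinations(range(m), r):
            v = sum(S[i] for i in combo) / np.sqrt(sum(L[i] for i in combo))
            if v > best:
                best, best_set = v, sorted(combo)
    return best_set, best


def test_optimal_readout_equals_brute_force():
    r = np.random.default_rng(42)
    for _ in range(100):
        n = int(r.integers(2, 13))
        S = r.exponential(1.0, n) * r.choice([1.0, 1.0, 1.0, -0.2], n)
        L = np.full(n, int(r.integers(10, 1000)))
        idx, snr = mf.optimal_readout(S, L)
        bset, bval = _brute_force_readout(list(S), list(L))
        assert np.isclose(snr, bval, rtol=1e-12)
        assert list(idx) == bset


@settings(derandomize=True, max_examples=60)
@given(
    signals=st.lists(st.floats(0.0, 1e4), min_size=1, max_size=20),
    L=st.integers(1, 10**6),
)
def test_optimal_readout_dominates_single_stages(signals, L):
    S = np.asarray(signals)
    sizes = np.full(len(signals), L)
    _, snr = mf.optimal_readout(S, sizes)
    assert snr >= (S / np.sqrt(L)).max() - 1e-12


# ---------------------------------------------------------------------------
# lifetimes and crossings


def test_lifetime_homogeneous_closed_form_vs_numeric():
    N, q = 10**4, 0.5
    exact = np.log(np.sqrt(N) * q) / q
    num = mf.lifetime_numeric(
        lambda t: mf.mf_homogeneous_snr_continuous(N, q, t), horizon=1e4
    )
    assert abs(num - exact) / exact < 1e-6
    assert mf.lifetime_homogeneous(N, q) == pytest.approx(exact)
    assert mf.lifetime_homogeneous(100, 0.01) == 0.0  # SNR(0) < 1


def test_lifetime_shift_property():
    N, q, dt = 10**6, 0.2, 7.0
    base = mf.lifetime_numeric(
        lambda t: mf.mf_homogeneous_snr_continuous(N, q, t), horizon=1e5
    )
    shifted = mf.lifetime_numeric(
        lambda t: mf.mf_homogeneous_snr_continuous(N, q, np.maximum(t - dt, 0.0)),
        horizon=1e5,
    )
    assert abs(shifted - base - dt) < 1e-5


def test_lifetime_on_sampled_nonmonotonic_curve():
    cfg = ModelConfig(N=5 * 10**5, n=5, q1=1.0, qn=1e-3)
    grid = np.concatenate([[0.0], np.logspace(-2, 5, 3000)])
    curve = mf.mf_transfer_ode(cfg, grid)
    life = mf.lifetime_numeric((grid, curve.snr_optimal))
    dense = np.concatenate([[0.0], np.logspace(-2, 5, 60000)])
    curve_d = mf.mf_transfer_ode(cfg, dense)
    life_d = mf.lifetime_numeric((dense, curve_d.snr_optimal))
    assert abs(life - life_d) / life_d < 1e-2  # grid-scan oracle agreement


def test_lifetime_horizon_error():
    with pytest.raises(mf.HorizonExceededError):
        mf.lifetime_numeric(lambda t: np.full_like(np.asarray(t, float), 2.0),
                            horizon=10.0)


def test_lifetime_asymptotic_vs_numeric_sweep():
    for n in (10, 20, 50):
        for qn in (1e-3, 1e-4):
            cfg = ModelConfig(N=n * 10**5, n=n, q1=1.0, qn=qn)
            la = mf.lifetime_asymptotic(cfg)
            t_arr = mf.pulse_travel_time(cfg)
            grid = np.concatenate(
                [[0.0], np.logspace(-2, np.log10(50 * max(la, t_arr)), 2500)]
            )
            ln = mf.lifetime_numeric((grid, mf.mf_transfer_ode(cfg, grid).snr_optimal))
            assert 0.5 < la / ln < 2.0


def test_lifetime_asymptotic_monotonicity():
    lifetimes_n = [
        mf.lifetime_asymptotic(ModelConfig(N=n * 10**5, n=n, q1=1.0, qn=1e-4))
        for n in (10, 20, 40)
    ]
    assert np.all(np.diff(lifetimes_n) > 0)  # increasing in n
    # slower last stage retains longer; needs the pulse to survive to the
    # last stage (large N), else the memory dies mid-chain and qn is moot
    lifetimes_qn = [
        mf.lifetime_asymptotic(ModelConfig(N=10 * 10**12, n=10, q1=1.0, qn=qn))
        for qn in (1e-3, 1e-4, 1e-5)
    ]
    assert np.all(np.diff(lifetimes_qn) > 0)  # decreasing in qn


def test_crossing_time_cases():
    t = np.linspace(0, 30, 3001)
    a = mf.mf_homogeneous_snr_continuous(10**6, 0.5, t)
    assert mf.crossing_time(t, a, a.copy()) == 0.0
    # two homogeneous curves: crossing at ln(qa/qb)/(qa-qb)
    b = mf.mf_homogeneous_snr_continuous(10**6, 0.1, t)
    expected = np.log(0.5 / 0.1) / (0.5 - 0.1)
    got = mf.crossing_time(t, a, b)
    assert abs(got - expected) < 1e-3  # linear interpolation on the grid
    # no crossing inside the horizon -> NaN sentinel
    assert np.isnan(mf.crossing_time(t, a + 10.0, a))


def test_initial_snr_scales_sqrt_N():
    Ns = np.logspace(4, 7, 8)
    snr0 = np.array([mf.mf_homogeneous_snr_continuous(N, 0.1, 0.0) for N in Ns])
    slope = np.polyfit(np.log(Ns), np.log(snr0), 1)[0]
    assert abs(slope - 0.5) < 0.02
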