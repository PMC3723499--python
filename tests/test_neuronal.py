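"""McCulloch-Pitts chain: encoding, replay, two-threshold copying, analytics."""

import numpy as np
import pytest
from scipy.stats import norm

from memsim.config import ConfigError
from memsim import neuronal as nn
from memsim import meanfield as mf
from memsim.config import ModelConfig
from memsim.rng import child_rng


# ---------------------------------------------------------------------------
# construction and encoding


def test_init_chain_basics():
    rng = child_rng(1, "init")
    ch = nn.init_chain(1, 2, rng)
    assert ch.n_stages == 1 and ch.N_neurons == 2
    assert np.count_nonzero(ch.J[0]) == 2  # two directed synapses, diag 0
    big = nn.init_chain(1, 200, child_rng(2, "x"))
    offdiag = big.J[0][~np.eye(200, dtype=bool)]
    frac = (offdiag == 1).mean()
    n_syn = offdiag.size
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n_syn)
    a = nn.init_chain(2, 50, child_rng(3, "s"))
    b = nn.init_chain(2, 50, child_rng(3, "s"))
    assert all(np.array_equal(x, y) for x, y in zip(a.J, b.J))
    with pytest.raises(ConfigError):
        nn.init_chain(0, 10, rng)


def test_encode_limits_and_count():
    N = 200
    rng = child_rng(4, "e")
    ch = nn.init_chain(1, N, rng)
    rec = nn.encode_neuronal(ch, rng, 1.0)
    tgt = rec.target()
    elig = rec.eligible_mask()
    assert np.array_equal(ch.J[0][elig], tgt[elig])  # q1=1: exact Hebbian imprint
    ch2 = nn.init_chain(1, N, child_rng(5, "e"))
    before = ch2.J[0].copy()
    nn.encode_neuronal(ch2, child_rng(6, "e"), 0.0)
    assert np.array_equal(ch2.J[0], before)  # q1=0: untouched
    # q1=0.2: number of refreshed synapses ~ Binomial(q1, eligible count)
    q1 = 0.2
    ch3 = nn.init_chain(1, N, child_rng(7, "e"))
    J_before = ch3.J[0].copy()
    rec3 = nn.encode_neuronal(ch3, child_rng(8, "e"), q1)
    elig3 = rec3.eligible_mask()
    tgt3 = rec3.target()
    # changed synapses are a subset of (eligible & previously != target)
    changed = ch3.J[0] != J_before
    assert not np.any(changed & ~elig3)
    mismatched = elig3 & (J_before != tgt3)
    n_mis = mismatched.sum()
    got = (changed & mismatched).sum()
    assert abs(got - q1 * n_mis) < 3 * np.sqrt(q1 * (1 - q1) * n_mis)


def test_neuronal_signal_fresh_and_downstream():
    N = 200
    rng = child_rng(9, "s")
    ch = nn.init_chain(2, N, rng)
    rec = nn.encode_neuronal(ch, rng, 1.0)
    sig, snr = nn.neuronal_signal(ch, 1, rec)
    E = rec.n_eligible
    assert sig == E and np.isclose(snr, np.sqrt(E))
    sig2, _ = nn.neuronal_signal(ch, 2, rec)
    assert abs(sig2) < 3 * np.sqrt(E)  # stage 2 untouched: zero-mean overlap


# ---------------------------------------------------------------------------
# replay and plasticity


def test_replay_single_neuron_responders():
    N = 60
    rng = child_rng(10, "r")
    ch = nn.init_chain(1, N, rng)
    rec = nn.replay_once(ch, 1, f=1.0 / N, theta=0.5, rng=rng)
    j = int(np.flatnonzero(rec.stimulated)[0])
    expected = ch.J[0][:, j] > 0
    assert np.array_equal(rec.responders, expected)
    assert rec.stimulated.sum() == 1


def test_replay_all_plus_weights_everyone_fires():
    N = 50
    ch = nn.NeuronalChain([np.ones((N, N), dtype=np.int8)])
    np.fill_diagonal(ch.J[0], 0)
    rng = child_rng(11, "r")
    f = 0.2
    m = round(f * N)
    rec = nn.replay_once(ch, 1, f=f, theta=m - 1.5, rng=rng)
    non_stim = ~rec.stimulated
    assert np.all(rec.responders[non_stim])  # h = m > m - 1.5 for them


def test_replay_gaussian_tail_fraction():
    # responder fraction at theta = 2 sigma matches the Normal upper tail
    N, f = 2000, 0.1
    sigma = np.sqrt(f * N)
    theta = 2 * sigma + 0.17  # non-integer
    rng = child_rng(12, "tail")
    ch = nn.init_chain(1, N, rng)
    fracs = []
    for _ in range(300):
        rec = nn.replay_once(ch, 1, f, theta, rng)
        fracs.append(rec.responders.mean())
    got = np.mean(fracs)
    expected = norm.sf(theta / sigma)
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(got - expected) < max(3 * se, 0.1 * expected)


def test_plasticity_q0_noop_and_missing_label():
    N = 40
    rng = child_rng(13, "p")
    ch = nn.init_chain(2, N, rng)
    rec = nn.replay_once(ch, 1, 0.1, 0.5, rng, threshold_label="high")
    before = ch.J[1].copy()
    nn.plasticity_two_threshold(ch, 2, rec, 0.0, rng)
    assert np.array_equal(ch.J[1], before)
    rec.threshold_label = "sideways"
    with pytest.raises(ValueError):
        nn.plasticity_two_threshold(ch, 2, rec, 1.0, rng)


def test_perfect_copy_session_exact():
    rng = child_rng(14, "pc")
    ch = nn.init_chain(2, 100, rng)
    assert not np.array_equal(ch.J[0], ch.J[1])
    nn.perfect_copy_session(ch, 1, q=1.0)
    assert np.array_equal(ch.J[0], ch.J[1])


def test_run_session_m0_noop():
    rng = child_rng(15, "m0")
    ch = nn.init_chain(3, 30, rng)
    before = [j.copy() for j in ch.J]
    proto = nn.TransferProtocol(f=0.2, theta_low=-2.5, theta_high=2.5, M=0)
    nn.run_session(ch, proto, rng)
    assert all(np.array_equal(x, y) for x, y in zip(ch.J, before))


def test_coupon_collector_coverage():
    # f=1/N, q=1: after N log N + cN single-neuron replays every column of
    # the downstream matrix has been copied with high probability
    N = 40
    rng = child_rng(16, "cc")
    ch = nn.init_chain(2, N, rng)
    # each column must be hit under BOTH threshold labels (high writes the
    # +1 entries, low the -1 entries): coupon collector over 2N pairs
    M = int(2 * N * np.log(N) + 6 * N)
    proto = nn.TransferProtocol(f=1.0 / N, theta_low=-0.5, theta_high=0.5, M=M, q=1.0)
    nn.run_session(ch, proto, rng)
    match = (ch.J[0] == ch.J[1])[~np.eye(N, dtype=bool)]
    assert match.mean() >= 0.99


def test_protocol_validation():
    with pytest.raises(ConfigError):
        nn.TransferProtocol(f=0.1, theta_low=2.5, theta_high=1.5, M=1)
    with pytest.raises(ConfigError):
        nn.TransferProtocol(f=0.1, theta_low=-2.0, theta_high=3.5, M=1)  # integer
    with pytest.raises(ConfigError):
        nn.TransferProtocol(f=0.0, theta_low=-0.5, theta_high=0.5, M=1)


# ---------------------------------------------------------------------------
# analytics


def test_input_stats_formulas():
    st = nn.input_stats(0.1, 2000, 0.5)
    assert st.mu_h == 0.0 and st.var_h == 0.1 * 2000
    st1 = nn.input_stats(0.1, 2000, 1.0)
    assert st1.mu_h == 200.0 and st1.var_h == 0.0


def test_input_stats_empirical():
    N, f = 2000, 0.1
    rng = child_rng(17, "h")
    ch = nn.init_chain(1, N, rng)
    hs = []
    for _ in range(200):
        stim = np.zeros(N, dtype=bool)
        stim[rng.permutation(N)[: round(f * N)]] = True
        hs.append(ch.J[0][:, stim].sum(axis=1))
    hs = np.concatenate(hs).astype(float)
    expected = nn.input_stats(f, N, 0.5)
    assert abs(hs.mean() - expected.mu_h) < 3 * hs.std() / np.sqrt(hs.size / N)
    assert abs(hs.var() - expected.var_h) < 0.1 * expected.var_h


def test_transfer_stats_limits():
    far = nn.TransferProtocol(f=0.1, theta_low=-2000.5, theta_high=2000.5, M=10)
    assert nn.transfer_stats(far, 2000).R == pytest.approx(0.0, abs=1e-12)
    near = nn.TransferProtocol(f=0.1, theta_low=-0.5, theta_high=0.5, M=100_000)
    assert nn.transfer_stats(near, 2000).R == pytest.approx(1.0, abs=1e-9)
    st = nn.transfer_stats(nn.TransferProtocol(f=0.1, theta_low=-28.5,
                                               theta_high=28.5, M=10), 2000)
    assert 0.0 <= st.R <= 1.0 and 0.5 <= st.A <= 1.0
    assert st.q_eff == pytest.approx(st.R * st.A)
    assert st.c == pytest.approx(st.R * (1 - st.A))


def test_transfer_stats_gaussian_close_to_exact_at_large_fN():
    proto = nn.TransferProtocol(f=0.25, theta_low=-40.5, theta_high=40.5, M=10)
    ex = nn.transfer_stats(proto, 10_000, method="exact")
    ga = nn.transfer_stats(proto, 10_000, method="gaussian")
    assert abs(ga.R - ex.R) / ex.R < 0.05
    assert abs(ga.A - ex.A) < 0.01


def test_speed_accuracy_tradeoff():
    N, sigma = 2000, np.sqrt(0.1 * 2000)
    Rs, As = [], []
    for k in (1.0, 1.5, 2.0, 2.5, 3.0):
        th = k * sigma + 0.13
        st = nn.transfer_stats(
            nn.TransferProtocol(f=0.1, theta_low=-th, theta_high=th, M=10), N
        )
        Rs.append(st.R)
        As.append(st.A)
    assert np.all(np.diff(Rs) < 0)  # strictly slower
    assert np.all(np.diff(As) >= -1e-12)  # weakly more accurate


def test_transfer_stats_vs_monte_carlo_small():
    proto = nn.TransferProtocol(f=0.1, theta_low=-28.5, theta_high=28.5, M=10)
    st = nn.transfer_stats(proto, 2000)
    mc = nn.monte_carlo_transfer_stats(proto, 2000, n_sessions=8, n_tracked=800,
                                       seed=18)
    assert abs(st.R - mc["R"]) < 3 * mc["se_R"]
    assert abs(st.A - mc["A"]) < 3 * mc["se_A"]


# ---------------------------------------------------------------------------
# corrupted mean field


def test_corrupted_mf_A1_equals_transfer_ode():
    cfg = ModelConfig(N=3 * 1000, n=3, q1=0.3, qn=0.05)
    t = np.linspace(0, 100, 500)
    ref = mf.mf_transfer_ode(cfg, t).per_stage_signal
    got = nn.mf_neuronal_corrupted(
        q1=0.3, R=cfg.rates[1:], A=[1.0, 1.0], S1_0=1000 * 0.3, t_grid=t
    )
    assert np.allclose(got, ref, rtol=1e-6, atol=1e-8 * ref.max())


def test_corrupted_mf_A_half_decouples():
    t = np.linspace(0, 50, 200)
    got = nn.mf_neuronal_corrupted(q1=0.3, R=[0.2], A=[0.5], S1_0=500.0, t_grid=t)
    assert np.allclose(got[1], 0.0, atol=1e-10)  # starts at 0, no drive


def test_corrupted_discrete_matches_ode_small_rates():
    T = 200
    t = np.arange(T + 1, dtype=float)
    R, A, q1 = [0.05, 0.02], [0.8, 0.7], 0.08
    ode = nn.mf_neuronal_corrupted(q1=q1, R=R, A=A, S1_0=1000.0, t_grid=t)
    rec = nn.mf_neuronal_corrupted_discrete(q1, R, A, 1000.0, T)
    # the recursion includes the transfer session that follows the t=0
    # encoding (offset R1*(2A1-1)*S1_0) on top of ~2% discretization error
    bound = (R[0] * (2 * A[0] - 1) + 0.02) * 1000.0
    assert np.max(np.abs(ode - rec)) < bound


def test_silencing_between_replays():
    # records are self-contained; a replay starts from silence and the
    # response depends only on the current stimulated set and weights
    N = 80
    rng = child_rng(19, "sil")
    ch = nn.init_chain(1, N, rng)
    rec1 = nn.replay_once(ch, 1, 0.1, 0.5, child_rng(20, "a"))
    rec2 = nn.replay_once(ch, 1, 0.1, 0.5, child_rng(20, "a"))
    assert np.array_equal(rec1.stimulated, rec2.stimulated)
    assert np.array_equal(rec1.responders, rec2.responders)
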