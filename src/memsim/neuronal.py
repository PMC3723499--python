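"""McCulloch-Pitts implementation of replay-driven memory transfer.

A chain of ``n`` stages, each ``N`` all-to-all connected binary neurons
with recurrent weights ``J_ij in {-1, +1}`` (no self-connections) and
fixed one-to-one feedforward links between corresponding neurons of
consecutive stages.

**Encoding** happens in stage 1 only: a random half of the neurons is
activated and every synapse with an active presynaptic neuron is driven
toward its Hebbian target (+1 if the postsynaptic neuron is also active,
-1 otherwise) with probability ``q1``.

**Transfer** (replay): a random fraction ``f`` of stage-k neurons is
stimulated; neuron ``i`` receives recurrent input
``h_i = sum_{j in stim} J_ij`` and fires if ``h_i`` exceeds the current
threshold. The strong feedforward links impose the same stimulated and
responding sets on stage k+1, where a two-threshold rule updates the
recurrent weights: under the *high* threshold, (stimulated -> responder)
synapses are potentiated with probability ``q``; under the *low*
threshold, (stimulated -> non-responder) synapses are depressed. Each
replay draws one of the two thresholds with probability 1/2 (a global
signal shared by the stage pair), and all activity is cleared afterwards.

Repeating the replay ``M`` times per encoding copies upstream synaptic
states downstream at transfer rate ``R = 1 - (1 - p)**M`` with per-replay
update probability ``p``, and accuracy ``A`` (fraction of updates that
match the upstream synapse). :func:`transfer_stats` computes ``R`` and
``A`` from the replay input distribution — exactly (binomial background)
or in the large-fN Gaussian approximation — and
:func:`mf_neuronal_corrupted` is the matching mean-field with learning
rate ``R_k A_k`` toward the upstream signal and corruption rate
``R_k (1 - A_k)`` (an incorrect copy of a binary synapse is necessarily
the opposite value, which forces the form
``dS_k/dt = R_k (2 A_k - 1) S_{k-1} - R_k S_k``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import binom, norm

from .config import ConfigError
from .markov import SignalTrace
from .rng import child_rng

__all__ = [
    "NeuronalChain",
    "TransferProtocol",
    "ActivityRecord",
    "InputStats",
    "TransferStats",
    "init_chain",
    "encode_neuronal",
    "neuronal_signal",
    "replay_once",
    "plasticity_two_threshold",
    "run_session",
    "perfect_copy_session",
    "input_stats",
    "transfer_stats",
    "linear_response_transfer",
    "monte_carlo_transfer_stats",
    "mf_neuronal_corrupted",
    "mf_neuronal_corrupted_discrete",
    "simulate_neuronal_chain",
]


# ---------------------------------------------------------------------------
# types


@dataclass
class NeuronalChain:
    """Recurrent ±1 weight matrices, one per stage; diagonals are zero."""

    J: list[np.ndarray]

    @property
    def n_stages(self) -> int:
        return len(self.J)

    @property
    def N_neurons(self) -> int:
        return self.J[0].shape[0]

    def copy(self) -> "NeuronalChain":
        return NeuronalChain([j.copy() for j in self.J])


@dataclass(frozen=True)
class TransferProtocol:
    """Replay parameters for one stage pair (shared by all pairs here).

    f : stimulated fraction in (0, 1]; ``round(f N)`` neurons per replay.
    theta_low, theta_high : firing thresholds; must be non-integer
        (input sums are integers, so non-integer thresholds rule out ties)
        with ``theta_low < theta_high``.
    M : replays per stage pair per encoding cycle.
    q : intrinsic plasticity rate of the downstream synapses.
    """

    f: float
    theta_low: float
    theta_high: float
    M: int
    q: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.f <= 1.0):
            raise ConfigError(f"stimulated fraction must be in (0, 1], got {self.f!r}")
        if not (0.0 < self.q <= 1.0):
            raise ConfigError(f"plasticity rate must be in (0, 1], got {self.q!r}")
        if self.M < 0:
            raise ConfigError("M must be non-negative")
        if self.theta_low >= self.theta_high:
            raise ConfigError("theta_low must be strictly below theta_high")
        for th in (self.theta_low, self.theta_high):
            if float(th).is_integer():
                raise ConfigError(
                    f"threshold {th!r} is integer-valued; inputs are integer sums, "
                    "use half-integer thresholds to avoid ties"
                )

    def n_stim(self, N: int) -> int:
        c = int(round(self.f * N))
        if c < 1:
            raise ConfigError(f"f*N = {self.f * N:.3g} < 1: no neuron stimulated")
        return c


@dataclass
class ActivityRecord:
    """One replay: who was stimulated, who responded, which threshold."""

    stimulated: np.ndarray  # bool mask, length N
    responders: np.ndarray  # bool mask, length N
    threshold_label: str  # "low" | "high"


@dataclass(frozen=True)
class InputStats:
    """Gaussian approximation of the replay input ``h_i``."""

    mu_h: float
    var_h: float


@dataclass(frozen=True)
class TransferStats:
    """Analytic transfer-rate/accuracy summary of a replay protocol."""

    p_replay: float  # per-replay per-synapse update probability
    R: float  # P(updated at least once in M replays)
    A: float  # P(update copies the upstream state)
    q_eff: float  # R * A, effective learning rate
    c: float  # R * (1 - A), corruption rate
    gamma: float  # prefactor in the small-p law R ~ gamma * M * q


# ---------------------------------------------------------------------------
# network construction and encoding


def init_chain(n_stages: int, N_neurons: int, rng: np.random.Generator) -> NeuronalChain:
    """Chain with i.i.d. ±1 off-diagonal weights (balanced stationary start)."""
    if n_stages < 1 or N_neurons < 2:
        raise ConfigError("need n_stages >= 1 and N_neurons >= 2")
    J = []
    for _ in range(n_stages):
        j = (rng.integers(0, 2, size=(N_neurons, N_neurons), dtype=np.int8) * 2 - 1)
        np.fill_diagonal(j, 0)
        J.append(j)
    return NeuronalChain(J)


@dataclass
class PatternRecord:
    """Stage-1 activity pattern of an encoded memory.

    ``active`` is the bool activity mask; the memory's synaptic target is
    every off-diagonal synapse with an active presynaptic neuron
    (the *eligible* set), with Hebbian value +1 if the postsynaptic neuron
    is active and -1 otherwise.
    """

    active: np.ndarray

    @property
    def n_eligible(self) -> int:
        N = self.active.size
        return int(self.active.sum()) * (N - 1)

    def eligible_mask(self) -> np.ndarray:
        N = self.active.size
        m = np.broadcast_to(self.active[None, :], (N, N)).copy()
        np.fill_diagonal(m, False)
        return m

    def target(self) -> np.ndarray:
        """Hebbian target matrix (rows = post): +1 where post active."""
        N = self.active.size
        return np.where(self.active, 1, -1).astype(np.int8)[:, None] * np.ones(
            (1, N), dtype=np.int8
        )


def encode_neuronal(
    chain: NeuronalChain, rng: np.random.Generator, q1: float
) -> PatternRecord:
    """Encode one random memory into stage 1 (in place).

    A random half of the neurons is activated; every eligible synapse
    (presynaptic neuron active) moves to its Hebbian target with
    probability ``q1``. Stages >= 2 are untouched.
    """
    if not (0.0 <= q1 <= 1.0):
        raise ConfigError(f"q1 must be in [0, 1], got {q1!r}")
    N = chain.N_neurons
    active = np.zeros(N, dtype=bool)
    active[rng.permutation(N)[: N // 2]] = True
    rec = PatternRecord(active=active)
    if q1 > 0.0:
        J = chain.J[0]
        coin = rng.random((N, N)) < q1
        mask = coin & active[None, :]
        np.fill_diagonal(mask, False)
        target = np.where(active, 1, -1).astype(np.int8)
        J[mask] = np.broadcast_to(target[:, None], (N, N))[mask]
    return rec


def neuronal_signal(
    chain: NeuronalChain, stage_k: int, record: PatternRecord
) -> tuple[int, float]:
    """Ideal-observer signal of a memory in stage ``k`` (1-based).

    Overlap of the stage's weights with the memory's Hebbian targets over
    the eligible synapses; SNR divides by sqrt(#eligible).
    """
    if not (1 <= stage_k <= chain.n_stages):
        raise ValueError(f"stage {stage_k} out of range 1..{chain.n_stages}")
    J = chain.J[stage_k - 1]
    active = record.active
    tgt = np.where(active, 1, -1).astype(np.int64)
    # signal = sum over eligible (i, j): J_ij * tgt_i, eligible = pre j active
    col_sums = J[:, active].sum(axis=1).astype(np.int64)  # per-post sums
    sig = int(np.dot(col_sums, tgt)) - 0  # diagonal is zero, self-pairs drop out
    return sig, sig / np.sqrt(record.n_eligible)


# ---------------------------------------------------------------------------
# replay and two-threshold plasticity


def replay_once(
    chain: NeuronalChain,
    stage_k: int,
    f: float,
    theta: float,
    rng: np.random.Generator,
    threshold_label: str = "high",
) -> ActivityRecord:
    """One replay on stage ``k``: stimulate round(f N) random neurons,
    collect responders ``{i : h_i > theta}`` with
    ``h_i = sum_{j in stim, j != i} J_ij``, then silence everyone.

    Via the strong one-to-one feedforward links the same stimulated and
    responding sets are imposed on stage k+1; the record returned is what
    :func:`plasticity_two_threshold` consumes there.
    """
    N = chain.N_neurons
    c = int(round(f * N))
    if c < 1:
        raise ConfigError(f"f*N = {f * N:.3g} < 1: no neuron stimulated")
    J = chain.J[stage_k - 1]
    stim = np.zeros(N, dtype=bool)
    stim[rng.permutation(N)[:c]] = True
    h = J[:, stim].sum(axis=1, dtype=np.int64)  # diagonal zero: j != i automatic
    responders = h > theta
    return ActivityRecord(stimulated=stim, responders=responders,
                          threshold_label=threshold_label)


def plasticity_two_threshold(
    chain: NeuronalChain,
    stage_k_plus_1: int,
    record: ActivityRecord,
    q: float,
    rng: np.random.Generator,
) -> None:
    """Apply the two-threshold copy rule to stage ``k+1`` (in place).

    High threshold: every (pre in stimulated, post in responders) synapse
    is potentiated to +1 with probability ``q`` — a responder fired despite
    the high bar, so its upstream synapses from the stimulated set were
    strong. Low threshold: (pre in stimulated, post not in responders)
    synapses are depressed to -1 — silence despite the low bar means weak
    upstream synapses.
    """
    if record.threshold_label not in ("low", "high"):
        raise ValueError(f"unknown threshold label {record.threshold_label!r}")
    if not (0.0 <= q <= 1.0):
        raise ConfigError(f"plasticity rate must be in [0, 1], got {q!r}")
    if q == 0.0:
        return
    J = chain.J[stage_k_plus_1 - 1]
    N = J.shape[0]
    stim_idx = np.flatnonzero(record.stimulated)
    if record.threshold_label == "high":
        posts, value = record.responders, np.int8(1)
    else:
        posts, value = ~record.responders, np.int8(-1)
    # column-wise: cheap when few neurons are stimulated
    for j in stim_idx:
        rows = posts.copy()
        rows[j] = False  # no self-connection
        if q < 1.0:
            rows &= rng.random(N) < q
        J[rows, j] = value


def run_session(
    chain: NeuronalChain, protocol: TransferProtocol, rng: np.random.Generator
) -> None:
    """One transfer session: M replays for each consecutive stage pair.

    Pairs are processed in order (1,2), (2,3), ...; per replay the
    threshold is low or high with probability 1/2 (one global draw shared
    by the interacting pair), the upstream stage is replayed, and the
    downstream stage updated. Activity never carries over between replays.
    """
    if chain.n_stages < 2:
        raise ConfigError("transfer needs at least 2 stages")
    for k in range(1, chain.n_stages):
        for _ in range(protocol.M):
            if rng.random() < 0.5:
                theta, label = protocol.theta_high, "high"
            else:
                theta, label = protocol.theta_low, "low"
            rec = replay_once(chain, k, protocol.f, theta, rng, threshold_label=label)
            plasticity_two_threshold(chain, k + 1, rec, protocol.q, rng)


def perfect_copy_session(
    chain: NeuronalChain,
    stage_k: int,
    q: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Exhaustive single-neuron transfer (the f = 1/N special case).

    Each neuron ``j`` of stage ``k`` is stimulated alone with threshold 0,
    so the responders are exactly ``{i : J_ij = +1}``; potentiating
    (j -> responders) and depressing (j -> non-responders) downstream at
    rate ``q = 1`` copies the upstream matrix column by column.
    """
    if rng is None:
        rng = np.random.default_rng()
    J_up = chain.J[stage_k - 1]
    J_dn = chain.J[stage_k]
    N = chain.N_neurons
    for j in range(N):
        responders = J_up[:, j] > 0  # h_i = J_ij, theta = 0
        col = np.where(responders, 1, -1).astype(np.int8)
        if q >= 1.0:
            upd = np.ones(N, dtype=bool)
        else:
            upd = rng.random(N) < q
        upd[j] = False  # no self-connection
        J_dn[upd, j] = col[upd]


# ---------------------------------------------------------------------------
# analytics


def input_stats(f: float, N: int, rho: float) -> InputStats:
    """Mean and variance of the replay input ``h_i``.

    ``h_i`` sums ``f N`` i.i.d. ±1 weights with P(+1) = rho, hence
    ``mu = f N (2 rho - 1)`` and ``var = 4 f N rho (1 - rho)`` — the
    Gaussian approximation behind :func:`transfer_stats`.
    """
    if not (0.0 < f <= 1.0):
        raise ConfigError(f"f must be in (0, 1], got {f!r}")
    if not (0.0 <= rho <= 1.0):
        raise ConfigError(f"rho must be in [0, 1], got {rho!r}")
    return InputStats(mu_h=f * N * (2.0 * rho - 1.0), var_h=4.0 * f * N * rho * (1.0 - rho))


def _tail_above(c: float, b: int, rho: float, method: str) -> float:
    """P(B > c) for B = sum of b i.i.d. ±1 with P(+1) = rho."""
    if method == "gaussian":
        mu = b * (2.0 * rho - 1.0)
        sd = np.sqrt(max(4.0 * b * rho * (1.0 - rho), 1e-300))
        return float(norm.sf((c - mu) / sd))
    # exact: B = 2 X - b, X ~ Binomial(b, rho); B > c  <=>  X > (c + b)/2
    return float(binom.sf(np.floor((c + b) / 2.0), b, rho))


def transfer_stats(
    protocol: TransferProtocol,
    N: int,
    rho: float = 0.5,
    method: str = "auto",
) -> TransferStats:
    """Analytic transfer rate R and accuracy A of the two-threshold rule.

    Tracks one upstream synapse (i, j). Per replay, ``j`` is stimulated
    with probability ``n_stim/N``; the input to ``i`` is ``J_ij`` plus a
    background of the other ``n_stim - 1`` stimulated weights (fraction
    ``rho`` potentiated). An update happens when the high threshold is
    drawn and ``h_i > theta_high`` (potentiation) or the low one is drawn
    and ``h_i <= theta_low`` (depression); it is correct when the written
    value matches ``J_ij``. ``method``: "exact" (binomial background
    tails), "gaussian" (the large-f N approximation), or "auto".
    """
    if not (0.0 <= rho <= 1.0):
        raise ConfigError(f"rho must be in [0, 1], got {rho!r}")
    if method == "auto":
        method = "exact" if protocol.n_stim(N) <= 100_000 else "gaussian"
    if method not in ("exact", "gaussian"):
        raise ValueError(f"unknown method {method!r}")
    m = protocol.n_stim(N)
    b = m - 1  # background synapses behind the tracked one
    thH, thL = protocol.theta_high, protocol.theta_low
    # tails conditioned on the tracked weight J_ij = ±1
    pH_plus = _tail_above(thH - 1.0, b, rho, method)
    pH_minus = _tail_above(thH + 1.0, b, rho, method)
    pL_plus = 1.0 - _tail_above(thL - 1.0, b, rho, method)  # P(+1 + B <= thL)
    pL_minus = 1.0 - _tail_above(thL + 1.0, b, rho, method)
    tail_H = rho * pH_plus + (1.0 - rho) * pH_minus
    tail_L = rho * pL_plus + (1.0 - rho) * pL_minus
    update = 0.5 * (tail_H + tail_L)
    p_replay = (m / N) * protocol.q * update
    R = 1.0 - (1.0 - p_replay) ** protocol.M
    correct = 0.5 * (rho * pH_plus + (1.0 - rho) * pL_minus)
    A = correct / update if update > 0.0 else 1.0
    return TransferStats(
        p_replay=p_replay,
        R=R,
        A=A,
        q_eff=R * A,
        c=R * (1.0 - A),
        gamma=(m / N) * update,
    )


def monte_carlo_transfer_stats(
    protocol: TransferProtocol,
    N: int,
    n_sessions: int,
    n_tracked: int,
    seed: int,
) -> dict:
    """Brute-force replay estimate of R and A (oracle for transfer_stats).

    Runs ``n_sessions`` independent sessions of ``M`` replays on fresh
    random two-stage chains, each tracking ``n_tracked`` random synapses,
    and reports across-session means and standard errors:
    ``{"R", "se_R", "A", "se_A", "n_updates"}``.
    """
    if n_sessions < 2:
        raise ConfigError("need >= 2 sessions for a standard error")
    R_hat = np.empty(n_sessions)
    A_hat = np.full(n_sessions, np.nan)
    n_upd_total = 0
    for s in range(n_sessions):
        rng = child_rng(seed, "mc-transfer", s)
        chain = init_chain(2, N, rng)
        J1 = chain.J[0]
        ii = rng.integers(0, N, size=n_tracked)
        jj = rng.integers(0, N - 1, size=n_tracked)
        jj[jj >= ii] += 1  # off-diagonal pairs
        upstream = J1[ii, jj]
        updated = np.zeros(n_tracked, dtype=bool)
        events = 0
        correct = 0
        for _ in range(protocol.M):
            if rng.random() < 0.5:
                theta, value, high = protocol.theta_high, 1, True
            else:
                theta, value, high = protocol.theta_low, -1, False
            rec = replay_once(chain, 1, protocol.f, theta, rng,
                              threshold_label="high" if high else "low")
            posts = rec.responders if high else ~rec.responders
            hit = rec.stimulated[jj] & posts[ii]
            if protocol.q < 1.0:
                hit &= rng.random(n_tracked) < protocol.q
            events += int(hit.sum())
            correct += int((upstream[hit] == value).sum())
            updated |= hit
        R_hat[s] = updated.mean()
        if events:
            A_hat[s] = correct / events
        n_upd_total += events
    good = ~np.isnan(A_hat)
    return {
        "R": float(R_hat.mean()),
        "se_R": float(R_hat.std(ddof=1) / np.sqrt(n_sessions)),
        "A": float(A_hat[good].mean()),
        "se_A": float(A_hat[good].std(ddof=1) / np.sqrt(good.sum())),
        "n_updates": n_upd_total,
    }


def _rho_derivative_tail(c: float, b: int) -> float:
    """d/drho P(B_rho > c) at rho = 1/2, B_rho = 2 X - b, X ~ Binomial(b, rho)."""
    if b < 1:
        return 0.0
    k = int(np.floor((c + b) / 2.0)) + 1  # B > c  <=>  X >= k
    if not (1 <= k <= b):
        return 0.0
    return float(b * binom.pmf(k - 1, b - 1, 0.5))


def linear_response_transfer(protocol: TransferProtocol, N: int) -> tuple[float, float]:
    """Exact linear-response coefficients of signal transfer by replay.

    Per replay, the expected downstream signal changes as
    ``dS_down = p * (gain_ratio * S_up - S_down)`` to linear order in the
    upstream alignment. The gain has two channels: the tracked synapse's
    own contribution to its postsynaptic input (the per-synapse accuracy
    of :func:`transfer_stats`) *and* the alignment carried by the other
    stimulated background synapses, which biases the response pattern
    toward the stored memory (replay reads out the whole row, not one
    synapse). Both are linear in the upstream signal; the background
    channel grows with the stimulated-set size and is why the effective
    gain can exceed the per-synapse accuracy bound.

    Returns ``(R, gain_ratio)`` with ``R = 1 - (1 - p)**M`` and the
    per-cycle recursion ``S_down <- (1-R) S_down + R * gain_ratio * S_up``.
    """
    m = protocol.n_stim(N)
    b = m - 1
    thH, thL = protocol.theta_high, protocol.theta_low

    def T(c: float) -> float:  # P(B > c), symmetric b-step walk
        if b < 1:
            return 1.0 if c < 0 else 0.0
        return float(binom.sf(np.floor((c + b) / 2.0), b, 0.5))

    def D(c: float) -> float:
        return _rho_derivative_tail(c, b)

    u_H = 0.5 * (T(thH - 1.0) + T(thH + 1.0))
    w_L = 1.0 - 0.5 * (T(thL - 1.0) + T(thL + 1.0))
    alpha_H = 0.5 * (T(thH - 1.0) - T(thH + 1.0)) + 0.125 * (D(thH - 1.0) + D(thH + 1.0))
    alpha_L = 0.5 * (T(thL - 1.0) - T(thL + 1.0)) + 0.125 * (D(thL - 1.0) + D(thL + 1.0))
    update = 0.5 * (u_H + w_L)
    p = (m / N) * protocol.q * update
    R = 1.0 - (1.0 - p) ** protocol.M
    gain_ratio = 0.5 * (alpha_H + alpha_L) / update if update > 0 else 0.0
    return R, gain_ratio


# ---------------------------------------------------------------------------
# corrupted mean field and the full chain simulation


def mf_neuronal_corrupted(
    q1: float,
    R: Sequence[float],
    A: Sequence[float],
    S1_0: float,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
) -> np.ndarray:
    """Continuous corrupted mean field of the neuronal chain.

    Integrates ``dS_1/dt = -q1 S_1`` and for k >= 2
    ``dS_k/dt = R_k (2 A_k - 1) S_{k-1} - R_k S_k`` (learning at rate
    ``R_k A_k`` toward upstream plus decay ``R_k (1 - A_k)`` from
    incorrect copies). ``R[k-2]``/``A[k-2]`` belong to stage k. With all
    A = 1 this is exactly the synaptic transfer-chain mean field with
    rates R. Returns signals of shape ``(n, len(t_grid))``.
    """
    R = np.asarray(R, dtype=float)
    A = np.asarray(A, dtype=float)
    if R.shape != A.shape:
        raise ValueError("R and A must have one entry per downstream stage")
    if np.any((R < 0) | (R > 1)):
        raise ConfigError("transfer rates must be in [0, 1]")
    if np.any((A < 0.5 - 1e-12) | (A > 1)):
        raise ConfigError("accuracies must be in [1/2, 1]")
    t = np.asarray(t_grid, dtype=float)
    n = R.size + 1
    S0 = np.zeros(n)
    S0[0] = S1_0

    def rhs(_t, S):
        dS = np.empty_like(S)
        dS[0] = -q1 * S[0]
        dS[1:] = R * (2.0 * A - 1.0) * S[:-1] - R * S[1:]
        return dS

    sol = solve_ivp(rhs, (t[0], t[-1]), S0, method="LSODA", t_eval=t,
                    rtol=rtol, atol=1e-12 * max(S1_0, 1.0))
    if not sol.success:
        raise RuntimeError(f"corrupted mean-field integration failed: {sol.message}")
    return sol.y


def mf_neuronal_corrupted_discrete(
    q1_eff: float,
    R: Sequence[float],
    A: Sequence[float],
    S1_0: float,
    T: int,
) -> np.ndarray:
    """Discrete corrupted recursion matching the simulator's cycle order.

    Cycle t: stage 1 decays by ``(1 - q1_eff)`` (new encoding), then each
    downstream stage k updates from the *already updated* upstream signal
    (sessions run 1->2, then 2->3, ... within the cycle):
    ``S_k <- (1 - R_k) S_k + R_k (2 A_k - 1) S_{k-1}``. At t = 0 the
    tracked memory is encoded and one session runs, so downstream stages
    start at their first-session value rather than 0.
    """
    R = np.asarray(R, dtype=float)
    A = np.asarray(A, dtype=float)
    n = R.size + 1
    S = np.zeros((n, T + 1))
    S[0, 0] = S1_0
    for k in range(1, n):  # the session that follows the t=0 encoding
        S[k, 0] = R[k - 1] * (2.0 * A[k - 1] - 1.0) * S[k - 1, 0]
    for t in range(T):
        S[0, t + 1] = (1.0 - q1_eff) * S[0, t]
        for k in range(1, n):
            S[k, t + 1] = (1.0 - R[k - 1]) * S[k, t] + R[k - 1] * (
                2.0 * A[k - 1] - 1.0
            ) * S[k - 1, t + 1]
    return S


def simulate_neuronal_chain(
    n_stages: int,
    N_neurons: int,
    protocol: TransferProtocol,
    q1: float,
    T: int,
    n_real: int,
    seed: int,
) -> SignalTrace:
    """Full network simulation over repeated encode + transfer cycles.

    Cycle t: encode a new random memory in stage 1, then run one transfer
    session (M replays per stage pair). The memory encoded at t = 0 is
    tracked: per-stage signal over its eligible synapses is recorded at
    the end of every cycle, averaged over ``n_real`` realizations.
    """
    if n_stages < 2:
        raise ConfigError("chain needs at least 2 stages for transfer")
    sig = np.empty((n_real, n_stages, T + 1), dtype=np.int64)
    n_elig = None
    for r in range(n_real):
        rng = child_rng(seed, "neuronal", r)
        chain = init_chain(n_stages, N_neurons, rng)
        tracked = encode_neuronal(chain, rng, q1)
        n_elig = tracked.n_eligible
        run_session(chain, protocol, rng)
        for k in range(n_stages):
            sig[r, k, 0] = neuronal_signal(chain, k + 1, tracked)[0]
        for t in range(1, T + 1):
            encode_neuronal(chain, rng, q1)
            run_session(chain, protocol, rng)
            for k in range(n_stages):
                sig[r, k, t] = neuronal_signal(chain, k + 1, tracked)[0]
    mean = sig.mean(axis=0)
    sd = sig.std(axis=0, ddof=1)
    return SignalTrace(
        times=np.arange(T + 1),
        signal_mean=mean,
        signal_sd=sd,
        snr=mean / np.sqrt(n_elig),
        stage_sizes=np.full(n_stages, n_elig),
        config={
            "n_stages": n_stages,
            "N_neurons": N_neurons,
            "q1": q1,
            "f": protocol.f,
            "theta_low": protocol.theta_low,
            "theta_high": protocol.theta_high,
            "M": protocol.M,
            "q": protocol.q,
        },
        seed=seed,
        n_real=n_real,
        source="neuronal",
    )
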