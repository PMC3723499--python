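"""Stochastic (Markov) simulation of binary-synapse palimpsest memories.

Three models share the same substrate — ``N`` synapses with states in
{-1, +1} that are overwritten as new random memories arrive:

* **homogeneous** (``n == 1``): every synapse adopts each new plasticity
  event with the same probability ``q``;
* **heterogeneous** (``n > 1``, :func:`simulate_population`): ``n``
  independent equal-size groups with rates ``q_1 >= ... >= q_n``, every
  group sees every memory;
* **transfer chain** (:func:`simulate_transfer_chain`): only stage 1 sees
  the memories; at every step synapse ``j`` of stage ``k+1`` copies the
  state of its counterpart in stage ``k`` with probability ``q_{k+1}``,
  so memory traces travel down the chain (systems consolidation).

The tracked memory is the one encoded at ``t = 0``; its signal is the dot
product of the current synaptic state with the tracked event pattern, and
the ideal-observer SNR divides by ``sqrt(#synapses read)`` — the standard
deviation of the overlap with an uncorrelated pattern.

All simulators are vectorized over realizations: states are int8 arrays of
shape ``(n_real, L)`` and each step consumes one float32 uniform per
synapse (the same uniform decides both whether a synapse updates and the
new ±1 value, which is valid because conditional on ``u < q`` the event
``u < q/2`` has probability 1/2 and is independent of everything else).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigError, ModelConfig
from .rng import child_rng

__all__ = [
    "sample_memory",
    "encode_step",
    "overlap_signal",
    "snr_from_signal",
    "estimate_noise_empirical",
    "SignalTrace",
    "simulate_population",
    "simulate_transfer_chain",
]


# ---------------------------------------------------------------------------
# elementary operations


def sample_memory(N: int, rng: np.random.Generator) -> np.ndarray:
    """An i.i.d. ±1 pattern of plasticity events (P(+1) = P(-1) = 1/2)."""
    if not isinstance(N, (int, np.integer)) or N < 1:
        raise ConfigError(f"pattern length must be a positive integer, got {N!r}")
    return (rng.integers(0, 2, size=N, dtype=np.int8) * 2 - 1).astype(np.int8)


def encode_step(
    state: np.ndarray, pattern: np.ndarray, q: float, rng: np.random.Generator
) -> np.ndarray:
    """One stochastic encoding: each synapse adopts its event w.p. ``q``.

    Returns a new state array; the input is not modified.
    """
    state = np.asarray(state)
    pattern = np.asarray(pattern)
    if state.shape != pattern.shape:
        raise ValueError(f"shape mismatch: state {state.shape} vs pattern {pattern.shape}")
    if not (0.0 <= q <= 1.0):
        raise ConfigError(f"learning rate must be in [0, 1], got {q!r}")
    mask = rng.random(state.shape) < q
    return np.where(mask, pattern, state).astype(np.int8)


def overlap_signal(state: np.ndarray, pattern: np.ndarray) -> int:
    """Memory signal: dot product of synaptic states with the event pattern."""
    state = np.asarray(state)
    pattern = np.asarray(pattern)
    if state.shape != pattern.shape:
        raise ValueError(f"shape mismatch: state {state.shape} vs pattern {pattern.shape}")
    return int(np.dot(state.astype(np.int64), pattern.astype(np.int64)))


def snr_from_signal(signal: float, n_read: int) -> float:
    """SNR convention: signal over ``sqrt(n_read)`` (ideal-observer noise)."""
    if n_read < 1:
        raise ValueError(f"n_read must be >= 1, got {n_read!r}")
    return float(signal) / float(np.sqrt(n_read))


def estimate_noise_empirical(
    state: np.ndarray, n_probes: int, rng: np.random.Generator
) -> float:
    """Sample SD of the overlap with fresh random patterns (validates sqrt(L)).

    This is a validation tool only; all SNRs in the package use the analytic
    sqrt(#synapses) noise.
    """
    if n_probes < 100:
        raise ConfigError(f"need at least 100 probes for a stable SD, got {n_probes}")
    state = np.asarray(state, dtype=np.int64).ravel()
    L = state.size
    probes = rng.integers(0, 2, size=(n_probes, L), dtype=np.int8) * 2 - 1
    overlaps = probes.astype(np.int64) @ state
    return float(np.std(overlaps, ddof=1))


# ---------------------------------------------------------------------------
# traces


@dataclass
class SignalTrace:
    """Per-stage signal statistics of the tracked memory on a discrete grid.

    ``signal_mean``, ``signal_sd`` and ``snr`` have shape ``(n_stages, T+1)``;
    ``snr`` is ``signal_mean / sqrt(stage_size)``. ``snr_combined`` (optimal
    readout over stages, length ``T+1``) is filled in by the mean-field layer
    or :func:`memsim.meanfield.optimal_readout`.
    """

    times: np.ndarray
    signal_mean: np.ndarray
    signal_sd: np.ndarray
    snr: np.ndarray
    stage_sizes: np.ndarray
    snr_combined: Optional[np.ndarray] = None
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    n_real: Optional[int] = None
    source: str = "markov"

    @property
    def n_stages(self) -> int:
        return self.signal_mean.shape[0]

    def signal_se(self) -> np.ndarray:
        """Standard error of ``signal_mean`` across realizations."""
        if not self.n_real:
            raise ValueError("trace carries no realization count")
        return self.signal_sd / np.sqrt(self.n_real)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: time, stage, signal_mean, signal_sd, snr, snr_combined."""
        n, T = self.signal_mean.shape
        combined = (
            np.broadcast_to(self.snr_combined, (n, T))
            if self.snr_combined is not None
            else np.full((n, T), np.nan)
        )
        return pd.DataFrame(
            {
                "time": np.tile(self.times, n),
                "stage": np.repeat(np.arange(1, n + 1), T),
                "signal_mean": self.signal_mean.ravel(),
                "signal_sd": self.signal_sd.ravel(),
                "snr": self.snr.ravel(),
                "snr_combined": combined.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# population simulators

_F32 = np.float32


def _update_inplace(states: np.ndarray, q: float, rng: np.random.Generator) -> None:
    """Encode a fresh random pattern into ``states`` at rate ``q``, in place.

    One uniform per synapse: u < q selects the update, u < q/2 the new value.
    """
    u = rng.random(states.shape, dtype=_F32)
    upd = u < q
    states[upd] = np.where(u[upd] < q / 2.0, 1, -1).astype(np.int8)


def _signals(states: np.ndarray, patterns: np.ndarray) -> np.ndarray:
    """Per-realization overlap, shape (n_real,)."""
    L = states.shape[1]
    return 2 * np.count_nonzero(states == patterns, axis=1) - L


def simulate_population(
    config: ModelConfig, T: int, n_real: int, seed: int
) -> SignalTrace:
    """Monte-Carlo trace of the homogeneous (n=1) or heterogeneous model.

    Every group sees every memory; groups are statistically independent.
    The tracked memory is encoded at t=0 into an i.i.d. ±1 initial state;
    one new uncorrelated memory follows per step.
    """
    if T < 1 or n_real < 1:
        raise ConfigError("T and n_real must be >= 1")
    L = config.stage_size
    n = config.n
    mean = np.empty((n, T + 1))
    sd = np.empty((n, T + 1))
    for k in range(n):
        q = float(config.rates[k])
        rng = child_rng(seed, "population", k)
        states = (rng.integers(0, 2, size=(n_real, L), dtype=np.int8) * 2 - 1)
        patterns = (rng.integers(0, 2, size=(n_real, L), dtype=np.int8) * 2 - 1)
        # t = 0: encode the tracked memory
        upd = rng.random((n_real, L), dtype=_F32) < q
        states[upd] = patterns[upd]
        sig = np.empty((T + 1, n_real), dtype=np.int64)
        sig[0] = _signals(states, patterns)
        for t in range(1, T + 1):
            _update_inplace(states, q, rng)
            sig[t] = _signals(states, patterns)
        mean[k] = sig.mean(axis=1)
        sd[k] = sig.std(axis=1, ddof=1)
    return SignalTrace(
        times=np.arange(T + 1),
        signal_mean=mean,
        signal_sd=sd,
        snr=mean / np.sqrt(L),
        stage_sizes=np.full(n, L),
        config=config.to_dict(),
        seed=seed,
        n_real=n_real,
        source="markov",
    )


def simulate_transfer_chain(
    config: ModelConfig, T: int, n_real: int, seed: int
) -> SignalTrace:
    """Monte-Carlo trace of the memory transfer (consolidation) chain.

    Stage 1 (N/n synapses) encodes each memory exactly as in
    :func:`simulate_population`; at every subsequent step each stage-(k+1)
    synapse copies its stage-k counterpart's *previous-step* state with
    probability ``q_{k+1}`` (copies are processed downstream-first so every
    copy reads the pre-step upstream state). Stage-k signal for k >= 2
    therefore starts at 0 and rises before decaying.
    """
    if config.n < 2:
        raise ConfigError("transfer chain needs at least 2 stages")
    if T < 1 or n_real < 1:
        raise ConfigError("T and n_real must be >= 1")
    L = config.stage_size
    n = config.n
    rates = config.rates
    rng = child_rng(seed, "transfer")
    states = [
        (rng.integers(0, 2, size=(n_real, L), dtype=np.int8) * 2 - 1) for _ in range(n)
    ]
    patterns = rng.integers(0, 2, size=(n_real, L), dtype=np.int8) * 2 - 1
    # t = 0: tracked memory encoded in stage 1 only
    upd = rng.random((n_real, L), dtype=_F32) < rates[0]
    states[0][upd] = patterns[upd]
    sig = np.empty((n, T + 1, n_real), dtype=np.int64)
    for k in range(n):
        sig[k, 0] = _signals(states[k], patterns)
    for t in range(1, T + 1):
        # copies first, downstream-first: each stage reads the upstream
        # state from the end of the previous step (Jacobi update)
        for k in range(n - 1, 0, -1):
            mask = rng.random((n_real, L), dtype=_F32) < rates[k]
            states[k][mask] = states[k - 1][mask]
        # then stage 1 encodes the next memory
        _update_inplace(states[0], float(rates[0]), rng)
        for k in range(n):
            sig[k, t] = _signals(states[k], patterns)
    mean = sig.mean(axis=2)
    sd = sig.std(axis=2, ddof=1)
    return SignalTrace(
        times=np.arange(T + 1),
        signal_mean=mean,
        signal_sd=sd,
        snr=mean / np.sqrt(L),
        stage_sizes=np.full(n, L),
        config=config.to_dict(),
        seed=seed,
        n_real=n_real,
        source="markov",
    )
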