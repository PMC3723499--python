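"""Mean-field theory of the binary-synapse memory models.

The expected signal of the tracked memory obeys linear dynamics:

* homogeneous, discrete time:  ``S(t) = N q (1-q)^t``;
* homogeneous, continuous time:  ``SNR(t) = sqrt(N) q exp(-q t)``;
* heterogeneous:  per group ``S_k(t) = (N/n) q_k exp(-q_k t)``;
* transfer chain, discrete:  ``S_1(t+1) = (1-q_1) S_1(t)`` with
  ``S_1(0) = (N/n) q_1``, and for k >= 2
  ``S_k(t+1) = (1-q_k) S_k(t) + q_k S_{k-1}(t)``, ``S_k(0) = 0``;
* transfer chain, continuous:  ``dS_1/dt = -q_1 S_1``,
  ``dS_k/dt = q_k (S_{k-1} - S_k)``.

With geometric rates ``q_k = q_1 r^{k-1}`` the transfer-chain signal is a
localized pulse in stage index that travels at an exponentially decreasing
speed; :func:`pulse_snr_asymptotic` evaluates a saddle-point asymptotic of
the exact Laplace-space solution

    S_k(s) = (S_1(0)/q_1) * prod_{j<=k} q_j / (s + q_j)

(a lower-bidiagonal chain, so the transform is a product of simple poles).

Reading out a subset K of stages gives combined SNR
``sum_{k in K} S_k / sqrt(sum_{k in K} L_k)`` (uncorrelated-noise
approximation); :func:`optimal_readout` maximizes this over subsets.
Memory lifetime is the largest time at which the (optimal-readout) SNR is
still >= 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .config import ConfigError, ModelConfig

__all__ = [
    "MeanFieldCurve",
    "mf_homogeneous_discrete",
    "mf_homogeneous_snr_continuous",
    "mf_heterogeneous",
    "mf_transfer_discrete",
    "mf_transfer_ode",
    "pulse_snr_asymptotic",
    "optimal_readout",
    "optimal_readout_curve",
    "lifetime_homogeneous",
    "lifetime_numeric",
    "lifetime_asymptotic",
    "crossing_time",
    "HorizonExceededError",
]


class HorizonExceededError(RuntimeError):
    """The SNR curve never dropped below 1 inside the supplied horizon."""


@dataclass
class MeanFieldCurve:
    """Deterministic per-stage signal/SNR on a time grid.

    ``per_stage_signal`` and ``per_stage_snr`` have shape ``(n, T)``;
    ``snr_optimal`` (length ``T``) is the optimal-readout combined SNR and
    ``readout_size`` the number of stages it reads at each time.
    """

    times: np.ndarray
    per_stage_signal: np.ndarray
    per_stage_snr: np.ndarray
    stage_sizes: np.ndarray
    snr_optimal: Optional[np.ndarray] = None
    readout_size: Optional[np.ndarray] = None
    config: dict = field(default_factory=dict)
    source: str = "meanfield"

    @property
    def n_stages(self) -> int:
        return self.per_stage_signal.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        n, T = self.per_stage_signal.shape
        combined = (
            np.broadcast_to(self.snr_optimal, (n, T))
            if self.snr_optimal is not None
            else np.full((n, T), np.nan)
        )
        return pd.DataFrame(
            {
                "time": np.tile(self.times, n),
                "stage": np.repeat(np.arange(1, n + 1), T),
                "signal_mean": self.per_stage_signal.ravel(),
                "signal_sd": np.zeros(n * T),
                "snr": self.per_stage_snr.ravel(),
                "snr_combined": combined.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# homogeneous / heterogeneous


def mf_homogeneous_discrete(N: int, q: float, t: int | np.ndarray) -> float | np.ndarray:
    """Expected discrete-time signal ``N q (1-q)^t`` of the t=0 memory."""
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not (0.0 < q <= 1.0):
        raise ConfigError(f"q must be in (0, 1], got {q!r}")
    out = N * q * (1.0 - q) ** t
    return float(out) if out.ndim == 0 else out


def mf_homogeneous_snr_continuous(
    N: int, q: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Continuous-time SNR ``sqrt(N) q exp(-q t)``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not (0.0 < q <= 1.0):
        raise ConfigError(f"q must be in (0, 1], got {q!r}")
    out = np.sqrt(N) * q * np.exp(-q * t)
    return float(out) if out.ndim == 0 else out


def mf_heterogeneous(
    config: ModelConfig, t_grid: Sequence[float], readout: str = "optimal"
) -> MeanFieldCurve:
    """Mean-field curve of the heterogeneous (non-interacting) model.

    ``readout`` is ``"all"`` (sum every group, noise sqrt(N)) or
    ``"optimal"`` (best subset of groups at each time).
    """
    if readout not in ("all", "optimal"):
        raise ValueError(f"unknown readout {readout!r}; use 'all' or 'optimal'")
    t = np.asarray(t_grid, dtype=float)
    L = config.stage_size
    signals = L * config.rates[:, None] * np.exp(-config.rates[:, None] * t[None, :])
    snr = signals / np.sqrt(L)
    sizes = np.full(config.n, L)
    if readout == "all":
        combined = signals.sum(axis=0) / np.sqrt(config.N)
        nread = np.full(t.size, config.n)
    else:
        combined, nread = optimal_readout_curve(signals, sizes)
    return MeanFieldCurve(
        times=t,
        per_stage_signal=signals,
        per_stage_snr=snr,
        stage_sizes=sizes,
        snr_optimal=combined,
        readout_size=nread,
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# transfer chain


def mf_transfer_discrete(config: ModelConfig, T: int) -> MeanFieldCurve:
    """Discrete mean-field recursion for the transfer chain (exact)."""
    if config.n < 2:
        raise ConfigError("transfer chain needs at least 2 stages")
    if T < 0:
        raise ValueError("T must be >= 0")
    n, L, q = config.n, config.stage_size, config.rates
    S = np.zeros((n, T + 1))
    S[0, 0] = L * q[0]
    for t in range(T):
        S[0, t + 1] = (1.0 - q[0]) * S[0, t]
        S[1:, t + 1] = (1.0 - q[1:]) * S[1:, t] + q[1:] * S[:-1, t]
    snr = S / np.sqrt(L)
    sizes = np.full(n, L)
    combined, nread = optimal_readout_curve(S, sizes)
    return MeanFieldCurve(
        times=np.arange(T + 1, dtype=float),
        per_stage_signal=S,
        per_stage_snr=snr,
        stage_sizes=sizes,
        snr_optimal=combined,
        readout_size=nread,
        config=config.to_dict(),
    )


def mf_transfer_ode(
    config: ModelConfig,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol_rel: float = 1e-12,
) -> MeanFieldCurve:
    """Continuous-time transfer-chain mean field (stiff-capable LSODA).

    ``atol_rel`` scales the absolute tolerance by the initial stage-1
    signal so accuracy is relative to the natural signal scale.
    """
    if config.n < 2:
        raise ConfigError("transfer chain needs at least 2 stages")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("t_grid must be increasing and non-negative")
    n, L, q = config.n, config.stage_size, config.rates
    S0 = np.zeros(n)
    S0[0] = L * q[0]

    def rhs(_t, S):
        dS = np.empty_like(S)
        dS[0] = -q[0] * S[0]
        dS[1:] = q[1:] * (S[:-1] - S[1:])
        return dS

    t0 = t[0]
    sol = solve_ivp(
        rhs,
        (t0, t[-1]),
        S0,
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol_rel * max(S0[0], 1.0),
    )
    if not sol.success:
        raise RuntimeError(f"transfer-chain ODE integration failed: {sol.message}")
    S = sol.y
    if t0 > 0:  # solve_ivp starts at t[0]; the initial condition is at t=0
        raise ValueError("t_grid must start at 0 (initial condition lives there)")
    snr = S / np.sqrt(L)
    sizes = np.full(n, L)
    combined, nread = optimal_readout_curve(S, sizes)
    return MeanFieldCurve(
        times=t,
        per_stage_signal=S,
        per_stage_snr=snr,
        stage_sizes=sizes,
        snr_optimal=combined,
        readout_size=nread,
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# asymptotic pulse


def _saddle_signal(k: int, t: float, rates: np.ndarray, S1_0: float) -> float:
    """Saddle-point value of S_k(t) for one stage (second-order Laplace).

    Inverts ``S_k(s) = (S1_0/q_1) prod_{j<=k} q_j/(s+q_j)`` along the
    vertical contour through the real saddle ``s*`` where
    ``sum_j 1/(s*+q_j) = t``.
    """
    q = rates[:k]
    qmin = q[-1]  # rates are non-increasing

    def fprime(u):  # u = s + qmin > 0
        return np.sum(1.0 / (u + (q - qmin))) - t

    u_hi = k / t + q[0]
    u_lo = min(1e-280, u_hi * 1e-30)
    ustar = brentq(fprime, u_lo, u_hi, rtol=1e-14, maxiter=200)
    s = ustar - qmin
    d = s + q  # distances to the poles, all > 0
    G = s * t + np.sum(np.log(q) - np.log(d))
    G2 = np.sum(1.0 / d**2)
    G3 = -2.0 * np.sum(1.0 / d**3)
    G4 = 6.0 * np.sum(1.0 / d**4)
    corr = 1.0 + G4 / (8.0 * G2**2) - 5.0 * G3**2 / (24.0 * G2**3)
    return (S1_0 / q[0]) * np.exp(G) / np.sqrt(2.0 * np.pi * G2) * max(corr, 0.0)


def pulse_travel_time(config: ModelConfig, stage: float | None = None) -> float:
    """Time for the pulse peak to reach ``stage`` (default: the last stage).

    The peak advances where the local rate matches 1/t; with geometric
    rates this gives ``t(x) = (exp(lam (x-1)) - 1) / (lam q1)`` where
    ``lam = ln(q1/qn)/(n-1)`` — exponentially decreasing speed.
    """
    if config.n < 2:
        raise ConfigError("pulse requires n >= 2")
    x = config.n if stage is None else float(stage)
    lam = np.log(config.q1 / config.qn) / (config.n - 1)
    if lam == 0.0:
        return (x - 1) / config.q1
    return float(np.expm1(lam * (x - 1)) / (lam * config.q1))


def pulse_snr_asymptotic(config: ModelConfig, t: float) -> np.ndarray:
    """Asymptotic per-stage SNR of the travelling consolidation pulse.

    Valid in the travelling-pulse regime: many stages (n >~ 10) and
    ``1/q1 << t <~`` the arrival time at the last stage; outside it a
    warning is issued (never an error). The peak stage is non-decreasing
    in ``t`` and the formula matches the ODE solution at the peak to
    ~O(1/k) (second-order Laplace correction included).
    """
    if config.n < 2:
        raise ConfigError("pulse requires n >= 2")
    if t < 0:
        raise ValueError("time must be non-negative")
    n, L = config.n, config.stage_size
    t_arr = pulse_travel_time(config)
    if n < 10 or t * config.q1 < 1.0 or t > t_arr:
        warnings.warn(
            "pulse asymptotics outside documented validity "
            f"(need n >= 10 and 1/q1 <= t <= {t_arr:.3g}); values may be inaccurate",
            stacklevel=2,
        )
    S1_0 = L * config.q1
    if t == 0.0:
        S = np.zeros(n)
        S[0] = S1_0
        return S / np.sqrt(L)
    S = np.array([_saddle_signal(k, t, config.rates, S1_0) for k in range(1, n + 1)])
    return S / np.sqrt(L)


# ---------------------------------------------------------------------------
# readout


def optimal_readout(
    per_stage_signal: Sequence[float], per_stage_size: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Best subset of stages for the combined SNR ``sum S / sqrt(sum L)``.

    Returns ``(indices, snr)``. For equal stage sizes the optimum is a
    prefix of the stages sorted by signal (provably: for fixed subset size
    take the largest signals, then scan sizes); that path is exact. For
    unequal sizes an exhaustive search is used up to 20 stages, beyond
    that a density-ordered prefix scan refined by single-stage swaps.
    """
    S = np.asarray(per_stage_signal, dtype=float)
    Ls = np.asarray(per_stage_size, dtype=float)
    if S.size == 0:
        raise ValueError("need at least one stage")
    if S.shape != Ls.shape or np.any(Ls <= 0):
        raise ValueError("signals and sizes must match and sizes be positive")
    m = S.size
    if np.all(Ls == Ls[0]):
        order = np.argsort(-S)
        csum = np.cumsum(S[order])
        vals = csum / np.sqrt(Ls[0] * np.arange(1, m + 1))
        best = int(np.argmax(vals))
        return np.sort(order[: best + 1]), float(vals[best])
    if m <= 20:
        best_val, best_set = -np.inf, None
        for r in range(1, m + 1):
            for combo in itertools.combinations(range(m), r):
                idx = list(combo)
                v = S[idx].sum() / np.sqrt(Ls[idx].sum())
                if v > best_val:
                    best_val, best_set = v, idx
        return np.array(best_set), float(best_val)
    # large, unequal sizes: density prefix + local search (heuristic)
    order = np.argsort(-(S / Ls))
    best_val, best_mask = -np.inf, None
    mask = np.zeros(m, dtype=bool)
    for j in order:
        mask[j] = True
        v = S[mask].sum() / np.sqrt(Ls[mask].sum())
        if v > best_val:
            best_val, best_mask = v, mask.copy()
    improved = True
    while improved:
        improved = False
        for j in range(m):
            trial = best_mask.copy()
            trial[j] = ~trial[j]
            if not trial.any():
                continue
            v = S[trial].sum() / np.sqrt(Ls[trial].sum())
            if v > best_val + 1e-15 * abs(best_val):
                best_val, best_mask, improved = v, trial, True
    return np.flatnonzero(best_mask), float(best_val)


def optimal_readout_curve(
    signals: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal combined SNR at every column of a (n_stages, T) signal array.

    Returns ``(snr_optimal, n_stages_read)``. Assumes equal stage sizes
    (the models here always have them); vectorized prefix scan.
    """
    if not np.all(sizes == sizes[0]):
        raise ValueError("optimal_readout_curve assumes equal stage sizes")
    n, T = signals.shape
    order = np.argsort(-signals, axis=0)
    csum = np.cumsum(np.take_along_axis(signals, order, axis=0), axis=0)
    vals = csum / np.sqrt(sizes[0] * np.arange(1, n + 1))[:, None]
    best = np.argmax(vals, axis=0)
    return vals[best, np.arange(T)], best + 1


# ---------------------------------------------------------------------------
# lifetimes and crossings


def lifetime_homogeneous(N: int, q: float) -> float:
    """Closed-form lifetime ``ln(sqrt(N) q)/q`` (0 if SNR never reaches 1)."""
    snr0 = np.sqrt(N) * q
    if snr0 < 1.0:
        return 0.0
    return float(np.log(snr0) / q)


def lifetime_numeric(
    snr_curve: Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray],
    horizon: float = 1e12,
    t_min: float = 1e-6,
    points_per_decade: int = 200,
) -> float:
    """Largest t with SNR(t) >= 1 (last downcrossing of 1).

    ``snr_curve`` is either a vectorized callable or a ``(times, values)``
    pair. Callables are bracketed on a log grid (>= ``points_per_decade``
    per decade) and refined by Brent's method; sampled curves use linear
    interpolation between grid points. Returns 0 if the curve never
    reaches 1; raises :class:`HorizonExceededError` if it is still >= 1
    at the horizon (or at the end of the sampled grid).
    """
    if callable(snr_curve):
        n_pts = max(2, int(np.log10(horizon / t_min) * points_per_decade))
        ts = np.concatenate([[0.0], np.logspace(np.log10(t_min), np.log10(horizon), n_pts)])
        vals = np.asarray(snr_curve(ts), dtype=float)
    else:
        ts, vals = (np.asarray(a, dtype=float) for a in snr_curve)
        if ts.shape != vals.shape or ts.ndim != 1:
            raise ValueError("sampled curve must be two matching 1-d arrays")
    above = vals >= 1.0
    if not above.any():
        return 0.0
    if above[-1]:
        raise HorizonExceededError(
            "SNR still >= 1 at the end of the horizon; extend it to bracket the lifetime"
        )
    i = int(np.max(np.flatnonzero(above)))  # last point at or above 1
    if callable(snr_curve):
        f = lambda t: float(snr_curve(np.asarray([t]))[0]) - 1.0
        return float(brentq(f, ts[i], ts[i + 1], xtol=1e-12, rtol=1e-12))
    # linear interpolation on the sampled segment
    t0, t1, v0, v1 = ts[i], ts[i + 1], vals[i], vals[i + 1]
    if v0 == v1:
        return float(t0)
    return float(t0 + (1.0 - v0) * (t1 - t0) / (v1 - v0))


def lifetime_asymptotic(config: ModelConfig) -> float:
    """Two-regime asymptotic lifetime of the transfer chain.

    If the pulse is still detectable (peak SNR > 1) when it reaches the
    last stage, the memory then sits in the slowest synapses and decays
    exponentially: ``lifetime ~ t_arrival + ln(SNR_arrival)/qn``.
    Otherwise the lifetime is where the travelling pulse's optimal-readout
    SNR itself drops to 1, found by bisection in log time. Order-of-
    magnitude accurate (validated against the ODE within a factor of 2).
    """
    if config.n < 2:
        raise ConfigError("transfer chain needs at least 2 stages")
    t_arr = pulse_travel_time(config)

    def peak_snr(t: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            snr = pulse_snr_asymptotic(config, t)
        combined, _ = optimal_readout_curve(
            snr[:, None] * np.sqrt(config.stage_size),
            np.full(config.n, config.stage_size),
        )
        return float(combined[0])

    snr_arr = peak_snr(t_arr)
    if snr_arr > 1.0:
        return float(t_arr + np.log(snr_arr) / config.qn)
    # pulse dies mid-chain: bisect peak SNR = 1 on log t
    lo = 1.0 / config.q1
    if peak_snr(lo) <= 1.0:
        return float(lo)
    f = lambda logt: np.log(peak_snr(np.exp(logt)))
    return float(np.exp(brentq(f, np.log(lo), np.log(t_arr), xtol=1e-10)))


def crossing_time(
    times: np.ndarray, curve_a: np.ndarray, curve_b: np.ndarray
) -> float:
    """Time from which curve_b (transfer) permanently dominates curve_a.

    Returns the interpolated time of the last ``b < a`` -> ``b >= a``
    transition, 0 if ``b >= a`` everywhere, and NaN (no-crossing sentinel)
    if ``b < a`` at the end of the grid.
    """
    times = np.asarray(times, dtype=float)
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if not (times.shape == a.shape == b.shape):
        raise ValueError("curves must share one time grid")
    below = b < a
    if not below.any():
        return 0.0
    if below[-1]:
        return float("nan")
    i = int(np.max(np.flatnonzero(below)))  # last index with b < a
    d0 = a[i] - b[i]
    d1 = a[i + 1] - b[i + 1]
    if d0 == d1:
        return float(times[i + 1])
    return float(times[i] + d0 * (times[i + 1] - times[i]) / (d0 - d1))
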