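"""Model configuration for the synaptic memory models.

A memory system is ``N`` binary synapses split into ``n`` equal stages
(groups).  Stage ``k`` has learning rate ``q_k`` on a geometric ladder from
``q1`` (fastest, stage 1) down to ``qn`` (slowest, stage n):

    q_k = q1 * r**(k-1),   r = (qn / q1) ** (1 / (n - 1))

so the timescales 1/q_k tile the interval [1/q1, 1/qn] evenly on a log axis.
The coding-level factor ``F`` rescales every rate uniformly (sparse memory
representations are equivalent to dense ones with all q's scaled by the
fraction of synapses addressed); the core simulators always run dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfigError", "geometric_rates", "ModelConfig"]


class ConfigError(ValueError):
    """Invalid model configuration."""


def geometric_rates(n: int, q1: float, qn: float) -> np.ndarray:
    """Geometric ladder of learning rates ``[q1, q1*r, ..., qn]``.

    Parameters
    ----------
    n : number of stages (>= 1).
    q1, qn : fastest and slowest rates, ``0 < qn <= q1 <= 1``.

    The endpoints are returned exactly; for ``n == 1`` the two must agree.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ConfigError(f"number of stages must be a positive integer, got {n!r}")
    if not (0.0 < qn <= q1 <= 1.0):
        raise ConfigError(
            f"rates must satisfy 0 < qn <= q1 <= 1, got q1={q1!r}, qn={qn!r}"
        )
    if n == 1:
        if qn != q1:
            raise ConfigError("with a single stage q1 and qn must coincide")
        return np.array([float(q1)])
    r = (qn / q1) ** (1.0 / (n - 1))
    rates = q1 * r ** np.arange(n, dtype=float)
    rates[0] = q1
    rates[-1] = qn
    return rates


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of a homogeneous / heterogeneous / transfer memory model.

    Attributes
    ----------
    N : total number of binary synapses (divisible by ``n``).
    n : number of equal-size stages; ``n == 1`` is the homogeneous model.
    q1, qn : fastest / slowest learning rate.
    F : coding-level factor in (0, 1]; rescales all rates uniformly
        (used by :func:`memsim.experiments.coding_level_rescale` only).
    """

    N: int
    n: int
    q1: float
    qn: float
    F: float = 1.0
    rates: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.N, (int, np.integer)) or self.N < 1:
            raise ConfigError(f"N must be a positive integer, got {self.N!r}")
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ConfigError(f"n must be a positive integer, got {self.n!r}")
        if self.N % self.n != 0:
            raise ConfigError(
                f"N={self.N} is not divisible by n={self.n}; refusing to truncate"
            )
        if not (0.0 < self.F <= 1.0):
            raise ConfigError(f"coding level F must be in (0, 1], got {self.F!r}")
        rates = geometric_rates(self.n, self.q1, self.qn) * self.F
        object.__setattr__(self, "rates", rates)

    @property
    def stage_size(self) -> int:
        """Synapses per stage, N/n."""
        return self.N // self.n

    @property
    def r(self) -> float:
        """Geometric ratio between consecutive stage rates."""
        if self.n == 1:
            return 1.0
        return (self.qn / self.q1) ** (1.0 / (self.n - 1))

    def to_dict(self) -> dict:
        return {"N": int(self.N), "n": int(self.n), "q1": float(self.q1),
                "qn": float(self.qn), "F": float(self.F)}

    @classmethod
    def homogeneous(cls, N: int, q: float, F: float = 1.0) -> "ModelConfig":
        """Single-stage model with one learning rate."""
        return cls(N=N, n=1, q1=q, qn=q, F=F)
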