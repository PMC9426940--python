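"""Classical random-walk baseline.

The classical counterpart of the quantum walk is the Markov chain

    p(x, t) = q p(x-1, t-1) + (1-q) p(x+1, t-1)

computed here by exact probability propagation (no Monte Carlo), so that
oracle comparisons against the quantum engine carry no sampling noise.
On a segment [0, N] with absorbing ends the walk started at x0 is the
gambler's-ruin chain: it hits 0 first with probability (N-x0)/N.
"""

from __future__ import annotations

import numpy as np

from .boundaries import STALL_PATIENCE, STALL_THRESHOLD, AbsorptionRecord

__all__ = [
    "ClassicalWalkSpec",
    "classical_distribution",
    "hitting_probability",
    "classical_absorption_series",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class ClassicalWalkSpec:
    """Step-right probability q, start x0, and optional absorbing ends."""

    q: float = 0.5
    x0: int = 0
    left_absorbing: int | None = None
    right_absorbing: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"step probability q must lie in [0, 1], got {self.q}")


def classical_distribution(spec: ClassicalWalkSpec, t: int) -> tuple[np.ndarray, np.ndarray]:
    """(sites, p(x, t)) on the boundary-free line after t steps."""
    if t < 0:
        raise ValueError(f"number of steps must be non-negative, got {t}")
    p = np.array([1.0])
    xmin = spec.x0
    for _ in range(t):
        n = len(p)
        nxt = np.zeros(n + 2)
        nxt[2:] += spec.q * p  # right steps
        nxt[:n] += (1.0 - spec.q) * p  # left steps
        p = nxt
        xmin -= 1
    return np.arange(xmin, xmin + len(p)), p


def hitting_probability(x0: int, n: int) -> float:
    """Gambler's-ruin probability of hitting 0 before N for the symmetric
    walk on [0, N] started at x0: (N - x0) / N."""
    if not 0 <= x0 <= n:
        raise ValueError(f"start x0={x0} outside segment [0, {n}]")
    return (n - x0) / n


def classical_absorption_series(spec: ClassicalWalkSpec, T: int) -> AbsorptionRecord:
    """Time-resolved absorption of the classical walk (exact propagation).

    Handles a single absorbing end (the other side unbounded) or two.
    Stops early once per-step absorption stalls, like the quantum driver.
    """
    left_b, right_b = spec.left_absorbing, spec.right_absorbing
    if left_b is None and right_b is None:
        raise ValueError("classical_absorption_series requires an absorbing boundary")
    lo = left_b if left_b is not None else spec.x0 - T - 1
    hi = right_b if right_b is not None else spec.x0 + T + 1
    p = np.zeros(hi - lo + 1)
    p[spec.x0 - lo] = 1.0
    inc_l = np.zeros(T)
    inc_r = np.zeros(T)
    stall = 0
    truncated_at = T
    for k in range(T):
        nxt = np.zeros_like(p)
        nxt[1:] += spec.q * p[:-1]
        nxt[:-1] += (1.0 - spec.q) * p[1:]
        p = nxt
        got = 0.0
        if left_b is not None:
            inc_l[k] = p[0]
            got += p[0]
            p[0] = 0.0
        if right_b is not None:
            inc_r[k] = p[-1]
            got += p[-1]
            p[-1] = 0.0
        stall = stall + 1 if got < STALL_THRESHOLD else 0
        if stall >= STALL_PATIENCE:
            truncated_at = k + 1
            inc_l, inc_r = inc_l[: k + 1], inc_r[: k + 1]
            break
    return AbsorptionRecord(inc_l, inc_r, residual=float(p.sum()), truncated_at=truncated_at)
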