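"""Decision models built on the walk engine.

Three applications:

* **Subjective probability** — an objective probability p is encoded in
  the geometry of a segment [0, N] with absorbing ends: the walker starts
  at x0 = N(1-p), so a classical walker given unlimited time exits left
  with probability exactly p.  The subjective judgment is the conditional
  absorption probability π(t) = p_L(t) / (p_L(t) + p_R(t)) of the quantum
  walk, which bends into the inverse-S curves familiar from probability
  weighting, while decoherence (p_m -> 1) restores the rational diagonal
  π = p.

* **Conjunction fallacy** — with a single left absorbing boundary the
  Hadamard walk started at x=1 exits left with probability 2/π; adding a
  second absorbing boundary on the right *increases* the left exit
  probability (interference removal), reversing the classical inequality
  P(A and B) <= P(A).

* **Choice-then-confidence interference** — a walk on [0, N] with
  reflecting walls and a position-dependent coin rho(x) = x/(N-1) drifts
  toward the left wall; expected position tracks the confidence rating and
  the global spin the binary choice.  A prior decision is a single full
  (position and spin) measurement event that visibly disturbs the
  subsequent confidence trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boundaries import AbsorptionRecord, absorption_series, reflecting_coin_map
from .classical import ClassicalWalkSpec, classical_absorption_series
from .evolution import StepOperator, density_step
from .measurement import kraus_set, position_distribution, spin_probabilities
from .states import CoinParams, DensityState, InitialSpec, WalkConfig, make_gaussian_state

__all__ = [
    "SubjectiveCurve",
    "ConfidenceTrajectory",
    "subjective_probability",
    "subjective_curve",
    "conjunction_demo",
    "confidence_task",
    "confidence_comparison",
]

#: default distance between the absorbing ends of the judgment segment
DEFAULT_SEGMENT = 50


def _judgment_record(
    n: int,
    x0: int,
    rho: float,
    xi: float,
    eta: float,
    t: int,
    p_m: float,
    basis: str,
) -> AbsorptionRecord:
    mechanism = "coin" if p_m == 0.0 else "measurement"
    config = WalkConfig(
        coin=CoinParams(rho=rho, xi=xi),
        domain=("segment", n),
        boundaries={"left": "absorbing", "right": "absorbing"},
        mechanism=mechanism,
        initial=InitialSpec(eta=eta, x0=x0),
        p_m=p_m,
        basis=basis,
        T=t,
    )
    return absorption_series(config, t)


def subjective_probability(
    p: float,
    n: int = DEFAULT_SEGMENT,
    rho: float = 0.5,
    xi: float = 0.0,
    eta: float = 0.5,
    t: int = 60,
    p_m: float = 0.0,
    basis: str = "position",
    engine: str = "quantum",
    conditional: str = "cumulative",
) -> float:
    """π for one objective probability p (see module docstring).

    x0 = round(N(1-p)) must be an interior site.  Returns NaN if nothing
    has been absorbed by time t.  ``engine="classical"`` swaps in the exact
    classical baseline.
    """
    x0 = round(n * (1.0 - p))
    if not 0 < x0 < n:
        raise ValueError(f"objective probability p={p} puts x0={x0} on a boundary of [0, {n}]")
    if engine == "classical":
        rec = classical_absorption_series(
            ClassicalWalkSpec(q=0.5, x0=x0, left_absorbing=0, right_absorbing=n), t
        )
    elif engine == "quantum":
        rec = _judgment_record(n, x0, rho, xi, eta, t, p_m, basis)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    pi = rec.conditional_left(conditional)
    return float(pi[-1])


@dataclass
class SubjectiveCurve:
    """π(p) over a grid of objective probabilities, plus the run parameters."""

    p_grid: np.ndarray
    pi: np.ndarray
    p_left: np.ndarray
    p_right: np.ndarray
    residual: np.ndarray
    params: dict


def subjective_curve(
    p_grid,
    n: int = DEFAULT_SEGMENT,
    rho: float = 0.5,
    xi: float = 0.0,
    eta: float = 0.5,
    t: int = 60,
    p_m: float = 0.0,
    basis: str = "position",
    engine: str = "quantum",
) -> SubjectiveCurve:
    """Vectorised :func:`subjective_probability` over a p grid."""
    p_grid = np.asarray(p_grid, float)
    pi = np.empty_like(p_grid)
    pl = np.empty_like(p_grid)
    pr = np.empty_like(p_grid)
    res = np.empty_like(p_grid)
    for i, p in enumerate(p_grid):
        x0 = round(n * (1.0 - p))
        if engine == "classical":
            rec = classical_absorption_series(
                ClassicalWalkSpec(q=0.5, x0=x0, left_absorbing=0, right_absorbing=n), t
            )
        else:
            rec = _judgment_record(n, x0, rho, xi, eta, t, p_m, basis)
        pl[i], pr[i], res[i] = rec.total_left, rec.total_right, rec.residual
        pi[i] = rec.conditional_left()[-1]
    return SubjectiveCurve(
        p_grid,
        pi,
        pl,
        pr,
        res,
        params={"n": n, "rho": rho, "xi": xi, "eta": eta, "t": t, "p_m": p_m, "basis": basis},
    )


def conjunction_demo(n: int = 100, T: int = 5000, mode: str = "quantum") -> dict:
    """Left-exit probability with one vs two absorbing boundaries.

    Start x=1, Hadamard coin (classical mode: q=0.5), left boundary at 0,
    optional right boundary at n.  Returns p_single, p_double and
    percent_increase = 100 (p_double/p_single - 1); quantum mode shows the
    conjunction-fallacy reversal p_double > p_single.
    """
    if n <= 1:
        raise ValueError(f"right boundary n must exceed 1, got {n}")
    if mode == "classical":
        single = classical_absorption_series(
            ClassicalWalkSpec(q=0.5, x0=1, left_absorbing=0), T
        )
        double = classical_absorption_series(
            ClassicalWalkSpec(q=0.5, x0=1, left_absorbing=0, right_absorbing=n), T
        )
    elif mode == "quantum":
        common = dict(initial=InitialSpec(eta=0.5, x0=1), T=T)
        single = absorption_series(
            WalkConfig(domain=("line",), boundaries={"left": "absorbing", "right": None}, **common)
        )
        double = absorption_series(
            WalkConfig(
                domain=("segment", n),
                boundaries={"left": "absorbing", "right": "absorbing"},
                **common,
            )
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p_single = single.total_left
    p_double = double.total_left
    return {
        "p_single": p_single,
        "p_double": p_double,
        "percent_increase": 100.0 * (p_double / p_single - 1.0),
        "residual_single": single.residual,
        "residual_double": double.residual,
    }


@dataclass
class ConfidenceTrajectory:
    """Expected position (confidence proxy) over time, plus the choice read-out."""

    times: np.ndarray
    expected_position: np.ndarray
    prior_time: int | None
    choice_probabilities: tuple[float, float] | None  # (p_L, p_R) at prior_time


def drift_coin_map(n: int):
    """Interior coin rho(x) = x/(N-1), xi=zeta=0: larger rho on the right
    drifts the walker toward the left wall."""

    def coin_at(x: int) -> CoinParams:
        xx = min(max(x, 1), n - 1)
        return CoinParams(rho=xx / (n - 1))

    return coin_at


def confidence_task(
    n: int = 100,
    T: int = 200,
    prior_time: int | None = None,
    sigma: float | None = None,
) -> ConfidenceTrajectory:
    """Run the choice-then-confidence walk and record expected position.

    Reflecting swap coins at 0 and N, drift coin rho(x)=x/(N-1) inside,
    Gaussian start at N/2 with width N/6.  ``prior_time`` triggers a single
    full position-and-spin measurement (the prior decision) at that step;
    the global spin probabilities there are the modelled choice
    probabilities.
    """
    if prior_time is not None and prior_time > T:
        raise ValueError(f"prior decision time {prior_time} exceeds the horizon T={T}")
    sigma = n / 6 if sigma is None else sigma
    spec = InitialSpec(eta=0.5, x0=n // 2, sigma=sigma)
    state = DensityState.from_pure(make_gaussian_state(spec, n))
    op = StepOperator(reflecting_coin_map(drift_coin_map(n), 0, n), grow=False)
    full_measurement = kraus_set("both", 1.0)

    expected = np.empty(T + 1)
    sites, probs = position_distribution(state)
    expected[0] = np.sum(sites * probs)
    choice = None
    for k in range(1, T + 1):
        state = density_step(state, op)
        if prior_time is not None and k == prior_time:
            pl, pr = spin_probabilities(state)
            # normalise by the live mass (a ~1e-5 tail of the initial
            # Gaussian leaks past the walls in the first steps)
            choice = (pl / (pl + pr), pr / (pl + pr))
            state = full_measurement.apply(state)
        sites, probs = position_distribution(state)
        expected[k] = np.sum(sites * probs)
    return ConfidenceTrajectory(
        times=np.arange(T + 1),
        expected_position=expected,
        prior_time=prior_time,
        choice_probabilities=choice,
    )


def confidence_comparison(
    n: int = 100, T: int = 200, prior_time: int = 50
) -> tuple[ConfidenceTrajectory, ConfidenceTrajectory]:
    """(with-prior, without-prior) confidence trajectories on one config."""
    with_prior = confidence_task(n=n, T=T, prior_time=prior_time)
    without = confidence_task(n=n, T=T, prior_time=None)
    return with_prior, without
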