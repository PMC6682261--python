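"""Cell-environment prediction-error toy model.

A cell C embedded in an environment E maintains an input state ``a(t)``
(what the environment does to it) and a prediction ``p(t)`` (what it
expects). Exposure is a single coupling parameter ``beta``: the
environment acts on the cell as ``a(t+1) = beta * e(t)``, with ``e(t)``
drawn at random each step. Under the homeostatic prediction
``p(t+1) = a(t)`` the prediction error ``delta(t) = |a(t) - p(t)|``
vanishes as ``beta -> 0`` and becomes random as ``beta -> 1``.

Death is tied to prediction failure: a prediction error exceeding the
lethal threshold ``delta_lethal`` kills the cell, and the expected
per-cycle death fraction is ``beta * delta_lethal`` — the quantity that
plays the role of ``beta * b`` in :mod:`somasim.growth`. The microscopic
death rule used here is calibrated so that the per-cycle death
probability equals ``beta * delta_lethal`` exactly (death iff
``u < beta * delta_lethal`` with ``u ~ uniform[0,1]``); the delta(t)
trajectory machinery is retained for illustration and property tests
rather than as the death trigger.

With ``d`` independent environmental dimensions, a prediction failure in
any single dimension is lethal, so the number of distinct lethal failure
combinations is ``2**d - 1`` (every non-empty subset of dimensions) and
survival stays probable only when exposure scales like ``2**-d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PredictiveCellState",
    "EnvState",
    "LethalityThreshold",
    "BufferEconomy",
    "couple",
    "prediction_error",
    "death_fraction",
    "simulate_death_fraction",
    "multidim_survival",
    "replacement_feasible",
    "protected_growth_rate",
]


def _unit_array(name: str, x) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a 1-d vector with at least one component")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"all components of {name} must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class PredictiveCellState:
    """Input state a(t) and prediction p(t), componentwise in [0, 1]."""

    input_state: np.ndarray
    prediction: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        a = _unit_array("input_state", self.input_state)
        p = _unit_array("prediction", self.prediction)
        if a.shape != p.shape:
            raise ValueError(
                f"input_state and prediction must have equal dimension, "
                f"got {a.shape} vs {p.shape}"
            )
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta!r}")
        object.__setattr__(self, "input_state", a)
        object.__setattr__(self, "prediction", p)

    @property
    def d(self) -> int:
        return int(self.input_state.size)


@dataclass(frozen=True)
class EnvState:
    """Environment state e(t); variation is a fresh uniform draw per step."""

    e: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "e", _unit_array("e", self.e))


@dataclass(frozen=True)
class LethalityThreshold:
    """Prediction error sufficient to cause cell death (scalar or per-dim)."""

    delta_lethal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "delta_lethal", _unit_array("delta_lethal", self.delta_lethal)
        )


@dataclass(frozen=True)
class BufferEconomy:
    """Resource economics of maintaining a protective buffered copy.

    ``beta_prot`` is the residual exposure of the protected cell (never
    more than its unprotected exposure), ``beta_prime`` the exposure of
    the protective copy itself, and ``k`` protective cells must be
    produced every ``m`` cell cycles.
    """

    beta_prot: float
    beta_prime: float
    m: int
    k: int
    beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta_prot", "beta_prime", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.beta_prot > self.beta:
            raise ValueError("protection cannot increase exposure (beta_prot > beta)")
        if self.m < 1:
            raise ValueError(f"maintenance period m must be >= 1, got {self.m!r}")
        if not 0 <= self.k < self.m:
            raise ValueError(f"need 0 <= k < m, got k={self.k!r}, m={self.m!r}")


def couple(env: EnvState, beta: float) -> np.ndarray:
    """Environmental action on the cell: ``a(t+1) = beta * e(t)``, componentwise."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta!r}")
    return beta * env.e


def prediction_error(state: PredictiveCellState) -> float:
    """Aggregate prediction error ``delta(t) = |a(t) - p(t)|``.

    The aggregate uses the max norm across dimensions: a failure in any
    one dimension is lethal, so the worst component is what matters for
    the lethality check. For a 1-d state this is the plain absolute
    difference.
    """
    return float(np.max(np.abs(state.input_state - state.prediction)))


def death_fraction(beta: float, thr: LethalityThreshold) -> float:
    """Expected per-cycle death probability ``beta * delta_lethal`` (1-d)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta!r}")
    if thr.delta_lethal.size != 1:
        raise ValueError("death_fraction is the 1-d load; use multidim_survival for d > 1")
    return float(beta * thr.delta_lethal[0])


def simulate_death_fraction(
    beta: float,
    thr: LethalityThreshold,
    n_trials: int = 100_000,
    rng: np.random.Generator | None = None,
    record_trajectory: bool = False,
):
    """Monte-Carlo estimate of the per-cycle death fraction in the 1-d model.

    Each trial runs one cell cycle of the homeostatic toy model:
    ``e(t) ~ uniform[0,1]``, ``a(t+1) = beta * e(t)``,
    ``p(t+1) = a(t)``. Death occurs iff ``u < beta * delta_lethal``
    with an independent ``u ~ uniform[0,1]`` — the rule calibrated so
    the expected death fraction is exactly ``beta * delta_lethal``.

    Returns the empirical death fraction; with ``record_trajectory`` also
    returns the mean prediction error over the trials (which shrinks
    linearly with ``beta`` under the homeostatic prediction).
    """
    rng = np.random.default_rng() if rng is None else rng
    load = death_fraction(beta, thr)
    u = rng.uniform(size=n_trials)
    died = u < load
    frac = float(died.mean())
    if not record_trajectory:
        return frac
    # One homeostatic step per trial: a(t) = beta*e(t-1), p(t) = a(t-1).
    e_prev = rng.uniform(size=n_trials)
    e_prev2 = rng.uniform(size=n_trials)
    delta = np.abs(beta * e_prev - beta * e_prev2)
    return frac, float(delta.mean())


def multidim_survival(
    betas, thrs, d: int | None = None
) -> tuple[float, int]:
    """Per-cycle survival probability with d independent lethal dimensions.

    Dimensions fail independently, each with probability
    ``beta_k * delta_lethal_k``; survival requires no failure in any
    dimension, so the survival probability is the product
    ``prod_k (1 - beta_k * delta_lethal_k)``. Also returns the number of
    distinct lethal failure-mode combinations, ``2**d - 1`` (every
    non-empty subset of dimensions).

    Scalars are broadcast to ``d`` dimensions when ``d`` is given.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    deltas = (
        thrs.delta_lethal
        if isinstance(thrs, LethalityThreshold)
        else np.atleast_1d(np.asarray(thrs, dtype=float))
    )
    if d is not None:
        if d < 1:
            raise ValueError(f"dimension count d must be >= 1, got {d!r}")
        if betas.size == 1:
            betas = np.full(d, betas[0])
        if deltas.size == 1:
            deltas = np.full(d, deltas[0])
    if betas.size != deltas.size:
        raise ValueError("betas and thresholds must have equal dimension")
    _unit_array("betas", betas)
    _unit_array("delta_lethal", deltas)
    dim = betas.size
    survival = float(np.prod(1.0 - betas * deltas))
    failure_modes = 2**dim - 1
    return survival, failure_modes


def replacement_feasible(
    econ: BufferEconomy, thr: LethalityThreshold, alpha: float, a: float
) -> dict:
    """Economics of replacing a protective copy that dies and re-exposes C.

    The protective copy C' dies each cycle with probability
    ``load = beta_prime * delta_lethal`` (the same load formula as
    :func:`death_fraction`). When ``load >= 0.5 * alpha * a`` all
    available resources must go to producing protection and C remains
    periodically exposed, so the strategy is infeasible. Population
    survival additionally requires ``load <= alpha*a / (1 + alpha*a)``.

    Returns a dict with ``load``, ``feasible`` and ``survives``.
    """
    for name, v in (("alpha", alpha), ("a", a)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    load = death_fraction(econ.beta_prime, thr)
    feasible = load < 0.5 * alpha * a - 1e-12 or load == 0.0
    survives = load <= alpha * a / (1.0 + alpha * a) + 1e-12
    return {"load": load, "feasible": bool(feasible), "survives": bool(survives)}


def protected_growth_rate(r: float, n: int, m: int, k: int) -> float:
    """Effective multiplier ``r**((n/m) * (m - k))`` for a protected lineage.

    A stem cell that diverts ``k`` of every ``m`` division cycles to
    producing protective somatic progeny grows its reproductive lineage
    as ``r**((n/m)(m-k))`` over ``n`` cycles; as ``k/m -> 0`` this
    approaches the unburdened rate ``r**n``. The exponent is real-valued,
    so ``n`` need not be a multiple of ``m``.
    """
    if r < 0:
        raise ValueError(f"growth factor r must be non-negative, got {r!r}")
    if n < 0:
        raise ValueError(f"cycle count n must be non-negative, got {n!r}")
    if m < 1:
        raise ValueError(f"maintenance period m must be >= 1, got {m!r}")
    if not 0 <= k < m:
        raise ValueError(f"need 0 <= k < m, got k={k!r}, m={m!r}")
    exponent = (n / m) * (m - k)
    return float(r**exponent)
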