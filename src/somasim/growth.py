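"""Closed-form population growth and survival thresholds.

A population of free-living reproductive cells in an environment with
resource level ``a`` and per-cycle lethality ``b`` grows per division cycle
by the expected factor

    r = (1 + alpha * a) * (1 - beta * b)

where ``alpha`` is the efficiency with which the cell converts resources
into division and ``beta`` is its degree of exposure to the environment
(``beta = 0`` is complete protection, ``beta = 1`` complete exposure).
After ``n`` cycles the expected population is ``N(t) = N0 * r**n``; with
``a = alpha = 1`` and ``b = 0`` this reduces to the familiar doubling
``N0 * 2**n``.

Survival (``r >= 1``) requires ``beta * b <= alpha * a / (1 + alpha * a)``.
Because ``alpha * a / (1 + alpha * a) <= 1/2`` for all admissible
parameters, a fully exposed population (``beta = 1``) cannot persist at any
lethality ``b > 0.5`` no matter how rich the environment — the origin of
the predicted phase transition from unprotected to protected growth.

All quantities here are deterministic expected values; stochastic
realizations of the same birth/death process live in :mod:`somasim.lattice`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvParams",
    "CellParams",
    "GrowthTrajectory",
    "growth_factor",
    "trajectory",
    "survival_condition",
    "critical_lethality",
    "figure_table",
    "ALWAYS_SURVIVES",
]

#: Sentinel returned by :func:`critical_lethality` when ``beta = 0``:
#: a fully protected population survives at every lethality level.
ALWAYS_SURVIVES = "always_survives"


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class EnvParams:
    """Environment parameters.

    Parameters
    ----------
    a : float
        Resource availability in [0, 1]; ``a = 0`` is starvation
        (maintenance only), ``a = 1`` supports unlimited growth.
    b : float
        Lethality per division cycle in [0, 1]; ``b = 0`` is benign,
        ``b = 1`` completely lethal for a fully exposed cell.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", _check_unit("a", self.a))
        object.__setattr__(self, "b", _check_unit("b", self.b))


@dataclass(frozen=True)
class CellParams:
    """Cell parameters.

    Parameters
    ----------
    alpha : float
        Resource-use efficiency in [0, 1].
    beta : float
        Environmental exposure in [0, 1]; 0 = complete protection,
        1 = complete exposure.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _check_unit("alpha", self.alpha))
        object.__setattr__(self, "beta", _check_unit("beta", self.beta))


@dataclass(frozen=True)
class GrowthTrajectory:
    """Expected population sizes ``N0 * r**k`` for ``k = 0..n``."""

    N0: float
    r: float
    n: int
    sizes: Sequence[float] = field(repr=False)

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError(f"N0 must be positive, got {self.N0!r}")
        if self.n < 0:
            raise ValueError(f"n must be non-negative, got {self.n!r}")


def growth_factor(env: EnvParams, cell: CellParams) -> float:
    """Per-cycle expected growth factor ``r = (1 + alpha*a) * (1 - beta*b)``.

    The result lies in [0, 2]; ``r = 2`` only at full resources, full
    efficiency and zero effective lethality.
    """
    return (1.0 + cell.alpha * env.a) * (1.0 - cell.beta * env.b)


def trajectory(N0: float, env: EnvParams, cell: CellParams, n: int) -> GrowthTrajectory:
    """Expected population sizes over ``n`` division cycles.

    Sizes are real-valued (expected counts), not integer-rounded.
    """
    if N0 <= 0:
        raise ValueError(f"N0 must be positive, got {N0!r}")
    n = int(n)
    if n < 0:
        raise ValueError(f"cycle count n must be non-negative, got {n!r}")
    r = growth_factor(env, cell)
    sizes = N0 * np.power(r, np.arange(n + 1, dtype=float))
    return GrowthTrajectory(N0=float(N0), r=r, n=n, sizes=tuple(sizes))


def survival_condition(env: EnvParams, cell: CellParams) -> bool:
    """True iff the population can grow or persist (``r >= 1``).

    Algebraically equivalent to ``beta*b <= alpha*a / (1 + alpha*a)``; a
    small floating tolerance keeps the boundary case exact.
    """
    lhs = cell.beta * env.b
    rhs = cell.alpha * env.a / (1.0 + cell.alpha * env.a)
    return bool(lhs <= rhs + 1e-12)


def critical_lethality(cell: CellParams, a: float) -> float | str:
    """Largest lethality ``b`` at which the population still survives.

    Returns ``alpha*a / ((1 + alpha*a) * beta)`` clamped to [0, 1], or the
    sentinel :data:`ALWAYS_SURVIVES` when ``beta = 0`` (a fully protected
    population persists at any lethality).
    """
    a = _check_unit("a", a)
    if cell.beta == 0.0:
        return ALWAYS_SURVIVES
    b_star = cell.alpha * a / ((1.0 + cell.alpha * a) * cell.beta)
    return float(min(1.0, max(0.0, b_star)))


def figure_table(
    settings: Sequence[tuple[str, float, float, float]],
    n: int = 10,
    b_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Population growth ``r**n`` across a lethality grid, per setting.

    Parameters
    ----------
    settings : sequence of (setting_id, a, alpha, beta)
        Resource/efficiency/exposure combinations; each is evaluated across
        the full lethality grid. Both ``alpha`` and ``beta`` are free so
        that partially protected and inefficient regimes can be compared.
    n : int
        Number of division cycles for the ``r**n`` column.
    b_grid : sequence of float, optional
        Lethality values; default is 0..1 in steps of 0.05.

    Returns
    -------
    pandas.DataFrame
        Columns ``setting_id, a, b, alpha, beta, r, r_pow_n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if b_grid is None:
        b_grid = np.linspace(0.0, 1.0, 21)
    rows = []
    for setting_id, a, alpha, beta in settings:
        cell = CellParams(alpha=alpha, beta=beta)
        for b in b_grid:
            env = EnvParams(a=a, b=float(b))
            r = growth_factor(env, cell)
            rows.append(
                {
                    "setting_id": setting_id,
                    "a": env.a,
                    "b": env.b,
                    "alpha": cell.alpha,
                    "beta": cell.beta,
                    "r": r,
                    "r_pow_n": r**n,
                }
            )
    return pd.DataFrame(rows)
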