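"""Stochastic lattice simulation of stem cells shielded by somatic progeny.

Stem cells are seeded at random on a rectangular grid whose columns carry a
lethality gradient from 0 (benign, left edge) to 1 (always lethal for a
fully exposed cell, right edge). On each division cycle every cell first
faces environmentally caused death with probability given by the local
lethality, attenuated by the protection it receives from neighboring
somatic (reproductively-disabled) cells; surviving stem cells with an open
neighboring site may then divide, with a division probability set by the
local resource level. Each division yields either another stem cell or a
somatic daughter, which never divides but shields its neighbors.

Death is synchronous across the grid (neighbor counts frozen at the start
of the cycle); division is sequential in uniformly random order, with each
daughter claiming its site immediately so that two divisions can never
place daughters on the same empty site. The grid boundary is non-periodic:
edge sites simply have fewer neighbors, which is the natural choice given
the column-wise environmental gradient.

The default geometry is 30 rows by 60 columns (1800 sites) with stem cells
seeded at 5% density and 120 division cycles per run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "EMPTY",
    "STEM",
    "SOMATIC",
    "SimConfig",
    "LatticeState",
    "RunResult",
    "lethality_field",
    "init_grid",
    "effective_exposure",
    "effective_resource",
    "step",
    "run",
    "sweep_protection",
    "colony_stats",
    "high_lethality_occupancy",
    "grid_to_text",
    "grid_from_text",
]

EMPTY, STEM, SOMATIC = 0, 1, 2

_GLYPHS = {EMPTY: ".", STEM: "S", SOMATIC: "O"}
_STATES = {v: k for k, v in _GLYPHS.items()}

_MOORE = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int64)
_VON_NEUMANN = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int64)


@dataclass(frozen=True)
class SimConfig:
    """All simulation parameters.

    Defaults follow the standard parameterization: 30x60 grid, 5% stem
    seeding density, 20% per-stem-neighbor resource competition, 20%
    per-somatic-neighbor resource boost, 20% somatic lethality
    resistance, 120 division cycles. ``beta_soma`` is the exposure a
    somatic neighbor transmits (protection factor is ``1 - beta_soma``);
    the default of 1.0 together with ``p_somatic = 0`` gives the
    baseline stem-cells-only condition.
    """

    rows: int = 30
    cols: int = 60
    a: float = 1.0
    seed_density: float = 0.05
    stem_competition: float = 0.20
    somatic_boost: float = 0.20
    beta_soma: float = 1.0
    soma_resistance: float = 0.20
    p_somatic: float = 0.0
    cycles: int = 120
    rng_seed: int = 0
    neighborhood: str = "moore"
    modifier_mode: str = "multiplicative"
    uniform_lethality: float | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 2:
            raise ValueError("grid must have rows >= 1 and cols >= 2")
        for name in (
            "a",
            "seed_density",
            "stem_competition",
            "somatic_boost",
            "beta_soma",
            "soma_resistance",
            "p_somatic",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.cycles < 0:
            raise ValueError(f"cycles must be non-negative, got {self.cycles!r}")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError(
                f"neighborhood must be 'moore' or 'von_neumann', got {self.neighborhood!r}"
            )
        if self.modifier_mode not in ("multiplicative", "additive"):
            raise ValueError(
                "modifier_mode must be 'multiplicative' or 'additive', "
                f"got {self.modifier_mode!r}"
            )
        if self.uniform_lethality is not None and not 0.0 <= self.uniform_lethality <= 1.0:
            raise ValueError("uniform_lethality must lie in [0, 1] or be None")

    @property
    def kernel(self) -> np.ndarray:
        return _MOORE if self.neighborhood == "moore" else _VON_NEUMANN

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class LatticeState:
    """Occupancy grid plus the per-column lethality field."""

    occupancy: np.ndarray
    lethality: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 2:
            raise ValueError("occupancy must be a 2-d array")
        if not np.isin(occ, (EMPTY, STEM, SOMATIC)).all():
            raise ValueError("occupancy values must be empty/stem/somatic")
        leth = np.asarray(self.lethality, dtype=float)
        if leth.shape != (occ.shape[1],):
            raise ValueError("lethality must have one value per column")
        self.occupancy = occ.astype(np.int8)
        self.lethality = leth

    @property
    def rows(self) -> int:
        return self.occupancy.shape[0]

    @property
    def cols(self) -> int:
        return self.occupancy.shape[1]

    def counts(self) -> tuple[int, int]:
        occ = self.occupancy
        return int((occ == STEM).sum()), int((occ == SOMATIC).sum())

    def copy(self) -> "LatticeState":
        return LatticeState(self.occupancy.copy(), self.lethality.copy())


@dataclass
class RunResult:
    """Outcome of a full simulation run."""

    final_state: LatticeState
    counts: pd.DataFrame  # columns: cycle, n_stem, n_somatic
    occupancy_high_b: float
    colonies: pd.DataFrame  # columns: size, n_stem, n_somatic
    config: SimConfig = field(repr=False, default=None)


def lethality_field(cols: int) -> np.ndarray:
    """Per-column lethality ``b_j = j / (cols - 1)``, endpoints exactly 0 and 1."""
    if cols < 2:
        raise ValueError(f"need at least 2 columns, got {cols!r}")
    return np.arange(cols, dtype=float) / (cols - 1)


def _field_for(config: SimConfig) -> np.ndarray:
    if config.uniform_lethality is not None:
        return np.full(config.cols, float(config.uniform_lethality))
    return lethality_field(config.cols)


def init_grid(config: SimConfig, rng: np.random.Generator | None = None) -> LatticeState:
    """Seed stem cells independently at ``seed_density``; no somatic cells."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    occ = np.where(
        rng.uniform(size=(config.rows, config.cols)) < config.seed_density, STEM, EMPTY
    ).astype(np.int8)
    return LatticeState(occ, _field_for(config))


def _neighbor_counts(occ: np.ndarray, kind: int, kernel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(
        (occ == kind).astype(np.int64), kernel, mode="constant", cval=0
    )


def effective_exposure(state: LatticeState, site: tuple[int, int], config: SimConfig) -> float:
    """Exposure multiplier ``beta_soma**s`` with ``s`` somatic neighbors.

    Protection compounds multiplicatively per somatic neighbor: a single
    fully protective neighbor (``beta_soma = 0``) already gives complete
    protection, and additional protectors never reduce it.
    """
    i, j = site
    s = _somatic_neighbors_at(state.occupancy, i, j, config.kernel)
    return float(config.beta_soma**s) if s else 1.0


def _somatic_neighbors_at(occ: np.ndarray, i: int, j: int, kernel: np.ndarray) -> int:
    return _kind_neighbors_at(occ, i, j, kernel, SOMATIC)


def _kind_neighbors_at(occ, i, j, kernel, kind) -> int:
    rows, cols = occ.shape
    total = 0
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if kernel[di + 1, dj + 1] == 0:
                continue
            ii, jj = i + di, j + dj
            if 0 <= ii < rows and 0 <= jj < cols and occ[ii, jj] == kind:
                total += 1
    return total


def effective_resource(state: LatticeState, site: tuple[int, int], config: SimConfig) -> float:
    """Local division probability ``clamp(alpha * a, 0, 1)`` at a stem site.

    ``alpha`` starts at 1 and is reduced 20% (default) for each stem
    neighbor (competition) and increased 20% (default) for each somatic
    neighbor (support). The multiplicative reading compounds per
    neighbor; the additive dialect uses ``1 - reduction*s`` instead.
    """
    i, j = site
    s_stem = _kind_neighbors_at(state.occupancy, i, j, config.kernel, STEM)
    s_soma = _somatic_neighbors_at(state.occupancy, i, j, config.kernel)
    return _division_prob(s_stem, s_soma, config)


def _division_prob(s_stem: int, s_soma: int, config: SimConfig) -> float:
    if config.modifier_mode == "multiplicative":
        alpha = (1.0 - config.stem_competition) ** s_stem * (
            1.0 + config.somatic_boost
        ) ** s_soma
    else:
        alpha = max(0.0, 1.0 - config.stem_competition * s_stem) * (
            1.0 + config.somatic_boost * s_soma
        )
    return float(min(1.0, max(0.0, alpha * config.a)))


def step(state: LatticeState, config: SimConfig, rng: np.random.Generator) -> LatticeState:
    """Advance one division cycle: synchronous death, then sequential division.

    Phase 1 (death): with neighbor counts frozen at cycle start, each
    stem cell dies with probability ``b_j * beta_soma**s`` and each
    somatic cell with ``b_j * (1 - soma_resistance) * beta_soma**s``,
    where ``s`` is its somatic-neighbor count.

    Phase 2 (division): surviving stem cells are visited in uniformly
    random order; a cell with at least one empty neighbor divides with
    probability ``clamp(alpha * a, 0, 1)`` computed from its live
    neighborhood, placing the daughter on a uniformly random empty
    neighbor, somatic with probability ``p_somatic``.
    """
    occ = state.occupancy.copy()
    kernel = config.kernel
    b = state.lethality[np.newaxis, :]

    # Phase 1: synchronous death with start-of-cycle neighbor counts.
    soma_nbrs = _neighbor_counts(occ, SOMATIC, kernel)
    exposure = np.where(soma_nbrs > 0, config.beta_soma ** soma_nbrs.astype(float), 1.0)
    p_death = np.zeros_like(exposure)
    stem_mask = occ == STEM
    soma_mask = occ == SOMATIC
    p_death[stem_mask] = (b * exposure)[stem_mask]
    p_death[soma_mask] = (b * (1.0 - config.soma_resistance) * exposure)[soma_mask]
    dies = rng.uniform(size=occ.shape) < p_death
    occ[dies & (stem_mask | soma_mask)] = EMPTY

    # Phase 2: sequential division over surviving stem cells, random order.
    stems = np.argwhere(occ == STEM)
    if len(stems):
        order = rng.permutation(len(stems))
        rows, cols = occ.shape
        offsets = [
            (di, dj)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if kernel[di + 1, dj + 1]
        ]
        for idx in order:
            i, j = stems[idx]
            empties = []
            s_stem = s_soma = 0
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if not (0 <= ii < rows and 0 <= jj < cols):
                    continue
                v = occ[ii, jj]
                if v == EMPTY:
                    empties.append((ii, jj))
                elif v == STEM:
                    s_stem += 1
                else:
                    s_soma += 1
            if not empties:
                continue
            if rng.uniform() < _division_prob(s_stem, s_soma, config):
                ii, jj = empties[rng.integers(len(empties))]
                occ[ii, jj] = SOMATIC if rng.uniform() < config.p_somatic else STEM

    return LatticeState(occ, state.lethality)


def high_lethality_occupancy(state: LatticeState, threshold: float = 0.5) -> float:
    """Fraction of sites occupied (stem or somatic) in columns with b > threshold."""
    high = state.lethality > threshold
    if not high.any():
        return 0.0
    sub = state.occupancy[:, high]
    return float((sub != EMPTY).mean())


def colony_stats(state: LatticeState, neighborhood: str = "moore") -> pd.DataFrame:
    """Connected components of occupied sites: size and stem/somatic makeup."""
    structure = (_MOORE if neighborhood == "moore" else _VON_NEUMANN).copy()
    structure[1, 1] = 1
    labels, n = ndimage.label(state.occupancy != EMPTY, structure=structure)
    rows = []
    for lab in range(1, n + 1):
        mask = labels == lab
        rows.append(
            {
                "size": int(mask.sum()),
                "n_stem": int((state.occupancy[mask] == STEM).sum()),
                "n_somatic": int((state.occupancy[mask] == SOMATIC).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["size", "n_stem", "n_somatic"])


def run(config: SimConfig) -> RunResult:
    """Run the full simulation; fully reproducible from ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    state = init_grid(config, rng)
    records = []
    n_stem, n_soma = state.counts()
    records.append({"cycle": 0, "n_stem": n_stem, "n_somatic": n_soma})
    for cycle in range(1, config.cycles + 1):
        state = step(state, config, rng)
        n_stem, n_soma = state.counts()
        records.append({"cycle": cycle, "n_stem": n_stem, "n_somatic": n_soma})
    counts = pd.DataFrame(records, columns=["cycle", "n_stem", "n_somatic"])
    return RunResult(
        final_state=state,
        counts=counts,
        occupancy_high_b=high_lethality_occupancy(state),
        colonies=colony_stats(state, config.neighborhood),
        config=config,
    )


def sweep_protection(
    config: SimConfig,
    protection_values: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    runs_per_value: int = 10,
) -> pd.DataFrame:
    """High-lethality occupancy as the somatic protection factor increases.

    For each protection value ``1 - beta_soma`` the simulation is run
    ``runs_per_value`` times with distinct, deterministically derived
    seeds (``rng_seed + value_index * runs_per_value + run_index``).

    Returns one row per run with columns
    ``protection, run, seed, occupancy_high_b, n_stem, n_somatic``.
    """
    rows = []
    for vi, protection in enumerate(protection_values):
        if not 0.0 <= protection <= 1.0:
            raise ValueError(f"protection must lie in [0, 1], got {protection!r}")
        for rep in range(runs_per_value):
            seed = config.rng_seed + vi * runs_per_value + rep
            cfg = config.replace(beta_soma=1.0 - protection, rng_seed=seed)
            result = run(cfg)
            n_stem, n_soma = result.final_state.counts()
            rows.append(
                {
                    "protection": float(protection),
                    "run": rep,
                    "seed": seed,
                    "occupancy_high_b": result.occupancy_high_b,
                    "n_stem": n_stem,
                    "n_somatic": n_soma,
                }
            )
    return pd.DataFrame(
        rows, columns=["protection", "run", "seed", "occupancy_high_b", "n_stem", "n_somatic"]
    )


def grid_to_text(state: LatticeState) -> str:
    """Render the grid as lines of ``.``/``S``/``O`` characters."""
    return "\n".join(
        "".join(_GLYPHS[int(v)] for v in row) for row in state.occupancy
    )


def grid_from_text(text: str, lethality: np.ndarray | None = None) -> LatticeState:
    """Parse a text snapshot back into a :class:`LatticeState`."""
    lines = [ln for ln in text.strip().splitlines() if ln]
    occ = np.array([[_STATES[ch] for ch in ln] for ln in lines], dtype=np.int8)
    if lethality is None:
        lethality = lethality_field(occ.shape[1])
    return LatticeState(occ, lethality)
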