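"""Extrinsic noise: cell-to-cell parameter variation and additive background.

Two noise sources act on the simulated single-cell responses:

(a) cell-specific noise — protein abundances and pseudo-first-order rates
    vary between cells; each flagged parameter is drawn per cell from a
    lognormal distribution whose *median* is the default value and whose
    log-scale standard deviation is ``sigma``;

(b) additive noise — background ERK activity from pathways outside the
    model, added to each integrated response R_i as an independent lognormal
    draw with median ``mu_star = mu0 * R_max * T/60min`` and log-scale SD
    ``sigma0`` (default 1).  ``mu0 = 0.03`` means roughly 3% of the per-slot
    ERK activity is background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List

import numpy as np

__all__ = ["NoiseSpec", "CellParameterSet", "sample_population", "additive_noise"]

SIGMA_GRID = (0.0, 0.1, 0.3, 0.5, 0.7, 1.0)
MU0_GRID = (0.0, 0.01, 0.03, 0.1, 0.3)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise strengths; sigma/sigma0 are log-scale standard deviations."""

    sigma: float = 0.0
    sigma0: float = 1.0
    mu0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma0 < 0 or self.mu0 < 0:
            raise ValueError("noise spreads must be nonnegative")


@dataclass(frozen=True)
class CellParameterSet:
    params: "ModelParameters"  # noqa: F821 - duck-typed, see model.ModelParameters
    cell_id: int
    seed: int


def _cell_rng(seed: int, cell_id: int) -> np.random.Generator:
    # one independent stream per cell: reproducible under any execution order
    return np.random.default_rng([seed, cell_id])


def sample_population(base, noise: NoiseSpec, M: int) -> List[CellParameterSet]:
    """Draw M cell-specific parameter sets around the defaults in ``base``.

    ``base`` must expose ``values`` (name -> float), ``cell_variable``
    (names subject to extrinsic noise) and ``with_values(dict)``.  Each
    flagged parameter is drawn independently per cell as
    exp(Normal(ln(default), sigma^2)), so its median equals the default;
    sigma = 0 reproduces the defaults exactly.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    varied = sorted(base.cell_variable)
    for name in varied:
        if base.values[name] <= 0:
            raise ValueError(f"cell-variable parameter {name!r} must be positive")
    cells = []
    for cid in range(M):
        if noise.sigma == 0:
            cells.append(CellParameterSet(base, cid, noise.seed))
            continue
        rng = _cell_rng(noise.seed, cid)
        draws = {
            name: base.values[name] * np.exp(rng.normal(0.0, noise.sigma))
            for name in varied
        }
        cells.append(CellParameterSet(base.with_values(draws), cid, noise.seed))
    return cells


def additive_noise(
    noise: NoiseSpec,
    R_max: float,
    T: float,
    L: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """L independent additive background terms (molecule*s), one per slot.

    Median mu_star = mu0 * R_max * T/60; mu0 = 0 gives exact zeros.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if noise.mu0 == 0.0:
        return np.zeros(L)
    mu_star = noise.mu0 * R_max * T / 60.0
    return mu_star * np.exp(rng.normal(0.0, noise.sigma0, size=L))


def population_frame(cells: Iterable[CellParameterSet]):
    """Serialize a population as a DataFrame (cell_id x parameter columns)."""
    import pandas as pd

    rows = []
    for c in cells:
        row = {"cell_id": c.cell_id, "seed": c.seed}
        row.update(c.params.values)
        rows.append(row)
    return pd.DataFrame(rows)
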