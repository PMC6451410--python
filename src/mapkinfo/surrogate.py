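"""ODE-free stochastic channel emulating the simulated ERK responses.

The MAPK model converts a binary EGF pulse train into near-digital ERK
pulses subject to a refractory period of about tau = 51.5 min; extrinsic
noise makes the transmission of a pulse near the refractory boundary
probabilistic and multiplies each cell's response amplitudes by a shared
lognormal gain.  This module reproduces exactly that statistical structure
in microseconds per cell: a per-pulse miss probability
``p_miss = logistic((tau - dt)/miss_width)`` (dt = time since the previous
emitted response), a per-cell lognormal gain shared across slots, and
independent additive lognormal background per slot.  In the hard limit
``miss_width -> 0`` the emitted sequence is the deterministic refractory
transcoding, so estimator and optimizer results can be checked against the
exact partition-channel theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .mi import ChannelDataset
from .population import NoiseSpec, additive_noise
from .theory import DEFAULT_TAU_MIN, refractory_index, transcode

__all__ = ["SurrogateSpec", "generate_dataset", "fraction_responding_surrogate"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Statistical parameters of the surrogate channel.

    R_max is the single-pulse integrated response scale (molecule*s);
    miss_width (minutes) is the logistic width of the transmission boundary
    around tau (0 = hard refractory rule); cell_cv is the log-scale SD of
    the per-cell multiplicative gain (maps 1:1 from the cell-specific noise
    sigma); noise carries the additive-background parameters.
    """

    R_max: float = 2.65e9
    tau: float = DEFAULT_TAU_MIN
    miss_width: float = 5.0
    cell_cv: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.R_max <= 0 or self.tau <= 0 or self.miss_width < 0 or self.cell_cv < 0:
            raise ValueError("surrogate parameters must be nonnegative (R_max, tau > 0)")

    def p_miss(self, dt: float) -> float:
        """Probability that a pulse arriving dt minutes after the previous
        emitted response fails to elicit one."""
        if self.miss_width == 0.0:
            return 1.0 if dt < self.tau else 0.0
        return float(1.0 / (1.0 + np.exp(-(self.tau - dt) / self.miss_width)))


def _emit(seq: str, T: float, spec: SurrogateSpec, rng: np.random.Generator) -> np.ndarray:
    """Stochastic refractory transcoding of one cell's input sequence."""
    if spec.miss_width == 0.0:
        k = refractory_index(T, spec.tau)
        return np.array([int(c) for c in transcode(seq, k)], dtype=float)
    out = np.zeros(len(seq))
    last = None
    for i, c in enumerate(seq):
        if c != "1":
            continue
        dt = np.inf if last is None else (i - last) * T
        if rng.random() >= spec.p_miss(dt):
            out[i] = 1.0
            last = i
    return out


def generate_dataset(
    sequences: Sequence[str],
    T: float,
    spec: SurrogateSpec,
    M: int,
    seed: int = 0,
) -> ChannelDataset:
    """M response vectors per input sequence.

    Per cell: (1) lognormal gain g = exp(Normal(0, cell_cv^2)) shared across
    slots; (2) stochastic refractory transcoding of the input; (3)
    R_i = emitted_i * g * R_max + additive background.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    samples = {}
    for si, seq in enumerate(sequences):
        rng = np.random.default_rng([seed, si])
        L = len(seq)
        R = np.empty((M, L))
        for m in range(M):
            g = np.exp(rng.normal(0.0, spec.cell_cv)) if spec.cell_cv > 0 else 1.0
            emitted = _emit(seq, T, spec, rng)
            R[m] = emitted * g * spec.R_max + additive_noise(
                spec.noise, spec.R_max, T, L, rng
            )
        samples[seq] = R
    return ChannelDataset(samples)


def fraction_responding_surrogate(
    T_grid: Sequence[float],
    spec: SurrogateSpec,
    M: int = 1000,
    seed: int = 0,
):
    """Fraction of cells with R_2 > 0.5*R_1 for a two-pulse '11' protocol.

    Returns a DataFrame with columns T_min, fraction, n_cells, p_respond
    (the closed-form per-pulse transmission probability 1 - p_miss(T), which
    the empirical fraction approaches for cell_cv = 0 and mu0 = 0).
    """
    import pandas as pd

    rows = []
    for ti, T in enumerate(T_grid):
        ds = generate_dataset(["11"], T, spec, M, seed=seed + ti)
        R = ds.samples["11"]
        frac = float(np.mean(R[:, 1] > 0.5 * R[:, 0]))
        rows.append(
            dict(T_min=T, fraction=frac, n_cells=M, p_respond=1.0 - spec.p_miss(T))
        )
    return pd.DataFrame(rows)
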