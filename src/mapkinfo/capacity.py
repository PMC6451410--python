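"""Channel capacity: MI maximization over the input distribution.

The input probabilities are parametrized as p = softmax(logits) and the
weighted kNN MI estimate is ascended with an Adam-style adaptive gradient
method.  Because the neighbour geometry (eps radii and within-eps counts)
does not depend on p, it is computed once per dataset and every iteration is
a cheap re-weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .mi import ChannelDataset, EstimatorConfig, NeighborStructure, discrete_entropy
from .theory import TranscodingPartition, bitrate

__all__ = ["OptimizerConfig", "CapacityEstimate", "maximize_mi", "mi_under_schemes"]


@dataclass(frozen=True)
class OptimizerConfig:
    step: float = 0.05
    iterations: int = 2000
    restarts: int = 3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    # converged when MI changed by less than conv_tol over conv_window iters
    conv_tol: float = 1e-4
    conv_window: int = 50
    init_spread: float = 0.5  # SD of the random logit initialization
    seed: int = 0


@dataclass
class CapacityEstimate:
    C: float
    p_star: Dict[str, float]
    trace: np.ndarray
    seed: int
    restarts: int
    converged: bool
    C_rate: float | None = None

    def group_mass(self, partition: TranscodingPartition) -> np.ndarray:
        """Summed optimal input mass per transcoding group."""
        gof = partition.group_of()
        mass = np.zeros(partition.K)
        for x, px in self.p_star.items():
            mass[gof[x]] += px
        return mass


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def maximize_mi(
    dataset: ChannelDataset,
    cfg: OptimizerConfig = OptimizerConfig(),
    est_cfg: EstimatorConfig = EstimatorConfig(),
    L: int | None = None,
    T: float | None = None,
) -> CapacityEstimate:
    """Maximize the weighted MI estimate over input distributions.

    Runs ``cfg.restarts`` Adam ascents from random logit initializations and
    returns the best.  If L and T (minutes) are given, the result also
    carries the bitrate C_rate = C / (L*T/60) in bit/h.
    """
    ns = NeighborStructure(dataset, est_cfg)
    ncat = len(dataset.categories)
    best: Tuple[float, np.ndarray, np.ndarray, bool] | None = None
    rng = np.random.default_rng(cfg.seed)

    for _ in range(max(cfg.restarts, 1)):
        z = rng.normal(0.0, cfg.init_spread, ncat)
        m = np.zeros(ncat)
        v = np.zeros(ncat)
        trace = []
        converged = False
        for it in range(1, cfg.iterations + 1):
            p = _softmax(z)
            mi, g_p = ns.mi_and_gradient(p, with_gradient=True)
            trace.append(mi)
            # chain rule through softmax: dMI/dz = J_softmax^T g_p
            g_z = p * (g_p - np.dot(g_p, p))
            m = cfg.beta1 * m + (1 - cfg.beta1) * g_z
            v = cfg.beta2 * v + (1 - cfg.beta2) * g_z**2
            mhat = m / (1 - cfg.beta1**it)
            vhat = v / (1 - cfg.beta2**it)
            z = z + cfg.step * mhat / (np.sqrt(vhat) + cfg.adam_eps)
            if it > cfg.conv_window and (
                abs(trace[-1] - trace[-1 - cfg.conv_window]) < cfg.conv_tol
            ):
                converged = True
                break
        p = _softmax(z)
        mi, _ = ns.mi_and_gradient(p)
        if best is None or mi > best[0]:
            best = (mi, p, np.array(trace), converged)

    mi, p, trace, converged = best
    if not converged:
        import warnings

        warnings.warn("capacity optimizer did not converge; returning best-so-far")
    est = CapacityEstimate(
        C=float(max(mi, 0.0)),
        p_star={x: float(px) for x, px in zip(dataset.categories, p)},
        trace=trace,
        seed=cfg.seed,
        restarts=cfg.restarts,
        converged=converged,
    )
    if L is not None and T is not None:
        est.C_rate = bitrate(est.C, L, T)
    return est


def mi_under_schemes(
    dataset: ChannelDataset,
    partition: TranscodingPartition,
    cfg: OptimizerConfig = OptimizerConfig(),
    est_cfg: EstimatorConfig = EstimatorConfig(),
) -> Dict[str, float]:
    """Estimated MI under the three input-probability schemes.

    (1) equal probabilities of all input sequences, (2) equal probabilities
    of the group representatives with zero mass elsewhere, (3) numerically
    maximized.  Returns a dict with keys 'equal-all', 'equal-representatives',
    'maximized' (bits).
    """
    cats = dataset.categories
    if set(cats) != {s for g in partition.groups for s in g}:
        raise ValueError("partition does not match dataset categories")
    ns = NeighborStructure(dataset, est_cfg)

    p_all = np.full(len(cats), 1.0 / len(cats))
    reps = set(partition.representatives)
    p_rep = np.array([1.0 / len(reps) if x in reps else 0.0 for x in cats])

    mi_all, _ = ns.mi_and_gradient(p_all)
    mi_rep, _ = ns.mi_and_gradient(p_rep)
    opt = maximize_mi(dataset, cfg, est_cfg)
    return {
        "equal-all": float(max(mi_all, 0.0)),
        "equal-representatives": float(max(mi_rep, 0.0)),
        "maximized": opt.C,
        "p_star": opt.p_star,
    }
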