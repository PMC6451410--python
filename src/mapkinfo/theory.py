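"""Deterministic theory of refractory pulse-interval coding.

A cell that emits an all-or-nothing ERK activity pulse cannot respond again
until a relaxation time ``tau`` has elapsed.  When binary EGF pulse trains are
delivered on a grid with base repeating time ``T`` (one slot every ``T``
minutes), the refractory period blocks the ``k`` slots following each emitted
response, where ``k = max{j >= 0 : j*T < tau}``.  This module contains the
noise-free consequences of that rule: the transcoding map from input to output
sequences, the induced partition of inputs into groups with identical outputs,
exact mutual information for the resulting deterministic channel, the
Fibonacci-type recurrence counting accurately transmitted sequences, and the
asymptotic channel capacity ``C(k) = (k+1) * log2(a_k)`` where ``a_k`` is the
dominant root of ``a**(k+1) = a**k + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TranscodingSpec",
    "TranscodingPartition",
    "RecurrenceResult",
    "PartitionMI",
    "refractory_index",
    "transcode",
    "enumerate_groups",
    "count_fixed_points",
    "dominant_root",
    "prefactor",
    "asymptotic_bitrate",
    "finite_L_mi",
    "exact_mi_partition",
    "bitrate",
    "all_sequences",
    "theory_report",
]

MAX_ENUM_L = 20  # enumerate_groups walks all 2**L sequences

# Relaxation time of the calibrated MAPK model, minutes.  Kept here because
# the theory is parametrized by tau through the refractory index only.
DEFAULT_TAU_MIN = 51.5


@dataclass(frozen=True)
class TranscodingSpec:
    """Slot geometry of a refractory pulse-interval code.

    ``k`` slots after each emitted response are blocked; equivalently
    ``k*T < tau <= (k+1)*T``.
    """

    tau: float
    T: float

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.T <= 0:
            raise ValueError("tau and T must be positive")

    @property
    def k(self) -> int:
        return refractory_index(self.T, self.tau)

    @property
    def carrier_frequency(self) -> float:
        """Slot frequency Phi = 1/T in 1/min."""
        return 1.0 / self.T


@dataclass(frozen=True)
class TranscodingPartition:
    """Partition of all 2**L binary inputs into groups with identical output."""

    L: int
    k: int
    groups: Tuple[Tuple[str, ...], ...]
    representatives: Tuple[str, ...]

    @property
    def K(self) -> int:
        return len(self.groups)

    def group_sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups])

    def group_of(self) -> Dict[str, int]:
        """Map each input sequence to its group index."""
        return {s: gi for gi, g in enumerate(self.groups) for s in g}


@dataclass(frozen=True)
class RecurrenceResult:
    k: int
    n_L: Tuple[int, ...]
    a_k: float
    a_k0: float
    C_k: float


@dataclass(frozen=True)
class PartitionMI:
    H_X: float
    H_X_given_Y: float
    MI: float
    scheme: str


def _validate_bits(seq: str) -> str:
    if len(seq) < 1 or any(c not in "01" for c in seq):
        raise ValueError(f"not a binary sequence: {seq!r}")
    return seq


def refractory_index(T: float, tau: float) -> int:
    """Number of slots blocked after a response: max{j >= 0 : j*T < tau}."""
    if T <= 0 or tau <= 0:
        raise ValueError("T and tau must be positive")
    # strict inequality: j*T < tau, so T exactly dividing tau stays below
    k = int(np.ceil(tau / T)) - 1
    if k * T >= tau:  # guard against float round-off at the boundary
        k -= 1
    while (k + 1) * T < tau:
        k += 1
    return max(k, 0)


def transcode(seq: str, k: int) -> str:
    """Greedy left-to-right refractory transcoding.

    Output bit i is 1 iff input bit i is 1 and no *output* 1 was emitted in
    the preceding k slots.  This reproduces e.g. '111' -> '101' for k=1 and
    '111' -> '100' for k=2.
    """
    _validate_bits(seq)
    if k < 0:
        raise ValueError("k must be >= 0")
    out = []
    last_emit = -(k + 1)  # far enough in the past
    for i, c in enumerate(seq):
        if c == "1" and i - last_emit > k:
            out.append("1")
            last_emit = i
        else:
            out.append("0")
    return "".join(out)


def all_sequences(L: int) -> List[str]:
    """All 2**L binary strings of length L, in lexicographic order."""
    if not 1 <= L <= MAX_ENUM_L:
        raise ValueError(f"L must be in [1, {MAX_ENUM_L}]")
    return [format(i, f"0{L}b") for i in range(2**L)]


def enumerate_groups(L: int, k: int) -> TranscodingPartition:
    """Group the 2**L inputs by their transcoded output.

    The representative of each group is the common output sequence, which is
    itself a member of the group (the unique fixed point of the transcoding
    map within it).
    """
    preimages: Dict[str, List[str]] = {}
    for s in all_sequences(L):
        preimages.setdefault(transcode(s, k), []).append(s)
    reps = sorted(preimages)
    groups = tuple(tuple(sorted(preimages[r])) for r in reps)
    return TranscodingPartition(L=L, k=k, groups=groups, representatives=tuple(reps))


def count_fixed_points(L: int, k: int) -> int:
    """Count binary sequences of length L whose 1s are pairwise > k slots apart.

    These are the fixed points of the transcoding map, i.e. the accurately
    transmitted sequences.  Satisfies n_{L+1} = n_L + n_{L-k} with
    n_L = L + 1 for L <= k + 1; k = 0 gives 2**L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 2**L
    if L <= k + 1:
        return L + 1
    # n[i] holds n_{i} for i = L-k .. L while iterating
    ns = [i + 1 for i in range(1, k + 2)]  # n_1 .. n_{k+1}
    for _ in range(k + 2, L + 1):
        ns.append(ns[-1] + ns[-1 - k])
    return ns[L - 1]


def dominant_root(k: int, tol: float = 1e-12) -> float:
    """Dominant root a_k in (1, 2) of a**(k+1) - a**k - 1 = 0.

    Governs the growth n_L ~ a_k0 * a_k**L of the count of accurately
    transmitted sequences; a_1 is the golden ratio.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    f = lambda a: a ** (k + 1) - a**k - 1.0
    return float(brentq(f, 1.0 + 1e-12, 2.0, xtol=tol))


def prefactor(k: int, tol: float = 1e-4) -> float:
    """Prefactor a_k0 such that n_L -> a_k0 * a_k**L for large L.

    Computed as the numerical limit of n_L / a_k**L, iterating L until
    successive estimates differ by less than ``tol``.
    """
    a = dominant_root(k)
    # subdominant roots can decay slowly relative to a_k (their moduli
    # approach a_k as k grows), so convergence is judged on the spread of a
    # trailing window of estimates rather than one successive difference
    window: List[float] = []
    est = None
    for L in range(k + 2, 2000):
        est = count_fixed_points(L, k) / a**L
        window.append(est)
        if len(window) > 12:
            window.pop(0)
            if max(window) - min(window) < tol:
                return est
    return est  # pragma: no cover - converges well before the cap


def asymptotic_bitrate(k: int) -> float:
    """Asymptotic capacity C(k) = (k+1) * log2(a_k) in bit/h.

    Assumes slots of duration T = 60/(k+1) minutes, i.e. k+1 slots per hour,
    the densest grid for which k slots after a response stay inside the
    refractory window.
    """
    return (k + 1) * np.log2(dominant_root(k))


def finite_L_mi(k: int, L: int) -> Tuple[float, float]:
    """Maximum MI of length-L sequences: exact and asymptotic values (bits).

    Returns ``(log2(n_L), log2(a_k0) + L*log2(a_k))``.  The two agree within
    ~0.02 bit for L >= 10.
    """
    exact = float(np.log2(count_fixed_points(L, k)))
    if k == 0:
        return exact, float(L)
    asym = float(np.log2(prefactor(k)) + L * np.log2(dominant_root(k)))
    return exact, asym


def recurrence_result(k: int, L_max: int = 30) -> RecurrenceResult:
    ns = tuple(count_fixed_points(L, k) for L in range(1, L_max + 1))
    return RecurrenceResult(
        k=k, n_L=ns, a_k=dominant_root(k), a_k0=prefactor(k), C_k=asymptotic_bitrate(k)
    )


def exact_mi_partition(
    partition: TranscodingPartition,
    p: Sequence[float] | None = None,
    scheme: str = "equal-all",
) -> PartitionMI:
    """Exact MI of the noise-free partition channel under an input distribution.

    The channel is deterministic (each input maps to its group's output), so
    MI = H(Y) = -sum_g q_g log2 q_g with q_g the total input mass of group g.

    scheme:
      'equal-all'             uniform over all 2**L inputs
      'equal-representatives' uniform over the K representatives, 0 elsewhere
      'maximized'             any distribution with mass 1/K per group
      'custom'                explicit ``p`` over all_sequences(L)
    """
    L, K = partition.L, partition.K
    n = 2**L
    if p is not None:
        scheme = "custom"
        p = np.asarray(p, dtype=float)
        if p.shape != (n,) or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("p must be a probability vector over all 2**L sequences")
    elif scheme == "equal-all":
        p = np.full(n, 1.0 / n)
    elif scheme in ("equal-representatives", "maximized"):
        p = np.zeros(n)
        seq_index = {s: i for i, s in enumerate(all_sequences(L))}
        for r in partition.representatives:
            p[seq_index[r]] = 1.0 / K
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    seqs = all_sequences(L)
    q = np.zeros(K)
    gof = partition.group_of()
    for i, s in enumerate(seqs):
        q[gof[s]] += p[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        H_Y = float(-np.sum(np.where(q > 0, q * np.log2(np.maximum(q, 1e-300)), 0.0)))
        H_X = float(-np.sum(np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)))
    # deterministic channel: H(Y|X) = 0, so MI = H(Y) = H(X) - H(X|Y)
    return PartitionMI(H_X=H_X, H_X_given_Y=H_X - H_Y, MI=H_Y, scheme=scheme)


def bitrate(MI: float, L: int, T: float) -> float:
    """Convert MI in bits over L slots of T minutes to bit/h: MI / (L*T/60)."""
    if MI < 0 or L < 1 or T <= 0:
        raise ValueError("need MI >= 0, L >= 1, T > 0")
    return MI * 60.0 / (L * T)


def theory_report(ks: Sequence[int] = (1, 2, 3), Ls: Sequence[int] = (3, 4, 6, 8)):
    """Tabular summary used by the `theory` CLI subcommand.

    Returns (per-k table, per-(L,k) table) as pandas DataFrames.
    """
    import pandas as pd

    rows = []
    for k in ks:
        rows.append(
            dict(
                k=k,
                T_min=60.0 / (k + 1),
                a_k=dominant_root(k),
                a_k0=prefactor(k),
                C_k_bit_per_h=asymptotic_bitrate(k),
            )
        )
    per_k = pd.DataFrame(rows)

    rows = []
    for k in ks:
        for L in Ls:
            part = enumerate_groups(L, k)
            n_L = count_fixed_points(L, k)
            rows.append(
                dict(
                    L=L,
                    k=k,
                    n_L=n_L,
                    log2_n_L=float(np.log2(n_L)),
                    MI_equal_all=exact_mi_partition(part, scheme="equal-all").MI,
                    MI_max=exact_mi_partition(part, scheme="maximized").MI,
                )
            )
    per_Lk = pd.DataFrame(rows)
    return per_k, per_Lk
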