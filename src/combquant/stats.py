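"""Mass estimation and small-sample method-comparison statistics.

Two independent routes to the mass of food stores on a frame:

* area route -- capped-honey surface (cm^2) times the mass of honey held
  by 1 cm^2 of capped comb;
* weight route -- measured frame weight minus the weight of the capped
  brood it carries and the weight of an empty drawn frame.

The per-area and empty-frame constants come from published reference
tables and are supplied by the caller; no defaults are baked in.

For paired method comparisons at very small n (e.g. six observers timed
with two tools) the package provides the exact Wilcoxon signed-rank
test: the null distribution of V (sum of ranks of positive differences)
is obtained by enumerating all 2^n sign assignments on the realised
rank multiset, so the p-value is exact, ties included, with no normal
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError, UndefinedCorrelationError

__all__ = [
    "MassConstants",
    "PairedSample",
    "SignedRankResult",
    "honey_mass_from_area",
    "food_mass_from_frame_weight",
    "exact_signed_rank_test",
    "agreement_report",
]

_MAX_EXACT_N = 25  # 2^25 sign vectors is the practical enumeration ceiling


@dataclass(frozen=True)
class MassConstants:
    """Reference masses for converting comb surfaces to grams.

    honey_mass_per_cm2 : g of honey per cm^2 of capped honey comb
    brood_mass_per_cm2 : g of brood per cm^2 of capped brood comb
    empty_frame_mass   : g, drawn frame (wood + wax, no content)
    """

    honey_mass_per_cm2: float
    brood_mass_per_cm2: float
    empty_frame_mass: float

    def __post_init__(self) -> None:
        for name in ("honey_mass_per_cm2", "brood_mass_per_cm2", "empty_frame_mass"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PairedSample:
    """Paired real-valued measurements of the same units by two methods."""

    pairs: tuple[tuple[float, float], ...]
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("need at least one pair")
        arr = np.asarray(self.pairs, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
            raise ValueError("pairs must be finite (a, b) tuples")

    @property
    def differences(self) -> np.ndarray:
        arr = np.asarray(self.pairs, dtype=np.float64)
        return arr[:, 1] - arr[:, 0]


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # V = sum of ranks of positive differences
    p_two_sided: float
    p_one_sided: float
    n_used: int  # pairs remaining after dropping zero differences
    null_support: tuple[float, ...] = field(repr=False, default=())
    null_probability: tuple[float, ...] = field(repr=False, default=())


def honey_mass_from_area(capped_honey_cm2: float, constants: MassConstants) -> float:
    """Mass (g) of capped honey from its comb surface area (cm^2)."""
    if capped_honey_cm2 < 0:
        raise ValueError("capped honey area must be >= 0")
    return float(capped_honey_cm2) * constants.honey_mass_per_cm2


def food_mass_from_frame_weight(
    frame_mass_g: float, capped_brood_cm2: float, constants: MassConstants
) -> float:
    """Mass (g) of stored food on a frame from its total weight.

    Subtracts the weight of the capped brood (area times per-cm^2 brood
    mass) and the weight of an empty drawn frame from the measured frame
    weight.  A negative result (frame lighter than its estimated empty
    weight) is returned unchanged with a warning: it signals a
    calibration problem in the constants, not an arithmetic error.
    """
    if frame_mass_g < 0:
        raise ValueError("frame mass must be >= 0")
    if capped_brood_cm2 < 0:
        raise ValueError("capped brood area must be >= 0")
    mass = (
        float(frame_mass_g)
        - float(capped_brood_cm2) * constants.brood_mass_per_cm2
        - constants.empty_frame_mass
    )
    if mass < 0:
        warnings.warn(
            f"estimated food mass is negative ({mass:.3f} g); check the "
            "mass constants against this frame",
            stacklevel=2,
        )
    return mass


def _signed_ranks(differences: np.ndarray) -> np.ndarray:
    """Midranks of |d| for the non-zero differences (zeros already dropped)."""
    return sps.rankdata(np.abs(differences), method="average")


def exact_signed_rank_test(sample: PairedSample) -> SignedRankResult:
    """Exact paired Wilcoxon signed-rank test by full sign enumeration.

    Differences d_i = b_i - a_i; zero differences are dropped
    (Wilcoxon's convention); |d_i| are ranked with midranks for ties;
    V is the sum of ranks of the positive differences.  The exact null
    distribution is built by enumerating all 2^n assignments of signs
    to the realised rank multiset, each with probability 2^-n.  The
    one-sided p is the smaller inclusive tail P(V* >= V) or P(V* <= V);
    the two-sided p doubles it, capped at 1.

    Only valid in the exact-enumeration regime (n <= 25 after zero
    removal); for six pairs all shifted the same way this yields
    V = n(n+1)/2 = 21 and p_two_sided = 2 * (1/64) = 0.03125.
    """
    d = sample.differences
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    if n > _MAX_EXACT_N:
        raise ValueError(f"exact enumeration limited to n <= {_MAX_EXACT_N}, got {n}")

    ranks = _signed_ranks(d)
    v_obs = float(ranks[d > 0].sum())

    # Null distribution: sum over subsets of ranks, each sign vector 2^-n.
    # Iterative subset-sum over the rank multiset keeps this O(2^n) in the
    # worst (all-tied) case but typically far smaller via value pooling.
    dist: dict[float, float] = {0.0: 1.0}
    for r in ranks:
        nxt: dict[float, float] = {}
        for v, c in dist.items():
            nxt[v] = nxt.get(v, 0.0) + c
            nxt[round(v + r, 9)] = nxt.get(round(v + r, 9), 0.0) + c
        dist = nxt
    total = 2.0 ** n
    support = np.array(sorted(dist))
    prob = np.array([dist[v] for v in support]) / total

    upper = float(prob[support >= v_obs - 1e-9].sum())
    lower = float(prob[support <= v_obs + 1e-9].sum())
    p_one = min(upper, lower)
    p_two = min(1.0, 2.0 * p_one)
    return SignedRankResult(
        statistic=v_obs,
        p_two_sided=p_two,
        p_one_sided=p_one,
        n_used=n,
        null_support=tuple(float(v) for v in support),
        null_probability=tuple(float(p) for p in prob),
    )


def agreement_report(
    method_a: Sequence[float], method_b: Sequence[float]
) -> dict[str, float]:
    """Pearson agreement between two measurement methods.

    Returns a summary dict with n, the product-moment correlation r,
    its two-sided p-value from the t transform, and the mean difference
    (b - a).  Requires >= 3 paired values with non-zero variance on
    both sides.
    """
    a = np.asarray(method_a, dtype=np.float64)
    b = np.asarray(method_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1-D samples with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in at least one method")
    res = sps.pearsonr(a, b)
    return {
        "n": int(a.size),
        "r": float(res.statistic),
        "p": float(res.pvalue),
        "mean_difference": float(np.mean(b - a)),
    }
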