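"""Closed forms and exact oracles validating both growth engines.

symmetric_final_size and linear_chain_size are the analytically solvable
regimes of the dilution model; exact_size_distribution is a brute-force
enumeration of the stochastic final-size law for small molecule counts,
independent of the Monte-Carlo engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.stats import binom

from .core import DivisionParams, RunawayGrowthError
from .stochastic import molecule_threshold

__all__ = [
    "ExactSizeDistribution",
    "symmetric_final_size",
    "linear_chain_size",
    "exact_size_distribution",
]


def symmetric_final_size(phi: float) -> int:
    """Final size 2**n under symmetric division (p = 0.5).

    Content halves each round; with the >=-divides boundary rule growth stops
    after n = min{n >= 1 : 2**-n < phi} rounds.  Powers of two are exact in
    floating point, so this matches the deterministic engine at p = 0.5
    identically, including boundary cases like phi = 0.25 -> N_f = 8.
    """
    if not (0.0 < phi <= 1.0):
        raise ValueError(f"threshold phi must lie in (0, 1], got {phi!r}")
    n = 1
    x = 0.5
    while x >= phi:
        x *= 0.5
        n += 1
    return 2**n


def linear_chain_size(p: float, phi: float) -> int:
    """Final size 1 + n of a linear chain, valid in the regime p < phi.

    When p < phi the small daughter (content <= p) can never divide, so only
    the large-daughter spine proliferates: content (1-p)**k after k rounds,
    one new quiescent cell per round, stopping at
    n = min{n >= 1 : (1-p)**n < phi}.  Powers are accumulated by repeated
    multiplication, the same float sequence the simulator produces along the
    spine, so agreement with the engine is exact.
    """
    params = DivisionParams(p=p, phi=phi)  # range validation
    if not (params.p < params.phi):
        raise ValueError(
            f"linear_chain_size requires the linear regime p < phi, got "
            f"(p={p}, phi={phi}); use the deterministic simulator instead"
        )
    n = 0
    x = 1.0
    while x >= phi:
        x *= 1.0 - p
        n += 1
    return 1 + n


@dataclass(frozen=True)
class ExactSizeDistribution:
    """Exact final-size law P(N_f = n) for a small founder molecule count.

    probs[n] is P(N_f = n) for n = 0..max_size (probs[0] = probs[1] = 0 for
    terminating parameters with n0 >= threshold).  Final-size laws have
    geometric tails (a dividing cell can pass all molecules to one daughter),
    so the support is truncated at max_size and the lost tail mass reported.
    """

    params: DivisionParams
    n0: int
    probs: np.ndarray
    truncated_mass: float

    def prob(self, nf: int) -> float:
        if nf < 0 or nf >= len(self.probs):
            return 0.0
        return float(self.probs[nf])


def exact_size_distribution(
    params: DivisionParams, n0: int, max_size: int = 512
) -> ExactSizeDistribution:
    """Exact distribution of N_f by recursion over molecule counts.

    A cell holding m < phi*n0 molecules is one quiescent cell.  Otherwise its
    subtree size is the sum of two independent subtrees over the binomial
    split a ~ Bin(m, p).  Writing D_m for the subtree-size law of a cell with
    m molecules, the all-or-none splits a in {0, m} reproduce D_m shifted by
    one leaf, giving the linear recurrence

        D_m[n] = (p**m + (1-p)**m) * D_m[n-1] + C_m[n],

    with C_m the convolution mixture over the proper splits 0 < a < m, solved
    exactly as an IIR filter.  Tractable for n0 up to a few tens.
    """
    if n0 < 1:
        raise ValueError(f"n0 must be >= 1, got {n0}")
    if n0 > 30:
        raise ValueError(
            f"exact enumeration is intended for n0 <= 30 molecules, got {n0}"
        )
    p = params.p
    threshold = molecule_threshold(params.phi, n0)
    if threshold <= 1.0:
        raise RunawayGrowthError(
            f"threshold phi*n0 = {threshold} <= 1 molecule: the final size is "
            "almost surely infinite"
        )
    size = max_size + 1
    dists = np.zeros((n0 + 1, size))
    for m in range(n0 + 1):
        if m < threshold:
            dists[m, 1] = 1.0
            continue
        pmf = binom.pmf(np.arange(m + 1), m, p)
        mixture = np.zeros(size)
        for a in range(1, m):
            conv = np.convolve(dists[a], dists[m - a])[:size]
            mixture += pmf[a] * conv
        loop = pmf[0] + pmf[m]
        dists[m] = lfilter([1.0], [1.0, -loop], mixture)
    probs = np.clip(dists[n0], 0.0, None)
    truncated = max(0.0, 1.0 - probs.sum())
    return ExactSizeDistribution(
        params=params, n0=n0, probs=probs, truncated_mass=truncated
    )
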