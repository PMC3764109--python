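"""Stochastic lineage growth with binomial segregation of integer molecules.

The founder carries n0 molecules of the division factor.  At each division
the p-side daughter receives a ~ Binomial(m, p) molecules and the other m - a,
modelling independent segregation of molecules (volume-asymmetry style
noise).  A cell divides iff its molecule count m satisfies m >= phi * n0,
i.e. its content as a fraction of the founder's is at least the threshold.
Zero-molecule daughters are legitimate quiescent cells and count toward N_f.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    DEFAULT_CAPS,
    DivisionParams,
    GrowthCaps,
    LineageNode,
    LineageTree,
    RunawayGrowthError,
)
from .rng import generator, seed_sequence, substream
from .topology import GrowthCurve

__all__ = [
    "SizeDistribution",
    "partition_molecules",
    "molecule_threshold",
    "grow_stochastic",
    "batch_final_stats",
    "simulate_size_distribution",
]


def molecule_threshold(phi: float, n0: int) -> float:
    """The molecule-count threshold phi * n0, snapped to an exact integer.

    Grid phi values are short decimals whose product with round n0 is meant
    to be an integer (e.g. 0.0025 * 10000 = 25) but floats give
    25.000000000000004; values within 1e-9 relative of an integer are snapped
    so the >= comparison honours the intended decimal threshold.
    """
    t = phi * n0
    nearest = round(t)
    if nearest > 0 and abs(t - nearest) <= 1e-9 * max(1.0, t):
        return float(nearest)
    return t


def _require_terminating(phi: float, n0: int, params_repr: str) -> float:
    threshold = molecule_threshold(phi, n0)
    if threshold <= 1.0:
        raise RunawayGrowthError(
            f"runaway growth at {params_repr}: threshold phi*n0 = {threshold} <= 1 "
            "molecule, so every cell holding at least one molecule divides and "
            "molecule conservation makes termination impossible"
        )
    return threshold


def partition_molecules(
    m: int, p: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomially split m molecules; returns (a, b) with a the p-side share."""
    if m < 0:
        raise ValueError(f"molecule count must be nonnegative, got {m}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"partition probability must lie in [0, 1], got {p}")
    a = int(rng.binomial(m, p))
    return a, m - a


@dataclass(frozen=True)
class SizeDistribution:
    """Empirical distribution of the final population size over replicates.

    mode is the most frequent N_f (ties broken toward the smallest size);
    confidence is the fraction of replicates hitting the mode.
    """

    counts: dict[int, int]
    reps: int
    mode: int
    confidence: float

    @staticmethod
    def from_sizes(sizes: np.ndarray | list[int]) -> "SizeDistribution":
        counts = Counter(int(s) for s in sizes)
        reps = sum(counts.values())
        if reps == 0:
            raise ValueError("size distribution needs at least one replicate")
        best = max(counts.values())
        mode = min(nf for nf, c in counts.items() if c == best)
        return SizeDistribution(
            counts=dict(sorted(counts.items())),
            reps=reps,
            mode=mode,
            confidence=best / reps,
        )


def grow_stochastic(
    params: DivisionParams,
    n0: int,
    seed=None,
    caps: GrowthCaps = DEFAULT_CAPS,
) -> LineageTree:
    """Grow one full stochastic lineage tree (nodes materialized)."""
    return _grow_tree(params, n0, seed, caps, sigma_p=0.0, sigma_phi=0.0)


def _grow_tree(
    params: DivisionParams,
    n0: int,
    seed,
    caps: GrowthCaps,
    sigma_p: float,
    sigma_phi: float,
) -> LineageTree:
    """Shared tree builder for the plain and parameter-perturbed engines.

    With both sigmas zero the draw sequence is exactly one binomial per
    division in frontier order, so perturbed(sigma=0) and plain runs with
    matched seeds produce identical trees.
    """
    if n0 < 1:
        raise ValueError(f"initial molecule count n0 must be >= 1, got {n0}")
    p, phi = params.p, params.phi
    threshold = _require_terminating(phi, n0, f"(p={p}, phi={phi}, n0={n0})")
    rng = generator(seed)
    seed_val = seed if isinstance(seed, int) else None
    nodes = [LineageNode(0, None, float(n0), 0)]
    frontier = [0]
    quiescent = 0
    sizes = [1]
    t = 0
    while frontier:
        t += 1
        if t > caps.max_iterations:
            raise RunawayGrowthError(
                f"runaway growth at (p={p}, phi={phi}, n0={n0}): exceeded "
                f"max_iterations={caps.max_iterations}"
            )
        new_frontier: list[int] = []
        divisions = 0
        for i in frontier:
            m = int(nodes[i].content)
            if sigma_phi > 0.0:
                thr = max(rng.normal(phi, sigma_phi * phi), 0.0) * n0
            else:
                thr = threshold
            if m < thr:
                quiescent += 1
                continue
            if sigma_p > 0.0:
                p_eff = min(max(rng.normal(p, sigma_p * p), 0.0), 1.0)
            else:
                p_eff = p
            a, b = partition_molecules(m, p_eff, rng)
            divisions += 1
            big = LineageNode(len(nodes), i, float(b), t)
            nodes.append(big)
            small = LineageNode(len(nodes), i, float(a), t)
            nodes.append(small)
            nodes[i].divided = True
            nodes[i].children = (big.node_id, small.node_id)
            new_frontier.extend((big.node_id, small.node_id))
        if divisions == 0:
            break
        frontier = new_frontier
        n = quiescent + len(frontier)
        if n > caps.max_cells:
            raise RunawayGrowthError(
                f"runaway growth at (p={p}, phi={phi}, n0={n0}): exceeded "
                f"max_cells={caps.max_cells}"
            )
        sizes.append(n)
    engine = "stochastic" if sigma_p == 0.0 and sigma_phi == 0.0 else "perturbed"
    return LineageTree(
        nodes=nodes,
        params=params,
        engine=engine,
        n0=n0,
        seed=seed_val,
        growth_curve=GrowthCurve(tuple(sizes)),
    )


def batch_final_stats(
    params: DivisionParams,
    n0: int,
    reps: int,
    rng: np.random.Generator,
    caps: GrowthCaps = DEFAULT_CAPS,
    sigma_p: float = 0.0,
    sigma_phi: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized counts-only growth of ``reps`` independent lineages.

    All replicates advance through synchronous iterations together; per
    iteration one binomial draw covers every dividing cell across replicates.
    Returns (final_sizes, linear_flags, durations), one entry per replicate.
    A lineage is linear iff every one of its iterations performed exactly one
    division.  Used by the sweep/confidence/perturbation analyses where the
    per-replicate node trees are not needed.
    """
    if n0 < 1:
        raise ValueError(f"initial molecule count n0 must be >= 1, got {n0}")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    p, phi = params.p, params.phi
    threshold = _require_terminating(phi, n0, f"(p={p}, phi={phi}, n0={n0})")
    live = np.full(reps, n0, dtype=np.int64)
    rep = np.arange(reps)
    leaves = np.zeros(reps, dtype=np.int64)
    linear = np.ones(reps, dtype=bool)
    duration = np.zeros(reps, dtype=np.int64)
    t = 0
    while live.size:
        t += 1
        if t > caps.max_iterations:
            raise RunawayGrowthError(
                f"runaway growth at (p={p}, phi={phi}, n0={n0}): exceeded "
                f"max_iterations={caps.max_iterations}"
            )
        if sigma_phi > 0.0:
            thr = np.clip(rng.normal(phi, sigma_phi * phi, live.size), 0.0, None) * n0
            eligible = live >= thr
        else:
            eligible = live >= threshold
        alive = np.bincount(rep, minlength=reps) > 0
        divs = np.bincount(rep[eligible], minlength=reps)
        done_now = alive & (divs == 0)
        duration[done_now] = t - 1
        linear[alive & (divs > 1)] = False
        leaves += np.bincount(rep[~eligible], minlength=reps)
        m = live[eligible]
        r = rep[eligible]
        if m.size == 0:
            break
        if sigma_p > 0.0:
            p_eff = np.clip(rng.normal(p, sigma_p * p, m.size), 0.0, 1.0)
            a = rng.binomial(m, p_eff)
        else:
            a = rng.binomial(m, p)
        live = np.concatenate([m - a, a])
        rep = np.concatenate([r, r])
        cells = leaves + np.bincount(rep, minlength=reps)
        worst = int(cells.max())
        if worst > caps.max_cells:
            raise RunawayGrowthError(
                f"runaway growth at (p={p}, phi={phi}, n0={n0}): exceeded "
                f"max_cells={caps.max_cells} in replicate "
                f"{int(cells.argmax())}"
            )
    return leaves, linear, duration


def simulate_size_distribution(
    params: DivisionParams,
    n0: int,
    reps: int = 100,
    seed=None,
    caps: GrowthCaps = DEFAULT_CAPS,
    stream: str = "per_replicate",
) -> SizeDistribution:
    """Distribution of N_f over ``reps`` independent stochastic lineages.

    stream="per_replicate" (default) gives every replicate its own derived
    substream so any single replicate can be re-run in isolation;
    stream="batched" advances all replicates together on one substream (much
    faster for sweeps; same model, different draw ordering).
    """
    root = seed_sequence(seed)
    if stream == "batched":
        sizes, _, _ = batch_final_stats(params, n0, reps, np.random.default_rng(root), caps)
    elif stream == "per_replicate":
        sizes = np.empty(reps, dtype=np.int64)
        for k in range(reps):
            rng = np.random.default_rng(substream(root, k))
            try:
                nf, _, _ = batch_final_stats(params, n0, 1, rng, caps)
            except RunawayGrowthError as err:
                raise RunawayGrowthError(f"replicate {k}: {err}") from err
            sizes[k] = nf[0]
    else:
        raise ValueError(f"unknown stream layout {stream!r}")
    return SizeDistribution.from_sizes(sizes)
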