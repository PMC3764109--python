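"""Deterministic lineage growth under asymmetric dilution of a division factor.

The model: a founder cell carries one unit of a cell-cycle factor.  At every
synchronous iteration each cell whose factor content x satisfies x >= phi
divides, passing a fraction p of its content to one daughter and 1-p to the
other.  Content strictly below the threshold phi makes a cell permanently
quiescent.  Because the factor is only ever diluted, proliferation terminates
by itself and the number of quiescent cells is the final population size N_f.

Boundary rule (fixed, documented): a cell divides iff content >= phi.  This
matters at exact powers, e.g. p = 0.5, phi = 0.25 gives N_f = 8 because the
content-0.25 generation still divides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .topology import GrowthCurve

__all__ = [
    "DivisionParams",
    "GrowthCaps",
    "DEFAULT_CAPS",
    "RunawayGrowthError",
    "LineageNode",
    "LineageTree",
    "validate_params",
    "grow_deterministic",
    "final_size_deterministic",
]


class RunawayGrowthError(RuntimeError):
    """Raised when growth exceeds a safety cap or provably never terminates."""


@dataclass(frozen=True)
class GrowthCaps:
    """Safety limits for lineage growth.

    max_iterations : synchronous division rounds allowed before aborting.
    max_cells      : total cells (quiescent + dividing) allowed in one tree.
    """

    max_iterations: int = 10**5
    max_cells: int = 10**6


DEFAULT_CAPS = GrowthCaps()


@dataclass(frozen=True)
class DivisionParams:
    """The (p, phi) pair governing division asymmetry and cell-cycle exit.

    p   : fraction of the factor inherited by the small-side daughter,
          canonical range (0, 0.5] (p and 1-p describe the same split).
    phi : quiescence threshold as a fraction of the founder's content,
          range (0, 1].
    """

    p: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 0.5):
            raise ValueError(
                f"p must lie in (0, 0.5] after canonicalization, got {self.p!r}"
            )
        if not (0.0 < self.phi <= 1.0):
            raise ValueError(f"threshold phi must lie in (0, 1], got {self.phi!r}")


def validate_params(p: float, phi: float) -> DivisionParams:
    """Validate raw user input and canonicalize p into (0, 0.5].

    By symmetry of the two daughters, p and 1-p describe the same division;
    p > 0.5 is folded to 1-p.  phi = 0 is rejected because no cell could ever
    become quiescent (unbounded growth); phi > 1 would stop the founder itself.
    """
    p = float(p)
    phi = float(phi)
    if not np.isfinite(p) or not (0.0 < p < 1.0):
        raise ValueError(f"asymmetry fraction p must lie in (0, 1), got {p!r}")
    if not np.isfinite(phi) or phi <= 0.0:
        raise ValueError(f"threshold must be positive, got {phi!r}")
    if phi > 1.0:
        raise ValueError(f"threshold phi must lie in (0, 1], got {phi!r}")
    if p > 0.5:
        p = 1.0 - p
    return DivisionParams(p=p, phi=phi)


@dataclass
class LineageNode:
    """One cell in a lineage tree.

    content is a fraction of the founder content (deterministic engine) or an
    integer molecule count (stochastic engines).  generation is the
    synchronous iteration at which the cell was born.
    """

    node_id: int
    parent_id: Optional[int]
    content: float
    generation: int
    divided: bool = False
    children: tuple[int, ...] = ()


@dataclass
class LineageTree:
    """Rooted binary lineage tree plus its growth record."""

    nodes: list[LineageNode]
    params: DivisionParams
    engine: str  # {"deterministic", "stochastic", "perturbed"}
    n0: int
    seed: Optional[int]
    growth_curve: GrowthCurve

    @property
    def root(self) -> LineageNode:
        return self.nodes[0]

    def leaves(self) -> list[LineageNode]:
        return [n for n in self.nodes if not n.divided]

    @property
    def final_size(self) -> int:
        return len(self.nodes) - sum(1 for n in self.nodes if n.divided)


def _check_iterations(t: int, caps: GrowthCaps, params: DivisionParams) -> None:
    if t > caps.max_iterations:
        raise RunawayGrowthError(
            f"runaway growth at (p={params.p}, phi={params.phi}): exceeded "
            f"max_iterations={caps.max_iterations}"
        )


def _check_cells(n: int, caps: GrowthCaps, params: DivisionParams) -> None:
    if n > caps.max_cells:
        raise RunawayGrowthError(
            f"runaway growth at (p={params.p}, phi={params.phi}): exceeded "
            f"max_cells={caps.max_cells}"
        )


def grow_deterministic(
    params: DivisionParams, caps: GrowthCaps = DEFAULT_CAPS
) -> LineageTree:
    """Grow the full deterministic lineage tree for (p, phi).

    The founder has content 1.  At each iteration every cell with content >=
    phi divides into daughters x*(1-p) and x*p; the large daughter is the
    first child so deterministic serialization is canonical.  Terminates when
    no cell is eligible.
    """
    p, phi = params.p, params.phi
    nodes = [LineageNode(0, None, 1.0, 0)]
    frontier = [0]  # untested cells born last iteration
    quiescent = 0
    sizes = [1]
    t = 0
    while True:
        dividers = [i for i in frontier if nodes[i].content >= phi]
        if not dividers:
            break
        t += 1
        _check_iterations(t, caps, params)
        quiescent += len(frontier) - len(dividers)
        new_frontier: list[int] = []
        for i in dividers:
            x = nodes[i].content
            big = LineageNode(len(nodes), i, x * (1.0 - p), t)
            nodes.append(big)
            small = LineageNode(len(nodes), i, x * p, t)
            nodes.append(small)
            nodes[i].divided = True
            nodes[i].children = (big.node_id, small.node_id)
            new_frontier.extend((big.node_id, small.node_id))
        frontier = new_frontier
        n = quiescent + len(frontier)
        _check_cells(n, caps, params)
        sizes.append(n)
    return LineageTree(
        nodes=nodes,
        params=params,
        engine="deterministic",
        n0=1,
        seed=None,
        growth_curve=GrowthCurve(tuple(sizes)),
    )


def deterministic_curve(
    params: DivisionParams, caps: GrowthCaps = DEFAULT_CAPS
) -> GrowthCurve:
    """Growth curve N(0..T) without materializing nodes.

    Performs the identical floating-point arithmetic to grow_deterministic
    (daughters x*(1-p) and x*p compared to phi with plain >=), but keeps only
    the frontier contents, so the two paths agree exactly at every grid point.
    """
    p, phi = params.p, params.phi
    live = np.array([1.0])
    quiescent = 0
    sizes = [1]
    t = 0
    while True:
        eligible = live >= phi
        m = live[eligible]
        if m.size == 0:
            break
        t += 1
        _check_iterations(t, caps, params)
        quiescent += live.size - m.size
        live = np.concatenate([m * (1.0 - p), m * p])
        n = quiescent + live.size
        _check_cells(n, caps, params)
        sizes.append(n)
    return GrowthCurve(tuple(int(s) for s in sizes))


def final_size_deterministic(
    params: DivisionParams, caps: GrowthCaps = DEFAULT_CAPS
) -> int:
    """Final population size N_f; fast path equal to grow_deterministic."""
    return deterministic_curve(params, caps).final_size
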