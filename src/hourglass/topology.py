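"""Growth curves and the linear / non-linear topology classification.

A growth curve records the population size N(t) at each synchronous iteration
t = 0..T.  A lineage is "linear" when exactly one cell divides per iteration,
i.e. N(t) = t + 1 for every t; any curve violating that at even a single t is
"non-linear".
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GrowthCurve", "classify_topology", "completion_duration", "is_linear"]


@dataclass(frozen=True)
class GrowthCurve:
    """Population size per synchronous iteration, N(0) = 1 .. N(T) = N_f."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) == 0:
            raise ValueError("growth curve must contain at least N(0)")
        if self.sizes[0] != 1:
            raise ValueError(f"growth curve must start at N(0)=1, got {self.sizes[0]}")
        for a, b in zip(self.sizes, self.sizes[1:]):
            if not (a < b <= 2 * a):
                raise ValueError(
                    f"growth curve must be strictly increasing with at most a "
                    f"doubling per step, got {a} -> {b}"
                )

    @property
    def final_size(self) -> int:
        return self.sizes[-1]

    @property
    def duration(self) -> int:
        return len(self.sizes) - 1

    def __len__(self) -> int:
        return len(self.sizes)


def is_linear(curve: GrowthCurve) -> bool:
    """True iff N(t) = t + 1 for every iteration (one division per step)."""
    return all(n == t + 1 for t, n in enumerate(curve.sizes))


def classify_topology(curve: GrowthCurve) -> str:
    """Classify a growth curve as "linear" or "nonlinear"."""
    return "linear" if is_linear(curve) else "nonlinear"


def completion_duration(curve: GrowthCurve) -> int:
    """Number of synchronous iterations T until the lineage stopped growing."""
    return curve.duration
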