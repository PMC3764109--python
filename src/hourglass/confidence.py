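"""Stochastic grid analyses: modal final sizes and their confidence, the
census of high-confidence ("special"/magic) population sizes across founder
molecule counts, topology-confidence summaries and the deterministic vs
stochastic divergence map."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_CAPS, GrowthCaps, RunawayGrowthError
from .rng import seed_sequence, substream
from .stochastic import batch_final_stats
from .sweeps import DeterministicMap, ParameterGrid

__all__ = [
    "ConfidenceMap",
    "confidence_map",
    "high_confidence_census",
    "census_vs_n0",
    "topology_confidence_summary",
    "det_stoch_divergence",
    "DivergenceResult",
]


@dataclass
class ConfidenceMap:
    """Stochastic sweep results: per grid point the modal N_f, the fraction
    of replicates hitting it (confidence), and the majority topology class.

    Grid points whose growth cannot terminate (or hit a safety cap) are
    flagged in ``missing`` with the reason in ``failures``; their mode is -1
    and confidence NaN.
    """

    grid: ParameterGrid
    n0: int
    reps: int
    mode: np.ndarray
    confidence: np.ndarray
    linear: np.ndarray
    missing: np.ndarray
    failures: dict[tuple[int, int], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.grid.p_values):
            for j, phi in enumerate(self.grid.phi_values):
                rows.append(
                    (
                        p,
                        phi,
                        self.n0,
                        self.reps,
                        int(self.mode[i, j]),
                        float(self.confidence[i, j]),
                        "linear" if self.linear[i, j] else "nonlinear",
                        bool(self.missing[i, j]),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["p", "phi", "n0", "reps", "mode", "confidence", "topology", "missing"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _point_stats(params, n0, reps, rng, caps):
    sizes, linear_flags, _ = batch_final_stats(params, n0, reps, rng, caps)
    values, counts = np.unique(sizes, return_counts=True)
    best = counts.max()
    mode = int(values[counts == best].min())  # ties toward the smallest N_f
    confidence = best / reps
    linear = int(linear_flags.sum()) * 2 > reps  # majority vote; tie -> nonlinear
    return mode, confidence, linear


def confidence_map(
    grid: ParameterGrid,
    n0: int = 10_000,
    reps: int = 100,
    seed=None,
    caps: GrowthCaps = DEFAULT_CAPS,
) -> ConfidenceMap:
    """Simulate ``reps`` lineages at every grid point and record the modal
    final size, its confidence and the majority topology class.

    Each grid point gets its own substream keyed by its (i, j) index, so any
    point is reproducible in isolation.  Non-terminating points (phi * n0 <=
    1 molecule) are recorded as missing rather than aborting the sweep.
    """
    root = seed_sequence(seed)
    shape = (len(grid.p_values), len(grid.phi_values))
    mode = np.full(shape, -1, dtype=np.int64)
    confidence = np.full(shape, np.nan)
    linear = np.zeros(shape, dtype=bool)
    missing = np.zeros(shape, dtype=bool)
    failures: dict[tuple[int, int], str] = {}
    for i, j, params in grid.points():
        rng = np.random.default_rng(substream(root, i, j))
        try:
            mode[i, j], confidence[i, j], linear[i, j] = _point_stats(
                params, n0, reps, rng, caps
            )
        except RunawayGrowthError as err:
            missing[i, j] = True
            failures[(i, j)] = str(err)
    return ConfidenceMap(
        grid=grid,
        n0=n0,
        reps=reps,
        mode=mode,
        confidence=confidence,
        linear=linear,
        missing=missing,
        failures=failures,
    )


def high_confidence_census(
    cmap: ConfidenceMap, threshold: float = 0.9
) -> tuple[pd.Series, int]:
    """Per final size, the number of grid pairs whose mode is that size with
    confidence strictly above ``threshold``; plus the largest such size.

    Returns (census, max_nf); max_nf is 0 when no point clears the threshold.
    """
    ok = (~cmap.missing) & (cmap.confidence > threshold)
    values, counts = np.unique(cmap.mode[ok], return_counts=True)
    census = pd.Series(counts, index=values, name="pairs").rename_axis("nf")
    max_nf = int(values.max()) if values.size else 0
    return census, max_nf


def census_vs_n0(
    grid: ParameterGrid,
    n0_list: list[int],
    reps: int = 100,
    seed=None,
    threshold: float = 0.9,
    caps: GrowthCaps = DEFAULT_CAPS,
) -> pd.DataFrame:
    """High-confidence census at each founder molecule count in n0_list.

    Long-format table (n0, nf, count) exposing the "special" population
    sizes: N_f values whose census turns non-zero at smaller n0 than their
    neighbours.  n0_list must be sorted ascending.  Emergence is sporadic, so
    no monotonicity in n0 is implied.
    """
    if list(n0_list) != sorted(n0_list):
        raise ValueError("n0_list must be sorted ascending")
    root = seed_sequence(seed)
    rows = []
    for k, n0 in enumerate(n0_list):
        cmap = confidence_map(grid, n0=n0, reps=reps, seed=substream(root, k), caps=caps)
        census, _ = high_confidence_census(cmap, threshold)
        for nf, count in census.items():
            rows.append((int(n0), int(nf), int(count)))
    return pd.DataFrame(rows, columns=["n0", "nf", "count"])


def topology_confidence_summary(cmap: ConfidenceMap) -> pd.DataFrame:
    """Per topology class, the fraction of grid points above 90% confidence
    and the fraction at exactly 100%.

    A class with no grid points gets NaN fractions (undefined, not zero).
    """
    rows = []
    valid = ~cmap.missing
    for name, mask in (("linear", cmap.linear), ("nonlinear", ~cmap.linear)):
        sel = valid & mask
        n = int(sel.sum())
        if n == 0:
            rows.append((name, 0, np.nan, np.nan))
            continue
        conf = cmap.confidence[sel]
        rows.append(
            (name, n, float((conf > 0.9).mean()), float((conf == 1.0).mean()))
        )
    return pd.DataFrame(
        rows, columns=["topology", "points", "frac_above_90", "frac_at_100"]
    ).set_index("topology")


@dataclass(frozen=True)
class DivergenceResult:
    """|N_f(deterministic) - mode(stochastic)| per grid point.

    identity_fraction counts missing stochastic points as disagreements.
    """

    diff: np.ndarray
    identity_fraction: float


def det_stoch_divergence(
    dmap: DeterministicMap, cmap: ConfidenceMap
) -> DivergenceResult:
    """Absolute deterministic-vs-modal difference and the identical fraction."""
    if dmap.grid != cmap.grid:
        raise ValueError("deterministic and confidence maps use different grids")
    diff = np.abs(dmap.nf.astype(float) - cmap.mode.astype(float))
    diff[cmap.missing] = np.nan
    identical = (~cmap.missing) & (dmap.nf == cmap.mode)
    return DivergenceResult(
        diff=diff, identity_fraction=float(identical.mean())
    )
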