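"""Deterministic parameter-grid sweeps: N_f maps, size histograms, topology
variety and same-size regions of (p, phi) space."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_CAPS,
    DivisionParams,
    GrowthCaps,
    RunawayGrowthError,
    deterministic_curve,
)
from .topology import GrowthCurve, is_linear

__all__ = [
    "ParameterGrid",
    "DeterministicMap",
    "make_grid",
    "deterministic_map",
    "pair_count_histogram",
    "topology_variety",
    "region_for_size",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered (p, phi) axes; the sweep runs over their Cartesian product."""

    p_values: tuple[float, ...]
    phi_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals, hi in (("p", self.p_values, 0.5), ("phi", self.phi_values, 1.0)):
            arr = np.asarray(vals)
            if arr.size == 0:
                raise ValueError(f"{name} axis is empty")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")
            if arr[0] <= 0 or arr[-1] > hi + 1e-12:
                raise ValueError(f"{name} axis must lie in (0, {hi}]")

    @property
    def size(self) -> int:
        return len(self.p_values) * len(self.phi_values)

    def points(self):
        for i, p in enumerate(self.p_values):
            for j, phi in enumerate(self.phi_values):
                yield i, j, DivisionParams(p=p, phi=phi)


def make_grid(mesh: float) -> ParameterGrid:
    """Uniform grid p in {mesh, ..., 0.5}, phi in {mesh, ..., 1.0}.

    Zero is excluded (phi = 0 never terminates; p = 0 is a degenerate
    no-split) and the upper bounds are included.  The mesh must tile (0, 0.5]
    exactly.
    """
    if not (0.0 < mesh <= 0.5):
        raise ValueError(f"mesh must lie in (0, 0.5], got {mesh!r}")
    n_p = round(0.5 / mesh)
    if abs(n_p * mesh - 0.5) > 1e-9:
        raise ValueError(f"mesh {mesh!r} does not divide 0.5 evenly")
    p_values = tuple(float(k * mesh) for k in range(1, n_p + 1))
    phi_values = tuple(float(k * mesh) for k in range(1, 2 * n_p + 1))
    return ParameterGrid(p_values=p_values, phi_values=phi_values)


@dataclass
class DeterministicMap:
    """Deterministic sweep results over a parameter grid.

    Matrices are indexed [i_p, j_phi].  curves keeps the full growth curve of
    every grid point (the topology fingerprint) for region grouping.
    """

    grid: ParameterGrid
    nf: np.ndarray
    duration: np.ndarray
    linear: np.ndarray
    curves: np.ndarray = field(repr=False)  # object array of GrowthCurve

    @property
    def p_values(self) -> tuple[float, ...]:
        return self.grid.p_values

    @property
    def phi_values(self) -> tuple[float, ...]:
        return self.grid.phi_values

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (p, phi, nf, duration, topology)."""
        rows = []
        for i, p in enumerate(self.grid.p_values):
            for j, phi in enumerate(self.grid.phi_values):
                rows.append(
                    (
                        p,
                        phi,
                        int(self.nf[i, j]),
                        int(self.duration[i, j]),
                        "linear" if self.linear[i, j] else "nonlinear",
                    )
                )
        return pd.DataFrame(rows, columns=["p", "phi", "nf", "duration", "topology"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "DeterministicMap":
        """Rebuild nf/duration/topology matrices from a to_csv export.

        Growth curves are not serialized; region_for_size needs a freshly
        computed map.
        """
        frame = pd.read_csv(path)
        p_values = tuple(np.unique(frame["p"].to_numpy()))
        phi_values = tuple(np.unique(frame["phi"].to_numpy()))
        grid = ParameterGrid(p_values=p_values, phi_values=phi_values)
        shape = (len(p_values), len(phi_values))
        pix = {p: i for i, p in enumerate(p_values)}
        jix = {phi: j for j, phi in enumerate(phi_values)}
        nf = np.zeros(shape, dtype=np.int64)
        duration = np.zeros(shape, dtype=np.int64)
        linear = np.zeros(shape, dtype=bool)
        curves = np.empty(shape, dtype=object)
        for row in frame.itertuples(index=False):
            i, j = pix[row.p], jix[row.phi]
            nf[i, j] = row.nf
            duration[i, j] = row.duration
            linear[i, j] = row.topology == "linear"
        return DeterministicMap(grid=grid, nf=nf, duration=duration, linear=linear, curves=curves)


def deterministic_map(
    grid: ParameterGrid, caps: GrowthCaps = DEFAULT_CAPS
) -> DeterministicMap:
    """Run the deterministic engine at every grid point."""
    shape = (len(grid.p_values), len(grid.phi_values))
    nf = np.zeros(shape, dtype=np.int64)
    duration = np.zeros(shape, dtype=np.int64)
    linear = np.zeros(shape, dtype=bool)
    curves = np.empty(shape, dtype=object)
    for i, j, params in grid.points():
        try:
            curve = deterministic_curve(params, caps)
        except RunawayGrowthError as err:
            raise RunawayGrowthError(
                f"grid point (p={params.p}, phi={params.phi}): {err}"
            ) from err
        nf[i, j] = curve.final_size
        duration[i, j] = curve.duration
        linear[i, j] = is_linear(curve)
        curves[i, j] = curve
    return DeterministicMap(grid=grid, nf=nf, duration=duration, linear=linear, curves=curves)


def pair_count_histogram(dmap: DeterministicMap) -> pd.Series:
    """Count of grid pairs per final size N_f; totals the grid size."""
    values, counts = np.unique(dmap.nf, return_counts=True)
    return pd.Series(counts, index=values, name="pairs").rename_axis("nf")


def topology_variety(
    dmap: DeterministicMap,
) -> tuple[pd.Series, int, int]:
    """Distinct completion durations per N_f; returns (series, max, argmax N_f).

    Each distinct number of iterations taken to reach a given final size is
    one distinct topology in the coarse sense of the growth-duration
    fingerprint.  The maximum variety and the N_f attaining it (smallest such
    N_f on ties) are returned alongside the full per-size series.
    """
    frame = pd.DataFrame(
        {"nf": dmap.nf.ravel(), "duration": dmap.duration.ravel()}
    )
    variety = (
        frame.groupby("nf")["duration"].nunique().rename("variety").sort_index()
    )
    best_nf = int(variety.idxmax())
    return variety, int(variety.max()), best_nf


def region_for_size(
    dmap: DeterministicMap, nf: int
) -> dict[GrowthCurve, list[tuple[float, float]]]:
    """All grid pairs with final size nf, grouped by identical growth curve.

    Returns {curve: [(p, phi), ...]}; empty dict when no grid pair produces
    nf.  Every grid pair belongs to exactly one group across all nf values.
    """
    groups: dict[GrowthCurve, list[tuple[float, float]]] = {}
    hits = np.argwhere(dmap.nf == nf)
    for i, j in hits:
        curve = dmap.curves[i, j]
        if curve is None:
            raise ValueError(
                "this map has no growth curves (loaded from CSV?); recompute "
                "with deterministic_map to group regions by topology"
            )
        groups.setdefault(curve, []).append(
            (dmap.grid.p_values[i], dmap.grid.phi_values[j])
        )
    return groups
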