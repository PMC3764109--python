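"""Serialization: Newick trees, CSV tables, YAML run configuration and JSON
run metadata.  CSV is the canonical tabular format; a JSON sidecar records
the configuration and seed so any run is reproducible from (config, seed)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .core import DEFAULT_CAPS, GrowthCaps, LineageTree

__all__ = ["export_newick", "RunConfig", "write_run_metadata"]


def _format_content(value: float, integer: bool) -> str:
    if integer:
        return str(int(value))
    return format(value, ".10g")


def export_newick(tree: LineageTree) -> str:
    """Serialize a finished lineage tree as a Newick string.

    Leaf labels carry the final factor content (fraction for the
    deterministic engine, molecule count otherwise); internal nodes are
    labelled g<generation>; every branch spans one generation.  Children are
    already stored large-daughter-first.
    """
    integer = tree.engine != "deterministic"
    nodes = tree.nodes

    def render(idx: int) -> str:
        node = nodes[idx]
        if not node.divided:
            return f"{_format_content(node.content, integer)}:1"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner})g{node.generation}:1"

    # the root has no incoming branch
    body = render(0)
    body = body.rsplit(":", 1)[0]
    return body + ";"


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: (config, seed) is sufficient.

    n0_list holds one value for single-n0 analyses; sigma settings are only
    consulted by the perturbation commands.
    """

    engine: str = "deterministic"
    mesh: float = 0.0025
    n0_list: tuple[int, ...] = (10_000,)
    reps: int = 100
    seed: Optional[int] = None
    max_iterations: int = DEFAULT_CAPS.max_iterations
    max_cells: int = DEFAULT_CAPS.max_cells
    sigma_max: float = 0.10
    sigma_steps: int = 11
    which: str = "both"
    out_dir: str = "hourglass-out"

    @property
    def caps(self) -> GrowthCaps:
        return GrowthCaps(max_iterations=self.max_iterations, max_cells=self.max_cells)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["n0_list"] = list(self.n0_list)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "n0_list" in data:
            data["n0_list"] = tuple(int(v) for v in data["n0_list"])
        return RunConfig(**data)


def write_run_metadata(path, config: RunConfig, extra: dict | None = None) -> None:
    """JSON sidecar with the configuration, seed and package version."""
    from . import __version__

    data = asdict(config)
    data["n0_list"] = list(config.n0_list)
    payload = {"version": __version__, "config": data}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
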