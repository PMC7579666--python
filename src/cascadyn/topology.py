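"""Idealized one-to-one interaction topologies and the A → M experiment.

The structure of emergent cascades depends only on *where* the non-zero cells
of the reduced adjacency sit, so this module builds families of edge patterns
on an abstract n×n grid (default 10×10) with a constant trigger probability
``p`` on every edge, then runs the truncated power series over a whole suite
of configurations at once.

Generator families implement the recurring pattern logic — self-triggering
diagonals, a single trigger row (1-to-n), a single triggered column (n-to-1),
multiple rows/columns, chains and cycles, converging paths, dense blocks,
seeded random edge sets, and near-full grids — each accepting an optional
``gaps`` list (edges removed after generation) and ``extra_edges`` list, plus
an ``explicit`` entry point for arbitrary masks.  The packaged preset
instantiates 24 configurations of increasing complexity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import yaml

from .markov import (
    InteractionMatrix,
    ReducedAdjacency,
    ValidationError,
    amplified_pairs,
    emergent_pairs,
    interaction_matrix_truncated,
)

__all__ = [
    "TopologySpec",
    "TopologyResult",
    "build_topology",
    "run_topology_suite",
    "preset_suite",
    "load_suite",
    "GENERATORS",
]

DEFAULT_SIZE = 10
DEFAULT_P = 0.1
DEFAULT_TAU_MAX = 10


@dataclass(frozen=True)
class TopologySpec:
    """One named edge-pattern configuration.

    ``generator`` selects a family from :data:`GENERATORS`; ``params`` are the
    family's keyword arguments.  ``seed`` feeds the random family only and
    makes generation reproducible.
    """

    name: str
    generator: str = "explicit"
    size: int = DEFAULT_SIZE
    params: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass(frozen=True)
class TopologyResult:
    """Outcome of the A → M experiment for one configuration."""

    spec: TopologySpec
    adjacency: ReducedAdjacency
    interaction: InteractionMatrix
    emergent: set[tuple[str, str]]
    amplified: set[tuple[str, str]]


# ---------------------------------------------------------------------------
# generator families — each returns a set of (row, col) index pairs


def _gen_empty(n: int, rng) -> set[tuple[int, int]]:
    return set()


def _gen_diagonal(n: int, rng, indices: Iterable[int] | None = None) -> set[tuple[int, int]]:
    idx = range(n) if indices is None else indices
    return {(i, i) for i in idx}


def _gen_single_row(n: int, rng, row: int = 0, targets: Iterable[int] | None = None,
                    self_loop: bool = False) -> set[tuple[int, int]]:
    tg = [j for j in range(n) if j != row] if targets is None else list(targets)
    edges = {(row, j) for j in tg}
    if self_loop:
        edges.add((row, row))
    return edges


def _gen_single_column(n: int, rng, column: int = 0, sources: Iterable[int] | None = None,
                       self_loop: bool = False) -> set[tuple[int, int]]:
    src = [i for i in range(n) if i != column] if sources is None else list(sources)
    edges = {(i, column) for i in src}
    if self_loop:
        edges.add((column, column))
    return edges


def _gen_rows(n: int, rng, rows: Iterable[int] = (), targets: Iterable[int] | None = None) -> set:
    tg = range(n) if targets is None else list(targets)
    return {(i, j) for i in rows for j in tg if j != i}


def _gen_columns(n: int, rng, columns: Iterable[int] = (), sources: Iterable[int] | None = None) -> set:
    src = range(n) if sources is None else list(sources)
    return {(i, j) for j in columns for i in src if i != j}


def _gen_chain(n: int, rng, offset: int = 1, wrap: bool = False,
               self_loops: bool = False) -> set[tuple[int, int]]:
    edges = set()
    for i in range(n):
        j = i + offset
        if j < n:
            edges.add((i, j))
        elif wrap:
            edges.add((i, j % n))
    if self_loops:
        edges |= {(i, i) for i in range(n)}
    return edges


def _gen_block(n: int, rng, rows: tuple[int, int] = (0, 0), cols: tuple[int, int] = (0, 0)) -> set:
    return {(i, j) for i in range(rows[0], rows[1]) for j in range(cols[0], cols[1])}


def _gen_blocks(n: int, rng, blocks: Iterable[dict] = ()) -> set[tuple[int, int]]:
    edges: set[tuple[int, int]] = set()
    for blk in blocks:
        edges |= _gen_block(n, rng, rows=tuple(blk["rows"]), cols=tuple(blk["cols"]))
    return edges


def _gen_random(n: int, rng, density: float = 0.2) -> set[tuple[int, int]]:
    if rng is None:
        raise ValidationError("the random family requires a seed")
    mask = rng.random((n, n)) < density
    return {(i, j) for i, j in zip(*np.nonzero(mask))}


def _gen_full(n: int, rng, include_diagonal: bool = True) -> set[tuple[int, int]]:
    return {(i, j) for i in range(n) for j in range(n) if include_diagonal or i != j}


def _gen_explicit(n: int, rng, edges: Iterable[Iterable[int]] = ()) -> set[tuple[int, int]]:
    return {(int(i), int(j)) for i, j in edges}


GENERATORS: dict[str, Callable] = {
    "empty": _gen_empty,
    "diagonal": _gen_diagonal,
    "single_row": _gen_single_row,
    "single_column": _gen_single_column,
    "rows": _gen_rows,
    "columns": _gen_columns,
    "chain": _gen_chain,
    "block": _gen_block,
    "blocks": _gen_blocks,
    "random": _gen_random,
    "full": _gen_full,
    "explicit": _gen_explicit,
}


def _edge_set(spec: TopologySpec) -> set[tuple[int, int]]:
    try:
        gen = GENERATORS[spec.generator]
    except KeyError:
        raise ValidationError(f"{spec.name}: unknown generator {spec.generator!r}") from None
    params = dict(spec.params)
    gaps = [tuple(e) for e in params.pop("gaps", [])]
    extra = [tuple(e) for e in params.pop("extra_edges", [])]
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    edges = set(gen(spec.size, rng, **params))
    edges |= {(int(i), int(j)) for i, j in extra}
    edges -= {(int(i), int(j)) for i, j in gaps}
    for i, j in edges:
        if not (0 <= i < spec.size and 0 <= j < spec.size):
            raise ValidationError(f"{spec.name}: edge ({i},{j}) outside [0,{spec.size})")
    return edges


def build_topology(spec: TopologySpec, p: float = DEFAULT_P) -> ReducedAdjacency:
    """Materialize a spec as a reduced adjacency with constant probability p.

    Every edge cell holds exactly ``p``; a row with more than ``floor(1/p)``
    edges would break substochasticity and raises a validation error naming
    the configuration.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    values = np.zeros((spec.size, spec.size))
    for i, j in _edge_set(spec):
        values[i, j] = p
    labels = tuple(f"E{i}" for i in range(spec.size))
    try:
        return ReducedAdjacency(labels, values)
    except ValidationError as exc:
        raise ValidationError(f"{spec.name}: {exc}") from exc


def run_topology_suite(specs: list[TopologySpec], p: float = DEFAULT_P,
                       tau_max: int = DEFAULT_TAU_MAX) -> list[TopologyResult]:
    """Run the A → M experiment for every configuration in the suite."""
    if not specs:
        raise ValueError("suite must contain at least one configuration")
    results = []
    for spec in specs:
        a = build_topology(spec, p=p)
        m = interaction_matrix_truncated(a, tau_max)
        results.append(TopologyResult(
            spec=spec,
            adjacency=a,
            interaction=m,
            emergent=emergent_pairs(a, m),
            amplified=amplified_pairs(m, p),
        ))
    return results


# ---------------------------------------------------------------------------
# suite files


def load_suite(path: str | Path) -> list[TopologySpec]:
    """Load a suite of specs from a YAML or JSON list."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    specs = []
    for entry in raw:
        specs.append(TopologySpec(
            name=entry["name"],
            generator=entry.get("generator", "explicit"),
            size=int(entry.get("size", DEFAULT_SIZE)),
            params=entry.get("params", {}) or {},
            seed=entry.get("seed"),
        ))
    return specs


def preset_suite() -> list[TopologySpec]:
    """The packaged suite of 24 idealized configurations.

    Ordered by increasing pattern complexity: self-triggering diagonals,
    single trigger rows / triggered columns (with and without feedback),
    pairs of rows/columns with gaps, chains, cycles, converging paths,
    dense blocks, merging random edge sets, and (near-)full grids.
    """
    path = Path(str(resources.files("cascadyn").joinpath("data", "topology_suite.yaml")))
    return load_suite(path)
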