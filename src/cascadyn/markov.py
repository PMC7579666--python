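"""Absorbing-Markov machinery for catastrophe dynamics.

A catastrophe is modelled as a finite chain-of-events over ``n`` peril states
plus one absorbing *outflow* state.  One-to-one trigger probabilities live in
the reduced adjacency matrix ``A`` (n×n, substochastic: every row sum ≤ 1);
appending the outflow state, which receives the residual probability
``1 − Σ_j a_ij`` on each row and maps to itself with probability 1, yields the
full row-stochastic transition matrix.

Because every row of ``A`` leaks probability to the outflow state, the chain
is absorbed almost surely and the fundamental matrix

    N = (I − A)⁻¹ = I + A + A² + ⋯

is finite; ``n_ij`` is the expected number of times a cascade starting at
peril *i* visits peril *j* before dying off (the start itself counted, so the
diagonal is ≥ 1).  The *interaction matrix* ``M = N − I`` drops the step-0
self-occupancy and captures the emergent, multi-step structure: if ``A``
encodes 1→2 and 2→3, ``M`` additionally contains the two-step chain 1→3.

Two readouts classify the cells of ``M`` against the one-step probability
level ``p``:

* *emergent* pairs — ``m_ij > 0`` where ``a_ij = 0``: interactions reachable
  only through intermediary events (the expansion of the space of
  possibilities);
* *amplified* pairs — ``m_ij > p``: expected revisit counts exceeding the
  one-step probability, produced by feedback loops or converging paths.

Ties (``m_ij`` equal to ``p`` to within numerical tolerance, e.g. a pair
reachable by exactly one single-step path) are classed as expanded, not
amplified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .taxonomy import PerilRegistry

__all__ = [
    "ReducedAdjacency",
    "FullAdjacency",
    "InteractionMatrix",
    "FundamentalMatrix",
    "ValidationError",
    "ConvergenceError",
    "OUTFLOW_LABEL",
    "to_full",
    "interaction_matrix_truncated",
    "interaction_matrix_closed",
    "fundamental_matrix",
    "emergent_pairs",
    "amplified_pairs",
    "read_matrix_csv",
    "write_matrix_csv",
]

#: Label of the appended absorbing state in serialized full matrices.
OUTFLOW_LABEL = "OUT"

#: Row-sum validation tolerance; inputs are products of decimal fractions.
ROW_SUM_TOL = 1e-9

#: Absolute floor below which an interaction-matrix cell is treated as zero
#: when classifying cells (guards against round-off in the linear solve).
CLASSIFY_ATOL = 1e-12


class ValidationError(ValueError):
    """A matrix violates its structural invariants."""


class ConvergenceError(ValueError):
    """The power series diverges / (I − A) is numerically singular."""


def _as_labels(labels: Iterable[str]) -> tuple[str, ...]:
    out = tuple(str(x) for x in labels)
    if len(set(out)) != len(out):
        raise ValidationError("matrix labels must be unique")
    return out


@dataclass(frozen=True)
class ReducedAdjacency:
    """Substochastic n×n matrix of one-to-one trigger probabilities.

    ``values[i, j]`` is the conditional probability that peril ``labels[i]``
    triggers peril ``labels[j]`` in one step.  Rows may sum to less than 1;
    the residual is the probability the cascade dies off at that step.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", _as_labels(self.labels))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"expected a {n}×{n} matrix, got shape {v.shape}")
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("entries must be probabilities in [0, 1]")
        sums = v.sum(axis=1)
        bad = np.nonzero(sums > 1 + ROW_SUM_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"row {self.labels[bad[0]]!r} sums to {sums[bad[0]]:.12g} > 1"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def support(self) -> set[tuple[str, str]]:
        """Ordered label pairs of strictly positive entries."""
        rows, cols = np.nonzero(self.values > 0)
        return {(self.labels[i], self.labels[j]) for i, j in zip(rows, cols)}

    def check_registry(self, registry: PerilRegistry) -> None:
        for lab in self.labels:
            if lab not in registry:
                raise ValidationError(f"label {lab!r} does not resolve in the registry")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class FullAdjacency:
    """(n+1)×(n+1) row-stochastic transition matrix with the outflow state."""

    labels: tuple[str, ...]          # peril ids plus the outflow label, last
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", _as_labels(self.labels))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        m = len(self.labels)
        if v.shape != (m, m):
            raise ValidationError(f"expected a {m}×{m} matrix, got shape {v.shape}")
        if not np.allclose(v.sum(axis=1), 1.0, rtol=0, atol=ROW_SUM_TOL):
            raise ValidationError("every row of a full adjacency must sum to 1")
        unit = np.zeros(m)
        unit[-1] = 1.0
        if not np.array_equal(v[-1], unit):
            raise ValidationError("last row must be the unit vector on the outflow state")

    @property
    def n(self) -> int:
        """Number of real peril states (excludes the outflow state)."""
        return len(self.labels) - 1

    @property
    def outflow_label(self) -> str:
        return self.labels[-1]

    def reduced(self) -> ReducedAdjacency:
        return ReducedAdjacency(self.labels[:-1], self.values[:-1, :-1].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class InteractionMatrix:
    """Expected transient visit counts beyond step 0 (the matrix M)."""

    labels: tuple[str, ...]
    values: np.ndarray
    tau_max: int | Literal["closed_form"]
    method: Literal["truncated", "closed_form"]

    def __post_init__(self):
        object.__setattr__(self, "labels", _as_labels(self.labels))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < -CLASSIFY_ATOL):
            raise ValidationError("interaction-matrix entries must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class FundamentalMatrix:
    """Expected total visit counts N = (I − A)⁻¹, diagonal ≥ 1."""

    labels: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


# ---------------------------------------------------------------------------
# constructions


def to_full(a: ReducedAdjacency, outflow_label: str = OUTFLOW_LABEL) -> FullAdjacency:
    """Append the absorbing outflow state to a reduced adjacency.

    The outflow column receives ``1 − Σ_j a_ij`` on each real row (probability
    conservation); the outflow row is the unit vector on itself, so the
    cascade dies off once it leaves the real perils.
    """
    if outflow_label in a.labels:
        raise ValidationError(f"outflow label {outflow_label!r} collides with a peril label")
    n = a.n
    full = np.zeros((n + 1, n + 1))
    full[:n, :n] = a.values
    full[:n, n] = 1.0 - a.values.sum(axis=1)
    full[n, n] = 1.0
    return FullAdjacency(a.labels + (outflow_label,), full)


def interaction_matrix_truncated(a: ReducedAdjacency, tau_max: int) -> InteractionMatrix:
    """Partial power series  M(τ_max) = Σ_{τ=1..τ_max} Aᵗ.

    The truncation depth is the maximum chain-of-events length considered;
    entries are non-decreasing in ``tau_max`` and converge to the closed-form
    interaction matrix whenever the spectral radius of ``A`` is below 1.
    """
    if tau_max < 1:
        raise ValueError(f"tau_max must be ≥ 1, got {tau_max}")
    power = a.values.copy()
    total = a.values.copy()
    for _ in range(2, tau_max + 1):
        power = power @ a.values
        total += power
    return InteractionMatrix(a.labels, total, tau_max=tau_max, method="truncated")


def fundamental_matrix(a: ReducedAdjacency, radius_tol: float = 1e-9) -> FundamentalMatrix:
    """Closed-form expected visit counts N = (I − A)⁻¹.

    Solves the linear system ``(I − A) N = I`` rather than forming an explicit
    inverse.  Requires the spectral radius of ``A`` to be strictly below 1
    (checked via the largest-magnitude eigenvalue); otherwise the cascade has
    a non-absorbing component and the series diverges.
    """
    radius = float(np.max(np.abs(np.linalg.eigvals(a.values))))
    if radius >= 1 - radius_tol:
        raise ConvergenceError(
            f"spectral radius {radius:.6g} ≥ 1: the chain may never be absorbed; "
            "use interaction_matrix_truncated instead"
        )
    eye = np.eye(a.n)
    try:
        n_mat = np.linalg.solve(eye - a.values, eye)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by radius check
        raise ConvergenceError(f"(I − A) is numerically singular: {exc}") from exc
    return FundamentalMatrix(a.labels, n_mat)


def interaction_matrix_closed(a: ReducedAdjacency) -> InteractionMatrix:
    """Closed-form interaction matrix M = N − I = (I − A)⁻¹ − I."""
    n_mat = fundamental_matrix(a)
    values = n_mat.values - np.eye(a.n)
    # round-off from the solve can leave tiny negative dust in exact zeros
    values[np.abs(values) < CLASSIFY_ATOL] = 0.0
    return InteractionMatrix(a.labels, values, tau_max="closed_form", method="closed_form")


# ---------------------------------------------------------------------------
# readouts


def _check_same_labels(a_labels: tuple[str, ...], m_labels: tuple[str, ...]) -> None:
    if a_labels != m_labels:
        raise ValueError("adjacency and interaction matrices carry different labels")


def emergent_pairs(a: ReducedAdjacency, m: InteractionMatrix,
                   atol: float = CLASSIFY_ATOL) -> set[tuple[str, str]]:
    """Ordered pairs reachable only through intermediaries: m_ij > 0, a_ij = 0."""
    _check_same_labels(a.labels, m.labels)
    rows, cols = np.nonzero((m.values > atol) & (a.values <= atol))
    return {(a.labels[i], a.labels[j]) for i, j in zip(rows, cols)}


def amplified_pairs(m: InteractionMatrix, p: float,
                    atol: float = CLASSIFY_ATOL) -> set[tuple[str, str]]:
    """Ordered pairs whose expected revisit count strictly exceeds ``p``.

    ``p`` is the one-step probability level of the binary encoding; cells at
    exactly ``p`` (single one-step path, no feedback) are not amplified.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    rows, cols = np.nonzero(m.values > p + atol)
    return {(m.labels[i], m.labels[j]) for i, j in zip(rows, cols)}


# ---------------------------------------------------------------------------
# CSV I/O (header row and column of peril ids; outflow column labelled OUT)


def write_matrix_csv(matrix, path: str | Path) -> None:
    """Write any labelled matrix (reduced/full/interaction/fundamental) as CSV."""
    matrix.to_frame().to_csv(path, index_label="")


def read_matrix_csv(path: str | Path,
                    registry: PerilRegistry | None = None) -> ReducedAdjacency | FullAdjacency:
    """Read a matrix CSV; a trailing OUT row/column yields a FullAdjacency."""
    frame = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in frame.columns]
    if list(frame.index.astype(str)) != labels:
        raise ValidationError(f"{path}: row and column labels differ")
    values = frame.to_numpy(dtype=float)
    if labels and labels[-1] == OUTFLOW_LABEL:
        return FullAdjacency(tuple(labels), values)
    a = ReducedAdjacency(tuple(labels), values)
    if registry is not None:
        a.check_registry(registry)
    return a
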