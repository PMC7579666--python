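"""Absorbing-Markov core: full-matrix construction, power series, readouts.

The frozen expected values come from independent oracles computed by hand
before the implementation: symbolic 2×2 inversion for the two-cycle, direct
matrix multiplication for the nilpotent 3-chain, and the geometric sum for
self-loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascadyn import (
    ConvergenceError,
    FullAdjacency,
    ReducedAdjacency,
    ValidationError,
    amplified_pairs,
    emergent_pairs,
    fundamental_matrix,
    interaction_matrix_closed,
    interaction_matrix_truncated,
    read_matrix_csv,
    to_full,
    write_matrix_csv,
)
from conftest import random_substochastic

# independent oracles, frozen
TWO_CYCLE_N = np.array([[1.0, 0.1], [0.1, 1.0]]) / 0.99   # inv([[1,-.1],[-.1,1]])
GEOM_SUM_10 = sum(0.1 ** t for t in range(1, 11))          # = (0.1 - 0.1**11) / 0.9


def substochastic_matrices(max_n=6):
    return st.builds(
        lambda seed, n: ReducedAdjacency(
            tuple(f"S{i}" for i in range(n)),
            random_substochastic(np.random.default_rng(seed), n)),
        st.integers(0, 2**31 - 1), st.integers(2, max_n))


# -- to_full ----------------------------------------------------------------

def test_to_full_zero_matrix():
    a = ReducedAdjacency(("A", "B"), np.zeros((2, 2)))
    full = to_full(a)
    assert full.values.shape == (3, 3)
    assert np.array_equal(full.values, [[0, 0, 1], [0, 0, 1], [0, 0, 1]])
    assert full.labels == ("A", "B", "OUT")


def test_to_full_outflow_column(two_cycle):
    full = to_full(two_cycle)
    np.testing.assert_array_equal(full.values[:2, 2], [0.9, 0.9])
    np.testing.assert_array_equal(full.values[2], [0, 0, 1])


def test_to_full_rejects_superstochastic_row():
    with pytest.raises(ValidationError, match="B"):
        ReducedAdjacency(("A", "B"), [[0.0, 0.5], [0.9, 0.2]])


def test_full_adjacency_requires_absorbing_last_row():
    with pytest.raises(ValidationError, match="unit vector"):
        FullAdjacency(("A", "OUT"), [[0.5, 0.5], [0.5, 0.5]])


@settings(derandomize=True, max_examples=50)
@given(substochastic_matrices())
def test_to_full_conserves_probability(a):
    """Every row of the full matrix sums to 1 within 1e-12 (conservation)."""
    full = to_full(a)
    np.testing.assert_allclose(full.values.sum(axis=1), 1.0, rtol=0, atol=1e-12)
    assert full.reduced().labels == a.labels
    np.testing.assert_array_equal(full.reduced().values, a.values)


# -- truncated power series -------------------------------------------------

def test_truncated_zero_matrix():
    a = ReducedAdjacency(("A", "B"), np.zeros((2, 2)))
    m = interaction_matrix_truncated(a, 5)
    assert not m.values.any()
    assert m.method == "truncated" and m.tau_max == 5


def test_truncated_chain_by_hand(chain3):
    """A² has the single entry 0.01 at (A,C); A³ = 0."""
    m = interaction_matrix_truncated(chain3, 10)
    expected = np.zeros((3, 3))
    expected[0, 1] = expected[1, 2] = 0.1
    expected[0, 2] = 0.01
    np.testing.assert_allclose(m.values, expected, rtol=0, atol=1e-15)


def test_truncated_diagonal_geometric_sum():
    a = ReducedAdjacency(tuple(f"E{i}" for i in range(10)), np.eye(10) * 0.1)
    m = interaction_matrix_truncated(a, 10)
    np.testing.assert_allclose(np.diag(m.values), GEOM_SUM_10, rtol=0, atol=1e-15)
    assert not (m.values - np.diag(np.diag(m.values))).any()


def test_truncated_rejects_bad_depth(two_cycle):
    with pytest.raises(ValueError, match="tau_max"):
        interaction_matrix_truncated(two_cycle, 0)


@settings(derandomize=True, max_examples=30)
@given(substochastic_matrices(), st.integers(1, 8))
def test_truncated_monotone_in_depth(a, tau):
    """Partial sums of a non-negative series are entrywise non-decreasing."""
    shallow = interaction_matrix_truncated(a, tau).values
    deep = interaction_matrix_truncated(a, tau + 3).values
    assert np.all(deep >= shallow - 1e-15)


@settings(derandomize=True, max_examples=30)
@given(substochastic_matrices())
def test_support_growth(a):
    """support(M) ⊇ support(A) for any truncation depth ≥ 1."""
    m = interaction_matrix_truncated(a, 4)
    assert np.all(m.values[a.values > 0] > 0)


# -- fundamental matrix / closed form ---------------------------------------

def test_fundamental_zero_matrix():
    a = ReducedAdjacency(("A", "B"), np.zeros((2, 2)))
    np.testing.assert_array_equal(fundamental_matrix(a).values, np.eye(2))


def test_fundamental_two_cycle_oracle(two_cycle):
    n = fundamental_matrix(two_cycle)
    np.testing.assert_allclose(n.values, TWO_CYCLE_N, rtol=0, atol=1e-12)
    assert np.all(np.diag(n.values) >= 1)


def test_fundamental_diverges_on_recurrent_state():
    a = ReducedAdjacency(("A",), [[1.0]])
    with pytest.raises(ConvergenceError, match="truncated"):
        fundamental_matrix(a)


def test_closed_form_two_cycle(two_cycle):
    m = interaction_matrix_closed(two_cycle)
    np.testing.assert_allclose(m.values, [[0.01 / 0.99, 0.1 / 0.99],
                                          [0.1 / 0.99, 0.01 / 0.99]], rtol=0, atol=1e-12)
    assert m.method == "closed_form"


def test_closed_form_matches_truncated_on_nilpotent(chain3):
    """A nilpotent series terminates: closed form equals any depth ≥ 2."""
    closed = interaction_matrix_closed(chain3).values
    np.testing.assert_allclose(closed, interaction_matrix_truncated(chain3, 2).values,
                               rtol=0, atol=1e-12)


@settings(derandomize=True, max_examples=30)
@given(substochastic_matrices())
def test_series_converges_to_closed_form(a):
    """Truncation error obeys the geometric tail bound c^(T+1)/(1−c), with c
    the largest row sum, checked at T = 50 (1e-10 numerical slack)."""
    c = float(a.values.sum(axis=1).max())
    closed = interaction_matrix_closed(a).values
    truncated = interaction_matrix_truncated(a, 50).values
    assert np.max(np.abs(closed - truncated)) <= c ** 51 / (1 - c) + 1e-10


# -- emergent / amplified readouts ------------------------------------------

def test_emergent_chain(chain3):
    m = interaction_matrix_truncated(chain3, 10)
    assert emergent_pairs(chain3, m) == {("A", "C")}


def test_emergent_empty_for_diagonal(diagonal3):
    m = interaction_matrix_closed(diagonal3)
    assert emergent_pairs(diagonal3, m) == set()


def test_emergent_label_mismatch(two_cycle, chain3):
    m = interaction_matrix_truncated(chain3, 3)
    with pytest.raises(ValueError, match="labels"):
        emergent_pairs(two_cycle, m)


def test_amplified_chain_is_empty(chain3):
    """m = p on the direct edges is a tie → expanded, not amplified."""
    m = interaction_matrix_truncated(chain3, 10)
    assert amplified_pairs(m, 0.1) == set()


def test_amplified_two_cycle(two_cycle):
    m = interaction_matrix_closed(two_cycle)
    assert amplified_pairs(m, 0.1) == {("X", "Y"), ("Y", "X")}


def test_amplified_diagonal(diagonal3):
    """Self-loops amplify: m_ii = 0.1/0.9 ≈ 0.111 > 0.1."""
    m = interaction_matrix_closed(diagonal3)
    assert amplified_pairs(m, 0.1) == {("A", "A"), ("B", "B"), ("C", "C")}


def test_amplified_rejects_bad_level(diagonal3):
    m = interaction_matrix_closed(diagonal3)
    with pytest.raises(ValueError, match="p"):
        amplified_pairs(m, 1.5)


# -- CSV round trips --------------------------------------------------------

def test_matrix_csv_round_trip(tmp_path, two_cycle):
    path = tmp_path / "a.csv"
    write_matrix_csv(two_cycle, path)
    back = read_matrix_csv(path)
    assert isinstance(back, ReducedAdjacency)
    assert back.labels == two_cycle.labels
    np.testing.assert_array_equal(back.values, two_cycle.values)


def test_full_matrix_csv_round_trip(tmp_path, two_cycle):
    path = tmp_path / "full.csv"
    full = to_full(two_cycle)
    write_matrix_csv(full, path)
    back = read_matrix_csv(path)
    assert isinstance(back, FullAdjacency)
    np.testing.assert_array_equal(back.values, full.values)
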