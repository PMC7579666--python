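# Methods

## Model and assumptions

A catastrophe is modelled as a discrete-time Markov chain over `n` peril
states plus one absorbing outflow state.  The reduced adjacency matrix `A`
holds stationary one-to-one trigger probabilities `a_ij ∈ [0, 1]` with row
sums ≤ 1; the outflow state absorbs the residual probability of each row, so
the chain is absorbed almost surely and every realized chain-of-events is
finite.  The model is linear and first order: interactions are one-to-one
(no multi-variate or conditioning effects), stationary in time, and carry no
severity or loss attributes.  Physical time is simplified to consecutive
trials — only causal order is preserved, not durations.

The fundamental matrix `N = (I − A)⁻¹` collects expected visit counts before
absorption (diagonal ≥ 1, the start itself counted); the interaction matrix
`M = N − I` excludes the step-0 occupancy.  `N` is defined on the *reduced*
matrix only: with the absorbing state included, `I − A` is singular by
construction, so the full matrix exists for simulation and probability
conservation while all closed-form algebra uses the reduced one.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p` | 0.1 | ad-hoc one-step probability of the binary encoding; every observed pair carries the same weight |
| `tau_max` (topology suite) | 10 | power-series truncation; most idealized patterns stabilize earlier |
| `tau_max` (historical) | 3 | chain depth of the historical readout: secondary/tertiary/quaternary effects |
| row-sum tolerance | 1e-9 | validation slack for substochasticity (inputs are decimal fractions) |
| classification tolerance | 1e-12 | absolute floor for the strict inequalities `m > 0` and `m > p` |
| `max_steps` (sampler) | 10,000 | absorption cap; hitting it signals a (near-)row-stochastic input, not bad luck |

`p = 0.1` keeps even the densest observed row (critical network failure,
6 outgoing edges) comfortably substochastic, and makes amplification
readable as "expected revisits exceed the one-step probability".

## Numerical choices

* The fundamental matrix is obtained by solving `(I − A) N = I`, not by
  explicit inversion; a spectral-radius precheck (largest eigenvalue
  magnitude < 1 − 1e-9) turns divergent inputs into a clear error that
  recommends the truncated series.
* The truncated series accumulates `A^τ` iteratively, so entries are exact
  partial sums and monotone in `tau_max`.
* The strict classification inequalities carry a 1e-12 absolute tolerance:
  solver round-off in cells that are exactly zero, or exactly at the tie
  `m = p` (a pair reachable by exactly one one-step path), can then never
  flip a classification.  Ties are classed as expanded, not amplified, since
  `p` itself is the boundary of the one-step regime.
* The truncation-error bound used in property tests is the geometric tail
  `c^(T+1)/(1 − c)` with `c` the largest row sum.  For the study's
  binary-encoded matrices (edges of 0.1, row sums ≤ 0.9, effective spectral
  radius far below the bound) the series at depth 50 agrees with the closed
  form to well below 1e-10; for arbitrary dense matrices with row sums near
  0.9 only the geometric bound itself holds at that depth.

## Taxonomy and historical encoding

The packaged taxonomy catalogues 19 generic perils — 11 natural, 8
anthropogenic — and fixes the matrix index order used by every output.  The
packaged case list transcribes 29 historical cascading catastrophes as
ordered directed pairs (122 listed, 64 distinct).  Encoding is binary by
design: no pair recurs often enough across 29 cases for a frequency
estimate, so a cell is `p` if observed at least once and 0 otherwise, and
recurrence information is kept as per-edge provenance instead of weight.
Normalization (uppercasing; the `ES` → `EC` alias for the economic-crisis
peril, which case encodings repeatedly write as "ES"; separator fixes such
as `(FL; FL)`) happens at parse time and is logged; the data file preserves
the raw strings for audit.  The extremely rare mass-slide→disease edge is
included by default with an exclusion flag, since with equal weights rare
interactions take a disproportionate role.

Known data limitations: the 29-case sample is indicative, not exhaustive;
multi-variate consequences (coinciding events, underlying conditions) are
out of the one-to-one model's scope and are not encoded.

## Idealized topology suite

The 24 packaged configurations are named generator families — diagonals,
single trigger rows / triggered columns with and without feedback, pairs of
rows/columns with gaps, chains, cycles, converging paths, dense and bridged
blocks, seeded random edge sets (density 0.2, which is enough for several
explored subspaces to merge), and (near-)full grids — ordered by increasing
pattern complexity.  The exact pixel patterns of the original figure-defined
suite are not reproducible from text, so the suite preserves the
experiment's structure and count while an `explicit` generator lets users
reproduce any specific mask.  Gap injection is an explicit edge-removal list
per spec, never implicit.

## Synthetic data and what it shows

The chain simulator samples finite chains-of-events from the full matrix —
exactly the process the algebra assumes: stationary categorical transitions,
absorption at outflow.  Synthetic catalogues record each chain as its
consecutive real-peril pairs in the same file dialect as the historical
transcription, so the full encoding pipeline can be validated end to end:
recorded pairs are provably a subset of the truth support (soundness), and
with strong edges (p = 0.9) and 500 round-robin cases the support is
recovered exactly.  Monte Carlo visit counts (initial occupancy included, to
target `N` rather than `M`) agree with fundamental-matrix entries within
three standard errors at 100,000 chains, and the chain-length distribution
of a single self-looping peril matches its geometric law.

Passing these tests shows the machinery is internally consistent under the
model's own assumptions.  It does not show that real catastrophe data are
stationary, Markovian, or completely observed — the synthetic generator
emulates none of the reporting biases, non-stationarity, or multi-variate
couplings of real event histories.

## Design choices on open points

* **Closeness** uses the harmonic variant on outgoing distances,
  `(1/(n−1)) Σ 1/d(i,j)` with `1/∞ = 0`: the empirical graph is not strongly
  connected (extraterrestrial perils are never triggered), so the plain
  average shortest-path length is undefined; the harmonic form keeps the
  "sources score high" interpretation.
* **Betweenness** uses fractional counting over tied shortest paths,
  endpoints excluded, self-loops ignored, unnormalized — stated explicitly
  so rankings are bit-for-bit reproducible; verified against brute-force
  path enumeration on small graphs.
* **Degrees** count self-loops once in each direction by default, with a
  flag to exclude them.
* Centralities are computed on the unweighted support graph, since the
  binary encoding makes all edge weights equal.
* The historical interaction matrix defaults to the truncated series at
  τ = 3 (the analysis depth of the historical readout); the closed form is
  available and both can be written side by side for comparison.

## Problem sizes

Default analyses are small by nature (10×10 and 19×19 matrices); the Monte
Carlo oracle runs 100,000 vectorized chains per fixture in well under a
second, and the complete test suite runs in a few seconds.
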