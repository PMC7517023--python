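# Methods

## Model and quantities

A bipartite interaction web is an `NX × NY` matrix of non-negative
integer counts `a_ij` with at least one positive entry (an all-zero
matrix is rejected as degenerate). Marginal totals `k_i(X) = Σ_j a_ij`
and `k_j(Y) = Σ_i a_ij` are the species degrees; `NM = Σ a_ij` is the
interaction total; occupancy (connectance) `ρ` is the fraction of cells
with at least one interaction.

Probabilities are maximum-likelihood cell and margin frequencies:
`p_i(X) = k_i/NM`, `p_j(Y) = k_j/NM`, `p_l(X,Y) = a_l/NM`. From these,
`H(X)`, `H(Y)`, `H(X,Y)`, the mutual information
`I(X;Y) = H(X)+H(Y)−H(X,Y)` and its normalization `S = I/H(X,Y)`.
Conventions:

- `0·log 0 = 0`; species with zero margin contribute nothing.
- Natural logarithms internally; entropies can be reported in bits or
  dits, but `S` and `H2′` are entropy ratios and therefore base-free.
- Weighted (count) matrices are accepted: the formulas generalize
  verbatim with weighted margins, while ρ still counts occupied cells.
- A matrix with a single occupied cell has `H(X,Y) = 0` and `S = 0/0`;
  this raises an error rather than returning a value.
- For a binary matrix every occupied cell has probability `1/NM`, so
  `H(X,Y) = log NM` exactly; `S` then depends on the margins only. This
  is the mechanism behind every swap-invariance result below.

`H2′ = (H(X,Y)max − H(X,Y)) / (H(X,Y)max − H(X,Y)min)` with
`H(X,Y)max = H(X)+H(Y)`. No closed form exists for `H(X,Y)min` over
tables with fixed margins; we use a greedy packing heuristic (repeatedly
place the largest feasible count at the row/column pair with the largest
remaining margins). Greedy packing is an upper bound on `I_max`, hence
`H2′` a (weak) upper bound on the exact index; it is exact on all the
small tables in the test suite, which cross-checks it against exhaustive
enumeration of every margin-preserving table. Degenerate margins that
admit a single table (e.g. 1×1) make `H2′` 0/0 and raise an error;
`decompose` reports `NaN` for `H2′` in that case rather than failing the
whole decomposition.

## Generators

Each family reproduces a closed-form test case; the equivalence
`|S_analytic − S_empirical| < 1e-10` is asserted over a grid of ≥120
parameter settings.

- **uniform_regular(N, ρ, seed)** — `k = ρN` must be an integer; the
  matrix is built from k cyclically shifted diagonals (every margin
  exactly k) and optionally shuffled by degree-preserving swaps. Because
  `S` for binary matrices depends only on margins, the shuffle is
  cosmetic; the closed form `S = log(1/ρ)/log(ρN²)` holds for any
  arrangement.
- **random_fill(NX, NY, ρ, seed)** — exactly `round(ρ·NX·NY)` cells
  drawn uniformly without replacement; margins free to vary. Rounding is
  half-away-from-zero throughout.
- **nested_packed(N)** — rows sorted by decreasing degree `N, N−1, …, 1`,
  left-packed above the antidiagonal; `NM = N(N+1)/2`.
- **nested_general(NX, NY, ρ, seed)** — perfectly nested at any feasible
  occupancy: left-packed rows with non-increasing lengths, first row
  full (no empty column), every row non-empty. A power-curve boundary
  `len(i) = clip(ceil(NY·(1−(i/NX)^γ)), 1, NY)` is bisected in γ toward
  the target cell count, then single cells are added/removed (seeded
  choice among rows that keep the profile non-increasing) until the
  count is met exactly. Any perfectly nested profile at the target ρ is
  admissible for the theory; this one was chosen for smoothness and
  exact occupancy control. Feasible ρ is `[(NY+NX−1)/(NX·NY), 1]`.
- **modular_isometric(m, t)**, **modular_rect(m, t, z)** — m fully
  occupied diagonal blocks; `ρ = 1/m`.
- **modular_increasing(m)** — blocks of sides 1..m; `N = m(m+1)/2`,
  `NM = m(m+1)(2m+1)/6`.
- **compound_nested(m, t)** — m diagonal blocks, each the packed-nested
  t×t pattern; `NM = m·t(t+1)/2`.

## Closed forms

Hyperfactorial sums are evaluated directly in log space:
`log Hyp(n) = Σ i·log i` and `log Hyp²(n) = Σ i²·log i` (the number
`Hyp(n)` itself overflows beyond n ≈ 100 and is never formed). The
nested and compound solutions follow from
`H(X) = log NM − log Hyp(N)/NM` (packed nested),
`H(X) = log NM − log Hyp²(m)/NM` (increasing modules) and
`H(X) = log NM − (m/NM)·log Hyp(t)` (compound), each with
`S = (2H(X) − log NM)/log NM` since `H(X) = H(Y)` and
`H(X,Y) = log NM` for these binary families.

Two isometric modular matrices share S iff `log N/log t` is equal, i.e.
module side and matrix side are in the same power relationship
(`equal_S_condition`, relative tolerance 1e-9; the diagonal class t = 1,
S = 1, matches only itself). Along a family with `log_t N` constant, S
is constant while `H(X,Y)` and `I` both grow — scale invariance.

## Null models and topology metrics

- **Checkerboard swap** — replace a `[[1,0],[0,1]]` submatrix by its
  complement on a random row and column pair. Candidates are found by
  rejection sampling capped at `10·NX·NY` tries, then by exhaustive
  scan; a matrix with no checkerboard raises a swap-rigidity error.
  Rejection is not exactly uniform over checkerboards; this does not
  affect any conclusion because every swap conserves all margins. Swap
  counts are accepted swaps, not attempts.
- **NODF** — mean over all row pairs and column pairs of
  `100·(shared interactions)/(smaller marginal total)`, with pairs of
  equal marginal totals contributing 0 (decreasing-fill condition). A
  pair whose smaller marginal is 0 also contributes 0. Note the
  consequence: a matrix with all margins equal (e.g. isometric modules)
  scores exactly 0 regardless of arrangement.
- **Modularity** — Barber's bipartite `Q = Σ_k (e_kk − a_k·b_k)` for an
  explicit module partition. The swap experiment tracks the *planted*
  partition laid down by the generator, since its purpose is to watch
  planted structure decay; `Q = 1 − 1/m` for m equal full blocks. For
  matrices without a known partition a greedy bipartite label-propagation
  heuristic (`detect_modules`) is provided, clearly a heuristic and not
  a community-detection algorithm.
- **swap_experiment** — applies sequential swaps to a generated matrix,
  recording step, S, NODF and Q at step 0, every `record_every` accepted
  swaps, and the final step. S is identical at every step to 1e-12
  (exactly, in fact: margins are conserved bit-for-bit), while NODF and
  Q decay; Q of the planted partition collapses within roughly ten swaps
  on the 3×(5×5 nested) compound matrix and then fluctuates near zero.

## Synthetic data and what the tests show

All matrices are generated by the package itself; no empirical web is
required or bundled. The generators emulate the idealized topologies the
closed forms describe — exact block structure, perfect nestedness, exact
margins. Real interaction webs have sampling noise, heavy-tailed degree
distributions and imperfect structure; passing tests demonstrate the
correctness of the formulas and their invariances, not that any
empirical web attains these values. Sampling-effort effects on S are
explicitly out of scope.

Problem sizes in the test and acceptance runs (20×20 nested, 120×120
modular, 100×100 random ensembles of 50 seeds, 200-swap trajectories at
15×15, a ~120-point analytic/empirical equivalence grid) match the model
sizes the closed forms are quoted at; the whole suite runs in well under
a minute.

## Known limitations

- `H2′` uses the greedy `H(X,Y)min` heuristic (exact on tested small
  tables; not guaranteed optimal in general).
- The uniform-margin closed form is a strict upper bound for the
  free-margin random model at finite N: hypergeometric margin
  fluctuations depress `H(X)+H(Y)` below `2 log N` by approximately
  `N·Var(k)/NM²` nats, so the random-model mean S sits a fraction of a
  percent below the closed form at N = 100 and converges only as N grows.
  The two agree at plot scale, not to within Monte-Carlo standard errors.
- Swap trajectories are not monotone step-by-step: NODF and Q can
  fluctuate upward locally after the initial collapse; only the net
  decay from the structured start is asserted.
- Three-dimensional (spatial) matrices, multitrophic extensions and
  significance testing against swap ensembles are out of scope.
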