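# Methods

## Problem and model

A *bicluster* of a binary matrix A ∈ {0,1}^(N×M) is a pair (I, J) of row and
column subsets whose induced submatrix is all ones; it is *maximal* when no
row or column can be added without breaking that property. In transcriptomics
a binary matrix typically arises from discretized expression (gene g responds
under condition c) or from an interaction adjacency (protein u binds protein
v), and maximal biclusters correspond to candidate co-expression modules or
interaction cliques-by-columns.

`nibclust` enumerates maximal biclusters by pairwise-AND template search:

1. **Encoding.** Each row is split into nibbles — every 4 consecutive
   columns become one decimal value d ∈ D = {0..15}, most significant bit
   first (column c inside a nibble occupies bit 3 − c mod 4, so the bit
   block 0101 is the value 5). Rows are zero-padded on the right to
   P = ⌈M/4⌉ nibbles; pad bits are 0 and can never enter a template.
2. **Templates.** For every seed-row pair (i, j), i < j, the template
   ρ_ij is the nibble-wise AND of the two encoded rows. Its 1-columns form
   the candidate column set J; the width ‖ρ‖ counts them. A template is
   processed once (the full nibble vector is the uniqueness key, recorded
   even when the width is below c_min so duplicates are never rescanned)
   and only if ‖ρ‖ ≥ c_min.
3. **Row inclusion by submask lookup.** The table V = {V_i}, i ∈ D holds
   V_0 = {0} and, for i ≥ 1, the nonzero values x with (i AND x) = x.
   Row l joins the bicluster iff every template nibble is a submask of the
   corresponding row nibble; positions are scanned left to right and a row
   is dropped at its first failing position. The emitted bicluster is
   (all matching rows ∪ {i, j}, J), kept iff it reaches r_min rows.

Membership uses one deliberate extension: a template nibble of 0 is treated
as contained in every row nibble (0 is a submask of everything). The strict
set definition, under which 0 only belongs to V_0, is what the analytic
results below are stated for; without the extension a template with any
empty nibble would reject all rows, and no multi-nibble search could work.
Both conventions live in one `SubmaskTable`; their agreement with the
bitwise-AND predicate is unit-tested.

### Average-case behaviour

Under the strict convention Σ_i |V_i| = 66 (|V_i| = 2^popcount(i) − 1 for
i ≥ 1, plus V_0), so when a template nibble and a row nibble are both
uniform over D the probability that the membership test succeeds is
66/256 ≈ 1/4: each nibble comparison retains about a quarter of the rows
still in play, the per-position work decays geometrically
(N, N/4, N/4², ...), and the expected cost per template is O(N) with an
N + (P − 1) best case (first position eliminates all but one non-seed row)
and an (N − 2)·P worst case (all-ones matrix, no early exit). The
instrumented search path counts one `contains()` call as one comparison —
nibble granularity, a factor-of-4 constant away from the bit-column
formulation; the geometric-decay property, not the absolute constant, is
the tested contract.

## Search modes

* **base** — r_min = c_min = 2 (forced, with a warning if the caller asks
  for more): the complete set of maximal biclusters reachable by pairwise
  AND.
* **flex** — user-raised minima, optional transpose-duplicate removal on
  square label-shared matrices (an adjacency bicluster (I, J) and its
  transpose (J, I) describe the same module; the lexicographically smaller
  key survives), and optional top-K truncation by area |I|·|J|
  (off by default). Flex is parameters + filters only; no scoring prior is
  invented.

Known completeness boundary: patterns reachable only from templates that no
seed pair generates exactly are not emitted (an inherent property of
pairwise-AND search). The contract, enforced by the oracle module, is
set-equality with the bit-level pairwise-AND reference and *subset* of the
full closed-pattern enumeration; single-row biclusters are never produced
because seeds are pairs. Duplicate rows are retained as distinct members
(collapsing them would change |I| and hence r_min semantics).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `r_min` | 2 | minimum rows per bicluster (≥ 2; seeds are pairs) |
| `c_min` | 2 | minimum template width (columns) |
| `mode` | base | base = forced 2/2; flex = user minima + filters |
| `top_k` | None | flex-mode truncation by area |
| binarize `quantile` | 0.5 | per-gene cutoff for the quantile rule |
| binarize `detection_floor` | per-gene min positive value | censoring point of the mixture method |

## Binarization

Expression matrices are discretized per gene. The `ltmg_simplified` method
approximates left-truncated mixture modelling with a censored two-component
Gaussian mixture: values below the detection floor are censored at the
floor, EM (scikit-learn `GaussianMixture`, median-split initialization,
seed from the config, tolerance 1e-4) fits two components, and a cell is
called 1 when the posterior of the higher-mean component exceeds 0.5. This
is a deliberate simplification — no per-gene model selection over component
counts, truncation approximated by censoring — chosen because discretization
is preprocessing here, not the subject of the package; degenerate genes
(constant, < 3 distinct values, one-sided median splits, singular fits)
fall back to the quantile rule and are listed in the provenance record. No
attempt is made to match any external tool's binary matrices bit-for-bit.

## Synthetic benchmarks

The generator module emulates three standard benchmark families and is
first-class, tested code:

* **Density matrices** — i.i.d. Bernoulli(p) cells; the density sweep
  convention is 200×200 at p = 5–50% in 5% steps.
* **Scaling suite** — square matrices 50×50 … 500×500 in steps of 50, each
  size crossed with densities 10–100% in 10% steps (10 groups × 10
  matrices). Test and acceptance runs use the 50–300 slice of this grid,
  a problem size chosen so the full stack re-runs in about a minute; the
  qualitative contract (per-group mean bicluster counts nondecreasing with
  dimension) is scale-free.
* **Implanted matrices** — all-ones ground-truth biclusters with sides
  drawn uniformly from 10–20, chained along the diagonal of a ~100×100
  matrix; consecutive implants share ⌊overlap% × min(side)⌋ rows and
  columns, overlap 0–100% in 10% steps (suite matrix g is
  (100+g)×(100+g)). Diagonal chaining is the conventional geometry and
  makes the attainable-Jaccard bound computable. Background density
  defaults to 0 (pure implants) and is overridable. At 100% overlap
  consecutive implants nest; the ground truth flags this degenerate case.

One RNG stream per matrix, derived from (master seed, matrix index), makes
every suite reproducible element-wise.

What the generators do *not* emulate: correlated row/column structure,
class-imbalanced densities, dropout patterns of real single-cell data, or
the exact matrices of any public benchmark repository. Passing the
synthetic suites therefore certifies algorithmic correctness (equivalence
with brute force, maximality, exact recovery of clean implants), not
biological performance on real data.

## Evaluation metrics

The match score of set A against set B is the mean over A of the best
Jaccard similarity against any member of B; *relevance* = score(found,
truth), *recovery* = score(truth, found). Both directions are always
reported (the score is not symmetric). The Jaccard scope is `rows` by
default (gene-set convention) with `rows_and_cols` (cell-set Jaccard)
available, and every report names the scope it used. Degenerate inputs:
an empty found set scores 0; an empty truth set is a validation error.

## Numerical and design choices

* Seed pairs iterate lexicographically over the input row order; emitted
  order is discovery order — identical inputs give identical outputs.
* Rows with fewer than c_min ones are skipped as *seeds* (their templates
  cannot reach c_min) but still scanned for inclusion; output-equivalence
  of this optimization is unit-tested.
* The fast path tests all rows against a template with vectorized byte
  AND/compare; the instrumented path walks the 16×16 membership grid with
  early exit. Set-equality of the two paths is unit-tested.
* Oracles enforce size caps at their boundary (pairwise-AND reference
  ≤ 64×64, closed-pattern enumeration ≤ 20 columns) and refuse larger
  instances explicitly.
* Serialized outputs identify rows and columns by label, with 0-based
  indices alongside labels in JSON only, avoiding 0/1-based ambiguity.
  MTX entries other than 1 are rejected for binary inputs, not coerced.

## Limitations

* Pairwise-AND search is not complete over all closed 1-patterns (see
  above); the oracle module documents the gap on small instances.
* The mixture binarizer is a two-component approximation; genes with
  genuinely multi-modal expression are reduced to on/off.
* The implant generator's geometry (diagonal chaining) is one convention;
  published relevance values on other repositories' implant matrices
  depend on their specific geometry and are not comparable number-for-number.
* Comparison counts are defined at nibble granularity; wall-clock
  performance claims between implementations on particular hardware are
  out of scope.
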