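# Methods

## Model

The phenotype is modelled as an additive fitness landscape truncated at
third order: for binary genotype/perturbation rows x ∈ {0,1}^p,

    f(x) = Σ_i x_i β_i + Σ_{i<j} x_i x_j β_{i,j} + Σ_{i<j<k} x_i x_j x_k β_{i,j,k}

with no intercept (screen phenotypes are centred scores) and no column
standardization (columns are indicators; rescaling them would distort the
meaning of an effect). β_{i,j} is the standard quantitative-genetics
epistasis coefficient. Coefficients are estimated on the interaction
matrix X* — one column per gene/pair/triple, formed by element-wise
products — with the square-root lasso

    argmin_β ‖y − X*β‖₂ + λ‖β‖₁ .

The square-root form is chosen over the plain lasso because its penalty is
pivotal: the terminal regularization λ_min = 1.1·n^{-1/2}·Φ^{-1}(1 −
0.05/(2 p_int)) (p_int = number of candidate columns at the fitted depth)
is independent of the unknown noise scale, so no cross-validation is run.
The path is geometric from λ_max = max_k |X_k·y|/‖y‖₂ (the smallest λ at
which the all-zero model is optimal; nudged up by a relative 1e-10 so the
statement survives floating-point ties) down to λ_min, 100 points by
default.

## Coordinate descent

Each coordinate update majorizes the norm term at the current residual
(tangent of √u at u₀ = ‖r‖²), which reduces the one-dimensional problem to
a soft threshold:

    z = β_k + (X*_k · r)/‖X*_k‖²,   β_k ← S(z, λ‖r‖₂/‖X*_k‖²)

followed by an in-place residual update. Because this is a
majorize-minimize step, the true objective is non-increasing at every
update (asserted in tests to 1e-10 per sweep), and its fixed points
satisfy the square-root-lasso KKT condition: a zero coefficient is
optimal iff |X*_k·r| ≤ λ‖r‖₂. The residual sum of squares is refreshed
from scratch at each sweep start and maintained incrementally within a
sweep; a sweep converges when the largest coefficient change is ≤ tol ×
max(1, largest |β|), tol = 1% by default (tightened to 1e-10/1e-11 where
tests compare solver outputs numerically). Members are updated in sorted
id order, making the whole procedure deterministic; a hard cap of 1e5
sweeps raises an error carrying the last sweep delta.

## Pruning and active sets

At each λ the candidate universe is screened in two layers:

1. **Branch bound.** For each feature i the cache holds ρ_i (residuals at
   the last full enumeration of i's partners) and π_i (largest |partner
   column · ρ_i| seen then, including i's own column and, at depth 3, its
   realized triples). With α = (ρ_i·r)/‖ρ_i‖² (the projection of the
   current residual on the snapshot; 0 for ρ_i = 0),

       η(i) = |α|·π_i + max( Σ_{supp(i)} (r − αρ_i)^+ , Σ_{supp(i)} (r − αρ_i)^- )

   upper-bounds |X*_{i∘j}·r| for every partner j > i (any partner selects
   a subset of supp(i)). If η(i) ≤ λ‖r‖₂ no interaction led by i can
   violate KKT and the branch is skipped. A missing snapshot means an
   infinite bound, forcing fresh enumeration. Cached η values are keyed by
   a residual-version counter and invalidated whenever the solver updates
   residuals.
2. **Row-major enumeration.** Surviving branches accumulate partner sums
   by walking only the rows in supp(X_i), so cost is proportional to
   actual co-occurrence. At depth 3 the same bound is applied a second
   time to realized pairs (i,j) before descending to triples; realized
   pair supports are cached Simple-8b compressed and re-used.

Candidates with |X*_id·r| > λ‖r‖₂ (strict, absolute value — negative
effects must be admitted) join the active set. Partner enumeration always
scans the full row supports rather than a working-set-reduced row index:
with bounds that only cover supra-indexed partners, dropping a pruned
partner column j from the rows would silently lose pairs (i,j) whose
branch i survives, breaking exactness. Admitted ids are processed in
sorted order against a sticky duplicate registry (128-bit BLAKE2b
fingerprint of the support; first admitted support wins, later ids with
the same support are permanently excluded), so an effect is never spread
over identical columns.

Each λ iterates: identify active set → solve stages (mains to
convergence, then mains+pairs, then mains+pairs+triples, so higher orders
only absorb variance lower orders cannot explain) → re-identify, until a
fresh identification admits nothing new. This fixed-point loop is what
makes the exhaustive KKT audit pass exactly and makes the solution at
each λ independent of the pruning machinery: fits with pruning enabled
and disabled produce identical coefficient paths (property-tested on 100
random instances against a fully materialized dense reference at
tolerance 1e-8, with the comparison run at convergence tol 1e-10 so a
±1-sweep discrepancy sits below the comparison tolerance).

Fitting halts at the end of the first λ iteration whose model holds at
least `max_nonzero` effects, or at λ_min.

### Approximate hierarchy

With `hierarchy=True` the η-based screen is replaced by a membership
screen: interactions are admitted only among features that have at some
point held a nonzero main effect (membership is sticky). η pruning is
deliberately disabled in this mode because π/ρ snapshots taken under a
smaller sticky set would miss partners once the set grows, invalidating
the bound. Within a λ iteration the identify/solve loop lets mains that
turn nonzero at this λ enable their interactions immediately.

### Non-binary designs

Entries may carry real values; interaction values are products of member
values. The branch bound then scales its remainder term by
|V_x^max|·max(|V_all^max|, |V_all^max|^g), where V_x^max is the branch
column's largest |value|, V_all^max the global largest, and g the number
of extra partner factors the bound must cover (2 when a single-feature
branch must also rule out triples). Columns with equal supports but
different values are still treated as duplicates — the support, not the
values, determines identifiability of which rows an effect explains.

## Compression

Realized interaction columns are stored as delta sequences (first row
index absolute, then successive differences) packed by Simple-8b: each
64-bit word spends 4 bits on a mode selector choosing among 16 layouts
(240 and 120 zeros; 60×1-bit through 1×60-bit values), greedy
longest-fitting-run packing. Decoding is exactly lossless
(property-tested with 10⁴ fuzzed round trips) and a column never needs
more than one word per entry. Whether the leading absolute index lives
inside or outside the packed stream is an arbitrary convention; it is
packed inline here.

## Synthetic benchmark generator

`simulate` emulates an siRNA off-target screen: X is i.i.d.
Bernoulli(density), planted effect ids are drawn uniformly per order with
coefficients Normal(0, effect_sd²) resampled while |β| < 0.1·effect_sd
(so "true effect" is unambiguous for ROC labeling), and y adds Gaussian
noise with variance Var(signal)/SNR. Defaults: density 0.05 (a plausible
off-target hit rate; at n=1000 it gives ~50-row main columns and
~2.5-row pair columns), effect_sd 1, SNR 5. Presets: small
(1000×100, 10+50), large (8000×4000, 40+200), wide (1000×10000, 100+500),
threeway (4000×400, 10+100+1000; a threeway-wide variant swaps n and p).
No hierarchy is imposed on planted pairs. The generator reports how many
planted effects are expressed (nonempty realized column) since an
unexpressed interaction is undetectable by any method — at density 0.05 a
triple column has ~n/8000 expected support rows, so most planted triples
in the three-way presets are unexpressed, exactly why overall three-way
recovery is poor while nonzero-only ranking is strong.

What the generator does **not** model: correlated off-target structure
(siRNAs sharing seed sequences hit correlated gene sets), batch/plate
effects, non-Gaussian noise, and real linkage between variants. Passing
benchmarks here therefore demonstrates algorithmic correctness and
ranking behaviour under idealized sparsity, not field performance on a
real screen.

## Evaluation

Recovery is scored on identity, not magnitude: every candidate id up to
the evaluated depth receives strength |β̂| (0 when unselected; sign
ignored) and a truth label; replicates are pooled; AUROC is trapezoidal
with tie-sharing (= Mann–Whitney), so the mass of zero-strength
candidates forms a terminal tied block and unrecovered true effects count
as misses. A nonzero-only filter reproduces the secondary analysis that
ranks only assigned effects. Precision/recall at k break strength ties by
sorted id.

On the 50-replicate small benchmark the pooled AUROC is ≈0.72 without
hierarchy (the acceptance script computes the exact value for its seed).
With hierarchy it drops to ≈0.66: at density 0.05 a true pair's endpoints
acquire (possibly spurious) main effects only about as often as chance,
since the pair leaks ≈2.5·β into a main inner product whose own noise
scale is ≈2.5, so many pairs never become eligible. The final models are
nonetheless exactly optimal for their restricted candidate sets (audited
against the KKT conditions), so the gap is a property of the screen under
these simulation conditions, not of the optimizer.

## Post-selection refit

Selected effects are realized as dense columns Z and refit by OLS with
intercept (statsmodels); collinear columns are detected by pivoted QR on
the intercept-augmented design and dropped (recorded in the returned
metadata), keeping the earlier id on ties. Reported p-values are ordinary
t-tests and do not account for the selection step; adjusted R² and AIC
are computed on the same data used for selection — deliberately so, to
mirror the selection-then-refit protocol rather than add an out-of-sample
layer the protocol does not contain.

## Known limitations

- Sequential implementation; no multi-threaded pruning (results are
  by construction independent of any parallelisation).
- Effects occupying exactly the same rows are indistinguishable; the
  first considered wins and near-duplicates are not merged.
- The additive third-order truncation can misattribute higher-order
  biology to lower-order terms.
- Running all three-way interactions is practical only for moderate p or
  with the hierarchy screen.
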