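# Methods

This note records the model as implemented, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Pipeline

The pipeline composes four stages over one indexing authority (entity
order fixed by the association table, all similarity inputs permuted to
it):

1. **Disease semantic similarity** from the term DAG.  For disease `D`,
   every ancestor `d` in the closure `T(D)` receives a contribution
   `DD(d)`: 1 for `D` itself, otherwise `Δ` times the maximum
   contribution among children of `d` that lie inside `T(D)` — only
   paths leading back to `D` carry contribution.  Children outside the
   closure are excluded; if the closure has several roots each is
   handled independently (no artificial super-root).  Similarity is the
   shared contribution mass normalized by the two semantic values, so
   it lies in [0, 1] with unit diagonal, and diseases with disjoint
   closures get exactly 0.
2. **GIP kernel similarity** for both entity classes, bandwidth
   `ρ = ρ′ / mean squared profile norm` with the squared norm of a
   binary profile computed as an exact integer count.  All-zero
   profiles (possible inside CV folds after masking) are retained:
   the kernel is well defined for them (two empty profiles have
   similarity 1); only an entirely zero profile *matrix* is an error.
3. **SNF cross diffusion** of (semantic, GIP) and (functional, GIP).
   Updates are simultaneous — both diffused kernels are computed from
   the previous pair — which is the standard cross-diffusion reading; a
   `sequential` mode implements the literal one-after-the-other
   variant.  After every step each kernel is symmetrized and
   re-normalized to the half-diagonal row-stochastic form; without this
   the iterates drift from row-stochasticity (the `symmetrize_each_step`
   flag disables it for the bare iteration).  The final average is
   symmetrized once more; its diagonal is left as produced (≈ 1/2 plus
   diffusion mass) rather than forced to 1, because the fused matrices
   enter the completion as feature matrices whose absolute scale the
   factors absorb.  Rows with zero admissible mass in either
   normalization receive a uniform distribution over their support,
   with a warning, keeping the operators total on degenerate inputs.
4. **Nonnegative inductive completion** by alternating multiplicative
   updates (V then U per iteration, the order being immaterial to the
   monotonicity contract).  Every matrix entering the update ratios is
   nonnegative, so the updates keep the factors nonnegative and never
   increase the objective; the per-iteration objective trace is
   retained and checked.  A guard `ε = 1e-12` on the denominators
   prevents 0/0 for zero entries — a true multiplicative zero stays
   zero via the leading factor.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `Δ` (semantic decay) | 0.5 | shallower shared ancestors count less; the conventional value in the semantic-similarity literature |
| `ρ′` (raw GIP bandwidth) | 1.0 | the convention of the GIP-kernel literature; the normalization by mean profile norm does the data adaptation |
| `K` (SNF neighbours) | min(20, n−1) | neighbourhood size of the local kernels |
| `T` (SNF iterations) | 20 | cross-diffusion steps; the fused matrix is stable well before this at the sizes used here |
| `r` (factor rank) | 50 | completion rank; must not exceed min(nd, nm) |
| `λ1, λ2` | 1.0 (`fixed` mode) | ridge weights on the factors; `scaled` mode sets both to `1/‖A‖_F` — the norm-scaled reading of the regularization. Both modes are first-class |
| `tol` | 1e-6 | stop when the relative change of the objective falls below this (interpreted as relative, not absolute; `max_iter` 1000 caps the run) |
| `seed` | 0 | factors initialize uniform-random in (0,1); mandatory part of the config so every fit is bit-reproducible |

## Evaluation protocols

Both protocols rank held-out positives against the candidate pool —
every pair with no verified association in the full matrix — scored by
the fold's own model.  By default the GIP kernels and the fusion are
recomputed from the masked matrix inside every fold, so no held-out
information reaches the similarity features; a `static-similarity` mode
reuses the full-data similarities (cheaper, leaky, for sensitivity
analysis only).  Repeat seeds derive as master seed + repeat index, so
any repeat is reproducible in isolation.  The 5-fold AUC is computed
per repeat over the union of the five folds' comparisons, then averaged
across repeats.

Because each positive is compared against candidate scores from its own
fold's model, no single pooled score vector exists; the ROC curve is
built from the per-positive candidate-percentiles (tie-aware rank of
the positive within its fold's candidate pool), swept as a staircase
against the empirical candidate distribution.  The trapezoidal area of
that staircase equals the mean percentile, which is exactly the
tie-aware pairwise AUC — the identity the result container asserts.
The generic `roc_auc` for flat score/label vectors uses the full
(no-points-dropped) ROC sweep, whose trapezoid is the same tie-aware
quantity.

## Synthetic generator

`generate_dataset` plants nonnegative factors `U*, V*` with
Gamma(shape 2, scale 1) entries, forms latent scores `L = U*V*ᵀ` scaled
to [0, 1], and samples each association independently as
Bernoulli(c·L(i,j)) with `c` calibrated so the expected density matches
the request.  The miRNA functional similarity is the cosine similarity
of the `V*` rows under a symmetric clipped perturbation of the given
magnitude; the disease DAG hangs each disease under a layered random
scaffold, grouped by k-means on the `U*` rows (a minority of diseases
get a second parent), so semantic similarity echoes the planted disease
geometry.  A sparse draw routinely leaves a few entities with no
associations; those profiles are redrawn in place (conditioning each on
being nonempty) rather than rejecting the whole matrix — whole-matrix
rejection at realistic densities almost never yields a clean draw, and
in-place redraws keep the realized density on target.  Degree counts,
not the independence structure, are what the rewire null preserves:
`degree_preserving_rewire` applies seeded checkerboard swaps until the
planted structure is destroyed while every row and column sum survives.

**What the generator does not emulate:** real association data are not
independent Bernoulli draws from a low-rank propensity — curation is
bursty, degree distributions are heavy-tailed, and similarity inputs
carry shared annotation biases.  Passing tests therefore demonstrate
correctness of the machinery and recovery of *this* planted structure,
not performance on curated databases.

**The ranking ceiling.**  Under Bernoulli-per-cell sampling, an oracle
knowing the planted factors exactly can do no better than ranking pairs
by the latent score itself, so the AUC of `L` against the realized draw
(`latent_oracle_auc`) is the information-theoretic ceiling for any
held-out ranking on the dataset.  At the default study conditions
(Gamma(2,1) factors, rank 3, density 0.06) this ceiling is ≈ 0.64–0.66:
the latent propensities are too concentrated for the draw to separate
sharply.  The pipeline's cross-validated AUC (~0.55 at defaults)
should be judged against that ceiling and the degree-preserving null
(~0.55), not against 1.0; on instances with dispersed factors the same
pipeline reaches ~90% of a much higher ceiling.  The acceptance script
reports the ceiling alongside the CV AUCs so the comparison is always
computed, never assumed.

## Numerical choices

- KNN neighbour selection breaks ties by column index (stable), self
  always excluded.
- The association matrix is validated strictly binary; masked copies
  are fresh objects — evaluation never mutates its inputs, and the
  LOOCV restoration test asserts bit-identity afterwards.
- Similarity containers enforce symmetry to 1e-10 and nonnegativity at
  construction; file readers symmetrize `(M + Mᵀ)/2` and warn above
  1e-8 asymmetry.
- Edge-list round trips preserve the disease ordering exactly
  (row-major write) but can only preserve the miRNA ordering up to
  first occurrence; readers accept expected id lists to re-anchor the
  ordering, and similarity/score tables round-trip bit-identically.
- Convergence is declared on relative objective change; the trace keeps
  the initial objective so monotonicity is checkable from the first
  step.  A non-finite objective aborts with the iteration index.
- Problem sizes in the tests and the acceptance script (60×80 study,
  30×40 solver instances, 5 CV repeats, full LOOCV over ~300 positives)
  were chosen as the smallest instances at which every property under
  test is comfortably resolved.

## Known limitations

- Exactly two views per entity class are fused (the model's setting);
  the general multi-view SNF is out of scope.
- The multiplicative solver is the only optimizer; no projected
  gradient or ADMM alternatives.
- The semantic model is the single decayed-contribution formulation;
  literature variants that average multiple DAG weightings are not
  provided.
- Whether the fused similarities should be rescaled to unit diagonal
  before completion is genuinely open; they are used as produced, and
  the factors absorb the scale.
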