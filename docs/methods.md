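# Methods

This note documents the statistical procedures implemented in
`pcscreen`, the conventions and numerical choices behind them, and what
the simulation-based tests do and do not establish.

## Model

Data are n i.i.d. draws of a mean-zero p-variate Gaussian vector with
covariance Σ and precision Ω = Σ⁻¹.  The object of inference is the
partial correlation matrix Γ with entries
ρ_ij = −ω_ij/√(ω_ii ω_jj) and the network E = {(i,j) : ρ_ij ≠ 0}.
Columns are mean-centered at ingestion (the objectives carry no
intercepts); variance standardization is optional and off by default,
since none of the procedures requires it and the simulation models are
specified on the covariance scale.

Three equivalent parameterizations are used and converted between:
precision (glasso), nodewise regression weights β_ij = −ω_ij/ω_ii
(nodewise lasso/ridge), and the shared partial correlations themselves
(SPACE).  For estimated regression weights, the pairwise conversion is
ρ̂_ij = sign(β̂_ij)√(β̂_ij β̂_ji) when the two weights agree in sign; a
discordant pair (possible only in finite samples) is set to 0,
consistent with the sparsity goal.  Ridge is the exception: because an
ℓ2 penalty produces no exact zeros, the ridge conversion instead
averages the two one-sided estimates δ̂_ij√(v̂_j/v̂_i) (v̂ the residual
variances), which keeps the ridge network complete with probability one
instead of inheriting sign-flip zeros from noise.

## Estimators and solvers

**Graphical lasso.** min_Ω≻0 tr(SΩ) − log det Ω + λ₁Σ_{i≠j}|ω_ij|, with
S the biased (1/n) sample covariance and only off-diagonal entries
penalized, so full shrinkage yields a diagonal precision.  The solver is
scikit-learn's coordinate-descent graphical lasso.  Single fits use
tol 1e-4 (max 200 sweeps); path fits inside cross-validation and
information criteria use tol 1e-3 (max 100 sweeps) — at the dense end of
the penalty grid tighter tolerances cost an order of magnitude more time
without changing any selected support in the regimes we test.  The test
suite cross-checks solutions against an independently written
proximal-gradient solver and the p=2 closed form (the solution
covariance is S with its off-diagonal soft-thresholded).

**Nodewise lasso.** p separate lasso regressions of each node on the
rest.  Losses are per observation (1/(2n)‖·‖², the glmnet/scikit-learn
convention); penalties, grids and the finite-sample closed form all live
on this scale.  Per-observation and unscaled objectives differ only by
the relabeling λ → λ/n, so cross-validated and BIC selections are
unaffected by the convention; the finite-sample formula pins the
absolute scale, and only on the per-observation scale does it produce
the near-empty high-confidence networks it is designed for.

**SPACE.** The joint objective ½Σ_i‖X_i − Σ_j ρ_ij√(ω_jj/ω_ii)X_j‖² +
λ₃Σ_{i<j}|ρ_ij| is kept on the unscaled (sum over observations) form;
its √n-scaled penalty grid is defined against that scale.  The solver
alternates (a) active-set coordinate descent on the shared ρ_ij — each
update a soft threshold of residual inner products aggregated over the
two regressions that contain the parameter — with (b) closed-form
updates ω_ii = n/RSS_i.  All inner products are carried on the Gram
matrix X'X, so a sweep is O(p³) regardless of n, and grid fits are
warm-started from the sparse end.  Initialization: ρ = 0,
ω_ii = 1/var(X_i); convergence when the relative objective change falls
below 1e-6 (default cap: 50 outer iterations, with a warning if hit).
The λ=0 fit is verified against a generic quasi-Newton minimizer of the
same objective.

**Nodewise ridge.** Closed form δ̂_i = (X'X + 2λ₄I)⁻¹X'X_i per node; the
cross-validation path is computed from one eigendecomposition of each
node's Gram matrix.

## Penalty selection

- Grids: glasso uses 100 equidistant values from 0.001 (0.05 when
  p ≥ 100) to max|S| — the maximum absolute entry, which is at least the
  off-diagonal maximum, so the path always contains the empty model.
  SPACE uses 100 equidistant values from √n Φ⁻¹(1−0.9/2p²) to
  √n Φ⁻¹(1−10⁻⁴/2p²).  The regression methods use a glmnet-style
  per-node grid: 100 log-spaced values down from the smallest penalty
  that zeroes the node's lasso problem, with ratio 1e-4 (1e-2 when
  n ≤ p).
- Cross-validation: K = 10 folds by default, assigned by a seeded
  permutation that is reused between penalty selection and threshold
  selection so the two loops see the same splits.  The reported loss is
  the sum over folds; the one-standard-error rule takes sd of the
  per-fold losses at the minimizer, divides by √K, and picks the most
  regularized value inside the band.  All argmin ties break toward the
  larger penalty (sparser model).
- Glasso losses: the likelihood loss tr(SᵏΩ̂) − log det Ω̂ with Sᵏ the
  held-out fold's own centered covariance (1/n_k), and the prediction
  loss Σ_i‖X_iᵏ − Σ_j(−ω̂_ij/ω̂_ii)X_jᵏ‖².  Ω̂ is refit per training
  fold at every grid value.
- Information criteria: per-regression BIC is the unit-variance Gaussian
  form ‖residual‖² + κ_i log n (κ_i the neighborhood size), summed over
  nodes for SPACE.  For glasso, EBIC = −2ℒ(Ω̂) + κ log n + 4κγ log p
  with ℒ the full Gaussian log-likelihood at the penalized estimate,
  γ = 0.5 by default (γ = 0 is BIC), and κ the number of non-zero
  off-diagonal precision entries — both symmetric entries of each edge.
  This doubled count is deliberate: with κ equal to the edge count the
  criterion retains moderately dense chain networks even at p = 60,
  n = 100, whereas the doubled count reproduces the sharply conservative
  behavior this selector is used for (near-empty networks when p > n/2,
  full recovery at n = 500).
- Finite-sample penalties: λ₂(α) = (2/√n)Φ⁻¹(1−α/2p²) for nodewise
  lasso and λ₃(α) = √n Φ⁻¹(1−α/2p²) for SPACE, default α = 0.05.

## Screening (PCS)

Given a first-stage Γ̂, the screened network at threshold τ ∈ (0,1) is
Ê_τ = {(i,j) : |ρ̂_ij| > τ} (strict inequality; Ê_τ is monotone
decreasing in τ and always a subset of the first-stage support — the
procedure never adds edges).  τ is selected by a double loop: the
first-stage penalty is chosen once on the full sample; then, per fold,
the first stage is re-estimated at that penalty on the training rows,
and for each of 100 equidistant τ in [0.0001, 1] the screened
neighborhoods are refit by per-node OLS on the training rows and scored
by squared prediction error on the held-out fold.  The refit is done on
training folds only (standard CV hygiene; the alternative of refitting
on the full sample is not implemented).  Ties in the argmin take the
largest τ.  The CV loss is piecewise constant in τ with breakpoints at
the sorted |ρ̂| values, so the implementation caches one OLS per
distinct neighborhood; the cached evaluation is verified against the
naive per-τ refit in the tests.  If a node's screened neighborhood ever
reaches the training row count (possible only for a dense ridge first
stage at tiny τ), minimum-norm least squares is used and flagged.  If
every per-fold first stage is empty the scan is degenerate; the smallest
τ is returned with a flag.  The final report keeps the first-stage ρ̂
values on the surviving edges (they are not re-estimated after the
refit).

## Simulation models

- Models 1–2 (chain graphs): Γ has −0.4 at lag 1 (and −0.2 at lag 2 for
  Model 2).  The precision is taken with unit diagonal (ω_ij = −ρ_ij);
  partial correlations are invariant to the precision's diagonal scale,
  so this canonical representative reproduces Γ exactly, and it is
  positive definite for these band values.  Edge counts: p−1 and
  (p−1)+(p−2).
- Model 3 (nearest-neighbor graph): p points uniform in the unit
  square; each node's candidates are its two nearest neighbors
  (Euclidean; ties — a measure-zero event — broken by lower index).  By
  default an edge requires the choice to be mutual, which realizes ≈14
  edges at p = 20 and ≈42 at p = 60; the union rule (`mutual=False`)
  gives ≈26/78.  The mutual default is the construction consistent with
  reference network sizes of 16 and 48 for these dimensions — a
  union-rule k-NN graph cannot have fewer than p edges.  Off-diagonal
  precision entries on the edges are drawn from [−1,−0.5] ∪ [0.5,1]
  around a unit diagonal.
- Model 4 (random graph): each upper-triangular precision entry is 0.3
  with probability ρ ∈ {0.1, 0.01, 0.001} for p ∈ {20, 60, 200}.
- Models 3–4 are made positive definite by the ridge repair
  Ω ← Ω + (|λ_min(Ω)| + 0.1)I (minimum eigenvalue ≥ 0.1 afterwards) and
  normalized to Γ by the precision-to-partial map.  The structure is
  fixed per model seed and reused across replicates, matching the
  single-realization design of the reference experiments;
  per-replicate structures are available by varying the model seed.
- The toy model is a fixed 6×6 covariance whose implied network has 5
  edges, all with ρ = −0.45, and one marginally correlated but
  conditionally independent pair.  Inverting a covariance printed at 2
  decimals leaves residues of ~2·10⁻³ in the zero cells; the toy edge
  set is therefore defined with a 0.05 tolerance.

Sampling is by Cholesky transform of seeded standard normals;
experiment replicates derive their seeds deterministically from the
top-level seed via `numpy` seed sequences.

The generator emulates exactly the Gaussian, fixed-structure,
independent-observation setting.  It does not emulate non-Gaussian
marginals (addressed separately by the nonparanormal transform),
temporal or sample dependence, measurement error, or heterogeneous
populations — recovery rates observed in the tests certify the
procedures under the stated models only.

## Test problem sizes

The replicated experiment cells in the test suite run at 20 replicates
(versus 100 in a full study) on p = 20 and p = 60 chain graphs, and the
toy end-to-end check uses 11 seeds; these sizes keep the full suite
under ten minutes while leaving Monte-Carlo standard errors (~0.002 on
an FPR of 0.01 at 20 replicates) well inside the asserted tolerances.

## Known limitations

- The glasso backend enforces its own duality-gap tolerance; extremely
  small penalties on near-singular covariances can exhaust the sweep cap
  (such fits are excluded from selection curves and counted).
- SPACE's alternating minimization is guaranteed non-increasing but not
  globally convergent in theory; in practice warm starts along the grid
  converge in a handful of outer iterations.
- The threshold grid's lower endpoint (10⁻⁴) is below any realistic
  noise floor, but a first stage whose smallest true |ρ̂| falls under
  the selected τ is irrecoverable — screening cannot fix false
  negatives.
- BIC tuning is not defined for ridge (no sparsity to count), and the
  finite-sample closed forms apply only to the two ℓ1 methods.
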