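# Methods

## Model

Given a non-negative expression matrix X ∈ ℝ^{D×N} (D genes, N samples),
the package factorizes X ≈ HW with H ∈ ℝ^{D×K} (meta-samples: basis
expression profiles over genes) and W ∈ ℝ^{K×N} (codings: each sample's
coefficients over the meta-samples), H, W ≥ 0 elementwise.  Instead of
minimizing the Frobenius or Kullback–Leibler divergence, the primary solver
maximizes the Gaussian-kernel correntropy between X and HW:

    F(H, W) = Σ_d exp( −e_d² / (2σ²) ),     e_d² = Σ_n (x_dn − (HW)_dn)²

Each gene contributes through a kernel of its own squared residual, so the
criterion behaves like a Welsch M-estimator applied per gene: a gene whose
residual is large relative to the bandwidth contributes almost nothing to
the objective, and therefore almost nothing to the fit.  This is what makes
the method robust to corrupted genes, and what gives it an implicit
feature-selection behavior — two properties ordinary l2/KL NMF lacks.

## Optimization: expectation conditional maximization

F is not jointly concave, but a half-quadratic (convex-conjugate) bound
turns it into alternating weighted least squares.  Each outer iteration:

1. **E-step.** Compute per-gene squared residuals e_d²; the adaptive
   bandwidth σ² = (θ / 2D) Σ_d e_d²; and auxiliary weights
   ρ_d = −exp(−e_d² / (2σ²)) ∈ [−1, 0).  The weight −ρ_d ∈ (0, 1] is the
   gene's effective weight in the next step.
2. **CM-steps.** With ρ fixed, minimize the surrogate
   O(H, W) = Tr[(X − HW)ᵀ diag(−ρ)(X − HW)] by one multiplicative update
   of H, then one of W conditioned on the fresh H:

       H ← H ∘ (diag(−ρ) X Wᵀ) / (diag(−ρ) H W Wᵀ + ε)
       W ← W ∘ (Hᵀ diag(−ρ) X) / (Hᵀ diag(−ρ) H W + ε)

With ρ fixed, O is nonincreasing under each update — the standard
auxiliary-function argument for multiplicative rules applies with the
weighted Gram matrix, and the denominator guard ε only shortens the step,
which cannot break monotonicity (the surrogate is quadratic per coordinate
and the guarded update stays between the current point and the exact
minimizer).  No such guarantee holds for F across outer iterations, because
σ² changes between them; the trace records both O and F so the user can
inspect F, but the tests assert monotonicity only of O within a CM pair.

With ρ pinned at −1 the updates reduce exactly to the classical Lee–Seung
l2 multiplicative rules; the l2 baseline is implemented that way, and one
test cross-checks its trajectory update-for-update against
scikit-learn's multiplicative-update NMF from an identical initialization.
The KL baseline uses the standard divergence update rules.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | — | number of meta-samples; normally the expected number of classes |
| `theta` | 1.0 | bandwidth scale in σ² = (θ/2D) Σ e_d²; controls how aggressively high-residual genes are downweighted (smaller θ → sparser −ρ) |
| `max_iter` | 500 | outer-iteration budget |
| `tol` | 1e−6 | stop when the relative change of O falls below this |
| `denom_guard` | 1e−10 | added to update denominators; 0 recovers exact fixed points |
| `seed` | 0 | fully determines the run (uniform (0,1] init, rescaled so mean(HW) = mean(X)) |

All quantities are unitless (expression levels on whatever scale the input
uses).  Rescaling X by c > 0 rescales σ² by c² and leaves ρ — and hence the
clustering trajectory — unchanged, so θ needs no re-tuning across
differently scaled inputs.

Numerical choices: σ² is floored at 1e−12·(1 + mean(X²)) so an exact fit
cannot produce a zero bandwidth (the flooring emits a warning); a zero
entry in H or W is absorbing under multiplicative updates, which is
accepted and tested rather than worked around; an all-zero gene row is
legal and simply receives weight 1.

## Clustering evaluation

Samples are clustered by k-means on the columns of W (K seeded k-means++
restarts).  Because cluster indices are arbitrary, accuracy is computed
after the optimal one-to-one assignment of predicted clusters to true
classes — the Hungarian algorithm on the contingency table — which is the
standard convention for clustering accuracy; unmatched clusters (when the
cluster and class counts differ) count as errors.  The repeated-trial
protocol refits from scratch with seeds base_seed+1 … base_seed+n and
reports per-trial accuracies, their mean and their n−1 standard deviation.

## Synthetic data

The generator emulates the structure of multi-class tumor expression data
as it matters to a robust factorization: K near-equal sample classes; a
small informative fraction of genes (default 10%) shifted upward by
`signal` (default 3) in exactly one class over a uniform(1, 2) baseline;
truncated Gaussian noise everywhere (sd 0.5); and a fraction of genes
(default 10%) replaced wholesale by heavy-tailed noise,
`outlier_scale·|t₃|` — whole corrupted rows, matching the per-gene
granularity of ρ.  Defaults (D=500, N=80, K=4) keep the informative genes a
small minority amid a dominant uninformative background, the regime in
which correntropy's gene weighting should matter.  The generator does not
attempt platform-specific artifacts (probe effects, batch effects,
missingness), so passing tests demonstrate robustness to heavy-tailed
row corruption, not to every failure mode of real microarray data.

## Behavior on clean data: θ matters

An empirical property worth knowing: with θ = 1 and *no* corrupted genes,
the method can fail outright on planted-class data (accuracy near chance)
while plain l2 NMF scores 1.0.  The mechanism is visible in the E-step:
early in the fit the informative minority carries the largest residuals
(their class structure is not yet captured), the adaptive bandwidth
collapses onto the homogeneous background residuals, and the informative
genes are suppressed as if they were outliers — a self-reinforcing loop.
Widening the bandwidth (θ ≈ 5) restores perfect accuracy on clean data.
In the presence of genuinely corrupted genes the corrupted rows absorb the
suppression and θ = 1 works well — the regime the method is for.  The
clean-data sanity tests therefore pass θ = 5 explicitly, and users applying
the solver to data they believe clean should do the same.

## Problem sizes in the test suite

The invariant and oracle tests run on instances from 2×2 up to 50×30; the
end-to-end robustness protocol uses the generator defaults (500×80, K=4)
with 20 trials per method plus twenty 5-trial batches for the stability
comparison, completing in about a minute.  `scripts/acceptance.py` re-runs
the same protocol from scratch for any seed.

## Known limitations

- K must be supplied; there is no model-order selection.
- Multiplicative updates stall near zero entries and converge sublinearly;
  a random-init fit on an exactly rank-K matrix decreases O by orders of
  magnitude but need not reach machine zero.
- Accuracy is the only clustering metric (no ARI/NMI).
- No preprocessing (log-transform, normalization) is applied by default.
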