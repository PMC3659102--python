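# nmfmcc — robust NMF by maximum correntropy for expression clustering

Unsupervised clustering of tumor samples from gene-expression matrices is
commonly done by non-negative matrix factorization: X ≈ HW, where the
columns of H are meta-samples (basis expression profiles) and the columns
of W are each sample's coordinates over them, which are then k-means
clustered.  Standard NMF minimizes the Frobenius or Kullback–Leibler
divergence, which weights every gene equally — so a handful of corrupted or
wildly noisy genes can dominate the fit.

`nmfmcc` instead **maximizes the Gaussian-kernel correntropy** between X
and HW:

    max_{H,W ≥ 0}  Σ_d exp( −e_d² / 2σ² ),    e_d² = Σ_n (x_dn − (HW)_dn)²

solved by expectation conditional maximization: an E-step computes per-gene
auxiliary weights −ρ_d = exp(−e_d²/2σ²) ∈ (0, 1] with an adaptive bandwidth
σ² = (θ/2D) Σ_d e_d², and CM-steps run multiplicative updates of H then W
on the weighted least-squares surrogate.  Genes with outlying residuals get
weights near 0 — the solver is simultaneously robust to corrupted genes and
an implicit gene selector (−ρ is the learned gene-relevance vector).
Classical l2 and KL NMF are included as baselines, together with
matched-accuracy clustering evaluation (Hungarian assignment of clusters to
classes) and a planted-class synthetic expression generator.

Intended users: anyone clustering non-negative feature-by-sample matrices
with suspected row-level contamination — bulk/single-cell transcriptomics
being the motivating case.

## Worked example

Generate a 500-gene × 80-sample dataset with 4 planted classes, 10%
informative genes and 10% genes replaced by heavy-tailed noise, then
compare the correntropy solver with plain l2 NMF over 5 repeated trials:

```sh
nmfmcc simulate --genes 500 --samples 80 --classes 4 --seed 7 --out demo
nmfmcc cluster --input demo/X.tsv --labels demo/labels.tsv --k 4 \
       --trials 5 --seed 100 --out demo/mcc
nmfmcc cluster --input demo/X.tsv --labels demo/labels.tsv --k 4 \
       --loss l2 --trials 5 --seed 100 --out demo/l2
```

which prints

```
mcc: mean accuracy 1.0000 (std 0.0000) over 5 trial(s)
l2: mean accuracy 0.3825 (std 0.0209) over 5 trial(s)
```

— with a tenth of the genes corrupted, the correntropy loss recovers the
planted classes perfectly in every trial while the l2 loss collapses.  The
learned gene weights make the mechanism visible:

```sh
nmfmcc fit --input demo/X.tsv --k 4 --seed 101 --out demo/fit
head -3 demo/fit/gene_weights.tsv
```

```
gene_id	rho	minus_rho
gene_0001	-0.94169596485583562	0.94169596485583562
gene_0002	-0.949016235352521	0.949016235352521
```

Informative and background genes end near weight 1; the corrupted rows end
near 0 (compare against `demo/gene_masks.tsv`).  The same functionality is
available as a library:

```python
from nmfmcc import generate, SolverConfig, run_trials

ds = generate(seed=7)
report = run_trials(ds.X, ds.truth, SolverConfig(k=4),
                    n_trials=5, base_seed=100, method="mcc")
print(report.mean_accuracy)       # 1.0
```

One practical note: the adaptive bandwidth with the default θ=1 is tuned
for contaminated data.  On clean, outlier-free matrices it can suppress the
informative gene minority itself; pass a wider bandwidth (`--theta 5`)
there.  See `docs/methods.md`.

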