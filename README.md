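# hemograph

Automated classification of acute leukemia blood-smear images into the two
acute classes — **ALL** (acute lymphocytic) and **AML** (acute myeloid) —
by a fusion of superpixel graph construction and spectral graph
convolution, with GAN-based class balancing and a noise-robustness
evaluation protocol. It is aimed at researchers in computational
hematology and biomedical image analysis who want a fully seeded,
CPU-only, inspectable reimplementation of this pipeline, plus a synthetic
smear generator that makes every stage testable without clinical data.

## Method

Each smear image is converted to grayscale, resized to 226 x 226 and
min-max normalized, then partitioned into ~100 SLIC superpixels. Regions
become graph nodes carrying their mean intensity; regions that touch are
connected, giving an adjacency W, degree matrix D_ii = sum_j W_ij and
combinatorial Laplacian L = D - W. With the eigendecomposition
L = U diag(lambda) U^T, a node signal q has graph Fourier transform
q_hat = U^T q, and spectral filtering is y = U g(Lambda) U^T x. The
classifier approximates such filters with Chebyshev polynomials in the
rescaled Laplacian L~ = 2L/lambda_max - I:

    Y = sum_{k<P} T_k(L~) X Theta_k + b,      T_k = 2 L~ T_{k-1} - T_{k-2}

stacked six layers deep (ReLU, batch norm, dropout 0.2), followed by a
dense softmax over the two classes. Training uses cross-entropy with SGD
(lr 1e-4, weight decay 4e-4, batch 32, 150 epochs). Class imbalance is
addressed before graph construction by per-class fully connected GANs
(noise dim 100; generator widths 512...51076 = 226^2; Adamax, lr 0.001,
batch 12) trained on the minimax value
V(G,D) = E_x[log D(x)] + E_z[log(1 - D(G(z)))]. Evaluation reports the
confusion matrix, accuracy, sensitivity, specificity, precision, Cohen's
kappa, ROC/AUC, stratified 5-fold cross-validation, and accuracy under
additive white Gaussian noise at chosen SNRs.

The clinical dataset behind the original study is private, so the package
ships a synthetic smear simulator (`hemograph.simulate`): pale-background
images with Poisson-many dark nuclei whose count, size, boundary
irregularity and intensity differ between classes, with a `separation`
knob from 0 (identical classes) to 1 (full gap). See `docs/methods.md`
for the model details and the simulator's design rationale.

## Worked example

Simulate a dataset, run the full pipeline, and sweep noise levels:

```bash
hemograph simulate --n-per-class 20 --side 64 --seed 1 --out smears/
hemograph run-all --seed 1 --out run1/
```

or from Python:

```python
from hemograph import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, out_dir="run1")
cfg.data.n_per_class = 100          # 200 images total
cfg.model.cheb_terms = [2] * 6      # order-1 Chebyshev filters
cfg.eval.snr_list = [20.0, 0.0]
results = run_pipeline(cfg)
print(results["test_metrics"])
print(results["noise_sweep"])
```

Output from this exact configuration:

```
{'confusion': [[10, 0], [0, 10]], 'accuracy': 1.0, 'sensitivity': 1.0,
 'specificity': 1.0, 'precision': 1.0, 'kappa': 1.0, 'auc': 1.0, 'n': 20}
{'20.0': 0.9, '0.0': 0.5}
```

Reading: on the held-out 10% test split (20 images) every sample is
classified correctly — the synthetic classes at full separation are
designed to be cleanly separable — so all confusion-derived metrics are
1.0. Under added noise the accuracy falls from 0.90 at 20 dB to chance
(0.5) at 0 dB, because the model was trained on clean images only. The
run directory also contains the model checkpoint, per-epoch training
history, a provenance record (config hash and per-stage seeds), and logs;
rerunning with the same seed reproduces the metrics bit-for-bit.

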