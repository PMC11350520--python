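# nucleoscatter

Simulation and inverse-regression toolkit for subnuclear refractive-index
fluctuations:

1. **Phantoms** — voxelated cell-nucleus models (spheres / ellipsoids) with
   Gaussian-correlated refractive-index fluctuations controlled by a spatial
   correlation length `lc` (um) and a fluctuation extent `dn` (standard
   deviation of the index inside the nucleus).
2. **Forward model** — first-order Born far-field computation of 181x361
   angle-resolved intensity maps `I(theta, phi)` at 800 nm (FFT + Ewald-sphere
   interpolation, dipole polarization factor). Externally computed signals
   (e.g. FDTD output) can be imported from HDF5 or CSV.
3. **Conditioning** — `log10` + full-scale contrast stretch to [0, 255],
   SNR-defined white-Gaussian-noise injection, polar-angle cropping.
4. **Regression** — a single-output convolutional network per parameter
   (five 3x3 conv/2x2 pool blocks with 8/16/32/64/128 filters, batch norm,
   dense 512 + dropout 0.5, linear output), trained with Adam
   (lr 5e-4, beta1 0.9, beta2 0.999, eps 1e-7) on MSE with a
   best-validation-loss checkpoint. Implemented in pure NumPy (float32,
   im2col + BLAS) with optional numba-accelerated kernels — no deep-learning
   framework required.
5. **Evaluation** — 60/20/20 splits under 5-fold cross-validation, pooled
   mean absolute percent error (MAPE), per-true-value box statistics with
   t-based 95% CIs, and a noise stress test that applies clean-trained models
   to noise-degraded test signals.

## CLI

```bash
nucleoscatter run-all  --config config.yaml --output results/   # end-to-end
nucleoscatter simulate --config config.yaml --output results/   # phantoms+signals
nucleoscatter preprocess --config config.yaml --output results/
nucleoscatter train    --config config.yaml --output results/ --target both
nucleoscatter evaluate --config config.yaml --output results/
nucleoscatter make-fixtures --output fixtures/ --seed 0         # tiny test set
```

`--seed INT` overrides the dataset and CV seeds; with no `--config` the
defaults reproduce the full protocol (7x7 parameter grid, 3 replicates,
both shapes, 800 nm, 5-fold CV) — note that is hours of CPU time.

Example configuration (strictly validated; unknown keys are rejected):

```yaml
dataset:
  shapes: [sphere, ellipsoid]
  corr_lengths_um: [0.4, 0.7, 1.0]
  fluct_stds: [0.005, 0.02, 0.035]
  replicates: 3
  voxel_um: 0.14
  base_seed: 11
forward: {wavelength_nm: 800.0, pad_factor: 2}
preprocess: {crop_theta: [10, 90], noise_snr_db: [25.0]}
regressor: {epochs: 120, batch_size: 8}
cv: {n_folds: 5, seed: 11}
```

`crop_theta` and `epochs` also accept per-target maps, e.g.
`crop_theta: {corr_length: [10, 90], fluct_std: [60, 120]}`.

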