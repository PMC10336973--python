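# eqcharge

Neural-network prediction of real-space (QTAIM-style) partial atomic
charges, with charge-equilibration schemes that make the corrected
charges reconstruct the molecular charge exactly.

## The problem

Partitioning a molecule's electron density into atomic basins gives each
atom a partial charge `q_A = Z_A − N_A` (atomic number minus basin
electron population). Machine-learned estimates of these charges are fast
but carry small independent per-atom errors, so their sum misses the true
molecular charge `Q` by a residual

```
ΔQ = Σ_A q_A^pred − Q
```

which breaks any downstream use that needs an exactly neutral (or integer
charged) molecule. **Charge equilibration** here is the post-hoc fix: each
atom receives a correction proportional to a weight `w_A` (Σ w_A = 1),

```
η_A = w_A · ΔQ        q_A^corr = q_A^pred − η_A
```

so that `Σ q_corr = Q` holds to machine precision. This is a rescaling of
model output, distinct from electronegativity-equalization methods that
*compute* charges.

The package provides, per module:

- **`eqcharge.elements`** — per-element constants (Z, Sanderson/Pauling
  electronegativities, covalent radii) and per-element Gaussian error
  statistics (μ, σ) of a charge model, with shipped CHON defaults.
- **`eqcharge.geometry`** — XYZ / extended-XYZ readers, `.nnaim` results
  writer.
- **`eqcharge.acsf`** — atom-centered symmetry functions (cosine cutoff,
  G2 radial, G4/G5 angular) assembling per-atom environment vectors
  (AEVs), configured by plain-text `input.type` / `input.rad` /
  `input.ang` files.
- **`eqcharge.model`** — one feed-forward network per element on
  standardized AEVs: dataset building, training, prediction, and a
  self-describing on-disk model folder.
- **`eqcharge.equilibrate`** — ΔQ, eleven deterministic weight kernels
  (uniform, |q|, electron count Z−q, χ^S, χ^P, and error-statistics
  combinations of |μ|, σ, Z−q, 1/r), two stochastic iterative variants,
  and user plug-in kernels.
- **`eqcharge.metrics`** — MAE / RMSE / Pearson r and normal fits of
  error distributions.
- **`eqcharge.synth`** — synthetic CHON clusters with analytic,
  exactly charge-conserving reference charges, so the whole pipeline is
  testable without quantum-chemical data.

## Worked example

Water with imperfect predicted charges `[-0.60, +0.38, +0.32]` e carries
a residual ΔQ = +0.10 e. `examples/01_equilibration_schemes.py` prints
the weights each kernel assigns and the corrected-charge sums:

```
predicted charges: [-0.6   0.38  0.32], delta_Q = +0.100 e

scheme       w_O     w_H1     w_H2     sum q_corr
     1   0.33333  0.33333  0.33333      5.551e-17
     2   0.46154  0.29231  0.24615     -5.551e-17
     3   0.86869  0.06263  0.06869      5.551e-17
     4   0.41336  0.29332  0.29332      0.000e+00
     5   0.43878  0.28061  0.28061      5.551e-17
     6   0.38197  0.30902  0.30902     -5.551e-17
     7   0.24842  0.37579  0.37579      5.551e-17
```

Scheme 1 splits the residual evenly; scheme 6 weights by each element's
error spread σ, so oxygen (σ = 0.0111 e) takes w_O = 0.0111/(0.0111 +
2·0.00898) ≈ 0.382 of the correction; in every scheme the corrected
charges sum to zero at machine precision.

`examples/03_train_and_predict.py` runs the full pipeline — synthetic
clusters → per-element training → prediction on an unseen cluster →
equilibration — and ends with

```
raw prediction residual delta_Q = +0.00666 e
corrected residual              = +4.2e-17 e
corrected vs true: MAE = 3.122361e-03 e, RMSE = 4.229032e-03 e, r = 0.999549 (n = 8)
```

i.e. per-atom errors of a few thousandths of an electron and an exactly
neutral molecule.

The same workflows are available from the shell:

```
eqcharge fixtures --composition C2H4ON --n 200 --output train.xyz --acsf-out acsf/
eqcharge train   --data train.xyz --acsf acsf/ --output model/
eqcharge predict --geometry probe.xyz --model model/ --ceq 6
```

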