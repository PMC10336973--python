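# Methods

## Model and pipeline

The package estimates per-atom, real-space (QTAIM-style) partial charges
and then enforces exact reconstruction of the molecular charge. The
pipeline is

1. **Featurization.** Each atom i is described by a fixed-length atomic
   environment vector (AEV) of atom-centered symmetry functions: sums of
   damped radial Gaussians over neighbours of one element, and damped
   angular terms over unordered neighbour-element pairs. The damping is
   the cosine cutoff `fc(r) = ½[cos(πr/R_c) + 1]` for `r ≤ R_c` and
   exactly 0 beyond, which makes every descriptor strictly local,
   continuous, and invariant under rigid motions and reflections. The
   radial form is `Σ_j exp(−η(R_ij − R_s)²)·fc(R_ij)`; the angular
   "narrow" form is
   `2^(1−ζ) Σ_{j<k} (1 + λcosθ_jik)^ζ exp(−η(R_ij² + R_ik² + R_jk²))·fc(R_ij)fc(R_ik)fc(R_jk)`,
   and the "wide" variant omits the j–k factors so more distant pairs
   contribute. An optional angular shift `R_s` replaces every distance d
   inside the Gaussian by `d − R_s`. Parameters live in three plain-text
   files (`input.type`, `input.rad`, `input.ang`); their line order fixes
   the AEV slot order, and the radial block is resolved per neighbour
   element.

2. **Per-element regression.** One independent feed-forward network per
   chemical element maps the z-scored AEV to a z-scored target. Features
   and targets are standardized per AEV slot / per element using
   training-split statistics only; zero-variance slots get unit scale so
   standardization is always invertible. Training minimizes mean-squared
   error; prediction destandardizes the network output. The trained
   weights are frozen into plain numpy arrays, so prediction has no
   dependence on the training library and a saved model reloads
   bit-identically (floats are serialized through JSON's shortest
   round-trip representation).

3. **Charge equilibration.** With `ΔQ = Σq_pred − Q`, the correction is
   `η_A = w_A·ΔQ` and `q_corr = q_pred − η`. Requiring the corrected
   charges to reconstruct Q for every input forces the weights to be
   normalized (`Σw = 1`); given that, the linear rule is exact by
   construction and conservation is a structural identity, not a
   numerical aspiration. Eleven deterministic kernels assign `w` from
   the predicted charges, element constants (Z, Sanderson and Pauling
   electronegativities, covalent radii) and the per-element error
   statistics (μ, σ) of the charge model; the rationale throughout is
   that atoms whose predictions are less certain (large σ), more biased
   (large |μ|), or better able to absorb charge (large electron count
   Z − q) should carry more of the correction.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `R_c` (Å) | descriptor cutoff | 3.5 | covers first and second neighbour shells of the synthetic clusters |
| `η` (Å⁻²) | Gaussian width | 4.0 radial / 0.5 angular | a 6-point shift grid at η=4 resolves ~0.3 Å; angular terms stay broad |
| `ζ`, `λ` | angular sharpness/phase | {1, 4} × {±1} | the customary minimal angular basis |
| hidden layers | per-element net | (64, 64), tanh | small enough to train in seconds, expressive enough for smooth local targets |
| solver | optimizer | L-BFGS, ≤400 iterations | full-batch and deterministic; clearly better than mini-batch Adam at the few-thousand-sample scale (Adam remains available for larger datasets) |
| `validation_fraction` | held-out share per element | 0.1 | standard, leaves ≥90% for fitting small datasets |
| `CEQ` | scheme id | 1 | uniform redistribution is the parameter-free default |
| `Sigma` | noise-width multiplier | 1.0 | draw noise at the model's own error scale |
| `Qtoler` (e) | iterative stop threshold | 1e-3 | well below chemical significance, reached in tens of draws |
| `mu`, `sigma` (e) | per-element error stats | shipped CHON table | defaults from the reference CHON charge model; user-overridable CSV for tailor-made models |

Electronegativities and covalent radii are taken from single standard
tabulations (revised Sanderson scale; Pauling scale; Cordero 2008
radii). Only their ratios within one molecule enter the weights, so any
consistent scale gives the same scheme behaviour up to small weight
shifts.

## Iterative schemes

Schemes 12 and 13 perturb the charges stochastically instead of solving
for the correction: proposals subtract per-atom noise drawn from
`Normal(μ_el, (Sigma·σ_el)²)` — independently per atom (12) or one
shared standard-normal deviate scaled per element so all atoms move
coherently (13) — and a proposal is accepted only if it strictly reduces
|ΔQ|. The loop stops at `|ΔQ| ≤ Qtoler` or `max_iter` proposals; a final
uniform redistribution removes whatever residual remains, so the
conservation guarantee is identical to the deterministic schemes. The
accept-if-improved loop with uniform cleanup is this package's
documented design for the iterative family. A consequence worth noting:
when the input already satisfies `|ΔQ| ≤ Qtoler`, zero stochastic
iterations run but the cleanup still applies, because exact
reconstruction is treated as non-negotiable. Runs are reproducible from
the seed.

## Numerical choices and degenerate inputs

- Weight kernels with a zero numerator sum (e.g. the |q|-kernel on
  all-zero charges) fall back to uniform weights with a warning —
  uniform is the only parameter-free choice and keeps conservation
  intact.
- Kernels using the electron count `Z − q` guard against nonpositive
  terms (unphysical for realistic charges): any violation triggers the
  same uniform fallback rather than negative weights.
- Custom plug-in kernels (`CEQ = −1`) are validated on every call:
  nonnegative weights summing to 1 within 1e−8, then renormalized
  exactly.
- `cosθ` is clipped to [−1, 1] before the power; coincident atoms raise
  a contract error rather than returning NaN.
- Angle-free conservation checks use the scale `1e−10 · max(1, N)`.

## The synthetic data generator

Real reference charges require a quantum-chemical density and basin
integration, which is out of scope; the generator substitutes an
analytic ground truth so every stage is testable at desk scale.

- **Geometries** are connected random clusters grown by placing each
  atom 0.8–1.3 bond lengths from a random existing atom, rejecting
  clashes below `min_separation` (0.9 Å default, ~1.4 Å bonds). They are
  not chemically valid conformers; all implemented operators depend only
  on distances and angles, for which random clusters are sufficient.
- **Charges** follow pairwise electronegativity-driven transfer,
  `q_A = κ Σ_j (χ_j^P − χ_A^P)·fc(r_Aj)/r_Aj` with κ = 0.2 and a 3 Å
  cutoff. Each pair term is antisymmetric, so `Σq = 0` holds to machine
  precision for every geometry without any global shift — the function
  is strictly local, which is what makes it learnable from AEVs, and it
  reproduces the expected signs (O negative in water) at realistic
  magnitudes (±0.2–0.4 e). A molecule-global formulation (e.g. one
  referencing the molecular mean electronegativity) was deliberately
  avoided: its per-molecule shift is invisible to any local descriptor
  and would put a floor under the achievable error unrelated to model
  quality.
- **Prediction error** is emulated by seeded per-atom Gaussian noise
  plus a uniformly distributed systematic shift chosen so the injected
  molecular residual ΔQ is exact — including the ≈0.5 e regime typical
  of extrapolation to strained geometries.

Passing tests on this generator demonstrate the correctness of the
featurization, training, prediction and equilibration machinery — not
the accuracy of any particular trained model on real quantum-chemical
charges, which depends on training data this package does not ship.

## Problem sizes

The test suite and the acceptance script train on 250 eight-atom
clusters (2,000 atoms; held-out MAE ≈ 0.005 e against the analytic
charges), verify conservation on 1,000 randomized molecule/scheme
combinations, and check descriptors against a naive triple-loop oracle
on ≤5-atom molecules at 1e−12. These sizes were chosen so the entire
pipeline reruns from scratch in well under a minute.

## Known limitations

- No periodic boundary conditions; open-boundary molecules only.
- No descriptor gradients (forces), no uncertainty estimates, no
  ensembling.
- Shipped element constants and error statistics cover C, H, O, N;
  other elements require registering constants and supplying error
  statistics.
- The `.nnaim` results table and the model-folder layout are this
  package's own formats (documented in the module docstrings); no
  interchange with other codes' binary model files.
- Training reproducibility is guaranteed for fixed seed, data,
  hyperparameters and library versions on one platform; cross-platform
  bit-identity of training is not promised (prediction from a saved
  bundle is bit-stable everywhere).
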