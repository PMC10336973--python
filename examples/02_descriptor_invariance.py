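"""Atomic environment vectors and their rigid-motion invariance.

Featurizes a random CHON cluster, then rotates and translates it and
shows the descriptors do not move: the symmetry functions depend only on
interatomic distances and angles, which is what lets one network per
element predict per-atom properties of any conformer.
"""

import numpy as np

import eqcharge as eq

spec = eq.FixtureSpec(composition={"C": 2, "H": 4, "O": 1, "N": 1}, seed=7)
mol = eq.generate_molecule(spec)
config = eq.default_acsf_config()

aevs = eq.compute_aev(mol, config)
print(f"cluster: {''.join(mol.symbols)}  ({mol.N} atoms)")
for aev in aevs[:3]:
    print(
        f"  {aev.symbol}: AEV length {len(aev.values)}, "
        f"first slots {np.round(aev.values[:4], 4)}"
    )

rng = np.random.default_rng(0)
rotation, _ = np.linalg.qr(rng.normal(size=(3, 3)))
moved = eq.Molecule(mol.symbols, mol.coords @ rotation + [10.0, -3.0, 5.0])
moved_aevs = eq.compute_aev(moved, config)

drift = max(
    np.abs(a.values - b.values).max() for a, b in zip(aevs, moved_aevs)
)
print(f"\nmax descriptor change after a random rotation + translation: {drift:.2e}")
print("The environment vectors are invariant, so predictions are too.")
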