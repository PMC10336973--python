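"""Compare weight-assignment kernels on a water molecule.

Builds a water geometry with imperfect predicted charges whose sum
misses neutrality by 0.1 e, then shows how each deterministic scheme
shares that residual out: the per-atom weights w_A, the corrections
eta_A = w_A * delta_Q and the corrected charges, whose sum is exactly
the molecular charge again.
"""

import numpy as np

import eqcharge as eq

water = eq.Molecule(
    ("O", "H", "H"),
    np.array([[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399872, 0.9266272, 0.0]]),
)
# "predicted" charges carrying a +0.1 e residual
q_pred = np.array([-0.60, 0.38, 0.32])
stats = eq.default_error_stats()

dq = eq.molecular_charge_error(q_pred, Q=0.0)
print(f"predicted charges: {q_pred}, delta_Q = {dq:+.3f} e\n")
print(f"{'scheme':>6s}  {'w_O':>8s} {'w_H1':>8s} {'w_H2':>8s}   {'sum q_corr':>12s}")
for scheme in range(1, 12):
    w = eq.assign_weights(scheme, water.symbols, q_pred, stats)
    cs = eq.equilibrate(q_pred, 0.0, w)
    print(
        f"{scheme:6d}  {w[0]:8.5f} {w[1]:8.5f} {w[2]:8.5f}   {sum(cs.q_corr):12.3e}"
    )

print(
    "\nEach row is one weight kernel: uniform (1), charge-magnitude (2),"
    "\nelectron-count (3), electronegativities (4-5) and error-statistics"
    "\nbased (6-11). Oxygen's larger error spread gives it the biggest"
    "\nshare under scheme 6 (w_O = 0.382); the corrected sums are zero to"
    "\nmachine precision in every scheme."
)
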