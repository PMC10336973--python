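import math

import numpy as np
import pytest

import eqcharge as eq
from eqcharge.errors import ContractError, FormatError, UnsupportedElementError


# ---------------------------------------------------------------- oracle
def naive_fc(r, rc):
    return 0.5 * (math.cos(math.pi * r / rc) + 1.0) if r <= rc else 0.0


def naive_aev(mol, config):
    """Triple-loop reference evaluation of the descriptor formulas."""
    out = []
    for i in range(mol.N):
        vals = []
        for p in config.radial_for(mol.symbols[i]):
            s = 0.0
            for j in range(mol.N):
                if j == i or mol.symbols[j] != p.neighbor:
                    continue
                r = float(np.linalg.norm(mol.coords[j] - mol.coords[i]))
                if r <= p.r_c:
                    s += math.exp(-p.eta * (r - p.r_s) ** 2) * naive_fc(r, p.r_c)
            vals.append(s)
        for p in config.angular_for(mol.symbols[i]):
            s = 0.0
            for j in range(mol.N):
                for k in range(j + 1, mol.N):
                    if i in (j, k):
                        continue
                    pair = tuple(sorted((mol.symbols[j], mol.symbols[k])))
                    if pair != p.neighbors:
                        continue
                    rij = float(np.linalg.norm(mol.coords[j] - mol.coords[i]))
                    rik = float(np.linalg.norm(mol.coords[k] - mol.coords[i]))
                    rjk = float(np.linalg.norm(mol.coords[k] - mol.coords[j]))
                    if rij > p.r_c or rik > p.r_c:
                        continue
                    if p.variant == "narrow" and rjk > p.r_c:
                        continue
                    cos_t = np.dot(
                        mol.coords[j] - mol.coords[i], mol.coords[k] - mol.coords[i]
                    ) / (rij * rik)
                    cos_t = min(1.0, max(-1.0, cos_t))
                    g = (rij - p.r_s) ** 2 + (rik - p.r_s) ** 2
                    f = naive_fc(rij, p.r_c) * naive_fc(rik, p.r_c)
                    if p.variant == "narrow":
                        g += (rjk - p.r_s) ** 2
                        f *= naive_fc(rjk, p.r_c)
                    s += (1 + p.lam * cos_t) ** p.zeta * math.exp(-p.eta * g) * f
            vals.append(2.0 ** (1.0 - p.zeta) * s)
        out.append(np.array(vals))
    return out


def random_molecule(rng, n=5, elements=("C", "H", "O", "N")):
    symbols = tuple(rng.choice(elements, size=n))
    return eq.Molecule(symbols, rng.normal(scale=1.5, size=(n, 3)))


# ------------------------------------------------------------- cutoff
def test_cutoff_function_analytic_points():
    assert eq.cutoff_function(0.0, 2.0) == 1.0
    assert eq.cutoff_function(1.0, 2.0) == pytest.approx(0.5)
    assert eq.cutoff_function(2.2, 2.0) == 0.0


def test_cutoff_function_monotone_and_continuous():
    r = np.linspace(0, 3.0, 400)
    v = eq.cutoff_function(r, 3.0)
    assert np.all(np.diff(v) <= 1e-12)
    assert v[-1] == pytest.approx(0.0, abs=1e-12)


def test_cutoff_function_rejects_negative_distance():
    with pytest.raises(ContractError):
        eq.cutoff_function(-0.1, 2.0)


# ------------------------------------------------------------- radial
def test_radial_sf_isolated_atom_is_zero():
    mol = eq.Molecule(("C", "H"), np.array([[0.0, 0, 0], [50.0, 0, 0]]))
    p = eq.RadialParam("C", "H", r_c=3.0, eta=1.0, r_s=0.0)
    assert eq.radial_sf(mol, 0, p) == 0.0


def test_radial_sf_single_neighbor_at_shift():
    # neighbor exactly at R_s = R_c/2: Gaussian is 1, cutoff is 0.5
    p = eq.RadialParam("C", "H", r_c=3.0, eta=2.0, r_s=1.5)
    mol = eq.Molecule(("C", "H"), np.array([[0.0, 0, 0], [1.5, 0, 0]]))
    assert eq.radial_sf(mol, 0, p) == pytest.approx(0.5, rel=1e-12)


def test_radial_sf_additive_over_symmetric_neighbors():
    p = eq.RadialParam("C", "H", r_c=3.0, eta=2.0, r_s=0.0)
    one = eq.Molecule(("C", "H"), np.array([[0.0, 0, 0], [1.1, 0, 0]]))
    two = eq.Molecule(
        ("C", "H", "H"), np.array([[0.0, 0, 0], [1.1, 0, 0], [-1.1, 0, 0]])
    )
    assert eq.radial_sf(two, 0, p) == pytest.approx(2 * eq.radial_sf(one, 0, p))


# ------------------------------------------------------------- angular
def test_angular_sf_needs_two_neighbors():
    mol = eq.Molecule(("C", "H"), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    p = eq.AngularParam("C", ("H", "H"), r_c=3.0, eta=0.5, zeta=1.0, lam=1)
    assert eq.angular_sf(mol, 0, p) == 0.0


def test_angular_sf_linear_arrangement_vanishes_for_lambda_plus():
    # theta = pi: (1 + cos pi) = 0
    mol = eq.Molecule(
        ("C", "H", "H"), np.array([[0.0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
    )
    p = eq.AngularParam("C", ("H", "H"), r_c=3.0, eta=0.5, zeta=1.0, lam=1)
    assert eq.angular_sf(mol, 0, p) == pytest.approx(0.0, abs=1e-14)


@pytest.mark.parametrize("variant", ["narrow", "wide"])
@pytest.mark.parametrize("zeta,lam", [(1.0, 1), (2.0, -1), (4.0, 1)])
def test_angular_sf_equilateral_triangle_matches_formula(variant, zeta, lam):
    """Single (j,k) pair at 60 degrees: hand-evaluate the stated formula."""
    d = 1.2
    mol = eq.Molecule(
        ("H", "H", "H"),
        np.array(
            [[0.0, 0, 0], [d, 0, 0], [d / 2, d * math.sqrt(3) / 2, 0]]
        ),
    )
    p = eq.AngularParam(
        "H", ("H", "H"), r_c=3.0, eta=0.5, zeta=zeta, lam=lam, variant=variant
    )
    gauss = 3 * d**2 if variant == "narrow" else 2 * d**2
    fcs = naive_fc(d, 3.0) ** (3 if variant == "narrow" else 2)
    expected = 2 ** (1 - zeta) * (1 + lam * 0.5) ** zeta * math.exp(-0.5 * gauss) * fcs
    assert eq.angular_sf(mol, 0, p) == pytest.approx(expected, rel=1e-12)


def test_angular_sf_coincident_atoms_raise():
    mol = eq.Molecule(
        ("C", "H", "H"), np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]])
    )
    p = eq.AngularParam("C", ("H", "H"), r_c=3.0, eta=0.5, zeta=1.0, lam=1)
    with pytest.raises(ContractError):
        eq.angular_sf(mol, 0, p)


# ------------------------------------------------------------- compute_aev
def test_aev_lengths_and_slot_counts(small_config, water):
    aevs = eq.compute_aev(water, small_config)
    assert len(aevs) == 3
    for aev, sym in zip(aevs, water.symbols):
        assert aev.symbol == sym
        assert len(aev.values) == small_config.aev_length(sym)
        assert np.all(aev.values >= 0)
        assert np.all(np.isfinite(aev.values))


def test_aev_lone_atom_is_zero(small_config):
    mol = eq.Molecule(("N",), np.zeros((1, 3)))
    (aev,) = eq.compute_aev(mol, small_config)
    assert np.all(aev.values == 0.0)


def test_aev_rigid_motion_invariance(small_config):
    rng = np.random.default_rng(42)
    mol = random_molecule(rng, n=5)
    ref = np.vstack([a.values for a in eq.compute_aev(mol, small_config)])
    for _ in range(10):
        # random rotation via QR, plus translation and a reflection
        qmat, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = eq.Molecule(
            mol.symbols, mol.coords @ qmat + rng.normal(scale=5.0, size=3)
        )
        got = np.vstack([a.values for a in eq.compute_aev(moved, small_config)])
        np.testing.assert_allclose(got, ref, rtol=1e-8, atol=1e-10)


def test_aev_permutation_equivariance(small_config):
    rng = np.random.default_rng(7)
    mol = random_molecule(rng, n=5)
    perm = rng.permutation(mol.N)
    permuted = eq.Molecule(
        tuple(mol.symbols[i] for i in perm), mol.coords[perm]
    )
    ref = eq.compute_aev(mol, small_config)
    got = eq.compute_aev(permuted, small_config)
    for new_idx, old_idx in enumerate(perm):
        np.testing.assert_allclose(
            got[new_idx].values, ref[old_idx].values, rtol=1e-12, atol=1e-15
        )


def test_aev_locality_distant_atom_contributes_nothing(small_config):
    near = eq.Molecule(
        ("C", "H", "O"), np.array([[0.0, 0, 0], [1.1, 0, 0], [0, 1.3, 0]])
    )
    far = eq.Molecule(
        ("C", "H", "O", "N"),
        np.vstack([near.coords, [[100.0, 100.0, 100.0]]]),
    )
    ref = eq.compute_aev(near, small_config)
    got = eq.compute_aev(far, small_config)
    for a in range(3):
        np.testing.assert_array_equal(got[a].values, ref[a].values)


def test_aev_matches_naive_triple_loop_oracle(small_config):
    rng = np.random.default_rng(123)
    for n in (2, 3, 4, 5):
        mol = random_molecule(rng, n=n)
        got = eq.compute_aev(mol, small_config)
        want = naive_aev(mol, small_config)
        for g, w in zip(got, want):
            np.testing.assert_allclose(g.values, w, rtol=1e-12, atol=1e-14)


def test_aev_uncovered_element_raises(oh_config):
    mol = eq.Molecule(("C", "H"), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    with pytest.raises(UnsupportedElementError, match="C"):
        eq.compute_aev(mol, oh_config)


# ------------------------------------------------------------- config I/O
def test_parse_acsf_config_round_trip(tmp_path, small_config):
    eq.write_acsf_config(small_config, tmp_path)
    back = eq.parse_acsf_config(
        tmp_path / "input.rad", tmp_path / "input.ang", tmp_path / "input.type"
    )
    assert back == small_config
    assert back.fingerprint() == small_config.fingerprint()


def test_parse_acsf_config_validates(tmp_path):
    (tmp_path / "input.type").write_text("C H\n")
    (tmp_path / "input.rad").write_text("C H 3.0 1.0 0.0\n")
    (tmp_path / "input.ang").write_text("C H H 3.0 0.5 1.0 0\n")  # lambda = 0
    with pytest.raises(ContractError):
        eq.parse_acsf_config(
            tmp_path / "input.rad", tmp_path / "input.ang", tmp_path / "input.type"
        )


def test_parse_acsf_config_rejects_non_numeric(tmp_path):
    (tmp_path / "input.type").write_text("C H\n")
    (tmp_path / "input.rad").write_text("C H x 1.0 0.0\n")
    (tmp_path / "input.ang").write_text("")
    with pytest.raises(FormatError, match="input.rad"):
        eq.parse_acsf_config(
            tmp_path / "input.rad", tmp_path / "input.ang", tmp_path / "input.type"
        )


def test_parse_acsf_config_rejects_unknown_element(tmp_path):
    (tmp_path / "input.type").write_text("C H\n")
    (tmp_path / "input.rad").write_text("C Zz 3.0 1.0 0.0\n")
    (tmp_path / "input.ang").write_text("")
    with pytest.raises(FormatError):
        eq.parse_acsf_config(
            tmp_path / "input.rad", tmp_path / "input.ang", tmp_path / "input.type"
        )
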