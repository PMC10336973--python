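"""Synthetic CHON geometries with analytic reference charges.

Real QTAIM charges require a quantum-chemical density and basin
integration, so the test and example pipeline runs on a synthetic
stand-in instead: randomly packed CHON clusters and an analytic,
exactly charge-conserving toy charge function.

The toy charges model electronegativity-driven charge transfer between
neighbouring atoms:

    q_A = κ · Σ_{j≠A} (χ_j^P − χ_A^P) · fc(r_Aj) / r_Aj

with the cosine cutoff ``fc`` (3 Å by default).  Each pair term is
antisymmetric, so Σ_A q_A = 0 holds to machine precision for every
geometry; the more electronegative partner of each pair gains electron
density (negative charge).  The function is smooth in the coordinates,
invariant under rigid motions and strictly local — every atom's charge
is a function of its own neighbourhood, which is what makes it
learnable from atomic environment vectors.

:func:`perturb_charges` then emulates model error: seeded per-atom
Gaussian noise plus a systematic offset distributed over the atoms so
the molecular-charge residual ΔQ takes a prescribed value exactly —
including the ≈0.5 e extrapolation-stress regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .acsf import ACSFConfig, AngularParam, RadialParam, cutoff_function
from .elements import ElementTable, default_elements
from .errors import EqChargeError, ContractError
from .geometry import LabeledMolecule, Molecule

__all__ = [
    "FixtureSpec",
    "generate_molecule",
    "toy_charges",
    "perturb_charges",
    "generate_labeled_frames",
    "default_acsf_config",
]


@dataclass
class FixtureSpec:
    """Recipe for one batch of synthetic molecules.

    ``composition`` maps element symbols to atom counts per molecule;
    ``geometry_scale`` is the typical bond length (Å), ``min_separation``
    the clash threshold (Å), ``noise_level`` the per-atom Gaussian noise
    on charges (e) and ``offset`` the molecular-charge residual ΔQ (e)
    injected by :func:`perturb_charges`.
    """

    composition: dict[str, int] = field(
        default_factory=lambda: {"C": 2, "H": 4, "O": 1, "N": 1}
    )
    n_molecules: int = 1
    geometry_scale: float = 1.4
    min_separation: float = 0.9
    noise_level: float = 0.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ContractError("min_separation must be > 0")
        if self.n_molecules < 1:
            raise ContractError("n_molecules must be >= 1")
        if any(c < 0 for c in self.composition.values()) or not any(
            self.composition.values()
        ):
            raise ContractError("composition must contain at least one atom")

    def symbols(self) -> list[str]:
        out: list[str] = []
        for el, count in self.composition.items():
            out.extend([el] * count)
        return out


def generate_molecule(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> Molecule:
    """Grow a clash-free connected random cluster with the requested
    composition; deterministic for a fixed spec seed."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    symbols = spec.symbols()
    rng.shuffle(symbols)
    n = len(symbols)
    # placement distances follow the typical bond length; a clash
    # threshold the geometry scale cannot satisfy must fail, not stretch
    low = 0.8 * spec.geometry_scale
    high = 1.3 * spec.geometry_scale
    for _attempt in range(30):
        coords = [np.zeros(3)]
        ok = True
        for _ in range(1, n):
            placed = False
            for _retry in range(200):
                anchor = coords[rng.integers(len(coords))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = anchor + direction * rng.uniform(low, high)
                dists = np.linalg.norm(np.array(coords) - pos, axis=1)
                if np.all(dists >= spec.min_separation):
                    coords.append(pos)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return Molecule(tuple(symbols), np.array(coords))
    raise EqChargeError(
        "could not pack atoms without clashes; increase geometry_scale "
        "relative to min_separation"
    )


def toy_charges(
    molecule: Molecule,
    elements: ElementTable | None = None,
    kappa: float = 0.2,
    cutoff: float = 3.0,
) -> np.ndarray:
    """Analytic reference charges (electrons); Σq = 0 to machine precision."""
    elements = elements if elements is not None else default_elements()
    chi = np.array([elements.lookup(s).chi_P for s in molecule.symbols])
    r = molecule.distance_matrix()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(
            (r > 0) & (r <= cutoff), cutoff_function(np.where(r > 0, r, 1.0), cutoff) / r, 0.0
        )
    np.fill_diagonal(h, 0.0)
    # pairwise antisymmetric transfer: q_A = κ Σ_j (χ_j − χ_A) h_Aj
    return kappa * (h @ chi - chi * h.sum(axis=1))


def perturb_charges(
    q: Sequence[float], spec: FixtureSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Emulated predictions: per-atom Gaussian noise plus a uniformly
    distributed systematic shift so that Σq_pred − Σq = ``spec.offset``
    exactly; seeded."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    q = np.asarray(q, dtype=float)
    noise = (
        rng.normal(0.0, spec.noise_level, q.size)
        if spec.noise_level > 0
        else np.zeros(q.size)
    )
    return q + noise + (spec.offset - noise.sum()) / q.size


def generate_labeled_frames(
    spec: FixtureSpec, elements: ElementTable | None = None
) -> list[LabeledMolecule]:
    """``n_molecules`` random clusters labelled with toy charges, for
    training and end-to-end tests; one master seed drives everything."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for _ in range(spec.n_molecules):
        mol = generate_molecule(spec, rng)
        frames.append(LabeledMolecule(mol, toy_charges(mol, elements)))
    return frames


def default_acsf_config(
    element_types: Sequence[str] = ("C", "H", "O", "N"),
    r_c: float = 3.5,
    n_shifts: int = 6,
) -> ACSFConfig:
    """A compact descriptor set suited to the synthetic clusters: a grid
    of shifted radial Gaussians per neighbour element and four angular
    slots per element pair."""
    shifts = np.linspace(0.8, r_c - 0.6, n_shifts)
    radial = [
        RadialParam(center=c, neighbor=nb, r_c=r_c, eta=4.0, r_s=float(rs))
        for c in element_types
        for nb in element_types
        for rs in shifts
    ]
    pairs = [
        (e1, e2)
        for i, e1 in enumerate(element_types)
        for e2 in element_types[i:]
    ]
    angular = [
        AngularParam(
            center=c, neighbors=p, r_c=r_c, eta=0.5, zeta=z, lam=l, variant="narrow"
        )
        for c in element_types
        for p in pairs
        for z, l in ((1.0, 1), (1.0, -1), (4.0, 1), (4.0, -1))
    ]
    return ACSFConfig(tuple(element_types), tuple(radial), tuple(angular))
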