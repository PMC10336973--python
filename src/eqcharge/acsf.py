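"""Atom-centered symmetry functions (ACSF) and atomic environment vectors.

Every atom is described by a fixed-length vector of rotation-, translation-
and permutation-invariant functions of its neighbourhood:

* cosine cutoff  ``fc(r) = 0.5·[cos(π r / R_c) + 1]`` for r ≤ R_c, else 0;
* radial (G2)    ``Σ_j exp(−η (R_ij − R_s)²) · fc(R_ij)`` over neighbours
  j of one element;
* angular, narrow (G4)
  ``2^(1−ζ) Σ_{j<k} (1 + λ cos θ_jik)^ζ · exp(−η (R_ij² + R_ik² + R_jk²))
  · fc(R_ij) fc(R_ik) fc(R_jk)`` over unordered neighbour pairs of one
  element pair, and the wide (G5) variant that omits the R_jk factors.

Parameters live in three plain-text files (``input.type``, ``input.rad``,
``input.ang``; whitespace-separated columns, ``#`` comments):

    input.type:  element symbols, e.g. ``C H O N``
    input.rad:   center  neighbor  R_c  eta  R_s
    input.ang:   center  n1  n2  R_c  eta  zeta  lambda  [R_s]  [variant]

with R_c and R_s in Å, η in Å⁻², ζ ≥ 1, λ ∈ {+1, −1} and variant
``narrow`` (default) or ``wide``.  A nonzero angular R_s shifts every
pair distance inside the Gaussian.  File order fixes the slot order of
each element's vector: all radial slots first, then all angular slots.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ContractError, FormatError, UnsupportedElementError
from .geometry import Molecule

__all__ = [
    "RadialParam",
    "AngularParam",
    "ACSFConfig",
    "AEV",
    "parse_acsf_config",
    "write_acsf_config",
    "cutoff_function",
    "radial_sf",
    "angular_sf",
    "compute_aev",
]


@dataclass(frozen=True)
class RadialParam:
    center: str
    neighbor: str
    r_c: float
    eta: float
    r_s: float = 0.0

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ContractError(f"radial cutoff must be > 0, got {self.r_c}")


@dataclass(frozen=True)
class AngularParam:
    center: str
    neighbors: tuple[str, str]
    r_c: float
    eta: float
    zeta: float
    lam: int
    r_s: float = 0.0
    variant: str = "narrow"

    def __post_init__(self) -> None:
        object.__setattr__(self, "neighbors", tuple(sorted(self.neighbors)))
        if self.r_c <= 0:
            raise ContractError(f"angular cutoff must be > 0, got {self.r_c}")
        if self.zeta < 1:
            raise ContractError(f"zeta must be >= 1, got {self.zeta}")
        if self.lam not in (1, -1):
            raise ContractError(f"lambda must be +1 or -1, got {self.lam}")
        if self.variant not in ("narrow", "wide"):
            raise ContractError(f"variant must be narrow or wide, got {self.variant}")


@dataclass
class ACSFConfig:
    """A full symmetry-function parameter set; slot order follows the
    order of the parameter records."""

    element_types: tuple[str, ...]
    radial_params: tuple[RadialParam, ...]
    angular_params: tuple[AngularParam, ...]

    def __post_init__(self) -> None:
        self.element_types = tuple(self.element_types)
        self.radial_params = tuple(self.radial_params)
        self.angular_params = tuple(self.angular_params)
        known = set(self.element_types)
        for p in self.radial_params:
            if p.center not in known or p.neighbor not in known:
                raise FormatError(
                    f"radial record references element outside input.type: {p}"
                )
        for p in self.angular_params:
            if p.center not in known or any(n not in known for n in p.neighbors):
                raise FormatError(
                    f"angular record references element outside input.type: {p}"
                )

    def radial_for(self, element: str) -> list[RadialParam]:
        return [p for p in self.radial_params if p.center == element]

    def angular_for(self, element: str) -> list[AngularParam]:
        return [p for p in self.angular_params if p.center == element]

    def aev_length(self, element: str) -> int:
        if element not in self.element_types:
            raise UnsupportedElementError(f"element {element!r} not in input.type")
        return len(self.radial_for(element)) + len(self.angular_for(element))

    def max_cutoff(self) -> float:
        cuts = [p.r_c for p in self.radial_params] + [
            p.r_c for p in self.angular_params
        ]
        return max(cuts) if cuts else 0.0

    def fingerprint(self) -> str:
        """Stable hash of the full parameter set, stored with trained
        models to guard against editing the ACSF files afterwards."""
        text = "|".join(
            [",".join(self.element_types)]
            + [
                f"rad {p.center} {p.neighbor} {p.r_c!r} {p.eta!r} {p.r_s!r}"
                for p in self.radial_params
            ]
            + [
                f"ang {p.center} {p.neighbors[0]} {p.neighbors[1]} "
                f"{p.r_c!r} {p.eta!r} {p.zeta!r} {p.lam} {p.r_s!r} {p.variant}"
                for p in self.angular_params
            ]
        )
        return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class AEV:
    """One atom's descriptor vector, tagged with its element symbol."""

    symbol: str
    values: np.ndarray


def _tokens(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if body:
            yield lineno, body.split()


def parse_acsf_config(
    rad_path: str | Path, ang_path: str | Path, type_path: str | Path
) -> ACSFConfig:
    """Parse ``input.rad``, ``input.ang`` and ``input.type`` (dialect in
    the module docstring) into a validated :class:`ACSFConfig`."""
    element_types: list[str] = []
    for _, fields in _tokens(type_path):
        element_types.extend(fields)

    def _num(value: str, path, lineno, what):
        try:
            return float(value)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric {what}: {value!r}"
            ) from None

    radial = []
    for lineno, f in _tokens(rad_path):
        if len(f) != 5:
            raise FormatError(
                f"{rad_path}:{lineno}: expected 'center neighbor R_c eta R_s', got {f}"
            )
        radial.append(
            RadialParam(
                center=f[0],
                neighbor=f[1],
                r_c=_num(f[2], rad_path, lineno, "R_c"),
                eta=_num(f[3], rad_path, lineno, "eta"),
                r_s=_num(f[4], rad_path, lineno, "R_s"),
            )
        )

    angular = []
    for lineno, f in _tokens(ang_path):
        if len(f) not in (7, 8, 9):
            raise FormatError(
                f"{ang_path}:{lineno}: expected 'center n1 n2 R_c eta zeta "
                f"lambda [R_s] [variant]', got {f}"
            )
        lam = _num(f[6], ang_path, lineno, "lambda")
        if lam not in (1.0, -1.0):
            raise ContractError(f"{ang_path}:{lineno}: lambda must be +1 or -1")
        angular.append(
            AngularParam(
                center=f[0],
                neighbors=(f[1], f[2]),
                r_c=_num(f[3], ang_path, lineno, "R_c"),
                eta=_num(f[4], ang_path, lineno, "eta"),
                zeta=_num(f[5], ang_path, lineno, "zeta"),
                lam=int(lam),
                r_s=_num(f[7], ang_path, lineno, "R_s") if len(f) >= 8 else 0.0,
                variant=f[8] if len(f) == 9 else "narrow",
            )
        )
    return ACSFConfig(tuple(element_types), tuple(radial), tuple(angular))


def write_acsf_config(config: ACSFConfig, dir_path: str | Path) -> None:
    """Write ``input.type`` / ``input.rad`` / ``input.ang`` so that
    :func:`parse_acsf_config` reproduces ``config`` exactly."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    (dir_path / "input.type").write_text(" ".join(config.element_types) + "\n")
    with open(dir_path / "input.rad", "w") as fh:
        fh.write("# center neighbor R_c eta R_s\n")
        for p in config.radial_params:
            fh.write(f"{p.center} {p.neighbor} {p.r_c!r} {p.eta!r} {p.r_s!r}\n")
    with open(dir_path / "input.ang", "w") as fh:
        fh.write("# center n1 n2 R_c eta zeta lambda R_s variant\n")
        for p in config.angular_params:
            fh.write(
                f"{p.center} {p.neighbors[0]} {p.neighbors[1]} {p.r_c!r} "
                f"{p.eta!r} {p.zeta!r} {p.lam} {p.r_s!r} {p.variant}\n"
            )


def cutoff_function(r, r_c: float):
    """Cosine cutoff: 0.5·[cos(π r / R_c) + 1] for r ≤ R_c, exactly 0 beyond."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ContractError("distances must be nonnegative")
    if r_c <= 0:
        raise ContractError(f"cutoff must be > 0, got {r_c}")
    out = np.where(r <= r_c, 0.5 * (np.cos(np.pi * r / r_c) + 1.0), 0.0)
    return out if out.ndim else float(out)


def radial_sf(molecule: Molecule, center: int, param: RadialParam) -> float:
    """One G2 radial slot for one atom."""
    if molecule.symbols[center] != param.center:
        raise ContractError(
            f"atom {center} is {molecule.symbols[center]}, record is for {param.center}"
        )
    r = np.linalg.norm(molecule.coords - molecule.coords[center], axis=1)
    mask = (np.arange(molecule.N) != center) & (
        np.array(molecule.symbols) == param.neighbor
    )
    r = r[mask]
    r = r[r <= param.r_c]
    if r.size == 0:
        return 0.0
    return float(
        np.sum(np.exp(-param.eta * (r - param.r_s) ** 2) * cutoff_function(r, param.r_c))
    )


def _pair_indices(symbols: np.ndarray, center: int, pair: tuple[str, str]):
    """Unordered neighbour pairs (j, k), j ≠ k ≠ center, matching the
    element pair; each pair counted once."""
    e1, e2 = pair
    idx = np.arange(len(symbols))
    if e1 == e2:
        cand = idx[(symbols == e1) & (idx != center)]
        return [(int(j), int(k)) for a, j in enumerate(cand) for k in cand[a + 1 :]]
    c1 = idx[(symbols == e1) & (idx != center)]
    c2 = idx[(symbols == e2) & (idx != center)]
    return [(int(j), int(k)) for j in c1 for k in c2]


def angular_sf(molecule: Molecule, center: int, param: AngularParam) -> float:
    """One G4 (narrow) or G5 (wide) angular slot for one atom."""
    if molecule.symbols[center] != param.center:
        raise ContractError(
            f"atom {center} is {molecule.symbols[center]}, record is for {param.center}"
        )
    symbols = np.array(molecule.symbols)
    coords = molecule.coords
    total = 0.0
    for j, k in _pair_indices(symbols, center, param.neighbors):
        v_ij = coords[j] - coords[center]
        v_ik = coords[k] - coords[center]
        r_ij = float(np.linalg.norm(v_ij))
        r_ik = float(np.linalg.norm(v_ik))
        if r_ij == 0.0 or r_ik == 0.0:
            raise ContractError(
                f"zero-length bond at center {center}: atoms coincide"
            )
        if r_ij > param.r_c or r_ik > param.r_c:
            continue
        r_jk = float(np.linalg.norm(coords[k] - coords[j]))
        if param.variant == "narrow" and r_jk > param.r_c:
            continue
        cos_t = float(np.clip(v_ij @ v_ik / (r_ij * r_ik), -1.0, 1.0))
        gauss_arg = (r_ij - param.r_s) ** 2 + (r_ik - param.r_s) ** 2
        fcs = cutoff_function(r_ij, param.r_c) * cutoff_function(r_ik, param.r_c)
        if param.variant == "narrow":
            gauss_arg += (r_jk - param.r_s) ** 2
            fcs *= cutoff_function(r_jk, param.r_c)
        total += (
            (1.0 + param.lam * cos_t) ** param.zeta
            * np.exp(-param.eta * gauss_arg)
            * fcs
        )
    return float(2.0 ** (1.0 - param.zeta) * total)


def compute_aev(molecule: Molecule, config: ACSFConfig) -> list[AEV]:
    """Compute every atom's environment vector.

    Slot order per atom: the element's radial records in file order,
    then its angular records in file order.
    """
    for a, s in enumerate(molecule.symbols):
        if s not in config.element_types:
            raise UnsupportedElementError(
                f"atom {a + 1} ({s}) is not covered by input.type"
            )
    out = []
    for a, s in enumerate(molecule.symbols):
        slots = [radial_sf(molecule, a, p) for p in config.radial_for(s)]
        slots += [angular_sf(molecule, a, p) for p in config.angular_for(s)]
        out.append(AEV(symbol=s, values=np.array(slots, dtype=float)))
    return out
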