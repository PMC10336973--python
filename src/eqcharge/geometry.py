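"""Molecular geometry containers and plain-text I/O.

Reads standard XYZ files (count line, comment line, ``symbol x y z`` per
atom, coordinates in Å) and extended XYZ files that append one per-atom
property value to each atom line — the format used to feed the trainer.
Writes prediction results as a ``.nnaim`` table: a commented header
followed by whitespace-separated columns ``index symbol raw [corrected]``
with 1-based atom indices.

The total molecular charge ``Q`` (electrons) defaults to 0; a
``charge=<int>`` token on the XYZ comment line overrides it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractError, FormatError, UnsupportedElementError

__all__ = [
    "Molecule",
    "LabeledMolecule",
    "read_xyz",
    "read_extended_xyz",
    "write_xyz",
    "write_extended_xyz",
    "write_nnaim",
]

# Symbols accepted by the parsers (the full periodic table); model
# coverage is checked separately at prediction time.
_KNOWN_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe
    Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn
    Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W
    Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf
    Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


def _check_symbol(raw: str, where: str) -> str:
    s = raw.strip()
    s = s[0].upper() + s[1:].lower() if s else s
    if s not in _KNOWN_SYMBOLS:
        raise UnsupportedElementError(f"unsupported element symbol {raw!r} {where}")
    return s


@dataclass
class Molecule:
    """An ordered set of atoms with Cartesian coordinates in Å and a total
    molecular charge ``Q`` in electrons."""

    symbols: tuple[str, ...]
    coords: np.ndarray
    Q: float = 0.0

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ContractError(f"coords must be (N, 3), got {self.coords.shape}")
        if len(self.symbols) != len(self.coords):
            raise ContractError(
                f"{len(self.symbols)} symbols but {len(self.coords)} coordinates"
            )
        if len(self.symbols) < 1:
            raise ContractError("a molecule needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("coordinates must be finite")

    @property
    def N(self) -> int:
        return len(self.symbols)

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))


@dataclass
class LabeledMolecule:
    """A molecule plus one target property value per atom (e.g. reference
    atomic charges in electrons) for training."""

    molecule: Molecule
    targets: np.ndarray
    units: str = "e"

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (self.molecule.N,):
            raise ContractError(
                f"{len(self.targets)} targets for {self.molecule.N} atoms"
            )


def _parse_charge_token(comment: str) -> float:
    m = re.search(r"\bcharge=(-?\d+)\b", comment)
    return float(m.group(1)) if m else 0.0


def _read_frames(lines: list[str], path: str, n_extra: int):
    """Yield (symbols, coords, extras, comment) per XYZ frame."""
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame += 1
        try:
            count = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise FormatError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if count < 1:
            raise FormatError(f"{path}:{i + 1}: atom count must be >= 1")
        comment = lines[i + 1].rstrip("\n") if i + 1 < len(lines) else ""
        body = lines[i + 2 : i + 2 + count]
        if len(body) < count:
            raise FormatError(
                f"{path}:{i + 1}: frame {frame} declares {count} atoms "
                f"but only {len(body)} atom lines follow"
            )
        symbols, coords, extras = [], [], []
        for k, line in enumerate(body):
            fields = line.split()
            lineno = i + 3 + k
            if len(fields) < 4 + n_extra:
                raise FormatError(
                    f"{path}:{lineno}: frame {frame} atom line needs "
                    f"{4 + n_extra} fields, got {len(fields)}"
                )
            symbols.append(_check_symbol(fields[0], f"at {path}:{lineno}"))
            try:
                coords.append([float(v) for v in fields[1:4]])
                extras.append([float(v) for v in fields[4 : 4 + n_extra]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unparsable numeric field in {line!r}"
                ) from None
        yield symbols, np.array(coords), np.array(extras), comment
        i += 2 + count


def read_xyz(path: str | Path) -> Molecule:
    """Read a single-frame XYZ file into a :class:`Molecule`.

    Trailing content after the first frame is a format error, as is an
    atom count that disagrees with the number of atom lines.
    """
    lines = Path(path).read_text().splitlines()
    frames = list(_read_frames(lines, str(path), n_extra=0))
    if not frames:
        raise FormatError(f"{path}: empty file")
    if len(frames) > 1:
        raise FormatError(f"{path}: expected a single frame, found {len(frames)}")
    symbols, coords, _, comment = frames[0]
    return Molecule(tuple(symbols), coords, Q=_parse_charge_token(comment))


def read_extended_xyz(path: str | Path) -> list[LabeledMolecule]:
    """Read a (multi-frame) extended XYZ file: one trailing per-atom
    property value after ``x y z`` on every atom line."""
    lines = Path(path).read_text().splitlines()
    out = []
    for symbols, coords, extras, comment in _read_frames(lines, str(path), n_extra=1):
        mol = Molecule(tuple(symbols), coords, Q=_parse_charge_token(comment))
        out.append(LabeledMolecule(mol, extras[:, 0]))
    if not out:
        raise FormatError(f"{path}: empty file")
    return out


def write_xyz(molecule: Molecule, path: str | Path, comment: str = "") -> None:
    _write_frames(path, [(molecule, None, comment)])


def write_extended_xyz(
    frames: Sequence[LabeledMolecule], path: str | Path, comment: str = ""
) -> None:
    _write_frames(path, [(f.molecule, f.targets, comment) for f in frames])


def _write_frames(path, frames) -> None:
    with open(path, "w") as fh:
        for mol, targets, comment in frames:
            if mol.Q and "charge=" not in comment:
                comment = (comment + f" charge={int(mol.Q)}").strip()
            fh.write(f"{mol.N}\n{comment}\n")
            for a in range(mol.N):
                x, y, z = mol.coords[a]
                fh.write(f"{mol.symbols[a]:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
                if targets is not None:
                    fh.write(f" {targets[a]:18.10f}")
                fh.write("\n")


def write_nnaim(
    molecule: Molecule,
    raw: Sequence[float],
    corrected: Sequence[float] | None,
    path: str | Path,
    property_name: str = "atomic charge",
    units: str = "e",
) -> None:
    """Write a per-atom results table (``.nnaim``).

    Columns: 1-based atom index, element symbol, raw predicted value and,
    when equilibration was applied, the corrected value. Values carry 12
    significant digits.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (molecule.N,):
        raise ContractError(f"{raw.size} raw values for {molecule.N} atoms")
    if corrected is not None:
        corrected = np.asarray(corrected, dtype=float)
        if corrected.shape != (molecule.N,):
            raise ContractError(
                f"{corrected.size} corrected values for {molecule.N} atoms"
            )
    with open(path, "w") as fh:
        fh.write(f"# property: {property_name} [{units}]\n")
        cols = "# index symbol raw" + (" corrected" if corrected is not None else "")
        fh.write(cols + "\n")
        for a in range(molecule.N):
            fh.write(f"{a + 1:6d} {molecule.symbols[a]:<2s} {raw[a]: .12e}")
            if corrected is not None:
                fh.write(f" {corrected[a]: .12e}")
            fh.write("\n")
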