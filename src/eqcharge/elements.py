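"""Per-element constants and per-element prediction-error statistics.

Two small tables drive the charge-equilibration weight kernels:

* :class:`ElementData` — atomic number ``Z``, Sanderson and Pauling
  electronegativities ``chi_S``/``chi_P`` and the covalent radius
  ``r_cov`` (Å).  Only *ratios* of these quantities within a molecule
  enter the weights, so any single consistent tabulation works; the
  shipped values come from the standard scales (see ``data/elements.csv``).
* :class:`ErrorStats` — per-element mean ``mu`` and standard deviation
  ``sigma`` (electrons) of the Gaussian fitted to a charge model's
  validation errors.  The shipped defaults are the published statistics
  of the reference CHON charge model; tailor-made models should supply
  their own via :meth:`ErrorStats.from_file`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ContractError, UnsupportedElementError

__all__ = [
    "ElementData",
    "ElementTable",
    "ErrorStats",
    "default_elements",
    "default_error_stats",
    "lookup_element",
]


@dataclass(frozen=True)
class ElementData:
    """Physical constants for one element."""

    symbol: str
    Z: int
    chi_S: float
    chi_P: float
    r_cov: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ContractError(f"Z must be >= 1, got {self.Z} for {self.symbol}")
        for name in ("chi_S", "chi_P", "r_cov"):
            if getattr(self, name) <= 0:
                raise ContractError(
                    f"{name} must be > 0, got {getattr(self, name)} for {self.symbol}"
                )


def _canonical(symbol: str) -> str:
    s = symbol.strip()
    if not s.isalpha():
        raise UnsupportedElementError(f"unsupported element symbol: {symbol!r}")
    return s[0].upper() + s[1:].lower()


class ElementTable:
    """Case-insensitive registry of :class:`ElementData`, extensible at run time."""

    def __init__(self, entries: dict[str, ElementData] | None = None):
        self._entries: dict[str, ElementData] = dict(entries or {})

    @classmethod
    def from_file(cls, path: str | Path) -> "ElementTable":
        table = cls()
        with open(path, newline="") as fh:
            rows = (r for r in fh if r.strip() and not r.lstrip().startswith("#"))
            for row in csv.DictReader(rows):
                table.register(
                    ElementData(
                        symbol=_canonical(row["symbol"]),
                        Z=int(row["Z"]),
                        chi_S=float(row["chi_S"]),
                        chi_P=float(row["chi_P"]),
                        r_cov=float(row["r_cov"]),
                    )
                )
        return table

    def register(self, data: ElementData) -> None:
        self._entries[_canonical(data.symbol)] = data

    def lookup(self, symbol: str) -> ElementData:
        key = _canonical(symbol)
        try:
            return self._entries[key]
        except KeyError:
            raise UnsupportedElementError(
                f"unsupported element: {symbol!r} (known: {sorted(self._entries)})"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        try:
            return _canonical(symbol) in self._entries
        except UnsupportedElementError:
            return False

    def symbols(self) -> list[str]:
        return sorted(self._entries)


@dataclass
class ErrorStats:
    """Per-element Gaussian parameters (mean, standard deviation) of the
    charge-prediction error distribution, in electrons."""

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        self.mu = {_canonical(k): float(v) for k, v in self.mu.items()}
        self.sigma = {_canonical(k): float(v) for k, v in self.sigma.items()}
        for el, s in self.sigma.items():
            if s < 0:
                raise ContractError(f"sigma must be >= 0, got {s} for {el}")

    def get(self, symbol: str) -> tuple[float, float]:
        key = _canonical(symbol)
        if key not in self.mu or key not in self.sigma:
            raise UnsupportedElementError(
                f"no error statistics for element {symbol!r}"
            )
        return self.mu[key], self.sigma[key]

    @classmethod
    def from_file(cls, path: str | Path) -> "ErrorStats":
        mu: dict[str, float] = {}
        sigma: dict[str, float] = {}
        with open(path, newline="") as fh:
            rows = (r for r in fh if r.strip() and not r.lstrip().startswith("#"))
            for row in csv.DictReader(rows):
                mu[row["symbol"]] = float(row["mu"])
                sigma[row["symbol"]] = float(row["sigma"])
        return cls(mu=mu, sigma=sigma)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["symbol", "mu", "sigma"])
            for el in sorted(self.mu):
                writer.writerow([el, repr(self.mu[el]), repr(self.sigma[el])])


def _data_path(name: str) -> Path:
    return Path(str(resources.files("eqcharge").joinpath("data", name)))


_DEFAULT_ELEMENTS: ElementTable | None = None


def default_elements() -> ElementTable:
    """The shipped CHON constants table (see ``data/elements.csv``)."""
    global _DEFAULT_ELEMENTS
    if _DEFAULT_ELEMENTS is None:
        _DEFAULT_ELEMENTS = ElementTable.from_file(_data_path("elements.csv"))
    return _DEFAULT_ELEMENTS


def lookup_element(symbol: str) -> ElementData:
    """Look up one element in the shipped table (case-insensitive)."""
    return default_elements().lookup(symbol)


def default_error_stats() -> ErrorStats:
    """The shipped per-element error statistics of the reference CHON
    charge model (electrons)."""
    return ErrorStats.from_file(_data_path("error_stats.csv"))
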