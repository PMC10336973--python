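"""Charge equilibration: redistribute the residual molecular charge.

Machine-learned atomic charges carry small independent errors, so their
sum misses the true molecular charge Q by a residual

    ΔQ = Σ_A q_A^pred − Q.

Equilibration removes the residual by subtracting a per-atom correction
η_A = w_A · ΔQ from each predicted charge,

    q_A^corr = q_A^pred − η_A,

where the nonnegative weights w_A sum to one, so Σ q^corr = Q exactly.
This is a post-hoc *rescaling* of model output, not an
electronegativity-equalization charge computation.

Eleven deterministic weight kernels (scheme ids 1–11) share out ΔQ by,
respectively: (1) uniform 1/N; (2) predicted-charge magnitude |q_A|;
(3) electron count Z_A − q_A; (4) Sanderson electronegativity χ^S;
(5) Pauling electronegativity χ^P; (6) per-element model error spread
σ_A; (7) error bias magnitude |μ_A|; (8) |μ_A|·σ_A; (9) |μ_A|·(Z_A −
q_A)/r_A; (10) |μ_A|·(Z_A − q_A); (11) |μ_A|·σ_A·(Z_A − q_A)/r_A — each
normalized by its molecular sum.  Ids 12 and 13 are stochastic
iterative variants that draw noise from each element's error
distribution; id 0 disables equilibration and id −1 loads a custom
weight kernel from a user plug-in file.
"""

from __future__ import annotations

import importlib.util
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .elements import ElementTable, ErrorStats, default_elements
from .errors import ContractError, EqChargeError

__all__ = [
    "ChargeSet",
    "EquilibrationSettings",
    "WeightFunction",
    "molecular_charge_error",
    "assign_weights",
    "equilibrate",
    "iterative_equilibrate",
    "load_custom_scheme",
    "apply_equilibration",
    "SCHEME_REQUIREMENTS",
]

logger = logging.getLogger(__name__)

#: per-scheme element data needed beyond the predicted charges
SCHEME_REQUIREMENTS = {
    1: (),
    2: (),
    3: ("Z",),
    4: ("chi_S",),
    5: ("chi_P",),
    6: ("sigma",),
    7: ("mu",),
    8: ("mu", "sigma"),
    9: ("mu", "Z", "r_cov"),
    10: ("mu", "Z"),
    11: ("mu", "sigma", "Z", "r_cov"),
}

WeightFunction = Callable[
    [Sequence[str], np.ndarray, ErrorStats | None, ElementTable], np.ndarray
]


@dataclass
class ChargeSet:
    """Predicted charges, their corrections and the corrected charges,
    all in electrons."""

    q_pred: np.ndarray
    Q: float
    delta_Q: float
    eta: np.ndarray
    q_corr: np.ndarray
    n_iterations: int = 0

    @property
    def residual(self) -> float:
        """Σ q_corr − Q after correction (should be ~0)."""
        return float(np.sum(self.q_corr) - self.Q)


@dataclass
class EquilibrationSettings:
    """Knobs of the equilibration stage.

    CEQ selects the scheme (0 none, 1–11 deterministic, 12–13 iterative,
    −1 custom plug-in).  Sigma scales the per-element noise width and
    Qtoler is the residual charge (electrons) at which the iterative
    loop stops; both only matter for CEQ 12/13.
    """

    CEQ: int = 1
    Sigma: float = 1.0
    Qtoler: float = 1e-3
    seed: int = 0
    max_iter: int = 10_000
    custom_path: str | None = None

    def __post_init__(self) -> None:
        if self.Qtoler <= 0:
            raise ContractError(f"Qtoler must be > 0, got {self.Qtoler}")
        if self.Sigma <= 0:
            raise ContractError(f"Sigma must be > 0, got {self.Sigma}")
        if self.max_iter < 1:
            raise ContractError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.CEQ == -1 and not self.custom_path:
            raise ContractError("CEQ = -1 requires a custom plug-in path")


def molecular_charge_error(q_pred: Sequence[float], Q: float = 0.0) -> float:
    """ΔQ = Σ q_pred − Q, the excess (or deficiency) of electrons."""
    q_pred = np.asarray(q_pred, dtype=float)
    if q_pred.size < 1:
        raise ContractError("need at least one atom")
    return float(np.sum(q_pred) - Q)


def _uniform(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def _fallback(raw: np.ndarray, scheme: int, reason: str) -> np.ndarray:
    logger.warning("scheme %d: %s; falling back to uniform weights", scheme, reason)
    warnings.warn(
        f"equilibration scheme {scheme}: {reason}; using uniform weights",
        RuntimeWarning,
        stacklevel=3,
    )
    return _uniform(raw.size)


def assign_weights(
    scheme: int,
    symbols: Sequence[str],
    q_pred: Sequence[float],
    stats: ErrorStats | None = None,
    elements: ElementTable | None = None,
) -> np.ndarray:
    """Per-atom weights for deterministic schemes 1–11, normalized to sum
    to one.

    Degenerate inputs (an all-zero weight numerator, or a nonpositive
    electron count Z − q in schemes 3/9/10/11) fall back to uniform
    weights with a warning.
    """
    if scheme not in SCHEME_REQUIREMENTS:
        raise EqChargeError(f"unknown equilibration scheme id {scheme}")
    symbols = list(symbols)
    q = np.asarray(q_pred, dtype=float)
    if q.shape != (len(symbols),):
        raise ContractError(f"{q.size} charges for {len(symbols)} atoms")
    n = len(symbols)
    elements = elements if elements is not None else default_elements()

    needs = SCHEME_REQUIREMENTS[scheme]
    if ("mu" in needs or "sigma" in needs) and stats is None:
        raise EqChargeError(f"scheme {scheme} needs per-element error statistics")
    mu = sigma = None
    if "mu" in needs or "sigma" in needs:
        pairs = [stats.get(s) for s in symbols]
        mu = np.array([p[0] for p in pairs])
        sigma = np.array([p[1] for p in pairs])
    data = [elements.lookup(s) for s in symbols] if any(
        k in needs for k in ("Z", "chi_S", "chi_P", "r_cov")
    ) else None

    if scheme == 1:
        return _uniform(n)
    if scheme == 2:
        raw = np.abs(q)
    elif scheme == 3:
        raw = np.array([d.Z for d in data]) - q
    elif scheme == 4:
        raw = np.array([d.chi_S for d in data])
    elif scheme == 5:
        raw = np.array([d.chi_P for d in data])
    elif scheme == 6:
        raw = sigma.copy()
    elif scheme == 7:
        raw = np.abs(mu)
    elif scheme == 8:
        raw = np.abs(mu) * sigma
    elif scheme == 9:
        z = np.array([d.Z for d in data])
        r = np.array([d.r_cov for d in data])
        raw = np.abs(mu) * (z - q) / r
    elif scheme == 10:
        z = np.array([d.Z for d in data])
        raw = np.abs(mu) * (z - q)
    else:  # scheme 11
        z = np.array([d.Z for d in data])
        r = np.array([d.r_cov for d in data])
        raw = np.abs(mu) * sigma * (z - q) / r

    if scheme in (3, 9, 10, 11) and np.any(raw <= 0):
        return _fallback(raw, scheme, "nonpositive electron-count term Z - q")
    if np.any(raw < 0):
        return _fallback(raw, scheme, "negative weight term")
    total = raw.sum()
    if total <= 1e-15:
        return _fallback(raw, scheme, "weight sum is (numerically) zero")
    return raw / total


def _validate_weights(w: np.ndarray, n: int, origin: str) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise EqChargeError(f"{origin}: expected {n} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise EqChargeError(f"{origin}: weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise EqChargeError(f"{origin}: weights sum to {w.sum()!r}, expected 1")
    return w / w.sum()


def equilibrate(
    q_pred: Sequence[float], Q: float, weights: Sequence[float]
) -> ChargeSet:
    """Apply η_A = w_A·ΔQ, q_corr = q_pred − η; Σ q_corr = Q by construction."""
    q = np.asarray(q_pred, dtype=float)
    w = _validate_weights(np.asarray(weights, dtype=float), q.size, "weights")
    dq = molecular_charge_error(q, Q)
    eta = w * dq
    return ChargeSet(q_pred=q, Q=Q, delta_Q=dq, eta=eta, q_corr=q - eta)


def iterative_equilibrate(
    q_pred: Sequence[float],
    Q: float,
    symbols: Sequence[str],
    stats: ErrorStats,
    settings: EquilibrationSettings,
) -> ChargeSet:
    """Stochastic equilibration (scheme ids 12 and 13).

    Starting from the predicted charges, proposes perturbed charge sets
    by drawing per-atom noise from each element's error distribution
    Normal(μ_el, (Sigma·σ_el)²) and accepts a proposal only if it
    strictly shrinks |ΔQ|.  Scheme 12 draws independently per atom;
    scheme 13 draws one shared standard-normal deviate per step and
    scales it by each atom's μ/σ, so all atoms move coherently.  The
    loop stops once |ΔQ| ≤ Qtoler or after max_iter proposals; any
    remaining residual is then removed by a uniform redistribution so
    the corrected charges reconstruct Q exactly.  Reproducible for a
    fixed seed.
    """
    if settings.CEQ not in (12, 13):
        raise EqChargeError(f"iterative schemes are 12 and 13, got CEQ={settings.CEQ}")
    q0 = np.asarray(q_pred, dtype=float)
    symbols = list(symbols)
    if q0.shape != (len(symbols),):
        raise ContractError(f"{q0.size} charges for {len(symbols)} atoms")
    pairs = [stats.get(s) for s in symbols]
    mu = np.array([p[0] for p in pairs])
    sig = settings.Sigma * np.array([p[1] for p in pairs])

    rng = np.random.default_rng(settings.seed)
    q = q0.copy()
    best = abs(molecular_charge_error(q, Q))
    iterations = 0
    while best > settings.Qtoler and iterations < settings.max_iter:
        iterations += 1
        if settings.CEQ == 12:
            noise = rng.normal(mu, sig)
        else:
            noise = mu + rng.standard_normal() * sig
        proposal = q - noise
        err = abs(molecular_charge_error(proposal, Q))
        if err < best:
            q, best = proposal, err

    # exact cleanup: share the leftover residual uniformly
    q = q - molecular_charge_error(q, Q) / q.size
    dq = molecular_charge_error(q0, Q)
    eta = q0 - q
    return ChargeSet(
        q_pred=q0, Q=Q, delta_Q=dq, eta=eta, q_corr=q, n_iterations=iterations
    )


def load_custom_scheme(path: str | Path) -> WeightFunction:
    """Load a user weight kernel (CEQ = −1) from a Python file.

    The file must define ``assign_weights(symbols, q_pred, stats,
    elements)`` returning per-atom weights; the output is validated
    (nonnegative, summing to one) on every call.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"custom scheme file not found: {path}")
    spec = importlib.util.spec_from_file_location(f"eqcharge_custom_{path.stem}", path)
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    if not hasattr(module, "assign_weights"):
        raise EqChargeError(f"{path} does not define assign_weights(...)")
    inner = module.assign_weights

    def wrapped(symbols, q_pred, stats, elements) -> np.ndarray:
        w = inner(symbols, np.asarray(q_pred, dtype=float), stats, elements)
        return _validate_weights(
            np.asarray(w, dtype=float), len(list(symbols)), f"custom scheme {path.name}"
        )

    return wrapped


def apply_equilibration(
    q_pred: Sequence[float],
    Q: float,
    symbols: Sequence[str],
    settings: EquilibrationSettings,
    stats: ErrorStats | None = None,
    elements: ElementTable | None = None,
) -> ChargeSet:
    """Dispatch on ``settings.CEQ``: 0 passthrough, 1–11 deterministic,
    12–13 iterative, −1 custom plug-in."""
    q = np.asarray(q_pred, dtype=float)
    if settings.CEQ == 0:
        dq = molecular_charge_error(q, Q)
        return ChargeSet(q, Q, dq, np.zeros_like(q), q.copy())
    if settings.CEQ in SCHEME_REQUIREMENTS:
        w = assign_weights(settings.CEQ, symbols, q, stats, elements)
        return equilibrate(q, Q, w)
    if settings.CEQ in (12, 13):
        if stats is None:
            raise EqChargeError("iterative schemes need per-element error statistics")
        return iterative_equilibrate(q, Q, symbols, stats, settings)
    if settings.CEQ == -1:
        fn = load_custom_scheme(settings.custom_path)
        w = fn(symbols, q, stats, elements or default_elements())
        return equilibrate(q, Q, w)
    raise EqChargeError(f"unknown CEQ scheme id {settings.CEQ}")
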