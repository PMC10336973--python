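"""Per-element feed-forward networks for atomic properties.

One independent network per chemical element maps that element's
standardized environment vector (AEV) to a standardized target value.
Training is delegated to scikit-learn's multilayer-perceptron regressor;
the fitted layer weights are then frozen into a :class:`ElementNet`,
whose plain numpy forward pass is the single prediction path.  A
:class:`ModelBundle` holds the per-element networks, the z-scoring
statistics for features and targets, and the exact ACSF configuration
the networks were trained with, and round-trips through a
self-describing model folder::

    model_dir/
      input.type, input.rad, input.ang    # the ACSF parameter files
      manifest.json                       # target property, units,
                                          # element list, ACSF fingerprint
      model_<El>.json                     # one per element: layer sizes,
                                          # activation, weights, biases,
                                          # standardization statistics

All numbers are serialized through JSON's shortest round-trip float
representation, so a saved-and-reloaded bundle predicts bit-identically.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from .acsf import ACSFConfig, compute_aev, parse_acsf_config, write_acsf_config
from .errors import ContractError, EqChargeError, UnsupportedElementError
from .geometry import LabeledMolecule, Molecule
from .metrics import MetricsReport, error_metrics

__all__ = [
    "Dataset",
    "Hyperparams",
    "ElementNet",
    "ModelBundle",
    "build_dataset",
    "train_model",
    "predict_properties",
    "save_bundle",
    "load_bundle",
]

_ACTIVATIONS = {
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "identity": lambda x: x,
}


@dataclass
class Dataset:
    """Per-element (AEV, target) training pairs."""

    features: dict[str, np.ndarray]
    targets: dict[str, np.ndarray]
    target_property: str
    units: str
    config: ACSFConfig

    @property
    def n_atoms(self) -> int:
        return sum(len(y) for y in self.targets.values())

    def elements(self) -> list[str]:
        return sorted(self.features)


@dataclass
class Hyperparams:
    """Architecture and optimization settings shared by all element nets.

    Defaults: two hidden tanh layers of 64 units, L-BFGS for up to 400
    iterations, 10% of each element's atoms held out for validation
    metrics.  ``solver`` may be "lbfgs" (full-batch, deterministic,
    well-suited to datasets of a few thousand atoms) or "adam"
    (mini-batch, for larger datasets); ``learning_rate`` applies to
    adam only.
    """

    hidden_layers: tuple[int, ...] = (64, 64)
    activation: str = "tanh"
    solver: str = "lbfgs"
    learning_rate: float = 1e-3
    epochs: int = 400
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.solver not in ("lbfgs", "adam"):
            raise ContractError(f"solver must be lbfgs or adam, got {self.solver!r}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ContractError(
                f"validation fraction must be in (0, 1), got {self.validation_fraction}"
            )
        if self.activation not in _ACTIVATIONS:
            raise ContractError(
                f"activation must be one of {sorted(_ACTIVATIONS)}, "
                f"got {self.activation!r}"
            )
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ContractError("epochs must be >= 1 and learning rate > 0")


@dataclass
class ElementNet:
    """A fully-connected network plus the z-scoring statistics of its
    element's features and targets.  ``weights[i]`` has shape
    (fan_in, fan_out); the output layer is linear."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    target_mean: float
    target_scale: float

    def forward(self, aev_matrix: np.ndarray) -> np.ndarray:
        """Raw AEVs (n, L) → property values (n,), destandardized."""
        act = _ACTIVATIONS[self.activation]
        h = (np.atleast_2d(aev_matrix) - self.feature_mean) / self.feature_scale
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = act(h @ w + b)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[:, 0] * self.target_scale + self.target_mean

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]


@dataclass
class ModelBundle:
    """Per-element networks plus the ACSF configuration they expect."""

    nets: dict[str, ElementNet]
    config: ACSFConfig
    target_property: str = "atomic charge"
    units: str = "e"
    validation: dict[str, dict] = field(default_factory=dict)

    def elements(self) -> list[str]:
        return sorted(self.nets)


def build_dataset(
    frames: Sequence[LabeledMolecule],
    config: ACSFConfig,
    target_property: str = "atomic charge",
    units: str = "e",
) -> Dataset:
    """Featurize labelled frames and partition (AEV, target) pairs by
    element; every atom contributes exactly one pair."""
    feats: dict[str, list[np.ndarray]] = {}
    targs: dict[str, list[float]] = {}
    for frame in frames:
        aevs = compute_aev(frame.molecule, config)
        for aev, y in zip(aevs, frame.targets):
            feats.setdefault(aev.symbol, []).append(aev.values)
            targs.setdefault(aev.symbol, []).append(float(y))
    return Dataset(
        features={el: np.vstack(v) for el, v in feats.items()},
        targets={el: np.array(v) for el, v in targs.items()},
        target_property=target_property,
        units=units,
        config=config,
    )


def _element_seed(seed: int, element: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(element.encode())) % (2**31 - 1)


def _standardize(values: np.ndarray, axis=0):
    mean = values.mean(axis=axis)
    scale = values.std(axis=axis)
    scale = np.where(np.asarray(scale) == 0, 1.0, scale)
    return mean, scale


def train_model(
    dataset: Dataset, hyperparams: Hyperparams | None = None, seed: int = 0
) -> ModelBundle:
    """Train one network per element on standardized (AEV, target)
    pairs, minimizing mean-squared error.

    A per-element validation split (``validation_fraction`` of the
    atoms, seeded shuffle) is held out of the fit; its MAE/RMSE/r are
    stored in ``bundle.validation``.  Standardization statistics are
    computed on the training split only.  The same seed, data and
    hyperparameters reproduce the bundle exactly.
    """
    hp = hyperparams or Hyperparams()
    if not dataset.features:
        raise EqChargeError("cannot train on an empty dataset")
    nets: dict[str, ElementNet] = {}
    validation: dict[str, dict] = {}
    for el in dataset.elements():
        X, y = dataset.features[el], dataset.targets[el]
        if len(y) < 2:
            raise EqChargeError(f"element {el}: need at least 2 atoms, got {len(y)}")
        el_seed = _element_seed(seed, el)
        rng = np.random.default_rng(el_seed)
        order = rng.permutation(len(y))
        n_val = max(1, int(round(hp.validation_fraction * len(y))))
        if n_val >= len(y):
            raise EqChargeError(f"element {el}: validation split leaves no training data")
        val_idx, train_idx = order[:n_val], order[n_val:]
        f_mean, f_scale = _standardize(X[train_idx])
        t_mean, t_scale = _standardize(y[train_idx])
        Xs = (X[train_idx] - f_mean) / f_scale
        ys = (y[train_idx] - t_mean) / t_scale

        kwargs = dict(
            hidden_layer_sizes=hp.hidden_layers,
            activation=hp.activation,
            solver=hp.solver,
            max_iter=hp.epochs,
            random_state=el_seed,
            tol=1e-10,
        )
        if hp.solver == "adam":
            # run the full epoch budget instead of early-stopping on tol
            kwargs.update(learning_rate_init=hp.learning_rate, n_iter_no_change=hp.epochs)
        reg = MLPRegressor(**kwargs)
        import warnings as _warnings

        with _warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            _warnings.simplefilter("ignore", ConvergenceWarning)
            reg.fit(Xs, ys)
        if not np.isfinite(reg.loss_):
            raise EqChargeError(
                f"element {el}: non-finite training loss after {reg.n_iter_} epochs"
            )
        net = ElementNet(
            weights=[np.array(w, dtype=float) for w in reg.coefs_],
            biases=[np.array(b, dtype=float).reshape(-1) for b in reg.intercepts_],
            activation=hp.activation,
            feature_mean=np.asarray(f_mean, dtype=float),
            feature_scale=np.asarray(f_scale, dtype=float),
            target_mean=float(t_mean),
            target_scale=float(t_scale),
        )
        nets[el] = net
        report = error_metrics(net.forward(X[val_idx]), y[val_idx])
        validation[el] = report.as_row()
    return ModelBundle(
        nets=nets,
        config=dataset.config,
        target_property=dataset.target_property,
        units=dataset.units,
        validation=validation,
    )


def predict_properties(molecule: Molecule, bundle: ModelBundle) -> np.ndarray:
    """Per-atom property values (bundle units); deterministic."""
    for a, s in enumerate(molecule.symbols):
        if s not in bundle.nets:
            raise UnsupportedElementError(
                f"atom {a + 1} ({s}) has no network in this model bundle"
            )
    aevs = compute_aev(molecule, bundle.config)
    out = np.empty(molecule.N)
    for a, aev in enumerate(aevs):
        out[a] = bundle.nets[aev.symbol].forward(aev.values[None, :])[0]
    return out


def save_bundle(bundle: ModelBundle, dir_path: str | Path) -> None:
    """Write the model folder described in the module docstring."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_acsf_config(bundle.config, dir_path)
    manifest = {
        "format_version": 1,
        "target_property": bundle.target_property,
        "units": bundle.units,
        "elements": bundle.elements(),
        "acsf_fingerprint": bundle.config.fingerprint(),
        "validation": bundle.validation,
    }
    (dir_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for el, net in bundle.nets.items():
        payload = {
            "element": el,
            "layer_sizes": net.layer_sizes,
            "activation": net.activation,
            "weights": [w.tolist() for w in net.weights],
            "biases": [b.tolist() for b in net.biases],
            "feature_mean": net.feature_mean.tolist(),
            "feature_scale": net.feature_scale.tolist(),
            "target_mean": net.target_mean,
            "target_scale": net.target_scale,
        }
        (dir_path / f"model_{el}.json").write_text(json.dumps(payload))


def load_bundle(dir_path: str | Path) -> ModelBundle:
    """Load a model folder; fails if pieces are missing or the ACSF
    files no longer match the fingerprint recorded at save time."""
    dir_path = Path(dir_path)
    required = ["manifest.json", "input.rad", "input.ang", "input.type"]
    missing = [n for n in required if not (dir_path / n).exists()]
    if missing:
        raise EqChargeError(f"model folder {dir_path} is missing: {', '.join(missing)}")
    manifest = json.loads((dir_path / "manifest.json").read_text())
    config = parse_acsf_config(
        dir_path / "input.rad", dir_path / "input.ang", dir_path / "input.type"
    )
    if config.fingerprint() != manifest["acsf_fingerprint"]:
        raise EqChargeError(
            f"ACSF files in {dir_path} do not match the fingerprint stored in "
            "manifest.json; the model folder was modified after saving"
        )
    nets: dict[str, ElementNet] = {}
    missing_nets = [
        el for el in manifest["elements"] if not (dir_path / f"model_{el}.json").exists()
    ]
    if missing_nets:
        raise EqChargeError(
            f"model folder {dir_path} is missing networks for: {missing_nets}"
        )
    for el in manifest["elements"]:
        p = json.loads((dir_path / f"model_{el}.json").read_text())
        nets[el] = ElementNet(
            weights=[np.array(w, dtype=float) for w in p["weights"]],
            biases=[np.array(b, dtype=float) for b in p["biases"]],
            activation=p["activation"],
            feature_mean=np.array(p["feature_mean"], dtype=float),
            feature_scale=np.array(p["feature_scale"], dtype=float),
            target_mean=float(p["target_mean"]),
            target_scale=float(p["target_scale"]),
        )
    return ModelBundle(
        nets=nets,
        config=config,
        target_property=manifest["target_property"],
        units=manifest["units"],
        validation=manifest.get("validation", {}),
    )
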