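"""Network building blocks: feature selection, mask-constrained, and dense layers.

The classifier is a feedforward binary network whose first layers encode
prior splicing knowledge:

* **Feature Selection Layer (FSL)** — a per-feature non-negative
  multiplicative weight ``w`` with an L1 penalty; the output is ``x * w``
  (no bias, no activation).  The learned weights double as feature
  importance scores.
* **Isoform Map Layer (IML) / Gene Map Layer (GML)** — a linear layer whose
  weight matrix ``W`` is elementwise-multiplied by a fixed binary
  relationship matrix ``R`` (exon x isoform, or exon x gene), so only
  annotated exon-to-isoform (or exon-to-gene) connections carry weight.
  Because masking happens in the forward pass, gradients at masked
  coordinates are identically zero and the effective weight ``R * W`` stays
  exactly zero there throughout training.
* **Dense** hidden layers with ReLU and dropout, and a single sigmoid
  output unit (implemented as a linear logit; the sigmoid lives in the loss
  and in :meth:`Network.predict_proba` for numerical stability).

Everything is plain numpy with hand-written backward passes; gradient
correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import RelationshipMatrix

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "NetworkError",
    "FSL",
    "MaskedLinear",
    "Dense",
    "Network",
    "build_network",
    "predict_proba",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("relu", "linear", "sigmoid")


class NetworkError(ValueError):
    pass


@dataclass
class LayerSpec:
    """Description of one layer: kind in {fsl, iml, gml, dense}."""

    kind: str
    width: int = 0  # ignored for fsl/iml/gml (set by features / mask columns)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kind not in ("fsl", "iml", "gml", "dense"):
            raise NetworkError(f"unknown layer kind {self.kind!r}")
        if self.kind == "dense" and self.width < 1:
            raise NetworkError("dense layer needs width >= 1")
        if self.activation not in _ACTIVATIONS:
            raise NetworkError(f"unknown activation {self.activation!r}")


@dataclass
class NetworkSpec:
    """Ordered layer stack ending in an implicit single sigmoid output unit."""

    input_dim: int
    layers: list[LayerSpec] = field(default_factory=list)
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise NetworkError("input_dim must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise NetworkError("dropout_rate must be in [0, 1)")
        for i, spec in enumerate(self.layers):
            if spec.kind == "fsl" and i != 0:
                raise NetworkError("fsl is only allowed as the first layer")
            if spec.kind in ("iml", "gml") and i > 1:
                raise NetworkError(f"{spec.kind} must follow the input or an fsl")
            if spec.kind in ("iml", "gml") and i == 1 and self.layers[0].kind != "fsl":
                raise NetworkError(f"{spec.kind} must follow the input or an fsl")
        widths = [s.width for s in self.layers if s.kind == "dense"]
        if any(b >= a for a, b in zip(widths, widths[1:])):
            raise NetworkError("dense widths must be strictly decreasing")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "dropout_rate": self.dropout_rate,
            "layers": [
                {"kind": s.kind, "width": s.width, "activation": s.activation}
                for s in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkSpec":
        return cls(
            input_dim=int(d["input_dim"]),
            layers=[LayerSpec(**ls) for ls in d.get("layers", [])],
            dropout_rate=float(d.get("dropout_rate", 0.2)),
        )


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return z


def _activate_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "sigmoid":
        return a * (1.0 - a)
    return np.ones_like(z)


class FSL:
    """Per-feature non-negative multiplicative reweighting with L1 penalty."""

    kind = "fsl"

    def __init__(self, n_features: int, l1_weight: float = 0.0005):
        self.w = np.ones(n_features)
        self.l1_weight = float(l1_weight)
        self.grad_w = np.zeros_like(self.w)
        self._x: np.ndarray | None = None

    @property
    def out_dim(self) -> int:
        return self.w.size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.w.size:
            raise NetworkError(f"FSL expects {self.w.size} features, got {x.shape[1]}")
        if training:
            self._x = x
        return x * self.w

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grad_w = (grad_out * self._x).sum(axis=0)
        return grad_out * self.w

    def penalty(self) -> float:
        return self.l1_weight * float(np.abs(self.w).sum())

    def penalty_grad(self) -> np.ndarray:
        # subgradient of lambda*|w|; at the non-negative orthant this is +lambda
        return self.l1_weight * np.sign(self.w)

    def project(self) -> None:
        """Clip weights at zero (non-negativity, applied after each optimizer step)."""
        np.maximum(self.w, 0.0, out=self.w)

    def params(self) -> list[tuple[str, np.ndarray]]:
        return [("w", self.w)]

    def grads(self) -> list[np.ndarray]:
        return [self.grad_w]


class MaskedLinear:
    """Linear layer with effective weight ``R * W``; ``R=None`` means dense."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        mask: np.ndarray | None = None,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
        kind: str = "dense",
    ):
        self.kind = kind
        self.activation = activation
        if mask is not None:
            mask = np.asarray(mask, dtype=float)
            if mask.shape != (n_in, n_out):
                raise NetworkError(
                    f"mask shape {mask.shape} does not match layer ({n_in}, {n_out})"
                )
        self.mask = mask
        rng = rng or np.random.default_rng()
        if mask is None:
            limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
            self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        else:
            # Glorot on the masked graph: each connection's fans are the
            # receiving unit's nonzero fan-in and sending unit's fan-out
            fan_in = np.maximum(mask.sum(axis=0), 1.0)[None, :]
            fan_out = np.maximum(mask.sum(axis=1), 1.0)[:, None]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W = rng.uniform(-1.0, 1.0, size=(n_in, n_out)) * limit
        self.b = np.zeros(n_out)
        self.grad_W = np.zeros_like(self.W)
        self.grad_b = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None
        self._a: np.ndarray | None = None

    @property
    def out_dim(self) -> int:
        return self.b.size

    def effective_weight(self) -> np.ndarray:
        return self.W if self.mask is None else self.mask * self.W

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        w_eff = self.effective_weight()
        z = x @ w_eff + self.b
        a = _activate(z, self.activation)
        if training:
            self._x, self._z, self._a = x, z, a
        return a

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._x is not None and self._z is not None and self._a is not None
        grad_z = grad_out * _activate_grad(self._z, self._a, self.activation)
        self.grad_W = self._x.T @ grad_z
        if self.mask is not None:
            self.grad_W *= self.mask
        self.grad_b = grad_z.sum(axis=0)
        return grad_z @ self.effective_weight().T

    def params(self) -> list[tuple[str, np.ndarray]]:
        return [("W", self.W), ("b", self.b)]

    def grads(self) -> list[np.ndarray]:
        return [self.grad_W, self.grad_b]


class _Dropout:
    """Inverted dropout; active only in training mode with an explicit rng."""

    kind = "dropout"

    def __init__(self, rate: float):
        self.rate = float(rate)
        self._mask: np.ndarray | None = None

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if not training or self.rate == 0.0 or rng is None:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out if self._mask is None else grad_out * self._mask

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []


Dense = MaskedLinear  # a dense layer is a masked layer with no mask


class Network:
    """Feedforward binary classifier assembled from a :class:`NetworkSpec`.

    The final layer produces a single linear logit; probabilities are
    ``sigmoid(logit)``.  ``feature_ids``, when given, lets prediction check
    and reorder incoming feature columns.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        layers: list,
        feature_ids: list[str] | None = None,
    ):
        self.spec = spec
        self.layers = layers
        self.feature_ids = feature_ids

    # -- introspection ------------------------------------------------------

    @property
    def fsl(self) -> FSL | None:
        first = self.layers[0] if self.layers else None
        return first if isinstance(first, FSL) else None

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for _, p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward -------------------------------------------------

    def forward_logits(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        if h.ndim == 1:
            h = h[None, :]
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                h = layer.forward(h, training=training, rng=rng)
            else:
                h = layer.forward(h, training=training)
        return h[:, 0]

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        """Propagate d(loss)/d(logit) back to the input; fills layer grads."""
        g = np.asarray(grad_logits, dtype=float)[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.forward_logits(X, training=False)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        """Per-sample gradient of the pre-sigmoid logit w.r.t. each input feature."""
        X = np.asarray(X, dtype=float)
        # caching forward pass without dropout, then backprop a unit gradient
        # per sample (rows are independent, so one pass suffices)
        h = X
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                continue
            h = layer.forward(h, training=True)
        g = np.ones((X.shape[0], 1))
        for layer in reversed(self.layers):
            if isinstance(layer, _Dropout):
                continue
            g = layer.backward(g)
        return g

    def loss_and_backward(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None
    ) -> float:
        """Mean binary cross-entropy (+ FSL penalty) and a full backward pass.

        Uses the logit formulation ``log(1+e^z) - y z`` for stability.
        Dropout is active only when an ``rng`` is supplied (i.e. during
        training steps); evaluation passes never sample dropout masks.
        """
        y = np.asarray(y, dtype=float)
        z = self.forward_logits(X, training=True, rng=rng)
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        self.backward((p - y) / y.size)
        if self.fsl is not None:
            loss += self.fsl.penalty()
            self.fsl.grad_w += self.fsl.penalty_grad()
        return loss


def build_network(
    spec: NetworkSpec,
    masks: Mapping[int, RelationshipMatrix] | None = None,
    seed: int = 0,
    feature_ids: list[str] | None = None,
    fsl_l1: float = 0.0005,
) -> Network:
    """Instantiate a :class:`Network` from a spec with seeded initialization.

    ``masks`` maps the index of each iml/gml entry in ``spec.layers`` to its
    relationship matrix; the mask's row count must equal the incoming
    dimension.  Dense weights are Glorot-uniform, biases zero, FSL weights
    one.  Dropout (rate from the spec) follows each hidden dense activation.
    """
    masks = masks or {}
    rng = np.random.default_rng(seed)
    layers: list = []
    dim = spec.input_dim
    for i, ls in enumerate(spec.layers):
        if ls.kind == "fsl":
            layers.append(FSL(dim, l1_weight=fsl_l1))
        elif ls.kind in ("iml", "gml"):
            if i not in masks:
                raise NetworkError(f"layer {i} ({ls.kind}) has no mask")
            rm = masks[i]
            if len(rm.row_ids) != dim:
                raise NetworkError(
                    f"mask for layer {i} has {len(rm.row_ids)} rows, expected {dim}"
                )
            layers.append(
                MaskedLinear(
                    dim,
                    len(rm.col_ids),
                    mask=rm.entries.astype(float),
                    activation=ls.activation,
                    rng=rng,
                    kind=ls.kind,
                )
            )
            dim = len(rm.col_ids)
        else:  # dense
            layers.append(
                MaskedLinear(dim, ls.width, activation=ls.activation, rng=rng)
            )
            dim = ls.width
            if spec.dropout_rate > 0:
                layers.append(_Dropout(spec.dropout_rate))
    # output unit: linear logit (sigmoid applied in loss / predict_proba)
    layers.append(MaskedLinear(dim, 1, activation="linear", rng=rng, kind="output"))
    return Network(spec, layers, feature_ids=feature_ids)


def predict_proba(model: Network, X, feature_ids: Sequence[str] | None = None) -> np.ndarray:
    """Predict P(class 1) for rows of ``X``, aligning features by id when known.

    When both the model and the caller provide feature ids, the columns of
    ``X`` are reordered to the training order; missing or extra ids raise.
    """
    if feature_ids is not None and model.feature_ids is not None:
        missing = [f for f in model.feature_ids if f not in set(feature_ids)]
        extra = [f for f in feature_ids if f not in set(model.feature_ids)]
        if missing or extra:
            raise NetworkError(
                f"feature mismatch; missing from input: {missing[:5]}, "
                f"unexpected: {extra[:5]}"
            )
        index = {f: j for j, f in enumerate(feature_ids)}
        X = np.asarray(X)[:, [index[f] for f in model.feature_ids]]
    return model.predict_proba(np.asarray(X))


# ---------------------------------------------------------------------------
# Serialization (flat NPZ container with a JSON header)


def save_model(model: Network, path: str) -> None:
    """Save spec, feature ids, parameters and masks to a flat NPZ container."""
    arrays: dict[str, np.ndarray] = {}
    descr: list[dict] = []
    for li, layer in enumerate(model.layers):
        entry: dict = {"kind": layer.kind, "params": []}
        if isinstance(layer, MaskedLinear):
            entry["activation"] = layer.activation
            if layer.mask is not None:
                arrays[f"layer{li}_mask"] = layer.mask
                entry["mask"] = f"layer{li}_mask"
        if isinstance(layer, FSL):
            entry["l1_weight"] = layer.l1_weight
        if isinstance(layer, _Dropout):
            entry["rate"] = layer.rate
        for name, p in layer.params():
            key = f"layer{li}_{name}"
            arrays[key] = p
            entry["params"].append(key)
        descr.append(entry)
    header = {
        "spec": model.spec.to_dict(),
        "feature_ids": model.feature_ids,
        "layers": descr,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> Network:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"].tobytes()).decode())
        spec = NetworkSpec.from_dict(header["spec"])
        layers: list = []
        for li, entry in enumerate(header["layers"]):
            kind = entry["kind"]
            if kind == "fsl":
                w = data[entry["params"][0]]
                layer = FSL(w.size, l1_weight=entry["l1_weight"])
                layer.w = w.copy()
            elif kind == "dropout":
                layer = _Dropout(entry["rate"])
            else:
                W = data[entry["params"][0]]
                b = data[entry["params"][1]]
                mask = data[entry["mask"]] if "mask" in entry else None
                layer = MaskedLinear(
                    W.shape[0],
                    W.shape[1],
                    mask=mask,
                    activation=entry["activation"],
                    kind=kind,
                )
                layer.W = W.copy()
                layer.b = b.copy()
            layers.append(layer)
        return Network(spec, layers, feature_ids=header["feature_ids"])
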