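"""Shared network components for the three transfer-learning techniques.

All three techniques use a common feed-forward feature extractor on the
seven vegetation-index inputs.  A linear predictor maps the latent features
to a relative-maturity-date estimate (mean-squared-error loss); one or more
two-class domain classifiers map the same latent features to log
source/target probabilities (negative-log-likelihood loss).  Adversarial
alignment couples the classification loss to the extractor through a
gradient reversal layer: the forward pass is the identity, while during
backpropagation the classification loss's sensitivity to the extractor
parameters is multiplied by -lambda.

The networks are tiny (tens of thousands of parameters), so forward and
backward passes are written directly in numpy; every operation is a pure
function of its inputs and the seeded initialiser, which keeps training
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ArchitectureSpec:
    """Layer widths and training-structure constants.

    ``extractor_widths`` runs from the 7 input features to the latent width;
    the predictor ends in 1 output and the classifier in 2 logits.
    ``freeze_depth`` leading extractor layers are held fixed during
    fine-tuning; ``grl_lambda`` is the magnitude of the negative constant
    applied by the gradient reversal layer.
    """

    extractor_widths: tuple = (7, 64, 64, 64, 32)
    predictor_widths: tuple = (32, 1)
    classifier_widths: tuple = (32, 16, 2)
    activation: str = "tanh"
    freeze_depth: int = 3
    grl_lambda: float = 1.0

    def __post_init__(self):
        for name in ("extractor_widths", "predictor_widths", "classifier_widths"):
            widths = getattr(self, name)
            if len(widths) < 2 or any(w < 1 for w in widths):
                raise ValueError(f"{name} must be >= 2 positive widths")
        if self.predictor_widths[-1] != 1:
            raise ValueError("predictor must end in width 1")
        if self.classifier_widths[-1] != 2:
            raise ValueError("classifier must end in width 2")
        if self.predictor_widths[0] != self.extractor_widths[-1]:
            raise ValueError("predictor input width must match extractor output")
        if self.classifier_widths[0] != self.extractor_widths[-1]:
            raise ValueError("classifier input width must match extractor output")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")
        n_extractor_layers = len(self.extractor_widths) - 1
        if not 0 <= self.freeze_depth < n_extractor_layers:
            raise ValueError(
                "freeze_depth must leave at least one tunable extractor layer"
            )
        if self.grl_lambda < 0:
            raise ValueError("grl_lambda must be >= 0")

    @property
    def n_extractor_layers(self) -> int:
        return len(self.extractor_widths) - 1


@dataclass
class LinearParams:
    W: np.ndarray
    b: np.ndarray

    def copy(self) -> "LinearParams":
        return LinearParams(self.W.copy(), self.b.copy())


@dataclass
class NetworkParams:
    """Extractor, predictor and per-source domain-classifier parameters."""

    extractor: list
    predictor: list
    classifiers: list = field(default_factory=list)  # list of layer lists

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            extractor=[p.copy() for p in self.extractor],
            predictor=[p.copy() for p in self.predictor],
            classifiers=[[p.copy() for p in clf] for clf in self.classifiers],
        )

    def flat(self):
        """All parameter arrays in a stable order (for the optimiser)."""
        arrays = []
        for layer in self.extractor + self.predictor:
            arrays += [layer.W, layer.b]
        for clf in self.classifiers:
            for layer in clf:
                arrays += [layer.W, layer.b]
        return arrays


def _init_layers(widths, rng) -> list:
    """Fan-in-scaled uniform initialisation, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    layers = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        layers.append(
            LinearParams(
                W=rng.uniform(-bound, bound, size=(fan_in, fan_out)),
                b=rng.uniform(-bound, bound, size=fan_out),
            )
        )
    return layers


def init_network(spec: ArchitectureSpec, seed, n_classifiers: int = 1) -> NetworkParams:
    """Seed-reproducible random initialisation of all parameter sets."""
    if n_classifiers < 1:
        raise ValueError("n_classifiers must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return NetworkParams(
        extractor=_init_layers(spec.extractor_widths, rng),
        predictor=_init_layers(spec.predictor_widths, rng),
        classifiers=[
            _init_layers(spec.classifier_widths, rng) for _ in range(n_classifiers)
        ],
    )


# ---------------------------------------------------------------------------
# forward / backward primitives


def _act(z, kind):
    if kind == "relu":
        return np.maximum(z, 0.0)
    return np.tanh(z)


def _act_grad(z, kind):
    if kind == "relu":
        return (z > 0.0).astype(float)
    return 1.0 - np.tanh(z) ** 2


def _mlp_forward(x, layers, activation, hidden_act_only=False):
    """Forward pass; returns (output, caches) for the backward pass.

    ``hidden_act_only`` leaves the final layer linear (predictor and
    classifier logits); otherwise the activation follows every layer
    (extractor).
    """
    caches = []
    h = np.asarray(x, dtype=float)
    for i, layer in enumerate(layers):
        if h.shape[-1] != layer.W.shape[0]:
            raise ValueError(
                f"input width {h.shape[-1]} does not match layer width {layer.W.shape[0]}"
            )
        z = h @ layer.W + layer.b
        last = i == len(layers) - 1
        out = z if (hidden_act_only and last) else _act(z, activation)
        caches.append((h, z))
        h = out
    return h, caches


def _mlp_backward(g_out, layers, caches, activation, hidden_act_only=False):
    """Backward pass; returns (grad wrt input, [LinearParams grads])."""
    grads = [None] * len(layers)
    g = g_out
    for i in range(len(layers) - 1, -1, -1):
        h_in, z = caches[i]
        last = i == len(layers) - 1
        if not (hidden_act_only and last):
            g = g * _act_grad(z, activation)
        grads[i] = LinearParams(W=h_in.T @ g, b=g.sum(axis=0))
        g = g @ layers[i].W.T
    return g, grads


def forward_features(x, extractor, activation: str = "relu") -> np.ndarray:
    """Latent feature vectors for a batch of standardized inputs."""
    out, _ = _mlp_forward(x, extractor, activation)
    return out


def predict_rmd(latent, predictor, activation: str = "relu") -> np.ndarray:
    """Predicted relative maturity dates (days), one per latent row."""
    out, _ = _mlp_forward(latent, predictor, activation, hidden_act_only=True)
    return out[..., 0]


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def domain_logprobs(latent, classifier, activation: str = "relu") -> np.ndarray:
    """Log-probabilities over {source=0, target=1} for each latent row."""
    logits, _ = _mlp_forward(latent, classifier, activation, hidden_act_only=True)
    return log_softmax(logits)


def grl_connect(latent: np.ndarray, grl_lambda: float) -> np.ndarray:
    """Gradient reversal layer: identity on the forward evaluation.

    During gradient-based training the classification loss's sensitivity to
    everything upstream of this connector is multiplied by ``-grl_lambda``
    (see the training module); parameters downstream (the domain classifier)
    see unreversed gradients.  With lambda = 0 the extractor is fully
    decoupled from the classification loss.
    """
    if grl_lambda < 0:
        raise ValueError("grl_lambda must be >= 0")
    return np.asarray(latent, dtype=float)


# ---------------------------------------------------------------------------
# losses


def mse_loss(predicted, observed) -> float:
    """Mean squared error between predicted and observed RMD (days^2)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal shapes")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.mean((predicted - observed) ** 2))


def mse_loss_grad(predicted, observed) -> np.ndarray:
    return 2.0 * (np.asarray(predicted) - np.asarray(observed)) / len(predicted)


def nll_loss(logprobs, labels) -> float:
    """Mean negative log-likelihood of the given {0,1} labels (nats)."""
    logprobs = np.asarray(logprobs, dtype=float)
    labels = np.asarray(labels)
    if logprobs.ndim != 2 or logprobs.shape[1] != 2:
        raise ValueError("logprobs must be (n, 2)")
    if len(labels) != len(logprobs):
        raise ValueError("labels length must match logprobs rows")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return float(-np.mean(logprobs[np.arange(len(labels)), labels]))


def nll_loss_grad(logprobs, labels) -> np.ndarray:
    """Gradient of nll_loss with respect to the log-probabilities."""
    g = np.zeros_like(logprobs)
    g[np.arange(len(labels)), labels] = -1.0 / len(labels)
    return g


def logsoftmax_backward(g_logprobs, logprobs) -> np.ndarray:
    """Pull a log-probability gradient back to the logits."""
    return g_logprobs - np.exp(logprobs) * g_logprobs.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# input standardisation


@dataclass
class Standardizer:
    """Per-feature zero-mean/unit-variance scaler fitted on source training data."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        scale = X.std(axis=0)
        return cls(mean=X.mean(axis=0), scale=np.where(scale < 1e-8, 1.0, scale))

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale
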