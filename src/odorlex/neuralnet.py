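"""From-scratch sigmoid feed-forward networks with momentum SGD.

The training rule is classical backpropagation with a momentum term,

    w(tau+1) = w(tau) - eta * dE/dw + alpha * (w(tau) - w(tau-1)),

where both the learning rate eta and the momentum coefficient alpha decay
geometrically per epoch (factor 0.99 by default).  The loss is the mean
squared error over output neurons plus an L2 weight penalty lambda * sum(w^2)
(biases unpenalized).  Updates are per-sample (pure stochastic), with the
sample order reshuffled each epoch from the run seed.

Three networks are built from this engine: a sandglass autoencoder that
compresses a mass spectrum to a low-dimensional feature vector at its
bottleneck, a mapping network from feature vector to odor-cluster labels,
and their concatenation -- the end-to-end predictor -- whose continuous
outputs a fitted step-function threshold converts to 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NetworkError(ValueError):
    """Raised for invalid network structure or divergent training."""


@dataclass
class NetworkSpec:
    """Layer sizes, input first; sigmoid on every non-input layer."""

    layer_sizes: list[int]

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise NetworkError("a network needs at least input and output layers")
        if any(s < 1 for s in self.layer_sizes):
            raise NetworkError("layer sizes must be >= 1")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)


@dataclass
class Network:
    """Weights and biases for a :class:`NetworkSpec`.

    ``weights[l]`` has shape (size[l+1], size[l]); ``biases[l]`` has shape
    (size[l+1],).
    """

    spec: NetworkSpec
    weights: list[np.ndarray] = field(repr=False)
    biases: list[np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        sizes = self.spec.layer_sizes
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise NetworkError("parameter count inconsistent with spec")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise NetworkError(f"layer {l}: shape mismatch")

    def copy(self) -> "Network":
        return Network(
            NetworkSpec(list(self.spec.layer_sizes)),
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
        )


@dataclass
class TrainingConfig:
    """Hyperparameters of one SGD run.

    eta0/alpha0 are the epoch-0 learning rate and momentum; both decay as
    value * decay**epoch.  ``lam`` is the L2 penalty constant.
    """

    eta0: float
    alpha0: float = 0.0
    decay: float = 0.99
    lam: float = 0.0
    norm_p: str = "L2"
    epochs: int = 100
    seed: int = 0
    init_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.eta0 < 0 or self.alpha0 < 0 or self.lam < 0:
            raise NetworkError("eta0, alpha0, lam must be non-negative")
        if not 0 < self.decay <= 1:
            raise NetworkError("decay must be in (0, 1]")
        if self.epochs < 1:
            raise NetworkError("epochs must be >= 1")
        if self.norm_p != "L2":
            raise NetworkError(f"unsupported regularization norm: {self.norm_p!r}")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_network(spec: NetworkSpec, seed: int, sigma: float = 0.1) -> Network:
    """Gaussian N(0, sigma^2) weights from the seeded generator; zero biases."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights = [rng.normal(0.0, sigma, size=(sizes[l + 1], sizes[l])) for l in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]
    return Network(spec, weights, biases)


def forward(net: Network, x: np.ndarray) -> list[np.ndarray]:
    """All layer activations for one input vector (input included)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.spec.layer_sizes[0],):
        raise NetworkError(
            f"input size {x.shape} != ({net.spec.layer_sizes[0]},)"
        )
    if not np.isfinite(x).all():
        raise NetworkError("non-finite input")
    acts = [x]
    for W, b in zip(net.weights, net.biases):
        acts.append(sigmoid(W @ acts[-1] + b))
    return acts


def forward_batch(net: Network, X: np.ndarray) -> np.ndarray:
    """Output activations for a (n_samples, n_in) batch."""
    A = np.asarray(X, dtype=float)
    for W, b in zip(net.weights, net.biases):
        A = sigmoid(A @ W.T + b)
    return A


def loss(net: Network, X: np.ndarray, Y: np.ndarray, lam: float = 0.0,
         norm_p: str = "L2") -> float:
    """Mean squared error over output neurons and batch + L2 weight penalty."""
    if norm_p != "L2":
        raise NetworkError(f"unsupported regularization norm: {norm_p!r}")
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    if X.shape[0] == 0:
        raise NetworkError("empty batch")
    out = forward_batch(net, X)
    data = float(np.mean((out - Y) ** 2))
    penalty = lam * sum(float((W ** 2).sum()) for W in net.weights)
    return data + penalty


def _gradients(net: Network, x: np.ndarray, y: np.ndarray, lam: float
               ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backprop gradients of the per-sample regularized loss."""
    acts = forward(net, x)
    n_out = net.spec.layer_sizes[-1]
    delta = (2.0 / n_out) * (acts[-1] - y) * acts[-1] * (1.0 - acts[-1])
    gw: list[np.ndarray] = [None] * len(net.weights)
    gb: list[np.ndarray] = [None] * len(net.biases)
    for l in range(len(net.weights) - 1, -1, -1):
        gw[l] = np.outer(delta, acts[l]) + 2.0 * lam * net.weights[l]
        gb[l] = delta.copy()
        if l > 0:
            delta = (net.weights[l].T @ delta) * acts[l] * (1.0 - acts[l])
    return gw, gb


def sgd_step(
    net: Network,
    velocity: tuple[list[np.ndarray], list[np.ndarray]] | None,
    sample: tuple[np.ndarray, np.ndarray],
    eta: float,
    alpha: float,
    lam: float = 0.0,
) -> tuple[Network, tuple[list[np.ndarray], list[np.ndarray]]]:
    """One momentum-SGD update on a single (x, y) sample, in place.

    The applied update is delta = -eta * grad + alpha * previous delta,
    for every weight matrix and bias vector; the returned velocity feeds
    the next step's momentum term.
    """
    x, y = sample
    if velocity is None:
        velocity = (
            [np.zeros_like(W) for W in net.weights],
            [np.zeros_like(b) for b in net.biases],
        )
    gw, gb = _gradients(net, np.asarray(x, float), np.asarray(y, float), lam)
    vw, vb = velocity
    for l in range(len(net.weights)):
        if not (np.isfinite(gw[l]).all() and np.isfinite(gb[l]).all()):
            raise NetworkError("non-finite gradient: training diverged")
        vw[l] = -eta * gw[l] + alpha * vw[l]
        vb[l] = -eta * gb[l] + alpha * vb[l]
        net.weights[l] += vw[l]
        net.biases[l] += vb[l]
    return net, (vw, vb)


def train(net: Network, X: np.ndarray, Y: np.ndarray, cfg: TrainingConfig
          ) -> tuple[Network, list[float]]:
    """Momentum SGD over epochs with geometric eta/alpha decay.

    Each epoch reshuffles the samples (seeded), applies a per-sample
    update with eta = eta0*decay**epoch and alpha = alpha0*decay**epoch,
    and records the full-batch loss.  Returns the trained network and the
    per-epoch loss trace.
    """
    X, Y = np.atleast_2d(np.asarray(X, float)), np.atleast_2d(np.asarray(Y, float))
    if X.shape[0] == 0:
        raise NetworkError("no training samples")
    if X.shape[0] != Y.shape[0]:
        raise NetworkError("inputs/targets length mismatch")
    rng = np.random.default_rng(cfg.seed)
    net = net.copy()
    velocity = None
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        eta = cfg.eta0 * cfg.decay ** epoch
        alpha = cfg.alpha0 * cfg.decay ** epoch
        for i in rng.permutation(X.shape[0]):
            net, velocity = sgd_step(net, velocity, (X[i], Y[i]), eta, alpha, cfg.lam)
        epoch_loss = loss(net, X, Y, cfg.lam)
        if not np.isfinite(epoch_loss):
            raise NetworkError(f"loss diverged at epoch {epoch}")
        trace.append(epoch_loss)
    return net, trace


def autoencoder_spec(input_dim: int = 212, hidden: int = 85, bottleneck: int = 30
                     ) -> NetworkSpec:
    """Five-layer sandglass spec [in, hidden, bottleneck, hidden, in]."""
    return NetworkSpec([input_dim, hidden, bottleneck, hidden, input_dim])


def mapper_spec(bottleneck: int = 30, h1: int = 50, h2: int = 20, n_out: int = 20
                ) -> NetworkSpec:
    """Four-layer feature-to-labels spec [bottleneck, h1, h2, n_out]."""
    return NetworkSpec([bottleneck, h1, h2, n_out])


def train_autoencoder(X: np.ndarray, spec: NetworkSpec, cfg: TrainingConfig
                      ) -> tuple[Network, Network, list[float]]:
    """Train input -> input; return (encoder half, full autoencoder, trace).

    The spec must be symmetric with an odd layer count; the middle layer
    is the bottleneck whose activations are the compressed feature
    vectors.  A bottleneck at least as wide as the input trains fine but
    compresses nothing, so it only warns.
    """
    sizes = spec.layer_sizes
    if len(sizes) % 2 == 0 or sizes != sizes[::-1]:
        raise NetworkError("autoencoder spec must be symmetric with odd layer count")
    mid = len(sizes) // 2
    if sizes[mid] >= sizes[0]:
        import warnings

        warnings.warn("bottleneck >= input size: no compression", stacklevel=2)
    net = init_network(spec, cfg.seed, cfg.init_sigma)
    trained, trace = train(net, X, X, cfg)
    encoder = Network(
        NetworkSpec(sizes[: mid + 1]),
        [W.copy() for W in trained.weights[:mid]],
        [b.copy() for b in trained.biases[:mid]],
    )
    return encoder, trained, trace


def encode(encoder: Network, X: np.ndarray) -> np.ndarray:
    """Bottleneck feature vectors for a batch of spectra."""
    return forward_batch(encoder, np.atleast_2d(X))


def assemble_predictor(encoder: Network, mapper: Network) -> Network:
    """Concatenate encoder and mapper into one end-to-end network.

    The assembled forward pass equals mapper(encode(x)) exactly (same
    floating-point operations, shared order).
    """
    if encoder.spec.layer_sizes[-1] != mapper.spec.layer_sizes[0]:
        raise NetworkError(
            f"encoder output {encoder.spec.layer_sizes[-1]} != "
            f"mapper input {mapper.spec.layer_sizes[0]}"
        )
    return Network(
        NetworkSpec(encoder.spec.layer_sizes + mapper.spec.layer_sizes[1:]),
        [W.copy() for W in encoder.weights + mapper.weights],
        [b.copy() for b in encoder.biases + mapper.biases],
    )


@dataclass
class ThresholdedPredictor:
    """Assembled network + the step-function threshold applied to outputs."""

    net: Network
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise NetworkError("threshold must lie strictly inside (0, 1)")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary predictions: 1 where the network output exceeds theta."""
        return (forward_batch(self.net, np.atleast_2d(X)) > self.theta).astype(np.int8)


DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


def fit_threshold(
    net: Network,
    X: np.ndarray,
    Y: np.ndarray,
    grid: np.ndarray | None = None,
) -> ThresholdedPredictor:
    """Pick the grid threshold maximizing balanced accuracy on training data.

    One global threshold is shared across all outputs; the objective is
    the mean of the pooled true-positive and true-negative rates (plain
    concordance would collapse to all-zeros on a ~98%-sparse target).
    Ties resolve to the smallest threshold.
    """
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, float)
    if grid.size == 0 or grid.min() <= 0 or grid.max() >= 1:
        raise NetworkError("threshold grid must be non-empty and inside (0, 1)")
    scores = forward_batch(net, np.atleast_2d(X)).ravel()
    truth = np.atleast_2d(Y).ravel().astype(bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    best_theta, best_obj = None, -np.inf
    for theta in np.sort(grid):
        pred = scores > theta
        tp = (pred & truth).sum() / n_pos if n_pos else np.nan
        tn = (~pred & ~truth).sum() / n_neg if n_neg else np.nan
        obj = np.nanmean([tp, tn])
        if obj > best_obj:  # strict: ties keep the smallest theta
            best_theta, best_obj = float(theta), float(obj)
    return ThresholdedPredictor(net, best_theta)


def save_network(net: Network, path, *, config: dict | None = None) -> None:
    """Serialize a network as a documented JSON container."""
    import json

    payload = {
        "format": "odorlex-network-v1",
        "layer_sizes": net.spec.layer_sizes,
        "weights": [W.tolist() for W in net.weights],  # row-major per layer
        "biases": [b.tolist() for b in net.biases],
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_network(path) -> Network:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "odorlex-network-v1":
        raise NetworkError("not an odorlex network file")
    return Network(
        NetworkSpec(payload["layer_sizes"]),
        [np.array(W, float) for W in payload["weights"]],
        [np.array(b, float) for b in payload["biases"]],
    )
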