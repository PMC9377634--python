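"""Feedforward neural-network estimators of theta and adaptive training.

Two architectures are used, both taking the raw SFS vector as input:

* a *linear* network — no hidden layer, no bias — whose prediction is by
  construction a linear function ``w' S`` of the spectrum, directly comparable
  to the model-based linear estimators; and
* a one-hidden-layer network with ReLU hidden units, bias terms and a linear
  output, flexible enough to change its effective linear weighting with the
  shape of the observed spectrum (and thereby with the local recombination
  rate).

Networks are trained by minimizing the weighted relative squared error

    mean_i  ((theta_hat_i - theta_i) / theta_i)^2 * omega(theta_i)

with the Adam optimizer.  ``omega`` is piecewise constant over six theta
subsets whose boundaries equalize the total variation of Fu's optimal
coefficients (:func:`compute_subset_boundaries`).

The *adaptive* procedure (:func:`adaptive_train`) retrains the network in
rounds: after each round the per-subset normalized MSE of the network is
compared on a held-out validation set against the best of Watterson's
estimator, the iterative Fu and Futschik estimators and the linear network
(the "floors" ``b_k``); subsets where the network lags get their loss weight
increased by a randomized step proportional to the normalized gap, and
training resumes.  The loop stops once the network is within a factor 1.02 of
every floor.  The result is a single estimator that tracks the best
model-based estimator at low and high recombination while improving on both
at intermediate rates.

Everything here is plain numpy; the networks are small enough that a deep
learning framework would add nothing but weight.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .estimators import (
    FuModel,
    IterativeEstimator,
    WattersonEstimator,
    _blue_batch,
)
from .evaluate import subset_nmse
from .sfs import SFSDataset, SiteFrequencySpectrum

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "AdaptiveConfig",
    "AdaptiveState",
    "TrainedEstimator",
    "build_network",
    "train_network",
    "compute_subset_boundaries",
    "subset_weight_function",
    "omega_update",
    "adaptive_train",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of a feedforward theta estimator.

    ``hidden = 0`` with ``bias = False`` is the pure linear network.  For the
    hidden-layer network at least ``2 n`` hidden nodes are advisable; below
    ``n`` nodes adaptive training often fails to terminate (a warning is
    logged).
    """

    n_input: int
    hidden: int = 0
    bias: bool = False
    activation: str = "relu"
    #: subtract the network's output at the empty spectrum, so that
    #: theta_hat(0) = 0 exactly.  An empty SFS is perfect evidence for
    #: theta ~ 0 and every model-based estimator maps it to 0; without the
    #: anchor the network's residual bias c at S = 0 contributes c^2/theta
    #: to the normalized MSE of the lowest theta subset, which diverges as
    #: theta -> 0 and makes the adaptive stopping rule unattainable.
    anchor_zero: bool = True

    def __post_init__(self) -> None:
        if self.n_input < 1 or self.hidden < 0:
            raise ValueError("invalid network spec")
        if self.hidden == 0 and self.bias:
            raise ValueError("the linear network has no bias node")
        if self.activation != "relu":
            raise ValueError("only 'relu' hidden activation is supported")
        if 0 < self.hidden < self.n_input:
            logger.warning(
                "hidden=%d is below the input width %d; training may not "
                "terminate", self.hidden, self.n_input,
            )

    @property
    def n(self) -> int:
        return self.n_input + 1


@dataclass
class TrainingConfig:
    """Adam / minibatch settings for network fitting.

    ``theta_floor`` clamps the denominator of the relative loss so that the
    rare near-zero theta draws do not dominate the gradient.
    ``refine_epochs`` is the (shorter) epoch budget used when training resumes
    from existing weights inside the adaptive loop.
    """

    epochs: int = 50
    refine_epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    refine_learning_rate: float = 3e-4
    patience: int = 5
    #: reduce-on-plateau: when validation loss stalls for ``patience`` epochs,
    #: restore the best weights, multiply the learning rate by
    #: ``plateau_decay`` and continue, up to ``plateau_stages`` reductions.
    plateau_decay: float = 0.3
    plateau_stages: int = 2
    theta_floor: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


class TrainedEstimator:
    """A (possibly untrained) network with deterministic prediction.

    Callable on an SFS replicate matrix, returning one estimate per row.  Raw
    network output is reported without clamping; negative predictions and
    predictions outside the training range are flagged by
    :meth:`predict_info`.
    """

    def __init__(self, spec: NetworkSpec, params: dict[str, np.ndarray],
                 name: str = "network", training_meta: dict | None = None):
        self.spec = spec
        self.params = params
        self.name = name
        self.training_meta = training_meta or {}

    def __call__(self, sfs_matrix: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(sfs_matrix, dtype=float))
        if x.shape[1] != self.spec.n_input:
            raise ValueError(
                f"expected {self.spec.n_input} SFS columns, got {x.shape[1]}"
            )
        return np.ravel(self._forward(x)[0])

    def _forward(self, x: np.ndarray):
        p = self.params
        if self.spec.hidden == 0:
            return x @ p["w"], None
        pre = x @ p["W1"] + p["b1"]
        h = np.maximum(pre, 0.0)
        out = h @ p["W2"] + p["b2"]
        if self.spec.anchor_zero:
            out = out - np.maximum(p["b1"], 0.0) @ p["W2"] - p["b2"]
        return out, (pre, h)

    def predict(self, sfs) -> float:
        """Point estimate for a single SFS."""
        arr = (sfs.counts if isinstance(sfs, SiteFrequencySpectrum)
               else np.asarray(sfs))
        return float(self(arr[None, :])[0])

    def predict_info(self, sfs, training_range: tuple[float, float] = (0.0, 100.0)
                     ) -> tuple[float, bool, bool]:
        """Estimate plus flags: (value, is_negative, outside_training_range).

        Networks can learn the simulation range of theta, so estimates beyond
        it deserve caution.
        """
        value = self.predict(sfs)
        return value, value < 0.0, not training_range[0] <= value <= training_range[1]

    def copy(self) -> "TrainedEstimator":
        return TrainedEstimator(
            self.spec, {k: v.copy() for k, v in self.params.items()},
            self.name, dict(self.training_meta),
        )

    def save(self, path) -> None:
        """Portable container: architecture JSON + weight arrays (npz)."""
        meta = json.dumps({
            "spec": {"n_input": self.spec.n_input, "hidden": self.spec.hidden,
                     "bias": self.spec.bias, "activation": self.spec.activation},
            "name": self.name,
            "training_meta": _jsonable(self.training_meta),
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "TrainedEstimator":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(NetworkSpec(**meta["spec"]), params, meta["name"],
                   meta["training_meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def build_network(spec: NetworkSpec, seed: int | None = None,
                  name: str | None = None) -> TrainedEstimator:
    """Initialize an untrained network (He-scaled Gaussian weights)."""
    rng = np.random.default_rng(seed)
    if spec.hidden == 0:
        params = {"w": rng.normal(0.0, 1.0 / np.sqrt(spec.n_input),
                                  size=spec.n_input)}
        default = "linear_nn"
    else:
        params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / spec.n_input),
                             size=(spec.n_input, spec.hidden)),
            "b1": np.zeros(spec.hidden),
            "W2": rng.normal(0.0, np.sqrt(2.0 / spec.hidden),
                             size=(spec.hidden, 1)),
            "b2": np.zeros(1),
        }
        default = "adaptive_nn"
    return TrainedEstimator(spec, params, name or default)


def _loss_weights(theta: np.ndarray, weight_fn, floor: float) -> np.ndarray:
    omega = np.ones_like(theta) if weight_fn is None else weight_fn(theta)
    return omega / np.maximum(theta, floor) ** 2


def _weighted_loss(pred: np.ndarray, theta: np.ndarray, w: np.ndarray) -> float:
    return float(np.mean(w * (np.ravel(pred) - theta) ** 2))


def train_network(
    net: TrainedEstimator,
    train: SFSDataset,
    val: SFSDataset,
    weights: Callable[[np.ndarray], np.ndarray] | None = None,
    config: TrainingConfig = TrainingConfig(),
    seed: int | None = None,
    epochs: int | None = None,
) -> TrainedEstimator:
    """Fit a network by Adam on the weighted relative squared error.

    ``weights`` maps true theta values to loss weights ``omega(theta)``
    (defaults to 1, reducing the loss to the plain mean relative squared
    error).  Returns a new :class:`TrainedEstimator`; the input network only
    provides the initial parameters.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n_epochs = cfg.epochs if epochs is None else epochs
    x = np.asarray(train.sfs, dtype=float)
    y = np.asarray(train.theta, dtype=float)
    w = _loss_weights(y, weights, cfg.theta_floor)
    xv = np.asarray(val.sfs, dtype=float)
    yv = np.asarray(val.theta, dtype=float)
    wv = _loss_weights(yv, weights, cfg.theta_floor)

    est = net.copy()
    params = est.params
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v2 = {k: np.zeros_like(v) for k, v in params.items()}
    t_step = 0
    best_loss = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    stall = 0
    lr = cfg.learning_rate
    stages_left = cfg.plateau_stages

    n_rows = len(y)
    for epoch in range(n_epochs):
        order = rng.permutation(n_rows)
        for lo in range(0, n_rows, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb, wb = x[idx], y[idx], w[idx]
            pred, cache = est._forward(xb)
            resid = np.ravel(pred) - yb
            if not np.all(np.isfinite(resid)):
                raise FloatingPointError(
                    "non-finite loss during training; inspect inputs/learning rate"
                )
            dout = (2.0 / len(idx)) * wb * resid
            grads: dict[str, np.ndarray] = {}
            if est.spec.hidden == 0:
                grads["w"] = xb.T @ dout
            else:
                pre, h = cache
                dh = dout[:, None] * params["W2"].T
                dh[pre <= 0] = 0.0
                grads["W1"] = xb.T @ dh
                grads["b1"] = dh.sum(axis=0)
                if est.spec.anchor_zero:
                    z = np.maximum(params["b1"], 0.0)
                    grads["W2"] = (h - z).T @ dout[:, None]
                    grads["b1"] = grads["b1"] - dout.sum() * (
                        params["W2"][:, 0] * (params["b1"] > 0)
                    )
                else:
                    grads["W2"] = h.T @ dout[:, None]
                    grads["b2"] = np.array([dout.sum()])
            t_step += 1
            b1c = 1.0 - cfg.adam_beta1**t_step
            b2c = 1.0 - cfg.adam_beta2**t_step
            for k, g in grads.items():
                m[k] = cfg.adam_beta1 * m[k] + (1 - cfg.adam_beta1) * g
                v2[k] = cfg.adam_beta2 * v2[k] + (1 - cfg.adam_beta2) * g**2
                params[k] -= lr * (m[k] / b1c) / (
                    np.sqrt(v2[k] / b2c) + cfg.adam_eps
                )
        val_loss = _weighted_loss(est._forward(xv)[0], yv, wv)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = {k: p.copy() for k, p in params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                if stages_left > 0:
                    stages_left -= 1
                    stall = 0
                    lr *= cfg.plateau_decay
                    for k in params:
                        params[k] = best_params[k].copy()
                else:
                    break
    est.params = best_params
    est.training_meta.update(
        {"val_loss": best_loss, "epochs_run": epoch + 1, "seed": seed}
    )
    return est


def compute_subset_boundaries(
    model: FuModel,
    n_subsets: int = 6,
    t1: float = 1.0,
    theta_max: float = 100.0,
    grid_size: int = 600,
) -> np.ndarray:
    """Theta-subset boundaries equalizing the movement of Fu's coefficients.

    Returns ``t_0 = 0 < t_1 = 1 < ... < t_K = theta_max`` with the interior
    boundaries chosen so that ``V(t_{k-1}, t_k) = sum_j |a_j(t_k) -
    a_j(t_{k-1})|`` — the total variation of the optimal BLUE coefficient
    vector across the subset — is the same for every ``k >= 2``.  Subsets
    where the optimal estimator changes quickly are thus kept narrow.
    """
    if n_subsets < 2:
        raise ValueError("need at least 2 subsets")
    from scipy.optimize import brentq

    grid = np.geomspace(t1, theta_max, grid_size)
    coeffs = _blue_batch(model, grid)
    v_from_t1 = np.abs(coeffs - coeffs[0]).sum(axis=1)
    if np.any(np.diff(v_from_t1) < -1e-12):
        raise RuntimeError(
            "coefficient variation is not monotone on the theta grid; "
            "cannot place subset boundaries by root-finding"
        )

    def pair_v(lo: float, hi: float) -> float:
        c = _blue_batch(model, np.array([lo, hi]))
        return float(np.abs(c[1] - c[0]).sum())

    k_free = n_subsets - 1  # intervals above t1

    def place(v_step: float) -> np.ndarray:
        """Sequentially place boundaries with equal per-interval variation."""
        ts = [t1]
        for _ in range(k_free - 1):
            lo = ts[-1]
            if pair_v(lo, theta_max) <= v_step:  # step too large to fit
                ts.append(theta_max)
                continue
            ts.append(brentq(lambda t: pair_v(lo, t) - v_step, lo, theta_max,
                             xtol=1e-10, rtol=1e-12))
        return np.asarray(ts)

    # Outer bisection: choose the common step so the last interval also
    # carries exactly v_step, i.e. the sequence ends at theta_max.
    def overshoot(v_step: float) -> float:
        ts = place(v_step)
        return pair_v(ts[-1], theta_max) - v_step

    v_hi = v_from_t1[-1]  # one step covering everything: overshoot < 0
    v_lo = v_hi / (4 * k_free)
    while overshoot(v_lo) < 0:  # pragma: no cover - defensive
        v_lo /= 2
    v_star = brentq(overshoot, v_lo, v_hi, xtol=1e-12)
    interior = place(v_star)[1:]
    return np.concatenate([[0.0, t1], interior, [theta_max]])


def subset_weight_function(boundaries: np.ndarray,
                           omegas: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-constant ``omega(theta)`` over the subset bins."""
    boundaries = np.asarray(boundaries, dtype=float)
    omegas = np.asarray(omegas, dtype=float)

    def weight(theta: np.ndarray) -> np.ndarray:
        k = np.clip(np.searchsorted(boundaries, theta, side="left") - 1,
                    0, len(omegas) - 1)
        return omegas[k]

    return weight


def omega_update(omega: np.ndarray, net_nmse: np.ndarray, floors: np.ndarray,
                 r_step: float) -> np.ndarray:
    """One adaptive reweighting step.

    Each subset's weight grows by ``r_step`` times its normalized nMSE gap
    ``max((nMSE_k - b_k)/b_k, 0)``, self-normalized by the largest gap — so
    the worst subset's weight increases by exactly ``r_step`` and weights
    never decrease.
    """
    rel = np.maximum((net_nmse - floors) / floors, 0.0)
    top = np.nanmax(rel)
    if not top > 0:
        return omega.copy()
    return omega + r_step * np.nan_to_num(rel) / top


@dataclass
class AdaptiveConfig:
    """Adaptive-loop settings: stop factor 1.02, step scale R ~ U(0.25, 0.5)."""

    stop_factor: float = 1.02
    r_range: tuple[float, float] = (0.25, 0.5)
    max_rounds: int = 100
    warm_start: bool = True


@dataclass
class AdaptiveState:
    """Final state of the adaptive loop (weights, floors, gaps, history)."""

    boundaries: np.ndarray
    weights: np.ndarray
    floors: np.ndarray
    gaps: np.ndarray
    nmse: np.ndarray
    stop_factor: float
    iteration: int
    converged: bool
    history: list = field(default_factory=list)


def adaptive_train(
    spec: NetworkSpec,
    train: SFSDataset,
    val: SFSDataset,
    floors_val: SFSDataset,
    seed: int | None = None,
    config: TrainingConfig = TrainingConfig(),
    adaptive: AdaptiveConfig = AdaptiveConfig(),
    boundaries: np.ndarray | None = None,
) -> tuple[TrainedEstimator, AdaptiveState]:
    """Train a network with adaptive reweighting against model-based floors.

    ``floors_val`` must be a second validation set, distinct from ``val``
    (which steers early stopping): on it the per-subset floors

        b_k = min over {Watterson, iterative Fu, iterative Futschik,
                        linear network} of nMSE_k

    are computed once, and after each training round the network's per-subset
    nMSE is compared against them.  Rounds continue — raising the loss weight
    of lagging subsets by ``R * gap_k / max_gap`` with ``R ~ U(0.25, 0.5)`` —
    until ``nMSE_k <= stop_factor * b_k`` for all subsets, or ``max_rounds``
    is hit (then the best round's network is returned with
    ``converged=False``).
    """
    n = spec.n
    if floors_val is val or floors_val is train:
        raise ValueError("floors_val must be a dataset distinct from train/val")
    model = FuModel(n)
    if boundaries is None:
        boundaries = compute_subset_boundaries(model)
    n_subsets = len(boundaries) - 1
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=adaptive.max_rounds + 2)

    # Model-based + linear-network floors on the held-out set.
    fx, ftheta = floors_val.sfs, floors_val.theta
    floor_preds = {
        "watterson": WattersonEstimator(n)(fx),
        "fu_iterative": IterativeEstimator(n, "fu")(fx),
        "futschik_iterative": IterativeEstimator(n, "futschik")(fx),
    }
    linear = train_network(
        build_network(NetworkSpec(n - 1), seed=int(seeds[0]), name="linear_nn"),
        train, val, None, config, seed=int(seeds[0]),
    )
    floor_preds["linear_nn"] = linear(fx)
    floor_table = np.vstack(
        [subset_nmse(p, ftheta, boundaries) for p in floor_preds.values()]
    )
    floors = np.nanmin(floor_table, axis=0)

    omega = np.ones(n_subsets)
    net = build_network(spec, seed=int(seeds[1]))
    best: tuple[float, TrainedEstimator, np.ndarray] | None = None
    history = []
    converged = False
    for round_no in range(1, adaptive.max_rounds + 1):
        weight_fn = subset_weight_function(boundaries, omega)
        refining = adaptive.warm_start and round_no > 1
        start = net if refining else build_network(spec, seed=int(seeds[1]))
        epochs = config.refine_epochs if refining else config.epochs
        round_cfg = (replace(config, learning_rate=config.refine_learning_rate)
                     if refining else config)
        net = train_network(start, train, val, weight_fn, round_cfg,
                            seed=int(seeds[round_no + 1]), epochs=epochs)
        net_nmse = subset_nmse(net(fx), ftheta, boundaries)
        gaps = net_nmse - floors
        rel = np.maximum(gaps / floors, 0.0)
        history.append({"round": round_no, "omega": omega.copy(),
                        "nmse": net_nmse.copy(), "gap": gaps.copy()})
        score = float(np.nanmax(rel))
        if best is None or score < best[0]:
            best = (score, net.copy(), net_nmse.copy())
        if np.all(net_nmse <= adaptive.stop_factor * floors):
            converged = True
            best = (score, net, net_nmse)
            break
        r_step = rng.uniform(*adaptive.r_range)
        omega = omega_update(omega, net_nmse, floors, r_step)
        logger.info("adaptive round %d: max rel gap %.3f, omega -> %s",
                    round_no, score, np.round(omega, 3))

    _, net, net_nmse = best
    net.name = "adaptive_nn" if spec.hidden else "linear_nn"
    net.training_meta["adaptive_rounds"] = round_no
    net.training_meta["converged"] = converged
    state = AdaptiveState(
        boundaries=boundaries, weights=omega, floors=floors,
        gaps=net_nmse - floors, nmse=net_nmse,
        stop_factor=adaptive.stop_factor, iteration=round_no,
        converged=converged, history=history,
    )
    return net, state


def predict(est: TrainedEstimator, sfs) -> float:
    """Point estimate for one SFS (raw network output, no clamping)."""
    value = est.predict(sfs)
    if value < 0:
        logger.warning("negative theta estimate %.4f returned unclamped", value)
    return value
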