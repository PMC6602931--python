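"""Datasets and fitting: self-energy regression, energy training, ensemble
splits, layer-freezing transfer learning, and the Δ-learning alternative.

Training minimizes the mean squared error of total energies with each
residual divided by √N_atoms, so molecules of different sizes carry
comparable weight.  Optimization is Adam with plateau learning-rate decay
and early stopping on a validation split; the best-validation snapshot is
returned.  All randomness is seeded and reproducible.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conformation import Conformation
from .featurization import AEVSpec, compute_aev
from .model import (
    Ensemble,
    NNPModel,
    mlp_backward,
    mlp_forward,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------
@dataclass
class Dataset:
    """Energy-labeled conformations at one fidelity, grouped by molecule.

    `split` is an optional per-conformation assignment to
    {"train", "validation", "test"}.
    """

    conformations: List[Conformation]
    fidelity: str = "low"
    split: Optional[List[str]] = None

    def __post_init__(self):
        if self.fidelity not in ("low", "high"):
            raise ValueError("fidelity must be 'low' or 'high'")
        self._aev_cache: Dict[AEVSpec, List[np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.conformations)

    def energies(self) -> np.ndarray:
        out = []
        for c in self.conformations:
            e = c.energy(self.fidelity)
            if e is None:
                raise ValueError(
                    f"conformation of {c.molecule_id} lacks a {self.fidelity}-fidelity energy"
                )
            out.append(e)
        return np.asarray(out, dtype=float)

    def groups(self) -> Dict[str, List[int]]:
        g: Dict[str, List[int]] = {}
        for i, c in enumerate(self.conformations):
            g.setdefault(c.molecule_id, []).append(i)
        return g

    def subset(self, indices: Sequence[int], split: Optional[List[str]] = None) -> "Dataset":
        out = Dataset(
            conformations=[self.conformations[i] for i in indices],
            fidelity=self.fidelity,
            split=split,
        )
        for spec, aevs in self._aev_cache.items():
            out._aev_cache[spec] = [aevs[i] for i in indices]
        return out

    def get_aevs(self, spec: AEVSpec) -> List[np.ndarray]:
        """Descriptor matrices for every conformation, memoized per spec."""
        if spec not in self._aev_cache:
            self._aev_cache[spec] = [
                compute_aev(c, spec).values for c in self.conformations
            ]
        return self._aev_cache[spec]

    def indices_with_split(self, name: str) -> List[int]:
        if self.split is None:
            raise ValueError("dataset has no split assignments")
        return [i for i, s in enumerate(self.split) if s == name]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------
@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_patience: int = 25
    min_learning_rate: float = 1e-5
    weight_decay: float = 1e-5
    batch_size: int = 64
    max_epochs: int = 300
    early_stopping_patience: int = 60
    validation_fraction: float = 0.1
    split_by: str = "molecule"  # how ensemble/validation splits group data
    loss_normalization: str = "per_sqrt_atoms"  # or "total"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation fraction must lie in (0, 1)")
        for name in ("learning_rate", "batch_size", "max_epochs", "early_stopping_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class FreezeSpec:
    """Which of the four hidden layers are frozen during transfer learning,
    uniformly across element networks.

    The default freezes the two hidden layers nearest the output and
    retrains the two input-side layers (plus the output head): the
    inter-fidelity correction is predominantly a function of local
    geometry, which the input-side feature detectors represent, and those
    layers also hold most of the capacity.  Freezing the input-side layers
    instead — keeping the pretrained feature detectors — is the obvious
    alternative and is one flag away.
    """

    hidden_frozen: tuple = (False, False, True, True)
    self_energies_frozen: bool = True

    def __post_init__(self):
        self.hidden_frozen = tuple(bool(b) for b in self.hidden_frozen)
        if len(self.hidden_frozen) != 4:
            raise ValueError("freeze flags are per hidden layer: exactly four")

    @property
    def all_frozen(self) -> bool:
        return all(self.hidden_frozen)

    def layer_is_frozen(self, layer_index: int) -> bool:
        """Layer indices 0..4: four hidden layers then the output head."""
        if layer_index < 4:
            return self.hidden_frozen[layer_index]
        return False  # output head follows the deepest hidden layers


# ---------------------------------------------------------------------------
# Self-energy regression
# ---------------------------------------------------------------------------
def fit_atomic_self_energies(
    dataset: Dataset, elements: Optional[Sequence[str]] = None
) -> Dict[str, float]:
    """Least-squares fit of E ≈ Σ_e n_e·ε_e over all labeled conformations.

    Raises a rank-deficiency error naming the confounded elements when the
    element-count matrix cannot identify every per-element energy.
    """
    if elements is None:
        seen = []
        for c in dataset.conformations:
            for s in c.species:
                if s not in seen:
                    seen.append(s)
        elements = seen
    elements = list(elements)
    A = np.array(
        [c.element_counts(elements) for c in dataset.conformations], dtype=float
    )
    y = dataset.energies()
    rank = np.linalg.matrix_rank(A)
    if rank < len(elements):
        _, _, vt = np.linalg.svd(A)
        null = vt[rank:]
        confounded = [
            elements[j] for j in range(len(elements)) if np.abs(null[:, j]).max() > 1e-8
        ]
        raise ValueError(
            "element-count matrix is rank deficient; confounded elements: "
            + ", ".join(confounded)
        )
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return {e: float(c) for e, c in zip(elements, coef)}


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------
def split_dataset(
    dataset: Dataset,
    K: int,
    seed: int,
    validation_fraction: float = 0.1,
    by: str = "molecule",
) -> List[Dataset]:
    """K distinct seeded train/validation splits of one dataset.

    By default whole molecule groups are assigned to one side, which
    prevents conformers of a molecule leaking between train and validation;
    ``by="conformation"`` splits individual conformations instead.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > len(dataset):
        raise ValueError(f"cannot make {K} splits from {len(dataset)} conformations")
    if by not in ("molecule", "conformation"):
        raise ValueError("split mode must be 'molecule' or 'conformation'")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(K):
        assign = ["train"] * len(dataset)
        if by == "molecule":
            groups = list(dataset.groups().items())
            order = rng.permutation(len(groups))
            n_val_target = validation_fraction * len(dataset)
            n_val = 0
            for gi in order:
                if n_val >= n_val_target:
                    break
                _, idxs = groups[gi]
                for i in idxs:
                    assign[i] = "validation"
                n_val += len(idxs)
        else:
            n_val = max(1, int(round(validation_fraction * len(dataset))))
            for i in rng.permutation(len(dataset))[:n_val]:
                assign[i] = "validation"
        if all(a == "train" for a in assign) and len(dataset) > 1:
            assign[int(rng.integers(len(dataset)))] = "validation"
        out.append(
            Dataset(list(dataset.conformations), fidelity=dataset.fidelity, split=assign)
        )
    return out


# ---------------------------------------------------------------------------
# Adam optimizer over the per-element parameter lists
# ---------------------------------------------------------------------------
class _Adam:
    """Adam with decoupled weight decay (applied to weights, not biases)."""

    def __init__(self, shapes, lr, weight_decay=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.wd and p.ndim == 2:
                p -= self.lr * self.wd * p


def _flatten_params(model: NNPModel, trainable: Callable[[int], bool]):
    """References to trainable parameter arrays, with (element, layer, which)
    bookkeeping for gradient routing."""
    params, keys = [], []
    for e in model.spec.supported_elements:
        for li, (W, b) in enumerate(model.element_networks[e]):
            if trainable(li):
                params.extend([W, b])
                keys.extend([(e, li, 0), (e, li, 1)])
    return params, keys


# ---------------------------------------------------------------------------
# Core energy trainer
# ---------------------------------------------------------------------------
def _prepare(dataset: Dataset, model: NNPModel):
    aevs = dataset.get_aevs(model.spec)
    energies = dataset.energies()
    baselines = np.array(
        [sum(model.self_energies[s] for s in c.species) for c in dataset.conformations]
    )
    natoms = np.array([c.n_atoms for c in dataset.conformations], dtype=float)
    return aevs, energies, baselines, natoms


class _Design:
    """Pre-stacked, pre-transformed per-element design matrices with
    row-ownership bookkeeping, so each minibatch is pure array indexing."""

    def __init__(self, dataset: Dataset, model: NNPModel, aevs):
        self.elements = [
            e
            for e in model.spec.supported_elements
            if any(e in c.species for c in dataset.conformations)
        ]
        self.X: Dict[str, np.ndarray] = {}
        self.rows_by_conf: Dict[str, List[np.ndarray]] = {}
        for e in self.elements:
            blocks = []
            rows: List[np.ndarray] = []
            pos = 0
            for ci, c in enumerate(dataset.conformations):
                idx = [i for i, s in enumerate(c.species) if s == e]
                blocks.append(aevs[ci][idx])
                rows.append(np.arange(pos, pos + len(idx)))
                pos += len(idx)
            self.X[e] = model.transform_inputs(np.vstack(blocks))
            self.rows_by_conf[e] = rows

    def batch(self, indices):
        out = {}
        for e in self.elements:
            rows = self.rows_by_conf[e]
            sel = np.concatenate([rows[ci] for ci in indices])
            owners = np.concatenate(
                [np.full(len(rows[ci]), b, dtype=int) for b, ci in enumerate(indices)]
            )
            out[e] = (sel, owners)
        return out


def _batch_energies(model, design: _Design, batch_map, nbatch):
    """Predicted network contribution per conformation; returns caches for
    the backward pass."""
    E = np.zeros(nbatch)
    caches = {}
    for e, (sel, owners) in batch_map.items():
        if len(sel) == 0:
            continue
        y, cache = mlp_forward(model.element_networks[e], design.X[e][sel])
        caches[e] = cache
        np.add.at(E, owners, y)
    return E, caches


def _loss_and_norm(E_pred, E_ref, natoms, mode):
    if mode == "per_sqrt_atoms":
        w = 1.0 / np.sqrt(natoms)
    else:
        w = np.ones_like(natoms)
    r = (E_pred - E_ref) * w
    return float(np.mean(r**2)), 2.0 * r * w / len(r)


def _eval_loss(model, design, energies, baselines, natoms, indices, mode):
    if len(indices) == 0:
        return 0.0
    batch_map = design.batch(indices)
    E, _ = _batch_energies(model, design, batch_map, len(indices))
    E = E + baselines[indices]
    loss, _ = _loss_and_norm(E, energies[indices], natoms[indices], mode)
    return loss


def train_model(
    model: NNPModel,
    dataset: Dataset,
    config: TrainConfig,
    freeze: Optional[FreezeSpec] = None,
) -> Tuple[NNPModel, Dict[str, list]]:
    """Fit the atomic networks to the dataset's energies.

    Self-energies must already be set (they are held fixed here; use
    :func:`fit_atomic_self_energies` first).  Returns the best-validation
    snapshot and the loss history, whose ``best_val`` track is by
    construction non-increasing.
    """
    model = model.copy()
    trainable = (lambda li: not freeze.layer_is_frozen(li)) if freeze else (lambda li: True)
    if freeze is not None and freeze.all_frozen:
        warnings.warn("all layers frozen: training is a no-op", stacklevel=2)
        return model, {"train_loss": [], "val_loss": [], "best_val": [], "lr": []}

    aevs, energies, baselines, natoms = _prepare(dataset, model)
    rng = np.random.default_rng(config.seed)

    if dataset.split is not None:
        train_idx = np.asarray(dataset.indices_with_split("train"), dtype=int)
        val_idx = np.asarray(dataset.indices_with_split("validation"), dtype=int)
    else:
        perm = rng.permutation(len(dataset))
        n_val = max(1, int(round(config.validation_fraction * len(dataset))))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("empty training set")

    if model.input_shift is None:
        model.set_input_standardization(np.vstack([aevs[i] for i in train_idx]))

    design = _Design(dataset, model, aevs)
    params, keys = _flatten_params(model, trainable)
    opt = _Adam([p.shape for p in params], config.learning_rate, config.weight_decay)

    history: Dict[str, list] = {"train_loss": [], "val_loss": [], "best_val": [], "lr": []}
    best_val = np.inf
    best_snapshot = model.copy()
    since_best = 0
    since_decay = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            batch_map = design.batch(batch)
            E_net, caches = _batch_energies(model, design, batch_map, len(batch))
            E_pred = E_net + baselines[batch]
            loss, dE = _loss_and_norm(
                E_pred, energies[batch], natoms[batch], config.loss_normalization
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            epoch_losses.append(loss)
            grad_map = {}
            for e, (sel, owners) in batch_map.items():
                if len(sel) == 0:
                    continue
                layers = model.element_networks[e]
                g, _ = mlp_backward(layers, caches[e], dE[owners])
                for li, (dW, db) in enumerate(g):
                    grad_map[(e, li, 0)] = dW
                    grad_map[(e, li, 1)] = db
            grads = [grad_map.get(k, np.zeros_like(p)) for k, p in zip(keys, params)]
            opt.step(params, grads)

        val_loss = _eval_loss(
            model, design, energies, baselines, natoms, val_idx,
            config.loss_normalization,
        )
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snapshot = model.copy()
            since_best = 0
            since_decay = 0
        else:
            since_best += 1
            since_decay += 1
        history["best_val"].append(best_val)
        history["lr"].append(opt.lr)
        if since_decay >= config.lr_patience and opt.lr > config.min_learning_rate:
            opt.lr = max(opt.lr * config.lr_decay_factor, config.min_learning_rate)
            since_decay = 0
        if since_best >= config.early_stopping_patience:
            break

    return best_snapshot, history


# ---------------------------------------------------------------------------
# Transfer learning
# ---------------------------------------------------------------------------
def count_frozen_parameters(model: NNPModel, freeze: FreezeSpec) -> Tuple[int, int]:
    """(frozen, total) trainable-scalar counts under a freeze specification."""
    frozen = 0
    total = 0
    for layers in model.element_networks.values():
        for li, (W, b) in enumerate(layers):
            n = W.size + b.size
            total += n
            if freeze.layer_is_frozen(li):
                frozen += n
    return frozen, total


def _refit_offset(model: NNPModel, dataset: Dataset, indices: Sequence[int]) -> None:
    """Add a per-element linear offset to self_energies so the systematic
    inter-fidelity shift is removed before gradient training."""
    from .model import predict_energy_from_aev

    elements = list(model.spec.supported_elements)
    sub = [dataset.conformations[i] for i in indices]
    A = np.array([c.element_counts(elements) for c in sub])
    aevs = dataset.get_aevs(model.spec)
    resid = []
    for i in indices:
        c = dataset.conformations[i]
        resid.append(c.energy(dataset.fidelity) - predict_energy_from_aev(model, c.species, aevs[i]))
    resid = np.asarray(resid)
    keep = [j for j in range(len(elements)) if A[:, j].any()]
    if keep:
        coef, *_ = np.linalg.lstsq(A[:, keep], resid, rcond=None)
        for j, cj in zip(keep, coef):
            model.self_energies[elements[j]] += float(cj)


def transfer_learn(
    ensemble: Ensemble,
    high_dataset: Dataset,
    freeze: Optional[FreezeSpec] = None,
    config: Optional[TrainConfig] = None,
) -> Ensemble:
    """Retrain a low-fidelity-pretrained ensemble against high-fidelity
    energies with some hidden layers held fixed.

    Each member first gets a per-element linear offset refit on its own
    high-fidelity training split (removing the systematic shift between the
    fidelity levels), then gradient training at a reduced learning rate with
    the frozen layers bit-identical before and after.  The frozen/total
    parameter counts are logged.
    """
    freeze = freeze if freeze is not None else FreezeSpec()
    config = config if config is not None else TrainConfig()
    frozen, total = count_frozen_parameters(ensemble.members[0], freeze)
    logger.info(
        "transfer learning: %d of %d optimizable network parameters held constant per member",
        frozen, total,
    )
    if freeze.all_frozen:
        warnings.warn(
            "all hidden layers frozen: transfer learning leaves the ensemble unchanged",
            stacklevel=2,
        )
        return ensemble.copy()

    splits = split_dataset(
        high_dataset, ensemble.size, config.seed, config.validation_fraction,
        by=config.split_by,
    )
    new_members = []
    for k, member in enumerate(ensemble.members):
        m = member.copy()
        split = splits[k]
        # self_energies_frozen governs gradient-time updates (this trainer
        # never gradient-trains them); the documented one-shot offset refit
        # below is always applied to remove the inter-fidelity shift.
        _refit_offset(m, split, split.indices_with_split("train"))
        member_cfg = config.replace(
            seed=config.seed + 1000 * (k + 1),
            learning_rate=config.learning_rate * 0.1,
        )
        trained, _ = train_model(m, split, member_cfg, freeze=freeze)
        new_members.append(trained)
    return Ensemble(members=new_members, member_seeds=list(ensemble.member_seeds))


# ---------------------------------------------------------------------------
# Δ-learning
# ---------------------------------------------------------------------------
class CombinedPredictor:
    """Base + correction predictor: two network evaluations per inference."""

    def __init__(self, base: Ensemble, correction: Ensemble):
        self.base = base
        self.correction = correction

    def base_energy(self, conformation: Conformation) -> float:
        from .model import ensemble_predict

        return ensemble_predict(self.base, conformation)[0]

    def correction_energy(self, conformation: Conformation) -> float:
        from .model import ensemble_predict

        return ensemble_predict(self.correction, conformation)[0]

    def predict_energy(self, conformation: Conformation) -> float:
        return self.base_energy(conformation) + self.correction_energy(conformation)


def delta_learn(
    base_ensemble: Ensemble,
    high_dataset: Dataset,
    config: Optional[TrainConfig] = None,
    widths: Optional[Sequence[int]] = None,
) -> Tuple[Ensemble, CombinedPredictor]:
    """Train a correction ensemble on residuals E_high − E_base.

    The combined predictor sums base and correction; by construction
    combined(x) − base(x) = correction(x) exactly.
    """
    from .model import init_model, member_energies_from_aev

    config = config if config is not None else TrainConfig()
    spec = base_ensemble.spec
    widths = tuple(widths) if widths is not None else base_ensemble.members[0].widths

    aevs = high_dataset.get_aevs(spec)
    base_pred = np.array(
        [
            member_energies_from_aev(base_ensemble, c.species, aevs[i]).mean()
            for i, c in enumerate(high_dataset.conformations)
        ]
    )
    residual = high_dataset.energies() - base_pred
    resid_confs = [
        (c.with_(energy_high=float(r)) if high_dataset.fidelity == "high" else c.with_(energy_low=float(r)))
        for c, r in zip(high_dataset.conformations, residual)
    ]
    resid_dataset = Dataset(resid_confs, fidelity=high_dataset.fidelity)

    splits = split_dataset(
        resid_dataset, base_ensemble.size, config.seed, config.validation_fraction,
        by=config.split_by,
    )
    members = []
    for k in range(base_ensemble.size):
        seed_k = config.seed + 31 * (k + 1)
        m = init_model(spec, widths, seed=seed_k)
        split = splits[k]
        train_idx = split.indices_with_split("train")
        m.self_energies = _lstsq_self_energies(split, train_idx, spec)
        trained, _ = train_model(m, split, config.replace(seed=seed_k))
        members.append(trained)
    correction = Ensemble(members=members)
    return correction, CombinedPredictor(base_ensemble, correction)


def _lstsq_self_energies(dataset: Dataset, indices, spec) -> Dict[str, float]:
    """Min-norm least-squares element baseline for a subset (no rank demand)."""
    elements = list(spec.supported_elements)
    sub = [dataset.conformations[i] for i in indices]
    A = np.array([c.element_counts(elements) for c in sub])
    y = np.array([c.energy(dataset.fidelity) for c in sub])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return {e: float(c) for e, c in zip(elements, coef)}
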