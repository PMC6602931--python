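"""Per-element feed-forward atomic networks and ensembles.

The molecular energy is decomposed as

    E = Σ_i ε(Z_i) + Σ_i f_{Z_i}(AEV_i)

where ε are linear atomic self-energies (kcal/mol) and f_Z is a small
four-hidden-layer network for element Z acting on that atom's environment
vector.  Forces are the exact negative gradient of this composition, via
backpropagation through the networks and the analytic descriptor gradients.

The activation is CELU (continuously differentiable exponential-linear,
α = 0.1): smooth everywhere, so analytic forces are well defined.

Everything is double precision numpy; networks are deliberately desk-scale
(default widths [64, 48, 32, 16] per element, a scaled-down version of
production-size symmetry-function potentials).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conformation import Conformation
from .featurization import AEVSpec, aev_adjoint_gradient, compute_aev

DEFAULT_WIDTHS = (64, 48, 32, 16)
CELU_ALPHA = 0.1

LayerParams = Tuple[np.ndarray, np.ndarray]  # (W: in×out, b: out)


def celu(x: np.ndarray, alpha: float = CELU_ALPHA) -> np.ndarray:
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0) / alpha))


def celu_deriv(x: np.ndarray, alpha: float = CELU_ALPHA) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0) / alpha))


def _init_layer(rng: np.random.Generator, fan_in: int, fan_out: int) -> LayerParams:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return W, b


def mlp_forward(layers: Sequence[LayerParams], X: np.ndarray):
    """Forward pass; returns (output (n,), cache for backward)."""
    pre: List[np.ndarray] = []
    acts = [X]
    h = X
    for li, (W, b) in enumerate(layers):
        z = h @ W + b
        pre.append(z)
        h = z if li == len(layers) - 1 else celu(z)
        acts.append(h)
    return h[:, 0], (pre, acts)


def mlp_backward(layers: Sequence[LayerParams], cache, dY: np.ndarray):
    """Backward pass for scalar-output MLP.

    dY has shape (n,): sensitivity of the loss to each row's output.
    Returns (per-layer (dW, db) grads, dX w.r.t. the input rows).
    """
    pre, acts = cache
    grads: List[LayerParams] = [None] * len(layers)  # type: ignore[list-item]
    delta = dY[:, None]
    for li in range(len(layers) - 1, -1, -1):
        W, _ = layers[li]
        h_in = acts[li]
        dW = h_in.T @ delta
        db = delta.sum(axis=0)
        grads[li] = (dW, db)
        delta = delta @ W.T
        if li > 0:
            delta = delta * celu_deriv(pre[li - 1])
    return grads, delta


@dataclass
class NNPModel:
    """A single neural network potential: one atomic network per element.

    Attributes
    ----------
    spec : AEVSpec
        The descriptor the networks were built for.
    widths : tuple of int
        The four hidden-layer widths, shared across elements.
    element_networks : dict element -> list of (W, b)
        Five layers per element: four hidden + scalar output head.
    self_energies : dict element -> float, kcal/mol
        Linear atomic baseline; initialized to 0, fitted from data.
    """

    spec: AEVSpec
    widths: tuple
    element_networks: Dict[str, List[LayerParams]]
    self_energies: Dict[str, float]
    seed: int = 0
    activation: str = "celu"
    # fixed (non-trainable) input standardization, set once from the
    # pretraining data; None means identity
    input_shift: Optional[np.ndarray] = None
    input_scale: Optional[np.ndarray] = None

    def transform_inputs(self, aev: np.ndarray) -> np.ndarray:
        if self.input_shift is None:
            return aev
        return (aev - self.input_shift) / self.input_scale

    def set_input_standardization(self, aev_rows: np.ndarray, floor: float = 1e-2):
        """Freeze a per-feature shift/scale from a stack of AEV rows.

        The scale is floored so features inactive in the reference data
        cannot blow up out of distribution."""
        self.input_shift = aev_rows.mean(axis=0)
        self.input_scale = np.maximum(aev_rows.std(axis=0), floor)

    @property
    def parameter_count(self) -> int:
        """Exact number of trainable network scalars (weights + biases)."""
        return sum(
            W.size + b.size for layers in self.element_networks.values() for W, b in layers
        )

    def copy(self) -> "NNPModel":
        return NNPModel(
            spec=self.spec,
            widths=tuple(self.widths),
            element_networks={
                e: [(W.copy(), b.copy()) for W, b in layers]
                for e, layers in self.element_networks.items()
            },
            self_energies=dict(self.self_energies),
            seed=self.seed,
            activation=self.activation,
            input_shift=None if self.input_shift is None else self.input_shift.copy(),
            input_scale=None if self.input_scale is None else self.input_scale.copy(),
        )


def init_model(
    spec: AEVSpec,
    widths: Sequence[int] = DEFAULT_WIDTHS,
    seed: int = 0,
) -> NNPModel:
    """Seeded-deterministic initialization; self-energies start at 0."""
    widths = tuple(int(w) for w in widths)
    if len(widths) == 0:
        raise ValueError("widths must be non-empty")
    if len(widths) != 4:
        raise ValueError("the architecture uses exactly four hidden layers")
    rng = np.random.default_rng(seed)
    nets: Dict[str, List[LayerParams]] = {}
    sizes = (spec.feature_length,) + widths + (1,)
    for e in spec.supported_elements:
        nets[e] = [
            _init_layer(rng, sizes[k], sizes[k + 1]) for k in range(len(sizes) - 1)
        ]
    return NNPModel(
        spec=spec,
        widths=widths,
        element_networks=nets,
        self_energies={e: 0.0 for e in spec.supported_elements},
        seed=int(seed),
    )


def _group_by_element(species: Sequence[str]) -> Dict[str, np.ndarray]:
    groups: Dict[str, list] = {}
    for i, s in enumerate(species):
        groups.setdefault(s, []).append(i)
    return {e: np.asarray(idx) for e, idx in groups.items()}


def atomic_contributions(model: NNPModel, species: Sequence[str], aev: np.ndarray) -> np.ndarray:
    """Per-atom network outputs (kcal/mol), excluding self-energies."""
    out = np.zeros(len(species))
    aev = model.transform_inputs(aev)
    for e, idx in _group_by_element(species).items():
        if e not in model.element_networks:
            raise ValueError(f"element {e!r} is not supported by this model")
        y, _ = mlp_forward(model.element_networks[e], aev[idx])
        out[idx] = y
    return out


def predict_energy_from_aev(
    model: NNPModel, species: Sequence[str], aev: np.ndarray
) -> float:
    base = sum(model.self_energies[s] for s in species)
    return float(base + atomic_contributions(model, species, aev).sum())


def predict_energy(model: NNPModel, conformation: Conformation) -> float:
    """Total energy in kcal/mol: self-energy baseline plus summed atomic
    network outputs."""
    aev = compute_aev(conformation, model.spec)
    return predict_energy_from_aev(model, conformation.species, aev.values)


def energy_aev_sensitivity(
    model: NNPModel, species: Sequence[str], aev: np.ndarray
) -> np.ndarray:
    """∂E/∂AEV (N×L) via a backward pass with unit output sensitivity."""
    W = np.zeros_like(aev)
    aev_t = model.transform_inputs(aev)
    for e, idx in _group_by_element(species).items():
        layers = model.element_networks[e]
        _, cache = mlp_forward(layers, aev_t[idx])
        _, dX = mlp_backward(layers, cache, np.ones(len(idx)))
        W[idx] = dX
    if model.input_scale is not None:
        W = W / model.input_scale
    return W


def predict_forces(model: NNPModel, conformation: Conformation) -> np.ndarray:
    """Forces = −∂E/∂coordinates (N×3, kcal/mol/Å), exact differentiation
    of the network∘descriptor composition."""
    aev = compute_aev(conformation, model.spec)
    sens = energy_aev_sensitivity(model, conformation.species, aev.values)
    grad = aev_adjoint_gradient(conformation, model.spec, sens)
    return -grad


@dataclass
class Ensemble:
    """An ordered committee of independently trained potentials sharing one
    descriptor spec; disagreement (member standard deviation) is the
    uncertainty proxy used for query-by-committee selection."""

    members: List[NNPModel]
    member_seeds: List[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        spec0 = self.members[0].spec
        for m in self.members[1:]:
            if m.spec != spec0:
                raise ValueError("all ensemble members must share one AEVSpec")
        if not self.member_seeds:
            self.member_seeds = [m.seed for m in self.members]

    @property
    def spec(self) -> AEVSpec:
        return self.members[0].spec

    @property
    def size(self) -> int:
        return len(self.members)

    def copy(self) -> "Ensemble":
        return Ensemble(
            members=[m.copy() for m in self.members],
            member_seeds=list(self.member_seeds),
        )


def member_energies_from_aev(
    ensemble: Ensemble, species: Sequence[str], aev: np.ndarray
) -> np.ndarray:
    return np.array(
        [predict_energy_from_aev(m, species, aev) for m in ensemble.members]
    )


def ensemble_predict(
    ensemble: Ensemble,
    conformation: Conformation,
    normalize: bool = True,
    return_forces: bool = False,
):
    """Committee prediction.

    Returns (mean energy, disagreement) where disagreement is the
    population standard deviation of member energies, divided by
    √N_atoms when `normalize` (default) so the query-by-committee
    threshold is size-independent.  With `return_forces`, a third item —
    the mean member force array — is appended.
    """
    if ensemble.size < 2:
        raise ValueError("disagreement requires at least two ensemble members")
    aev = compute_aev(conformation, ensemble.spec)
    energies = member_energies_from_aev(ensemble, conformation.species, aev.values)
    mean = float(energies.mean())
    dis = float(energies.std())
    if normalize:
        dis /= np.sqrt(conformation.n_atoms)
    if return_forces:
        forces = np.mean(
            [predict_forces(m, conformation) for m in ensemble.members], axis=0
        )
        return mean, dis, forces
    return mean, dis
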