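"""Standard synthetic-benchmark experiments.

These functions tie the package together into the canonical desk-scale
experiment: a two-fidelity synthetic corpus (≈60 molecules × 12–24
normal-mode conformers, low-fidelity labels everywhere, high-fidelity
labels for a scarce budget), a committee of eight potentials pretrained on
the low level, and the three competing routes to high-fidelity accuracy —
layer-frozen transfer learning, Δ-learning, and training from scratch on
the scarce data — plus query-by-committee curation against random
selection.  Results are reported as held-out conformer-ΔE RMSD at the high
fidelity level.

Problem sizes default to what a single CPU core handles in minutes; every
function is deterministic given its seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.stats

from .conformation import Conformation
from .featurization import AEVSpec
from .model import (
    Ensemble,
    init_model,
    member_energies_from_aev,
)
from .training import (
    Dataset,
    FreezeSpec,
    TrainConfig,
    count_frozen_parameters,
    delta_learn,
    fit_atomic_self_energies,
    split_dataset,
    train_model,
    transfer_learn,
)
from .active_learning import ALConfig, active_learning_loop, pool_disagreements
from .evaluation import conformer_pair_errors, mad_rmsd
from .synthetic import SyntheticCorpus, generate_corpus, label_dataset, normal_mode_sample

logger = logging.getLogger(__name__)

DEFAULT_WIDTHS = (32, 32, 32, 32)


# ---------------------------------------------------------------------------
# fast cached-AEV evaluation helpers
# ---------------------------------------------------------------------------
def dataset_energies(predictor, dataset: Dataset, spec: AEVSpec) -> np.ndarray:
    """Mean predicted energy per conformation, reusing cached descriptors."""
    aevs = dataset.get_aevs(spec)
    if isinstance(predictor, Ensemble):
        return np.array(
            [
                member_energies_from_aev(predictor, c.species, aevs[i]).mean()
                for i, c in enumerate(dataset.conformations)
            ]
        )
    if hasattr(predictor, "base") and hasattr(predictor, "correction"):
        return dataset_energies(predictor.base, dataset, spec) + dataset_energies(
            predictor.correction, dataset, spec
        )
    from .model import predict_energy_from_aev

    return np.array(
        [
            predict_energy_from_aev(predictor, c.species, aevs[i])
            for i, c in enumerate(dataset.conformations)
        ]
    )


def delta_e_errors(predictor, dataset: Dataset, spec: AEVSpec) -> Tuple[float, float]:
    """(MAD, RMSD) of conformer ΔE of a predictor against a labeled
    dataset."""
    pred_e = dataset_energies(predictor, dataset, spec)
    ref_e = dataset.energies()
    pred: Dict[str, np.ndarray] = {}
    ref: Dict[str, np.ndarray] = {}
    for mol, idx in dataset.groups().items():
        pred[mol] = pred_e[idx]
        ref[mol] = ref_e[idx]
    return conformer_pair_errors(pred, ref)


# ---------------------------------------------------------------------------
# benchmark world
# ---------------------------------------------------------------------------
@dataclass
class BenchmarkWorld:
    """The shared state of one benchmark run: corpus, descriptor spec,
    fitted self-energies, and high-fidelity-labeled test sets."""

    corpus: SyntheticCorpus
    spec: AEVSpec
    self_energies: Dict[str, float]
    test_high: Dataset
    test_low: Dataset
    seed: int


def build_world(
    seed: int,
    n_molecules: int = 60,
    n_test_per_molecule: int = 6,
    spec: Optional[AEVSpec] = None,
    scale: float = 0.6,
    delta: float = 0.05,
) -> BenchmarkWorld:
    """Generate the corpus plus a fresh-conformer test set labeled at both
    fidelity levels."""
    spec = spec or AEVSpec()
    corpus = generate_corpus(
        seed, n_molecules=n_molecules, scale=scale, delta=delta
    )
    low_pes = corpus.low_pes()
    high_pes = corpus.high_pes()
    rng = np.random.default_rng(seed + 101)
    test_confs: List[Conformation] = []
    for t in corpus.templates:
        test_confs.extend(
            normal_mode_sample(
                corpus.minima[t.molecule_id],
                low_pes[t.molecule_id],
                n_test_per_molecule,
                scale=scale,
                seed=int(rng.integers(2**31)),
            )
        )
    test_high = label_dataset(test_confs, high_pes, "high")
    test_low = label_dataset(test_confs, low_pes, "low")
    corpus.low_dataset.get_aevs(spec)
    test_high.get_aevs(spec)
    test_low._aev_cache[spec] = test_high.get_aevs(spec)  # same geometries
    se = fit_atomic_self_energies(corpus.low_dataset)
    return BenchmarkWorld(
        corpus=corpus, spec=spec, self_energies=se,
        test_high=test_high, test_low=test_low, seed=int(seed),
    )


def pretrain_low_ensemble(
    world: BenchmarkWorld,
    K: int = 8,
    widths: Sequence[int] = DEFAULT_WIDTHS,
    epochs: int = 150,
    batch_size: int = 96,
) -> Ensemble:
    """Train the committee on the low-fidelity corpus, each member on its
    own conformation-level split and from its own initialization."""
    cfg = TrainConfig(
        max_epochs=epochs, batch_size=batch_size, split_by="conformation",
        seed=world.seed,
    )
    splits = split_dataset(
        world.corpus.low_dataset, K, world.seed + 1, by="conformation"
    )
    members = []
    for k in range(K):
        m = init_model(world.spec, widths, seed=world.seed + 1000 + k)
        m.self_energies = dict(world.self_energies)
        trained, hist = train_model(
            m, splits[k], cfg.replace(seed=world.seed + 2000 + k)
        )
        logger.info("low member %d: best val %.4f", k, hist["best_val"][-1])
        members.append(trained)
    return Ensemble(members)


def sample_high_dataset(
    world: BenchmarkWorld, budget: int, seed: int
) -> Dataset:
    """Random high-fidelity labeling of `budget` corpus conformations."""
    ds = world.corpus.low_dataset
    high_pes = world.corpus.high_pes()
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(ds), size=budget, replace=False).tolist())
    aevs = ds.get_aevs(world.spec)
    confs = []
    for i in idx:
        c = ds.conformations[i]
        E, F = high_pes[c.molecule_id].energy_forces(c.coordinates)
        confs.append(c.with_(energy_high=float(E), forces=F))
    out = Dataset(confs, fidelity="high")
    out._aev_cache[world.spec] = [aevs[i] for i in idx]
    return out


# ---------------------------------------------------------------------------
# transfer / Δ / scratch comparison
# ---------------------------------------------------------------------------
def run_transfer_benchmark(
    world: BenchmarkWorld,
    low_ensemble: Ensemble,
    n_repeats: int = 5,
    high_budget: int = 108,
    transfer_epochs: int = 400,
    scratch_epochs: int = 150,
    include_delta: bool = True,
) -> Dict[str, object]:
    """Compare transfer learning, Δ-learning, and scratch training at equal
    high-fidelity budget, over `n_repeats` seeds.

    Returns per-repeat and median held-out conformer-ΔE RMSDs against the
    high-fidelity labels, plus the low-only baseline and per-member
    statistics of the low ensemble.
    """
    spec = world.spec
    K = low_ensemble.size
    widths = low_ensemble.members[0].widths

    low_mad, low_rmsd = delta_e_errors(low_ensemble, world.test_high, spec)
    member_rmsds = [
        delta_e_errors(m, world.test_high, spec)[1] for m in low_ensemble.members
    ]
    low_self_mad, low_self_rmsd = delta_e_errors(low_ensemble, world.test_low, spec)

    out: Dict[str, object] = {
        "low_only_mad": low_mad,
        "low_only_rmsd": low_rmsd,
        "low_vs_low_rmsd": low_self_rmsd,
        "member_rmsds_low_only": member_rmsds,
        "median_member_rmsd": float(np.median(member_rmsds)),
        "transfer_rmsd": [],
        "transfer_mad": [],
        "scratch_rmsd": [],
        "delta_rmsd": [],
        "n_low": len(world.corpus.low_dataset),
        "n_test": len(world.test_high),
        "high_budget": high_budget,
    }
    freeze = FreezeSpec()
    out["frozen_parameters"], out["total_parameters"] = count_frozen_parameters(
        low_ensemble.members[0], freeze
    )

    for r in range(n_repeats):
        seed_r = world.seed + 5000 + 97 * r
        high = sample_high_dataset(world, high_budget, seed_r)
        tcfg = TrainConfig(
            max_epochs=transfer_epochs, batch_size=32,
            validation_fraction=0.25, early_stopping_patience=100,
            lr_patience=40, split_by="conformation", seed=seed_r,
        )
        transferred = transfer_learn(low_ensemble, high, freeze, tcfg)
        t_mad, t_rmsd = delta_e_errors(transferred, world.test_high, spec)
        out["transfer_rmsd"].append(t_rmsd)
        out["transfer_mad"].append(t_mad)

        scfg = TrainConfig(
            max_epochs=scratch_epochs, split_by="conformation", seed=seed_r + 1
        )
        scratch_members = []
        se_high = _safe_self_energies(high, spec)
        s_splits = split_dataset(high, K, seed_r + 2, by="conformation")
        for k in range(K):
            m = init_model(spec, widths, seed=seed_r + 300 + k)
            m.self_energies = dict(se_high)
            trained, _ = train_model(m, s_splits[k], scfg.replace(seed=seed_r + 400 + k))
            scratch_members.append(trained)
        s_rmsd = delta_e_errors(Ensemble(scratch_members), world.test_high, spec)[1]
        out["scratch_rmsd"].append(s_rmsd)

        if include_delta:
            dcfg = TrainConfig(
                max_epochs=scratch_epochs, split_by="conformation", seed=seed_r + 3
            )
            _, combined = delta_learn(low_ensemble, high, dcfg)
            d_rmsd = delta_e_errors(combined, world.test_high, spec)[1]
            out["delta_rmsd"].append(d_rmsd)

        logger.info(
            "repeat %d: transfer %.2f scratch %.2f delta %s low %.2f",
            r, t_rmsd, s_rmsd,
            f"{out['delta_rmsd'][-1]:.2f}" if include_delta else "-", low_rmsd,
        )

    for key in ("transfer_rmsd", "transfer_mad", "scratch_rmsd", "delta_rmsd"):
        if out[key]:
            out["median_" + key] = float(np.median(out[key]))
    return out


def _safe_self_energies(dataset: Dataset, spec: AEVSpec) -> Dict[str, float]:
    """Least-squares baseline that tolerates rank deficiency (min-norm)."""
    elements = list(spec.supported_elements)
    A = np.array([c.element_counts(elements) for c in dataset.conformations])
    y = dataset.energies()
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return {e: float(c) for e, c in zip(elements, coef)}


def atomization_spread(
    predictor, world: BenchmarkWorld, self_energies: Dict[str, float]
) -> float:
    """Standard deviation of atomization-energy errors on the high test
    set; the desk-scale analogue of the error-distribution width."""
    pred_e = dataset_energies(predictor, world.test_high, world.spec)
    errs = pred_e - world.test_high.energies()
    return float(np.std(errs))


def disagreement_error_spearman(
    ensemble: Ensemble, test: Dataset, spec: AEVSpec
) -> float:
    """Spearman correlation between committee disagreement and absolute
    ensemble error on a held-out labeled set."""
    pred = dataset_energies(ensemble, test, spec)
    err = np.abs(pred - test.energies())
    dis = pool_disagreements(ensemble, test, normalize=True)
    rho = scipy.stats.spearmanr(dis, err).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# active learning vs random selection
# ---------------------------------------------------------------------------
def run_al_benchmark(
    world: BenchmarkWorld,
    low_ensemble: Ensemble,
    n_repeats: int = 5,
    initial: int = 24,
    iterations: int = 3,
    budget: int = 24,
    transfer_epochs: int = 200,
    K: int = 4,
) -> Dict[str, object]:
    """Query-by-committee curation versus random selection at equal total
    labeling budget, over `n_repeats` seeds.

    A K-member sub-committee keeps each retraining cheap; the total budget
    is `initial + iterations·budget` high-fidelity labels.
    """
    spec = world.spec
    committee = Ensemble(low_ensemble.members[:K])
    pool = world.corpus.low_dataset
    oracle = world.corpus.high_oracle()
    total = initial + iterations * budget

    out: Dict[str, object] = {
        "al_rmsd": [], "random_rmsd": [],
        "mean_disagreement_by_iteration": [],
        "total_budget": total,
    }
    for r in range(n_repeats):
        seed_r = world.seed + 9000 + 131 * r
        cfg = ALConfig(
            initial_random_size=initial, iterations=iterations,
            per_iteration_budget=budget, seed=seed_r,
        )
        tcfg = TrainConfig(
            max_epochs=transfer_epochs, batch_size=32,
            validation_fraction=0.25, early_stopping_patience=100,
            lr_patience=40, split_by="conformation", seed=seed_r,
        )
        curated, final, trace = active_learning_loop(
            committee, pool, oracle, cfg, tcfg
        )
        al_rmsd = delta_e_errors(final, world.test_high, spec)[1]

        rand = sample_high_dataset(world, total, seed_r + 7)
        rand_ens = transfer_learn(committee, rand, None, tcfg)
        rand_rmsd = delta_e_errors(rand_ens, world.test_high, spec)[1]

        out["al_rmsd"].append(al_rmsd)
        out["random_rmsd"].append(rand_rmsd)
        sel_rounds = [
            float(np.mean(rd["scores"])) if len(rd["scores"]) else np.nan
            for rd in trace.rounds
            if rd.get("kind") == "selection"
        ]
        out["mean_disagreement_by_iteration"].append(sel_rounds)
        logger.info("AL repeat %d: al %.2f random %.2f", r, al_rmsd, rand_rmsd)

    out["median_al_rmsd"] = float(np.median(out["al_rmsd"]))
    out["median_random_rmsd"] = float(np.median(out["random_rmsd"]))
    return out


# ---------------------------------------------------------------------------
# miniature end-to-end pipeline (determinism / smoke scale)
# ---------------------------------------------------------------------------
def run_small_pipeline(seed: int) -> Dict[str, float]:
    """A minutes-scale end-to-end run: tiny corpus → committee → active
    learning → transfer → evaluation.  Returns the flat numeric report used
    to verify bit-for-bit reproducibility under one master seed."""
    spec = AEVSpec(
        radial_shifts=tuple(np.linspace(0.9, 5.2, 8, endpoint=False)),
        angular_radial_shifts=tuple(np.linspace(0.9, 3.5, 2, endpoint=False)),
        angle_shifts=tuple(np.linspace(0.0, np.pi, 4, endpoint=False)),
    )
    world = build_world(seed, n_molecules=8, n_test_per_molecule=4, spec=spec)
    low_ens = pretrain_low_ensemble(world, K=2, widths=(16, 16, 8, 8), epochs=40)
    cfg = ALConfig(initial_random_size=12, iterations=2, per_iteration_budget=8,
                   seed=seed + 1)
    tcfg = TrainConfig(max_epochs=40, split_by="conformation", seed=seed + 2)
    curated, final, trace = active_learning_loop(
        low_ens, world.corpus.low_dataset, world.corpus.high_oracle(), cfg, tcfg
    )
    mad, rmsd = delta_e_errors(final, world.test_high, spec)
    low_mad, low_rmsd = delta_e_errors(low_ens, world.test_high, spec)
    return {
        "curated_size": float(len(curated)),
        "final_mad": mad,
        "final_rmsd": rmsd,
        "low_mad": low_mad,
        "low_rmsd": low_rmsd,
        "trace_sizes": float(sum(trace.dataset_sizes())),
    }
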