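"""Training contracts: self-energy regression, splits, optimizer progress,
freezing, and Δ-learning identities — on tiny fittable problems."""
import warnings

import numpy as np
import pytest

from nnpkit.conformation import Conformation
from nnpkit.model import Ensemble, init_model, predict_energy
from nnpkit.training import (
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


def _conf(mol, species, rng, energy_low=None, energy_high=None):
    coords = rng.normal(scale=1.2, size=(len(species), 3))
    return Conformation(mol, species, coords, energy_low=energy_low,
                        energy_high=energy_high)


def linear_dataset(rng, eps, n=20, fidelity="low"):
    """Energies exactly linear in element counts: E = sum_e n_e * eps[e]."""
    confs = []
    pool = list(eps)
    for m in range(n):
        k = int(rng.integers(2, 6))
        species = tuple(rng.choice(pool, size=k))
        e = float(sum(eps[s] for s in species))
        kw = {"energy_low": e} if fidelity == "low" else {"energy_high": e}
        confs.append(_conf(f"m{m}", species, rng, **kw))
    return Dataset(confs, fidelity=fidelity)


# ---------------------------------------------------------------------------
# self-energies
# ---------------------------------------------------------------------------
def test_self_energy_exact_recovery(rng):
    eps = {"H": 2.0, "C": 5.0}
    ds = linear_dataset(rng, eps)
    got = fit_atomic_self_energies(ds)
    assert got["H"] == pytest.approx(2.0, abs=1e-8)
    assert got["C"] == pytest.approx(5.0, abs=1e-8)


def test_self_energy_rank_deficiency_names_elements(rng):
    c = _conf("only", ("C", "O"), rng, energy_low=1.0)
    with pytest.raises(ValueError, match="confounded"):
        fit_atomic_self_energies(Dataset([c], fidelity="low"))


def test_self_energy_matches_normal_equations(rng):
    eps = {"H": -1.3, "C": 4.7, "O": -2.2}
    ds = linear_dataset(rng, eps, n=40)
    noisy = Dataset(
        [
            c.with_(energy_low=c.energy_low + float(rng.normal(scale=0.3)))
            for c in ds.conformations
        ],
        fidelity="low",
    )
    elements = ["H", "C", "O"]
    A = np.array([c.element_counts(elements) for c in noisy.conformations])
    y = noisy.energies()
    ref = np.linalg.solve(A.T @ A, A.T @ y)
    got = fit_atomic_self_energies(noisy, elements)
    for e, r in zip(elements, ref):
        assert got[e] == pytest.approx(r, abs=1e-8)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------
def test_split_count_and_determinism(rng):
    ds = linear_dataset(rng, {"H": 1.0, "C": 2.0}, n=30)
    a = split_dataset(ds, 8, seed=5)
    b = split_dataset(ds, 8, seed=5)
    assert len(a) == 8
    for sa, sb in zip(a, b):
        assert sa.split == sb.split


def test_split_is_partition(rng):
    ds = linear_dataset(rng, {"H": 1.0, "C": 2.0}, n=30)
    for s in split_dataset(ds, 3, seed=1):
        assert sorted(
            s.indices_with_split("train") + s.indices_with_split("validation")
        ) == list(range(len(ds)))


def test_split_by_molecule_keeps_groups_together(rng):
    confs = []
    for m in range(10):
        for _ in range(4):
            confs.append(_conf(f"m{m}", ("C", "H"), rng, energy_low=1.0))
    ds = Dataset(confs, fidelity="low")
    for s in split_dataset(ds, 2, seed=0, by="molecule"):
        for idx in ds.groups().values():
            sides = {s.split[i] for i in idx}
            assert len(sides) == 1


def test_split_rejects_oversized_k(rng):
    ds = linear_dataset(rng, {"H": 1.0}, n=5)
    with pytest.raises(ValueError):
        split_dataset(ds, 6, seed=0)


# ---------------------------------------------------------------------------
# train_model
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def baseline_fit(small_spec_module, rng_module):
    """Dataset whose energies equal the self-energy baseline exactly."""
    eps = {"H": -0.5, "C": 1.5, "N": 0.7, "O": -1.1}
    ds = linear_dataset(rng_module, eps, n=24)
    m = init_model(small_spec_module, (8, 8, 4, 4), seed=0)
    m.self_energies = dict(eps)
    cfg = TrainConfig(max_epochs=250, batch_size=8, learning_rate=3e-3, seed=0,
                      split_by="conformation")
    trained, hist = train_model(m, ds, cfg)
    return ds, trained, hist, eps


# module-scoped copies of the fixtures
@pytest.fixture(scope="module")
def small_spec_module():
    from conftest import SMALL_SPEC

    return SMALL_SPEC


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(77)


def test_zero_residual_target_reaches_small_train_rmse(baseline_fit, small_spec_module):
    ds, trained, hist, eps = baseline_fit
    from nnpkit.model import predict_energy_from_aev

    # the loss target is exactly representable (all-zero atomic outputs):
    # the trained network must drive the training residuals to ~0
    rng = np.random.default_rng(0)
    aevs = ds.get_aevs(small_spec_module)
    energies = ds.energies()
    n_val = max(1, round(0.1 * len(ds)))
    train_idx = np.random.default_rng(0).permutation(len(ds))[n_val:]
    pred = np.array(
        [
            predict_energy_from_aev(trained, ds.conformations[i].species, aevs[i])
            for i in train_idx
        ]
    )
    rmse = np.sqrt(np.mean((pred - energies[train_idx]) ** 2))
    assert rmse < 1e-2


def test_training_reduces_loss(baseline_fit):
    _, _, hist, _ = baseline_fit
    assert hist["train_loss"][-1] < hist["train_loss"][0]


def test_best_validation_curve_non_increasing(baseline_fit):
    _, _, hist, _ = baseline_fit
    bv = hist["best_val"]
    assert all(b <= a + 1e-15 for a, b in zip(bv, bv[1:]))


def test_training_is_seed_deterministic(small_spec, rng):
    eps = {"H": 0.3, "C": -0.9}
    ds = linear_dataset(rng, eps, n=12)
    cfg = TrainConfig(max_epochs=5, batch_size=4, seed=3, split_by="conformation")
    runs = []
    for _ in range(2):
        m = init_model(small_spec, (8, 8, 4, 4), seed=1)
        m.self_energies = {e: 0.0 for e in small_spec.supported_elements}
        _, hist = train_model(m, ds, cfg)
        runs.append(hist["train_loss"])
    assert runs[0] == runs[1]


def test_empty_training_set_rejected(small_spec, rng):
    ds = linear_dataset(rng, {"H": 1.0}, n=3)
    ds.split = ["validation"] * 3
    m = init_model(small_spec, (8, 8, 4, 4), seed=0)
    m.self_energies = {e: 0.0 for e in small_spec.supported_elements}
    with pytest.raises(ValueError, match="empty training set"):
        train_model(m, ds, TrainConfig(max_epochs=2, seed=0))


# ---------------------------------------------------------------------------
# freezing / transfer
# ---------------------------------------------------------------------------
def _tiny_ensemble(small_spec, rng, eps, k=2):
    ds = linear_dataset(rng, eps, n=16)
    members = []
    for i in range(k):
        m = init_model(small_spec, (8, 8, 4, 4), seed=10 + i)
        m.self_energies = dict(eps)
        trained, _ = train_model(
            m, ds,
            TrainConfig(max_epochs=10, batch_size=8, seed=i, split_by="conformation"),
        )
        members.append(trained)
    return ds, Ensemble(members)


def test_freeze_spec_validation():
    with pytest.raises(ValueError):
        FreezeSpec(hidden_frozen=(True, False))
    fs = FreezeSpec()
    assert fs.hidden_frozen == (False, False, True, True)
    assert not fs.layer_is_frozen(4)  # output head always trainable


def test_frozen_layers_bit_identical_after_transfer(small_spec, rng):
    eps = {"H": 0.1, "C": 0.2, "N": -0.1, "O": 0.05}
    ds, ens = _tiny_ensemble(small_spec, rng, eps)
    hi = Dataset(
        [
            c.with_(energy_high=c.energy_low + 1.0 + 0.05 * c.n_atoms)
            for c in ds.conformations
        ],
        fidelity="high",
    )
    freeze = FreezeSpec()
    cfg = TrainConfig(max_epochs=8, batch_size=8, seed=0, split_by="conformation")
    new = transfer_learn(ens, hi, freeze, cfg)
    changed = 0
    for old_m, new_m in zip(ens.members, new.members):
        for e in small_spec.supported_elements:
            for li, ((Wo, bo), (Wn, bn)) in enumerate(
                zip(old_m.element_networks[e], new_m.element_networks[e])
            ):
                if freeze.layer_is_frozen(li):
                    np.testing.assert_array_equal(Wo, Wn)
                    np.testing.assert_array_equal(bo, bn)
                else:
                    changed += int(not np.array_equal(Wo, Wn))
    assert changed > 0


def test_frozen_parameter_count_matches_enumeration(small_spec):
    m = init_model(small_spec, (16, 16, 8, 8), seed=0)
    freeze = FreezeSpec()  # hidden layers 2 and 3 frozen
    frozen, total = count_frozen_parameters(m, freeze)
    per_elem_frozen = (16 * 8 + 8) + (8 * 8 + 8)
    assert frozen == per_elem_frozen * len(small_spec.supported_elements)
    assert total == m.parameter_count
    assert 0 < frozen < total


def test_all_frozen_transfer_is_noop_with_warning(small_spec, rng):
    eps = {"H": 0.1, "C": 0.2, "N": -0.1, "O": 0.05}
    ds, ens = _tiny_ensemble(small_spec, rng, eps)
    hi = Dataset(
        [c.with_(energy_high=c.energy_low + 2.0) for c in ds.conformations],
        fidelity="high",
    )
    with pytest.warns(UserWarning, match="frozen"):
        new = transfer_learn(
            ens, hi, FreezeSpec(hidden_frozen=(True,) * 4),
            TrainConfig(max_epochs=4, seed=0),
        )
    c = ds.conformations[0]
    assert predict_energy(new.members[0], c) == pytest.approx(
        predict_energy(ens.members[0], c), abs=1e-12
    )


# ---------------------------------------------------------------------------
# Δ-learning
# ---------------------------------------------------------------------------
def test_delta_learning_identity_and_zero_residual(small_spec, rng):
    eps = {"H": 0.1, "C": 0.2, "N": -0.1, "O": 0.05}
    ds, ens = _tiny_ensemble(small_spec, rng, eps)
    # high fidelity identical to low: correction target is ~zero residual
    hi = Dataset(
        [c.with_(energy_high=c.energy_low) for c in ds.conformations],
        fidelity="high",
    )
    cfg = TrainConfig(max_epochs=10, batch_size=8, seed=0, split_by="conformation")
    correction, combined = delta_learn(ens, hi, cfg, widths=(8, 8, 4, 4))
    from nnpkit.model import ensemble_predict

    for c in ds.conformations[:5]:
        base = ensemble_predict(ens, c)[0]
        corr = ensemble_predict(correction, c)[0]
        # combined(x) - base(x) = correction(x) exactly
        assert combined.predict_energy(c) - base == pytest.approx(corr, abs=1e-10)
        # zero-residual target: combined stays near base
        assert abs(combined.predict_energy(c) - base) < 1.0
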