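"""Metric correctness: energy-window filtering, pairwise conformer errors
against hand enumeration, atomization-error linearity, force errors, and
restrained torsion scans on analytic potentials."""
import math

import numpy as np
import pytest

from nnpkit.conformation import Conformation
from nnpkit.evaluation import (
    EvaluationReport,
    atomization_errors,
    conformer_pair_errors,
    filter_energy_window,
    force_errors,
    mad_rmsd,
    summarize_report,
    torsion_profile_mad,
    torsion_scan,
)
from nnpkit.training import Dataset
from nnpkit.synthetic import (
    ForceField,
    MoleculeTemplate,
    build_fidelity_pair,
    relax_geometry,
)


def _ds(energy_groups, fidelity="high"):
    confs = []
    for mol, energies in energy_groups.items():
        for e in energies:
            kw = {"energy_high": e} if fidelity == "high" else {"energy_low": e}
            confs.append(
                Conformation(mol, ("H", "H"), [[0, 0, 0], [0.8, 0, 0]], **kw)
            )
    return Dataset(confs, fidelity=fidelity)


# ---------------------------------------------------------------------------
# energy window
# ---------------------------------------------------------------------------
def test_window_threshold():
    ds = _ds({"a": [0.0, 50.0, 150.0]})
    kept = filter_energy_window(ds, 100.0)
    assert sorted(kept.energies()) == [0.0, 50.0]


def test_infinite_window_keeps_everything():
    ds = _ds({"a": [0.0, 50.0, 150.0], "b": [3.0]})
    assert len(filter_energy_window(ds, np.inf)) == len(ds)


def test_window_monotone_in_kept_count():
    ds = _ds({"a": list(np.linspace(0, 200, 17)), "b": [0.0, 90.0, 180.0]})
    counts = [len(filter_energy_window(ds, w)) for w in (10, 50, 100, 250)]
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# conformer pair errors
# ---------------------------------------------------------------------------
def test_identical_predictions_zero_error():
    ref = {"m": np.array([0.0, 1.0, 2.0])}
    assert conformer_pair_errors(ref, ref) == (0.0, 0.0)


def test_pairwise_errors_hand_enumerated():
    # pairs of pred {0,1,3}: 1,3,2 ; ref {0,1,2}: 1,2,1 -> errors {0,1,1}
    pred = {"m": np.array([0.0, 1.0, 3.0])}
    ref = {"m": np.array([0.0, 1.0, 2.0])}
    mad, rmsd = conformer_pair_errors(pred, ref)
    assert mad == pytest.approx(2.0 / 3.0)
    assert rmsd == pytest.approx(math.sqrt(2.0 / 3.0))


def test_shift_invariance_of_pair_errors(rng):
    pred = {"m": rng.normal(size=6), "n": rng.normal(size=5)}
    ref = {"m": rng.normal(size=6), "n": rng.normal(size=5)}
    base = conformer_pair_errors(pred, ref)
    shifted = {k: v + 17.3 for k, v in pred.items()}
    assert conformer_pair_errors(shifted, ref) == pytest.approx(base)


def test_single_conformer_molecules_are_skipped():
    pred = {"a": np.array([1.0]), "b": np.array([0.0, 1.0])}
    ref = {"a": np.array([5.0]), "b": np.array([0.0, 1.0])}
    assert conformer_pair_errors(pred, ref) == (0.0, 0.0)
    with pytest.raises(ValueError):
        conformer_pair_errors({"a": np.array([1.0])}, {"a": np.array([5.0])})


def test_mad_rmsd_two_routes_agree(rng):
    errs = rng.normal(size=1000)
    mad, rmsd = mad_rmsd(errs)
    # independent streaming computation
    s_abs = 0.0
    s_sq = 0.0
    for e in errs:
        s_abs += abs(e)
        s_sq += e * e
    assert mad == pytest.approx(s_abs / len(errs), abs=1e-12)
    assert rmsd == pytest.approx(math.sqrt(s_sq / len(errs)), abs=1e-12)
    assert rmsd >= mad


# ---------------------------------------------------------------------------
# atomization errors
# ---------------------------------------------------------------------------
def test_atomization_zero_when_shared(rng):
    ds = _ds({"a": [3.0, 4.0], "b": [5.0]})
    se = {"H": 1.5}
    mad, rmsd, errs = atomization_errors(
        lambda c: c.energy_high, ds, se
    )
    np.testing.assert_allclose(errs, 0.0, atol=1e-12)


def test_atomization_self_energy_linearity():
    ds = _ds({"a": [3.0], "b": [7.0]})
    base = atomization_errors(lambda c: c.energy_high, ds, {"H": 1.0},
                              ref_self_energies={"H": 1.0})[2]
    shifted = atomization_errors(lambda c: c.energy_high, ds, {"H": 1.0 + 0.25},
                                 ref_self_energies={"H": 1.0})[2]
    np.testing.assert_allclose(shifted - base, -0.25 * 2, atol=1e-12)


def test_atomization_linear_refit_removes_element_shift(rng):
    confs = []
    for m in range(8):
        n_h = int(rng.integers(1, 5))
        species = tuple(["C"] + ["H"] * n_h)
        e = 10.0 + 0.5 * n_h
        confs.append(
            Conformation(f"m{m}", species, rng.normal(size=(1 + n_h, 3)) * 3,
                         energy_high=e)
        )
    ds = Dataset(confs, fidelity="high")
    # prediction differs from reference by an element-linear shift only
    pred = lambda c: c.energy_high + 1.2 * c.species.count("H") - 0.7
    se = {"H": 0.0, "C": 0.0}
    _, _, errs = atomization_errors(pred, ds, se, linear_refit=True)
    np.testing.assert_allclose(errs, 0.0, atol=1e-8)


def test_atomization_missing_element_raises():
    ds = _ds({"a": [1.0]})
    with pytest.raises(KeyError):
        atomization_errors(lambda c: 0.0, ds, {"C": 1.0})


# ---------------------------------------------------------------------------
# force errors
# ---------------------------------------------------------------------------
def test_force_errors_basic_and_oracle(rng):
    a = rng.normal(size=(5, 3))
    assert force_errors(a, a) == (0.0, 0.0)
    mae, rmse = force_errors(a + 1.0, a)
    assert (mae, rmse) == (pytest.approx(1.0), pytest.approx(1.0))
    b = rng.normal(size=(5, 3))
    mae, rmse = force_errors(a, b)
    diffs = [a[i, d] - b[i, d] for i in range(5) for d in range(3)]
    assert mae == pytest.approx(np.mean(np.abs(diffs)))
    assert rmse == pytest.approx(np.sqrt(np.mean(np.square(diffs))))
    with pytest.raises(ValueError):
        force_errors(a, b[:3])


# ---------------------------------------------------------------------------
# torsion scans
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def butane_like():
    """C4 chain saturated with H, relaxed on the low-fidelity oracle."""
    pair = build_fidelity_pair(seed=17, delta=0.05)
    species = ["C", "C", "C", "C"]
    bonds = [(0, 1), (1, 2), (2, 3)]
    deg = [1, 2, 2, 1]
    for a in range(4):
        for _ in range(4 - deg[a]):
            h = len(species)
            species.append("H")
            bonds.append((a, h))
    rng = np.random.default_rng(5)
    guess = np.array(
        [[0, 0, 0], [1.5, 0, 0], [2.2, 1.3, 0], [3.7, 1.3, 0.2]], dtype=float
    )
    coords = np.zeros((len(species), 3))
    coords[:4] = guess
    hi = 4
    for a in range(4):
        for _ in range(4 - deg[a]):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            coords[hi] = coords[a] + 1.09 * d
            hi += 1
    t = MoleculeTemplate("butane", tuple(species), tuple(bonds), coords)
    pes = pair.potential(t, "low")
    minimum = relax_geometry(t, pes)
    return pair, t, pes, minimum


def test_torsion_scan_grid_and_restraint(butane_like):
    pair, t, pes, minimum = butane_like
    profile = torsion_scan(pes, minimum, (0, 1, 2, 3), step=10.0)
    assert profile.shape == (36, 2)
    np.testing.assert_array_equal(profile[:, 0], np.arange(0, 360, 10.0))
    assert profile[:, 1].min() == 0.0
    assert np.all(profile[:, 1] >= 0)


def _ethane_template(rng_seed=2):
    species = ["C", "C"]
    bonds = [(0, 1)]
    rng = np.random.default_rng(rng_seed)
    coords = np.array([[0.0, 0, 0], [1.53, 0, 0]])
    for a in range(2):
        for _ in range(3):
            h = len(species)
            species.append("H")
            bonds.append((a, h))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            coords = np.vstack([coords, coords[a] + 1.09 * d])
    return MoleculeTemplate("ethane", tuple(species), tuple(bonds), coords)


def test_torsion_barrier_matches_analytic_coefficient(butane_like):
    """Single-cosine limit: an ethane-like rotor whose nine H-C-C-H 3-fold
    terms stay in phase sweeps a barrier of exactly 9V when the caps are
    held rigid by stiff bends; the restrained scan must recover it."""
    pair, _, _, _ = butane_like
    ff = pair.low
    V = 2.0
    stiff = ForceField(
        baselines=ff.baselines,
        bond=ff.bond,
        angle={e: (500.0, t0) for e, (k, t0) in ff.angle.items()},
        torsion={p: (V, 3, 0.0) for p in ff.torsion},
        repulsion=(0.0, 0.35),
    )
    t = _ethane_template()
    pes = stiff.bind(t)
    minimum = relax_geometry(t, pes)
    profile = torsion_scan(pes, minimum, (2, 0, 1, 5), step=10.0)
    barrier = profile[:, 1].max()
    assert barrier == pytest.approx(9 * V, rel=0.02)


def test_flat_profile_without_torsion_term(butane_like):
    pair, _, _, _ = butane_like
    ff = pair.low
    flat = ForceField(
        baselines=ff.baselines,
        bond=ff.bond,
        angle={e: (k, t0) for e, (k, t0) in ff.angle.items()},
        torsion={p: (0.0, 3, 0.0) for p in ff.torsion},
        repulsion=(0.0, 0.35),
    )
    t = _ethane_template(rng_seed=3)
    pes = flat.bind(t)
    minimum = relax_geometry(t, pes)
    profile = torsion_scan(pes, minimum, (2, 0, 1, 5), step=30.0)
    assert profile[:, 1].max() < 0.1


def test_torsion_profile_mad_alignment():
    a = np.column_stack([np.arange(0, 360, 10.0), np.zeros(36)])
    b = a.copy()
    b[:, 1] += 5.0  # constant offset disappears after min alignment
    assert torsion_profile_mad(a, b) == 0.0


def test_torsion_scan_input_validation(butane_like):
    _, _, pes, minimum = butane_like
    with pytest.raises(ValueError):
        torsion_scan(pes, minimum, (0, 1, 2, 3), step=7.0)
    with pytest.raises(ValueError):
        torsion_scan(pes, minimum, (0, 1, 1, 3), step=10.0)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------
def test_report_round_trip_and_invariants():
    rep = summarize_report(
        metadata={"window": 100.0},
        conformer_delta_e=(1.25, 2.5),
        forces={"mae": 0.3, "rmse": 0.4},
    )
    again = EvaluationReport.from_json(rep.to_json())
    assert again.metrics == rep.metrics
    with pytest.raises(ValueError):
        summarize_report()
    with pytest.raises(ValueError):
        summarize_report(bad=(2.0, 1.0))  # RMSD < MAD is impossible
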