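"""Self-contained correctness probes used by the acceptance tooling.

Each function recomputes one verifiable quantity from scratch — descriptor
agreement with a naive reference implementation, force/finite-difference
consistency, self-energy recovery, torsion-scan fidelity — and returns
plain numbers.  The heavyweight learning comparisons live in
:mod:`nnpkit.benchmarks`.
"""
from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np

from .conformation import Conformation
from .featurization import AEVSpec, compute_aev
from .model import init_model, predict_energy, predict_forces
from .training import Dataset, fit_atomic_self_energies


def _random_conformation(rng, n_max=8):
    n = int(rng.integers(2, n_max + 1))
    species = tuple(rng.choice(["H", "C", "N", "O"], size=n))
    coords = rng.normal(scale=1.3, size=(n, 3))
    for _ in range(60):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.6:
            break
        i, _ = np.unravel_index(np.argmin(d), d.shape)
        coords[i] += rng.normal(scale=0.4, size=3)
    return Conformation("probe", species, coords)


def naive_aev_reference(conf: Conformation, spec: AEVSpec) -> np.ndarray:
    """Direct triple-loop evaluation of the symmetry functions, written
    independently of the vectorized production path."""
    n = conf.n_atoms
    x = conf.coordinates
    out = np.zeros((n, spec.feature_length))
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            r = float(np.linalg.norm(x[i] - x[j]))
            if r >= spec.radial_cutoff:
                continue
            fc = 0.5 * math.cos(math.pi * r / spec.radial_cutoff) + 0.5
            off = spec.radial_offset(conf.species[j])
            for si, rs in enumerate(spec.radial_shifts):
                out[i, off + si] += math.exp(-spec.radial_width * (r - rs) ** 2) * fc
        for j in range(n):
            if j == i:
                continue
            for k in range(j + 1, n):
                if k == i:
                    continue
                r1 = float(np.linalg.norm(x[j] - x[i]))
                r2 = float(np.linalg.norm(x[k] - x[i]))
                if r1 >= spec.angular_cutoff or r2 >= spec.angular_cutoff:
                    continue
                cosv = float((x[j] - x[i]) @ (x[k] - x[i]) / (r1 * r2))
                theta = math.acos(max(-1.0, min(1.0, cosv)))
                fc1 = 0.5 * math.cos(math.pi * r1 / spec.angular_cutoff) + 0.5
                fc2 = 0.5 * math.cos(math.pi * r2 / spec.angular_cutoff) + 0.5
                off = spec.angular_offset(conf.species[j], conf.species[k])
                z = spec.angular_sharpness
                pos = 0
                for rs in spec.angular_radial_shifts:
                    for ts in spec.angle_shifts:
                        out[i, off + pos] += (
                            2 ** (1 - z)
                            * (1 + math.cos(theta - ts)) ** z
                            * math.exp(-spec.angular_width * ((r1 + r2) / 2 - rs) ** 2)
                            * fc1 * fc2
                        )
                        pos += 1
    return out


def aev_oracle_deviation(seed: int, n_conformations: int = 100) -> Tuple[float, int]:
    """Largest |AEV − naive reference| over random conformations (N ≤ 8),
    including randomly rotated/translated/permuted replicas."""
    rng = np.random.default_rng(seed)
    spec = AEVSpec()
    worst = 0.0
    for _ in range(n_conformations):
        conf = _random_conformation(rng)
        got = compute_aev(conf, spec).values
        ref = naive_aev_reference(conf, spec)
        worst = max(worst, float(np.abs(got - ref).max()))
        # invariance replica
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, a, b, c = q
        R = np.array([
            [1 - 2 * (b * b + c * c), 2 * (a * b - w * c), 2 * (a * c + w * b)],
            [2 * (a * b + w * c), 1 - 2 * (a * a + c * c), 2 * (b * c - w * a)],
            [2 * (a * c - w * b), 2 * (b * c + w * a), 1 - 2 * (a * a + b * b)],
        ])
        perm = rng.permutation(conf.n_atoms)
        moved = Conformation(
            "probe",
            tuple(conf.species[p] for p in perm),
            (conf.coordinates @ R.T + rng.normal(scale=5, size=3))[perm],
        )
        worst = max(
            worst, float(np.abs(compute_aev(moved, spec).values - got[perm]).max())
        )
    return worst, n_conformations


def force_fd_deviation(seed: int, n_conformations: int = 20) -> Dict[str, float]:
    """Analytic forces of a random model vs central finite differences
    (step 1e-4 Å): worst relative deviation and worst net-force residual."""
    rng = np.random.default_rng(seed)
    spec = AEVSpec()
    model = init_model(spec, (16, 16, 8, 8), seed=seed)
    model.self_energies = {e: 0.0 for e in spec.supported_elements}
    h = 1e-4
    worst_rel = 0.0
    worst_net = 0.0
    for _ in range(n_conformations):
        conf = _random_conformation(rng, n_max=6)
        F = predict_forces(model, conf)
        scale = max(float(np.abs(F).max()), 1e-6)
        worst_net = max(worst_net, float(np.abs(F.sum(axis=0)).max()))
        x = conf.coordinates
        for i in range(conf.n_atoms):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                fd = -(
                    predict_energy(model, conf.with_(coordinates=xp))
                    - predict_energy(model, conf.with_(coordinates=xm))
                ) / (2 * h)
                worst_rel = max(worst_rel, abs(F[i, d] - fd) / scale)
    return {"max_rel_dev": worst_rel, "max_net_force": worst_net, "n": n_conformations}


def self_energy_recovery(seed: int, n_molecules: int = 30) -> Tuple[float, int]:
    """Largest |fitted − true| per-element energy on an exactly linear
    synthetic energy model."""
    rng = np.random.default_rng(seed)
    eps = {"H": -0.5 + rng.normal(), "C": 1.5 + rng.normal(),
           "N": 0.7 + rng.normal(), "O": -1.1 + rng.normal()}
    confs = []
    for m in range(n_molecules):
        k = int(rng.integers(2, 7))
        species = tuple(rng.choice(list(eps), size=k))
        confs.append(
            Conformation(
                f"m{m}", species, rng.normal(size=(k, 3)) * 2,
                energy_low=float(sum(eps[s] for s in species)),
            )
        )
    fitted = fit_atomic_self_energies(Dataset(confs, fidelity="low"))
    worst = max(abs(fitted[e] - eps[e]) for e in eps)
    return worst, n_molecules


def torsion_machinery_check(seed: int) -> Dict[str, float]:
    """10° restrained scan of a stiff-capped ethane-like rotor with a
    single 3-fold cosine: point count, worst dihedral miss, and barrier
    error against the closed-form 9V."""
    from .evaluation import torsion_scan
    from .geometry import wrap_angle
    from .synthetic import ForceField, MoleculeTemplate, build_fidelity_pair, relax_geometry

    pair = build_fidelity_pair(seed=seed, delta=0.05)
    V = 2.0
    ff = ForceField(
        baselines=pair.low.baselines,
        bond=pair.low.bond,
        angle={e: (500.0, t0) for e, (k, t0) in pair.low.angle.items()},
        torsion={p: (V, 3, 0.0) for p in pair.low.torsion},
        repulsion=(0.0, 0.35),
    )
    rng = np.random.default_rng(seed)
    species = ["C", "C"]
    bonds = [(0, 1)]
    coords = np.array([[0.0, 0, 0], [1.53, 0, 0]])
    for a in range(2):
        for _ in range(3):
            hidx = len(species)
            species.append("H")
            bonds.append((a, hidx))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            coords = np.vstack([coords, coords[a] + 1.09 * d])
    t = MoleculeTemplate("rotor", tuple(species), tuple(bonds), coords)
    pes = ff.bind(t)
    minimum = relax_geometry(t, pes)

    profile = torsion_scan(pes, minimum, (2, 0, 1, 5), step=10.0, include_achieved=True)
    barrier = float(profile[:, 1].max())
    miss = max(
        abs(math.degrees(wrap_angle(math.radians(a - tgt))))
        for tgt, a in zip(profile[:, 0], profile[:, 2])
    )
    return {
        "n_points": float(len(profile)),
        "barrier": barrier,
        "barrier_rel_err_pct": abs(barrier - 9 * V) / (9 * V) * 100.0,
        "max_dihedral_miss_deg": miss,
    }
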