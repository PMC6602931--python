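"""Synthetic two-fidelity molecular world.

This module generates everything the learning pipeline consumes: random
valence-respecting CHNO molecule templates, relaxed geometries, normal-mode
perturbed conformers, and a pair of analytic potential-energy oracles — a
"low" level and a "high" level — standing in for two levels of quantum
chemistry (an abundant, cheap method and a scarce, accurate one).

Both oracles share one functional family over the bonded topology:

    E = Σ_e n_e ε_e                                    (atomic baselines)
      + Σ_bonds    D (1 − exp(−a (r − r0)))²           (Morse)
      + Σ_angles   k_θ (θ − θ0)²                       (harmonic bend)
      + Σ_torsions ½ V (1 + cos(n φ − γ))              (periodic torsion)
      + Σ_nb       A exp(−r/ρ)                         (soft repulsion)

The high level differs from the low level in three controlled ways that
mimic the relationship between two levels of theory: (a) systematically
shifted per-element baselines, (b) every bonded parameter perturbed by a
relative scale δ (default 0.05), and (c) an extra bond–bond coupling term
k_c Δr_ij Δr_jk over bends, absent from the low level, so the discrepancy
has a conformation-dependent component as well as a systematic one.  Both
oracles are C¹ with analytic forces.

All generation is deterministic from a single seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

from .conformation import Conformation
from .geometry import (
    bend_gradient,
    bond_gradient,
    dihedral_gradient,
)
from .training import Dataset

VALENCE = {"H": 1, "C": 4, "N": 3, "O": 2}
HEAVY = ("C", "N", "O")
# reference equilibrium bond lengths, Å, by sorted element pair
_R0 = {
    ("C", "C"): 1.53, ("C", "H"): 1.09, ("C", "N"): 1.47, ("C", "O"): 1.43,
    ("H", "H"): 0.74, ("H", "N"): 1.01, ("H", "O"): 0.96,
    ("N", "N"): 1.45, ("N", "O"): 1.40, ("O", "O"): 1.48,
}


@dataclass
class MoleculeTemplate:
    """Species, bonded topology (tree or a single ring), and an
    equilibrium-guess geometry."""

    molecule_id: str
    species: tuple
    bonds: tuple  # tuple of (i, j) with i < j
    coordinates: np.ndarray

    def __post_init__(self):
        self.species = tuple(self.species)
        self.bonds = tuple(tuple(sorted(b)) for b in self.bonds)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        deg = [0] * len(self.species)
        for i, j in self.bonds:
            deg[i] += 1
            deg[j] += 1
        for a, (s, d) in enumerate(zip(self.species, deg)):
            if d > VALENCE[s]:
                raise ValueError(f"atom {a} ({s}) exceeds valence {VALENCE[s]}")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def neighbor_lists(self) -> List[List[int]]:
        nb: List[List[int]] = [[] for _ in self.species]
        for i, j in self.bonds:
            nb[i].append(j)
            nb[j].append(i)
        return nb

    def angles(self) -> List[Tuple[int, int, int]]:
        """All bend triples (i, j, k) with j the center, i < k."""
        nb = self.neighbor_lists()
        out = []
        for j, ns in enumerate(nb):
            for ai in range(len(ns)):
                for bi in range(ai + 1, len(ns)):
                    out.append((ns[ai], j, ns[bi]))
        return out

    def torsions(self) -> List[Tuple[int, int, int, int]]:
        """All proper dihedrals (i, j, k, l) over central bonds j-k."""
        nb = self.neighbor_lists()
        out = []
        for j, k in self.bonds:
            for i in nb[j]:
                if i == k:
                    continue
                for l in nb[k]:
                    if l == j or l == i:
                        continue
                    out.append((i, j, k, l))
        return out

    def nonbonded_pairs(self) -> List[Tuple[int, int]]:
        """Atom pairs separated by three or more bonds (1-2 and 1-3
        excluded)."""
        n = self.n_atoms
        excluded = {tuple(sorted(b)) for b in self.bonds}
        for i, j, k in self.angles():
            excluded.add(tuple(sorted((i, k))))
        return [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in excluded
        ]


# ---------------------------------------------------------------------------
# Force-field parameter tables
# ---------------------------------------------------------------------------
@dataclass
class ForceField:
    """Type-keyed parameter tables defining one analytic PES level."""

    baselines: Dict[str, float]
    bond: Dict[tuple, Tuple[float, float, float]]  # pair -> (D, a, r0)
    angle: Dict[str, Tuple[float, float]]  # center element -> (k, theta0)
    torsion: Dict[tuple, Tuple[float, int, float]]  # central pair -> (V, n, gamma)
    repulsion: Tuple[float, float] = (2500.0, 0.35)  # (A, rho)
    bond_coupling: float = 0.0  # k_c of the bend-adjacent Δr·Δr term

    def bind(self, template: MoleculeTemplate) -> "MoleculePES":
        return MoleculePES(self, template)


class MoleculePES:
    """A force field bound to one molecule's topology: a callable analytic
    potential with exact gradients."""

    def __init__(self, ff: ForceField, template: MoleculeTemplate):
        self.ff = ff
        self.template = template
        t = template
        self._bond_terms = [
            ((i, j), ff.bond[tuple(sorted((t.species[i], t.species[j])))])
            for i, j in t.bonds
        ]
        self._angle_terms = [
            ((i, j, k), ff.angle[t.species[j]]) for i, j, k in t.angles()
        ]
        self._torsion_terms = [
            ((i, j, k, l), ff.torsion[tuple(sorted((t.species[j], t.species[k])))])
            for i, j, k, l in t.torsions()
        ]
        self._nb_pairs = t.nonbonded_pairs()
        self._baseline = sum(ff.baselines[s] for s in t.species)

    def energy(self, coords: np.ndarray) -> float:
        return self._eval(np.asarray(coords, dtype=float), want_grad=False)[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self._eval(np.asarray(coords, dtype=float), want_grad=True)[1]

    def energy_forces(self, coords: np.ndarray) -> Tuple[float, np.ndarray]:
        e, g = self._eval(np.asarray(coords, dtype=float), want_grad=True)
        return e, -g

    def __call__(self, conformation: Conformation) -> Tuple[float, np.ndarray]:
        return self.energy_forces(conformation.coordinates)

    def _eval(self, x: np.ndarray, want_grad: bool):
        E = self._baseline
        g = np.zeros_like(x) if want_grad else None
        A_rep, rho = self.ff.repulsion

        bond_dev = {}  # (i, j) -> r - r0, reused by the coupling term
        for (i, j), (D, a, r0) in self._bond_terms:
            r, ui, uj = bond_gradient(x, i, j)
            e = math.exp(-a * (r - r0))
            E += D * (1.0 - e) ** 2
            bond_dev[(i, j)] = r - r0
            bond_dev[(j, i)] = r - r0
            if want_grad:
                dEdr = 2.0 * D * (1.0 - e) * a * e
                g[i] += dEdr * ui
                g[j] += dEdr * uj

        for (i, j, k), (kth, th0) in self._angle_terms:
            theta, gi, gj, gk = bend_gradient(x, i, j, k)
            E += kth * (theta - th0) ** 2
            if want_grad:
                dEdth = 2.0 * kth * (theta - th0)
                g[i] += dEdth * gi
                g[j] += dEdth * gj
                g[k] += dEdth * gk

        for (i, j, k, l), (V, n, gamma) in self._torsion_terms:
            phi, gi, gj, gk, gl = dihedral_gradient(x, i, j, k, l)
            E += 0.5 * V * (1.0 + math.cos(n * phi - gamma))
            if want_grad:
                dEdphi = -0.5 * V * n * math.sin(n * phi - gamma)
                g[i] += dEdphi * gi
                g[j] += dEdphi * gj
                g[k] += dEdphi * gk
                g[l] += dEdphi * gl

        for i, j in self._nb_pairs:
            r, ui, uj = bond_gradient(x, i, j)
            e = A_rep * math.exp(-r / rho)
            E += e
            if want_grad:
                dEdr = -e / rho
                g[i] += dEdr * ui
                g[j] += dEdr * uj

        kc = self.ff.bond_coupling
        if kc != 0.0:
            for (i, j, k), _ in self._angle_terms:
                d1 = bond_dev.get((j, i))
                d2 = bond_dev.get((j, k))
                if d1 is None or d2 is None:
                    continue  # bend arms are always bonds; defensive
                E += kc * d1 * d2
                if want_grad:
                    _, ui, uj1 = bond_gradient(x, i, j)
                    _, uk, uj2 = bond_gradient(x, k, j)
                    g[i] += kc * d2 * ui
                    g[j] += kc * (d2 * uj1 + d1 * uj2)
                    g[k] += kc * d1 * uk
        if not np.isfinite(E):
            raise FloatingPointError("non-finite energy")
        return float(E), g


@dataclass
class FidelityPair:
    """The paired low/high analytic oracles plus the perturbation scale
    that generated them."""

    low: ForceField
    high: ForceField
    delta: float
    seed: int

    def potential(self, template: MoleculeTemplate, fidelity: str) -> MoleculePES:
        if fidelity == "low":
            return self.low.bind(template)
        if fidelity == "high":
            return self.high.bind(template)
        raise ValueError(f"unknown fidelity {fidelity!r}")


def build_fidelity_pair(seed: int, delta: float = 0.05) -> FidelityPair:
    """Deterministically construct the paired oracles.

    At δ = 0 the high level coincides with the low level up to the
    systematic per-element baseline shift, which is drawn independently of
    δ (the shift models the offset between levels of theory; δ models the
    conformation-dependent disagreement).
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    rng = np.random.default_rng(seed)

    baselines = {"H": -340.0, "C": -23700.0, "N": -34200.0, "O": -47000.0}
    bond: Dict[tuple, Tuple[float, float, float]] = {}
    for pair, r0 in _R0.items():
        D = float(rng.uniform(80.0, 110.0))
        a = float(rng.uniform(1.8, 2.2))
        bond[pair] = (D, a, r0)
    angle = {
        e: (float(rng.uniform(30.0, 60.0)), math.radians(109.5))
        for e in ("H", "C", "N", "O")
    }
    torsion: Dict[tuple, Tuple[float, int, float]] = {}
    for pair in _R0:
        torsion[pair] = (float(rng.uniform(1.0, 3.0)), 3, 0.0)
    low = ForceField(baselines=baselines, bond=bond, angle=angle, torsion=torsion)

    # high level: shifted baselines, δ-perturbed bonded terms, extra coupling
    shift_rng = np.random.default_rng(seed + 1)
    hi_base = {
        e: v + float(shift_rng.normal(0.0, 4.0)) for e, v in baselines.items()
    }

    def perturb(v: float) -> float:
        return v * (1.0 + delta * float(shift_rng.uniform(-1.0, 1.0)))

    hi_bond = {
        p: (perturb(D), perturb(a), perturb(r0)) for p, (D, a, r0) in bond.items()
    }
    hi_angle = {e: (perturb(k), perturb(t0)) for e, (k, t0) in angle.items()}
    hi_torsion = {
        p: (perturb(V), n, g) for p, (V, n, g) in torsion.items()
    }
    high = ForceField(
        baselines=hi_base,
        bond=hi_bond,
        angle=hi_angle,
        torsion=hi_torsion,
        bond_coupling=delta * 200.0,
    )
    return FidelityPair(low=low, high=high, delta=delta, seed=int(seed))


# ---------------------------------------------------------------------------
# Molecule generation
# ---------------------------------------------------------------------------
def generate_molecules(
    n: int,
    heavy_atom_range: Tuple[int, int] = (2, 5),
    seed: int = 0,
    ring_probability: float = 0.3,
    id_prefix: str = "mol",
) -> List[MoleculeTemplate]:
    """Random valence-respecting heavy-atom trees (optionally closed into a
    single ring), saturated with hydrogens, with a rough 3D embedding as
    the equilibrium guess.

    Heavy atoms are drawn from {C, N, O} with carbon favoured; each heavy
    atom then receives hydrogens up to its free valence.
    """
    lo, hi = heavy_atom_range
    if not (2 <= lo <= hi <= 8):
        raise ValueError("heavy_atom_range must satisfy 2 <= min <= max <= 8")
    rng = np.random.default_rng(seed)
    out = []
    for m in range(n):
        n_heavy = int(rng.integers(lo, hi + 1))
        species = list(rng.choice(HEAVY, size=n_heavy, p=[0.6, 0.2, 0.2]))
        deg = [0] * n_heavy
        bonds = []
        for a in range(1, n_heavy):
            # attach to a random earlier atom with spare valence
            candidates = [
                b for b in range(a) if deg[b] < VALENCE[species[b]]
            ]
            if not candidates:
                # regrow impossible trees with a fresh draw (O-only chains
                # can dead-end); retry by restarting this molecule
                break
            b = int(rng.choice(candidates))
            bonds.append((b, a))
            deg[a] += 1
            deg[b] += 1
        else:
            if n_heavy >= 3 and rng.random() < ring_probability:
                ring_cands = [
                    (i, j)
                    for i in range(n_heavy)
                    for j in range(i + 1, n_heavy)
                    if (i, j) not in bonds
                    and deg[i] < VALENCE[species[i]]
                    and deg[j] < VALENCE[species[j]]
                ]
                if ring_cands:
                    i, j = ring_cands[int(rng.integers(len(ring_cands)))]
                    bonds.append((i, j))
                    deg[i] += 1
                    deg[j] += 1
            # saturate with H
            for a in range(n_heavy):
                for _ in range(VALENCE[species[a]] - deg[a]):
                    h = len(species)
                    species.append("H")
                    bonds.append((a, h))
            coords = _embed(species, bonds, rng)
            out.append(
                MoleculeTemplate(
                    molecule_id=f"{id_prefix}{m:04d}",
                    species=tuple(species),
                    bonds=tuple(bonds),
                    coordinates=coords,
                )
            )
            continue
        # retry loop for the rare dead-end: draw again with fresh randomness
        while True:
            retry = generate_molecules(
                1, (n_heavy, n_heavy), seed=int(rng.integers(2**31)),
                ring_probability=ring_probability, id_prefix="tmp",
            )
            if retry:
                t = retry[0]
                out.append(
                    MoleculeTemplate(
                        molecule_id=f"{id_prefix}{m:04d}",
                        species=t.species,
                        bonds=t.bonds,
                        coordinates=t.coordinates,
                    )
                )
                break
    return out


def _embed(species, bonds, rng) -> np.ndarray:
    """Greedy 3D embedding: BFS placement at reference bond lengths with
    clash rejection; good enough as a relaxation starting point."""
    n = len(species)
    nb: List[List[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        nb[i].append(j)
        nb[j].append(i)
    coords = np.zeros((n, 3))
    placed = {0}
    queue = [0]
    while queue:
        p = queue.pop(0)
        for q in nb[p]:
            if q in placed:
                continue
            r0 = _R0[tuple(sorted((species[p], species[q])))]
            for _ in range(60):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                pos = coords[p] + r0 * d
                dists = np.linalg.norm(
                    coords[list(placed - {p})] - pos, axis=1
                ) if len(placed) > 1 else np.array([np.inf])
                if dists.min() > 0.85 * r0:
                    break
            coords[q] = pos
            placed.add(q)
            queue.append(q)
    return coords + rng.normal(scale=0.02, size=coords.shape)


# ---------------------------------------------------------------------------
# Relaxation and normal-mode sampling
# ---------------------------------------------------------------------------
def relax_geometry(
    template: MoleculeTemplate,
    pes: MoleculePES,
    tol: float = 1e-5,
    max_steps: int = 2000,
    coordinates: Optional[np.ndarray] = None,
) -> Conformation:
    """Minimize the PES from the template's guess geometry until the
    largest force component is below `tol` (kcal/mol/Å)."""
    x0 = np.asarray(
        coordinates if coordinates is not None else template.coordinates, dtype=float
    )
    if not np.all(np.isfinite(x0)):
        raise ValueError("starting coordinates must be finite")
    def fun(v):
        e, f = pes.energy_forces(v.reshape(-1, 3))
        return e, -f.ravel()

    res = scipy.optimize.minimize(
        fun,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": tol * 0.1, "ftol": 1e-16},
    )
    x = res.x.reshape(-1, 3)
    # Newton polish with a finite-difference Hessian if L-BFGS stalls short
    for _ in range(30):
        g = pes.gradient(x)
        if np.abs(g).max() <= tol:
            break
        H = _fd_hessian(pes, x)
        H_reg = H + 1e-8 * np.eye(H.shape[0])
        step = np.linalg.solve(H_reg, g.ravel())
        x = x - step.reshape(-1, 3)
    else:
        raise RuntimeError(
            f"relaxation did not reach |F|max <= {tol}; "
            f"residual {np.abs(pes.gradient(x)).max():.3e} for {template.molecule_id}"
        )
    g = pes.gradient(x)
    if np.abs(g).max() > tol:
        raise RuntimeError(
            f"relaxation did not reach |F|max <= {tol}; residual "
            f"{np.abs(g).max():.3e} for {template.molecule_id}"
        )
    return Conformation(template.molecule_id, template.species, x)


def _fd_hessian(pes: MoleculePES, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of the PES from analytic gradients."""
    n3 = x.size
    H = np.zeros((n3, n3))
    flat = x.ravel()
    for k in range(n3):
        xp = flat.copy()
        xm = flat.copy()
        xp[k] += step
        xm[k] -= step
        gp = pes.gradient(xp.reshape(-1, 3)).ravel()
        gm = pes.gradient(xm.reshape(-1, 3)).ravel()
        H[:, k] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def _is_linear(x: np.ndarray, tol: float = 1e-6) -> bool:
    if len(x) <= 2:
        return True
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] < tol * max(s[0], 1.0))


def normal_mode_sample(
    minimum: Conformation,
    pes: MoleculePES,
    n_conf: int,
    scale: float = 0.6,
    seed: int = 0,
    grad_tol: float = 1e-3,
) -> List[Conformation]:
    """Displace a minimized geometry along its (unit-mass) normal modes.

    The Hessian comes from central finite differences of the analytic
    gradient; the 6 near-zero modes (5 for linear molecules) are dropped,
    and each remaining mode k gets a seeded Gaussian coefficient with
    variance 2·scale/λ_k so its expected harmonic energy is `scale`
    (kcal/mol) — a temperature-like knob (0.6 ≈ kT at room temperature).
    """
    x0 = minimum.coordinates
    if np.abs(pes.gradient(x0)).max() > grad_tol:
        raise ValueError("normal-mode sampling requires a relaxed minimum")
    H = _fd_hessian(pes, x0)
    evals, evecs = np.linalg.eigh(H)
    n_drop = 5 if _is_linear(x0) else 6
    order = np.argsort(np.abs(evals))
    keep = np.sort(order[n_drop:])
    lam = evals[keep]
    if np.any(lam < -1e-4 * max(np.abs(evals).max(), 1.0)):
        raise ValueError("negative Hessian eigenvalue: not a minimum (saddle point?)")
    lam = np.maximum(lam, 1e-8)
    modes = evecs[:, keep]
    rng = np.random.default_rng(seed)
    out = []
    for c in range(n_conf):
        coeff = rng.normal(size=len(lam)) * np.sqrt(2.0 * scale / lam)
        disp = (modes @ coeff).reshape(-1, 3)
        out.append(
            Conformation(minimum.molecule_id, minimum.species, x0 + disp)
        )
    return out


# ---------------------------------------------------------------------------
# Labeling and the full corpus pipeline
# ---------------------------------------------------------------------------
def label_dataset(
    conformations: Sequence[Conformation],
    pes_by_molecule: Dict[str, MoleculePES],
    fidelity: str,
    attach_forces: bool = True,
    check_forces: bool = False,
) -> Dataset:
    """Attach oracle energies (and forces) at one fidelity.

    `check_forces` spot-verifies the analytic forces against central finite
    differences on up to 10 conformations.
    """
    labeled = []
    for c in conformations:
        pes = pes_by_molecule[c.molecule_id]
        E, F = pes.energy_forces(c.coordinates)
        if not np.isfinite(E):
            raise FloatingPointError(f"non-finite energy for {c.molecule_id}")
        kw = {"forces": F} if attach_forces else {}
        if fidelity == "low":
            labeled.append(c.with_(energy_low=float(E), **kw))
        else:
            labeled.append(c.with_(energy_high=float(E), **kw))
    if check_forces and labeled:
        rng = np.random.default_rng(0)
        picks = rng.choice(len(labeled), size=min(10, len(labeled)), replace=False)
        for i in picks:
            c = labeled[i]
            pes = pes_by_molecule[c.molecule_id]
            _spot_check_forces(pes, c.coordinates)
    return Dataset(list(labeled), fidelity=fidelity)


def _spot_check_forces(pes: MoleculePES, x: np.ndarray, h: float = 1e-5, rtol: float = 1e-5):
    _, F = pes.energy_forces(x)
    scale = max(np.abs(F).max(), 1.0)
    rng = np.random.default_rng(1)
    for _ in range(6):
        i = int(rng.integers(x.shape[0]))
        d = int(rng.integers(3))
        xp = x.copy()
        xm = x.copy()
        xp[i, d] += h
        xm[i, d] -= h
        fd = -(pes.energy(xp) - pes.energy(xm)) / (2.0 * h)
        if abs(fd - F[i, d]) > rtol * scale + 1e-7:
            raise AssertionError(
                f"analytic force mismatch at atom {i} component {d}: "
                f"{F[i, d]:.8f} vs FD {fd:.8f}"
            )


@dataclass
class SyntheticCorpus:
    """The full deterministic synthetic world used by the benchmarks."""

    templates: List[MoleculeTemplate]
    pair: FidelityPair
    minima: Dict[str, Conformation]
    low_dataset: Dataset
    conformers: Dict[str, List[Conformation]]
    seed: int

    def low_pes(self) -> Dict[str, MoleculePES]:
        return {t.molecule_id: self.pair.potential(t, "low") for t in self.templates}

    def high_pes(self) -> Dict[str, MoleculePES]:
        return {t.molecule_id: self.pair.potential(t, "high") for t in self.templates}

    def high_oracle(self) -> Callable[[Conformation], Tuple[float, np.ndarray]]:
        pes = self.high_pes()
        return lambda conf: pes[conf.molecule_id].energy_forces(conf.coordinates)


def generate_corpus(
    seed: int,
    n_molecules: int = 60,
    conformers_per_molecule: Tuple[int, int] = (12, 24),
    heavy_atom_range: Tuple[int, int] = (2, 5),
    scale: float = 0.6,
    delta: float = 0.05,
) -> SyntheticCorpus:
    """End-to-end corpus generation: molecules → low-level minima →
    normal-mode conformers → low-fidelity labels.

    Defaults emulate the study conditions at desk scale: ~60 molecules with
    12–24 non-equilibrium conformers each (≈ 1,000 low-fidelity points),
    with the high-fidelity oracle reserved for a small, actively selected
    subset.
    """
    ss = np.random.SeedSequence(seed)
    s_mol, s_conf = [int(s) % 2**31 for s in ss.generate_state(2)]
    templates = generate_molecules(n_molecules, heavy_atom_range, seed=s_mol)
    pair = build_fidelity_pair(seed=s_mol + 7, delta=delta)
    rng = np.random.default_rng(s_conf)
    minima: Dict[str, Conformation] = {}
    conformers: Dict[str, List[Conformation]] = {}
    low_pes: Dict[str, MoleculePES] = {}
    all_confs: List[Conformation] = []
    for t in templates:
        pes = pair.potential(t, "low")
        low_pes[t.molecule_id] = pes
        minimum = relax_geometry(t, pes)
        minima[t.molecule_id] = minimum
        n_conf = int(rng.integers(conformers_per_molecule[0], conformers_per_molecule[1] + 1))
        confs = normal_mode_sample(
            minimum, pes, n_conf, scale=scale, seed=int(rng.integers(2**31))
        )
        conformers[t.molecule_id] = confs
        all_confs.extend(confs)
    low_dataset = label_dataset(all_confs, low_pes, "low")
    return SyntheticCorpus(
        templates=templates,
        pair=pair,
        minima=minima,
        low_dataset=low_dataset,
        conformers=conformers,
        seed=int(seed),
    )


def find_rotatable_bond(template: MoleculeTemplate) -> Optional[Tuple[int, int, int, int]]:
    """A proper dihedral (i, j, k, l) around a heavy-heavy bond whose both
    ends carry at least one further neighbor; None when the molecule has no
    rotatable bond."""
    nb = template.neighbor_lists()
    for j, k in template.bonds:
        if template.species[j] == "H" or template.species[k] == "H":
            continue
        js = [a for a in nb[j] if a != k]
        ks = [a for a in nb[k] if a != j]
        if js and ks:
            return (js[0], j, k, ks[0])
    return None
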