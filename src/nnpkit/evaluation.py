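"""Accuracy metrics: conformer ΔE MAD/RMSD, atomization-energy errors,
force MAE/RMSE, and restrained torsion profiles.

Conformer ΔE is formed over all unordered conformer pairs of each molecule
(so any per-molecule constant offset cancels), errors pooled across
molecules by default.  An energy window relative to each molecule's
reference minimum (default 100 kcal/mol) filters high-energy conformations
before scoring.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.optimize

from .conformation import Conformation
from .geometry import dihedral_angle, dihedral_gradient, wrap_angle
from .model import Ensemble, NNPModel, ensemble_predict, predict_energy
from .training import Dataset

EnergyModel = Union[NNPModel, Ensemble, Callable[[Conformation], float]]


def _as_energy_fn(model: EnergyModel) -> Callable[[Conformation], float]:
    if isinstance(model, NNPModel):
        return lambda c: predict_energy(model, c)
    if isinstance(model, Ensemble):
        return lambda c: ensemble_predict(model, c)[0]
    if hasattr(model, "predict_energy"):
        return model.predict_energy  # e.g. the Δ-learning combined predictor
    return model


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------
def filter_energy_window(dataset: Dataset, window: float = 100.0) -> Dataset:
    """Keep conformations within `window` kcal/mol of each molecule's own
    reference-energy minimum."""
    energies = dataset.energies()
    keep: List[int] = []
    for mol, idx in dataset.groups().items():
        if not idx:
            raise ValueError(f"empty conformer group for {mol}")
        emin = energies[idx].min()
        keep.extend(i for i in idx if energies[i] - emin <= window)
    keep.sort()
    return dataset.subset(keep)


# ---------------------------------------------------------------------------
# Scalar error summaries
# ---------------------------------------------------------------------------
def mad_rmsd(errors: np.ndarray) -> Tuple[float, float]:
    errors = np.asarray(errors, dtype=float)
    return float(np.mean(np.abs(errors))), float(np.sqrt(np.mean(errors**2)))


def conformer_pair_errors(
    pred: Dict[str, np.ndarray],
    ref: Dict[str, np.ndarray],
    per_molecule: bool = False,
    min_referenced: bool = False,
) -> Tuple[float, float]:
    """(MAD, RMSD) of conformer energy differences.

    `pred` and `ref` map molecule id → aligned energy arrays.  By default
    ΔE runs over all unordered conformer pairs and errors are pooled across
    molecules; `min_referenced` instead references every conformer to its
    molecule's reference-minimum conformer, and `per_molecule` averages the
    per-molecule MAD/RMSD instead of pooling.
    """
    pooled: List[float] = []
    per_mol: List[Tuple[float, float]] = []
    for mol, r in ref.items():
        p = np.asarray(pred[mol], dtype=float)
        r = np.asarray(r, dtype=float)
        if p.shape != r.shape:
            raise ValueError(f"misaligned energies for {mol}")
        if len(r) < 2:
            continue
        if min_referenced:
            i0 = int(np.argmin(r))
            errs = (p - p[i0]) - (r - r[i0])
            errs = np.delete(errs, i0)
        else:
            iu, ju = np.triu_indices(len(r), k=1)
            errs = (p[iu] - p[ju]) - (r[iu] - r[ju])
        pooled.extend(errs.tolist())
        per_mol.append(mad_rmsd(errs))
    if not pooled:
        raise ValueError("no molecule has two or more conformers")
    if per_molecule:
        mads, rmsds = zip(*per_mol)
        return float(np.mean(mads)), float(np.mean(rmsds))
    return mad_rmsd(np.asarray(pooled))


def dataset_pair_errors(
    model: EnergyModel, dataset: Dataset, **kw
) -> Tuple[float, float]:
    """Conformer ΔE errors of a model against a labeled dataset."""
    fn = _as_energy_fn(model)
    ref_e = dataset.energies()
    pred: Dict[str, np.ndarray] = {}
    ref: Dict[str, np.ndarray] = {}
    for mol, idx in dataset.groups().items():
        pred[mol] = np.array([fn(dataset.conformations[i]) for i in idx])
        ref[mol] = ref_e[idx]
    return conformer_pair_errors(pred, ref, **kw)


def atomization_errors(
    pred_model: EnergyModel,
    dataset: Dataset,
    self_energies: Dict[str, float],
    ref_self_energies: Optional[Dict[str, float]] = None,
    linear_refit: bool = False,
) -> Tuple[float, float, np.ndarray]:
    """(MAD, RMSD, error distribution) of atomization energies
    E^a = E_total − Σ_i ε(Z_i).

    `self_energies` are used on the prediction side and, unless
    `ref_self_energies` is given, on the reference side too.  With
    `linear_refit`, a per-element linear correction is least-squares
    fitted to the errors and removed first — the post-hoc correction of a
    systematic inter-method shift.
    """
    fn = _as_energy_fn(pred_model)
    ref_se = ref_self_energies if ref_self_energies is not None else self_energies
    errs = []
    counts = []
    elements = sorted(
        {s for c in dataset.conformations for s in c.species}
    )
    for c, e_ref in zip(dataset.conformations, dataset.energies()):
        for s in set(c.species):
            if s not in self_energies or s not in ref_se:
                raise KeyError(f"missing self-energy for element {s!r}")
        ea_pred = fn(c) - sum(self_energies[s] for s in c.species)
        ea_ref = e_ref - sum(ref_se[s] for s in c.species)
        errs.append(ea_pred - ea_ref)
        counts.append(c.element_counts(elements))
    errs = np.asarray(errs)
    if linear_refit:
        A = np.asarray(counts)
        coef, *_ = np.linalg.lstsq(A, errs, rcond=None)
        errs = errs - A @ coef
    mad, rmsd = mad_rmsd(errs)
    return mad, rmsd, errs


def force_errors(pred_forces, ref_forces) -> Tuple[float, float]:
    """(MAE, RMSE) pooled over all atoms and Cartesian components.

    Accepts single N×3 arrays or sequences of them.
    """
    if isinstance(pred_forces, np.ndarray):
        pred_forces, ref_forces = [pred_forces], [ref_forces]
    diffs = []
    for p, r in zip(pred_forces, ref_forces):
        p = np.asarray(p, dtype=float)
        r = np.asarray(r, dtype=float)
        if p.shape != r.shape:
            raise ValueError(f"force shape mismatch: {p.shape} vs {r.shape}")
        diffs.append((p - r).ravel())
    d = np.concatenate(diffs)
    return float(np.mean(np.abs(d))), float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# Torsion scans
# ---------------------------------------------------------------------------
class _ScanTarget:
    """Adapter exposing energy/gradient for either an analytic PES object
    (``.energy``/``.gradient``) or a neural potential."""

    def __init__(self, target, conformation: Conformation):
        if hasattr(target, "energy") and hasattr(target, "gradient"):
            self.energy = lambda x: target.energy(x)
            self.gradient = lambda x: target.gradient(x)
        elif isinstance(target, (NNPModel, Ensemble)):
            members = target.members if isinstance(target, Ensemble) else [target]
            sp = conformation.species
            mid = conformation.molecule_id

            def energy(x):
                c = Conformation(mid, sp, x)
                return float(np.mean([predict_energy(m, c) for m in members]))

            def gradient(x):
                from .model import predict_forces

                c = Conformation(mid, sp, x)
                return -np.mean([predict_forces(m, c) for m in members], axis=0)

            self.energy = energy
            self.gradient = gradient
        else:
            raise TypeError("torsion_scan needs a PES-like object or a model/ensemble")


def torsion_scan(
    target,
    conformation: Conformation,
    dihedral: Tuple[int, int, int, int],
    step: float = 10.0,
    restraint_k: float = 1000.0,
    angle_tolerance: float = 0.5,
    include_achieved: bool = False,
) -> np.ndarray:
    """Restrained torsion profile.

    The dihedral is driven to each grid angle (every `step` degrees over
    360°) with a harmonic restraint on the wrapped angle difference while
    all other degrees of freedom relax; the restraint force constant is
    escalated until the achieved dihedral is within `angle_tolerance`
    degrees of the target.  Returns an array of shape (360/step, 2):
    (target angle in degrees, relaxed energy relative to the profile
    minimum, kcal/mol); with `include_achieved`, a third column carries the
    achieved dihedral in degrees.
    """
    if 360.0 % step != 0:
        raise ValueError("step must divide 360")
    i, j, k, l = dihedral
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    tgt = _ScanTarget(target, conformation)
    angles = np.arange(0.0, 360.0, step)
    energies = np.empty_like(angles)
    achieved_angles = np.empty_like(angles)
    x = conformation.coordinates.copy()

    for gi, ang in enumerate(angles):
        phi0 = math.radians(ang)
        kr = restraint_k
        for attempt in range(5):
            def fun(v, kr=kr):
                xx = v.reshape(-1, 3)
                g = tgt.gradient(xx).copy()
                e = tgt.energy(xx)
                phi, gi_, gj_, gk_, gl_ = dihedral_gradient(xx, i, j, k, l)
                d = wrap_angle(phi - phi0)
                c = kr * d
                g[i] += c * gi_
                g[j] += c * gj_
                g[k] += c * gk_
                g[l] += c * gl_
                return e + 0.5 * kr * d * d, g.ravel()

            res = scipy.optimize.minimize(
                fun, x.ravel(), jac=True, method="L-BFGS-B",
                options={"maxiter": 800, "ftol": 1e-14, "gtol": 1e-8},
            )
            xr = res.x.reshape(-1, 3)
            achieved = math.degrees(dihedral_angle(xr, i, j, k, l)) % 360.0
            miss = abs(wrap_angle(math.radians(achieved - ang)))
            if math.degrees(miss) <= angle_tolerance:
                break
            kr *= 10.0
        else:
            raise RuntimeError(
                f"restraint failed at {ang:.0f}°: achieved {achieved:.2f}°"
            )
        x = xr  # continue the scan from the previous relaxed geometry
        energies[gi] = tgt.energy(xr)
        achieved_angles[gi] = achieved

    energies -= energies.min()
    cols = [angles, energies] + ([achieved_angles] if include_achieved else [])
    return np.column_stack(cols)


def torsion_profile_mad(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """MAD between two min-aligned profiles on a shared angle grid."""
    a, b = np.asarray(profile_a), np.asarray(profile_b)
    if a.shape != b.shape or not np.allclose(a[:, 0], b[:, 0]):
        raise ValueError("profiles must share one angle grid")
    ea = a[:, 1] - a[:, 1].min()
    eb = b[:, 1] - b[:, 1].min()
    return float(np.mean(np.abs(ea - eb)))


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------
@dataclass
class EvaluationReport:
    """MAD/RMSD tables plus bookkeeping; serializes losslessly to JSON."""

    metrics: Dict[str, Dict[str, float]]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.metrics:
            raise ValueError("a report needs at least one metric")
        for name, m in self.metrics.items():
            mad = m.get("mad")
            rmsd = m.get("rmsd")
            if mad is not None and rmsd is not None and rmsd < mad - 1e-12:
                raise ValueError(f"metric {name}: RMSD {rmsd} below MAD {mad}")

    def to_json(self) -> str:
        return json.dumps(
            {"metrics": self.metrics, "metadata": self.metadata}, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(metrics=d["metrics"], metadata=d.get("metadata", {}))

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "statistic", "value"])
            for name in sorted(self.metrics):
                for stat in sorted(self.metrics[name]):
                    w.writerow([name, stat, repr(self.metrics[name][stat])])


def summarize_report(metadata: Optional[dict] = None, **metrics) -> EvaluationReport:
    """Bundle named (MAD, RMSD) pairs or {stat: value} dicts into a report."""
    table: Dict[str, Dict[str, float]] = {}
    for name, v in metrics.items():
        if isinstance(v, dict):
            table[name] = {k: float(x) for k, x in v.items()}
        else:
            mad, rmsd = v
            table[name] = {"mad": float(mad), "rmsd": float(rmsd)}
    return EvaluationReport(metrics=table, metadata=metadata or {})
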