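"""Atomic environment vectors (AEVs): element-resolved radial and angular
symmetry functions.

Each atom is described by a fixed-length vector built from smooth, strictly
local functions of interatomic distances and angles, so the descriptor is
invariant to translation, rotation, and permutation of same-element atoms,
and every term vanishes smoothly at the cutoff.

Feature layout of a row (length ``spec.feature_length``):

* first, one radial block per supported element, in ``supported_elements``
  order; within a block, one entry per radial shift ``R_s``;
* then, one angular block per unordered element pair, pairs enumerated in
  lexicographic symbol order (e.g. ("C","C"), ("C","H"), ... for CHNO);
  within a block the entries run over angular radial shifts (outer) and
  angle shifts (inner).

This ordering is stable across versions and is serialized with every model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .conformation import Conformation, DEFAULT_ELEMENTS

_SIN_EPS = 1e-8  # lower clamp on sin(theta) in gradient denominators


def _default_radial_shifts() -> tuple:
    return tuple(np.linspace(0.9, 5.2, 16, endpoint=False))


def _default_angular_radial_shifts() -> tuple:
    return tuple(np.linspace(0.9, 3.5, 4, endpoint=False))


def _default_angle_shifts() -> tuple:
    return tuple(np.linspace(0.0, math.pi, 8, endpoint=False))


@dataclass(frozen=True)
class AEVSpec:
    """Hyperparameters of the atomic environment vector.

    Defaults follow the conventions of symmetry-function potentials for
    CHNO organic molecules; all values are configurable and are stored
    inside saved models so predictions are reproducible.

    Attributes
    ----------
    supported_elements : tuple of str
        Ordered element vocabulary; one radial block per element and one
        angular block per unordered pair.
    radial_cutoff, angular_cutoff : float, Å
        Cutoffs of the cosine switching function (angular <= radial).
    radial_shifts : tuple of float, Å
        Gaussian centers ``R_s`` of the radial functions.
    radial_width : float, Å⁻²
        Gaussian width ``η_R``.
    angular_radial_shifts : tuple of float, Å
        Centers ``R'_s`` applied to the mean pair distance.
    angular_width : float, Å⁻²
        Gaussian width ``η_A``.
    angle_shifts : tuple of float, radians
        Angular centers ``θ_s``.
    angular_sharpness : float
        Exponent ``ζ`` of the ``(1 + cos(θ − θ_s))`` factor.
    """

    supported_elements: tuple = DEFAULT_ELEMENTS
    radial_cutoff: float = 5.2
    angular_cutoff: float = 3.5
    radial_shifts: tuple = field(default_factory=_default_radial_shifts)
    radial_width: float = 16.0
    angular_radial_shifts: tuple = field(default_factory=_default_angular_radial_shifts)
    angular_width: float = 8.0
    angle_shifts: tuple = field(default_factory=_default_angle_shifts)
    angular_sharpness: float = 32.0

    def __post_init__(self):
        object.__setattr__(self, "supported_elements", tuple(self.supported_elements))
        object.__setattr__(self, "radial_shifts", tuple(float(x) for x in self.radial_shifts))
        object.__setattr__(
            self, "angular_radial_shifts", tuple(float(x) for x in self.angular_radial_shifts)
        )
        object.__setattr__(self, "angle_shifts", tuple(float(x) for x in self.angle_shifts))
        if self.angular_cutoff > self.radial_cutoff:
            raise ValueError("angular cutoff must not exceed the radial cutoff")
        if self.radial_cutoff <= 0 or self.angular_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if max(self.radial_shifts) >= self.radial_cutoff:
            raise ValueError("radial shifts must lie below the radial cutoff")
        if max(self.angular_radial_shifts) >= self.angular_cutoff:
            raise ValueError("angular radial shifts must lie below the angular cutoff")

    # -- derived layout ----------------------------------------------------
    @property
    def element_pairs(self) -> List[Tuple[str, str]]:
        """Unordered element pairs in lexicographic symbol order."""
        sorted_elems = sorted(self.supported_elements)
        return [
            (a, b)
            for ia, a in enumerate(sorted_elems)
            for b in sorted_elems[ia:]
        ]

    @property
    def n_radial_features(self) -> int:
        return len(self.supported_elements) * len(self.radial_shifts)

    @property
    def n_angular_features(self) -> int:
        return len(self.element_pairs) * len(self.angular_radial_shifts) * len(self.angle_shifts)

    @property
    def feature_length(self) -> int:
        return self.n_radial_features + self.n_angular_features

    def radial_offset(self, element: str) -> int:
        """Start index of the radial block for `element`."""
        return self.supported_elements.index(element) * len(self.radial_shifts)

    def angular_offset(self, e1: str, e2: str) -> int:
        """Start index of the angular block for the unordered pair (e1, e2)."""
        pair = tuple(sorted((e1, e2)))
        k = self.element_pairs.index(pair)
        return self.n_radial_features + k * len(self.angular_radial_shifts) * len(self.angle_shifts)

    def feature_labels(self) -> List[tuple]:
        """Per-feature provenance: (kind, element(s), shift indices)."""
        labels: List[tuple] = []
        for e in self.supported_elements:
            for si in range(len(self.radial_shifts)):
                labels.append(("radial", e, si))
        for pair in self.element_pairs:
            for ri in range(len(self.angular_radial_shifts)):
                for ti in range(len(self.angle_shifts)):
                    labels.append(("angular", pair, ri, ti))
        return labels

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "supported_elements": list(self.supported_elements),
            "radial_cutoff": self.radial_cutoff,
            "angular_cutoff": self.angular_cutoff,
            "radial_shifts": list(self.radial_shifts),
            "radial_width": self.radial_width,
            "angular_radial_shifts": list(self.angular_radial_shifts),
            "angular_width": self.angular_width,
            "angle_shifts": list(self.angle_shifts),
            "angular_sharpness": self.angular_sharpness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AEVSpec":
        return cls(
            supported_elements=tuple(d["supported_elements"]),
            radial_cutoff=float(d["radial_cutoff"]),
            angular_cutoff=float(d["angular_cutoff"]),
            radial_shifts=tuple(d["radial_shifts"]),
            radial_width=float(d["radial_width"]),
            angular_radial_shifts=tuple(d["angular_radial_shifts"]),
            angular_width=float(d["angular_width"]),
            angle_shifts=tuple(d["angle_shifts"]),
            angular_sharpness=float(d["angular_sharpness"]),
        )


@dataclass
class AEVMatrix:
    """The realized N×L descriptor, with the layout metadata that names
    each column."""

    values: np.ndarray
    spec: AEVSpec

    @property
    def element_block_index(self) -> List[tuple]:
        return self.spec.feature_labels()


def cutoff_fn(R, R_c: float):
    """Cosine switching function: 0.5·cos(πR/R_c) + 0.5 for R ≤ R_c, else 0.

    Continuous, monotone non-increasing on [0, R_c], exactly zero beyond.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("distances must be non-negative")
    if R_c <= 0:
        raise ValueError("cutoff must be positive")
    out = np.where(R < R_c, 0.5 * np.cos(np.pi * R / R_c) + 0.5, 0.0)
    return out if out.ndim else float(out)


def _cutoff_deriv(R, R_c: float):
    R = np.asarray(R, dtype=float)
    out = np.where(R < R_c, -0.5 * np.pi / R_c * np.sin(np.pi * R / R_c), 0.0)
    return out


def _check_species(conformation: Conformation, spec: AEVSpec) -> None:
    for s in conformation.species:
        if s not in spec.supported_elements:
            raise ValueError(
                f"element {s!r} is not in the supported set {spec.supported_elements}"
            )


def radial_block(center_atom: int, conformation: Conformation, spec: AEVSpec) -> np.ndarray:
    """Radial symmetry functions of one atom.

    Entry (element e, shift R_s) = Σ_{j: Z_j = e, j ≠ i}
    exp(−η_R (R_ij − R_s)²) · fc(R_ij, R_cR).
    """
    _check_species(conformation, spec)
    x = conformation.coordinates
    i = center_atom
    n = conformation.n_atoms
    shifts = np.asarray(spec.radial_shifts)
    out = np.zeros(spec.n_radial_features)
    if n == 1:
        return out
    others = [j for j in range(n) if j != i]
    d = np.linalg.norm(x[others] - x[i], axis=1)
    fc = cutoff_fn(d, spec.radial_cutoff)
    gauss = np.exp(-spec.radial_width * (d[:, None] - shifts[None, :]) ** 2)
    terms = gauss * fc[:, None]
    for row, j in zip(terms, others):
        off = spec.radial_offset(conformation.species[j])
        out[off : off + len(shifts)] += row
    return out


def _angular_terms(spec: AEVSpec, R1: float, R2: float, cos_t: float) -> np.ndarray:
    """All (R'_s, θ_s) terms for one (j, k) neighbor pair; shape (n_R', n_θ)."""
    zeta = spec.angular_sharpness
    theta = math.acos(min(1.0, max(-1.0, cos_t)))
    th_shifts = np.asarray(spec.angle_shifts)
    r_shifts = np.asarray(spec.angular_radial_shifts)
    ang = (1.0 + np.cos(theta - th_shifts)) ** zeta
    rad = np.exp(-spec.angular_width * (0.5 * (R1 + R2) - r_shifts) ** 2)
    fcc = cutoff_fn(R1, spec.angular_cutoff) * cutoff_fn(R2, spec.angular_cutoff)
    return 2.0 ** (1.0 - zeta) * fcc * rad[:, None] * ang[None, :]


def angular_block(center_atom: int, conformation: Conformation, spec: AEVSpec) -> np.ndarray:
    """Angular symmetry functions of one atom.

    Entry (pair (e1,e2), R'_s, θ_s) = 2^{1−ζ} Σ_{(j,k)} (1+cos(θ_ijk−θ_s))^ζ
    · exp(−η_A ((R_ij+R_ik)/2 − R'_s)²) · fc(R_ij) fc(R_ik), the sum running
    over unordered neighbor pairs of matching elements within the angular
    cutoff.  cos θ is clamped to [−1, 1] before acos, so colinear triples
    are handled without NaN.
    """
    _check_species(conformation, spec)
    x = conformation.coordinates
    i = center_atom
    out = np.zeros(spec.n_angular_features)
    blk = len(spec.angular_radial_shifts) * len(spec.angle_shifts)
    neigh = []
    for j in range(conformation.n_atoms):
        if j == i:
            continue
        R = float(np.linalg.norm(x[j] - x[i]))
        if 0 < R < spec.angular_cutoff:
            neigh.append((j, R))
    for a in range(len(neigh)):
        j, R1 = neigh[a]
        for b in range(a + 1, len(neigh)):
            k, R2 = neigh[b]
            rij = x[j] - x[i]
            rik = x[k] - x[i]
            cos_t = float(rij @ rik) / (R1 * R2)
            terms = _angular_terms(spec, R1, R2, cos_t)
            off = spec.angular_offset(conformation.species[j], conformation.species[k])
            out[off - spec.n_radial_features + 0 : off - spec.n_radial_features + blk] += (
                terms.ravel()
            )
    return out


def compute_aev(conformation: Conformation, spec: AEVSpec = AEVSpec()) -> AEVMatrix:
    """Full N×L descriptor matrix: per atom, radial blocks then angular
    blocks, in the fixed layout of `spec`."""
    _check_species(conformation, spec)
    n = conformation.n_atoms
    values = np.zeros((n, spec.feature_length))
    for i in range(n):
        values[i, : spec.n_radial_features] = radial_block(i, conformation, spec)
        values[i, spec.n_radial_features :] = angular_block(i, conformation, spec)
    return AEVMatrix(values=values, spec=spec)


def aev_adjoint_gradient(
    conformation: Conformation, spec: AEVSpec, weights: np.ndarray
) -> np.ndarray:
    """Chain-rule contraction Σ_{i,f} weights[i,f] · ∂AEV[i,f]/∂x → (N, 3).

    `weights` is typically ∂E/∂AEV from a network backward pass; the result
    is then ∂E/∂coordinates, from which forces are −gradient.  All
    derivatives are analytic; the only guard is a lower clamp on sin θ in
    the angle-derivative denominator, which matters only within 1e−8 of
    exactly colinear triples.
    """
    _check_species(conformation, spec)
    x = conformation.coordinates
    n = conformation.n_atoms
    grad = np.zeros((n, 3))
    r_shifts = np.asarray(spec.radial_shifts)
    a_r_shifts = np.asarray(spec.angular_radial_shifts)
    th_shifts = np.asarray(spec.angle_shifts)
    zeta = spec.angular_sharpness
    n_rs = len(r_shifts)

    # radial part: ordered pairs (i, j); feature rows of atom i, block of Z_j
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            rij = x[i] - x[j]
            R = float(np.linalg.norm(rij))
            if R >= spec.radial_cutoff or R == 0.0:
                continue
            u = rij / R
            off = spec.radial_offset(conformation.species[j])
            w = weights[i, off : off + n_rs]
            gauss = np.exp(-spec.radial_width * (R - r_shifts) ** 2)
            fc = cutoff_fn(R, spec.radial_cutoff)
            dfc = _cutoff_deriv(R, spec.radial_cutoff)
            dg_dR = gauss * (-2.0 * spec.radial_width * (R - r_shifts) * fc + dfc)
            coeff = float(w @ dg_dR)
            grad[i] += coeff * u
            grad[j] -= coeff * u

    # angular part: center i, unordered neighbor pair (j, k)
    blk = len(a_r_shifts) * len(th_shifts)
    for i in range(n):
        neigh = []
        for j in range(n):
            if j == i:
                continue
            R = float(np.linalg.norm(x[j] - x[i]))
            if 0 < R < spec.angular_cutoff:
                neigh.append((j, R))
        for a in range(len(neigh)):
            j, R1 = neigh[a]
            for b in range(a + 1, len(neigh)):
                k, R2 = neigh[b]
                va = x[j] - x[i]
                vb = x[k] - x[i]
                c = float(va @ vb) / (R1 * R2)
                c = min(1.0, max(-1.0, c))
                theta = math.acos(c)
                sin_t = max(math.sqrt(max(0.0, 1.0 - c * c)), _SIN_EPS)

                off = spec.angular_offset(
                    conformation.species[j], conformation.species[k]
                )
                w = weights[i, off : off + blk].reshape(len(a_r_shifts), len(th_shifts))

                fc1 = cutoff_fn(R1, spec.angular_cutoff)
                fc2 = cutoff_fn(R2, spec.angular_cutoff)
                dfc1 = float(_cutoff_deriv(R1, spec.angular_cutoff))
                dfc2 = float(_cutoff_deriv(R2, spec.angular_cutoff))
                ravg = 0.5 * (R1 + R2)
                gr = np.exp(-spec.angular_width * (ravg - a_r_shifts) ** 2)
                dgr = gr * (-2.0 * spec.angular_width * (ravg - a_r_shifts)) * 0.5
                base_ang = 1.0 + np.cos(theta - th_shifts)
                ang = base_ang**zeta
                dang = zeta * base_ang ** (zeta - 1.0) * (-np.sin(theta - th_shifts))
                pref = 2.0 ** (1.0 - zeta)

                # scalar sensitivities contracted with the weight block
                dT_dtheta = pref * fc1 * fc2 * float((w * (gr[:, None] * dang[None, :])).sum())
                s_rad = float((w * (dgr[:, None] * ang[None, :])).sum())
                s_full = float((w * (gr[:, None] * ang[None, :])).sum())
                dT_dR1 = pref * (fc1 * fc2 * s_rad + dfc1 * fc2 * s_full)
                dT_dR2 = pref * (fc1 * fc2 * s_rad + fc1 * dfc2 * s_full)

                ua = va / R1
                ub = vb / R2
                # dθ/d(va), dθ/d(vb) via θ = acos(va·vb / R1 R2)
                dc_da = vb / (R1 * R2) - c * va / (R1 * R1)
                dc_db = va / (R1 * R2) - c * vb / (R2 * R2)
                dth_da = -dc_da / sin_t
                dth_db = -dc_db / sin_t

                g_a = dT_dtheta * dth_da + dT_dR1 * ua  # ∂/∂va
                g_b = dT_dtheta * dth_db + dT_dR2 * ub  # ∂/∂vb
                grad[i] -= g_a + g_b  # va = xj − xi, vb = xk − xi
                grad[j] += g_a
                grad[k] += g_b
    return grad
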