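"""Internal-coordinate values and analytic Cartesian gradients.

Angles clamp the cosine into [-1, 1]; dihedrals use the atan2 form, so the
value is well defined except for exactly colinear backbone bonds.
"""
from __future__ import annotations

import math
from typing import Tuple

import numpy as np


def bond_length(x: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(x[i] - x[j]))


def bond_gradient(x: np.ndarray, i: int, j: int) -> Tuple[float, np.ndarray, np.ndarray]:
    """(r, dr/dxi, dr/dxj)."""
    d = x[i] - x[j]
    r = float(np.linalg.norm(d))
    u = d / r
    return r, u, -u


def bend_angle(x: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k at center j, radians."""
    a = x[i] - x[j]
    b = x[k] - x[j]
    c = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.acos(min(1.0, max(-1.0, c)))


def bend_gradient(x: np.ndarray, i: int, j: int, k: int):
    """(θ, dθ/dxi, dθ/dxj, dθ/dxk)."""
    a = x[i] - x[j]
    b = x[k] - x[j]
    ra = float(np.linalg.norm(a))
    rb = float(np.linalg.norm(b))
    c = float(a @ b) / (ra * rb)
    c = min(1.0, max(-1.0, c))
    s = max(math.sqrt(max(0.0, 1.0 - c * c)), 1e-10)
    theta = math.acos(c)
    dc_da = b / (ra * rb) - c * a / (ra * ra)
    dc_db = a / (ra * rb) - c * b / (rb * rb)
    gi = -dc_da / s
    gk = -dc_db / s
    gj = -(gi + gk)
    return theta, gi, gj, gk


def dihedral_angle(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Proper dihedral i-j-k-l in radians, in (−π, π]."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    y = float(m1 @ n2)
    c = float(n1 @ n2)
    return math.atan2(y, c)


def dihedral_gradient(x: np.ndarray, i: int, j: int, k: int, l: int):
    """(φ, dφ/dx for the four atoms) — the standard rigid-rotation-free
    result used in molecular mechanics."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    n1sq = float(n1 @ n1)
    n2sq = float(n2 @ n2)
    if n1sq < 1e-18 or n2sq < 1e-18:
        raise ValueError("dihedral undefined: colinear backbone atoms")
    phi = dihedral_angle(x, i, j, k, l)
    gi = nb2 / n1sq * n1
    gl = -nb2 / n2sq * n2
    f1 = float(b1 @ b2) / (nb2 * nb2)
    f2 = float(b3 @ b2) / (nb2 * nb2)
    gj = -(1.0 + f1) * gi + f2 * gl
    gk = f1 * gi - (1.0 + f2) * gl
    return phi, gi, gj, gk, gl


def wrap_angle(a: float) -> float:
    """Wrap to (−π, π]."""
    return float(math.atan2(math.sin(a), math.cos(a)))
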