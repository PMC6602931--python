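"""Descriptor correctness: cutoff function, radial/angular blocks against
hand/naive oracles, and the symmetry invariances of the full AEV."""
import math

import numpy as np
import pytest

from nnpkit.conformation import Conformation
from nnpkit.featurization import (
    AEVSpec,
    aev_adjoint_gradient,
    angular_block,
    compute_aev,
    cutoff_fn,
    radial_block,
)

from conftest import random_conformation


# ---------------------------------------------------------------------------
# Naive triple-loop reference implementation (the independent oracle)
# ---------------------------------------------------------------------------
def naive_aev(conf: Conformation, spec: AEVSpec) -> np.ndarray:
    n = conf.n_atoms
    x = conf.coordinates
    out = np.zeros((n, spec.feature_length))
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            r = np.linalg.norm(x[i] - x[j])
            if r >= spec.radial_cutoff:
                continue
            fc = 0.5 * math.cos(math.pi * r / spec.radial_cutoff) + 0.5
            off = spec.radial_offset(conf.species[j])
            for si, rs in enumerate(spec.radial_shifts):
                out[i, off + si] += math.exp(-spec.radial_width * (r - rs) ** 2) * fc
        for j in range(n):
            for k in range(j + 1, n):
                if j == i or k == i:
                    continue
                r1 = np.linalg.norm(x[j] - x[i])
                r2 = np.linalg.norm(x[k] - x[i])
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
                        term = (
                            2 ** (1 - z)
                            * (1 + math.cos(theta - ts)) ** z
                            * math.exp(-spec.angular_width * ((r1 + r2) / 2 - rs) ** 2)
                            * fc1
                            * fc2
                        )
                        out[i, off + pos] += term
                        pos += 1
    return out


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    return np.array(
        [
            [1 - 2 * (yq**2 + zq**2), 2 * (xq * yq - w * zq), 2 * (xq * zq + w * yq)],
            [2 * (xq * yq + w * zq), 1 - 2 * (xq**2 + zq**2), 2 * (yq * zq - w * xq)],
            [2 * (xq * zq - w * yq), 2 * (yq * zq + w * xq), 1 - 2 * (xq**2 + yq**2)],
        ]
    )


# ---------------------------------------------------------------------------
# cutoff
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "r, rc, expected",
    [(0.0, 5.2, 1.0), (5.2, 5.2, 0.0), (2.6, 5.2, 0.5), (7.0, 5.2, 0.0)],
)
def test_cutoff_fixed_points(r, rc, expected):
    assert cutoff_fn(r, rc) == pytest.approx(expected, abs=1e-15)


def test_cutoff_monotone_and_smooth():
    r = np.linspace(0, 5.2, 500)
    v = cutoff_fn(r, 5.2)
    assert np.all(np.diff(v) <= 1e-15)
    assert cutoff_fn(5.2 - 1e-6, 5.2) < 1e-5


def test_cutoff_invalid_arguments():
    with pytest.raises(ValueError):
        cutoff_fn(-0.1, 5.2)
    with pytest.raises(ValueError):
        cutoff_fn(1.0, 0.0)


# ---------------------------------------------------------------------------
# radial block
# ---------------------------------------------------------------------------
def test_radial_single_atom_is_zero(small_spec):
    c = Conformation("m", ("C",), np.zeros((1, 3)))
    assert np.all(radial_block(0, c, small_spec) == 0)


def test_radial_beyond_cutoff_is_zero(small_spec):
    c = Conformation("m", ("H", "H"), [[0, 0, 0], [10, 0, 0]])
    assert np.all(radial_block(0, c, small_spec) == 0)


def test_radial_diatomic_at_shift_equals_cutoff_value():
    spec = AEVSpec(radial_shifts=(1.5,), angular_radial_shifts=(0.9,), angle_shifts=(0.0,))
    c = Conformation("m", ("H", "H"), [[0, 0, 0], [1.5, 0, 0]])
    block = radial_block(0, c, spec)
    h_off = spec.radial_offset("H")
    assert block[h_off] == pytest.approx(cutoff_fn(1.5, spec.radial_cutoff), abs=1e-14)
    assert np.count_nonzero(block) == 1


# ---------------------------------------------------------------------------
# angular block
# ---------------------------------------------------------------------------
def test_angular_fewer_than_two_neighbors(small_spec):
    c = Conformation("m", ("O", "H"), [[0, 0, 0], [0.96, 0, 0]])
    assert np.all(angular_block(0, c, small_spec) == 0)


def test_angular_rotation_invariance(small_spec, rng):
    conf = random_conformation(rng, 4, 6)
    R = random_rotation(rng)
    rotated = Conformation("m", conf.species, conf.coordinates @ R.T)
    for i in range(conf.n_atoms):
        a = angular_block(i, conf, small_spec)
        b = angular_block(i, rotated, small_spec)
        np.testing.assert_allclose(a, b, atol=1e-10)


def test_angular_single_pair_matches_hand_evaluation():
    spec = AEVSpec(
        radial_shifts=(1.0,), angular_radial_shifts=(1.0,), angle_shifts=(math.pi / 2,)
    )
    # water-like: O at origin, two H at 0.96 Å, 104.5° apart
    ang = math.radians(104.5)
    c = Conformation(
        "w",
        ("O", "H", "H"),
        [[0, 0, 0], [0.96, 0, 0], [0.96 * math.cos(ang), 0.96 * math.sin(ang), 0]],
    )
    z = spec.angular_sharpness
    fc = 0.5 * math.cos(math.pi * 0.96 / spec.angular_cutoff) + 0.5
    expected = (
        2 ** (1 - z)
        * (1 + math.cos(ang - math.pi / 2)) ** z
        * math.exp(-spec.angular_width * (0.96 - 1.0) ** 2)
        * fc
        * fc
    )
    block = angular_block(0, c, spec)
    off = spec.angular_offset("H", "H") - spec.n_radial_features
    assert block[off] == pytest.approx(expected, rel=1e-12)


def test_colinear_triple_is_finite(small_spec):
    c = Conformation("m", ("C", "H", "H"), [[0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
    block = angular_block(0, c, small_spec)
    assert np.all(np.isfinite(block))


# ---------------------------------------------------------------------------
# full AEV
# ---------------------------------------------------------------------------
def test_aev_matches_naive_oracle(small_spec, rng):
    for _ in range(100):
        conf = random_conformation(rng)
        got = compute_aev(conf, small_spec).values
        ref = naive_aev(conf, small_spec)
        np.testing.assert_allclose(got, ref, atol=1e-10)


def test_aev_rotation_translation_permutation_invariance(small_spec, rng):
    for _ in range(25):
        conf = random_conformation(rng)
        base = compute_aev(conf, small_spec).values
        R = random_rotation(rng)
        t = rng.normal(scale=10, size=3)
        moved = Conformation("m", conf.species, conf.coordinates @ R.T + t)
        np.testing.assert_allclose(
            compute_aev(moved, small_spec).values, base, atol=1e-10
        )
        same = [
            (i, j)
            for i in range(conf.n_atoms)
            for j in range(i + 1, conf.n_atoms)
            if conf.species[i] == conf.species[j]
        ]
        if same:
            i, j = same[0]
            perm = list(range(conf.n_atoms))
            perm[i], perm[j] = perm[j], perm[i]
            swapped = Conformation(
                "m",
                tuple(conf.species[p] for p in perm),
                conf.coordinates[perm],
            )
            np.testing.assert_allclose(
                compute_aev(swapped, small_spec).values, base[perm], atol=1e-10
            )


def test_aev_locality(small_spec):
    base = Conformation(
        "m", ("C", "H", "O"), [[0, 0, 0], [1.1, 0, 0], [20.0, 0, 0]]
    )
    moved = Conformation(
        "m", ("C", "H", "O"), [[0, 0, 0], [1.1, 0, 0], [25.0, 3.0, 0]]
    )
    a = compute_aev(base, small_spec).values
    b = compute_aev(moved, small_spec).values
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_aev_nonnegative_and_shape(small_spec, rng):
    conf = random_conformation(rng)
    aev = compute_aev(conf, small_spec)
    assert aev.values.shape == (conf.n_atoms, small_spec.feature_length)
    assert np.all(aev.values >= 0)
    assert len(aev.element_block_index) == small_spec.feature_length


def test_unsupported_element_named_in_error(small_spec):
    c = Conformation("m", ("C", "Si"), [[0, 0, 0], [1.5, 0, 0]])
    with pytest.raises(ValueError, match="Si"):
        compute_aev(c, small_spec)


def test_feature_length_formula():
    spec = AEVSpec()
    n_elem = len(spec.supported_elements)
    expected = n_elem * len(spec.radial_shifts) + (
        n_elem * (n_elem + 1) // 2
    ) * len(spec.angular_radial_shifts) * len(spec.angle_shifts)
    assert spec.feature_length == expected == 384


def test_angular_cutoff_must_not_exceed_radial():
    with pytest.raises(ValueError):
        AEVSpec(radial_cutoff=3.0, angular_cutoff=3.5,
                radial_shifts=(1.0,), angular_radial_shifts=(1.0,))


def test_adjoint_gradient_matches_finite_differences(small_spec, rng):
    conf = random_conformation(rng, 4, 6)
    W = rng.normal(size=(conf.n_atoms, small_spec.feature_length))
    g = aev_adjoint_gradient(conf, small_spec, W)
    h = 1e-5
    x = conf.coordinates
    for i in range(conf.n_atoms):
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, d] += h
            xm[i, d] -= h
            fp = float((compute_aev(Conformation("m", conf.species, xp), small_spec).values * W).sum())
            fm = float((compute_aev(Conformation("m", conf.species, xm), small_spec).values * W).sum())
            assert g[i, d] == pytest.approx((fp - fm) / (2 * h), rel=1e-5, abs=1e-7)


def test_spec_round_trips_through_dict(small_spec):
    assert AEVSpec.from_dict(small_spec.to_dict()) == small_spec
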