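"""Equivariance contracts of the tensor-algebra primitives.

The rotation oracle (wigner_D) is constructed from closed-form Wigner
small-d matrices and the complex-to-real basis change - independently of
the Cartesian spherical-harmonic polynomials and of the Clebsch-Gordan
construction it checks.
"""

import numpy as np
import pytest

from e3pot import irreps as ir
from e3pot.autodiff import Tensor
from e3pot.irreps import (
    EquivariantArray,
    Irrep,
    IrrepsSignature,
    clebsch_gordan,
    enumerate_paths,
    random_rotation,
    real_spherical_harmonics,
    weighted_tensor_product,
    wigner_D,
)

RNG = np.random.default_rng(7)


def unit(rng):
    u = rng.normal(size=3)
    return u / np.linalg.norm(u)


# --------------------------------------------------------------------------
# spherical harmonics
# --------------------------------------------------------------------------

def test_l0_harmonic_is_constant():
    vals = {tuple(np.round(real_spherical_harmonics(0, unit(RNG)), 12))
            for _ in range(5)}
    assert len(vals) == 1


def test_l1_harmonic_has_odd_parity():
    u = unit(RNG)
    assert np.allclose(real_spherical_harmonics(1, -u),
                       -real_spherical_harmonics(1, u))


@pytest.mark.parametrize("l", [0, 1, 2, 3])
def test_component_normalization_sum_rule(l):
    """Documented normalization: ||Y^(l)(u)||^2 = 2l+1 on the unit sphere."""
    for _ in range(5):
        y = real_spherical_harmonics(l, unit(RNG))
        assert np.isclose(np.dot(y, y), 2 * l + 1, atol=1e-12)


@pytest.mark.parametrize("l", [1, 2, 3])
@pytest.mark.parametrize("improper", [False, True])
def test_harmonics_rotate_with_wigner_matrix(l, improper):
    for _ in range(10):
        R = random_rotation(RNG, improper=improper)
        u = unit(RNG)
        lhs = real_spherical_harmonics(l, R.matrix @ u)
        rhs = wigner_D(l, R) @ real_spherical_harmonics(l, u)
        assert np.allclose(lhs, rhs, atol=1e-10)


def test_harmonics_reject_bad_input():
    with pytest.raises(ValueError):
        real_spherical_harmonics(1, np.array([1.0, 1.0, 0.0]))
    with pytest.raises(ValueError):
        real_spherical_harmonics(-1, np.array([1.0, 0.0, 0.0]))


# --------------------------------------------------------------------------
# Wigner matrices
# --------------------------------------------------------------------------

@pytest.mark.parametrize("l", [0, 1, 2, 3])
def test_wigner_identity(l):
    D = wigner_D(l, ir.RotationOperator(np.eye(3)))
    assert np.allclose(D, np.eye(2 * l + 1), atol=1e-12)


def test_wigner_l1_pi_about_z():
    """Rotation by pi about z maps (x,y,z)->(-x,-y,z) in the (y,z,x) ordering."""
    R = ir.RotationOperator(np.diag([-1.0, -1.0, 1.0]))
    D = wigner_D(1, R)
    assert np.allclose(D, np.diag([-1.0, 1.0, -1.0]), atol=1e-12)


@pytest.mark.parametrize("l", [1, 2, 3])
def test_wigner_respects_group_composition(l):
    for _ in range(5):
        R1 = random_rotation(RNG, improper=bool(RNG.integers(2)))
        R2 = random_rotation(RNG, improper=bool(RNG.integers(2)))
        D12 = wigner_D(l, R1.compose(R2))
        assert np.allclose(D12, wigner_D(l, R1) @ wigner_D(l, R2), atol=1e-10)


def test_wigner_parity_factor_for_improper_elements():
    inv = ir.RotationOperator(-np.eye(3))
    for l in range(4):
        # natural parity: inversion acts as (-1)^l
        assert np.allclose(wigner_D(l, inv), (-1) ** l * np.eye(2 * l + 1))
        # explicit parity overrides: p = +1 ignores the inversion
        assert np.allclose(wigner_D(l, inv, parity=1), np.eye(2 * l + 1))
        assert np.allclose(wigner_D(l, inv, parity=-1), -np.eye(2 * l + 1))


def test_wigner_rejects_non_orthogonal():
    with pytest.raises(ValueError):
        ir.RotationOperator(np.eye(3) * 2.0)


# --------------------------------------------------------------------------
# Clebsch-Gordan
# --------------------------------------------------------------------------

def cg_nullspace_oracle(l1, l2, l3, n_rotations=6):
    """Independent oracle: solve the equivariance constraint
    D1 (x) D2 . C = C . D3 by SVD over random rotations; the solution space
    of a valid triple is one-dimensional."""
    rows = []
    d1, d2, d3 = 2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1
    rng = np.random.default_rng(100 * l1 + 10 * l2 + l3)
    for _ in range(n_rotations):
        R = random_rotation(rng)
        D1, D2, D3 = wigner_D(l1, R), wigner_D(l2, R), wigner_D(l3, R)
        # constraint: sum_AB D1[A,a] D2[B,b] C[A,B,c] = sum_C D3[c,C] C[a,b,C]
        M = np.einsum("Aa,Bb,cC->abcABC", D1, D2, np.eye(d3)) \
            - np.einsum("aA,bB,cC->abcABC", np.eye(d1), np.eye(d2), D3)
        rows.append(M.reshape(d1 * d2 * d3, d1 * d2 * d3))
    M = np.concatenate(rows)
    _, s, vt = np.linalg.svd(M)
    null_dim = int((s < 1e-8).sum())
    return null_dim, vt[-1].reshape(d1, d2, d3)


def valid_triples(lmax=3):
    return [(l1, l2, l3)
            for l1 in range(lmax + 1) for l2 in range(lmax + 1)
            for l3 in range(abs(l1 - l2), min(lmax, l1 + l2) + 1)]


@pytest.mark.parametrize("l1,l2,l3", valid_triples(3))
def test_cg_matches_equivariance_nullspace(l1, l2, l3):
    """Every valid triple spans exactly the 1-D null space of the constraint."""
    null_dim, basis = cg_nullspace_oracle(l1, l2, l3)
    assert null_dim == 1
    C = clebsch_gordan(l1, l2, l3)
    # proportional to the null-space vector, unit Frobenius norm
    overlap = abs(np.sum(C * basis))
    assert np.isclose(np.linalg.norm(C), 1.0, atol=1e-12)
    assert np.isclose(overlap, 1.0, atol=1e-8)


def test_cg_scalar_coupling_is_identity():
    assert np.allclose(clebsch_gordan(0, 0, 0), np.ones((1, 1, 1)))


def test_cg_vector_couplings_recover_dot_and_cross_products():
    dot = clebsch_gordan(1, 1, 0)[:, :, 0]
    assert np.allclose(dot, np.eye(3) / np.sqrt(3), atol=1e-12)
    eps = np.zeros((3, 3, 3))
    for i, j, k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
        eps[i, j, k], eps[j, i, k] = 1.0, -1.0
    cross = clebsch_gordan(1, 1, 1)
    assert np.allclose(np.abs(cross), np.abs(eps) / np.sqrt(6), atol=1e-12)


def test_cg_rejects_violated_selection_rule():
    with pytest.raises(ValueError):
        clebsch_gordan(1, 1, 3)
    with pytest.raises(ValueError):
        clebsch_gordan(0, 0, 1)


# --------------------------------------------------------------------------
# path enumeration
# --------------------------------------------------------------------------

def test_paths_basic_selection_rules():
    sig_in = IrrepsSignature([(1, "0e")])
    sig_f = IrrepsSignature([(1, "0e"), (1, "1o")])
    paths = enumerate_paths(sig_in, sig_f, l_max=1)
    triples = [(p.input_irrep, p.filter_irrep, p.output_irrep) for p in paths]
    assert triples == [
        (Irrep(0, 1), Irrep(0, 1), Irrep(0, 1)),
        (Irrep(0, 1), Irrep(1, -1), Irrep(1, -1)),
    ]


def test_paths_vector_vector_products_and_truncation():
    sig = IrrepsSignature([(1, "1o")])
    paths = enumerate_paths(sig, sig, l_max=2)
    outs = [p.output_irrep for p in paths]
    assert outs == [Irrep(0, 1), Irrep(1, 1), Irrep(2, 1)]
    paths0 = enumerate_paths(sig, sig, l_max=0)
    assert [p.output_irrep for p in paths0] == [Irrep(0, 1)]


def test_paths_match_exhaustive_enumeration_and_parity_rule():
    """Deterministic order; every allowed triple exactly once; p_o = p_i p_f."""
    rng = np.random.default_rng(3)
    sig_in = IrrepsSignature([(2, "0e"), (1, "1o"), (1, "1e"), (1, "2e"), (1, "3o")])
    sig_f = IrrepsSignature([(1, "0e"), (1, "1o"), (1, "2e"), (1, "3o")])
    for l_max in (0, 1, 2, 3):
        paths = enumerate_paths(sig_in, sig_f, l_max)
        expected = []
        for i, (_, iri) in enumerate(sig_in.segments):
            for j, (_, irf) in enumerate(sig_f.segments):
                for lo in range(abs(iri.l - irf.l), iri.l + irf.l + 1):
                    if lo <= l_max:
                        expected.append((i, j, lo, iri.p * irf.p))
        got = [(p.input_index, p.filter_index, p.output_irrep.l, p.output_irrep.p)
               for p in paths]
        assert got == expected
        for p in paths:
            assert p.output_irrep.p == p.input_irrep.p * p.filter_irrep.p


# --------------------------------------------------------------------------
# EquivariantArray and the weighted tensor product
# --------------------------------------------------------------------------

def test_equivariant_array_segment_roundtrip():
    sig = IrrepsSignature([(2, "0e"), (3, "1o"), (1, "2e")])
    x = RNG.normal(size=(4, sig.dim))
    ea = EquivariantArray(sig, x)
    rebuilt = EquivariantArray.from_segments(sig, [b for _, _, b in ea.segments()])
    assert np.array_equal(rebuilt.values, x)


def test_equivariant_array_rejects_wrong_length():
    with pytest.raises(ValueError):
        EquivariantArray(IrrepsSignature([(1, "1o")]), np.zeros((2, 4)))


def test_scalar_tensor_product_is_elementwise_multiplication():
    sig = IrrepsSignature([(4, "0e")])
    paths = enumerate_paths(sig, IrrepsSignature([(1, "0e")]), 0)
    x = RNG.normal(size=(2, 4))
    f = RNG.normal(size=(2, 1))
    w = RNG.normal(size=4)
    out = weighted_tensor_product(
        EquivariantArray(sig, x), EquivariantArray(IrrepsSignature([(1, "0e")]), f),
        paths, [w],
    )
    assert np.allclose(out.values, w * x * f)


def test_vector_vector_scalar_path_is_scaled_dot_product():
    sig = IrrepsSignature([(1, "1o")])
    paths = enumerate_paths(sig, sig, 0)
    v = RNG.normal(size=3)
    out = weighted_tensor_product(
        EquivariantArray(sig, v[None]), EquivariantArray(sig, v[None]),
        paths, [np.ones(1)],
    )
    # (1,1,0) coupling is the dot product scaled by 1/sqrt(3)
    assert np.allclose(out.values, np.dot(v, v) / np.sqrt(3))


@pytest.mark.parametrize("improper", [False, True])
def test_weighted_tensor_product_equivariance(improper):
    """Rotate-then-couple equals couple-then-rotate for l <= 3 features."""
    sig_x = IrrepsSignature([(2, "0e"), (2, "1o"), (1, "2e"), (1, "3o")])
    sig_f = IrrepsSignature([(1, "0e"), (1, "1o"), (1, "2e"), (1, "3o")])
    paths = enumerate_paths(sig_x, sig_f, 3)
    weights = [RNG.normal(size=sig_x.segments[p.input_index][0]) for p in paths]
    x = EquivariantArray(sig_x, RNG.normal(size=(3, sig_x.dim)))
    f = EquivariantArray(sig_f, RNG.normal(size=(3, sig_f.dim)))
    for _ in range(10):
        R = random_rotation(RNG, improper=improper)
        out_then_rot = weighted_tensor_product(x, f, paths, weights).rotate(R)
        rot_then_out = weighted_tensor_product(x.rotate(R), f.rotate(R), paths, weights)
        assert np.allclose(out_then_rot.values, rot_then_out.values, atol=1e-10)


def test_weighted_tensor_product_rejects_multichannel_filter():
    sig = IrrepsSignature([(2, "0e")])
    paths = enumerate_paths(sig, sig, 0)
    with pytest.raises(ValueError):
        weighted_tensor_product(
            EquivariantArray(sig, np.zeros((1, 2))),
            EquivariantArray(sig, np.zeros((1, 2))),
            paths, [np.ones(2)],
        )
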