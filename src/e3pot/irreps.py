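"""Irreducible representations of O(3) and the equivariant primitives.

Features of the network are geometric tensors living in direct sums of
irreducible representations (irreps) of O(3), labeled by a rotation order
``l`` (dimension ``2l+1``) and a parity ``p`` (+1 even, -1 odd).  This module
provides:

* the irrep data model (:class:`Irrep`, :class:`IrrepsSignature`,
  :class:`EquivariantArray`),
* real spherical harmonics in Cartesian polynomial form (autodiff-friendly,
  no angular coordinates, hence no pole singularities),
* real Wigner rotation matrices (used throughout the tests as the oracle for
  equivariance contracts),
* Clebsch-Gordan coupling coefficients in the real basis,
* tensor-product path enumeration under the selection rules, and the
  weighted tensor product itself.

Conventions (documented choices; any self-consistent set works):

* Real spherical harmonics with *component* normalization,
  ``sum_m Y_m^(l)(u)^2 = 2l+1`` for unit ``u``; components ordered
  ``m = -l .. l`` with the standard real combinations (so ``l=1`` is
  ``sqrt(3) * (y, z, x)``).
* Clebsch-Gordan tensors normalized to unit Frobenius norm per ``(l1,l2,l3)``
  triple, so contracting two unit-norm inputs yields a bounded output.
  Coefficients are independent of the parities of the arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Irrep",
    "IrrepsSignature",
    "EquivariantArray",
    "RotationOperator",
    "TensorProductPath",
    "real_spherical_harmonics",
    "spherical_harmonics_tensor",
    "wigner_D",
    "clebsch_gordan",
    "enumerate_paths",
    "weighted_tensor_product",
    "random_rotation",
]


# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Irrep:
    """One irreducible representation of O(3): rotation order l, parity p."""

    l: int
    p: int

    def __post_init__(self):
        if self.l < 0 or not isinstance(self.l, (int, np.integer)):
            raise ValueError(f"rotation order must be a non-negative integer, got {self.l}")
        if self.p not in (1, -1):
            raise ValueError(f"parity must be +1 or -1, got {self.p}")

    @property
    def dim(self) -> int:
        return 2 * self.l + 1

    def __repr__(self):
        return f"{self.l}{'e' if self.p == 1 else 'o'}"

    @classmethod
    def parse(cls, text: str) -> "Irrep":
        text = text.strip()
        return cls(int(text[:-1]), {"e": 1, "o": -1}[text[-1]])


class IrrepsSignature:
    """Ordered list of ``(multiplicity, Irrep)`` defining a flat feature layout."""

    def __init__(self, segments):
        segs = []
        for mult, ir in segments:
            if isinstance(ir, str):
                ir = Irrep.parse(ir)
            if mult <= 0:
                raise ValueError("multiplicity must be positive")
            segs.append((int(mult), ir))
        self.segments = tuple(segs)

    @classmethod
    def parse(cls, text: str) -> "IrrepsSignature":
        """Parse e.g. ``"16x0e + 16x1o"``."""
        parts = [p.strip() for p in text.split("+")]
        segs = []
        for p in parts:
            mult, ir = p.split("x")
            segs.append((int(mult), Irrep.parse(ir)))
        return cls(segs)

    @property
    def dim(self) -> int:
        return sum(m * ir.dim for m, ir in self.segments)

    @property
    def num_segments(self) -> int:
        return len(self.segments)

    def slices(self):
        """Flat slice per segment, in order."""
        out, off = [], 0
        for mult, ir in self.segments:
            n = mult * ir.dim
            out.append(slice(off, off + n))
            off += n
        return out

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def __eq__(self, other):
        return isinstance(other, IrrepsSignature) and self.segments == other.segments

    def __hash__(self):
        return hash(self.segments)

    def __repr__(self):
        return " + ".join(f"{m}x{ir}" for m, ir in self.segments)

    def count(self, irrep: Irrep) -> int:
        return sum(m for m, ir in self.segments if ir == irrep)


class EquivariantArray:
    """A flat numeric block (numpy or autodiff Tensor) with an irreps layout.

    The last axis is the flat representation axis of length ``signature.dim``;
    leading axes (atoms, edges, ...) are free.
    """

    def __init__(self, signature: IrrepsSignature, values):
        self.signature = signature
        self.values = values
        if self._shape()[-1] != signature.dim:
            raise ValueError(
                f"flat dimension {self._shape()[-1]} does not match signature "
                f"{signature!r} (dim {signature.dim})"
            )

    def _shape(self):
        return self.values.shape

    @property
    def shape(self):
        return self._shape()

    def segments(self):
        """Yield ``(mult, irrep, block)`` with block shaped (..., mult, 2l+1)."""
        for (mult, ir), sl in zip(self.signature.segments, self.signature.slices()):
            block = self.values[(Ellipsis, sl)] if isinstance(self.values, np.ndarray) \
                else ad.take(self.values, (Ellipsis, sl))
            lead = self._shape()[:-1]
            block = block.reshape(lead + (mult, ir.dim))
            yield mult, ir, block

    @classmethod
    def from_segments(cls, signature: IrrepsSignature, blocks):
        """Inverse of :meth:`segments`: reassemble the flat layout."""
        flat = []
        for (mult, ir), b in zip(signature.segments, blocks):
            lead = b.shape[:-2]
            flat.append(b.reshape(lead + (mult * ir.dim,)))
        if isinstance(flat[0], np.ndarray):
            values = np.concatenate(flat, axis=-1)
        else:
            values = ad.concatenate(flat, axis=-1)
        return cls(signature, values)

    def rotate(self, rotation: "RotationOperator") -> "EquivariantArray":
        """Apply an O(3) element to every irrep segment (numpy values only)."""
        blocks = []
        for mult, ir, block in self.segments():
            D = wigner_D(ir.l, rotation, parity=ir.p)
            arr = block if isinstance(block, np.ndarray) else block.data
            blocks.append(np.einsum("nm,...cm->...cn", D, arr))
        return EquivariantArray.from_segments(self.signature, blocks)


@dataclass(frozen=True)
class TensorProductPath:
    """One allowed coupling (l_i, p_i) x (l_f, p_f) -> (l_o, p_o)."""

    input_index: int
    filter_index: int
    input_irrep: Irrep
    filter_irrep: Irrep
    output_irrep: Irrep

    def __post_init__(self):
        li, lf, lo = self.input_irrep.l, self.filter_irrep.l, self.output_irrep.l
        if not abs(li - lf) <= lo <= li + lf:
            raise ValueError(f"selection rule violated: |{li}-{lf}| <= {lo} <= {li}+{lf}")
        if self.output_irrep.p != self.input_irrep.p * self.filter_irrep.p:
            raise ValueError("parity selection rule violated: p_o must equal p_i * p_f")


class RotationOperator:
    """A proper or improper orthogonal 3x3 transformation."""

    def __init__(self, matrix, tol=1e-8):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError("rotation matrix must be 3x3")
        if not np.allclose(matrix @ matrix.T, np.eye(3), atol=tol):
            raise ValueError("matrix is not orthogonal")
        self.matrix = matrix
        self.det = float(np.sign(np.linalg.det(matrix)))

    @property
    def is_proper(self) -> bool:
        return self.det > 0

    def compose(self, other: "RotationOperator") -> "RotationOperator":
        return RotationOperator(self.matrix @ other.matrix)


def random_rotation(rng, improper=False) -> RotationOperator:
    """Haar-random rotation; optionally composed with the inversion."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    if improper:
        Q = -Q
    return RotationOperator(Q)


# --------------------------------------------------------------------------
# real spherical harmonics (Cartesian polynomials, component-normalized)
# --------------------------------------------------------------------------

_SQ = np.sqrt


def _sh_blocks(x, y, z, lmax, lib):
    """Polynomial blocks for l = 0..lmax given coordinate arrays.

    ``lib`` supplies ``mul/add`` semantics: works for both numpy arrays and
    autodiff Tensors because only +, -, * and scalar scaling are used.
    """
    one = x * 0.0 + 1.0
    blocks = [[one]]
    if lmax >= 1:
        c = _SQ(3.0)
        blocks.append([c * y, c * z, c * x])
    if lmax >= 2:
        c1, c2 = _SQ(15.0), _SQ(5.0) / 2.0
        blocks.append([
            c1 * (x * y),
            c1 * (y * z),
            c2 * (3.0 * (z * z) - 1.0),
            c1 * (x * z),
            (c1 / 2.0) * (x * x - y * y),
        ])
    if lmax >= 3:
        a = _SQ(35.0 / 8.0)
        b = _SQ(105.0)
        c = _SQ(21.0 / 8.0)
        d = _SQ(7.0) / 2.0
        z2 = z * z
        blocks.append([
            a * (y * (3.0 * (x * x) - y * y)),
            b * (x * (y * z)),
            c * (y * (5.0 * z2 - 1.0)),
            d * (z * (5.0 * z2 - 3.0)),
            c * (x * (5.0 * z2 - 1.0)),
            (b / 2.0) * (z * (x * x - y * y)),
            a * (x * (x * x - 3.0 * (y * y))),
        ])
    if lmax >= 4:
        raise NotImplementedError("spherical harmonics implemented for l <= 3")
    return blocks


def real_spherical_harmonics(l: int, u) -> np.ndarray:
    """Real spherical harmonics ``Y_m^(l)(u)``, m = -l..l, component-normalized.

    ``u`` must be a unit 3-vector (tolerance 1e-8); non-unit input is
    rejected rather than silently normalized.
    """
    if l < 0:
        raise ValueError("rotation order l must be non-negative")
    u = np.asarray(u, dtype=float)
    if u.shape != (3,):
        raise ValueError("u must be a 3-vector")
    if abs(np.dot(u, u) - 1.0) > 1e-8:
        raise ValueError("u must be a unit vector")
    x, y, z = u
    blocks = _sh_blocks(np.float64(x), np.float64(y), np.float64(z), l, np)
    return np.array(blocks[l], dtype=float)


def spherical_harmonics_tensor(lmax: int, unit_vectors: Tensor) -> list:
    """Autodiff version: list of Tensors (n, 2l+1) for l = 0..lmax.

    ``unit_vectors`` is an (n, 3) Tensor of already-normalized directions.
    """
    x = unit_vectors[(slice(None), 0)]
    y = unit_vectors[(slice(None), 1)]
    z = unit_vectors[(slice(None), 2)]
    blocks = _sh_blocks(x, y, z, lmax, ad)
    out = []
    for comp_list in blocks:
        cols = [c.reshape((c.shape[0], 1)) for c in comp_list]
        out.append(ad.concatenate(cols, axis=1))
    return out


# --------------------------------------------------------------------------
# Wigner matrices (test oracle; built from the closed-form small-d matrices,
# independent of the Cartesian polynomials above)
# --------------------------------------------------------------------------

def _small_d(l: int, beta: float) -> np.ndarray:
    """Wigner small-d matrix d^l_{m'm}(beta) from the factorial sum formula."""
    d = np.zeros((2 * l + 1, 2 * l + 1))
    cb, sb = np.cos(beta / 2.0), np.sin(beta / 2.0)
    for mp in range(-l, l + 1):
        for m in range(-l, l + 1):
            pref = np.sqrt(
                factorial(l + mp) * factorial(l - mp) * factorial(l + m) * factorial(l - m)
            )
            total = 0.0
            for s in range(0, 2 * l + 1):
                if l + m - s < 0 or mp - m + s < 0 or l - mp - s < 0:
                    continue
                num = (-1.0) ** (mp - m + s)
                den = (
                    factorial(l + m - s)
                    * factorial(s)
                    * factorial(mp - m + s)
                    * factorial(l - mp - s)
                )
                total += (
                    num / den
                    * cb ** (2 * l - 2 * s + m - mp)
                    * sb ** (mp - m + 2 * s)
                )
            d[mp + l, m + l] = pref * total
    return d


@lru_cache(maxsize=None)
def _real_basis_change(l: int) -> np.ndarray:
    """Unitary U with Y_real = U @ Y_complex (standard real combinations)."""
    n = 2 * l + 1
    U = np.zeros((n, n), dtype=complex)
    s2 = 1.0 / np.sqrt(2.0)
    U[l, l] = 1.0
    for m in range(1, l + 1):
        # real index l+m <-> cosine-type; l-m <-> sine-type
        U[l + m, l + m] = (-1.0) ** m * s2
        U[l + m, l - m] = s2
        U[l - m, l + m] = (-1.0) ** m * -1j * s2
        U[l - m, l - m] = 1j * s2
    return U


def _euler_zyz(R: np.ndarray):
    """ZYZ Euler angles with R = Rz(a) @ Ry(b) @ Rz(c) (proper rotation)."""
    b = np.arccos(np.clip(R[2, 2], -1.0, 1.0))
    if abs(R[2, 2]) > 1.0 - 1e-12:
        a = np.arctan2(R[1, 0], R[0, 0])
        if R[2, 2] < 0:
            a = -a
        return a, (0.0 if R[2, 2] > 0 else np.pi), 0.0
    a = np.arctan2(R[1, 2], R[0, 2])
    c = np.arctan2(R[2, 1], -R[2, 0])
    return a, b, c


def wigner_D(l: int, rotation: RotationOperator, parity: int | None = None) -> np.ndarray:
    """Real-basis Wigner matrix of an O(3) element for irrep (l, p).

    For improper elements the inversion acts as multiplication by ``p``;
    ``parity=None`` uses the natural parity ``(-1)**l`` of the spherical
    harmonics, so ``Y(R u) = wigner_D(l, R) @ Y(u)`` for every O(3) element.
    """
    if not isinstance(rotation, RotationOperator):
        rotation = RotationOperator(rotation)
    if parity is None:
        parity = (-1) ** l
    R = rotation.matrix
    factor = 1.0
    if rotation.det < 0:
        R = -R
        factor = float(parity)
    a, b, c = _euler_zyz(R)
    m = np.arange(-l, l + 1)
    Dc = np.exp(1j * np.outer(m, np.ones(2 * l + 1)) * a) \
        * _small_d(l, b) \
        * np.exp(1j * np.outer(np.ones(2 * l + 1), m) * c)
    U = _real_basis_change(l)
    Dr = U @ Dc @ U.conj().T
    if np.abs(Dr.imag).max() > 1e-9:
        raise RuntimeError("real Wigner matrix has nonzero imaginary part")
    return factor * Dr.real


# --------------------------------------------------------------------------
# Clebsch-Gordan coefficients (real basis)
# --------------------------------------------------------------------------

def _cg_complex(j1: int, j2: int, j3: int) -> np.ndarray:
    """Complex-basis Clebsch-Gordan tensor from the Racah factorial formula."""
    C = np.zeros((2 * j1 + 1, 2 * j2 + 1, 2 * j3 + 1))
    def f(n):
        return factorial(n)
    delta = np.sqrt(
        f(j1 + j2 - j3) * f(j1 - j2 + j3) * f(-j1 + j2 + j3) / f(j1 + j2 + j3 + 1)
    )
    for m1 in range(-j1, j1 + 1):
        for m2 in range(-j2, j2 + 1):
            m3 = m1 + m2
            if abs(m3) > j3:
                continue
            pref = np.sqrt(2 * j3 + 1) * delta * np.sqrt(
                f(j3 + m3) * f(j3 - m3)
                * f(j1 - m1) * f(j1 + m1)
                * f(j2 - m2) * f(j2 + m2)
            )
            total = 0.0
            for k in range(0, j1 + j2 + j3 + 1):
                d1 = j1 + j2 - j3 - k
                d2 = j1 - m1 - k
                d3 = j2 + m2 - k
                d4 = j3 - j2 + m1 + k
                d5 = j3 - j1 - m2 + k
                if min(d1, d2, d3, d4, d5) < 0:
                    continue
                total += (-1.0) ** k / (
                    f(k) * f(d1) * f(d2) * f(d3) * f(d4) * f(d5)
                )
            C[m1 + j1, m2 + j2, m3 + j3] = pref * total
    return C


@lru_cache(maxsize=None)
def clebsch_gordan(l1: int, l2: int, l3: int) -> np.ndarray:
    """Real-basis coupling tensor C[m1, m2, m3], unit Frobenius norm.

    Contracting two equivariant vectors of orders (l1, l2) with C yields an
    l3-equivariant vector.  The coefficients depend only on the rotation
    orders, never on parities.  Violating |l1-l2| <= l3 <= l1+l2 is an error.
    """
    for l in (l1, l2, l3):
        if l < 0:
            raise ValueError("rotation orders must be non-negative")
    if not abs(l1 - l2) <= l3 <= l1 + l2:
        raise ValueError(
            f"selection rule violated: need |{l1}-{l2}| <= {l3} <= {l1}+{l2}"
        )
    Cc = _cg_complex(l1, l2, l3).astype(complex)
    U1 = _real_basis_change(l1)
    U2 = _real_basis_change(l2)
    U3 = _real_basis_change(l3)
    # transform each complex index to the real basis
    Cr = np.einsum("au,bv,cw,uvw->abc", U1, U2, U3.conj(), Cc)
    re, im = np.abs(Cr.real).max(), np.abs(Cr.imag).max()
    if im > 1e-10 * max(re, 1e-30):
        if re > 1e-10 * im:
            raise RuntimeError("real CG tensor is neither purely real nor imaginary")
        Cr = Cr.imag  # overall phase is free; rotate -i onto the tensor
    else:
        Cr = Cr.real
    norm = np.linalg.norm(Cr)
    if norm < 1e-12:
        raise RuntimeError("degenerate CG tensor")
    Cr = Cr / norm
    # deterministic sign: make the first nonzero entry positive
    flat = Cr.ravel()
    first = flat[np.abs(flat) > 1e-10][0]
    if first < 0:
        Cr = -Cr
    return Cr


# --------------------------------------------------------------------------
# path enumeration and the weighted tensor product
# --------------------------------------------------------------------------

def enumerate_paths(input_sig: IrrepsSignature, filter_sig: IrrepsSignature,
                    l_max: int) -> list[TensorProductPath]:
    """All allowed couplings, lexicographic in (input seg, filter seg, l_o).

    Every triple satisfying the rotation-order triangle rule, the parity rule
    p_o = p_i * p_f, and the truncation l_o <= l_max appears exactly once.
    The order is the contract downstream weight layouts index into.
    """
    if l_max < 0:
        raise ValueError("l_max must be non-negative")
    paths = []
    for i, (_, ir_in) in enumerate(input_sig.segments):
        for j, (_, ir_f) in enumerate(filter_sig.segments):
            for lo in range(abs(ir_in.l - ir_f.l), ir_in.l + ir_f.l + 1):
                if lo > l_max:
                    continue
                paths.append(TensorProductPath(
                    input_index=i,
                    filter_index=j,
                    input_irrep=ir_in,
                    filter_irrep=ir_f,
                    output_irrep=Irrep(lo, ir_in.p * ir_f.p),
                ))
    return paths


def tensor_product_output_signature(input_sig: IrrepsSignature,
                                    paths) -> IrrepsSignature:
    """Output layout: one segment per path, multiplicity of the input segment."""
    segs = []
    for path in paths:
        mult = input_sig.segments[path.input_index][0]
        segs.append((mult, path.output_irrep))
    return IrrepsSignature(segs)


def weighted_tensor_product(x: EquivariantArray, f: EquivariantArray,
                            paths, weights) -> EquivariantArray:
    """Channel-wise weighted tensor product of features with a filter.

    ``x`` has per-channel multiplicities; every filter segment must have
    multiplicity 1 (a spherical-harmonic filter has a single copy of each
    order).  ``weights`` is a list with one array per path, each shaped like
    the leading axes of ``x`` plus the channel axis (or just ``(mult,)``),
    scaling each channel's contribution.  Output segments are concatenated in
    path enumeration order.
    """
    for mult, ir in f.signature.segments:
        if mult != 1:
            raise ValueError(f"filter segment {mult}x{ir} must have multiplicity 1")
    if len(weights) != len(paths):
        raise ValueError(f"need one weight block per path: {len(weights)} != {len(paths)}")
    x_blocks = list(x.segments())
    f_blocks = list(f.segments())
    is_np = isinstance(x.values, np.ndarray)
    ein = np.einsum if is_np else ad.einsum
    out_blocks = []
    for path, w in zip(paths, weights):
        mult_i, ir_i, xi = x_blocks[path.input_index]
        _, ir_f, ff = f_blocks[path.filter_index]
        if ir_i != path.input_irrep or ir_f != path.filter_irrep:
            raise ValueError(f"signature does not match path {path}")
        C = clebsch_gordan(ir_i.l, ir_f.l, path.output_irrep.l)
        # xi: (..., c, mi); ff: (..., 1, mf); w: (..., c) or (c,)
        if is_np:
            fd = ff[..., 0, :]
            block = np.einsum("ifo,...ci,...f->...co", C, xi, fd)
            block = block * np.asarray(w)[..., :, None]
        else:
            lead = ff.shape[:-2]
            fd = ff.reshape(lead + (ff.shape[-1],))
            if xi.ndim == 3:
                di, df, do = C.shape
                n_e, mult = xi.shape[0], xi.shape[1]
                # contract the filter with the CG tensor (one GEMM), then a
                # batched (channels x m_i) @ (m_i x m_o) product per edge
                C2 = np.ascontiguousarray(C.transpose(1, 0, 2)).reshape(df, di * do)
                G = ad.matmul(fd, Tensor(C2)).reshape((n_e, di, do))
                block = ad.bmm(xi, G)
                wt = w if isinstance(w, Tensor) else Tensor(np.asarray(w))
                if wt.ndim == 1:
                    block = block * wt.reshape((1, mult, 1))
                else:
                    block = block * wt.reshape((n_e, mult, 1))
            else:
                raise ValueError("Tensor inputs must be (n, channels, 2l+1)")
        out_blocks.append(block)
    out_sig = tensor_product_output_signature(x.signature, paths)
    return EquivariantArray.from_segments(out_sig, out_blocks)
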