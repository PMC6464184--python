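"""A commutative (d+1)-component hypercomplex number system and its matrix algebra.

A hypercomplex scalar is ``y = y0 + y1*e_1 + ... + yd*e_d`` with one real part
and ``d`` imaginary units.  The product rule used throughout is the bilinear,
commutative rule in which every unit squares to -1 and products of *distinct*
units vanish::

    (a0 + sum_k ak e_k)(b0 + sum_k bk e_k)
        = (a0 b0 - sum_k ak bk) + sum_k (a0 bk + ak b0) e_k

This is the unique (d+1)-component rule under which the conjugate
``y* = y0 - sum_k yk e_k`` satisfies ``y y* = |y|^2`` exactly, with
``|y|^2 = sum of squared coefficients``, and it coincides with ordinary
complex arithmetic at d=1 (and with the reals at d=0).  For d >= 2 the rule
is non-associative, so matrix inversion is order-sensitive; see
:func:`hc_block_inverse` and :func:`real_embed_solve` for the two solver
routes the package offers.

Matrices over this system are stored as d+1 stacked real component matrices
(component 0 = real part, component k = coefficient matrix of ``e_k``), which
lets every matrix operation be phrased in terms of a handful of real BLAS
calls.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = [
    "HCScalar",
    "HCMatrix",
    "HCLinAlgError",
    "hc_conj",
    "hc_norm",
    "hc_mul",
    "hc_add",
    "hc_sub",
    "hc_scale",
    "hc_matmul",
    "hc_hermitian",
    "hc_scalar_inv",
    "hc_block_inverse",
    "hc_frobenius",
    "real_embed_solve",
    "hc_identity",
]

#: default tolerance below which a scalar norm is treated as zero
DEFAULT_EPS = 1e-12


class HCLinAlgError(np.linalg.LinAlgError):
    """Raised when a hypercomplex scalar/matrix is (numerically) singular."""


class HCScalar:
    """One hypercomplex number: a real part plus ``d`` imaginary coefficients.

    Parameters
    ----------
    re : float
        Coefficient of 1.
    im : sequence of float, optional
        Coefficients of ``e_1 .. e_d``.  An empty sequence gives a plain
        real number (d=0).
    """

    __slots__ = ("coeffs",)

    def __init__(self, re: float, im=()) -> None:
        coeffs = np.empty(1 + len(im), dtype=float)
        coeffs[0] = re
        coeffs[1:] = im
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("hypercomplex coefficients must be finite")
        self.coeffs = coeffs

    @classmethod
    def from_coeffs(cls, coeffs) -> "HCScalar":
        c = np.asarray(coeffs, dtype=float)
        return cls(c[0], c[1:])

    @property
    def re(self) -> float:
        return float(self.coeffs[0])

    @property
    def im(self) -> np.ndarray:
        return self.coeffs[1:]

    @property
    def d(self) -> int:
        return self.coeffs.size - 1

    def conj(self) -> "HCScalar":
        out = self.coeffs.copy()
        out[1:] *= -1.0
        return HCScalar.from_coeffs(out)

    def norm(self) -> float:
        return float(np.sqrt(np.dot(self.coeffs, self.coeffs)))

    def __add__(self, other: "HCScalar") -> "HCScalar":
        _check_same_d(self, other)
        return HCScalar.from_coeffs(self.coeffs + other.coeffs)

    def __sub__(self, other: "HCScalar") -> "HCScalar":
        _check_same_d(self, other)
        return HCScalar.from_coeffs(self.coeffs - other.coeffs)

    def __mul__(self, other):
        if isinstance(other, HCScalar):
            return hc_mul(self, other)
        return HCScalar.from_coeffs(float(other) * self.coeffs)

    __rmul__ = __mul__

    def __neg__(self) -> "HCScalar":
        return HCScalar.from_coeffs(-self.coeffs)

    def __eq__(self, other) -> bool:
        return isinstance(other, HCScalar) and np.array_equal(self.coeffs, other.coeffs)

    def __hash__(self):  # pragma: no cover - scalars are not meant for sets
        return hash(self.coeffs.tobytes())

    def isclose(self, other: "HCScalar", atol: float = 1e-12) -> bool:
        return self.d == other.d and bool(
            np.allclose(self.coeffs, other.coeffs, atol=atol, rtol=0.0)
        )

    def __repr__(self) -> str:
        if self.d == 0:
            return f"HCScalar({self.re:g})"
        im = " + ".join(f"{c:g}*e{k + 1}" for k, c in enumerate(self.im))
        return f"HCScalar({self.re:g} + {im})"


class HCMatrix:
    """A matrix over the hypercomplex system, stored per real component.

    ``components`` has shape ``(d+1, rows, cols)``: slab 0 is the real part,
    slab k the coefficient matrix of ``e_k``.
    """

    __slots__ = ("components",)

    def __init__(self, components) -> None:
        comps = np.asarray(components, dtype=float)
        if comps.ndim != 3:
            raise ValueError("components must be a (d+1, rows, cols) array")
        self.components = comps

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_real(cls, mat, d: int = 0) -> "HCMatrix":
        """Embed a real matrix as component 0 with d zero imaginary slabs."""
        mat = np.asarray(mat, dtype=float)
        comps = np.zeros((d + 1,) + mat.shape)
        comps[0] = mat
        return cls(comps)

    @classmethod
    def from_complex(cls, mat) -> "HCMatrix":
        """Build a d=1 matrix from an ordinary complex matrix."""
        mat = np.asarray(mat, dtype=complex)
        return cls(np.stack([mat.real, mat.imag]))

    def to_complex(self) -> np.ndarray:
        if self.d != 1:
            raise ValueError("to_complex requires d=1")
        return self.components[0] + 1j * self.components[1]

    @classmethod
    def zeros(cls, rows: int, cols: int, d: int) -> "HCMatrix":
        return cls(np.zeros((d + 1, rows, cols)))

    # -- basic introspection --------------------------------------------------
    @property
    def d(self) -> int:
        return self.components.shape[0] - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.components.shape[1:]

    @property
    def rows(self) -> int:
        return self.components.shape[1]

    @property
    def cols(self) -> int:
        return self.components.shape[2]

    def entry(self, i: int, j: int) -> HCScalar:
        return HCScalar.from_coeffs(self.components[:, i, j])

    def block(self, r0: int, r1: int, c0: int, c1: int) -> "HCMatrix":
        return HCMatrix(self.components[:, r0:r1, c0:c1])

    def copy(self) -> "HCMatrix":
        return HCMatrix(self.components.copy())

    # -- algebra --------------------------------------------------------------
    def __add__(self, other: "HCMatrix") -> "HCMatrix":
        _check_same_shape(self, other)
        return HCMatrix(self.components + other.components)

    def __sub__(self, other: "HCMatrix") -> "HCMatrix":
        _check_same_shape(self, other)
        return HCMatrix(self.components - other.components)

    def __neg__(self) -> "HCMatrix":
        return HCMatrix(-self.components)

    def __mul__(self, other) -> "HCMatrix":
        return HCMatrix(float(other) * self.components)

    __rmul__ = __mul__

    def __matmul__(self, other: "HCMatrix") -> "HCMatrix":
        return hc_matmul(self, other)

    def allclose(self, other: "HCMatrix", atol: float = 1e-10) -> bool:
        return self.d == other.d and bool(
            np.allclose(self.components, other.components, atol=atol, rtol=0.0)
        )

    def __repr__(self) -> str:
        return f"HCMatrix(d={self.d}, shape={self.shape})"


def _check_same_d(a, b) -> None:
    if a.d != b.d:
        raise ValueError(f"mismatched imaginary dimension: d={a.d} vs d={b.d}")


def _check_same_shape(a: HCMatrix, b: HCMatrix) -> None:
    _check_same_d(a, b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# scalar / elementwise operations
# ---------------------------------------------------------------------------

def hc_conj(y):
    """Hypercomplex conjugate: negate every imaginary coefficient.

    Works elementwise on :class:`HCMatrix`; an involution in both cases.
    """
    if isinstance(y, HCScalar):
        return y.conj()
    comps = y.components.copy()
    comps[1:] *= -1.0
    return HCMatrix(comps)


def hc_norm(y: HCScalar) -> float:
    """Euclidean norm of a scalar: sqrt of the sum of squared coefficients."""
    return y.norm()


def hc_mul(a: HCScalar, b: HCScalar) -> HCScalar:
    """Commutative product: units square to -1, distinct units annihilate."""
    _check_same_d(a, b)
    re = a.re * b.re - float(np.dot(a.im, b.im))
    im = a.re * b.im + a.im * b.re
    return HCScalar(re, im)


def hc_add(a, b):
    return a + b


def hc_sub(a, b):
    return a - b


def hc_scale(r: float, a):
    return float(r) * a


def hc_scalar_inv(y: HCScalar, eps: float = DEFAULT_EPS) -> HCScalar:
    """Multiplicative inverse ``y* / |y|^2``; exact under the product rule."""
    n = y.norm()
    if n <= eps:
        raise HCLinAlgError(f"cannot invert hypercomplex scalar with norm {n:g}")
    return (1.0 / n**2) * y.conj()


# ---------------------------------------------------------------------------
# matrix operations
# ---------------------------------------------------------------------------

def hc_matmul(A: HCMatrix, B: HCMatrix) -> HCMatrix:
    """Hypercomplex matrix product via real component products.

    Component 0 of the result is ``A0 B0 - sum_k Ak Bk``; component k is
    ``A0 Bk + Ak B0``.  This is exactly the scalar-by-scalar row/column
    accumulation, vectorised.
    """
    _check_same_d(A, B)
    if A.cols != B.rows:
        raise ValueError(f"inner dimensions differ: {A.shape} @ {B.shape}")
    a, b = A.components, B.components
    out = np.empty((A.d + 1, A.rows, B.cols))
    out[0] = a[0] @ b[0]
    for k in range(1, A.d + 1):
        out[0] -= a[k] @ b[k]
        out[k] = a[0] @ b[k] + a[k] @ b[0]
    return HCMatrix(out)


def hc_hermitian(A: HCMatrix) -> HCMatrix:
    """Transpose with elementwise conjugation (the ``H``-superscript matrix)."""
    comps = np.transpose(A.components, (0, 2, 1)).copy()
    comps[1:] *= -1.0
    return HCMatrix(comps)


def hc_identity(n: int, d: int) -> HCMatrix:
    """The n x n hypercomplex identity (real identity, zero imaginary slabs)."""
    return HCMatrix.from_real(np.eye(n), d=d)


def hc_frobenius(A: HCMatrix) -> float:
    """Frobenius norm: sqrt of the summed squared norms of all entries."""
    return float(np.sqrt(np.sum(A.components**2)))


def hc_block_inverse(A: HCMatrix, eps: float = DEFAULT_EPS, _depth: int = 0) -> HCMatrix:
    """Recursive 2x2-block inverse with a Schur complement.

    The matrix is split at ``floor(n/2)`` into ``[[P, Q], [R, S]]``; the
    inverse is assembled from ``P``'s inverse and the inverse of the Schur
    complement ``S - R P^-1 Q``, recursing until 1x1 blocks are inverted by
    :func:`hc_scalar_inv`.  Products inside the block formulas are evaluated
    left-to-right, which matters because the algebra is non-associative for
    d >= 2: there the result is only an approximate inverse and callers
    should check the residual ``||A A^-1 - I||`` (see
    :func:`block_inverse_residual`).  For d <= 1 the algebra is associative
    and the result is an exact inverse up to rounding.
    """
    n, m = A.shape
    if n != m:
        raise ValueError("only square matrices can be inverted")
    if n == 1:
        try:
            y_inv = hc_scalar_inv(A.entry(0, 0), eps=eps)
        except HCLinAlgError as exc:
            raise HCLinAlgError(
                f"singular 1x1 block at recursion depth {_depth}: {exc}"
            ) from exc
        out = HCMatrix.zeros(1, 1, A.d)
        out.components[:, 0, 0] = y_inv.coeffs
        return out

    p = n // 2
    P = A.block(0, p, 0, p)
    Q = A.block(0, p, p, n)
    R = A.block(p, n, 0, p)
    S = A.block(p, n, p, n)

    P_inv = hc_block_inverse(P, eps=eps, _depth=_depth + 1)
    # Schur complement of the leading block, evaluated left-to-right
    schur = S - (R @ P_inv) @ Q
    try:
        schur_inv = hc_block_inverse(schur, eps=eps, _depth=_depth + 1)
    except HCLinAlgError as exc:
        raise HCLinAlgError(
            f"singular Schur complement at recursion depth {_depth}: {exc}"
        ) from exc

    PQ = P_inv @ Q
    RP = R @ P_inv
    top_left = P_inv + ((PQ @ schur_inv) @ RP)
    top_right = -(PQ @ schur_inv)
    bottom_left = -(schur_inv @ RP)

    out = HCMatrix.zeros(n, n, A.d)
    out.components[:, :p, :p] = top_left.components
    out.components[:, :p, p:] = top_right.components
    out.components[:, p:, :p] = bottom_left.components
    out.components[:, p:, p:] = schur_inv.components
    return out


def block_inverse_residual(A: HCMatrix, A_inv: HCMatrix) -> float:
    """Relative residual ``||A A_inv - I||_F / sqrt(n)`` of a claimed inverse."""
    n = A.rows
    eye = hc_identity(n, A.d)
    return hc_frobenius(hc_matmul(A, A_inv) - eye) / np.sqrt(n)


# ---------------------------------------------------------------------------
# exact real-embedding solver
# ---------------------------------------------------------------------------

def real_embedding_matrix(A: HCMatrix) -> np.ndarray:
    """The real matrix of the left-multiplication operator ``X -> A X``.

    Stacking the d+1 components of X into one tall real vector per column,
    left-multiplication by A is the real-linear map with block structure::

        [ A0  -A1  ...  -Ad ]
        [ A1   A0        0  ]
        [ ...      ...      ]
        [ Ad   0        A0  ]

    mirroring the per-scalar multiplication rule.
    """
    d = A.d
    n, m = A.shape
    if n != m:
        raise ValueError("embedding a left-multiplication operator needs a square A")
    big = np.zeros(((d + 1) * n, (d + 1) * n))
    comps = A.components
    for k in range(d + 1):
        big[k * n:(k + 1) * n, k * n:(k + 1) * n] = comps[0]
    for k in range(1, d + 1):
        big[0:n, k * n:(k + 1) * n] = -comps[k]
        big[k * n:(k + 1) * n, 0:n] = comps[k]
    return big


def real_embed_solve(A: HCMatrix, B: HCMatrix) -> HCMatrix:
    """Solve ``A X = B`` exactly by embedding into one real linear system.

    One factorization of the ``(d+1)n x (d+1)n`` embedded operator serves all
    columns of B.  The returned X satisfies ``hc_matmul(A, X) = B`` to linear
    solver precision for every d, including the non-associative d >= 2 case,
    because left-multiplication by A is a genuine real-linear map.
    """
    _check_same_d(A, B)
    if A.rows != A.cols:
        raise ValueError("A must be square")
    if A.cols != B.rows:
        raise ValueError(f"incompatible shapes: {A.shape} and {B.shape}")
    d, n = A.d, A.rows
    big = real_embedding_matrix(A)
    rhs = B.components.reshape((d + 1) * n, B.cols)
    try:
        lu, piv = scipy.linalg.lu_factor(big)
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise HCLinAlgError(f"singular embedded system: {exc}") from exc
    if not np.all(np.isfinite(lu)):
        raise HCLinAlgError("singular embedded system (non-finite factorization)")
    diag = np.abs(np.diag(lu))
    if diag.min() <= DEFAULT_EPS * max(1.0, diag.max()):
        raise HCLinAlgError("singular embedded system (zero pivot)")
    sol = scipy.linalg.lu_solve((lu, piv), rhs)
    return HCMatrix(sol.reshape(d + 1, n, B.cols))
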