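"""Cubic B-spline free-form deformation on a regular grid.

The displacement u(x) is a tensor-product cubic B-spline over a coarse
control-point lattice (spacing delta, in mm, per axis), evaluated on the
voxel grid of the reference image.  Because voxels lie on a regular grid,
evaluation and its adjoint are separable dense matrix contractions with
small per-axis basis matrices, which keeps cost/gradient evaluations fast
in pure numpy.

Conventions: positions are grid-local mm (index * spacing); the lattice has
one knot of margin before 0 and after the last voxel so the spline support
covers the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["FFDTransform", "bspline_weights", "bspline_dweights"]


def bspline_weights(s: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values B0..B3 at local offset s in [0,1].

    Returns array (..., 4); the weights sum to 1 (partition of unity).
    """
    s = np.asarray(s, dtype=np.float64)
    s2, s3 = s * s, s * s * s
    return np.stack(
        [
            (1 - 3 * s + 3 * s2 - s3) / 6.0,
            (4 - 6 * s2 + 3 * s3) / 6.0,
            (1 + 3 * s + 3 * s2 - 3 * s3) / 6.0,
            s3 / 6.0,
        ],
        axis=-1,
    )


def bspline_dweights(s: np.ndarray) -> np.ndarray:
    """Derivatives dB/ds of the four cubic basis functions; sum to 0."""
    s = np.asarray(s, dtype=np.float64)
    s2 = s * s
    return np.stack(
        [
            (-3 + 6 * s - 3 * s2) / 6.0,
            (-12 * s + 9 * s2) / 6.0,
            (3 + 6 * s - 9 * s2) / 6.0,
            3 * s2 / 6.0,
        ],
        axis=-1,
    )


def _axis_matrices(n: int, h: float, delta: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Dense basis matrix B (n, nc) and derivative matrix D (d/dx, mm^-1)."""
    extent = (n - 1) * h
    nseg = max(1, int(np.ceil(extent / delta - 1e-12)))
    nc = nseg + 3
    x = np.arange(n) * h
    t = x / delta
    i = np.minimum(np.floor(t).astype(int), nseg - 1)
    s = t - i
    w = bspline_weights(s)
    dw = bspline_dweights(s) / delta
    B = np.zeros((n, nc))
    D = np.zeros((n, nc))
    rows = np.arange(n)
    for l in range(4):
        B[rows, i + l] = w[:, l]
        D[rows, i + l] = dw[:, l]
    return B, D, nc


@dataclass
class FFDTransform:
    """A displacement field parameterized by B-spline control coefficients.

    Parameters
    ----------
    grid_shape, grid_spacing
        Voxel grid the transform is evaluated on (reference image grid).
    control_spacing
        Lattice spacing in mm per axis.
    coefficients
        (ncx, ncy, ncz, 3) control displacements in mm; zero = identity.
    """

    grid_shape: tuple[int, int, int]
    grid_spacing: tuple[float, float, float]
    control_spacing: tuple[float, float, float]
    coefficients: np.ndarray = None  # set in __post_init__ when None

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.grid_spacing = tuple(float(h) for h in self.grid_spacing)
        self.control_spacing = tuple(float(d) for d in self.control_spacing)
        self._B, self._D, ncs = [], [], []
        for a in range(3):
            B, D, nc = _axis_matrices(
                self.grid_shape[a], self.grid_spacing[a], self.control_spacing[a]
            )
            self._B.append(B)
            self._D.append(D)
            ncs.append(nc)
        self.control_shape = tuple(ncs)
        if self.coefficients is None:
            self.coefficients = np.zeros(self.control_shape + (3,))
        else:
            self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
            if self.coefficients.shape != self.control_shape + (3,):
                raise ValueError(
                    f"coefficients shape {self.coefficients.shape} != "
                    f"{self.control_shape + (3,)}"
                )

    # -- forward evaluation -------------------------------------------------

    def _chain(self, C: np.ndarray, mats: Sequence[np.ndarray]) -> np.ndarray:
        out = np.einsum(
            "xi,yj,zk,ijkc->xyzc", mats[0], mats[1], mats[2], C, optimize=True
        )
        return out

    def displacement(self, coefficients: np.ndarray | None = None) -> np.ndarray:
        """Displacement u (mm) at every voxel: (nx, ny, nz, 3)."""
        C = self.coefficients if coefficients is None else coefficients
        return self._chain(C, self._B)

    def displacement_gradient(self, coefficients: np.ndarray | None = None) -> np.ndarray:
        """Spatial gradient du_c/dx_a at every voxel: (nx, ny, nz, 3, 3).

        Index order: [..., c, a] = d u_c / d x_a.
        """
        C = self.coefficients if coefficients is None else coefficients
        out = np.empty(self.grid_shape + (3, 3))
        for a in range(3):
            mats = [self._D[i] if i == a else self._B[i] for i in range(3)]
            out[..., :, a] = self._chain(C, mats)
        return out

    # -- adjoints (for analytic cost gradients) -----------------------------

    def backproject(self, W: np.ndarray, deriv_axis: int | None = None) -> np.ndarray:
        """Adjoint of displacement (or of one spatial-derivative channel).

        Given voxelwise sensitivities W (nx, ny, nz, 3) = dE/du (or
        dE/d(du/dx_a) when `deriv_axis` = a), returns dE/dC with the
        coefficient array's shape.
        """
        mats = [
            self._D[i] if i == deriv_axis else self._B[i] for i in range(3)
        ]
        return np.einsum(
            "xi,yj,zk,xyzc->ijkc", mats[0], mats[1], mats[2], W, optimize=True
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, field: np.ndarray, rcond: float = 1e-8) -> np.ndarray:
        """Least-squares B-spline coefficients reproducing a voxel-grid field.

        Separable per-axis solve; exact whenever `field` is representable on
        this lattice (e.g. when transferring a coarser-level transform).
        Sets and returns the coefficients.
        """
        field = np.asarray(field, dtype=np.float64)
        if field.shape != self.grid_shape + (3,):
            raise ValueError(f"field shape {field.shape} != {self.grid_shape + (3,)}")
        out = field
        for a in range(3):
            P = np.linalg.pinv(self._B[a], rcond=rcond)  # (nc, n)
            out = np.moveaxis(np.tensordot(P, out, axes=(1, a)), 0, a)
        self.coefficients = out
        return out

    def jacobian_matrices(self, coefficients: np.ndarray | None = None) -> np.ndarray:
        """Per-voxel Jacobian of T(x) = x + u(x): identity + displacement gradient."""
        G = self.displacement_gradient(coefficients)
        G[..., 0, 0] += 1.0
        G[..., 1, 1] += 1.0
        G[..., 2, 2] += 1.0
        return G


def det3(M: np.ndarray) -> np.ndarray:
    """Determinant of (..., 3, 3) matrices, explicit cofactor expansion."""
    return (
        M[..., 0, 0] * (M[..., 1, 1] * M[..., 2, 2] - M[..., 1, 2] * M[..., 2, 1])
        - M[..., 0, 1] * (M[..., 1, 0] * M[..., 2, 2] - M[..., 1, 2] * M[..., 2, 0])
        + M[..., 0, 2] * (M[..., 1, 0] * M[..., 2, 1] - M[..., 1, 1] * M[..., 2, 0])
    )


def cofactor3(M: np.ndarray) -> np.ndarray:
    """Cofactor matrix of (..., 3, 3) matrices: d det(M) / d M (Jacobi's formula)."""
    C = np.empty_like(M)
    C[..., 0, 0] = M[..., 1, 1] * M[..., 2, 2] - M[..., 1, 2] * M[..., 2, 1]
    C[..., 0, 1] = M[..., 1, 2] * M[..., 2, 0] - M[..., 1, 0] * M[..., 2, 2]
    C[..., 0, 2] = M[..., 1, 0] * M[..., 2, 1] - M[..., 1, 1] * M[..., 2, 0]
    C[..., 1, 0] = M[..., 0, 2] * M[..., 2, 1] - M[..., 0, 1] * M[..., 2, 2]
    C[..., 1, 1] = M[..., 0, 0] * M[..., 2, 2] - M[..., 0, 2] * M[..., 2, 0]
    C[..., 1, 2] = M[..., 0, 1] * M[..., 2, 0] - M[..., 0, 0] * M[..., 2, 1]
    C[..., 2, 0] = M[..., 0, 1] * M[..., 1, 2] - M[..., 0, 2] * M[..., 1, 1]
    C[..., 2, 1] = M[..., 0, 2] * M[..., 1, 0] - M[..., 0, 0] * M[..., 1, 2]
    C[..., 2, 2] = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    return C


def trilinear(
    data: np.ndarray, idx: np.ndarray, fill: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trilinear interpolation at continuous voxel indices.

    Parameters
    ----------
    data
        3-D array.
    idx
        (n, 3) continuous indices.
    fill
        Value (with zero gradient) for samples outside the grid.

    Returns
    -------
    values : (n,), gradient w.r.t. index : (n, 3), inside : (n,) bool.
    """
    shape = np.asarray(data.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    p = np.clip(idx, 0, shape - 1)
    i0 = np.minimum(p.astype(np.intp), shape - 2)  # exact at the last grid plane
    f = p - i0
    i1 = i0 + 1

    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1, y1, z1 = i1[:, 0], i1[:, 1], i1[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]

    c000 = data[x0, y0, z0]
    c100 = data[x1, y0, z0]
    c010 = data[x0, y1, z0]
    c110 = data[x1, y1, z0]
    c001 = data[x0, y0, z1]
    c101 = data[x1, y0, z1]
    c011 = data[x0, y1, z1]
    c111 = data[x1, y1, z1]

    # collapse z, then y, then x; track partials on the way
    c00 = c000 * (1 - fz) + c001 * fz
    c10 = c100 * (1 - fz) + c101 * fz
    c01 = c010 * (1 - fz) + c011 * fz
    c11 = c110 * (1 - fz) + c111 * fz

    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    val = c0 * (1 - fx) + c1 * fx

    dx = c1 - c0
    dy = (c01 - c00) * (1 - fx) + (c11 - c10) * fx
    dz0 = (c001 - c000) * (1 - fy) + (c011 - c010) * fy
    dz1 = (c101 - c100) * (1 - fy) + (c111 - c110) * fy
    dz = dz0 * (1 - fx) + dz1 * fx

    grad = np.stack([dx, dy, dz], axis=1)
    if not inside.all():
        out = ~inside
        val = np.where(out, fill, val)
        grad[out] = 0.0
    return val, grad, inside
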