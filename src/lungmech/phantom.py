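"""Digital serial-CT phantoms with known deformation and ground truth.

A phantom pair stands in for two inspiratory scans of the same subject: the
Time 0 (floating) image is built from simple geometry — an ellipsoidal lung
of air-dominated parenchyma with smooth HU texture, a trachea-like air
cylinder, bright vessel-like tubes and a soft-tissue body — and the Time 1
(reference) image is synthesized by warping it with an analytic, invertible
deformation using the mass-preserving intensity rule: the warped tissue
fraction is the source fraction times the local volume contraction
det(dT/dx), so the tissue volume of matched regions is conserved and the HU
of an expanded region drops exactly as a real inflating lung's would.
Independent Gaussian HU noise is then added to each time point.

Because the deformation is analytic, the phantom carries exact ground truth:
the true displacement field, the true Jacobian volume ratio J = 1/det(dT/dx)
and the true delta*, delta_air*, delta_tissue* maps computed from the
generator's own global lung volumes.  A "hyper-expansion" region — a sphere
whose core expands uniformly toward a requested target delta*, blended to
the identity over a C1 falloff shell of width radius/4 — and a "tissue
lesion" (a multiplicative tissue-fraction increase applied before warping)
emulate the focal signals the method is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi

from ._ffd import FFDTransform, det3, trilinear
from .density import tissue_fraction
from .mechanics import (
    DEFAULT_PAIR_CUTOFFS,
    DEFAULT_THRESHOLDS,
    ExpansionSummary,
    MechanicsMaps,
    expansion_summary,
)
from .register import DeformationField
from .volio import HU_AIR, HU_TISSUE, MaskSet, ScalarVolume

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "HyperRegion",
    "TissueLesion",
    "generate",
    "oracle_summary",
]

_HU_RANGE = HU_TISSUE - HU_AIR


class PhantomSpecError(ValueError):
    pass


@dataclass
class HyperRegion:
    """Spherical region whose core hyper-expands between the time points.

    `center` in grid-local mm on the reference grid (None = lung center
    offset), `radius` in mm, `target_delta_star` the intended core delta*.
    """

    radius: float
    target_delta_star: float
    center: Optional[tuple[float, float, float]] = None


@dataclass
class TissueLesion:
    """Multiplicative tissue-fraction increase (capped at 1) before warping."""

    radius: float
    multiplier: float = 1.6
    center: Optional[tuple[float, float, float]] = None


@dataclass
class PhantomSpec:
    """Study-condition parameters of one synthetic serial pair.

    Defaults emulate a scaled-down thorax: a ~70% of grid-extent ellipsoidal
    lung of parenchyma near −860 HU with smooth 40 HU texture, trachea at
    −1000 HU, body at +55 HU, a few bright vessels, and 20 HU additive scan
    noise.  `deformation` is the background inter-scan deformation
    ("identity", "affine", "bspline-random"); a `hyper_region` composes a
    local radial expansion on top of it.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    lung_axes_frac: tuple[float, float, float] = (0.33, 0.36, 0.40)
    parenchyma_hu_mean: float = -860.0
    parenchyma_texture_sd: float = 40.0
    texture_smoothing_vox: float = 2.0
    trachea_hu: float = HU_AIR
    body_hu: float = HU_TISSUE
    trachea_radius_frac: float = 0.06
    vessel_count: int = 4
    vessel_radius: float = 3.0
    vessel_hu: float = HU_TISSUE
    deformation: str = "identity"
    affine_scale: float | tuple[float, float, float] = 1.0
    bspline_amplitude_frac: float = 0.15
    bspline_control_spacing: float = 24.0
    hyper_region: Optional[HyperRegion] = None
    tissue_lesion: Optional[TissueLesion] = None
    noise_sd: float = 20.0
    seed: int = 0

    def extent(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def lung_center(self) -> np.ndarray:
        return self.extent() / 2.0

    def lung_axes(self) -> np.ndarray:
        return self.extent() * np.asarray(self.lung_axes_frac)


@dataclass
class PhantomPair:
    """A synthetic serial pair plus its exact ground truth.

    time1 is the reference (later) image; all truth maps live on its grid.
    """

    time0: ScalarVolume
    time0_mask: MaskSet
    time1: ScalarVolume
    time1_mask: MaskSet
    true_field: DeformationField
    true_J: np.ndarray
    true_delta_star: np.ndarray
    true_delta_air_star: np.ndarray
    true_delta_tissue_star: np.ndarray
    Vr: float
    Vf: float
    spec: PhantomSpec

    def true_maps(self) -> MechanicsMaps:
        """Package the ground truth as MechanicsMaps (the run_pair oracle)."""
        domain = self.time1_mask.lung
        nanify = lambda m: np.where(domain, m, np.nan)
        return MechanicsMaps(
            J=nanify(self.true_J),
            delta_star=nanify(self.true_delta_star),
            delta_air_star=nanify(self.true_delta_air_star),
            delta_tissue_star=nanify(self.true_delta_tissue_star),
            Vr=self.Vr,
            Vf=self.Vf,
            domain=domain,
        )


# ---------------------------------------------------------------------------
# analytic deformations: objects mapping reference points -> floating points
# ---------------------------------------------------------------------------


class _Identity:
    def map(self, pts: np.ndarray) -> np.ndarray:
        return pts

    def det(self, pts: np.ndarray) -> np.ndarray:
        return np.ones(pts.shape[0])


class _Affine:
    """T(x) = c + A (x - c); for an expansion S from Time 0 to Time 1, A = S^-1."""

    def __init__(self, A: np.ndarray, center: np.ndarray):
        self.A = np.asarray(A, dtype=np.float64)
        self.center = np.asarray(center, dtype=np.float64)
        self._det = float(np.linalg.det(self.A))

    def map(self, pts: np.ndarray) -> np.ndarray:
        return self.center + (pts - self.center) @ self.A.T

    def det(self, pts: np.ndarray) -> np.ndarray:
        return np.full(pts.shape[0], self._det)


class _RadialContraction:
    """Radial map about a center: uniform scale s0 < 1 in the core, C1-blended
    to the identity across a shell [R - w, R] (w = R/4) via a monotone cubic
    Hermite radius profile g(rho)."""

    def __init__(self, center: np.ndarray, radius: float, s0: float):
        self.center = np.asarray(center, dtype=np.float64)
        self.R = float(radius)
        self.w = self.R / 4.0
        self.R1 = self.R - self.w
        self.s0 = float(s0)

    def _profile(self, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """g(rho) and g'(rho)."""
        g = rho.copy()
        dg = np.ones_like(rho)
        core = rho <= self.R1
        g[core] = self.s0 * rho[core]
        dg[core] = self.s0
        shell = (rho > self.R1) & (rho < self.R)
        if shell.any():
            t = (rho[shell] - self.R1) / self.w  # in (0, 1)
            p0, p1 = self.s0 * self.R1, self.R
            m0, m1 = self.s0 * self.w, 1.0 * self.w  # slopes scaled by w
            h00 = 2 * t**3 - 3 * t**2 + 1
            h10 = t**3 - 2 * t**2 + t
            h01 = -2 * t**3 + 3 * t**2
            h11 = t**3 - t**2
            g[shell] = h00 * p0 + h10 * m0 + h01 * p1 + h11 * m1
            dh00 = 6 * t**2 - 6 * t
            dh10 = 3 * t**2 - 4 * t + 1
            dh01 = -6 * t**2 + 6 * t
            dh11 = 3 * t**2 - 2 * t
            dg[shell] = (dh00 * p0 + dh10 * m0 + dh01 * p1 + dh11 * m1) / self.w
        return g, dg

    def map(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        rho = np.linalg.norm(d, axis=1)
        g, _ = self._profile(rho)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rho > 0, g / rho, self.s0)
        return self.center + scale[:, None] * d

    def det(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.center
        rho = np.linalg.norm(d, axis=1)
        g, dg = self._profile(rho)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(rho > 0, g / rho, self.s0)
        return dg * ratio * ratio


class _BSplineField:
    """Random smooth B-spline displacement with analytic Jacobian."""

    def __init__(self, shape, spacing, control_spacing, amplitude, rng):
        self.ffd = FFDTransform(shape, spacing, (control_spacing,) * 3)
        coeffs = rng.normal(0.0, amplitude, size=self.ffd.control_shape + (3,))
        self.ffd.coefficients = coeffs
        self._u = self.ffd.displacement()
        self._det = det3(self.ffd.jacobian_matrices())
        self.shape = tuple(shape)
        self.spacing = np.asarray(spacing)

    def _interp(self, arr, pts):
        idx = pts / self.spacing
        if arr.ndim == 3:
            val, _, _ = trilinear(arr, idx, fill=0.0)
            return val
        return np.stack(
            [trilinear(arr[..., c], idx, fill=0.0)[0] for c in range(arr.shape[-1])],
            axis=1,
        )

    def map(self, pts: np.ndarray) -> np.ndarray:
        return pts + self._interp(self._u, pts)

    def det(self, pts: np.ndarray) -> np.ndarray:
        return self._interp(self._det, pts)


class _Composed:
    """T = outer o inner; det(x) = det_outer(inner(x)) * det_inner(x)."""

    def __init__(self, outer, inner):
        self.outer = outer
        self.inner = inner

    def map(self, pts: np.ndarray) -> np.ndarray:
        return self.outer.map(self.inner.map(pts))

    def det(self, pts: np.ndarray) -> np.ndarray:
        mid = self.inner.map(pts)
        return self.outer.det(mid) * self.inner.det(pts)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape).reshape(3, -1).T
    return idx * np.asarray(spec.spacing)


def _inside_ellipsoid(pts: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    q = (pts - center) / axes
    return np.einsum("ij,ij->i", q, q) <= 1.0


def _trachea_test(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Vertical air cylinder along the superior half of the z axis, mid-thorax."""
    ext = spec.extent()
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    r = spec.trachea_radius_frac * min(ext[0], ext[1])
    in_xy = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= r * r
    return in_xy & (pts[:, 2] >= 0.55 * ext[2])


def _vessel_segments(spec: PhantomSpec, rng: np.random.Generator) -> list:
    """Random straight tubes from near the lung center outward."""
    c = spec.lung_center()
    axes = spec.lung_axes()
    segs = []
    for _ in range(spec.vessel_count):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start = c + rng.normal(0, 0.1, 3) * axes
        end = c + direction * axes * rng.uniform(0.5, 0.85)
        segs.append((start, end))
    return segs


def _vessel_test(pts: np.ndarray, segs, radius: float) -> np.ndarray:
    out = np.zeros(pts.shape[0], dtype=bool)
    for a, b in segs:
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        closest = a + t[:, None] * ab
        out |= np.linalg.norm(pts - closest, axis=1) <= radius
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _build_time0(spec: PhantomSpec, rng: np.random.Generator, segs):
    """Noiseless Time 0 HU grid and its analytic membership tests."""
    pts = _grid_points(spec)
    lung = _inside_ellipsoid(pts, spec.lung_center(), spec.lung_axes())
    trachea = _trachea_test(pts, spec)
    vessels = _vessel_test(pts, segs, spec.vessel_radius) & lung & ~trachea

    hu = np.full(pts.shape[0], spec.body_hu)
    texture = rng.normal(size=spec.shape)
    texture = ndi.gaussian_filter(texture, spec.texture_smoothing_vox)
    sd = texture.std()
    if sd > 0:
        texture *= spec.parenchyma_texture_sd / sd
    hu[lung] = spec.parenchyma_hu_mean + texture.reshape(-1)[lung]
    hu[vessels] = spec.vessel_hu
    hu[trachea] = spec.trachea_hu
    hu = np.clip(hu, HU_AIR, HU_TISSUE)
    return hu.reshape(spec.shape), lung.reshape(spec.shape), trachea.reshape(
        spec.shape
    ), vessels.reshape(spec.shape)


def _background_deformation(spec: PhantomSpec, rng: np.random.Generator):
    if spec.deformation == "identity":
        return _Identity()
    if spec.deformation == "affine":
        s = spec.affine_scale
        s = (float(s),) * 3 if np.isscalar(s) else tuple(float(v) for v in s)
        A = np.diag([1.0 / v for v in s])  # expansion s from Time 0 -> Time 1
        return _Affine(A, spec.lung_center())
    if spec.deformation == "bspline-random":
        amp = spec.bspline_amplitude_frac * spec.bspline_control_spacing
        return _BSplineField(
            spec.shape, spec.spacing, spec.bspline_control_spacing, amp, rng
        )
    raise PhantomSpecError(f"unknown deformation model {spec.deformation!r}")


def generate(spec: PhantomSpec) -> PhantomPair:
    """Generate a deterministic phantom pair from a spec and its seed.

    The Time 1 (reference) image is synthesized by the mass-preserving rule
    f1(x) = f0(T(x)) * det(dT/dx) on tissue fractions, with the optional
    lesion multiplier applied to f0 first; the hyper-expansion core scale is
    calibrated (two fixed-point sweeps over the resulting lung masks) so the
    core delta* matches the requested target.  Raises
    :class:`PhantomSpecError` if the requested deformation is not invertible
    on the grid (reporting the minimum Jacobian determinant found).
    """
    rng = np.random.default_rng(spec.seed)
    segs = _vessel_segments(spec, rng)
    hu0, lung0, trachea0, vessels0 = _build_time0(spec, rng, segs)
    pts = _grid_points(spec)
    background = _background_deformation(spec, rng)

    center_r = None
    if spec.hyper_region is not None:
        hr = spec.hyper_region
        if hr.target_delta_star <= -1:
            raise PhantomSpecError("target delta* must exceed -1")
        center_r = (
            np.asarray(hr.center, dtype=np.float64)
            if hr.center is not None
            else spec.lung_center() + spec.lung_axes() * np.array([0.45, 0.0, 0.2])
        )

    def assemble(s0: Optional[float]):
        if center_r is None or s0 is None:
            return background
        radial = _RadialContraction(center_r, spec.hyper_region.radius, s0)
        return _Composed(background, radial)

    def lung_mask_time1(T) -> np.ndarray:
        mapped = T.map(pts)
        in_lung = _inside_ellipsoid(mapped, spec.lung_center(), spec.lung_axes())
        in_trach = _trachea_test(mapped, spec)
        return (in_lung & ~in_trach).reshape(spec.shape)

    n_flt = int((lung0 & ~trachea0).sum())
    Vf = n_flt * float(np.prod(spec.spacing))

    # calibrate the hyper-expansion core scale against the actual V_r/V_f
    s0 = None
    if center_r is not None:
        ratio = 1.0
        for _ in range(2):
            target_J = (1.0 + spec.hyper_region.target_delta_star) * ratio
            s0 = target_J ** (-1.0 / 3.0)
            mask1 = lung_mask_time1(assemble(s0))
            Vr = int(mask1.sum()) * float(np.prod(spec.spacing))
            ratio = Vr / Vf

    T = assemble(s0)
    det = T.det(pts)
    min_det = float(det.min())
    if min_det <= 0:
        raise PhantomSpecError(
            f"requested deformation is not invertible on the grid "
            f"(min det = {min_det:.4g})"
        )

    lung1 = lung_mask_time1(T)
    mapped = T.map(pts)
    trachea1 = _trachea_test(mapped, spec).reshape(spec.shape)
    vessels1 = (
        _vessel_test(mapped, segs, spec.vessel_radius).reshape(spec.shape) & lung1
    )
    Vr = int(lung1.sum()) * float(np.prod(spec.spacing))

    # mass-preserving intensity synthesis
    f0 = tissue_fraction(hu0)
    if spec.tissue_lesion is not None:
        tl = spec.tissue_lesion
        center_l = (
            np.asarray(tl.center, dtype=np.float64)
            if tl.center is not None
            else (T.map(center_r[None, :])[0] if center_r is not None
                  else spec.lung_center())
        )
        grid_pts = _grid_points(spec)
        in_lesion = (
            np.linalg.norm(grid_pts - center_l, axis=1) <= tl.radius
        ).reshape(spec.shape)
        f0_lesioned = np.where(in_lesion, np.minimum(1.0, tl.multiplier * f0), f0)
        mult_grid = np.where(in_lesion, tl.multiplier, 1.0)
    else:
        f0_lesioned = f0
        mult_grid = np.ones(spec.shape)

    idx_f = mapped / np.asarray(spec.spacing)
    f0L_at_T, _, _ = trilinear(f0_lesioned, idx_f, fill=0.0)
    f0_at_T, _, _ = trilinear(f0, idx_f, fill=0.0)
    mult_at_T, _, _ = trilinear(mult_grid.astype(np.float64), idx_f, fill=1.0)
    f1 = np.clip(f0L_at_T * det, 0.0, 1.0).reshape(spec.shape)
    hu1 = HU_AIR + _HU_RANGE * f1

    noise0 = rng.normal(0.0, spec.noise_sd, size=spec.shape)
    noise1 = rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol0 = ScalarVolume(hu0 + noise0, spec.spacing)
    vol1 = ScalarVolume(hu1 + noise1, spec.spacing)

    # exact ground truth on the reference grid
    v = float(np.prod(spec.spacing))
    det_grid = det.reshape(spec.shape)
    with np.errstate(divide="ignore"):
        true_J = np.where(det_grid > 0, 1.0 / det_grid, np.nan)
    true_delta = true_J * (Vf / Vr) - 1.0
    mult_at_T = mult_at_T.reshape(spec.shape)
    true_d_tis = mult_at_T * (Vf / Vr) - 1.0
    # air ratio from the synthesized fractions: v_air_r / v_air_f_matched
    f0g = f0_at_T.reshape(spec.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        air_ratio = (1.0 - f1) / (det_grid * (1.0 - f0g))
    true_d_air = np.where(
        (1.0 - f0g) > 1e-9, air_ratio * (Vf / Vr) - 1.0, np.nan
    )

    u = (mapped - pts).reshape(spec.shape + (3,))
    pair = PhantomPair(
        time0=vol0,
        time0_mask=MaskSet(lung=lung0 & ~trachea0, airways=trachea0,
                           vessels=vessels0),
        time1=vol1,
        time1_mask=MaskSet(lung=lung1, airways=trachea1, vessels=vessels1),
        true_field=DeformationField(u, spec.spacing),
        true_J=true_J,
        true_delta_star=true_delta,
        true_delta_air_star=true_d_air,
        true_delta_tissue_star=true_d_tis,
        Vr=Vr,
        Vf=Vf,
        spec=spec,
    )
    return pair


def oracle_summary(
    pair: PhantomPair,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    pair_cutoffs: Sequence[float] = DEFAULT_PAIR_CUTOFFS,
    erosion: int = 0,
) -> ExpansionSummary:
    """Expansion summary computed from the exact ground-truth maps.

    This bypasses registration entirely and is the end-to-end oracle the
    full pipeline is validated against.
    """
    return expansion_summary(pair.true_maps(), thresholds, pair_cutoffs, erosion)
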