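"""Micronucleus morphometry: projected area, volume, surface, NPC spots.

The MN volume is the average of two estimators computed from the
lamin-positive voxel cloud — the minimum-volume enclosing ellipsoid and
the convex hull — and the surface area is derived from that volume by
sphere equivalence. Nuclear-pore (Nup133) foci are detected as
scale-matched Laplacian-of-Gaussian blobs with sub-voxel refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .core_io import VoxelSpacing

__all__ = [
    "VolumeEstimate",
    "SpotSet",
    "mn_area",
    "fit_enclosing_ellipsoid",
    "convex_hull_volume",
    "mn_volume_surface",
    "detect_spots",
    "spot_density",
    "sphere_equivalent_surface",
]


@dataclass
class VolumeEstimate:
    """Ellipsoid / hull volumes (um^3), their mean, and derived surface."""

    v_ellipsoid_um3: float
    v_hull_um3: float
    v_mn_um3: float
    surface_um2: float


@dataclass
class SpotSet:
    """Detected fluorescent foci with physical coordinates (z, y, x) in um."""

    coordinates: np.ndarray  # (n, 3)
    threshold: float
    diameter_um: float = 0.2

    @property
    def count(self) -> int:
        return len(self.coordinates)


def mn_area(projected_mask: np.ndarray, spacing: VoxelSpacing) -> float:
    """Object area of a maximum-projection mask, converted to um^2."""
    return float(np.count_nonzero(projected_mask)) * spacing.pixel_area_um2


def fit_enclosing_ellipsoid(points: np.ndarray, tolerance: float = 1e-6):
    """Minimum-volume enclosing ellipsoid by Khachiyan's algorithm.

    Parameters
    ----------
    points:
        (n, 3) coordinates in um; needs >= 4 affinely independent points.

    Returns
    -------
    (center, radii, rotation, volume):
        Ellipsoid centre, semi-axes (descending), rotation matrix with
        axes as rows, and 4pi/3 * abc. Every input point lies inside or on
        the ellipsoid up to the iteration tolerance.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("need >= 4 affinely independent points")
    # the MVEE is determined by the convex hull vertices alone
    if len(pts) > 64:
        pts = pts[ConvexHull(pts).vertices]
    n, d = pts.shape
    q = np.column_stack([pts, np.ones(n)]).T  # (4, n)
    u = np.full(n, 1.0 / n)
    for _ in range(10000):
        x = (q * u) @ q.T
        m = np.einsum("ji,jk,ki->i", q, np.linalg.inv(x), q)  # Mahalanobis
        j = int(np.argmax(m))
        step = (m[j] - d - 1.0) / ((d + 1.0) * (m[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        err = np.linalg.norm(new_u - u)
        u = new_u
        if err < tolerance:
            break
    center = pts.T @ u
    # ellipsoid {x : (x-c)^T A (x-c) <= 1}, A = inv(sum_i u_i x x^T - c c^T)/d
    scatter = (pts.T * u) @ pts - np.outer(center, center)
    a_mat = np.linalg.inv(scatter) / d
    eigval, eigvec = np.linalg.eigh(a_mat)
    radii = 1.0 / np.sqrt(eigval)
    order = np.argsort(radii)[::-1]
    radii = radii[order]
    rotation = eigvec[:, order].T
    volume = 4.0 * np.pi / 3.0 * float(np.prod(radii))
    return center, radii, rotation, volume


def convex_hull_volume(points: np.ndarray) -> float:
    """Exact convex-hull volume of a 3D point cloud (um^3)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need >= 4 points in 3D")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("degenerate (coplanar/collinear) points")
    return float(ConvexHull(pts).volume)


def sphere_equivalent_surface(volume_um3: float) -> float:
    """Surface area of the sphere with the given volume."""
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0))


def mn_volume_surface(lamin_positive_points: np.ndarray) -> VolumeEstimate:
    """MN volume and derived surface from lamin-positive voxel coordinates.

    v_mn is the mean of the enclosing-ellipsoid and convex-hull volumes;
    the surface is the sphere-equivalent surface of v_mn.
    """
    *_, v_ell = fit_enclosing_ellipsoid(lamin_positive_points)
    v_hull = convex_hull_volume(lamin_positive_points)
    v_mn = 0.5 * (v_ell + v_hull)
    return VolumeEstimate(
        v_ellipsoid_um3=v_ell,
        v_hull_um3=v_hull,
        v_mn_um3=v_mn,
        surface_um2=sphere_equivalent_surface(v_mn),
    )


def _log_peak(sigma_px: tuple[float, float, float]) -> float:
    """Centre response of the (negated) LoG filter to a matched unit spot."""
    radii = [max(1, int(np.ceil(4 * s))) for s in sigma_px]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in radii], indexing="ij")
    spot = np.exp(-0.5 * sum((g / s) ** 2 for g, s in zip(grids, sigma_px)))
    resp = -ndimage.gaussian_laplace(spot, sigma_px)
    return float(resp[tuple(radii)])


def _quadratic_refine(values: np.ndarray, idx: tuple[int, ...]) -> np.ndarray:
    """Per-axis 3-point quadratic peak interpolation around a local maximum."""
    offset = np.zeros(values.ndim)
    for ax in range(values.ndim):
        i = idx[ax]
        if 0 < i < values.shape[ax] - 1:
            sl = list(idx)
            sl[ax] = slice(i - 1, i + 2)
            f = values[tuple(sl)]
            denom = f[0] - 2 * f[1] + f[2]
            if denom < 0:
                offset[ax] = float(np.clip(0.5 * (f[0] - f[2]) / denom, -0.5, 0.5))
    return offset


def detect_spots(stack_channel: np.ndarray,
                 spacing: VoxelSpacing,
                 diameter_um: float = 0.2,
                 threshold: float = 0.0,
                 region_mask: np.ndarray | None = None) -> SpotSet:
    """Detect diffraction-sized foci by Laplacian-of-Gaussian matching.

    The lateral LoG scale is sigma = diameter / (2*sqrt(2)), the optimum
    for a Gaussian spot of the given FWHM-scale diameter; the axial sigma
    is scaled by the voxel anisotropy. Local maxima of the
    scale-normalised negated LoG above ``threshold`` are kept and refined
    to sub-voxel positions by a per-axis quadratic fit. The threshold is a
    per-image parameter, matching how foci were gated in the source
    workflow; there is no auto-tuning.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    arr = np.asarray(stack_channel, dtype=np.float64)
    sigma_um = diameter_um / (2.0 * np.sqrt(2.0))
    sigma_px = (
        sigma_um * 1000.0 / spacing.dz_nm,
        sigma_um * 1000.0 / spacing.dy_nm,
        sigma_um * 1000.0 / spacing.dx_nm,
    )
    # normalise so a matched unit-amplitude Gaussian focus peaks at ~1:
    # the threshold is then an amplitude in image-intensity units
    log_resp = -ndimage.gaussian_laplace(arr, sigma_px) / _log_peak(sigma_px)
    if region_mask is not None:
        log_resp = np.where(region_mask, log_resp, 0.0)
    local_max = ndimage.maximum_filter(log_resp, size=3, mode="constant")
    peaks = (log_resp == local_max) & (log_resp > threshold)
    coords_px = np.argwhere(peaks)
    # merge peaks closer than one spot radius (plateaus, shoulder maxima):
    # strongest wins, mirroring one focus = one spot
    order = np.argsort(log_resp[tuple(coords_px.T)])[::-1]
    zyx_um = np.asarray(spacing.zyx_um)
    kept_um: list[np.ndarray] = []
    kept_idx: list[np.ndarray] = []
    min_sep = diameter_um / 2.0
    for i in order:
        p_um = coords_px[i] * zyx_um
        if all(np.linalg.norm(p_um - q) >= min_sep for q in kept_um):
            kept_um.append(p_um)
            kept_idx.append(coords_px[i])
    refined = [idx + _quadratic_refine(log_resp, tuple(idx))
               for idx in kept_idx]
    if refined:
        coords = np.asarray(refined) * zyx_um
    else:
        coords = np.empty((0, 3))
    return SpotSet(coordinates=coords, threshold=threshold,
                   diameter_um=diameter_um)


def spot_density(spots: SpotSet, surface_um2: float,
                 reference_density: float | None = None):
    """Foci per um^2 of surface, optionally normalised to a reference.

    Returns ``(density, normalized)``; normalized is None without a
    reference. The reference is typically the matched nucleus density.
    """
    if surface_um2 <= 0:
        raise ValueError("surface area must be positive")
    density = spots.count / surface_um2
    if reference_density is None:
        return density, None
    if reference_density == 0:
        raise ZeroDivisionError("reference density is zero")
    return density, density / reference_density
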