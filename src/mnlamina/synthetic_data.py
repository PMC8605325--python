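"""Synthetic micronucleus stacks, contingency tables and genomic fixtures.

Every generator is a pure function of (spec, seed) and returns its ground
truth alongside the data, so each pipeline stage can be tested against a
known answer without any external download.

The image model emulates a STED-like acquisition of a micronucleus: an
oblate-spheroid lamin shell carrying a meshwork texture (a thresholded
band of a smoothed random field — real lamin meshwork geometry is not
modelled, only its line-like statistics), optional lamina gaps of known
projected area and residual intensity, a DNA-filled interior, an H3K27ac
channel whose mean encodes the rupture state, Gaussian nuclear-pore and
centromere foci, an anisotropic Gaussian PSF, and Poisson + Gaussian
noise. Default spacing is 20 nm laterally with a 0.15 um z-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import DEFAULT_SPACING, ImageStack, VoxelSpacing
from .lad_genomics import GenomicIntervalSet, normalize_intervals
from .stats import ContingencyTable2x2

__all__ = [
    "GapSpec",
    "SyntheticMNSpec",
    "GroundTruth",
    "generate_mn_stack",
    "generate_population",
    "generate_contingency",
    "generate_bed_fixture",
    "bed_text",
]

_THOMSEN_P = 1.6075  # Knud Thomsen approximation exponent for ellipsoid surface


@dataclass(frozen=True)
class GapSpec:
    """One lamina gap: shell position (polar, azimuth), projected area,
    and the fraction of lamin intensity retained inside."""

    theta: float  # polar angle from +z, radians
    phi: float  # azimuth, radians
    area_um2: float
    residual_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("gap area must be positive")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticMNSpec:
    """Full description of one synthetic micronucleus acquisition."""

    semi_axes_um: tuple[float, float, float] = (1.5, 1.4, 1.0)
    shell_thickness_um: float = 0.12
    mesh_corr_um: float = 0.15  # correlation length of the meshwork texture
    mesh_line_frac: float = 0.45  # shell fraction covered by bright lines
    mesh_floor: float = 0.5  # lamin level between mesh lines
    gaps: tuple[GapSpec, ...] = ()
    channels: tuple[str, ...] = ("dna", "laminA", "h3k27ac")
    # PSF of a deconvolved STED stack: ~50 nm lateral FWHM, and an axial
    # extent below the 150 nm z-step
    psf_sigma_nm: tuple[float, float] = (25.0, 120.0)  # (lateral, axial)
    poisson_scale: float = 200.0  # photons per unit intensity; 0 disables
    gaussian_sigma: float = 0.01  # additive read noise, 0 disables
    spacing: VoxelSpacing = DEFAULT_SPACING
    rupture_state: str = "intact"  # intact | ruptured
    ruptured_h3k27ac_ratio: float = 0.39
    n_spots: int = 0
    n_centromeres: int = 1
    min_spot_separation_um: float = 0.4

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes_um
        if not (a >= b >= c > 0):
            raise ValueError("semi-axes must satisfy a >= b >= c > 0")
        if self.rupture_state not in ("intact", "ruptured"):
            raise ValueError(f"unknown rupture state {self.rupture_state!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    gap_areas_um2: list[float]
    gap_footprints: list[np.ndarray]  # 2D boolean, projected
    gap_hemispheres: list[str]
    volume_um3: float
    surface_um2: float
    footprint2d: np.ndarray
    equator_z: int
    spot_coords_um: np.ndarray
    centromere_coords_um: np.ndarray
    noiseless: dict[str, np.ndarray]
    rupture_state: str
    nucleus_h3k27ac_mean: float = 1.0
    extras: dict = field(default_factory=dict)


def _ellipsoid_surface(a: float, b: float, c: float) -> float:
    p = _THOMSEN_P
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def _grid(spec: SyntheticMNSpec):
    """Physical coordinate grids (um), MN centred at the grid centre."""
    a, b, c = spec.semi_axes_um
    dz, dy, dx = spec.spacing.zyx_um
    nz = 2 * int(np.ceil(c / dz)) + 5
    ny = 2 * int(np.ceil((b + 0.3) / dy)) + 1
    nx = 2 * int(np.ceil((a + 0.3) / dx)) + 1
    if 2 * c / dz < 4:  # fewer than 5 planes across the MN
        raise ValueError("z-spacing incompatible with semi-axes: "
                         "fewer than 5 z-planes across the MN")
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    return z[:, None, None], y[None, :, None], x[None, None, :], (nz, ny, nx)


def _mesh_field(shape, spec: SyntheticMNSpec, rng: np.random.Generator):
    """Smoothed unit-variance random field; its near-zero band forms the
    line network of the meshwork texture."""
    dz, dy, dx = spec.spacing.zyx_um
    sig = (spec.mesh_corr_um / dz, spec.mesh_corr_um / dy, spec.mesh_corr_um / dx)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sig, mode="wrap")
    f -= f.mean()
    f /= f.std()
    return f


def _disk_pixels(ny, nx, cy, cx, n_pixels, dy_um, dx_um):
    """Boolean 2D mask of exactly n_pixels closest to (cy, cx) in um."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = ((yy - cy) * dy_um) ** 2 + ((xx - cx) * dx_um) ** 2
    order = np.argsort(d2, axis=None)[:n_pixels]
    mask = np.zeros(ny * nx, dtype=bool)
    mask[order] = True
    return mask.reshape(ny, nx)


def _sample_separated_points(rng, n, sampler, min_sep, max_tries=20000):
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        p = sampler()
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    if len(pts) < n:
        raise RuntimeError("could not place foci at the requested separation")
    return np.asarray(pts)


def _render_foci(shape, coords_um, spacing, sigma_um, amplitude=2.0):
    """Render Gaussian foci of FWHM ~= 2.355 * sigma_um at coords (z,y,x) um
    relative to the stack centre."""
    dz, dy, dx = spacing.zyx_um
    img = np.zeros(shape)
    nz, ny, nx = shape
    centre = np.array([(nz - 1) / 2.0 * dz, (ny - 1) / 2.0 * dy,
                       (nx - 1) / 2.0 * dx])
    for p in coords_um:
        pz, py, px = p + centre
        iz, iy, ix = int(round(pz / dz)), int(round(py / dy)), int(round(px / dx))
        rz = max(1, int(np.ceil(3 * sigma_um / dz)))
        ry = max(1, int(np.ceil(3 * sigma_um / dy)))
        rx = max(1, int(np.ceil(3 * sigma_um / dx)))
        zs = slice(max(0, iz - rz), min(nz, iz + rz + 1))
        ys = slice(max(0, iy - ry), min(ny, iy + ry + 1))
        xs = slice(max(0, ix - rx), min(nx, ix + rx + 1))
        z = np.arange(zs.start, zs.stop)[:, None, None] * dz - pz
        y = np.arange(ys.start, ys.stop)[None, :, None] * dy - py
        x = np.arange(xs.start, xs.stop)[None, None, :] * dx - px
        img[zs, ys, xs] += amplitude * np.exp(
            -(z * z + y * y + x * x) / (2.0 * sigma_um ** 2))
    return img


def generate_mn_stack(spec: SyntheticMNSpec, seed: int):
    """Render one synthetic micronucleus stack with its ground truth.

    Deterministic given (spec, seed). Gap footprints are rasterised with
    an exact pixel count, so the realized projected area equals the
    requested area to within half a pixel.
    """
    a, b, c = spec.semi_axes_um
    if spec.gaps:
        total_gap = sum(g.area_um2 for g in spec.gaps)
        if total_gap >= _ellipsoid_surface(a, b, c):
            raise ValueError("gap areas jointly exceed the shell surface")
    rng = np.random.default_rng(seed)
    z, y, x, shape = _grid(spec)
    nz, ny, nx = shape
    dz, dy, dx = spec.spacing.zyx_um

    # implicit ellipsoid and approximate signed distance to its surface
    f = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    grad = np.sqrt((x / a ** 2) ** 2 + (y / b ** 2) ** 2 + (z / c ** 2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, (f - 1.0) * f / grad, -1.0)
    # soft shell: Gaussian profile across the surface, sigma = half the
    # nominal thickness, so the coarse z-grid never slips through the
    # membrane between two plane centres (a hard band would alias into
    # spurious concentric dark rings at ~20 nm xy / 150 nm z)
    sigma_prof = spec.shell_thickness_um / 2.0
    profile = np.exp(-0.5 * (dist / sigma_prof) ** 2)
    shell = profile > 0.05
    interior = dist < -spec.shell_thickness_um / 2.0

    # meshwork texture: filaments live on the zero level set of the random
    # field and carry a peaked (Gaussian) cross-section, as a thin
    # filament imaged through a finite PSF would — the intensity crest
    # then coincides with the filament midline
    field_ = _mesh_field(shape, spec, rng)
    tau = float(np.quantile(np.abs(field_[shell]), spec.mesh_line_frac)) \
        if shell.any() else 1.0
    lines = np.abs(field_) <= tau
    mesh = spec.mesh_floor + (1.0 - spec.mesh_floor) * \
        np.exp(-2.0 * (field_ / tau) ** 2)
    lamin = profile * mesh
    lamin[~shell] = 0.0

    # insert gaps: scale the shell down inside an exact-area projected disk
    gap_areas, gap_footprints, gap_hemis = [], [], []
    pixel_area = spec.spacing.pixel_area_um2
    zc = (nz - 1) / 2.0
    for g in spec.gaps:
        gz = c * np.cos(g.theta)
        gy = b * np.sin(g.theta) * np.sin(g.phi)
        gx = a * np.sin(g.theta) * np.cos(g.phi)
        cy = (ny - 1) / 2.0 + gy / dy
        cx = (nx - 1) / 2.0 + gx / dx
        n_px = max(1, int(round(g.area_um2 / pixel_area)))
        disk = _disk_pixels(ny, nx, cy, cx, n_px, dy, dx)
        hemi = "top" if gz >= 0 else "bottom"
        zmask = (z[:, 0, 0] >= 0) if hemi == "top" else (z[:, 0, 0] < 0)
        region = shell & disk[None, :, :] & zmask[:, None, None]
        lamin = np.where(region, lamin * g.residual_fraction, lamin)
        gap_areas.append(n_px * pixel_area)
        gap_footprints.append(disk)
        gap_hemis.append(hemi)

    h3_level = 1.0 if spec.rupture_state == "intact" else spec.ruptured_h3k27ac_ratio
    noiseless: dict[str, np.ndarray] = {}
    rendered: dict[str, np.ndarray] = {}

    # foci ground truth (coordinates relative to stack centre, um)
    spot_coords = np.empty((0, 3))
    if spec.n_spots > 0:
        def on_shell():
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            return np.array([c * u[0], b * u[1], a * u[2]])
        spot_coords = _sample_separated_points(
            rng, spec.n_spots, on_shell, spec.min_spot_separation_um)
    cen_coords = np.empty((0, 3))
    if spec.n_centromeres > 0:
        def inside():
            while True:
                p = rng.uniform(-1, 1, 3)
                if np.linalg.norm(p) < 0.6:
                    return np.array([c * p[0], b * p[1], a * p[2]])
        cen_coords = _sample_separated_points(
            rng, spec.n_centromeres, inside, 0.5)

    sigma_spot_um = 0.2 / 2.355  # FWHM 0.2 um
    for name in spec.channels:
        if name == "laminA":
            img = lamin
        elif name == "dna":
            img = np.where(interior, 1.0, 0.0)
        elif name == "h3k27ac":
            img = np.where(interior, h3_level, 0.0)
        elif name == "spots":
            img = _render_foci(shape, spot_coords, spec.spacing, sigma_spot_um)
        elif name == "centromere":
            img = _render_foci(shape, cen_coords, spec.spacing, sigma_spot_um)
        else:
            raise ValueError(f"unknown channel {name!r}")
        sig_lat = spec.psf_sigma_nm[0] / spec.spacing.dx_nm
        sig_ax = spec.psf_sigma_nm[1] / spec.spacing.dz_nm
        if sig_lat > 0 or sig_ax > 0:
            img = ndimage.gaussian_filter(img, (sig_ax, sig_lat, sig_lat))
        noiseless[name] = img
        noisy = img
        if spec.poisson_scale > 0:
            noisy = rng.poisson(noisy * spec.poisson_scale) / spec.poisson_scale
        if spec.gaussian_sigma > 0:
            noisy = noisy + rng.normal(0.0, spec.gaussian_sigma, shape)
        rendered[name] = np.clip(noisy, 0.0, None)

    footprint2d = (f.min(axis=0) <= 1.0) if nz else np.zeros((ny, nx), bool)
    truth = GroundTruth(
        gap_areas_um2=gap_areas,
        gap_footprints=gap_footprints,
        gap_hemispheres=gap_hemis,
        volume_um3=4.0 * np.pi / 3.0 * a * b * c,
        surface_um2=_ellipsoid_surface(a, b, c),
        footprint2d=footprint2d,
        equator_z=int(round(zc)),
        spot_coords_um=spot_coords,
        centromere_coords_um=cen_coords,
        noiseless=noiseless,
        rupture_state=spec.rupture_state,
        extras={"lines_shell": lines & shell,
                "mesh_centerline": (np.abs(field_) <= 0.15 * tau) & shell},
    )
    stack = ImageStack(voxels=rendered, spacing=spec.spacing,
                       metadata={"seed": seed})
    return stack, truth


def sample_gap_specs(n: int,
                     rng: np.random.Generator,
                     area_range_um2: tuple[float, float] = (0.15, 0.5),
                     residual_range: tuple[float, float] = (0.0, 0.2),
                     polar_range: tuple[float, float] = (0.15, 0.6),
                     semi_axes_um: tuple[float, float, float] = (1.5, 1.4, 1.0),
                     min_edge_sep_um: float = 0.15) -> tuple[GapSpec, ...]:
    """Draw ``n`` distinct lamina gaps on the polar caps of the shell.

    Hemisphere projection can only resolve gaps on the top/bottom caps:
    near the equator the membrane is seen edge-on and a gap's projected
    footprint collapses, so recovery experiments place gaps within the
    caps (polar angle within ``polar_range`` of either pole) and keep
    their projected footprints separated by ``min_edge_sep_um`` so the
    ground-truth count is unambiguous.
    """
    a, b, c = semi_axes_um
    specs: list[GapSpec] = []
    centres: list[tuple[float, float, float]] = []
    for _ in range(5000):
        if len(specs) == n:
            break
        theta = rng.uniform(*polar_range)
        if rng.random() < 0.5:
            theta = np.pi - theta
        phi = rng.uniform(0.0, 2.0 * np.pi)
        area = rng.uniform(*area_range_um2)
        gy = b * np.sin(theta) * np.sin(phi)
        gx = a * np.sin(theta) * np.cos(phi)
        hemi = np.sign(np.cos(theta))
        r = np.sqrt(area / np.pi)
        ok = True
        for (oy, ox, oh, orad) in centres:
            if oh == hemi and np.hypot(gy - oy, gx - ox) < r + orad + min_edge_sep_um:
                ok = False
                break
        if ok:
            centres.append((gy, gx, hemi, r))
            specs.append(GapSpec(theta, phi, area,
                                 rng.uniform(*residual_range)))
    if len(specs) < n:
        raise RuntimeError("could not place the requested number of gaps")
    return tuple(specs)


def generate_population(n_per_class: dict[str, int],
                        intact_probability: dict[str, float],
                        spec_template: SyntheticMNSpec | None = None,
                        seed: int = 0,
                        render: bool = False):
    """Sample a population of micronuclei across chromosome classes.

    Per class, the number of intact MN is a Binomial(n, p) draw; each MN
    row records its class, index, rupture state and per-MN seed. With
    ``render=True`` every MN stack is generated via :func:`generate_mn_stack`
    (slow for large n); otherwise only the truth table is returned.

    Returns ``(truth_table, stacks)`` where stacks is a dict keyed by
    (class, index) or None.
    """
    if spec_template is None:
        spec_template = SyntheticMNSpec()
    rng = np.random.default_rng(seed)
    rows = []
    stacks: dict | None = {} if render else None
    for cls, n in n_per_class.items():
        if n <= 0:
            raise ValueError(f"empty class {cls!r}")
        p = intact_probability[cls]
        if not 0.0 <= p <= 1.0:
            raise ValueError("intact probability must be in [0, 1]")
        intact = np.zeros(n, dtype=bool)
        n_intact = rng.binomial(n, p)
        intact[:n_intact] = True
        rng.shuffle(intact)
        for i in range(n):
            mn_seed = int(rng.integers(0, 2 ** 31 - 1))
            state = "intact" if intact[i] else "ruptured"
            rows.append({"class": cls, "index": i, "rupture_state": state,
                         "seed": mn_seed,
                         "nucleus_h3k27ac_mean": 1.0})
            if render:
                spec = replace(spec_template, rupture_state=state)
                stacks[(cls, i)] = generate_mn_stack(spec, mn_seed)
    return pd.DataFrame(rows), stacks


def generate_contingency(n1: int, p1: float, n2: int, p2: float,
                         seed: int = 0,
                         expected: bool = False) -> ContingencyTable2x2:
    """Sample a 2x2 table with fixed row totals and binomial successes.

    With ``expected=True`` no sampling occurs: successes are the
    nearest-integer expected values round(n*p), which reconstructs a
    printed table from group sizes and percentages.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("row totals must be positive")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if expected:
        s1, s2 = int(round(n1 * p1)), int(round(n2 * p2))
    else:
        rng = np.random.default_rng(seed)
        s1 = int(rng.binomial(n1, p1))
        s2 = int(rng.binomial(n2, p2))
    return ContingencyTable2x2(s1, n1 - s1, s2, n2 - s2)


def generate_bed_fixture(chrom_lengths: dict[str, int],
                         lad_fraction: float,
                         blacklist_fraction: float,
                         seed: int = 0):
    """Toy LAD + blacklist interval fixtures with controlled coverage.

    Each chromosome is divided into slots and one interval is placed per
    slot with a jittered start, so realized coverage is within 1% of the
    requested fraction on chromosomes >= 10 kb. Intervals within each set
    are non-overlapping. Returns ``(lads, blacklist)`` interval sets.
    """
    for frac in (lad_fraction, blacklist_fraction):
        if not 0.0 <= frac < 1.0:
            raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def place(frac: float) -> dict[str, np.ndarray]:
        out = {}
        for chrom, length in chrom_lengths.items():
            if frac == 0.0:
                out[chrom] = np.empty((0, 2), dtype=np.int64)
                continue
            n_slots = max(1, length // 5000)
            slot = length / n_slots
            ivl_len = int(round(frac * slot))
            ivls = []
            for k in range(n_slots):
                lo = int(k * slot)
                hi = int((k + 1) * slot)
                if ivl_len <= 0 or lo + ivl_len > hi:
                    continue
                start = int(rng.integers(lo, hi - ivl_len + 1))
                ivls.append((start, start + ivl_len))
            out[chrom] = np.asarray(ivls, dtype=np.int64).reshape(-1, 2)
        return out

    lads = GenomicIntervalSet(place(lad_fraction))
    blacklist = GenomicIntervalSet(place(blacklist_fraction))
    return lads, blacklist


def bed_text(intervals: GenomicIntervalSet) -> str:
    """Serialise an interval set as BED text."""
    lines = []
    for chrom in sorted(intervals.intervals):
        for start, end in intervals.intervals[chrom]:
            lines.append(f"{chrom}\t{start}\t{end}")
    return "\n".join(lines) + ("\n" if lines else "")
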