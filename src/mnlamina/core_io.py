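"""Data model, readers/writers, configuration and logging shared by all stages.

Conventions used throughout the package:

* array index order is ``(z, y, x)``, 0-based;
* physical quantities cross module boundaries in nanometres / micrometres,
  never in pixels;
* channels are addressed by name, never by index, in downstream APIs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("mnlamina")

#: Columns of the per-micronucleus measurement table, in output order.
MEASUREMENT_COLUMNS = [
    "label_id",
    "kind",
    "rupture_call",
    "n_centromere_foci",
    "area_um2",
    "volume_um3",
    "surface_um2",
    "laminB1_FN",
    "laminB1_norm",
    "spot_count",
    "spot_density",
    "gap_count",
    "gap_density",
    "has_gap",
]


def configure_logging(level: str = "INFO") -> None:
    """Send package logs to stderr with ISO timestamps."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size of an anisotropic stack.

    STED acquisitions in this workflow use ~20 nm lateral pixels and a
    0.15 um z-step, so the default anisotropy ratio is 7.5.
    """

    dx_nm: float
    dy_nm: float
    dz_nm: float

    def __post_init__(self) -> None:
        if not (self.dx_nm > 0 and self.dy_nm > 0 and self.dz_nm > 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def pixel_area_um2(self) -> float:
        return (self.dx_nm / 1000.0) * (self.dy_nm / 1000.0)

    @property
    def zyx_um(self) -> tuple[float, float, float]:
        return (self.dz_nm / 1000.0, self.dy_nm / 1000.0, self.dx_nm / 1000.0)


DEFAULT_SPACING = VoxelSpacing(20.0, 20.0, 150.0)


@dataclass
class ImageStack:
    """Multi-channel 3D voxel grid with physical spacing.

    ``voxels`` maps channel name -> array of shape (z, y, x); all channels
    share one shape and non-negative intensities.
    """

    voxels: dict[str, np.ndarray]
    spacing: VoxelSpacing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.voxels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        for name, v in self.voxels.items():
            if v.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3D")
            if np.any(v < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def channels(self) -> list[str]:
        return list(self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.voxels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.voxels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channels})") from None


@dataclass
class RegionMask:
    """Labelled nucleus or micronucleus mask aligned to an ImageStack."""

    label_id: int
    kind: str  # "nucleus" | "micronucleus"
    mask: np.ndarray  # boolean, 3D (z,y,x) or 2D projected (y,x)

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValueError("label_id must be positive")
        if self.kind not in ("nucleus", "micronucleus"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not np.any(self.mask):
            raise ValueError("empty region mask")


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline with their published defaults.

    The gap cut-offs (0.12 um^2 area, 0.5 intensity ratio), the rupture
    ratio (0.4, i.e. a >60% H3K27ac decrease), the 0.2 um spot diameter and
    alpha = 0.05 reproduce the printed analysis values.
    """

    # meshwork segmentation
    scale_nm: float = 60.0
    n_orientations: int = 16
    response_quantile: float | None = None  # None -> automatic bimodal cut
    # gap filters
    theta_area_um2: float = 0.12
    theta_ratio: float = 0.5
    # rupture scoring
    rupture_ratio: float = 0.4
    # spot detection
    spot_diameter_um: float = 0.2
    spot_threshold: float = 0.0
    # rim intensity
    background_mode: str = "scaled"  # printed | scaled | annulus
    rim_width_px: int = 4
    expand_factor: float = 2.0
    # statistics
    alpha: float = 0.05
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_area_um2 <= 0 or self.theta_ratio <= 0:
            raise ValueError("gap thresholds must be positive")
        if self.background_mode not in ("printed", "scaled", "annulus"):
            raise ValueError(f"unknown background mode {self.background_mode!r}")

    def hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _spacing_from_tiff(tif: tifffile.TiffFile) -> VoxelSpacing | None:
    """Extract voxel spacing from OME metadata, if present."""
    try:
        import xml.etree.ElementTree as ET

        if tif.ome_metadata is None:
            return None
        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None
        attrs = px.attrib
        dx = float(attrs["PhysicalSizeX"]) * 1000.0  # um -> nm
        dy = float(attrs["PhysicalSizeY"]) * 1000.0
        dz = float(attrs.get("PhysicalSizeZ", 0)) * 1000.0
        if dz == 0:
            dz = dx
        return VoxelSpacing(dx, dy, dz)
    except Exception:
        return None


def read_stack(path: str | Path,
               channel_map: Mapping[str, int],
               spacing_override: VoxelSpacing | None = None) -> ImageStack:
    """Read a TIFF / OME-TIFF into an ImageStack.

    ``channel_map`` names the channel axis indices to extract. Spacing
    comes from OME metadata unless ``spacing_override`` is given; with
    neither available the call fails.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        spacing = spacing_override or _spacing_from_tiff(tif)
    if spacing is None:
        raise ValueError(f"spacing unavailable for {path}: no OME metadata "
                         "and no spacing_override given")
    # normalise to (c, z, y, x)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        # ambiguous (z,y,x) vs (c,y,x): a single channel_map entry of index 0
        # means a plain z-stack; otherwise the leading axis is channels
        if len(channel_map) == 1 and next(iter(channel_map.values())) == 0:
            data = data[None]
        else:
            data = data[:, None] if data.shape[0] <= 8 else data[None]
    elif data.ndim == 4:
        # tifffile writes (z, c, y, x) for volumetric OME; move c first
        if data.shape[1] < data.shape[0]:
            data = np.moveaxis(data, 1, 0)
    else:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")

    voxels: dict[str, np.ndarray] = {}
    for name, idx in channel_map.items():
        if not 0 <= idx < data.shape[0]:
            raise IndexError(
                f"channel index {idx} out of range for {data.shape[0]} channels")
        voxels[name] = np.asarray(data[idx], dtype=np.float64)
    return ImageStack(voxels=voxels, spacing=spacing,
                      metadata={"path": str(path)})


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageStack as OME-TIFF with physical pixel sizes."""
    arr = np.stack([stack.voxels[c] for c in stack.channels], axis=1)
    arr = arr.astype(np.float32)  # (z, c, y, x)
    tifffile.imwrite(
        path, arr,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.spacing.dx_nm / 1000.0,
            "PhysicalSizeY": stack.spacing.dy_nm / 1000.0,
            "PhysicalSizeZ": stack.spacing.dz_nm / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": stack.channels},
        },
    )


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, mask.astype(np.uint16))


def write_measurements(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write per-MN measurement rows to CSV in the documented column order.

    Floats are serialised at 6 significant digits; a write-then-read
    round-trip reproduces the table.
    """
    df = pd.DataFrame(list(rows), columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML key-value file.

    Unspecified keys take the published defaults; unknown keys are an
    error (a silent typo would silently change thresholds). The effective
    configuration is echoed to the log.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a mapping")
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, val in raw.items():
            fld = AnalysisConfig.__dataclass_fields__[key]
            if fld.type in ("float", "int") and not isinstance(val, (int, float)):
                raise ValueError(f"config key {key!r} must be numeric, got {val!r}")
            values[key] = val
    cfg = AnalysisConfig(**values)
    log.info("effective config (hash %s): %s", cfg.hash(), dataclasses.asdict(cfg))
    return cfg
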