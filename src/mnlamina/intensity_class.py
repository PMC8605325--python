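"""Rim-intensity quantification and photometric classification rules.

Lamin B1 at the nuclear rim is quantified on a single equatorial z-slice:
the object outline is converted to a four-pixel inner border (the rim),
the selection is expanded by at least 2x, and a local-background-corrected
integrated intensity F_N is computed from the two (area, integrated
intensity) pairs. Micronucleus rupture is scored photometrically from the
H3K27ac mean ratio to the nucleus (< 0.4, i.e. a > 60% decrease, means
ruptured), FISH positivity requires a focus at >= 2x local background
co-localising with a centromere, and the chromosome number of an MN is
the number of centromere foci inside it.

Background-correction modes
---------------------------
Three algebraic forms of the correction are provided. Writing B for the
per-pixel background estimated from the expansion ring:

``annulus``
    exact ring estimate, ``F_N = F_I - A_I * (F_O - F_I) / (A_O - A_I)``;
``scaled``
    the ring estimate with the ratio approximated as ``A_I / A_O``
    (accurate when the expansion is much larger than the rim) —
    ``F_N = F_I - (F_O - F_I) * (A_I / A_O)``; this is the default;
``printed``
    the same expression with the ratio inverted,
    ``F_N = F_I - (F_O - F_I) * (A_O / A_I)``, kept for provenance: it
    yields negative values for typical inputs and is presumed a
    transcription error in the formula this workflow originated from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morphometry import SpotSet

__all__ = [
    "RimMeasurement",
    "RuptureCall",
    "rim_selection",
    "expand_selection",
    "measure_rim",
    "background_subtracted_intensity",
    "normalized_rim_intensity",
    "classify_rupture",
    "fish_positive",
    "chromosome_count",
    "apply_inclusion_rules",
]

RUPTURE_RATIO = 0.4  # ruptured iff MN/nucleus H3K27ac mean ratio < 0.4


@dataclass
class RimMeasurement:
    """Areas (px) and integrated intensities of rim and expanded selections."""

    f_i: float
    a_i: int
    f_o: float
    a_o: int
    mode: str = "scaled"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.a_o <= self.a_i:
            raise ValueError("expanded area must exceed rim area")

    @property
    def f_n(self) -> float:
        return background_subtracted_intensity(self)


@dataclass
class RuptureCall:
    mn_mean: float
    nuc_mean: float
    ratio: float
    call: str  # "intact" | "ruptured"


def rim_selection(mask: np.ndarray, width_px: int = 4):
    """Inner border band of the mask: mask minus its erosion by width_px.

    If the object is thinner than twice the width the erosion empties and
    the rim falls back to the whole mask, with a flag.
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    if width_px < 1:
        raise ValueError("rim width must be >= 1")
    eroded = ndimage.binary_erosion(mask, iterations=width_px,
                                    structure=np.ones((3, 3), bool),
                                    border_value=0)
    rim = mask & ~eroded
    flags = []
    if not eroded.any():
        flags.append("rim-is-whole-mask")
    return rim, flags


def expand_selection(rim: np.ndarray, factor: float = 2.0):
    """Dilate the rim until its area reaches ``factor`` times the original.

    Returns ``(expanded, flags)``; if the image boundary stops growth
    before the target area a flag is raised and the largest achievable
    selection is returned.
    """
    if factor < 2:
        raise ValueError("expansion factor must be >= 2")
    a_i = int(np.count_nonzero(rim))
    if a_i == 0:
        raise ValueError("empty rim")
    target = factor * a_i
    expanded = rim.copy()
    flags: list[str] = []
    struct = ndimage.generate_binary_structure(rim.ndim, 2)
    while np.count_nonzero(expanded) < target:
        grown = ndimage.binary_dilation(expanded, structure=struct)
        if np.count_nonzero(grown) == np.count_nonzero(expanded):
            flags.append("image-boundary-reached")
            break
        expanded = grown
    return expanded, flags


def measure_rim(image: np.ndarray, mask: np.ndarray,
                width_px: int = 4, factor: float = 2.0,
                mode: str = "scaled") -> RimMeasurement:
    """Full rim measurement of one object on a single z-slice."""
    rim, flags = rim_selection(mask, width_px)
    expanded, eflags = expand_selection(rim, factor)
    return RimMeasurement(
        f_i=float(image[rim].sum()),
        a_i=int(rim.sum()),
        f_o=float(image[expanded].sum()),
        a_o=int(expanded.sum()),
        mode=mode,
        flags=flags + eflags,
    )


def background_subtracted_intensity(m: RimMeasurement) -> float:
    """Background-corrected integrated rim intensity F_N (see module docs)."""
    if not m.a_o > m.a_i > 0:
        raise ValueError("need A_O > A_I > 0")
    excess = m.f_o - m.f_i
    if m.mode == "printed":
        return m.f_i - excess * (m.a_o / m.a_i)
    if m.mode == "scaled":
        return m.f_i - excess * (m.a_i / m.a_o)
    if m.mode == "annulus":
        return m.f_i - m.a_i * excess / (m.a_o - m.a_i)
    raise ValueError(f"unknown background mode {m.mode!r}")


def normalized_rim_intensity(mn: RimMeasurement,
                             nucleus: RimMeasurement) -> float:
    """MN F_N divided by nucleus F_N (both in the same mode).

    Returns NaN with a warning-style flag when the nucleus value is not
    positive (background-dominated measurement).
    """
    if mn.mode != nucleus.mode:
        raise ValueError("MN and nucleus measured in different modes")
    nuc_fn = nucleus.f_n
    if nuc_fn <= 0:
        return float("nan")
    return mn.f_n / nuc_fn


def classify_rupture(mn_mean: float, nuc_mean: float) -> RuptureCall:
    """Score MN integrity from the H3K27ac mean-intensity ratio.

    Ruptured iff the MN mean is decreased by more than 60% relative to
    the nucleus, i.e. ratio < 0.4 strictly; a ratio of exactly 0.40 is
    intact. Scale-invariant by construction.
    """
    if nuc_mean <= 0:
        raise ValueError("nucleus mean must be positive")
    ratio = mn_mean / nuc_mean
    return RuptureCall(mn_mean=mn_mean, nuc_mean=nuc_mean, ratio=ratio,
                       call="ruptured" if ratio < RUPTURE_RATIO else "intact")


def fish_positive(focus_peak: float, local_background: float,
                  overlaps_centromere: bool) -> bool:
    """FISH positivity: >= 2x local background AND centromere overlap."""
    if local_background <= 0:
        raise ValueError("local background must be positive")
    return bool(focus_peak >= 2.0 * local_background and overlaps_centromere)


def chromosome_count(centromere_spots: SpotSet, mn_mask: np.ndarray,
                     spacing) -> int:
    """Chromosome number of an MN = centromere foci inside its mask."""
    if centromere_spots.count == 0:
        return 0
    zyx_um = np.asarray(spacing.zyx_um)
    idx = np.rint(centromere_spots.coordinates / zyx_um).astype(int)
    inside = 0
    for z, y, x in idx:
        if (0 <= z < mn_mask.shape[0] and 0 <= y < mn_mask.shape[1]
                and 0 <= x < mn_mask.shape[2] and mn_mask[z, y, x]):
            inside += 1
    return inside


def apply_inclusion_rules(n_fish_foci: int):
    """Cell-level inclusion: > 3 FISH foci for one chromosome excludes.

    Cells with more than three foci are either tetraploid or too noisy to
    score. Zero foci are included but flagged (no evidence of the probed
    chromosome). Returns ``(include, reason)``.
    """
    if n_fish_foci > 3:
        return False, "FISH foci > 3"
    if n_fish_foci == 0:
        return True, "no FISH foci (flagged)"
    return True, ""
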