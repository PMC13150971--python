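"""Named constants of the training-free edge-prior heuristic.

Every coefficient used by the Stage-1 pipeline lives in one serializable
object so that parameter ablations are configuration, not code edits, and
so that a run manifest can capture the exact settings that produced a
channel bundle.

Structuring-element sizes are *adaptive*: most are computed at run time as
``round(min(M, N) * epsilon * c)`` where ``epsilon`` is the normalized
local-variance statistic of the image being processed (see
:func:`lungprior.imops.local_std_epsilon`) and ``c`` is one of the
coefficients below.  This makes the heuristic scale with image resolution
and contrast rather than relying on pixel-unit constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple


@dataclass
class ClaheParams:
    """Settings for one contrast-limited adaptive histogram equalization call."""

    tiles: Tuple[int, int] = (5, 5)
    clip: float = 0.01
    dist: str = "uniform"  # "uniform" | "rayleigh"
    bins: int = 256
    alpha: float | None = None


@dataclass
class HeuristicParams:
    """All tunable constants of the edge-prior extraction stage."""

    # -- geometry ----------------------------------------------------------
    input_width: int = 1024           # images are rescaled to this many columns

    # -- body-blob stage ---------------------------------------------------
    histogram_range8: Tuple[int, int] = (130, 170)  # valley search, 8-bit scale
    blob_close_c: float = 0.1         # closing disk = round(min(M,N) * c)
    blob_prune_iters: int = 3         # spur-removal passes on the raw blob

    # -- LoG stage ---------------------------------------------------------
    precondition_clahe: ClaheParams = field(
        default_factory=lambda: ClaheParams(clip=0.001, dist="uniform"))
    rayleigh_clahe: ClaheParams = field(
        default_factory=lambda: ClaheParams(clip=0.005, dist="rayleigh", alpha=0.7))
    stretch_mid: Tuple[float, float] = (0.05, 0.95)
    log_sigma_c: float = 0.6          # LoG variance = min(M,N) * eps * c
    log_zc_rms_factor: float = 2.0    # zero-crossing cut, in response-RMS units
    ribcage_close_c: float = 0.7      # closing disk for the ribcage mask
    ribcage_erode_c: float = 6.0      # adaptive erosion of the closed blob
    shoulder_dilate_c: float = 0.05   # dilation of the complemented upper half
    roi_dilate_close_c: float = 1.5   # S1/S2 dilate+close+open element
    roi_seed_erode_c: float = 3.0     # erosion of ribcage mask before seeding
    roi_hull_erode_c: float = 2.0     # erosion of the hull before final seeding

    # -- spine stage -------------------------------------------------------
    band_width_frac: float = 0.15     # half-width of spine band = frac * hull width
    bone_clahe: ClaheParams = field(
        default_factory=lambda: ClaheParams(clip=1.0, dist="rayleigh", alpha=0.2))
    bone_stretch: Tuple[float, float] = (0.4, 1.0)
    bone_canny_t1: float | None = None  # None -> use epsilon of the conditioned image
    bone_canny_t2: float = 2.0
    bone_canny_sigma_c: float = 0.67
    bone_close_c: float = 1.0
    spline_residual_px: float = 2.0   # target RMS residual of the spine spline
    spine_thicken_frac: float = 0.5   # dilation disk = frac * band width

    # -- Canny stage -------------------------------------------------------
    canny_stretch: Tuple[float, float] = (0.4, 0.73)
    canny1_t1_scale: float = 10.0     # T1 = max(floor, eps * scale - offset)
    canny1_t1_offset: float = 0.4
    canny1_t1_floor: float = 0.01
    canny_t2: float = 2.0
    canny1_sigma_c: float = 1.0
    canny2_sigma_c: float = 0.7
    saturation_clahe: ClaheParams = field(
        default_factory=lambda: ClaheParams(clip=1.0, dist="rayleigh", alpha=0.7))
    saturation_lo_cap: float = 0.89
    saturation_binarize: float = 0.5
    lung_dilate_c: float = 0.006      # of hull height; per-side enhancement
    lung_close_c: float = 0.005
    lung_final_dilate_c: float = 0.03

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_params() -> HeuristicParams:
    return HeuristicParams()
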