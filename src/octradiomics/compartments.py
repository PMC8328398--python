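"""Derivation of the four analysis subcompartments.

From the layer surfaces and fluid masks of one eye, four pairwise-disjoint
binary sub-volumes are derived within the central slice window:

* ``IRF``  -- intraretinal fluid, inside the ILM-EZ band,
* ``SRF``  -- subretinal fluid, inside the EZ-RPE band,
* ``RTC1`` -- ILM-EZ retinal tissue minus IRF,
* ``RTC2`` -- EZ-RPE retinal tissue minus SRF.

``RTC1 | IRF`` tiles the ILM-EZ band exactly, and ``RTC2 | SRF`` the
EZ-RPE band, restricted to the slice window.  Depth bands are half-open
([ILM, EZ), [EZ, RPE)) so every voxel belongs to exactly one band.

Slice windows are 1-based inclusive in user-facing form (the clinical
convention "slices 43-85 of 128"), scaled proportionally for volumes with
other slice counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import (
    COMPARTMENT_NAMES,
    FluidMasks,
    GeometryError,
    LayerSurfaces,
    NoFluidInWindowError,
    ValidationError,
)

logger = logging.getLogger(__name__)

# reference window: slices 43..85 (1-based inclusive) of a 128-slice cube
_REF_WINDOW = (43, 85)
_REF_SLICES = 128


@dataclass
class CompartmentSet:
    """Binary masks of the four subcompartments for one eye."""

    masks: dict[str, np.ndarray]
    slice_window: tuple[int, int]  # 1-based inclusive
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(COMPARTMENT_NAMES) - set(self.masks)
        if missing:
            raise ValidationError(f"missing compartment masks: {sorted(missing)}")

    def counts(self) -> dict[str, int]:
        return {name: int(self.masks[name].sum()) for name in COMPARTMENT_NAMES}


def scaled_window(n_slices: int) -> tuple[int, int]:
    """Scale the reference 43-85/128 window to ``n_slices`` (1-based inclusive).

    Both ends are scaled proportionally and rounded half away from zero,
    which reproduces 43..85 at 128 slices and 22..43 at 64 slices.
    """
    if n_slices <= 0:
        raise ValidationError("n_slices must be positive")
    lo = int(np.floor(_REF_WINDOW[0] * n_slices / _REF_SLICES + 0.5))
    hi = int(np.floor(_REF_WINDOW[1] * n_slices / _REF_SLICES + 0.5))
    lo = max(lo, 1)
    hi = min(max(hi, lo), n_slices)
    return lo, hi


def select_slices(
    n_slices: int,
    mode: str,
    fluid: FluidMasks | None = None,
    window: tuple[int, int] | None = None,
) -> list[int]:
    """Return the 1-based slice indices used for feature extraction.

    ``mode="tissue"`` returns the central window itself.  ``mode="fluid"``
    additionally drops slices whose fluid masks (IRF and SRF both) are
    empty; if nothing remains a :class:`NoFluidInWindowError` is raised
    rather than silently producing a zero-feature row.
    """
    if mode not in ("tissue", "fluid"):
        raise ValidationError(f"mode must be 'tissue' or 'fluid', got {mode!r}")
    lo, hi = window if window is not None else scaled_window(n_slices)
    slices = list(range(lo, hi + 1))
    if mode == "tissue":
        return slices
    if fluid is None:
        raise ValidationError("mode='fluid' requires fluid masks")
    kept = [
        s for s in slices
        if fluid.irf[s - 1].any() or fluid.srf[s - 1].any()
    ]
    if not kept:
        raise NoFluidInWindowError(
            f"no fluid voxels in slice window {lo}..{hi}"
        )
    return kept


def derive_compartments(
    surfaces: LayerSurfaces,
    fluid: FluidMasks,
    slice_window: tuple[int, int] | None = None,
    provenance: str = "",
) -> CompartmentSet:
    """Derive {IRF, SRF, RTC1, RTC2} masks restricted to the slice window.

    Raises :class:`GeometryError` citing (slice, ascan) if the surface
    ordering ILM < EZ <= RPE is violated, and a validation error if a fluid
    mask strays outside its band.
    """
    surfaces.validate_ordering()
    n_slices, depth, n_ascans = fluid.shape
    if surfaces.grid_shape != (n_slices, n_ascans):
        raise ValidationError(
            f"surfaces grid {surfaces.grid_shape} inconsistent with fluid shape {fluid.shape}"
        )
    if slice_window is None:
        slice_window = scaled_window(n_slices)
    lo, hi = slice_window
    if not (1 <= lo <= hi <= n_slices):
        raise ValidationError(f"slice_window {slice_window} out of range for {n_slices} slices")

    d = np.arange(depth)[None, :, None]
    inner = (d >= surfaces.ilm[:, None, :]) & (d < surfaces.ez[:, None, :])
    outer = (d >= surfaces.ez[:, None, :]) & (d < surfaces.rpe[:, None, :])

    in_window = np.zeros(n_slices, dtype=bool)
    in_window[lo - 1 : hi] = True
    win = in_window[:, None, None]

    irf = fluid.irf & win
    srf = fluid.srf & win
    if (fluid.irf & ~inner).any():
        raise ValidationError("IRF mask has voxels outside the ILM-EZ band")
    if (fluid.srf & ~outer).any():
        raise ValidationError("SRF mask has voxels outside the EZ-RPE band")

    masks = {
        "IRF": irf,
        "SRF": srf,
        "RTC1": (inner & win) & ~irf,
        "RTC2": (outer & win) & ~srf,
    }
    return CompartmentSet(masks=masks, slice_window=(lo, hi), provenance=provenance)
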