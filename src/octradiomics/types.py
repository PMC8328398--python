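"""Shared containers and error types for the OCT radiomics pipeline.

Axis convention used throughout the package: axis 0 indexes B-scan slices,
axis 1 indexes depth (increasing away from the vitreous), axis 2 indexes
A-scans within a slice.  Depth bands are half-open voxel intervals:
a voxel at depth ``d`` belongs to the inner band when ``ilm <= d < ez`` and
to the outer band when ``ez <= d < rpe``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Invalid user input (shapes, counts, config values)."""


class FormatError(ValueError):
    """Unreadable or structurally wrong file content."""


class GeometryError(ValueError):
    """Layer-surface ordering or containment violated."""


class NoFluidInWindowError(RuntimeError):
    """Raised when fluid-mode slice selection finds no fluid voxels."""


@dataclass
class OctVolume:
    """A 3D grayscale OCT cube with voxel spacing in micrometers per axis."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"OctVolume requires a 3D array, got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LayerSurfaces:
    """Per-A-scan depth of the ILM, EZ and RPE boundaries.

    Each field is a ``(n_slices, n_ascans)`` array of depth coordinates
    (voxel units along axis 1).  Validity requires ``ilm < ez <= rpe``
    at every A-scan.
    """

    ilm: np.ndarray
    ez: np.ndarray
    rpe: np.ndarray

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=float)
        self.ez = np.asarray(self.ez, dtype=float)
        self.rpe = np.asarray(self.rpe, dtype=float)
        if not (self.ilm.shape == self.ez.shape == self.rpe.shape):
            raise ValidationError("surface fields must share one (n_slices, n_ascans) shape")
        if self.ilm.ndim != 2:
            raise ValidationError("surfaces must be 2D (n_slices, n_ascans)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.ilm.shape  # type: ignore[return-value]

    def validate_ordering(self) -> None:
        """Raise :class:`GeometryError` citing the first offending A-scan."""
        bad = ~((self.ilm < self.ez) & (self.ez <= self.rpe))
        if bad.any():
            s, a = np.argwhere(bad)[0]
            raise GeometryError(
                f"surface ordering ILM < EZ <= RPE violated at slice={int(s)}, ascan={int(a)}"
            )


@dataclass
class FluidMasks:
    """Binary voxel masks of intraretinal (IRF) and subretinal (SRF) fluid."""

    irf: np.ndarray
    srf: np.ndarray

    def __post_init__(self) -> None:
        self.irf = np.asarray(self.irf).astype(bool)
        self.srf = np.asarray(self.srf).astype(bool)
        if self.irf.shape != self.srf.shape:
            raise ValidationError("IRF and SRF masks must share a shape")
        if self.irf.ndim != 3:
            raise ValidationError("fluid masks must be 3D volumes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.irf.shape  # type: ignore[return-value]


COMPARTMENT_NAMES = ("IRF", "SRF", "RTC1", "RTC2")

REBOUNDER = "rebounder"
NONREBOUNDER = "nonrebounder"
LABELS = (REBOUNDER, NONREBOUNDER)


def check_label(label: str) -> str:
    if label not in LABELS:
        raise ValidationError(f"label must be one of {LABELS}, got {label!r}")
    return label
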