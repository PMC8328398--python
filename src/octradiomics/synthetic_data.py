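"""Synthetic OCT cohort generator.

Produces labeled macular cubes that emulate the study setting of a
28-eye anti-VEGF durability cohort: three smooth retinal surfaces
(ILM, EZ, RPE) with a foveal depression, hyporeflective intraretinal
(IRF) and subretinal (SRF) fluid pockets, multiplicative gamma speckle
over band-dependent reflectivity, and a tunable class effect -- extra
spot-scale texture energy inside the IRF of rebounder eyes, which is the
signal the downstream Laws-energy descriptors are meant to recover.

All randomness flows from ``CohortSpec.seed`` through named
``numpy.random.SeedSequence`` substreams, so a cohort regenerates
bit-for-bit.  The class-effect noise is drawn from its own substream:
with ``effect_size = 0`` the rendered volume is byte-identical whichever
label the eye carries, making the two classes exchangeable by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import (
    FluidMasks,
    LayerSurfaces,
    NONREBOUNDER,
    OctVolume,
    REBOUNDER,
    ValidationError,
    check_label,
)

logger = logging.getLogger(__name__)



@dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the emulated trial: 11 rebounders vs 17 non-rebounders,
    desk-scale 64 x 96 x 64 cubes (slices x depth x A-scans) standing in for
    128-slice, 512-A-scan clinical cubes, 1-3 IRF pockets and 0-2 SRF
    pockets per eye (an empty SRF compartment is common, as in clinic), and
    a class effect of 2 planted in the IRF subcompartment.
    """

    n_rebounder: int = 11
    n_nonrebounder: int = 17
    volume_shape: tuple[int, int, int] = (64, 96, 64)
    voxel_spacing: tuple[float, float, float] = (94.0, 20.0, 94.0)
    n_irf_pockets: tuple[int, int] = (1, 3)
    n_srf_pockets: tuple[int, int] = (0, 2)
    effect_size: float = 2.0
    speckle_shape: float = 4.0
    seed: int = 0
    # rendering conventions (8-bit range; see docs/methods.md)
    surface_amplitude: float | None = None
    fovea_depth: float | None = None
    fluid_attenuation: float = 0.35
    effect_amplitude: float = 35.0

    def validate(self) -> None:
        if self.n_rebounder < 0:
            raise ValidationError("n_rebounder must be >= 0")
        if self.n_nonrebounder < 0:
            raise ValidationError("n_nonrebounder must be >= 0")
        if self.n_rebounder + self.n_nonrebounder < 2:
            raise ValidationError("n_rebounder + n_nonrebounder must be >= 2")
        if len(self.volume_shape) != 3 or any(s <= 0 for s in self.volume_shape):
            raise ValidationError(f"volume_shape must be 3 positive ints, got {self.volume_shape}")
        if self.volume_shape[1] < 16:
            raise ValidationError("volume_shape depth must be >= 16 so three layers fit")
        for name in ("n_irf_pockets", "n_srf_pockets"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValidationError(f"{name} must be a (lo, hi) range with 0 <= lo <= hi")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.speckle_shape <= 0:
            raise ValidationError("speckle_shape must be > 0")


@dataclass
class SyntheticEye:
    """One generated eye: volume, geometry, fluid, outcome label."""

    volume: OctVolume
    surfaces: LayerSurfaces
    fluid: FluidMasks
    label: str
    eye_id: str
    seed: int


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance low-frequency random surface over (n_slices, n_ascans)."""
    noise = rng.standard_normal(shape)
    sigma = (max(shape[0] / 8.0, 1.0), max(shape[1] / 8.0, 1.0))
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_surfaces(
    volume_shape: tuple[int, int, int],
    seed: int,
    *,
    amplitude: float | None = None,
    fovea_depth: float | None = None,
    base_fracs: tuple[float, float, float] = (0.25, 0.55, 0.78),
) -> LayerSurfaces:
    """Generate smooth ILM/EZ/RPE depth fields with a foveal depression.

    ``amplitude`` (voxels) scales low-frequency surface undulation and
    ``fovea_depth`` the central ILM depression; both default to fractions
    of the depth extent.  ``amplitude = 0`` together with
    ``fovea_depth = 0`` yields flat surfaces at the configured constant
    depths.  The ordering ILM < EZ <= RPE is enforced everywhere.
    """
    n_slices, depth, n_ascans = volume_shape
    if depth < 16:
        raise ValidationError("depth must be >= 16 so three layers fit")
    if amplitude is None:
        amplitude = 0.03 * depth
    if fovea_depth is None:
        fovea_depth = 0.08 * depth

    rng = np.random.default_rng(seed)
    grid = (n_slices, n_ascans)
    ilm = base_fracs[0] * depth + amplitude * _smooth_field(grid, rng)
    ez = base_fracs[1] * depth + amplitude * _smooth_field(grid, rng)
    rpe = base_fracs[2] * depth + 0.5 * amplitude * _smooth_field(grid, rng)

    if fovea_depth > 0:
        s = np.arange(n_slices)[:, None] - (n_slices - 1) / 2.0
        a = np.arange(n_ascans)[None, :] - (n_ascans - 1) / 2.0
        sig_s = max(n_slices / 6.0, 1.0)
        sig_a = max(n_ascans / 6.0, 1.0)
        bump = np.exp(-0.5 * ((s / sig_s) ** 2 + (a / sig_a) ** 2))
        ilm = ilm + fovea_depth * bump  # depression: ILM pushed deeper centrally

    min_inner = max(2.0, depth / 12.0)
    min_outer = max(2.0, depth / 16.0)
    ilm = np.clip(ilm, 1.0, depth - min_inner - min_outer - 2.0)
    ez = np.maximum(ez, ilm + min_inner)
    rpe = np.maximum(rpe, ez + min_outer)
    rpe = np.minimum(rpe, depth - 1.0)
    ez = np.minimum(ez, rpe - min_outer)
    ilm = np.minimum(ilm, ez - 1.0)

    surfaces = LayerSurfaces(ilm=ilm, ez=ez, rpe=rpe)
    surfaces.validate_ordering()
    return surfaces


def ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    """Discrete ellipsoid: voxels whose centers satisfy the ellipsoid inequality."""
    z, d, a = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((z - center[0]) / radii[0]) ** 2
        + ((d - center[1]) / radii[1]) ** 2
        + ((a - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _band_masks(surfaces: LayerSurfaces, depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [ILM, EZ) and [EZ, RPE) band membership volumes."""
    d = np.arange(depth)[None, :, None]
    ilm = surfaces.ilm[:, None, :]
    ez = surfaces.ez[:, None, :]
    rpe = surfaces.rpe[:, None, :]
    inner = (d >= ilm) & (d < ez)
    outer = (d >= ez) & (d < rpe)
    return inner, outer


def plant_fluid(surfaces: LayerSurfaces, spec: CohortSpec, seed: int) -> FluidMasks:
    """Plant hyporeflective pockets: IRF ellipsoids in the ILM-EZ band,
    SRF lens-shaped pockets in the EZ-RPE band.  Pockets are clipped to
    their band, so a radius exceeding the band thickness never escapes it.
    """
    surfaces.validate_ordering()
    n_slices, depth, n_ascans = spec.volume_shape
    if surfaces.grid_shape != (n_slices, n_ascans):
        raise ValidationError("surfaces grid does not match spec.volume_shape")
    rng = np.random.default_rng(seed)
    inner_band, outer_band = _band_masks(surfaces, depth)

    shape = (n_slices, depth, n_ascans)
    irf = np.zeros(shape, dtype=bool)
    srf = np.zeros(shape, dtype=bool)

    def central(n: int) -> float:
        # pocket centers stay in the central 60% of the lateral extent
        return float(rng.uniform(0.2 * n, 0.8 * n))

    n_irf = int(rng.integers(spec.n_irf_pockets[0], spec.n_irf_pockets[1] + 1))
    for _ in range(n_irf):
        cs, ca = central(n_slices), central(n_ascans)
        si, ai = int(np.clip(cs, 0, n_slices - 1)), int(np.clip(ca, 0, n_ascans - 1))
        lo, hi = surfaces.ilm[si, ai], surfaces.ez[si, ai]
        cd = float(rng.uniform(lo, hi))
        r_depth = float(rng.uniform(2.5, max(3.0, (hi - lo) / 2.0)))
        r_slice = float(rng.uniform(2.5, max(3.0, 0.15 * n_slices)))
        r_ascan = float(rng.uniform(3.0, max(4.0, 0.15 * n_ascans)))
        irf |= ellipsoid_mask(shape, (cs, cd, ca), (r_slice, r_depth, r_ascan))

    n_srf = int(rng.integers(spec.n_srf_pockets[0], spec.n_srf_pockets[1] + 1))
    for _ in range(n_srf):
        cs, ca = central(n_slices), central(n_ascans)
        si, ai = int(np.clip(cs, 0, n_slices - 1)), int(np.clip(ca, 0, n_ascans - 1))
        lo, hi = surfaces.ez[si, ai], surfaces.rpe[si, ai]
        # lens shape: wide laterally, thin axially, seated on the EZ line
        cd = float(rng.uniform(lo, max(lo + 1.0, hi - 1.0)))
        r_depth = float(rng.uniform(1.0, max(1.5, (hi - lo))))
        r_slice = float(rng.uniform(2.0, max(3.0, 0.12 * n_slices)))
        r_ascan = float(rng.uniform(3.0, max(4.0, 0.18 * n_ascans)))
        srf |= ellipsoid_mask(shape, (cs, cd, ca), (r_slice, r_depth, r_ascan))

    irf &= inner_band
    srf &= outer_band
    return FluidMasks(irf=irf, srf=srf)


def _spot_noise(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance high-frequency noise (spot scale and finer).

    White noise with its local (sigma = 1 voxel) Gaussian mean removed:
    flat at high spatial frequencies, suppressed at scales coarser than a
    few voxels, so every edge/spot/ripple-sensitive texture kernel sees it.
    """
    noise = rng.standard_normal(shape)
    noise = noise - ndimage.gaussian_filter(noise, sigma=1.0, mode="reflect")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


# band base reflectivities on the 8-bit convention (vitreous, ILM-EZ, EZ-RPE, sub-RPE)
_REFLECTIVITY = (30.0, 110.0, 170.0, 60.0)


def render_eye(
    surfaces: LayerSurfaces,
    fluid: FluidMasks,
    label: str,
    spec: CohortSpec,
    seed: int,
) -> OctVolume:
    """Render an intensity cube: band reflectivity x gamma speckle, fluid
    attenuated, and -- for rebounders -- spot-scale noise of amplitude
    ``effect_size * effect_amplitude`` added inside the IRF mask.
    """
    check_label(label)
    n_slices, depth, n_ascans = spec.volume_shape
    shape = (n_slices, depth, n_ascans)
    if fluid.shape != shape or surfaces.grid_shape != (n_slices, n_ascans):
        raise ValidationError("surfaces/fluid shapes inconsistent with spec.volume_shape")

    base_ss, effect_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(base_ss)

    inner_band, outer_band = _band_masks(surfaces, depth)
    d = np.arange(depth)[None, :, None]
    below = d >= surfaces.rpe[:, None, :]
    base = np.full(shape, _REFLECTIVITY[0])
    base[inner_band] = _REFLECTIVITY[1]
    base[outer_band] = _REFLECTIVITY[2]
    base[below] = _REFLECTIVITY[3]

    k = spec.speckle_shape
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=shape)
    img = base * speckle
    img[fluid.irf | fluid.srf] *= spec.fluid_attenuation

    amp = spec.effect_size * spec.effect_amplitude
    if label == REBOUNDER and amp > 0 and fluid.irf.any():
        noise = _spot_noise(shape, np.random.default_rng(effect_ss))
        img[fluid.irf] += amp * noise[fluid.irf]

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return OctVolume(data=img, spacing=spec.voxel_spacing)


def _eye_seeds(spec: CohortSpec, index: int) -> tuple[int, int, int, int]:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(index,))
    state = ss.generate_state(4)
    return tuple(int(s) % (2**31) for s in state)  # type: ignore[return-value]


def generate_cohort(spec: CohortSpec) -> list[SyntheticEye]:
    """Generate the full labeled cohort (rebounders first, then non-rebounders).

    Per-eye seeds derive deterministically from ``spec.seed``; calling twice
    with the same spec yields element-wise identical volumes and masks.
    """
    spec.validate()
    eyes: list[SyntheticEye] = []
    n_total = spec.n_rebounder + spec.n_nonrebounder
    for i in range(n_total):
        label = REBOUNDER if i < spec.n_rebounder else NONREBOUNDER
        eye_seed, surf_seed, fluid_seed, render_seed = _eye_seeds(spec, i)
        surfaces = make_surfaces(
            spec.volume_shape,
            surf_seed,
            amplitude=spec.surface_amplitude,
            fovea_depth=spec.fovea_depth,
        )
        fluid = plant_fluid(surfaces, spec, fluid_seed)
        volume = render_eye(surfaces, fluid, label, spec, render_seed)
        eyes.append(
            SyntheticEye(
                volume=volume,
                surfaces=surfaces,
                fluid=fluid,
                label=label,
                eye_id=f"eye_{i:03d}",
                seed=eye_seed,
            )
        )
    logger.info(
        "generated cohort: %d rebounders, %d non-rebounders, shape %s",
        spec.n_rebounder,
        spec.n_nonrebounder,
        spec.volume_shape,
    )
    return eyes


def write_cohort(
    eyes: list[SyntheticEye],
    spec: CohortSpec,
    out_dir: str | Path,
    fmt: str = "nifti",
) -> Path:
    """Write volumes, masks, surfaces, labels and a JSON manifest to disk.

    Returns the manifest path, which :func:`octradiomics.volume_io.read_cohort`
    accepts.
    """
    from . import volume_io  # deferred: keeps generation import-light

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = {"nifti": ".nii.gz", "tiff": ".tif"}[fmt]

    records = []
    surface_frames = []
    for eye in eyes:
        vol_path = out / f"{eye.eye_id}_volume{ext}"
        irf_path = out / f"{eye.eye_id}_irf{ext}"
        srf_path = out / f"{eye.eye_id}_srf{ext}"
        volume_io.write_volume(eye.volume, vol_path)
        volume_io.write_volume(
            OctVolume(eye.fluid.irf.astype(np.uint8), eye.volume.spacing), irf_path
        )
        volume_io.write_volume(
            OctVolume(eye.fluid.srf.astype(np.uint8), eye.volume.spacing), srf_path
        )
        surface_frames.append(volume_io.surfaces_to_frame(eye.eye_id, eye.surfaces))
        records.append(
            {
                "eye_id": eye.eye_id,
                "volume": vol_path.name,
                "irf_mask": irf_path.name,
                "srf_mask": srf_path.name,
                "label": eye.label,
                "seed": eye.seed,
            }
        )

    import pandas as pd

    surfaces_path = out / "surfaces.csv"
    pd.concat(surface_frames, ignore_index=True).to_csv(surfaces_path, index=False)
    labels_path = out / "labels.csv"
    pd.DataFrame(
        [{"eye_id": e.eye_id, "label": e.label} for e in eyes]
    ).to_csv(labels_path, index=False)

    spec_dict = asdict(spec)
    manifest = {
        "format": fmt,
        "spec": spec_dict,
        "surfaces": surfaces_path.name,
        "labels": labels_path.name,
        "eyes": records,
    }
    manifest_path = out / "cohort.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
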