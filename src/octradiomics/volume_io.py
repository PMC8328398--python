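"""Reading and writing the pipeline's on-disk formats.

Volumes and masks travel as NIfTI (via nibabel) or multi-page TIFF (via
tifffile); layer surfaces as long-format CSV (eye_id, slice, ascan,
ilm_depth, ez_depth, rpe_depth); labels as CSV; cohorts as a JSON manifest;
feature tables as CSV keyed by eye_id.  Integer volumes round-trip
losslessly; float tables round-trip within 1e-12 relative tolerance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .types import FluidMasks, FormatError, LayerSurfaces, OctVolume, ValidationError

logger = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def write_volume(volume: OctVolume, path: str | Path) -> None:
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag(list(volume.spacing) + [1.0])
        nib.save(nib.Nifti1Image(volume.data, affine), str(path))
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), volume.data)
    else:
        raise FormatError(f"unsupported volume format: {path}")


def read_volume(path: str | Path) -> OctVolume:
    """Load a NIfTI or multi-page TIFF cube, preserving integer dtypes.

    Spacing defaults to 1.0 per axis when the container carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) if z else 1.0 for z in zooms)
        if len(spacing) < 3:
            spacing = (1.0, 1.0, 1.0)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        data = tifffile.imread(str(path))
        spacing = (1.0, 1.0, 1.0)
    else:
        raise FormatError(f"unsupported volume format: {path}")
    if np.ndim(data) != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={np.ndim(data)}")
    return OctVolume(data=data, spacing=spacing)  # type: ignore[arg-type]


def surfaces_to_frame(eye_id: str, surfaces: LayerSurfaces) -> pd.DataFrame:
    n_slices, n_ascans = surfaces.grid_shape
    s, a = np.meshgrid(np.arange(n_slices), np.arange(n_ascans), indexing="ij")
    return pd.DataFrame(
        {
            "eye_id": eye_id,
            "slice": s.ravel(),
            "ascan": a.ravel(),
            "ilm_depth": surfaces.ilm.ravel(),
            "ez_depth": surfaces.ez.ravel(),
            "rpe_depth": surfaces.rpe.ravel(),
        }
    )


def frame_to_surfaces(frame: pd.DataFrame) -> LayerSurfaces:
    n_slices = int(frame["slice"].max()) + 1
    n_ascans = int(frame["ascan"].max()) + 1
    grids = {}
    for col in ("ilm_depth", "ez_depth", "rpe_depth"):
        g = np.full((n_slices, n_ascans), np.nan)
        g[frame["slice"].to_numpy(), frame["ascan"].to_numpy()] = frame[col].to_numpy()
        if np.isnan(g).any():
            raise FormatError("surface table does not cover the full (slice, ascan) grid")
        grids[col] = g
    return LayerSurfaces(ilm=grids["ilm_depth"], ez=grids["ez_depth"], rpe=grids["rpe_depth"])


@dataclass
class EyeRecord:
    """One cohort entry: paths plus (optionally) the outcome label."""

    eye_id: str
    volume_path: Path
    irf_path: Path
    srf_path: Path
    surfaces: LayerSurfaces
    label: str | None = None
    seed: int | None = None

    def load_volume(self) -> OctVolume:
        return read_volume(self.volume_path)

    def load_fluid(self) -> FluidMasks:
        irf = read_volume(self.irf_path).data.astype(bool)
        srf = read_volume(self.srf_path).data.astype(bool)
        return FluidMasks(irf=irf, srf=srf)


def read_cohort(manifest_path: str | Path) -> list[EyeRecord]:
    """Load a cohort manifest, validating shape consistency per eye.

    Missing labels are allowed (prediction-only mode); a mask whose shape
    differs from its volume raises a validation error naming the eye.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    surface_table = None
    if manifest.get("surfaces"):
        surface_table = pd.read_csv(root / manifest["surfaces"])

    records: list[EyeRecord] = []
    for entry in manifest.get("eyes", []):
        eye_id = entry["eye_id"]
        vol_path = root / entry["volume"]
        irf_path = root / entry["irf_mask"]
        srf_path = root / entry["srf_mask"]
        vol = read_volume(vol_path)
        for name, mpath in (("IRF", irf_path), ("SRF", srf_path)):
            mask = read_volume(mpath)
            if mask.data.shape != vol.data.shape:
                raise ValidationError(
                    f"eye {eye_id}: {name} mask shape {mask.data.shape} "
                    f"!= volume shape {vol.data.shape}"
                )
        if surface_table is None:
            raise FormatError(f"manifest {manifest_path} lists no surfaces table")
        sub = surface_table[surface_table["eye_id"] == eye_id]
        if sub.empty:
            raise ValidationError(f"eye {eye_id}: no rows in surfaces table")
        surfaces = frame_to_surfaces(sub)
        if surfaces.grid_shape != (vol.data.shape[0], vol.data.shape[2]):
            raise ValidationError(
                f"eye {eye_id}: surfaces grid {surfaces.grid_shape} inconsistent "
                f"with volume shape {vol.data.shape}"
            )
        records.append(
            EyeRecord(
                eye_id=eye_id,
                volume_path=vol_path,
                irf_path=irf_path,
                srf_path=srf_path,
                surfaces=surfaces,
                label=entry.get("label"),
                seed=entry.get("seed"),
            )
        )
    return records


def read_labels(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path)
    return frame.set_index("eye_id")["label"]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an eyes x features table as CSV with an eye_id key column."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate feature names: {dupes}")
    if table.isna().any().any():
        n = int(table.isna().sum().sum())
        logger.warning("feature table contains %d NaN entries (undefined statistics)", n)
    out = table.copy()
    out.index.name = "eye_id"
    out.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="eye_id")
    if table.columns.duplicated().any():
        raise ValidationError("duplicate feature names in table on disk")
    return table
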