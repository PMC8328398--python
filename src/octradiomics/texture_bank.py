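"""The 962-descriptor 3D texture feature bank.

Per-voxel texture maps from four families are aggregated over each
compartment mask with four first-order statistics (median, variance,
skewness, kurtosis) folded into the feature name, e.g.
``Median-Laws_E3S3S3``.  The published family totals (52 Haralick,
501 Laws, 383 Gabor, 26 CoLlAGe; 962 in all) do not factor cleanly into
(maps x statistics) grids, so a versioned :class:`FeatureBankManifest`
enumerates an explicit descriptor list per family, truncated to the
published counts, and is the single source of truth for what the
extractor emits.

Family construction:

* Haralick -- 13 classical gray-level co-occurrence statistics computed
  per voxel from a sliding 5^3 window (32 gray levels, min-max quantized
  within the mask, symmetric GLCM pooled over the 13 unique 3D direction
  classes); 13 maps x 4 aggregations = 52.
* Laws -- separable energy maps over all ordered triplets of the 1D
  kernels {L3,E3,S3} (27) and {L5,E5,S5,R5,W5} (125); triplet order maps
  to (depth, A-scan, slice); 152 maps x 4 aggregations truncated to 501.
* Gabor -- magnitude responses of DC-corrected 2D Gabor filters applied
  within each B-scan plane over an 8-orientation x 6-wavelength x
  2-bandwidth grid; 96 maps x 4 aggregations truncated to 383.
* CoLlAGe -- dominant local gradient orientations (structure-tensor
  eigenvector, two angle channels: in-plane and through-plane) quantized
  to 16 bins, with the 13 co-occurrence statistics computed per voxel on
  the angle volume; 26 maps x median = 26.

Boundary policy: convolutions use reflect padding; co-occurrence windows
are clipped to the mask, so no out-of-retina intensity is fabricated.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage, signal

from .types import COMPARTMENT_NAMES, OctVolume, ValidationError

logger = logging.getLogger(__name__)

MANIFEST_VERSION = "1.0"

AGG_STATS = ("Median", "Variance", "Skewness", "Kurtosis")

FAMILY_TARGETS = {"Haralick": 52, "Laws": 501, "Gabor": 383, "CoLlAGe": 26}

HARALICK_STATS = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

LAWS_KERNELS = {
    "L3": np.array([1.0, 2.0, 1.0]),
    "E3": np.array([-1.0, 0.0, 1.0]),
    "S3": np.array([-1.0, 2.0, -1.0]),
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}

# the 13 unique 3D direction classes (offsets up to sign)
OFFSETS_3D = np.array(
    [
        (0, 0, 1), (0, 1, 0), (1, 0, 0),
        (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)

COLLAGE_CHANNELS = ("inplane", "throughplane")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _laws_params() -> list[str]:
    three = ["".join(t) for t in itertools.product(("L3", "E3", "S3"), repeat=3)]
    five = ["".join(t) for t in itertools.product(("L5", "E5", "S5", "R5", "W5"), repeat=3)]
    return three + five


def _gabor_params(
    n_orientations: int = 8,
    wavelengths: tuple[float, ...] = (3.0, 4.0, 6.0, 8.0, 10.0, 12.0),
    bandwidths: tuple[float, ...] = (1.0, 1.5),
) -> list[str]:
    out = []
    for i in range(n_orientations):
        for wl in wavelengths:
            for bw in bandwidths:
                out.append(f"t{i}_wl{wl:g}_bw{bw:g}")
    return out


@dataclass
class FeatureBankManifest:
    """Versioned enumeration of the 962 named descriptors.

    ``pairs[family]`` is the ordered list of ``(agg_stat, map_param)``
    pairs whose full names are ``f"{stat}-{family}_{param}"``.
    """

    version: str = MANIFEST_VERSION
    haralick_window: int = 5
    gray_levels: int = 32
    laws_energy_window: int = 5
    collage_window: int = 5
    collage_bins: int = 16
    gabor_orientations: int = 8
    gabor_wavelengths: tuple[float, ...] = (3.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    gabor_bandwidths: tuple[float, ...] = (1.0, 1.5)
    pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pairs:
            self.pairs = self._enumerate()
        self.validate()

    def _enumerate(self) -> dict[str, list[tuple[str, str]]]:
        grids = {
            "Haralick": (list(HARALICK_STATS), AGG_STATS),
            "Laws": (_laws_params(), AGG_STATS),
            "Gabor": (
                _gabor_params(
                    self.gabor_orientations, self.gabor_wavelengths, self.gabor_bandwidths
                ),
                AGG_STATS,
            ),
            "CoLlAGe": (
                [f"{ch}_{stat}" for ch in COLLAGE_CHANNELS for stat in HARALICK_STATS],
                ("Median",),
            ),
        }
        pairs: dict[str, list[tuple[str, str]]] = {}
        for family, (params, stats) in grids.items():
            flat = [(stat, param) for param in params for stat in stats]
            target = FAMILY_TARGETS[family]
            if len(flat) < target:
                raise ValidationError(
                    f"{family} grid enumerates only {len(flat)} descriptors < {target}"
                )
            pairs[family] = flat[:target]
        return pairs

    def validate(self) -> None:
        for family, target in FAMILY_TARGETS.items():
            got = len(self.pairs.get(family, []))
            if got != target:
                raise ValidationError(f"{family}: manifest lists {got} descriptors, need {target}")
        names = self.descriptor_names()
        if len(set(names)) != len(names):
            raise ValidationError("descriptor names are not unique")

    def family_counts(self) -> dict[str, int]:
        return {family: len(p) for family, p in self.pairs.items()}

    @property
    def total(self) -> int:
        return sum(self.family_counts().values())

    def descriptor_names(self, family: str | None = None) -> list[str]:
        families = [family] if family else list(FAMILY_TARGETS)
        return [
            f"{stat}-{fam}_{param}"
            for fam in families
            for stat, param in self.pairs[fam]
        ]

    def map_params(self, family: str) -> list[str]:
        """Map parameters actually referenced by the (truncated) descriptor list."""
        seen: dict[str, None] = {}
        for _stat, param in self.pairs[family]:
            seen.setdefault(param)
        return list(seen)

    def stats_for(self, family: str, param: str) -> list[str]:
        return [stat for stat, p in self.pairs[family] if p == param]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": self.version,
            "haralick_window": self.haralick_window,
            "gray_levels": self.gray_levels,
            "laws_energy_window": self.laws_energy_window,
            "collage_window": self.collage_window,
            "collage_bins": self.collage_bins,
            "gabor_orientations": self.gabor_orientations,
            "gabor_wavelengths": list(self.gabor_wavelengths),
            "gabor_bandwidths": list(self.gabor_bandwidths),
            "pairs": {fam: [list(p) for p in pl] for fam, pl in self.pairs.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureBankManifest":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["gabor_wavelengths"] = tuple(payload["gabor_wavelengths"])
        payload["gabor_bandwidths"] = tuple(payload["gabor_bandwidths"])
        payload["pairs"] = {
            fam: [tuple(p) for p in pl] for fam, pl in payload["pairs"].items()
        }
        return cls(**payload)


def default_manifest() -> FeatureBankManifest:
    return FeatureBankManifest()


@dataclass
class VoxelFeatureMap:
    """A per-voxel texture response volume for one named map."""

    values: np.ndarray
    descriptor: str
    mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Laws energy maps
# ---------------------------------------------------------------------------

def laws_response(volume: np.ndarray, triplet: str) -> np.ndarray:
    """Raw separable response; triplet order maps to (depth, A-scan, slice)."""
    tokens = [triplet[i : i + 2] for i in range(0, len(triplet), 2)]
    if len(tokens) != 3 or any(t not in LAWS_KERNELS for t in tokens):
        raise ValidationError(f"unknown Laws triplet {triplet!r}")
    support = max(len(LAWS_KERNELS[t]) for t in tokens)
    if min(volume.shape) < support:
        raise ValidationError(
            f"volume shape {volume.shape} smaller than kernel support {support}"
        )
    out = np.asarray(volume, dtype=float)
    for token, axis in zip(tokens, (1, 2, 0)):
        out = ndimage.correlate1d(out, LAWS_KERNELS[token], axis=axis, mode="reflect")
    return out


def laws_energy_map(volume: np.ndarray, triplet: str, energy_window: int) -> np.ndarray:
    """Local energy: windowed mean absolute separable response."""
    resp = laws_response(volume, triplet)
    return ndimage.uniform_filter(np.abs(resp), size=energy_window, mode="reflect")


def laws_maps(
    volume: OctVolume | np.ndarray, manifest: FeatureBankManifest
) -> list[VoxelFeatureMap]:
    data = volume.data if isinstance(volume, OctVolume) else np.asarray(volume)
    return [
        VoxelFeatureMap(
            values=laws_energy_map(data.astype(float), param, manifest.laws_energy_window),
            descriptor=f"Laws_{param}",
        )
        for param in manifest.map_params("Laws")
    ]


# ---------------------------------------------------------------------------
# Gabor maps (2D within the B-scan plane, applied slice-wise)
# ---------------------------------------------------------------------------

def _gabor_kernel(theta: float, wavelength: float, bandwidth: float) -> np.ndarray:
    from skimage.filters import gabor_kernel

    if wavelength < 2.0:
        raise ValidationError(f"wavelength {wavelength} < 2 voxels is sub-Nyquist")
    k = gabor_kernel(frequency=1.0 / wavelength, theta=theta, bandwidth=bandwidth)
    return np.asarray(k) - np.asarray(k).mean()  # DC-free: constant input -> 0


def _parse_gabor_param(param: str, n_orientations: int) -> tuple[float, float, float]:
    t, wl, bw = param.split("_")
    theta = int(t[1:]) * np.pi / n_orientations
    return theta, float(wl[2:]), float(bw[2:])


def gabor_maps(
    volume: OctVolume | np.ndarray, manifest: FeatureBankManifest
) -> list[VoxelFeatureMap]:
    data = volume.data if isinstance(volume, OctVolume) else np.asarray(volume)
    data = data.astype(float)
    maps = []
    for param in manifest.map_params("Gabor"):
        theta, wl, bw = _parse_gabor_param(param, manifest.gabor_orientations)
        kernel = _gabor_kernel(theta, wl, bw)
        ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
        resp = np.empty(data.shape, dtype=float)
        for s in range(data.shape[0]):
            # reflect-pad so the DC-free kernel annihilates constants at borders
            padded = np.pad(data[s], ((ph, ph), (pw, pw)), mode="symmetric")
            conv = signal.fftconvolve(padded, kernel, mode="same")
            resp[s] = np.abs(conv[ph : ph + data.shape[1], pw : pw + data.shape[2]])
        maps.append(VoxelFeatureMap(values=resp, descriptor=f"Gabor_{param}"))
    return maps


# ---------------------------------------------------------------------------
# per-voxel co-occurrence statistics (shared by Haralick and CoLlAGe)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _glcm_stat_maps_kernel(codes, valid, half, offsets, n_levels, out):  # pragma: no cover
    Z, Y, X = codes.shape
    L = n_levels
    n_off = offsets.shape[0]
    P = np.zeros((L, L), dtype=np.float64)
    px = np.zeros(L, dtype=np.float64)
    p_sum = np.zeros(2 * L - 1, dtype=np.float64)
    p_diff = np.zeros(L, dtype=np.float64)
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not valid[z, y, x]:
                    continue
                for i in range(L):
                    for j in range(L):
                        P[i, j] = 0.0
                total = 0.0
                for dz in range(-half, half + 1):
                    uz = z + dz
                    if uz < 0 or uz >= Z:
                        continue
                    for dy in range(-half, half + 1):
                        uy = y + dy
                        if uy < 0 or uy >= Y:
                            continue
                        for dx in range(-half, half + 1):
                            ux = x + dx
                            if ux < 0 or ux >= X:
                                continue
                            if not valid[uz, uy, ux]:
                                continue
                            ci = codes[uz, uy, ux]
                            for o in range(n_off):
                                vz = uz + offsets[o, 0]
                                vy = uy + offsets[o, 1]
                                vx = ux + offsets[o, 2]
                                # partner must stay inside the same window
                                if vz < z - half or vz > z + half or vz < 0 or vz >= Z:
                                    continue
                                if vy < y - half or vy > y + half or vy < 0 or vy >= Y:
                                    continue
                                if vx < x - half or vx > x + half or vx < 0 or vx >= X:
                                    continue
                                if not valid[vz, vy, vx]:
                                    continue
                                cj = codes[vz, vy, vx]
                                P[ci, cj] += 1.0
                                P[cj, ci] += 1.0
                                total += 2.0
                if total == 0.0:
                    for k in range(13):
                        out[k, z, y, x] = np.nan
                    continue
                for i in range(L):
                    px[i] = 0.0
                for k in range(2 * L - 1):
                    p_sum[k] = 0.0
                for k in range(L):
                    p_diff[k] = 0.0
                asm = 0.0
                contrast = 0.0
                idm = 0.0
                entropy = 0.0
                cross = 0.0
                for i in range(L):
                    for j in range(L):
                        p = P[i, j] / total
                        P[i, j] = p
                        if p > 0.0:
                            px[i] += p
                            p_sum[i + j] += p
                            d = i - j if i >= j else j - i
                            p_diff[d] += p
                            asm += p * p
                            contrast += (i - j) * (i - j) * p
                            idm += p / (1.0 + (i - j) * (i - j))
                            entropy -= p * np.log(p)
                            cross += i * j * p
                mu = 0.0
                for i in range(L):
                    mu += i * px[i]
                var = 0.0
                hx = 0.0
                for i in range(L):
                    var += (i - mu) * (i - mu) * px[i]
                    if px[i] > 0.0:
                        hx -= px[i] * np.log(px[i])
                if var > 0.0:
                    correlation = (cross - mu * mu) / var
                else:
                    correlation = 0.0
                sum_avg = 0.0
                for k in range(2 * L - 1):
                    sum_avg += k * p_sum[k]
                sum_var = 0.0
                sum_ent = 0.0
                for k in range(2 * L - 1):
                    sum_var += (k - sum_avg) * (k - sum_avg) * p_sum[k]
                    if p_sum[k] > 0.0:
                        sum_ent -= p_sum[k] * np.log(p_sum[k])
                diff_avg = 0.0
                for k in range(L):
                    diff_avg += k * p_diff[k]
                diff_var = 0.0
                diff_ent = 0.0
                for k in range(L):
                    diff_var += (k - diff_avg) * (k - diff_avg) * p_diff[k]
                    if p_diff[k] > 0.0:
                        diff_ent -= p_diff[k] * np.log(p_diff[k])
                # information measures of correlation (symmetric GLCM: py = px)
                hxy1 = 0.0
                hxy2 = 0.0
                for i in range(L):
                    for j in range(L):
                        q = px[i] * px[j]
                        if q > 0.0:
                            hxy2 -= q * np.log(q)
                            if P[i, j] > 0.0:
                                hxy1 -= P[i, j] * np.log(q)
                if hx > 0.0:
                    imc1 = (entropy - hxy1) / hx
                else:
                    imc1 = 0.0
                arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
                imc2 = np.sqrt(arg) if arg > 0.0 else 0.0
                out[0, z, y, x] = asm
                out[1, z, y, x] = contrast
                out[2, z, y, x] = correlation
                out[3, z, y, x] = var
                out[4, z, y, x] = idm
                out[5, z, y, x] = sum_avg
                out[6, z, y, x] = sum_var
                out[7, z, y, x] = sum_ent
                out[8, z, y, x] = entropy
                out[9, z, y, x] = diff_var
                out[10, z, y, x] = diff_ent
                out[11, z, y, x] = imc1
                out[12, z, y, x] = imc2


def glcm_stat_maps(
    codes: np.ndarray,
    valid: np.ndarray,
    window: int,
    n_levels: int,
    offsets: np.ndarray = OFFSETS_3D,
) -> np.ndarray:
    """13 per-voxel co-occurrence statistic maps (NaN outside ``valid``).

    The local GLCM at a voxel pools pairs (u, u+offset) with both ends
    inside the voxel's window and inside the mask, symmetrized and
    normalized; statistics follow the classical 13-feature set in
    :data:`HARALICK_STATS` order.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be odd and >= 3")
    codes = np.ascontiguousarray(codes, dtype=np.int64)
    valid = np.ascontiguousarray(valid, dtype=np.bool_)
    out = np.full((13,) + codes.shape, np.nan, dtype=np.float64)
    _glcm_stat_maps_kernel(
        codes, valid, window // 2, np.ascontiguousarray(offsets), n_levels, out
    )
    return out


def quantize(volume: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization within the mask to ``levels`` gray codes."""
    codes = np.zeros(volume.shape, dtype=np.int64)
    vals = volume[mask]
    if vals.size == 0:
        return codes
    mn, mx = float(vals.min()), float(vals.max())
    if mx > mn:
        scaled = (volume.astype(float) - mn) / (mx - mn) * levels
        codes = np.clip(np.floor(scaled), 0, levels - 1).astype(np.int64)
    return codes


def haralick_maps(
    volume: OctVolume | np.ndarray,
    mask: np.ndarray,
    manifest: FeatureBankManifest,
) -> list[VoxelFeatureMap]:
    """Per-voxel Haralick statistic maps over the sliding window, on the mask."""
    data = volume.data if isinstance(volume, OctVolume) else np.asarray(volume)
    if not mask.any():
        logger.warning("haralick_maps: empty mask, returning empty maps")
        return [
            VoxelFeatureMap(np.full(data.shape, np.nan), f"Haralick_{s}", mask)
            for s in HARALICK_STATS
        ]
    codes = quantize(data, mask, manifest.gray_levels)
    stats = glcm_stat_maps(codes, mask, manifest.haralick_window, manifest.gray_levels)
    return [
        VoxelFeatureMap(values=stats[i], descriptor=f"Haralick_{name}", mask=mask)
        for i, name in enumerate(HARALICK_STATS)
    ]


# ---------------------------------------------------------------------------
# CoLlAGe maps
# ---------------------------------------------------------------------------

def dominant_orientation_angles(
    volume: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-voxel dominant gradient orientation via the windowed structure tensor.

    Returns (in-plane angle in [0, pi), through-plane angle in [0, pi/2],
    count of degenerate zero-gradient voxels assigned angle 0).
    """
    g = np.gradient(np.asarray(volume, dtype=float))
    # windowed second-moment (structure tensor) components, reflect boundary
    comps = {}
    for a in range(3):
        for b in range(a, 3):
            comps[(a, b)] = ndimage.uniform_filter(g[a] * g[b], size=window, mode="reflect")
    T = np.empty(volume.shape + (3, 3))
    for a in range(3):
        for b in range(3):
            T[..., a, b] = comps[(min(a, b), max(a, b))]
    evals, evecs = np.linalg.eigh(T.reshape(-1, 3, 3))
    v = evecs[:, :, 2]  # eigenvector of the largest eigenvalue
    lead = evals[:, 2]
    degenerate = lead < 1e-12
    v_slice, v_depth, v_ascan = v[:, 0], v[:, 1], v[:, 2]
    inplane = np.mod(np.arctan2(v_ascan, v_depth), np.pi)
    through = np.arctan2(np.abs(v_slice), np.hypot(v_depth, v_ascan))
    inplane[degenerate] = 0.0
    through[degenerate] = 0.0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info("collage: %d zero-gradient voxels assigned orientation bin 0", n_degenerate)
    return (
        inplane.reshape(volume.shape),
        through.reshape(volume.shape),
        n_degenerate,
    )


def collage_maps(
    volume: OctVolume | np.ndarray,
    mask: np.ndarray,
    manifest: FeatureBankManifest,
    angle_codes: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[VoxelFeatureMap]:
    """Co-occurrence statistics of binned dominant-orientation angles.

    ``angle_codes`` may be precomputed (orientation is mask-independent)
    to share work across compartments of the same eye.
    """
    data = volume.data if isinstance(volume, OctVolume) else np.asarray(volume)
    if angle_codes is None:
        angle_codes = collage_angle_codes(data, manifest)
    maps: list[VoxelFeatureMap] = []
    for channel, codes in zip(COLLAGE_CHANNELS, angle_codes):
        if mask.any():
            stats = glcm_stat_maps(codes, mask, manifest.collage_window, manifest.collage_bins)
        else:
            stats = np.full((13,) + data.shape, np.nan)
        for i, name in enumerate(HARALICK_STATS):
            maps.append(
                VoxelFeatureMap(
                    values=stats[i], descriptor=f"CoLlAGe_{channel}_{name}", mask=mask
                )
            )
    return maps


def collage_angle_codes(
    volume: np.ndarray, manifest: FeatureBankManifest
) -> tuple[np.ndarray, np.ndarray]:
    inplane, through, _ = dominant_orientation_angles(volume, manifest.collage_window)
    bins = manifest.collage_bins
    in_codes = np.clip(np.floor(inplane / np.pi * bins), 0, bins - 1).astype(np.int64)
    th_codes = np.clip(np.floor(through / (np.pi / 2) * bins), 0, bins - 1).astype(np.int64)
    return in_codes, th_codes


# ---------------------------------------------------------------------------
# aggregation over compartments
# ---------------------------------------------------------------------------

def aggregate(feature_map: VoxelFeatureMap | np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Median / variance / skewness / kurtosis over masked voxels.

    Variance uses denominator n; skewness and kurtosis are standardized
    3rd/4th central moments (kurtosis non-excess: 3 for a Gaussian).
    Degenerate cases: n < 2 leaves variance/skewness/kurtosis missing;
    a constant sample gets skewness = kurtosis = 0 by convention.
    """
    values = feature_map.values if isinstance(feature_map, VoxelFeatureMap) else feature_map
    if not mask.any():
        raise ValidationError("aggregate requires a non-empty mask")
    vals = values[mask]
    vals = vals[np.isfinite(vals)]
    n = vals.size
    out = {"Median": np.nan, "Variance": np.nan, "Skewness": np.nan, "Kurtosis": np.nan}
    if n == 0:
        return out
    out["Median"] = float(np.median(vals))
    if n < 2:
        logger.debug("aggregate: n=%d < 2, higher moments undefined", n)
        return out
    mu = vals.mean()
    centered = vals - mu
    m2 = float(np.mean(centered**2))
    out["Variance"] = m2
    if m2 == 0.0:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    else:
        out["Skewness"] = float(np.mean(centered**3) / m2**1.5)
        out["Kurtosis"] = float(np.mean(centered**4) / m2**2)
    return out


def extract_features(
    volume: OctVolume | np.ndarray,
    compartments,
    manifest: FeatureBankManifest,
) -> dict[str, dict[str, float]]:
    """All 962 named descriptor values for each of the four compartments.

    Mask-independent maps (Laws, Gabor, orientation angles) are computed
    once per eye; mask-dependent co-occurrence maps per compartment.
    Empty compartments yield all-missing rows (NaN), logged, not dropped.
    """
    data = volume.data if isinstance(volume, OctVolume) else np.asarray(volume)
    data = data.astype(float)

    laws_cache = {
        f"Laws_{p}": laws_energy_map(data, p, manifest.laws_energy_window)
        for p in manifest.map_params("Laws")
    }
    gabor_cache = {m.descriptor: m.values for m in gabor_maps(data, manifest)}
    angle_codes = collage_angle_codes(data, manifest)

    names = manifest.descriptor_names()
    rows: dict[str, dict[str, float]] = {}
    for comp in COMPARTMENT_NAMES:
        mask = compartments.masks[comp]
        if not mask.any():
            logger.warning("compartment %s is empty: emitting %d missing values", comp, len(names))
            rows[comp] = {name: np.nan for name in names}
            continue
        map_cache: dict[str, np.ndarray] = {}
        map_cache.update(laws_cache)
        map_cache.update(gabor_cache)
        for m in haralick_maps(data, mask, manifest):
            map_cache[m.descriptor] = m.values
        for m in collage_maps(data, mask, manifest, angle_codes=angle_codes):
            map_cache[m.descriptor] = m.values

        row: dict[str, float] = {}
        for family in FAMILY_TARGETS:
            for param in manifest.map_params(family):
                stats_needed = manifest.stats_for(family, param)
                agg = aggregate(map_cache[f"{family}_{param}"], mask)
                for stat in stats_needed:
                    row[f"{stat}-{family}_{param}"] = agg[stat]
        rows[comp] = {name: row[name] for name in names}
    return rows


def extract_cohort(
    eyes,
    manifest: FeatureBankManifest,
    slice_window: tuple[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-compartment feature tables (eyes x 962) for a synthetic cohort
    or a list of objects exposing volume/surfaces/fluid/eye_id."""
    from .compartments import derive_compartments

    per_comp: dict[str, dict[str, dict[str, float]]] = {c: {} for c in COMPARTMENT_NAMES}
    for eye in eyes:
        comps = derive_compartments(
            eye.surfaces, eye.fluid, slice_window=slice_window, provenance=eye.eye_id
        )
        rows = extract_features(eye.volume, comps, manifest)
        for comp in COMPARTMENT_NAMES:
            per_comp[comp][eye.eye_id] = rows[comp]
    names = manifest.descriptor_names()
    return {
        comp: pd.DataFrame.from_dict(d, orient="index").reindex(columns=names)
        for comp, d in per_comp.items()
    }


# ---------------------------------------------------------------------------
# fusion and normalization
# ---------------------------------------------------------------------------

_FUSIONS = {
    "f": ("IRF", "SRF"),
    "rtc": ("RTC1", "RTC2"),
    "oct": ("IRF", "SRF", "RTC1", "RTC2"),
}


def fuse(tables: dict[str, pd.DataFrame], which: str) -> pd.DataFrame:
    """Column-concatenate compartment tables with compartment-name prefixes.

    ``which`` is one of ``f`` (IRF+SRF), ``rtc`` (RTC1+RTC2) or ``oct``
    (all four).  Eye-id sets must agree exactly.
    """
    if which not in _FUSIONS:
        raise ValidationError(f"which must be one of {sorted(_FUSIONS)}, got {which!r}")
    parts = []
    reference = None
    for comp in _FUSIONS[which]:
        if comp not in tables:
            raise ValidationError(f"fusion {which!r} needs table {comp}")
        t = tables[comp]
        if reference is None:
            reference = t.index
        elif set(t.index) != set(reference):
            diff = sorted(set(t.index) ^ set(reference))
            raise ValidationError(f"eye_id mismatch between compartment tables: {diff}")
        parts.append(t.reindex(reference).add_prefix(f"{comp}/"))
    return pd.concat(parts, axis=1)


def znormalize(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, population sd 1 over non-missing rows.

    Zero-variance columns are set to 0 and recorded in
    ``result.attrs["constant_columns"]``.
    """
    mean = table.mean(axis=0, skipna=True)
    sd = table.std(axis=0, ddof=0, skipna=True)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    safe_sd = sd.replace(0, np.nan)
    out = (table - mean) / safe_sd
    if constant:
        logger.info("znormalize: %d constant columns set to 0", len(constant))
        out[constant] = out[constant].where(table[constant].isna(), 0.0)
    out.attrs["constant_columns"] = constant
    return out
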