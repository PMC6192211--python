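"""Reference density maps: loading real images and generating synthetic phantoms.

A :class:`DensityImage` plays two roles at once.  It is the relative emitter
(labeling) density ``rho(x, y)`` in ``[0, 1]`` that drives the rejection
sampler, and it is the ground-truth reference image against which the
reconstruction is scored.

Coordinate convention (used everywhere in the package): origin at the
top-left corner, x increases rightward (columns), y increases downward
(rows); the continuous coordinate of the center of pixel ``(i, j)`` is
``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)`` in nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = [
    "DensityImage",
    "load_reference",
    "make_filament_phantom",
    "make_nucleus_phantom",
]


@dataclass(frozen=True)
class DensityImage:
    """A 2-D relative emitter-density map with physical pixel size.

    Parameters
    ----------
    values
        2-D float array with every element in ``[0, 1]``.
    pixel_size
        Physical side length of one pixel, in nm.
    meta
        Free-form provenance (generator parameters, source path).
    """

    values: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise FormatError(f"density map must be 2-D, got shape {v.shape}")
        if v.shape[0] < 8 or v.shape[1] < 8:
            raise ParameterError("density map must be at least 8x8 pixels")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ParameterError("density values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the image in nm."""
        return (self.width * self.pixel_size, self.height * self.pixel_size)

    def save(self, path: str | Path) -> None:
        """Write a 16-bit TIFF plus a JSON sidecar with pixel size and metadata."""
        path = Path(path)
        scaled = np.round(self.values * 65535.0).astype(np.uint16)
        tifffile.imwrite(path, scaled)
        sidecar = {"pixel_size_nm": self.pixel_size, "scale": 65535, **self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_reference(path: str | Path, pixel_size: float) -> DensityImage:
    """Load a grayscale TIFF and min-max rescale it to a density map in [0, 1].

    Parameters
    ----------
    path
        Single-channel 8- or 16-bit grayscale TIFF.
    pixel_size
        Physical pixel side in nm (e.g. 6.4 for the SEM reference frames).

    Raises
    ------
    FormatError
        If the image is multi-channel / RGB.
    DegenerateInputError
        If the image is constant (zero dynamic range cannot define a density).
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(
            f"expected a single-channel grayscale image, got shape {arr.shape}"
        )
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateInputError("constant image: no density information")
    vals = (arr - lo) / (hi - lo)
    return DensityImage(vals, pixel_size, meta={"source": str(path)})


def _ridge_profile(mask: np.ndarray, pixel_size: float, thickness: float) -> np.ndarray:
    """Turn a 1-px-wide curve mask into a smooth ridge of the given thickness (nm)."""
    dist = ndimage.distance_transform_edt(~mask) * pixel_size
    half = thickness / 2.0
    vals = np.clip(1.0 - (dist / half) ** 2, 0.0, 1.0)
    # light smoothing so the ridge flanks are differentiable, then renormalize
    vals = ndimage.gaussian_filter(vals, sigma=0.7)
    vmax = vals.max()
    if vmax > 0:
        vals = vals / vmax
    return np.clip(vals, 0.0, 1.0)


def make_filament_phantom(
    width: int,
    height: int,
    pixel_size: float,
    n_filaments: int = 5,
    thickness: float = 50.0,
    seed: int = 0,
) -> DensityImage:
    """Generate a filament phantom: thin curvilinear ridges on an empty background.

    Emulates repetitive membrane-like structures that are distributed fairly
    uniformly over the field of view: quasi-parallel wavy ridges spanning the
    full image width, stacked at roughly even vertical spacing with random
    undulation (a sum of random sinusoids) and jitter.  Each ridge is
    rasterized and dilated to the requested ``thickness`` with a parabolic
    cross-section.  Undulation amplitude is capped well below the ridge
    spacing, so the filaments stay disjoint and the phantom has one
    foreground component per filament — in contrast to the few-blob nucleus
    phantom.

    Deterministic for a fixed seed.
    """
    if width <= 0 or height <= 0:
        raise ParameterError("image dimensions must be positive")
    if n_filaments < 1:
        raise ParameterError("n_filaments must be >= 1")
    if thickness < pixel_size:
        raise ParameterError("thickness must be at least one pixel")
    rng = np.random.default_rng(seed)
    w_nm, h_nm = width * pixel_size, height * pixel_size
    mask = np.zeros((height, width), dtype=bool)
    spacing = h_nm / n_filaments
    xs = np.arange(0.0, w_nm, pixel_size / 2.0)
    for f in range(n_filaments):
        y_base = (f + 0.5) * spacing + rng.uniform(-0.1, 0.1) * spacing
        ys = np.full_like(xs, y_base)
        # two random sinusoids; total amplitude stays below 0.3 * spacing so
        # neighboring ridges cannot touch after dilation to `thickness`
        for amp_frac in (0.2, 0.1):
            amp = rng.uniform(0.3, 1.0) * amp_frac * spacing
            wavelength = rng.uniform(0.3, 0.8) * w_nm
            phase = rng.uniform(0, 2 * np.pi)
            ys = ys + amp * np.sin(2 * np.pi * xs / wavelength + phase)
        ys = np.clip(ys, 0.0, h_nm - 1e-9)
        i = (ys / pixel_size).astype(np.intp)
        j = (xs / pixel_size).astype(np.intp)
        mask[i, j] = True
    vals = _ridge_profile(mask, pixel_size, thickness)
    return DensityImage(
        vals,
        pixel_size,
        meta={
            "phantom": "filament",
            "n_filaments": n_filaments,
            "thickness_nm": thickness,
            "seed": seed,
        },
    )


def make_nucleus_phantom(
    width: int,
    height: int,
    pixel_size: float,
    n_blobs: int = 3,
    blob_radius: float = 400.0,
    seed: int = 0,
) -> DensityImage:
    """Generate a nucleus-like phantom: few dense compact blobs on a sparse background.

    Emulates a structure class with a small number of concentrated regions
    (dense chromatin) occupying a small fraction of the image area, while most
    of the field carries only sparse low-level labeling.

    Blobs have a super-Gaussian profile (flat core, steep flank) with peak
    density 0.95 over a uniform background density of 0.05.  Deterministic for
    a fixed seed.
    """
    if width <= 0 or height <= 0:
        raise ParameterError("image dimensions must be positive")
    if n_blobs < 1:
        raise ParameterError("n_blobs must be >= 1")
    w_nm, h_nm = width * pixel_size, height * pixel_size
    if 2.0 * blob_radius > min(w_nm, h_nm):
        raise ParameterError(
            f"blob_radius {blob_radius} nm does not fit a {w_nm:.0f}x{h_nm:.0f} nm image"
        )
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    cx = (xx + 0.5) * pixel_size
    cy = (yy + 0.5) * pixel_size
    background = 0.05
    vals = np.full((height, width), background, dtype=np.float64)
    margin = blob_radius
    for _ in range(n_blobs):
        bx = rng.uniform(margin, w_nm - margin)
        by = rng.uniform(margin, h_nm - margin)
        r = blob_radius * rng.uniform(0.8, 1.2)
        r = min(r, min(w_nm, h_nm) / 2.0)
        r2 = (cx - bx) ** 2 + (cy - by) ** 2
        vals += 0.9 * np.exp(-((r2 / r**2) ** 2))
    vals = np.clip(vals, 0.0, 1.0)
    return DensityImage(
        vals,
        pixel_size,
        meta={
            "phantom": "nucleus",
            "n_blobs": n_blobs,
            "blob_radius_nm": blob_radius,
            "seed": seed,
        },
    )
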