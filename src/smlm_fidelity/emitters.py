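"""Emitter simulation: rejection sampling from a density map plus localization error.

The detected-emitter model has two steps.  Candidate positions are drawn
uniformly over the image rectangle and accepted with probability equal to the
local relative density ``rho(x, y)``; each accepted position is then perturbed
by an isotropic Gaussian localization error of standard deviation ``kappa``
(nm) per axis.  ``kappa`` lumps together all sources of localization
uncertainty — photon count, camera pixelation and noise, wavelength, and the
fitting algorithm — which are not modeled individually.

Random-draw order (fixed, so runs are bit-reproducible for a given seed):
candidates are drawn in batches of (x, y, p) triples until the requested
count is accepted, then the 2 * n Gaussian offsets are drawn in one block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError
from .reference import DensityImage

__all__ = ["EmitterSet", "sample_emitters", "emitter_density_per_um2"]

_MAX_BATCH = 4_000_000


@dataclass(frozen=True)
class EmitterSet:
    """Localized emitter positions in physical (nm) coordinates.

    ``positions`` are the *localized* coordinates, i.e. after the Gaussian
    perturbation; they may lie slightly outside the image rectangle.
    ``true_positions`` keeps the pre-perturbation coordinates for validation.
    """

    positions: np.ndarray  # (n, 2) array of (x, y) in nm
    kappa: float
    seed: int
    true_positions: np.ndarray | None = field(default=None, repr=False)
    n_candidates: int | None = None  # candidates examined up to the n-th acceptance

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ParameterError(f"positions must be (n, 2), got {p.shape}")
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")
        object.__setattr__(self, "positions", p)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    def to_csv(self, path: str | Path) -> None:
        """Write a localization table with columns ``x_nm, y_nm``."""
        np.savetxt(
            path,
            self.positions,
            delimiter=",",
            header="x_nm,y_nm",
            comments="",
            fmt="%.6f",
        )

    @classmethod
    def from_csv(cls, path: str | Path, kappa: float = 0.0, seed: int = 0) -> "EmitterSet":
        pos = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(pos, kappa=kappa, seed=seed)


def sample_emitters(
    density: DensityImage,
    n_max: int,
    kappa: float,
    seed: int,
    interp: str = "nearest",
) -> EmitterSet:
    """Draw ``n_max`` emitters from a density map by rejection sampling.

    Candidates (x, y) are continuous-uniform over the image rectangle; a
    candidate is accepted when a uniform variate p satisfies
    ``p <= rho(x, y)``.  By default rho is looked up at the containing pixel
    (``interp="nearest"``); ``interp="bilinear"`` interpolates between pixel
    centers instead.  Accepted positions are perturbed by independent
    N(0, kappa^2) offsets in x and y and the perturbed positions are kept even
    when they fall outside the rectangle.

    Raises
    ------
    DegenerateInputError
        If the density map is identically zero (sampling could never finish).
    """
    if n_max < 1:
        raise ParameterError("n_max must be >= 1")
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    if interp not in ("nearest", "bilinear"):
        raise ParameterError(f"unknown interpolation {interp!r}")
    rho = density.values
    mean_rho = float(rho.mean())
    if rho.max() <= 0.0:
        raise DegenerateInputError("all-zero density map: no emitter can be accepted")
    rng = np.random.default_rng(seed)
    w_nm, h_nm = density.extent_nm
    ps = density.pixel_size

    chunks_x: list[np.ndarray] = []
    chunks_y: list[np.ndarray] = []
    accepted = 0
    n_candidates = 0
    while accepted < n_max:
        need = n_max - accepted
        batch = int(min(max(1.2 * need / max(mean_rho, 1e-6), 1000), _MAX_BATCH))
        x = rng.uniform(0.0, w_nm, batch)
        y = rng.uniform(0.0, h_nm, batch)
        p = rng.uniform(0.0, 1.0, batch)
        if interp == "nearest":
            j = np.minimum((x / ps).astype(np.intp), density.width - 1)
            i = np.minimum((y / ps).astype(np.intp), density.height - 1)
            local = rho[i, j]
        else:
            # map physical coords to the pixel-center grid (center of (i,j) at
            # ((j+.5)ps, (i+.5)ps)); edges are clamped
            local = ndimage.map_coordinates(
                rho, [y / ps - 0.5, x / ps - 0.5], order=1, mode="nearest"
            )
        keep = p <= local
        chunks_x.append(x[keep])
        chunks_y.append(y[keep])
        got = int(keep.sum())
        if accepted + got >= n_max:
            # index (within this batch) of the candidate that completes n_max
            last = np.nonzero(keep)[0][n_max - accepted - 1]
            n_candidates += int(last) + 1
        else:
            n_candidates += batch
        accepted += got
    true_x = np.concatenate(chunks_x)[:n_max]
    true_y = np.concatenate(chunks_y)[:n_max]
    true_pos = np.column_stack([true_x, true_y])
    if kappa > 0:
        offsets = rng.normal(0.0, kappa, size=(n_max, 2))
        pos = true_pos + offsets
    else:
        pos = true_pos.copy()
    return EmitterSet(
        pos,
        kappa=kappa,
        seed=seed,
        true_positions=true_pos,
        n_candidates=n_candidates,
    )


def emitter_density_per_um2(
    n: int, width: int, height: int, pixel_size: float
) -> float:
    """Convert an emitter count to a surface density in emitters per square micron.

    ``50e3`` emitters on a 2048 x 2048 frame at 6.4 nm per pixel correspond to
    about 291 per um^2.
    """
    if width <= 0 or height <= 0 or pixel_size <= 0:
        raise ParameterError("image area must be positive")
    if n < 0:
        raise ParameterError("n must be >= 0")
    area_um2 = width * height * pixel_size**2 * 1e-6
    return n / area_um2
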