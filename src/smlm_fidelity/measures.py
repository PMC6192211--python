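"""Image-fidelity measures between a reference and a reconstruction.

Four measures, all invariant to a global intensity scale (a reconstruction
has no natural absolute intensity):

* ``q_pearson`` — Pearson correlation coefficient of the two pixel arrays.
* ``q_binarized`` — overlap of the two independently Otsu-binarized images:
  ``1 - sum|B0 - Brec| / sum B0``.  It can be negative when the
  false-positive area exceeds the reference foreground; the raw value is
  returned unclamped.
* ``q_l2`` — squared L2 distance between the mean-centered, L2-normalized
  images.  Zero for perfect agreement; algebraically equal to
  ``2 * (1 - q_pearson)``.
* ``q_freq`` — a frequency-resolved phase-agreement spectrum, mathematically
  similar to Fourier ring correlation but computed against a known
  reference: the 2-D DFTs are split into phase and amplitude factors, and
  each ring of radial frequency width ``delta_f = f_max / k`` reports the
  mean of ``cos(eta_0 - eta_rec)`` over its frequency samples.  The value is
  1 on every ring for identical images and 0 in expectation when the images
  are uncorrelated at that frequency.

Notes on ``q_freq``: the ring average is normalized by the number of samples
in the ring (otherwise the value 1 for perfect agreement would be
unattainable); the DC sample is excluded; samples where either amplitude is
exactly zero have no defined phase and are excluded, and a ring with no
usable sample is reported as NaN rather than 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal.windows import tukey
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "FreqSimilarity",
    "q_pearson",
    "otsu_threshold",
    "q_binarized",
    "q_l2",
    "q_freq",
]


def _as_float(img) -> np.ndarray:
    a = np.asarray(getattr(img, "values", img), dtype=np.float64)
    if a.ndim != 2:
        raise ParameterError(f"expected a 2-D image, got shape {a.shape}")
    return a


def _check_pair(ref, rec) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_float(ref), _as_float(rec)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _centered_unit(a: np.ndarray, name: str) -> np.ndarray:
    c = a - a.mean()
    norm = np.sqrt((c * c).sum())
    if norm == 0.0:
        raise DegenerateInputError(f"{name} image is constant")
    return c / norm


def q_pearson(ref, rec) -> float:
    """Pearson correlation coefficient between two same-shape images."""
    a, b = _check_pair(ref, rec)
    ua = _centered_unit(a, "reference")
    ub = _centered_unit(b, "reconstructed")
    return float((ua * ub).sum())


def otsu_threshold(img) -> float:
    """Otsu's threshold on a 256-bin histogram over the image's [min, max] range."""
    a = _as_float(img)
    if a.min() == a.max():
        raise DegenerateInputError("image has fewer than 2 distinct values")
    return float(threshold_otsu(a, nbins=256))


def binarize(img) -> np.ndarray:
    """Foreground mask: pixels strictly above the Otsu threshold."""
    a = _as_float(img)
    return a > otsu_threshold(a)


def q_binarized(ref, rec) -> float:
    """Overlap agreement between independently binarized images.

    Boolean arrays are taken as masks directly; anything else is Otsu-
    binarized first.  Raises DegenerateInputError when the reference
    foreground is empty (the normalization would divide by zero).
    """
    a, b = np.asarray(getattr(ref, "values", ref)), np.asarray(
        getattr(rec, "values", rec)
    )
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    ma = a if a.dtype == bool else binarize(a)
    mb = b if b.dtype == bool else binarize(b)
    fg = int(ma.sum())
    if fg == 0:
        raise DegenerateInputError("reference foreground is empty")
    mismatch = int(np.logical_xor(ma, mb).sum())
    return 1.0 - mismatch / fg


def q_l2(ref, rec) -> float:
    """Normalized squared L2 distance; 0 for perfect agreement, at most 4."""
    a, b = _check_pair(ref, rec)
    ua = _centered_unit(a, "reference")
    ub = _centered_unit(b, "reconstructed")
    diff = ua - ub
    return float((diff * diff).sum())


@dataclass(frozen=True)
class FreqSimilarity:
    """Phase-agreement spectrum sampled on k rings of width delta_f.

    ``frequencies`` are ring centers; with a pixel size given they are in
    cycles/nm, otherwise in cycles/pixel.  ``values`` lie in [-1, 1]; NaN
    marks a ring with no usable frequency sample.
    """

    frequencies: np.ndarray
    values: np.ndarray
    k: int
    delta_f: float
    pixel_size: float | None = None

    @property
    def freq_unit(self) -> str:
        return "cycles/nm" if self.pixel_size is not None else "cycles/pixel"

    def mean(self) -> float:
        """Mean ring value, ignoring empty rings."""
        return float(np.nanmean(self.values))

    def to_csv(self, path: str | Path) -> None:
        col = "f_cycles_per_nm" if self.pixel_size is not None else "f_cycles_per_px"
        np.savetxt(
            path,
            np.column_stack([self.frequencies, self.values]),
            delimiter=",",
            header=f"{col},q",
            comments="",
            fmt="%.8g",
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "k": self.k,
                "delta_f": self.delta_f,
                "freq_unit": self.freq_unit,
                "frequencies": self.frequencies.tolist(),
                "values": [None if np.isnan(v) else v for v in self.values],
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def q_freq(
    ref,
    rec,
    k: int = 32,
    pixel_size: float | None = None,
    window: str | None = None,
) -> FreqSimilarity:
    """Phase-agreement spectrum between two same-shape images.

    Parameters
    ----------
    ref, rec
        Same-shape 2-D images (arrays or objects with ``.values``); when a
        DensityImage/RenderedImage is passed its pixel size is picked up
        automatically.
    k
        Number of frequency rings between 0 and the Nyquist frequency of the
        pixel grid; each ring is the half-open radial band ]f, f + delta_f].
    pixel_size
        Physical pixel size in nm; frequencies are then in cycles/nm.
    window
        ``None`` (default) or ``"tukey"`` to taper non-periodic images and
        reduce spectral leakage from the image borders.
    """
    if pixel_size is None:
        pixel_size = getattr(ref, "pixel_size", None) or getattr(
            rec, "pixel_size", None
        )
    a, b = _check_pair(ref, rec)
    h, w = a.shape
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > min(h, w) // 2:
        raise ParameterError(
            f"k={k} exceeds the {min(h, w) // 2} resolvable rings of a {h}x{w} image"
        )
    if window == "tukey":
        win = np.outer(tukey(h, 0.25), tukey(w, 0.25))
        a, b = a * win, b * win
    elif window is not None:
        raise ParameterError(f"unknown window {window!r}")

    d = pixel_size if pixel_size is not None else 1.0
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    fy = np.fft.fftfreq(h, d=d)
    fx = np.fft.fftfreq(w, d=d)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    f_max = 1.0 / (2.0 * d)
    delta_f = f_max / k

    amp_a = np.abs(fa)
    amp_b = np.abs(fb)
    # ring membership: ring i is ]i*delta_f, (i+1)*delta_f]; DC lands at -1
    ring = np.ceil(fr / delta_f).astype(np.intp) - 1
    usable = (ring >= 0) & (ring < k) & (amp_a > 0) & (amp_b > 0)
    # cos(eta_a - eta_b) without forming the angles explicitly
    cross = fa * np.conj(fb)
    cosd = np.empty_like(fr)
    cosd[usable] = np.real(cross[usable]) / (amp_a[usable] * amp_b[usable])

    idx = ring[usable]
    sums = np.bincount(idx, weights=cosd[usable], minlength=k)
    counts = np.bincount(idx, minlength=k)
    values = np.full(k, np.nan)
    nz = counts > 0
    values[nz] = np.clip(sums[nz] / counts[nz], -1.0, 1.0)
    centers = (np.arange(k) + 0.5) * delta_f
    return FreqSimilarity(centers, values, k, delta_f, pixel_size)
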