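"""Local sampling density from Voronoi tessellation, and the limiting precision.

The local sampling interval around each localized emitter is quantified by
the radius ``delta_r = sqrt(area / pi)`` of the circle whose area equals the
emitter's Voronoi cell, with cells clipped to the image rectangle so the
areas exactly tile the field of view.  The limiting precision combines the
sampling interval with the localization precision ``delta_g`` in quadrature:

    delta_l = sqrt(delta_r**2 + delta_g**2)

``delta_g`` is identified with the localization accuracy kappa of the run
(the quadrature structure — a sampling term combined with a localization
term — forces this reading; it is an assumption, flagged here).

Two derived quantities are reported side by side, because "the limiting
frequency is delta_l / 2" admits two readings: the *limiting period*
``2 * delta_l`` (a length: the finest full cycle that can be recovered) and
the Nyquist-style *limiting frequency* ``1 / (2 * delta_l)`` (in cycles per
nm).  Both are computed from the median and the 95th-percentile delta_l —
the 95th percentile matters because the maximal recoverable spatial
frequency is restricted by the worst-sampled, not the average, region.

Clipping is implemented by mirroring the emitter set across the four
rectangle edges before tessellating; every original point's cell in the
augmented diagram is then finite and exactly equal to its clipped cell, so
the areas sum to the rectangle area by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import Voronoi, QhullError

from .errors import ParameterError, TessellationError
from .emitters import EmitterSet
from .reference import DensityImage

__all__ = [
    "SamplingStats",
    "voronoi_radii",
    "limiting_precision",
    "summarize_sampling",
]

_PCTS = (5, 25, 50, 75, 95)


def _bounds(bounds) -> tuple[float, float]:
    if isinstance(bounds, DensityImage):
        return bounds.extent_nm
    w, h = bounds
    if w <= 0 or h <= 0:
        raise ParameterError("bounds must be positive")
    return float(w), float(h)


def _dedup_jitter(pts: np.ndarray, eps: float) -> np.ndarray:
    """Deterministically separate exactly-coincident points by a tiny spiral."""
    _, inverse, counts = np.unique(
        pts, axis=0, return_inverse=True, return_counts=True
    )
    if counts.max() <= 1:
        return pts
    out = pts.copy()
    seen: dict[int, int] = {}
    for idx, grp in enumerate(inverse):
        g = int(grp)
        rank = seen.get(g, 0)
        seen[g] = rank + 1
        if rank > 0:
            ang = 2.39996 * rank  # golden angle, never collides
            out[idx, 0] += eps * rank * np.cos(ang)
            out[idx, 1] += eps * rank * np.sin(ang)
    return out


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def voronoi_radii(
    emitters: EmitterSet | np.ndarray,
    bounds,
    jitter_scale: float = 1.0,
) -> np.ndarray:
    """Equivalent-circle radius of each emitter's clipped Voronoi cell, in nm.

    Parameters
    ----------
    emitters
        An :class:`EmitterSet` or an (n, 2) coordinate array; only emitters
        strictly inside ``bounds`` receive a radius.
    bounds
        The image rectangle: a :class:`DensityImage` or a ``(width_nm,
        height_nm)`` pair (origin at 0, 0).
    jitter_scale
        Length scale (nm) for the deterministic 1e-6-scale jitter applied to
        exactly duplicated positions; pass the pixel size to jitter by 1e-6
        pixel.

    Returns
    -------
    radii : one ``delta_r`` per in-bounds emitter, in input order.
    """
    pos = emitters.positions if isinstance(emitters, EmitterSet) else np.asarray(
        emitters, dtype=np.float64
    )
    w, h = _bounds(bounds)
    inside = (pos[:, 0] > 0) & (pos[:, 0] < w) & (pos[:, 1] > 0) & (pos[:, 1] < h)
    pts = pos[inside]
    n = len(pts)
    if n == 0:
        raise TessellationError("no emitters inside the bounds")
    if n == 1:
        return np.array([np.sqrt(w * h / np.pi)])
    pts = _dedup_jitter(pts, 1e-6 * jitter_scale)
    # mirror across the four edges: original cells become the clipped cells
    mirrored = np.vstack(
        [
            pts,
            np.column_stack([-pts[:, 0], pts[:, 1]]),
            np.column_stack([2 * w - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], -pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * h - pts[:, 1]]),
        ]
    )
    try:
        vor = Voronoi(mirrored)
    except QhullError as exc:  # pragma: no cover - qhull degeneracies
        raise TessellationError(f"Voronoi tessellation failed: {exc}") from exc
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise TessellationError(
                "unbounded cell after mirroring (degenerate emitter configuration)"
            )
        areas[i] = _polygon_area(vor.vertices[region])
    return np.sqrt(areas / np.pi)


def limiting_precision(delta_r, delta_g):
    """Quadrature combination sqrt(delta_r^2 + delta_g^2), elementwise (nm)."""
    dr = np.asarray(delta_r, dtype=np.float64)
    dg = np.asarray(delta_g, dtype=np.float64)
    if np.any(dr < 0) or np.any(dg < 0):
        raise ParameterError("delta_r and delta_g must be >= 0")
    out = np.hypot(dr, dg)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SamplingStats:
    """Distribution summary of sampling radii and the derived limiting precision."""

    radii: np.ndarray
    delta_g: float
    delta_l: np.ndarray
    summary: dict  # mean + percentiles of delta_r (5/25/50/75/95)
    limiting_period_median: float  # 2 * median(delta_l), nm
    limiting_frequency_median: float  # 1 / (2 * median(delta_l)), cycles/nm
    limiting_period_p95: float
    limiting_frequency_p95: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "delta_g_nm": self.delta_g,
                "delta_r_summary_nm": self.summary,
                "limiting_period_median_nm": self.limiting_period_median,
                "limiting_frequency_median_per_nm": self.limiting_frequency_median,
                "limiting_period_p95_nm": self.limiting_period_p95,
                "limiting_frequency_p95_per_nm": self.limiting_frequency_p95,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.radii, self.delta_l]),
            delimiter=",",
            header="delta_r_nm,delta_l_nm",
            comments="",
            fmt="%.6f",
        )


def summarize_sampling(radii, delta_g: float) -> SamplingStats:
    """Percentile summary of sampling radii plus elementwise limiting precision.

    The summary follows the box-plot convention: mean, median, 25/75th and
    5/95th percentiles.
    """
    r = np.asarray(radii, dtype=np.float64)
    if r.size == 0:
        raise ParameterError("radii must be non-empty")
    if np.any(r <= 0):
        raise ParameterError("radii must be positive")
    if delta_g < 0:
        raise ParameterError("delta_g must be >= 0")
    dl = limiting_precision(r, delta_g)
    pct = np.percentile(r, _PCTS)
    summary = {"mean": float(r.mean())}
    summary.update({f"p{p}": float(v) for p, v in zip(_PCTS, pct)})
    dl_med = float(np.median(dl))
    dl_p95 = float(np.percentile(dl, 95))
    return SamplingStats(
        radii=r,
        delta_g=float(delta_g),
        delta_l=np.atleast_1d(dl),
        summary=summary,
        limiting_period_median=2.0 * dl_med,
        limiting_frequency_median=1.0 / (2.0 * dl_med),
        limiting_period_p95=2.0 * dl_p95,
        limiting_frequency_p95=1.0 / (2.0 * dl_p95),
    )
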