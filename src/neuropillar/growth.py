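"""Neurite growth metrics on nanopillar arrays.

Quantifies how strongly cultured neurons align with the rows and columns of
a pillar array from a fluorescence image: the neuron channel is thresholded
and skeletonized, the skeleton is traced into polylines, and the *ordered
fraction* is the traced length lying within an angular tolerance of either
grid axis divided by the total traced length.  *Total growth* is the
foreground area fraction of the region of interest (skeletons discard
neurite thickness, so they are not used for total growth).

A synthetic image generator draws random-walk neurites — a controllable
fraction locked to the grid axes, the rest oriented obliquely — renders them
with width, blur and noise, and returns the ground-truth polylines, so the
whole measurement chain can be validated without microscope data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import draw as skdraw
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "ArrayImage",
    "NeuriteSkeleton",
    "GrowthMetrics",
    "synth_array_image",
    "segment_and_skeletonize",
    "trace_neurites",
    "resample_polyline",
    "ordered_fraction",
    "fractional_separation",
    "growth_stats",
    "analyze_image",
    "polyline_length",
]


@dataclass
class ArrayImage:
    """Single-channel neuron-fluorescence image on a known pillar grid.

    ``pixel_size`` in um/px; ``pitch`` in um; ``diameter`` in nm;
    ``axes`` are the (row, column) grid directions in degrees (column axis is
    kept orthogonal to the row axis, so one angle suffices).
    """

    image: np.ndarray
    pixel_size: float = 0.2
    pitch: float = 2.0
    diameter: float = 200.0
    row_axis_deg: float = 0.0
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.pitch * 1e3 <= self.diameter:
            raise ValueError("pitch must exceed pillar diameter")

    @classmethod
    def from_file(cls, path, pixel_size=0.2, pitch=2.0, diameter=200.0,
                  row_axis_deg=0.0, channel=None):
        """Load a TIFF or PNG fluorescence image.

        Multi-channel images need ``channel`` (index of the neuron stain).
        Intensities are rescaled to [0, 1].
        """
        import os

        ext = os.path.splitext(str(path))[1].lower()
        if ext in (".tif", ".tiff"):
            import tifffile

            img = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            img = iio.imread(path)
        img = np.asarray(img, dtype=float)
        if img.ndim == 3:
            if channel is None:
                raise ValueError("multi-channel image: specify channel")
            img = img[..., channel] if img.shape[-1] <= 4 else img[channel]
        if img.max() > 0:
            img = img / img.max()
        return cls(image=img, pixel_size=pixel_size, pitch=pitch,
                   diameter=diameter, row_axis_deg=row_axis_deg)


@dataclass
class NeuriteSkeleton:
    """Traced 1-px-wide skeleton: polylines of (row, col) pixel centers."""

    polylines: list
    pixel_size: float = 0.2

    @property
    def total_length(self) -> float:
        """Total traced length in um."""
        return sum(
            polyline_length(p) for p in self.polylines
        ) * self.pixel_size


def polyline_length(p: np.ndarray) -> float:
    """Arc length of a polyline in pixel units."""
    p = np.asarray(p, dtype=float)
    if len(p) < 2:
        return 0.0
    return float(np.sqrt(((p[1:] - p[:-1]) ** 2).sum(axis=1)).sum())


@dataclass
class GrowthMetrics:
    """Per-array outcome of the growth analysis."""

    total_growth: float  # foreground area fraction, in [0, 1]
    ordered: float | None  # ordered length fraction, in [0, 1] (None if empty)
    pitch: float
    diameter: float

    @property
    def fractional_separation(self) -> float:
        return fractional_separation(self.pitch, self.diameter / 1e3)


def fractional_separation(p: float, d: float) -> float:
    """(p - d) / p for pitch p and pillar diameter d in the same units."""
    if d < 0 or p <= d:
        raise ValueError("need pitch > diameter >= 0")
    return (p - d) / p


# ---------------------------------------------------------------------------
# synthetic generator

def _walk(rng, start, base_deg, n_steps, step, jitter_deg):
    """Persistent random walk polyline; heading diffuses around base_deg."""
    ang = np.deg2rad(base_deg)
    pts = [np.asarray(start, dtype=float)]
    heading = ang
    for _ in range(n_steps):
        heading += np.deg2rad(rng.normal(0.0, jitter_deg))
        # soft pull back toward the base direction keeps walks straight-ish
        heading += 0.25 * (ang - heading)
        pts.append(pts[-1] + step * np.array([np.sin(heading), np.cos(heading)]))
    return np.array(pts)


def synth_array_image(
    pitch: float = 2.0,
    diameter: float = 200.0,
    n_neurites: int = 30,
    aligned_fraction: float = 0.5,
    width: float = 3.0,
    noise: float = 0.05,
    seed: int = 0,
    shape: tuple = (512, 512),
    pixel_size: float = 0.2,
    blur_sigma: float = 1.0,
):
    """Render a synthetic stained-neurite image on a pillar grid.

    A fraction ``aligned_fraction`` of the neurites follow a grid axis (row
    or column, small angular jitter); the rest follow oblique base directions
    drawn uniformly from 20-70 degrees off-axis, so their ground-truth
    orientation is unambiguous.  Returns ``(ArrayImage, truth_polylines,
    truth_aligned_flags)``; all randomness comes from ``seed``.
    """
    if not 0.0 <= aligned_fraction <= 1.0:
        raise ValueError("aligned_fraction must lie in [0, 1]")
    if min(shape) < 64 or width <= 0 or pitch * 1e3 <= diameter:
        raise ValueError("degenerate geometry")
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    truth = []
    flags = []
    n_aligned = int(round(aligned_fraction * n_neurites))
    margin = 20
    for i in range(n_neurites):
        aligned = i < n_aligned
        if aligned:
            base = rng.choice([0.0, 90.0]) + rng.normal(0.0, 1.5)
        else:
            # oblique: keep the base direction well clear of both axes so the
            # ground-truth label is unambiguous at the 10-degree tolerance
            base = rng.choice([0.0, 90.0]) + rng.uniform(20.0, 70.0) * rng.choice(
                [-1.0, 1.0]
            )
        jitter = 1.5
        start = rng.uniform(margin, np.array(shape) - margin)
        n_steps = int(rng.integers(60, 140))
        poly = _walk(rng, start, base, n_steps, step=2.0, jitter_deg=jitter)
        # terminate at the field of view rather than clip (clipping would
        # fabricate axis-aligned runs along the image border)
        inside = np.all((poly >= 1) & (poly <= np.array(shape) - 2), axis=1)
        cut = np.argmin(inside) if not inside.all() else len(poly)
        if cut < 2:
            continue
        poly = poly[:cut]
        truth.append(poly)
        flags.append(aligned)
        for a, b in zip(poly[:-1], poly[1:]):
            rr, cc = skdraw.line(
                int(round(a[0])), int(round(a[1])),
                int(round(b[0])), int(round(b[1])),
            )
            img[rr, cc] = 1.0
    if width > 1:
        from scipy.ndimage import grey_dilation

        k = int(round(width))
        img = grey_dilation(img, size=(k, k))
    img = gaussian_filter(img, blur_sigma)
    if img.max() > 0:
        img /= img.max()
    img = img + rng.normal(0.0, noise, size=shape)
    arr = ArrayImage(
        image=img, pixel_size=pixel_size, pitch=pitch, diameter=diameter
    )
    return arr, truth, flags


# ---------------------------------------------------------------------------
# segmentation, skeletonization, tracing

def segment_and_skeletonize(
    image: ArrayImage,
    threshold: float | Literal["otsu"] = "otsu",
    min_object_px: int = 30,
):
    """Threshold, clean and thin the neuron channel.

    Returns ``(NeuriteSkeleton, mask)``.  An empty foreground yields an empty
    skeleton (with a warning) rather than an error.
    """
    img = np.asarray(image.image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if threshold == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    mask = _remove_small(mask, min_object_px)
    if not mask.any():
        import warnings

        warnings.warn("empty foreground: returning empty skeleton")
        return NeuriteSkeleton(polylines=[], pixel_size=image.pixel_size), mask
    skel = skeletonize(mask)
    polylines = trace_neurites(skel)
    return NeuriteSkeleton(polylines=polylines, pixel_size=image.pixel_size), mask


def _remove_small(mask, min_px: int):
    """Drop connected components with fewer than ``min_px`` pixels."""
    from scipy.ndimage import label

    lab, n = label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[lab]


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def trace_neurites(skeleton: np.ndarray) -> list:
    """Decompose a 1-px skeleton (8-connected) into simple paths.

    Pixels with degree != 2 (endpoints and branch points) are nodes; each
    path runs from node to node (isolated cycles are traced from an
    arbitrary pixel).  Returns a list of (n, 2) float arrays of (row, col).
    """
    pix = np.argwhere(skeleton)
    if len(pix) == 0:
        return []
    pset = {tuple(p) for p in pix}
    nbrs = {
        p: [q for q in ((p[0] + dr, p[1] + dc) for dr, dc in _NBRS) if q in pset]
        for p in pset
    }
    nodes = {p for p, nb in nbrs.items() if len(nb) != 2}
    visited_edges = set()
    paths = []

    def edge(a, b):
        return (a, b) if a <= b else (b, a)

    def follow(start, nxt):
        path = [start, nxt]
        visited_edges.add(edge(start, nxt))
        prev, cur = start, nxt
        while cur not in nodes:
            options = [q for q in nbrs[cur] if q != prev and edge(cur, q) not in visited_edges]
            if not options:
                break
            nxt_p = options[0]
            visited_edges.add(edge(cur, nxt_p))
            path.append(nxt_p)
            prev, cur = cur, nxt_p
        return np.array(path, dtype=float)

    for node in sorted(nodes):
        for nb in nbrs[node]:
            if edge(node, nb) not in visited_edges:
                paths.append(follow(node, nb))
    # isolated cycles: every pixel has degree 2 and none visited
    for p in sorted(pset - nodes):
        for nb in nbrs[p]:
            if edge(p, nb) not in visited_edges:
                paths.append(follow(p, nb))
    return [p for p in paths if len(p) >= 2]


def resample_polyline(p: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing (pixel units).

    Chord-resampling smooths out the 45-degree quantization of raw skeleton
    steps before orientations are measured.
    """
    p = np.asarray(p, dtype=float)
    if len(p) < 2:
        return p
    seg = np.sqrt(((p[1:] - p[:-1]) ** 2).sum(axis=1))
    s = np.concatenate(([0.0], np.cumsum(seg)))
    if s[-1] <= spacing:
        return p[[0, -1]]
    n = max(int(np.floor(s[-1] / spacing)) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack(
        [np.interp(si, s, p[:, 0]), np.interp(si, s, p[:, 1])]
    )


def _segment_angles_lengths(polylines):
    """Orientations (deg in [0, 180)) and lengths of all polyline segments.

    Angle convention: 0 deg = +column (image x) direction, measured toward
    +row; the (row, col) pixel layout maps to (y, x)."""
    angs, lens = [], []
    for p in polylines:
        p = np.asarray(p, dtype=float)
        if len(p) < 2:
            continue
        d = p[1:] - p[:-1]
        length = np.sqrt((d**2).sum(axis=1))
        keep = length > 0
        ang = np.rad2deg(np.arctan2(d[keep, 0], d[keep, 1])) % 180.0
        angs.append(ang)
        lens.append(length[keep])
    if not angs:
        return np.array([]), np.array([])
    return np.concatenate(angs), np.concatenate(lens)


def ordered_fraction(
    polylines,
    row_axis_deg: float = 0.0,
    theta_tol: float = 10.0,
    chord: float | None = None,
):
    """Fraction of polyline length aligned with the grid axes.

    A segment is *ordered* iff its orientation lies within ``theta_tol``
    degrees of the row axis or the (orthogonal) column axis.  ``chord``
    optionally resamples polylines at that arc-length spacing first (use ~4 px
    for raw skeleton traces).  Returns None for zero total length — an
    undefined fraction is reported as missing, never as 0.
    """
    if not 0.0 < theta_tol < 45.0:
        raise ValueError("theta_tol must lie in (0, 45) degrees")
    if chord is not None:
        polylines = [resample_polyline(p, chord) for p in polylines]
    ang, lens = _segment_angles_lengths(polylines)
    if lens.sum() == 0:
        return None
    # angular distance to the nearest of the two axes, folded to [0, 90]
    rel = (ang - row_axis_deg) % 90.0
    dist = np.minimum(rel, 90.0 - rel)
    return float(lens[dist <= theta_tol].sum() / lens.sum())


def analyze_image(
    image: ArrayImage,
    threshold: float | Literal["otsu"] = "otsu",
    min_object_px: int = 30,
    theta_tol: float = 10.0,
    chord: float = 8.0,
    min_path_px: float = 6.0,
) -> GrowthMetrics:
    """Full per-array measurement: segmentation, tracing, both metrics.

    Traced paths shorter than ``min_path_px`` (junction debris left by
    thinning) are excluded from the orientation metric; ``chord`` resampling
    removes the 45-degree step quantization of raw skeletons.
    """
    skel, mask = segment_and_skeletonize(image, threshold, min_object_px)
    paths = [p for p in skel.polylines if polyline_length(p) >= min_path_px]
    frac = ordered_fraction(
        paths, image.row_axis_deg, theta_tol, chord=chord
    )
    return GrowthMetrics(
        total_growth=float(mask.mean()),
        ordered=frac,
        pitch=image.pitch,
        diameter=image.diameter,
    )


def growth_stats(metrics, by: str = "pitch") -> pd.DataFrame:
    """Group per-array metrics and report mean +/- standard error.

    ``metrics``: iterable of :class:`GrowthMetrics` or a DataFrame with
    columns total_growth/ordered/pitch/diameter.  ``by`` is one of 'pitch',
    'diameter' or 'fractional_separation'.  Groups of size 1 report SE as
    NaN (missing), not 0.
    """
    if by not in ("pitch", "diameter", "fractional_separation"):
        raise ValueError(f"unknown grouping {by!r}")
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
        if "fractional_separation" not in df:
            df["fractional_separation"] = (
                df["pitch"] - df["diameter"] / 1e3
            ) / df["pitch"]
    else:
        metrics = list(metrics)
        if not metrics:
            raise ValueError("no per-array metrics supplied")
        df = pd.DataFrame(
            {
                "total_growth": [m.total_growth for m in metrics],
                "ordered": [m.ordered for m in metrics],
                "pitch": [m.pitch for m in metrics],
                "diameter": [m.diameter for m in metrics],
                "fractional_separation": [
                    m.fractional_separation for m in metrics
                ],
            }
        )
    out = df.groupby(by).agg(
        total_growth_mean=("total_growth", "mean"),
        total_growth_se=("total_growth", "sem"),
        ordered_mean=("ordered", "mean"),
        ordered_se=("ordered", "sem"),
        n=("total_growth", "size"),
    )
    return out.reset_index()
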