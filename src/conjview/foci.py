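"""Fluorescent-focus detection, classification and localisation statistics.

Foci are detected by a difference-of-Gaussians band-pass followed by local
maxima above a robust-noise prominence threshold, with subpixel centres
from a 3x3 intensity centroid. Each detection is expressed in normalised
cell coordinates: ``l`` runs along the cell axis (0 = midcell, ±0.5 = the
poles, after dividing by cell length) and ``d`` across it (0 = axis,
±0.5 = the membrane, after dividing by cell width). In these coordinates
replicative Ssb foci sit in the inner region near midcell/quarter
positions, while conjugative foci — ssDNA at the conjugation pore — are
membrane proximal (|d| large), which is what the classifier keys on.

``skewness`` is the third standardised moment of the in-mask pixel
intensities: a threshold-free measure of how strongly fluorescence is
concentrated into foci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .render import MovieStack
from .segmentation import CellRecord

__all__ = [
    "FocusParams",
    "FocusDetection",
    "HeatmapGrid",
    "detect_foci",
    "detect_foci_movie",
    "classify_focus",
    "skewness",
    "heatmap",
    "colocalise",
]


@dataclass
class FocusParams:
    sigma_small_px: float = 1.0
    sigma_large_px: float = 3.0
    prominence_k: float = 5.0  # threshold = k * robust sigma of the band-pass
    min_distance_px: int = 2
    integration_radius_px: int = 3
    # integrated intensity must exceed k_int x the shot-noise scale of the
    # integration window, or the peak is discarded as noise
    intensity_k: float = 3.0
    conjugative_d_min: float = 0.3
    conjugative_intensity_min: float = 0.0


@dataclass
class FocusDetection:
    cell_id: int  # track id (pipeline) or label (single frame)
    frame: int
    channel: str
    x_um: float
    y_um: float
    l: float  # normalised longitudinal position, |l| <= 0.5
    d: float  # normalised transverse position, |d| <= 0.5
    intensity: float  # integrated signal above local cytoplasm
    focus_class: str = "unclassified"


@dataclass
class HeatmapGrid:
    """2D focus-density histogram over normalised cell coordinates."""

    grid: np.ndarray  # (n_l_bins, n_d_bins)
    l_edges: np.ndarray
    d_edges: np.ndarray
    n_foci: int
    normalised: bool


def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med))) + 1e-12


def _median_by_label(img: np.ndarray, lab: np.ndarray) -> dict[int, float]:
    """Median intensity per labelled region (cytoplasm estimate)."""
    flat_lab = lab.ravel()
    order = np.argsort(flat_lab, kind="stable")
    sorted_lab = flat_lab[order]
    sorted_img = img.ravel()[order]
    out: dict[int, float] = {}
    bounds = np.searchsorted(sorted_lab, np.arange(1, lab.max() + 2))
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        if b > a:
            out[i] = float(np.median(sorted_img[a:b]))
    return out


def _subpixel_centroid(img: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Centroid of the positive 3x3 neighbourhood around a maximum."""
    ys = slice(max(y - 1, 0), min(y + 2, img.shape[0]))
    xs = slice(max(x - 1, 0), min(x + 2, img.shape[1]))
    patch = np.clip(img[ys, xs], 0.0, None)
    tot = patch.sum()
    if tot <= 0:
        return float(y), float(x)
    yy, xx = np.mgrid[ys, xs]
    return float((patch * yy).sum() / tot), float((patch * xx).sum() / tot)


def normalised_coords(rec: CellRecord, x_um: float, y_um: float) -> tuple[float, float]:
    """Project an absolute position into the cell's (l, d) frame."""
    (x0, y0), (x1, y1) = rec.centerline_um
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    ux, uy = x1 - x0, y1 - y0
    nrm = math.hypot(ux, uy)
    if nrm == 0:
        ux, uy = 1.0, 0.0
    else:
        ux, uy = ux / nrm, uy / nrm
    rx, ry = x_um - cx, y_um - cy
    l = (rx * ux + ry * uy) / max(rec.length_um, 1e-9)
    d = (-rx * uy + ry * ux) / max(rec.width_um, 1e-9)
    return float(np.clip(l, -0.5, 0.5)), float(np.clip(d, -0.5, 0.5))


def detect_foci(
    patch: np.ndarray,
    mask: np.ndarray,
    channel: str,
    params: FocusParams | None = None,
    rec: CellRecord | None = None,
    pixel_size_um: float = 0.065,
    frame: int = 0,
    origin_px: tuple[float, float] = (0.0, 0.0),
) -> list[FocusDetection]:
    """Detect foci on one cell image patch (or a whole frame).

    ``origin_px`` is the (y, x) offset of the patch within the full frame,
    so returned positions are in absolute µm. No foci found is an empty
    list, never an error.
    """
    p = params or FocusParams()
    img = np.asarray(patch, dtype=float)
    if img.shape[0] < 5 or img.shape[1] < 5:
        raise ValueError("patch must be at least 5x5 px")
    dog = gaussian(img, p.sigma_small_px, preserve_range=True) - gaussian(
        img, p.sigma_large_px, preserve_range=True
    )
    thr = p.prominence_k * _robust_sigma(dog)
    peaks = peak_local_max(
        dog, min_distance=p.min_distance_px, threshold_abs=thr, exclude_border=False
    )
    out: list[FocusDetection] = []
    cyto = float(np.median(img[mask])) if mask.any() else float(np.median(img))
    r = p.integration_radius_px
    raw_in = img[mask] if mask.any() else img
    min_intensity = p.intensity_k * (2 * r + 1) * _robust_sigma(raw_in)
    for y, x in peaks:
        if not mask[y, x]:
            continue
        yc, xc = _subpixel_centroid(dog, y, x)
        ys = slice(max(y - r, 0), min(y + r + 1, img.shape[0]))
        xs = slice(max(x - r, 0), min(x + r + 1, img.shape[1]))
        intensity = float((img[ys, xs] - cyto).sum())
        if intensity < min_intensity:
            continue
        x_um = (xc + origin_px[1]) * pixel_size_um
        y_um = (yc + origin_px[0]) * pixel_size_um
        if rec is not None:
            l, d = normalised_coords(rec, x_um, y_um)
            cid = rec.cell_id if rec.cell_id > 0 else rec.label
        else:
            l = d = 0.0
            cid = -1
        det = FocusDetection(
            cell_id=cid,
            frame=frame,
            channel=channel,
            x_um=x_um,
            y_um=y_um,
            l=l,
            d=d,
            intensity=intensity,
        )
        det.focus_class = classify_focus(det, p)
        out.append(det)
    return out


def detect_foci_movie(
    movie: MovieStack,
    labels: np.ndarray,
    per_frame: list[list[CellRecord]],
    channels: tuple[str, ...] = ("ypet", "mcherry"),
    params: FocusParams | None = None,
    track_of_label: dict[tuple[int, int], int] | None = None,
) -> pd.DataFrame:
    """Whole-movie focus detection, assigned to segmented cells.

    Works frame-by-frame on the full field (one band-pass per channel per
    frame), then attributes each peak to the cell whose mask contains it;
    peaks a pixel outside any mask (membrane-proximal foci blurred by the
    PSF) are attributed to the dominant label in their 3x3 neighbourhood.
    """
    p = params or FocusParams()
    px = movie.pixel_size_um
    rows = []
    for f in range(movie.n_frames):
        lab = labels[f]
        rec_of_label = {r.label: r for r in per_frame[f]}
        for ch in channels:
            img = movie.channels[ch][f].astype(float)
            dog = gaussian(img, p.sigma_small_px, preserve_range=True) - gaussian(
                img, p.sigma_large_px, preserve_range=True
            )
            # noise floor from in-cell pixels (diffuse signal dominates the
            # shot noise there; foci are too sparse to move the MAD)
            incell = dog[lab > 0]
            thr = p.prominence_k * _robust_sigma(incell if incell.size else dog)
            raw_incell = img[lab > 0]
            win = 2 * p.integration_radius_px + 1
            min_intensity = p.intensity_k * win * _robust_sigma(
                raw_incell if raw_incell.size else img
            )
            peaks = peak_local_max(
                dog, min_distance=p.min_distance_px, threshold_abs=thr, exclude_border=False
            )
            med_by_label = _median_by_label(img, lab)
            for y, x in peaks:
                lval = int(lab[y, x])
                if lval == 0:
                    # membrane-proximal foci blur past the (slightly eroded)
                    # mask edge: take the label of the nearest mask pixel
                    # within a 7x7 window
                    rw = 3
                    y0, x0 = max(y - rw, 0), max(x - rw, 0)
                    neigh = lab[y0 : y + rw + 1, x0 : x + rw + 1]
                    ys_n, xs_n = np.nonzero(neigh)
                    if ys_n.size == 0:
                        continue
                    d2 = (ys_n + y0 - y) ** 2 + (xs_n + x0 - x) ** 2
                    j = int(np.argmin(d2))
                    lval = int(neigh[ys_n[j], xs_n[j]])
                rec = rec_of_label.get(lval)
                if rec is None:
                    continue
                yc, xc = _subpixel_centroid(dog, y, x)
                r = p.integration_radius_px
                ys = slice(max(y - r, 0), min(y + r + 1, img.shape[0]))
                xs = slice(max(x - r, 0), min(x + r + 1, img.shape[1]))
                cyto = med_by_label.get(lval)
                if cyto is None:
                    continue
                intensity = float((img[ys, xs] - cyto).sum())
                if intensity < min_intensity:
                    continue
                x_um = xc * px
                y_um = yc * px
                l, d = normalised_coords(rec, x_um, y_um)
                det = FocusDetection(
                    cell_id=lval,
                    frame=f,
                    channel=ch,
                    x_um=x_um,
                    y_um=y_um,
                    l=l,
                    d=d,
                    intensity=intensity,
                )
                det.focus_class = "parB" if ch == "mcherry" else classify_focus(det, p)
                tid = -1
                if track_of_label is not None:
                    tid = track_of_label.get((f, lval), -1)
                rows.append(
                    dict(
                        frame=f,
                        label=lval,
                        track_id=tid,
                        channel=ch,
                        x_um=det.x_um,
                        y_um=det.y_um,
                        l=l,
                        d=d,
                        intensity=intensity,
                        focus_class=det.focus_class,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "frame",
            "label",
            "track_id",
            "channel",
            "x_um",
            "y_um",
            "l",
            "d",
            "intensity",
            "focus_class",
        ],
    )


def classify_focus(f: FocusDetection, params: FocusParams | None = None) -> str:
    """Membrane-proximal bright foci are conjugative; interior ones replicative."""
    p = params or FocusParams()
    if f.channel == "mcherry":
        return "parB"
    if abs(f.d) >= p.conjugative_d_min:
        if f.intensity >= p.conjugative_intensity_min:
            return "conjugative"
        return "unclassified"
    return "replicative"


def skewness(values: np.ndarray, corrected: bool = False) -> float:
    """Third standardised central moment of in-mask pixel intensities.

    Population-moment definition m3 / m2^1.5 by default; ``corrected``
    applies the sample-size bias correction. Zero variance is undefined:
    returns NaN with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("skewness needs at least 3 pixels")
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0:
        warnings.warn("zero variance: skewness undefined", stacklevel=2)
        return float("nan")
    g1 = ((x - m) ** 3).mean() / m2**1.5
    if corrected:
        n = x.size
        g1 *= math.sqrt(n * (n - 1)) / (n - 2)
    return float(g1)


def heatmap(
    foci: pd.DataFrame | list[FocusDetection],
    bins: tuple[int, int] = (20, 10),
    mirror_fold: bool = False,
    normalise: bool = True,
) -> HeatmapGrid:
    """2D localisation histogram over normalised cell coordinates.

    ``mirror_fold`` symmetrises over the pole axis (l -> -l), reflecting
    that cells have no intrinsic polarity in these movies.
    """
    if isinstance(foci, pd.DataFrame):
        l = foci["l"].to_numpy(float)
        d = foci["d"].to_numpy(float)
    else:
        l = np.array([f.l for f in foci])
        d = np.array([f.d for f in foci])
    if l.size == 0:
        raise ValueError("heatmap needs at least one focus")
    grid, l_edges, d_edges = np.histogram2d(
        l, d, bins=bins, range=[[-0.5, 0.5], [-0.5, 0.5]]
    )
    if mirror_fold:
        grid = 0.5 * (grid + grid[::-1, :])
    if normalise:
        grid = grid / grid.sum()
    return HeatmapGrid(
        grid=grid, l_edges=l_edges, d_edges=d_edges, n_foci=int(l.size), normalised=normalise
    )


def colocalise(
    foci_a: pd.DataFrame,
    foci_b: pd.DataFrame,
    radius_um: float,
) -> float:
    """Fraction of foci in ``a`` with a same-frame neighbour in ``b``.

    Nearest-neighbour matching within ``radius_um``. Undefined (NaN, with a
    warning) when ``foci_a`` is empty.
    """
    if len(foci_a) == 0:
        warnings.warn("colocalise: empty reference focus set", stacklevel=2)
        return float("nan")
    matched = 0
    for frame, grp_a in foci_a.groupby("frame"):
        grp_b = foci_b[foci_b["frame"] == frame]
        if len(grp_b) == 0:
            continue
        tree = cKDTree(grp_b[["x_um", "y_um"]].to_numpy(float))
        dists, _ = tree.query(grp_a[["x_um", "y_um"]].to_numpy(float))
        matched += int((dists <= radius_um).sum())
    return matched / len(foci_a)
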