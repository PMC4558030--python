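"""Locating and decoding tags in a single image.

Pipeline: grayscale -> binarise (global or locally adaptive threshold) ->
8-connected white regions -> quadrilateral fit on each region's convex hull
-> perspective grid sampling of the 5x5 code -> parity/codebook decode.
Each stage is exposed on its own so that tests and benchmarks can probe it
in isolation; :func:`locate_codes` runs the whole chain.

Coordinates are (x, y) with the origin at the top-left pixel centre, x to
the right, y down, 0-based.  Quadrilateral corners are ordered clockwise as
displayed, starting at the tag's canonical top-left once decoded.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import approximate_polygon, label, regionprops
from skimage.transform import ProjectiveTransform

from .codebook import Codebook, rotate_tag, validate_matrix

WHITE_QUAD_MODULES = 7   # the fitted quad spans 7x7 modules (code + white ring)


@dataclass(frozen=True)
class DetectorOptions:
    """Tunable knobs of the detection pipeline.

    threshold
        Global binarisation cutoff on normalised intensity, also used to
        binarise the sampled grid values.
    thresh_mode
        "global" or "adaptive" (local-mean/Bradley thresholding, robust to
        illumination gradients).
    min_area, max_area
        Size limits in px^2 for candidate white regions; ``max_area=None``
        means a quarter of the image area.
    adaptive_window, adaptive_sensitivity
        Window (odd, px) and relative sensitivity of the adaptive threshold:
        a pixel is white iff brighter than local_mean * (1 - sensitivity).
    fill_ratio_min, angle_tol_deg
        Rectangularity acceptance: region area / quad area and interior
        angle tolerance around 90 degrees.
    sample_neighborhood
        Odd side of the pixel neighbourhood averaged at each grid sample
        point.  The default 1 reads a separate single pixel value per grid
        point, as the original method does; 3 averages a 3x3 patch and is
        markedly more noise-robust.
    visualize
        When set, :func:`locate_codes` writes an annotated overlay.
    """
    threshold: float = 0.5
    thresh_mode: str = "global"
    min_area: int = 100
    max_area: int | None = None
    adaptive_window: int = 15
    adaptive_sensitivity: float = 0.1
    fill_ratio_min: float = 0.8
    angle_tol_deg: float = 30.0
    sample_neighborhood: int = 1
    visualize: str | Path | None = None

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.thresh_mode not in ("global", "adaptive"):
            raise ValueError(f"unknown thresh_mode {self.thresh_mode!r}")
        if self.min_area < 0 or (self.max_area is not None
                                 and self.max_area <= self.min_area):
            raise ValueError("need 0 <= min_area < max_area")
        if self.adaptive_window < 3 or self.adaptive_window % 2 == 0:
            raise ValueError("adaptive_window must be odd and >= 3")
        if self.sample_neighborhood < 1 or self.sample_neighborhood % 2 == 0:
            raise ValueError("sample_neighborhood must be odd and >= 1")


@dataclass(frozen=True)
class Detection:
    """One decoded tag in one frame."""
    id: int
    corners: np.ndarray          # (4, 2) float (x, y), clockwise from the
                                 # canonical top-left
    centroid: np.ndarray         # (2,) mean of the corners
    orientation_deg: float       # CCW rotation of the tag's canonical "up"
    frame_index: int = 0
    passed_threshold: float = 0.5
    margin: float = 0.0          # mean |sample - threshold|; decode quality


@dataclass(frozen=True)
class CandidateRegion:
    """A white connected component and its quadrilateral fit (or rejection)."""
    label: int
    area: int
    centroid: np.ndarray
    coords: np.ndarray           # (n, 2) pixel (row, col)
    corners: np.ndarray | None   # (4, 2) (x, y) or None when rejected
    reject_reason: str | None = None


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec.601 luminance of an RGB image, normalised to [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] not in (3, 4):
        raise ValueError(f"expected an RGB(A) image, got shape {image.shape}")
    img = image[..., :3].astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    return img @ np.array([0.299, 0.587, 0.114])


def as_gray(image: np.ndarray) -> np.ndarray:
    """Any input raster as normalised grayscale float."""
    image = np.asarray(image)
    if image.ndim == 3:
        return to_grayscale(image)
    img = image.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def binarize_global(gray: np.ndarray, threshold: float) -> np.ndarray:
    """White where intensity >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (np.asarray(gray) >= threshold)


def binarize_adaptive(gray: np.ndarray, window: int = 15,
                      sensitivity: float = 0.1) -> np.ndarray:
    """Local-mean (Bradley-style) thresholding.

    A pixel is white iff its intensity exceeds the mean of its
    ``window`` x ``window`` neighbourhood scaled by (1 - sensitivity).
    Insensitive to smooth illumination gradients that defeat any single
    global threshold.
    """
    gray = np.asarray(gray, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(gray.shape):
        raise ValueError(f"window {window} larger than image {gray.shape}")
    local_mean = uniform_filter(gray, size=window, mode="reflect")
    return gray > local_mean * (1.0 - sensitivity)


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _interior_angles(quad: np.ndarray) -> np.ndarray:
    angles = []
    for i in range(4):
        a, b, c = quad[i - 1], quad[i], quad[(i + 1) % 4]
        v1, v2 = a - b, c - b
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return np.array(angles)


def _best_quad_from_hull(hull_pts: np.ndarray) -> np.ndarray | None:
    """Reduce an ordered convex hull to the maximum-area 4-vertex subset.

    Any 4 vertices taken in hull order form a convex quadrilateral, and the
    area-maximising one hugs the true corners even when anti-aliasing
    rounds them off.  Very long hulls are first simplified (tolerance grown
    until tractable) to bound the combinatorial search.
    """
    n = len(hull_pts)
    if n < 4:
        return None
    if n == 4:
        return hull_pts
    tol = 0.3
    while n > 60:
        closed = np.vstack([hull_pts, hull_pts[:1]])
        approx = approximate_polygon(closed, tolerance=tol)[:-1]
        if len(approx) < 4:
            break
        hull_pts, n = approx, len(approx)
        tol *= 1.5
    if n < 4:
        return None
    if n == 4:
        return hull_pts
    x, y = hull_pts[:, 0], hull_pts[:, 1]
    cross = np.outer(x, y) - np.outer(y, x)        # cross[a, b]
    idx = np.array(list(itertools.combinations(range(n), 4)))
    a, b, c, d = idx.T
    areas = np.abs(cross[a, b] + cross[b, c] + cross[c, d] + cross[d, a])
    return hull_pts[idx[int(np.argmax(areas))]]


def fit_quad(coords: np.ndarray, area: int | None = None,
             fill_ratio_min: float = 0.8,
             angle_tol_deg: float = 30.0) -> tuple[np.ndarray | None, str | None]:
    """Fit a convex quadrilateral to a region's pixel set.

    ``coords`` are (row, col) pixel positions.  Returns (corners, None) on
    success — corners (x, y), clockwise as displayed, starting at the
    topmost-then-leftmost — or (None, reason) on rejection.  Acceptance
    requires region_area / quad_area >= ``fill_ratio_min`` and all interior
    angles within ``angle_tol_deg`` of 90 degrees.
    """
    coords = np.asarray(coords)
    if area is None:
        area = len(coords)
    pts = coords[:, ::-1].astype(float)          # (x, y)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None, "degenerate"
    hull_pts = pts[hull.vertices]                # CCW in (x, y) math coords
    quad = _best_quad_from_hull(hull_pts)
    if quad is None:
        return None, "no-quad"
    quad_area = _polygon_area(quad)
    if quad_area <= 0:
        return None, "degenerate"
    # the quad must essentially BE the hull: rounded shapes (e.g. disks)
    # leave a large hull fraction outside their best inscribed quad
    if quad_area < 0.9 * hull.volume:            # 2-D ConvexHull volume = area
        return None, f"hull-fit {quad_area / hull.volume:.2f}"
    fill = area / quad_area
    if fill < fill_ratio_min:
        return None, f"fill-ratio {fill:.2f}"
    angles = _interior_angles(quad)
    if np.any(np.abs(angles - 90.0) > angle_tol_deg):
        return None, f"angles {np.round(angles, 1)}"
    # math-CCW order is clockwise as displayed (y down); rotate start to
    # the topmost (then leftmost) corner for determinism
    start = np.lexsort((quad[:, 0], quad[:, 1]))[0]
    quad = np.roll(quad, -start, axis=0)
    return quad, None


def find_candidate_regions(binary: np.ndarray, min_area: int = 100,
                           max_area: int | None = None,
                           fill_ratio_min: float = 0.8,
                           angle_tol_deg: float = 30.0) -> list[CandidateRegion]:
    """8-connected white components within the area limits, with quad fits."""
    binary = np.asarray(binary).astype(bool)
    if max_area is None:
        max_area = binary.size // 4
    lab = label(binary, connectivity=2)
    out = []
    for rp in regionprops(lab):
        if not min_area <= rp.area <= max_area:
            continue
        # a tag's white component is a ring (border plus attached modules),
        # so rectangularity is judged on the hole-filled footprint
        corners, reason = fit_quad(rp.coords, int(rp.area_filled),
                                   fill_ratio_min, angle_tol_deg)
        out.append(CandidateRegion(rp.label, int(rp.area),
                                   np.array(rp.centroid[::-1]), rp.coords,
                                   corners, reason))
    return out


def _grid_transform(corners: np.ndarray) -> ProjectiveTransform:
    src = np.array([[0.0, 0.0], [WHITE_QUAD_MODULES, 0.0],
                    [WHITE_QUAD_MODULES, WHITE_QUAD_MODULES],
                    [0.0, WHITE_QUAD_MODULES]])
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, corners)
        if not tf:
            raise ValueError("could not estimate perspective transform")
        return tf
    tf = ProjectiveTransform()
    if not tf.estimate(src, corners):
        raise ValueError("could not estimate perspective transform")
    return tf


def _is_convex(quad: np.ndarray) -> bool:
    cross = []
    for i in range(4):
        a, b, c = quad[i], quad[(i + 1) % 4], quad[(i + 2) % 4]
        u, v = b - a, c - b
        cross.append(u[0] * v[1] - u[1] * v[0])
    cross = np.array(cross)
    return bool(np.all(cross > 0) or np.all(cross < 0))


def sample_code_grid(gray: np.ndarray, corners: np.ndarray, threshold: float,
                     neighborhood: int = 3) -> tuple[np.ndarray, float]:
    """Read the 5x5 code through a perspective map of the white quad.

    ``corners`` outline the white quad (a 7x7-module square).  Samples are
    taken at the centres of the central 5x5 cells; each sample is the mean
    of a ``neighborhood`` x ``neighborhood`` pixel patch, then binarised at
    ``threshold``.  Returns the matrix and the mean absolute margin of the
    samples from the threshold (a decode-quality measure).
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise ValueError("corners must be 4 (x, y) points")
    if not _is_convex(corners):
        raise ValueError("corners must describe a convex quadrilateral")
    tf = _grid_transform(corners)
    uv = np.array([[1.5 + j, 1.5 + i] for i in range(5) for j in range(5)])
    xy = tf(uv)                                    # (25, 2) image points
    half = neighborhood // 2
    offs = np.arange(-half, half + 1)
    ox, oy = np.meshgrid(offs, offs)
    xs = xy[:, 0][:, None] + ox.ravel()[None, :]
    ys = xy[:, 1][:, None] + oy.ravel()[None, :]
    # neighborhood 1 reads the raw pixel under each point; larger
    # neighbourhoods average bilinear reads around it
    order = 0 if neighborhood == 1 else 1
    vals = map_coordinates(np.asarray(gray, dtype=float), [ys.ravel(), xs.ravel()],
                           order=order, mode="nearest").reshape(25, -1).mean(axis=1)
    matrix = (vals >= threshold).astype(np.uint8).reshape(5, 5)
    margin = float(np.abs(vals - threshold).mean())
    return matrix, margin


def decode_candidate(matrix: np.ndarray,
                     codebook: Codebook) -> tuple[int, int] | None:
    """Decode a sampled 5x5 matrix against the codebook.

    Success requires the parity self-check AND codebook membership in
    exactly one of the four rotations; parity alone is not trusted because
    the codebook's Hamming filtering is the defence against misreads.
    Returns (id, k) with k the number of CCW quarter turns from the
    observed matrix to canonical, or None.
    """
    hits = []
    for k in range(4):
        rot = rotate_tag(matrix, k)
        v = validate_matrix(rot)
        if v.valid and v.orientation == 0 and v.id in codebook:
            hits.append((v.id, k))
    if len(hits) != 1:
        return None
    return hits[0]


def _orientation_from_corners(corners: np.ndarray) -> float:
    """CCW angle (deg) of the canonical top edge, 0 for an upright tag."""
    d = corners[1] - corners[0]
    return float(np.degrees(np.arctan2(-d[1], d[0])))


def locate_codes(image: np.ndarray | str | Path,
                 options: DetectorOptions | None = None,
                 codebook: Codebook | None = None,
                 frame_index: int = 0) -> list[Detection]:
    """Find and decode every tag in one image.

    Returns one Detection per decoded quad, ordered by centroid row then
    column.  An empty list is a normal outcome, not an error.
    """
    if codebook is None:
        raise ValueError("a codebook is required")
    options = options or DetectorOptions()
    if isinstance(image, (str, Path)):
        image = iio.imread(image)
    gray = as_gray(image)

    if options.thresh_mode == "adaptive":
        binary = binarize_adaptive(gray, options.adaptive_window,
                                   options.adaptive_sensitivity)
        sample_img, sample_thr = binary.astype(float), 0.5
    else:
        binary = binarize_global(gray, options.threshold)
        sample_img, sample_thr = gray, options.threshold

    regions = find_candidate_regions(binary, options.min_area,
                                     options.max_area,
                                     options.fill_ratio_min,
                                     options.angle_tol_deg)
    detections: list[Detection] = []
    for reg in regions:
        if reg.corners is None:
            continue
        try:
            matrix, margin = sample_code_grid(sample_img, reg.corners,
                                              sample_thr,
                                              options.sample_neighborhood)
        except ValueError:
            continue
        dec = decode_candidate(matrix, codebook)
        if dec is None:
            continue
        tag_id, k = dec
        # the sampled matrix needs k CCW quarter turns to reach canonical,
        # so the tag appears rotated k turns clockwise relative to the fit
        # corner order: the canonical top-left is k steps along the
        # clockwise corner list
        corners = np.roll(reg.corners, -k, axis=0)
        centroid = corners.mean(axis=0)
        detections.append(Detection(
            id=tag_id, corners=corners, centroid=centroid,
            orientation_deg=_orientation_from_corners(corners),
            frame_index=frame_index, passed_threshold=options.threshold,
            margin=margin))
    detections.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
    if options.visualize:
        save_overlay(gray, detections, options.visualize)
    return detections


def detections_to_table(detections: list[Detection]):
    """Detections as a pandas DataFrame in the CSV column layout."""
    import pandas as pd
    rows = []
    for d in detections:
        row = {"frame": d.frame_index, "id": d.id,
               "cx": d.centroid[0], "cy": d.centroid[1]}
        for i, (x, y) in enumerate(d.corners, start=1):
            row[f"x{i}"], row[f"y{i}"] = x, y
        row["orientation_deg"] = d.orientation_deg
        row["threshold"] = d.passed_threshold
        rows.append(row)
    cols = (["frame", "id", "cx", "cy"]
            + [c for i in range(1, 5) for c in (f"x{i}", f"y{i}")]
            + ["orientation_deg", "threshold"])
    return pd.DataFrame(rows, columns=cols)


def save_overlay(gray: np.ndarray, detections: list[Detection],
                 path: str | Path) -> None:
    """Write an annotated image: fitted quads, corner marks and id labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 8 * gray.shape[0] / gray.shape[1]))
    ax.imshow(gray, cmap="gray", vmin=0, vmax=1)
    for d in detections:
        closed = np.vstack([d.corners, d.corners[:1]])
        ax.plot(closed[:, 0], closed[:, 1], "-", color="lime", lw=1.5)
        ax.plot(d.corners[:, 0], d.corners[:, 1], "o", color="lime", ms=3)
        ax.text(d.centroid[0], d.centroid[1], str(d.id), color="red",
                ha="center", va="center", fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
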