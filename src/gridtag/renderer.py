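"""Synthetic tag rendering, scene composition and image degradation.

Every detector and tracker test in this package runs against images produced
here, so each scene carries exact ground truth: the identity, white-quad
corner coordinates and rotation angle of every tag placed.  A rendered tag is
a 9x9-module square: the 5x5 code matrix, a 1-module white border and a
1-module black outer border.  Intensities are normalised floats in [0, 1]
with 1 = white.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image, ImageDraw
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .codebook import Codebook, TagCode, assemble_tag

MODULES_PER_TAG = 9          # 5x5 code + white ring + black ring
WHITE_QUAD_MODULES = 7       # outer edge of the white border


def render_tag(code: TagCode | np.ndarray, px_per_module: int) -> np.ndarray:
    """Render one tag as a float image with values in {0.0, 1.0}.

    Parameters
    ----------
    code
        A TagCode, or a raw 5x5 binary matrix.
    px_per_module
        Side length in pixels of one module (one cell of the 9x9 grid).
    """
    if px_per_module < 1:
        raise ValueError(f"px_per_module must be >= 1, got {px_per_module}")
    matrix = code.matrix if isinstance(code, TagCode) else np.asarray(code)
    if matrix.shape != (5, 5):
        raise ValueError(f"expected a 5x5 matrix, got shape {matrix.shape}")
    tile = np.zeros((MODULES_PER_TAG, MODULES_PER_TAG), dtype=float)
    tile[1:8, 1:8] = 1.0                    # white border ring
    tile[2:7, 2:7] = matrix                 # code modules
    return np.kron(tile, np.ones((px_per_module, px_per_module)))


@dataclass(frozen=True)
class Placement:
    """Ground truth for one tag composited into a scene."""
    id: int
    corners: np.ndarray          # (4, 2) float, (x, y); white-quad outline,
                                 # clockwise from the canonical top-left
    angle_deg: float             # counter-clockwise rotation applied
    px_per_module: int

    @property
    def centroid(self) -> np.ndarray:
        return self.corners.mean(axis=0)

    def to_dict(self) -> dict:
        return {"id": self.id, "corners": self.corners.tolist(),
                "angle_deg": self.angle_deg, "px_per_module": self.px_per_module}

    @staticmethod
    def from_dict(d: dict) -> "Placement":
        return Placement(int(d["id"]), np.asarray(d["corners"], dtype=float),
                         float(d["angle_deg"]), int(d["px_per_module"]))


@dataclass
class SceneGroundTruth:
    """A synthetic frame plus the truth about every tag it contains."""
    image: np.ndarray
    placements: list[Placement] = field(default_factory=list)

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.placements]

    def scaled(self, factor: float) -> "SceneGroundTruth":
        """Ground truth with corner coordinates scaled by ``factor``.

        The image itself is not resampled here; pair with :func:`rescale`.
        """
        pls = [Placement(p.id, p.corners * factor, p.angle_deg, p.px_per_module)
               for p in self.placements]
        return SceneGroundTruth(self.image, pls)

    def save(self, image_path: str | Path) -> None:
        """Write the frame (8-bit PNG/TIFF) and ground truth JSON alongside."""
        image_path = Path(image_path)
        img8 = np.clip(np.round(self.image * 255), 0, 255).astype(np.uint8)
        iio.imwrite(image_path, img8)
        meta = {"placements": [p.to_dict() for p in self.placements]}
        image_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def load(image_path: str | Path) -> "SceneGroundTruth":
        image_path = Path(image_path)
        img = np.asarray(iio.imread(image_path), dtype=float) / 255.0
        meta = json.loads(image_path.with_suffix(".json").read_text())
        return SceneGroundTruth(img, [Placement.from_dict(d)
                                      for d in meta["placements"]])


def _local_white_quad_corners(px_per_module: int) -> np.ndarray:
    """White-quad corners (x, y) relative to the tag centre, angle 0.

    Order: top-left, top-right, bottom-right, bottom-left (clockwise as
    displayed, y pointing down).
    """
    p = px_per_module
    half = MODULES_PER_TAG * p / 2.0
    lo, hi = 1 * p, (MODULES_PER_TAG - 1) * p
    return np.array([[lo, lo], [hi, lo], [hi, hi], [lo, hi]], dtype=float) - half


def _rotate_offsets(offsets: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate (x, y) offsets counter-clockwise as displayed (y down)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y = offsets[:, 0], offsets[:, 1]
    return np.stack([c * x + s * y, -s * x + c * y], axis=1)


def compose_scene(codebook: Codebook,
                  ids,
                  positions,
                  angles=None,
                  px_per_module: int = 6,
                  background: float | np.ndarray = 0.5,
                  shape: tuple[int, int] | None = None) -> SceneGroundTruth:
    """Paste rendered tags onto a background and record exact ground truth.

    Parameters
    ----------
    codebook
        Source of tag bit matrices; every id must be a member.
    ids, positions, angles
        Per-tag identity, (x, y) centre in pixels, and counter-clockwise
        rotation in degrees (0 for all if omitted).
    background
        Constant intensity or a 2-D float image in [0, 1].
    shape
        (height, width) when ``background`` is a constant.

    Tags may not overlap; overlapping bounding boxes raise ``ValueError``.
    """
    ids = list(ids)
    positions = [np.asarray(p, dtype=float) for p in positions]
    angles = [0.0] * len(ids) if angles is None else [float(a) for a in angles]
    if not (len(ids) == len(positions) == len(angles)):
        raise ValueError("ids, positions and angles must have equal length")

    if np.isscalar(background):
        if shape is None:
            raise ValueError("shape is required with a constant background")
        image = np.full(shape, float(background), dtype=float)
    else:
        image = np.array(background, dtype=float)
    h, w = image.shape

    placements: list[Placement] = []
    boxes: list[tuple[int, int, int, int]] = []
    for tag_id, pos, ang in zip(ids, positions, angles):
        code = codebook[tag_id]
        patch = render_tag(code, px_per_module)
        alpha = np.ones_like(patch)
        if ang % 360 != 0.0:
            patch = _sk_rotate(patch, ang, resize=True, order=1, cval=0.0)
            alpha = _sk_rotate(alpha, ang, resize=True, order=1, cval=0.0)
        ph, pw = patch.shape
        top = int(round(pos[1] - ph / 2.0))
        left = int(round(pos[0] - pw / 2.0))
        if top < 0 or left < 0 or top + ph > h or left + pw > w:
            raise ValueError(f"tag id {tag_id} does not fit inside the image")
        box = (top, left, top + ph, left + pw)
        for other in boxes:
            if not (box[2] <= other[0] or other[2] <= box[0]
                    or box[3] <= other[1] or other[3] <= box[1]):
                raise ValueError("overlapping tag placements are not supported")
        boxes.append(box)
        region = image[top:top + ph, left:left + pw]
        image[top:top + ph, left:left + pw] = region * (1 - alpha) + patch * alpha

        centre = np.array([left + pw / 2.0, top + ph / 2.0])
        corners = centre + _rotate_offsets(
            _local_white_quad_corners(px_per_module), ang)
        placements.append(Placement(tag_id, corners, ang, px_per_module))
    return SceneGroundTruth(image, placements)


def add_gaussian_noise(image: np.ndarray, variance: float,
                       seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise and clip to [0, 1].

    ``variance`` is expressed on the normalised 0..1 intensity scale, e.g.
    0.05 means a noise variance of 5% of the full intensity range.
    """
    if variance < 0:
        raise ValueError(f"variance must be >= 0, got {variance}")
    if variance == 0:
        return np.array(image, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = image + rng.normal(0.0, np.sqrt(variance), size=image.shape)
    return np.clip(noisy, 0.0, 1.0)


def rescale(image: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear resampling to round(factor x original) dimensions."""
    if factor <= 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    if factor == 1.0:
        return np.array(image, dtype=float)
    out_shape = (max(1, round(image.shape[0] * factor)),
                 max(1, round(image.shape[1] * factor)))
    return _sk_resize(image, out_shape, order=1, anti_aliasing=factor < 1,
                      preserve_range=True).astype(float)


def render_print_sheet(codes,
                       tag_mm: float = 2.1,
                       dpi: int = 1200,
                       page_mm: tuple[float, float] = (215.9, 279.4),
                       margin_mm: float = 8.0) -> np.ndarray:
    """Lay out tags with id labels on a printable page; returns 8-bit grayscale.

    The tag square is ``round(tag_mm / 25.4 * dpi)`` pixels; the grid pitch
    leaves room for a label strip beside each tag.  Raises ``ValueError``
    naming the page capacity when the requested tags do not fit.
    """
    codes = list(codes)
    tag_px = int(round(tag_mm / 25.4 * dpi))
    ppm = max(1, int(round(tag_px / MODULES_PER_TAG)))
    page_w = int(round(page_mm[0] / 25.4 * dpi))
    page_h = int(round(page_mm[1] / 25.4 * dpi))
    margin = int(round(margin_mm / 25.4 * dpi))
    render_px = ppm * MODULES_PER_TAG
    label_w = render_px  # label strip to the right of each tag
    pitch_x = render_px + label_w + ppm * 2
    pitch_y = render_px + ppm * 2
    ncols = max(0, (page_w - 2 * margin) // pitch_x)
    nrows = max(0, (page_h - 2 * margin) // pitch_y)
    capacity = ncols * nrows
    if len(codes) > capacity:
        raise ValueError(
            f"{len(codes)} tags do not fit: page holds at most {capacity} "
            f"at {tag_mm} mm and {dpi} dpi")

    sheet = Image.new("L", (page_w, page_h), color=255)
    draw = ImageDraw.Draw(sheet)
    for i, code in enumerate(codes):
        code = code if isinstance(code, TagCode) else assemble_tag(int(code))
        r, c = divmod(i, ncols)
        x0 = margin + c * pitch_x
        y0 = margin + r * pitch_y
        patch = (render_tag(code, ppm) * 255).astype(np.uint8)
        sheet.paste(Image.fromarray(patch), (x0, y0))
        draw.text((x0 + render_px + ppm, y0 + render_px // 2 - 5),
                  str(code.id), fill=0)
    return np.asarray(sheet)
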