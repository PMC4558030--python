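"""Standard synthetic scenes for benchmarking and acceptance runs.

These factories define the package's reference study conditions: a grid of
12 tags per frame (mirroring a printed-tag test card filmed from a moving
viewpoint), with per-frame jitter in position and orientation, and a
gradient-lit variant whose illumination spans enough of the intensity range
to defeat extreme global thresholds while leaving an interior optimum.
"""
from __future__ import annotations

import numpy as np

from .codebook import Codebook
from .renderer import SceneGroundTruth, compose_scene


def _grid_positions(n_tags: int, pitch: int, margin: int):
    ncols = int(np.ceil(np.sqrt(n_tags)))
    return [(margin + pitch * (i % ncols), margin + pitch * (i // ncols))
            for i in range(n_tags)], ncols


def default_sweep_frames(codebook: Codebook,
                         n_frames: int = 10,
                         n_tags: int = 12,
                         seed: int = 0,
                         px_per_module: int = 6,
                         background: float = 0.5) -> list[SceneGroundTruth]:
    """Frames of ``n_tags`` jittered, randomly oriented tags on a flat field.

    Tag identities are drawn once per sequence; positions and angles are
    re-drawn each frame (seeded), emulating a hand-held viewpoint.
    """
    rng = np.random.default_rng([int(seed), 101])
    ids = sorted(rng.choice(codebook.ids, size=n_tags, replace=False).tolist())
    tag_px = 9 * px_per_module
    pitch = int(np.ceil(tag_px * 1.55)) + 4   # room for any rotation
    margin = pitch // 2 + tag_px
    base, ncols = _grid_positions(n_tags, pitch, margin)
    nrows = int(np.ceil(n_tags / ncols))
    shape = (margin + pitch * (nrows - 1) + margin,
             margin + pitch * (ncols - 1) + margin)
    jitter = max(1, int(round(pitch * 0.04)))
    frames = []
    for f in range(n_frames):
        frng = np.random.default_rng([int(seed), 202, f])
        positions = [(x + frng.integers(-jitter, jitter + 1),
                      y + frng.integers(-jitter, jitter + 1))
                     for x, y in base]
        angles = frng.uniform(0, 360, size=n_tags)
        frames.append(compose_scene(codebook, ids, positions, angles,
                                    px_per_module, background, shape))
    return frames


def gradient_lit_frames(codebook: Codebook,
                        n_frames: int = 10,
                        n_tags: int = 12,
                        seed: int = 0,
                        px_per_module: int = 6,
                        ambient_range: tuple[float, float] = (0.10, 0.50),
                        contrast: float = 0.45) -> list[SceneGroundTruth]:
    """The default frames under a horizontal illumination gradient.

    Pixel intensity becomes ``albedo * contrast + ambient(x)`` with ambient
    rising linearly across the width: black modules span
    ``ambient_range`` and white modules ``contrast + ambient_range``, so a
    global threshold near the middle separates them everywhere while
    thresholds at either extreme misclassify one side of the image.
    Ground-truth geometry is unchanged.
    """
    frames = default_sweep_frames(codebook, n_frames, n_tags, seed,
                                  px_per_module, background=0.3)
    lo, hi = ambient_range
    out = []
    for scene in frames:
        h, w = scene.image.shape
        ambient = np.linspace(lo, hi, w)[None, :]
        lit = np.clip(scene.image * contrast + ambient, 0.0, 1.0)
        out.append(SceneGroundTruth(lit, scene.placements))
    return out
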