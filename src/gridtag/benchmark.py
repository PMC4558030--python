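"""Detection-performance characterisation on synthetic ground-truth scenes.

Three stressors are swept: image resolution, additive Gaussian noise and
the global binarisation threshold.  Every fraction is computed against the
scene's ground truth, never against detector self-report: a tag counts as
correctly tracked in a frame iff its identity is detected AND the detected
centroid falls inside the true white-quad outline.  Any detection that
fails that test is a false positive.

Also provided: the count-based estimator of the false-positive
identification rate used when ground truth is only partial — detections
whose identity falls outside the known-present set are certain false
positives, and their count is scaled up by the probability that a spurious
but valid code would land outside the known set.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .codebook import Codebook
from .detector import Detection, DetectorOptions, locate_codes
from .renderer import SceneGroundTruth, rescale


def quad_area(corners: np.ndarray) -> float:
    """Shoelace area of a quadrilateral given (4, 2) corners."""
    pts = np.asarray(corners, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def effective_tag_resolution(quads) -> float:
    """Functional resolution in px per tag edge: sqrt of the mean quad area.

    ``quads`` is a sequence of (4, 2) corner arrays (ground-truth
    placements or detections).
    """
    quads = list(quads)
    if not quads:
        raise ValueError("at least one quad is required")
    areas = [quad_area(q) for q in quads]
    return float(np.sqrt(np.mean(areas)))


@dataclass
class SweepResult:
    """Per-frame tracking fractions across the levels of one sweep axis."""
    axis: str
    levels: list[float]
    fractions: np.ndarray          # (n_frames, n_levels) in [0, 1]
    false_positives: np.ndarray    # (n_frames, n_levels) counts
    extra: dict = field(default_factory=dict)   # e.g. px_per_edge, recovery

    @property
    def mean_fraction(self) -> np.ndarray:
        return self.fractions.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, level, fraction, false_positives."""
        rows = []
        for f in range(self.fractions.shape[0]):
            for j, lev in enumerate(self.levels):
                rows.append({"frame": f, "level": lev,
                             "fraction": self.fractions[f, j],
                             "false_positives": int(self.false_positives[f, j])})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Per-frame curves (transparent blue) and their mean (red)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        x = self.extra.get("px_per_edge", self.levels)
        fig, ax = plt.subplots(figsize=(5, 4))
        for row in self.fractions:
            ax.plot(x, row, color="tab:blue", alpha=0.15, lw=1)
        ax.plot(x, self.mean_fraction, color="tab:red", lw=2.5)
        xlabel = {"resolution": "functional resolution (px per tag edge)",
                  "noise": "Gaussian noise variance",
                  "threshold": "binarisation threshold"}.get(self.axis, self.axis)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("fraction of tags tracked")
        ax.set_ylim(-0.02, 1.02)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _score_frame(scene: SceneGroundTruth,
                 detections: list[Detection],
                 corner_scale: float = 1.0) -> tuple[float, int]:
    """(fraction of ground-truth tags tracked, false-positive count)."""
    paths = {p.id: MplPath(p.corners * corner_scale) for p in scene.placements}
    tracked = set()
    n_fp = 0
    for d in detections:
        path = paths.get(d.id)
        if path is not None and path.contains_point(d.centroid, radius=1e-6):
            tracked.add(d.id)
        else:
            n_fp += 1
    frac = len(tracked) / len(paths) if paths else 0.0
    return frac, n_fp


def _tracked_ids(scene: SceneGroundTruth, detections: list[Detection],
                 corner_scale: float = 1.0) -> set[int]:
    paths = {p.id: MplPath(p.corners * corner_scale) for p in scene.placements}
    return {d.id for d in detections
            if d.id in paths and paths[d.id].contains_point(d.centroid, radius=1e-6)}


def resolution_sweep(frames: list[SceneGroundTruth],
                     scale_factors,
                     options: DetectorOptions | None = None,
                     codebook: Codebook | None = None) -> SweepResult:
    """Detection fraction vs image resolution.

    Each frame is bilinearly rescaled by every factor (factors whose output
    would fall below 20 px on a side are skipped with a warning) and
    re-detected; the per-level functional resolution is measured from the
    scaled ground-truth quads.
    """
    import warnings
    factors = []
    for f in scale_factors:
        shapes = [(round(s.image.shape[0] * f), round(s.image.shape[1] * f))
                  for s in frames]
        if min(min(sh) for sh in shapes) < 20:
            warnings.warn(f"scale factor {f} skipped: image below 20 px")
            continue
        factors.append(float(f))
    fractions = np.zeros((len(frames), len(factors)))
    fps = np.zeros((len(frames), len(factors)), dtype=int)
    px_per_edge = np.zeros(len(factors))
    for j, f in enumerate(factors):
        quads = []
        for i, scene in enumerate(frames):
            img = rescale(scene.image, f)
            dets = locate_codes(img, options, codebook, frame_index=i)
            fractions[i, j], fps[i, j] = _score_frame(scene, dets, corner_scale=f)
            quads += [p.corners * f for p in scene.placements]
        px_per_edge[j] = effective_tag_resolution(quads)
    return SweepResult("resolution", factors, fractions, fps,
                       {"px_per_edge": px_per_edge})


def noise_sweep(frames: list[SceneGroundTruth],
                variances,
                options: DetectorOptions | None = None,
                codebook: Codebook | None = None,
                seed: int = 0) -> SweepResult:
    """Detection fraction vs additive Gaussian noise variance.

    One standard-normal noise field is drawn per frame (seeded) and scaled
    by sqrt(variance) at every level — common random numbers across levels,
    so the degradation curve is not blurred by independent sampling noise.
    The sweep is reproducible bit-exactly for a fixed ``seed``.
    """
    variances = [float(v) for v in variances]
    if any(v < 0 for v in variances):
        raise ValueError("variances must be >= 0")
    fractions = np.zeros((len(frames), len(variances)))
    fps = np.zeros((len(frames), len(variances)), dtype=int)
    for i, scene in enumerate(frames):
        rng = np.random.default_rng([int(seed), i])
        field = rng.standard_normal(scene.image.shape)
        for j, var in enumerate(variances):
            img = np.clip(scene.image + np.sqrt(var) * field, 0.0, 1.0)
            dets = locate_codes(img, options, codebook, frame_index=i)
            fractions[i, j], fps[i, j] = _score_frame(scene, dets)
    return SweepResult("noise", variances, fractions, fps)


def threshold_sweep(frames: list[SceneGroundTruth],
                    thresholds,
                    options: DetectorOptions | None = None,
                    codebook: Codebook | None = None) -> SweepResult:
    """Detection fraction vs global binarisation threshold.

    Also computes, per frame, the recoverable-tag set (union of correctly
    tracked tags across all thresholds) and each threshold's mean recovery
    fraction of that union (``extra["recovery"]``).
    """
    thresholds = [float(t) for t in thresholds]
    options = options or DetectorOptions()
    fractions = np.zeros((len(frames), len(thresholds)))
    fps = np.zeros((len(frames), len(thresholds)), dtype=int)
    tracked: list[list[set[int]]] = [[set() for _ in thresholds] for _ in frames]
    from dataclasses import replace
    for j, thr in enumerate(thresholds):
        opt = replace(options, threshold=thr, thresh_mode="global")
        for i, scene in enumerate(frames):
            dets = locate_codes(scene.image, opt, codebook, frame_index=i)
            fractions[i, j], fps[i, j] = _score_frame(scene, dets)
            tracked[i][j] = _tracked_ids(scene, dets)
    recovery = np.zeros((len(frames), len(thresholds)))
    recoverable_sizes = []
    for i in range(len(frames)):
        union = set().union(*tracked[i]) if tracked[i] else set()
        recoverable_sizes.append(len(union))
        for j in range(len(thresholds)):
            recovery[i, j] = (len(tracked[i][j] & union) / len(union)
                              if union else 0.0)
    return SweepResult("threshold", thresholds, fractions, fps,
                       {"recovery": recovery.mean(axis=0),
                        "recoverable_per_frame": recoverable_sizes})


def estimate_false_positive_rate(n_detections: int,
                                 n_out_of_set: int,
                                 n_known_ids: int,
                                 n_valid_codes: int) -> tuple[float, float]:
    """Estimate the false-positive identification rate from partial truth.

    Detections decoding to identities outside the known-present set are
    certain false positives.  A spurious decode that happens to be a valid
    code lands outside the known set with probability
    (n_valid_codes - n_known_ids) / n_valid_codes, so the observed
    out-of-set count is scaled by the reciprocal:

        estimated_total_fp = n_out_of_set * n_valid_codes
                             / (n_valid_codes - n_known_ids)

    Returns (fp_rate, correct_rate) as fractions of ``n_detections``.
    With ``n_known_ids=0`` the scaling is 1 and the result is the raw,
    uncorrected rate.
    """
    if n_detections <= 0:
        raise ValueError("n_detections must be positive")
    if not 0 <= n_out_of_set <= n_detections:
        raise ValueError("need 0 <= n_out_of_set <= n_detections")
    if n_known_ids >= n_valid_codes:
        raise ValueError("scaling undefined: n_known_ids >= n_valid_codes")
    est_fp = n_out_of_set * n_valid_codes / (n_valid_codes - n_known_ids)
    fp_rate = est_fp / n_detections
    return fp_rate, 1.0 - fp_rate
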