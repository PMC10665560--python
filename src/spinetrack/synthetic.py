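"""Synthetic two-photon stacks with known spine ground truth.

The generator emulates the statistics of in-vivo two-photon stacks of
sparsely GFP-labeled dendrites: 512x512 slices at 0.1 um/px, 0.5 um z-steps,
5-68 slices per stack, spine areas mostly 100-700 px (hard max 1300 px), and
8-bit intensities saturating at 255 inside dendrites and spine heads.

Each dendrite is a smooth random curve drawn as a tube with a Gaussian
cross-section whose core saturates at the clip value.  Spines are blurred
ellipses attached at random arc positions, offset from the shaft, visible
over a contiguous z-extent with intensity peaking at the central slice.
Ground truth is exact: one 3D track per spine whose per-slice box is the
tight bounding box of the rendered spine mask (shaft pixels excluded).

By default spines are *separated* protrusions (their mask keeps >= 2 px
clearance from the shaft and their boxes are pairwise disjoint), the regime
in which detection and tracking are well posed; ``attached=True`` allows
spines to touch the shaft, the known hard case.

A second half of the module simulates annotator variability: boxes jittered
per slice, whole spines dropped, spurious boxes added — enough to exercise
the consensus machinery without real expert labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .types import AnnotationSet, Box2D, Detection2D, ImageStack, SpineTrack3D

__all__ = [
    "SimulationParams",
    "PerturbationParams",
    "simulate_stack",
    "perturb_annotations",
    "make_annotator_panel",
    "ground_truth_detections",
    "ground_truth_annotations",
]


@dataclass(frozen=True)
class SimulationParams:
    """Stack-generation parameters; defaults mirror the main dataset."""

    image_size: int = 512
    pixel_size_um: float = 0.1
    z_step_um: float = 0.5
    n_slices: int | None = None  # sampled uniformly from n_slices_range if None
    n_slices_range: tuple[int, int] = (5, 68)
    n_dendrites: int = 2
    n_spines: int = 15
    spine_area_px: tuple[float, float] = (100.0, 700.0)
    spine_area_hard_max: float = 1300.0
    spine_z_extent: tuple[int, int] = (2, 7)  # slices
    dendrite_width_px: float = 8.0
    background_noise_sigma: float = 8.0
    intensity_clip: float = 255.0
    spine_shaft_gap_px: float = 2.0
    attached: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.n_dendrites < 0 or self.n_spines < 0:
            raise ValueError("sizes and counts must be non-negative")
        lo, hi = self.spine_area_px
        if not (0 < lo <= hi <= self.spine_area_hard_max):
            raise ValueError("spine area range must lie within (0, hard max]")
        if self.intensity_clip <= 0:
            raise ValueError("intensity_clip must be positive")


@dataclass(frozen=True)
class PerturbationParams:
    """Simulated-annotator noise model."""

    corner_jitter_sigma_px: float = 1.0
    drop_probability: float = 0.0
    spurious_rate_per_slice: float = 0.0
    z_extent_jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.drop_probability <= 1.0):
            raise ValueError("drop_probability must be in [0, 1]")
        if min(self.corner_jitter_sigma_px, self.spurious_rate_per_slice,
               self.z_extent_jitter_sigma) < 0:
            raise ValueError("sigmas and rates must be >= 0")


# ---------------------------------------------------------------------------
# rendering


def _render_dendrites(
    rng: np.random.Generator, size: int, n_dendrites: int, width_px: float, clip: float
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Render all dendrites once (they are constant across depth).

    Returns (image, shaft mask, list of dense centerline point arrays).
    """
    canvas = np.zeros((size, size), dtype=float)
    centerlines: list[np.ndarray] = []
    t = np.linspace(0.0, 1.0, 4 * size)
    for _ in range(n_dendrites):
        horizontal = rng.random() < 0.5
        offset = rng.uniform(0.15, 0.85) * size
        amp = rng.uniform(0.05, 0.18) * size
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        along = t * (size - 1)
        across = offset + amp * np.sin(2.0 * math.pi * freq * t + phase)
        across = np.clip(across, 0, size - 1)
        if horizontal:
            xs, ys = along, across
        else:
            xs, ys = across, along
        centerlines.append(np.stack([xs, ys], axis=1))
        canvas[np.round(ys).astype(int), np.round(xs).astype(int)] = 1.0
    sigma = max(width_px / 2.355, 0.8)  # FWHM ~ tube width
    tube = ndimage.gaussian_filter(canvas, sigma)
    if tube.max() > 0:
        tube = tube / tube.max()
    # scale so the core saturates once clipped at `clip`
    img = np.minimum(1.6 * clip * tube, clip)
    shaft_mask = img > 0.25 * clip
    return img, shaft_mask, centerlines


def _ellipse_mask_and_box(
    cx: float, cy: float, a: float, b: float, theta: float, size: int
) -> tuple[np.ndarray, tuple[int, int], Box2D] | None:
    """Rasterize an ellipse; return (local mask, patch origin, tight box)."""
    ex = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    ey = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    x0, x1 = int(math.floor(cx - ex)) - 2, int(math.ceil(cx + ex)) + 2
    y0, y1 = int(math.floor(cy - ey)) - 2, int(math.ceil(cy + ey)) + 2
    if x0 < 0 or y0 < 0 or x1 >= size or y1 >= size:
        return None
    xs = np.arange(x0, x1 + 1) + 0.5
    ys = np.arange(y0, y1 + 1) + 0.5
    gx, gy = np.meshgrid(xs - cx, ys - cy)
    u = gx * math.cos(theta) + gy * math.sin(theta)
    v = -gx * math.sin(theta) + gy * math.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = Box2D(
        float(x0 + cols[0]),
        float(y0 + rows[0]),
        float(x0 + cols[-1] + 1),
        float(y0 + rows[-1] + 1),
    )
    return mask, (y0, x0), box


def _boxes_disjoint(b1: Box2D, b2: Box2D, margin: float) -> bool:
    return (
        b1.x_max + margin <= b2.x_min
        or b2.x_max + margin <= b1.x_min
        or b1.y_max + margin <= b2.y_min
        or b2.y_max + margin <= b1.y_min
    )


@dataclass
class _Spine:
    mask: np.ndarray
    origin: tuple[int, int]
    box: Box2D
    z_first: int
    z_second: int
    peak_intensity: float
    target_area: float


def simulate_stack(
    params: SimulationParams | None = None,
) -> tuple[ImageStack, list[SpineTrack3D]]:
    """Render a stack and return it with its exact 3D ground-truth tracks.

    Deterministic under ``params.seed``.  Raises if the requested number of
    spines cannot be placed (infeasible geometry).
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)
    size = p.image_size
    n_slices = (
        p.n_slices
        if p.n_slices is not None
        else int(rng.integers(p.n_slices_range[0], p.n_slices_range[1] + 1))
    )
    dendrite_img, shaft_mask, centerlines = _render_dendrites(
        rng, size, p.n_dendrites, p.dendrite_width_px, p.intensity_clip
    )
    if p.attached:
        clearance = shaft_mask
    else:
        clearance = ndimage.binary_dilation(
            shaft_mask, iterations=max(int(round(p.spine_shaft_gap_px)), 1)
        )

    spines: list[_Spine] = []
    attempts = 0
    max_attempts = 300 * max(p.n_spines, 1)
    while len(spines) < p.n_spines:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"infeasible geometry: placed {len(spines)} of {p.n_spines} "
                f"spines in {max_attempts} attempts"
            )
        area = rng.uniform(*p.spine_area_px)
        q = rng.uniform(0.6, 1.6)  # axis ratio
        a = math.sqrt(area * q / math.pi)
        b = math.sqrt(area / (q * math.pi))
        theta = rng.uniform(0.0, math.pi)
        if centerlines:
            line = centerlines[int(rng.integers(len(centerlines)))]
            i = int(rng.integers(1, len(line) - 1))
            point = line[i]
            tangent = line[i + 1] - line[i - 1]
            norm = np.array([-tangent[1], tangent[0]])
            norm = norm / (np.linalg.norm(norm) + 1e-12)
            side = 1.0 if rng.random() < 0.5 else -1.0
            gap = 0.0 if p.attached else p.spine_shaft_gap_px
            dist = p.dendrite_width_px / 2 + gap + max(a, b)
            cx, cy = point + side * dist * norm
        else:
            cx, cy = rng.uniform(0.1 * size, 0.9 * size, size=2)
        res = _ellipse_mask_and_box(cx, cy, a, b, theta, size)
        if res is None:
            continue
        mask, origin, box = res
        y0, x0 = origin
        h, w = mask.shape
        if not p.attached and clearance[y0 : y0 + h, x0 : x0 + w][mask].any():
            continue
        if any(not _boxes_disjoint(box, s.box, margin=3.0) for s in spines):
            continue
        z_lo, z_hi = p.spine_z_extent
        length = int(rng.integers(z_lo, z_hi + 1))
        length = min(length, n_slices)
        z1 = int(rng.integers(0, n_slices - length + 1))
        spines.append(
            _Spine(
                mask=mask,
                origin=origin,
                box=box,
                z_first=z1,
                z_second=z1 + length - 1,
                peak_intensity=rng.uniform(0.75, 1.1) * p.intensity_clip,
                target_area=area,
            )
        )

    # per-spine z intensity profile: peaks at the central slice, floored so
    # the spine stays visible over its whole extent
    slices = []
    noise = rng.normal(0.0, p.background_noise_sigma, size=(n_slices, size, size))
    for z in range(n_slices):
        img = dendrite_img + noise[z]
        for s in spines:
            if not (s.z_first <= z <= s.z_second):
                continue
            zc = 0.5 * (s.z_first + s.z_second)
            sig = max((s.z_second - s.z_first + 1) / 4.0, 0.8)
            w_z = 0.4 + 0.6 * math.exp(-((z - zc) ** 2) / (2.0 * sig * sig))
            patch = ndimage.gaussian_filter(
                s.mask.astype(float) * s.peak_intensity * w_z, 1.0
            )
            y0, x0 = s.origin
            h, wdt = s.mask.shape
            img[y0 : y0 + h, x0 : x0 + wdt] += patch
        slices.append(np.clip(img, 0.0, p.intensity_clip))

    tracks = []
    for i, s in enumerate(spines):
        t = SpineTrack3D.from_boxes(
            spine_id=i,
            boxes_by_slice={z: s.box for z in range(s.z_first, s.z_second + 1)},
            confidence=1.0,
        )
        # sampled target area, exposed for rendering-fidelity checks
        t.target_area_px = float(s.target_area)
        tracks.append(t)
    stack = ImageStack(
        slices=slices, pixel_size_um=p.pixel_size_um, z_step_um=p.z_step_um
    )
    return stack, tracks


# ---------------------------------------------------------------------------
# ground-truth plumbing and simulated annotators


def ground_truth_detections(
    tracks: Sequence[SpineTrack3D], confidence: float = 1.0
) -> list[Detection2D]:
    """Flatten ground-truth tracks into per-slice detections."""
    return [
        Detection2D(box=t.boxes_by_slice[z], slice_index=z, confidence=confidence)
        for t in tracks
        for z in range(t.z_first, t.z_second + 1)
    ]


def ground_truth_annotations(
    tracks: Sequence[SpineTrack3D], annotator_id: str = "ground_truth"
) -> AnnotationSet:
    """Flatten ground-truth tracks into an annotation set."""
    boxes = [
        (z, t.boxes_by_slice[z])
        for t in tracks
        for z in range(t.z_first, t.z_second + 1)
    ]
    return AnnotationSet(annotator_id=annotator_id, boxes=boxes)


def _repair_interval(lo: float, hi: float, minimum: float = 1.0) -> tuple[float, float]:
    if hi - lo >= minimum:
        return lo, hi
    mid = 0.5 * (lo + hi)
    return mid - minimum / 2, mid + minimum / 2


def perturb_annotations(
    gts: Sequence[SpineTrack3D],
    pparams: PerturbationParams,
    depth: int | None = None,
    image_size: int = 512,
    annotator_id: str = "simulated",
) -> AnnotationSet:
    """Simulate one annotator labeling the stack.

    Per spine: dropped entirely with ``drop_probability``; otherwise its
    z-endpoints are jittered and on each covered slice the four box corners
    receive independent Gaussian jitter.  Spurious boxes are added per slice
    at the configured Poisson rate.  All random draws are generated as unit
    variates scaled by the sigmas, so two runs with the same seed and
    different sigmas perturb the *same* underlying sample.
    """
    rng = np.random.default_rng(pparams.seed)
    if depth is None:
        depth = 1 + max((t.z_second for t in gts), default=0)
    boxes: list[tuple[int, Box2D]] = []
    for t in sorted(gts, key=lambda t: t.spine_id):
        u_drop = rng.random()
        eps_z = rng.standard_normal(2)
        if u_drop < pparams.drop_probability:
            continue
        z1 = t.z_first + int(round(pparams.z_extent_jitter_sigma * eps_z[0]))
        z2 = t.z_second + int(round(pparams.z_extent_jitter_sigma * eps_z[1]))
        z1, z2 = max(0, min(z1, z2)), min(depth - 1, max(z1, z2))
        for z in range(z1, z2 + 1):
            src = min(max(z, t.z_first), t.z_second)
            b = t.boxes_by_slice[src]
            eps = rng.standard_normal(4)
            s = pparams.corner_jitter_sigma_px
            x_lo, x_hi = _repair_interval(
                max(0.0, b.x_min + s * eps[0]), max(0.0, b.x_max + s * eps[1])
            )
            y_lo, y_hi = _repair_interval(
                max(0.0, b.y_min + s * eps[2]), max(0.0, b.y_max + s * eps[3])
            )
            boxes.append((z, Box2D(max(0.0, x_lo), max(0.0, y_lo), x_hi, y_hi)))
    if pparams.spurious_rate_per_slice > 0:
        for z in range(depth):
            for _ in range(int(rng.poisson(pparams.spurious_rate_per_slice))):
                side_x = rng.uniform(8.0, 28.0)
                side_y = rng.uniform(8.0, 28.0)
                x0 = rng.uniform(0.0, image_size - side_x)
                y0 = rng.uniform(0.0, image_size - side_y)
                boxes.append((z, Box2D(x0, y0, x0 + side_x, y0 + side_y)))
    return AnnotationSet(annotator_id=annotator_id, boxes=boxes)


def make_annotator_panel(
    gts: Sequence[SpineTrack3D],
    k_annotators: int,
    pparams: Sequence[PerturbationParams],
    depth: int | None = None,
    image_size: int = 512,
) -> list[AnnotationSet]:
    """k independent simulated annotators over the same ground truth."""
    if len(pparams) != k_annotators:
        raise ValueError(
            f"need one PerturbationParams per annotator: {k_annotators} != {len(pparams)}"
        )
    return [
        perturb_annotations(
            gts, pp, depth=depth, image_size=image_size, annotator_id=f"annotator_{i}"
        )
        for i, pp in enumerate(pparams)
    ]
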