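"""Synthetic CAM-like images and dose-response tables with exact ground truth.

The vascular generator grows a branching random walk: root vessels enter the
field from its edges and split with a per-step probability, each generation
halving in width down to a capillary floor. This reproduces the two-calibre
structure the analysis pipeline must separate — thick pre-existing feeder
vessels (> 15 um) and the thin capillary bed (<= 15 um) whose area is the
drug readout. The renderer rasterizes the tree as dark capsules on a bright
background with a linear illumination ramp, Gaussian sensor noise and salt
speckle, and returns the exact vessel raster, the thin-vessel raster and the
ground-truth branch points alongside the image. Everything is deterministic
for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pharmacology import DoseResponseData, HillFit, hill_curve
from .preprocess import CalibratedImage
from .segmentation import BinaryMask

__all__ = [
    "VesselTreeSpec",
    "RenderSpec",
    "VesselSegment",
    "VesselTree",
    "generate_vessel_tree",
    "render",
    "generate_dose_response",
]

# Physical diameter separating capillaries from feeder vessels in the truth
# masks; matches the analysis pipeline's thin-vessel cutoff.
THIN_VESSEL_CUTOFF_UM = 15.0

# Half-angle between daughter branches at a bifurcation (radians). Wide
# enough that sibling branches separate cleanly instead of re-merging.
_BRANCH_HALF_ANGLE = 0.55

# Steps per unbranched run before the vessel ends as a blind sprout.
# Capillary segments between branch points are a few hundred um long;
# unbounded runs would wander across the field and criss-cross themselves.
_MAX_STEPS = 15


@dataclass(frozen=True)
class VesselTreeSpec:
    """Parameters of the branching-walk vascular generator.

    Defaults emulate a capillary bed at the scale of one camera field:
    a few feeder vessels entering a 600 x 900 um window, branching every
    ~8 steps on average, widths halving from 40 um down to a 10 um
    capillary floor so the 15 um cutoff falls between generations.
    """

    n_roots: int = 4
    branching_prob: float = 0.15
    step_length_um: float = 20.0
    direction_jitter_sd: float = 0.12
    root_width_um: float = 40.0
    capillary_width_um: float = 10.0
    max_depth: int = 4
    field_height_um: float = 600.0
    field_width_um: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if not (0.0 <= self.branching_prob <= 1.0):
            raise ValueError("branching_prob must lie in [0, 1]")
        if not (self.step_length_um > 0):
            raise ValueError("step_length_um must be positive")
        if self.direction_jitter_sd < 0:
            raise ValueError("direction_jitter_sd must be >= 0")
        if not (self.root_width_um > 0 and self.capillary_width_um > 0):
            raise ValueError("vessel widths must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if (
            self.field_height_um < self.step_length_um
            or self.field_width_um < self.step_length_um
        ):
            raise ValueError("field must accommodate at least one step")


@dataclass(frozen=True)
class RenderSpec:
    """Rasterization and noise model for one synthetic acquisition.

    The default 1 um/px resolves the 10 um capillary floor at ~10 px per
    diameter; coarser sampling aliases inter-capillary gaps to single
    pixels, which the median despeckle then bridges.
    """

    pixel_size_um: float = 1.0
    background_level: float = 0.8
    illumination_gradient: float = 0.1
    vessel_darkness: float = 0.6
    speckle_density: float = 0.002
    gaussian_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must lie in [0, 1]")
        if not (0.0 <= self.illumination_gradient <= 0.5):
            raise ValueError("illumination_gradient must lie in [0, 0.5]")
        if not (0.0 <= self.vessel_darkness <= 1.0):
            raise ValueError("vessel_darkness must lie in [0, 1]")
        if not (0.0 <= self.speckle_density <= 1.0):
            raise ValueError("speckle_density must lie in [0, 1]")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be >= 0")


@dataclass(frozen=True)
class VesselSegment:
    """One unbranched vessel run: polyline vertices (um), width (um), depth."""

    points: tuple[tuple[float, float], ...]  # (x, y) in um
    width_um: float
    depth: int


@dataclass(frozen=True)
class VesselTree:
    """Generated vasculature with its ground-truth branch points."""

    segments: tuple[VesselSegment, ...]
    branch_points: tuple[tuple[float, float], ...]  # (x, y) in um
    spec: VesselTreeSpec


def _root_state(rng: np.random.Generator, spec: VesselTreeSpec):
    """Entry point on a random field edge with an inward-pointing direction."""
    edge = rng.integers(4)
    w, h = spec.field_width_um, spec.field_height_um
    if edge == 0:  # left, heading right
        return (0.0, float(rng.uniform(0.15 * h, 0.85 * h))), 0.0
    if edge == 1:  # right, heading left
        return (w, float(rng.uniform(0.15 * h, 0.85 * h))), math.pi
    if edge == 2:  # top, heading down
        return (float(rng.uniform(0.15 * w, 0.85 * w)), 0.0), math.pi / 2
    return (float(rng.uniform(0.15 * w, 0.85 * w)), h), -math.pi / 2


def generate_vessel_tree(spec: VesselTreeSpec) -> VesselTree:
    """Grow a branching vascular tree as a seeded random walk.

    Each active branch takes steps of ``step_length_um`` with Gaussian
    heading jitter; after every step it bifurcates with probability
    ``branching_prob`` (while below ``max_depth``), spawning two daughters
    at +/- a fixed half-angle with half the width, floored at
    ``capillary_width_um``. Branches terminate at the field boundary.
    Segments are the unbranched runs between bifurcations; roots have
    depth 1.
    """
    rng = np.random.default_rng(spec.seed)
    segments: list[VesselSegment] = []
    branch_points: list[tuple[float, float]] = []

    # FIFO queue keeps generation order deterministic for a fixed seed.
    queue: list[tuple[tuple[float, float], float, float, int]] = []
    for _ in range(spec.n_roots):
        start, direction = _root_state(rng, spec)
        queue.append((start, direction, spec.root_width_um, 1))

    while queue:
        (x, y), direction, width, depth = queue.pop(0)
        points = [(x, y)]
        for _ in range(_MAX_STEPS):
            if spec.direction_jitter_sd > 0:
                direction += float(rng.normal(0.0, spec.direction_jitter_sd))
            nx = x + spec.step_length_um * math.cos(direction)
            ny = y + spec.step_length_um * math.sin(direction)
            if not (0.0 <= nx <= spec.field_width_um and 0.0 <= ny <= spec.field_height_um):
                # clip the last step to the field boundary and terminate
                t = _clip_factor(x, y, nx, ny, spec.field_width_um, spec.field_height_um)
                if t > 0:
                    points.append((x + t * (nx - x), y + t * (ny - y)))
                break
            x, y = nx, ny
            points.append((x, y))
            if depth < spec.max_depth and rng.random() < spec.branching_prob:
                child_width = max(width / 2.0, spec.capillary_width_um)
                branch_points.append((x, y))
                for sign in (+1.0, -1.0):
                    queue.append(
                        ((x, y), direction + sign * _BRANCH_HALF_ANGLE, child_width, depth + 1)
                    )
                break
        if len(points) >= 2:
            segments.append(
                VesselSegment(points=tuple(points), width_um=width, depth=depth)
            )
    return VesselTree(
        segments=tuple(segments), branch_points=tuple(branch_points), spec=spec
    )


def _clip_factor(x0, y0, x1, y1, w, h) -> float:
    """Largest t in [0,1] keeping (x0,y0)+t*(dx,dy) inside [0,w]x[0,h]."""
    t = 1.0
    dx, dy = x1 - x0, y1 - y0
    for d, lo, hi, p in ((dx, 0.0, w, x0), (dy, 0.0, h, y0)):
        if d > 0 and p + d > hi:
            t = min(t, (hi - p) / d)
        elif d < 0 and p + d < lo:
            t = min(t, (lo - p) / d)
    return max(t, 0.0)


def _rasterize_segments(
    segments: Sequence[VesselSegment], height_px: int, width_px: int, ps: float
) -> np.ndarray:
    """Paint each polyline as a chain of capsules (stadium shapes).

    A pixel belongs to a vessel when its centre lies within width/2 of the
    segment's centreline.
    """
    mask = np.zeros((height_px, width_px), dtype=bool)
    for seg in segments:
        half = seg.width_um / 2.0
        pts = seg.points
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            # bounding box in pixels, padded by the half-width
            lo_x = max(int((min(x0, x1) - half) / ps) - 1, 0)
            hi_x = min(int((max(x0, x1) + half) / ps) + 2, width_px)
            lo_y = max(int((min(y0, y1) - half) / ps) - 1, 0)
            hi_y = min(int((max(y0, y1) + half) / ps) + 2, height_px)
            if lo_x >= hi_x or lo_y >= hi_y:
                continue
            yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
            cx = (xx + 0.5) * ps
            cy = (yy + 0.5) * ps
            dx, dy = x1 - x0, y1 - y0
            seg_len2 = dx * dx + dy * dy
            if seg_len2 == 0:
                dist2 = (cx - x0) ** 2 + (cy - y0) ** 2
            else:
                t = np.clip(((cx - x0) * dx + (cy - y0) * dy) / seg_len2, 0.0, 1.0)
                dist2 = (cx - (x0 + t * dx)) ** 2 + (cy - (y0 + t * dy)) ** 2
            mask[lo_y:hi_y, lo_x:hi_x] |= dist2 <= half * half
    return mask


def render(
    tree: VesselTree, rspec: RenderSpec = RenderSpec()
) -> tuple[CalibratedImage, BinaryMask, BinaryMask, tuple[tuple[float, float], ...]]:
    """Rasterize a vessel tree into a noisy acquisition plus ground truth.

    Returns ``(image, truth_mask, thin_truth_mask, truth_junctions)``:
    the simulated photomicrograph, the exact vessel raster, the raster of
    segments no wider than 15 um, and the branch-point positions in um.
    The background carries a left-to-right linear illumination ramp of the
    requested amplitude; vessels darken the local background by
    ``vessel_darkness``; Gaussian noise and salt speckle are applied last.
    """
    ps = rspec.pixel_size_um
    if ps > tree.spec.capillary_width_um:
        import warnings

        warnings.warn(
            f"pixel_size_um={ps} exceeds the capillary width "
            f"{tree.spec.capillary_width_um} um; capillaries are sub-pixel",
            stacklevel=2,
        )
    height_px = max(int(round(tree.spec.field_height_um / ps)), 1)
    width_px = max(int(round(tree.spec.field_width_um / ps)), 1)

    truth = _rasterize_segments(tree.segments, height_px, width_px, ps)
    thin_segments = [s for s in tree.segments if s.width_um <= THIN_VESSEL_CUTOFF_UM]
    wide_segments = [s for s in tree.segments if s.width_um > THIN_VESSEL_CUTOFF_UM]
    thin_truth = _rasterize_segments(thin_segments, height_px, width_px, ps)
    if wide_segments:
        # Occlusion-aware ground truth: capillary pixels lying underneath a
        # feeder vessel are not visible in the image and cannot be measured,
        # so they do not count as thin-vessel area.
        thin_truth &= ~_rasterize_segments(wide_segments, height_px, width_px, ps)

    x_norm = (np.arange(width_px) + 0.5) / width_px
    background = rspec.background_level + rspec.illumination_gradient * (x_norm - 0.5)
    img = np.broadcast_to(background, (height_px, width_px)).copy()
    img[truth] *= 1.0 - rspec.vessel_darkness

    rng = np.random.default_rng(rspec.seed)
    if rspec.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, rspec.gaussian_noise_sd, img.shape)
    if rspec.speckle_density > 0:
        salt = rng.random(img.shape) < rspec.speckle_density
        img[salt] = 1.0
    img = np.clip(img, 0.0, 1.0)

    return (
        CalibratedImage(pixels=img, pixel_size_um=ps),
        BinaryMask(labels=truth.astype(np.uint8), pixel_size_um=ps),
        BinaryMask(labels=thin_truth.astype(np.uint8), pixel_size_um=ps),
        tree.branch_points,
    )


def generate_dose_response(
    true_fit: HillFit,
    doses: Sequence[float],
    noise_sd_pct: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> DoseResponseData:
    """Sample a four-parameter logistic with optional Gaussian noise.

    Noise is scaled as ``noise_sd_pct`` percent of the top asymptote, the
    convention for assay variability quoted as %CV of the maximal signal.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd_pct < 0:
        raise ValueError("noise_sd_pct must be >= 0")
    d = np.repeat(np.asarray(doses, dtype=float), n_replicates)
    replicate = np.tile(np.arange(n_replicates), len(doses))
    r = hill_curve(d, true_fit.bottom, true_fit.top, true_fit.ic50, true_fit.hill_slope)
    if noise_sd_pct > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd_pct / 100.0 * true_fit.top, r.shape)
    return DoseResponseData(doses=d, responses=r, replicate=replicate)
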