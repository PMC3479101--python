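"""Seedable generators for synthetic micrographs and cohort tables.

These stand in for the study's embryos so every downstream analysis is
testable without real data:

* chevron micrographs — laminin-stained myotendinous-junction (MTJ) bands
  rendered as V-shaped chevrons with a tunable vertex angle, repeated along
  the anterior-posterior axis. Disorganization is emulated by erasing
  contiguous arcs of band ("holes" in the basement membrane), adding
  intramyotomal speckle puncta, blur, and additive Gaussian noise;
* isotropic noise fields — a null texture with no preferred orientation,
  for anisotropy calibration;
* per-embryo fiber-detachment cohorts — binomial segment scores;
* escape-response trials — straight-line swim trajectories in the 10 mm
  arena sampled at 1 ms, including stationary non-responders.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .motility import EscapeTrial
from .wtmm2d import MicrographImage

__all__ = [
    "SceneParams",
    "SceneTruth",
    "CohortParams",
    "generate_chevron_micrograph",
    "generate_isotropic_micrograph",
    "generate_detachment_cohort",
    "generate_escape_trials",
]


@dataclass
class SceneParams:
    """Parameters of one synthetic chevron-band scene.

    Lengths are in µm and converted to pixels via ``pixel_size``;
    intensities are arbitrary units. Defaults emulate an organized
    control-like MTJ at 0.3 µm/pixel.
    """

    image_size: tuple[int, int] = (512, 512)  # (H, W) pixels
    pixel_size: float = 0.3                   # µm / pixel
    vertex_angle: float = 100.0               # degrees at the chevron vertex
    band_spacing: float = 30.0                # µm between successive vertices
    band_width: float = 1.5                   # µm full band width
    band_intensity: float = 1000.0            # a.u.
    hole_fraction: float = 0.0                # fraction of band length erased
    speckle_density: float = 0.0              # puncta per 100 µm²
    blur_sigma: float = 0.5                   # µm (point-spread proxy)
    noise_sd: float = 0.0                     # a.u. additive Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hole_fraction <= 1.0:
            raise ValueError("hole_fraction must be in [0, 1]")
        if not 0.0 < self.vertex_angle < 180.0:
            raise ValueError("vertex_angle must be in (0, 180) degrees")
        for name in ("pixel_size", "band_spacing", "band_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.band_spacing < 2.0 * self.pixel_size:
            raise ValueError(
                "band_spacing below 2*pixel_size: unresolvable pattern")


@dataclass
class SceneTruth:
    """Pre-noise ground truth of a chevron scene.

    boundary_mask marks the effective (post-hole) band pixels;
    vertex_points holds one (dorsal end, vertex, ventral end) triple per
    chevron in float (row, col) pixel coordinates.
    """

    boundary_mask: np.ndarray
    vertex_points: list[np.ndarray]  # each (3, 2): dorsal, vertex, ventral
    vertex_angle: float


#: Hole arcs erased from bands are drawn with this length range (µm).
HOLE_LENGTH_RANGE_UM = (2.0, 6.0)
#: Gaussian σ (µm) of a speckle punctum.
SPECKLE_SIGMA_UM = 0.4


def _chevron_geometry(params: SceneParams):
    """Vertex/arm-end coordinates (µm, x right / y down) per chevron."""
    h, w = params.image_size
    height_um = h * params.pixel_size
    width_um = w * params.pixel_size
    half = np.radians(params.vertex_angle / 2.0)
    y_mid = height_um / 2.0
    # arm from the vertex at ±(vertex_angle/2) off the +x axis, to the edges
    arm_dx = y_mid / np.tan(half) if np.tan(half) > 0 else np.inf
    chevrons = []
    x = params.band_spacing / 2.0
    # allow vertices slightly off-canvas so arms still cross the field
    while x < width_um + max(arm_dx, 0.0):
        vertex = np.array([x, y_mid])
        dorsal = vertex + np.array([arm_dx, -y_mid])   # top edge (y = 0)
        ventral = vertex + np.array([arm_dx, y_mid])   # bottom edge
        chevrons.append((dorsal, vertex, ventral))
        x += params.band_spacing
    return chevrons


def _segment_fields(px, py, a, b):
    """Distance and arc-length parameter of grid points to segment a->b."""
    ab = b - a
    denom = float(ab @ ab)
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    dx = px - (a[0] + t * ab[0])
    dy = py - (a[1] + t * ab[1])
    return np.hypot(dx, dy), t


def _render_bands(params: SceneParams, chevrons):
    """Band mask plus per-pixel (chevron index, arc-length) coordinates."""
    h, w = params.image_size
    px = (np.arange(w) + 0.5) * params.pixel_size
    py = (np.arange(h) + 0.5) * params.pixel_size
    PX, PY = np.meshgrid(px, py)
    best_dist = np.full((h, w), np.inf)
    chev_idx = np.full((h, w), -1, dtype=int)
    arc_s = np.zeros((h, w))
    for k, (dorsal, vertex, ventral) in enumerate(chevrons):
        len_d = float(np.linalg.norm(dorsal - vertex))
        for start, end, offset, reverse in (
                (dorsal, vertex, 0.0, False),
                (vertex, ventral, len_d, False)):
            dist, t = _segment_fields(PX, PY, start, end)
            seg_len = float(np.linalg.norm(end - start))
            closer = dist < best_dist
            best_dist[closer] = dist[closer]
            chev_idx[closer] = k
            arc_s[closer] = offset + t[closer] * seg_len
    mask = best_dist <= params.band_width / 2.0
    return mask, chev_idx, arc_s


def _erase_holes(mask, chev_idx, arc_s, chevrons, params, rng):
    """Erase contiguous arcs of band until hole_fraction of pixels is gone."""
    if params.hole_fraction <= 0.0 or not mask.any():
        return mask
    if params.hole_fraction >= 1.0:
        return np.zeros_like(mask)
    target = int(round(params.hole_fraction * mask.sum()))
    lengths = np.array([np.linalg.norm(d - v) + np.linalg.norm(vn - v)
                        for d, v, vn in chevrons])
    probs = lengths / lengths.sum()
    erased = 0
    lo, hi = HOLE_LENGTH_RANGE_UM
    for _ in range(10_000):
        if erased >= target:
            break
        k = int(rng.choice(len(chevrons), p=probs))
        center = rng.uniform(0.0, lengths[k])
        half_len = rng.uniform(lo, hi) / 2.0
        hit = (mask & (chev_idx == k)
               & (np.abs(arc_s - center) <= half_len))
        n_hit = int(hit.sum())
        if n_hit:
            mask = mask & ~hit
            erased += n_hit
    return mask


def _add_speckle(image, mask, params, rng):
    """Poisson-count puncta at off-band positions, as Gaussian blobs."""
    h, w = params.image_size
    area_100um2 = h * w * params.pixel_size**2 / 100.0
    n = int(rng.poisson(params.speckle_density * area_100um2))
    sigma_px = SPECKLE_SIGMA_UM / params.pixel_size
    rad = max(1, int(np.ceil(3 * sigma_px)))
    for _ in range(n):
        for _try in range(50):
            r = rng.uniform(0, h - 1)
            c = rng.uniform(0, w - 1)
            if not mask[int(round(r)), int(round(c))]:
                break
        amp = params.band_intensity * rng.uniform(0.4, 1.0)
        r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
        c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        image[r0:r1, c0:c1] += amp * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma_px**2))
    return image


def generate_chevron_micrograph(
        params: SceneParams) -> tuple[MicrographImage, SceneTruth]:
    """Render a chevron-band micrograph plus its pre-noise ground truth.

    Bright bands at the stated vertex angle are drawn, ``hole_fraction`` of
    band pixels is erased as contiguous arcs, speckle puncta are added
    off-band, then Gaussian blur and additive noise (clipped at zero) are
    applied last. Deterministic for a fixed seed; the returned truth
    reflects the post-hole, pre-noise geometry.
    """
    rng = np.random.default_rng(params.seed)
    chevrons = _chevron_geometry(params)
    mask, chev_idx, arc_s = _render_bands(params, chevrons)
    mask = _erase_holes(mask, chev_idx, arc_s, chevrons, params, rng)

    image = np.zeros(params.image_size, dtype=float)
    image[mask] = params.band_intensity
    if params.speckle_density > 0:
        image = _add_speckle(image, mask, params, rng)
    if params.blur_sigma > 0:
        image = ndimage.gaussian_filter(
            image, params.blur_sigma / params.pixel_size, mode="reflect")
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, params.image_size)
    image = np.clip(image, 0.0, None)

    vertex_points = [
        np.array([[d[1], d[0]], [v[1], v[0]], [vn[1], vn[0]]])
        / params.pixel_size
        for d, v, vn in chevrons
    ]  # (row, col) pixel coordinates
    truth = SceneTruth(mask, vertex_points, params.vertex_angle)
    return MicrographImage(image, params.pixel_size,
                           f"chevron-seed{params.seed}"), truth


def generate_isotropic_micrograph(image_size=(512, 512), pixel_size=0.3,
                                  noise_sd=20.0, seed=0,
                                  offset: Optional[float] = None,
                                  ) -> MicrographImage:
    """An i.i.d. Gaussian field clipped at zero: no preferred orientation.

    ``offset`` (default 5*noise_sd) keeps clipping negligible so the pixel
    mean approximates the offset.
    """
    if not noise_sd > 0:
        raise ValueError("noise_sd must be positive")
    if offset is None:
        offset = 5.0 * noise_sd
    rng = np.random.default_rng(seed)
    pixels = np.clip(rng.normal(offset, noise_sd, image_size), 0.0, None)
    return MicrographImage(pixels, pixel_size, f"isotropic-seed{seed}")


@dataclass
class CohortParams:
    """Sampling structure of a per-embryo detachment cohort."""

    n_embryos: int = 20
    segments_per_embryo: int = 20
    p_detach: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos < 1 or self.segments_per_embryo < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.p_detach <= 1.0:
            raise ValueError("p_detach must be in [0, 1]")


def generate_detachment_cohort(params: CohortParams,
                               group: str = "sim") -> pd.DataFrame:
    """Per-embryo segment scores: n_detached ~ Binomial(n_segments, p)."""
    rng = np.random.default_rng(params.seed)
    detached = rng.binomial(params.segments_per_embryo, params.p_detach,
                            params.n_embryos)
    return pd.DataFrame({
        "embryo_id": [f"{group}-{i:04d}" for i in range(params.n_embryos)],
        "group": group,
        "n_segments": params.segments_per_embryo,
        "n_detached_segments": detached,
    })


def generate_escape_trials(n: int, speed_mean_mm_s: float,
                           speed_sd: float, p_nonresponder: float,
                           seed: int = 0, group: str = "sim",
                           replicate: int = 0,
                           max_duration_ms: float = 5000.0,
                           ) -> list[EscapeTrial]:
    """Synthetic touch-evoked trials sampled at 1 ms from the arena center.

    Responders swim on a straight line at a drawn speed (truncated below at
    0.1 mm/s) in a uniform random heading; non-responders (probability
    ``p_nonresponder``) stay at the center for the whole recording.
    """
    if not 0.0 <= p_nonresponder <= 1.0:
        raise ValueError("p_nonresponder must be in [0, 1]")
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n):
        nonresponder = rng.uniform() < p_nonresponder
        if nonresponder:
            t = np.arange(0.0, max_duration_ms + 1.0)
            x = np.zeros_like(t)
            y = np.zeros_like(t)
        else:
            speed = max(rng.normal(speed_mean_mm_s, speed_sd), 0.1)  # mm/s
            heading = rng.uniform(0.0, 2 * np.pi)
            # sample until just past the outer circle (5 mm), capped
            exit_ms = 5.0 / speed * 1000.0
            t = np.arange(0.0, min(exit_ms + 2.0, max_duration_ms) + 1.0)
            dist = speed * t / 1000.0
            x = dist * np.cos(heading)
            y = dist * np.sin(heading)
        trials.append(EscapeTrial(
            embryo_id=f"{group}-{i:04d}", group=group, replicate=replicate,
            t_ms=t, x_mm=x, y_mm=y))
    return trials
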