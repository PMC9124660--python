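"""Synthetic fetoscopy-like sequences with ground-truth motion.

The simulator emulates the phenomena that make fetoscopic mosaicking
hard: a textured placenta-like background with curvilinear vessels,
smooth affine camera motion, the circular fetoscope field of view,
vignetting, floating particles whose motion is inconsistent with the
camera (independent random walks), and saturated specular blobs anchored
to the camera frame.  Every sequence carries ground-truth pairwise
transforms, analytic flow and artifact label rasters, so each pipeline
stage is testable without any external data.

Ground-truth flow stores the *background* motion everywhere; artifact
pixels are labelled and their apparent (inconsistent) motion is kept
separately, so both a clean-flow and a corrupted-flow oracle regime can
be produced from one sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .correspondence import CircularMask
from .flow import FlowField
from .geometry import AffineTransform
from .registration import RansacConfig, register_pair

__all__ = [
    "SceneConfig",
    "MotionConfig",
    "ArtifactConfig",
    "SyntheticSequence",
    "TrajectoryConfigError",
    "make_texture",
    "sample_trajectory",
    "render_sequence",
    "simulate_sequence",
    "recovery_experiment",
]

_BASE_COLOR = np.array([0.58, 0.30, 0.26])  # placenta-like reddish hue
_VESSEL_TINT = np.array([0.45, 0.75, 0.75])  # multiplicative darkening, strongest in G/B


class TrajectoryConfigError(ValueError):
    """The sampled trajectory would leave the texture bounds."""


@dataclass(frozen=True)
class SceneConfig:
    texture_size: int = 1024
    vessel_count: int = 8
    vessel_width_range: tuple[float, float] = (3.0, 9.0)
    background_noise_sigma: float = 0.002
    illumination_falloff_strength: float = 0.4
    seed: int = 0


@dataclass(frozen=True)
class MotionConfig:
    n_frames: int = 50
    max_translation_step: float = 5.0
    max_rotation_step: float = 2.0
    max_scale_step: float = 0.0
    smoothness: float = 0.8  # AR(1) coefficient
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.smoothness < 1.0:
            raise ValueError("smoothness must lie in (0, 1)")
        if min(self.max_translation_step, self.max_rotation_step, self.max_scale_step) < 0:
            raise ValueError("motion step caps must be non-negative")


@dataclass(frozen=True)
class ArtifactConfig:
    particle_density: float = 0.1  # fraction of mask pixels covered
    particle_size_range: tuple[float, float] = (2.0, 6.0)  # blob radius, px
    particle_step: tuple[float, float] = (10.0, 25.0)  # random-walk step, px/frame
    specular_count: int = 3
    specular_radius_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.particle_density <= 0.5:
            raise ValueError("particle_density must lie in [0, 0.5]")


@dataclass
class SyntheticSequence:
    """Rendered frames + every piece of ground truth the pipeline can use."""

    frames: list[np.ndarray]
    mask: CircularMask
    gt_pairwise: list[AffineTransform]  # maps frame k+1 coords into frame k
    gt_flow: list[FlowField]  # background motion, frame k -> k+1
    artifact_labels: list[np.ndarray]  # uint8: 0 none, 1 particle, 2 specular
    artifact_flow: list[np.ndarray] | None = None  # (2, h, w) apparent artifact motion

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def corrupted_flow(self, k: int) -> FlowField:
        """Flow for pair k with artifact pixels carrying their own apparent
        motion instead of the background motion (the regime a real dense
        flow estimator produces on floating debris and reflections)."""
        clean = self.gt_flow[k]
        lab = self.artifact_labels[k]
        u = clean.u.copy()
        v = clean.v.copy()
        bad = lab > 0
        if self.artifact_flow is not None:
            u[bad] = self.artifact_flow[k][0][bad]
            v[bad] = self.artifact_flow[k][1][bad]
        return FlowField(u=u, v=v, valid=clean.valid)


def make_texture(cfg: SceneConfig) -> np.ndarray:
    """Reddish placenta-like RGB texture with dark curvilinear vessels."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.texture_size
    # low-frequency background modulation
    coarse = ndimage.gaussian_filter(rng.normal(size=(s, s)), sigma=s / 16.0, mode="wrap")
    coarse = coarse / (np.abs(coarse).max() + 1e-12)
    fine = ndimage.gaussian_filter(rng.normal(size=(s, s)), sigma=3.0, mode="wrap")
    fine = fine / (np.abs(fine).max() + 1e-12)
    lum = 1.0 + 0.25 * coarse + 0.12 * fine
    tex = _BASE_COLOR[None, None, :] * lum[..., None]

    vessel_map = np.zeros((s, s))
    for _ in range(cfg.vessel_count):
        canvas = np.zeros((s, s), dtype=bool)
        # random smooth path: AR(1)-filtered heading random walk
        n_pts = 4 * s
        pos = rng.uniform(0.1 * s, 0.9 * s, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        turn = 0.0
        for _step in range(n_pts):
            turn = 0.95 * turn + 0.05 * rng.normal(scale=0.6)
            heading += turn
            pos = pos + np.array([np.cos(heading), np.sin(heading)])
            xi, yi = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= xi < s and 0 <= yi < s):
                break
            canvas[yi, xi] = True
        width = rng.uniform(*cfg.vessel_width_range)
        r = max(int(round(width / 2.0)), 1)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        canvas = ndimage.binary_dilation(canvas, structure=xx**2 + yy**2 <= r**2)
        vessel_map = np.maximum(vessel_map, ndimage.gaussian_filter(canvas.astype(float), 1.0))
    vessel_map = np.clip(vessel_map, 0.0, 1.0)
    tex = tex * (1.0 - vessel_map[..., None] * (1.0 - _VESSEL_TINT)[None, None, :])

    tex = tex + rng.normal(scale=cfg.background_noise_sigma, size=tex.shape)
    return np.clip(tex, 0.0, 1.0)


def sample_trajectory(
    cfg: MotionConfig,
    frame_shape: tuple[int, int] = (320, 320),
    texture_size: int | None = None,
) -> list[AffineTransform]:
    """AR(1)-smoothed per-step similarity transforms (pairwise, k+1 -> k).

    Steps are capped at the configured maxima; with ``texture_size`` given
    the cumulative window placement is checked against the texture bounds
    and a :class:`TrajectoryConfigError` raised on excursion.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = frame_shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    caps = np.array(
        [cfg.max_translation_step, cfg.max_translation_step, cfg.max_rotation_step, cfg.max_scale_step]
    )
    state = np.zeros(4)
    steps = []
    for _ in range(cfg.n_frames - 1):
        innov = rng.uniform(-1.0, 1.0, size=4) * caps
        state = cfg.smoothness * state + (1.0 - cfg.smoothness) * innov
        step = np.clip(state, -caps, caps)
        steps.append(
            AffineTransform.similarity(
                rotation_deg=step[2], scale=float(np.exp(step[3])), tx=step[0], ty=step[1], center=center
            )
        )
    if texture_size is not None:
        for M in cumulative_placements(steps, frame_shape, texture_size):
            corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
            pts = M.apply(corners)
            if pts.min() < 0 or pts.max() > texture_size - 1:
                raise TrajectoryConfigError(
                    "trajectory excursion exceeds texture bounds; enlarge the texture or shorten the walk"
                )
    return steps


def cumulative_placements(
    pairwise: list[AffineTransform], frame_shape: tuple[int, int], texture_size: int
) -> list[AffineTransform]:
    """Transforms mapping each frame's coordinates into texture coordinates,
    with frame 0 centred in the texture."""
    h, w = frame_shape
    t0 = AffineTransform.translation(
        (texture_size - 1) / 2.0 - (w - 1) / 2.0, (texture_size - 1) / 2.0 - (h - 1) / 2.0
    )
    placements = [t0]
    for A in pairwise:
        placements.append(placements[-1] @ A)
    return placements


def _sample_texture(texture: np.ndarray, placement: AffineTransform, frame_shape) -> np.ndarray:
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([xx, yy], axis=-1) @ placement.linear.T + placement.translation_part
    coords = [pts[..., 1], pts[..., 0]]
    return np.stack(
        [ndimage.map_coordinates(texture[..., c], coords, order=1, mode="nearest") for c in range(3)],
        axis=-1,
    )


def _stamp_blob(img, labels, art_u, art_v, x, y, radius, color, label, step, saturate=False):
    h, w = labels.shape
    r = int(np.ceil(radius)) + 2
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    xs0, xs1 = max(x0, 0), min(x1, w)
    ys0, ys1 = max(y0, 0), min(y1, h)
    if xs0 >= xs1 or ys0 >= ys1:
        return
    yy, xx = np.mgrid[ys0:ys1, xs0:xs1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    profile = np.exp(-0.5 * d2 / (radius / 2.0) ** 2)
    footprint = d2 <= radius**2
    patch = img[ys0:ys1, xs0:xs1]
    if saturate:
        patch[:] = patch + (color[None, None, :] - patch) * np.minimum(profile * 1.6, 1.0)[..., None]
    else:
        patch[:] = patch + (color[None, None, :] - patch) * (0.85 * profile)[..., None]
    lab_patch = labels[ys0:ys1, xs0:xs1]
    lab_patch[footprint] = np.maximum(lab_patch[footprint], label)
    art_u[ys0:ys1, xs0:xs1][footprint] = step[0]
    art_v[ys0:ys1, xs0:xs1][footprint] = step[1]


def render_sequence(
    texture: np.ndarray,
    trajectory: list[AffineTransform],
    scene: SceneConfig,
    artifacts: ArtifactConfig | None = None,
    frame_shape: tuple[int, int] = (320, 320),
    mask_shrink: float = 0.9,
) -> SyntheticSequence:
    """Render frames along the trajectory with vignetting, circular mask,
    floating particles and specular blobs, plus all ground truth."""
    h, w = frame_shape
    n_frames = len(trajectory) + 1
    mask = CircularMask.inscribed(frame_shape, shrink=mask_shrink)
    mask_raster = mask.raster(frame_shape)
    placements = cumulative_placements(trajectory, frame_shape, texture.shape[0])

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r2 = ((xx - mask.cx) ** 2 + (yy - mask.cy) ** 2) / mask.radius**2
    vignette = np.clip(1.0 - scene.illumination_falloff_strength * r2, 0.0, 1.0)

    rng = np.random.default_rng(None if artifacts is None else artifacts.seed)
    particles = []
    speculars = []
    if artifacts is not None:
        lo, hi = artifacts.particle_size_range
        mean_area = np.pi * (lo**2 + lo * hi + hi**2) / 3.0  # E[pi r^2], r ~ U(lo, hi)
        # Poisson coverage model: n blobs cover 1 - exp(-n a / A) of the mask
        n_particles = int(round(
            -np.log(max(1.0 - artifacts.particle_density, 1e-9)) * mask_raster.sum() / max(mean_area, 1.0)
        ))
        for _ in range(n_particles):
            radius = rng.uniform(*artifacts.particle_size_range)
            ang = rng.uniform(0, 2 * np.pi)
            rr = max(mask.radius - radius, 0.0) * np.sqrt(rng.uniform())
            particles.append(
                {
                    "pos": np.array([mask.cx + rr * np.cos(ang), mask.cy + rr * np.sin(ang)]),
                    "radius": radius,
                }
            )
        for _ in range(artifacts.specular_count):
            ang = rng.uniform(0, 2 * np.pi)
            rr = 0.8 * mask.radius * np.sqrt(rng.uniform())
            speculars.append(
                {
                    "pos": np.array([mask.cx + rr * np.cos(ang), mask.cy + rr * np.sin(ang)]),
                    "radius": rng.uniform(*artifacts.specular_radius_range),
                }
            )

    frame_noise = np.random.default_rng(scene.seed + 1)
    frames, labels_list, art_flow = [], [], []
    particle_color = np.array([0.85, 0.82, 0.78])
    specular_color = np.array([1.0, 1.0, 1.0])
    for k in range(n_frames):
        img = _sample_texture(texture, placements[k], frame_shape)
        img = img * vignette[..., None]
        labels = np.zeros((h, w), dtype=np.uint8)
        art_u = np.zeros((h, w), dtype=np.float32)
        art_v = np.zeros((h, w), dtype=np.float32)

        if artifacts is not None:
            # draw each particle at its current position, labelled with the
            # step it will take toward frame k+1 (its apparent motion, which
            # is deliberately inconsistent with the camera motion)
            for p in particles:
                mag = rng.uniform(*artifacts.particle_step)
                ang = rng.uniform(0, 2 * np.pi)
                step = np.array([mag * np.cos(ang), mag * np.sin(ang)])
                newpos = p["pos"] + step
                if not mask.contains(newpos[None, :])[0]:
                    ang2 = rng.uniform(0, 2 * np.pi)
                    rr = max(mask.radius - p["radius"], 0.0) * np.sqrt(rng.uniform())
                    newpos = np.array([mask.cx + rr * np.cos(ang2), mask.cy + rr * np.sin(ang2)])
                    step = newpos - p["pos"]
                _stamp_blob(
                    img, labels, art_u, art_v, p["pos"][0], p["pos"][1], p["radius"],
                    particle_color, 1, step,
                )
                p["pos"] = newpos
            for sp in speculars:
                _stamp_blob(
                    img, labels, art_u, art_v, sp["pos"][0], sp["pos"][1], sp["radius"],
                    specular_color, 2, np.zeros(2), saturate=True,
                )

        img = img + frame_noise.normal(scale=scene.background_noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        img[~mask_raster] = 0.0
        frames.append(img)
        labels_list.append(labels)
        art_flow.append(np.stack([art_u, art_v]))

    gt_flow = []
    for k in range(n_frames - 1):
        inv = trajectory[k].invert()  # maps frame k coords into frame k+1
        pts = np.stack([xx, yy], axis=-1) @ inv.linear.T + inv.translation_part
        gt_flow.append(
            FlowField(u=pts[..., 0] - xx, v=pts[..., 1] - yy, valid=mask_raster.copy())
        )

    return SyntheticSequence(
        frames=frames,
        mask=mask,
        gt_pairwise=list(trajectory),
        gt_flow=gt_flow,
        artifact_labels=labels_list,
        artifact_flow=art_flow,
    )


def simulate_sequence(
    scene: SceneConfig | None = None,
    motion: MotionConfig | None = None,
    artifacts: ArtifactConfig | None = None,
    frame_shape: tuple[int, int] = (320, 320),
) -> SyntheticSequence:
    """Convenience wrapper: texture -> trajectory -> rendered sequence."""
    scene = scene or SceneConfig()
    motion = motion or MotionConfig()
    texture = make_texture(scene)
    trajectory = sample_trajectory(motion, frame_shape, texture_size=scene.texture_size)
    return render_sequence(texture, trajectory, scene, artifacts, frame_shape)


def _max_corner_error(A_est: AffineTransform, A_gt: AffineTransform, frame_shape) -> float:
    h, w = frame_shape
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    return float(np.linalg.norm(A_est.apply(corners) - A_gt.apply(corners), axis=1).max())


def recovery_experiment(
    seq: SyntheticSequence,
    flow_source: str = "gt",
    method: str = "ransac_lm",
    cfg: RansacConfig | None = None,
    stride: int = 2,
    csv_path=None,
) -> tuple[pd.DataFrame, dict]:
    """Register every pair and compare against ground truth.

    ``flow_source``: ``"gt"`` (clean analytic flow), ``"gt_corrupted"``
    (artifact pixels carry their inconsistent apparent motion) or ``"lk"``
    (built-in pyramidal Lucas-Kanade).  Reports per-pair max corner
    re-projection error, inlier counts, particle-pixel outlier recall, and
    the endpoint drift of the composed trajectory.
    """
    cfg = cfg or RansacConfig()
    frame_shape = seq.frames[0].shape[:2]
    rows = []
    estimates = []
    for k in range(seq.n_frames - 1):
        if flow_source == "gt":
            flow = seq.gt_flow[k]
        elif flow_source == "gt_corrupted":
            flow = seq.corrupted_flow(k)
        elif flow_source == "lk":
            flow = None
        else:
            raise ValueError(f"unknown flow source {flow_source!r}")
        reg = register_pair(
            seq.frames[k],
            seq.frames[k + 1],
            flow=flow,
            mask=seq.mask,
            stride=stride,
            cfg=cfg,
            method=method,
            pair_index=k,
        )
        estimates.append(reg.transform)
        err = _max_corner_error(reg.transform, seq.gt_pairwise[k], frame_shape)

        lab = seq.artifact_labels[k]
        if reg.outlier_points is not None and (lab == 1).any():
            out = np.zeros(frame_shape, dtype=bool)
            pts = reg.outlier_points.astype(int)
            inb = (pts[:, 0] >= 0) & (pts[:, 0] < frame_shape[1]) & (pts[:, 1] >= 0) & (pts[:, 1] < frame_shape[0])
            out[pts[inb, 1], pts[inb, 0]] = True
            sampled = np.zeros(frame_shape, dtype=bool)
            sampled[::stride, ::stride] = True
            sampled &= seq.mask.raster(frame_shape)
            particle_px = (lab == 1) & sampled
            recall = float(np.count_nonzero(out & particle_px)) / max(
                np.count_nonzero(particle_px), 1
            )
        else:
            recall = np.nan
        rows.append((k, reg.n, reg.n_inliers, reg.rmse, err, recall))

    df = pd.DataFrame(
        rows, columns=["pair", "n", "n_inliers", "rmse", "max_corner_error", "particle_outlier_recall"]
    )

    E = estimates[0]
    G = seq.gt_pairwise[0]
    for k in range(1, len(estimates)):
        E = E @ estimates[k]
        G = G @ seq.gt_pairwise[k]
    summary = {
        "max_corner_error_max": float(df["max_corner_error"].max()),
        "max_corner_error_median": float(df["max_corner_error"].median()),
        "endpoint_drift": _max_corner_error(E, G, frame_shape),
        "particle_outlier_recall": float(df["particle_outlier_recall"].mean()),
    }
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df, summary
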