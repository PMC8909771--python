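"""Seeded synthetic CT phantom generator and procedure simulator.

Every downstream stage of the guidance pipeline (segmentation, fiducial
registration, trajectory planning, tracked insertion, ablation confirmation)
is exercised on scenes produced here, so no patient data is ever required.
A scene is a CT-like volume painted from geometric truth masks with a fixed
Hounsfield palette: air, soft tissue, liver, spleen, tumors, enhanced
vessels, bone and radiopaque skin markers. Twenty skin fiducials form a
constellation whose pairwise distances avoid repetition, and the needle
carries a five-marker clip with the same property, which is what makes
marker correspondence geometrically unambiguous.

All generation is deterministic under a fixed seed. The tracker camera is
abstracted to an observation model that delivers noisy, occluded,
randomly-permuted 3D marker positions; stereo triangulation error is folded
into the per-axis noise sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .registration import Constellation, RigidTransform
from .volume import BinaryMask, Volume, dilate_metric


class GenerationError(RuntimeError):
    """Requested geometry could not be realised after bounded retries."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Hounsfield-like palette painted into phantom volumes. Marker size and HU
#: are not physically calibrated quantities here; they are configuration.
DEFAULT_HU = {
    "air": -1000.0,
    "soft": 45.0,
    "spleen": 100.0,
    "liver": 65.0,
    "tumor": 30.0,
    "vessel": 150.0,
    "bone": 700.0,
    "marker": 2000.0,
}


@dataclass
class PhantomConfig:
    """Geometry and acquisition parameters of a synthetic scene.

    The acquisition grid emulates a clinical abdominal CT protocol:
    512x512-class in-plane matrices at sub-millimetre pixels and 2 mm
    slices, scaled here to a desk-size field of view around the liver so
    that whole simulation studies stay cheap.
    """

    shape: tuple[int, int, int] = (192, 192, 72)
    spacing: tuple[float, float, float] = (0.75, 0.75, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    n_fiducials: int = 20
    fiducial_min_separation: float = 15.0
    #: minimum gap between any two values of the pairwise-distance multiset
    fiducial_distinct_tol: float = 0.1
    marker_diameter: float = 4.0
    tumor_diameters: tuple[float, ...] = (15.0,)
    image_noise_sigma: float = 0.0
    max_retries: int = 20

    def grid(self) -> Volume:
        return Volume(
            intensities=np.zeros(self.shape, dtype=np.float32),
            spacing=np.asarray(self.spacing),
            origin=np.asarray(self.origin),
        )


@dataclass
class ClipModel:
    """Five-marker clip rigidly attached to the coaxial needle.

    ``marker_points`` live in the clip frame (mm); ``tip_offset`` is the
    vector from the clip origin to the needle tip, and ``axis`` the unit
    shaft direction, both in the clip frame.
    """

    marker_points: np.ndarray
    tip_offset: np.ndarray
    axis: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.marker_points = np.asarray(self.marker_points, dtype=float)
        self.tip_offset = np.asarray(self.tip_offset, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.marker_points.shape != (5, 3):
            raise ValueError("clip must carry exactly 5 markers")
        n = np.linalg.norm(self.axis)
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            raise ValueError("clip axis must be a unit vector")
        if not self.labels:
            self.labels = [f"C{i}" for i in range(5)]

    def constellation(self) -> Constellation:
        return Constellation(self.marker_points, list(self.labels))

    @classmethod
    def default(cls) -> "ClipModel":
        # Asymmetric marker layout: all 10 pairwise distances differ by >4 mm.
        pts = np.array([
            [0.0, 0.0, 0.0],
            [8.0, 33.0, -3.0],
            [-16.0, -8.0, 9.0],
            [39.0, -13.0, 43.0],
            [-9.0, 8.0, 27.0],
        ])
        return cls(pts, tip_offset=np.array([0.0, 0.0, 120.0]),
                   axis=np.array([0.0, 0.0, 1.0]))


@dataclass
class ObservationModel:
    """Abstract tracker camera: rigid frame change + noise + dropouts."""

    sigma: float = 0.5
    occlusion_prob: float = 0.0
    frame: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.occlusion_prob < 1):
            raise ValueError("occlusion probability must be in [0, 1)")


@dataclass
class ObservedMarkers:
    """Tracker output: unlabelled points plus the withheld ground truth."""

    points: np.ndarray
    true_indices: np.ndarray  # original index of each observed point


@dataclass
class PhantomScene:
    """A synthetic acquisition: volume, truth masks, fiducials, truth state."""

    volume: Volume
    masks: dict[str, BinaryMask]
    tumors: list[BinaryMask]
    fiducials: np.ndarray            # (n, 3) world mm, on body-surface voxels
    fiducial_labels: list[str]
    config: PhantomConfig
    seed: int
    displacement: np.ndarray = field(default_factory=lambda: np.zeros(3))
    skin_displacement: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def fiducial_constellation(self) -> Constellation:
        return Constellation(self.fiducials, list(self.fiducial_labels))

    def tumor_centers(self) -> np.ndarray:
        return np.array([t.centroid_world() for t in self.tumors])


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _world_grids(grid: Volume):
    sp, o = grid.spacing, grid.origin
    xs = o[0] + sp[0] * np.arange(grid.shape[0])
    ys = o[1] + sp[1] * np.arange(grid.shape[1])
    zs = o[2] + sp[2] * np.arange(grid.shape[2])
    return np.meshgrid(xs, ys, zs, indexing="ij")


def ellipsoid_mask(grid: Volume, center, semi_axes) -> BinaryMask:
    gx, gy, gz = _world_grids(grid)
    c, a = np.asarray(center, float), np.asarray(semi_axes, float)
    q = ((gx - c[0]) / a[0]) ** 2 + ((gy - c[1]) / a[1]) ** 2 + ((gz - c[2]) / a[2]) ** 2
    return BinaryMask(bits=q <= 1.0, grid=grid)


def ball_mask(grid: Volume, center, radius: float) -> BinaryMask:
    return ellipsoid_mask(grid, center, (radius, radius, radius))


def cylinder_mask(grid: Volume, p0, p1, radius: float) -> BinaryMask:
    """Capsule of given radius around the segment p0-p1 (world mm)."""
    gx, gy, gz = _world_grids(grid)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    L2 = float(d @ d)
    vx, vy, vz = gx - p0[0], gy - p0[1], gz - p0[2]
    t = np.clip((vx * d[0] + vy * d[1] + vz * d[2]) / max(L2, 1e-12), 0.0, 1.0)
    dist2 = (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2
    return BinaryMask(bits=dist2 <= radius**2, grid=grid)


def _surface_voxels(mask: BinaryMask) -> np.ndarray:
    er = ndimage.binary_erosion(mask.bits)
    return np.argwhere(mask.bits & ~er)


# ---------------------------------------------------------------------------
# Fiducial constellation sampling
# ---------------------------------------------------------------------------

def _sample_constellation(candidates: np.ndarray, n: int, min_sep: float,
                          distinct_tol: float, rng: np.random.Generator,
                          restarts: int = 30) -> np.ndarray:
    """Greedy rejection sampling of a non-repetitive constellation.

    Markers are added one at a time; a candidate is accepted only if it is
    at least ``min_sep`` from every placed marker and every new pairwise
    distance stays more than ``distinct_tol`` away from all distances
    already in the multiset (and from each other).
    """
    for _ in range(restarts):
        order = rng.permutation(len(candidates))
        chosen: list[np.ndarray] = []
        dists = np.empty(0)
        ptr = 0
        while len(chosen) < n:
            placed = False
            while ptr < len(order):
                cand = candidates[order[ptr]]
                ptr += 1
                if chosen:
                    new_d = np.linalg.norm(np.asarray(chosen) - cand, axis=1)
                    if new_d.min() < min_sep:
                        continue
                    all_d = np.sort(np.concatenate([dists, new_d]))
                    if len(all_d) > 1 and np.min(np.diff(all_d)) <= distinct_tol:
                        continue
                    dists = np.concatenate([dists, new_d])
                chosen.append(cand)
                placed = True
                break
            if not placed:
                break
        if len(chosen) == n:
            return np.asarray(chosen)
    raise GenerationError(
        f"could not place {n} fiducials with min separation {min_sep} mm "
        f"and distance distinctness {distinct_tol} mm"
    )


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _paint(scene_masks: dict, tumors: list[BinaryMask], fiducials: np.ndarray,
           config: PhantomConfig, rng: np.random.Generator | None) -> Volume:
    grid = config.grid()
    hu = config.hu
    img = np.full(grid.shape, hu["air"], dtype=np.float32)
    img[scene_masks["body"].bits] = hu["soft"]
    img[scene_masks["spleen"].bits] = hu["spleen"]
    img[scene_masks["liver"].bits] = hu["liver"]
    for t in tumors:
        img[t.bits] = hu["tumor"]
    img[scene_masks["vessels"].bits] = hu["vessel"]
    img[scene_masks["bone"].bits] = hu["bone"]
    marker_bits = np.zeros(grid.shape, dtype=bool)
    r = config.marker_diameter / 2.0
    for p in fiducials:
        marker_bits |= ball_mask(grid, p, r).bits
    img[marker_bits] = hu["marker"]
    if config.image_noise_sigma > 0 and rng is not None:
        img += rng.normal(0.0, config.image_noise_sigma, size=img.shape).astype(np.float32)
    vol = Volume(intensities=img, spacing=grid.spacing, origin=grid.origin)
    return vol, BinaryMask(bits=marker_bits, grid=grid)


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomScene:
    """Build a deterministic synthetic abdominal scene.

    Raises :class:`GenerationError` when the requested tumors or fiducial
    constellation cannot be fitted after bounded retries.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    grid = config.grid()
    fov = np.asarray(config.shape) * np.asarray(config.spacing)
    center = np.asarray(config.origin) + fov / 2.0

    body_axes = fov * np.array([0.42, 0.40, 0.47])
    body = ellipsoid_mask(grid, center, body_axes)
    # soft-tissue rind: internal organs stay >= 6 mm under the skin so that
    # surface markers can never touch them
    body_inner = ellipsoid_mask(grid, center, body_axes - 6.0)
    spine = cylinder_mask(
        grid,
        [center[0], center[1] + 0.30 * fov[1], config.origin[2]],
        [center[0], center[1] + 0.30 * fov[1], config.origin[2] + fov[2]],
        0.07 * min(fov[0], fov[1]),
    )
    bone = BinaryMask(bits=spine.bits & body.bits, grid=grid)
    liver_c = center + np.array([0.16 * fov[0], -0.06 * fov[1], 0.0])
    liver = ellipsoid_mask(grid, liver_c, np.array([0.26 * fov[0], 0.24 * fov[1], 0.33 * fov[2]]))
    liver = BinaryMask(bits=liver.bits & body_inner.bits & ~bone.bits, grid=grid)
    spleen_c = center + np.array([-0.26 * fov[0], -0.04 * fov[1], 0.05 * fov[2]])
    spleen = ellipsoid_mask(grid, spleen_c, 0.08 * fov)
    spleen = BinaryMask(bits=spleen.bits & body.bits & ~liver.bits, grid=grid)

    # Portal-like vessel tree: three capsules well inside the liver.
    liver_ax = np.array([0.26 * fov[0], 0.24 * fov[1], 0.33 * fov[2]])
    vr = 2.5
    vessels = np.zeros(grid.shape, dtype=bool)
    for a, b in [
        (liver_c - 0.55 * liver_ax * np.array([1, 0, 0]), liver_c + 0.55 * liver_ax * np.array([1, 0, 0])),
        (liver_c, liver_c + 0.5 * liver_ax * np.array([0.3, 0.6, 0.6])),
        (liver_c, liver_c + 0.5 * liver_ax * np.array([-0.2, 0.5, -0.6])),
    ]:
        vessels |= cylinder_mask(grid, a, b, vr).bits
    vessels &= ndimage.binary_erosion(liver.bits, iterations=2)
    vessels_mask = BinaryMask(bits=vessels, grid=grid)

    # Tumors: spheres at deterministic pseudo-random interior sites.
    tumors: list[BinaryMask] = []
    interior = ndimage.binary_erosion(liver.bits, iterations=3)
    interior_idx = np.argwhere(interior & ~vessels)
    for d in config.tumor_diameters:
        if not (5.0 <= d <= 40.0):
            raise GenerationError(f"tumor diameter {d} mm outside the 0.5-4 cm envelope")
        placed = False
        for _ in range(config.max_retries * 10):
            c_idx = interior_idx[rng.integers(len(interior_idx))]
            c_world = grid.origin + c_idx * grid.spacing
            t = ball_mask(grid, c_world, d / 2.0)
            if not t.bits.any():
                continue
            inside = (t.bits & liver.bits).sum() / t.bits.sum()
            overlaps = any((t.bits & prev.bits).any() for prev in tumors)
            # vessels are painted over tumors: an overlap would make the
            # truth mask inconsistent with the rendered intensities
            touches_vessel = bool((t.bits & vessels).any())
            if inside >= 1.0 and not overlaps and not touches_vessel:
                tumors.append(t)
                placed = True
                break
        if not placed:
            raise GenerationError(f"could not place a {d} mm tumor inside the liver")

    # Fiducials on the anterior body surface, clear of the volume boundary.
    surf = _surface_voxels(body)
    margin_vox = np.ceil(config.marker_diameter / grid.spacing).astype(int) + 1
    keep = np.all(surf >= margin_vox, axis=1) & np.all(
        surf < np.asarray(grid.shape) - margin_vox, axis=1)
    anterior = surf[:, 1] < (center[1] - grid.origin[1]) / grid.spacing[1]
    cand_idx = surf[keep & anterior]
    cand_world = grid.origin + cand_idx * grid.spacing
    fid = _sample_constellation(
        cand_world, config.n_fiducials, config.fiducial_min_separation,
        config.fiducial_distinct_tol, rng)
    labels = [f"F{i:02d}" for i in range(len(fid))]

    masks = {"body": body, "liver": liver, "spleen": spleen, "bone": bone,
             "vessels": vessels_mask}
    volume, marker_mask = _paint(masks, tumors, fid, config, rng)
    masks["markers"] = marker_mask
    return PhantomScene(volume=volume, masks=masks, tumors=tumors,
                        fiducials=fid, fiducial_labels=labels,
                        config=config, seed=seed)


# ---------------------------------------------------------------------------
# Observation
# ---------------------------------------------------------------------------

def observe_markers(points, model: ObservationModel,
                    rng: np.random.Generator | None = None) -> ObservedMarkers:
    """Simulate the tracker's view of a labelled world point set.

    Each surviving point is mapped into the tracker frame and perturbed by
    i.i.d. per-axis Gaussian noise; occluded markers are dropped and the
    output order is randomly permuted. The true identity of each observed
    point is returned separately so that simulations can audit matching.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    keep = rng.random(len(pts)) >= model.occlusion_prob
    idx = np.nonzero(keep)[0]
    obs = model.frame.apply(pts[idx])
    if model.sigma > 0:
        obs = obs + rng.normal(0.0, model.sigma, size=obs.shape)
    perm = rng.permutation(len(idx))
    return ObservedMarkers(points=obs[perm], true_indices=idx[perm])


# ---------------------------------------------------------------------------
# Breathing
# ---------------------------------------------------------------------------

def breathing_displacement(amplitude: float, direction, phase: float) -> np.ndarray:
    """Internal-structure displacement at a breathing phase in [0, 1]."""
    d = np.asarray(direction, dtype=float)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude > 0 and not math.isclose(np.linalg.norm(d), 1.0, abs_tol=1e-6):
        raise ValueError("direction must be a unit vector")
    return amplitude * math.sin(2.0 * math.pi * phase) * d


def simulate_breathing(scene: PhantomScene, amplitude: float, direction,
                       phase: float, skin_attenuation: float = 0.3) -> PhantomScene:
    """Displace internal structures rigidly; skin follows with attenuation.

    The liver, spleen, vessels and tumors translate by the full breathing
    vector while the skin fiducials move by ``skin_attenuation`` of it —
    the mechanism by which free breathing degrades a skin-registered frame.
    The scene volume is re-painted from the displaced masks and the truth
    displacement recorded.
    """
    disp = breathing_displacement(amplitude, direction, phase)
    grid = scene.volume
    shift_vox = disp / grid.spacing

    def _shift(mask: BinaryMask) -> BinaryMask:
        if not np.any(shift_vox):
            return BinaryMask(bits=mask.bits.copy(), grid=mask.grid)
        moved = ndimage.shift(mask.bits.astype(np.uint8), shift_vox, order=0,
                              mode="constant", cval=0)
        return BinaryMask(bits=moved.astype(bool), grid=mask.grid)

    masks = dict(scene.masks)
    for name in ("liver", "spleen", "vessels"):
        masks[name] = _shift(scene.masks[name])
    masks["liver"] = BinaryMask(bits=masks["liver"].bits & scene.masks["body"].bits,
                                grid=grid)
    tumors = [_shift(t) for t in scene.tumors]
    skin_disp = skin_attenuation * disp
    fiducials = scene.fiducials + skin_disp
    volume, marker_mask = _paint(masks, tumors, fiducials, scene.config, None)
    masks["markers"] = marker_mask
    return PhantomScene(volume=volume, masks=masks, tumors=tumors,
                        fiducials=fiducials,
                        fiducial_labels=list(scene.fiducial_labels),
                        config=scene.config, seed=scene.seed,
                        displacement=disp, skin_displacement=skin_disp)


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

def simulate_ablation(tumor: BinaryMask, center_offset, radius: float) -> BinaryMask:
    """Spherical necrosis of given radius about the (offset) tumor centroid."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    center = tumor.centroid_world() + np.asarray(center_offset, dtype=float)
    return ball_mask(tumor.grid, center, radius)


# ---------------------------------------------------------------------------
# End-to-end session simulation
# ---------------------------------------------------------------------------

@dataclass
class GuidanceConfig:
    """Knobs of the simulated insertion procedure."""

    step_mm: float = 1.0
    tau_ang_deg: float = 1.0
    tau_lat_mm: float = 2.0
    fre_ceiling: float = 5.0
    match_dist_tol: float = 2.0
    min_clearance_mm: float = 3.0
    max_path_length_mm: float = 250.0
    overshoot_mm: float = 6.0          # recommended tip advance past the deep margin
    pose_frames: int = 5               # tracker frames averaged per pose estimate
    breathing_amplitude: float = 0.0
    breathing_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    breathing_phase: float | str = 0.0  # planning phase is 0; "random" draws per target
    skin_attenuation: float = 0.3


@dataclass
class TargetOutcome:
    """Per-target audit record of one simulated insertion."""

    target_index: int
    tip_to_target_mm: float
    registration_fre_mm: float
    registration_tre_mm: float
    planned_depth_mm: float
    steps: int
    tip_world: np.ndarray
    target_world: np.ndarray


@dataclass
class SimulatedSession:
    """Result of one seeded end-to-end phantom session."""

    outcomes: list[TargetOutcome]
    registration: object
    plan_entries: list[np.ndarray]
    seed: int

    @property
    def tip_to_target_mm(self) -> list[float]:
        return [o.tip_to_target_mm for o in self.outcomes]


def _clip_pose_markers(clip: ClipModel, tip_world, axis_world,
                       roll_rng: np.random.Generator) -> np.ndarray:
    """World positions of the clip markers for a needle at tip/axis."""
    a = np.asarray(axis_world, float)
    a = a / np.linalg.norm(a)
    c = clip.axis
    v = np.cross(c, a)
    s, cth = np.linalg.norm(v), float(c @ a)
    if s < 1e-12:
        rot = np.eye(3) if cth > 0 else -np.eye(3) + 2 * np.outer(c, c)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)
    # arbitrary roll about the shaft — the clip can sit at any rotation
    th = roll_rng.uniform(0, 2 * np.pi)
    ct, st = np.cos(th), np.sin(th)
    k = a
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    roll = np.eye(3) * ct + kx * st + np.outer(k, k) * (1 - ct)
    r_full = roll @ rot
    t = np.asarray(tip_world, float) - r_full @ clip.tip_offset
    return (r_full @ clip.marker_points.T).T + t


def simulate_session(scene: PhantomScene, obs_model: ObservationModel,
                     guidance_cfg: GuidanceConfig | None = None,
                     seed: int = 0, clip: ClipModel | None = None,
                     segmentation=None) -> SimulatedSession:
    """Run the full pipeline on a phantom scene with a noisy tracker.

    segmentation -> fiducial co-registration -> per-tumor trajectory
    planning -> tracked insertion with clip-pose feedback -> tip placement.
    Emits per-target tip-to-target distances along with all intermediate
    truths needed for audit. Deterministic for a fixed seed.
    """
    from . import guidance as gd
    from . import segmentation as seg
    from .registration import match_constellation, target_registration_error

    if not scene.tumors:
        raise ValueError("scene has no tumors to target")
    cfg = guidance_cfg or GuidanceConfig()
    clip = clip or ClipModel.default()
    rng = np.random.default_rng(seed)

    if segmentation is None:
        segmentation = seg.segment_auto(scene.volume)
    ct_fid = Constellation(segmentation.marker_centroids,
                           list(segmentation.marker_labels))

    outcomes = []
    entries = []
    per_target_phase = []
    n_t = len(scene.tumors)
    for ti in range(n_t):
        if cfg.breathing_phase == "random":
            per_target_phase.append(float(rng.random()))
        else:
            per_target_phase.append(float(cfg.breathing_phase))

    # Registration from skin fiducials as seen at treatment time.
    # Breathing moves skin fiducials by the attenuated displacement only.
    reg_phase = per_target_phase[0]
    disp0 = breathing_displacement(cfg.breathing_amplitude,
                                   cfg.breathing_direction, reg_phase)
    skin_pts = scene.fiducials + cfg.skin_attenuation * disp0
    obs = observe_markers(skin_pts, obs_model, rng)
    reg = match_constellation(obs.points, ct_fid,
                              dist_tol=cfg.match_dist_tol,
                              fre_ceiling=cfg.fre_ceiling)
    est = reg.transform            # CT world -> tracker
    est_inv = est.inverse()

    forbidden = [scene.masks["bone"], scene.masks["vessels"]]
    for ti, tumor in enumerate(scene.tumors):
        phase = per_target_phase[ti]
        disp = breathing_displacement(cfg.breathing_amplitude,
                                      cfg.breathing_direction, phase)
        true_center = tumor.centroid_world() + disp

        # Plan on the (static) planning CT.
        seed_pt = tumor.centroid_world()
        tmask = seg.segment_tumor_seeded(scene.volume, seed_pt)
        plan_target = tmask.centroid_world()
        plan = gd.plan_trajectory(
            scene.masks["body"], plan_target, forbidden,
            min_clearance=cfg.min_clearance_mm,
            max_path_length=cfg.max_path_length_mm)
        entries.append(plan.entry)

        tre = float(target_registration_error(
            reg, obs_model.frame, plan_target[None, :])[0])

        # The operator works in tracker space through the estimated
        # registration; mapping back through the true frame gives the
        # needle's true world pose.
        err_map = obs_model.frame.inverse().compose(est)  # believed CT -> true CT
        tip = err_map.apply(plan.entry[None, :])[0]
        axis = err_map.rotation @ plan.direction

        steps = 0
        max_steps = int(cfg.max_path_length_mm / cfg.step_mm) + 50
        while steps < max_steps:
            steps += 1
            # tracker observes the clip over several video frames; the
            # averaged marker positions feed one pose estimate
            clip_world = _clip_pose_markers(clip, tip, axis, rng)
            frame_model = replace(obs_model,
                                  sigma=obs_model.sigma / math.sqrt(cfg.pose_frames),
                                  occlusion_prob=0.0)
            clip_obs = observe_markers(clip_world, frame_model, rng)
            pose = gd.needle_pose(clip_obs.points, clip, est_inv)
            remaining = float((plan_target - pose.tip) @ plan.direction)
            if remaining <= 0.05:
                break
            tip = tip + min(cfg.step_mm, remaining) * axis

        d = float(np.linalg.norm(tip - true_center))
        outcomes.append(TargetOutcome(
            target_index=ti, tip_to_target_mm=d,
            registration_fre_mm=reg.fre, registration_tre_mm=tre,
            planned_depth_mm=plan.planned_depth, steps=steps,
            tip_world=tip, target_world=true_center))

    return SimulatedSession(outcomes=outcomes, registration=reg,
                            plan_entries=entries, seed=seed)
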