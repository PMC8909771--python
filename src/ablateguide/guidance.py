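"""Trajectory planning, tracked needle pose, alignment logic and accuracy.

The planned trajectory is a straight line from a skin entry point to the
target centre. During insertion the needle is tracked through its 5-marker
clip; the displayed path turns from "blue" to "green" when the needle line
overlaps the planned line within angular and lateral tolerances, and the
remaining depth along the shaft is reported continuously (negative values
mean the tip has passed the target — deliberate overshoot of ~5-7 mm past
the deep margin is standard practice before deploying the ablation device).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import ClipModel
from .registration import (Constellation, RigidTransform, fit_rigid,
                           match_brute_force, match_constellation)
from .volume import BinaryMask, distance_to_mask, voxel_from_world, world_from_voxel


class PlanningFailureError(RuntimeError):
    """No feasible entry point under the given constraints."""


class TrackingLostError(RuntimeError):
    """Clip fit residual exceeded the acceptance ceiling."""


@dataclass
class TrajectoryPlan:
    """Straight-line plan from skin entry to target centre (world mm)."""

    entry: np.ndarray
    target: np.ndarray
    direction: np.ndarray
    planned_depth: float
    clearance: float

    def to_dict(self) -> dict:
        return {
            "entry_mm": self.entry.tolist(),
            "target_mm": self.target.tolist(),
            "direction": self.direction.tolist(),
            "planned_depth_mm": self.planned_depth,
            "clearance_mm": self.clearance,
        }


@dataclass
class NeedlePose:
    """Tracked needle state in the world frame."""

    tip: np.ndarray
    axis: np.ndarray
    clip_fre: float


@dataclass
class AlignmentStatus:
    """Blue/green alignment feedback for the displayed trajectory."""

    aligned: bool
    angular_deviation_deg: float
    lateral_offset_mm: float
    remaining_depth_mm: float


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------

def _skin_surface_points(body: BinaryMask, max_candidates: int = 5000) -> np.ndarray:
    from scipy import ndimage
    surf = body.bits & ~ndimage.binary_erosion(body.bits)
    idx = np.argwhere(surf)
    if len(idx) > max_candidates:
        stride = int(np.ceil(len(idx) / max_candidates))
        idx = idx[::stride]
    return world_from_voxel(body.grid, idx)


def _segment_min_clearance(entry, target, forbidden_dist, grid, step: float,
                           target_exclusion: float = 0.0) -> float:
    """Minimum distance to forbidden structures along the entry-target segment.

    Sample points within ``target_exclusion`` mm of the target are skipped:
    the terminal approach into the ablation zone cannot avoid structures
    that abut the tumor itself.
    """
    entry, target = np.asarray(entry, float), np.asarray(target, float)
    n = max(int(np.ceil(np.linalg.norm(target - entry) / step)), 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = entry[None, :] + ts[:, None] * (target - entry)[None, :]
    if target_exclusion > 0:
        far = np.linalg.norm(pts - target, axis=1) > target_exclusion
        if not far.any():
            return float("inf")
        pts = pts[far]
    idx = np.rint(voxel_from_world(grid, pts)).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    return float(forbidden_dist[idx[:, 0], idx[:, 1], idx[:, 2]].min())


def plan_trajectory(body: BinaryMask, target, forbidden: list[BinaryMask],
                    min_clearance: float = 3.0,
                    max_path_length: float = 250.0,
                    max_candidates: int = 5000,
                    target_exclusion: float = 10.0) -> TrajectoryPlan:
    """Choose the most suitable skin entry for a straight path to the target.

    Candidate entries are skin-surface voxel centres (deterministically
    subsampled); feasibility requires the segment to the target to keep at
    least ``min_clearance`` mm from every forbidden structure — except in
    the last ``target_exclusion`` mm before the target, where abutting
    structures are unavoidable — and the path to stay below
    ``max_path_length`` mm. Among feasible entries the shortest path wins,
    ties broken by lexicographic entry coordinates.

    Raises :class:`PlanningFailureError` naming the binding constraint.
    """
    target = np.asarray(target, dtype=float)
    cands = _skin_surface_points(body, max_candidates)
    if len(cands) == 0:
        raise PlanningFailureError("skin surface is empty")
    lengths = np.linalg.norm(cands - target, axis=1)
    order = np.lexsort((cands[:, 2], cands[:, 1], cands[:, 0], lengths))

    if forbidden and any(f.bits.any() for f in forbidden):
        union = np.zeros(body.grid.shape, dtype=bool)
        for f in forbidden:
            union |= f.bits
        fdist = distance_to_mask(BinaryMask(bits=union, grid=body.grid))
    else:
        fdist = np.full(body.grid.shape, np.inf)

    step = float(min(body.grid.spacing)) / 2.0
    too_long = True
    for i in order:
        if lengths[i] > max_path_length:
            continue
        too_long = False
        clear = _segment_min_clearance(cands[i], target, fdist, body.grid, step,
                                       target_exclusion)
        if clear >= min_clearance:
            entry = cands[i]
            depth = float(lengths[i])
            direction = (target - entry) / depth
            return TrajectoryPlan(entry=entry, target=target, direction=direction,
                                  planned_depth=depth, clearance=clear)
    binding = "max path length" if too_long else "minimum clearance"
    raise PlanningFailureError(f"no feasible entry point: binding constraint is {binding}")


# ---------------------------------------------------------------------------
# Needle tracking
# ---------------------------------------------------------------------------

def needle_pose(observed_markers, clip: ClipModel,
                tracker_to_world: RigidTransform | None = None,
                fre_ceiling: float = 5.0,
                labels_known: bool = False) -> NeedlePose:
    """Needle tip and axis from tracked clip markers.

    Fits the clip model rigidly to the observed marker positions (identity
    recovered by the same distance-signature matching used for skin
    fiducials, unless ``labels_known``), maps the calibrated tip offset and
    shaft axis through the fitted transform, and expresses the pose in the
    world frame via ``tracker_to_world``.

    Raises :class:`TrackingLostError` when the clip fit FRE exceeds
    ``fre_ceiling`` mm.
    """
    obs = np.atleast_2d(np.asarray(observed_markers, dtype=float))
    if len(obs) < 3:
        raise TrackingLostError(f"need >= 3 clip markers, saw {len(obs)}")
    try:
        if labels_known and len(obs) == len(clip.marker_points):
            res = fit_rigid(clip.marker_points, obs)
        elif len(obs) < 4:
            res = match_brute_force(obs, clip.constellation(),
                                    fre_ceiling=fre_ceiling)
        else:
            res = match_constellation(obs, clip.constellation(),
                                      dist_tol=2.0, fre_ceiling=fre_ceiling)
    except Exception as exc:
        raise TrackingLostError(f"clip fit failed: {exc}") from exc
    if res.fre > fre_ceiling:
        raise TrackingLostError(
            f"clip fit FRE {res.fre:.2f} mm exceeds ceiling {fre_ceiling} mm")
    t = res.transform  # clip frame -> tracker frame
    if tracker_to_world is not None:
        t = tracker_to_world.compose(t)
    tip = t.apply(clip.tip_offset[None, :])[0]
    axis = t.rotation @ clip.axis
    return NeedlePose(tip=tip, axis=axis / np.linalg.norm(axis), clip_fre=res.fre)


# ---------------------------------------------------------------------------
# Alignment feedback and accuracy
# ---------------------------------------------------------------------------

def alignment_status(pose: NeedlePose, plan: TrajectoryPlan,
                     tau_ang_deg: float = 1.0,
                     tau_lat_mm: float = 2.0) -> AlignmentStatus:
    """Blue/green alignment: inclusive thresholds on angle and lateral offset.

    The angular deviation is the angle between the needle axis and the
    planned direction; the lateral offset is the distance from the target
    centre to the infinite needle line. The path shows green exactly when
    both are within tolerance (boundary inclusive).
    """
    cosang = float(np.clip(pose.axis @ plan.direction, -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    v = plan.target - pose.tip
    lat = float(np.linalg.norm(v - (v @ pose.axis) * pose.axis))
    remaining = float(v @ pose.axis)
    aligned = (ang <= tau_ang_deg) and (lat <= tau_lat_mm)
    return AlignmentStatus(aligned=aligned, angular_deviation_deg=ang,
                           lateral_offset_mm=lat, remaining_depth_mm=remaining)


def insertion_depth(plan: TrajectoryPlan, pose: NeedlePose) -> dict:
    """Real-time depth readout: skin-to-target depth and remaining depth.

    The remaining depth is the projection of tip-to-target on the needle
    axis; negative values indicate overshoot past the target centre.
    """
    remaining = float((plan.target - pose.tip) @ pose.axis)
    return {"depth_mm": plan.planned_depth, "remaining_mm": remaining}


def tip_to_target(tip, target) -> float:
    """Euclidean tip-to-target-centre distance, reported to 0.1 mm."""
    tip, target = np.asarray(tip, float), np.asarray(target, float)
    if not (np.all(np.isfinite(tip)) and np.all(np.isfinite(target))):
        raise ValueError("tip and target must be finite points")
    return round(float(np.linalg.norm(tip - target)), 1)
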