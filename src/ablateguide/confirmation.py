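"""Post-ablation confirmation: pre/post co-registration and margin analysis.

After the ablation a new CT is acquired and the necrosis volume is compared
against the planned target: the assessment quantifies, as percentages, how
much of the tumor and of a predefined periablational margin shell (5 mm
thick by default) lies outside the necrosis. Technical success requires
complete tumor ablation together with more than 90% of the 5-mm margin
shell ablated (equivalently, a residual margin strictly below 10%).

Pre/post alignment here is rigid — centroid plus principal-axes
initialisation refined by maximising smoothed mask overlap — which is
sufficient for phantom validation and keeps an auditable oracle. Clinical
confirmation tools use non-rigid registration; that generalisation is a
declared divergence and out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .registration import RigidTransform
from .volume import BinaryMask, Volume, dilate_metric, resample_mask


class RegistrationFailureError(RuntimeError):
    """Pre/post mask alignment did not reach the minimum overlap."""


@dataclass
class AblationAssessment:
    """Coverage and residual-margin quantification with success flags.

    ``tumor_residual_pct`` is the percentage of tumor voxels outside the
    necrosis; ``margin_residual_pct`` the same for the margin shell.
    ``margin_success`` means the shell was ablated > 90% (residual < 10%,
    strictly: a residual of exactly 10.0% fails).
    """

    tumor_residual_pct: float
    margin_residual_pct: float
    complete_ablation: bool
    margin_success: bool
    technical_success: bool
    margin_mm: float
    tumor_volume_mm3: float
    necrosis_volume_mm3: float
    shell_volume_mm3: float
    margin_clipped_to_liver: bool = False
    empty_necrosis_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "tumor_residual_pct": round(self.tumor_residual_pct, 1),
            "margin_residual_pct": round(self.margin_residual_pct, 1),
            "complete_ablation": self.complete_ablation,
            "margin_success": self.margin_success,
            "technical_success": self.technical_success,
            "margin_mm": self.margin_mm,
            "tumor_volume_mm3": self.tumor_volume_mm3,
            "necrosis_volume_mm3": self.necrosis_volume_mm3,
            "shell_volume_mm3": self.shell_volume_mm3,
            "margin_clipped_to_liver": self.margin_clipped_to_liver,
            "empty_necrosis_warning": self.empty_necrosis_warning,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Pre/post rigid registration of organ masks
# ---------------------------------------------------------------------------

def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.logical_and(a, b).sum())
    denom = float(a.sum() + b.sum())
    return 2.0 * inter / denom if denom else 0.0


def _principal_axes(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask.bits).astype(float) * mask.grid.spacing
    c = idx.mean(axis=0)
    cov = np.cov((idx - c).T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return c + mask.grid.origin, v


def _euler_to_rot(angles):
    return RigidTransform.from_euler(np.degrees(angles)).rotation


def register_pre_post(pre: BinaryMask, post: BinaryMask,
                      min_dice: float = 0.5) -> tuple[RigidTransform, float]:
    """Rigid transform mapping pre-frame world points into the post frame.

    Initialised from the mask centroids and principal axes, then refined by
    maximising overlap of Gaussian-smoothed masks with a derivative-free
    local search over the six rigid parameters.

    Returns ``(transform, dice)``; raises
    :class:`RegistrationFailureError` if the refined Dice is below
    ``min_dice``.
    """
    if not pre.bits.any() or not post.bits.any():
        raise RegistrationFailureError("pre/post masks must be nonempty")

    c_pre, v_pre = _principal_axes(pre)
    c_post, v_post = _principal_axes(post)
    # axis signs are ambiguous: try the four proper-rotation combinations
    best_init = None
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        vp = v_pre * np.array([sx, sy, sx * sy])
        r0 = v_post @ vp.T
        if np.linalg.det(r0) < 0:
            continue
        t0 = c_post - r0 @ c_pre
        tr = RigidTransform(r0, t0)
        d = _dice(resample_mask(pre, post.grid, tr).bits, post.bits)
        if best_init is None or d > best_init[1]:
            best_init = (tr, d)
    init, _ = best_init

    sm_pre = ndimage.gaussian_filter(pre.bits.astype(np.float32), 2.0)
    sm_post = ndimage.gaussian_filter(post.bits.astype(np.float32), 2.0)

    rot0 = init.rotation
    sp_pre, o_pre = pre.grid.spacing, pre.grid.origin
    sp_post, o_post = post.grid.spacing, post.grid.origin

    def objective(params):
        dang = params[:3]
        dt = params[3:]
        rot = _euler_to_rot(dang) @ rot0
        trans = init.translation + dt
        # map post-grid voxel coords -> pre-grid voxel coords
        # world_post = R world_pre + t  =>  world_pre = R^T (world_post - t)
        a = rot.T
        # index_pre = (a (S_post i + o_post - t) - o_pre)/S_post... done via matrices
        m = (a * sp_post[None, :]) / sp_pre[:, None]
        off = (a @ (o_post - trans) - o_pre) / sp_pre
        warped = ndimage.affine_transform(sm_pre, m, offset=off,
                                          output_shape=post.grid.shape,
                                          order=1, mode="constant", cval=0.0)
        denom = np.sqrt((warped**2).sum() * (sm_post**2).sum()) + 1e-9
        return -float((warped * sm_post).sum() / denom)

    res = optimize.minimize(objective, np.zeros(6), method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 400})
    rot = _euler_to_rot(res.x[:3]) @ rot0
    trans = init.translation + res.x[3:]
    transform = RigidTransform(rot, trans)
    dice = _dice(resample_mask(pre, post.grid, transform).bits, post.bits)
    if dice < min_dice:
        raise RegistrationFailureError(
            f"pre/post registration Dice {dice:.3f} below {min_dice}")
    return transform, dice


# ---------------------------------------------------------------------------
# Margin shell and assessment
# ---------------------------------------------------------------------------

def margin_shell(tumor: BinaryMask, margin: float = 5.0,
                 liver: BinaryMask | None = None,
                 clip_to_liver: bool = True) -> BinaryMask:
    """Periablational shell: metric dilation of the tumor minus the tumor.

    With ``clip_to_liver`` and a liver mask, shell voxels outside the organ
    are discarded — tissue outside the liver cannot be ablated.
    """
    if margin <= 0:
        raise ValueError(f"margin must be > 0, got {margin}")
    if not tumor.bits.any():
        raise ValueError("empty tumor mask")
    dil = dilate_metric(tumor, margin)
    bits = dil.bits & ~tumor.bits
    if clip_to_liver and liver is not None:
        bits &= liver.bits
    return BinaryMask(bits=bits, grid=tumor.grid)


def assess_ablation(tumor_pre: BinaryMask, necrosis_post: BinaryMask,
                    transform: RigidTransform | None = None,
                    margin: float = 5.0,
                    liver_pre: BinaryMask | None = None,
                    clip_to_liver: bool = True) -> AblationAssessment:
    """Quantify tumor coverage and residual margin on the post-ablation grid.

    The tumor and its margin shell (built in the pre frame) are mapped into
    the post frame by nearest neighbour through ``transform`` and compared
    against the necrosis: ``residual = 100 * |X \\ necrosis| / |X|``.
    An empty necrosis yields 100% residuals with a warning flag rather than
    an error.
    """
    shell_pre = margin_shell(tumor_pre, margin, liver_pre, clip_to_liver)
    post_grid = necrosis_post.grid
    same_frame = transform is None and tumor_pre.grid.same_grid(post_grid)
    if same_frame:
        tumor_post, shell_post = tumor_pre, shell_pre
    else:
        tr = transform or RigidTransform.identity()
        tumor_post = resample_mask(tumor_pre, post_grid, tr)
        shell_post = resample_mask(shell_pre, post_grid, tr)

    warn = not necrosis_post.bits.any()
    def residual(x: BinaryMask) -> float:
        total = x.count
        if total == 0:
            return 0.0
        out = int((x.bits & ~necrosis_post.bits).sum())
        return 100.0 * out / total

    t_res = residual(tumor_post)
    m_res = residual(shell_post)
    complete = t_res == 0.0
    margin_ok = m_res < 10.0
    return AblationAssessment(
        tumor_residual_pct=t_res,
        margin_residual_pct=m_res,
        complete_ablation=complete,
        margin_success=margin_ok,
        technical_success=complete and margin_ok,
        margin_mm=margin,
        tumor_volume_mm3=tumor_post.volume_mm3,
        necrosis_volume_mm3=necrosis_post.volume_mm3,
        shell_volume_mm3=shell_post.volume_mm3,
        margin_clipped_to_liver=clip_to_liver and liver_pre is not None,
        empty_necrosis_warning=warn,
    )


def technical_success(assessment_or_tumor_residual,
                      margin_residual_pct: float | None = None) -> dict:
    """Success flags re-derived from stored residual percentages.

    Accepts either an :class:`AblationAssessment` or the two residual
    percentages. Complete ablation requires a zero tumor residual; margin
    success means more than 90% of the 5-mm shell was ablated, i.e.
    residual strictly below 10%; technical success is their conjunction.
    """
    if isinstance(assessment_or_tumor_residual, AblationAssessment):
        tumor_residual_pct = assessment_or_tumor_residual.tumor_residual_pct
        margin_residual_pct = assessment_or_tumor_residual.margin_residual_pct
    else:
        tumor_residual_pct = float(assessment_or_tumor_residual)
        if margin_residual_pct is None:
            raise ValueError("margin residual percentage required")
    complete = tumor_residual_pct == 0.0
    margin_ok = margin_residual_pct < 10.0
    return {
        "complete_ablation": complete,
        "margin_success": margin_ok,
        "technical_success": complete and margin_ok,
    }
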