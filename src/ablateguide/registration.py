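"""Fiducial correspondence and rigid point-set registration.

The patient's skin carries a constellation of radiopaque markers whose
pairwise distances form a non-repetitive pattern. Matching the CT-segmented
constellation to the tracker-observed one therefore reduces to a geometric
correspondence problem: candidate identities are scored by pairwise-distance
compatibility (a voting scheme over marker pairs), the best assignment is
verified by a closed-form rigid fit, and the fit is refined by
nearest-neighbour reassignment. The fiducial registration error (FRE) of
the accepted hypothesis gates acceptance.

The rigid fit itself is the classical closed-form least-squares solution:
demean both point sets, take the SVD of the cross-covariance, and guard
against reflections by flipping the smallest singular direction when the
orthogonal factor has determinant -1.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment


class DegenerateConfigurationError(ValueError):
    """Point configuration too degenerate (collinear / too few) for a rigid fit."""


class MatchingFailureError(RuntimeError):
    """No correspondence hypothesis achieved an FRE below the acceptance ceiling."""


# ---------------------------------------------------------------------------
# Rigid transform
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rotation + translation mapping one world frame to another."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection (det = -1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (self.rotation @ pts.T).T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    # JSON round-trip: row-major rotation + translation
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.ravel().tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]).reshape(3, 3), np.asarray(d["translation"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from x/y/z intrinsic rotations in degrees plus a translation."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(rz @ ry @ rx, np.asarray(translation, dtype=float))


# ---------------------------------------------------------------------------
# Constellations
# ---------------------------------------------------------------------------

@dataclass
class Constellation:
    """A labelled 3D point set with per-point pairwise-distance signatures."""

    points: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not self.labels:
            self.labels = [f"M{i:02d}" for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("label count must match point count")

    def __len__(self) -> int:
        return len(self.points)

    def distance_matrix(self) -> np.ndarray:
        d = self.points[:, None, :] - self.points[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def signatures(self) -> np.ndarray:
        """Per-point sorted distances to all other points, shape (n, n-1)."""
        dm = self.distance_matrix()
        n = len(self)
        sig = np.sort(dm[~np.eye(n, dtype=bool)].reshape(n, n - 1), axis=1)
        return sig

    def is_non_repetitive(self, tol: float) -> bool:
        """All pairwise distances mutually distinct by more than ``tol`` mm."""
        dm = self.distance_matrix()
        n = len(self)
        dists = np.sort(dm[np.triu_indices(n, k=1)])
        return bool(np.all(np.diff(dists) > tol)) if len(dists) > 1 else True


def save_points_csv(points: np.ndarray, labels, path: str | Path) -> None:
    lines = ["label,x,y,z"]
    for lab, p in zip(labels, np.atleast_2d(points)):
        lines.append(f"{lab},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_points_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    rows = Path(path).read_text().strip().splitlines()[1:]
    labels, pts = [], []
    for row in rows:
        lab, x, y, z = row.split(",")
        labels.append(lab)
        pts.append([float(x), float(y), float(z)])
    return np.asarray(pts), labels


# ---------------------------------------------------------------------------
# Closed-form rigid fit
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    """Outcome of a rigid fiducial fit.

    ``transform`` maps points from the source (first-column) frame into the
    destination (second-column) frame. ``fre`` is the RMS fiducial residual,
    so ``fre**2 == mean(residuals**2)``.
    """

    transform: RigidTransform
    correspondence: list[tuple[int, int]]
    fre: float
    residuals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "correspondence": [list(c) for c in self.correspondence],
            "fre_mm": self.fre,
            "residuals_mm": self.residuals.tolist(),
        }


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def fit_rigid(source: np.ndarray, destination: np.ndarray,
              correspondence: list[tuple[int, int]] | None = None) -> RegistrationResult:
    """Least-squares rigid transform taking ``source`` points onto ``destination``.

    Closed-form solution via SVD of the cross-covariance of the demeaned
    sets. If the orthogonal factor comes out as a reflection the smallest
    singular direction is flipped, guaranteeing a proper rotation.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    dst = np.atleast_2d(np.asarray(destination, dtype=float))
    if correspondence is None:
        if len(src) != len(dst):
            raise ValueError("point counts differ and no correspondence given")
        correspondence = [(i, i) for i in range(len(src))]
    si = np.array([c[0] for c in correspondence])
    di = np.array([c[1] for c in correspondence])
    a, b = src[si], dst[di]
    if len(a) < 3 or _collinear(a) or _collinear(b):
        raise DegenerateConfigurationError(
            f"need >= 3 non-collinear pairs, got {len(a)}"
        )
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = cb - rot @ ca
    transform = RigidTransform(rot, trans)
    res = np.linalg.norm(transform.apply(a) - b, axis=1)
    fre = float(np.sqrt(np.mean(res**2)))
    return RegistrationResult(transform, list(correspondence), fre, res)


# ---------------------------------------------------------------------------
# Correspondence by pairwise-distance voting
# ---------------------------------------------------------------------------

def _vote_matrix(obs: np.ndarray, ref: np.ndarray, tol: float) -> np.ndarray:
    """Accumulate identity votes from compatible observed/reference pairs.

    Every observed pair whose separation matches a reference pair's within
    ``tol`` casts a vote for both orderings of the identification; correct
    identities collect ~(n-1) coherent votes while spurious matches scatter.
    """
    n_o, n_r = len(obs), len(ref)
    d_o = np.linalg.norm(obs[:, None] - obs[None, :], axis=-1)
    d_r = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
    votes = np.zeros((n_o, n_r))
    iu_o = np.column_stack(np.triu_indices(n_o, k=1))
    iu_r = np.column_stack(np.triu_indices(n_r, k=1))
    do = d_o[iu_o[:, 0], iu_o[:, 1]]
    dr = d_r[iu_r[:, 0], iu_r[:, 1]]
    close = np.abs(do[:, None] - dr[None, :]) <= tol
    for oi, ri in np.column_stack(np.nonzero(close)):
        i, j = iu_o[oi]
        a, b = iu_r[ri]
        votes[i, a] += 1
        votes[j, b] += 1
        votes[i, b] += 1
        votes[j, a] += 1
    return votes


def _refine(obs: np.ndarray, ref: np.ndarray,
            corr: list[tuple[int, int]], n_iter: int = 3):
    """Alternate rigid fit and globally optimal nearest-neighbour reassignment."""
    best = fit_rigid(ref, obs, [(r, o) for o, r in corr])
    for _ in range(n_iter):
        mapped = best.transform.apply(ref)
        cost = np.linalg.norm(obs[:, None] - mapped[None, :], axis=-1)
        rows, cols = linear_sum_assignment(cost)
        new_corr = [(int(o), int(r)) for o, r in zip(rows, cols)]
        cand = fit_rigid(ref, obs, [(r, o) for o, r in new_corr])
        if sorted(new_corr) == sorted(corr):
            return new_corr, cand
        corr, best = new_corr, cand
    return corr, best


def match_constellation(observed, reference: Constellation,
                        dist_tol: float = 2.0,
                        fre_ceiling: float = 5.0) -> RegistrationResult:
    """Identify observed (unlabelled) markers against a reference constellation.

    Returns a :class:`RegistrationResult` whose ``transform`` maps
    reference-frame points into the observed frame and whose
    ``correspondence`` pairs are ``(observed_index, reference_index)``.
    Tolerates occluded markers (fewer observed points than reference).

    Raises :class:`MatchingFailureError` if no hypothesis reaches an FRE
    below ``fre_ceiling`` mm.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    ref = reference.points
    if len(obs) < 4:
        raise ValueError(f"need >= 4 observed points, got {len(obs)}")

    votes = _vote_matrix(obs, ref, dist_tol)
    cost = -votes
    rows, cols = linear_sum_assignment(cost)
    corr = [(int(o), int(r)) for o, r in zip(rows, cols)]
    try:
        corr, result = _refine(obs, ref, corr)
        result = RegistrationResult(result.transform, corr, result.fre, result.residuals)
        if result.fre <= fre_ceiling:
            return result
    except DegenerateConfigurationError:
        pass

    # Fallback: seed hypotheses from observed triangles matched to reference
    # triangles by side-length compatibility, verified by inlier rigid fits.
    result = _triangle_hypotheses(obs, ref, dist_tol, fre_ceiling)
    if result is None:
        raise MatchingFailureError(
            f"no correspondence hypothesis with FRE <= {fre_ceiling} mm"
        )
    return result


def _triangle_hypotheses(obs, ref, tol, fre_ceiling, max_hyp=2000):
    d_r = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
    n_r = len(ref)
    best = None
    n_hyp = 0
    obs_tris = list(itertools.combinations(range(min(len(obs), 8)), 3))
    for (i, j, k) in obs_tris:
        sides = (np.linalg.norm(obs[i] - obs[j]),
                 np.linalg.norm(obs[j] - obs[k]),
                 np.linalg.norm(obs[i] - obs[k]))
        for (a, b, c) in itertools.permutations(range(n_r), 3):
            if (abs(d_r[a, b] - sides[0]) > tol or abs(d_r[b, c] - sides[1]) > tol
                    or abs(d_r[a, c] - sides[2]) > tol):
                continue
            n_hyp += 1
            if n_hyp > max_hyp:
                return best
            try:
                corr, cand = _refine(obs, ref, [(i, a), (j, b), (k, c)])
            except DegenerateConfigurationError:
                continue
            if cand.fre <= fre_ceiling and (best is None or cand.fre < best.fre):
                best = RegistrationResult(cand.transform, corr, cand.fre,
                                          cand.residuals)
    return best


def match_brute_force(observed, reference: Constellation,
                      fre_ceiling: float = 5.0) -> RegistrationResult:
    """Exhaustive correspondence search; only tractable for small constellations.

    Serves as an independent oracle for :func:`match_constellation` on
    point sets of about seven markers or fewer.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    ref = reference.points
    best = None
    for perm in itertools.permutations(range(len(ref)), len(obs)):
        corr = [(r, o) for o, r in enumerate(perm)]
        try:
            cand = fit_rigid(ref, obs, corr)
        except DegenerateConfigurationError:
            continue
        if best is None or cand.fre < best.fre:
            best = RegistrationResult(cand.transform,
                                      [(o, r) for r, o in corr],
                                      cand.fre, cand.residuals)
    if best is None or best.fre > fre_ceiling:
        raise MatchingFailureError("brute-force search found no acceptable match")
    return best


def target_registration_error(result: RegistrationResult,
                              truth: RigidTransform,
                              targets) -> np.ndarray:
    """Per-target TRE: distance between estimated and true mapped positions.

    Only meaningful in simulation, where the generating transform is known.
    """
    pts = np.atleast_2d(np.asarray(targets, dtype=float))
    est = result.transform.apply(pts)
    tru = truth.apply(pts)
    return np.linalg.norm(est - tru, axis=1)
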