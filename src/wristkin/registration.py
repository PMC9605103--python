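"""Rigid coherent point drift (CPD) registration of radius point clouds.

Every scan of one hand is aligned to a chosen reference radius: the
scan's radius surface is converted to a point cloud, down-sampled on a
deterministic voxel grid, and registered to the (equally down-sampled)
reference cloud with rigid CPD — an EM fit of a Gaussian-mixture model
whose centroids are the source points moved coherently by one rigid
transform (scale locked at 1, uniform outlier component).  The resulting
transform is then propagated to that scan's carpal-bone meshes, so all
scans share the reference attitude while inter-bone geometry within a
scan is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .mesh import TriMesh
from .transforms import RigidTransform

__all__ = [
    "PointCloud",
    "CPDResult",
    "downsample",
    "stride_downsample",
    "cpd_rigid",
    "propagate",
    "inertia_prealign",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PointCloud:
    """An (n, 3) set of points in mm with a scan identifier."""

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def require_registrable(self) -> None:
        """At least 3 non-collinear points."""
        if len(self) < 3:
            raise ValueError(f"{self.source_id or 'cloud'}: needs >= 3 points")
        centered = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise ValueError(f"{self.source_id or 'cloud'}: points are (near) collinear")


def _voxel_reduce(points: np.ndarray, pitch: float) -> np.ndarray:
    """Centroid of the points falling in each occupied voxel of pitch `pitch`."""
    keys = np.floor((points - points.min(axis=0)) / pitch).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((counts.size, 3))
    np.add.at(sums, inverse, points)
    return sums / counts[:, None]


def downsample(cloud: PointCloud, target_count: int) -> PointCloud:
    """Deterministic voxel-grid down-sampling with centroid representatives.

    The grid pitch is solved by bisection so the number of occupied
    voxels lands within 10% of ``target_count``.  A cloud already at or
    below the target is returned unchanged (logged).
    """
    if target_count < 3:
        raise ValueError("target_count must be >= 3")
    pts = cloud.points
    n = pts.shape[0]
    if n <= target_count:
        log.info("%s: %d points <= target %d, returned unchanged",
                 cloud.source_id or "cloud", n, target_count)
        return cloud
    extent = pts.max(axis=0) - pts.min(axis=0)
    hi = float(np.linalg.norm(extent)) + 1e-9  # one voxel -> 1 point
    lo = hi * 1e-4
    best = None
    for _ in range(60):
        pitch = np.sqrt(lo * hi)
        reduced = _voxel_reduce(pts, pitch)
        count = reduced.shape[0]
        if best is None or abs(count - target_count) < abs(best[0] - target_count):
            best = (count, reduced)
        if abs(count - target_count) <= 0.1 * target_count:
            best = (count, reduced)
            break
        if count > target_count:
            lo = pitch  # need a coarser grid
        else:
            hi = pitch
    count, reduced = best
    if abs(count - target_count) > 0.1 * target_count:
        log.warning("%s: voxel down-sampling reached %d points (target %d)",
                    cloud.source_id or "cloud", count, target_count)
    return PointCloud(reduced, source_id=cloud.source_id)


def stride_downsample(cloud: PointCloud, target_count: int) -> PointCloud:
    """Uniform-stride down-sampling: every k-th stored point, k chosen so at
    most ``target_count`` points remain.

    Seed-free and deterministic like the voxel grid, but it applies the
    identical selection rule to every cloud, so clouds that are rigid
    copies of one another yield corresponding subsets — the property the
    registration stage needs (voxel representatives are re-quantized per
    pose, which biases the GMM fit between two down-sampled clouds).
    """
    if target_count < 3:
        raise ValueError("target_count must be >= 3")
    n = len(cloud)
    if n <= target_count:
        return cloud
    idx = np.linspace(0, n - 1, target_count).round().astype(int)
    return PointCloud(cloud.points[np.unique(idx)], source_id=cloud.source_id)


@dataclass(frozen=True)
class CPDResult:
    """Outcome of a rigid CPD registration (transform maps source -> target)."""

    transform: RigidTransform
    converged: bool
    n_iter: int
    sigma2: float
    objective: float

    @property
    def rotation(self) -> np.ndarray:
        return self.transform.rotation

    @property
    def translation(self) -> np.ndarray:
        return self.transform.translation


def inertia_prealign(source: PointCloud, target: PointCloud, probe: int = 500) -> RigidTransform:
    """Coarse alignment from cloud centroids + covariance principal axes.

    The principal axes of a point cloud are defined up to sign; the four
    proper sign patterns are scored by nearest-neighbour cost on a point
    subsample and the cheapest kept.  Intended as a warm start for
    :func:`cpd_rigid` when source and target are the same physical shape.
    """
    xs, ys = target.points, source.points
    mx, my = xs.mean(axis=0), ys.mean(axis=0)
    _, _, vx = np.linalg.svd(xs - mx, full_matrices=False)
    _, _, vy = np.linalg.svd(ys - my, full_matrices=False)
    ax, ay = vx.T, vy.T  # columns = principal directions
    if np.linalg.det(ax) < 0:
        ax[:, 2] = -ax[:, 2]
    if np.linalg.det(ay) < 0:
        ay[:, 2] = -ay[:, 2]
    tree = cKDTree(xs[:: max(1, len(xs) // probe)])
    sub = ys[:: max(1, len(ys) // probe)]
    best: tuple[float, RigidTransform] | None = None
    for signs in (np.array(s, dtype=float) for s in
                  ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))):
        rot = ax @ np.diag(signs) @ ay.T
        cand = RigidTransform(rot, mx - rot @ my)
        cost = float(tree.query(cand.apply(sub), k=1)[0].mean())
        if best is None or cost < best[0]:
            best = (cost, cand)
    return best[1]


def cpd_rigid(
    source: PointCloud,
    target: PointCloud,
    outlier_weight: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 150,
    init: RigidTransform | None = None,
) -> CPDResult:
    """Rigid coherent point drift: register ``source`` onto ``target``.

    The source points are Gaussian-mixture centroids (isotropic, shared
    variance ``sigma2``), the target points the data, plus a uniform
    outlier component of weight ``outlier_weight``.  EM alternates soft
    correspondences with a closed-form weighted Procrustes update (scale
    fixed at 1) and stops when the relative change of the negative
    log-likelihood drops below ``tol`` or at ``max_iter`` (then flagged
    unconverged).

    When ``init`` is given, EM starts from that transform and ``sigma2``
    is initialised from post-init nearest-neighbour residuals instead of
    the all-pairs mean — a warm start that skips the diffuse phase.
    """
    if not 0.0 <= outlier_weight < 1.0:
        raise ValueError("outlier_weight must be in [0, 1)")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    source.require_registrable()
    target.require_registrable()
    x = target.points  # (N, 3) data
    y = source.points  # (M, 3) GMM centroids
    n_pts, m_pts = x.shape[0], y.shape[0]

    if init is None:
        rot, trans = np.eye(3), np.zeros(3)
        ty = y
        diff2 = (
            (x * x).sum() * m_pts + (y * y).sum() * n_pts
            - 2.0 * float(x.sum(axis=0) @ y.sum(axis=0))
        )
        sigma2 = diff2 / (3.0 * n_pts * m_pts)
    else:
        rot, trans = init.rotation, init.translation
        ty = y @ rot.T + trans
        d, _ = cKDTree(x).query(ty, k=1)
        sigma2 = max(float(np.mean(d * d)), 1e-10)

    w = outlier_weight
    extent = x.max(axis=0) - x.min(axis=0)
    vol = float(np.prod(extent)) or 1.0
    diag = float(np.linalg.norm(extent))
    tree_x = cKDTree(x)
    prev_obj = np.inf
    obj = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: soft correspondences.  The Gaussian kernel is negligible
        # beyond ~7 sigma (exp(-24.5) ~ 2e-11, below the convergence tol), so
        # for large problems with small sigma the (M, N) kernel is built
        # sparsely from a KD-tree neighbour search; otherwise densely.
        cutoff = 7.0 * np.sqrt(sigma2)
        c = (2.0 * np.pi * sigma2) ** 1.5 * (w / max(1.0 - w, 1e-12)) * m_pts / vol
        if m_pts * n_pts > 250_000 and cutoff < 0.5 * diag:
            dist = tree_x.sparse_distance_matrix(
                cKDTree(ty), cutoff, output_type="coo_matrix"
            )  # (N, M)
            g = sparse.csr_matrix(
                (np.exp(-(dist.data**2) / (2.0 * sigma2)), (dist.col, dist.row)),
                shape=(m_pts, n_pts),
            )
            denom = np.asarray(g.sum(axis=0)).ravel() + c
            p = g.multiply(sparse.csr_matrix(1.0 / denom)).tocsr()
            p1 = np.asarray(p.sum(axis=1)).ravel()
            pt1 = np.asarray(p.sum(axis=0)).ravel()
            px = p @ x
        else:
            d2 = (
                (ty * ty).sum(axis=1)[:, None]
                + (x * x).sum(axis=1)[None, :]
                - 2.0 * (ty @ x.T)
            )  # (M, N)
            np.maximum(d2, 0.0, out=d2)
            g = np.exp(d2 / (-2.0 * sigma2))
            denom = g.sum(axis=0) + c
            p = g / denom
            p1 = p.sum(axis=1)
            pt1 = p.sum(axis=0)
            px = p @ x
        # negative log-likelihood of the data under the current mixture
        obj = float(
            -np.sum(np.log(denom))
            + 1.5 * n_pts * np.log(2.0 * np.pi * sigma2)
            + n_pts * np.log(m_pts / max(1.0 - w, 1e-12))
        )
        if np.isfinite(prev_obj) and abs(prev_obj - obj) < tol * abs(prev_obj):
            converged = True
            break
        prev_obj = obj
        # M-step: weighted Procrustes, scale = 1
        np_tot = float(p1.sum())
        if np_tot < 1e-12:
            log.warning("CPD: all points explained by the outlier component")
            break
        mu_x = (pt1 @ x) / np_tot
        mu_y = (p1 @ y) / np_tot
        a = (px - np.outer(p1, mu_x)).T @ (y - mu_y)  # 3x3
        u, _, vt = np.linalg.svd(a)
        s_corr = np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))])
        rot = u @ s_corr @ vt
        trans = mu_x - rot @ mu_y
        ty = y @ rot.T + trans
        xc = x - mu_x
        yc = ty - mu_x  # transformed centroids, centred on data mean
        sigma2 = (
            float((xc * xc).sum(axis=1) @ pt1)
            - 2.0 * float(np.trace((p @ xc).T @ yc))
            + float((yc * yc).sum(axis=1) @ p1)
        ) / (3.0 * np_tot)
        sigma2 = max(sigma2, 1e-12)
    if not converged:
        log.warning("CPD did not converge in %d iterations (source %s)", max_iter,
                    source.source_id or "?")
    return CPDResult(
        transform=RigidTransform(rot, trans),
        converged=converged,
        n_iter=it,
        sigma2=sigma2,
        objective=obj,
    )


def propagate(transform: RigidTransform, models: Iterable[TriMesh] | TriMesh) -> list[TriMesh] | TriMesh:
    """Apply one scan's registration transform to its carpal meshes.

    Vertices are mapped; connectivity is untouched.  Accepts one mesh or
    an iterable (a list is returned in the latter case).
    """
    single = isinstance(models, TriMesh)
    meshes: Sequence[TriMesh] = [models] if single else list(models)
    out = [
        TriMesh(vertices=transform.apply(m.vertices), faces=m.faces.copy(), process=False)
        for m in meshes
    ]
    return out[0] if single else out
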