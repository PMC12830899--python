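"""Structure comparison and shape analysis.

Two reconstructed structures of the same circular molecule live in arbitrary
frames: Hi-C constrains only pairwise distances, so comparisons must be
invariant to translation, global scale, rotation — and, because chirality is
unidentifiable from contact frequencies, optionally reflection.  Alignment
follows the Kabsch–Umeyama recipe: subtract centroids, rescale each structure
by its maximum diameter (largest pairwise distance), then rotate one onto the
other with the SVD-derived orthogonal matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist


@dataclass
class AlignmentResult:
    rotation: np.ndarray          # 3x3 orthogonal
    centroid_x: np.ndarray
    centroid_y: np.ndarray
    scale_x: float                # max diameter of X
    scale_y: float
    rmsd: float
    aligned_x: np.ndarray         # X after center/scale/rotate
    aligned_y: np.ndarray         # Y after center/scale
    reflected: bool               # True if the optimal map is improper


def max_diameter(X: np.ndarray) -> float:
    """Largest pairwise Euclidean distance (exact, O(N^2))."""
    return float(pdist(X).max())


def _kabsch(X: np.ndarray, Y: np.ndarray, allow_reflection: bool) -> tuple[np.ndarray, bool]:
    """Orthogonal R minimizing ||X R - Y||_F over O(3) (or SO(3))."""
    H = X.T @ Y
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    reflected = bool(np.linalg.det(R) < 0)
    if reflected and not allow_reflection:
        U[:, -1] *= -1
        R = U @ Vt
        reflected = False
    return R, reflected


def align(X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True) -> AlignmentResult:
    """Superpose ``X`` onto ``Y`` by centroid removal, max-diameter rescaling,
    and SVD rotation.

    By default the smaller-RMSD map over the full orthogonal group is used
    (reflection permitted, since handedness is not observable in Hi-C); set
    ``allow_reflection=False`` to restrict to proper rotations.  Degenerate
    (e.g. collinear) inputs still return an alignment.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.shape[0] < 3:
        raise ValueError("structures must share a shape with at least 3 points")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    sx, sy = max_diameter(X), max_diameter(Y)
    Xn = (X - cx) / (sx if sx > 0 else 1.0)
    Yn = (Y - cy) / (sy if sy > 0 else 1.0)
    R, reflected = _kabsch(Xn, Yn, allow_reflection)
    Xa = Xn @ R
    rmsd = float(np.sqrt(np.mean(np.sum((Xa - Yn) ** 2, axis=1))))
    return AlignmentResult(R, cx, cy, sx, sy, rmsd, Xa, Yn, reflected)


def distance_pcc(X: np.ndarray, Y: np.ndarray) -> float:
    """Pearson correlation of the two off-diagonal pairwise-distance sets.

    Needs no alignment: pairwise distances are invariant to rigid motion,
    and correlation is invariant to the global scale of either input.
    """
    dx, dy = pdist(X), pdist(Y)
    return float(np.corrcoef(dx, dy)[0, 1])


def compare(X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True) -> tuple[float, float]:
    """(RMSD after alignment, distance-matrix PCC) for two same-size structures."""
    if np.asarray(X).shape[0] < 3:
        raise ValueError("need at least 3 points")
    return align(X, Y, allow_reflection).rmsd, distance_pcc(X, Y)


def _window(X: np.ndarray, start: int, length: int) -> np.ndarray:
    idx = np.arange(start, start + length) % X.shape[0]
    return X[idx]


def permutation_similarity(
    X: np.ndarray,
    region1: tuple[int, int],
    region2: tuple[int, int],
    n_perm: int = 5000,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> dict:
    """Permutation test for similarity of two equal-length windows of a structure.

    Random windows ``S_i`` of the same length are sampled (circularly, with
    wrap-around) from ``background`` — by default the molecule itself — and
    the empirical p-value is the fraction of times the random pair
    ``(D1, S_i)`` is at least as similar (smaller RMSD / larger PCC) as the
    tested pair ``(D1, D2)``, with a +1 pseudocount so p >= 1/(n_perm+1).
    """
    (s1, l1), (s2, l2) = region1, region2
    if l1 != l2:
        raise ValueError("regions must have equal length")
    bg = X if background is None else np.asarray(background, dtype=float)
    if l1 > bg.shape[0]:
        raise ValueError("region longer than the sampled molecule")
    D1, D2 = _window(X, s1, l1), _window(X, s2, l2)
    obs_rmsd, obs_pcc = compare(D1, D2)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, bg.shape[0], size=n_perm)
    hits_rmsd = hits_pcc = 0
    for s in starts:
        r, p = compare(D1, _window(bg, int(s), l1))
        hits_rmsd += r <= obs_rmsd
        hits_pcc += p >= obs_pcc
    return {
        "rmsd": obs_rmsd,
        "pcc": obs_pcc,
        "p_rmsd": (hits_rmsd + 1) / (n_perm + 1),
        "p_pcc": (hits_pcc + 1) / (n_perm + 1),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# minimum bounding box


def _box_in_frame(P: np.ndarray, frame: np.ndarray) -> tuple[float, np.ndarray]:
    proj = P @ frame.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    return float(np.prod(ext)), ext


def _pca_frame(P: np.ndarray) -> np.ndarray:
    C = np.cov((P - P.mean(axis=0)).T)
    _, vecs = np.linalg.eigh(C)
    return vecs.T


def _min_area_rect_2d(pts: np.ndarray) -> tuple[float, float, float]:
    """Rotating calipers in the plane: (area, width, height) of the minimal
    enclosing rectangle of a 2D point set."""
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:
        # collinear points: rectangle degenerates to a segment
        d = pdist(pts)
        return 0.0, float(d.max() if len(d) else 0.0), 0.0
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))
    best = (np.inf, 0.0, 0.0)
    for th in angles:
        R = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        q = hull @ R.T
        w, h = q.max(axis=0) - q.min(axis=0)
        if w * h < best[0]:
            best = (float(w * h), float(w), float(h))
    return best


def bounding_box(X: np.ndarray, method: str = "calipers") -> dict:
    """Minimum-volume bounding cuboid of a 3D point set.

    ``pca``: the box aligned with the principal axes (fast, no optimality
    guarantee).  ``calipers``: search boxes flush with each convex-hull face,
    solving the in-plane problem exactly by rotating calipers; the PCA frame
    is included among the candidates, so the calipers volume never exceeds
    the PCA volume.  Returns sorted edge lengths and the min/max edge ratio
    (0 for degenerate, e.g. coplanar, inputs).
    """
    P = np.asarray(X, dtype=float)
    if P.shape[0] < 4:
        raise ValueError("need at least 4 points for a 3D bounding box")
    pca_frame = _pca_frame(P)
    if method == "pca":
        vol, ext = _box_in_frame(P, pca_frame)
        edges = np.sort(ext)
    elif method == "calipers":
        best_vol, best_edges = _box_in_frame(P, pca_frame)
        best_edges = np.sort(best_edges)
        try:
            hull = ConvexHull(P)
            normals = hull.equations[:, :3]
        except QhullError:
            normals = np.empty((0, 3))
        for n in normals:
            n = n / np.linalg.norm(n)
            # orthonormal in-plane frame
            u = np.cross(n, [1.0, 0.0, 0.0])
            if np.linalg.norm(u) < 1e-9:
                u = np.cross(n, [0.0, 1.0, 0.0])
            u /= np.linalg.norm(u)
            v = np.cross(n, u)
            height = float((P @ n).max() - (P @ n).min())
            area, w, h = _min_area_rect_2d(P @ np.stack([u, v]).T)
            if area * height < best_vol:
                best_vol = area * height
                best_edges = np.sort([w, h, height])
        vol, edges = best_vol, best_edges
    else:
        raise ValueError(f"unknown method {method!r}")
    ratio = float(edges[0] / edges[-1]) if edges[-1] > 0 else 0.0
    return {"edges": np.asarray(edges, dtype=float), "volume": float(vol), "ratio": ratio}


def alpha_error(true_alphas, estimated_alphas) -> float:
    """Mean relative error of the decay exponent, |a_hat - a| / |a|.

    The magnitude of the true exponent sits in the denominator so that the
    error is a positive fraction even though alpha itself is negative.
    """
    t = np.atleast_1d(np.asarray(true_alphas, dtype=float))
    e = np.atleast_1d(np.asarray(estimated_alphas, dtype=float))
    if t.size == 0 or t.size != e.size:
        raise ValueError("need equal-length, non-empty inputs")
    if np.any(t == 0):
        raise ValueError("true alpha must be nonzero")
    return float(np.mean(np.abs(e - t) / np.abs(t)))
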