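"""Cross-microscope coordinate registration.

Cells are selected under a fluorescence microscope and must be found again
on the Raman instrument's stage.  Both stages report positions in
micrometres, and a projective transformation (homography) between the two
planes is estimated from engraved registration marks: four or more point
correspondences per well.

Estimation uses the normalized direct linear transform (DLT): both point
sets are translated to their centroid and scaled so the mean distance from
it is sqrt(2), the 2n x 9 homogeneous system is solved by the smallest
right singular vector, and the result is denormalized.  With exactly four
non-degenerate pairs the fit is exact; with more it is the algebraic
least-squares homography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ArityError, PointAtInfinityError, RankError

__all__ = [
    "PointPair",
    "ProjectiveTransform",
    "estimate_projective",
    "apply_transform",
    "registration_rmse",
    "read_point_pairs",
    "write_transform",
    "read_transform",
]

_W_TOL = 1e-12


@dataclass(frozen=True)
class PointPair:
    """One (source, destination) stage-coordinate correspondence in um."""

    src: tuple[float, float]
    dst: tuple[float, float]

    def __post_init__(self) -> None:
        for p in (self.src, self.dst):
            if not all(np.isfinite(p)):
                raise ValueError(f"non-finite point coordinate {p}")


@dataclass(frozen=True)
class ProjectiveTransform:
    """3x3 homogeneous matrix mapping source-plane to destination-plane points."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.matrix, dtype=float)
        if h.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(h)) < 1e-12 * max(1.0, np.abs(h).max() ** 3):
            raise RankError("homography matrix is singular")
        if abs(h[2, 2]) > _W_TOL:
            h = h / h[2, 2]
        object.__setattr__(self, "matrix", h)

    @classmethod
    def identity(cls) -> "ProjectiveTransform":
        return cls(np.eye(3))

    @property
    def inverse(self) -> "ProjectiveTransform":
        return ProjectiveTransform(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "ProjectiveTransform") -> "ProjectiveTransform":
        return ProjectiveTransform(self.matrix @ other.matrix)


def _collinearity_check(points: np.ndarray) -> None:
    """Raise RankError if any 3 points among any 4 used are (near-)collinear."""
    n = len(points)
    scale = max(np.ptp(points[:, 0]), np.ptp(points[:, 1]), 1e-12)
    groups = combinations(range(n), 3) if n == 4 else []
    for i, j, k in groups:
        a, b, c = points[[i, j, k]]
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        if area2 < 1e-9 * scale**2:
            raise RankError(f"source points {i}, {j}, {k} are collinear")


def _normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid at origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    if d < 1e-12:
        raise RankError("all points coincide")
    s = np.sqrt(2.0) / d
    t = np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )
    homog = np.column_stack([pts, np.ones(len(pts))])
    return (homog @ t.T)[:, :2], t


def estimate_projective(pairs: list[PointPair]) -> ProjectiveTransform:
    """Estimate the homography carrying each pair's src to its dst.

    Exact on four non-degenerate pairs; least squares (normalized DLT)
    beyond four.
    """
    if len(pairs) < 4:
        raise ArityError(f"need at least 4 point pairs, got {len(pairs)}")
    src = np.array([p.src for p in pairs], dtype=float)
    dst = np.array([p.dst for p in pairs], dtype=float)
    _collinearity_check(src)
    src_n, t_src = _normalize(src)
    dst_n, t_dst = _normalize(dst)

    n = len(pairs)
    a = np.zeros((2 * n, 9))
    for i, ((x, y), (u, v)) in enumerate(zip(src_n, dst_n)):
        a[2 * i] = [-x, -y, -1, 0, 0, 0, u * x, u * y, u]
        a[2 * i + 1] = [0, 0, 0, -x, -y, -1, v * x, v * y, v]
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-9 * s[0]:
        raise RankError("degenerate point configuration: DLT system is rank deficient")
    h_n = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h_n @ t_src
    return ProjectiveTransform(h)


def apply_transform(transform: ProjectiveTransform, points) -> np.ndarray:
    """Map (x, y) points through the homography; returns an (n, 2) array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    homog = np.column_stack([pts, np.ones(len(pts))])
    out = homog @ transform.matrix.T
    w = out[:, 2]
    scale = max(1.0, np.abs(transform.matrix).max())
    bad = np.abs(w) < _W_TOL * scale
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise PointAtInfinityError(f"point {tuple(pts[i])} maps to infinity (w={w[i]:g})")
    return out[:, :2] / w[:, None]


def registration_rmse(transform: ProjectiveTransform, pairs: list[PointPair]) -> float:
    """Root-mean-square Euclidean residual of the transform on the pairs, in um."""
    if len(pairs) < 1:
        raise ArityError("need at least one pair to compute an RMSE")
    src = np.array([p.src for p in pairs], dtype=float)
    dst = np.array([p.dst for p in pairs], dtype=float)
    res = apply_transform(transform, src) - dst
    return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))


# ---------------------------------------------------------------------------
# plain-text interfaces


def read_point_pairs(path) -> list[PointPair]:
    """CSV with columns (name, src_x, src_y, dst_x, dst_y)."""
    df = pd.read_csv(path)
    needed = {"src_x", "src_y", "dst_x", "dst_y"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: point-pair CSV needs columns {sorted(needed)}")
    return [
        PointPair((float(r.src_x), float(r.src_y)), (float(r.dst_x), float(r.dst_y)))
        for r in df.itertuples()
    ]


def write_transform(transform: ProjectiveTransform, path, rmse: float | None = None) -> None:
    payload = {"matrix": [float(x) for x in transform.matrix.ravel()]}
    if rmse is not None:
        payload["rmse_um"] = float(rmse)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_transform(path) -> ProjectiveTransform:
    with open(path) as fh:
        payload = json.load(fh)
    return ProjectiveTransform(np.array(payload["matrix"], dtype=float).reshape(3, 3))
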