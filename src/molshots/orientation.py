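"""Canonical camera orientation from PCA of atomic coordinates.

The front view lays the structure flat against the screen: the direction of
largest coordinate variance goes along screen-x, the second along screen-y,
the smallest along depth.  Axis signs are fixed deterministically so that
arbitrarily pre-rotated copies of the same structure land in the same pose:

* per axis, pick the sign making the third central moment (skewness) of the
  projected coordinates non-negative;
* if the projection is essentially symmetric (|skewness| < 1e-9), make the
  projection of the atom furthest from the centroid non-negative instead;
* the third axis is the cross product of the first two, so the result is
  always a proper rotation (det = +1).

Degenerate spectra (tied eigenvalues, collinear or coincident points) are
completed deterministically by preferring alignment with the world axes in
x, y, z priority order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

_SKEW_TOL = 1e-9
_TIE_RTOL = 1e-9

VIEW_KINDS = ("front", "side", "top")

# +90 degrees about screen-y: viewer moves to the structure's right.
ROT_SIDE = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
# +90 degrees about screen-x: viewer moves above.
ROT_TOP = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class PrincipalAxes:
    """Orthonormal principal axes (rows) with descending variances."""

    axes: np.ndarray  # (3, 3), row i is axis i
    variances: np.ndarray  # (3,), descending
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = self.variances
        if not (v[0] >= v[1] >= v[2] >= -1e-12):
            raise ValueError(f"variances not descending/non-negative: {v}")
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValueError("axes not orthonormal within 1e-9")


def assert_rotation(m: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate that ``m`` is a proper rotation matrix; returns it."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {m.shape}")
    if not np.allclose(m @ m.T, np.eye(3), atol=atol):
        raise ValueError("matrix is not orthonormal")
    if not np.isclose(np.linalg.det(m), 1.0, atol=atol):
        raise ValueError(f"determinant {np.linalg.det(m)} != +1")
    return m


def principal_axes(coords) -> PrincipalAxes:
    """Eigendecomposition of the mean-centered coordinate covariance.

    All points are weighted equally.  Raises
    :class:`DegenerateGeometryError` for an empty input; coincident or
    collinear inputs are flagged degenerate and completed with world axes.
    """
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    if pts.size == 0:
        raise DegenerateGeometryError("principal_axes requires at least 1 point")
    if pts.shape[1] != 3:
        raise ValueError(f"expected (N, 3) coordinates, got {pts.shape}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    variances = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T  # rows

    scale = max(variances[0], 1.0)
    ties = [
        abs(variances[i] - variances[i + 1]) <= _TIE_RTOL * scale for i in range(2)
    ]
    degenerate = any(ties)
    if degenerate:
        axes = _complete_degenerate(axes, variances, ties)
    return PrincipalAxes(axes=axes, variances=variances, degenerate=degenerate)


def _complete_degenerate(axes: np.ndarray, variances: np.ndarray, ties) -> np.ndarray:
    """Re-pick bases inside tied eigen-subspaces to favour world axes."""
    # Partition 0..2 into groups of tied indices.
    groups: list[list[int]] = [[0]]
    for i in range(1, 3):
        if ties[i - 1]:
            groups[-1].append(i)
        else:
            groups.append([i])
    world = np.eye(3)
    new_axes = axes.copy()
    for group in groups:
        if len(group) == 1:
            continue
        basis = axes[group]  # spans the tied subspace
        proj = basis.T @ basis  # projector onto subspace (basis rows orthonormal)
        chosen: list[np.ndarray] = []
        for w in world:  # x, y, z priority
            v = proj @ w
            for c in chosen:
                v = v - (v @ c) * c
            norm = np.linalg.norm(v)
            if norm > 1e-6:
                chosen.append(v / norm)
            if len(chosen) == len(group):
                break
        # Fall back to the original eigenvectors if the subspace was odd.
        i = 0
        while len(chosen) < len(group) and i < len(group):
            v = basis[i]
            for c in chosen:
                v = v - (v @ c) * c
            norm = np.linalg.norm(v)
            if norm > 1e-6:
                chosen.append(v / norm)
            i += 1
        new_axes[group] = np.stack(chosen)
    return new_axes


def _fix_sign(axis: np.ndarray, centered: np.ndarray) -> np.ndarray:
    proj = centered @ axis
    spread = float(np.mean(proj**2))
    if spread > 0:
        skew = float(np.mean(proj**3)) / spread**1.5
    else:
        skew = 0.0
    if abs(skew) >= _SKEW_TOL:
        return axis if skew > 0 else -axis
    # Symmetric distribution: orient toward the atom furthest from centroid.
    far = int(np.argmax(np.linalg.norm(centered, axis=1)))
    coord = float(centered[far] @ axis)
    if abs(coord) > 1e-12:
        return axis if coord > 0 else -axis
    return axis


def canonical_rotation(coords) -> np.ndarray:
    """Rotation R mapping the structure into its canonical front pose.

    ``R @ (x - centroid)`` puts the largest-variance direction on screen-x,
    the second on screen-y, the smallest on depth-z; det(R) = +1.
    """
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    pa = principal_axes(pts)
    centered = pts - pts.mean(axis=0)
    a1 = _fix_sign(pa.axes[0], centered)
    a2 = _fix_sign(pa.axes[1], centered)
    a3 = np.cross(a1, a2)
    rot = np.stack([a1, a2, a3])
    return assert_rotation(rot, atol=1e-9)


def view_rotation(front: np.ndarray, view: str) -> np.ndarray:
    """Derive the side/top camera from the front rotation."""
    front = np.asarray(front, dtype=float)
    if view == "front":
        return front
    if view == "side":
        return ROT_SIDE @ front
    if view == "top":
        return ROT_TOP @ front
    raise ValueError(f"unknown view {view!r}; expected one of {VIEW_KINDS}")
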