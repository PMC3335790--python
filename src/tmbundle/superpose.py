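"""Rigid-body superposition of 7TM bundles.

Two fitting modes are provided:

* :func:`kabsch_fit` — the plain least-squares optimum over proper rotations
  and translations (Kabsch), used as the inner solver everywhere.
* :func:`ssm_fit` — a secondary-structure-matching style two-stage fit for
  bundles: the seven helices are first matched as rigid elements through
  their axes and centroids to get an initial transform, which is then
  refined by iterated trimmed least squares on the 200 matched Cαs.

The reported rmsd of an SSM fit always covers all 200 positions in the
converged frame; ``n_matched`` records how many positions survived the
distance trimming separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .numbering import Bundle

__all__ = [
    "Superposition",
    "FitError",
    "kabsch_fit",
    "ssm_fit",
    "per_position_deviation",
    "rmsd_between",
    "helix_axis",
]


class FitError(ValueError):
    """Degenerate or underdetermined superposition input."""


@dataclass
class Superposition:
    """Proper rigid transform y = R x + t with its fit quality."""

    rotation: np.ndarray      # (3, 3), orthonormal, det +1
    translation: np.ndarray   # (3,), Å
    rmsd: float               # Å, over the positions the caller asked about
    n_matched: int
    converged: bool = True

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1), not a reflection")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls, rmsd: float = 0.0, n_matched: int = 0) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), rmsd, n_matched)

    def as_row_major(self) -> list[float]:
        """Transform export: 9 rotation entries (row-major) + 3 translation."""
        return [*self.rotation.reshape(-1).tolist(), *self.translation.tolist()]


def _as_coords(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise FitError(f"{name} must be an N x 3 array, got shape {x.shape}")
    return x


def kabsch_fit(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (matched order).

    Minimises the root-mean-square Cα distance over all proper rotations and
    translations.  Degenerate input (fewer than 3 points, or points that are
    collinear so the rotation is not unique) raises :class:`FitError`.
    """
    moving = _as_coords(moving, "moving")
    fixed = _as_coords(fixed, "fixed")
    if moving.shape != fixed.shape:
        raise FitError(f"shape mismatch: {moving.shape} vs {fixed.shape}")
    n = moving.shape[0]
    if n < 3:
        raise FitError(f"need at least 3 points, got {n}")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    m0, f0 = moving - mc, fixed - fc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(f0, tol=1e-8) < 2:
        raise FitError("degenerate (collinear) coordinates: rotation not determined")
    rot, _ = Rotation.align_vectors(f0, m0)
    R = rot.as_matrix()
    t = fc - R @ mc
    rmsd = float(np.sqrt(np.mean(np.sum((moving @ R.T + t - fixed) ** 2, axis=1))))
    return Superposition(R, t, rmsd, n_matched=n)


def helix_axis(coords: np.ndarray) -> np.ndarray:
    """Unit principal axis of a helix's Cα set, oriented N→C."""
    coords = _as_coords(coords, "helix")
    c = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - c)
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ssm_fit(moving: Bundle, fixed: Bundle, cutoff: float = 3.0,
            max_rounds: int = 20) -> Superposition:
    """Secondary-structure-matching superposition of one bundle onto another.

    Stage 1 treats each of the seven helices as a rigid element: for every
    helix, three pseudo-points (centroid and centroid ± quarter-length along
    the N→C axis) are matched between the bundles, and a Kabsch fit over the
    21 pseudo-points yields the initial transform.  Stage 2 refines with
    iterated least squares on the 200 Cα pairs: each round, pairs farther
    than min(``cutoff``, max(0.5 Å, 2 × rms distance of the currently
    matched pairs)) are discarded and the fit recomputed, until the matched
    set is stable
    (or ``max_rounds`` is hit, in which case ``converged`` is False).  The
    adaptive term lets the refinement lock onto the mutually consistent core
    when a single helix is rigidly displaced by less than ``cutoff``; if
    trimming would leave fewer than 3 pairs, all pairs are kept.

    The returned rmsd covers all 200 positions in the final frame.
    """
    def helix_points(b: Bundle) -> np.ndarray:
        pts = []
        for h in range(1, 8):
            xyz = b.helix_coords(h)
            c = xyz.mean(axis=0)
            u = helix_axis(xyz)
            half = 0.25 * np.linalg.norm(xyz[-1] - xyz[0])
            pts.extend([c - half * u, c, c + half * u])
        return np.array(pts)

    init = kabsch_fit(helix_points(moving), helix_points(fixed))

    mov, fix = moving.coords, fixed.coords
    n = mov.shape[0]
    sup = init
    matched = np.ones(n, dtype=bool)
    converged = False
    for _ in range(max_rounds):
        moved = sup.apply(mov)
        d = np.linalg.norm(moved - fix, axis=1)
        rms_matched = np.sqrt(np.mean(d[matched] ** 2))
        # floor keeps a noise-free matched core from shrinking the threshold
        # to zero and un-trimming genuine outliers
        new = d < min(cutoff, max(0.5, 2.0 * rms_matched))
        if new.sum() < 3:  # trimming collapsed; keep everything
            new = np.ones(n, dtype=bool)
        if np.array_equal(new, matched) and sup is not init:
            converged = True
            break
        matched = new
        sup = kabsch_fit(mov[matched], fix[matched])
    final_rmsd = _rmsd(sup.apply(mov), fix)
    return Superposition(sup.rotation, sup.translation, final_rmsd,
                         n_matched=int(matched.sum()), converged=converged)


def per_position_deviation(a: Bundle, b: Bundle, frame: str = "common_reference") -> np.ndarray:
    """Cα–Cα distance at each serial position between two bundles.

    ``frame="common_reference"`` assumes both bundles are already expressed
    in a shared frame (e.g. each fitted once onto the reference chain) and
    measures raw distances.  ``frame="pairwise"`` performs a fresh SSM fit of
    ``b`` onto ``a`` first, so any whole-bundle rigid offset is removed.
    """
    if frame == "pairwise":
        b = b.transformed(ssm_fit(b, a))
    elif frame != "common_reference":
        raise ValueError(f"unknown frame {frame!r}")
    return np.linalg.norm(a.coords - b.coords, axis=1)


def rmsd_between(a: Bundle, b: Bundle, method: str = "ssm") -> float:
    """Rmsd over the 200 Cαs after superposing ``b`` onto ``a``."""
    if method == "ssm":
        return ssm_fit(b, a).rmsd
    if method == "kabsch":
        return kabsch_fit(b.coords, a.coords).rmsd
    raise ValueError(f"unknown method {method!r}; expected 'ssm' or 'kabsch'")
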