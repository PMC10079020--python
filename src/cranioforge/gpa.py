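"""Generalized Procrustes superimposition with bending-energy sliding.

Configurations are centred, scaled to unit centroid size, and rotated to an
iteratively updated consensus (partial Procrustes: no tangent-space
projection; reflections are disallowed, det(R) = +1, since mandible photos
are flipped to one side upstream).  Semilandmarks may then slide along their
curve tangents to minimize the thin-plate-spline bending energy of each
specimen relative to the consensus, after which the superimposition is
re-run; the cycle repeats a configurable number of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import LandmarkConfiguration


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of the points from their centroid."""
    pts = np.asarray(points, dtype=float)
    centred = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs <= 0:
        raise ValueError("all points identical: centroid size is zero")
    return cs


def optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det = +1) minimizing ||X R - target||_F."""
    H = X.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


def _canonical_rotation(shape: np.ndarray) -> np.ndarray:
    """Rotation (det = +1) taking a centred shape onto its principal axes."""
    c = shape - shape.mean(axis=0)
    _, V = np.linalg.eigh(c.T @ c)
    V = V[:, ::-1]  # descending variance
    if np.linalg.det(V) < 0:
        V[:, 1] = -V[:, 1]
    rotated = c @ V
    if np.sum(rotated[:, 0] ** 3) < 0:
        V = -V  # 180-degree turn, still a rotation
    return V


def procrustes_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Partial Procrustes distance after centring, unit-scaling and rotating B onto A."""
    A = np.asarray(A, float) - np.mean(A, axis=0)
    B = np.asarray(B, float) - np.mean(B, axis=0)
    A = A / np.sqrt(np.sum(A**2))
    B = B / np.sqrt(np.sum(B**2))
    R = optimal_rotation(B, A)
    return float(np.sqrt(np.sum((B @ R - A) ** 2)))


@dataclass
class ShapeDataset:
    """Superimposed landmark data for a sample of specimens."""

    aligned: np.ndarray  # (n, k, 2) Procrustes coordinates
    consensus: np.ndarray  # (k, 2) mean shape, unit centroid size
    centroid_size: np.ndarray  # (n,) in input units
    specimen_ids: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    curves: list[list[int]] = field(default_factory=list)

    @property
    def log10_centroid_size(self) -> np.ndarray:
        return np.log10(self.centroid_size)

    def flat(self) -> np.ndarray:
        """(n, 2k) matrix of aligned coordinates, x1 y1 x2 y2 ..."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


class GeneralizedProcrustes:
    """Generalized Procrustes analysis, optionally with sliding semilandmarks.

    Parameters
    ----------
    tol : float
        Convergence threshold on the root-mean-square change of the consensus.
    max_iter : int
        Maximum superimposition iterations per GPA pass.
    n_slide_cycles : int
        Bending-energy sliding cycles (0 disables sliding).

    Fitted attributes (trailing underscore): ``consensus_``, ``aligned_``,
    ``centroid_size_``, ``n_iter_``, ``bending_energy_path_`` (per-cycle total
    bending energy when sliding), ``max_slide_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, n_slide_cycles: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.n_slide_cycles = n_slide_cycles

    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter, "n_slide_cycles": self.n_slide_cycles}

    def set_params(self, **params) -> "GeneralizedProcrustes":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        X: Sequence[LandmarkConfiguration] | np.ndarray,
        roles: Optional[Sequence[str]] = None,
        curves: Optional[Sequence[Sequence[int]]] = None,
    ) -> "GeneralizedProcrustes":
        arr, ids, roles, curves = _coerce_configs(X, roles, curves)
        n, k, _ = arr.shape
        if n < 2:
            raise ValueError("GPA needs at least 2 configurations")

        sizes = np.empty(n)
        scaled = np.empty_like(arr)
        for i in range(n):
            c = arr[i] - arr[i].mean(axis=0)
            cs = np.sqrt(np.sum(c**2))
            if cs <= 0:
                raise ValueError(f"degenerate (zero-size) configuration: {ids[i]}")
            sizes[i] = cs
            scaled[i] = c / cs

        aligned, consensus, n_iter = self._superimpose(scaled)
        self.bending_energy_path_: list[np.ndarray] = []
        self.max_slide_: float = 0.0
        if self.n_slide_cycles > 0:
            semis = [i for i, r in enumerate(roles) if r == "semi"]
            if semis and not curves:
                raise ValueError("sliding requires curve membership for semilandmarks")
            for _ in range(self.n_slide_cycles):
                # energies measured around the slide step itself (same
                # consensus, same B): the least-squares slide cannot increase
                # them; the subsequent GPA re-fit changes the consensus
                before = _total_bending_energies(aligned, consensus)
                slid, max_t = _slide_once(aligned, consensus, curves)
                after = _total_bending_energies(slid, consensus)
                self.max_slide_ = max(self.max_slide_, max_t)
                self.bending_energy_path_.append(np.column_stack([before, after]))
                aligned, consensus, _ = self._superimpose(slid)

        self.aligned_ = aligned
        self.consensus_ = consensus
        self.centroid_size_ = sizes
        self.specimen_ids_ = ids
        self.roles_ = list(roles)
        self.curves_ = [list(c) for c in curves]
        self.n_iter_ = n_iter
        return self

    def _superimpose(self, scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        n = scaled.shape[0]
        work = np.empty_like(scaled)
        for i in range(n):  # re-centre/re-scale (needed after sliding)
            c = scaled[i] - scaled[i].mean(axis=0)
            work[i] = c / np.sqrt(np.sum(c**2))
        consensus = work[0].copy()
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for i in range(n):
                work[i] = work[i] @ optimal_rotation(work[i], consensus)
            new = work.mean(axis=0)
            new -= new.mean(axis=0)
            new /= np.sqrt(np.sum(new**2))
            delta = np.sqrt(np.mean((new - consensus) ** 2))
            consensus = new
            if delta < self.tol:
                break
        # final rotation pass so aligned configs match the converged consensus
        for i in range(n):
            work[i] = work[i] @ optimal_rotation(work[i], consensus)
        consensus = work.mean(axis=0)
        # canonical orientation: consensus principal axes on the coordinate
        # axes, 180-degree ambiguity broken by the sign of the x third moment,
        # so the output does not depend on input order or pre-rotation
        R = _canonical_rotation(consensus)
        work = work @ R
        return work, consensus @ R, n_iter

    def transform(self, X: Sequence[LandmarkConfiguration] | np.ndarray) -> np.ndarray:
        """Align new configurations to the fitted consensus (no sliding)."""
        arr, _, _, _ = _coerce_configs(X, None, None)
        out = np.empty_like(arr)
        for i in range(arr.shape[0]):
            c = arr[i] - arr[i].mean(axis=0)
            c /= np.sqrt(np.sum(c**2))
            out[i] = c @ optimal_rotation(c, self.consensus_)
        return out

    def fit_transform(self, X, roles=None, curves=None) -> np.ndarray:
        return self.fit(X, roles, curves).aligned_

    def dataset(self) -> ShapeDataset:
        return ShapeDataset(
            aligned=self.aligned_,
            consensus=self.consensus_,
            centroid_size=self.centroid_size_,
            specimen_ids=self.specimen_ids_,
            roles=self.roles_,
            curves=self.curves_,
        )


def gpa(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ShapeDataset:
    """Functional wrapper: superimpose configurations without sliding."""
    return GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(configs).dataset()


def slide_semilandmarks(
    dataset: ShapeDataset,
    n_cycles: int = 3,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ShapeDataset:
    """Slide semilandmarks by the bending-energy criterion, re-running GPA each cycle."""
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter, n_slide_cycles=n_cycles)
    est.fit(dataset.aligned, roles=dataset.roles, curves=dataset.curves)
    out = est.dataset()
    out.centroid_size = dataset.centroid_size  # sizes come from the raw data
    out.specimen_ids = dataset.specimen_ids
    return out


# ---------------------------------------------------------------------------
# Thin-plate-spline bending energy
# ---------------------------------------------------------------------------

def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """TPS bending-energy matrix of a 2-D reference configuration.

    Kernel U(r) = r^2 log r^2 with U(0) = 0; L = [[K, Q], [Q^T, 0]] with
    Q = [1, x, y]; returns the upper-left k x k block of L^{-1}.  The result
    is symmetric positive-semidefinite with a 3-dimensional (affine) null
    space.
    """
    P = np.asarray(reference, dtype=float)
    k = P.shape[0]
    d2 = np.sum((P[:, None, :] - P[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(k), P])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError:
        raise ValueError("reference points are collinear: TPS matrix is singular") from None
    if not np.all(np.isfinite(Linv)) or np.linalg.cond(L) > 1e14:
        raise ValueError("reference points are (near-)collinear: TPS matrix is singular")
    B = Linv[:k, :k]
    return (B + B.T) / 2.0


def bending_energy(B: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of mapping the reference of ``B`` onto ``target``."""
    t = np.asarray(target, dtype=float)
    return float(t[:, 0] @ B @ t[:, 0] + t[:, 1] @ B @ t[:, 1])


def _total_bending_energies(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    B = bending_energy_matrix(consensus)
    return np.array([bending_energy(B, cfg) for cfg in aligned])


def _curve_tangents(points: np.ndarray, curves: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangents at each semilandmark from neighbour chords.

    Interior points use the chord between their two curve neighbours;
    endpoint semilandmarks use the chord to their single neighbour.
    Returns (semi_indices, tangents).
    """
    idx: list[int] = []
    tans: list[np.ndarray] = []
    for curve in curves:
        if len(curve) < 2:
            raise ValueError("a sliding curve needs at least 2 semilandmarks for tangents")
        for pos, j in enumerate(curve):
            if pos == 0:
                chord = points[curve[1]] - points[j]
            elif pos == len(curve) - 1:
                chord = points[j] - points[curve[-2]]
            else:
                chord = points[curve[pos + 1]] - points[curve[pos - 1]]
            norm = np.linalg.norm(chord)
            if norm <= 0:
                raise ValueError("zero-length tangent chord on a sliding curve")
            idx.append(j)
            tans.append(chord / norm)
    return np.asarray(idx, dtype=int), np.asarray(tans)


def _slide_once(
    aligned: np.ndarray, consensus: np.ndarray, curves: Sequence[Sequence[int]]
) -> tuple[np.ndarray, float]:
    """One sliding pass of every specimen against the current consensus.

    Solves, per specimen, the least-squares problem for slide amounts t that
    minimize (v + U t)^T B~ (v + U t), with B~ the bending-energy matrix of
    the consensus expanded over x and y and U the tangent design restricted
    to the semilandmarks; fixed landmarks stay immobile.
    """
    B = bending_energy_matrix(consensus)
    out = aligned.copy()
    max_t = 0.0
    for i in range(aligned.shape[0]):
        pts = aligned[i]
        semi, T = _curve_tangents(pts, curves)
        if semi.size == 0:
            continue
        Bx = B @ pts[:, 0]
        By = B @ pts[:, 1]
        # U^T B~ U with the block-diagonal expansion collapses to an
        # elementwise product over the semilandmark submatrix
        Bss = B[np.ix_(semi, semi)]
        A = Bss * (np.outer(T[:, 0], T[:, 0]) + np.outer(T[:, 1], T[:, 1]))
        b = -(T[:, 0] * Bx[semi] + T[:, 1] * By[semi])
        t, *_ = np.linalg.lstsq(A, b, rcond=None)
        out[i, semi, 0] = pts[semi, 0] + t * T[:, 0]
        out[i, semi, 1] = pts[semi, 1] + t * T[:, 1]
        max_t = max(max_t, float(np.max(np.abs(t))))
    return out, max_t


def _coerce_configs(X, roles, curves):
    """Accept a list of LandmarkConfiguration or an (n, k, 2) array."""
    if isinstance(X, np.ndarray):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("landmark array must have shape (n, k, 2)")
        ids = [f"spec_{i}" for i in range(arr.shape[0])]
        roles = list(roles) if roles is not None else ["fixed"] * arr.shape[1]
        curves = [list(c) for c in curves] if curves is not None else []
        return arr, ids, roles, curves
    configs = list(X)
    k0, roles0 = configs[0].points.shape[0], list(configs[0].roles)
    for c in configs[1:]:
        if c.points.shape[0] != k0 or list(c.roles) != roles0:
            raise ValueError(f"{c.specimen_id}: point count/roles differ across configurations")
    arr = np.stack([c.points for c in configs])
    ids = [c.specimen_id for c in configs]
    if roles is None:
        roles = roles0
    if curves is None:
        curves = [list(cv) for cv in configs[0].curves]
    return arr, ids, list(roles), [list(c) for c in curves]
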