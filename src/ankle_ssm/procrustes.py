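"""Ordinary and generalized Procrustes superimposition for 2-D landmarks.

Full Procrustes conventions: translation removed by centering, size removed
by scaling every configuration to unit centroid size, rotation removed by
the SVD-optimal (Kabsch) rotation.  Reflections are never part of the
fitted transform — laterality is handled explicitly upstream by mirroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_landmarks import Configuration, ShapeDataset

__all__ = [
    "AlignedDataset",
    "centroid_size",
    "superimpose_pair",
    "procrustes_distance",
    "generalized_procrustes",
    "align_to_frame",
]


@dataclass
class AlignedDataset:
    """Procrustes-superimposed shapes (dimensionless, unit centroid size).

    ``shapes`` is (n, 2k) with each row an aligned configuration flattened
    point-major (x1, y1, x2, y2, ...); ``consensus`` is the unit-size mean
    shape; ``centroid_sizes`` keeps the original sizes in mm.
    """

    shapes: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    ankle_ids: list[str]
    iterations: int
    final_change: float
    ss_history: list[float]

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1] // 2

    def shape_matrix(self, i: int) -> np.ndarray:
        return self.shapes[i].reshape(-1, 2)


def _as_matrix(config) -> np.ndarray:
    if isinstance(config, Configuration):
        return np.asarray(config.coords, dtype=float)
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Root-sum-of-squared distances of landmarks from their centroid (mm)."""
    x = _as_matrix(config)
    if x.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 points")
    centered = x - x.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size == 0.0:
        raise ValueError("all landmarks coincident: centroid size is zero")
    return size


def _optimal_rotation(moving: np.ndarray, target: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """Kabsch rotation R minimizing ||moving @ R - target||_F (both centered)."""
    u, s, vt = np.linalg.svd(moving.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection:
        d = 1.0
    corr = np.ones(len(s))
    corr[-1] = d
    return (u * corr) @ vt


def superimpose_pair(moving, target, allow_reflection: bool = False):
    """Ordinary Procrustes fit of ``moving`` onto ``target``.

    Returns ``(aligned, distance)``: the moving configuration centered,
    optimally rotated and scaled onto the centered target (then translated
    to the target's centroid), and the root-sum-square residual, which is
    minimal over similarity transforms.  With ``allow_reflection=False`` an
    improper (reflecting) optimum is repaired to the best proper rotation.
    """
    m = _as_matrix(moving)
    t = _as_matrix(target)
    if m.shape != t.shape:
        raise ValueError("configurations must have equal point counts")
    m_size = centroid_size(m)  # raises on degenerate input
    centroid_size(t)
    m0 = (m - m.mean(axis=0)) / m_size
    t0 = t - t.mean(axis=0)
    u, s, vt = np.linalg.svd(m0.T @ t0)
    d = 1.0 if allow_reflection else np.sign(np.linalg.det(u @ vt))
    corr = np.ones(len(s))
    corr[-1] = d
    rotation = (u * corr) @ vt
    scale = float((s * corr).sum())  # optimal since ||m0|| = 1
    fitted = scale * (m0 @ rotation)
    aligned = fitted + t.mean(axis=0)
    distance = float(np.sqrt(((t0 - fitted) ** 2).sum()))
    return aligned, distance


def procrustes_distance(a, b, allow_reflection: bool = False) -> float:
    """Full Procrustes distance between two shapes.

    Both configurations are centered and scaled to unit centroid size
    before the optimal superimposition, so the distance is invariant to
    similarity transforms of either argument and symmetric.
    """
    am = _as_matrix(a)
    bm = _as_matrix(b)
    a0 = am - am.mean(axis=0)
    a0 = a0 / np.sqrt((a0**2).sum())
    b0 = bm - bm.mean(axis=0)
    b0 = b0 / np.sqrt((b0**2).sum())
    _, dist = superimpose_pair(a0, b0, allow_reflection=allow_reflection)
    return dist


def align_to_frame(consensus: np.ndarray, configs) -> np.ndarray:
    """Superimpose configurations onto a fixed consensus shape.

    Each configuration is centered, scaled to unit centroid size and
    rotated onto the (unit-size) consensus; used to place new or repeat
    readings in the frame of an already-fitted shape model.  Returns the
    (n, 2k) matrix of aligned shape vectors.
    """
    cons = np.asarray(consensus, dtype=float).reshape(-1, 2)
    out = []
    for c in configs:
        x = _as_matrix(c)
        x = x - x.mean(axis=0)
        x = x / np.sqrt((x**2).sum())
        out.append((x @ _optimal_rotation(x, cons)).ravel())
    return np.array(out)


def generalized_procrustes(
    dataset: ShapeDataset | list, tol: float = 1e-8, max_iter: int = 100
) -> AlignedDataset:
    """Generalized Procrustes analysis across all configurations.

    All shapes are centered and scaled to unit centroid size; the consensus
    is initialized as the first shape, then the scheme alternates rotating
    every shape onto the consensus with recomputing (and re-normalizing)
    the consensus, until the root-mean-square consensus change drops below
    ``tol``.  The total Procrustes sum of squares is non-increasing across
    iterations, and the result is invariant (up to numerical tolerance) to
    input similarity transforms and input order.
    """
    if isinstance(dataset, ShapeDataset):
        configs = dataset.configurations
        ids = [c.ankle_id for c in configs]
        if any(c.side == "left" for c in configs):
            warnings.warn("left-sided configurations present; mirror before GPA")
    else:
        configs = list(dataset)
        ids = [getattr(c, "ankle_id", str(i)) for i, c in enumerate(configs)]
    if len(configs) < 2:
        raise ValueError("generalized Procrustes needs at least 2 configurations")

    sizes = np.array([centroid_size(c) for c in configs])
    mats = []
    for c in configs:
        x = _as_matrix(c)
        x = x - x.mean(axis=0)
        mats.append(x / np.sqrt((x**2).sum()))
    mats = np.array(mats)  # (n, k, 2)
    n = len(mats)

    consensus = mats[0].copy()
    ss_history: list[float] = []
    final_change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            mats[i] = mats[i] @ _optimal_rotation(mats[i], consensus)
        ss_history.append(float(((mats - consensus) ** 2).sum()))
        new_consensus = mats.mean(axis=0)
        new_consensus = new_consensus - new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus**2).sum())
        if norm == 0.0:
            raise ValueError("degenerate consensus (shapes cancel)")
        new_consensus /= norm
        final_change = float(
            np.sqrt(((new_consensus - consensus) ** 2).mean())
        )
        consensus = new_consensus
        if final_change < tol:
            break
    else:
        warnings.warn(
            f"generalized Procrustes did not converge in {max_iter} iterations "
            f"(final consensus change {final_change:.3e})"
        )
    # final rotation pass onto the converged consensus
    for i in range(n):
        mats[i] = mats[i] @ _optimal_rotation(mats[i], consensus)

    return AlignedDataset(
        shapes=mats.reshape(n, -1),
        consensus=consensus.reshape(-1),
        centroid_sizes=sizes,
        ankle_ids=ids,
        iterations=iterations,
        final_change=final_change,
        ss_history=ss_history,
    )
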