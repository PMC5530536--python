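"""Point-distribution shape model: mean shape + orthogonal modes of variation.

The model is a PCA of Procrustes-aligned coordinate vectors.  Each mode is
one principal component; its score is a continuous per-ankle shape
variable.  Retention follows the parsimony rule of keeping the smallest
leading set of modes that together explain 80% of shape variance, dropping
any member explaining less than 1% individually.

Two entry points:

* function style — :func:`fit_shape_model`, :func:`select_modes`,
  :func:`score_shapes`, :func:`synthesize_mode_shape`;
* model/results style — ``ShapePCA(aligned).fit()`` returning a
  :class:`ShapeModelResults` with a ``summary()`` variance table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_landmarks import LandmarkScheme
from .procrustes import AlignedDataset

__all__ = [
    "ShapeModel",
    "ModeScores",
    "ShapePCA",
    "ShapeModelResults",
    "fit_shape_model",
    "select_modes",
    "score_shapes",
    "synthesize_mode_shape",
    "render_mode_figure",
]


@dataclass
class ShapeModel:
    """Mean shape, orthonormal mode basis and per-mode variances.

    ``basis`` is (2k, m) with columns ordered by decreasing variance;
    ``variances`` are the sample variances (1/(n-1) divisor) of the mode
    scores on the fitting set; ``fractions`` are variances / total
    variance; ``retained`` holds the 0-based indices kept by the retention
    rule.  Mode *j* in tables and figures is ``retained``/basis index
    ``j - 1``.
    """

    mean: np.ndarray
    basis: np.ndarray
    variances: np.ndarray
    fractions: np.ndarray
    retained: list[int] = field(default_factory=list)
    n_fit: int = 0

    @property
    def n_modes(self) -> int:
        return self.basis.shape[1]

    def to_json(self, path) -> None:
        doc = {
            "mean": self.mean.tolist(),
            "basis": self.basis.tolist(),
            "variances": self.variances.tolist(),
            "retained": list(self.retained),
            "n_fit": self.n_fit,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ShapeModel":
        with open(path) as fh:
            doc = json.load(fh)
        variances = np.asarray(doc["variances"], dtype=float)
        total = variances.sum()
        return cls(
            mean=np.asarray(doc["mean"], dtype=float),
            basis=np.asarray(doc["basis"], dtype=float),
            variances=variances,
            fractions=variances / total if total > 0 else variances,
            retained=list(doc["retained"]),
            n_fit=int(doc["n_fit"]),
        )


@dataclass
class ModeScores:
    """Per-ankle scores on the retained modes.

    When ``standardized`` each column is divided by the mode's fitting-set
    SD (sqrt of variance), so regression effects read "per SD of shape".
    """

    scores: np.ndarray  # (n, len(modes))
    modes: list[int]    # 0-based basis indices
    standardized: bool
    ankle_ids: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        cols = [f"mode{j + 1}" for j in self.modes]
        idx = self.ankle_ids if self.ankle_ids else None
        return pd.DataFrame(self.scores, columns=cols, index=idx)


def fit_shape_model(aligned: AlignedDataset | np.ndarray) -> ShapeModel:
    """PCA of aligned shape vectors via SVD of the centered shape matrix."""
    x = aligned.shapes if isinstance(aligned, AlignedDataset) else np.asarray(aligned, float)
    n, p = x.shape
    if n < 3:
        raise ValueError("shape model needs at least 3 shapes")
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n_modes = min(n - 1, p)
    basis = vt[:n_modes].T
    variances = (s[:n_modes] ** 2) / (n - 1)
    # deterministic sign: largest-magnitude basis component positive
    for j in range(n_modes):
        k = np.argmax(np.abs(basis[:, j]))
        if basis[k, j] < 0:
            basis[:, j] = -basis[:, j]
    total = variances.sum()
    fractions = variances / total if total > 0 else np.zeros_like(variances)
    return ShapeModel(
        mean=mean, basis=basis, variances=variances, fractions=fractions, n_fit=n
    )


def select_modes(
    fractions: np.ndarray, cum_threshold: float = 0.80, min_fraction: float = 0.01
) -> list[int]:
    """Retention rule: cumulative-80% first, then the per-mode >=1% filter.

    Returns 0-based indices of the smallest leading set of modes whose
    cumulative variance fraction reaches ``cum_threshold``, with any member
    explaining less than ``min_fraction`` removed afterwards.  If the modes
    at or above ``min_fraction`` cannot jointly reach the threshold, all of
    them are returned with a warning.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("empty variance-fraction vector")
    if np.any(np.diff(fractions) > 1e-12):
        raise ValueError("fractions must be sorted non-increasing")
    if fractions.sum() > 1 + 1e-9:
        raise ValueError("fractions sum above 1")
    big = fractions >= min_fraction
    if fractions[big].sum() < cum_threshold:
        warnings.warn(
            f"modes with fraction >= {min_fraction} explain only "
            f"{fractions[big].sum():.3f} < {cum_threshold}; returning all of them"
        )
        return [int(i) for i in np.nonzero(big)[0]]
    cum = np.cumsum(fractions)
    n_lead = int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)
    return [i for i in range(n_lead) if fractions[i] >= min_fraction]


def score_shapes(
    model: ShapeModel,
    shapes: np.ndarray | AlignedDataset,
    standardize: bool = True,
    modes: list[int] | None = None,
    ankle_ids: list[str] | None = None,
) -> ModeScores:
    """Project aligned shapes onto the model's modes.

    ``score_k = basis_k . (shape - mean)``; standardized scores are divided
    by sqrt(variance_k) so each retained mode has unit variance on the
    fitting set.
    """
    if isinstance(shapes, AlignedDataset):
        if ankle_ids is None:
            ankle_ids = shapes.ankle_ids
        shapes = shapes.shapes
    x = np.atleast_2d(np.asarray(shapes, dtype=float))
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"shape dimension {x.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    if modes is None:
        modes = model.retained if model.retained else list(range(model.n_modes))
    raw = (x - model.mean) @ model.basis[:, modes]
    if standardize:
        sd = np.sqrt(model.variances[modes])
        if np.any(sd == 0):
            raise ValueError("cannot standardize a zero-variance mode")
        raw = raw / sd
    return ModeScores(
        scores=raw, modes=list(modes), standardized=standardize,
        ankle_ids=ankle_ids or [],
    )


def synthesize_mode_shape(model: ShapeModel, mode: int, k_sd: float) -> np.ndarray:
    """Mean shape displaced along one mode: ``mean + k_sd * sqrt(var) * basis``."""
    if not 0 <= mode < model.n_modes:
        raise ValueError(f"mode {mode} outside 0..{model.n_modes - 1}")
    null_level = 1e-12 * max(model.variances.max(), 1e-300)
    if model.variances[mode] <= null_level and k_sd != 0:
        raise ValueError(f"mode {mode} has null variance; cannot synthesize")
    return model.mean + k_sd * np.sqrt(model.variances[mode]) * model.basis[:, mode]


def render_mode_figure(
    model: ShapeModel,
    modes: list[int],
    k_sd: list[float] | float = 2.0,
    scheme: LandmarkScheme | None = None,
    path=None,
):
    """One panel per mode: mean shape with +SD (dashed) and -SD (dotted) outlines.

    Landmarks are joined by polylines within each bone group of ``scheme``
    (plain point clouds if no scheme is given).  Returns the figure;
    saves to ``path`` (SVG/PNG by extension) when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if np.isscalar(k_sd):
        k_sd = [float(k_sd)] * len(modes)
    if len(k_sd) != len(modes):
        raise ValueError("one k_sd per mode required")
    for m in modes:
        if not 0 <= m < model.n_modes:
            raise ValueError(f"unknown mode {m}")

    fig, axes = plt.subplots(1, len(modes), figsize=(4 * len(modes), 4.2),
                             squeeze=False)
    for ax, mode, k in zip(axes[0], modes, k_sd):
        for vec, style, label in (
            (model.mean, dict(ls="-", color="0.2"), "mean"),
            (synthesize_mode_shape(model, mode, +k), dict(ls="--", color="tab:orange"), f"+{k:g} SD"),
            (synthesize_mode_shape(model, mode, -k), dict(ls=":", color="tab:blue"), f"-{k:g} SD"),
        ):
            pts = vec.reshape(-1, 2)
            if scheme is not None and scheme.bone_groups:
                first = True
                for bone in scheme.bone_groups:
                    idx = scheme.group_indices(bone)
                    ax.plot(pts[idx, 0], pts[idx, 1], marker=".", ms=2,
                            label=label if first else None, **style)
                    first = False
            else:
                ax.plot(pts[:, 0], pts[:, 1], marker=".", ms=2, label=label, **style)
        ax.set_title(f"Mode {mode + 1} ({100 * model.fractions[mode]:.1f}%)")
        ax.set_aspect("equal")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------

class ShapePCA:
    """Point-distribution shape model builder.

    Parameters
    ----------
    aligned : AlignedDataset or (n, 2k) array
        Procrustes-aligned shape vectors.
    scheme : LandmarkScheme, optional
        Used only for figure rendering.
    """

    def __init__(self, aligned, scheme: LandmarkScheme | None = None):
        self.aligned = aligned
        self.scheme = scheme

    def fit(self, cum_threshold: float = 0.80, min_fraction: float = 0.01,
            standardize: bool = True) -> "ShapeModelResults":
        model = fit_shape_model(self.aligned)
        model.retained = select_modes(model.fractions, cum_threshold, min_fraction)
        scores = score_shapes(model, self.aligned, standardize=standardize)
        return ShapeModelResults(model=model, scores=scores, scheme=self.scheme)


@dataclass
class ShapeModelResults:
    """Fitted shape model with its fitting-set mode scores."""

    model: ShapeModel
    scores: ModeScores
    scheme: LandmarkScheme | None = None

    @property
    def retained(self) -> list[int]:
        return self.model.retained

    def summary(self) -> pd.DataFrame:
        """Variance table: per-mode variance, % explained, cumulative %, retained."""
        m = self.model
        return pd.DataFrame(
            {
                "mode": np.arange(1, m.n_modes + 1),
                "variance": m.variances,
                "pct_explained": 100 * m.fractions,
                "cum_pct": 100 * np.cumsum(m.fractions),
                "retained": [j in m.retained for j in range(m.n_modes)],
            }
        )

    def synthesize(self, mode: int, k_sd: float) -> np.ndarray:
        return synthesize_mode_shape(self.model, mode, k_sd)

    def plot_modes(self, modes=None, k_sd=2.0, path=None):
        if modes is None:
            modes = self.model.retained[:4]
        return render_mode_figure(self.model, modes, k_sd, self.scheme, path)
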