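"""Distribution-shift quantification between ensembles of sequence variants.

Wild-type and mutant ensembles are pooled, a 2-component PCA is fitted
on the pooled Cα coordinates, every ensemble is projected onto (PC1,
PC2), shared-bin 2D histograms are built over the pooled range, and the
shift of each mutant distribution from the wild type is summarised by
the Kullback–Leibler divergence KL(WT ‖ Mut) in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .ensemble_io import AtomSelection, ConformationEnsemble

__all__ = [
    "ProjectionModel",
    "ProjectedEnsemble",
    "GridHistogram",
    "fit_projection",
    "fit_projection_matrix",
    "project",
    "project_matrix",
    "shared_histogram",
    "kl_divergence",
]


@dataclass
class ProjectionModel:
    """A fitted linear projection onto the top principal components.

    The sign of each component is fixed so its largest-magnitude entry
    is positive, making projections reproducible across fits.
    """

    mean_vector: np.ndarray          # (n_features,)
    components: np.ndarray           # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray   # (n_components,), non-increasing

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-9):
            raise ValueError("projection components must be orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained variance must be non-increasing")


@dataclass
class ProjectedEnsemble:
    """Per-frame coordinates in the projected (PC1, PC2, ...) space."""

    points: np.ndarray               # (n_frames, n_components)


@dataclass
class GridHistogram:
    """A normalized 2D histogram on shared bin edges."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    probabilities: np.ndarray        # (n_bins_x, n_bins_y), sums to 1

    def __post_init__(self) -> None:
        total = self.probabilities.sum()
        if self.probabilities.min() < 0 or abs(total - 1.0) > 1e-12:
            raise ValueError("histogram must be a normalized probability table")


def fit_projection_matrix(X: np.ndarray, n_components: int = 2) -> ProjectionModel:
    """Fit a PCA projection on a plain (n_samples, n_features) matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to fit a projection")
    n_components = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for k in range(components.shape[0]):
        if components[k, np.argmax(np.abs(components[k]))] < 0:
            components[k] = -components[k]
    return ProjectionModel(pca.mean_, components, pca.explained_variance_)


def _calpha_matrix(ensemble: ConformationEnsemble, selection: AtomSelection) -> np.ndarray:
    return ensemble.frames[:, selection.indices, :].reshape(ensemble.n_frames, -1)


def fit_projection(
    combined: ConformationEnsemble, selection: AtomSelection, n_components: int = 2
) -> ProjectionModel:
    """Fit the projection on a pooled, aligned ensemble (Cα coordinates).

    The pooled ensemble should concatenate all variants' frames, every
    frame aligned to one common reference; the model is fitted once and
    reused for every variant so all projections share axes.
    """
    return fit_projection_matrix(_calpha_matrix(combined, selection), n_components)


def project_matrix(X: np.ndarray, model: ProjectionModel) -> ProjectedEnsemble:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean_vector.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.mean_vector.size})"
        )
    return ProjectedEnsemble((X - model.mean_vector) @ model.components.T)


def project(
    ensemble: ConformationEnsemble, model: ProjectionModel, selection: AtomSelection
) -> ProjectedEnsemble:
    """Project an aligned ensemble onto the fitted components."""
    return project_matrix(_calpha_matrix(ensemble, selection), model)


def shared_histogram(
    groups: list[ProjectedEnsemble], n_bins: int = 50
) -> list[GridHistogram]:
    """Build 2D histograms with identical bins for every group.

    Bin edges are uniform and span the pooled min/max of all groups on
    each axis, so the histograms are directly comparable bin by bin.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups for a shared histogram")
    if n_bins < 2:
        raise ValueError("need at least 2 bins per axis")
    pooled = np.concatenate([g.points[:, :2] for g in groups], axis=0)
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    if np.any(hi - lo <= 0):
        axis = int(np.flatnonzero(hi - lo <= 0)[0])
        raise ValueError(f"all points identical along axis {axis}; zero bin range")
    x_edges = np.linspace(lo[0], hi[0], n_bins + 1)
    y_edges = np.linspace(lo[1], hi[1], n_bins + 1)
    out = []
    for g in groups:
        counts, _, _ = np.histogram2d(
            g.points[:, 0], g.points[:, 1], bins=(x_edges, y_edges)
        )
        probs = counts / counts.sum()
        # exact normalization for the invariant check
        probs = probs / probs.sum()
        out.append(GridHistogram(x_edges, y_edges, probs))
    return out


def kl_divergence(
    wt: GridHistogram, mut: GridHistogram, pseudocount: float = 1e-6
) -> float:
    """KL(WT ‖ Mut) = Σ_i B_i^WT · ln(B_i^WT / B_i^Mut), in nats.

    Both tables get an additive pseudocount per bin and are renormalized
    first, which keeps the divergence finite when a mutant bin is empty
    where the wild type has mass.  Identical histograms give exactly 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not (
        np.array_equal(wt.x_edges, mut.x_edges)
        and np.array_equal(wt.y_edges, mut.y_edges)
    ):
        raise ValueError("histograms must share identical bin edges")
    p = wt.probabilities + pseudocount
    q = mut.probabilities + pseudocount
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))
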