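"""Cell-to-cell heterogeneity: Euclidean distance statistics and PCA.

The cell-to-cell Euclidean distance D_Eu(p, q) = sqrt(sum_i (p_i - q_i)^2)
between two cells' spectral feature vectors measures dissimilarity: larger
distance means lower cell-to-cell similarity. For k cells, all k^2 ordered
distances form the heatmap; the C(k,2) = k(k-1)/2 unique pair distances form
the histogram and the summary indices. Distances run on the full 14-dim
feature matrix or on its 4/7/3-dim subregional views.

PCA operates on second-derivative spectra (mean-centered, no scaling),
either over the full wavenumber range or restricted to one biochemical
region; components are ordered by explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .features import FeatureMatrix, split_subregions
from .spectra import RegionTable, SpectrumSet, default_region_table

__all__ = [
    "DistanceMatrix",
    "PcaResult",
    "euclidean_distance",
    "distance_matrix",
    "pair_histogram",
    "heterogeneity_index",
    "pca_spectra",
    "group_silhouette",
    "REGION_SCOPES",
]

REGION_SCOPES = {
    "full_14": None,
    "fatty_acid_4": "fatty_acid",
    "protein_7": "protein",
    "carbohydrate_3": "carbohydrate",
}


@dataclass(frozen=True)
class DistanceMatrix:
    """k x k cell-to-cell Euclidean distances for one region scope."""

    cell_ids: tuple[str, ...]
    D: np.ndarray
    region_scope: str = "full_14"

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        k = len(self.cell_ids)
        if D.shape != (k, k):
            raise ValueError(f"distance matrix shape {D.shape} != ({k}, {k})")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (D < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "D", D)

    @property
    def k(self) -> int:
        return len(self.cell_ids)

    def unique_pair_distances(self) -> np.ndarray:
        """The k(k-1)/2 upper-triangle distances (histogram basis)."""
        iu = np.triu_indices(self.k, k=1)
        return self.D[iu]


def euclidean_distance(p, q) -> float:
    """D_Eu(p, q) = sqrt(sum_i (p_i - q_i)^2) for equal-length vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((p - q) ** 2)))


def distance_matrix(fm: FeatureMatrix, region_scope: str = "full_14") -> DistanceMatrix:
    """All-pairs D_Eu on the scoped feature columns (14, 4, 7 or 3)."""
    if region_scope not in REGION_SCOPES:
        raise ValueError(
            f"unknown region_scope {region_scope!r}; expected one of {sorted(REGION_SCOPES)}"
        )
    region = REGION_SCOPES[region_scope]
    values = (
        fm.values if region is None else split_subregions(fm)[region].values
    )
    if values.shape[0] < 2:
        raise ValueError("distance matrix requires >= 2 cells")
    D = cdist(values, values, metric="euclidean")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float round-off
    return DistanceMatrix(tuple(fm.cell_ids), D, region_scope)


def pair_histogram(dm: DistanceMatrix, n_bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (edges, counts) over the k(k-1)/2 unique pair distances."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = dm.unique_pair_distances()
    hi = values.max() if values.max() > 0 else 1.0
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, hi))
    return edges, counts


def heterogeneity_index(dm: DistanceMatrix) -> dict[str, float]:
    """Mean, median and IQR of the unique pair distances.

    Larger values mean greater cell-to-cell dissimilarity (distance is
    negatively correlated with similarity).
    """
    values = dm.unique_pair_distances()
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "iqr": float(q3 - q1),
        "n_pairs": int(values.size),
    }


@dataclass(frozen=True)
class PcaResult:
    """Scores, explained-variance fractions and loadings of a spectral PCA."""

    cell_ids: tuple[str, ...]
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray
    wavenumbers: np.ndarray
    region_scope: str = "full_spectrum"

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(np.diff(evf) > 1e-12) or np.any(evf < -1e-12) or evf.sum() > 1 + 1e-9:
            raise ValueError(
                "explained variance fractions must be non-increasing, in [0,1], sum <= 1"
            )


def _scope_columns(
    grid: np.ndarray, region_scope: str, regions: RegionTable
) -> np.ndarray:
    if region_scope == "full_spectrum":
        return np.ones(grid.size, dtype=bool)
    if region_scope not in regions.names:
        raise ValueError(
            f"unknown region_scope {region_scope!r}; expected 'full_spectrum' "
            f"or one of {regions.names}"
        )
    mask = regions.mask(grid, region_scope)
    if not mask.any():
        raise ValueError(f"region {region_scope!r} does not overlap the grid")
    return mask


def pca_spectra(
    deriv_set: SpectrumSet,
    region_scope: str = "full_spectrum",
    n_components: int = 2,
    regions: RegionTable | None = None,
) -> PcaResult:
    """Mean-centered PCA of second-derivative spectra over one wavenumber scope.

    Components are ordered by explained variance (descending); the sign
    convention makes each loading's largest-magnitude element positive.
    No unit-variance scaling is applied.
    """
    regions = regions or default_region_table()
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    if len(deriv_set) <= n_components:
        raise ValueError(
            f"need more cells ({len(deriv_set)}) than components ({n_components})"
        )
    grid = deriv_set.shared_grid
    mask = _scope_columns(grid, region_scope, regions)
    X = deriv_set.to_matrix()[:, mask]
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate input: spectra constant across cells")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # sign convention: largest-|.| loading element positive per component
    for c in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            loadings[c] *= -1.0
            scores[:, c] *= -1.0
    return PcaResult(
        cell_ids=tuple(deriv_set.cell_ids),
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_,
        loadings=loadings,
        wavenumbers=grid[mask],
        region_scope=region_scope,
    )


def render_heatmap(dm: DistanceMatrix, path) -> str:
    """Save the k x k distance heatmap (all k^2 entries) as an image."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(dm.D, cmap="viridis")
    ax.set_title(f"cell-to-cell D_Eu ({dm.region_scope}, k={dm.k})")
    ax.set_xlabel("cell index")
    ax.set_ylabel("cell index")
    fig.colorbar(im, ax=ax, label="D_Eu (a.u.)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return str(path)


def render_histogram(dm: DistanceMatrix, path, n_bins: int = 30) -> str:
    """Save the histogram of the k(k-1)/2 unique pair distances as an image."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    edges, counts = pair_histogram(dm, n_bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge")
    ax.set_xlabel("D_Eu (a.u.)")
    ax.set_ylabel("pair count")
    ax.set_title(f"unique pair distances ({dm.region_scope}, {counts.sum()} pairs)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return str(path)


def group_silhouette(result: PcaResult, labels) -> float:
    """Silhouette of group labels on the first two PC scores.

    Quantifies how separately the treatment groups cluster in the score
    plot: > 0.5 reads as clear separation, near 0 as overlapping clouds.
    """
    labels = list(labels)
    if len(labels) != len(result.cell_ids):
        raise ValueError("one label per cell required")
    return float(silhouette_score(result.scores[:, :2], labels))
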