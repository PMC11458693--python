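"""Single-cell spectral absorption matrices.

Absorption bands appear as sharp minima in Savitzky-Golay second-derivative
spectra. This module detects a consensus set of 14 such minima on the
cohort-mean second derivative (4 in the fatty-acid intervals, 7 in the
protein interval, 3 in the carbohydrate interval by default), then extracts
one value per cell per peak — the cell's processed absorbance at its own
locally refined minimum position — to build a cells x 14 feature matrix.
The matrix splits into 4-, 7- and 3-column subregional views whose column
concatenation reproduces it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .spectra import RegionTable, SpectrumSet, default_region_table

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "FeatureMatrix",
    "PeakExtractionError",
    "DEFAULT_EXPECTED_COUNTS",
    "detect_peaks",
    "build_feature_matrix",
    "split_subregions",
    "PeakFeatureExtractor",
]

DEFAULT_EXPECTED_COUNTS = {"fatty_acid": 4, "protein": 7, "carbohydrate": 3}
REFINE_HALFWIDTH_CM = 8.0


class PeakExtractionError(ValueError):
    """Raised when a region yields fewer second-derivative minima than expected."""


@dataclass(frozen=True)
class PeakSet:
    """Consensus peak positions (cm^-1, strictly descending) with region labels."""

    positions: tuple[float, ...]
    region_of: dict[float, str]

    def __post_init__(self) -> None:
        if any(p2 >= p1 for p1, p2 in zip(self.positions, self.positions[1:])):
            raise ValueError("peak positions must be strictly descending")
        missing = [p for p in self.positions if p not in self.region_of]
        if missing:
            raise ValueError(f"positions without region label: {missing}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def regions(self) -> list[str]:
        return [self.region_of[p] for p in self.positions]

    def region_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.regions:
            counts[r] = counts.get(r, 0) + 1
        return counts

    def columns_for(self, region: str) -> list[int]:
        return [i for i, r in enumerate(self.regions) if r == region]


@dataclass(frozen=True)
class FeatureMatrix:
    """Cells x peaks matrix of extracted spectral values.

    Column order follows the PeakSet (peak 1 = highest wavenumber).
    ``value_source`` records whether entries are processed absorbance at the
    peak positions (default) or second-derivative depths (sign-flipped so
    stronger absorption gives larger values).
    """

    cell_ids: tuple[str, ...]
    values: np.ndarray
    peaks: PeakSet
    value_source: str = "original_absorbance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.cell_ids), len(self.peaks)):
            raise ValueError(
                f"values shape {v.shape} != (n_cells={len(self.cell_ids)}, "
                f"n_peaks={len(self.peaks)})"
            )
        if np.isnan(v).any():
            raise ValueError("feature matrix must not contain missing values")
        object.__setattr__(self, "values", v)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            f"peak{i + 1:02d}_{p:g}" for i, p in enumerate(self.peaks.positions)
        ]
        return pd.DataFrame(self.values, index=list(self.cell_ids), columns=cols)


def _mean_spectrum_minima(
    grid: np.ndarray, mean_deriv: np.ndarray, prominence_quantile: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and depths of local minima of the mean second derivative."""
    idx, props = find_peaks(-mean_deriv, prominence=0.0)
    prominences = props["prominences"]
    if prominence_quantile > 0 and idx.size:
        cutoff = np.quantile(prominences, prominence_quantile)
        keep = prominences >= cutoff
        idx = idx[keep]
    # true absorption bands have negative second derivative at the minimum
    keep = mean_deriv[idx] < 0
    return idx[keep], -mean_deriv[idx[keep]]


def detect_peaks(
    deriv_set: SpectrumSet,
    regions: RegionTable | None = None,
    expected_counts: dict[str, int] | None = None,
    prominence_quantile: float = 0.0,
) -> PeakSet:
    """Consensus peak detection on the cohort-mean second-derivative spectrum.

    Per region, local minima are ranked by depth and the expected count is
    kept (4 fatty-acid / 7 protein / 3 carbohydrate by default); depth ties
    break toward higher wavenumber. Raises :class:`PeakExtractionError`
    naming the region when too few minima are found.
    """
    regions = regions or default_region_table()
    expected_counts = expected_counts or DEFAULT_EXPECTED_COUNTS
    if not any(
        "second_derivative" in tag for s in deriv_set for tag in s.provenance
    ):
        raise ValueError(
            "detect_peaks expects second-derivative spectra "
            "(no 'second_derivative' provenance tag found)"
        )
    grid = deriv_set.shared_grid
    mean_deriv = deriv_set.to_matrix().mean(axis=0)
    idx, depths = _mean_spectrum_minima(grid, mean_deriv, prominence_quantile)

    chosen: list[tuple[float, str]] = []
    for region, want in expected_counts.items():
        in_region = [
            (depths[j], grid[idx[j]])
            for j in range(idx.size)
            if regions.region_of(grid[idx[j]]) == region
        ]
        if len(in_region) < want:
            raise PeakExtractionError(
                f"region {region!r}: found {len(in_region)} second-derivative "
                f"minima, expected {want}"
            )
        # sort by (depth desc, wavenumber desc): ties break to higher wavenumber
        in_region.sort(key=lambda t: (-t[0], -t[1]))
        chosen.extend((w, region) for _, w in in_region[:want])

    chosen.sort(key=lambda t: -t[0])
    return PeakSet(
        positions=tuple(w for w, _ in chosen),
        region_of={w: r for w, r in chosen},
    )


def _refine_position(
    grid: np.ndarray,
    cell_deriv: np.ndarray,
    consensus: float,
    region: str,
    regions: RegionTable,
    halfwidth: float,
) -> int:
    """Grid index of the cell's own derivative minimum near the consensus peak.

    The search window is +/- ``halfwidth`` cm^-1 around the consensus
    position, restricted to grid points owned by the peak's region; if the
    restriction empties the window the consensus position is used.
    """
    near = np.abs(grid - consensus) <= halfwidth
    owned = near & regions.mask(grid, region)
    if not owned.any():
        logger.warning(
            "refinement window at %.0f cm^-1 leaves region %s; using consensus",
            consensus, region,
        )
        return int(np.argmin(np.abs(grid - consensus)))
    cand = np.flatnonzero(owned)
    return int(cand[np.argmin(cell_deriv[cand])])


def build_feature_matrix(
    raw_set: SpectrumSet,
    deriv_set: SpectrumSet,
    peaks: PeakSet,
    value_source: str = "original_absorbance",
    regions: RegionTable | None = None,
    refine_halfwidth: float = REFINE_HALFWIDTH_CM,
) -> FeatureMatrix:
    """Extract per-cell values at the consensus peaks.

    For each cell and peak, the consensus position is refined to the cell's
    own second-derivative minimum within +/- ``refine_halfwidth`` cm^-1;
    the extracted value is the cell's processed absorbance there
    (``original_absorbance``) or the sign-flipped second-derivative depth
    (``second_derivative_depth``).
    """
    if value_source not in {"original_absorbance", "second_derivative_depth"}:
        raise ValueError(f"unknown value_source {value_source!r}")
    regions = regions or default_region_table()
    if raw_set.cell_ids != deriv_set.cell_ids:
        raise ValueError("raw and derivative cohorts must list the same cells in order")
    grid = raw_set.shared_grid
    if not np.array_equal(grid, deriv_set.shared_grid):
        raise ValueError("raw and derivative cohorts must share one grid")
    lo, hi = grid.min(), grid.max()
    outside = [p for p in peaks.positions if not lo <= p <= hi]
    if outside:
        raise ValueError(f"peak positions outside the grid: {outside}")

    raw_mat = raw_set.to_matrix()
    deriv_mat = deriv_set.to_matrix()
    values = np.empty((len(raw_set), len(peaks)))
    for c in range(len(raw_set)):
        for j, pos in enumerate(peaks.positions):
            i = _refine_position(
                grid, deriv_mat[c], pos, peaks.region_of[pos], regions, refine_halfwidth
            )
            values[c, j] = (
                raw_mat[c, i]
                if value_source == "original_absorbance"
                else -deriv_mat[c, i]
            )
    return FeatureMatrix(
        cell_ids=tuple(raw_set.cell_ids),
        values=values,
        peaks=peaks,
        value_source=value_source,
    )


def split_subregions(fm: FeatureMatrix) -> dict[str, FeatureMatrix]:
    """Partition the feature matrix into per-region views (4/7/3 columns
    by default); concatenating the views in region-of-column order
    reproduces the input exactly."""
    out: dict[str, FeatureMatrix] = {}
    seen: list[int] = []
    for region in dict.fromkeys(fm.peaks.regions):
        cols = fm.peaks.columns_for(region)
        seen.extend(cols)
        positions = tuple(fm.peaks.positions[i] for i in cols)
        out[region] = FeatureMatrix(
            cell_ids=fm.cell_ids,
            values=fm.values[:, cols],
            peaks=PeakSet(positions, {p: region for p in positions}),
            value_source=fm.value_source,
        )
    if sorted(seen) != list(range(len(fm.peaks))):
        raise ValueError("subregional views do not partition the columns")
    return out


class PeakFeatureExtractor(TransformerMixin, BaseEstimator):
    """scikit-learn view of the peak-feature pipeline.

    ``fit(X_deriv)`` learns the consensus :class:`PeakSet` from
    second-derivative spectra on ``wavenumbers``; ``transform(X_raw)``
    extracts the per-cell matrix (X_raw rows must correspond to the same
    cells as the derivative rows for per-cell refinement; pass the
    derivative matrix again via ``transform(X_raw, X_deriv)`` semantics is
    not supported — the estimator stores the fitted derivative matrix).
    """

    def __init__(
        self,
        wavenumbers=None,
        regions: RegionTable | None = None,
        expected_counts: dict[str, int] | None = None,
        prominence_quantile: float = 0.0,
        value_source: str = "original_absorbance",
        refine_halfwidth: float = REFINE_HALFWIDTH_CM,
    ):
        self.wavenumbers = wavenumbers
        self.regions = regions
        self.expected_counts = expected_counts
        self.prominence_quantile = prominence_quantile
        self.value_source = value_source
        self.refine_halfwidth = refine_halfwidth

    def _as_sets(self, X_deriv, X_raw=None):
        grid = np.asarray(self.wavenumbers, dtype=float)
        ids = [f"cell_{i:04d}" for i in range(X_deriv.shape[0])]
        deriv = SpectrumSet.from_matrix(
            grid, X_deriv, ids, provenance=("second_derivative[external]",)
        )
        raw = (
            SpectrumSet.from_matrix(grid, X_raw, ids)
            if X_raw is not None
            else None
        )
        return deriv, raw

    def fit(self, X, y=None):
        X = check_array(X)
        if self.wavenumbers is None:
            raise ValueError("wavenumbers must be provided")
        deriv, _ = self._as_sets(X)
        self.peaks_ = detect_peaks(
            deriv,
            self.regions,
            self.expected_counts,
            self.prominence_quantile,
        )
        self._deriv_matrix_ = np.array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[0] != self._deriv_matrix_.shape[0]:
            raise ValueError(
                "transform rows must match the fitted derivative cohort "
                "(per-cell refinement uses the stored derivatives)"
            )
        deriv, raw = self._as_sets(self._deriv_matrix_, X)
        fm = build_feature_matrix(
            raw, deriv, self.peaks_,
            value_source=self.value_source,
            regions=self.regions,
            refine_halfwidth=self.refine_halfwidth,
        )
        return fm.values
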