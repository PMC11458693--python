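"""Spectral preprocessing chain for single-cell infrared cohorts.

The chain mirrors standard FTIR practice for single cells: 9-point
smoothing, linear automatic baseline correction, Savitzky-Golay second
derivatives, and EMSC-based Mie scattering correction. Each step is exposed
both as a scikit-learn transformer operating on a (cells x wavenumbers)
array and as a thin function over :class:`~scftir.spectra.Spectrum` /
:class:`~scftir.spectra.SpectrumSet` that tags provenance.

The EMSC corrector regresses each raw spectrum on a reference spectrum plus
interferent terms (polynomial baseline and a basis of van de Hulst Mie
extinction curves spanning a grid of sphere sizes and refractive indices),
then reconstructs the chemistry-only signal as
``(raw - fitted interferents) / reference coefficient``. This is the
non-resonant Mie-EMSC variant: the full resonant (complex-index,
Kramers-Kronig) treatment is out of scope, and the downstream features
depend on peak positions, which this variant preserves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .simulate import mie_artifact
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "MovingAverageSmoother",
    "LinearBaselineCorrector",
    "SavitzkyGolaySecondDerivative",
    "EMSCMieCorrector",
    "smooth",
    "baseline_linear",
    "second_derivative",
    "emsc_mie_correct",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``smooth_points``: moving-average width (odd, default 9).
    ``sg_window`` / ``sg_polyorder``: Savitzky-Golay second-derivative
    window and polynomial order (defaults 9 and 3, matching the 9-point
    smoothing scale). ``emsc_*``: EMSC design (polynomial order, number of
    Mie curves, iterations). ``reference_choice``: how the EMSC reference is
    obtained (cohort mean by default). ``apply_emsc``: whether scattering
    correction runs at all (it precedes smoothing when it does).
    """

    smooth_points: int = 9
    sg_window: int = 9
    sg_polyorder: int = 3
    sg_deriv: int = 2
    emsc_poly_order: int = 2
    emsc_n_mie_curves: int = 9
    emsc_iterations: int = 1
    reference_choice: str = "cohort_mean"
    apply_emsc: bool = True

    def __post_init__(self) -> None:
        if self.smooth_points < 3 or self.smooth_points % 2 == 0:
            raise ValueError("smooth_points must be odd and >= 3")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.sg_polyorder < self.sg_deriv:
            raise ValueError("sg_polyorder must be >= sg_deriv")
        if self.sg_deriv != 2:
            raise ValueError("this chain computes second derivatives (sg_deriv=2)")
        if min(self.emsc_poly_order, self.emsc_n_mie_curves, self.emsc_iterations) < 0:
            raise ValueError("EMSC counts must be non-negative")
        if self.reference_choice not in {"cohort_mean", "explicit"}:
            raise ValueError("reference_choice must be 'cohort_mean' or 'explicit'")


# ---------------------------------------------------------------------------
# scikit-learn transformers (rows = cells, columns = wavenumber points)
# ---------------------------------------------------------------------------


class MovingAverageSmoother(TransformerMixin, BaseEstimator):
    """Centered moving average of odd width; edge windows shrink symmetrically."""

    def __init__(self, points: int = 9):
        self.points = points

    def fit(self, X, y=None):
        X = check_array(X)
        if self.points % 2 == 0 or self.points < 3:
            raise ValueError(f"points must be odd and >= 3, got {self.points}")
        if self.points >= X.shape[1]:
            raise ValueError(
                f"points={self.points} must be smaller than the grid ({X.shape[1]} points)"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        n = X.shape[1]
        half = (self.points - 1) // 2
        idx = np.arange(n)
        h = np.minimum(half, np.minimum(idx, n - 1 - idx))
        lo, hi = idx - h, idx + h + 1
        csum = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
        return (csum[:, hi] - csum[:, lo]) / (hi - lo)


class LinearBaselineCorrector(TransformerMixin, BaseEstimator):
    """Two-point linear automatic baseline correction.

    Subtracts, per spectrum, the straight line through the minimum point of
    the first ``edge_fraction`` of the grid and the minimum point of the
    last ``edge_fraction``; the corrected spectrum is exactly zero at both
    anchors. This single-segment convention matches common "automatic
    baseline" behavior and is deterministic (first occurrence wins a tied
    minimum). ``wavenumbers``, when given, puts the line in physical
    coordinates; otherwise sample index is used.
    """

    def __init__(self, edge_fraction: float = 0.05, wavenumbers=None):
        self.edge_fraction = edge_fraction
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        X = check_array(X)
        if not 0 < self.edge_fraction <= 0.5:
            raise ValueError("edge_fraction must be in (0, 0.5]")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        n = X.shape[1]
        w = (
            np.asarray(self.wavenumbers, dtype=float)
            if self.wavenumbers is not None
            else np.arange(n, dtype=float)
        )
        n_edge = max(1, int(np.ceil(self.edge_fraction * n)))
        i1 = np.argmin(X[:, :n_edge], axis=1)
        i2 = n - n_edge + np.argmin(X[:, n - n_edge:], axis=1)
        out = np.empty_like(X)
        for r in range(X.shape[0]):
            a, b = i1[r], i2[r]
            if w[a] == w[b]:
                out[r] = X[r] - X[r, a]
                continue
            slope = (X[r, b] - X[r, a]) / (w[b] - w[a])
            out[r] = X[r] - (X[r, a] + slope * (w - w[a]))
        return out


class SavitzkyGolaySecondDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay second derivative d2A/dw2 (units a.u. x cm^2).

    Local least-squares polynomial fit of order ``polyorder`` over an odd
    ``window``; the second derivative is scaled by 1/delta^2 so results are
    grid-spacing-invariant. Edge points come from one-sided polynomial fits
    (``mode='interp'``).
    """

    def __init__(self, window: int = 9, polyorder: int = 3, delta: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.delta = delta

    def fit(self, X, y=None):
        X = check_array(X)
        if self.window % 2 == 0 or not 2 <= self.polyorder <= self.window - 1:
            raise ValueError(
                f"window must be odd with 2 <= polyorder <= window-1, "
                f"got window={self.window}, polyorder={self.polyorder}"
            )
        if self.window > X.shape[1]:
            raise ValueError("window larger than the grid")
        if self.delta <= 0:
            raise ValueError("delta (grid spacing, cm^-1) must be > 0")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return savgol_filter(
            X, self.window, self.polyorder, deriv=2, delta=self.delta,
            axis=1, mode="interp",
        )


def _mie_basis(wavenumbers: np.ndarray, n_curves: int) -> np.ndarray:
    """Unit-amplitude van de Hulst curves on a (diameter, index) grid."""
    if n_curves == 0:
        return np.empty((0, wavenumbers.size))
    n_d = int(np.ceil(np.sqrt(n_curves)))
    n_n = int(np.ceil(n_curves / n_d))
    diameters = np.linspace(8.0, 18.0, n_d)
    indices = np.linspace(1.3, 1.45, n_n)
    curves = [
        mie_artifact(wavenumbers, 1.0, d, ri)
        for d in diameters
        for ri in indices
    ]
    return np.vstack(curves[:n_curves])


class EMSCMieCorrector(TransformerMixin, BaseEstimator):
    """Extended multiplicative signal correction with a Mie-extinction basis.

    ``fit`` establishes the reference spectrum (cohort mean of the training
    cohort, or an explicit reference) and the interferent design; ``transform``
    regresses each spectrum on [reference | polynomial | Mie curves] by
    ordinary least squares and returns
    ``(raw - fitted interferents) / reference coefficient``.
    With ``iterations > 1`` the corrected cohort mean replaces the reference
    and the fit repeats.
    """

    def __init__(
        self,
        wavenumbers=None,
        poly_order: int = 2,
        n_mie_curves: int = 9,
        iterations: int = 1,
        reference=None,
        min_reference_coef: float = 1e-6,
    ):
        self.wavenumbers = wavenumbers
        self.poly_order = poly_order
        self.n_mie_curves = n_mie_curves
        self.iterations = iterations
        self.reference = reference
        self.min_reference_coef = min_reference_coef

    def fit(self, X, y=None):
        X = check_array(X)
        if self.reference is None and X.shape[0] < 2:
            raise ValueError("cohort-mean reference requires >= 2 cells; pass reference=")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        w = (
            np.asarray(self.wavenumbers, dtype=float)
            if self.wavenumbers is not None
            else np.arange(X.shape[1], dtype=float)
        )
        if w.size != X.shape[1]:
            raise ValueError("wavenumbers length must match the grid")
        self.grid_ = w
        self.reference_ = (
            np.asarray(self.reference, dtype=float)
            if self.reference is not None
            else X.mean(axis=0)
        )
        # interferent design: polynomial in scaled wavenumber + Mie curves
        t = 2.0 * (w - w.min()) / (w.max() - w.min()) - 1.0
        poly = np.vstack([t**p for p in range(self.poly_order + 1)])
        self.interferents_ = np.vstack([poly, _mie_basis(w, self.n_mie_curves)])
        self.n_features_in_ = X.shape[1]
        return self

    def _correct_once(self, X: np.ndarray, reference: np.ndarray) -> np.ndarray:
        design = np.column_stack([reference, self.interferents_.T])
        coefs, *_ = np.linalg.lstsq(design, X.T, rcond=None)
        b = coefs[0]
        low = np.abs(b) <= self.min_reference_coef
        if low.any():
            raise ValueError(
                f"degenerate EMSC fit (reference coefficient <= {self.min_reference_coef}) "
                f"for cells at rows {np.flatnonzero(low).tolist()}"
            )
        interf = (self.interferents_.T @ coefs[1:]).T  # (n_cells, n_points)
        return (X - interf) / b[:, None]

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        reference = self.reference_
        corrected = X
        for _ in range(self.iterations):
            corrected = self._correct_once(X, reference)
            reference = corrected.mean(axis=0)
        return corrected


# ---------------------------------------------------------------------------
# Spectrum / SpectrumSet wrappers
# ---------------------------------------------------------------------------


def smooth(spec: Spectrum, points: int = 9) -> Spectrum:
    """Centered moving average of odd width ``points``; shrinking edge windows."""
    tr = MovingAverageSmoother(points).fit(spec.absorbance[None, :])
    return spec.with_absorbance(
        tr.transform(spec.absorbance[None, :])[0], f"smooth[{points}]"
    )


def baseline_linear(spec: Spectrum, edge_fraction: float = 0.05) -> Spectrum:
    """Linear automatic baseline correction (two-point anchor line)."""
    tr = LinearBaselineCorrector(edge_fraction, wavenumbers=spec.wavenumbers)
    tr.fit(spec.absorbance[None, :])
    return spec.with_absorbance(
        tr.transform(spec.absorbance[None, :])[0], "baseline_linear"
    )


def second_derivative(spec: Spectrum, window: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative with respect to wavenumber."""
    spacing = float(np.mean(np.abs(np.diff(spec.wavenumbers))))
    tr = SavitzkyGolaySecondDerivative(window, polyorder, delta=spacing)
    tr.fit(spec.absorbance[None, :])
    return spec.with_absorbance(
        tr.transform(spec.absorbance[None, :])[0],
        f"second_derivative[sg,{window},{polyorder}]",
    )


def emsc_mie_correct(
    spectrum_set: SpectrumSet,
    config: PreprocessConfig | None = None,
    reference: np.ndarray | None = None,
) -> SpectrumSet:
    """EMSC Mie-scattering correction of a cohort against its mean spectrum."""
    config = config or PreprocessConfig()
    if config.reference_choice == "explicit" and reference is None:
        raise ValueError("reference_choice='explicit' requires a reference spectrum")
    X = spectrum_set.to_matrix()
    tr = EMSCMieCorrector(
        wavenumbers=spectrum_set.shared_grid,
        poly_order=config.emsc_poly_order,
        n_mie_curves=config.emsc_n_mie_curves,
        iterations=config.emsc_iterations,
        reference=reference,
    ).fit(X)
    corrected = tr.transform(X)
    tag = f"emsc_mie[p{config.emsc_poly_order},m{config.emsc_n_mie_curves},i{config.emsc_iterations}]"
    return SpectrumSet(
        [
            s.with_absorbance(row, tag)
            for s, row in zip(spectrum_set, corrected)
        ]
    )


def preprocess_cohort(
    spectrum_set: SpectrumSet,
    config: PreprocessConfig | None = None,
) -> tuple[SpectrumSet, SpectrumSet]:
    """Run the full chain; return (processed absorbance, second derivative).

    Order: EMSC scattering correction (optional, on raw absorbance) ->
    9-point smoothing -> linear baseline correction -> Savitzky-Golay second
    derivative. The first element is the corrected absorbance cohort (input
    to feature extraction at peak positions); the second is its second
    derivative (input to peak detection and PCA).
    """
    config = config or PreprocessConfig()
    working = spectrum_set
    if config.apply_emsc and len(spectrum_set) >= 2:
        working = emsc_mie_correct(working, config)
    working = SpectrumSet([smooth(s, config.smooth_points) for s in working])
    working = SpectrumSet([baseline_linear(s) for s in working])
    deriv = SpectrumSet(
        [second_derivative(s, config.sg_window, config.sg_polyorder) for s in working]
    )
    return working, deriv
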