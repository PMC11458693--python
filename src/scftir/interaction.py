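"""Drug-combination interaction models and dose-response utilities.

Three null models classify a single dose pair from the fractional responses
Pa, Pb (single agents) and P(a+b) (combination):

* additivity (CDI): CDI = P(a+b) / (Pa * Pb); CDI < 1 synergy, = 1
  additivity, > 1 antagonism. Applied to the response kind supplied
  (the classical formulation uses viability fractions).
* statistical independence (Bliss): expected combined inhibition
  1 - (1 - Pa)(1 - Pb) = Pa + Pb - Pa*Pb; observed above expectation is
  synergy, below is antagonism. Requires inhibition fractions.
* pharmacological independence (highest single agent, HSA): expected
  combined inhibition max(Pa, Pb); observed above is synergy. Requires
  inhibition fractions.

Classification uses a small boundary tolerance (strict-sign rules are
brittle against assay noise); tolerances are configurable. A consensus
report runs all three and takes a 2-of-3 majority.

Dose utilities convert mass concentration (ug/mL) to molarity (uM) and fit
four-parameter logistic (4PL) dose-response curves for relative IC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CombinationMeasurement",
    "InteractionResult",
    "DoseResponseTable",
    "IC50Fit",
    "FourParamLogisticIC50",
    "mass_to_molar",
    "format_molar",
    "to_inhibition",
    "cdi_additivity",
    "bliss_independence",
    "hsa_independence",
    "interaction_report",
    "fit_ic50_4pl",
]

CDI_TOL = 0.05
EXCESS_TOL = 0.01


@dataclass(frozen=True)
class CombinationMeasurement:
    """Single-agent and combined fractional responses for one dose pair."""

    response_a: float
    response_b: float
    response_ab: float
    response_kind: str = "viability"
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (
            ("response_a", self.response_a),
            ("response_b", self.response_b),
            ("response_ab", self.response_ab),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.response_kind not in {"viability", "inhibition"}:
            raise ValueError("response_kind must be 'viability' or 'inhibition'")


@dataclass(frozen=True)
class InteractionResult:
    """Outcome of one interaction model on one measurement."""

    model: str
    statistic: float
    call: str
    expected: float | None = None
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.call not in {"synergy", "additivity", "antagonism"}:
            raise ValueError(f"unknown call {self.call!r}")


def to_inhibition(m: CombinationMeasurement) -> CombinationMeasurement:
    """Complement every response and flip the kind (involution)."""
    return replace(
        m,
        response_a=1.0 - m.response_a,
        response_b=1.0 - m.response_b,
        response_ab=1.0 - m.response_ab,
        response_kind="inhibition" if m.response_kind == "viability" else "viability",
    )


def cdi_additivity(m: CombinationMeasurement, tol: float = CDI_TOL) -> InteractionResult:
    """Coefficient of drug interaction: CDI = P(a+b) / (Pa * Pb)."""
    denom = m.response_a * m.response_b
    if denom <= 0:
        raise ZeroDivisionError(
            "CDI undefined: product of single-agent responses is zero"
        )
    cdi = m.response_ab / denom
    if cdi < 1.0 - tol:
        call = "synergy"
    elif cdi > 1.0 + tol:
        call = "antagonism"
    else:
        call = "additivity"
    return InteractionResult("additivity_cdi", cdi, call, expected=1.0, tolerance=tol)


def _require_inhibition(m: CombinationMeasurement, model: str) -> None:
    if m.response_kind != "inhibition":
        raise ValueError(
            f"{model} expects inhibition fractions; convert viability "
            "measurements with to_inhibition() first"
        )


def bliss_independence(
    m: CombinationMeasurement, tol: float = EXCESS_TOL
) -> InteractionResult:
    """Bliss statistical independence: expected = 1 - (1-Pa)(1-Pb)."""
    _require_inhibition(m, "bliss_independence")
    expected = 1.0 - (1.0 - m.response_a) * (1.0 - m.response_b)
    excess = m.response_ab - expected
    if excess > tol:
        call = "synergy"
    elif excess < -tol:
        call = "antagonism"
    else:
        call = "additivity"
    return InteractionResult(
        "statistical_independence", excess, call, expected=expected, tolerance=tol
    )


def hsa_independence(
    m: CombinationMeasurement, tol: float = EXCESS_TOL
) -> InteractionResult:
    """Highest single agent: expected = max(Pa, Pb)."""
    _require_inhibition(m, "hsa_independence")
    expected = max(m.response_a, m.response_b)
    excess = m.response_ab - expected
    if excess > tol:
        call = "synergy"
    elif excess < -tol:
        call = "antagonism"
    else:
        call = "additivity"
    return InteractionResult(
        "pharmacological_independence", excess, call, expected=expected, tolerance=tol
    )


def consensus_call(results) -> str:
    """2-of-3 majority over model calls; 'mixed' when all three disagree."""
    calls = [r.call for r in results]
    for candidate in ("synergy", "antagonism", "additivity"):
        if calls.count(candidate) >= 2:
            return candidate
    return "mixed"


def interaction_report(
    m: CombinationMeasurement,
    cdi_tol: float = CDI_TOL,
    excess_tol: float = EXCESS_TOL,
) -> dict:
    """Run all three models and form a 2-of-3 majority consensus.

    CDI runs on the response kind supplied; Bliss and HSA run on inhibition
    fractions (converted automatically when a viability measurement is
    given). Note that on a single self-consistent measurement CDI > 1 on
    viability is algebraically equivalent to observed-below-Bliss on
    inhibition, so discordant published calls across the models imply the
    underlying response estimates came from different assays; no
    reconciliation is attempted here. Use :func:`consensus_call` directly to
    combine per-model results computed on separately measured inputs.
    """
    inh = m if m.response_kind == "inhibition" else to_inhibition(m)
    results = [
        cdi_additivity(m, tol=cdi_tol),
        bliss_independence(inh, tol=excess_tol),
        hsa_independence(inh, tol=excess_tol),
    ]
    return {
        "results": results,
        "consensus": consensus_call(results),
        "note": "consensus is a 2-of-3 majority over the three model calls",
    }


# ---------------------------------------------------------------------------
# dose utilities
# ---------------------------------------------------------------------------


def mass_to_molar(conc_ug_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert ug/mL to uM: conc / M * 1000. Exact value; see format_molar
    for the 2-decimal display convention."""
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be > 0")
    if conc_ug_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return conc_ug_per_ml / molar_mass_g_per_mol * 1000.0


def format_molar(conc_um: float) -> str:
    """Render a molar concentration at 2 decimals (round-half-even)."""
    return f"{np.round(conc_um, 2):.2f}"


@dataclass(frozen=True)
class DoseResponseTable:
    """Rows of (concentration, unit, response fraction, replicate id)."""

    data: pd.DataFrame

    REQUIRED = ("concentration", "response")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"dose-response table missing columns: {missing}")
        if (df["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        if ((df["response"] < 0) | (df["response"] > 1)).any():
            raise ValueError("responses must be fractions in [0, 1]")

    @property
    def n_distinct_concentrations(self) -> int:
        return int(self.data["concentration"].nunique())

    @classmethod
    def from_arrays(cls, concentration, response, replicate=None, unit="ug/mL"):
        df = pd.DataFrame(
            {
                "concentration": np.asarray(concentration, dtype=float),
                "response": np.asarray(response, dtype=float),
            }
        )
        df["replicate"] = replicate if replicate is not None else 0
        df["unit"] = unit
        return cls(df)


@dataclass(frozen=True)
class IC50Fit:
    """Relative IC50 and companion 4PL parameters with fit diagnostics."""

    ic50: float
    hill: float
    top: float
    bottom: float
    sse: float
    n_points: int
    spearman_rho: float


def four_param_logistic(c, bottom, top, ic50, hill):
    """response = bottom + (top - bottom) / (1 + (c / IC50)^hill)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, c / ic50, 0.0)
        term = np.where(c > 0, ratio**hill, 0.0)
    return bottom + (top - bottom) / (1.0 + term)


class FourParamLogisticIC50(RegressorMixin, BaseEstimator):
    """Four-parameter logistic dose-response fit (relative IC50).

    Least squares over (bottom, top, log10 IC50, hill) with multi-start
    initialization over hill in {0.5, 1, 2, 4}; bounds bottom in [0, 0.5],
    top in [0.5, 1.1], IC50 within two decades of the observed dose range.
    ``fit(X, y)`` takes concentrations as a column vector X and fractional
    responses y; fitted attributes are ``ic50_``, ``hill_``, ``top_``,
    ``bottom_``.
    """

    HILL_STARTS = (0.5, 1.0, 2.0, 4.0)

    def __init__(self, monotonicity_warn_rho: float = 0.5):
        self.monotonicity_warn_rho = monotonicity_warn_rho

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if c.size != y.size:
            raise ValueError("X and y must have the same length")
        if np.unique(c).size < 4:
            raise ValueError("IC50 fitting requires >= 4 distinct concentrations")
        if np.ptp(y) < 1e-9:
            raise ValueError("degenerate dose-response: responses are constant")
        rho = spearmanr(c, y).statistic
        if abs(rho) < self.monotonicity_warn_rho:
            warnings.warn(
                f"dose-response not monotone (Spearman |rho|={abs(rho):.2f} "
                f"< {self.monotonicity_warn_rho}); IC50 may be unreliable",
                UserWarning,
                stacklevel=2,
            )
        pos = c[c > 0]
        if pos.size == 0:
            raise ValueError("need at least one positive concentration")
        log_lo = np.log10(pos.min()) - 2.0
        log_hi = np.log10(pos.max()) + 2.0
        log_init = float(np.mean(np.log10(pos)))
        bottom0 = float(np.clip(y.min(), 0.0, 0.5))
        top0 = float(np.clip(y.max(), 0.5, 1.1))

        def residuals(params):
            bottom, top, log_ic50, hill = params
            return four_param_logistic(c, bottom, top, 10.0**log_ic50, hill) - y

        best = None
        for hill0 in self.HILL_STARTS:
            try:
                sol = least_squares(
                    residuals,
                    x0=[bottom0, top0, log_init, hill0],
                    bounds=([0.0, 0.5, log_lo, 0.05], [0.5, 1.1, log_hi, 10.0]),
                    method="trf",
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                "4PL fit failed to converge from any start; check the dose range "
                "and response scale"
            )
        bottom, top, log_ic50, hill = best.x
        self.bottom_, self.top_ = float(bottom), float(top)
        self.ic50_, self.hill_ = float(10.0**log_ic50), float(hill)
        self.sse_ = float(2.0 * best.cost)
        self.spearman_rho_ = float(rho)
        self.n_points_ = int(c.size)
        return self

    def predict(self, X):
        check_is_fitted(self)
        c = np.asarray(X, dtype=float).reshape(-1)
        return four_param_logistic(c, self.bottom_, self.top_, self.ic50_, self.hill_)


def fit_ic50_4pl(table: DoseResponseTable, seed: int | None = None) -> IC50Fit:
    """Fit a 4PL curve to a dose-response table; return the relative IC50.

    The fit is deterministic (fixed multi-start grid); ``seed`` is accepted
    for pipeline-interface symmetry and unused.
    """
    est = FourParamLogisticIC50().fit(
        table.data["concentration"].to_numpy(), table.data["response"].to_numpy()
    )
    return IC50Fit(
        ic50=est.ic50_,
        hill=est.hill_,
        top=est.top_,
        bottom=est.bottom_,
        sse=est.sse_,
        n_points=est.n_points_,
        spearman_rho=est.spearman_rho_,
    )
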