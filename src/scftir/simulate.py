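"""Synthetic single-cell infrared cohort generator.

Emulates the statistical structure a single-cell FTIR heterogeneity analysis
assumes: each cell's absorbance is a sum of Gaussian absorption bands in the
fatty-acid, protein, and carbohydrate regions, with treatment-group
multiplicative effects on band amplitudes, per-cell log-normal amplitude
variability (biological heterogeneity), a Mie-like scattering baseline with
per-cell effective sphere size and refractive index, a small linear drift,
and additive white noise. All randomness flows from one seeded generator per
cohort, with per-cell draws consumed in cell-id order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, SpectrumSet, default_region_table

__all__ = [
    "Band",
    "BandTable",
    "CohortDesign",
    "default_band_table",
    "default_grid",
    "mie_artifact",
    "simulate_cohort",
    "noise_free_design",
]

_UM_TO_CM = 1e-4


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center and FWHM in cm^-1, mean amplitude
    in absorbance units, region label."""

    center: float
    fwhm: float
    amplitude: float
    region: str

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian evaluated on the grid."""
        sigma2 = self.fwhm**2 / (8.0 * np.log(2.0))
        return np.exp(-((wavenumbers - self.center) ** 2) / (2.0 * sigma2))


@dataclass(frozen=True)
class BandTable:
    """Ordered band list, strictly descending in center wavenumber."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        centers = [b.center for b in self.bands]
        if any(c2 >= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly descending")
        for b in self.bands:
            if b.fwhm <= 0 or b.amplitude < 0:
                raise ValueError(f"band at {b.center} cm^-1: fwhm must be > 0, amplitude >= 0")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.bands])

    @property
    def regions(self) -> list[str]:
        return [b.region for b in self.bands]

    def region_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.bands:
            counts[b.region] = counts.get(b.region, 0) + 1
        return counts


def default_band_table() -> BandTable:
    """Fourteen canonical cell-FTIR bands: 4 fatty-acid CH stretches, 7
    protein-region bands (ester carbonyl, amide I components, amide II,
    tyrosine ring, amide II'), 3 carbohydrate/nucleic-acid bands.

    Centers are canonical literature assignments; amplitudes are typical
    relative intensities for a fixed hydrated cell (amide I dominant).
    Widths are kept narrow enough that the closest default pairs (18 and
    17 cm^-1 apart) stay resolved as distinct second-derivative minima
    after 9-point smoothing.
    """
    rows = [
        # (center, fwhm, amplitude, region)
        (2956.0, 14.0, 0.40, "fatty_acid"),   # nu_as CH3
        (2922.0, 16.0, 0.50, "fatty_acid"),   # nu_as CH2
        (2874.0, 10.0, 0.25, "fatty_acid"),   # nu_s CH3
        (2852.0, 10.0, 0.30, "fatty_acid"),   # nu_s CH2
        (1740.0, 14.0, 0.20, "protein"),      # ester C=O (lipid, protein-region interval)
        (1695.0, 12.0, 0.25, "protein"),      # amide I (beta-turn)
        (1655.0, 12.0, 1.00, "protein"),      # amide I (alpha-helix)
        (1630.0, 10.0, 0.45, "protein"),      # amide I (beta-sheet)
        (1585.0, 12.0, 0.20, "protein"),      # COO- / side chain
        (1545.0, 14.0, 0.60, "protein"),      # amide II
        (1515.0, 10.0, 0.20, "protein"),      # tyrosine ring
        (1240.0, 20.0, 0.35, "carbohydrate"), # nu_as PO2-
        (1085.0, 18.0, 0.40, "carbohydrate"), # nu_s PO2- / C-O
        (1050.0, 14.0, 0.30, "carbohydrate"), # C-O sugars
    ]
    return BandTable(tuple(Band(*r) for r in rows))


def default_grid(hi: float = 4000.0, lo: float = 650.0, spacing: float = 2.0) -> np.ndarray:
    """Descending wavenumber grid, default 4,000 -> 650 cm^-1 at 2 cm^-1."""
    n = int(round((hi - lo) / spacing)) + 1
    return np.linspace(hi, lo, n)


@dataclass(frozen=True)
class CohortDesign:
    """Study design for one simulated cohort.

    ``group_effects`` maps group label -> per-band multiplicative factor
    (scalar applied to every band, or one factor per band). ``cell_cv`` is
    the log-normal coefficient of variation of per-cell band amplitudes;
    ``noise_sd`` the additive Gaussian noise sd (a.u.); ``mie_amplitude``
    the scattering-artifact scale (a.u.); ``drift_sd`` the sd of the random
    per-cell linear baseline drift over the full grid span (a.u.).
    """

    n_cells_per_group: int = 50
    group_effects: dict[str, object] = field(
        default_factory=lambda: {"untreated": 1.0}
    )
    cell_cv: float = 0.15
    noise_sd: float = 0.002
    mie_amplitude: float = 0.05
    drift_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_group < 1:
            raise ValueError("n_cells_per_group must be >= 1")
        if self.cell_cv < 0 or self.noise_sd < 0 or self.mie_amplitude < 0 or self.drift_sd < 0:
            raise ValueError("cell_cv, noise_sd, mie_amplitude, drift_sd must be >= 0")
        if not self.group_effects:
            raise ValueError("at least one group required")
        for g, eff in self.group_effects.items():
            if np.any(np.asarray(eff, dtype=float) <= 0):
                raise ValueError(f"group {g!r}: effects must be > 0")


def mie_artifact(
    grid: np.ndarray,
    amplitude: float,
    sphere_diameter: float = 12.0,
    refractive_index: float = 1.4,
    seed: int | None = None,
) -> np.ndarray:
    """Non-resonant Mie scattering baseline on the grid.

    Van de Hulst approximate extinction efficiency for a homogeneous sphere,

        Q(w) = 2 - (4/rho) sin(rho) + (4/rho^2)(1 - cos(rho)),
        rho = 2 pi d (n - 1) w,

    with sphere diameter ``d`` converted from um to cm and ``w`` in cm^-1.
    The curve is normalized to unit max |Q| over the grid, then scaled to
    the requested ``amplitude``. The function is a closed form in (d, n);
    ``seed`` is accepted for interface symmetry and unused.
    """
    if not 2.0 <= sphere_diameter <= 30.0:
        raise ValueError(f"sphere_diameter {sphere_diameter} um outside [2, 30]")
    if not 1.1 <= refractive_index <= 1.5:
        raise ValueError(f"refractive_index {refractive_index} outside [1.1, 1.5]")
    w = np.asarray(grid, dtype=float)
    if amplitude == 0:
        return np.zeros_like(w)
    rho = 2.0 * np.pi * sphere_diameter * _UM_TO_CM * (refractive_index - 1.0) * w
    q = 2.0 - (4.0 / rho) * np.sin(rho) + (4.0 / rho**2) * (1.0 - np.cos(rho))
    return amplitude * q / np.max(np.abs(q))


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 log-normal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def simulate_cohort(
    design: CohortDesign,
    bands: BandTable | None = None,
    grid: np.ndarray | None = None,
) -> SpectrumSet:
    """Simulate a cohort of single-cell absorbance spectra.

    Per cell: absorbance = sum_b amp_{cell,b} * Gaussian(center_b, fwhm_b)
    + mie baseline + linear drift + noise, with
    amp_{cell,b} = amplitude_b * group_effect_b * lognormal(cv).
    Deterministic given ``design.seed``; group labels are attached; cell ids
    are ``<group>_<index>`` and draws are consumed in cell-id order.
    """
    bands = bands if bands is not None else default_band_table()
    grid = np.asarray(grid, dtype=float) if grid is not None else default_grid()
    lo, hi = grid.min(), grid.max()
    outside = [b.center for b in bands if not lo <= b.center <= hi]
    if outside:
        raise ValueError(f"band centers outside grid [{lo}, {hi}]: {outside}")

    rng = np.random.default_rng(design.seed)
    profiles = np.vstack([b.profile(grid) for b in bands])  # (n_bands, n_points)
    base_amp = bands.amplitudes
    span = grid.max() - grid.min()

    spectra = []
    for group, effect in design.group_effects.items():
        eff = np.broadcast_to(np.asarray(effect, dtype=float), base_amp.shape)
        for i in range(design.n_cells_per_group):
            amps = base_amp * eff * _lognormal_factors(rng, design.cell_cv, len(bands))
            absorb = amps @ profiles
            if design.mie_amplitude > 0:
                d = rng.uniform(8.0, 18.0)
                n_idx = rng.uniform(1.3, 1.45)
                absorb = absorb + mie_artifact(grid, design.mie_amplitude, d, n_idx)
            if design.drift_sd > 0:
                slope = rng.normal(0.0, design.drift_sd) / span
                intercept = rng.normal(0.0, design.drift_sd)
                absorb = absorb + intercept + slope * (grid - grid.min())
            if design.noise_sd > 0:
                absorb = absorb + rng.normal(0.0, design.noise_sd, size=grid.size)
            spectra.append(
                Spectrum(
                    f"{group}_{i:03d}",
                    grid.copy(),
                    absorb,
                    group=group,
                    provenance=("simulated",),
                )
            )
    return SpectrumSet(spectra)


def noise_free_design(groups: dict[str, object] | None = None, n_cells: int = 1) -> CohortDesign:
    """Convenience: a deterministic design with all stochastic terms off."""
    return CohortDesign(
        n_cells_per_group=n_cells,
        group_effects=groups or {"untreated": 1.0},
        cell_cv=0.0,
        noise_sd=0.0,
        mie_amplitude=0.0,
        drift_sd=0.0,
        seed=0,
    )


# re-export for configs that pair bands with the region table
DEFAULT_REGIONS = default_region_table()
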