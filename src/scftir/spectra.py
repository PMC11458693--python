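"""Domain types for single-cell infrared spectra and cohorts.

A :class:`Spectrum` is one cell's mid-infrared absorbance trace on a
wavenumber grid stored high-to-low (4,000 -> 650 cm^-1, the spectrometer
convention). A :class:`SpectrumSet` is a cohort of spectra sharing one grid,
with treatment-group labels — the in-memory analog of a cohort of ~200
single-cell measurements. A :class:`RegionTable` names the biochemical
wavenumber regions (fatty acid, protein, carbohydrate) used throughout the
subregional analyses.

Cohorts are read and written as plain-text wide or long tables; grids must
match exactly across cells (no interpolation on load).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MIN_GRID_POINTS = 16
_SPACING_RATIO_LIMIT = 1.01

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "RegionTable",
    "AlignmentError",
    "SpectrumParseError",
    "read_spectrum_set",
    "write_spectrum_set",
    "crop",
    "default_region_table",
]


class AlignmentError(ValueError):
    """Raised when cohort members do not share an identical wavenumber grid."""


class SpectrumParseError(ValueError):
    """Raised when a spectral table contains non-numeric or malformed cells."""


def _validate_grid(wavenumbers: np.ndarray) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < MIN_GRID_POINTS:
        raise ValueError(
            f"wavenumber grid must be 1-D with >= {MIN_GRID_POINTS} points, got shape {w.shape}"
        )
    dw = np.diff(w)
    if np.all(dw > 0):  # ascending input: flip to descending convention
        w = w[::-1]
        dw = np.diff(w)
    if not np.all(dw < 0):
        raise ValueError("wavenumber grid must be strictly monotone")
    spacing = -dw
    if spacing.max() / spacing.min() >= _SPACING_RATIO_LIMIT:
        raise ValueError(
            "wavenumber grid spacing not approximately uniform "
            f"(max/min adjacent ratio {spacing.max() / spacing.min():.4f} >= {_SPACING_RATIO_LIMIT})"
        )
    return w


@dataclass(frozen=True)
class Spectrum:
    """One cell's absorbance spectrum on a descending wavenumber grid."""

    cell_id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    group: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = _validate_grid(self.wavenumbers)
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != np.asarray(self.wavenumbers).shape:
            raise ValueError(
                f"wavenumbers and absorbance length mismatch for cell {self.cell_id!r}"
            )
        if w is not self.wavenumbers and not np.array_equal(w, self.wavenumbers):
            a = a[::-1]  # grid was flipped ascending -> descending
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, absorbance: np.ndarray, tag: str) -> "Spectrum":
        """Return a copy with new absorbance values and a provenance tag appended."""
        return replace(
            self,
            absorbance=np.asarray(absorbance, dtype=float),
            provenance=self.provenance + (tag,),
        )


@dataclass
class SpectrumSet:
    """An ordered cohort of spectra on one shared wavenumber grid."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            return
        grid = self.spectra[0].wavenumbers
        offenders = [
            s.cell_id
            for s in self.spectra
            if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid)
        ]
        if offenders:
            raise AlignmentError(
                f"spectra not on the shared grid (exact match required): {offenders}"
            )
        ids = [s.cell_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cell_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def shared_grid(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty SpectrumSet has no grid")
        return self.spectra[0].wavenumbers

    @property
    def cell_ids(self) -> list[str]:
        return [s.cell_id for s in self.spectra]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.spectra]

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def to_matrix(self) -> np.ndarray:
        """Cohort absorbance as a (k cells x n wavenumbers) array."""
        return np.vstack([s.absorbance for s in self.spectra])

    @classmethod
    def from_matrix(
        cls,
        wavenumbers: np.ndarray,
        matrix: np.ndarray,
        cell_ids: list[str],
        groups: list[str] | None = None,
        provenance: tuple[str, ...] = (),
    ) -> "SpectrumSet":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != len(cell_ids):
            raise ValueError("matrix must be (n_cells, n_points)")
        groups = groups if groups is not None else [""] * len(cell_ids)
        return cls(
            [
                Spectrum(cid, np.array(wavenumbers, dtype=float), row, group=g,
                         provenance=provenance)
                for cid, g, row in zip(cell_ids, groups, matrix)
            ]
        )

    def map_absorbance(self, fn, tag: str) -> "SpectrumSet":
        """Apply ``fn(spectrum) -> absorbance array`` to every cell; tag provenance."""
        return SpectrumSet([s.with_absorbance(fn(s), tag) for s in self.spectra])

    def subset(self, indices) -> "SpectrumSet":
        return SpectrumSet([self.spectra[i] for i in indices])


@dataclass(frozen=True)
class RegionTable:
    """Named wavenumber regions, each a tuple of closed intervals (lo, hi) in cm^-1.

    Interval membership is lo <= w <= hi regardless of storage order. A
    wavenumber shared by two adjacent regions (e.g., 1,480 or 1,300 cm^-1)
    belongs to the region whose containing interval has the higher upper
    bound, so subregional point sets partition the grid.
    """

    regions: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for name, intervals in self.regions.items():
            for lo, hi in intervals:
                if not lo < hi:
                    raise ValueError(f"region {name!r}: interval must have lo < hi, got ({lo}, {hi})")
            ordered = sorted(intervals)
            for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
                if hi1 > lo2:
                    raise ValueError(f"region {name!r}: overlapping intervals")

    @property
    def names(self) -> list[str]:
        return list(self.regions)

    def intervals(self, name: str) -> tuple[tuple[float, float], ...]:
        return self.regions[name]

    def region_of(self, w: float) -> str | None:
        """Region owning wavenumber ``w`` under the higher-region boundary rule."""
        candidates = []
        for name, intervals in self.regions.items():
            for lo, hi in intervals:
                if lo <= w <= hi:
                    candidates.append((hi, name))
        if not candidates:
            return None
        return max(candidates)[1]

    def mask(self, wavenumbers: np.ndarray, name: str) -> np.ndarray:
        """Boolean mask of grid points owned by region ``name`` (boundary rule applied)."""
        w = np.asarray(wavenumbers, dtype=float)
        return np.array([self.region_of(x) == name for x in w])


def default_region_table() -> RegionTable:
    """Fatty acid (3,000-2,800 and 1,480-1,300), protein (1,800-1,480),
    carbohydrate/nucleic acid (1,300-900) cm^-1."""
    return RegionTable(
        {
            "fatty_acid": ((2800.0, 3000.0), (1300.0, 1480.0)),
            "protein": ((1480.0, 1800.0),),
            "carbohydrate": ((900.0, 1300.0),),
        }
    )


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

_WIDE_FIRST_COL = "wavenumber_cm-1"


def write_spectrum_set(spectrum_set: SpectrumSet, path, delimiter: str = ",") -> str:
    """Write a cohort as a wide text table.

    First column is the wavenumber grid, one column per cell, full float
    precision. Group labels go in a ``#group:`` header line; provenance tags
    in ``#provenance:`` lines.
    """
    if len(spectrum_set) == 0:
        raise ValueError("cannot write an empty SpectrumSet")
    path = str(path)
    with open(path, "w") as fh:
        group_map = delimiter.join(
            f"{s.cell_id}={s.group}" for s in spectrum_set if s.group
        )
        if group_map:
            fh.write(f"#group: {group_map}\n")
        tags = {s.provenance for s in spectrum_set}
        if len(tags) == 1 and next(iter(tags)):
            fh.write("#provenance: " + ";".join(next(iter(tags))) + "\n")
        header = delimiter.join([_WIDE_FIRST_COL] + spectrum_set.cell_ids)
        fh.write(header + "\n")
        grid = spectrum_set.shared_grid
        mat = spectrum_set.to_matrix()
        for j, w in enumerate(grid):
            row = [np.format_float_scientific(w, unique=True)] + [
                np.format_float_scientific(v, unique=True) for v in mat[:, j]
            ]
            fh.write(delimiter.join(row) + "\n")
    return path


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_spectrum_set(path, format: str = "wide_table") -> SpectrumSet:
    """Read a cohort from a wide or long text table.

    Wide tables: header ``wavenumber_cm-1,<cell_id>,...`` with optional
    ``#group:`` metadata lines. Long tables: columns
    ``cell_id, group, wavenumber_cm-1, absorbance``. Ascending grids are
    reversed to the descending storage convention. Cells whose grids do not
    match exactly raise :class:`AlignmentError` naming the offenders.
    """
    if format == "wide_table":
        return _read_wide(path)
    if format == "long_table":
        return _read_long(path)
    raise ValueError(f"unknown format {format!r}; expected 'wide_table' or 'long_table'")


def _read_wide(path) -> SpectrumSet:
    groups: dict[str, str] = {}
    provenance: tuple[str, ...] = ()
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#group:"):
                payload = line[len("#group:"):].strip()
                delim = _sniff_delimiter(payload)
                for pair in payload.split(delim):
                    if "=" in pair:
                        cid, grp = pair.split("=", 1)
                        groups[cid.strip()] = grp.strip()
            elif line.startswith("#provenance:"):
                provenance = tuple(line[len("#provenance:"):].strip().split(";"))
            elif line.startswith("#"):
                continue
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise SpectrumParseError(f"no data rows in {path}")
    delim = _sniff_delimiter(body_lines[0])
    try:
        df = pd.read_csv(io.StringIO("".join(body_lines)), sep=delim, dtype=str)
    except Exception as exc:  # malformed table structure
        raise SpectrumParseError(f"cannot parse {path}: {exc}") from exc
    raw = df.to_numpy(dtype=str)
    try:
        # numpy's string->float conversion is exact (round-trips shortest reprs)
        values = raw.astype(float)
    except ValueError:
        for r in range(raw.shape[0]):
            for cell in raw[r]:
                try:
                    float(cell)
                except ValueError:
                    raise SpectrumParseError(
                        f"non-numeric cell {cell!r} at data row {r + 1} in {path}"
                    ) from None
        raise
    grid = values[:, 0]
    cell_ids = list(df.columns[1:])
    mat = values[:, 1:].T
    return SpectrumSet.from_matrix(
        grid, mat, cell_ids, [groups.get(c, "") for c in cell_ids], provenance
    )


def _read_long(path) -> SpectrumSet:
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    except Exception as exc:
        raise SpectrumParseError(f"cannot parse {path}: {exc}") from exc
    required = {"cell_id", "group", "wavenumber_cm-1", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise SpectrumParseError(f"long table missing columns: {sorted(missing)}")
    for col in ("wavenumber_cm-1", "absorbance"):
        vals = df[col].to_numpy()
        try:
            df[col] = vals.astype(float)  # exact string->float conversion
        except (ValueError, TypeError):
            for r, cell in enumerate(vals):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise SpectrumParseError(
                        f"non-numeric {col} value {cell!r} at row {r + 1} in {path}"
                    ) from None
            raise
    spectra = []
    ref_grid: np.ndarray | None = None
    offenders: list[str] = []
    for cid, sub in df.groupby("cell_id", sort=False):
        w = sub["wavenumber_cm-1"].to_numpy(dtype=float)
        a = sub["absorbance"].to_numpy(dtype=float)
        order = np.argsort(-w, kind="stable")
        w, a = w[order], a[order]
        if ref_grid is None:
            ref_grid = w
        if w.shape != ref_grid.shape or not np.array_equal(w, ref_grid):
            offenders.append(str(cid))
            continue
        group = str(sub["group"].iloc[0]) if not sub["group"].isna().all() else ""
        spectra.append(Spectrum(str(cid), w.copy(), a, group=group))
    if offenders:
        raise AlignmentError(
            f"spectra not on the shared grid (exact match required): {offenders}"
        )
    return SpectrumSet(spectra)


def crop(spectrum_set: SpectrumSet, interval: tuple[float, float]) -> SpectrumSet:
    """Restrict the cohort grid to the closed interval [lo, hi] (cm^-1).

    Point order is preserved; a provenance tag records the crop.
    """
    lo, hi = sorted(interval)
    grid = spectrum_set.shared_grid
    keep = (grid >= lo) & (grid <= hi)
    if not keep.any():
        raise ValueError(
            f"crop interval [{lo}, {hi}] does not overlap grid "
            f"[{grid.min()}, {grid.max()}]"
        )
    if keep.all():
        return spectrum_set
    if keep.sum() < MIN_GRID_POINTS:
        raise ValueError(
            f"crop interval [{lo}, {hi}] retains {int(keep.sum())} points; "
            f"at least {MIN_GRID_POINTS} required"
        )
    tag = f"crop[{lo:g},{hi:g}]"
    return SpectrumSet(
        [
            Spectrum(
                s.cell_id,
                grid[keep].copy(),
                s.absorbance[keep].copy(),
                group=s.group,
                provenance=s.provenance + (tag,),
            )
            for s in spectrum_set
        ]
    )
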