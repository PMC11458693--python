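"""End-to-end pipeline: simulate/load -> preprocess -> features -> heterogeneity.

One :class:`PipelineConfig` drives every stage; a run writes all artifacts
(cohort tables, feature matrix, four distance matrices, four PCA results)
into an output directory together with a manifest recording each file, the
config hash and the seed. Reruns with the same config reproduce all numeric
outputs bitwise: the only randomness is the seeded cohort simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_EXPECTED_COUNTS,
    build_feature_matrix,
    detect_peaks,
    split_subregions,
)
from .heterogeneity import (
    REGION_SCOPES,
    distance_matrix,
    heterogeneity_index,
    pair_histogram,
    pca_spectra,
)
from .preprocess import PreprocessConfig, preprocess_cohort
from .simulate import BandTable, CohortDesign, default_band_table, simulate_cohort
from .spectra import read_spectrum_set, write_spectrum_set

__all__ = ["PipelineConfig", "run_pipeline"]

PCA_SCOPES = ("full_spectrum", "fatty_acid", "protein", "carbohydrate")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``input_path`` (an existing wide-table cohort) or ``design``
    (a simulation) supplies the cohort. ``out_dir`` receives all artifacts.
    """

    out_dir: str = "scftir_run"
    input_path: str | None = None
    design: CohortDesign = field(default_factory=CohortDesign)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    expected_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EXPECTED_COUNTS)
    )
    value_source: str = "original_absorbance"
    n_histogram_bins: int = 30
    seed: int | None = None

    def config_hash(self) -> str:
        payload = asdict(self)
        if self.seed is not None:
            payload["design"]["seed"] = self.seed
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_df(df: pd.DataFrame, path: Path, manifest: list[str], **kwargs) -> None:
    df.to_csv(path, **kwargs)
    manifest.append(path.name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    design = config.design
    if config.seed is not None:
        design = CohortDesign(**{**asdict(design), "seed": config.seed})

    try:
        if config.input_path is not None:
            if not Path(config.input_path).exists():
                raise FileNotFoundError(f"input cohort not found: {config.input_path}")
            cohort = read_spectrum_set(config.input_path)
        else:
            cohort = simulate_cohort(design)
            write_spectrum_set(cohort, out / "cohort.csv")
            files.append("cohort.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'load/simulate' failed: {exc}") from exc

    try:
        processed, deriv = preprocess_cohort(cohort, config.preprocess)
        write_spectrum_set(processed, out / "processed.csv")
        files.append("processed.csv")
        write_spectrum_set(deriv, out / "second_derivative.csv")
        files.append("second_derivative.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        peaks = detect_peaks(deriv, expected_counts=config.expected_counts)
        _write_df(
            pd.DataFrame(
                {"position_cm-1": peaks.positions, "region": peaks.regions}
            ),
            out / "peaks.csv",
            files,
            index=False,
        )
        fm = build_feature_matrix(processed, deriv, peaks, config.value_source)
        _write_df(fm.to_dataframe(), out / "features.csv", files, index_label="cell_id")
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    indices: dict[str, dict] = {}
    try:
        for scope in REGION_SCOPES:
            dm = distance_matrix(fm, scope)
            _write_df(
                pd.DataFrame(dm.D, index=dm.cell_ids, columns=dm.cell_ids),
                out / f"distances_{scope}.csv",
                files,
                index_label="cell_id",
            )
            edges, counts = pair_histogram(dm, config.n_histogram_bins)
            _write_df(
                pd.DataFrame(
                    {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
                ),
                out / f"histogram_{scope}.csv",
                files,
                index=False,
            )
            indices[scope] = heterogeneity_index(dm)
        (out / "heterogeneity.json").write_text(json.dumps(indices, indent=2))
        files.append("heterogeneity.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'distances' failed: {exc}") from exc

    try:
        for scope in PCA_SCOPES:
            res = pca_spectra(deriv, scope)
            df = pd.DataFrame(
                res.scores,
                index=res.cell_ids,
                columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])],
            )
            df["group"] = cohort.groups
            _write_df(df, out / f"pca_{scope}_scores.csv", files, index_label="cell_id")
            _write_df(
                pd.DataFrame(
                    {
                        "component": np.arange(1, res.scores.shape[1] + 1),
                        "explained_variance_fraction": res.explained_variance_fraction,
                    }
                ),
                out / f"pca_{scope}_variance.csv",
                files,
                index=False,
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'pca' failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": design.seed,
        "n_cells": len(cohort),
        "groups": cohort.group_labels,
        "n_peaks": len(peaks),
        "files": sorted(files),
        "heterogeneity": indices,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
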