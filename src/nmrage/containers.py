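"""In-memory containers and text I/O for 1D NMR spectra.

The universal currency of the pipeline is the :class:`SpectraMatrix`: a
cohort of spectra sharing one descending ppm axis, with per-sample
metadata and an append-only processing log.

On-disk formats (plain text):

* intensity matrix — CSV, first column ``ppm`` (descending), one column
  per sample named by ``sample_id``; '.' decimal, no thousands separators;
* metadata — TSV with exact columns ``sample_id  mouse_id  genotype
  week  fluid  batch``.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["sample_id", "mouse_id", "genotype", "week", "fluid", "batch"]
VALID_GENOTYPES = {"WT", "KO"}
VALID_FLUIDS = {"urine", "plasma_1d", "plasma_cpmg"}


def _check_axis(ppm: np.ndarray) -> np.ndarray:
    ppm = np.asarray(ppm, dtype=float)
    if ppm.ndim != 1 or ppm.size < 2:
        raise ValueError("ppm axis must be a 1-D array with at least 2 points")
    d = np.diff(ppm)
    if not (np.all(d < 0) or np.all(d > 0)):
        raise ValueError("ppm axis must be strictly monotone")
    if np.all(d > 0):  # store descending, NMR plotting convention
        ppm = ppm[::-1]
    return ppm


@dataclass
class Spectrum:
    """A single 1D spectrum on a descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ppm = _check_axis(self.ppm)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm is not self.ppm and np.all(np.diff(np.asarray(self.ppm)) > 0):
            intensity = intensity[::-1]
        if intensity.shape != ppm.shape:
            raise ValueError(
                f"intensity length {intensity.size} != axis length {ppm.size}"
            )
        if not np.all(np.isfinite(intensity)):
            raise ValueError("spectrum contains non-finite intensities")
        self.ppm = ppm
        self.intensity = intensity


class SpectraMatrix:
    """Samples × ppm-grid intensity matrix with shared axis and metadata.

    Parameters
    ----------
    ppm
        Shared chemical-shift axis; stored strictly descending.
    intensities
        Array of shape ``(n_samples, n_points)``.
    meta
        DataFrame with :data:`METADATA_COLUMNS`; row order matches the
        intensity rows.
    log
        Ordered list of applied processing steps, each a dict with at
        least a ``"step"`` key. Append-only.
    """

    def __init__(
        self,
        ppm: np.ndarray,
        intensities: np.ndarray,
        meta: pd.DataFrame,
        log: list[dict] | None = None,
    ):
        raw_ppm = np.asarray(ppm, dtype=float)
        ppm = _check_axis(raw_ppm)
        X = np.asarray(intensities, dtype=float)
        if raw_ppm.size > 1 and np.all(np.diff(raw_ppm) > 0):
            X = X[:, ::-1]  # store descending
        if X.ndim != 2 or X.shape[1] != ppm.size:
            raise ValueError(
                f"intensities shape {X.shape} incompatible with axis of {ppm.size} points"
            )
        meta = meta.reset_index(drop=True)
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(meta) != X.shape[0]:
            raise ValueError(
                f"{len(meta)} metadata rows for {X.shape[0]} spectra"
            )
        dup = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicated sample ids: {sorted(set(dup))}")
        self.ppm = ppm
        self.intensities = X
        self.meta = meta[METADATA_COLUMNS].copy()
        self._log: list[dict] = list(log) if log else []

    # -- basic protocol ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()

    @property
    def log(self) -> tuple[dict, ...]:
        return tuple(self._log)

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.ppm.copy(),
            self.intensities.copy(),
            self.meta.copy(),
            _copy.deepcopy(self._log),
        )

    def with_step(self, step: str, **params) -> "SpectraMatrix":
        """Return self after appending a processing-log entry (in place)."""
        self._log.append({"step": step, **params})
        return self

    def has_step(self, step: str) -> bool:
        return any(e.get("step") == step for e in self._log)

    def sample(self, sample_id: str) -> Spectrum:
        idx = self.sample_ids.index(sample_id)
        return Spectrum(
            self.ppm.copy(),
            self.intensities[idx].copy(),
            self.meta.iloc[idx].to_dict(),
        )

    def subset(self, mask) -> "SpectraMatrix":
        """Row-subset by boolean mask or list of sample ids."""
        if isinstance(mask, (list, tuple)) and mask and isinstance(mask[0], str):
            mask = self.meta["sample_id"].isin(mask).to_numpy()
        mask = np.asarray(mask)
        return SpectraMatrix(
            self.ppm.copy(),
            self.intensities[mask].copy(),
            self.meta.loc[mask].copy(),
            _copy.deepcopy(self._log),
        )

    def sort_samples(self) -> "SpectraMatrix":
        """Deterministic sample order: lexicographic by sample_id."""
        order = np.argsort(self.meta["sample_id"].to_numpy())
        return SpectraMatrix(
            self.ppm.copy(),
            self.intensities[order].copy(),
            self.meta.iloc[order].copy(),
            _copy.deepcopy(self._log),
        )


def _grid_summary(ppm: np.ndarray) -> str:
    return (
        f"[{ppm.max():.6g}..{ppm.min():.6g}] ppm, {ppm.size} points, "
        f"step {abs(np.median(np.diff(ppm))):.6g}"
    )


def read_spectra(
    matrix_path: str | Path | Sequence[str | Path],
    metadata_path: str | Path,
) -> SpectraMatrix:
    """Read a :class:`SpectraMatrix` from CSV matrix file(s) + metadata TSV.

    Several matrix CSVs may be given (e.g. a cohort split across files);
    they must share the ppm axis exactly.
    """
    if isinstance(matrix_path, (str, Path)):
        matrix_paths = [Path(matrix_path)]
    else:
        matrix_paths = [Path(p) for p in matrix_path]
    frames = []
    for p in matrix_paths:
        df = pd.read_csv(p, float_precision="round_trip")
        if df.columns[0] != "ppm":
            raise ValueError(f"{p}: first column must be 'ppm', got {df.columns[0]!r}")
        frames.append(df)
    ppm0 = frames[0]["ppm"].to_numpy()
    for p, df in zip(matrix_paths[1:], frames[1:]):
        ppm = df["ppm"].to_numpy()
        if ppm.size != ppm0.size or not np.array_equal(ppm, ppm0):
            raise ValueError(
                "ppm axes differ between matrix files: "
                f"{matrix_paths[0]}: {_grid_summary(ppm0)} vs {p}: {_grid_summary(ppm)}"
            )
    wide = pd.concat(
        [frames[0]] + [df.drop(columns="ppm") for df in frames[1:]], axis=1
    )
    sample_cols = [c for c in wide.columns if c != "ppm"]
    if len(set(sample_cols)) != len(sample_cols):
        dups = sorted({c for c in sample_cols if sample_cols.count(c) > 1})
        raise ValueError(f"duplicated sample ids in matrix files: {dups}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata file missing columns: {missing_cols}")
    meta_ids = meta["sample_id"].tolist()
    missing_meta = sorted(set(sample_cols) - set(meta_ids))
    if missing_meta:
        raise ValueError(f"metadata missing sample ids: {missing_meta}")
    extra_meta = sorted(set(meta_ids) - set(sample_cols))
    if extra_meta:
        raise ValueError(f"metadata lists samples absent from matrix: {extra_meta}")
    # align metadata to matrix column order
    meta = meta.set_index("sample_id").loc[sample_cols].reset_index()

    bad_geno = sorted(set(meta["genotype"]) - VALID_GENOTYPES)
    if bad_geno:
        raise ValueError(f"invalid genotype values: {bad_geno}")
    bad_fluid = sorted(set(meta["fluid"]) - VALID_FLUIDS)
    if bad_fluid:
        raise ValueError(f"invalid fluid values: {bad_fluid}")

    X = wide[sample_cols].to_numpy(dtype=float).T
    if not np.all(np.isfinite(X)):
        bad = [sample_cols[i] for i in np.unique(np.where(~np.isfinite(X))[0])]
        raise ValueError(f"non-finite intensities in samples: {bad}")
    sm = SpectraMatrix(ppm0, X, meta)
    return sm.with_step("read", files=[str(p) for p in matrix_paths])


def write_spectra(
    matrix: SpectraMatrix,
    matrix_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write matrix CSV + metadata TSV. Floats use 17 significant digits,
    so read ∘ write round-trips float64 exactly."""
    df = pd.DataFrame({"ppm": matrix.ppm})
    for sid, row in zip(matrix.sample_ids, matrix.intensities):
        df[sid] = row
    df.to_csv(matrix_path, index=False, float_format="%.17g")
    matrix.meta.to_csv(metadata_path, sep="\t", index=False)
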