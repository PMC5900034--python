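"""Spectral preprocessing: ppm calibration, region exclusion, PQN, log.

The preprocessing chain for urine/plasma profiling is: calibrate the
ppm axis to a reference resonance (TSP at 0 ppm for urine, the anomeric
α-D-glucose doublet at 5.233 ppm for plasma), remove uninformative
regions (noise flanks and the residual water band), correct per-sample
dilution with probabilistic quotient normalization (PQN), and
log-transform to turn multiplicative noise into additive noise before
pattern recognition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nmrage.containers import Spectrum, SpectraMatrix

# Retained region is the complement of the open excluded intervals, i.e.
# band endpoints themselves are retained. (lo, hi) pairs in ppm;
# None means unbounded.
EXCLUSION_PRESETS: dict[str, list[tuple[float | None, float | None]]] = {
    # noise flanks upfield of 0.8 / downfield of 10, water 4.7-4.9
    "urine": [(None, 0.8), (4.7, 4.9), (10.0, None)],
    # 1D plasma: upfield of 0.2, water 4.2-5.2, downfield of 10
    "plasma_1d": [(None, 0.2), (4.2, 5.2), (10.0, None)],
    # CPMG plasma: upfield of 0.8, water 4.6-5.15, downfield of 10
    "plasma_cpmg": [(None, 0.8), (4.6, 5.15), (10.0, None)],
}

#: calibration presets: (search window, target ppm)
CALIBRATION_PRESETS = {
    "urine": ((-0.2, 0.2), 0.0),       # TSP singlet
    "plasma_1d": ((5.15, 5.30), 5.233),  # anomeric alpha-D-glucose doublet
    "plasma_cpmg": ((5.15, 5.30), 5.233),
}


@dataclass
class NormalizationResult:
    """Outcome of PQN: the normalized matrix, the per-sample dilution
    factors that were divided out, and the reference spectrum used."""

    matrix: SpectraMatrix
    dilution_factors: pd.Series  # indexed by sample_id
    reference: str  # description of the reference definition
    reference_spectrum: np.ndarray


def calibrate_ppm(
    spectrum: Spectrum,
    search_window: tuple[float, float],
    target: float,
    noise_k: float = 5.0,
) -> Spectrum:
    """Shift the ppm axis so the tallest peak in ``search_window`` sits at
    ``target``. Fails if no peak rises ``noise_k`` noise-sd above the
    window median (noise sd estimated as 1.4826·MAD of the spectrum)."""
    lo, hi = sorted(search_window)
    if lo < spectrum.ppm.min() or hi > spectrum.ppm.max():
        raise ValueError(
            f"search window [{lo}, {hi}] outside axis "
            f"[{spectrum.ppm.min():.4g}, {spectrum.ppm.max():.4g}]"
        )
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    window = spectrum.intensity[mask]
    noise_sd = 1.4826 * np.median(np.abs(spectrum.intensity - np.median(spectrum.intensity)))
    height = window.max() - np.median(window)
    if noise_sd > 0 and height < noise_k * noise_sd:
        raise ValueError(
            f"no peak above noise floor in [{lo}, {hi}] "
            f"(height {height:.3g} < {noise_k} x sd {noise_sd:.3g})"
        )
    peak_ppm = spectrum.ppm[mask][np.argmax(window)]
    shift = target - peak_ppm
    out = Spectrum(spectrum.ppm + shift, spectrum.intensity.copy(), dict(spectrum.meta))
    out.meta["calibration_shift_ppm"] = float(shift)
    return out


def calibrate_matrix(
    matrix: SpectraMatrix,
    search_window: tuple[float, float],
    target: float,
    noise_k: float = 5.0,
) -> SpectraMatrix:
    """Calibrate each sample, then linearly re-interpolate onto the shared
    axis (each sample may need a different shift)."""
    ppm = matrix.ppm
    asc = ppm[::-1]
    out = np.empty_like(matrix.intensities)
    shifts = []
    for i, sid in enumerate(matrix.sample_ids):
        spec = Spectrum(ppm.copy(), matrix.intensities[i].copy())
        cal = calibrate_ppm(spec, search_window, target, noise_k=noise_k)
        shifts.append(cal.meta["calibration_shift_ppm"])
        out[i] = np.interp(asc, cal.ppm[::-1], cal.intensity[::-1])[::-1]
    result = SpectraMatrix(ppm.copy(), out, matrix.meta.copy(), list(matrix.log))
    return result.with_step(
        "calibrate", target=target, window=list(search_window),
        shifts_ppm={s: float(v) for s, v in zip(matrix.sample_ids, shifts)},
    )


def _resolve_intervals(preset_or_intervals):
    if isinstance(preset_or_intervals, str):
        try:
            return EXCLUSION_PRESETS[preset_or_intervals], preset_or_intervals
        except KeyError:
            raise ValueError(
                f"unknown preset {preset_or_intervals!r}; "
                f"known: {sorted(EXCLUSION_PRESETS)}"
            ) from None
    return list(preset_or_intervals), "explicit"


def exclude_regions(matrix: SpectraMatrix, preset_or_intervals) -> SpectraMatrix:
    """Drop grid points inside the excluded intervals (open intervals: the
    interval endpoints themselves are retained). Overlapping intervals are
    unioned; an inverted interval is an error. ``preset_or_intervals`` is a
    preset name or an explicit list of ``(lo, hi)`` with None = unbounded."""
    intervals, label = _resolve_intervals(preset_or_intervals)
    keep = np.ones(matrix.n_variables, dtype=bool)
    for lo, hi in intervals:
        lo_v = -np.inf if lo is None else float(lo)
        hi_v = np.inf if hi is None else float(hi)
        if hi_v < lo_v:
            raise ValueError(f"inverted exclusion interval ({lo}, {hi})")
        keep &= ~((matrix.ppm > lo_v) & (matrix.ppm < hi_v))
    if not keep.any():
        raise ValueError("exclusion removed every grid point")
    out = SpectraMatrix(
        matrix.ppm[keep], matrix.intensities[:, keep], matrix.meta.copy(),
        list(matrix.log),
    )
    return out.with_step(
        "exclude", preset=label,
        intervals=[[lo, hi] for lo, hi in intervals],
        n_retained=int(keep.sum()),
    )


def pqn_normalize(
    matrix: SpectraMatrix,
    reference="median",
    floor_fraction: float = 1e-12,
) -> NormalizationResult:
    """Probabilistic quotient normalization.

    For each sample the quotients ``q_v = x_v / ref_v`` are formed over
    variables where the reference exceeds ``floor_fraction`` of its
    maximum; the sample's dilution factor is the median quotient and the
    sample is divided by it. ``reference`` is ``"median"`` (element-wise
    median spectrum of the cohort — the canonical choice), a sample id,
    or an explicit reference vector.
    """
    X = matrix.intensities
    if matrix.n_samples < 2 and not isinstance(reference, np.ndarray):
        raise ValueError("PQN needs at least 2 samples (or an explicit reference)")
    if isinstance(reference, np.ndarray):
        ref = np.asarray(reference, dtype=float)
        ref_desc = "explicit"
        if ref.shape != (matrix.n_variables,):
            raise ValueError("explicit reference length mismatch")
    elif reference == "median":
        ref = np.median(X, axis=0)
        ref_desc = "median_spectrum"
    else:
        if reference not in matrix.sample_ids:
            raise ValueError(f"reference sample {reference!r} not in matrix")
        ref = X[matrix.sample_ids.index(reference)].copy()
        ref_desc = f"sample:{reference}"
    if np.all(ref <= 0):
        raise ValueError("reference spectrum has no positive variables")
    use = ref > floor_fraction * ref.max()
    if not use.any():
        raise ValueError("reference has no variables above the quotient floor")

    factors = np.empty(matrix.n_samples)
    for i, sid in enumerate(matrix.sample_ids):
        if np.all(X[i] == 0):
            raise ValueError(f"sample {sid} is all-zero; cannot normalize")
        factors[i] = np.median(X[i, use] / ref[use])
        if not np.isfinite(factors[i]) or factors[i] <= 0:
            raise ValueError(
                f"sample {sid}: non-positive dilution factor {factors[i]!r}"
            )
    out = SpectraMatrix(
        matrix.ppm.copy(), X / factors[:, None], matrix.meta.copy(),
        list(matrix.log),
    )
    out.with_step("pqn", reference=ref_desc)
    return NormalizationResult(
        matrix=out,
        dilution_factors=pd.Series(factors, index=matrix.sample_ids, name="dilution"),
        reference=ref_desc,
        reference_spectrum=ref,
    )


def log_transform(
    matrix: SpectraMatrix,
    offset: float | str = "auto",
    require_normalized: bool = True,
) -> SpectraMatrix:
    """``y = ln(x + offset)``. ``offset="auto"`` uses the smallest positive
    matrix entry. By default refuses to run before normalization (checked
    via the processing log; pass ``require_normalized=False`` to override)."""
    if require_normalized and not matrix.has_step("pqn"):
        raise ValueError(
            "matrix has not been normalized (no 'pqn' step in the processing "
            "log); normalize first or pass require_normalized=False"
        )
    X = matrix.intensities
    if offset == "auto":
        pos = X[X > 0]
        if pos.size == 0:
            raise ValueError("no positive intensities; cannot choose auto offset")
        offset = float(pos.min())
        if X.min() <= 0:
            # thermal noise leaves small negative baseline values; lift
            # everything safely into the log's domain
            offset += float(-X.min())
    offset = float(offset)
    if offset < 0:
        raise ValueError("offset must be >= 0")
    shifted = X + offset
    if np.any(shifted <= 0):
        bad = np.argwhere(shifted <= 0)
        locs = [
            f"(sample {matrix.sample_ids[i]}, {matrix.ppm[j]:.4f} ppm)"
            for i, j in bad[:5]
        ]
        raise ValueError(
            f"x + offset <= 0 at {len(bad)} locations, e.g. {', '.join(locs)}"
        )
    out = SpectraMatrix(
        matrix.ppm.copy(), np.log(shifted), matrix.meta.copy(), list(matrix.log)
    )
    return out.with_step("log", offset=offset)
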