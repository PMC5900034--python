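"""Univariate biomarker detection: spectral ANOVA, BH-FDR, tiers, tables.

Each retained spectral variable is tested with a one-way ANOVA across
groups (on the log scale, after normalization). Multiple testing is
controlled with the Benjamini–Hochberg step-up procedure at FDR 0.05 or
0.10; variables below the adjusted threshold are *FDR-significant*,
variables with unadjusted p < 0.05 are *potentially* discriminating
(tier "potential"), everything else is "ns". Per-variable results are
collapsed to annotated metabolites via ppm windows, yielding a table of
metabolite, direction of change (↑/↓ on the log-mean difference) and
significance tier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from nmrage.containers import SpectraMatrix

TIER_ORDER = {"FDR_significant": 2, "potential": 1, "ns": 0}


def anova_f_arrays(X: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA per column of ``X``.

    Returns ``(F, p, degenerate)``. Columns with zero within-group
    variance *and* zero between-group difference get ``F = 0, p = 1``
    and are flagged in ``degenerate``; zero within-group variance with a
    real between-group difference gives ``F = inf, p = 0``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    n, k = X.shape[0], classes.size
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c, nc in zip(classes, counts):
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        ssb += nc * (mc - grand) ** 2
        ssw += ((Xc - mc) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    degenerate = (ssw <= 0) & (ssb <= np.finfo(float).eps * np.maximum(grand**2, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F = np.where(degenerate, 0.0, F)
    F = np.where((ssw <= 0) & ~degenerate, np.inf, F)
    p = np.where(
        np.isinf(F), 0.0,
        stats.f.sf(np.where(np.isfinite(F), F, 0.0), k - 1, n - k),
    )
    p = np.where(degenerate, 1.0, p)
    return F, p, degenerate


def anova_f(matrix: SpectraMatrix, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-way ANOVA per spectral variable; see :func:`anova_f_arrays`."""
    return anova_f_arrays(matrix.intensities, labels)


def bh_adjust(p: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up at FDR level ``q``.

    Sort p ascending; find the largest k with ``p(k) <= k·q/m``; every p
    at or below ``p(k)`` is significant. Returns ``(mask, threshold)``
    with threshold 0 when nothing passes.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ok = ps <= (np.arange(1, m + 1) * q / m)
    if not ok.any():
        return np.zeros(m, dtype=bool), 0.0
    threshold = float(ps[np.nonzero(ok)[0].max()])
    return p <= threshold, threshold


def classify_tiers(p: np.ndarray, bh_mask: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Three significance tiers: FDR_significant (in the BH mask),
    potential (unadjusted p < alpha), ns."""
    p = np.asarray(p, dtype=float)
    bh_mask = np.asarray(bh_mask, dtype=bool)
    if p.shape != bh_mask.shape:
        raise ValueError("p and mask must align")
    tiers = np.where(bh_mask, "FDR_significant", np.where(p < alpha, "potential", "ns"))
    return tiers


def significance_profile(
    matrix: SpectraMatrix, labels, p: np.ndarray, order: tuple | None = None
) -> pd.DataFrame:
    """Signed difference profile for a two-group comparison.

    Per variable: ``mean(group A) − mean(group B)`` on the (log) scale
    (so a "week 60 vs 15" profile is positive where week 60 is more
    intense), paired with the per-variable p-value for colour mapping.
    ``order=(A, B)`` fixes which group is subtracted from which; the
    default takes A as the lexicographically larger label.
    """
    y = np.asarray(labels)
    groups = np.unique(y)
    if groups.size != 2:
        raise ValueError(
            f"significance_profile needs exactly 2 groups, got {groups.size}; "
            "run pairwise comparisons instead"
        )
    if order is not None:
        a, b = order
        if {a, b} != set(groups):
            raise ValueError(f"order {order} does not match groups {groups}")
    else:
        a, b = groups[1], groups[0]
    diff = matrix.intensities[y == a].mean(axis=0) - matrix.intensities[y == b].mean(axis=0)
    return pd.DataFrame({
        "ppm": matrix.ppm,
        "difference": diff,
        "p": np.asarray(p, dtype=float),
        "direction": np.where(diff > 0, "up", np.where(diff < 0, "down", "none")),
    })


# -- annotation windows ------------------------------------------------

def load_annotation_windows(path: str | Path | None = None) -> pd.DataFrame:
    """Load a metabolite ppm-window library (TSV columns: metabolite,
    window_start_ppm, window_end_ppm). Default: the shipped urine library."""
    if path is None:
        ref = resources.files("nmrage.data") / "urine_annotation_windows.tsv"
        with resources.as_file(ref) as f:
            df = pd.read_csv(f, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    need = {"metabolite", "window_start_ppm", "window_end_ppm"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return df


@dataclass
class BiomarkerTable:
    """Per-variable and per-metabolite results of one group comparison."""

    comparison: str
    fdr: float
    bh_threshold: float
    per_variable: pd.DataFrame
    per_metabolite: pd.DataFrame


def _select_group(meta: pd.DataFrame, selector: dict) -> np.ndarray:
    mask = np.ones(len(meta), dtype=bool)
    for key, value in selector.items():
        if key not in meta.columns:
            raise ValueError(f"unknown metadata column {key!r}")
        col = meta[key].astype(str)
        mask &= (col == str(value)).to_numpy()
        if not mask.any():
            raise ValueError(
                f"no samples with {key}={value!r}; available {key} values: "
                f"{sorted(meta[key].astype(str).unique())}"
            )
    return mask


def build_biomarker_table(
    matrix: SpectraMatrix,
    comparison: tuple[dict, dict],
    fdr: float = 0.1,
    annotation_windows: pd.DataFrame | None = None,
    label: str | None = None,
    alpha: float = 0.05,
) -> BiomarkerTable:
    """Two-group comparison → ANOVA → BH → tiers → direction → table.

    ``comparison`` is a pair of metadata selectors, e.g.
    ``({"genotype": "WT", "week": "60"}, {"genotype": "WT", "week": "15"})``
    read as "A vs B"; the direction column is the sign of
    ``mean(A) − mean(B)`` per variable. Metabolites are called from their
    annotation windows: tier = best tier among window variables, p_min =
    smallest p, direction = consensus of the per-window calls (each
    window votes with the sign at its minimum-p variable); conflicting
    windows are flagged rather than resolved.
    """
    sel_a, sel_b = comparison
    mask_a = _select_group(matrix.meta, sel_a)
    mask_b = _select_group(matrix.meta, sel_b)
    if (mask_a & mask_b).any():
        raise ValueError("comparison groups overlap")
    sub = matrix.subset(mask_a | mask_b)
    in_a = _select_group(sub.meta, sel_a)
    y = np.where(in_a, "A", "B")

    F, p, degenerate = anova_f_arrays(sub.intensities, y)
    bh_mask, threshold = bh_adjust(p, fdr)
    tiers = classify_tiers(p, bh_mask, alpha=alpha)
    diff = sub.intensities[in_a].mean(axis=0) - sub.intensities[~in_a].mean(axis=0)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))

    per_variable = pd.DataFrame({
        "ppm": sub.ppm,
        "F": F,
        "p": p,
        "fdr_significant": bh_mask,
        "tier": tiers,
        "direction": direction,
        "mean_log_difference": diff,
    }).sort_values("ppm", kind="stable").reset_index(drop=True)

    rows = []
    if annotation_windows is not None and len(annotation_windows):
        for metab, grp in annotation_windows.groupby("metabolite", sort=True):
            win_tiers, win_dirs, win_pmins, windows = [], [], [], []
            for _, w in grp.iterrows():
                lo = min(w.window_start_ppm, w.window_end_ppm)
                hi = max(w.window_start_ppm, w.window_end_ppm)
                in_win = (sub.ppm >= lo) & (sub.ppm <= hi)
                if not in_win.any():
                    warnings.warn(
                        f"annotation window [{lo},{hi}] for {metab} is off-grid; skipped"
                    )
                    continue
                pw = p[in_win]
                win_pmins.append(float(pw.min()))
                win_tiers.append(max(tiers[in_win], key=lambda t: TIER_ORDER[t]))
                # window votes with its aggregate log-difference: more
                # robust than the single min-p variable under residual
                # misalignment
                agg = float(diff[in_win].sum())
                win_dirs.append("up" if agg > 0 else "down" if agg < 0 else "none")
                windows.append(f"{lo:g}:{hi:g}")
            if not windows:
                continue
            dirs = {d for d in win_dirs if d != "none"}
            consensus = dirs.pop() if len(dirs) == 1 else "none"
            rows.append({
                "metabolite": metab,
                "ppm_windows": ",".join(windows),
                "tier": max(win_tiers, key=lambda t: TIER_ORDER[t]),
                "direction": consensus,
                "direction_conflict": len({d for d in win_dirs if d != "none"}) > 1,
                "p_min": min(win_pmins),
                "threshold": threshold,
            })
    per_metabolite = pd.DataFrame(
        rows,
        columns=["metabolite", "ppm_windows", "tier", "direction",
                 "direction_conflict", "p_min", "threshold"],
    )
    if label is None:
        fmt = lambda s: ",".join(f"{k}={v}" for k, v in s.items())
        label = f"{fmt(sel_a)} vs {fmt(sel_b)}"
    return BiomarkerTable(
        comparison=label, fdr=fdr, bh_threshold=threshold,
        per_variable=per_variable, per_metabolite=per_metabolite,
    )
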