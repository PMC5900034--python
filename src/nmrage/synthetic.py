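"""Synthetic 1D ¹H NMR cohort generator with complete ground truth.

Emulates the statistical structure a urine/plasma metabonomics analysis
has to cope with: Lorentzian multiplets of known metabolites, per-sample
dilution (exercises quotient normalization), pH-driven chemical-shift
jitter on specific signals (exercises alignment), multiplicative
intensity noise (exercises the log transform), planted group × time fold
changes (exercises ANOVA/FDR and discriminant analysis), and
exchange-broadened line widths for protein-bound metabolites (exercises
the line-width analysis). Everything that is planted is returned as
:class:`GroundTruth` so recovery can be tested.

Randomness: one seed per cohort; each sample draws from its own
substream keyed by ``(seed, sample_index)``, so appending samples to a
design never perturbs earlier ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from nmrage.containers import SpectraMatrix
from nmrage.templates import MetaboliteTemplate, Multiplet, default_urine_templates


class TruncationWarning(UserWarning):
    """A multiplet's lines extend beyond the simulated grid."""


#: binomial intensity patterns for first-order multiplets
_PATTERNS = {
    "s": ((0.0, 1.0),),
    "d": ((-0.5, 1.0), (0.5, 1.0)),
    "t": ((-1.0, 1.0), (0.0, 2.0), (1.0, 1.0)),
    "q": ((-1.5, 1.0), (-0.5, 3.0), (0.5, 3.0), (1.5, 1.0)),
}


def render_multiplet(
    center: float,
    multiplicity: str,
    J: float,
    fwhm: float,
    integral: float,
    grid: np.ndarray,
    freq: float,
    lines: tuple[tuple[float, float], ...] = (),
) -> np.ndarray:
    """Render one multiplet as a sum of Lorentzians on ``grid``.

    Line positions are ``center ± k·J/freq`` (J in Hz, freq in MHz, so
    J/freq is the splitting in ppm) with binomial intensity ratios
    (s: 1; d: 1,1; t: 1,2,1; q: 1,3,3,1). Multiplicity ``"m"`` uses the
    explicit ``lines`` list of ``(offset_hz, weight)`` pairs. The
    rendered vector integrates to ``integral`` (rectangle rule) when the
    lines sit well inside the grid.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm}")
    if J < 0:
        raise ValueError(f"J must be >= 0, got {J}")
    grid = np.asarray(grid, dtype=float)
    if multiplicity == "m":
        if not lines:
            raise ValueError("multiplicity 'm' requires an explicit line list")
        pattern = tuple((off / freq, w) for off, w in lines)  # offsets in Hz -> ppm
    elif multiplicity in _PATTERNS:
        pattern = tuple((k * J / freq, w) for k, w in _PATTERNS[multiplicity])
    else:
        raise ValueError(f"unknown multiplicity code {multiplicity!r}")

    fwhm_ppm = fwhm / freq
    hw = fwhm_ppm / 2.0
    lo, hi = grid.min(), grid.max()
    total_w = sum(w for _, w in pattern)

    positions = np.array([center + off for off, _ in pattern])
    weights = np.array([w for _, w in pattern]) / total_w
    if np.any(positions - 2 * fwhm_ppm < lo) or np.any(positions + 2 * fwhm_ppm > hi):
        warnings.warn(
            f"multiplet at {center} ppm extends beyond grid "
            f"[{lo:.4g}, {hi:.4g}]; truncated",
            TruncationWarning,
            stacklevel=2,
        )
    # Lorentzian pdf: hw / (pi * ((x-x0)^2 + hw^2)); unit area per line
    diff = grid[None, :] - positions[:, None]
    shapes = hw / (np.pi * (diff * diff + hw * hw))
    return integral * (weights @ shapes)


def broadened_width(free_fwhm: float, bound_fwhm: float, bound_fraction: float) -> float:
    """Observed line width of a ligand in fast exchange with a protein.

    Under fast exchange the observed width is the population-weighted
    average of the free and bound states:
    ``(1 - f)·free_fwhm + f·bound_fwhm``.
    """
    if free_fwhm <= 0 or bound_fwhm <= 0:
        raise ValueError("line widths must be > 0")
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError(f"bound_fraction {bound_fraction} outside [0, 1]")
    return (1.0 - bound_fraction) * free_fwhm + bound_fraction * bound_fwhm


@dataclass(frozen=True)
class GroupSpec:
    """One design cell: genotype × week, with its mice."""

    genotype: str
    week: str
    n_mice: int
    spectra_per_mouse: int = 1
    batch: str = "B1"

    def __post_init__(self):
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.spectra_per_mouse < 1:
            raise ValueError("spectra_per_mouse must be >= 1")


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply a template's concentration by 2**log2fc in matching groups.

    ``selector`` matches a group when every key/value pair equals the
    group's attribute (e.g. ``{"genotype": "WT", "week": "60"}``).
    """

    template: str
    selector: dict
    log2fc: float

    def matches(self, group: GroupSpec) -> bool:
        return all(str(getattr(group, k)) == str(v) for k, v in self.selector.items())


@dataclass
class CohortDesign:
    """Generative parameters of a synthetic cohort.

    ``grid`` is ``(ppm_min, ppm_max, step)``; the axis is stored
    descending. ``dilution_log_range`` bounds a log-uniform per-sample
    dilution multiplier. ``mult_noise_cv`` is the coefficient of
    variation of the lognormal concentration noise; ``add_noise_sd`` the
    thermal-noise standard deviation in intensity units.
    """

    templates: list[MetaboliteTemplate] = field(default_factory=default_urine_templates)
    base_concentrations: dict[str, float] | None = None
    groups: list[GroupSpec] = field(default_factory=lambda: [
        GroupSpec("WT", w, 4) for w in ("15", "30", "45", "60")
    ] + [GroupSpec("KO", w, 4) for w in ("15", "30", "45", "60")])
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    dilution_log_range: tuple[float, float] = (0.5, 2.0)
    mult_noise_cv: float = 0.15
    add_noise_sd: float = 0.2
    grid: tuple[float, float, float] = (0.5, 10.0, 0.00025)
    spectrometer_freq: float = 600.44
    seed: int = 0

    def __post_init__(self):
        lo, hi, step = self.grid
        if step <= 0:
            raise ValueError("grid step must be > 0")
        if hi <= lo:
            raise ValueError("grid must satisfy ppm_max > ppm_min")
        dlo, dhi = self.dilution_log_range
        if dlo <= 0 or dhi <= 0 or dhi < dlo:
            raise ValueError("dilution bounds must be positive with high >= low")
        if self.base_concentrations is None:
            # typical relative urine intensities; absolute units are
            # arbitrary — the pipeline never uses them
            from nmrage.templates import DEFAULT_URINE_CONCENTRATIONS

            self.base_concentrations = {
                t.name: DEFAULT_URINE_CONCENTRATIONS.get(t.name, 100.0)
                for t in self.templates
            }
        unknown = set(self.base_concentrations) - {t.name for t in self.templates}
        if unknown:
            raise ValueError(f"base_concentrations for unknown templates: {sorted(unknown)}")

    def axis(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return (lo + step * np.arange(n))[::-1]


@dataclass
class GroundTruth:
    """What the generator actually planted, one record per spectrum."""

    dilutions: pd.DataFrame  # sample_id, dilution
    shifts: pd.DataFrame  # sample_id, template, shift_ppm
    concentrations: pd.DataFrame  # sample_id, template, concentration
    planted_effects: list[PlantedEffect]


def simulate_cohort(
    design: CohortDesign, ultrafiltered: bool = False
) -> tuple[SpectraMatrix, GroundTruth]:
    """Generate a cohort from ``design``; see the module docstring.

    ``ultrafiltered=True`` simulates protein removal by ultrafiltration:
    every template's bound fraction is forced to 0, so protein-bound
    signals sharpen to their free line width.
    """
    if not design.templates:
        raise ValueError("design has no metabolite templates")
    ppm = design.axis()
    freq = design.spectrometer_freq
    sigma_ln = float(np.sqrt(np.log(1.0 + design.mult_noise_cv**2)))
    log_dlo, log_dhi = np.log(design.dilution_log_range)

    rows, meta_rows = [], []
    dil_rec, shift_rec, conc_rec = [], [], []
    sample_index = 0
    for group in design.groups:
        fold = {t.name: 1.0 for t in design.templates}
        for eff in design.planted_effects:
            if eff.matches(group):
                fold[eff.template] *= 2.0 ** eff.log2fc
        for mouse in range(1, group.n_mice + 1):
            # batch in the id keeps mice distinct across replicate cohorts
            mouse_id = f"{group.genotype}{group.week}{group.batch}_m{mouse:02d}"
            for rep in range(1, group.spectra_per_mouse + 1):
                sid = f"{mouse_id}_r{rep}"
                rng = np.random.default_rng([design.seed, sample_index])
                spectrum = np.zeros_like(ppm)
                for t in design.templates:
                    base = design.base_concentrations[t.name]
                    if sigma_ln > 0:
                        noise = float(np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln)))
                    else:
                        noise = 1.0
                    conc = base * fold[t.name] * noise
                    jitter = (
                        float(rng.normal(0.0, t.shift_jitter_sd))
                        if t.shift_jitter_sd > 0 else 0.0
                    )
                    f_bound = 0.0 if ultrafiltered else t.bound_fraction
                    for m in t.multiplets:
                        width = broadened_width(m.fwhm, t.bound_fwhm, f_bound) \
                            if f_bound > 0 else m.fwhm
                        spectrum += render_multiplet(
                            m.center + jitter, m.multiplicity, m.J, width,
                            conc * m.relative_integral, ppm, freq, lines=m.lines,
                        )
                    shift_rec.append((sid, t.name, jitter))
                    conc_rec.append((sid, t.name, conc))
                dilution = float(np.exp(rng.uniform(log_dlo, log_dhi)))
                spectrum *= dilution
                if design.add_noise_sd > 0:
                    spectrum = spectrum + rng.normal(0.0, design.add_noise_sd, ppm.size)
                rows.append(spectrum)
                meta_rows.append({
                    "sample_id": sid, "mouse_id": mouse_id,
                    "genotype": group.genotype, "week": str(group.week),
                    "fluid": "urine", "batch": group.batch,
                })
                dil_rec.append((sid, dilution))
                sample_index += 1

    matrix = SpectraMatrix(ppm, np.vstack(rows), pd.DataFrame(meta_rows))
    matrix.with_step(
        "simulate", seed=design.seed, n_samples=sample_index,
        ultrafiltered=ultrafiltered,
    )
    truth = GroundTruth(
        dilutions=pd.DataFrame(dil_rec, columns=["sample_id", "dilution"]),
        shifts=pd.DataFrame(shift_rec, columns=["sample_id", "template", "shift_ppm"]),
        concentrations=pd.DataFrame(conc_rec, columns=["sample_id", "template", "concentration"]),
        planted_effects=list(design.planted_effects),
    )
    return matrix, truth


# -- design (de)serialization -----------------------------------------

def design_to_yaml(design: CohortDesign, path) -> None:
    doc = {
        "templates": [
            {
                "name": t.name,
                "shift_jitter_sd": t.shift_jitter_sd,
                "bound_fraction": t.bound_fraction,
                "bound_fwhm": t.bound_fwhm,
                "multiplets": [
                    {
                        "center": m.center, "multiplicity": m.multiplicity,
                        "J": m.J, "relative_integral": m.relative_integral,
                        "fwhm": m.fwhm, "lines": [list(l) for l in m.lines],
                    }
                    for m in t.multiplets
                ],
            }
            for t in design.templates
        ],
        "base_concentrations": design.base_concentrations,
        "groups": [asdict(g) for g in design.groups],
        "planted_effects": [asdict(e) for e in design.planted_effects],
        "dilution_log_range": list(design.dilution_log_range),
        "mult_noise_cv": design.mult_noise_cv,
        "add_noise_sd": design.add_noise_sd,
        "grid": list(design.grid),
        "spectrometer_freq": design.spectrometer_freq,
        "seed": design.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def design_from_yaml(path) -> CohortDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    templates = [
        MetaboliteTemplate(
            name=td["name"],
            multiplets=tuple(
                Multiplet(
                    center=md["center"], multiplicity=md["multiplicity"],
                    J=md.get("J", 0.0),
                    relative_integral=md.get("relative_integral", 1.0),
                    fwhm=md.get("fwhm", 1.0),
                    lines=tuple(tuple(l) for l in md.get("lines", [])),
                )
                for md in td["multiplets"]
            ),
            shift_jitter_sd=td.get("shift_jitter_sd", 0.0),
            bound_fraction=td.get("bound_fraction", 0.0),
            bound_fwhm=td.get("bound_fwhm", 5.0),
        )
        for td in doc["templates"]
    ]
    return CohortDesign(
        templates=templates,
        base_concentrations=doc.get("base_concentrations"),
        groups=[GroupSpec(**g) for g in doc["groups"]],
        planted_effects=[PlantedEffect(**e) for e in doc.get("planted_effects", [])],
        dilution_log_range=tuple(doc.get("dilution_log_range", (0.5, 2.0))),
        mult_noise_cv=doc.get("mult_noise_cv", 0.15),
        add_noise_sd=doc.get("add_noise_sd", 0.2),
        grid=tuple(doc.get("grid", (0.5, 10.0, 0.00025))),
        spectrometer_freq=doc.get("spectrometer_freq", 600.44),
        seed=doc.get("seed", 0),
    )
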