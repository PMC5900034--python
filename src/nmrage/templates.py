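"""Metabolite signal templates for the synthetic cohort generator.

A :class:`MetaboliteTemplate` describes where a metabolite resonates
(one or more multiplets), how much its chemical shift wanders with pH /
ionic strength, and how strongly it binds the major urinary proteins
(MUPs) — binding in fast exchange broadens its lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Multiplet:
    """One multiplet: center (ppm), multiplicity code, J coupling (Hz),
    fraction of the template's total integral, and free-solution FWHM (Hz).

    ``lines`` is only used for multiplicity ``"m"``: an explicit list of
    ``(offset_hz, weight)`` pairs relative to the center.
    """

    center: float
    multiplicity: str
    J: float = 0.0
    relative_integral: float = 1.0
    fwhm: float = 1.0
    lines: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.J < 0:
            raise ValueError(f"J must be >= 0, got {self.J}")


@dataclass(frozen=True)
class MetaboliteTemplate:
    name: str
    multiplets: tuple[Multiplet, ...]
    shift_jitter_sd: float = 0.0  # ppm; pH-driven positional wander
    bound_fraction: float = 0.0  # fraction bound to MUPs (fast exchange)
    bound_fwhm: float = 5.0  # Hz; line width of the fully bound state

    def __post_init__(self):
        if not self.multiplets:
            raise ValueError(f"{self.name}: template needs at least one multiplet")
        total = sum(m.relative_integral for m in self.multiplets)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: relative integrals sum to {total}, expected 1"
            )
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError(
                f"{self.name}: bound_fraction {self.bound_fraction} outside [0, 1]"
            )


def default_urine_templates() -> list[MetaboliteTemplate]:
    """Small library of urine metabolites covering the pipeline's stress
    cases: pH-sensitive multiplets (citrate, taurine), MUP-bound pheromone
    signals (6H6MH3O), sharp reference/abundant singlets, and aromatic
    signals. Shifts and multiplicities follow standard urine assignments.
    """
    t = []
    t.append(MetaboliteTemplate(
        "hexanoylglycine",
        (Multiplet(0.88, "t", J=7.4, relative_integral=1.0, fwhm=1.2),)))
    t.append(MetaboliteTemplate(
        "isovalerate",
        (Multiplet(0.92, "d", J=6.6, relative_integral=1.0, fwhm=1.2),)))
    t.append(MetaboliteTemplate(
        "3-methyl-2-oxovalerate",
        (Multiplet(1.10, "d", J=6.6, relative_integral=1.0, fwhm=1.2),)))
    t.append(MetaboliteTemplate(
        "6H6MH3O",
        (
            Multiplet(1.017, "t", J=7.3, relative_integral=0.3, fwhm=1.0),
            Multiplet(1.209, "s", relative_integral=0.5, fwhm=1.0),
            Multiplet(1.74, "m", relative_integral=0.2, fwhm=1.4,
                      lines=((-4.0, 1.0), (0.0, 2.0), (4.0, 1.0))),
        ),
        bound_fraction=0.5,  # pheromone in fast exchange with MUPs
        bound_fwhm=2.52,
    ))
    t.append(MetaboliteTemplate(
        "fucose", (Multiplet(1.25, "d", J=6.5, fwhm=1.2),)))
    t.append(MetaboliteTemplate(
        "lactate", (Multiplet(1.34, "d", J=7.0, fwhm=1.1),)))
    t.append(MetaboliteTemplate(
        "alanine", (Multiplet(1.48, "d", J=7.2, fwhm=1.1),)))
    t.append(MetaboliteTemplate(
        "putrescine",
        (Multiplet(1.78, "m", fwhm=1.6,
                   lines=((-4.5, 1.0), (0.0, 2.0), (4.5, 1.0))),)))
    t.append(MetaboliteTemplate(
        "acetate", (Multiplet(1.92, "s", fwhm=1.0),)))
    t.append(MetaboliteTemplate(
        "U4", (Multiplet(2.064, "s", fwhm=1.2),)))
    t.append(MetaboliteTemplate(
        "U5", (Multiplet(2.182, "s", fwhm=1.2),)))
    t.append(MetaboliteTemplate(
        "ureidopropionate",
        (
            Multiplet(2.38, "t", J=6.7, relative_integral=0.5, fwhm=1.2),
            Multiplet(3.31, "t", J=6.7, relative_integral=0.5, fwhm=1.2),
        )))
    t.append(MetaboliteTemplate(
        "succinate", (Multiplet(2.41, "s", fwhm=1.1),)))
    t.append(MetaboliteTemplate(
        "2-oxoglutarate",
        (
            Multiplet(2.45, "t", J=6.9, relative_integral=0.5, fwhm=1.2),
            Multiplet(3.01, "t", J=6.9, relative_integral=0.5, fwhm=1.2),
        ),
        shift_jitter_sd=0.002,
    ))
    t.append(MetaboliteTemplate(
        "citrate",
        (
            Multiplet(2.56, "d", J=15.1, relative_integral=0.5, fwhm=1.3),
            Multiplet(2.70, "d", J=15.1, relative_integral=0.5, fwhm=1.3),
        ),
        shift_jitter_sd=0.01,  # strongly pH-dependent
    ))
    t.append(MetaboliteTemplate(
        "dimethylamine", (Multiplet(2.73, "s", fwhm=1.0),)))
    t.append(MetaboliteTemplate(
        "trimethylamine", (Multiplet(2.884, "s", fwhm=0.73),)))
    t.append(MetaboliteTemplate(
        "creatinine",
        (
            Multiplet(3.04, "s", relative_integral=0.6, fwhm=1.1),
            Multiplet(4.05, "s", relative_integral=0.4, fwhm=1.1),
        )))
    t.append(MetaboliteTemplate(
        "taurine",
        (
            Multiplet(3.27, "t", J=6.6, relative_integral=0.5, fwhm=0.73),
            Multiplet(3.433, "t", J=6.6, relative_integral=0.5, fwhm=0.73),
        ),
        shift_jitter_sd=0.008,  # pH/ionic-strength sensitive
    ))
    t.append(MetaboliteTemplate(
        "glycine", (Multiplet(3.56, "s", fwhm=1.0),)))
    t.append(MetaboliteTemplate(
        "glucose", (Multiplet(4.66, "d", J=7.9, fwhm=1.3),),
        shift_jitter_sd=0.001))
    t.append(MetaboliteTemplate(
        "allantoin", (Multiplet(5.40, "s", fwhm=1.4),)))
    t.append(MetaboliteTemplate(
        "hippurate",
        (
            Multiplet(7.56, "t", J=7.7, relative_integral=0.4, fwhm=1.4),
            Multiplet(7.84, "d", J=7.7, relative_integral=0.6, fwhm=1.4),
        )))
    return t


#: typical relative signal intensities in mouse urine (arbitrary units;
#: creatinine, citrate and taurine dominate the aliphatic region)
DEFAULT_URINE_CONCENTRATIONS: dict[str, float] = {
    "hexanoylglycine": 40.0,
    "isovalerate": 40.0,
    "3-methyl-2-oxovalerate": 40.0,
    "6H6MH3O": 120.0,
    "fucose": 40.0,
    "lactate": 60.0,
    "alanine": 80.0,
    "putrescine": 40.0,
    "acetate": 50.0,
    "U4": 30.0,
    "U5": 30.0,
    "ureidopropionate": 50.0,
    "succinate": 60.0,
    "2-oxoglutarate": 150.0,
    "citrate": 300.0,
    "dimethylamine": 40.0,
    "trimethylamine": 30.0,
    "creatinine": 400.0,
    "taurine": 250.0,
    "glycine": 100.0,
    "glucose": 80.0,
    "allantoin": 80.0,
    "hippurate": 150.0,
}


def tsp_template(center: float = 0.0) -> MetaboliteTemplate:
    """TSP chemical-shift reference singlet (nominally 0 ppm). Not part of
    the default library because the default grid starts at 0.5 ppm; add it
    together with a grid extending below 0 when testing calibration."""
    return MetaboliteTemplate("TSP", (Multiplet(center, "s", fwhm=1.0),))


def templates_by_name(templates) -> dict[str, MetaboliteTemplate]:
    return {t.name: t for t in templates}


def templates_within(templates, ppm_min: float, ppm_max: float,
                     margin: float = 0.05) -> list[MetaboliteTemplate]:
    """Subset of templates whose every multiplet sits inside
    ``[ppm_min + margin, ppm_max - margin]`` — handy when simulating on a
    reduced grid."""
    lo, hi = ppm_min + margin, ppm_max - margin
    return [
        t for t in templates
        if all(lo <= m.center <= hi for m in t.multiplets)
    ]
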