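"""Plate-reader quantification: standard curves, per-animal amounts,
glycogen by the glucose-oxidase difference method, and citrate synthase
activity from the DTNB absorbance slope.

Each biochemical assay reads a 96-well plate: a standard dilution series
plus blank fixes a linear calibration ``reading = a * concentration + b``,
and sample wells are inverted through it. Amounts are normalized to the
number of animals homogenized per sample, so panels hold amount-per-animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AssaySpec",
    "Calibration",
    "CSAssayParams",
    "MetaboliteMeasurement",
    "fit_standard_curve",
    "quantify",
    "glycogen_from_go",
    "citrate_synthase_activity",
]


@dataclass(frozen=True)
class AssaySpec:
    """Parameters of one assay run.

    dilution
        fold dilution of the homogenate aliquot before reading (>= 1);
        e.g. glycogen: larvae 1:2, males 1:3, females 1:6 basal / 1:10
        diet-switch; lactate: larvae 1:15, adults 1:10.
    n_animals
        animals homogenized per sample (5 larvae or 8 adults).
    sample_volume
        homogenization volume in the concentration unit's volume basis;
        amount per animal = concentration * sample_volume / n_animals.
    """

    name: str
    dilution: float = 1.0
    n_animals: int = 1
    sample_volume: float = 1.0
    read_mode: str = "absorbance"  # or "fluorescence"

    def __post_init__(self):
        if self.dilution < 1:
            raise ValueError(f"dilution must be >= 1, got {self.dilution}")
        if self.n_animals <= 0:
            raise ValueError(f"n_animals must be > 0, got {self.n_animals}")
        if self.sample_volume <= 0:
            raise ValueError("sample_volume must be > 0")
        if self.read_mode not in {"absorbance", "fluorescence"}:
            raise ValueError(f"unknown read mode {self.read_mode!r}")


@dataclass(frozen=True)
class Calibration:
    slope: float
    intercept: float
    r_squared: float
    n_standards: int

    def concentration(self, reading: float) -> float:
        return (reading - self.intercept) / self.slope


@dataclass(frozen=True)
class CSAssayParams:
    """Citrate synthase activity assay constants.

    Defaults follow the DTNB protocol: 0.22 mL total reaction volume,
    0.02 mL enzyme (sample) volume, ~0.63 cm light path in a 96-well
    plate, and the TNB^2- attenuation coefficient 13.6 mM^-1 cm^-1.
    """

    dA412_per_min: float = 0.0
    V_reaction: float = 0.22   # mL
    V_enz: float = 0.02        # mL
    dil: float = 1.0
    epsilon: float = 13.6      # mM^-1 cm^-1
    L: float = 0.63            # cm

    def __post_init__(self):
        if self.epsilon <= 0 or self.L <= 0 or self.V_enz <= 0:
            raise ValueError("epsilon, L and V_enz must be positive")


@dataclass(frozen=True)
class MetaboliteMeasurement:
    sample_id: str
    metabolite: str
    amount_per_animal: float | None  # None when below detection
    below_detection: bool = False
    flags: tuple[str, ...] = field(default=())


def fit_standard_curve(standards) -> Calibration:
    """Least-squares linear fit of reading on standard concentration.

    ``standards`` is an iterable of (concentration, reading) pairs; at
    least two distinct concentrations (a blank counts) are required. The
    intercept is fitted, not forced through zero — the blank reading and
    plate background are absorbed by it.
    """
    pts = [(float(c), float(r)) for c, r in standards]
    if len(pts) < 2:
        raise ValueError("need >= 2 standard points")
    conc = np.array([c for c, _ in pts])
    read = np.array([r for _, r in pts])
    if len(np.unique(conc)) < 2:
        raise ValueError("degenerate design: all standard concentrations equal")
    fit = stats.linregress(conc, read)
    return Calibration(slope=float(fit.slope), intercept=float(fit.intercept),
                       r_squared=float(fit.rvalue) ** 2, n_standards=len(pts))


def quantify(reading: float, cal: Calibration, spec: AssaySpec,
             sample_id: str = "", metabolite: str = "",
             blank_tolerance: float = 0.0) -> MetaboliteMeasurement:
    """Invert a sample reading through the calibration.

    concentration = (reading - intercept) / slope * dilution;
    amount per animal = concentration * sample_volume / n_animals.
    Readings at or below the blank (beyond ``blank_tolerance`` in
    concentration units) yield a below-detection measurement rather than a
    negative amount.
    """
    if cal.slope == 0:
        raise ValueError("calibration slope is zero")
    metabolite = metabolite or spec.name
    conc = cal.concentration(float(reading)) * spec.dilution
    if conc < -abs(blank_tolerance):
        return MetaboliteMeasurement(sample_id, metabolite, None,
                                     below_detection=True)
    conc = max(conc, 0.0)
    amount = conc * spec.sample_volume / spec.n_animals
    return MetaboliteMeasurement(sample_id, metabolite, amount)


def glycogen_from_go(total_glucose_reading: float, free_glucose_reading: float,
                     cal: Calibration, spec: AssaySpec,
                     sample_id: str = "") -> MetaboliteMeasurement:
    """Glycogen from the glucose-oxidase assay: amyloglucosidase-digested
    total glucose minus free glucose, floored at zero.

    A negative difference (free > total, a measurement artifact) is
    reported as 0 with a ``negative_difference`` flag.
    """
    total = quantify(total_glucose_reading, cal, spec, sample_id, "glycogen")
    free = quantify(free_glucose_reading, cal, spec, sample_id, "glycogen")
    if total.below_detection or free.below_detection:
        return MetaboliteMeasurement(sample_id, "glycogen", None,
                                     below_detection=True)
    diff = total.amount_per_animal - free.amount_per_animal
    if diff < 0:
        return MetaboliteMeasurement(sample_id, "glycogen", 0.0,
                                     flags=("negative_difference",))
    return MetaboliteMeasurement(sample_id, "glycogen", diff)


def citrate_synthase_activity(p: CSAssayParams) -> float:
    """Citrate synthase activity in U/mL from the DTNB reduction slope:

        activity = (dA412/min * V_reaction * dil) / (epsilon * L * V_enz)
    """
    return (p.dA412_per_min * p.V_reaction * p.dil) / (p.epsilon * p.L * p.V_enz)
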