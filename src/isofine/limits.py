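"""Resolution-limit models.

Two instrument-independent ceilings on isotopic resolution:

* **Fine-structure overlap** — the variance of the most abundant aggregated
  variant grows linearly with mass; once its standard deviation reaches
  ~0.5 Da, neighbouring 1-Da-spaced variants blur together.  Pinned linear
  models for proteins (an OLS fit over ~58,000 UniProt entries), DNA, and
  intact virus particles predict where that happens.

* **Thermorelativistic mass uncertainty** — an isolated ion's internal
  energy fluctuates with sigma_E = sqrt(k_B T^2 C); through E = m c^2 this
  is a mass blur Delta_m = sigma_E / c^2 that no instrument can resolve away
  and that grows with the square root of the ion's size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import ChemicalFormula
from .constants import ATOMIC_MASS_KG, C_LIGHT, K_B
from .errors import DomainError
from .isotopes import DEFAULT_TABLE, IsotopeTable


@dataclass(frozen=True)
class LinearVarianceModel:
    """Var(m_a) = intercept + slope * m_a for the most abundant variant."""

    intercept: float  # Da^2
    slope: float  # Da^2 per Da
    label: str = "custom"

    def predict_variance(self, mass: float) -> float:
        if mass <= 0:
            raise DomainError("mass must be positive")
        v = self.intercept + self.slope * mass
        if v <= 0:
            raise DomainError(f"model {self.label!r} predicts non-positive variance")
        return v


#: Protein model: most-abundant-variant variance vs center mass,
#: fitted on ~58,000 UniProt proteins (pinned coefficients).
PROTEIN_MODEL = LinearVarianceModel(1.503e-6, 3.077e-9, "protein")
#: Pure scaling for large DNA (variance per Da of molecular weight).
DNA_MODEL = LinearVarianceModel(0.0, 1.68e-9, "DNA")
#: Intact virus particles: average of the protein and DNA scalings.
VIRUS_MODEL = LinearVarianceModel(0.0, 2.4e-9, "virus")

MODELS = {"protein": PROTEIN_MODEL, "dna": DNA_MODEL, "virus": VIRUS_MODEL}


@dataclass(frozen=True)
class ThermoConfig:
    """Temperature and heat-capacity model for the thermorelativistic blur.

    The ion's heat capacity is C = dof_per_atom * N_atoms * k_B; the default
    3/2 is the equipartition value per classical degree of freedom triple.
    """

    temperature: float = 300.0  # K
    dof_per_atom: float = 1.5
    k_b: float = K_B
    c_light: float = C_LIGHT
    u_kg: float = ATOMIC_MASS_KG

    def __post_init__(self):
        if self.temperature < 0:
            raise DomainError("temperature must be >= 0")
        if self.dof_per_atom <= 0:
            raise DomainError("dof_per_atom must be > 0")


def predict_sigma(model: LinearVarianceModel, mass: float) -> float:
    """Fine-structure standard deviation (Da) of the most abundant variant
    predicted by a linear variance model at the given mass."""
    return math.sqrt(model.predict_variance(mass))


def overlap_onset_mass(model: LinearVarianceModel, sigma_threshold: float = 0.5) -> float:
    """Mass (Da) at which the predicted sigma reaches *sigma_threshold*.

    Solves intercept + slope * m = sigma_threshold**2; at the default 0.5 Da
    threshold the fine structures of consecutive aggregated variants begin
    to overlap.
    """
    if sigma_threshold <= 0:
        raise DomainError("sigma_threshold must be positive")
    if model.slope <= 0:
        raise DomainError("onset undefined for non-positive slope")
    target = sigma_threshold**2
    if target <= model.intercept:
        raise DomainError(
            f"threshold^2 = {target!r} does not exceed the intercept; no onset"
        )
    return (target - model.intercept) / model.slope


def fit_variance_model(
    points: list[tuple[float, float]], label: str = "custom"
) -> LinearVarianceModel:
    """Ordinary least squares fit of variance against mass."""
    if len(points) < 2:
        raise DomainError("need at least two (mass, variance) points")
    masses = np.array([p[0] for p in points], dtype=float)
    variances = np.array([p[1] for p in points], dtype=float)
    if np.ptp(masses) == 0:
        raise DomainError("degenerate design: all masses equal")
    design = np.column_stack([np.ones_like(masses), masses])
    (intercept, slope), *_ = np.linalg.lstsq(design, variances, rcond=None)
    return LinearVarianceModel(float(intercept), float(slope), label)


def thermorelativistic_dm(
    formula: ChemicalFormula, config: ThermoConfig = ThermoConfig()
) -> tuple[float, float]:
    """Thermorelativistic mass uncertainty of one ion, returned as (Da, kg).

    sigma_E = sqrt(k_B T^2 C) with C = dof_per_atom * N_atoms * k_B;
    Delta_m = sigma_E / c^2.  Fine-structure components closer than Delta_m
    cannot be resolved however good the analyser; the blur falls only with
    ion temperature.
    """
    heat_capacity = config.dof_per_atom * formula.n_atoms * config.k_b
    sigma_e = math.sqrt(config.k_b * config.temperature**2 * heat_capacity)
    dm_kg = sigma_e / config.c_light**2
    return dm_kg / config.u_kg, dm_kg


@dataclass(frozen=True)
class ResolvabilityReport:
    """Fine-structure resolvability summary for the most abundant variant."""

    formula: str
    j: int
    q_j: float
    sigma: float  # Da
    spread_max: float  # Da
    n_fine_peaks: int
    spacing_spread: float  # Da per peak
    spacing_k_sigma: float  # Da per peak
    k: float
    dm_thermo_da: float
    dm_thermo_kg: float
    spacing_to_dm: float  # spacing_spread / Delta_m


def resolvability_report(
    formula: ChemicalFormula,
    table: IsotopeTable = DEFAULT_TABLE,
    config: ThermoConfig = ThermoConfig(),
    k: float = 4.0,
    j: int | None = None,
) -> ResolvabilityReport:
    """Bundle sigma, spread, peak count, spacings and the thermorelativistic
    blur for one aggregated variant (default: the most abundant) of *formula*.

    A ratio spacing/Delta_m well below 1 means most fine peaks sit closer
    together than the thermorelativistic blur and are unresolvable even at
    infinite instrument resolution.
    """
    from .finestructure import count_fine_peaks, max_spread
    from .moments import aggregated_distribution

    agg = aggregated_distribution(formula, table)
    if j is None:
        j = agg.most_abundant()
    sigma = agg.sigma(j)
    spread = max_spread(formula, j, table, mode="universal")
    n = count_fine_peaks(formula, j, table)
    if n < 2:
        raise DomainError(f"variant j={j} has fewer than 2 fine peaks")
    dm_da, dm_kg = thermorelativistic_dm(formula, config)
    spacing = spread / n
    return ResolvabilityReport(
        formula=str(formula),
        j=j,
        q_j=float(agg.q[agg._loc(j)]),
        sigma=sigma,
        spread_max=spread,
        n_fine_peaks=n,
        spacing_spread=spacing,
        spacing_k_sigma=k * sigma / n,
        k=k,
        dm_thermo_da=dm_da,
        dm_thermo_kg=dm_kg,
        spacing_to_dm=spacing / dm_da if dm_da > 0 else float("inf"),
    )
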