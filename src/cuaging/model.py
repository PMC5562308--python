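"""Closed-form evaluation of the erfc aging model for Cu added to soils.

The model predicts the isotopically exchangeable fraction of freshly added
water-soluble Cu (``E_add``) as a function of incubation time, soil pH,
soil organic carbon and temperature.  Lability is lost through three
channels:

* **precipitation/nucleation** (``Y1``) — a fast, pH-controlled process tied
  to the fraction of Cu present as CuOH+;
* **occlusion** (``Y2``) — entrapment of Cu within soil organic matter,
  proportional to organic carbon content;
* **micropore/mesopore diffusion** (``Y3``) — a slow process described by
  the plane-sheet/limited-volume diffusion solution, whose survival factor
  is ``exp(x)·erfc(√x)`` with an Arrhenius-scaled argument
  ``x = N·exp(K/T)·t``.

The prediction is ``E_add = exp(x)·erfc(√x) · (1 − Y1 − Y2)`` with the
bracket clamped to ``[0, 1]`` (and flagged) when the two fast channels
overshoot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfcx

__all__ = [
    "SoilSample",
    "ModelParams",
    "AgingComponents",
    "DAYS_PER_YEAR",
    "GAS_CONSTANT",
    "arrhenius_k",
    "hydroxide_fraction",
    "kinetic_factor",
    "precipitation_fraction",
    "occlusion_fraction",
    "diffusion_survival",
    "predict_e_add",
    "predict_components",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.0
#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


def arrhenius_k(ea_j_per_mol: float) -> float:
    """Arrhenius composite K = -Ea/R (kelvin) for an activation energy in J/mol."""
    return -ea_j_per_mol / GAS_CONSTANT


@dataclass(frozen=True)
class SoilSample:
    """One soil x treatment condition: the model's covariates.

    Parameters
    ----------
    sample_id : str
        Free-text identifier.
    ph : float
        Soil pH measured in 0.01 M CaCl2.
    corg : float
        Total organic carbon content, % w/w.
    temperature : float
        Aging temperature in kelvin; for outdoor incubations the arithmetic
        mean temperature of the aging period.
    time : float
        Days since Cu addition.
    """

    sample_id: str
    ph: float
    corg: float
    temperature: float
    time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"ph must be in [0, 14], got {self.ph}")
        if self.corg < 0.0:
            raise ValueError(f"corg must be >= 0, got {self.corg}")
        if self.temperature <= 0.0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.time < 0.0:
            raise ValueError(f"time must be >= 0 days, got {self.time}")

    @classmethod
    def from_years(
        cls, sample_id: str, ph: float, corg: float, temperature: float, years: float
    ) -> "SoilSample":
        """Build a sample with aging time given in years (365 d/y)."""
        return cls(sample_id, ph, corg, temperature, years * DAYS_PER_YEAR)


@dataclass(frozen=True)
class ModelParams:
    """The seven constants of the aging model.

    Defaults are the published long-term fit: B=1.14, C=0, N=214.91,
    F=2.85, G=0, with K=-4330 K (activation energy 36 kJ/mol) and the first
    hydrolysis constant of Cu pK0=7.7 fixed from bulk-solution chemistry.

    Attributes
    ----------
    b : float
        Precipitation/nucleation coefficient (dimensionless, >= 0).
    c : float
        Fast-process kinetics scale in the factor t**(c/t) (days, >= 0).
    n : float
        Diffusion pre-factor N = D0/(alpha^2 l^2) (per day, >= 0).
    f : float
        Occlusion coefficient (dimensionless, >= 0).
    g : float
        Occlusion kinetics scale in t**(g/t) (days, >= 0).
    k : float
        Arrhenius composite K = -Ea/R (kelvin, <= 0).
    pk0 : float
        First hydrolysis constant of Cu (dimensionless).
    """

    b: float = 1.14
    c: float = 0.0
    n: float = 214.91
    f: float = 2.85
    g: float = 0.0
    k: float = -4330.0
    pk0: float = 7.7

    def __post_init__(self) -> None:
        for name in ("b", "c", "n", "f", "g"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k > 0.0:
            raise ValueError(f"k = -Ea/R must be <= 0, got {self.k}")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AgingComponents:
    """Decomposition of one E_add prediction into its loss channels.

    ``diffusion_survival`` is the factor ``exp(x)·erfc(√x)``, i.e. the
    complement of the diffusion loss Y3 relative to what survives the fast
    processes: ``Y3 = (1 − y1 − y2)(1 − diffusion_survival)``.  ``clamped``
    is set when the raw bracket ``1 − y1 − y2`` was negative and the output
    was clamped to zero.
    """

    y1: float
    y2: float
    diffusion_survival: float
    e_add: float
    clamped: bool

    @property
    def y3(self) -> float:
        """Diffusion loss fraction, per the additive decomposition."""
        bracket = max(0.0, 1.0 - self.y1 - self.y2)
        return bracket * (1.0 - self.diffusion_survival)


def hydroxide_fraction(ph, pk0):
    """Fraction of dissolved Cu present as CuOH+, ``1 / (10**(pk0 - ph) + 1)``.

    Strictly increasing in pH; equals 0.5 at ph == pk0.  Accepts scalars or
    arrays.
    """
    return 1.0 / (np.power(10.0, np.asarray(pk0) - np.asarray(ph)) + 1.0)


def kinetic_factor(time, scale):
    """The fast-process kinetic factor ``t**(scale/t)``.

    For ``scale == 0`` the factor is identically 1 (including at t = 0).
    For ``scale > 0`` the t -> 0+ limit is 0, which is returned at t == 0.
    """
    t = np.asarray(time, dtype=float)
    s = np.asarray(scale, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(np.where(t > 0, s / np.where(t > 0, t, 1.0) * np.log(np.where(t > 0, t, 1.0)), 0.0))
    out = np.where((t == 0) & (s > 0), 0.0, out)
    out = np.where(s == 0, 1.0, out)
    if np.isscalar(time) and np.isscalar(scale):
        return float(out)
    return out


def precipitation_fraction(sample: SoilSample, params: ModelParams) -> float:
    """Fast lability loss Y1 = B * CuOH+ fraction * t**(C/t)."""
    return float(
        params.b
        * hydroxide_fraction(sample.ph, params.pk0)
        * kinetic_factor(sample.time, params.c)
    )


def occlusion_fraction(sample: SoilSample, params: ModelParams) -> float:
    """Occlusion loss Y2 = F * (Corg/100) * t**(G/t); linear in organic carbon."""
    return float(params.f * (sample.corg / 100.0) * kinetic_factor(sample.time, params.g))


def diffusion_survival(sample: SoilSample, params: ModelParams) -> float:
    """Diffusion survival S(x) = exp(x)·erfc(√x), x = N·exp(K/T)·t.

    Computed through the exponentially scaled complementary error function
    (``erfcx(√x)``), so it neither overflows nor loses precision for large
    x; S(0) = 1 and S is strictly decreasing in x.
    """
    x = params.n * math.exp(params.k / sample.temperature) * sample.time
    return float(erfcx(math.sqrt(x)))


def _predict_arrays(ph, corg, temperature, time, params: ModelParams):
    """Vectorized prediction; returns (y1, y2, survival, e_add, clamped).

    This is the hot path used by the fitting objective.
    """
    ph = np.asarray(ph, dtype=float)
    corg = np.asarray(corg, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    time = np.asarray(time, dtype=float)

    y1 = params.b * hydroxide_fraction(ph, params.pk0) * kinetic_factor(time, params.c)
    y2 = params.f * (corg / 100.0) * kinetic_factor(time, params.g)
    x = params.n * np.exp(params.k / temperature) * time
    survival = erfcx(np.sqrt(x))

    bracket = 1.0 - y1 - y2
    clamped = bracket < 0.0
    e_add = survival * np.clip(bracket, 0.0, 1.0)
    # nothing has aged at t = 0: fast-process kinetics are undefined there
    at_zero = time == 0.0
    y1 = np.where(at_zero, 0.0, y1)
    y2 = np.where(at_zero, 0.0, y2)
    e_add = np.where(at_zero, 1.0, e_add)
    clamped = np.where(at_zero, False, clamped)
    return y1, y2, survival, e_add, clamped


def predict_components(sample: SoilSample, params: ModelParams) -> AgingComponents:
    """Evaluate the full model for one sample, returning all components."""
    y1, y2, surv, e_add, clamped = _predict_arrays(
        sample.ph, sample.corg, sample.temperature, sample.time, params
    )
    if bool(clamped):
        logger.warning(
            "sample %s: fast-process losses exceed 1 (Y1=%.3f, Y2=%.3f); "
            "E_add clamped to the [0, 1] range",
            sample.sample_id,
            float(y1),
            float(y2),
        )
    return AgingComponents(
        y1=float(y1),
        y2=float(y2),
        diffusion_survival=float(surv),
        e_add=float(e_add),
        clamped=bool(clamped),
    )


def predict_e_add(sample: SoilSample, params: ModelParams) -> AgingComponents:
    """Alias of :func:`predict_components` (named for the quantity returned)."""
    return predict_components(sample, params)
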