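"""Parameter records for the synthetic screen generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SEXES = ("male", "female")


@dataclass
class GrowthParams:
    """Sex-dimorphic multiplicative growth and nuclear-size dynamics.

    GTme cells grow exponentially over the assay window, males faster than
    females (androgen-primed proliferation), while mean nuclear area rises
    and approaches a plateau.  ``modulators`` maps a treatment name (e.g.
    methyltestosterone ``"MT"``, flutamide ``"FLUT"``) to a per-sex
    multiplicative effect on the growth rate.

    Attributes
    ----------
    rate_male, rate_female
        Per-day multiplicative growth factors (cells double every
        ``log(2)/log(rate)`` days).  Defaults give males the growth
        advantage seen in culture.
    n0_range
        Inclusive interval of initial cells per well (seeding density).
    size0, size_plateau
        Initial and asymptotic mean nuclear area, pixel^2.
    size_rate
        Per-day fractional approach to the plateau, in [0, 1].
    count_cv
        Coefficient of variation of observed well counts (multiplicative
        lognormal noise).
    size_cv
        Coefficient of variation of observed mean nuclear areas.
    size_growth_coupling
        Optional deceleration of growth as nuclear size approaches its
        plateau (0 = pure exponential growth).
    epithelial_fraction, epithelial_rate
        Optional contaminating epithelial subpopulation, a feature of
        crude (non-FACS) isolation: that fraction of seeded cells grows
        at its own sex-independent rate, blind to compound and hormone
        effects.
    modulators
        treatment name -> {sex: multiplicative factor on the growth rate}.
    """

    rate_male: float = 1.35
    rate_female: float = 1.25
    n0_range: tuple[int, int] = (300, 500)
    size0: float = 80.0
    size_plateau: float = 150.0
    size_rate: float = 0.35
    count_cv: float = 0.08
    size_cv: float = 0.02
    size_growth_coupling: float = 0.0
    epithelial_fraction: float = 0.0
    epithelial_rate: float = 1.15
    modulators: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            # MT boosts female proliferation markedly, males only mildly;
            # the androgen antagonist FLUT attenuates male growth only.
            "MT": {"male": 1.02, "female": 1.08},
            "FLUT": {"male": 0.92, "female": 1.00},
        }
    )

    def __post_init__(self) -> None:
        if self.rate_male <= 0 or self.rate_female <= 0:
            raise ValueError("growth rates must be positive")
        if not (self.size_plateau >= self.size0 > 0):
            raise ValueError("require size_plateau >= size0 > 0")
        if not (0.0 <= self.size_rate <= 1.0):
            raise ValueError("size_rate must lie in [0, 1]")
        if self.count_cv < 0 or self.size_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if not (0.0 <= self.size_growth_coupling <= 1.0):
            raise ValueError("size_growth_coupling must lie in [0, 1]")
        if not (0.0 <= self.epithelial_fraction < 1.0):
            raise ValueError("epithelial_fraction must lie in [0, 1)")
        if self.epithelial_rate <= 0:
            raise ValueError("epithelial_rate must be positive")
        lo, hi = self.n0_range
        if not (0 < lo <= hi):
            raise ValueError("n0_range must be a positive interval")

    def rate(self, sex: str, modulators: Sequence[str] = ()) -> float:
        """Effective per-day growth factor for a sex under treatments."""
        r = {"male": self.rate_male, "female": self.rate_female}[sex]
        for m in modulators:
            r *= self.modulators.get(m, {}).get(sex, 1.0)
        return r

    def mean_size(self, days: float) -> float:
        """Expected mean nuclear area after ``days`` in culture."""
        return self.size_plateau - (self.size_plateau - self.size0) * (
            1.0 - self.size_rate
        ) ** days


@dataclass(frozen=True)
class CompoundEffect:
    """Planted truth for one library compound.

    ``effect_male`` / ``effect_female`` multiply the expected final well
    count (1.0 = null compound); ``size_shift_*`` add to the expected mean
    nuclear area in pixel^2 (nuclear shrinkage < 0).  ``family`` is the
    kinase-family annotation used for enrichment analysis.
    """

    effect_male: float = 1.0
    effect_female: float = 1.0
    family: str = "other"
    size_shift_male: float = 0.0
    size_shift_female: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_male <= 0 or self.effect_female <= 0:
            raise ValueError("count effects must be positive multiplicative factors")

    def effect(self, sex: str) -> float:
        return self.effect_male if sex == "male" else self.effect_female

    def size_shift(self, sex: str) -> float:
        return self.size_shift_male if sex == "male" else self.size_shift_female


#: compound_id -> CompoundEffect
EffectMap = Mapping[str, CompoundEffect]


@dataclass
class ImageParams:
    """Rendering parameters for synthetic nuclei fields (16-bit grayscale)."""

    field_shape: tuple[int, int] = (512, 512)
    nuclei_per_field: int = 30
    radius_mean: float = 6.0
    radius_sd: float = 0.8
    peak_intensity: float = 30000.0
    background: float = 1200.0
    noise_sd: float = 150.0
    overlap_allowed: bool = False
    fields_per_well: int = 4

    def __post_init__(self) -> None:
        if not (self.radius_mean > self.radius_sd >= 0):
            raise ValueError("require radius_mean > radius_sd >= 0")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        top = self.peak_intensity + self.background
        if not (0 <= self.background and top <= 65535):
            raise ValueError("intensity levels must fit 16-bit range")


@dataclass
class FieldTruth:
    """Ground truth for one rendered field: exact centers and intended areas."""

    plate_id: str
    well: str
    field_index: int
    centers: np.ndarray  # (n, 2) row, col
    radii: np.ndarray  # (n,)
    areas: np.ndarray  # (n,) = pi * r^2

    @property
    def count(self) -> int:
        return len(self.centers)
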