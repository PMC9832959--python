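"""Well-level screen simulation: counts and nuclear sizes with planted effects."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from gtscreen._rng import substream
from gtscreen.simulate.layout import ROLE_COMPOUND, ROLE_CONTROL
from gtscreen.simulate.params import CompoundEffect, EffectMap, GrowthParams

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "plate_id",
    "well",
    "sex",
    "cell_count",
    "mean_nuclear_area",
    "n_fields",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=n))


def expected_count(
    growth: GrowthParams,
    sex: str,
    days: float,
    n0: float,
    modulators: tuple[str, ...] = (),
    effect: float = 1.0,
) -> float:
    """Expected (noise-free) cell count per well after ``days`` in culture.

    Pure exponential growth by default.  With ``size_growth_coupling``
    set, the instantaneous rate decelerates as nuclear size approaches
    its plateau (proliferation slows as cells differentiate); the closed
    form integrates the decelerating log-rate.  With
    ``epithelial_fraction`` set, that fraction of the seeded cells is a
    contaminating epithelial population growing at ``epithelial_rate``,
    unresponsive to sex, compounds and hormonal modulators.
    """
    rate = growth.rate(sex, modulators)
    coupling = growth.size_growth_coupling
    if coupling:
        q = 1.0 - growth.size_rate
        if q <= 0:
            exponent = days * (1.0 - coupling)
        else:
            log_q = np.log(q)
            exponent = days * (1.0 - coupling) + coupling * (q**days - 1.0) / log_q
    else:
        exponent = days
    f = growth.epithelial_fraction
    mesenchymal = (1.0 - f) * rate**exponent * effect
    epithelial = f * growth.epithelial_rate**days
    return float(n0 * (mesenchymal + epithelial))


def simulate_screen_counts(
    layout: pd.DataFrame,
    effects: EffectMap,
    growth: GrowthParams | None = None,
    days: float = 6.0,
    seed: int = 0,
    n_fields_nominal: int = 4,
) -> pd.DataFrame:
    """Simulate the per-well readout of the compound screen.

    Every compound and control well of ``layout`` receives an observed
    cell count ``round(n0 * rate_sex**days * effect_sex * noise)`` (noise
    is multiplicative lognormal with CV ``growth.count_cv``, counts
    floored at 0) and a mean nuclear area following the
    increase-to-plateau trajectory plus any compound-declared size shift.
    Empty wells are not measured.  Reproducible for a fixed seed.
    """
    growth = growth or GrowthParams()
    measured = layout[layout["role"].isin([ROLE_COMPOUND, ROLE_CONTROL])].copy()

    unknown = (
        set(measured.loc[measured["role"] == ROLE_COMPOUND, "compound_id"])
        - set(effects)
    )
    if unknown:
        logger.warning(
            "%d compounds missing from effect map; treated as null (effect 1.0)",
            len(unknown),
        )
    null = CompoundEffect()

    rng_counts = substream(seed, "counts")
    rng_n0 = substream(seed, "counts-n0")
    rng_size = substream(seed, "sizes")

    n = len(measured)
    lo, hi = growth.n0_range
    # One seeding density per run: all wells are plated from the same cell
    # suspension, so n0_range describes the protocol's target window, not
    # well-to-well scatter (which count_cv carries).
    n0 = np.full(n, float(rng_n0.integers(lo, hi + 1)))
    count_noise = _lognormal_factors(rng_counts, growth.count_cv, n)
    size_noise = _lognormal_factors(rng_size, growth.size_cv, n)

    base_size = growth.mean_size(days)
    counts = np.empty(n)
    sizes = np.empty(n)
    rows = measured.itertuples(index=False)
    for i, row in enumerate(rows):
        if row.role == ROLE_COMPOUND:
            eff = effects.get(row.compound_id, null)
        else:
            eff = null
        mu = expected_count(growth, row.sex, days, n0[i], effect=eff.effect(row.sex))
        counts[i] = max(0.0, mu * count_noise[i])
        sizes[i] = max(1.0, (base_size + eff.size_shift(row.sex)) * size_noise[i])

    out = measured[["plate_id", "well", "sex"]].copy()
    out["cell_count"] = np.rint(counts).astype(int)
    out["mean_nuclear_area"] = sizes
    out["n_fields"] = n_fields_nominal
    return out.reset_index(drop=True)


def make_effect_map(
    compound_ids: list[str],
    n_hypo: int = 60,
    effect_hypo: float = 0.3,
    n_hyper: int = 20,
    effect_hyper: float = 1.8,
    shrinkage_fraction: float = 0.5,
    shrinkage_shift: float = -40.0,
    seed: int = 0,
) -> dict[str, CompoundEffect]:
    """Plant hypo/hyper compound effects in a library, for recovery tests.

    Randomly assigns ``n_hypo`` compounds a count effect of
    ``effect_hypo`` and ``n_hyper`` compounds ``effect_hyper`` in both
    sexes; the rest are null.  A ``shrinkage_fraction`` of each hit class
    additionally shrinks nuclei by ``shrinkage_shift`` pixel^2 (yielding
    C1/C2 hits; the remainder are C3).  Kinase-family labels are drawn so
    that hypo hits concentrate in cell-cycle kinase families (mTOR, PLK,
    Aurora, CDK, PI3K), hyper hits in growth-restraining ones (Bcr-Abl,
    p38 MAPK, RAF, ROCK), and nulls spread over the remaining library.
    """
    if n_hypo + n_hyper > len(compound_ids):
        raise ValueError("more planted hits than compounds")
    rng = substream(seed, "effects")
    order = rng.permutation(len(compound_ids))
    hypo_ids = [compound_ids[i] for i in order[:n_hypo]]
    hyper_ids = [compound_ids[i] for i in order[n_hypo : n_hypo + n_hyper]]
    null_ids = [compound_ids[i] for i in order[n_hypo + n_hyper :]]

    hypo_families = ["mTOR", "PLK", "Aurora", "CDK", "PI3K"]
    hyper_families = ["Bcr-Abl", "p38 MAPK", "RAF", "ROCK"]
    null_families = ["EGFR", "JAK", "Src", "GSK-3", "MEK", "FGFR", "ALK", "other"]

    effects: dict[str, CompoundEffect] = {}
    for j, cpd in enumerate(hypo_ids):
        shrink = shrinkage_shift if rng.random() < shrinkage_fraction else 0.0
        effects[cpd] = CompoundEffect(
            effect_male=effect_hypo,
            effect_female=effect_hypo,
            family=hypo_families[j % len(hypo_families)],
            size_shift_male=shrink,
            size_shift_female=shrink,
        )
    for j, cpd in enumerate(hyper_ids):
        shrink = shrinkage_shift if rng.random() < shrinkage_fraction else 0.0
        effects[cpd] = CompoundEffect(
            effect_male=effect_hyper,
            effect_female=effect_hyper,
            family=hyper_families[j % len(hyper_families)],
            size_shift_male=shrink,
            size_shift_female=shrink,
        )
    for j, cpd in enumerate(null_ids):
        effects[cpd] = CompoundEffect(family=null_families[j % len(null_families)])
    return effects
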