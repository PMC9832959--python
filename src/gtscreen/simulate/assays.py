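"""Generators for the supporting assays: growth courses, qPCR Ct tables,
and BrdU region-of-interest point sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from gtscreen._rng import substream
from gtscreen.simulate.params import GrowthParams
from gtscreen.simulate.wells import _lognormal_factors, expected_count
from gtscreen.stats import BrduRoi, GrowthCurve


def simulate_growth_course(
    conditions: list[tuple[str, tuple[str, ...]]],
    timepoints: list[float],
    growth: GrowthParams | None = None,
    replicates: int = 4,
    seed: int = 0,
) -> list[GrowthCurve]:
    """Simulate replicate growth curves for a list of culture conditions.

    ``conditions`` is a list of ``(sex, treatments)`` pairs; treatment
    effects compose multiplicatively on the sex growth rate.  The seeding
    density is drawn once per run and shared by all replicates and
    conditions (one cell prep split across treatment arms); count and
    size observation noise are per condition, replicate and timepoint.
    """
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be sorted strictly ascending")
    growth = growth or GrowthParams()
    lo, hi = growth.n0_range
    # Single seeding density per run, shared by replicates and conditions:
    # one cell prep is split across all arms of a time course.
    n0 = np.full(replicates, float(substream(seed, "growth-n0").integers(lo, hi + 1)))

    curves = []
    for sex, treatments in conditions:
        treatments = tuple(treatments)
        label = "+".join([sex, *treatments])
        rng = substream(seed, f"growth/{label}")
        counts = np.empty((replicates, len(t)))
        areas = np.empty((replicates, len(t)))
        for j, day in enumerate(t):
            mu = np.array(
                [expected_count(growth, sex, day, n0[r], treatments) for r in range(replicates)]
            )
            counts[:, j] = np.rint(
                np.maximum(0.0, mu * _lognormal_factors(rng, growth.count_cv, replicates))
            )
            areas[:, j] = growth.mean_size(day) * _lognormal_factors(
                rng, growth.size_cv, replicates
            )
        curves.append(
            GrowthCurve(
                condition=label,
                sex=sex,
                treatments=treatments,
                timepoints=t,
                counts=counts,
                areas=areas,
            )
        )
    return curves


def simulate_qpcr(
    genes: list[str],
    fold_changes: dict[str, float],
    ct_ref_level: float = 18.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    target_base_ct: float = 25.0,
    calibrator_group: str = "calibrator",
    treated_group: str = "treated",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with planted fold changes.

    For each gene, the calibrator group's target Ct sits at
    ``target_base_ct`` while the treated group's is lowered by
    ``log2(fold)`` (higher expression = earlier amplification = lower Ct);
    the reference (housekeeping) gene amplifies at ``ct_ref_level`` in all
    samples.  Gaussian cycle noise of ``noise_sd`` is added to every Ct.
    Delta-delta-Ct analysis of the output recovers the planted folds
    within noise.
    """
    for gene in genes:
        fold = fold_changes.get(gene, 1.0)
        if fold <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
    rng = substream(seed, "qpcr")
    rows = []
    for gene in genes:
        fold = fold_changes.get(gene, 1.0)
        for group, shift in ((calibrator_group, 0.0), (treated_group, -np.log2(fold))):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": f"{gene}_{group}_{rep}",
                        "group": group,
                        "gene": gene,
                        "ct_target": target_base_ct
                        + shift
                        + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                        "ct_reference": ct_ref_level
                        + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                    }
                )
    return pd.DataFrame(rows)


def simulate_brdu_roi(
    density: float,
    roi: np.ndarray | list[tuple[float, float]],
    seed: int = 0,
    label: str = "",
) -> BrduRoi:
    """Scatter BrdU+ points uniformly inside a region of interest.

    The point count is ``round(density * polygon_area)``; points are
    drawn by rejection sampling in the bounding box.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    poly = Polygon(np.asarray(roi, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("ROI polygon must be simple with positive area")
    n = int(round(density * poly.area))
    rng = substream(seed, f"brdu/{label}")
    minx, miny, maxx, maxy = poly.bounds
    pts: list[tuple[float, float]] = []
    while len(pts) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(Point(x, y)):
            pts.append((x, y))
    return BrduRoi(
        polygon=np.asarray(poly.exterior.coords[:-1]),
        points=np.asarray(pts, dtype=float).reshape(-1, 2),
        label=label,
    )
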