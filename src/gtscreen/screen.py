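"""Hit-calling mathematics of the proliferation screen.

Each plate is analysed independently per sex: the plate median and raw
(unscaled) median absolute deviation (MAD) of the per-well cell count set
the null band, and a compound is a hit when the mean count of its
technical replicates lies k MADs (default 3) or more away from the plate
median — above for hyperhits, below for hypohits.  Vehicle (DMSO) control
wells, judged individually against the same band, give an empirical false
discovery rate.  Hits are then categorised on the count vs nuclear-size
plane (C1 hypo+shrinkage, C2 hyper+shrinkage, C3 count change with minimal
size change), partitioned by sex, and tested for kinase-family enrichment
with an exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gtscreen.simulate.layout import ROLE_COMPOUND, ROLE_CONTROL

logger = logging.getLogger(__name__)

DIRECTION_HYPER = "hyper"
DIRECTION_HYPO = "hypo"
DIRECTION_NONE = "none"


@dataclass
class ControlFdr:
    """Per-direction false discovery rate from vehicle control wells."""

    fdr_hyper_percent: float
    fdr_hypo_percent: float
    n_controls: int
    n_hyper_flagged: int
    n_hypo_flagged: int
    flagged_hyper: list = field(default_factory=list)
    flagged_hypo: list = field(default_factory=list)


def plate_mad(counts: Sequence[float]) -> tuple[float, float]:
    """Plate median and raw median absolute deviation of well counts.

    The MAD is the median of |count - plate median|, deliberately left
    unscaled (no 1.4826 normal-consistency factor): the screen's hit band
    is defined in raw MAD units.
    """
    x = np.asarray(counts, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("plate_mad needs at least 2 finite values")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, mad


def _merge(measurements: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    merged = measurements.merge(
        layout[["plate_id", "well", "sex", "role", "compound_id"]],
        on=["plate_id", "well", "sex"],
        how="left",
        validate="one_to_one",
    )
    if merged["role"].isna().any():
        missing = merged.loc[merged["role"].isna(), ["plate_id", "well", "sex"]]
        raise ValueError(f"measured wells absent from layout:\n{missing}")
    return merged


def plate_count_stats(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    include_controls: bool = True,
    value: str = "cell_count",
) -> pd.DataFrame:
    """Per-(plate, sex) median/MAD of a measured well value.

    By default the statistics pool all measured compound *and* control
    wells (controls stabilise the null; configurable to compound wells
    only).  Empty wells never enter.  A plate with MAD 0 is flagged
    degenerate.
    """
    merged = _merge(measurements, layout)
    roles = [ROLE_COMPOUND, ROLE_CONTROL] if include_controls else [ROLE_COMPOUND]
    pool = merged[merged["role"].isin(roles)]
    rows = []
    for (plate_id, sex), sub in pool.groupby(["plate_id", "sex"], sort=True):
        med, mad = plate_mad(sub[value].to_numpy())
        rows.append(
            {
                "plate_id": plate_id,
                "sex": sex,
                "median": med,
                "mad": mad,
                "n_wells_used": len(sub),
                "degenerate": mad == 0.0,
            }
        )
        if mad == 0.0:
            logger.warning(
                "plate %s (%s): MAD of %s is 0 — degenerate, no calls will be made",
                plate_id, sex, value,
            )
    return pd.DataFrame(rows)


def _classify(deviation: float, k: float, inclusive: bool) -> str:
    if np.isnan(deviation):
        return DIRECTION_NONE
    if inclusive:
        if deviation >= k:
            return DIRECTION_HYPER
        if deviation <= -k:
            return DIRECTION_HYPO
    else:
        if deviation > k:
            return DIRECTION_HYPER
        if deviation < -k:
            return DIRECTION_HYPO
    return DIRECTION_NONE


def call_hits(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    k: float = 3.0,
    include_controls: bool = True,
    inclusive: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call hyper/hypo hits on replicate-averaged compound counts.

    For every compound and sex, the mean cell count of its technical
    replicates is expressed in MAD units from its plate's median; the
    direction is hyper at ``>= median + k*MAD``, hypo at
    ``<= median - k*MAD`` (inclusive band by default — "k MAD or more";
    set ``inclusive=False`` for the strict variant).  Degenerate plates
    (MAD 0) yield no calls.

    Returns ``(compound_table, plate_stats)``; the compound table holds
    one row per (compound, sex) with ``mean_count, mean_nuclear_area,
    deviation_mads, direction``.  Hits are the rows with direction other
    than "none"; a compound is a screen hit if it is a hit in either sex.
    """
    if k <= 0:
        raise ValueError("MAD multiplier k must be positive")
    merged = _merge(measurements, layout)
    cpd = merged[merged["role"] == ROLE_COMPOUND]
    plates_per = cpd.groupby(["compound_id", "sex"])["plate_id"].nunique()
    if (plates_per > 1).any():
        bad = plates_per[plates_per > 1].index.get_level_values(0).unique().tolist()
        raise ValueError(f"compounds measured on multiple plates: {bad}")

    stats = plate_count_stats(measurements, layout, include_controls)
    stats_ix = stats.set_index(["plate_id", "sex"])

    rows = []
    for (compound_id, sex), sub in cpd.groupby(["compound_id", "sex"], sort=True):
        plate_id = sub["plate_id"].iloc[0]
        st = stats_ix.loc[(plate_id, sex)]
        mean_count = float(sub["cell_count"].mean())
        if st["degenerate"]:
            deviation = float("nan")
        else:
            deviation = (mean_count - st["median"]) / st["mad"]
        rows.append(
            {
                "compound_id": compound_id,
                "sex": sex,
                "plate_id": plate_id,
                "n_replicates": len(sub),
                "mean_count": mean_count,
                "mean_nuclear_area": float(sub["mean_nuclear_area"].mean()),
                "deviation_mads": deviation,
                "direction": _classify(deviation, k, inclusive),
            }
        )
    compound_table = pd.DataFrame(rows)
    return compound_table, stats


def control_fdr(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    k: float = 3.0,
    include_controls: bool = True,
    inclusive: bool = True,
) -> ControlFdr:
    """Empirical FDR from individual vehicle control wells.

    Each control well (not replicate-averaged — the asymmetry with
    compounds is intentional) is tested against its own plate's hit band;
    the FDR per direction is ``100 * flagged / total`` percent.  Zero
    flagged wells report 0% — the rate is below the threshold of
    detection at that control count.
    """
    merged = _merge(measurements, layout)
    controls = merged[merged["role"] == ROLE_CONTROL]
    if controls.empty:
        raise ValueError("no control wells in the measurements")
    stats_ix = plate_count_stats(measurements, layout, include_controls).set_index(
        ["plate_id", "sex"]
    )
    flagged_hyper, flagged_hypo = [], []
    for row in controls.itertuples(index=False):
        st = stats_ix.loc[(row.plate_id, row.sex)]
        if st["degenerate"]:
            continue
        deviation = (row.cell_count - st["median"]) / st["mad"]
        direction = _classify(deviation, k, inclusive)
        if direction == DIRECTION_HYPER:
            flagged_hyper.append((row.plate_id, row.well, row.sex))
        elif direction == DIRECTION_HYPO:
            flagged_hypo.append((row.plate_id, row.well, row.sex))
    n = len(controls)
    return ControlFdr(
        fdr_hyper_percent=100.0 * len(flagged_hyper) / n,
        fdr_hypo_percent=100.0 * len(flagged_hypo) / n,
        n_controls=n,
        n_hyper_flagged=len(flagged_hyper),
        n_hypo_flagged=len(flagged_hypo),
        flagged_hyper=flagged_hyper,
        flagged_hypo=flagged_hypo,
    )


CATEGORY_C1 = "C1"  # hypo + nuclear shrinkage (cytotoxic signature)
CATEGORY_C2 = "C2"  # hyper + nuclear shrinkage
CATEGORY_C3 = "C3"  # count change, minimal nuclear-size impact
CATEGORY_NOT_HIT = "not_a_hit"


def categorize_hits(
    compound_table: pd.DataFrame,
    size_stats: pd.DataFrame,
    size_k: float = 3.0,
) -> pd.DataFrame:
    """Place each hit on the count vs nuclear-size plane (C1/C2/C3).

    ``size_stats`` is ``plate_count_stats(..., value="mean_nuclear_area")``.
    The nuclear-size shift is the compound's replicate-mean nuclear area
    in MAD units from the plate's size median; shrinkage means a shift of
    ``-size_k`` or beyond.  C1 = hypo with shrinkage, C2 = hyper with
    shrinkage, C3 = any hit without shrinkage; size-enlarged C3 hits are
    additionally flagged ``size_enlarged``.  Non-hits get "not_a_hit";
    hits on plates with degenerate size statistics remain undetermined
    (NaN shift) and are logged.
    """
    out = compound_table.copy()
    stats_ix = size_stats.set_index(["plate_id", "sex"])
    shifts, categories, enlarged = [], [], []
    for row in out.itertuples(index=False):
        try:
            st = stats_ix.loc[(row.plate_id, row.sex)]
        except KeyError:
            st = None
        if st is None or st["degenerate"] or np.isnan(row.mean_nuclear_area):
            shift = float("nan")
        else:
            shift = (row.mean_nuclear_area - st["median"]) / st["mad"]
        shifts.append(shift)
        if row.direction == DIRECTION_NONE:
            categories.append(CATEGORY_NOT_HIT)
            enlarged.append(False)
            continue
        if np.isnan(shift):
            logger.warning(
                "hit %s (%s): nuclear-size statistics unavailable, category undetermined",
                row.compound_id, row.sex,
            )
            categories.append(None)
            enlarged.append(False)
            continue
        shrinkage = shift <= -size_k
        if shrinkage:
            categories.append(CATEGORY_C1 if row.direction == DIRECTION_HYPO else CATEGORY_C2)
            enlarged.append(False)
        else:
            categories.append(CATEGORY_C3)
            enlarged.append(shift >= size_k)
    out["nuclear_size_shift"] = shifts
    out["category"] = categories
    out["size_enlarged"] = enlarged
    return out


def venn_partition(
    hits_male: Iterable[str], hits_female: Iterable[str]
) -> dict[str, set[str]]:
    """Partition screen hits into male-only / female-only / both sets."""
    male, female = set(hits_male), set(hits_female)
    parts = {
        "male_only": male - female,
        "female_only": female - male,
        "both": male & female,
    }
    union = parts["male_only"] | parts["female_only"] | parts["both"]
    assert union == male | female, "venn partition must cover the hit set"
    assert (
        len(parts["male_only"]) + len(parts["female_only"]) + len(parts["both"])
        == len(union)
    ), "venn parts must be disjoint"
    return parts


def screen_direction(compound_table: pd.DataFrame) -> dict[str, str]:
    """Collapse per-sex directions to one per compound (hit in either sex).

    A compound that is hyper in one sex and hypo in the other maps to
    "mixed" (none observed in practice, but the case must be explicit).
    """
    out: dict[str, str] = {}
    for compound_id, sub in compound_table.groupby("compound_id", sort=True):
        dirs = set(sub["direction"]) - {DIRECTION_NONE}
        if not dirs:
            out[compound_id] = DIRECTION_NONE
        elif len(dirs) == 1:
            out[compound_id] = dirs.pop()
        else:
            out[compound_id] = "mixed"
    return out


def concordance(
    ref_table: pd.DataFrame,
    test_table: pd.DataFrame,
    compounds: Iterable[str] | None = None,
) -> tuple[int, int, pd.DataFrame]:
    """Cross-screen agreement of hit directions for retested compounds.

    A compound repeats when its screen-level direction (hyper/hypo, in
    either sex) matches between the reference and the retest screen.
    Compounds absent from either screen are excluded and logged.
    """
    ref_dir = screen_direction(ref_table)
    test_dir = screen_direction(test_table)
    if compounds is None:
        compounds = sorted(set(ref_dir) & set(test_dir))
    rows = []
    for cpd in compounds:
        if cpd not in ref_dir or cpd not in test_dir:
            logger.warning("compound %s absent from one screen; excluded", cpd)
            continue
        agree = ref_dir[cpd] == test_dir[cpd] and ref_dir[cpd] in (
            DIRECTION_HYPER,
            DIRECTION_HYPO,
        )
        rows.append(
            {
                "compound_id": cpd,
                "direction_ref": ref_dir[cpd],
                "direction_test": test_dir[cpd],
                "repeated": agree,
            }
        )
    table = pd.DataFrame(rows)
    n_tested = len(table)
    n_repeated = int(table["repeated"].sum()) if n_tested else 0
    return n_repeated, n_tested, table


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 count table.

    Sums the hypergeometric probabilities (at fixed margins) of all
    tables whose probability does not exceed the observed table's, with
    exact rational arithmetic, so the result is correct to float
    rounding.
    """
    (a, b), (c, d) = table
    cells = [int(a), int(b), int(c), int(d)]
    if any(x < 0 for x in cells):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = cells
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be positive")
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


def family_enrichment(
    hits: Iterable[str],
    library_annotation: Mapping[str, str],
) -> pd.DataFrame:
    """Kinase-family enrichment of a hit set by Fisher's exact test.

    For each family f the 2x2 table
    ``[[hits in f, hits not in f], [non-hits in f, non-hits not in f]]``
    is tested; a family is labelled enriched when its hit fraction
    strictly exceeds the library-wide hit fraction, disenriched otherwise
    (the tie rule).  Rows are ranked by p within each label.  Unannotated
    hits fall into an "other" family with a log message.
    """
    if not library_annotation:
        raise ValueError("empty compound library annotation")
    hits = set(hits)
    annotation = dict(library_annotation)
    for cpd in hits - set(annotation):
        logger.warning("hit %s unannotated; assigned family 'other'", cpd)
        annotation[cpd] = "other"
    compounds = set(annotation)
    n_hits = len(hits & compounds)
    overall = n_hits / len(compounds)
    rows = []
    for fam in sorted(set(annotation.values())):
        members = {c for c, f in annotation.items() if f == fam}
        h_in = len(hits & members)
        h_out = n_hits - h_in
        n_in = len(members) - h_in
        n_out = len(compounds) - len(members) - h_out
        p = fisher_exact_2x2([[h_in, h_out], [n_in, n_out]])
        frac = h_in / len(members)
        rows.append(
            {
                "family": fam,
                "n_compounds": len(members),
                "n_hits": h_in,
                "hit_fraction": frac,
                "overall_hit_fraction": overall,
                "label": "enriched" if frac > overall else "disenriched",
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(["label", "p"], ascending=[True, True]).reset_index(
        drop=True
    )
    table["rank_in_label"] = table.groupby("label").cumcount() + 1
    return table
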