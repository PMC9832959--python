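"""Supporting quantifications: Welch t-tests, growth-curve comparison,
nuclear-size vs growth trend, delta-delta-Ct expression, BrdU density.

All group comparisons use the two-tailed Welch (unequal-variance) t-test;
no multiple-testing correction is applied anywhere, and every report says
so — single readouts per condition are compared, not families of
hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point, Polygon


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


@dataclass
class GrowthCurve:
    """Time course of replicate well counts (and mean nuclear areas) for
    one culture condition (sex plus optional treatments)."""

    condition: str
    sex: str
    treatments: tuple[str, ...]
    timepoints: np.ndarray  # (T,) days
    counts: np.ndarray  # (replicates, T)
    areas: np.ndarray | None = None  # (replicates, T) pixel^2

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.counts.shape[1] != len(self.timepoints):
            raise ValueError("counts must have one column per timepoint")
        if self.areas is not None:
            self.areas = np.atleast_2d(np.asarray(self.areas, dtype=float))
            if self.areas.shape != self.counts.shape:
                raise ValueError("areas must match counts in shape")


@dataclass
class BrduRoi:
    """A tissue region of interest with BrdU+ cell coordinates.

    ``polygon`` is a simple (non-self-intersecting) pixel-coordinate ring;
    ``points`` are detected BrdU-positive nuclei centres.
    """

    polygon: np.ndarray  # (V, 2) x, y vertices
    points: np.ndarray  # (N, 2) x, y
    label: str = ""

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class BrduDensity:
    density: float  # cells per pixel^2
    n_inside: int
    n_outside: int
    area: float
    label: str = ""


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-tailed Welch t-test (unequal variances).

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom; the p-value comes from the
    two-sided t distribution.  When both sample variances are zero the
    convention is p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    return welch_t_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def welch_t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    scale: str = "sd",
) -> WelchResult:
    """Welch t-test from summary statistics (mean, spread, n per group).

    ``scale`` may be ``"sd"`` or ``"sem"``; a SEM is converted with
    sd = sem * sqrt(n), so published "mean ± sem, N" panels can be tested
    directly.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if scale == "sem":
        sd_a = sd_a * np.sqrt(n_a)
        sd_b = sd_b * np.sqrt(n_b)
    elif scale != "sd":
        raise ValueError("scale must be 'sd' or 'sem'")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0.0:
        if mean_a == mean_b:
            return WelchResult(0.0, float(n_a + n_b - 2), 1.0)
        return WelchResult(np.inf if mean_a > mean_b else -np.inf, float(n_a + n_b - 2), 0.0)
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(1.0, p)))


def compare_growth_curves(curve_a: GrowthCurve, curve_b: GrowthCurve) -> pd.DataFrame:
    """Per-timepoint Welch tests between two growth curves.

    Only shared timepoints are compared; significance is flagged at 0.05
    and 0.01 with no multiplicity correction.
    """
    shared = sorted(set(curve_a.timepoints) & set(curve_b.timepoints))
    if not shared:
        raise ValueError("curves share no timepoints")
    rows = []
    for day in shared:
        ia = int(np.flatnonzero(curve_a.timepoints == day)[0])
        ib = int(np.flatnonzero(curve_b.timepoints == day)[0])
        res = welch_t_test(curve_a.counts[:, ia], curve_b.counts[:, ib])
        rows.append(
            {
                "day": day,
                "mean_a": curve_a.counts[:, ia].mean(),
                "mean_b": curve_b.counts[:, ib].mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "sig_05": res.p < 0.05,
                "sig_01": res.p < 0.01,
            }
        )
    return pd.DataFrame(rows)


def size_growth_correlation(curve: GrowthCurve) -> tuple[float, str]:
    """Spearman correlation between interval growth rate and nuclear size.

    For each interval [t_i, t_(i+1)] the growth rate is the log count
    ratio per day (replicate-mean counts); it is ranked against the mean
    nuclear area at the interval start.  The claim tested is monotone
    (faster-growing cultures have smaller nuclei), hence a rank
    correlation rather than a linear one.

    Returns ``(rho, direction)`` with direction in
    {"negative", "positive", "none", "undefined"}.
    """
    if curve.areas is None:
        raise ValueError("curve has no nuclear-size series")
    t = curve.timepoints
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    mean_counts = curve.counts.mean(axis=0)
    mean_areas = curve.areas.mean(axis=0)
    rates = np.diff(np.log(mean_counts)) / np.diff(t)
    start_sizes = mean_areas[:-1]
    if np.ptp(rates) == 0 or np.ptp(start_sizes) == 0:
        return (float("nan"), "undefined")
    rho = float(sps.spearmanr(start_sizes, rates).statistic)
    if np.isnan(rho):
        return (rho, "undefined")
    direction = "negative" if rho < 0 else ("positive" if rho > 0 else "none")
    return (rho, direction)


def delta_delta_ct(
    records: pd.DataFrame, calibrator_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the delta-delta-Ct method.

    ``records`` needs columns ``sample, group, gene, ct_target,
    ct_reference`` (reference = housekeeping gene, e.g. Rpl7).  Per gene:
    dCt = Ct_target - Ct_reference for each sample, ddCt = dCt minus the
    calibrator group's mean dCt, relative expression = 2^(-ddCt).  The
    calibrator's geometric-mean fold is 1 by construction.

    Returns ``(per_sample, summary)``; the summary carries group mean, sd
    and sem of the fold, labelled separately because published panels
    report either spread.  Samples lacking a reference Ct are dropped.
    """
    required = {"sample", "group", "gene", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    rec = records.dropna(subset=["ct_target", "ct_reference"]).copy()
    n_dropped = len(records) - len(rec)
    rec["delta_ct"] = rec["ct_target"] - rec["ct_reference"]
    out = []
    for gene, sub in rec.groupby("gene", sort=False):
        calib = sub.loc[sub["group"] == calibrator_group, "delta_ct"]
        if calib.empty:
            raise ValueError(f"calibrator group {calibrator_group!r} empty for {gene!r}")
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - calib.mean()
        sub["fold"] = 2.0 ** (-sub["delta_delta_ct"])
        out.append(sub)
    per_sample = pd.concat(out, ignore_index=True)
    per_sample.attrs["n_dropped_missing_reference"] = n_dropped
    summary = (
        per_sample.groupby(["gene", "group"], sort=False)["fold"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
        .reset_index()
    )
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    return per_sample, summary


def _roi_polygon(roi: BrduRoi) -> Polygon:
    poly = Polygon(roi.polygon)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("ROI polygon must be simple with positive area")
    return poly


def brdu_density(roi: BrduRoi) -> BrduDensity:
    """BrdU+ cells per unit pixel area inside a region of interest.

    Points on the polygon boundary count as inside; points outside are
    excluded from the density but reported in ``n_outside`` for QC.
    """
    poly = _roi_polygon(roi)
    inside = sum(1 for p in roi.points if poly.covers(Point(p)))
    outside = len(roi.points) - inside
    return BrduDensity(
        density=inside / poly.area,
        n_inside=inside,
        n_outside=outside,
        area=poly.area,
        label=roi.label,
    )


def brdu_group_compare(
    densities_a: Sequence[float],
    densities_b: Sequence[float],
    label_a: str = "group_a",
    label_b: str = "group_b",
) -> dict:
    """Welch comparison of two sets of per-animal BrdU densities.

    Reports per-group mean with both sd and sem (labelled) plus n, and
    formatted ``mean ± sem, N = n`` strings matching figure-legend style.
    """
    res = welch_t_test(densities_a, densities_b)
    out = {"t": res.t, "df": res.df, "p": res.p, "groups": {}}
    for label, values in ((label_a, densities_a), (label_b, densities_b)):
        v = np.asarray(values, dtype=float)
        sem = v.std(ddof=1) / np.sqrt(len(v))
        out["groups"][label] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "sem": float(sem),
            "n": int(len(v)),
            "formatted": f"{v.mean():.4g} ± {sem:.4g}, N = {len(v)}",
        }
    return out
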