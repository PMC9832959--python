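"""Nuclear segmentation and per-well measurement of Hoechst-stained fields.

Reproduces the function of a commercial high-content readout: capture each
nucleus in a fluorescence field, count nuclei and measure their areas, then
aggregate the four fields of a well into one measurement (total cell count
and unweighted mean nuclear area over the pooled objects).

The segmentation pipeline is background subtraction (white top-hat, a
rolling-ball-style operation) -> global threshold (Otsu by default, fixed
available for noiseless data) -> optional distance-transform watershed to
split touching nuclei -> area filter.  Everything is deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

FIELD_FILE_RE = re.compile(r"^(?P<plate>[^_]+)_(?P<well>[A-P]\d{1,2})_f(?P<field>\d+)\.tiff?$")


class DegenerateImageError(ValueError):
    """Raised for a constant-valued image under automatic thresholding."""


class NucleusObject(NamedTuple):
    label: int
    area: float
    centroid: tuple[float, float]


@dataclass
class SegmentedField:
    """Labelled nuclei of one field: label map, per-object areas, settings."""

    label_map: np.ndarray
    objects: list[NucleusObject]
    params_used: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.objects)

    @property
    def areas(self) -> np.ndarray:
        return np.array([o.area for o in self.objects], dtype=float)


@dataclass
class WellMeasurement:
    plate_id: str
    well: str
    sex: str
    cell_count: int
    mean_nuclear_area: float  # NaN when cell_count == 0
    n_fields: int


def segment_nuclei(
    field_image: np.ndarray,
    min_area: float = 20.0,
    max_area: float = 5000.0,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    split_touching: bool = True,
    min_separation: float = 6.0,
    background_subtract: bool = True,
    bg_radius: int | None = None,
    exclude_border: bool = False,
) -> SegmentedField:
    """Segment nuclei in a single grayscale field.

    Parameters
    ----------
    field_image
        2-D finite-valued grayscale array.
    min_area, max_area
        Object-area acceptance band in pixel^2.
    threshold_method
        ``"otsu"`` (global automatic) or ``"fixed"`` (requires
        ``fixed_threshold``; the path of choice for noiseless images and
        legal blank fields).
    split_touching
        Split merged blobs at the distance-transform ridge, seeding the
        watershed from distance maxima at least ``min_separation`` pixels
        apart (use the expected nucleus radius).
    background_subtract
        White top-hat with a disk of ``bg_radius`` (default
        ``3 * min_separation``) to flatten slow background variation.
    exclude_border
        Drop objects touching the field border (kept by default: the bias
        is symmetric across wells and cancels in plate MAD statistics).
    """
    img = np.asarray(field_image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {img.ndim}-D")
    img = img.astype(float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")

    work = img
    if background_subtract:
        radius = int(bg_radius if bg_radius is not None else 3 * min_separation)
        footprint = skmorph.disk(radius, decomposition="sequence")
        work = skmorph.white_tophat(img, footprint=footprint)

    if threshold_method == "otsu":
        if np.ptp(work) == 0:
            raise DegenerateImageError(
                "constant-valued image: Otsu thresholding is undefined "
                "(blank fields are legal via threshold_method='fixed')"
            )
        thr = float(threshold_otsu(work))
        # Otsu misbehaves on sparse fields (it splits the read noise);
        # floor the threshold at a robust noise ceiling.
        med = float(np.median(work))
        sigma = 1.4826 * float(np.median(np.abs(work - med)))
        thr = max(thr, med + 6.0 * sigma)
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required with threshold_method='fixed'")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold_method: {threshold_method!r}")

    binary = work > thr
    labels = skmeasure.label(binary)

    if split_touching and labels.max() > 0:
        distance = ndi.distance_transform_edt(binary)
        coords = peak_local_max(
            distance,
            min_distance=max(1, int(round(min_separation))),
            labels=labels,
            exclude_border=False,
        )
        markers = np.zeros_like(labels)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        labels = watershed(-distance, markers, mask=binary)

    if exclude_border and labels.max() > 0:
        border = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, border[border > 0])] = 0

    objects: list[NucleusObject] = []
    relabel = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    next_label = 1
    for prop in skmeasure.regionprops(labels):
        if min_area <= prop.area <= max_area:
            relabel[prop.label] = next_label
            objects.append(
                NucleusObject(next_label, float(prop.area), tuple(prop.centroid))
            )
            next_label += 1
    label_map = relabel[labels]

    return SegmentedField(
        label_map=label_map,
        objects=objects,
        params_used={
            "min_area": min_area,
            "max_area": max_area,
            "threshold_method": threshold_method,
            "threshold": thr,
            "split_touching": split_touching,
            "min_separation": min_separation,
            "background_subtract": background_subtract,
            "exclude_border": exclude_border,
        },
    )


def summarize_well(
    fields: Sequence[SegmentedField], plate_id: str, well: str, sex: str
) -> WellMeasurement:
    """Aggregate a well's fields: total count, pooled mean nuclear area.

    The mean is unweighted over the pooled objects of all fields; an
    empty pool yields count 0 with the area flagged as NaN.
    """
    if not fields:
        raise ValueError("need at least one segmented field")
    shapes = {f.label_map.shape for f in fields}
    if len(shapes) > 1:
        logger.warning("well %s/%s mixes field shapes %s", plate_id, well, shapes)
    pooled = np.concatenate([f.areas for f in fields]) if fields else np.array([])
    count = int(sum(f.count for f in fields))
    mean_area = float(pooled.mean()) if count else float("nan")
    return WellMeasurement(plate_id, well, sex, count, mean_area, len(fields))


def measure_plate(
    image_dir: str | Path,
    layout: pd.DataFrame,
    fields_per_well: int = 4,
    **segment_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Batch-measure every non-empty layout well from a directory of fields.

    Expects TIFF files named ``{plate}_{well}_f{i}.tif``; ``layout`` must
    cover a single sex (file names carry no sex).  Wells with missing
    field images are excluded and reported in the run log; results are
    independent of file enumeration order.

    Returns ``(measurements, run_log)`` where measurements has columns
    ``plate_id, well, sex, cell_count, mean_nuclear_area, n_fields``.
    """
    image_dir = Path(image_dir)
    files: dict[tuple[str, str], dict[int, Path]] = {}
    n_files = 0
    for path in sorted(image_dir.glob("*.tif*")):
        m = FIELD_FILE_RE.match(path.name)
        if not m:
            continue
        files.setdefault((m["plate"], m["well"]), {})[int(m["field"])] = path
        n_files += 1
    if n_files == 0:
        raise FileNotFoundError(f"no field images found in {image_dir}")

    sexes = layout["sex"].unique()
    if len(sexes) != 1:
        raise ValueError("measure_plate requires a single-sex layout slice")

    wells = (
        layout[layout["role"] != "empty"][["plate_id", "well", "sex"]]
        .drop_duplicates()
        .sort_values(["plate_id", "well"])
    )
    rows, skipped, failures = [], [], []
    for plate_id, well, sex in wells.itertuples(index=False):
        have = files.get((plate_id, well), {})
        if len(have) < fields_per_well:
            skipped.append((plate_id, well, f"{len(have)}/{fields_per_well} fields"))
            logger.warning("well %s/%s skipped: %d/%d fields present",
                           plate_id, well, len(have), fields_per_well)
            continue
        try:
            segmented = [
                segment_nuclei(tifffile.imread(have[fi]), **segment_kwargs)
                for fi in sorted(have)
            ]
            rows.append(summarize_well(segmented, plate_id, well, sex).__dict__)
        except Exception as exc:  # per-well failures are collected, not fatal
            failures.append((plate_id, well, str(exc)))
            logger.error("well %s/%s failed: %s", plate_id, well, exc)
    run_log = {
        "n_files": n_files,
        "n_wells_measured": len(rows),
        "skipped_wells": skipped,
        "failed_wells": failures,
        "segment_kwargs": segment_kwargs,
    }
    return pd.DataFrame(rows), run_log
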