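"""Synthetic Hoechst-stained nuclei fields with exact ground truth.

Each nucleus is rendered as a flat-top radially decaying intensity profile
(an order-8 super-Gaussian): nearly uniform brightness inside the drawn
radius with a sharp shoulder, so that any threshold between background and
peak recovers an area close to the intended pi*r^2.  Placement is hard-disk
(non-overlapping) by default, with overlaps available as a stress mode.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from gtscreen._rng import substream
from gtscreen.simulate.params import FieldTruth, ImageParams

_SUPER_GAUSSIAN_ORDER = 8


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails repeatedly."""


def _place_centers(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    shape: tuple[int, int],
    overlap_allowed: bool,
    max_attempts_per_nucleus: int = 500,
) -> np.ndarray:
    h, w = shape
    centers = np.empty((n, 2))
    margin = radii + 1.0
    if np.any(2 * margin >= min(h, w)):
        raise PlacementError("nucleus radius too large for the field")
    for i in range(n):
        r = radii[i]
        for _ in range(max_attempts_per_nucleus):
            y = rng.uniform(margin[i], h - margin[i])
            x = rng.uniform(margin[i], w - margin[i])
            if overlap_allowed or i == 0:
                centers[i] = (y, x)
                break
            d2 = np.sum((centers[:i] - (y, x)) ** 2, axis=1)
            min_sep = radii[:i] + r + 2.0
            if np.all(d2 > min_sep**2):
                centers[i] = (y, x)
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} without overlap; "
                "lower the density or set overlap_allowed=True"
            )
    return centers


def _render(
    centers: np.ndarray,
    radii: np.ndarray,
    params: ImageParams,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = params.field_shape
    img = np.full((h, w), params.background, dtype=float)
    for (cy, cx), r in zip(centers, radii):
        pad = int(np.ceil(r)) + 3
        y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
        x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy - cy, xx - cx)
        img[y0:y1, x0:x1] += params.peak_intensity * np.exp(
            -((d / r) ** _SUPER_GAUSSIAN_ORDER)
        )
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


def render_field_images(
    params: ImageParams,
    well_counts: dict[tuple[str, str], int],
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[tuple[str, str, int], np.ndarray], list[FieldTruth]]:
    """Render per-field nuclei images for a set of wells.

    ``well_counts`` maps ``(plate_id, well)`` to the well's total nucleus
    count, which is split across ``params.fields_per_well`` fields by a
    multinomial draw.  Returns the images keyed by
    ``(plate_id, well, field_index)`` together with per-field ground truth
    (exact centers and intended areas pi*r^2).  When ``out_dir`` is given,
    writes one 16-bit grayscale TIFF per field, named
    ``{plate}_{well}_f{i}.tif``, plus a ``field_truth.csv`` sidecar.
    """
    images: dict[tuple[str, str, int], np.ndarray] = {}
    truths: list[FieldTruth] = []
    f = params.fields_per_well
    for (plate_id, well), total in sorted(well_counts.items()):
        rng = substream(seed, f"images/{plate_id}/{well}")
        per_field = rng.multinomial(int(total), np.full(f, 1.0 / f))
        for fi in range(1, f + 1):
            n = int(per_field[fi - 1])
            radii = np.clip(
                rng.normal(params.radius_mean, params.radius_sd, size=n), 2.0, None
            )
            centers = _place_centers(
                rng, n, radii, params.field_shape, params.overlap_allowed
            )
            images[(plate_id, well, fi)] = _render(centers, radii, params, rng)
            truths.append(
                FieldTruth(
                    plate_id=plate_id,
                    well=well,
                    field_index=fi,
                    centers=centers,
                    radii=radii,
                    areas=np.pi * radii**2,
                )
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (plate_id, well, fi), img in images.items():
            tifffile.imwrite(out / f"{plate_id}_{well}_f{fi}.tif", img)
        truth_table(truths).to_csv(out / "field_truth.csv", index=False)
    return images, truths


def truth_table(truths: list[FieldTruth]) -> pd.DataFrame:
    """Tidy per-field summary of the ground truth (counts and mean areas)."""
    return pd.DataFrame(
        {
            "plate_id": [t.plate_id for t in truths],
            "well": [t.well for t in truths],
            "field_index": [t.field_index for t in truths],
            "count": [t.count for t in truths],
            "mean_area": [float(np.mean(t.areas)) if t.count else np.nan for t in truths],
        }
    )
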