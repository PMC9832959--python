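"""Plate layouts for the compound screen.

A layout assigns every well of every assay plate a role — a compound in
technical replicate, a DMSO vehicle control, or empty — separately for the
male and female screens.  Each library plate of (by default) 80 compounds
maps onto one 384-well assay plate per sex; compound positions are
randomised within a plate, identically for both sexes, so the two screens
share plate geography.
"""

from __future__ import annotations

import string

import numpy as np
import pandas as pd

from gtscreen._rng import substream
from gtscreen.simulate.params import SEXES

PLATE_FORMATS = {96: (8, 12), 384: (16, 24)}

ROLE_COMPOUND = "compound"
ROLE_CONTROL = "control"
ROLE_EMPTY = "empty"

LAYOUT_COLUMNS = ["plate_id", "well", "role", "compound_id", "replicate_index", "sex"]


class LayoutError(ValueError):
    """Raised when a requested layout cannot fit its plate format."""


def well_names(plate_format: int = 384) -> list[str]:
    """Row-major well names (A1..P24 for 384, A1..H12 for 96)."""
    try:
        n_rows, n_cols = PLATE_FORMATS[plate_format]
    except KeyError:  # pragma: no cover - guarded by callers
        raise LayoutError(f"unsupported plate format: {plate_format}")
    rows = string.ascii_uppercase[:n_rows]
    return [f"{r}{c}" for r in rows for c in range(1, n_cols + 1)]


def generate_plate_layout(
    n_compounds: int,
    compounds_per_plate: int = 80,
    replicates: int = 4,
    controls_per_plate: int = 32,
    plate_format: int = 384,
    seed: int = 0,
    compound_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Lay out a compound library across assay plates, one plate per sex.

    Compounds are chunked into library plates of ``compounds_per_plate``;
    each compound occupies exactly ``replicates`` wells on exactly one
    plate per sex, plus ``controls_per_plate`` DMSO wells per plate; the
    remaining wells are empty.  Deterministic for a fixed seed.

    Returns a tidy table with columns
    ``plate_id, well, role, compound_id, replicate_index, sex``.
    """
    if n_compounds < 1:
        raise LayoutError("need at least one compound")
    if compounds_per_plate < 1 or replicates < 1 or controls_per_plate < 0:
        raise LayoutError("plate composition parameters must be positive")
    needed = replicates * compounds_per_plate + controls_per_plate
    if needed > plate_format:
        raise LayoutError(
            f"plate capacity exceeded: {compounds_per_plate} compounds x "
            f"{replicates} replicates + {controls_per_plate} controls = "
            f"{needed} wells > {plate_format}-well format"
        )
    if compound_ids is None:
        width = len(str(n_compounds))
        compound_ids = [f"CPD{str(i + 1).zfill(width)}" for i in range(n_compounds)]
    elif len(compound_ids) != n_compounds:
        raise LayoutError("compound_ids length must equal n_compounds")

    wells = well_names(plate_format)
    rng = substream(seed, "layout")
    records: list[tuple] = []
    n_plates = int(np.ceil(n_compounds / compounds_per_plate))
    for p in range(n_plates):
        plate_id = f"P{p + 1}"
        chunk = compound_ids[p * compounds_per_plate : (p + 1) * compounds_per_plate]
        n_used = len(chunk) * replicates + controls_per_plate
        order = rng.permutation(len(wells))
        used = [wells[i] for i in order[:n_used]]
        assignments: list[tuple[str, str, int | None]] = []
        k = 0
        for cpd in chunk:
            for rep in range(1, replicates + 1):
                assignments.append((ROLE_COMPOUND, cpd, rep))
                k += 1
        for _ in range(controls_per_plate):
            assignments.append((ROLE_CONTROL, "DMSO", None))
        empty_wells = [wells[i] for i in order[n_used:]]
        for sex in SEXES:
            for w, (role, cpd, rep) in zip(used, assignments):
                records.append((plate_id, w, role, cpd, rep, sex))
            for w in empty_wells:
                records.append((plate_id, w, ROLE_EMPTY, None, None, sex))

    layout = pd.DataFrame.from_records(records, columns=LAYOUT_COLUMNS)
    layout["replicate_index"] = layout["replicate_index"].astype("Int64")
    return layout


def validate_layout(layout: pd.DataFrame) -> None:
    """Check the structural invariants of a layout table.

    Wells must partition into compound/control/empty; every compound must
    appear on exactly one plate with a constant replicate count; wells must
    be unique within a (plate, sex).
    """
    missing = set(LAYOUT_COLUMNS) - set(layout.columns)
    if missing:
        raise LayoutError(f"layout missing columns: {sorted(missing)}")
    bad_roles = set(layout["role"]) - {ROLE_COMPOUND, ROLE_CONTROL, ROLE_EMPTY}
    if bad_roles:
        raise LayoutError(f"unknown roles: {sorted(bad_roles)}")
    dup = layout.duplicated(subset=["plate_id", "well", "sex"])
    if dup.any():
        raise LayoutError("duplicate (plate, well, sex) assignments")
    cpd = layout[layout["role"] == ROLE_COMPOUND]
    plates_per_cpd = cpd.groupby(["compound_id", "sex"])["plate_id"].nunique()
    if (plates_per_cpd != 1).any():
        split = plates_per_cpd[plates_per_cpd != 1].index.tolist()
        raise LayoutError(f"compounds split across plates: {split}")
    reps = cpd.groupby(["compound_id", "sex"]).size()
    if reps.nunique() != 1:
        raise LayoutError("unequal replicate counts across compounds")
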