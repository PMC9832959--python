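"""Workflow orchestration: the compound screen and the siRNA assay.

``run_screen`` chains the stages end to end — synthetic plate layout and
well counts (optionally rendered to images and re-measured by
segmentation), per-plate MAD statistics, hit calling, control-based FDR,
C1/C2/C3 categorisation, sex partition and kinase-family enrichment — and
writes a JSON report plus CSV artifacts.  ``run_sirna_assay`` runs the
gene-silencing variant: per-gene per-sex growth curves with per-timepoint
Welch tests and a knockdown-confirmation delta-delta-Ct table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import gtscreen
from gtscreen import simulate
from gtscreen import screen as scr
from gtscreen import stats as st
from gtscreen.config import RunConfig
from gtscreen.imaging import measure_plate
from gtscreen.simulate.layout import ROLE_COMPOUND

logger = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    config: dict
    config_hash: str
    plate_stats: pd.DataFrame
    compound_table: pd.DataFrame  # categorised; hits = direction != "none"
    venn: dict[str, set[str]]
    fdr: scr.ControlFdr
    enrichment: pd.DataFrame
    effects_truth: dict

    @property
    def hits(self) -> pd.DataFrame:
        return self.compound_table[self.compound_table["direction"] != "none"]


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default, sort_keys=True))
    json.loads(path.read_text())  # round-trip validation on write


def _measure_by_imaging(config: RunConfig, layout, counts, out: Path) -> pd.DataFrame:
    frames = []
    for sex in simulate.SEXES:
        sub = counts[counts["sex"] == sex]
        well_counts = {
            (r.plate_id, r.well): int(r.cell_count) for r in sub.itertuples(index=False)
        }
        img_dir = out / "images" / sex
        simulate.render_field_images(
            config.imaging, well_counts, seed=config.seed, out_dir=img_dir
        )
        seg = dataclasses.asdict(config.segmentation)
        measured, run_log = measure_plate(
            img_dir,
            layout[layout["sex"] == sex],
            fields_per_well=config.imaging.fields_per_well,
            **seg,
        )
        logger.info("imaging (%s): %s", sex, run_log)
        frames.append(measured)
    return pd.concat(frames, ignore_index=True)


def run_screen(config: RunConfig, out_dir: str | Path | None = None) -> ScreenReport:
    """Execute the compound-screen workflow and write its artifacts.

    With ``config.from_counts`` (default) the well table is simulated
    directly; otherwise nuclei fields are rendered to TIFF and re-measured
    by segmentation before hit calling.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    p = config.plate
    layout = simulate.generate_plate_layout(
        p.n_compounds,
        p.compounds_per_plate,
        p.replicates,
        p.controls_per_plate,
        p.plate_format,
        seed=config.seed,
    )
    simulate.validate_layout(layout)
    compound_ids = sorted(
        layout.loc[layout["role"] == ROLE_COMPOUND, "compound_id"].unique()
    )
    e = config.effects
    effects = simulate.make_effect_map(
        compound_ids,
        n_hypo=e.n_hypo,
        effect_hypo=e.effect_hypo,
        n_hyper=e.n_hyper,
        effect_hyper=e.effect_hyper,
        shrinkage_fraction=e.shrinkage_fraction,
        shrinkage_shift=e.shrinkage_shift,
        seed=config.seed,
    )
    counts = simulate.simulate_screen_counts(
        layout, effects, config.growth, days=config.days, seed=config.seed
    )
    measurements = (
        counts if config.from_counts else _measure_by_imaging(config, layout, counts, out)
    )

    compound_table, plate_stats = scr.call_hits(
        measurements,
        layout,
        k=config.k,
        include_controls=config.include_controls_in_stats,
        inclusive=config.inclusive,
    )
    size_stats = scr.plate_count_stats(
        measurements,
        layout,
        include_controls=config.include_controls_in_stats,
        value="mean_nuclear_area",
    )
    compound_table = scr.categorize_hits(compound_table, size_stats, size_k=config.size_k)
    fdr = scr.control_fdr(
        measurements,
        layout,
        k=config.k,
        include_controls=config.include_controls_in_stats,
        inclusive=config.inclusive,
    )
    hits = compound_table[compound_table["direction"] != "none"]
    venn = scr.venn_partition(
        hits.loc[hits["sex"] == "male", "compound_id"],
        hits.loc[hits["sex"] == "female", "compound_id"],
    )
    annotation = {c: eff.family for c, eff in effects.items()}
    hit_compounds = set(hits["compound_id"])
    enrichment = scr.family_enrichment(hit_compounds, annotation)

    layout.to_csv(out / "layout.csv", index=False)
    measurements.to_csv(out / "measurements.csv", index=False)
    plate_stats.to_csv(out / "plate_stats.csv", index=False)
    compound_table.to_csv(out / "compound_table.csv", index=False)
    hits.to_csv(out / "hits.csv", index=False)
    enrichment.to_csv(out / "enrichment.csv", index=False)

    effects_truth = {
        c: dataclasses.asdict(eff) for c, eff in effects.items() if eff.effect_male != 1.0
    }
    report_payload = {
        "gtscreen_version": gtscreen.__version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "thresholds": {
            "k": config.k,
            "size_k": config.size_k,
            "band": "inclusive (k MAD or more)" if config.inclusive else "strict (beyond k MAD)",
            "plate_statistics_include_controls": config.include_controls_in_stats,
            "mad_scaling": "raw (no normal-consistency factor)",
        },
        "plate_stats": plate_stats.to_dict(orient="records"),
        "n_hit_compounds": len(hit_compounds),
        "venn": {k: sorted(v) for k, v in venn.items()},
        "venn_sizes": {k: len(v) for k, v in venn.items()},
        "fdr": dataclasses.asdict(fdr),
        "category_counts": hits["category"].value_counts().to_dict(),
        "enrichment": enrichment.to_dict(orient="records"),
        "planted_effects": effects_truth,
    }
    _write_json(out / "report.json", report_payload)

    return ScreenReport(
        config=config.to_dict(),
        config_hash=config.hash(),
        plate_stats=plate_stats,
        compound_table=compound_table,
        venn=venn,
        fdr=fdr,
        enrichment=enrichment,
        effects_truth=effects_truth,
    )


def run_sirna_assay(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the gene-silencing workflow.

    For each target gene, growth of siRNA-treated vs mock-transfected
    cultures is simulated per sex (silencing acts as a multiplicative
    factor on the sex growth rate), compared timepoint-by-timepoint with
    Welch tests, and the knockdown is confirmed by a delta-delta-Ct table
    against mock.  Returns the report payload (also written to disk).
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    s = config.sirna
    growth = dataclasses.replace(
        config.growth,
        modulators={
            **{k: dict(v) for k, v in config.growth.modulators.items()},
            **{f"si{g}": dict(fx) for g, fx in s.genes.items()},
        },
    )
    timepoints = list(s.timepoints)
    gene_reports = {}
    test_frames = []
    for gene, fx in s.genes.items():
        per_sex = {}
        for sex in simulate.SEXES:
            curves = simulate.simulate_growth_course(
                [(sex, ()), (sex, (f"si{gene}",))],
                timepoints,
                growth,
                replicates=s.replicates,
                seed=config.seed,
            )
            mock, silenced = curves
            tests = st.compare_growth_curves(silenced, mock)
            tests.insert(0, "gene", gene)
            tests.insert(1, "sex", sex)
            test_frames.append(tests)
            per_sex[sex] = {
                "rate_factor": fx.get(sex, 1.0),
                "final_day_p": float(tests["p"].iloc[-1]),
                "final_day_significant": bool(tests["sig_05"].iloc[-1]),
            }
        gene_reports[gene] = per_sex

    genes = list(s.genes)
    ct = simulate.simulate_qpcr(
        genes,
        {g: s.knockdown_fold for g in genes},
        noise_sd=s.qpcr_noise_sd,
        replicates=s.replicates,
        seed=config.seed,
        calibrator_group="mock",
        treated_group="siRNA",
    )
    per_sample, summary = st.delta_delta_ct(ct, calibrator_group="mock")

    tests_table = pd.concat(test_frames, ignore_index=True)
    tests_table.to_csv(out / "sirna_growth_tests.csv", index=False)
    ct.to_csv(out / "sirna_qpcr_ct.csv", index=False)
    summary.to_csv(out / "sirna_knockdown_folds.csv", index=False)

    payload = {
        "gtscreen_version": gtscreen.__version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "multiple_testing_correction": "none (single readouts per timepoint)",
        "genes": gene_reports,
        "knockdown_folds": summary.to_dict(orient="records"),
        "growth_tests": tests_table.to_dict(orient="records"),
    }
    _write_json(out / "sirna_report.json", payload)
    return payload
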