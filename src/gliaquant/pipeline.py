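"""End-to-end per-field measurement: segmentation -> morphometry -> assays.

`measure_field` runs the whole per-field pipeline and returns a per-cell
table (one row per nucleated microglial cell) and a per-field summary row
with the counts, fractions and intensities the experiment reports.
`measure_experiment` maps it over a collection of fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from . import assays, morphometry, segmentation
from .config import ExperimentConfig
from .synthetic import FieldImage

__all__ = ["measure_field", "measure_experiment", "FIELD_METRICS"]

#: per-field summary columns carrying assay results (identifiers excluded)
FIELD_METRICS = [
    "total_nuclei",
    "cd45_cells",
    "pu1_positive_nuclei",
    "proliferation_fraction",
    "phagocytic_fraction",
    "hla_fraction",
    "cebpb_fraction",
    "mean_eff",
    "mean_shape_factor",
    "intensity_pu1",
    "intensity_cebpb",
    "intensity_hla",
    "intensity_dap12",
    "intensity_csf1r",
    "intensity_igf1r",
]


def _foreground_mask(nuclei, cells, dilate: int = 3) -> np.ndarray:
    fg = (nuclei.labels > 0) | (cells.labels > 0)
    if dilate:
        fg = ndimage.binary_dilation(fg, iterations=dilate)
    return fg


def measure_field(
    field: FieldImage, cfg: ExperimentConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Measure one field; returns (per-cell table, per-field summary row).

    Microglia are surface-marker cells owning at least one nucleus.  Marker
    channels present in the field but absent from the configuration are
    ignored; configured channels missing from the field yield NaN summary
    entries rather than errors, so partial acquisitions remain usable.
    """
    cfg = cfg or ExperimentConfig()
    nuclei = segmentation.segment_nuclei(
        field,
        min_area=cfg.nucleus_min_area,
        max_area=cfg.nucleus_max_area,
        seed_min_distance=cfg.nucleus_seed_min_distance,
        channel_role=cfg.nuclei_channel,
    )
    cells = segmentation.segment_microglia(
        field, min_area=cfg.cell_min_area, channel_role=cfg.surface_channel
    )
    assignment = segmentation.assign_nuclei_to_cells(nuclei, cells)
    fg_mask = _foreground_mask(nuclei, cells)

    assigned = assignment.assigned
    cell_ids = assigned.cell_id.to_numpy()

    # morphometry of nucleated cells only, border labels excluded
    morpho = {
        m.cell_id: m
        for m in morphometry.measure_cells(
            cells.labels,
            eff_definition=cfg.eff_definition,
            perimeter_method=cfg.perimeter_method,
        )
    }

    records = pd.DataFrame(
        {
            "field_id": field.field_id,
            "well_id": field.well_id,
            "case_id": field.case_id,
            "condition": field.condition,
            "cell_id": cell_ids,
            "nucleus_id": assigned.nucleus_id.to_numpy(),
        }
    )
    for col, attr in [
        ("area", "area"),
        ("perimeter", "perimeter"),
        ("shape_factor", "shape_factor"),
        ("eff", "elliptical_form_factor"),
    ]:
        records[col] = [
            getattr(morpho[c], attr) if c in morpho else np.nan for c in cell_ids
        ]

    summary: dict = {
        "field_id": field.field_id,
        "well_id": field.well_id,
        "case_id": field.case_id,
        "condition": field.condition,
    }

    # marker positivity and intensities
    pu1_nuclei = None
    marker_frac_cols = {"ki67": "proliferation_fraction", "hla": "hla_fraction",
                        "cebpb": "cebpb_fraction"}
    for marker in cfg.marker_channels:
        if marker not in field.channels:
            for target in ([marker_frac_cols[marker]] if marker in marker_frac_cols else []):
                summary[target] = np.nan
            summary[f"intensity_{marker}"] = np.nan
            continue
        channel = field.channel(marker).astype(np.float64)
        background = segmentation.estimate_background(channel, fg_mask)
        rule = cfg.rule_for(marker)
        calls = assays.classify_marker(
            channel, cells, nuclei, assignment, rule, background
        )
        records[f"{marker}_score"] = calls.score.to_numpy()
        records[f"{marker}_positive"] = calls.positive.to_numpy()
        if marker == "pu1":
            pu1_nuclei = assays.classify_nuclei(
                channel, nuclei, rule, background
            )
        if marker in marker_frac_cols:
            summary[marker_frac_cols[marker]] = assays._fraction(calls.positive)
        # intensity: nuclear markers over the nucleus, cell markers over body
        if rule.compartment == "nucleus":
            labels, ids = nuclei.labels, assigned.nucleus_id.to_numpy()
        else:
            labels, ids = cells.labels, cell_ids
        positive = None if cfg.is_constitutive(marker) else calls.positive.to_numpy()
        table, field_mean = assays.marker_intensity(
            channel, labels, ids, background, positive
        )
        records[f"{marker}_intensity"] = table.intensity.to_numpy()
        summary[f"intensity_{marker}"] = field_mean

    # phagocytosis
    if cfg.cargo_channel in field.channels:
        channel = field.channel(cfg.cargo_channel).astype(np.float64)
        background = segmentation.estimate_background(channel, fg_mask)
        rule = assays.PositivityRule(
            marker="cargo", compartment="cell", k=cfg.positivity_k,
            min_area_fraction=cfg.cargo_min_area_fraction,
        )
        phago_frac, cargo_table = assays.phagocytosis_fraction(
            channel, cells, assignment, rule, background
        )
        records["cargo_area_fraction"] = cargo_table.cargo_area_fraction.to_numpy()
        records["phagocytic"] = cargo_table.positive.to_numpy()
        summary["phagocytic_fraction"] = phago_frac
    else:
        summary["phagocytic_fraction"] = np.nan

    counts = assays.count_microglia(nuclei, cells, assignment, pu1_nuclei)
    summary.update(counts)
    measured = records.dropna(subset=["eff"]) if len(records) else records
    summary["mean_eff"] = float(measured.eff.mean()) if len(measured) else np.nan
    summary["mean_shape_factor"] = (
        float(measured.shape_factor.mean()) if len(measured) else np.nan
    )
    return records, summary


def measure_experiment(
    fields: list[FieldImage], cfg: ExperimentConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure many fields into one per-cell and one per-field table."""
    cfg = cfg or ExperimentConfig()
    cell_tables = []
    summaries = []
    for field in fields:
        records, summary = measure_field(field, cfg)
        cell_tables.append(records)
        summaries.append(summary)
    per_cell = (
        pd.concat(cell_tables, ignore_index=True) if cell_tables else pd.DataFrame()
    )
    per_field = pd.DataFrame(summaries)
    return per_cell, per_field
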