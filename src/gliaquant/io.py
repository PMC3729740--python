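"""File formats: 16-bit grayscale TIFF per channel, flat CSV tables, YAML.

A fixture set on disk is::

    out_dir/
      config.yaml        # generation parameters echoed for provenance
      layout.csv         # field_id, well_id, case_id, condition, channel paths
      ground_truth.csv   # one row per simulated cell, all fields
      images/{well}_{field}_{role}.tif

Every writer has a matching reader; images round-trip bit-exactly and
tables value-exactly (comma-separated, UTF-8, header row, '.' decimal).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import CultureParams, FieldImage

__all__ = [
    "read_field",
    "read_fixture_set",
    "read_image",
    "write_fixture_set",
    "write_image",
    "write_labels",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint16:
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.clip(np.rint(arr), 0, 65535)
        arr = arr.astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Labeled masks as 16-bit TIFF (errors above 65535 objects)."""
    labels = np.asarray(labels)
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def _params_echo(params: CultureParams | dict) -> dict:
    if isinstance(params, CultureParams):
        d = dataclasses.asdict(params)
    else:
        d = dict(params)
    return d


def write_fixture_set(
    out_dir: str | Path,
    fields: list[tuple[FieldImage, pd.DataFrame]],
    layout: pd.DataFrame,
    params: CultureParams | dict | None = None,
) -> Path:
    """Write rendered fields, ground truth and layout as a file tree."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    layout = layout.copy()
    channel_roles: list[str] = []
    truths = []
    for fimg, truth in fields:
        if fimg is None:
            raise ValueError("cannot write a fixture set from unrendered fields")
        for role, img in fimg.channels.items():
            if role not in channel_roles:
                channel_roles.append(role)
            name = f"{fimg.well_id or 'well'}_{fimg.field_id}_{role}.tif"
            write_image(out / "images" / name, img)
            layout.loc[layout.field_id == fimg.field_id, f"file_{role}"] = (
                f"images/{name}"
            )
        truths.append(truth)
    truth_all = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    truth_all.to_csv(out / "ground_truth.csv", index=False)
    layout.to_csv(out / "layout.csv", index=False)
    echo = {"schema_version": 1, "channel_roles": channel_roles}
    if params is not None:
        echo["generation_params"] = _params_echo(params)
    (out / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return out


def read_field(base: Path, row: pd.Series) -> FieldImage:
    channels = {}
    for col in row.index:
        if col.startswith("file_") and isinstance(row[col], str):
            channels[col[len("file_") :]] = read_image(base / row[col])
    if not channels:
        raise ValueError(f"layout row for field {row.get('field_id')} lists no files")
    return FieldImage(
        channels=channels,
        field_id=str(row.get("field_id", "")),
        well_id=str(row.get("well_id", "")),
        case_id=str(row.get("case_id", "")),
        condition=str(row.get("condition", "")),
    )


def read_fixture_set(
    in_dir: str | Path,
) -> tuple[list[FieldImage], pd.DataFrame, pd.DataFrame | None]:
    """Read a fixture tree back: (fields, layout, ground truth or None)."""
    base = Path(in_dir)
    layout_path = base / "layout.csv"
    if not layout_path.exists():
        raise FileNotFoundError(f"no layout.csv under {base}")
    layout = pd.read_csv(layout_path)
    fields = [read_field(base, row) for _, row in layout.iterrows()]
    truth_path = base / "ground_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return fields, layout, truth
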