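"""Drug descriptor tables and random-subset view masks.

Drugs are represented by externally computed 1D/2D molecular descriptors
(1444 numeric columns per molecule in the default geometry; the width is
configurable so small synthetic runs can shrink it).  This module never
computes descriptors from structures — it reads, validates and cleans the
CSV the external calculator produces.

Cleaning is fit on training rows only and re-applied verbatim to held-out
rows: missing cells are imputed with the training-column median (0 when a
column is entirely missing on training rows), then each column is min-max
scaled to [0, 1] with training statistics; constant columns map to 0.
Held-out values outside the training range are NOT clipped, so a scaled
value may fall outside [0, 1] — this is recorded in the cleaning report.

An augmented "view" of the data is defined by a DescriptorMask: a seeded
uniform sample of subset_size (default 342) distinct columns.  Masks are
drawn once per experiment and shared by every drug-target pair, so column
k of view j means the same descriptor for every sample at train and
predict time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DescriptorFormatError(ValueError):
    """Raised when a descriptor CSV does not match the configured contract."""


@dataclass
class DrugDescriptorTable:
    """A drugs x width numeric descriptor matrix with cleaning bookkeeping."""

    drug_ids: list[str]
    column_names: list[str]
    values: np.ndarray  # may contain NaN before cleaning
    cleaning_report: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.drug_ids.index(drug_id)]

    def row_map(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drug_ids)}


@dataclass(frozen=True)
class DescriptorMask:
    """One augmented view: a seeded selection of subset_size descriptor columns."""

    view_index: int
    column_indices: np.ndarray  # sorted, distinct, in [0, width)
    seed: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.column_indices)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("mask indices must be distinct")
        if not np.all(np.diff(idx) > 0):
            raise ValueError("mask indices must be sorted ascending")

    def __len__(self) -> int:
        return len(self.column_indices)

    def apply(self, rows: np.ndarray) -> np.ndarray:
        """Select the masked columns from a row or matrix of descriptor values."""
        return rows[..., self.column_indices]


def load_descriptor_table(path_or_buffer, expected_width: int = 1444) -> DrugDescriptorTable:
    """Read a descriptor CSV: identifier column first (typically "Name"),
    then ``expected_width`` numeric columns.  Non-numeric cells become NaN
    and are reported; cleaning happens separately in :func:`clean_table`."""
    df = pd.read_csv(path_or_buffer, dtype=str)
    if df.shape[1] != expected_width + 1:
        raise DescriptorFormatError(
            f"expected {expected_width} descriptor columns, found {df.shape[1] - 1}"
        )
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise DescriptorFormatError(f"duplicate drug ids: {dupes}")
    numeric = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    values = numeric.to_numpy(dtype=float)
    values[~np.isfinite(values)] = np.nan
    n_missing = int(np.isnan(values).sum())
    report = {
        "n_drugs": len(ids),
        "width": expected_width,
        "missing_cells": n_missing,
        "cleaned": False,
    }
    return DrugDescriptorTable(ids, list(df.columns[1:]), values, report)


def clean_table(table: DrugDescriptorTable, train_ids: list[str]) -> DrugDescriptorTable:
    """Impute and min-max scale using statistics from training rows only.

    Idempotent: cleaning an already-clean table with the same training rows
    leaves it unchanged (a [0,1]-scaled column rescales to itself).
    """
    rows = table.row_map()
    unknown = [d for d in train_ids if d not in rows]
    if unknown:
        raise DescriptorFormatError(f"train ids not in table: {unknown[:5]}")
    train_idx = np.array([rows[d] for d in train_ids], dtype=int)

    values = table.values.copy()
    train = values[train_idx]
    with np.errstate(all="ignore"):
        medians = np.nanmedian(train, axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)  # all-missing column rule
    nan_mask = np.isnan(values)
    values[nan_mask] = np.take(medians, np.nonzero(nan_mask)[1])

    train = values[train_idx]
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (values - lo) / safe_span
    scaled[:, constant] = 0.0

    out_of_range = int(((scaled < 0) | (scaled > 1)).sum())
    report = dict(table.cleaning_report)
    report.update(
        {
            "cleaned": True,
            "train_ids": list(train_ids),
            "imputed_cells": int(nan_mask.sum()),
            "impute_medians": medians,
            "scale_min": lo,
            "scale_span": safe_span,
            "constant_columns": int(constant.sum()),
            "out_of_range_scaled_cells": out_of_range,
        }
    )
    return DrugDescriptorTable(list(table.drug_ids), list(table.column_names), scaled, report)


def draw_masks(
    n_views: int,
    subset_size: int = 342,
    width: int = 1444,
    seed: int = 0,
) -> list[DescriptorMask]:
    """Draw ``n_views`` seeded masks, each a uniform sample (without
    replacement) of ``subset_size`` distinct columns out of ``width``.

    Mask j is reproducible from (seed, j): each view uses its own child
    generator so inserting or removing views never reshuffles the others.
    """
    if subset_size > width:
        raise ValueError(f"subset_size {subset_size} exceeds width {width}")
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    masks = []
    for j in range(1, n_views + 1):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(j,)))
        cols = np.sort(rng.choice(width, size=subset_size, replace=False))
        masks.append(DescriptorMask(view_index=j, column_indices=cols, seed=seed))
    return masks


def write_mask_manifest(masks: list[DescriptorMask], path) -> None:
    """Persist masks as JSON so a prediction run can rebuild the exact views."""
    payload = {
        "seed": masks[0].seed if masks else None,
        "n_views": len(masks),
        "masks": [
            {"view_index": m.view_index, "column_indices": m.column_indices.tolist()}
            for m in masks
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_mask_manifest(path) -> list[DescriptorMask]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        DescriptorMask(
            view_index=m["view_index"],
            column_indices=np.array(m["column_indices"], dtype=int),
            seed=payload["seed"],
        )
        for m in payload["masks"]
    ]
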