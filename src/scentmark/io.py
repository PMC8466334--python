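"""Tabular input/output for the scent-mark pipeline.

Three comma-separated, UTF-8 files describe one dataset:

* ``areas.csv`` — samples (rows) × compounds (columns), non-negative
  integrated peak areas in arbitrary units;
* ``samples.csv`` — columns ``sample_id``, ``nest_id``, ``source``;
* ``compounds.csv`` — columns ``name``, ``compound_class``, ``chain_length``,
  ``db_position``, ``kovats``.

Alignment between the files is by identifier, never by row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COMPOUND_CLASSES = frozenset(
    {"alkane", "alkene", "ester", "aldehyde", "alcohol", "methyl_branched"})

SAMPLE_SOURCES = frozenset(
    {"mark1", "mark2", "head", "gland", "control_sleeve", "blank"})

#: Sources that are per-bee samples (subject to the one-sample-per-source rule).
BEE_SOURCES = frozenset({"mark1", "mark2", "head", "gland"})

MARK_SOURCES = frozenset({"mark1", "mark2"})
CONTROL_SOURCES = frozenset({"control_sleeve", "blank"})

#: shortest-exact float formatting: written areas read back bit-identical
_FLOAT_FMT = "%.17g"


class PeakTableError(ValueError):
    """Raised when a peak table or its on-disk representation is invalid."""


@dataclass
class PeakTable:
    """Samples × compounds peak-area matrix with aligned metadata.

    areas
        DataFrame indexed by ``sample_id``, columns are compound names.
    sample_meta
        DataFrame indexed by ``sample_id`` with columns ``nest_id``,
        ``source``.
    annotations
        DataFrame indexed by compound ``name`` with columns
        ``compound_class``, ``chain_length``, ``db_position``, ``kovats``.
    """

    areas: pd.DataFrame
    sample_meta: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        areas, meta, annot = self.areas, self.sample_meta, self.annotations
        dup = areas.index[areas.index.duplicated()].unique().tolist()
        if dup:
            raise PeakTableError(f"duplicate sample IDs: {dup}")
        dup = areas.columns[areas.columns.duplicated()].unique().tolist()
        if dup:
            raise PeakTableError(f"duplicate compound names: {dup}")
        missing = areas.index.difference(meta.index).tolist()
        if missing:
            raise PeakTableError(
                f"samples missing from metadata: {missing}")
        extra = meta.index.difference(areas.index).tolist()
        if extra:
            raise PeakTableError(
                f"metadata samples absent from area table: {extra}")
        missing = areas.columns.difference(annot.index).tolist()
        if missing:
            raise PeakTableError(
                f"compounds missing from annotations: {missing}")
        extra = annot.index.difference(areas.columns).tolist()
        if extra:
            raise PeakTableError(
                f"annotated compounds absent from area table: {extra}")

        vals = areas.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PeakTableError(
                f"invalid area at sample {areas.index[i]!r}, "
                f"compound {areas.columns[j]!r}: {vals[i, j]!r} "
                "(areas must be finite and >= 0)")

        bad_src = sorted(set(meta["source"]) - SAMPLE_SOURCES)
        if bad_src:
            raise PeakTableError(f"unknown sample sources: {bad_src}")
        bad_kov = annot.index[annot["kovats"] <= 0].tolist()
        if bad_kov:
            raise PeakTableError(f"non-positive Kovats index for: {bad_kov}")

        bee = meta[meta["source"].isin(BEE_SOURCES)]
        dup_pairs = bee[bee.duplicated(subset=["nest_id", "source"], keep=False)]
        if len(dup_pairs):
            pairs = sorted(set(map(tuple, dup_pairs[["nest_id", "source"]].values)))
            raise PeakTableError(
                f"more than one sample per (nest, source): {pairs}")

        # canonical order: metadata/annotations follow the area matrix
        self.sample_meta = meta.loc[areas.index]
        self.annotations = annot.loc[areas.columns]

    # -- convenience ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.areas.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.areas.shape[1]

    def samples_with_source(self, sources) -> list[str]:
        mask = self.sample_meta["source"].isin(set(sources))
        return self.sample_meta.index[mask].tolist()

    def subset(self, samples=None, compounds=None) -> "PeakTable":
        """Return a new PeakTable restricted to the given IDs (order kept)."""
        samples = list(samples) if samples is not None else list(self.areas.index)
        compounds = (list(compounds) if compounds is not None
                     else list(self.areas.columns))
        return PeakTable(self.areas.loc[samples, compounds].copy(),
                         self.sample_meta.loc[samples].copy(),
                         self.annotations.loc[compounds].copy())

    def nest_of(self, sample_id: str) -> str:
        return str(self.sample_meta.at[sample_id, "nest_id"])


def read_peak_table(areas_path, meta_path, annot_path) -> PeakTable:
    """Read and validate the three pipeline CSVs.

    Raises :class:`PeakTableError` naming the offending identifiers or cell
    on any inconsistency (missing/duplicate IDs, negative or non-numeric
    areas, misaligned files).
    """
    areas_raw = pd.read_csv(areas_path, index_col=0)
    areas_raw.index = areas_raw.index.astype(str)
    for col in areas_raw.columns:
        coerced = pd.to_numeric(areas_raw[col], errors="coerce")
        bad = coerced.isna() & areas_raw[col].notna()
        if bad.any():
            sample = areas_raw.index[bad.to_numpy().argmax()]
            raise PeakTableError(
                f"non-numeric area at sample {sample!r}, compound {col!r}: "
                f"{areas_raw.loc[sample, col]!r}")
        if coerced.isna().any():
            sample = areas_raw.index[coerced.isna().to_numpy().argmax()]
            raise PeakTableError(
                f"missing area at sample {sample!r}, compound {col!r}")
        areas_raw[col] = coerced
    meta = pd.read_csv(meta_path, dtype=str)
    if "sample_id" not in meta.columns:
        raise PeakTableError(f"{meta_path}: missing 'sample_id' column")
    meta = meta.set_index("sample_id")
    annot = pd.read_csv(annot_path)
    if "name" not in annot.columns:
        raise PeakTableError(f"{annot_path}: missing 'name' column")
    annot["name"] = annot["name"].astype(str)
    annot = annot.set_index("name")
    if "db_position" in annot.columns:
        annot["db_position"] = annot["db_position"].astype("Int64")
    return PeakTable(areas_raw, meta, annot)


def write_peak_table(table: PeakTable, out_dir) -> dict[str, Path]:
    """Write ``areas.csv``, ``samples.csv`` and ``compounds.csv``.

    Output is byte-stable for a given table (fixed 17-significant-digit
    float formatting, so values survive a write/read cycle exactly; fixed
    row/column order).
    """
    if table.n_compounds == 0:
        raise PeakTableError("peak table has no compounds; nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "areas": out_dir / "areas.csv",
        "samples": out_dir / "samples.csv",
        "compounds": out_dir / "compounds.csv",
    }
    table.areas.to_csv(paths["areas"], float_format=_FLOAT_FMT,
                       index_label="sample_id")
    table.sample_meta.to_csv(paths["samples"], index_label="sample_id")
    table.annotations.to_csv(paths["compounds"], float_format=_FLOAT_FMT,
                             index_label="name")
    return paths
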