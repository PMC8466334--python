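"""Substance filtering and compositional preprocessing.

The analysis retains only compounds that are present in every sample of the
analysis set and that are not attributable to ambient/paper background (as
judged against control sleeves and solvent blanks), screens for
individual-specific "private" substances, and then maps peak areas into a
space where relative, not absolute, amounts carry the signal:

1. **quantile normalization** — every sample is forced onto the common
   distribution of mean order statistics, removing per-sample intensity
   bias (body size, extraction yield);
2. **centered log-ratio (clr)** — per sample ``clr(y_i) = ln(y_i / g(y))``
   with ``g`` the geometric mean, the standard transform for compositional
   data; rows sum to zero and the transform is invariant to per-sample
   rescaling.

The fixed order is filter → quantile normalize → clr: filtering guarantees
the strict positivity that clr requires, so no pseudo-count is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTROL_SOURCES, PeakTable


class PreprocessingError(ValueError):
    pass


@dataclass
class FilterReport:
    """Outcome of the substance-retention screen."""

    retained: list[str]
    dropped_absent: list[str]
    dropped_background: list[str]
    #: per-compound (control mean, analysis mean) for the background screen
    background_log: dict[str, tuple[float, float]]
    analysis_sources: frozenset[str]
    presence_threshold: float
    private: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "dropped_absent": self.dropped_absent,
            "dropped_background": self.dropped_background,
            "background_log": {k: list(v) for k, v in self.background_log.items()},
            "analysis_sources": sorted(self.analysis_sources),
            "presence_threshold": self.presence_threshold,
            "private": self.private,
        }


def filter_substances(table: PeakTable, analysis_sources,
                      presence_threshold: float = 0.0) -> FilterReport:
    """Retain compounds present in all analysis samples and not background.

    A compound is retained iff its area exceeds ``presence_threshold`` in
    *every* sample whose source is in ``analysis_sources``, and its mean
    area over control sleeves / blanks is smaller than its mean area over
    the analysis samples (otherwise it is classified as ambient or paper
    background).  Every dropped compound is listed with its reason.
    """
    analysis_sources = frozenset(analysis_sources)
    if not analysis_sources:
        raise PreprocessingError("analysis_sources must be non-empty")
    if presence_threshold < 0:
        raise PreprocessingError("presence_threshold must be non-negative")

    analysis_ids = table.samples_with_source(analysis_sources)
    if not analysis_ids:
        raise PreprocessingError(
            f"no samples with source in {sorted(analysis_sources)}")
    control_ids = table.samples_with_source(CONTROL_SOURCES)

    analysis = table.areas.loc[analysis_ids]
    present_everywhere = (analysis > presence_threshold).all(axis=0)

    dropped_absent = analysis.columns[~present_everywhere].tolist()

    background_log: dict[str, tuple[float, float]] = {}
    dropped_background: list[str] = []
    if control_ids:
        control_mean = table.areas.loc[control_ids].mean(axis=0)
        analysis_mean = analysis.mean(axis=0)
        for name in analysis.columns[present_everywhere]:
            cm, am = float(control_mean[name]), float(analysis_mean[name])
            background_log[name] = (cm, am)
            if cm >= am:
                dropped_background.append(name)

    retained = [c for c in analysis.columns
                if present_everywhere[c] and c not in dropped_background]
    if not retained:
        raise PreprocessingError(
            "all compounds were dropped by the presence/background screen; "
            "the dataset is unusable for this analysis set")
    return FilterReport(retained, dropped_absent, dropped_background,
                        background_log, analysis_sources,
                        float(presence_threshold))


def detect_private_substances(table: PeakTable,
                              filter_report: FilterReport) -> dict[str, list[str]]:
    """Find compounds detected in exactly one bee's samples.

    A compound is private to bee ``b`` iff its area exceeds the report's
    presence threshold in at least one of b's samples and in no sample of
    any other bee.  Background compounds (control-sleeve attributable) are
    excluded.  With a single bee in the table, every present compound is by
    definition private to it — a documented degenerate case.

    The result is also stored on ``filter_report.private``.
    """
    thr = filter_report.presence_threshold
    meta = table.sample_meta
    bee_mask = ~meta["source"].isin(CONTROL_SOURCES)
    candidates = [c for c in table.areas.columns
                  if c not in filter_report.dropped_background]

    present = table.areas.loc[bee_mask.index[bee_mask], candidates] > thr
    nest = meta.loc[present.index, "nest_id"]
    # per-bee presence (any sample of that bee)
    by_bee = present.groupby(nest).any()

    private: dict[str, list[str]] = {}
    n_bees_with = by_bee.sum(axis=0)
    for compound in candidates:
        if n_bees_with[compound] == 1:
            bee = by_bee.index[by_bee[compound]][0]
            private.setdefault(str(bee), []).append(compound)
    filter_report.private = private
    return private


def quantile_normalize(matrix):
    """Force every sample (row) onto the common mean-order-statistic scale.

    The reference distribution is the rank-wise mean of the sorted rows;
    each value is replaced by the reference value at its within-row rank.
    Ties within a row receive the mean of the reference values at the tied
    ranks.  Accepts a DataFrame or ndarray; returns the same type.
    """
    df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if df else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise PreprocessingError("expected a 2-D samples × compounds matrix")
    n, p = X.shape
    if n < 2:
        raise PreprocessingError(
            "quantile normalization needs at least 2 samples")
    if not np.isfinite(X).all():
        raise PreprocessingError("matrix contains non-finite values")

    reference = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n):
        order = np.argsort(X[i], kind="stable")
        row = np.empty(p)
        row[order] = reference
        # average reference values over tied observations
        uniq, inv = np.unique(X[i], return_inverse=True)
        if uniq.size < p:
            sums = np.bincount(inv, weights=row)
            counts = np.bincount(inv)
            row = (sums / counts)[inv]
        out[i] = row
    if df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def clr_transform(matrix):
    """Centered log-ratio transform, row-wise.

    ``clr(y)_i = ln(y_i) − mean_k ln(y_k)``.  Every value must be strictly
    positive — zeros are a filtering failure upstream, and no pseudo-count
    is silently applied.  Accepts a DataFrame or ndarray; returns the same
    type.  Output rows sum to zero (within 1e-9).
    """
    df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if df else np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    bad = ~(X > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        if df:
            where = (f"sample {matrix.index[i]!r}, "
                     f"compound {matrix.columns[j]!r}")
        else:
            where = f"row {i}, column {j}"
        raise PreprocessingError(
            f"clr requires strictly positive values; found {X[i, j]!r} at "
            f"{where} (zeros must be removed by substance filtering)")
    logs = np.log(X)
    out = logs - logs.mean(axis=1, keepdims=True)
    if df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    if np.asarray(matrix).ndim == 1:
        return out[0]
    return out
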