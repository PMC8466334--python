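"""Attribution of nest-mark compounds to their glandular/cuticular sources.

Nest marks blend Dufour's gland secretion, cuticular/head-gland material
rubbed off the body surface, and exogenous volatiles from the nest cavity
and flower visits.  This module reconstructs the bee-derived share of a
mark in three screens plus an estimation step:

1. **Kovats band** (`dufour_band_selection`): over compounds quantified in
   both marks and gland extracts, the log quotient of mark to gland mean
   areas is regressed on the Kovats retention index (a volatility proxy).
   Compounds scattered around the slowly ascending line are gland-derived;
   compounds far off the band were enriched in marks by other sources and
   are removed from the gland-related tag analysis.
2. **Exogenous enrichment** (`exogenous_filter`): a compound more than
   two-fold enriched in marks relative to the *sum* of the head and gland
   means is judged externally sourced and discarded.
3. **Contribution factors** (`contribution_factors`): for retained
   compounds the ratio of the larger to the smaller bee-source mean decides
   whether both sources contribute (ratio ≤ 2 → factors (1,1)) or only the
   dominant one (factor 1 for it, 0 for the other).
4. **Bouquet estimation** (`estimate_bee_bouquet`): per bee, the factors
   are applied to the normalized head and gland values and summed per
   compound, yielding the estimated individual total-bee bouquet.

All means are taken over quantile-normalized samples rescaled to a common
total within the compound universe (total-sum scaling), so only relative
amounts enter the screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import MARK_SOURCES, PeakTable
from .preprocessing import quantile_normalize


class AttributionError(ValueError):
    pass


@dataclass
class BandFit:
    """OLS fit of ln(mark/gland mean) on Kovats index, with the retention
    verdict per compound (|studentized residual| ≤ band_k)."""

    retained: set[str]
    eliminated: set[str]
    slope: float
    intercept: float
    residual_sd: float
    band_k: float
    studentized: dict[str, float]


@dataclass
class AttributionModel:
    dufour_retained: set[str]
    exogenous_discarded: set[str]
    #: compound → (factor_head, factor_gland); proportional case = (1, 1)
    contribution: dict[str, tuple[int, int]]
    band_fit: BandFit | None
    #: compound → max/min of head vs gland mean (≥ 1)
    source_ratio: dict[str, float]
    discard_reasons: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dufour_retained": sorted(self.dufour_retained),
            "exogenous_discarded": sorted(self.exogenous_discarded),
            "contribution": {k: list(v) for k, v in self.contribution.items()},
            "band_fit": None if self.band_fit is None else {
                "slope": self.band_fit.slope,
                "intercept": self.band_fit.intercept,
                "residual_sd": self.band_fit.residual_sd,
                "band_k": self.band_fit.band_k,
                "eliminated": sorted(self.band_fit.eliminated),
            },
            "source_ratio": self.source_ratio,
            "discard_reasons": self.discard_reasons,
        }


@dataclass
class BeeBouquet:
    bee_id: str
    values: dict[str, float]


def total_sum_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale every row to unit total (relative peak areas)."""
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise AttributionError(f"samples with non-positive total area: {bad}")
    return matrix.div(totals, axis=0)


def source_means(table: PeakTable, compounds, normalize: bool = True
                 ) -> dict[str, pd.Series]:
    """Mean relative area per compound for marks, head and gland extracts.

    Samples are quantile-normalized jointly (marks + extracts) and then
    total-sum scaled within the compound universe before averaging, so the
    means are comparable across sources of very different absolute yield.
    """
    compounds = list(compounds)
    groups = {
        "mark": table.samples_with_source(MARK_SOURCES),
        "head": table.samples_with_source({"head"}),
        "gland": table.samples_with_source({"gland"}),
    }
    all_ids = [s for ids in groups.values() for s in ids]
    if not groups["mark"]:
        raise AttributionError("no mark samples in table")
    sub = table.areas.loc[all_ids, compounds]
    if normalize and len(all_ids) >= 2:
        sub = quantile_normalize(sub)
    sub = total_sum_scale(sub)
    return {name: sub.loc[ids].mean(axis=0)
            for name, ids in groups.items() if ids}


def dufour_band_selection(mark_means, gland_means, kovats,
                          band_k: float = 2.0) -> BandFit:
    """Retain compounds whose mark/gland quotient sits in the Kovats band.

    Fits OLS of ``ln(mark_mean / gland_mean)`` on the Kovats index over all
    compounds with positive gland means and keeps those with absolute
    externally studentized (jackknife) residual ≤ ``band_k``; external
    studentization is used because internally studentized residuals are
    bounded by sqrt(df) and saturate on small panels.  Compounds with zero
    gland mean are excluded from both the fit and the retained set.
    """
    mark_means = pd.Series(mark_means, dtype=float)
    gland_means = pd.Series(gland_means, dtype=float)
    kovats = pd.Series(kovats, dtype=float)
    candidates = [c for c in mark_means.index
                  if gland_means.get(c, 0.0) > 0 and mark_means[c] > 0]
    if len(candidates) < 3:
        raise AttributionError(
            "Kovats band regression needs at least 3 compounds with "
            f"positive gland and mark means; got {len(candidates)}")

    y = np.log(mark_means[candidates].to_numpy()
               / gland_means[candidates].to_numpy())
    x = kovats[candidates].to_numpy()
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    sigma = math.sqrt(fit.scale) if fit.df_resid > 0 else 0.0
    if sigma < 1e-12:
        # quotients exactly on the line: nothing deserts the band
        student = np.zeros(len(candidates))
    else:
        student = fit.get_influence().resid_studentized_external
    studentized = dict(zip(candidates, (float(t) for t in student)))
    retained = {c for c, t in studentized.items() if abs(t) <= band_k}
    eliminated = set(candidates) - retained
    return BandFit(retained=retained, eliminated=eliminated,
                   slope=float(fit.params[1]), intercept=float(fit.params[0]),
                   residual_sd=float(sigma), band_k=float(band_k),
                   studentized=studentized)


def exogenous_filter(mark_means, head_means, gland_means,
                     enrichment_threshold: float = 2.0):
    """Discard compounds enriched in marks beyond the bee-source sum.

    A compound is discarded iff ``mark_mean / (head_mean + gland_mean)``
    strictly exceeds the threshold ("more than two-fold enriched");
    compounds with no bee source at all (head + gland mean = 0) are
    discarded with reason ``"no bee source"``.

    Returns ``(retained, discarded, reasons)``.
    """
    mark_means = pd.Series(mark_means, dtype=float)
    head_means = pd.Series(head_means, dtype=float)
    gland_means = pd.Series(gland_means, dtype=float)
    retained: set[str] = set()
    discarded: set[str] = set()
    reasons: dict[str, str] = {}
    for c in mark_means.index:
        bee_sum = head_means.get(c, 0.0) + gland_means.get(c, 0.0)
        if bee_sum <= 0:
            discarded.add(c)
            reasons[c] = "no bee source"
            continue
        ratio = mark_means[c] / bee_sum
        if ratio > enrichment_threshold:
            discarded.add(c)
            reasons[c] = f"mark/bee enrichment {ratio:.3g} > {enrichment_threshold:g}"
        else:
            retained.add(c)
    return retained, discarded, reasons


def contribution_factors(head_means, gland_means,
                         ratio_threshold: float = 2.0):
    """Assign per-compound source factors from the head:gland ratio.

    ``r = max(head, gland) / min(head, gland)``.  For ``r ≤ threshold`` a
    proportional contribution of both sources is assumed — factors (1, 1),
    i.e. the sources are summed; for larger ratios only the dominant source
    counts.  A zero mean on one side yields (1, 0) / (0, 1) directly.

    Returns ``(factors, ratios)`` where ``ratios`` maps each compound to r
    (``inf`` when one source mean is zero) so the empirical ratio
    distribution can be inspected.
    """
    head_means = pd.Series(head_means, dtype=float)
    gland_means = pd.Series(gland_means, dtype=float)
    factors: dict[str, tuple[int, int]] = {}
    ratios: dict[str, float] = {}
    for c in head_means.index:
        h, g = head_means[c], gland_means.get(c, 0.0)
        if h <= 0 and g <= 0:
            raise AttributionError(
                f"{c!r}: both source means are zero; compound should have "
                "been discarded by the exogenous filter")
        if h <= 0 or g <= 0:
            ratios[c] = math.inf
            factors[c] = (1, 0) if h > 0 else (0, 1)
            continue
        r = max(h, g) / min(h, g)
        ratios[c] = float(r)
        if r <= ratio_threshold:
            factors[c] = (1, 1)
        else:
            factors[c] = (1, 0) if h > g else (0, 1)
    return factors, ratios


def estimate_bee_bouquet(bee_id: str, head_values, gland_values,
                         contribution) -> BeeBouquet:
    """Apply contribution factors to one bee's normalized extract values.

    ``bouquet_i = factor_head_i · head_i + factor_gland_i · gland_i`` over
    the retained compounds (the keys of ``contribution``).
    """
    if head_values is None or gland_values is None:
        raise AttributionError(
            f"bee {bee_id!r} is missing a head or gland extract")
    head_values = pd.Series(head_values, dtype=float)
    gland_values = pd.Series(gland_values, dtype=float)
    values: dict[str, float] = {}
    for c, (fh, fg) in contribution.items():
        if c not in head_values.index or c not in gland_values.index:
            raise AttributionError(
                f"bee {bee_id!r}: compound {c!r} missing from extract values")
        values[c] = float(fh * head_values[c] + fg * gland_values[c])
    return BeeBouquet(bee_id=bee_id, values=values)


def mark_present_compounds(table: PeakTable, threshold: float = 0.0,
                           bee_required: bool = False) -> list[str]:
    """Compounds detected in at least one nest mark (the §-universe is
    'present in head and/or gland extracts as well as in nest marks' when
    ``bee_required``; otherwise mark presence alone)."""
    marks = table.areas.loc[table.samples_with_source(MARK_SOURCES)]
    present = (marks > threshold).any(axis=0)
    names = marks.columns[present]
    if bee_required:
        extract_ids = table.samples_with_source({"head", "gland"})
        extracts = table.areas.loc[extract_ids, names]
        names = names[(extracts > threshold).any(axis=0)]
    return names.tolist()


def attribute_sources(table: PeakTable, band_k: float = 2.0,
                      enrichment_threshold: float = 2.0,
                      ratio_threshold: float = 2.0,
                      presence_threshold: float = 0.0
                      ) -> tuple[AttributionModel, dict[str, BeeBouquet]]:
    """Run the full attribution chain on a peak table.

    Returns the attribution model plus the estimated bouquet of every bee
    that has both a head and a gland extract.
    """
    universe = mark_present_compounds(table, presence_threshold)
    if not universe:
        raise AttributionError("no compounds present in nest marks")
    means = source_means(table, universe)
    if "head" not in means or "gland" not in means:
        raise AttributionError("table lacks head or gland extract samples")

    band = dufour_band_selection(
        means["mark"], means["gland"],
        table.annotations["kovats"], band_k=band_k)

    retained, discarded, reasons = exogenous_filter(
        means["mark"], means["head"], means["gland"],
        enrichment_threshold=enrichment_threshold)

    factors, ratios = contribution_factors(
        means["head"][sorted(retained)], means["gland"], ratio_threshold)

    # per-bee normalized extract values on the same scale as the means
    groups = {
        "mark": table.samples_with_source(MARK_SOURCES),
        "head": table.samples_with_source({"head"}),
        "gland": table.samples_with_source({"gland"}),
    }
    all_ids = [s for ids in groups.values() for s in ids]
    sub = table.areas.loc[all_ids, universe]
    if len(all_ids) >= 2:
        sub = quantile_normalize(sub)
    sub = total_sum_scale(sub)

    meta = table.sample_meta
    head_by_bee = {meta.at[s, "nest_id"]: s for s in groups["head"]}
    gland_by_bee = {meta.at[s, "nest_id"]: s for s in groups["gland"]}
    bouquets: dict[str, BeeBouquet] = {}
    for bee in sorted(set(head_by_bee) & set(gland_by_bee)):
        bouquets[bee] = estimate_bee_bouquet(
            bee, sub.loc[head_by_bee[bee]], sub.loc[gland_by_bee[bee]],
            factors)

    model = AttributionModel(
        # both screens flag foreign enrichment; a compound discarded as
        # exogenous cannot stand in the gland-derived set either
        dufour_retained=band.retained - discarded,
        exogenous_discarded=discarded,
        contribution=factors,
        band_fit=band,
        source_ratio={c: r for c, r in ratios.items() if math.isfinite(r)},
        discard_reasons=reasons,
    )
    return model, bouquets
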