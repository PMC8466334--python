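"""End-to-end orchestration: simulate/load → preprocess → attribute →
similarity → report, as a seeded, logged, reproducible run.

Three comparison modes mirror the study's analyses:

* ``marks`` — all mark sleeves, every retained substance: are marks of the
  same nest more similar than marks of different nests?
* ``gland-vs-marks`` — Dufour's gland extracts against marks, restricted to
  the band-selected gland-derived substances.
* ``bouquet-vs-marks`` — estimated per-bee total bouquets (contribution
  factors applied to head + gland extracts) against marks.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import AttributionError, attribute_sources, total_sum_scale
from .io import MARK_SOURCES, PeakTable, read_peak_table, write_peak_table
from .preprocessing import (clr_transform, detect_private_substances,
                            filter_substances, quantile_normalize)
from .reporting import (render_heatmap, sort_dendrogram, tag_adjacency,
                        upgma_cluster)
from .similarity import (label_pairs, pca_factor_scores, prune_outliers,
                         sed_matrix, summarize_similarity, wald_glm)
from .synthetic import SimulationConfig, simulate_dataset

COMPARISONS = ("marks", "gland-vs-marks", "bouquet-vs-marks")

CLASS_COLORS = {
    "alkane": "#d73027", "alkene": "#fc8d59", "ester": "#4575b4",
    "aldehyde": "#91bfdb", "alcohol": "#7b3294", "methyl_branched": "#1a9850",
}


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """One pipeline run.  Exactly one of ``input_dir`` (a directory holding
    areas.csv / samples.csv / compounds.csv) or ``simulation`` must be set."""

    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    comparison: str = "marks"
    presence_threshold: float = 0.0
    band_k: float = 2.0
    enrichment_threshold: float = 2.0
    ratio_threshold: float = 2.0
    prune_k: float = 3.0
    seed: int = 0
    out_dir: str = "scentmark_run"
    heatmap: bool = True

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise PipelineError(
                "exactly one of input_dir or simulation must be supplied")
        if self.comparison not in COMPARISONS:
            raise PipelineError(
                f"comparison must be one of {COMPARISONS}, "
                f"got {self.comparison!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = raw.pop("simulation", None)
        if sim is not None and not isinstance(sim, SimulationConfig):
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def _preprocess(table: PeakTable, sources, presence_threshold: float):
    """filter → quantile normalize → clr on the samples of ``sources``."""
    report = filter_substances(table, sources, presence_threshold)
    detect_private_substances(table, report)
    ids = table.samples_with_source(sources)
    sub = table.areas.loc[ids, report.retained]
    normalized = quantile_normalize(sub)
    clr = clr_transform(normalized)
    return report, normalized, clr


def marks_similarity_analysis(table: PeakTable, presence_threshold=0.0,
                              prune_k=3.0, compounds=None) -> dict:
    """Same-nest vs different-nest discrimination over mark sleeves.

    When ``compounds`` is given (e.g. the band-selected gland-derived set),
    the analysis is restricted to those substances.
    """
    report, normalized, clr = _preprocess(table, MARK_SOURCES,
                                          presence_threshold)
    if compounds is not None:
        keep = [c for c in report.retained if c in set(compounds)]
        if len(keep) < 2:
            raise PipelineError(
                "fewer than 2 retained compounds in the requested subset")
        ids = normalized.index
        sub = table.areas.loc[ids, keep]
        normalized = quantile_normalize(sub)
        clr = clr_transform(normalized)
    factors = pca_factor_scores(clr)
    sed = sed_matrix(factors.scores)
    pairs = label_pairs(sed, table.sample_meta, MARK_SOURCES, MARK_SOURCES)
    raw_counts = pairs.counts()
    pruned = prune_outliers(pairs, prune_k)
    glm = wald_glm(pruned)
    return {
        "filter_report": report,
        "normalized": normalized,
        "clr": clr,
        "factor_model": factors,
        "sed": sed,
        "pairs_raw_counts": raw_counts,
        "pairset": pruned,
        "glm": glm,
        "summary": summarize_similarity(pruned),
    }


def extracts_vs_marks_analysis(table: PeakTable, mode: str,
                               presence_threshold=0.0, prune_k=3.0,
                               band_k=2.0, enrichment_threshold=2.0,
                               ratio_threshold=2.0) -> dict:
    """Own-bee vs foreign-bee comparison of extracts/bouquets against marks.

    ``mode="gland-vs-marks"`` compares Dufour's gland extracts on the
    band-selected gland-derived substances; ``mode="bouquet-vs-marks"``
    compares the estimated per-bee bouquets on the substances surviving the
    exogenous-enrichment filter.
    """
    model, bouquets = attribute_sources(
        table, band_k=band_k, enrichment_threshold=enrichment_threshold,
        ratio_threshold=ratio_threshold, presence_threshold=presence_threshold)

    mark_ids = table.samples_with_source(MARK_SOURCES)
    meta = table.sample_meta

    if mode == "gland-vs-marks":
        compounds = sorted(model.dufour_retained)
        gland_ids = table.samples_with_source({"gland"})
        ids = mark_ids + gland_ids
        report = filter_substances(
            table.subset(compounds=compounds),
            MARK_SOURCES | {"gland"}, presence_threshold)
        keep = report.retained
        normalized = quantile_normalize(table.areas.loc[ids, keep])
        clr = clr_transform(normalized)
        other_sources = {"gland"}
        comp_meta = meta
    elif mode == "bouquet-vs-marks":
        compounds = sorted(set(model.contribution))
        report = filter_substances(
            table.subset(compounds=compounds), MARK_SOURCES,
            presence_threshold)
        keep = report.retained
        marks_rel = total_sum_scale(
            quantile_normalize(table.areas.loc[mark_ids, keep]))
        rows = {f"{bee}_bouquet": pd.Series(bq.values)[keep]
                for bee, bq in bouquets.items()}
        bouquet_rel = total_sum_scale(pd.DataFrame(rows).T)
        normalized = pd.concat([marks_rel, bouquet_rel])
        clr = clr_transform(normalized)
        # estimated bouquets enter the pair labelling under the "gland"
        # source tag (only marks and bouquets are in the score matrix)
        extra = pd.DataFrame(
            {"nest_id": list(bouquets), "source": "gland"},
            index=pd.Index(list(rows), name="sample_id"))
        comp_meta = pd.concat([meta, extra])
        other_sources = {"gland"}
    else:
        raise PipelineError(f"unknown mode {mode!r}")

    if len(keep) < 2:
        raise PipelineError("fewer than 2 compounds after attribution filters")

    factors = pca_factor_scores(clr)
    sed = sed_matrix(factors.scores)
    pairs = label_pairs(sed, comp_meta, other_sources, MARK_SOURCES)
    raw_counts = pairs.counts()
    pruned = prune_outliers(pairs, prune_k)
    glm = wald_glm(pruned)
    return {
        "attribution": model,
        "bouquets": bouquets,
        "filter_report": report,
        "normalized": normalized,
        "clr": clr,
        "factor_model": factors,
        "sed": sed,
        "pairs_raw_counts": raw_counts,
        "pairset": pruned,
        "glm": glm,
        "summary": summarize_similarity(pruned),
    }


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline and write all artifacts to
    ``config.out_dir``.  Rerunning with the same config and seed is
    bit-identical for every numerical output."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = config.simulation.with_seed(config.seed)
        dataset = simulate_dataset(sim)
        table = dataset.peak_table
        dataset.write(out / "dataset")
    else:
        d = Path(config.input_dir)
        table = read_peak_table(d / "areas.csv", d / "samples.csv",
                                d / "compounds.csv")

    if config.comparison == "marks":
        result = marks_similarity_analysis(
            table, config.presence_threshold, config.prune_k)
    else:
        result = extracts_vs_marks_analysis(
            table, config.comparison, config.presence_threshold,
            config.prune_k, config.band_k, config.enrichment_threshold,
            config.ratio_threshold)

    # artifacts
    result["normalized"].to_csv(out / "normalized.csv", float_format="%.12g")
    result["clr"].to_csv(out / "clr.csv", float_format="%.12g")
    result["sed"].to_csv(out / "sed.csv", float_format="%.12g")
    result["pairset"].pairs.to_csv(out / "pairs.csv", index=False,
                                   float_format="%.12g")
    (out / "filter_report.json").write_text(
        json.dumps(result["filter_report"].to_dict(), indent=1,
                   default=_json_default))
    if "attribution" in result:
        (out / "attribution.json").write_text(
            json.dumps(result["attribution"].to_dict(), indent=1,
                       default=_json_default))
        bouquet_df = pd.DataFrame(
            {bee: bq.values for bee, bq in result["bouquets"].items()}).T
        bouquet_df.index.name = "bee_id"
        bouquet_df.to_csv(out / "bouquets.csv", float_format="%.12g")

    adjacency = None
    if config.heatmap:
        clr = result["clr"]
        col_cluster = sort_dendrogram(upgma_cluster(_euclidean(clr)))
        row_cluster = sort_dendrogram(upgma_cluster(_euclidean(clr.T)))
        render_heatmap(clr.T, row_cluster, col_cluster, CLASS_COLORS,
                       out / "heatmap.png",
                       leaf_order_path=out / "leaf_order.tsv")
        if config.comparison == "marks":
            adjacency = tag_adjacency(col_cluster, table.sample_meta)

    fm = result["factor_model"]
    summary = {
        "comparison": config.comparison,
        "n_samples": int(result["clr"].shape[0]),
        "n_compounds_analyzed": int(result["clr"].shape[1]),
        "n_retained_compounds": len(result["filter_report"].retained),
        "n_factors": fm.n_factors,
        "explained_pct": fm.explained_pct,
        "pairs_raw": result["pairs_raw_counts"],
        "pairs_pruned": len(result["pairset"].pruned),
        "glm": result["glm"].to_dict(),
        "sed_summary": result["summary"],
        "tag_adjacency": adjacency,
        "private_substances": result["filter_report"].private,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_json_default))

    log = {
        "scentmark_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {
            k: (asdict(v) if isinstance(v, SimulationConfig) else v)
            for k, v in asdict(config).items()
            if k != "simulation" or v is None
        },
        "thresholds": {
            "presence_threshold": config.presence_threshold,
            "band_k": config.band_k,
            "enrichment_threshold": config.enrichment_threshold,
            "ratio_threshold": config.ratio_threshold,
            "prune_k": config.prune_k,
        },
    }
    if config.simulation is not None:
        sim_dict = asdict(config.simulation.with_seed(config.seed))
        sim_dict["compound_panel"] = f"{len(config.simulation.compound_panel)} compounds"
        log["simulation"] = sim_dict
    (out / "run_log.json").write_text(
        json.dumps(log, indent=1, sort_keys=True, default=_json_default))
    return out


def _euclidean(matrix: pd.DataFrame) -> pd.DataFrame:
    from scipy.spatial.distance import pdist, squareform
    D = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)
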