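"""Synthetic GC/MS peak tables for solitary-bee nest-mark analysis.

The generator emulates the sampling design of a nest-marking study on the
mason bee *Osmia cornuta*: each nesting female contributes two sequential
filter-paper entrance sleeves (nest marks), one head extract and one
Dufour's gland extract; a few control sleeves are exposed to ambient
conditions without a nesting bee.

The generative model is multiplicative (log-normal) throughout, because
integrated peak areas are positive and span several orders of magnitude:

* Each compound has a fixed expected relative abundance in each of three
  latent sources: Dufour's gland secretion, the cuticular/head bouquet, and
  the ambient environment (nest material, flower visits).
* Each bee perturbs the gland and head source profiles compound-wise by
  ``exp(N(0, sigma_individual^2))`` — the individual signature.
* A nest mark is a weighted mixture of the bee's gland and head profiles
  plus an environmental contribution; every sleeve drifts independently by
  ``exp(N(0, sigma_drift^2))`` per compound (temporal tag instability —
  sleeves are deposited at different times).
* Every observed sample is multiplied by one scalar intensity factor
  ``exp(N(0, sigma_intensity^2))`` (body size / extraction yield) and by
  compound-wise measurement noise ``exp(N(0, sigma_noise^2))``.

Ground truth (per-bee latent profiles and per-compound source labels) is
returned alongside the peak table so downstream parameter-recovery tests can
score the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import COMPOUND_CLASSES, PeakTable, write_peak_table

SOURCES = ("gland", "head", "environment")

#: Mixing weights of the three latent sources in a nest mark.  Solved once
#: from the measured class compositions of gland, head and mark samples so
#: that the expected mark composition reproduces the empirical class
#: percentages (alkanes 44.7%, alkenes 39.8%, aldehydes 9.1%, esters 0.5%).
DEFAULT_MIX_GLAND = 0.32
DEFAULT_MIX_CUTICLE = 0.244
DEFAULT_ENV_ENRICHMENT = 0.436

#: Class-level composition of each latent source (mass fractions, sum 1).
#: Gland and head columns follow the reported source compositions; the
#: environment column is the non-negative completion that makes the default
#: mixture reproduce the reported mark composition.
CLASS_COMPOSITION = {
    "gland": {
        "alkene": 0.787,
        "alkane": 0.191,
        "alcohol": 0.013,
        "ester": 0.005,
        "aldehyde": 0.001,
        "methyl_branched": 0.003,
    },
    "head": {
        "alkene": 0.600,
        "alkane": 0.371,
        "methyl_branched": 0.024,
        "ester": 0.002,
        "aldehyde": 0.001,
        "alcohol": 0.002,
    },
    "environment": {
        "alkane": 0.677,
        "aldehyde": 0.207,
        "methyl_branched": 0.088,
        "alcohol": 0.021,
        "ester": 0.007,
    },
}

#: Double-bond-position mass split within the alkene class, per source.
#: Head values follow the reported 1.8 / 51.9 / 6.4 (% of total) split; the
#: gland split is tuned so the default mixture reproduces the mark split of
#: 1.0 / 33.5 / 5.3.
ALKENE_POSITION_SPLIT = {
    "gland": {5: 0.025, 7: 0.825, 9: 0.150},
    "head": {5: 0.030, 7: 0.8633, 9: 0.1067},
}

# Chain-length profile within the n-alkane class (odd chains dominate;
# pentacosane C25 is the most abundant compound).  Shared by all sources.
_ALKANE_CHAIN_WEIGHTS = {
    21: 0.040, 22: 0.009, 23: 0.160, 24: 0.009, 25: 0.380, 26: 0.009,
    27: 0.250, 28: 0.009, 29: 0.100, 30: 0.009, 31: 0.025,
}

# Chain profile within one double-bond-position series (7-pentacosene peak).
_ALKENE_CHAIN_WEIGHTS = {
    21: 0.060, 22: 0.004, 23: 0.220, 24: 0.004, 25: 0.400, 26: 0.002,
    27: 0.220, 29: 0.090,
}

_GREEK = {
    21: "heneicosane", 22: "docosane", 23: "tricosane", 24: "tetracosane",
    25: "pentacosane", 26: "hexacosane", 27: "heptacosane", 28: "octacosane",
    29: "nonacosane", 30: "triacontane", 31: "hentriacontane",
}
_ENE = {
    21: "heneicosene", 22: "docosene", 23: "tricosene", 24: "tetracosene",
    25: "pentacosene", 26: "hexacosene", 27: "heptacosene", 29: "nonacosene",
}


@dataclass(frozen=True)
class CompoundSpec:
    """One compound of the simulation panel.

    ``source_mean`` maps each latent source ("gland", "head", "environment")
    to the compound's expected relative abundance in that source; the three
    source vectors each sum to 1 over the default panel.
    """

    name: str
    compound_class: str
    chain_length: int
    db_position: int | None
    kovats: float
    source_mean: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if self.kovats <= 0:
            raise ValueError(f"{self.name}: Kovats index must be positive")
        if not any(self.source_mean.get(s, 0.0) > 0 for s in SOURCES):
            raise ValueError(f"{self.name}: all source means are zero")
        if any(v < 0 for v in self.source_mean.values()):
            raise ValueError(f"{self.name}: negative source mean")


def _normalized(weights: Mapping[int, float]) -> dict[int, float]:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def default_compound_panel() -> list[CompoundSpec]:
    """Build the default 59-compound panel.

    The panel mirrors the chemistry of mason-bee nest marks: n-alkanes
    C21–C31 (odd chains dominant, pentacosane the major peak), 5-/7-/9-
    mono-alkenes with 7-pentacosene dominant, trace fatty-acid esters,
    primary alcohols, methyl-branched alkanes, and primary aldehydes — a
    subset of which occur only in the environment (nest material), never in
    bee extracts.  Kovats retention indices follow the n-alkane convention
    (chain C → 100·C); alkenes elute slightly before the same-chain alkane.
    """
    specs: list[CompoundSpec] = []

    def add(name, cls, chain, db, kovats, means):
        specs.append(CompoundSpec(name, cls, chain, db, float(kovats),
                                  {s: float(means.get(s, 0.0)) for s in SOURCES}))

    comp = CLASS_COMPOSITION

    # --- n-alkanes (11): same chain profile in every source -----------------
    chain_w = _normalized(_ALKANE_CHAIN_WEIGHTS)
    for chain, w in chain_w.items():
        add(f"n-{_GREEK[chain]}", "alkane", chain, None, 100 * chain,
            {s: comp[s].get("alkane", 0.0) * w for s in SOURCES})

    # --- mono-alkenes (18): per-position chain profiles ---------------------
    ene_chain_w = _normalized(_ALKENE_CHAIN_WEIGHTS)
    for pos in (5, 7, 9):
        chains = list(_ALKENE_CHAIN_WEIGHTS) if pos == 7 else [
            c for c in _ALKENE_CHAIN_WEIGHTS if c % 2 == 1]
        pos_w = _normalized({c: _ALKENE_CHAIN_WEIGHTS[c] for c in chains})
        for chain, w in pos_w.items():
            means = {
                s: comp[s].get("alkene", 0.0) * ALKENE_POSITION_SPLIT[s][pos] * w
                for s in ("gland", "head")
            }
            add(f"{pos}-{_ENE[chain]}", "alkene", chain, pos,
                100 * chain - 30 + pos, means)

    # --- fatty-acid esters (6): chain = acid + alcohol carbons --------------
    esters = [
        # name, total C, kovats, weight within class
        ("methyl hexadecanoate", 17, 1926, 0.30),
        ("ethyl hexadecanoate", 18, 1993, 0.12),
        ("isopropyl hexadecanoate", 19, 2041, 0.08),
        ("methyl 9-octadecenoate", 19, 2085, 0.20),
        ("methyl octadecanoate", 19, 2126, 0.20),
        ("ethyl octadecanoate", 20, 2195, 0.10),
    ]
    for name, chain, kovats, w in esters:
        add(name, "ester", chain, None, kovats,
            {s: comp[s].get("ester", 0.0) * w for s in SOURCES})

    # --- primary alcohols (3): mainly a gland trace class -------------------
    for chain, w in ((24, 0.30), (26, 0.45), (28, 0.25)):
        add(f"1-{_GREEK[chain][:-1]}ol", "alcohol", chain, None,
            100 * chain + 70,
            {s: comp[s].get("alcohol", 0.0) * w for s in SOURCES})

    # --- primary aldehydes (10) ---------------------------------------------
    # Even-chain aldehydes occur in nest entrances only (environment source);
    # odd-chain aldehydes are bee-derived traces.
    ald_names = {15: "pentadecanal", 16: "hexadecanal", 17: "heptadecanal",
                 18: "octadecanal", 19: "nonadecanal", 20: "eicosanal",
                 21: "heneicosanal", 22: "docosanal", 23: "tricosanal",
                 24: "tetracosanal"}
    env_ald = {15: 0.10, 16: 0.14, 18: 0.20, 20: 0.24, 22: 0.18, 24: 0.14}
    for chain, w in env_ald.items():
        add(ald_names[chain], "aldehyde", chain, None, 100 * chain + 12,
            {"environment": comp["environment"]["aldehyde"] * w})
    bee_ald = {17: 0.20, 19: 0.30, 21: 0.30, 23: 0.20}
    for chain, w in bee_ald.items():
        add(ald_names[chain], "aldehyde", chain, None, 100 * chain + 12,
            {s: comp[s].get("aldehyde", 0.0) * w for s in ("gland", "head")})

    # --- methyl-branched alkanes (11) ---------------------------------------
    branched = [
        ("11-methyltricosane", 23, 11, 0.04),
        ("13-methylpentacosane", 25, 13, 0.14),
        ("11-methylpentacosane", 25, 11, 0.08),
        ("13-methylheptacosane", 27, 13, 0.16),
        ("11-methylheptacosane", 27, 11, 0.08),
        ("15-methylheptacosane", 27, 15, 0.06),
        ("13-methylnonacosane", 29, 13, 0.16),
        ("15-methylnonacosane", 29, 15, 0.10),
        ("11-methylnonacosane", 29, 11, 0.06),
        ("13-methylhentriacontane", 31, 13, 0.07),
        ("15-methylhentriacontane", 31, 15, 0.05),
    ]
    for name, chain, branch, w in branched:
        # monomethyl isomers elute between the same-chain and next alkane;
        # lower branch positions elute marginally later
        add(name, "methyl_branched", chain, None,
            100 * chain + 28 + (15 - branch) / 2,
            {s: comp[s].get("methyl_branched", 0.0) * w for s in SOURCES})

    assert len(specs) == 59
    return specs


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings; defaults reproduce the field study's design
    (25 bees, two sequential mark sleeves each, three control sleeves).

    All sigmas are log-scale standard deviations of multiplicative factors.
    """

    n_bees: int = 25
    marks_per_bee: int = 2
    n_control_sleeves: int = 3
    compound_panel: Sequence[CompoundSpec] = field(default_factory=default_compound_panel)
    sigma_individual: float = 0.70
    sigma_drift: float = 0.25
    sigma_noise: float = 0.10
    sigma_intensity: float = 0.50
    mix_gland: float = DEFAULT_MIX_GLAND
    mix_cuticle: float = DEFAULT_MIX_CUTICLE
    env_enrichment: float = DEFAULT_ENV_ENRICHMENT
    env_control_factor: float = 0.5
    seed: int = 0
    base_area: float = 1e6

    def __post_init__(self) -> None:
        for attr in ("sigma_individual", "sigma_drift", "sigma_noise",
                     "sigma_intensity"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.n_bees < 2:
            raise ValueError(
                "n_bees must be >= 2: a single nest yields no different-nest "
                "pairs for the downstream similarity analysis")
        if self.marks_per_bee < 1:
            raise ValueError("marks_per_bee must be >= 1")
        if self.n_control_sleeves < 0:
            raise ValueError("n_control_sleeves must be >= 0")
        if not (0 <= self.mix_gland <= 1 and 0 <= self.mix_cuticle <= 1):
            raise ValueError("mixing weights must lie in [0, 1]")
        if self.mix_gland + self.mix_cuticle > 1:
            raise ValueError("mix_gland + mix_cuticle must not exceed 1")
        if self.env_enrichment < 0 or self.env_control_factor < 0:
            raise ValueError("environment multipliers must be non-negative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticDataset:
    """A simulated peak table plus its generative ground truth.

    ``truth_bouquets`` maps each bee to its latent (noise-free) gland and
    head profiles; ``truth_source`` labels each compound gland / head /
    both / environment according to which source means are positive.
    """

    peak_table: PeakTable
    truth_bouquets: dict[str, dict[str, np.ndarray]]
    truth_source: dict[str, str]
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the pipeline input CSVs plus a ground-truth JSON."""
        out_dir = Path(out_dir)
        paths = write_peak_table(self.peak_table, out_dir)
        truth = {
            "truth_source": self.truth_source,
            "truth_bouquets": {
                bee: {src: list(vals) for src, vals in profiles.items()}
                for bee, profiles in self.truth_bouquets.items()
            },
            "compounds": list(self.peak_table.areas.columns),
        }
        truth_path = out_dir / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
        paths["truth"] = truth_path
        return paths


def _source_label(spec: CompoundSpec) -> str:
    g = spec.source_mean.get("gland", 0.0) > 0
    h = spec.source_mean.get("head", 0.0) > 0
    if g and h:
        return "both"
    if g:
        return "gland"
    if h:
        return "head"
    return "environment"


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset under ``config``.

    Fully reproducible: the same config (including seed) yields a
    bit-identical peak table.
    """
    rng = np.random.default_rng(config.seed)
    panel = list(config.compound_panel)
    p = len(panel)
    names = [c.name for c in panel]
    gland_mean = np.array([c.source_mean.get("gland", 0.0) for c in panel])
    head_mean = np.array([c.source_mean.get("head", 0.0) for c in panel])
    env_mean = np.array([c.source_mean.get("environment", 0.0) for c in panel])

    def lognorm(sigma: float, size) -> np.ndarray:
        """Mean-one log-normal factors: E[exp(N(0, s^2) - s^2/2)] = 1, so
        perturbations do not shift expected compositions (the bee-source
        share of a mark would otherwise inflate relative to the constant
        environmental term)."""
        if sigma == 0:
            return np.ones(size)
        return np.exp(rng.normal(0.0, sigma, size) - sigma ** 2 / 2.0)

    rows: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, str]] = []
    truth_bouquets: dict[str, dict[str, np.ndarray]] = {}

    env_in_marks = config.env_enrichment * env_mean

    for b in range(config.n_bees):
        bee = f"N{b + 1:02d}"
        gland_b = gland_mean * lognorm(config.sigma_individual, p)
        head_b = head_mean * lognorm(config.sigma_individual, p)
        truth_bouquets[bee] = {"gland": gland_b, "head": head_b}
        mark_base = (config.mix_gland * gland_b
                     + config.mix_cuticle * head_b
                     + env_in_marks)
        for m in range(config.marks_per_bee):
            # every sleeve carries its own temporal state: sleeves are
            # deposited at different times, so each drifts independently
            # from the bee's latent tag (between-sleeve log-difference SD
            # is sqrt(2)·sigma_drift).  This also makes the same/different
            # labels exchangeable when sigma_individual = 0, the regime the
            # type-I-control property assumes.
            mark = mark_base * lognorm(config.sigma_drift, p)
            rows.append(mark)
            meta_rows.append((f"{bee}_m{m + 1}", bee, f"mark{m + 1}"))
        rows.append(head_b)
        meta_rows.append((f"{bee}_head", bee, "head"))
        rows.append(gland_b)
        meta_rows.append((f"{bee}_gland", bee, "gland"))

    control_level = config.env_control_factor * config.env_enrichment
    for c in range(config.n_control_sleeves):
        rows.append(control_level * env_mean)
        meta_rows.append((f"CTRL{c + 1}", "control", "control_sleeve"))

    latent = np.vstack(rows) if rows else np.empty((0, p))
    n = latent.shape[0]
    intensity = lognorm(config.sigma_intensity, n)[:, None]
    noise = lognorm(config.sigma_noise, (n, p))
    areas = config.base_area * latent * intensity * noise

    sample_ids = [m[0] for m in meta_rows]
    areas_df = pd.DataFrame(areas, index=pd.Index(sample_ids, name="sample_id"),
                            columns=names)
    meta_df = pd.DataFrame(
        {"nest_id": [m[1] for m in meta_rows],
         "source": [m[2] for m in meta_rows]},
        index=pd.Index(sample_ids, name="sample_id"))
    annot_df = pd.DataFrame(
        {"compound_class": [c.compound_class for c in panel],
         "chain_length": [c.chain_length for c in panel],
         "db_position": pd.array([c.db_position for c in panel], dtype="Int64"),
         "kovats": [c.kovats for c in panel]},
        index=pd.Index(names, name="name"))

    table = PeakTable(areas_df, meta_df, annot_df)
    expected = (config.n_bees * (config.marks_per_bee + 2)
                + config.n_control_sleeves)
    assert table.n_samples == expected
    truth_source = {c.name: _source_label(c) for c in panel}
    return SyntheticDataset(table, truth_bouquets, truth_source, config)


def expected_mark_class_proportions(config: SimulationConfig) -> dict[str, float]:
    """Expected class mass fractions of a mark under the mixing model
    (ignoring the log-normal mean offset, which cancels across compounds)."""
    panel = list(config.compound_panel)
    mark = np.array([
        config.mix_gland * c.source_mean.get("gland", 0.0)
        + config.mix_cuticle * c.source_mean.get("head", 0.0)
        + config.env_enrichment * c.source_mean.get("environment", 0.0)
        for c in panel])
    mark = mark / mark.sum()
    out: dict[str, float] = {}
    for spec, frac in zip(panel, mark):
        out[spec.compound_class] = out.get(spec.compound_class, 0.0) + frac
    return out
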