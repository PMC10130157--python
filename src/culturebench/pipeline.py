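"""End-to-end orchestration: simulate or load inputs, compute the metric
panel, partition variance, enterotype, rank media, and run the drug track,
all from a single YAML config with a mandatory seed.

Every run writes TSV artifacts plus ``manifest.json`` recording the fully
resolved config (no silent defaults), the seed, and a SHA-256 digest per
output file, so reruns with the same config and seed are byte-identical
and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, drugs, metrics, ranking, synthetic
from .enterotypes import enterotype
from .io_tables import (
    FeatureTable,
    SampleMetadata,
    Taxonomy,
    align,
    read_feature_table,
    read_metadata,
    read_pathway_table,
    read_taxonomy,
    write_distance_matrix,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)
from .variance import Permanova

logger = logging.getLogger("culturebench")

DEFAULT_FACTORS = ["donor", "medium", "time_h", "replicate"]


@dataclass
class RunConfig:
    """Fully resolved run configuration (one of inputs / simulation)."""

    seed: int
    out_dir: str
    simulate: dict | None = None  # CommunitySimSpec kwargs
    inputs: dict | None = None  # paths: feature_table, taxonomy, metadata, ...
    factors: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    n_perm: int = 999
    ranking_preset: str = "panel"
    directions: dict | None = None  # required when preset == "custom"
    aggregation_rank: str = "family"
    jsd_level: str = "family"
    euclidean_level: str = "asv"
    enterotype_per_donor: bool = True
    k_range: tuple = (2, 6)
    drug_track: dict | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be given")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.factors:
            raise ValueError("PERMANOVA factor order must be configured")
        if self.ranking_preset not in (*ranking.PRESETS, "custom"):
            raise ValueError(f"unknown ranking preset {self.ranking_preset!r}")
        if self.ranking_preset == "custom" and not self.directions:
            raise ValueError("custom ranking preset needs a direction map")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolved(self) -> dict:
        out = asdict(self)
        out["k_range"] = list(self.k_range)
        return out


def _direction_map(config: RunConfig) -> dict:
    if config.ranking_preset == "custom":
        return dict(config.directions)
    return dict(ranking.PRESETS[config.ranking_preset])


def _load_inputs(config: RunConfig):
    paths = config.inputs
    meta = read_metadata(paths["metadata"])
    table = read_feature_table(paths["feature_table"], sample_ids=meta.sample_ids)
    tax = read_taxonomy(paths["taxonomy"])
    pathway = (
        read_pathway_table(paths["pathway_table"]) if "pathway_table" in paths else None
    )
    od = assays.read_od_table(paths["od"]) if "od" in paths else None
    ct = assays.read_ct_table(paths["ct"]) if "ct" in paths else None
    return table, tax, meta, pathway, od, ct


def _simulate_inputs(config: RunConfig):
    kwargs = dict(config.simulate or {})
    kwargs.setdefault("seed", config.seed)
    spec = synthetic.CommunitySimSpec(**kwargs)
    table, tax, meta, _truth = synthetic.simulate_experiment(spec)
    pathway = synthetic.simulate_pathways(table, tax, seed=spec.seed + 1)
    od = _simulate_od(meta, seed=spec.seed + 2)
    ct = _simulate_ct(table, meta, seed=spec.seed + 3)
    return table, tax, meta, pathway, od, ct


def _simulate_od(meta: SampleMetadata, seed: int) -> pd.DataFrame:
    """One ΔOD600 reading per culture: medium-specific logistic endpoints."""
    rng = np.random.default_rng(seed)
    cultures = meta.data[meta.data["role"] == "culture"]
    media = sorted(cultures["medium"].dropna().unique())
    K = {m: float(rng.uniform(0.6, 1.6)) for m in media}
    r = {m: float(rng.uniform(0.3, 0.8)) for m in media}
    rows = []
    for sid, row in cultures.iterrows():
        curve = synthetic.simulate_growth(
            K=K[row["medium"]],
            r=r[row["medium"]],
            lag=4.0,
            times=[row["time_h"]],
            noise_sd=0.02,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(
            {
                "sample_id": sid,
                "time_h": row["time_h"],
                "od_culture": float(curve["od_culture"].iloc[0]),
                "od_supernatant": float(curve["od_supernatant"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


_GENES = ("baiJ", "bsh", "bcoA")


def _simulate_ct(table: FeatureTable, meta: SampleMetadata, seed: int) -> pd.DataFrame:
    """Functional-gene CTs tied loosely to sample composition."""
    rng = np.random.default_rng(seed)
    rel = table.data.div(table.data.sum(axis=1), axis=0)
    # gene abundance proxy: weighted slice of the community per gene
    weights = {g: rng.dirichlet(np.ones(rel.shape[1]) * 0.3) for g in _GENES}
    target_ra = {}
    for sid in table.sample_ids:
        target_ra[sid] = {
            g: float(np.clip(rel.loc[sid].to_numpy() @ w, 1e-6, 1.0))
            for g, w in weights.items()
        }
    return synthetic.simulate_qpcr(
        target_ra, ct_16s=18.0, noise_sd=0.15, seed=int(rng.integers(2**31 - 1))
    )


def _feces_of(meta: SampleMetadata) -> dict:
    """donor -> feces sample id; errors if a donor lacks one."""
    feces = meta.data[meta.data["role"] == "feces"]
    return {row["donor"]: sid for sid, row in feces.iterrows()}


def build_metric_panel(
    table: FeatureTable,
    tax: Taxonomy,
    meta: SampleMetadata,
    pathway=None,
    od: pd.DataFrame | None = None,
    ct: pd.DataFrame | None = None,
    jsd_level: str = "family",
    euclidean_level: str = "asv",
) -> pd.DataFrame:
    """Per-culture values of the seven evaluation metrics.

    Each culture is compared to its own donor's feces sample. Metrics whose
    input table is absent are emitted as NaN columns (they rank worst).
    """
    feces_by_donor = _feces_of(meta)
    cultures = meta.data[meta.data["role"] == "culture"]
    missing = sorted(set(cultures["donor"]) - set(feces_by_donor))
    if missing:
        raise ValueError(f"donor(s) without a feces sample: {missing}")

    asv_profiles = metrics.to_relative(table, level="asv")
    fam_table = metrics.aggregate(table, tax, jsd_level)
    fam_profiles = metrics.to_relative(fam_table, level=jsd_level)

    rows = {}
    for sid, row in cultures.iterrows():
        fid = feces_by_donor[row["donor"]]
        entry = {
            "donor": row["donor"],
            "medium": row["medium"],
            "time_h": row["time_h"],
            "d_js_family": metrics.jsd(fam_profiles[sid], fam_profiles[fid]),
            "euclidean_asv": metrics.euclidean(asv_profiles[sid], asv_profiles[fid]),
            "shannon_asv": metrics.shannon(asv_profiles[sid]),
            "simpson_asv": metrics.simpson(asv_profiles[sid]),
            "d_js_pathway": np.nan,
            "gene_variation": np.nan,
            "delta_od600": np.nan,
        }
        if pathway is not None and sid in pathway.data.index:
            entry["d_js_pathway"] = assays.functional_jsd(
                pathway.data.loc[sid], pathway.data.loc[fid]
            )
        if ct is not None:
            genes = sorted(set(ct["gene"]) - {"16S"})
            fc = assays.gene_fold_changes(ct, sid, fid, genes)
            if fc.notna().any():
                entry["gene_variation"] = assays.gene_variation_score(fc.dropna())
        rows[sid] = entry
    panel = pd.DataFrame(rows).T
    if od is not None:
        od_indexed = od.set_index("sample_id")
        delta = od_indexed["od_culture"] - od_indexed["od_supernatant"]
        panel["delta_od600"] = delta.reindex(panel.index)
    for col in ("d_js_family", "euclidean_asv", "shannon_asv", "simpson_asv",
                "d_js_pathway", "gene_variation", "delta_od600", "time_h"):
        panel[col] = pd.to_numeric(panel[col])
    return panel


def average_replicates(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate cultures to one row per (donor, medium, time)."""
    grouped = panel.groupby(["donor", "medium", "time_h"], dropna=False).mean(
        numeric_only=True
    )
    keys = list(grouped.index)
    grouped.index = [f"{d}_{m}_{int(t)}h" for d, m, t in keys]
    grouped["donor"] = [d for d, _, _ in keys]
    grouped["medium"] = [m for _, m, _ in keys]
    grouped["time_h"] = [t for _, _, t in keys]
    return grouped


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, config: RunConfig, extra: dict | None = None) -> None:
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.resolved(),
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_evaluation(config: RunConfig, out_dir=None) -> Path:
    """Run the community-evaluation track; returns the artifact directory."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        logger.info("stage simulate: generating synthetic experiment")
        table, tax, meta, pathway, od, ct = _simulate_inputs(config)
        write_feature_table(table, out / "feature_table.tsv")
        write_taxonomy(tax, out / "taxonomy.tsv")
        write_metadata(meta, out / "metadata.tsv")
        pathway.data.to_csv(out / "pathway_table.tsv", sep="\t", index_label="sample_id")
        od.to_csv(out / "od600.tsv", sep="\t", index=False)
        ct.to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)
    else:
        logger.info("stage load: reading input tables")
        table, tax, meta, pathway, od, ct = _load_inputs(config)

    table, meta = align(table, meta)

    logger.info("stage metrics: building the per-culture metric panel")
    panel = build_metric_panel(
        table, tax, meta, pathway, od, ct,
        jsd_level=config.jsd_level, euclidean_level=config.euclidean_level,
    )
    panel.to_csv(out / "metric_panel.tsv", sep="\t", index_label="sample_id")

    logger.info("stage permanova: %s", config.factors)
    cultures = [s for s in table.sample_ids
                if meta.data.at[s, "role"] == "culture"]
    culture_table = FeatureTable(table.data.loc[cultures].copy())
    profiles = metrics.to_relative(culture_table)
    dmat = metrics.distance_matrix(profiles, "braycurtis")
    write_distance_matrix(dmat, out / "braycurtis.tsv")
    result = Permanova(dmat, meta.subset(cultures), config.factors).fit(
        permutations=config.n_perm, seed=config.seed
    )
    result.anova_table.to_csv(out / "permanova.tsv", sep="\t", index_label="Factor")

    logger.info("stage enterotype")
    genus_table = metrics.aggregate(table, tax, "genus")
    ent_rows, quality_rows = [], []
    if config.enterotype_per_donor:
        groups = meta.data.groupby("donor").groups.items()
    else:
        groups = [("all", meta.data.index)]
    for donor, idx in groups:
        sub = FeatureTable(genus_table.data.loc[list(idx)].copy())
        res = enterotype(sub, k_range=range(config.k_range[0], config.k_range[1] + 1),
                         seed=config.seed)
        for sid, cluster in res.assignment.items():
            ent_rows.append(
                {"sample_id": sid, "group": donor, "cluster": int(cluster),
                 "enterotype": res.labels[cluster]}
            )
        for k, q in res.quality.items():
            quality_rows.append({"group": donor, "k": int(k), "calinski_harabasz": q})
    pd.DataFrame(ent_rows).to_csv(out / "enterotypes.tsv", sep="\t", index=False)
    pd.DataFrame(quality_rows).to_csv(out / "enterotype_quality.tsv", sep="\t", index=False)

    logger.info("stage rank: preset %s", config.ranking_preset)
    directions = _direction_map(config)
    collapsed = average_replicates(panel)
    metric_cols = [m for m in directions if m in collapsed.columns]
    usable = collapsed[metric_cols].dropna(axis=1, how="all")
    blocks = (
        collapsed["donor"] if config.ranking_preset == "panel" else None
    )
    rank_table = ranking.comprehensive_rank(
        usable, {m: directions[m] for m in usable.columns}, blocks
    )
    for c in ("donor", "medium", "time_h"):
        rank_table[c] = collapsed[c]
    rank_table.to_csv(out / "rank_table.tsv", sep="\t", index_label="culture")
    media_summary = ranking.summarize_media(rank_table, collapsed["medium"])
    media_summary.to_csv(out / "media_summary.tsv", sep="\t", index_label="medium")

    _write_manifest(out, config)
    logger.info("evaluation artifacts written to %s", out)
    return out


def run_drug_track(config: RunConfig, out_dir=None) -> Path:
    """Run the drug-metabolism track; returns the artifact directory."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config.drug_track or {})
    reference = cfg.get("reference", "control")

    if "inputs" in cfg:
        cal = drugs.read_calibration_table(cfg["inputs"]["calibration"])
        meas = drugs.read_measurement_table(cfg["inputs"]["measurements"])
        curves = {
            analyte: drugs.fit_calibration(
                grp[["conc_uM", "area_ratio"]].to_numpy(), analyte=analyte
            )
            for analyte, grp in cal.groupby("analyte")
        }
    else:
        sim = cfg.get("simulate", {})
        specs = synthetic.default_drug_specs(
            n_donors=int(sim.get("n_donors", 10)),
            seed=config.seed,
            noise_cv=float(sim.get("noise_cv", 0.05)),
        )
        meas_parts, cal_rows = [], []
        grid = np.array([0.5, 1.0, 5.0, 25.0, 100.0, 500.0])
        for spec in specs:
            m, _ = synthetic.simulate_drug_assay(spec)
            meas_parts.append(m)
            for analyte, (a, b) in spec.calibration.items():
                for conc in grid:
                    cal_rows.append(
                        {"analyte": analyte, "conc_uM": conc, "area_ratio": a * conc + b}
                    )
        meas = pd.concat(meas_parts, ignore_index=True)
        cal = pd.DataFrame(cal_rows).drop_duplicates()
        meas.to_csv(out / "drug_measurements.tsv", sep="\t", index=False)
        cal.to_csv(out / "drug_calibration.tsv", sep="\t", index=False)
        curves = {
            analyte: drugs.fit_calibration(
                grp[["conc_uM", "area_ratio"]].to_numpy(), analyte=analyte
            )
            for analyte, grp in cal.groupby("analyte")
        }

    summary = drugs.quantify_assay(meas, curves, reference=reference)
    summary["concentrations"].to_csv(out / "drug_concentrations.tsv", sep="\t", index=False)
    summary["remaining"].to_csv(out / "drug_remaining.tsv", sep="\t", index=False)
    summary["interdonor"].to_csv(out / "drug_interdonor.tsv", sep="\t",
                                 index_label="drug")
    curve_lines = pd.DataFrame(
        {
            "analyte": list(curves),
            "slope": [c.slope for c in curves.values()],
            "intercept": [c.intercept for c in curves.values()],
            "r_squared": [c.r_squared for c in curves.values()],
        }
    )
    curve_lines.to_csv(out / "calibration_curves.tsv", sep="\t", index=False)

    _write_manifest(out, config)
    logger.info("drug-track artifacts written to %s", out)
    return out
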