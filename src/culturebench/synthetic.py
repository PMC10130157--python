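"""Synthetic data generators with the statistical structure the analysis
assumes: Dirichlet-multinomial community profiles under a donor x medium x
time x replicate design, logistic growth curves, qPCR cycle thresholds and
LC-MS peak areas, so every pipeline stage is testable without sequencing
data.

The community model is multiplicative on abundance (additive on
log-abundance): each donor has a baseline log-abundance vector, media and
time shift whole taxonomic families, and per-sample noise enters through a
Dirichlet draw around the expected composition followed by a multinomial at
fixed sequencing depth. Effect magnitudes default to donor > medium > time,
the ordering the variance partitioning of real culture experiments shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .drugs import DRUG_METABOLITES, PUBLISHED_CALIBRATIONS
from .io_tables import RANKS, FeatureTable, SampleMetadata, PathwayTable, Taxonomy


@dataclass
class CommunitySimSpec:
    """Design and effect magnitudes for a simulated culture experiment.

    Defaults mirror the medium-screening design: 3 donors x 7 media x
    {6, 24} h x 2 replicates (84 cultures) plus one feces sample per donor.
    Effect SDs are on the log-abundance scale; ``dirichlet_concentration``
    controls replicate-to-replicate compositional noise (larger = tighter);
    ``depth`` is reads per sample.
    """

    n_donors: int = 3
    n_media: int = 7
    time_points_h: tuple = (6, 24)
    n_replicates: int = 2
    n_taxa: int = 150
    n_families: int = 25
    donor_effect_sd: float = 1.4
    medium_effect_sd: float = 1.0
    time_effect_sd: float = 0.3
    dirichlet_concentration: float = 200.0
    depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_donors",
            "n_media",
            "n_replicates",
            "n_taxa",
            "n_families",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("donor_effect_sd", "medium_effect_sd", "time_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DrugSimSpec:
    """First-order decay model of one drug across donor cultures.

    Parent concentration C(t) = C0 exp(-k_d t) per donor; metabolite
    M(t) = yield * (C0 - C(t)); the no-microbiome control decays at the
    (small) abiotic rate. Concentrations are mapped to peak-area ratios
    through each analyte's calibration line and multiplied by lognormal
    noise of the stated CV.
    """

    drug: str
    decay_rate_per_h: dict  # donor -> k_d (1/h)
    metabolite: str | None = None
    initial_conc_uM: float = 500.0
    metabolite_yield: float = 0.8
    control_decay_rate_per_h: float = 0.0
    calibration: dict = field(default_factory=dict)  # analyte -> (slope, intercept)
    noise_cv: float = 0.05
    time_points_h: tuple = (0, 6, 12, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metabolite is None:
            self.metabolite = DRUG_METABOLITES.get(self.drug)
        if self.metabolite is None:
            raise ValueError(f"no metabolite known for drug {self.drug!r}")
        if any(k < 0 for k in self.decay_rate_per_h.values()):
            raise ValueError("decay rates must be >= 0")
        if self.control_decay_rate_per_h < 0:
            raise ValueError("control decay rate must be >= 0")
        if not 0 <= self.metabolite_yield <= 1:
            raise ValueError("metabolite_yield must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.initial_conc_uM <= 0:
            raise ValueError("initial concentration must be positive")
        if not self.calibration:
            self.calibration = {
                a: PUBLISHED_CALIBRATIONS[a]
                for a in (self.drug, self.metabolite)
                if a in PUBLISHED_CALIBRATIONS
            }
        for analyte in (self.drug, self.metabolite):
            if analyte not in self.calibration:
                raise ValueError(f"no calibration line for analyte {analyte!r}")


def _taxonomy_frame(n_taxa: int, n_families: int) -> pd.DataFrame:
    """Even partition of taxa into families, two genera per family."""
    taxa = [f"ASV_{i + 1:04d}" for i in range(n_taxa)]
    fam_of = np.minimum(np.arange(n_taxa) * n_families // n_taxa, n_families - 1)
    rows = []
    for i in range(n_taxa):
        f = fam_of[i]
        genus = f"Genus_{f + 1:02d}{'a' if i % 2 == 0 else 'b'}"
        rows.append(
            {
                "kingdom": "Bacteria",
                "phylum": f"Phylum_{f % 4 + 1}",
                "class": f"Class_{f % 8 + 1}",
                "order": f"Order_{f % 12 + 1}",
                "family": f"Family_{f + 1:02d}",
                "genus": genus,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(taxa, name="taxon_id"))[list(RANKS)]


def simulate_experiment(
    spec: CommunitySimSpec,
) -> tuple[FeatureTable, Taxonomy, SampleMetadata, dict]:
    """Simulate the full culture design: counts, taxonomy, metadata, truth.

    Cultures get donor baseline + family-level medium and time effects;
    feces samples carry the donor baseline only. ``true_params`` returns
    every drawn effect for parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.depth < spec.n_taxa:
        import logging

        logging.getLogger("culturebench").warning(
            "depth %d < n_taxa %d: many taxa will drop out", spec.depth, spec.n_taxa
        )

    tax_frame = _taxonomy_frame(spec.n_taxa, spec.n_families)
    fam_codes = pd.Categorical(tax_frame["family"]).codes

    donors = [f"D{i + 1}" for i in range(spec.n_donors)]
    media = [f"M{i + 1:02d}" for i in range(spec.n_media)]
    reps = [f"r{i + 1}" for i in range(spec.n_replicates)]

    base = rng.normal(0.0, 1.0, spec.n_taxa)
    donor_eff = rng.normal(0.0, spec.donor_effect_sd, (spec.n_donors, spec.n_taxa))
    medium_eff_fam = rng.normal(
        0.0, spec.medium_effect_sd, (spec.n_media, spec.n_families)
    )
    time_eff_fam = rng.normal(
        0.0, spec.time_effect_sd, (len(spec.time_points_h), spec.n_families)
    )

    sample_ids, meta_rows, count_rows = [], [], []

    def draw_counts(logit: np.ndarray) -> np.ndarray:
        prop = np.exp(logit - logit.max())
        prop /= prop.sum()
        alpha = spec.dirichlet_concentration * prop
        p = rng.dirichlet(alpha)
        return rng.multinomial(spec.depth, p)

    for di, donor in enumerate(donors):
        sid = f"{donor}_feces"
        sample_ids.append(sid)
        meta_rows.append(
            {"donor": donor, "medium": "", "time_h": 0, "replicate": "r1", "role": "feces"}
        )
        count_rows.append(draw_counts(base + donor_eff[di]))
        for mi, medium in enumerate(media):
            for ti, t in enumerate(spec.time_points_h):
                for rep in reps:
                    sid = f"{donor}_{medium}_{t}h_{rep}"
                    sample_ids.append(sid)
                    meta_rows.append(
                        {
                            "donor": donor,
                            "medium": medium,
                            "time_h": t,
                            "replicate": rep,
                            "role": "culture",
                        }
                    )
                    logit = (
                        base
                        + donor_eff[di]
                        + medium_eff_fam[mi][fam_codes]
                        + time_eff_fam[ti][fam_codes]
                    )
                    count_rows.append(draw_counts(logit))

    counts = pd.DataFrame(
        np.vstack(count_rows), index=sample_ids, columns=tax_frame.index
    )
    table = FeatureTable(counts)
    meta = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids))
    truth = {
        "base": base,
        "donor_effect": donor_eff,
        "medium_effect_family": medium_eff_fam,
        "time_effect_family": time_eff_fam,
        "donor_effect_sd": spec.donor_effect_sd,
        "medium_effect_sd": spec.medium_effect_sd,
        "time_effect_sd": spec.time_effect_sd,
        "family_codes": fam_codes,
    }
    return table, Taxonomy(tax_frame), meta, truth


def simulate_pathways(
    table: FeatureTable,
    tax: Taxonomy,
    n_pathways: int = 8,
    seed: int = 0,
) -> PathwayTable:
    """Derive a coarse functional-category table from family abundances.

    Each level-1 category is a fixed non-negative linear combination of
    family relative abundances (a crude stand-in for metagenome function
    prediction): samples with similar family composition get similar
    functional profiles, which is the property the functional-divergence
    metric needs.
    """
    from .metrics import aggregate

    fam = aggregate(table, tax, "family")
    rel = fam.data.div(fam.data.sum(axis=1), axis=0)
    rng = np.random.default_rng(seed)
    loadings = rng.gamma(2.0, 1.0, (rel.shape[1], n_pathways))
    pathways = rel.to_numpy() @ loadings
    cols = [f"PWY_L1_{i + 1}" for i in range(n_pathways)]
    return PathwayTable(
        pd.DataFrame(pathways, index=rel.index, columns=cols) * 1e4
    )


def simulate_growth(
    K: float,
    r: float,
    lag: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    supernatant_od: float = 0.05,
) -> pd.DataFrame:
    """Logistic OD600 curve with a constant supernatant background.

    OD(t) = K / (1 + exp(-r (t - lag))); Gaussian noise on both channels.
    Returns one row per time with od_culture and od_supernatant columns.
    """
    if K <= 0:
        raise ValueError("carrying capacity K must be positive")
    if r < 0:
        raise ValueError("growth rate r must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(list(times), dtype=float)
    od = K / (1.0 + np.exp(-r * (t - lag)))
    culture = np.clip(od + supernatant_od + rng.normal(0, noise_sd, t.size), 0, None)
    supernatant = np.clip(
        supernatant_od + rng.normal(0, noise_sd, t.size), 0, None
    )
    return pd.DataFrame(
        {"time_h": t, "od_culture": culture, "od_supernatant": supernatant}
    )


def simulate_qpcr(
    target_ra: dict,
    ct_16s: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CT values consistent with the 2^(CT16S - CTtarget) quantification.

    ``target_ra`` maps sample_id -> {gene: relative abundance in (0, 1]};
    CT_target = CT_16S - log2(RA) + Gaussian noise. The 16S reference row
    is emitted per sample.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid, genes in target_ra.items():
        rows.append({"sample_id": sid, "gene": "16S", "ct": ct_16s})
        for gene, ra in genes.items():
            if not 0 < ra <= 1:
                raise ValueError(f"relative abundance {ra} for {sid}/{gene} not in (0,1]")
            ct = ct_16s - np.log2(ra) + rng.normal(0, noise_sd)
            rows.append({"sample_id": sid, "gene": gene, "ct": float(ct)})
    return pd.DataFrame(rows)


def simulate_drug_assay(spec: DrugSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-area table plus true concentrations for one drug's assay.

    Emits culture rows per donor and a shared no-microbiome control series
    for both parent and metabolite analytes. Negative computed areas
    (possible with a negative calibration intercept near the LOQ) are
    clipped to 0 with a warning.
    """
    import logging

    logger = logging.getLogger("culturebench")
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))

    def noisy(x: float) -> float:
        if spec.noise_cv == 0:
            return x
        return x * float(rng.lognormal(-(sigma**2) / 2.0, sigma))

    def area(analyte: str, conc: float) -> float:
        a, b = spec.calibration[analyte]
        y = noisy(a * conc + b)
        if y < 0:
            logger.warning(
                "negative simulated area %.3g for %s; clipping to 0", y, analyte
            )
            return 0.0
        return y

    meas, truth = [], []
    c0 = spec.initial_conc_uM
    for donor, k_d in spec.decay_rate_per_h.items():
        for t in spec.time_points_h:
            parent = c0 * np.exp(-k_d * t)
            metab = spec.metabolite_yield * (c0 - parent)
            for analyte, conc in ((spec.drug, parent), (spec.metabolite, metab)):
                meas.append(
                    {
                        "donor": donor,
                        "drug": spec.drug,
                        "analyte": analyte,
                        "time_h": t,
                        "condition": "culture",
                        "area_ratio": area(analyte, conc),
                    }
                )
                truth.append(
                    {
                        "donor": donor,
                        "drug": spec.drug,
                        "analyte": analyte,
                        "time_h": t,
                        "condition": "culture",
                        "conc_uM": conc,
                    }
                )
    for t in spec.time_points_h:
        parent = c0 * np.exp(-spec.control_decay_rate_per_h * t)
        for analyte, conc in ((spec.drug, parent), (spec.metabolite, 0.0)):
            meas.append(
                {
                    "donor": "none",
                    "drug": spec.drug,
                    "analyte": analyte,
                    "time_h": t,
                    "condition": "control",
                    "area_ratio": area(analyte, conc),
                }
            )
            truth.append(
                {
                    "donor": "none",
                    "drug": spec.drug,
                    "analyte": analyte,
                    "time_h": t,
                    "condition": "control",
                    "conc_uM": conc,
                }
            )
    return pd.DataFrame(meas), pd.DataFrame(truth)


def default_drug_specs(
    n_donors: int = 10, seed: int = 0, noise_cv: float = 0.05
) -> list[DrugSimSpec]:
    """Three-drug panel emulating the reported metabolism phenotypes.

    Aspirin: fast hydrolysis, little inter-donor spread. Levodopa: mean
    half-life ~24 h (half the dose remains at 24 h) with large inter-donor
    spread in decarboxylation. Doxifluridine: fast conversion with large
    inter-donor spread. Spreads are lognormal over donors.
    """
    rng = np.random.default_rng(seed)
    donors = [f"D{i + 1}" for i in range(n_donors)]

    def rates(mean_k: float, sigma: float) -> dict:
        return {
            d: float(mean_k * rng.lognormal(-(sigma**2) / 2.0, sigma)) for d in donors
        }

    ln2_24 = np.log(2.0) / 24.0
    return [
        DrugSimSpec(
            drug="aspirin",
            decay_rate_per_h=rates(0.35, 0.08),
            metabolite_yield=0.9,
            control_decay_rate_per_h=0.01,
            noise_cv=noise_cv,
            seed=int(rng.integers(2**31 - 1)),
        ),
        DrugSimSpec(
            drug="levodopa",
            decay_rate_per_h=rates(ln2_24, 0.6),
            metabolite_yield=0.6,
            control_decay_rate_per_h=0.0,
            noise_cv=noise_cv,
            seed=int(rng.integers(2**31 - 1)),
        ),
        DrugSimSpec(
            drug="doxifluridine",
            decay_rate_per_h=rates(0.30, 0.5),
            metabolite_yield=0.5,
            control_decay_rate_per_h=0.0,
            noise_cv=noise_cv,
            seed=int(rng.integers(2**31 - 1)),
        ),
    ]


def with_seed(spec: CommunitySimSpec, seed: int) -> CommunitySimSpec:
    """Copy of a community spec with a different seed."""
    return replace(spec, seed=seed)
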