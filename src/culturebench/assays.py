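"""Non-sequencing evaluation inputs: ΔOD600 growth, qPCR-derived gene
abundance/fold change, and pathway-level functional divergence."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import PathwayTable
from .metrics import Profile, jsd

logger = logging.getLogger("culturebench")

QPCR_MAX_CYCLES = 40.0


@dataclass
class ODRecord:
    """One OD600 reading: whole culture and its centrifuged supernatant."""

    sample_id: str
    time_h: float
    od_culture: float
    od_supernatant: float

    def __post_init__(self) -> None:
        if self.od_culture < 0 or self.od_supernatant < 0:
            raise ValueError(f"negative absorbance for {self.sample_id}")


@dataclass
class CtRecord:
    """One qPCR cycle-threshold reading for a (sample, gene) pair."""

    sample_id: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if not (0 < self.ct <= QPCR_MAX_CYCLES):
            raise ValueError(
                f"CT {self.ct} for {self.sample_id}/{self.gene} outside "
                f"(0, {QPCR_MAX_CYCLES}] (40-cycle protocol)"
            )


def delta_od(r: ODRecord) -> float:
    """ΔOD600 = whole-culture OD minus supernatant OD (biomass proxy).

    Negative values (measurement noise) are preserved but logged, so the
    downstream ranking sees the raw data.
    """
    value = r.od_culture - r.od_supernatant
    if value < 0:
        logger.warning("negative ΔOD600 %.4f for %s (noise?)", value, r.sample_id)
    return value


def relative_abundance(ct_16s: float, ct_target: float) -> float:
    """Target-gene abundance relative to total 16S: 2^(CT_16S - CT_target)."""
    return float(2.0 ** (ct_16s - ct_target))


def fold_change_log2(ra_culture: float, ra_feces: float) -> float:
    """log2 fold change of a gene's relative abundance, culture over feces."""
    if ra_culture <= 0 or ra_feces <= 0:
        raise ValueError("relative abundances must be positive")
    return float(np.log2(ra_culture / ra_feces))


def gene_variation_score(fold_changes) -> float:
    """Mean |log2 fold change| across genes; 0 means identical to feces.

    Aggregation across genes is a design choice: the mean absolute log2
    fold change is symmetric in direction, zero iff every gene is
    unchanged, and invariant to gene order.
    """
    fc = np.asarray(list(fold_changes), dtype=float)
    fc = fc[~np.isnan(fc)]
    if fc.size == 0:
        raise ValueError("need at least one non-missing fold change")
    return float(np.abs(fc).mean())


def gene_fold_changes(
    ct: pd.DataFrame,
    culture_id: str,
    feces_id: str,
    genes,
    reference_gene: str = "16S",
) -> pd.Series:
    """Per-gene log2 fold changes of a culture versus its matched feces.

    ``ct`` is long-format with columns sample_id, gene, ct. A missing CT
    (no amplification within 40 cycles) is censored: the gene's abundance
    is only bounded above by 2^(CT16S - 40), so the gene is excluded from
    the fold-change vector with a log entry rather than imputed.
    """
    wide = ct.pivot_table(index="sample_id", columns="gene", values="ct")
    out = {}
    for g in genes:
        vals = []
        censored = False
        for sid in (culture_id, feces_id):
            ct_ref = wide.at[sid, reference_gene]
            ct_g = wide.at[sid, g] if g in wide.columns else np.nan
            if np.isnan(ct_g):
                bound = relative_abundance(ct_ref, QPCR_MAX_CYCLES)
                logger.warning(
                    "gene %s not amplified in %s; abundance <= %.3g (censored, "
                    "excluded from fold changes)",
                    g,
                    sid,
                    bound,
                )
                censored = True
                break
            vals.append(relative_abundance(ct_ref, ct_g))
        out[g] = np.nan if censored else fold_change_log2(vals[0], vals[1])
    return pd.Series(out, name=culture_id)


def functional_jsd(culture_row: pd.Series, feces_row: pd.Series) -> float:
    """Jensen-Shannon divergence between two pathway-abundance rows.

    Rows are normalised to relative abundances and passed through the same
    base-2 JSD used for taxonomic profiles.
    """
    pathways = list(culture_row.index)
    if list(feces_row.index) != pathways:
        feces_row = feces_row.reindex(pathways, fill_value=0.0)
    p = Profile(pathways, culture_row.to_numpy(float) / culture_row.sum(), level="pathway")
    q = Profile(pathways, feces_row.to_numpy(float) / feces_row.sum(), level="pathway")
    return jsd(p, q)


def pathway_divergences(
    table: PathwayTable, pairs: dict[str, str]
) -> pd.Series:
    """functional_jsd for many (culture -> feces) pairs from one table."""
    out = {}
    for culture, feces in pairs.items():
        out[culture] = functional_jsd(table.data.loc[culture], table.data.loc[feces])
    return pd.Series(out, name="d_js_pathway")


def read_od_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time_h", "od_culture", "od_supernatant"}
    if not required <= set(df.columns):
        raise ValueError(f"OD table missing columns {sorted(required - set(df.columns))}")
    return df


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    required = {"sample_id", "gene", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"CT table missing columns {sorted(required - set(df.columns))}")
    return df
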