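"""Composite medium ranking: per-metric ranks with metric-specific
directions, averaged into a comprehensive rank per culture.

Divergence-type metrics (distance from the source feces, gene variation)
rank ascending — the most faithful culture gets rank 1. Diversity and
growth metrics (Shannon, Simpson, ΔOD600) rank descending — the most
diverse / fastest-growing culture gets rank 1. The comprehensive rank is
the unweighted mean of the per-metric ranks inside a ranking block (the
whole culture set, or one donor's cultures), so a smaller comprehensive
rank always means higher growth, similarity and diversity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("culturebench")

ASCENDING = "ascending"
DESCENDING = "descending"

#: The three-metric composition/diversity panel (15-culture screen).
SCREEN_DIRECTIONS = {
    "euclidean_asv": ASCENDING,
    "d_js_family": ASCENDING,
    "shannon_asv": DESCENDING,
}

#: The full seven-metric panel ranked within per-donor blocks of media.
PANEL_DIRECTIONS = {
    "d_js_family": ASCENDING,
    "euclidean_asv": ASCENDING,
    "d_js_pathway": ASCENDING,
    "gene_variation": ASCENDING,
    "delta_od600": DESCENDING,
    "shannon_asv": DESCENDING,
    "simpson_asv": DESCENDING,
}

PRESETS = {"screen": SCREEN_DIRECTIONS, "panel": PANEL_DIRECTIONS}


def rank_metric(values: pd.Series, direction: str) -> pd.Series:
    """Rank one metric's values; ties get the mean of tied positions.

    Ascending: smallest value -> rank 1. Descending: largest -> rank 1.
    Missing values rank worst (n), with a log entry: a failed assay should
    penalise, not silently vanish.
    """
    if direction not in (ASCENDING, DESCENDING):
        raise ValueError(f"direction must be {ASCENDING!r} or {DESCENDING!r}")
    v = values.astype(float)
    if v.isna().all():
        raise ValueError("no non-missing value to rank")
    n = len(v)
    x = v.to_numpy(copy=True)
    if direction == DESCENDING:
        x = -x
    ranks = np.full(n, float(n))
    ok = ~np.isnan(x)
    ranks[ok] = rankdata(x[ok], method="average")
    if (~ok).any():
        logger.warning(
            "%d missing value(s) in %s assigned worst rank %d",
            int((~ok).sum()),
            values.name or "metric",
            n,
        )
    return pd.Series(ranks, index=v.index, name=values.name)


def comprehensive_rank(
    panel: pd.DataFrame,
    direction_map: dict[str, str],
    blocks: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-metric ranks and their mean (the comprehensive rank) per block.

    ``panel`` has one row per culture and one column per metric;
    ``blocks`` assigns each culture to a ranking block (default: one block
    over the whole panel). Output columns: ``rank_<metric>`` per metric,
    ``comprehensive_rank``, and ``block``; rows sorted by block then
    comprehensive rank.
    """
    missing_dir = [m for m in panel.columns if m not in direction_map]
    if missing_dir:
        raise ValueError(f"metrics without a direction: {missing_dir}")
    if blocks is None:
        blocks = pd.Series("all", index=panel.index)
    blocks = blocks.reindex(panel.index)
    if blocks.isna().any():
        raise ValueError("every culture needs a block assignment")

    pieces = []
    for block_id, idx in panel.groupby(blocks).groups.items():
        sub = panel.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"empty block {block_id!r}")
        ranks = pd.DataFrame(
            {f"rank_{m}": rank_metric(sub[m], direction_map[m]) for m in panel.columns}
        )
        ranks["comprehensive_rank"] = ranks.mean(axis=1)
        ranks["block"] = block_id
        pieces.append(ranks)
    out = pd.concat(pieces).loc[panel.index]
    return out.sort_values(["block", "comprehensive_rank"], kind="stable")


def summarize_media(
    rank_table: pd.DataFrame, media: pd.Series
) -> pd.DataFrame:
    """Mean and dispersion of comprehensive ranks per medium across blocks.

    The best medium minimises the mean comprehensive rank; exact ties are
    reported (``best`` True for all tied media), never broken arbitrarily.
    """
    media = media.reindex(rank_table.index)
    grouped = rank_table["comprehensive_rank"].groupby(media)
    out = pd.DataFrame(
        {
            "mean_rank": grouped.mean(),
            "sd_rank": grouped.std(ddof=1),
            "n": grouped.size(),
        }
    ).sort_values("mean_rank", kind="stable")
    best = out["mean_rank"].min()
    out["best"] = np.isclose(out["mean_rank"], best)
    if int(out["best"].sum()) > 1:
        logger.info("tie for best medium: %s", out.index[out["best"]].tolist())
    return out
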