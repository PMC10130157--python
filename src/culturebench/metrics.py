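"""Normalisation, taxonomic aggregation, alpha-diversity and pairwise
dissimilarities — the metric substrate of the culture evaluation.

All beta-diversity metrics operate on relative abundances (total-sum
scaling); no rarefaction is performed. The Jensen-Shannon divergence is the
divergence itself (not its square root), computed with base-2 logarithms so
it is bounded by [0, 1], matching the base-2 convention used for the
Shannon index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import rel_entr

from .io_tables import DistanceMatrix, FeatureTable, Taxonomy

_SUM_TOL = 1e-9


@dataclass
class Profile:
    """A relative-abundance vector over a taxon (or pathway) universe."""

    taxon_ids: list
    proportions: np.ndarray
    level: str = "asv"

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if (self.proportions < 0).any():
            raise ValueError("negative proportion")
        total = self.proportions.sum()
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"proportions sum to {total}, not 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.taxon_ids)


def to_relative(table: FeatureTable, level: str = "asv") -> dict[str, Profile]:
    """Total-sum scale each sample into a Profile. All-zero samples error."""
    totals = table.counts.sum(axis=1)
    zero = np.asarray(totals == 0).nonzero()[0]
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[table.sample_ids[i] for i in zero]}")
    props = table.counts / totals[:, None]
    return {
        s: Profile(table.taxon_ids, props[i], level=level)
        for i, s in enumerate(table.sample_ids)
    }


def aggregate(table: FeatureTable, tax: Taxonomy, rank: str) -> FeatureTable:
    """Sum counts over taxa sharing a rank label; totals conserved exactly.

    Taxa with missing assignments land in the ``unclassified_<rank>`` bucket
    rather than being dropped.
    """
    labels = [tax.label(t, rank) for t in table.taxon_ids]
    agg = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return FeatureTable(agg)


def _zero_fill(p: Profile, q: Profile) -> tuple[np.ndarray, np.ndarray]:
    if p.taxon_ids == q.taxon_ids:
        return p.proportions, q.proportions
    union = list(dict.fromkeys(list(p.taxon_ids) + list(q.taxon_ids)))
    return (
        p.as_series().reindex(union, fill_value=0.0).to_numpy(),
        q.as_series().reindex(union, fill_value=0.0).to_numpy(),
    )


def shannon(p: Profile, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i, with 0 log 0 = 0."""
    x = p.proportions[p.proportions > 0]
    return float(-(x * (np.log(x) / np.log(base))).sum())


def simpson(p: Profile) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (higher = more diverse)."""
    return float(1.0 - (p.proportions**2).sum())


def _jsd_vec(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    kl_pm = rel_entr(p, m).sum() / np.log(2.0)
    kl_qm = rel_entr(q, m).sum() / np.log(2.0)
    return float(np.clip(0.5 * kl_pm + 0.5 * kl_qm, 0.0, 1.0))


def jsd(p: Profile, q: Profile) -> float:
    """Jensen-Shannon divergence, base 2, in [0, 1]."""
    return _jsd_vec(*_zero_fill(p, q))


def euclidean(p: Profile, q: Profile) -> float:
    """Euclidean distance between relative-abundance vectors."""
    a, b = _zero_fill(p, q)
    return float(np.sqrt(((a - b) ** 2).sum()))


def braycurtis(p: Profile, q: Profile) -> float:
    """Bray-Curtis dissimilarity sum|p-q| / sum(p+q), in [0, 1]."""
    a, b = _zero_fill(p, q)
    denom = (a + b).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(a - b).sum() / denom)


_PAIRWISE = {"jsd": jsd, "euclidean": euclidean, "braycurtis": braycurtis}


def distance_matrix(profiles: dict[str, Profile], metric: str) -> DistanceMatrix:
    """Pairwise dissimilarity matrix over a set of profiles."""
    if metric not in _PAIRWISE:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_PAIRWISE)}")
    ids = list(profiles)
    universe = list(dict.fromkeys(t for s in ids for t in profiles[s].taxon_ids))
    mat = np.vstack(
        [profiles[s].as_series().reindex(universe, fill_value=0.0).to_numpy() for s in ids]
    )
    if metric == "jsd":
        n = len(ids)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = _jsd_vec(mat[i], mat[j])
    else:
        vals = squareform(pdist(mat, metric=metric))
    return DistanceMatrix(ids, vals, metric=metric)


def divergence_from_source(
    cultures: dict[str, Profile],
    source: Profile,
    metric: str = "jsd",
) -> pd.Series:
    """Dissimilarity of each culture profile from its source (feces) profile.

    The source must be at the same level as the cultures; jsd is the default
    family-level similarity measure, euclidean the ASV-level one, either can
    be requested explicitly.
    """
    if metric not in _PAIRWISE:
        raise ValueError(f"unknown metric {metric!r}")
    fn = _PAIRWISE[metric]
    levels = {p.level for p in cultures.values()}
    if levels and levels != {source.level}:
        raise ValueError(
            f"level mismatch: cultures at {sorted(levels)}, source at {source.level!r}"
        )
    return pd.Series({s: fn(p, source) for s, p in cultures.items()}, name=metric)
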