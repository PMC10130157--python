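"""Enterotype clustering: PAM on Jensen-Shannon divergences, cluster count
chosen by the Calinski-Harabasz index, clusters labelled by dominant genus.

The clustering recipe (JSD distance, partitioning around medoids, CH index
over a small k range) is the community-standard enterotyping procedure.
PAM is the classic BUILD + SWAP algorithm run directly on the precomputed
distance matrix; it is deterministic up to seeded tie-breaking. The CH
index is evaluated from the distance matrix through the pairwise-distance
identity for sums of squares (no coordinates needed):

    W = sum over clusters of (sum of within-cluster squared d) / cluster size
    T = (sum of all squared d) / n,  B = T - W
    CH(k) = (B / (k - 1)) / (W / (n - k))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import DistanceMatrix, FeatureTable
from .metrics import distance_matrix, to_relative

logger = logging.getLogger("culturebench")


@dataclass
class EnterotypeResult:
    k: int
    assignment: pd.Series  # sample_id -> cluster index (0-based)
    labels: dict[int, str]  # cluster -> dominant genus name, "g_" prefixed
    quality: pd.Series  # k -> Calinski-Harabasz index
    medoids: dict[int, str]

    def labelled_assignment(self) -> pd.Series:
        return self.assignment.map(self.labels)


def _pam(d: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Partitioning around medoids on a distance matrix; returns medoid indices."""
    n = d.shape[0]
    # BUILD: first medoid minimises total distance; then greedy gain
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(nearest - d[:, c], 0.0).sum() if c not in medoids else -1.0
                for c in range(n)
            ]
        )
        best = np.flatnonzero(gains == gains.max())
        medoids.append(int(rng.choice(best)))
    medoids = sorted(medoids)
    # SWAP until no improving exchange
    def cost(ms):
        return d[:, ms].min(axis=1).sum()

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1 :])
                c = cost(trial)
                if c < current - 1e-12:
                    medoids, current, improved = trial, c, True
        # loop until stable
    return np.asarray(medoids)


def _assign(d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    return np.argmin(d[:, medoids], axis=1)


def calinski_harabasz(d: np.ndarray, labels: np.ndarray) -> float:
    """CH index from a distance matrix via the pairwise-SS identity."""
    n = d.shape[0]
    k = len(np.unique(labels))
    d2 = d**2
    total = d2.sum() / (2.0 * n)
    within = 0.0
    for lvl in np.unique(labels):
        idx = np.where(labels == lvl)[0]
        within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    between = total - within
    if k <= 1 or n <= k or within <= 0:
        return np.nan
    return (between / (k - 1)) / (within / (n - k))


def enterotype(
    genus_table: FeatureTable,
    k_range=range(2, 7),
    seed: int = 0,
) -> EnterotypeResult:
    """Cluster samples of a genus-level table into enterotypes.

    Returns the PAM partition at the CH-optimal k, each cluster labelled by
    the genus with the highest mean relative abundance among its samples.
    """
    ids = genus_table.sample_ids
    n = len(ids)
    if n < 4:
        raise ValueError(f"need >= 4 samples to enterotype, got {n}")
    profiles = to_relative(genus_table, level="genus")
    dm = distance_matrix(profiles, "jsd")
    d = dm.values
    if d.max() <= 1e-12:
        raise ValueError("all samples identical: PAM is degenerate")

    ks = [k for k in k_range if 2 <= k <= n - 1]
    dropped = [k for k in k_range if k not in ks]
    if dropped:
        logger.warning("k values %s exceed n-1=%d; truncated", dropped, n - 1)
    if not ks:
        raise ValueError("no admissible k in k_range")

    rng = np.random.default_rng(seed)
    quality = {}
    partitions = {}
    for k in ks:
        medoids = _pam(d, k, rng)
        labels = _assign(d, medoids)
        quality[k] = calinski_harabasz(d, labels)
        partitions[k] = (medoids, labels)
    quality = pd.Series(quality, name="calinski_harabasz")

    if quality.isna().all():
        best_k = min(ks)
        logger.warning(
            "CH index undefined for every k (no separable structure); "
            "returning smallest k=%d",
            best_k,
        )
    else:
        best_k = int(quality.idxmax())

    medoids, labels = partitions[best_k]
    assignment = pd.Series(labels, index=ids, name="cluster")

    rel = genus_table.data.div(genus_table.data.sum(axis=1), axis=0)
    cluster_labels = {}
    for c in range(best_k):
        members = assignment.index[assignment == c]
        mean_profile = rel.loc[members].mean(axis=0)
        genus = str(mean_profile.idxmax())
        cluster_labels[c] = genus if genus.startswith("g_") else f"g_{genus}"

    return EnterotypeResult(
        k=best_k,
        assignment=assignment,
        labels=cluster_labels,
        quality=quality,
        medoids={c: ids[m] for c, m in enumerate(medoids)},
    )
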