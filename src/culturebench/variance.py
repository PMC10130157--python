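"""Multi-factor PERMANOVA with sequential (Type I) sums of squares.

The total sum of squares of a distance matrix ``d`` is partitioned among an
ordered list of categorical factors. Following McArdle & Anderson's
trace formulation, the matrix ``A = -d^2/2`` is double-centred into the
Gower matrix ``G``; the sum of squares explained by a design matrix with
orthogonal projector ``H`` is ``tr(H G)``. Sequential SS for factor ``k`` is
the increment ``tr(H_k G) - tr(H_{k-1} G)`` where ``H_k`` projects onto the
intercept plus dummy columns of factors ``1..k``. Each factor's pseudo-F is
tested against the single residual mean square; p-values come from free
permutation of sample identities, or from exhaustive enumeration when the
design admits fewer distinct label arrangements than requested permutations.

``Permanova`` / ``PermanovaResults`` follow the statsmodels Model/Results
convention: construct from data, call ``fit()``, read the ANOVA table off
the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .io_tables import DistanceMatrix, SampleMetadata

logger = logging.getLogger("culturebench")

ANOVA_COLUMNS = ["Df", "SumsOfSqs", "MeanSqs", "F.Models", "R2", "Pr(>F)"]

_SS_TOL = 1e-8


def design_df(meta: SampleMetadata, factors: list[str]) -> dict[str, int]:
    """Degrees of freedom per factor (#levels - 1), residual and total.

    Main effects only: residual df = (n - 1) - sum of factor df.
    """
    n = len(meta.sample_ids)
    out: dict[str, int] = {}
    for f in factors:
        out[f] = int(meta.factor(f).nunique()) - 1
    out["Residuals"] = (n - 1) - sum(out.values())
    out["Total"] = n - 1
    return out


def _gower(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d.astype(float) ** 2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str), drop_first=False, dtype=float).to_numpy()


def _projector(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(x) and its rank, via SVD."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * max(x.shape) * np.finfo(float).eps).sum()) if s.size else 0
    u = u[:, :rank]
    return u @ u.T, rank


def _sequential_projectors(
    meta: SampleMetadata, factors: list[str]
) -> tuple[list[np.ndarray], list[int]]:
    """Projectors H_0..H_m for the nested design sequence; checks aliasing."""
    n = len(meta.sample_ids)
    x = np.ones((n, 1))
    h, rank = _projector(x)
    projectors = [h]
    dfs = []
    for f in factors:
        x = np.hstack([x, _dummies(meta.factor(f))])
        h, new_rank = _projector(x)
        df_f = new_rank - rank
        expected = int(meta.factor(f).nunique()) - 1
        if df_f == 0:
            raise ValueError(f"factor {f!r} is aliased with preceding terms")
        if df_f < expected:
            logger.warning(
                "factor %r partially aliased: df %d < %d", f, df_f, expected
            )
        projectors.append(h)
        dfs.append(df_f)
        rank = new_rank
    return projectors, dfs


def _seq_ss(projectors: list[np.ndarray], g: np.ndarray) -> tuple[np.ndarray, float]:
    """Sequential SS per factor plus residual SS, from tr(H G) increments."""
    traces = np.array([float((h * g).sum()) for h in projectors])
    ss = np.diff(traces)
    ss_res = float(np.trace(g)) - traces[-1]
    return ss, ss_res


def _n_distinct_arrangements(meta: SampleMetadata, factors: list[str]) -> int:
    """Distinct permutations of the combined factor-level rows."""
    rows = list(zip(*(meta.factor(f).astype(str) for f in factors)))
    n = len(rows)
    counts: dict[tuple, int] = {}
    for r in rows:
        counts[r] = counts.get(r, 0) + 1
    total = factorial(n)
    for c in counts.values():
        total //= factorial(c)
    return total


def anova_from_ss(
    factor_ss: dict[str, float],
    residual_ss: float,
    df: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble the R2 accounting of an ANOVA table from raw sums of squares.

    Total SS is the sum of the component SS (factors + residual), so the R2
    column always sums to 1 regardless of rounding in the inputs.
    """
    total = sum(factor_ss.values()) + residual_ss
    rows = {}
    for name, ss in factor_ss.items():
        rows[name] = {"SumsOfSqs": ss, "R2": ss / total}
    rows["Residuals"] = {"SumsOfSqs": residual_ss, "R2": residual_ss / total}
    rows["Total"] = {"SumsOfSqs": total, "R2": 1.0}
    out = pd.DataFrame(rows).T
    if df is not None:
        out.insert(0, "Df", [df.get(k, np.nan) for k in out.index])
    return out


@dataclass
class PermanovaResults:
    """Fitted PERMANOVA partition: ANOVA table plus fit metadata."""

    anova_table: pd.DataFrame
    factors: list[str]
    n_samples: int
    n_permutations: int
    exhaustive: bool
    metric: str = ""

    def r2(self, factor: str) -> float:
        return float(self.anova_table.loc[factor, "R2"])

    def p_value(self, factor: str) -> float:
        return float(self.anova_table.loc[factor, "Pr(>F)"])

    def summary(self) -> str:
        scheme = (
            f"exhaustive enumeration ({self.n_permutations} arrangements)"
            if self.exhaustive
            else f"{self.n_permutations} free permutations"
        )
        lines = [
            "PERMANOVA (sequential SS)" + (f" on {self.metric}" if self.metric else ""),
            f"n = {self.n_samples} samples, factors: {', '.join(self.factors)}",
            f"p-values by {scheme}",
            "",
            self.anova_table.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class Permanova:
    """Permutational multivariate ANOVA of a distance matrix.

    Parameters
    ----------
    distance:
        Square symmetric dissimilarity matrix over the samples.
    metadata:
        Per-sample factors; every sample in ``distance`` needs a level for
        every requested factor.
    factors:
        Ordered factor names. Order matters: sums of squares are sequential,
        each factor conditional on those before it.
    """

    def __init__(
        self,
        distance: DistanceMatrix,
        metadata: SampleMetadata,
        factors: list[str],
    ):
        if not factors:
            raise ValueError("at least one factor required")
        missing = [s for s in distance.ids if s not in set(metadata.sample_ids)]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        self.distance = distance
        self.metadata = metadata.subset(distance.ids)
        self.factors = list(factors)
        for f in self.factors:
            levels = self.metadata.factor(f)
            if levels.isna().any():
                bad = levels.index[levels.isna()].tolist()
                raise ValueError(f"factor {f!r} missing for samples {bad}")

    def fit(self, permutations: int = 999, seed: int | None = None) -> PermanovaResults:
        d = self.distance.values
        n = d.shape[0]
        g = _gower(d)
        projectors, dfs = self._checked_projectors()
        ss, ss_res = _seq_ss(projectors, g)
        ss_total = float(np.trace(g))
        df_res = (n - 1) - sum(dfs)
        if df_res <= 0:
            raise ValueError("saturated design: no residual degrees of freedom")

        ms = ss / np.array(dfs, dtype=float)
        ms_res = ss_res / df_res
        degenerate = ss_total <= _SS_TOL
        if degenerate:
            f_obs = np.zeros(len(self.factors))
        else:
            f_obs = ms / ms_res

        exhaustive, p = self._permutation_p(
            g, projectors, dfs, df_res, f_obs, permutations, seed, degenerate
        )

        table = self._assemble(dfs, ss, ss_res, ss_total, ms, ms_res, f_obs, p, df_res, n)
        self._check_invariants(table, n)
        return PermanovaResults(
            anova_table=table,
            factors=self.factors,
            n_samples=n,
            n_permutations=len(p["_nperm"]) if isinstance(p, dict) else permutations,
            exhaustive=exhaustive,
            metric=self.distance.metric,
        )

    # -- internals ----------------------------------------------------------

    def _checked_projectors(self):
        return _sequential_projectors(self.metadata, self.factors)

    def _permutation_p(
        self, g, projectors, dfs, df_res, f_obs, permutations, seed, degenerate
    ):
        n = g.shape[0]
        if degenerate:
            p = {"p": np.ones(len(self.factors)), "_nperm": range(permutations)}
            return False, p
        n_distinct = _n_distinct_arrangements(self.metadata, self.factors)
        exhaustive = n_distinct <= permutations
        if exhaustive:
            logger.info(
                "only %d distinct arrangements <= %d requested permutations; "
                "switching to exhaustive enumeration",
                n_distinct,
                permutations,
            )
            perms = _distinct_row_permutations(self.metadata, self.factors)
        else:
            rng = np.random.default_rng(seed)
            perms = [rng.permutation(n) for _ in range(permutations)]

        count = np.zeros(len(self.factors))
        for perm in perms:
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_res_p = _seq_ss(projectors, gp)
            ms_res_p = ss_res_p / df_res
            if ms_res_p <= 0:
                f_p = np.full(len(dfs), np.inf)
            else:
                f_p = (ss_p / np.array(dfs, dtype=float)) / ms_res_p
            count += f_p >= f_obs - 1e-12
        if exhaustive:
            p_vals = count / len(perms)
        else:
            p_vals = (1.0 + count) / (1.0 + len(perms))
        return exhaustive, {"p": p_vals, "_nperm": perms}

    def _assemble(self, dfs, ss, ss_res, ss_total, ms, ms_res, f_obs, p, df_res, n):
        p_vals = p["p"]
        degenerate = ss_total <= _SS_TOL

        def r2(x: float) -> float:
            return np.nan if degenerate else x / ss_total

        rows = []
        for i, f in enumerate(self.factors):
            rows.append([dfs[i], ss[i], ms[i], f_obs[i], r2(ss[i]), p_vals[i]])
        rows.append([df_res, ss_res, ms_res, np.nan, r2(ss_res), np.nan])
        rows.append([n - 1, ss_total, np.nan, np.nan, 1.0, np.nan])
        return pd.DataFrame(
            rows, index=self.factors + ["Residuals", "Total"], columns=ANOVA_COLUMNS
        )

    @staticmethod
    def _check_invariants(table: pd.DataFrame, n: int) -> None:
        ss = table["SumsOfSqs"]
        assert abs(ss.iloc[:-1].sum() - ss.loc["Total"]) <= _SS_TOL * max(
            1.0, abs(ss.loc["Total"])
        ), "SS additivity violated"
        if ss.loc["Total"] > _SS_TOL:  # R2 undefined on a constant matrix
            assert (
                abs(table["R2"].iloc[:-1].sum() - 1.0) <= 1e-9
            ), "R2 normalisation violated"
        assert int(table["Df"].loc["Total"]) == n - 1


def _distinct_row_permutations(meta: SampleMetadata, factors: list[str]):
    """Index permutations producing each distinct arrangement of design rows once."""
    rows = list(zip(*(meta.factor(f).astype(str) for f in factors)))
    uniq = sorted(set(rows))
    codes = [uniq.index(r) for r in rows]
    # each multiset permutation is a reassignment of design rows to samples;
    # realise it as an index permutation against the fixed by-position design:
    # position i (design row codes[i]) receives the next sample whose newly
    # assigned row equals codes[i]
    out = []
    for arrangement in multiset_permutations(codes):
        pools: dict[int, list[int]] = {c: [] for c in set(codes)}
        for sample_idx, c in enumerate(arrangement):
            pools[c].append(sample_idx)
        cursors = {c: 0 for c in pools}
        perm = []
        for c in codes:
            perm.append(pools[c][cursors[c]])
            cursors[c] += 1
        out.append(np.array(perm))
    return out


def permanova(
    d: DistanceMatrix,
    meta: SampleMetadata,
    factors: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResults:
    """Convenience wrapper: ``Permanova(d, meta, factors).fit(n_perm, seed)``."""
    return Permanova(d, meta, factors).fit(permutations=n_perm, seed=seed)


def exhaustive_permutation_p(
    d: DistanceMatrix, meta: SampleMetadata, factor: str
) -> float:
    """Exact one-factor permutation p-value by enumerating all distinct
    label arrangements, with SS computed from within-group pairwise
    distances (independent of the projector route).

    p = #{arrangements with F >= F_observed} / #arrangements, the observed
    arrangement included.
    """
    labels = np.asarray(meta.subset(d.ids).factor(factor).astype(str))
    n = len(labels)
    d2 = d.values.astype(float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    if ss_total <= _SS_TOL:
        return 1.0
    levels, codes = np.unique(labels, return_counts=False), None
    codes = np.searchsorted(np.unique(labels), labels)
    k = len(np.unique(codes))
    df_a = k - 1
    df_r = n - k
    if df_r <= 0:
        raise ValueError("no residual degrees of freedom")

    def f_stat(c: np.ndarray) -> float:
        ss_within = 0.0
        for lvl in range(k):
            idx = np.where(c == lvl)[0]
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        ss_a = ss_total - ss_within
        if ss_within <= 0:
            return np.inf
        return (ss_a / df_a) / (ss_within / df_r)

    n_distinct = _n_distinct_arrangements(meta.subset(d.ids), [factor])
    if n_distinct > 10_000:
        raise ValueError(f"{n_distinct} distinct arrangements exceed the 10,000 cap")
    f_obs = f_stat(codes)
    hits = 0
    total = 0
    for arrangement in multiset_permutations(list(codes)):
        total += 1
        if f_stat(np.asarray(arrangement)) >= f_obs - 1e-12:
            hits += 1
    return hits / total
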