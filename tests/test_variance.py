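import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from culturebench.io_tables import DistanceMatrix, FeatureTable, SampleMetadata
from culturebench.metrics import distance_matrix, to_relative
from culturebench.variance import (
    Permanova,
    anova_from_ss,
    design_df,
    exhaustive_permutation_p,
    permanova,
)

from conftest import one_factor_metadata, random_distance

TABLE1_SS = {
    "Inter-individual": 5.830,
    "Media": 4.945,
    "Time": 0.522,
    "Reproducibility": 0.005,
}
TABLE2_SS = {"Inter-individual": 4.149, "Media": 0.654}


def brute_force_oneway_ss(d: np.ndarray, labels) -> tuple[float, float]:
    """One-way PERMANOVA SS from within-group pairwise distances (oracle)."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for lvl in np.unique(labels):
        idx = np.where(labels == lvl)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total - ss_within, ss_within


class TestDesignDf:
    def test_three_donor_seven_media_design(self):
        rows = []
        for d, m, t, r in itertools.product(range(3), range(7), (6, 24), range(2)):
            rows.append(
                {
                    "donor": f"D{d}",
                    "medium": f"M{m}",
                    "time_h": t,
                    "replicate": f"r{r}",
                    "role": "culture",
                }
            )
        meta = SampleMetadata(
            pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))])
        )
        df = design_df(meta, ["donor", "medium", "time_h", "replicate"])
        assert (df["donor"], df["medium"], df["time_h"], df["replicate"]) == (2, 6, 1, 1)
        assert df["Residuals"] == 73
        assert df["Total"] == 83

    def test_ten_donor_three_media_design(self):
        rows = []
        for d, m in itertools.product(range(10), range(3)):
            rows.append(
                {
                    "donor": f"D{d}",
                    "medium": f"M{m}",
                    "time_h": 24,
                    "replicate": "r1",
                    "role": "culture",
                }
            )
        meta = SampleMetadata(
            pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))])
        )
        df = design_df(meta, ["donor", "medium"])
        assert (df["donor"], df["medium"], df["Residuals"], df["Total"]) == (9, 2, 18, 29)

    def test_single_factor_two_levels(self):
        meta = one_factor_metadata(["a", "a", "b", "b"])
        df = design_df(meta, ["donor"])
        assert (df["donor"], df["Residuals"]) == (1, 2)


class TestR2Accounting:
    def test_published_medium_screen_r2(self):
        table = anova_from_ss(TABLE1_SS, residual_ss=4.234)
        r2 = table["R2"].round(3)
        assert r2["Inter-individual"] == 0.375
        assert r2["Media"] == 0.318
        assert r2["Time"] == 0.034
        assert r2["Reproducibility"] == 0.000
        assert r2["Residuals"] == 0.273
        assert table.loc["Total", "SumsOfSqs"] == pytest.approx(15.536)

    def test_published_validation_r2(self):
        table = anova_from_ss(TABLE2_SS, residual_ss=1.119)
        r2 = table["R2"].round(3)
        assert r2["Inter-individual"] == 0.701
        assert r2["Media"] == 0.110
        assert r2["Residuals"] == 0.189

    def test_r2_column_sums_to_one(self):
        table = anova_from_ss({"a": 1.0, "b": 2.0}, residual_ss=3.0)
        assert table["R2"].iloc[:-1].sum() == pytest.approx(1.0)


class TestPermanova:
    def test_perfect_two_group_separation(self):
        # within-group distance 0, between-group 1: hand Gower centring
        # gives SS_total = 1, all of it explained by the grouping.
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(list("ABCD"), d)
        meta = one_factor_metadata(["g1", "g1", "g2", "g2"])
        meta.data.index = list("ABCD")
        res = Permanova(dm, meta, ["donor"]).fit(permutations=999, seed=0)
        assert res.r2("donor") == pytest.approx(1.0, abs=1e-12)
        assert res.anova_table.loc["Residuals", "SumsOfSqs"] == pytest.approx(0.0, abs=1e-12)
        assert res.anova_table.loc["Total", "SumsOfSqs"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "labels",
        [
            ["a", "a", "b", "b"],
            ["a", "a", "a", "b", "b", "b"],
            ["a", "a", "b", "b", "c", "c"],
            ["a", "a", "a", "a", "b", "b", "b"],
            ["a", "a", "a", "b", "b", "c", "c", "c"],
        ],
    )
    def test_small_designs_match_brute_force(self, labels):
        """Sequential SS and exhaustive p agree with the enumeration oracle
        on every small one-factor design."""
        n = len(labels)
        dm = random_distance(n, seed=n * 7 + 1)
        meta = one_factor_metadata(labels)
        res = Permanova(dm, meta, ["donor"]).fit(permutations=10_000, seed=0)
        assert res.exhaustive
        ss_between, ss_within = brute_force_oneway_ss(dm.values, labels)
        assert res.anova_table.loc["donor", "SumsOfSqs"] == pytest.approx(
            ss_between, abs=1e-9
        )
        assert res.anova_table.loc["Residuals", "SumsOfSqs"] == pytest.approx(
            ss_within, abs=1e-9
        )
        assert res.p_value("donor") == pytest.approx(
            exhaustive_permutation_p(dm, meta, "donor"), abs=1e-12
        )

    def test_exhaustive_2v2_perfectly_separating(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix([f"S{i}" for i in range(4)], d)
        meta = one_factor_metadata(["a", "a", "b", "b"])
        assert exhaustive_permutation_p(dm, meta, "donor") == pytest.approx(1 / 3)

    def test_constant_distance_degenerate(self):
        dm = DistanceMatrix(list("ABCD"), np.zeros((4, 4)))
        meta = one_factor_metadata(["a", "a", "b", "b"])
        meta.data.index = list("ABCD")
        res = Permanova(dm, meta, ["donor"]).fit(permutations=99, seed=0)
        assert res.p_value("donor") == 1.0
        assert exhaustive_permutation_p(dm, meta, "donor") == 1.0

    def test_one_way_f_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        dm = random_distance(12, seed=42)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        meta = one_factor_metadata(labels)
        mine = Permanova(dm, meta, ["donor"]).fit(permutations=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, dm.ids), grouping=labels, permutations=99
        )
        assert mine.anova_table.loc["donor", "F.Models"] == pytest.approx(
            theirs["test statistic"], abs=1e-9
        )

    def test_sequential_ss_matches_vegan_adonis2(self, tmp_path):
        """Multi-factor sequential SS/R2/F agree with R vegan::adonis2 by='terms'."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the vegan cross-check")
        rng = np.random.default_rng(7)
        ids = [f"S{i}" for i in range(12)]
        counts = pd.DataFrame(
            rng.integers(1, 200, (12, 20)).astype(float),
            index=ids,
            columns=[f"T{j}" for j in range(20)],
        )
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "donor": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                    "medium": ["x", "y"] * 6,
                    "time_h": [6] * 6 + [24] * 6,
                    "replicate": "r1",
                    "role": "culture",
                },
                index=ids,
            )
        )
        dm = distance_matrix(to_relative(FeatureTable(counts)), "braycurtis")
        res = Permanova(dm, meta, ["donor", "medium", "time_h"]).fit(
            permutations=99, seed=1
        )
        dm.to_frame().to_csv(tmp_path / "d.tsv", sep="\t")
        meta.data.to_csv(tmp_path / "meta.tsv", sep="\t", index_label="sample_id")
        rscript = f"""
        suppressMessages(library(vegan))
        d <- as.dist(as.matrix(read.table("{tmp_path}/d.tsv", header=TRUE,
             row.names=1, sep="\\t")))
        meta <- read.table("{tmp_path}/meta.tsv", header=TRUE, row.names=1, sep="\\t")
        meta$time_h <- factor(meta$time_h)
        out <- adonis2(d ~ donor + medium + time_h, data=meta, permutations=99,
                       by="terms")
        write.csv(as.data.frame(out), "{tmp_path}/vegan.csv")
        """
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        vegan = pd.read_csv(tmp_path / "vegan.csv", index_col=0)
        for mine_row, vegan_row in zip(
            ["donor", "medium", "time_h", "Residuals", "Total"],
            ["donor", "medium", "time_h", "Residual", "Total"],
        ):
            assert res.anova_table.loc[mine_row, "SumsOfSqs"] == pytest.approx(
                vegan.loc[vegan_row, "SumOfSqs"], abs=1e-8
            )
            assert res.anova_table.loc[mine_row, "R2"] == pytest.approx(
                vegan.loc[vegan_row, "R2"], abs=1e-8
            )

    def test_aliased_factor_named_in_error(self):
        dm = random_distance(6, seed=3)
        meta = one_factor_metadata(["a", "a", "a", "b", "b", "b"])
        meta.data["medium"] = meta.data["donor"]  # perfectly aliased copy
        with pytest.raises(ValueError, match="medium"):
            Permanova(dm, meta, ["donor", "medium"]).fit(permutations=9)

    def test_permutation_p_reproducible_given_seed(self):
        dm = random_distance(20, seed=8)
        meta = one_factor_metadata(["a"] * 10 + ["b"] * 10)
        p1 = permanova(dm, meta, ["donor"], n_perm=199, seed=5).p_value("donor")
        p2 = permanova(dm, meta, ["donor"], n_perm=199, seed=5).p_value("donor")
        assert p1 == p2

    def test_ss_additivity_and_r2_normalisation(self, small_experiment):
        table, _, meta, _ = small_experiment
        cultures = [s for s in table.sample_ids if meta.data.at[s, "role"] == "culture"]
        sub = FeatureTable(table.data.loc[cultures].copy())
        dm = distance_matrix(to_relative(sub), "braycurtis")
        res = Permanova(dm, meta.subset(cultures), ["donor", "medium", "time_h"]).fit(
            permutations=49, seed=0
        )
        tab = res.anova_table
        assert tab["SumsOfSqs"].iloc[:-1].sum() == pytest.approx(
            tab.loc["Total", "SumsOfSqs"], rel=1e-9
        )
        assert tab["R2"].iloc[:-1].sum() == pytest.approx(1.0, abs=1e-9)


class TestEffectMonotonicity:
    def test_p_decreases_with_effect_size(self):
        """Stronger group separation gives smaller permutation p (in expectation)."""
        rng = np.random.default_rng(0)
        from scipy.spatial.distance import pdist, squareform

        def p_at(shift):
            ps = []
            for seed in range(5):
                local = np.random.default_rng(seed)
                x = local.normal(size=(16, 4))
                x[8:] += shift
                dm = DistanceMatrix(
                    [f"S{i}" for i in range(16)], squareform(pdist(x))
                )
                meta = one_factor_metadata(["a"] * 8 + ["b"] * 8)
                ps.append(
                    permanova(dm, meta, ["donor"], n_perm=199, seed=seed).p_value("donor")
                )
            return np.mean(ps)

        assert p_at(2.0) < p_at(0.0)
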