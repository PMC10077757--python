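"""enrichment: moderated t, weighted-KS scores, permutations, BH."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special
from scipy import stats as sps

from synscreen import simulate
from synscreen.enrichment import (
    bh_adjust,
    biomarker_gsea,
    build_continuous_design,
    build_group_design,
    compound_set_enrichment,
    enrichment_score,
    moderated_t,
    mutation_association,
    permutation_test,
    rank_features,
)
from synscreen.errors import ValidationError
from synscreen.screen_io import SensitivityDataset, SetCollection


def brute_force_es(ranking: pd.Series, members, weight=1.0):
    """Independent O(N*|set|) running-sum recomputation."""
    member_set = set(members)
    t = ranking.to_numpy(dtype=float)
    ids = list(ranking.index)
    n = len(ids)
    in_set = [f in member_set for f in ids]
    denom = sum(abs(t[i]) ** weight for i in range(n) if in_set[i])
    n_miss = n - sum(in_set)
    running = []
    total = 0.0
    for i in range(n):
        if in_set[i]:
            total += abs(t[i]) ** weight / denom
        else:
            total -= 1.0 / n_miss
        running.append(total)
    best = max(running)
    worst = min(running)
    return best if best >= -worst else worst


def ols_t(y, X, j):
    """Ordinary-least-squares t for column j (direct formula)."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    return beta[j] / np.sqrt(s2 * XtX_inv[j, j])


@pytest.fixture
def group_design():
    idx = [f"s{i}" for i in range(10)]
    flags = pd.Series([True] * 5 + [False] * 5, index=idx)
    return build_group_design(flags, name="group")


class TestModeratedT:
    def test_equal_variances_shrink_fully_preserving_ordering(self, group_design):
        """Identical residual variances: complete shrinkage (d0 = inf)
        and every moderated t proportional to the ordinary t by the same
        factor (the log-scale moment estimator's finite-df correction
        exp(log(d/2) - digamma(d/2)), as in the R reference)."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 10)
        Y = pd.DataFrame([base + 0.5 * group_design["group"].to_numpy(),
                          base - 1.0 * group_design["group"].to_numpy(),
                          base], index=list("abc"),
                         columns=group_design.index)
        res = moderated_t(Y, group_design, coef="group")
        assert np.isinf(res.d0)
        X = group_design.to_numpy()
        d = 10 - 2
        factor = np.exp(0.5 * (np.log(d / 2) - special.digamma(d / 2)))
        for fid in "ab":
            expected = ols_t(Y.loc[fid].to_numpy(), X, 1)
            assert res.table.loc[fid, "t"] == pytest.approx(
                expected / factor, rel=1e-9)

    def test_single_feature_is_ordinary_t(self, group_design):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 10) + group_design["group"].to_numpy()
        Y = pd.DataFrame([y], index=["only"], columns=group_design.index)
        res = moderated_t(Y, group_design, coef="group")
        assert res.d0 == 0.0
        assert res.table.loc["only", "t"] == pytest.approx(
            ols_t(y, group_design.to_numpy(), 1), rel=1e-9)

    def test_moderation_bridging_by_injection(self, group_design):
        rng = np.random.default_rng(2)
        Y = pd.DataFrame(rng.normal(0, rng.uniform(0.5, 2, (30, 1)), (30, 10)),
                         index=[f"f{i}" for i in range(30)],
                         columns=group_design.index)
        none = moderated_t(Y, group_design, coef="group", d0_override=0.0)
        full = moderated_t(Y, group_design, coef="group", d0_override=np.inf)
        X = group_design.to_numpy()
        for fid in Y.index[:5]:
            assert none.table.loc[fid, "t"] == pytest.approx(
                ols_t(Y.loc[fid].to_numpy(), X, 1), rel=1e-9)
        assert np.allclose(full.table["s2_post"], full.s0_sq)

    def test_posterior_variance_between_prior_and_sample(self, group_design):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.normal(0, rng.uniform(0.2, 3, (40, 1)), (40, 10)),
                         index=[f"f{i}" for i in range(40)],
                         columns=group_design.index)
        res = moderated_t(Y, group_design, coef="group")
        lo = np.minimum(res.table["s2"], res.s0_sq) - 1e-12
        hi = np.maximum(res.table["s2"], res.s0_sq) + 1e-12
        assert ((res.table["s2_post"] >= lo) & (res.table["s2_post"] <= hi)).all()

    def test_sign_recovery_of_planted_effects(self, group_design):
        rng = np.random.default_rng(4)
        effects = np.where(np.arange(50) < 25, 3.0, -3.0)  # 3 sigma
        Y = pd.DataFrame(
            rng.normal(0, 1, (50, 10))
            + effects[:, None] * group_design["group"].to_numpy()[None, :],
            index=[f"f{i}" for i in range(50)], columns=group_design.index)
        res = moderated_t(Y, group_design, coef="group")
        assert (np.sign(res.table["t"]) == np.sign(effects)).all()

    def test_rank_deficient_design_names_columns(self):
        idx = [f"s{i}" for i in range(6)]
        design = pd.DataFrame({"intercept": 1.0,
                               "a": [1, 1, 1, 0, 0, 0],
                               "b": [0, 0, 0, 1, 1, 1]}, index=idx)
        Y = pd.DataFrame(np.random.default_rng(5).normal(size=(3, 6)),
                         columns=idx)
        with pytest.raises(ValidationError, match="collinear"):
            moderated_t(Y, design, coef="a")

    def test_missing_data_min_observation_rules(self, group_design):
        rng = np.random.default_rng(6)
        Y = pd.DataFrame(rng.normal(size=(4, 10)),
                         index=list("wxyz"), columns=group_design.index)
        Y.iloc[0, :4] = np.nan   # only 1 obs in group True -> dropped
        res = moderated_t(Y, group_design, coef="group", group="group")
        assert "w" not in res.table.index
        assert set("xyz") <= set(res.table.index)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestLimmaCrossCheck:
    def test_moderated_t_matches_limma(self, tmp_path, group_design):
        """Independent oracle: the R implementation of empirical-Bayes
        moderated t-statistics on the same matrix and design."""
        rng = np.random.default_rng(17)
        Y = pd.DataFrame(
            rng.normal(0, rng.uniform(0.5, 2.0, (40, 1)), (40, 10))
            + rng.normal(0, 1, (40, 1)) * group_design["group"].to_numpy(),
            index=[f"f{i}" for i in range(40)], columns=group_design.index)
        Y.to_csv(tmp_path / "y.csv")
        group_design.to_csv(tmp_path / "design.csv")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            y <- as.matrix(read.csv(commandArgs(TRUE)[1], row.names = 1))
            design <- as.matrix(read.csv(commandArgs(TRUE)[2], row.names = 1))
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(t = fit$t[, "group"], d0 = fit$df.prior,
                              s0 = fit$s2.prior)
            write.csv(out, commandArgs(TRUE)[3])
        """)
        (tmp_path / "limma.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "limma.R"), str(tmp_path / "y.csv"),
             str(tmp_path / "design.csv"), str(tmp_path / "out.csv")],
            check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        res = moderated_t(Y, group_design, coef="group")
        np.testing.assert_allclose(res.table["t"], ref["t"], rtol=1e-6)
        assert res.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert res.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)


class TestRankFeatures:
    def test_descending_with_lexicographic_ties(self):
        t = pd.Series({"a": 2.0, "b": -1.0, "c": 3.0})
        assert list(rank_features(t).index) == ["c", "a", "b"]
        tied = pd.Series({"b": 1.0, "a": 1.0})
        assert list(rank_features(tied).index) == ["a", "b"]

    def test_non_finite_dropped(self):
        t = pd.Series({"a": 1.0, "b": np.nan, "c": 0.5})
        assert list(rank_features(t).index) == ["a", "c"]


class TestEnrichmentScore:
    def test_single_top_hit_scores_one(self):
        ranking = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                            index=list("abcde"))
        es, running, leading = enrichment_score(ranking, {"a"})
        assert es == pytest.approx(1.0)
        assert leading == ["a"]

    def test_whole_universe_set_scores_one(self):
        ranking = pd.Series([2.0, 1.0, -1.0], index=list("abc"))
        es, _, _ = enrichment_score(ranking, set("abc"))
        assert es == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(20, 200))
            ids = [f"g{i:03d}" for i in range(n)]
            ranking = rank_features(
                pd.Series(rng.normal(0, 1, n), index=ids))
            size = int(rng.integers(1, max(2, n // 3)))
            members = set(rng.choice(ids, size=size, replace=False))
            es, _, _ = enrichment_score(ranking, members)
            assert es == pytest.approx(brute_force_es(ranking, members),
                                       abs=1e-12)

    def test_bottom_heavy_set_is_negative(self):
        ranking = pd.Series(np.linspace(3, -3, 30),
                            index=[f"g{i:02d}" for i in range(30)])
        es, _, leading = enrichment_score(ranking, {"g27", "g28", "g29"})
        assert es < -0.5
        assert set(leading) == {"g27", "g28", "g29"}


class TestPermutationTest:
    @staticmethod
    def _ranking(n=100, seed=0):
        rng = np.random.default_rng(seed)
        return rank_features(pd.Series(rng.normal(0, 1, n),
                                       index=[f"g{i:03d}" for i in range(n)]))

    def test_same_seed_identical_results(self):
        ranking = self._ranking()
        sets = SetCollection.from_dict(
            {f"S{i}": [f"g{j:03d}" for j in range(i, i + 10)] for i in range(5)})
        a = permutation_test(ranking, sets, n_perm=200, seed=11)
        b = permutation_test(ranking, sets, n_perm=200, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_top_set_reaches_floor_p(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.normal(0, 1, 200))[::-1]
        ids = [f"g{i:03d}" for i in range(200)]
        ranking = pd.Series(t, index=ids)
        sets = SetCollection.from_dict({"TOP": ids[:15]})
        res = permutation_test(ranking, sets, n_perm=1000, seed=1)
        assert res.loc[0, "pval"] <= 0.005
        assert res.loc[0, "nes"] > 1.5

    def test_min_size_filter(self):
        ranking = self._ranking()
        sets = SetCollection.from_dict({"small": ["g001", "g002"],
                                        "ok": [f"g{i:03d}" for i in range(8)]})
        res = permutation_test(ranking, sets, n_perm=200, seed=0, min_size=5)
        assert list(res["set"]) == ["ok"]

    def test_nperm_minimum_enforced(self):
        with pytest.raises(ValidationError):
            permutation_test(self._ranking(),
                             SetCollection.from_dict({"s": ["g001"] * 5}),
                             n_perm=10)

    def test_null_p_roughly_uniform(self):
        ranking = self._ranking(n=300, seed=3)
        sets = simulate.gen_gene_sets(list(ranking.index), n_sets=60,
                                      size_range=(8, 25), seed=4)
        res = permutation_test(ranking, sets, n_perm=300, seed=5)
        frac = (res["pval"] < 0.25).mean()
        assert 0.1 < frac < 0.45


class TestBHAdjust:
    def test_step_up_hand_computed(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_constant(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.4, 0.4, 0.4]), 0.4)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 50)
        padj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= p - 1e-12).all() and (padj <= 1).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


def _dataset(seed=0, **kwargs):
    ds, truth = simulate.gen_sensitivity_dataset(seed=seed, **kwargs)
    return ds, truth


class TestCompoundSetEnrichment:
    def test_planted_pathway_most_negative_and_significant(self):
        ds, _ = _dataset(n_ped=30, n_adult=120,
                         shifted_pathways={"DNA replication": -0.15}, seed=21)
        res, _ = compound_set_enrichment(ds, n_perm=500, seed=21)
        top = res.loc[res["nes"].abs().idxmax()]
        assert top["set"] == "DNA replication"
        assert top["nes"] < 0          # more sensitive in pediatric lines
        assert top["padj"] < 0.05

    def test_sign_convention_flips_with_response(self):
        ds, _ = _dataset(n_ped=30, n_adult=120,
                         shifted_pathways={"WNT signaling": 0.15}, seed=22)
        res, _ = compound_set_enrichment(ds, n_perm=500, seed=22)
        row = res[res["set"] == "WNT signaling"].iloc[0]
        assert row["nes"] > 0          # less sensitive in pediatric lines


class TestBiomarkerGsea:
    def test_permuting_labels_destroys_association(self):
        ds, _ = _dataset(n_ped=20, n_adult=40, seed=23)
        genes = [f"G{i + 1:05d}" for i in range(400)]
        sets = simulate.gen_gene_sets(genes, n_sets=10, size_range=(15, 30),
                                      seed=23)
        expr, _ = simulate.gen_expression_dataset(
            n_genes=400, planted_sets=sets, betas={"SET001": 2.0},
            dataset=ds, compound="CPD001", noise_sd=0.5, seed=23)
        res, _ = biomarker_gsea(expr, ds, "CPD001", sets, n_perm=500, seed=23)
        planted_p = res.loc[res["set"] == "SET001", "pval"].iloc[0]
        rng = np.random.default_rng(24)
        shuffled = expr.copy()
        shuffled.columns = rng.permutation(expr.columns)
        shuffled = shuffled[expr.columns]
        res_null = biomarker_gsea(shuffled, ds, "CPD001", sets,
                                  n_perm=500, seed=24)[0]
        null_p = res_null.loc[res_null["set"] == "SET001", "pval"].iloc[0]
        assert planted_p < 0.01
        assert null_p > planted_p

    def test_unknown_compound_is_error(self):
        ds, _ = _dataset(seed=25)
        with pytest.raises(ValidationError):
            biomarker_gsea(pd.DataFrame(), ds, "NOPE",
                           SetCollection(), n_perm=100)


class TestMutationAssociation:
    def test_extreme_separation_matches_exact_enumeration(self):
        # 3 mutant lines all strictly below 5 wild-type lines
        from itertools import combinations
        auc = pd.DataFrame({"c1": [0.1, 0.12, 0.15, 0.6, 0.7, 0.75, 0.8, 0.9]},
                           index=[f"L{i}" for i in range(8)])
        meta = pd.DataFrame({
            "pediatric": True, "tumor_type": "NB",
            "mut": [True] * 3 + [False] * 5}, index=auc.index)
        cmeta = pd.DataFrame({"target": ["t"], "target_pathway": ["p"]},
                             index=["c1"])
        ds = SensitivityDataset(auc=auc, cell_meta=meta, compound_meta=cmeta)
        res = mutation_association(ds, "c1", "mut")
        # exact two-sided p: enumerate all rank-sum assignments
        values = auc["c1"].to_numpy()
        ranks = sps.rankdata(values)
        observed = ranks[:3].sum()
        sums = [sum(ranks[list(c)]) for c in combinations(range(8), 3)]
        lo = sum(s <= observed for s in sums) / len(sums)
        hi = sum(s >= observed for s in sums) / len(sums)
        exact_p = min(1.0, 2 * min(lo, hi))
        assert res["pval"] == pytest.approx(exact_p, rel=1e-9)
        assert res["n_mutant"] == 3 and res["median_mutant"] < res["median_wildtype"]

    def test_single_mutant_line_defined(self):
        auc = pd.DataFrame({"c1": [0.3, 0.6, 0.7, 0.8]},
                           index=[f"L{i}" for i in range(4)])
        meta = pd.DataFrame({"pediatric": True, "tumor_type": "NB",
                             "mut": [True, False, False, False]},
                            index=auc.index)
        cmeta = pd.DataFrame({"target": ["t"], "target_pathway": ["p"]},
                             index=["c1"])
        ds = SensitivityDataset(auc=auc, cell_meta=meta, compound_meta=cmeta)
        res = mutation_association(ds, "c1", "mut")
        assert 0 < res["pval"] <= 1

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(26)
        auc = pd.DataFrame({"c1": rng.uniform(0.3, 0.7, 40)},
                           index=[f"L{i}" for i in range(40)])
        meta = pd.DataFrame({"pediatric": True, "tumor_type": "NB",
                             "mut": [True] * 20 + [False] * 20},
                            index=auc.index)
        cmeta = pd.DataFrame({"target": ["t"], "target_pathway": ["p"]},
                             index=["c1"])
        ds = SensitivityDataset(auc=auc, cell_meta=meta, compound_meta=cmeta)
        assert mutation_association(ds, "c1", "mut")["pval"] > 0.01


class TestDesignBuilders:
    def test_continuous_design_with_categorical(self):
        idx = [f"s{i}" for i in range(8)]
        cov = pd.Series(np.linspace(0, 1, 8), index=idx)
        cat = pd.Series(["a", "a", "b", "b", "c", "c", "a", "b"], index=idx,
                        name="type")
        design = build_continuous_design(cov, cat, name="auc")
        assert design.shape == (8, 4)  # intercept + auc + 2 dummies
        assert np.linalg.matrix_rank(design.to_numpy(float)) == 4
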