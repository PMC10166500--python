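import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stagediv import CountMatrix
from stagediv.de import (
    DesignSpec,
    bh_adjust,
    compare_magnitudes,
    de_table,
    estimate_dispersion,
    lrt_interaction,
    six_level_design,
    strain_de,
    upset_intersections,
    wald_contrast,
)
from stagediv.simulate import SimConfig, simulate_counts


def nb_counts(rng, mu, alpha, shape):
    if alpha <= 0:
        return rng.poisson(mu, size=shape)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=shape)


def frame(arr, prefix="s"):
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


@pytest.fixture(scope="module")
def six_groups():
    cols = [f"s{j}" for j in range(18)]
    groups = pd.Series([f"G{j // 3}" for j in range(18)], index=cols, name="group")
    sf = pd.Series(1.0, index=cols, name="size_factor")
    return cols, groups, sf


class TestDispersion:
    def test_poisson_counts_yield_tiny_alpha(self, six_groups):
        cols, groups, sf = six_groups
        rng = np.random.default_rng(0)
        counts = frame(nb_counts(rng, 100.0, 0.0, (400, 18)))
        disp = estimate_dispersion(counts, groups, sf)
        assert (disp["alpha"] <= 0.01).mean() >= 0.9

    def test_true_alpha_half_recovered(self, six_groups):
        cols, groups, sf = six_groups
        rng = np.random.default_rng(1)
        counts = frame(nb_counts(rng, 100.0, 0.5, (400, 18)))
        disp = estimate_dispersion(counts, groups, sf)
        assert 0.3 <= disp["alpha"].median() <= 0.8

    def test_all_zero_gene_flagged_untestable(self, six_groups):
        cols, groups, sf = six_groups
        counts = frame(np.zeros((2, 18), dtype=int))
        counts.iloc[1] = 5
        disp = estimate_dispersion(counts, groups, sf)
        assert disp.loc["g0", "untestable"]
        assert np.isnan(disp.loc["g0", "alpha"])
        assert not disp.loc["g1", "untestable"]


class TestWald:
    def test_sign_convention_zero_group_down(self, six_groups):
        cols, groups, sf = six_groups
        arr = np.zeros((1, 18), dtype=int)
        arr[0, :3] = 500  # group G0 high, others zero
        counts = frame(arr)
        alpha = pd.Series([0.05], index=counts.index)
        res = wald_contrast(counts, groups, ("G0", "G1"), sf, alpha)
        assert res["log2fc"].iloc[0] > 5
        assert res["direction"].iloc[0] == "G0"
        assert res["pvalue"].iloc[0] < 1e-4

    def test_antisymmetric_under_reversal(self, six_groups):
        cols, groups, sf = six_groups
        rng = np.random.default_rng(2)
        counts = frame(nb_counts(rng, 80.0, 0.1, (50, 18)))
        alpha = estimate_dispersion(counts, groups, sf)["alpha"]
        fwd = wald_contrast(counts, groups, ("G0", "G1"), sf, alpha)
        rev = wald_contrast(counts, groups, ("G1", "G0"), sf, alpha)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)

    def test_effect_recovery_small(self):
        cfg = SimConfig(n_genes=600, frac_stage_de=0, frac_interaction=0,
                        frac_stage_specific=0, frac_pop_de=0.2,
                        baseline_logmean_range=(7.0, 10.0), seed=13)
        cm, truth = simulate_counts(cfg)
        design = six_level_design(cm, contrasts="canonical")
        de = de_table(cm, design)
        sub = de[de["contrast"] == "NL_early_vs_ZI_early"].set_index("gene")
        pos = truth[truth["is_pop_de"]]
        err = sub.loc[pos.index, "log2fc"] - pos["true_pop_log2fc"]
        assert err.abs().median() < 0.3


class TestLrt:
    def test_identical_models_statistic_zero(self, six_groups):
        # no interaction structure possible with a single population level
        cols, groups, sf = six_groups
        rng = np.random.default_rng(3)
        counts = frame(nb_counts(rng, 100.0, 0.05, (5, 18)))
        stage = pd.Series(["early", "late", "prepup"] * 6, index=cols)
        pop = pd.Series(["NL"] * 18, index=cols)
        alpha = pd.Series(0.05, index=counts.index)
        res = lrt_interaction(counts, stage, pop, sf, alpha)
        # with one population the interaction design collapses: df = 0
        assert (res["df"] == 0).all() or np.allclose(res["stat"].fillna(0), 0, atol=1e-6)

    def test_strong_interaction_detected(self):
        rng = np.random.default_rng(4)
        cols = [f"s{j}" for j in range(18)]
        stage = pd.Series((["early"] * 3 + ["late"] * 3 + ["prepup"] * 3) * 2,
                          index=cols)
        pop = pd.Series(["NL"] * 9 + ["ZI"] * 9, index=cols)
        sf = pd.Series(1.0, index=cols)
        mu = np.full(18, 200.0)
        # opposite late-stage response in the two populations
        mu[(stage == "late") & (pop == "NL")] = 800.0
        mu[(stage == "late") & (pop == "ZI")] = 50.0
        counts = frame(nb_counts(rng, mu, 0.05, (20, 18)))
        alpha = pd.Series(0.05, index=counts.index)
        res = lrt_interaction(counts, stage, pop, sf, alpha)
        assert (res["pvalue"] < 1e-4).mean() > 0.9


class TestBh:
    def test_hand_values(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)
        np.testing.assert_allclose(bh_adjust([0.001, 0.5, 0.9, 1.0]),
                                   [0.004, 1.0, 1.0, 1.0], atol=1e-12)
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_excluded_from_m(self):
        out = bh_adjust(pd.Series([0.01, np.nan, 0.02]))
        assert np.isnan(out.iloc[1])
        np.testing.assert_allclose(out.dropna(), [0.02, 0.02], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert (adj <= 1 + 1e-12).all()
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDeTable:
    def test_all_null_few_calls(self):
        cfg = SimConfig(n_genes=800, frac_stage_de=0, frac_pop_de=0,
                        frac_interaction=0, frac_stage_specific=0, seed=17)
        cm, _ = simulate_counts(cfg)
        design = six_level_design(cm, contrasts="canonical")
        de = de_table(cm, design)
        per_contrast = de.groupby("contrast")["significant"].mean()
        assert (per_contrast <= 0.01).all()

    def test_upset_intersections_partition(self):
        sets = {"A": {"g1", "g2", "g3"}, "B": {"g2", "g3"}, "C": {"g3", "g4"}}
        out = upset_intersections(sets)
        assert out["count"].sum() == 4  # union size
        row = out[out["sets"] == "A&B&C"]
        assert row["count"].iloc[0] == 1


class TestCompareMagnitudes:
    def test_identical_sets_t_zero(self):
        r = compare_magnitudes([1, 2, 3], [1, 2, 3])
        assert r["t"] == pytest.approx(0.0)
        assert r["pvalue"] == pytest.approx(1.0)

    def test_shifted_normals_strongly_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 0.1, 100)
        b = rng.normal(2.0, 0.1, 100)
        r = compare_magnitudes(a, b, n_tests=10)
        assert r["p_bonferroni"] < 1e-10

    def test_single_test_bonferroni_is_raw(self):
        r = compare_magnitudes([1.0, 2.0, 3.0], [1.5, 2.5, 3.5], n_tests=1)
        assert r["p_bonferroni"] == pytest.approx(r["pvalue"])


class TestStrainDe:
    @staticmethod
    def strain_cm(shift_strain=None, n_genes=300, seed=6):
        rng = np.random.default_rng(seed)
        strains = ["m1", "m2", "m3", "m4", "m5"]
        cols = [f"{s}_r{r}" for s in strains for r in (1, 2)]
        mu = np.full((n_genes, len(cols)), 100.0)
        truth = np.zeros(n_genes, dtype=bool)
        if shift_strain is not None:
            shifted = rng.choice(n_genes, size=n_genes // 10, replace=False)
            truth[shifted] = True
            idx = [j for j, c in enumerate(cols) if c.startswith(shift_strain)]
            mu[np.ix_(shifted, idx)] *= 4.0
        counts = nb_counts(rng, mu, 0.05, mu.shape)
        cdf = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                           columns=cols)
        sample_meta = pd.DataFrame({
            "population": "MU", "stage": "late",
            "replicate": [c.split("_r")[1] for c in cols],
            "strain": [c.split("_r")[0] for c in cols],
        }, index=cols)
        gene_meta = pd.DataFrame({"biotype": "protein_coding"}, index=cdf.index)
        return CountMatrix(counts=cdf, sample_meta=sample_meta,
                           gene_meta=gene_meta), truth

    def test_pairwise_contrast_count(self):
        cm, _ = self.strain_cm()
        de = strain_de(cm, mode="pairwise")
        assert de["contrast"].nunique() == 10  # 5*4/2

    def test_identical_strains_near_zero_calls(self):
        cm, _ = self.strain_cm()
        de = strain_de(cm, mode="pairwise")
        assert de["significant"].mean() < 0.01

    def test_one_vs_rest_recovers_shifted_strain(self):
        cm, truth = self.strain_cm(shift_strain="m3")
        de = strain_de(cm, mode="one_vs_rest")
        sub = de[de["contrast"] == "m3_vs_rest"].set_index("gene")
        recall = sub.loc[[f"g{i}" for i in np.flatnonzero(truth)],
                         "significant"].mean()
        assert recall >= 0.7
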