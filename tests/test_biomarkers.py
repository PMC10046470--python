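import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hma_kit import biomarkers, dose_response as dr
from hma_kit.errors import InputError, UndefinedCorrelationError

LINES = [f"c{i}" for i in range(12)]
CLASSES = pd.Series([dr.RESPONDER] * 4 + [dr.INTERMEDIATE] * 4
                    + [dr.NONRESPONDER] * 4, index=LINES)
LINEAGE = pd.Series([1, 0, 1, 0] * 3, index=LINES)


def lstsq_oracle(y, classes=CLASSES, lineage=LINEAGE):
    """Independent normal-equations fit of y ~ 1 + group + lineage."""
    used = classes.index[classes.isin([dr.RESPONDER, dr.NONRESPONDER])]
    X = np.column_stack([
        np.ones(len(used)),
        (classes[used] == dr.NONRESPONDER).astype(float),
        lineage[used].astype(float),
    ])
    yv = np.asarray(y)[[list(classes.index).index(u) for u in used]]
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    return beta


class TestDifferentialExpression:
    def test_exact_planted_effect(self):
        y = 2.0 + 1.0 * (CLASSES == dr.NONRESPONDER).astype(float)
        expr = pd.DataFrame([y.to_numpy()], index=["g1"], columns=LINES)
        res = biomarkers.differential_expression(expr, CLASSES, LINEAGE)
        assert res["coefficient"].item() == pytest.approx(1.0)
        assert res["p_value"].item() < 1e-10
        assert res["direction"].item() == biomarkers.RESISTANCE

    def test_lineage_only_gene_has_zero_group_coefficient(self):
        y = 3.0 + 2.0 * LINEAGE.astype(float)
        expr = pd.DataFrame([y.to_numpy()], index=["g1"], columns=LINES)
        res = biomarkers.differential_expression(expr, CLASSES, LINEAGE)
        assert res["coefficient"].item() == pytest.approx(0.0, abs=1e-10)
        oracle = lstsq_oracle(y.to_numpy())
        assert res["coefficient"].item() == pytest.approx(oracle[1], abs=1e-10)

    def test_oracle_equivalence_random_matrix(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(40, 12)),
                            index=[f"g{i}" for i in range(40)], columns=LINES)
        res = biomarkers.differential_expression(expr, CLASSES, LINEAGE)
        for i in range(40):
            oracle = lstsq_oracle(expr.iloc[i].to_numpy())
            assert res["coefficient"].iloc[i] == pytest.approx(oracle[1])

    def test_p_values_match_statsmodels_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        expr = pd.DataFrame([y], index=["g1"], columns=LINES)
        res = biomarkers.differential_expression(expr, CLASSES, LINEAGE)
        used = CLASSES.index[CLASSES.isin([dr.RESPONDER, dr.NONRESPONDER])]
        X = sm.add_constant(np.column_stack([
            (CLASSES[used] == dr.NONRESPONDER).astype(float),
            LINEAGE[used].astype(float)]))
        fit = sm.OLS(y[[list(LINES).index(u) for u in used]], X).fit()
        assert res["p_value"].item() == pytest.approx(fit.pvalues[1])

    def test_constant_gene_flagged_p_one(self):
        expr = pd.DataFrame([[5.0] * 12], index=["g1"], columns=LINES)
        res = biomarkers.differential_expression(expr, CLASSES, LINEAGE)
        assert res["p_value"].item() == 1.0
        assert res["constant"].item()

    def test_small_class_rejected(self):
        classes = CLASSES.copy()
        classes.iloc[:2] = dr.INTERMEDIATE
        expr = pd.DataFrame(np.zeros((1, 12)), index=["g1"], columns=LINES)
        with pytest.raises(InputError):
            biomarkers.differential_expression(expr, classes, LINEAGE)

    def test_bh_adjustment_monotone_and_order_invariant(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(100, 12)),
                            index=[f"g{i}" for i in range(100)], columns=LINES)
        res = biomarkers.differential_expression(expr, CLASSES, LINEAGE)
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        by_p = res.sort_values("p_value")
        assert by_p["p_adjusted"].is_monotonic_increasing
        shuffled = expr.sample(frac=1, random_state=1)
        res2 = biomarkers.differential_expression(shuffled, CLASSES, LINEAGE)
        merged = res.set_index("feature_id").join(
            res2.set_index("feature_id"), rsuffix="_2")
        assert np.allclose(merged["p_adjusted"], merged["p_adjusted_2"])

    def test_confounded_genes_center_on_zero(self, panel60, omics60):
        rec = panel60.records.set_index("cell_line")
        res = biomarkers.differential_expression(
            omics60.expression, rec["response_class"],
            rec["hematopoietic"].astype(int))
        conf = res[res["feature_id"].isin(omics60.confounded_genes)]
        assert abs(conf["coefficient"].mean()) < 0.3
        planted = res[res["feature_id"].isin(omics60.planted_expression_genes)]
        assert planted["coefficient"].mean() == pytest.approx(
            omics60.spec.planted_log2fc, abs=0.5)


class TestFilterMutations:
    MAT = pd.DataFrame(np.eye(5, dtype=int),
                       index=["TP53", "RB1", "KRAS", "EGFR", "MYC"],
                       columns=[f"c{i}" for i in range(5)])

    def test_whitelist_filter(self):
        out = biomarkers.filter_mutations(self.MAT, {"TP53", "RB1"})
        assert sorted(out.index) == ["RB1", "TP53"]

    def test_no_whitelist_identity(self):
        out = biomarkers.filter_mutations(self.MAT, None)
        pd.testing.assert_frame_equal(out, self.MAT)

    def test_disjoint_whitelist_rejected(self):
        with pytest.raises(InputError):
            biomarkers.filter_mutations(self.MAT, {"BRAF"})


class TestMutationAssociation:
    @staticmethod
    def build(n_mut_nr, n_mut_r, n_per_class=10):
        lines = [f"c{i}" for i in range(2 * n_per_class)]
        classes = pd.Series([dr.RESPONDER] * n_per_class
                            + [dr.NONRESPONDER] * n_per_class, index=lines)
        lineage = pd.Series([0, 1] * n_per_class, index=lines)
        mut = np.zeros(2 * n_per_class, dtype=int)
        mut[:n_mut_r] = 1  # responders mutated
        mut[n_per_class:n_per_class + n_mut_nr] = 1
        mat = pd.DataFrame([mut], index=["g1"], columns=lines)
        return mat, classes, lineage

    def test_enriched_in_nonresponders(self):
        mat, classes, lineage = self.build(n_mut_nr=8, n_mut_r=2)
        res = biomarkers.mutation_association(mat, classes, lineage)
        # 2x2 oracle: (8*8)/(2*2) = 16; logistic ~ same on balanced design
        assert res["odds_ratio"].item() == pytest.approx(16.0, rel=0.3)
        assert res["coefficient"].item() > 0
        assert res["direction"].item() == biomarkers.RESISTANCE

    def test_balanced_mutation_null(self):
        mat, classes, lineage = self.build(n_mut_nr=5, n_mut_r=5)
        res = biomarkers.mutation_association(mat, classes, lineage)
        assert res["odds_ratio"].item() == pytest.approx(1.0, abs=0.2)
        assert res["p_value"].item() > 0.5

    def test_separation_falls_back_to_corrected_2x2(self):
        mat, classes, lineage = self.build(n_mut_nr=6, n_mut_r=0)
        res = biomarkers.mutation_association(mat, classes, lineage)
        assert res["fallback"].item()
        assert np.isfinite(res["odds_ratio"].item())
        # Haldane oracle: (6.5*10.5)/(4.5*0.5)
        assert res["odds_ratio"].item() == pytest.approx(
            (6.5 * 10.5) / (4.5 * 0.5))

    def test_singleton_gene_skipped(self):
        mat, classes, lineage = self.build(n_mut_nr=1, n_mut_r=0)
        res = biomarkers.mutation_association(mat, classes, lineage)
        assert res["skipped"].item()

    def test_planted_mutations_recovered(self, panel60, omics60):
        rec = panel60.records.set_index("cell_line")
        res = biomarkers.mutation_association(
            omics60.mutations, rec["response_class"],
            rec["hematopoietic"].astype(int))
        planted = res[res["feature_id"].isin(omics60.planted_mutation_genes)]
        tested = planted[~planted["skipped"]]
        assert (tested["odds_ratio"] > 1).mean() > 0.7


class TestMutationBurden:
    MAT = pd.DataFrame([[0, 1, 1], [0, 1, 1], [0, 1, 1], [0, 1, 0],
                        [0, 1, 0], [0, 1, 0], [0, 1, 0]],
                       index=[f"g{i}" for i in range(7)],
                       columns=["zero", "seven", "three"])

    def test_counts(self):
        burden = biomarkers.mutation_burden(self.MAT)
        assert burden["zero"] == 0
        assert burden["seven"] == 7
        assert burden["three"] == 3

    def test_log2_transform(self):
        burden = biomarkers.mutation_burden(self.MAT, log2=True)
        assert burden["zero"] == 0.0
        assert burden["seven"] == pytest.approx(3.0)  # log2(8)

    def test_conservation(self):
        assert biomarkers.mutation_burden(self.MAT).sum() == self.MAT.to_numpy().sum()


class TestRegionScore:
    @staticmethod
    def setup_meth(n_regions=20, n_lines=15, seed=0):
        rng = np.random.default_rng(seed)
        lines = [f"c{i}" for i in range(n_lines)]
        meth = pd.DataFrame(rng.uniform(0.2, 0.8, (n_regions, n_lines)),
                            index=[f"R{i}" for i in range(n_regions)],
                            columns=lines)
        ic50 = pd.Series(rng.uniform(10, 1000, n_lines), index=lines)
        return meth, ic50

    def test_exact_anticorrelation(self):
        meth, ic50 = self.setup_meth()
        meth.loc["R0"] = -np.log2(ic50) / 20 + 0.6
        score = biomarkers.region_set_score(["R0"], meth, ic50)
        assert score.r_observed == pytest.approx(-1.0)

    def test_single_region_reduction(self):
        meth, ic50 = self.setup_meth()
        score = biomarkers.region_set_score(["R3"], meth, ic50)
        r, _ = stats.pearsonr(meth.loc["R3"], np.log2(ic50))
        assert score.r_observed == pytest.approx(r)

    def test_censored_lines_excluded(self):
        meth, ic50 = self.setup_meth()
        censored = pd.Series(False, index=ic50.index)
        censored.iloc[:5] = True
        score = biomarkers.region_set_score(["R1", "R2"], meth, ic50, censored)
        assert score.n_lines == 10
        assert score.n_excluded_censored == 5

    def test_constant_methylation_rejected(self):
        meth, ic50 = self.setup_meth()
        meth.loc["R0"] = 0.5
        with pytest.raises(UndefinedCorrelationError):
            biomarkers.region_set_score(["R0"], meth, ic50)

    def test_planted_direction_recovered(self, panel60, methylome60):
        rec = panel60.records.set_index("cell_line")
        region_meth = biomarkers.aggregate_regions(methylome60.panel_beta,
                                                   methylome60.region_map)
        score = biomarkers.region_set_score(
            methylome60.planted_regions, region_meth, rec["ic50"],
            rec["ic50_censored"])
        assert score.r_observed < -0.3  # hypermethylated responders = low IC50


class TestPermutationNull:
    def test_add_one_formula_no_exceedance(self):
        meth, ic50 = TestRegionScore.setup_meth(n_regions=50)
        res = biomarkers.permutation_null(5, list(meth.index), meth, ic50,
                                          n_iterations=999, seed=0,
                                          r_observed=1.0)
        assert res.empirical_p == pytest.approx(1 / 1000)

    def test_single_iteration_bound(self):
        meth, ic50 = TestRegionScore.setup_meth(n_regions=50)
        res = biomarkers.permutation_null(5, list(meth.index), meth, ic50,
                                          n_iterations=1, seed=0,
                                          r_observed=0.0)
        assert res.empirical_p == 1.0

    def test_never_zero(self):
        meth, ic50 = TestRegionScore.setup_meth(n_regions=30)
        res = biomarkers.permutation_null(3, list(meth.index), meth, ic50,
                                          n_iterations=200, seed=1,
                                          r_observed=0.99)
        assert res.empirical_p > 0

    def test_reproducible(self):
        meth, ic50 = TestRegionScore.setup_meth(n_regions=30)
        kw = dict(n_iterations=500, seed=42, r_observed=0.5)
        r1 = biomarkers.permutation_null(4, list(meth.index), meth, ic50, **kw)
        r2 = biomarkers.permutation_null(4, list(meth.index), meth, ic50, **kw)
        assert r1 == r2

    def test_oversized_set_rejected(self):
        meth, ic50 = TestRegionScore.setup_meth(n_regions=10)
        with pytest.raises(InputError):
            biomarkers.permutation_null(11, list(meth.index), meth, ic50,
                                        n_iterations=10, seed=0,
                                        r_observed=0.5)

    def test_null_calibration_mean_half(self):
        # observed sets drawn from the null are uniformly ranked
        meth, ic50 = TestRegionScore.setup_meth(n_regions=100, n_lines=20,
                                                seed=9)
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(60):
            chosen = list(rng.choice(meth.index, 8, replace=False))
            sc = biomarkers.region_set_score(chosen, meth, ic50)
            res = biomarkers.permutation_null(
                8, list(meth.index), meth, ic50, n_iterations=400,
                seed=int(rng.integers(1 << 31)), r_observed=sc.r_observed)
            ps.append(res.empirical_p)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.12)


class TestDmrPipeline:
    def test_planted_region_recovery(self, panel60, methylome60):
        rec = panel60.records.set_index("cell_line")
        region_meth = biomarkers.aggregate_regions(methylome60.panel_beta,
                                                   methylome60.region_map)
        screen = biomarkers.differential_methylation_regions(
            region_meth, rec["response_class"], rec["hematopoietic"].astype(int))
        sig = set(biomarkers.significant_regions(screen, fdr=0.05))
        planted = set(methylome60.planted_regions)
        assert len(sig & planted) / len(planted) >= 0.8
        # hypermethylated-in-responder regions have negative coefficients
        hits = screen[screen["feature_id"].isin(planted)]
        assert (hits["coefficient"] < 0).mean() > 0.9

    def test_aggregate_regions_mean(self):
        beta = pd.DataFrame({"s1": [0.2, 0.4, 0.9], "s2": [0.6, 0.8, 0.1]},
                            index=["p1", "p2", "p3"])
        rmap = pd.Series({"p1": "R1", "p2": "R1", "p3": "R2"})
        out = biomarkers.aggregate_regions(beta, rmap)
        assert out.loc["R1", "s1"] == pytest.approx(0.3)
        assert out.loc["R2", "s2"] == pytest.approx(0.1)
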