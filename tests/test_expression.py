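"""Normalization, the Tukey-based BGS classification, the flowering
correlation scan, and qPCR arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetrapop import expression as expr
from tetrapop import simulate as sim

POPS = {"TBG": "RW", "STE": "RW", "KA": "MT", "HO": "MT", "CA2": "MT",
        "SWA": "MT", "BGS": "BGS"}


def small_counts(seed=40, n_genes=60, **kwargs):
    return sim.simulate_expression(
        n_genes, POPS, sim.DePlan(5, 5, 5), seed=seed, **kwargs
    )


class TestNormalize:
    def test_doubled_sample_equalized(self):
        rng = np.random.default_rng(41)
        base = rng.integers(10, 1000, size=50)
        counts = pd.DataFrame({"a": base, "b": 2 * base, "c": base})
        normalized, sf = expr.normalize_counts(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.allclose(normalized["a"], normalized["b"])

    def test_identical_samples_unit_factors(self):
        base = np.arange(10, 60)
        counts = pd.DataFrame({"a": base, "b": base})
        _, sf = expr.normalize_counts(counts)
        assert np.allclose(sf, 1.0)

    def test_invariant_to_gene_order(self):
        counts, _, _ = small_counts()
        _, sf1 = expr.normalize_counts(counts)
        shuffled = counts.sample(frac=1.0, random_state=0)
        _, sf2 = expr.normalize_counts(shuffled)
        assert np.allclose(sf1, sf2[sf1.index])

    def test_recovers_simulated_depth_factors(self):
        counts, _, truth = small_counts(n_genes=400, depth_sd=0.5)
        _, sf = expr.normalize_counts(counts)
        est = sf / np.exp(np.mean(np.log(sf)))
        true = truth.size_factors / np.exp(np.mean(np.log(truth.size_factors)))
        assert np.corrcoef(np.log(est), np.log(true[est.index]))[0, 1] > 0.95

    def test_no_common_gene_errors(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        with pytest.raises(ValueError):
            expr.normalize_counts(counts)


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        counts, _, _ = small_counts(n_genes=100, depth_sd=0.0)
        counts["dup"] = counts["BGS_1"]
        normalized, _ = expr.normalize_counts(counts)
        coords, var_exp = expr.top_variable_pca(normalized, n_genes=50)
        assert np.allclose(coords.loc["dup"], coords.loc["BGS_1"], atol=1e-9)
        assert var_exp.sum() <= 100.0 + 1e-9

    def test_group_structure_separates_on_pc1(self):
        counts, sample_pops, _ = sim.simulate_expression(
            300, POPS, sim.DePlan(40, 40, 80, fold=8.0), seed=42
        )
        normalized, _ = expr.normalize_counts(counts)
        coords, _ = expr.top_variable_pca(normalized, n_genes=100)
        rw = [s for s, p in sample_pops.items() if POPS[p] == "RW"]
        mt = [s for s, p in sample_pops.items() if POPS[p] == "MT"]
        lo, hi = coords.loc[rw, "PC1"], coords.loc[mt, "PC1"]
        assert max(lo.max(), hi.max()) > min(lo.min(), hi.min())
        assert (lo.max() < hi.min()) or (hi.max() < lo.min())

    def test_requests_beyond_gene_count_warns(self, caplog):
        counts, _, _ = small_counts(n_genes=30)
        normalized, _ = expr.normalize_counts(counts)
        with caplog.at_level("WARNING"):
            coords, _ = expr.top_variable_pca(normalized, n_genes=500)
        assert any("using all" in m for m in caplog.messages)


class TestTukeyClassify:
    def _classes(self, sample_pops):
        return {s: POPS[p] for s, p in sample_pops.items()}

    def test_rule_application_extreme_genes(self):
        rng = np.random.default_rng(43)
        samples = {f"{p}_{r}": p for p in POPS for r in (1, 2, 3)}
        classes = {s: POPS[p] for s, p in samples.items()}
        mountain_like = {
            s: (100 if classes[s] in ("MT", "BGS") else 1) + rng.normal(0, 0.5)
            for s in samples
        }
        railway_like = {
            s: (100 if classes[s] in ("RW", "BGS") else 1) + rng.normal(0, 0.5)
            for s in samples
        }
        normalized = pd.DataFrame([mountain_like, railway_like],
                                  index=["gm", "gr"])
        table, counts = expr.tukey_classify(normalized, classes)
        out = table.set_index("gene")["bgs_class"]
        assert out["gm"] == "mountain_like"
        assert out["gr"] == "railway_like"
        assert counts.n_de == 2

    def test_zero_variance_gene_skipped(self):
        samples = {f"{p}_{r}": p for p in POPS for r in (1, 2, 3)}
        classes = {s: POPS[p] for s, p in samples.items()}
        normalized = pd.DataFrame(
            [dict.fromkeys(samples, 5.0)], index=["flat"]
        )
        table, _ = expr.tukey_classify(normalized, classes)
        assert table.empty

    def test_classes_disjoint_and_subset_of_de(self):
        counts, sample_pops, _ = small_counts(n_genes=120)
        normalized, _ = expr.normalize_counts(counts)
        table, _ = expr.tukey_classify(normalized, self._classes(sample_pops))
        labelled = table[table["bgs_class"].isin(["mountain_like", "railway_like"])]
        assert labelled["de"].all()
        assert (table["bgs_class"] != "not_de").sum() == table["de"].sum()

    def test_matches_statsmodels_tukey(self):
        # cross-check one gene's pairwise p-values against statsmodels
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(44)
        samples = {f"{p}_{r}": p for p in POPS for r in (1, 2, 3)}
        classes = {s: POPS[p] for s, p in samples.items()}
        values = {s: rng.normal(10 if classes[s] == "RW" else 5, 1)
                  for s in samples}
        normalized = pd.DataFrame([values], index=["g"])
        table, _ = expr.tukey_classify(normalized, classes)
        res = pairwise_tukeyhsd(
            np.array(list(values.values())),
            np.array([classes[s] for s in values]),
        )
        sm = {
            tuple(sorted((a, b))): p
            for (a, b), p in zip(
                [(res.groupsunique[i], res.groupsunique[j])
                 for i, j in zip(*np.triu_indices(3, 1))],
                res.pvalues,
            )
        }
        row = table.iloc[0]
        assert row["p_rw_mt"] == pytest.approx(sm[("MT", "RW")], abs=1e-6)
        assert row["p_bgs_mt"] == pytest.approx(sm[("BGS", "MT")], abs=1e-6)
        assert row["p_bgs_rw"] == pytest.approx(sm[("BGS", "RW")], abs=1e-6)

    def test_scaling_a_sample_leaves_classes_unchanged(self):
        counts, sample_pops, _ = small_counts(n_genes=80)
        table1, _ = expr.tukey_classify(
            expr.normalize_counts(counts)[0], self._classes(sample_pops)
        )
        scaled = counts.copy()
        scaled["BGS_2"] = scaled["BGS_2"] * 7
        table2, _ = expr.tukey_classify(
            expr.normalize_counts(scaled)[0], self._classes(sample_pops)
        )
        assert (table1["bgs_class"] == table2["bgs_class"]).all()


class TestFloweringScan:
    # flowering times with substantial spread *within* the railway and
    # mountain classes: a gene that merely differs between the classes
    # correlates imperfectly (|r| ~ 0.85) with this gradient, while a gene
    # whose expression is proportional to flowering time reaches |r| ~ 1
    TIMES = {"TBG": 20.0, "STE": 38.0, "KA": 52.0, "HO": 60.0, "CA2": 75.0,
             "SWA": 90.0, "BGS": 25.0}

    def _run(self, seed=45, n_planted=4, n_genes=800):
        # moderate biological noise so the test isolates the *ranking*
        # behavior: planted proportional genes must outrank class-DE genes,
        # whose step-like profiles correlate with the gradient at |r|~0.85
        counts, sample_pops, truth = sim.simulate_expression(
            n_genes, POPS, sim.DePlan(120, 120, 160), seed=seed,
            dispersion=0.02,
            flowering=sim.FloweringPlan(self.TIMES, n_planted),
        )
        normalized, _ = expr.normalize_counts(counts)
        # synthesize the DE filter from truth (the scan consumes any
        # classification table with gene + p_rw_mt columns)
        de = truth.table["is_de"] | truth.table["flowering_correlated"]
        classification = pd.DataFrame(
            {"gene": truth.table["gene"], "p_rw_mt": np.where(de, 1e-4, 0.9)}
        )
        out = expr.flowering_correlation_scan(
            normalized, sample_pops, self.TIMES, classification
        )
        return out, truth

    def test_planted_correlated_genes_recovered(self):
        hits = 0
        total = 0
        for seed in (45, 46, 47):
            out, truth = self._run(seed=seed)
            planted = set(truth.table.loc[truth.table["flowering_correlated"],
                                          "gene"])
            hits += len(planted & set(out["gene"]))
            total += len(planted)
        assert hits / total >= 0.8

    def test_proportional_gene_r_near_one(self):
        out, truth = self._run(seed=48)
        planted = set(truth.table.loc[truth.table["flowering_correlated"], "gene"])
        top = out[out["gene"].isin(planted)]
        assert (top["r"].abs() > 0.9).all()

    def test_too_few_populations_errors(self):
        counts, sample_pops, truth = small_counts()
        normalized, _ = expr.normalize_counts(counts)
        few = {s: p for s, p in sample_pops.items() if p in ("TBG", "KA", "BGS")}
        classification = pd.DataFrame({"gene": counts.index, "p_rw_mt": 0.01})
        with pytest.raises(ValueError):
            expr.flowering_correlation_scan(
                normalized[list(few)], few,
                self.TIMES, classification,
            )


class TestResidualOutlier:
    def _line_points(self, d):
        # points on y=x with orthogonal offsets +/- d chosen uncorrelated
        # with the position along the line, so the total-least-squares fit
        # is exactly y=x and the RMS orthogonal residual is exactly d
        t = np.array([-3.0, -1.0, 1.0, 3.0])
        off = np.array([d, -d, -d, d]) / np.sqrt(2)
        return t + off, t - off

    @pytest.mark.parametrize("z,expected", [(0.0, 1.0), (1.0, 0.31731), (3.0, 0.0027)])
    def test_standard_normal_tail_values(self, z, expected):
        x, y = self._line_points(1.0)
        ex = 5.0 + z / np.sqrt(2), 5.0 - z / np.sqrt(2)
        p = expr.residual_outlier_p(x, y, ex[0], ex[1])
        assert p == pytest.approx(expected, abs=5e-5)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(49)
        x = np.arange(10, dtype=float)
        y = 2.0 * x + rng.normal(0, 1.0, 10)
        p0 = expr.residual_outlier_p(x, y, 5.0, 20.0)
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        xr, yr = c * x - s * y, s * x + c * y
        exr, eyr = c * 5.0 - s * 20.0, s * 5.0 + c * 20.0
        p1 = expr.residual_outlier_p(xr, yr, exr, eyr)
        assert p0 == pytest.approx(p1, abs=1e-9)

    def test_zero_sigma_degenerate(self):
        x = np.arange(5, dtype=float)
        assert expr.residual_outlier_p(x, 2 * x, 1.0, 2.0) == 1.0
        assert expr.residual_outlier_p(x, 2 * x, 1.0, 99.0) == 0.0


class TestQpcr:
    def test_unit_ratio_when_no_shift(self):
        ratio, sd = expr.qpcr_relative_expression(
            [20.0, 20.1], [20.0, 20.1], [18.0, 18.1], [18.0, 18.1], 0.9, 0.9
        )
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_perfect_efficiency_doubling(self):
        ratio, _ = expr.qpcr_relative_expression(
            [19.0, 19.0], [20.0, 20.0], [18.0, 18.0], [18.0, 18.0], 1.0, 1.0
        )
        assert ratio == pytest.approx(2.0)

    def test_bad_efficiency_errors(self):
        with pytest.raises(ValueError):
            expr.qpcr_relative_expression([1, 2], [1, 2], [1, 2], [1, 2], 1.6, 0.9)

    def test_delta_method_matches_monte_carlo(self):
        rng = np.random.default_rng(50)
        ts, tc = [20.0, 20.2, 19.9], [22.0, 22.1, 21.9]
        rs, rc = [18.0, 18.1, 17.9], [18.5, 18.4, 18.6]
        et, er = 0.87, 0.91
        ratio, sd = expr.qpcr_relative_expression(ts, tc, rs, rc, et, er)
        n = 100_000
        ts_, tc_, rs_, rc_ = (np.asarray(g) for g in (ts, tc, rs, rc))

        def draw(g):
            return rng.normal(g.mean(), g.std(ddof=1) / np.sqrt(len(g)), n)

        dct_t = draw(ts_) - draw(tc_)
        dct_r = draw(rs_) - draw(rc_)
        sims = (1 + et) ** (-dct_t) / (1 + er) ** (-dct_r)
        assert sd == pytest.approx(sims.std(), rel=0.05)
        assert ratio == pytest.approx(sims.mean(), rel=0.05)
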