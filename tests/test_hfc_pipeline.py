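import numpy as np
import pandas as pd
import pytest

from hetfit import hfc_pipeline as hp
from hetfit import marker_stats
from hetfit.heterozygosity import slh_matrix
from hetfit.hfc_pipeline import (body_condition, build_year_datasets,
                                 effect_size_model, holm_correction,
                                 run_multilocus_hfc, single_locus_scan,
                                 univariate_het_fit)


def holm_brute_force(p, alpha=0.05):
    """Largest rejection set {p_(1)..p_(r)} with p_(i) <= alpha/(m-i+1) for all i <= r."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    r = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= alpha / (m - i + 1):
            r = i
        else:
            break
    reject = np.zeros(m, bool)
    reject[order[:r]] = True
    return reject


class TestBodyCondition:
    def _frame(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "year": 2010,
            "body_mass": rng.normal(11, 0.5, n),
            "laying_date": rng.normal(100, 7, n),
            "wing": rng.normal(65, 2, n),
            "tarsus": rng.normal(16.5, 0.5, n),
        })

    def test_residuals_sum_to_zero(self):
        resid = body_condition(self._frame())
        assert abs(resid.sum()) < 1e-10

    def test_exact_linear_mass_gives_zero_residuals(self):
        df = self._frame()
        df["body_mass"] = 2.0 * df["tarsus"]
        resid = body_condition(df)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_independent_mass_is_centered_mass(self):
        df = self._frame(n=2000, seed=1)
        resid = body_condition(df)
        assert np.corrcoef(resid, df["body_mass"] - df["body_mass"].mean())[0, 1] > 0.99

    def test_collinear_predictors_raise(self):
        df = self._frame()
        df["wing"] = 2.0 * df["tarsus"]
        with pytest.raises(ValueError, match="collinear"):
            body_condition(df)


class TestHolm:
    def test_hand_example(self):
        p = [0.001, 0.03, 0.04]
        reject, thr = holm_correction(p, alpha=0.05)
        assert np.allclose(thr, [0.05 / 3, 0.05 / 2, 0.05])
        assert list(reject) == [True, False, False]

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = rng.integers(1, 30)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            r1, _ = holm_correction(p, alpha=0.05)
            r2 = holm_brute_force(p, alpha=0.05)
            assert np.array_equal(r1, r2)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        p = rng.random(15)
        r_small, _ = holm_correction(p, alpha=0.01)
        r_big, _ = holm_correction(p, alpha=0.10)
        assert (~r_small | r_big).all()  # rejections only grow with alpha


class TestYearDatasets:
    def test_final_year_excluded_and_rows_counted(self, sim_study, sim_het_table):
        cfg, study = sim_study
        ds = build_year_datasets(study.individuals, sim_het_table)
        years = [d.year for d in ds]
        assert max(study.individuals["year"]) not in years
        assert len(years) == cfg.n_years - 1
        for d in ds:
            assert d.data["recruited"].notna().all()
            assert len(d.data) >= 20

    def test_min_rows_floor(self, sim_study, sim_het_table):
        cfg, study = sim_study
        with pytest.raises(ValueError, match="modeled rows"):
            build_year_datasets(study.individuals, sim_het_table,
                                min_rows=cfg.n_per_year + 1)


class TestMultilocusHFC:
    def test_strong_effect_recovered_with_right_sign(self, sim_study, sim_het_table):
        """With a strong generative slope, the averaged het coefficient and the
        univariate het-only fit agree in sign (both follow the true effect)."""
        import hetfit.synthetic_data as sd
        cfg = sd.SimConfig(seed=99, n_per_year=250, n_years=2,
                           beta1_base=8.0, beta1_precip_slope=0.0)
        study = sd.simulate_dataset(cfg)
        w = marker_stats.expected_het_weights(marker_stats.marker_summary(study.genotypes))
        het = pd.DataFrame({"individual_id": study.genotypes.ids})
        from hetfit.heterozygosity import het_estimates
        het = het_estimates(study.genotypes, w,
                            {n: study.panel.subset(n) for n in ("total", "neutral", "functional")})
        ds = build_year_datasets(study.individuals, het)
        table = run_multilocus_hfc(ds[0], family="total").set_index("term")
        assert "het_total" in table.index
        est = table.loc["het_total", "estimate"]
        assert est > 0
        uni = univariate_het_fit(ds[0])
        assert np.sign(uni.coef("het_total")) == np.sign(est)

    def test_neutral_plus_functional_family_terms(self, sim_study, sim_het_table):
        cfg, study = sim_study
        ds = build_year_datasets(study.individuals, sim_het_table)
        table = run_multilocus_hfc(ds[0], family="neutral_plus_functional",
                                   use_random_intercept=False)
        assert {"het_neutral", "het_functional"} & set(table["term"]) or len(table) > 0
        assert (table["ci_low"] < table["ci_high"]).all()
        # sorted by term importance
        sw = table["sum_weights"].to_numpy()
        assert (np.diff(sw) <= 1e-12).all()


class TestSingleLocusScan:
    def test_scan_outputs_and_effect_size_definition(self, sim_study, sim_het_table):
        cfg, study = sim_study
        ds = build_year_datasets(study.individuals, sim_het_table)
        slh = slh_matrix(study.genotypes, subset=study.panel.loci[:6])
        scan = single_locus_scan(ds[0], slh, covariates=False,
                                 use_random_intercept=False)
        assert len(scan) >= 5
        r = scan["z"] / np.sqrt(scan["n"])
        assert np.allclose(scan["effect_size_r"], np.clip(r, -1, 1))
        assert scan["effect_size_r"].abs().le(1).all()
        # Holm columns consistent with the sorted-p definition
        reject = holm_brute_force(scan["p_raw"].to_numpy())
        assert np.array_equal(scan["significant_after_correction"].to_numpy(), reject)


class TestEffectSizeModel:
    def _inputs(self, sim_study, abs_r):
        cfg, study = sim_study
        stats_list = marker_stats.marker_summary(study.genotypes)
        scan = pd.DataFrame({"locus": [s.locus for s in stats_list],
                             "effect_size_r": abs_r})
        return scan, stats_list, study.panel

    def test_exact_linear_in_allelic_richness(self, sim_study):
        cfg, study = sim_study
        stats_list = marker_stats.marker_summary(study.genotypes)
        abs_r = np.array([0.01 * s.n_alleles for s in stats_list])
        scan, stats_list, panel = self._inputs(sim_study, abs_r)
        table = effect_size_model(scan, stats_list, panel).set_index("term")
        assert table.loc["A_R", "estimate"] == pytest.approx(0.01, abs=1e-10)
        assert abs(table.loc["H_O", "estimate"]) < 1e-9
        assert abs(table.loc["category_neutral", "estimate"]) < 1e-9

    def test_constant_effect_sizes_give_zero_slopes(self, sim_study):
        scan, stats_list, panel = self._inputs(sim_study, 0.07)
        table = effect_size_model(scan, stats_list, panel).set_index("term")
        for term in ("A_R", "H_O", "category_neutral"):
            assert abs(table.loc[term, "estimate"]) < 1e-10

    def test_category_permutation_flips_category_sign(self, sim_study):
        cfg, study = sim_study
        rng = np.random.default_rng(5)
        abs_r = rng.uniform(0.0, 0.3, len(study.panel.loci))
        scan, stats_list, panel = self._inputs(sim_study, abs_r)
        t1 = effect_size_model(scan, stats_list, panel).set_index("term")
        flipped = panel.table.copy()
        flipped["category"] = np.where(flipped["category"] == "neutral",
                                       "functional", "neutral")
        from hetfit.io_core import MarkerPanel
        t2 = effect_size_model(scan, stats_list, MarkerPanel(flipped)).set_index("term")
        assert t1.loc["category_neutral", "estimate"] == pytest.approx(
            -t2.loc["category_neutral", "estimate"])
        assert t1.loc["A_R", "estimate"] == pytest.approx(t2.loc["A_R", "estimate"])
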