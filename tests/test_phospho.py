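"""Phosphosite pipeline: filters, imputation, normalisation, moderated tests."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitentry.phospho import (
    GROUPS,
    FactorialFit,
    PhosphositeTable,
    bh_adjust,
    classify_hits,
    filter_sites,
    fit_factorial,
    impute_mnar,
    interaction_contrast,
    median_polish,
    median_polish_normalize,
    moderate_variances,
    pairwise_contrasts,
    valid_value_filter,
)
from mitentry.synthetic import PhosphoSimSpec, generate_phospho


def make_table(intensities: pd.DataFrame, samples: pd.DataFrame,
               sites: pd.DataFrame | None = None) -> PhosphositeTable:
    if sites is None:
        sites = pd.DataFrame(
            {"protein": "P", "localization_prob": 1.0,
             "contaminant": False, "reverse": False},
            index=intensities.index,
        )
    return PhosphositeTable(sites=sites, intensities=intensities, samples=samples)


def flat_samples(n_cols: int, batch: int = 1) -> pd.DataFrame:
    names = [f"c{i}" for i in range(n_cols)]
    return pd.DataFrame({
        "group": "G2", "treatment": "DMSO", "fraction": "attached",
        "replicate": 1, "batch": batch, "is_reference": False,
    }, index=pd.Index(names, name="sample"))


class TestFilterSites:
    def test_empty_table_passes_through(self):
        samples = flat_samples(2)
        idx = pd.Index([], name="site_id")
        t = make_table(pd.DataFrame(columns=samples.index, index=idx, dtype=float),
                       samples)
        assert len(filter_sites(t).sites) == 0

    def test_boundary_probability_and_flag_rules(self):
        samples = flat_samples(2)
        idx = pd.Index([f"s{i}" for i in range(5)], name="site_id")
        sites = pd.DataFrame({
            "protein": "P",
            "localization_prob": [0.9, 0.74, 0.75, 0.8, 0.8],
            "contaminant": [False, False, False, True, False],
            "reverse": [False, False, False, False, True],
        }, index=idx)
        intens = pd.DataFrame(20.0, index=idx, columns=samples.index)
        out = filter_sites(make_table(intens, samples, sites))
        # the rule removes prob < 0.75, so 0.75 itself survives
        assert list(out.sites.index) == ["s0", "s2"]


class TestValidValueFilter:
    def test_fully_observed_site_is_kept(self):
        samples = flat_samples(4)
        idx = pd.Index(["a"], name="site_id")
        t = make_table(pd.DataFrame(20.0, index=idx, columns=samples.index), samples)
        assert list(valid_value_filter(t).sites.index) == ["a"]

    def test_seventy_percent_threshold_arithmetic(self):
        # 18 channels in one labeling experiment: 12/18 = 66.7% -> dropped,
        # 13/18 = 72.2% -> kept
        samples = flat_samples(18)
        idx = pd.Index(["twelve", "thirteen"], name="site_id")
        vals = pd.DataFrame(20.0, index=idx, columns=samples.index)
        vals.iloc[0, 12:] = np.nan
        vals.iloc[1, 13:] = np.nan
        out = valid_value_filter(make_table(vals, samples))
        assert list(out.sites.index) == ["thirteen"]

    def test_per_batch_granularity_blanks_only_that_batch(self):
        s1 = flat_samples(4, batch=1)
        s2 = flat_samples(4, batch=2)
        s2.index = [f"d{i}" for i in range(4)]
        samples = pd.concat([s1, s2])
        idx = pd.Index(["x"], name="site_id")
        vals = pd.DataFrame(20.0, index=idx, columns=samples.index)
        vals.loc["x", ["c0", "c1"]] = np.nan  # 50% valid in batch 1 only
        out = valid_value_filter(make_table(vals, samples))
        assert out.intensities.loc["x", ["c2", "c3"]].isna().all()
        assert out.intensities.loc["x", ["d0", "d1", "d2", "d3"]].notna().all()


class TestImputeMnar:
    def test_complete_table_unchanged(self):
        samples = flat_samples(3)
        idx = pd.Index(["a", "b"], name="site_id")
        vals = pd.DataFrame(np.arange(6, dtype=float).reshape(2, 3),
                            index=idx, columns=samples.index)
        out = impute_mnar(make_table(vals, samples), seed=0)
        pd.testing.assert_frame_equal(out.intensities, vals)

    def test_monte_carlo_moments_match_perseus_convention(self):
        rng = np.random.default_rng(42)
        n_obs, n_miss = 100_000, 10_000
        obs = rng.normal(20.0, 1.0, n_obs)
        samples = flat_samples(1)
        idx = pd.Index([f"s{i}" for i in range(n_obs + n_miss)], name="site_id")
        col = np.concatenate([obs, np.full(n_miss, np.nan)])
        vals = pd.DataFrame({samples.index[0]: col}, index=idx)
        out = impute_mnar(make_table(vals, samples), width=0.3, downshift=1.8, seed=1)
        mu, sd = obs.mean(), obs.std(ddof=1)
        imputed = out.intensities.iloc[n_obs:, 0].to_numpy()
        # downshift and width in units of the observed column SD, +/- MC error
        assert (mu - imputed.mean()) / sd == pytest.approx(1.8, abs=0.02)
        assert imputed.std(ddof=1) / sd == pytest.approx(0.3, abs=0.01)

    def test_seed_reproducibility(self):
        samples = flat_samples(2)
        idx = pd.Index([f"s{i}" for i in range(30)], name="site_id")
        vals = pd.DataFrame(np.random.default_rng(0).normal(20, 1, (30, 2)),
                            index=idx, columns=samples.index)
        vals.iloc[:5, 0] = np.nan
        a = impute_mnar(make_table(vals, samples), seed=9).intensities
        b = impute_mnar(make_table(vals, samples), seed=9).intensities
        pd.testing.assert_frame_equal(a, b)

    def test_column_with_too_few_observations_errors(self):
        samples = flat_samples(2)
        idx = pd.Index(["a", "b", "c"], name="site_id")
        vals = pd.DataFrame(np.nan, index=idx, columns=samples.index)
        vals.iloc[0, 0] = 20.0
        vals.iloc[:, 1] = 20.0
        with pytest.raises(ValueError, match="c0"):
            impute_mnar(make_table(vals, samples))


class TestMedianPolish:
    def test_zero_median_matrix_is_unchanged(self):
        m = np.array([[-1.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, -1.0]])
        res = median_polish(m)
        assert res["converged"]
        assert np.allclose(res["residual"], m)
        assert np.allclose(res["col"], 0.0)

    def test_worked_three_by_three_example(self):
        m = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        res = median_polish(m)
        assert np.allclose(res["col"], [-1.0, 0.0, 1.0])
        recon = m - res["col"][None, :]
        assert np.allclose(recon, [[2, 2, 2], [5, 5, 5], [8, 8, 8]])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=20)
    def test_residual_medians_vanish_after_convergence(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(0, 1, (7, 5)) + rng.normal(0, 2, (7, 1)) + rng.normal(0, 2, (1, 5))
        res = median_polish(m, tol=1e-9, max_iter=200)
        assert np.abs(np.median(res["residual"], axis=0)).max() < 1e-6
        assert np.abs(np.median(res["residual"], axis=1)).max() < 1e-6

    def test_normalisation_requires_complete_matrix(self, small_factorial_table):
        t = small_factorial_table.copy()
        t.intensities.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            median_polish_normalize(t)

    def test_normalisation_aligns_batch_offsets(self, small_factorial_table):
        t = small_factorial_table.copy()
        cols_b2 = t.sample_columns(batch=2)
        t.intensities[cols_b2] += 5.0  # constant batch shift
        out, effects = median_polish_normalize(t)
        ref, _ = median_polish_normalize(small_factorial_table)
        # the shift is absorbed into the grand level: the normalised matrices
        # differ by one global constant, so the batches are mutually aligned
        diff = out.intensities.to_numpy() - ref.intensities.to_numpy()
        assert np.allclose(diff, diff.mean(), atol=1e-9)
        assert diff.mean() == pytest.approx(5.0 / 3.0)


class TestFactorialFit:
    def test_group_means_recovered_exactly(self):
        means = {"G2": 10.0, "Prometa": 12.0, "ProPro": 9.0, "Polo": 11.0}
        samples = []
        for b in (1, 2, 3):
            for g, (treat, frac) in GROUPS.items():
                samples.append({"sample": f"{g}_r{b}", "group": g,
                                "treatment": treat, "fraction": frac,
                                "replicate": b, "batch": b, "is_reference": False})
        samples = pd.DataFrame(samples).set_index("sample")
        idx = pd.Index(["a"], name="site_id")
        offs = {1: -0.5, 2: 0.0, 3: 0.5}  # replicate offsets, mean zero
        vals = {f"{g}_r{b}": [means[g] + offs[b]] for b in (1, 2, 3) for g in GROUPS}
        t = make_table(pd.DataFrame(vals, index=idx), samples)
        fit = fit_factorial(t)
        for g, m in means.items():
            assert fit.coefficients.loc["a", g] == pytest.approx(m)
        assert fit.df.loc["a"] == 8
        # residual variance is the pooled within-group variance of the offsets
        assert fit.sigma2.loc["a"] == pytest.approx(4 * (0.25 + 0.0 + 0.25) / 8)

    def test_constant_data_has_zero_residual_variance(self, small_factorial_table):
        t = small_factorial_table.copy()
        t.intensities.loc[:, :] = 21.0
        fit = fit_factorial(t)
        assert np.allclose(fit.sigma2.to_numpy(), 0.0)
        assert np.allclose(fit.coefficients.to_numpy(), 21.0)

    def test_missing_group_is_rank_deficient(self, small_factorial_table):
        t = small_factorial_table.copy()
        keep = t.samples["group"] != "Polo"
        t2 = PhosphositeTable(t.sites, t.intensities[t.samples.index[keep]],
                              t.samples[keep])
        with pytest.raises(ValueError, match="Polo"):
            fit_factorial(t2)


class TestModeration:
    def test_shrinkage_formula_and_convexity(self, small_factorial_table):
        fit = moderate_variances(fit_factorial(small_factorial_table))
        assert fit.d0 > 0
        if np.isfinite(fit.d0):
            expect = (fit.d0 * fit.s0_2 + fit.df * fit.sigma2) / (fit.d0 + fit.df)
            assert np.allclose(fit.s2_post.to_numpy(), expect.to_numpy())
        lo = np.minimum(fit.sigma2, fit.s0_2)
        hi = np.maximum(fit.sigma2, fit.s0_2)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()

    def test_worked_shrinkage_value(self):
        # s2=2, d=4, d0=4, s0^2=1 -> s2_post = (4*1 + 4*2)/8 = 1.5
        d0, s0_2, d, s2 = 4.0, 1.0, 4.0, 2.0
        assert (d0 * s0_2 + d * s2) / (d0 + d) == pytest.approx(1.5)

    def test_identical_variances_take_infinite_prior_branch(self, small_factorial_table):
        fit = fit_factorial(small_factorial_table)
        fit.sigma2[:] = 0.04
        out = moderate_variances(fit)
        assert np.isinf(out.d0)
        assert np.allclose(out.s2_post.to_numpy(), out.s0_2)

    def test_hyperparameter_recovery_from_scaled_f_variances(self):
        rng = np.random.default_rng(3)
        n, d0_true, s0_true, d = 5000, 6.0, 0.05, 8.0
        sig2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sig2 * rng.chisquare(int(d), n) / d
        fit = FactorialFit(
            coefficients=pd.DataFrame(0.0, index=range(n), columns=list(GROUPS)),
            sigma2=pd.Series(s2), df=pd.Series(d, index=range(n)),
            n_per_group=pd.DataFrame(3.0, index=range(n), columns=list(GROUPS)),
        )
        out = moderate_variances(fit)
        assert out.d0 == pytest.approx(d0_true, rel=0.15)
        assert out.s0_2 == pytest.approx(s0_true, rel=0.1)

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        idx = pd.Index(["a"], name="site_id")
        fit = FactorialFit(
            coefficients=pd.DataFrame({"G2": [10.0], "Prometa": [10.0],
                                       "ProPro": [11.0], "Polo": [10.0]}, index=idx),
            sigma2=pd.Series([0.09], index=idx),
            df=pd.Series([8.0], index=idx),
            n_per_group=pd.DataFrame(3.0, index=idx, columns=list(GROUPS)),
            s2_post=pd.Series([0.09], index=idx), d0=0.0, s0_2=0.09,
        )
        tab = interaction_contrast(fit)
        se = np.sqrt(0.09 * 4 / 3)
        assert tab["t"].iloc[0] == pytest.approx(1.0 / se)
        from scipy import stats
        assert tab["p"].iloc[0] == pytest.approx(2 * stats.t.sf(1.0 / se, df=8))


class TestContrasts:
    @pytest.fixture()
    def unit_fit(self):
        idx = pd.Index(["a", "b"], name="site_id")
        coef = pd.DataFrame({
            # site a: means (ProPro, Polo, G2, Prometa) = (10, 7, 9, 9)
            "G2": [9.0, 5.0], "Prometa": [9.0, 5.0],
            "ProPro": [10.0, 5.0], "Polo": [7.0, 5.0],
        }, index=idx)
        return FactorialFit(
            coefficients=coef,
            sigma2=pd.Series([0.12, 0.12], index=idx),
            df=pd.Series([8.0, 8.0], index=idx),
            n_per_group=pd.DataFrame(3.0, index=idx, columns=list(GROUPS)),
            s2_post=pd.Series([0.12, 0.12], index=idx), d0=4.0, s0_2=0.12,
        )

    def test_interaction_arithmetic(self, unit_fit):
        tab = interaction_contrast(unit_fit)
        assert tab.loc["a", "log2fc"] == pytest.approx(3.0)
        assert tab.loc["b", "log2fc"] == pytest.approx(0.0)

    def test_pairwise_edges_and_signs(self, unit_fit):
        tabs = pairwise_contrasts(unit_fit)
        assert set(tabs) == {"Prometa_vs_G2", "Polo_vs_ProPro",
                             "ProPro_vs_G2", "Polo_vs_Prometa"}
        assert tabs["Polo_vs_ProPro"].loc["a", "log2fc"] == pytest.approx(-3.0)
        assert tabs["ProPro_vs_G2"].loc["a", "log2fc"] == pytest.approx(1.0)

    def test_spiked_site_signs_recovered_end_to_end(self):
        table, truth = generate_phospho(PhosphoSimSpec(
            n_sites=300, interaction_effect=2.5, spike_fraction=0.05,
            within_sd=0.15, dropout_slope=0.0, seed=8))
        fit = moderate_variances(fit_factorial(table))
        tab = interaction_contrast(fit)
        spiked = truth[truth.spiked]
        got = tab.loc[spiked.index, "log2fc"]
        assert np.all(np.sign(got) == np.sign(spiked["interaction_effect"]))
        assert got.to_numpy() == pytest.approx(
            spiked["interaction_effect"].to_numpy(), abs=0.8)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_dominates_raw_and_preserves_order(self, ps):
        adj = bh_adjust(ps)
        p = np.asarray(ps)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestClassifyHits:
    def test_rule_application(self):
        tab = pd.DataFrame({
            "log2fc": [0.8, -0.8, 0.8, 0.3],
            "adj_p": [0.01, 0.01, 0.2, 0.01],
        })
        out = classify_hits(tab)
        assert list(out) == ["up", "down", "ns", "ns"]

    def test_sign_only_mode(self):
        tab = pd.DataFrame({"log2fc": [0.3, -0.3], "adj_p": [0.01, 0.01]})
        assert list(classify_hits(tab, lfc_cut=0.0)) == ["up", "down"]


class TestAgainstLimma:
    def test_moderated_statistics_match_limma(self, tmp_path):
        """Independent oracle: the same normalised matrix analysed with
        Bioconductor limma (lmFit + contrasts.fit + eBayes) must give the
        same moderated t and p for the interaction contrast."""
        rng = np.random.default_rng(7)
        n = 300
        samples = []
        for b in (1, 2, 3):
            for g, (treat, frac) in GROUPS.items():
                samples.append({"sample": f"{g}_r{b}", "group": g,
                                "treatment": treat, "fraction": frac,
                                "replicate": b, "batch": b, "is_reference": False})
        samples = pd.DataFrame(samples).set_index("sample")
        idx = pd.Index([f"s{i}" for i in range(n)], name="site_id")
        d0_true, s0_true = 5.0, 0.06
        sig2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        vals = {s: 20 + rng.normal(0, np.sqrt(sig2)) for s in samples.index}
        t = make_table(pd.DataFrame(vals, index=idx), samples)
        fit = moderate_variances(fit_factorial(t))
        mine = interaction_contrast(fit)

        mat_path = tmp_path / "mat.tsv"
        grp_path = tmp_path / "groups.tsv"
        out_path = tmp_path / "limma.tsv"
        t.intensities.to_csv(mat_path, sep="\t")
        samples[["group"]].to_csv(grp_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            mat <- as.matrix(read.delim("{mat_path}", row.names=1))
            grp <- read.delim("{grp_path}", row.names=1)
            g <- factor(grp$group, levels=c("G2","Prometa","ProPro","Polo"))
            design <- model.matrix(~0+g)
            colnames(design) <- levels(g)
            fit <- lmFit(mat, design)
            cm <- makeContrasts((ProPro - Polo) - (G2 - Prometa), levels=design)
            fit2 <- eBayes(contrasts.fit(fit, cm))
            out <- data.frame(t=fit2$t[,1], p=fit2$p.value[,1], d0=fit2$df.prior,
                              s02=fit2$s2.prior)
            write.table(out, "{out_path}", sep="\\t", quote=FALSE)
        """)
        r_file = tmp_path / "check.R"
        r_file.write_text(script)
        proc = subprocess.run(["Rscript", str(r_file)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out_path, sep="\t", index_col=0)
        assert np.abs(mine["t"].to_numpy() - ref["t"].to_numpy()).max() < 1e-6
        assert np.abs(mine["p"].to_numpy() - ref["p"].to_numpy()).max() < 1e-6
        assert fit.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert fit.s0_2 == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
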