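"""Moderated-t differential methylation: BH, moderation limits, heatmaps,
and a machine-precision cross-check against the Bioconductor reference."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methclock.dma import (
    bh_adjust,
    build_heatmap,
    fit_dma,
    fit_f_dist,
    trigamma_inverse,
)
from methclock.simulate import SimConfig, generate_dataset
from conftest import make_beta, make_sheet


def recovery_config(seed, noise_sd=0.1):
    """30 liver samples, 10 cases, 100 planted disease CpGs of |delta|=0.2."""
    return SimConfig(
        n_samples=30, n_probes=2000, n_age_cpgs=0, n_sex_cpgs=0,
        n_disease_cpgs=100, disease_delta=0.2, disease_hypo_fraction=0.83,
        noise_sd=noise_sd, age_distribution=(4.0, 16.0), disease_age_min=3.0,
        disease_prevalence=1 / 3, tissue_weights=(1.0, 0, 0), seed=seed,
    )


class TestBhAdjust:
    def test_hand_examples(self):
        np.testing.assert_allclose(bh_adjust([0.005, 0.04, 0.03]),
                                   [0.015, 0.04, 0.04])
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_equal_pass_through(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_nan_passthrough_excluded_from_m(self):
        out = bh_adjust([0.005, np.nan, 0.04, 0.03])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2, 3]], [0.015, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_permutation_invariance_and_cap(self, rng):
        p = rng.uniform(0, 1, 200)
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]),
                                   atol=1e-15)
        assert bh_adjust(np.full(5, 0.9)).max() <= 1.0


class TestModeration:
    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (0.1, 0.5, 2.0, 10.0, 100.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(
                x, rel=1e-6
            )

    def test_f_dist_recovers_known_prior(self, rng):
        # variances drawn as scaled-F around s0=0.05 with d0=4, d=10
        d0, s0, d = 4.0, 0.05, 10
        s2 = s0 * (rng.chisquare(d, 20000) / d) / (rng.chisquare(d0, 20000) / d0)
        d0_hat, s0_hat = fit_f_dist(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.1)
        assert s0_hat == pytest.approx(s0, rel=0.05)

    def test_prior_df_zero_is_ordinary_t(self):
        cfg = recovery_config(seed=2)
        beta, sheet, *_ = generate_dataset(cfg)
        res = fit_dma(beta, sheet, prior_df=0)
        # recompute ordinary two-group t through plain OLS formulas
        meta = sheet.aligned_to(beta)
        case = (meta["disease_status"] == "sos_positive").to_numpy(float)
        X = np.column_stack([np.ones(len(case)), case])
        Y = beta.values
        B = np.linalg.lstsq(X, Y, rcond=None)[0]
        resid = Y - X @ B
        df = len(case) - 2
        s2 = (resid ** 2).sum(0) / df
        se = np.sqrt(np.linalg.inv(X.T @ X)[1, 1] * s2)
        t = B[1] / se
        p = 2 * stats.t.sf(np.abs(t), df)
        np.testing.assert_allclose(res.table["t_mod"], t, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p, atol=1e-10)

    def test_matches_limma_reference(self, tmp_path):
        """logFC, moderated t, p and (d0, s0^2) agree with limma to ~1e-12."""
        cfg = SimConfig(n_samples=16, n_probes=60, n_age_cpgs=0, n_sex_cpgs=0,
                        n_disease_cpgs=10, noise_sd=0.2,
                        age_distribution=(4.0, 16.0), disease_prevalence=0.4,
                        tissue_weights=(1.0, 0, 0), seed=7)
        beta, sheet, *_ = generate_dataset(cfg)
        res = fit_dma(beta, sheet)
        Y = beta.to_frame().T
        Y.to_csv(tmp_path / "y.csv")
        grp = (sheet.data.set_index("sample_id").loc[Y.columns, "disease_status"]
               == "sos_positive").astype(int)
        grp.to_csv(tmp_path / "g.csv")
        script = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1, check.names=FALSE))
        g <- read.csv("{tmp_path}/g.csv", row.names=1)[colnames(y), 1]
        fit <- eBayes(lmFit(y, model.matrix(~g)))
        out <- data.frame(logFC=fit$coefficients[,2], t=fit$t[,2],
                          p=fit$p.value[,2], d0=fit$df.prior, s0=fit$s2.prior)
        write.csv(out, "{tmp_path}/limma.csv")
        """
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        ours = res.table.loc[ref.index]
        assert res.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-10)
        assert res.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-10)
        np.testing.assert_allclose(ours["logFC"], ref["logFC"], atol=1e-12)
        np.testing.assert_allclose(ours["t_mod"], ref["t"], atol=1e-10)
        np.testing.assert_allclose(ours["p"], ref["p"], atol=1e-12)


class TestFitDma:
    def test_null_simulation_calibrated(self):
        """No planted effects: raw p well calibrated, BH finds ~nothing."""
        n_fdr_hits = 0
        for seed in range(1, 21):
            cfg = SimConfig(n_samples=30, n_probes=2000, n_age_cpgs=0,
                            n_sex_cpgs=0, n_disease_cpgs=0, noise_sd=0.1,
                            age_distribution=(4.0, 16.0), disease_prevalence=1 / 3,
                            tissue_weights=(1.0, 0, 0), seed=seed)
            beta, sheet, *_ = generate_dataset(cfg)
            res = fit_dma(beta, sheet)
            frac = float((res.table["p"] < 0.05).mean())
            assert 0.03 < frac < 0.07, f"seed {seed}: {frac}"
            n_fdr_hits += int(res.table["significant"].any())
        assert n_fdr_hits <= 2  # >= 18/20 seeds fully clean

    def test_recovery_and_direction(self):
        cfg = recovery_config(seed=1)
        beta, sheet, _, truth = generate_dataset(cfg)
        res = fit_dma(beta, sheet)
        true = set(truth.probes_of("disease"))
        sig = set(res.significant_probes)
        assert len(sig & true) >= 80
        detected = res.table.loc[sorted(sig & true)]
        hypo_frac = float((detected["logFC"] < 0).mean())
        assert abs(hypo_frac - 0.83) <= 0.1

    def test_age_filter_and_group_sizes(self):
        cfg = recovery_config(seed=4)
        beta, sheet, *_ = generate_dataset(cfg)
        res = fit_dma(beta, sheet, min_age=3.0)
        ages = sheet.data.set_index("sample_id")["age_years"]
        used = res.case_sample_ids + res.control_sample_ids
        assert (ages.loc[used] > 3.0).all()

    def test_too_small_group_rejected(self):
        beta = make_beta(np.random.default_rng(0).uniform(0.2, 0.8, (6, 10)))
        sheet = make_sheet(beta.sample_ids, age_years=10.0,
                           disease_status=["sos_positive"] + ["none"] * 5)
        with pytest.raises(ValueError, match="2 samples per group"):
            fit_dma(beta, sheet)

    def test_padj_monotone_and_above_p(self):
        cfg = recovery_config(seed=5)
        beta, sheet, *_ = generate_dataset(cfg)
        t = fit_dma(beta, sheet).table
        assert (t["p_adj"] >= t["p"] - 1e-15).all()
        ordered = t.sort_values("p")
        assert (np.diff(ordered["p_adj"]) >= -1e-15).all()


class TestHeatmap:
    def test_reference_rows_zero_mean_unit_sd(self):
        cfg = recovery_config(seed=1)
        beta, sheet, *_ = generate_dataset(cfg)
        res = fit_dma(beta, sheet)
        ref = beta.subset_samples(res.case_sample_ids + res.control_sample_ids)
        bundle = build_heatmap(res, ref, k=50, sheet=sheet)
        M = bundle.matrix.to_numpy()
        np.testing.assert_allclose(M.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(M.std(axis=1), 1.0, atol=1e-9)
        assert bundle.matrix.shape[0] == 50

    def test_projected_copy_equals_reference_column(self):
        cfg = recovery_config(seed=1)
        beta, sheet, *_ = generate_dataset(cfg)
        res = fit_dma(beta, sheet)
        ref = beta.subset_samples(res.case_sample_ids + res.control_sample_ids)
        clone = ref.subset_samples([ref.sample_ids[0]])
        clone.sample_ids = ["COPY"]
        bundle = build_heatmap(res, ref, beta_extra=clone, k=30)
        np.testing.assert_allclose(bundle.matrix["COPY"],
                                   bundle.matrix[ref.sample_ids[0]], atol=1e-12)

    def test_two_cluster_cut_separates_cases(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = recovery_config(seed=2, noise_sd=0.1)
        beta, sheet, *_ = generate_dataset(cfg)
        res = fit_dma(beta, sheet)
        ref = beta.subset_samples(res.case_sample_ids + res.control_sample_ids)
        bundle = build_heatmap(res, ref, k=100, sheet=sheet)
        status = sheet.data.set_index("sample_id").loc[
            bundle.col_clusters.index, "disease_status"] == "sos_positive"
        assert adjusted_rand_score(status, bundle.col_clusters) == 1.0

    def test_k_must_be_positive(self):
        cfg = recovery_config(seed=1)
        beta, sheet, *_ = generate_dataset(cfg)
        res = fit_dma(beta, sheet)
        with pytest.raises(ValueError, match="k"):
            build_heatmap(res, beta, k=0)
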