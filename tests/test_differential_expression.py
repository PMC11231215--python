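import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from coexnet.community_detection import Community, CommunitySet
from coexnet.differential_expression import (
    EBayesPrior,
    classify,
    community_de_profile,
    estimate_prior,
    fit_two_group,
    moderate,
    run_de,
)
from coexnet.mi_network import ExpressionMatrix


def matrix(values, phenotype="X"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
        values,
        phenotype,
    )


class TestTwoGroupFit:
    def test_log_fc_is_mean_difference(self):
        case = matrix([[5.0, 5.0, 5.0]])
        ctrl = matrix([[3.0, 3.0, 3.0]])
        fits = fit_two_group(case, ctrl)
        assert fits["log_fc"].iloc[0] == pytest.approx(2.0)
        assert fits["zero_variance"].iloc[0]

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(59)
        v = rng.normal(size=(5, 10))
        fits = fit_two_group(matrix(v), matrix(v))
        assert fits["log_fc"].abs().max() == pytest.approx(0.0)
        assert fits["t_ordinary"].abs().max() == pytest.approx(0.0)

    def test_recovers_programmed_shift(self):
        rng = np.random.default_rng(61)
        delta, sd, n, reps = 1.2, 0.7, 50, 200
        case = matrix(rng.normal(delta, sd, (reps, n)))
        ctrl = matrix(rng.normal(0.0, sd, (reps, n)))
        fits = fit_two_group(case, ctrl)
        se = sd * np.sqrt(2 / n) / np.sqrt(reps)
        assert fits["log_fc"].mean() == pytest.approx(delta, abs=3 * se)

    def test_residual_df(self):
        rng = np.random.default_rng(67)
        fits = fit_two_group(
            matrix(rng.normal(size=(3, 7))), matrix(rng.normal(size=(3, 5)))
        )
        assert (fits["df_residual"] == 10).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_two_group(matrix(np.zeros((2, 1))), matrix(np.zeros((2, 5))))


class TestPriorEstimation:
    @staticmethod
    def _results_from(s2, df, rng, logfc_sd=0.1):
        g = len(s2)
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(g)],
                "log_fc": rng.normal(0, logfc_sd, g),
                "s2": s2,
                "df_residual": float(df),
                "t_ordinary": 0.0,
                "stdev_unscaled": np.sqrt(2 / 50),
                "zero_variance": s2 == 0,
            }
        )

    def test_hierarchical_parameter_recovery(self):
        # variances from the scaled inverse-chi-square prior, then a
        # chi-square residual layer: the moment estimator must recover
        # d0 and s0^2 within 10%
        rng = np.random.default_rng(71)
        d0, s0, df, g = 4.0, 2.0, 10, 10_000
        sigma2 = d0 * s0 / rng.chisquare(d0, g)
        s2 = sigma2 * rng.chisquare(df, g) / df
        prior = estimate_prior(self._results_from(s2, df, rng))
        assert prior.d0 == pytest.approx(d0, rel=0.10)
        assert prior.s0_sq == pytest.approx(s0, rel=0.10)

    def test_constant_variances_give_infinite_d0(self):
        rng = np.random.default_rng(73)
        res = self._results_from(np.full(200, 1.7), 10, rng)
        prior = estimate_prior(res)
        assert np.isinf(prior.d0)
        out = moderate(res, prior)
        assert out["s2_post"].to_numpy() == pytest.approx(
            np.full(200, prior.s0_sq)
        )

    def test_matches_limma_hyperparameters(self, tmp_path):
        rscript = shutil.which("Rscript")
        if rscript is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(42)
        g, n = 300, 8
        x = rng.normal(0, 1, (g, n))
        y = rng.normal(0, 1, (g, n))
        x[:20] += 2.0
        case = matrix(x, "case")
        ctrl = matrix(y, "ctrl")
        fits = fit_two_group(case, ctrl)
        prior = estimate_prior(fits)
        ours = moderate(fits, prior)
        expr_csv = tmp_path / "expr.csv"
        pd.DataFrame(np.hstack([x, y]), index=case.genes).to_csv(expr_csv)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"m <- as.matrix(read.csv('{expr_csv}', row.names=1))\n"
            f"design <- cbind(Intercept=1, case=c(rep(1,{n}), rep(0,{n})))\n"
            "fit <- eBayes(lmFit(m, design))\n"
            "out <- data.frame(gene=rownames(m), t=fit$t[,'case'],\n"
            "                  lods=fit$lods[,'case'], s2post=fit$s2.post)\n"
            f"write.csv(out, '{tmp_path / 'limma.csv'}', row.names=FALSE)\n"
            "cat(fit$df.prior, fit$s2.prior, sep='\\n')\n"
        )
        proc = subprocess.run(
            [rscript, str(script)], capture_output=True, text=True, check=True
        )
        d0_limma, s20_limma = map(float, proc.stdout.split())
        assert prior.d0 == pytest.approx(d0_limma, rel=1e-4)
        assert prior.s0_sq == pytest.approx(s20_limma, rel=1e-4)
        ref = pd.read_csv(tmp_path / "limma.csv")
        m = ours.merge(ref, on="gene")
        np.testing.assert_allclose(m["t_moderated"], m["t"], rtol=1e-8)
        np.testing.assert_allclose(m["s2_post"], m["s2post"], rtol=1e-8)
        # B uses a different v0 estimator than limma's tmixture, so only
        # the ranking is required to agree
        assert np.corrcoef(m["B"], m["lods"])[0, 1] > 0.999


class TestModeration:
    def test_d0_zero_leaves_t_unchanged(self):
        rng = np.random.default_rng(79)
        res = TestPriorEstimation._results_from(
            rng.chisquare(5, 100) / 5, 10, rng, logfc_sd=0.5
        )
        res["t_ordinary"] = res["log_fc"] / (
            np.sqrt(res["s2"]) * res["stdev_unscaled"]
        )
        out = moderate(res, EBayesPrior(d0=0.0, s0_sq=1.0, v0=1.0))
        np.testing.assert_allclose(out["t_moderated"], out["t_ordinary"], rtol=1e-12)
        assert (out["df_total"] == out["df_residual"]).all()

    def test_b_increasing_in_abs_t(self):
        rng = np.random.default_rng(83)
        res = TestPriorEstimation._results_from(
            np.ones(50), 10, rng, logfc_sd=2.0
        )
        out = moderate(res, EBayesPrior(d0=4.0, s0_sq=1.0, v0=2.0))
        o = out.sort_values("t_moderated", key=np.abs)
        assert o["B"].is_monotonic_increasing

    def test_b_collapses_as_v0_vanishes_at_even_prior(self):
        rng = np.random.default_rng(89)
        res = TestPriorEstimation._results_from(
            np.ones(20), 10, rng, logfc_sd=1.0
        )
        out = moderate(
            res, EBayesPrior(d0=4.0, s0_sq=1.0, v0=1e-12, p_prior=0.5)
        )
        assert out["B"].abs().max() < 1e-6

    def test_posterior_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(97)
        s2 = rng.chisquare(5, 100) / 5
        res = TestPriorEstimation._results_from(s2, 10, rng)
        prior = EBayesPrior(d0=4.0, s0_sq=1.0, v0=1.0)
        out = moderate(res, prior)
        lo = np.minimum(s2, prior.s0_sq)
        hi = np.maximum(s2, prior.s0_sq)
        assert ((out["s2_post"] >= lo - 1e-12) & (out["s2_post"] <= hi + 1e-12)).all()


class TestClassification:
    @pytest.mark.parametrize(
        "lfc,b,expected",
        [(1.5, 7.0, "over"), (-2.0, 8.0, "under"), (1.5, 2.0, "ns"),
         (0.5, 10.0, "ns"), (-1.0, 6.0, "under")],
    )
    def test_threshold_rules(self, lfc, b, expected):
        res = pd.DataFrame({"gene": ["g"], "log_fc": [lfc], "B": [b]})
        assert classify(res)["call"].iloc[0] == expected

    def test_null_data_call_rate_controlled(self):
        rng = np.random.default_rng(101)
        case = matrix(rng.normal(0, 0.7, (2000, 50)))
        ctrl = matrix(rng.normal(0, 0.7, (2000, 50)))
        out = run_de(case, ctrl)
        assert (out["call"] != "ns").mean() <= 0.01

    def test_sensitivity_at_strong_shift(self):
        rng = np.random.default_rng(103)
        x = rng.normal(0, 0.7, (2000, 50))
        x[:100] += 1.5
        out = run_de(matrix(x), matrix(rng.normal(0, 0.7, (2000, 50))))
        assert (out["call"].to_numpy()[:100] == "over").mean() >= 0.9


class TestCommunityProfiles:
    def test_counts_sum_to_community_size(self):
        cset = {"N": CommunitySet(
            [Community("N 1", frozenset({"g0", "g1", "g2"}), frozenset())], "N"
        )}
        calls = {"T": pd.DataFrame({"gene": ["g0", "g1"], "call": ["over", "under"]})}
        prof = community_de_profile(cset, calls)
        row = prof.iloc[0]
        assert row["n_over"] + row["n_under"] + row["n_ns"] == row["size"] == 3
        assert row["n_ns"] == 1  # g2 missing from the DE table counts as ns

    def test_all_over_community(self):
        genes = [f"g{i}" for i in range(10)]
        cset = {"N": CommunitySet(
            [Community("N 1", frozenset(genes), frozenset())], "N"
        )}
        calls = {"T": pd.DataFrame({"gene": genes, "call": ["over"] * 10})}
        prof = community_de_profile(cset, calls)
        assert prof.iloc[0][["n_over", "n_under", "n_ns"]].tolist() == [10, 0, 0]
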