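"""Moderated-t machinery: group stats, prior estimation, BH, DEG calls."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from urimark.diffexpr import (
    ContrastSpec,
    ShrinkagePrior,
    VARIANCE_FLOOR,
    bh_adjust,
    call_degs,
    estimate_prior,
    fit_gene_stats,
    gene_contrast_report,
    moderated_t,
    run_contrast,
    trigamma_inverse,
)
from urimark.errors import ContrastError, EstimationError, ValidationError

from conftest import make_matrix


def bh_bruteforce(p):
    """O(m^2) step-up definition: q_i = min over p_j >= p_i of p_j*m/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    ranks = stats.rankdata(p, method="max")
    out = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(candidates))
    return out


class TestFitGeneStats:
    def test_hand_computed_two_group_summary(self):
        m = make_matrix(np.array([[1.0, 3.0, 0.0, 2.0]]),
                        classes=["T", "T", "R", "R"])
        out = fit_gene_stats(m, ContrastSpec("T", "R"))
        row = out.iloc[0]
        assert row["mean_test"] == 2.0
        assert row["mean_ref"] == 1.0
        assert row["log2fc"] == 1.0
        assert row["s2"] == pytest.approx(2.0)
        assert row["df"] == 2.0

    def test_identical_groups_have_zero_log2fc(self):
        block = np.random.default_rng(0).normal(size=(20, 3))
        m = make_matrix(np.hstack([block, block]),
                        classes=["T"] * 3 + ["R"] * 3)
        out = fit_gene_stats(m, ContrastSpec("T", "R"))
        assert np.allclose(out["log2fc"], 0.0)

    def test_constant_gene_is_floored_and_flagged(self):
        m = make_matrix(np.full((1, 4), 5.0), classes=["T", "T", "R", "R"])
        out = fit_gene_stats(m, ContrastSpec("T", "R"))
        assert out["zero_variance"].iloc[0]
        assert out["s2"].iloc[0] == VARIANCE_FLOOR

    def test_undersized_class_raises(self):
        m = make_matrix(np.zeros((2, 3)), classes=["T", "R", "R"])
        with pytest.raises(ContrastError, match="'T'"):
            fit_gene_stats(m, ContrastSpec("T", "R"))


class TestPriorEstimation:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(100)
        d0, s0sq, dg, n = 4.0, 0.05, 6.0, 5000
        sigma2 = s0sq * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        prior = estimate_prior(s2, np.full(n, dg))
        assert abs(prior.d0 - d0) / d0 < 0.2
        assert abs(prior.s0sq - s0sq) / s0sq < 0.2

    def test_equal_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 0.04)
        prior = estimate_prior(s2, np.full(100, 6.0))
        assert math.isinf(prior.d0)
        e = np.log(0.04) - special.digamma(3.0) + np.log(3.0)
        assert prior.s0sq == pytest.approx(math.exp(e))

    def test_trigamma_inverse_forward_roundtrip(self):
        for y in (0.5, 0.01, 3.0, 150.0):
            x = trigamma_inverse(y)
            assert float(special.polygamma(1, x)) == pytest.approx(y, abs=1e-8)

    def test_too_few_usable_genes_raises(self):
        with pytest.raises(EstimationError, match="10"):
            estimate_prior(np.full(5, 0.1), np.full(5, 4.0))


class TestModeratedT:
    @staticmethod
    def _fitted(seed=0, n=200, delta=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(8, 0.3, size=(n, 12))
        x[:, :6] += delta
        m = make_matrix(x, classes=["T"] * 6 + ["R"] * 6)
        return fit_gene_stats(m, ContrastSpec("T", "R"))

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        fitted = self._fitted(seed=1)
        prior = ShrinkagePrior(d0=1e-12, s0sq=1.0)
        out = moderated_t(fitted, prior)
        se = np.sqrt(fitted["s2"] * (1 / 6 + 1 / 6))
        assert np.allclose(out["t"], fitted["log2fc"] / se, rtol=1e-6)

    def test_full_shrinkage_limit_uses_prior_variance_everywhere(self):
        fitted = self._fitted(seed=2)
        prior = ShrinkagePrior(d0=math.inf, s0sq=0.09)
        out = moderated_t(fitted, prior)
        assert np.allclose(out["s2_post"], 0.09)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(33)
        n = 2000
        sigma2 = 0.05 * 4 / rng.chisquare(4.0, n)
        x = rng.normal(0, 1, size=(n, 12)) * np.sqrt(sigma2)[:, None] + 8.0
        m = make_matrix(x, classes=["T"] * 6 + ["R"] * 6)
        res = run_contrast(m, ContrastSpec("T", "R"))
        ks = stats.kstest(res["p"], "uniform").statistic
        assert ks < 0.05

    def test_p_symmetric_under_group_swap(self):
        fitted = self._fitted(seed=3, delta=0.5)
        prior = estimate_prior(fitted["s2"].to_numpy(), fitted["df"].to_numpy())
        fwd = moderated_t(fitted, prior)
        swapped = fitted.copy()
        swapped[["mean_test", "mean_ref"]] = fitted[["mean_ref", "mean_test"]].to_numpy()
        swapped["log2fc"] = -fitted["log2fc"]
        rev = moderated_t(swapped, prior)
        assert np.allclose(rev["t"], -fwd["t"])
        assert np.allclose(rev["p"], fwd["p"])

    def test_t_monotone_in_effect_size_at_fixed_variance(self):
        fitted = self._fitted(seed=4).iloc[:1].copy()
        prior = ShrinkagePrior(d0=4.0, s0sq=0.05)
        rows = []
        for fc in (0.1, 0.5, 1.0, 2.0):
            f = fitted.copy()
            f["log2fc"] = fc
            rows.append(abs(moderated_t(f, prior)["t"].iloc[0]))
        assert rows == sorted(rows)


class TestLimmaCrossCheck:
    def test_prior_and_statistics_match_limma(self, tmp_path):
        """Independent oracle: the Bioconductor limma eBayes fit on the
        same matrix must agree on (d0, s0^2), moderated t and p."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma oracle cannot run")
        rng = np.random.default_rng(12)
        sigma2 = 0.05 * 4 / rng.chisquare(4.0, 120)
        x = rng.normal(0, 1, size=(120, 10)) * np.sqrt(sigma2)[:, None] + 8.0
        x[:10, :5] += 1.0
        m = make_matrix(x, classes=["T"] * 5 + ["R"] * 5)
        res = run_contrast(m, ContrastSpec("T", "R"))
        prior = res.attrs["prior"]

        mat_path = tmp_path / "expr.tsv"
        m.values.to_csv(mat_path, sep="\t", float_format="%.17g")
        rcode = f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{mat_path}", row.names=1, check.names=FALSE))
design <- cbind(Intercept=1, T=c(rep(1,5), rep(0,5)))
fit <- eBayes(lmFit(x, design))
out <- data.frame(t=fit$t[,"T"], p=fit$p.value[,"T"])
write.table(out, "{tmp_path / 'limma.tsv'}", sep="\\t", quote=FALSE)
cat(fit$df.prior, fit$s2.prior, sep="\\n")
"""
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True,
            timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        d0_r, s0sq_r = [float(v) for v in proc.stdout.split()[:2]]
        limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert prior.d0 == pytest.approx(d0_r, rel=1e-4)
        assert prior.s0sq == pytest.approx(s0sq_r, rel=1e-4)
        assert np.allclose(res["t"], limma["t"], rtol=1e-6)
        assert np.allclose(res["p"], limma["p"], rtol=1e-6)


class TestBhAdjust:
    def test_worked_example_four_pvalues(self):
        adjusted = bh_adjust(np.array([0.0021, 0.0094, 0.024, 0.031]))
        assert np.allclose(adjusted, [0.0084, 0.0188, 0.031, 0.031])

    def test_equal_and_singleton_inputs(self):
        assert np.allclose(bh_adjust(np.full(7, 0.03)), 0.03)
        assert bh_adjust(np.array([0.2]))[0] == 0.2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=50,
        )
    )
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(bh_adjust(np.array(p)), bh_bruteforce(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(77)
        p = rng.uniform(size=300)
        assert np.allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.1, 1.5]))


class TestDegCalls:
    @pytest.mark.parametrize(
        "padj,log2fc,expected",
        [
            (0.04, 1.5, "up"),
            (0.04, 0.5, "none"),
            (0.06, 3.0, "none"),
            (0.04, -1.5, "down"),
        ],
    )
    def test_call_rule(self, padj, log2fc, expected):
        out = call_degs(np.array([log2fc]), np.array([padj]))
        assert out[0] == expected


class TestGeneContrastReport:
    def test_noiseless_planted_shift_reports_exact_fold(self):
        rng = np.random.default_rng(5)
        x = np.repeat(rng.normal(8, 1, 30)[:, None], 8, axis=1)
        x[0, :4] += 1.0
        m = make_matrix(x, classes=["T"] * 4 + ["R"] * 4)
        report = gene_contrast_report(m, "G001", [ContrastSpec("T", "R")])
        assert report["relative_expression"].iloc[0] == pytest.approx(2.0)

    def test_equal_distributions_report_unit_fold(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(8, 0.05, size=(50, 20)),
                        classes=["T"] * 10 + ["R"] * 10)
        report = gene_contrast_report(m, "G010", [ContrastSpec("T", "R")])
        assert report["relative_expression"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_unknown_gene_raises(self, two_class_matrix):
        with pytest.raises(ValidationError, match="unknown gene"):
            gene_contrast_report(two_class_matrix, "nope",
                                 [ContrastSpec("A", "B")])
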