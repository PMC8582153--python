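"""Moderated t-test: filtering, shrinkage limits, calibration, limma cross-check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfdirect.de import (
    CountMatrix,
    ModeratedTTest,
    benjamini_hochberg,
    cpm,
    filter_and_transform,
)


def make_sheet(n_lines=2, reps=3):
    rows = []
    for li in range(n_lines):
        for cond in ("control", "knockdown"):
            for r in range(reps):
                rows.append((f"L{li}.{cond}.{r}", f"L{li}", cond, r))
    return pd.DataFrame(
        rows, columns=["sample", "cell_line", "condition", "replicate"]
    ).set_index("sample")


def simulate_logexpr(rng, n_genes, sheet, effect=None):
    """Normal log-expression with per-gene variances; optional knockdown effect."""
    n = len(sheet)
    sd = np.sqrt(rng.gamma(4.0, 0.05, size=n_genes))
    X = rng.normal(8.0, 1.0, size=(n_genes, 1)) + rng.normal(size=(n_genes, n)) * sd[:, None]
    if effect is not None:
        kd = (sheet["condition"] == "knockdown").to_numpy()
        X[:, kd] += effect[:, None]
    return pd.DataFrame(X, index=[f"G{i}" for i in range(n_genes)], columns=sheet.index)


class TestFilterTransform:
    def test_cpm_definition(self):
        sheet = make_sheet()
        # library size 1e6 per sample, focal gene contributes 10 counts
        counts = pd.DataFrame(
            [[10] * 12, [999_990] * 12], index=["G0", "FILL"], columns=sheet.index
        )
        c = cpm(counts)
        assert np.allclose(c.loc["G0"], 10.0)

    def test_filter_keeps_gene_passing_in_three_samples(self):
        sheet = make_sheet(n_lines=1, reps=3)
        lib = pd.DataFrame(
            np.full((1, 6), 1_000_000), index=["LIB"], columns=sheet.index
        )
        gene = pd.DataFrame(
            [[2, 2, 2, 0, 0, 0]], index=["G1"], columns=sheet.index
        )
        zero = pd.DataFrame([[0] * 6], index=["G2"], columns=sheet.index)
        cm = CountMatrix(pd.concat([lib, gene, zero]), sheet)
        logcpm, _ = filter_and_transform(cm, min_cpm=1, min_samples=3)
        assert "G1" in logcpm.index and "G2" not in logcpm.index

    def test_all_zero_library_errors(self):
        sheet = make_sheet(n_lines=1, reps=3)
        counts = pd.DataFrame(
            np.ones((3, 6), dtype=int), index=list("abc"), columns=sheet.index
        )
        counts.iloc[:, 2] = 0
        cm = CountMatrix(counts, sheet)
        with pytest.raises(ValueError, match=sheet.index[2]):
            filter_and_transform(cm)


class TestBenjaminiHochberg:
    def test_hand_stepup_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)


class TestModeratedT:
    def test_identical_conditions_give_null_result(self):
        sheet = make_sheet(n_lines=1, reps=3)
        X = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (5, 1))
            + np.arange(5)[:, None],
            index=[f"G{i}" for i in range(5)],
            columns=sheet.index,
        )
        res = ModeratedTTest(X, sheet).fit()
        assert np.allclose(res.table["logFC"], 0.0, atol=1e-12)
        assert np.allclose(res.table["p"], 1.0)

    def test_d0_zero_equals_ordinary_ols_t(self, rng):
        sheet = make_sheet()
        X = simulate_logexpr(rng, 500, sheet)
        res = ModeratedTTest(X, sheet).fit(d0=0.0)
        # reference: per-gene OLS via explicit linear algebra
        design = np.column_stack(
            [
                np.ones(12),
                (sheet["condition"] == "knockdown").to_numpy(float),
                (sheet["cell_line"] == "L1").to_numpy(float),
            ]
        )
        xtx_inv = np.linalg.inv(design.T @ design)
        H = xtx_inv @ design.T
        for i in range(0, 500, 17):
            y = X.iloc[i].to_numpy()
            beta = H @ y
            resid = y - design @ beta
            s2 = resid @ resid / (12 - 3)
            t_ref = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
            assert res.table["t"].iloc[i] == pytest.approx(t_ref, abs=1e-8)

    def test_d0_infinite_pools_variances(self, rng):
        sheet = make_sheet()
        X = simulate_logexpr(rng, 200, sheet)
        res = ModeratedTTest(X, sheet).fit(d0=np.inf)
        assert res.table["s2_post"].nunique() == 1

    def test_large_d0_converges_to_pooled(self, rng):
        sheet = make_sheet()
        X = simulate_logexpr(rng, 200, sheet)
        model = ModeratedTTest(X, sheet)
        r_inf = model.fit(d0=np.inf)
        r_big = model.fit(d0=1e9)
        assert np.allclose(r_big.table["s2_post"], r_inf.table["s2_post"], rtol=1e-5)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        sheet = make_sheet()
        X = simulate_logexpr(rng, 5000, sheet)
        res = ModeratedTTest(X, sheet).fit()
        rate = float((res.table["p"] < 0.05).mean())
        assert 0.04 <= rate <= 0.06

    def test_strict_threshold_boundary(self, rng):
        sheet = make_sheet()
        X = simulate_logexpr(rng, 10, sheet)
        res = ModeratedTTest(X, sheet).fit()
        # force a gene exactly at the threshold: strict inequality => ns
        res.table.iloc[0, res.table.columns.get_loc("logFC")] = 0.1
        res.table.iloc[0, res.table.columns.get_loc("adj_p")] = 1e-6
        called = res.call_de(lfc_threshold=0.1, alpha=0.05)
        assert called.table["call"].iloc[0] == "ns"

    def test_singular_design_rejected(self, rng):
        sheet = make_sheet(n_lines=1, reps=3)
        sheet = sheet.assign(cell_line="same", condition="control")
        X = simulate_logexpr(rng, 5, sheet)
        with pytest.raises(ValueError):
            ModeratedTTest(X, sheet)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaCrossCheck:
    def test_matches_limma_ebayes(self, tmp_path, rng):
        """Independent oracle: R limma lmFit + eBayes(trend=FALSE) on the
        same matrix must reproduce logFC, moderated t and p."""
        sheet = make_sheet()
        effect = np.where(np.arange(60) < 10, 1.0, 0.0)
        X = simulate_logexpr(rng, 60, sheet, effect=effect)
        X.to_csv(tmp_path / "x.tsv", sep="\t")
        sheet.to_csv(tmp_path / "s.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names=1, check.names=FALSE))
            s <- read.delim(commandArgs(TRUE)[2], row.names=1)
            design <- model.matrix(~ condition + cell_line, data=s)
            fit <- eBayes(lmFit(x, design), trend=FALSE)
            i <- grep("knockdown", colnames(design))
            out <- data.frame(logFC=fit$coefficients[,i], t=fit$t[,i],
                              p=fit$p.value[,i], d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, commandArgs(TRUE)[3], sep="\t", quote=FALSE)
            """
        )
        out = tmp_path / "limma_out.tsv"
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "x.tsv"), str(tmp_path / "s.tsv"), str(out)],
            check=True, capture_output=True, timeout=300,
        )
        ref = pd.read_csv(out, sep="\t")
        res = ModeratedTTest(X, sheet).fit()
        # condition is alphabetically control < knockdown in R too
        assert np.allclose(res.table["logFC"], ref["logFC"], atol=1e-8)
        assert res.params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert res.params.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        assert np.allclose(res.table["t"], ref["t"], rtol=1e-6, atol=1e-8)
        assert np.allclose(res.table["p"], ref["p"], rtol=1e-6, atol=1e-12)
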