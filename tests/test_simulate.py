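"""Synthetic-bundle generator: determinism, construction invariants, moments."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from tfdirect.de import CountMatrix, ModeratedTTest, filter_and_transform
from tfdirect.genome import promoter_windows, read_gene_annotation
from tfdirect.peaks import annotate_peaks, promoter_gene_sets, read_peaks
from tfdirect.simulate import (
    GroundTruth,
    SimConfig,
    simulate_clinical_matrix,
    simulate_counts,
    simulate_dataset,
    validate_bundle,
)

SMALL = dict(
    n_genes=400, n_direct_pos=10, n_direct_neg=10, n_distal_pos=4,
    n_distal_neg=4, n_indirect=15, n_null_bound=30, background_peak_count=80,
    clinical_n_gcb=40, clinical_n_abc=40,
)


def test_same_seed_gives_byte_identical_bundle(tmp_path):
    cfg = SimConfig(seed=11, **SMALL)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_dataset(cfg, a)
    simulate_dataset(cfg, b)
    names = [p.name for p in sorted(a.iterdir())]
    match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
    assert mismatch == [] and errors == [] and len(match) == len(names)


def test_bundle_passes_validator(sim_bundle):
    cfg, outdir, _ = sim_bundle
    validate_bundle(outdir, cfg)


def test_promoter_targets_have_promoter_peaks(sim_bundle):
    cfg, outdir, truth = sim_bundle
    ann = read_gene_annotation(outdir / "annotation.gtf", "gtf")
    windows = promoter_windows(ann, cfg.promoter_flank)
    anns = {}
    for line in cfg.cell_lines:
        pk = read_peaks(outdir / f"peaks_{line}.bed", line)
        anns[line] = annotate_peaks(pk, ann, windows)
    _, union, _ = promoter_gene_sets(anns)
    promoter_targets = truth.genes_in("direct_pos_promoter", "direct_neg_promoter")
    assert promoter_targets <= union


def test_category_disjointness_and_counts(sim_bundle):
    cfg, _, truth = sim_bundle
    vc = truth.table["category"].value_counts()
    assert vc["direct_pos_promoter"] == cfg.n_direct_pos
    assert vc["direct_neg_promoter"] == cfg.n_direct_neg
    assert vc["direct_pos_distal"] == cfg.n_distal_pos
    assert vc["direct_neg_distal"] == cfg.n_distal_neg
    assert vc["indirect"] == cfg.n_indirect
    assert vc["tf"] == 1
    assert vc.sum() == cfg.n_genes


def test_null_genes_logfc_centered_at_zero(sim_bundle):
    """Realized knockdown-vs-control logFC of null genes is centred at 0."""
    cfg, outdir, truth = sim_bundle
    cm = CountMatrix.from_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    logcpm, _ = filter_and_transform(cm)
    res = ModeratedTTest(logcpm, cm.samples).fit()
    nulls = truth.genes_in("null") & set(res.table.index)
    assert len(nulls) > 800
    med = float(res.table.loc[sorted(nulls), "logFC"].median())
    assert abs(med) < 0.05


def test_planted_logfc_recovered_in_median(sim_bundle):
    cfg, outdir, truth = sim_bundle
    cm = CountMatrix.from_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    logcpm, _ = filter_and_transform(cm)
    res = ModeratedTTest(logcpm, cm.samples).fit()
    pos = sorted(truth.genes_in("direct_pos_promoter") & set(res.table.index))
    med = float(res.table.loc[pos, "logFC"].median())
    assert med == pytest.approx(-cfg.effect_size_log2, abs=0.3)


def test_zero_effect_size_gives_no_expected_difference(tmp_path):
    cfg = SimConfig(seed=5, effect_size_log2=0.0, **SMALL)
    rng = np.random.default_rng(5)
    truth = GroundTruth(
        pd.DataFrame(
            {
                "category": ["null"] * 200 + ["tf"],
                "planted_logfc": [0.0] * 201,
                "planted_r": [0.0] * 201,
                "essential": [False] * 201,
            },
            index=[f"G{i:05d}" for i in range(200)] + [cfg.tf_gene],
        )
    )
    counts, sheet = simulate_counts(truth, cfg, rng)
    kd = sheet.index[sheet["condition"] == "knockdown"]
    ct = sheet.index[sheet["condition"] == "control"]
    # TF excluded (it is knocked down by construction)
    ratio = counts.loc[counts.index != cfg.tf_gene, kd].mean(axis=1).sum() / \
        counts.loc[counts.index != cfg.tf_gene, ct].mean(axis=1).sum()
    assert ratio == pytest.approx(1.0, abs=0.1)


def test_poisson_limit_at_zero_dispersion():
    cfg = SimConfig(seed=2, nb_dispersion=0.0, **SMALL)
    rng = np.random.default_rng(2)
    truth = GroundTruth(
        pd.DataFrame(
            {
                "category": ["null"] * 500 + ["tf"],
                "planted_logfc": [0.0] * 501,
                "planted_r": [0.0] * 501,
                "essential": [False] * 501,
            },
            index=[f"G{i:05d}" for i in range(500)] + [cfg.tf_gene],
        )
    )
    counts, sheet = simulate_counts(truth, cfg, rng)
    # across genes at similar mean, variance/mean ratio near 1 within a sample
    # is confounded by baseline spread; instead check replicate variance of a
    # single sample-wise standardized gene panel
    ct = counts[sheet.index[sheet["condition"] == "control"]]
    lib = ct.sum(axis=0)
    norm = ct / lib.to_numpy() * lib.mean()
    disp = ((norm.var(axis=1) - norm.mean(axis=1)) / norm.mean(axis=1) ** 2).median()
    assert abs(disp) < 0.05


def test_clinical_planted_correlation_recovered(sim_bundle):
    cfg, outdir, truth = sim_bundle
    expr = pd.read_csv(outdir / "clinical_expression.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(outdir / "clinical_samples.tsv", sep="\t", index_col=0)
    gcb = samples.index[samples["subtype"] == "GCB"]
    tf = expr.loc[cfg.tf_gene, gcb]
    supported = truth.table.index[truth.table["planted_r"] != 0]
    emp = [
        np.corrcoef(expr.loc[g, gcb], tf)[0, 1] * np.sign(truth.table.loc[g, "planted_r"])
        for g in supported
    ]
    # signed empirical correlations cluster near the planted magnitude
    assert np.median(emp) == pytest.approx(cfg.clinical_target_r, abs=0.15)


def test_high_planted_r_yields_high_empirical_r():
    cfg = SimConfig(seed=13, clinical_target_r=0.99, clinical_n_gcb=100,
                    clinical_n_abc=50, **{k: v for k, v in SMALL.items()
                                          if not k.startswith("clinical")})
    rng = np.random.default_rng(13)
    idx = [f"G{i:05d}" for i in range(100)] + [cfg.tf_gene]
    r = pd.Series(0.0, index=idx)
    r.iloc[0] = 0.99
    truth = GroundTruth(
        pd.DataFrame(
            {"category": "null", "planted_logfc": 0.0, "planted_r": r,
             "essential": False},
            index=idx,
        )
    )
    values, subtypes = simulate_clinical_matrix(truth, cfg, rng)
    gcb = subtypes.index[subtypes == "GCB"]
    emp = np.corrcoef(values.loc[idx[0], gcb], values.loc[cfg.tf_gene, gcb])[0, 1]
    assert emp > 0.9


def test_config_rejects_oversubscribed_categories():
    with pytest.raises(ValueError):
        SimConfig(seed=1, n_genes=50, n_direct_pos=40, n_direct_neg=40)
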