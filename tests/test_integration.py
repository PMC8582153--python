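"""Target integration: binding gate, sign convention, tiers, pipeline run."""

import json

import numpy as np
import pandas as pd
import pytest

from tfdirect.clinical import CorrelationResult
from tfdirect.de import DEResults, ModeratedTestParams
from tfdirect.integrate import (
    EssentialGeneList,
    PipelineConfigError,
    TargetNetwork,
    call_direct_targets,
    run_pipeline,
    summarize_targets,
    tier_targets,
)
from tfdirect.simulate import SimConfig, default_pipeline_config, simulate_dataset


def mk_de(calls: dict[str, str]) -> DEResults:
    lfc = {"up": 1.0, "down": -1.0, "ns": 0.0}
    table = pd.DataFrame(
        {
            "logFC": [lfc[c] for c in calls.values()],
            "t": 0.0,
            "p": 0.5,
            "adj_p": 0.5,
            "call": list(calls.values()),
        },
        index=list(calls.keys()),
    )
    return DEResults(table, ModeratedTestParams(4.0, 0.1), 9.0, 13.0)


class TestCallDirectTargets:
    def test_down_after_knockdown_is_positive_regulation(self):
        de = mk_de({"G1": "down"})
        (t,) = call_direct_targets(de, {"G1"}, set())
        assert t.binding == "promoter" and t.regulation == "positive" and t.is_direct

    def test_binding_without_de_is_not_direct(self):
        de = mk_de({"G1": "ns"})
        (t,) = call_direct_targets(de, {"G1"}, set())
        assert not t.is_direct and t.tier == 0

    def test_de_without_binding_is_not_direct(self):
        de = mk_de({"G1": "up"})
        (t,) = call_direct_targets(de, set(), set())
        assert t.binding == "none" and not t.is_direct

    def test_distal_only_overlap_with_promoter_rejected(self):
        de = mk_de({"G1": "up"})
        with pytest.raises(ValueError):
            call_direct_targets(de, {"G1"}, {"G1"})


class TestTiering:
    def test_concordant_correlation_gives_support(self):
        de = mk_de({"G1": "down"})
        targets = call_direct_targets(de, {"G1"}, set())
        out = tier_targets(targets, [CorrelationResult("G1", 0.5, 0.001)])
        assert out[0].clinical_support and out[0].tier == 2

    def test_discordant_correlation_gives_no_support(self):
        de = mk_de({"G1": "down"})
        targets = call_direct_targets(de, {"G1"}, set())
        out = tier_targets(targets, [CorrelationResult("G1", -0.5, 0.001)])
        assert not out[0].clinical_support and out[0].tier == 1

    def test_truth_table_on_toy_input(self):
        """Hand-enumerated tiers on a 10-gene toy input."""
        calls = {
            "A": "down", "B": "down", "C": "up", "D": "up", "E": "ns",
            "F": "down", "G": "up", "H": "ns", "I": "down", "J": "up",
        }
        de = mk_de(calls)
        promoter = {"A", "B", "C", "E", "H"}
        distal = {"F", "G"}
        corr = [
            CorrelationResult("A", 0.6, 1e-3),   # concordant (+reg, r>0)
            CorrelationResult("B", -0.6, 1e-3),  # discordant
            CorrelationResult("C", -0.4, 1e-3),  # concordant (-reg, r<0)
            CorrelationResult("F", 0.5, 1e-3),   # concordant
        ]
        ess = EssentialGeneList(frozenset({"A", "C", "I"}))
        out = tier_targets(call_direct_targets(de, promoter, distal), corr, ess)
        tiers = {t.gene_id: t.tier for t in out}
        assert tiers == {
            "A": 3,  # direct + clinical + essential
            "B": 1,  # direct, discordant corr
            "C": 3, "D": 0, "E": 0,
            "F": 2,  # distal direct + clinical
            "G": 1, "H": 0, "I": 0, "J": 0,
        }
        summary = summarize_targets(out)
        assert summary["n_direct"] == 5
        assert summary["direct_positive_promoter"] == 2  # A, B
        assert summary["direct_negative_promoter"] == 1  # C
        assert summary["direct_positive_distal"] == 1   # F
        assert summary["direct_negative_distal"] == 1   # G

    def test_summary_venn_identities(self):
        calls = {f"G{i}": c for i, c in enumerate(["down"] * 5 + ["up"] * 5)}
        de = mk_de(calls)
        targets = call_direct_targets(de, set(list(calls)[:7]), set())
        out = tier_targets(targets, [], None)
        s = summarize_targets(out)
        direct = [t for t in out if t.is_direct]
        assert s["n_direct"] == len(direct)
        assert s["direct_positive_promoter"] == sum(
            t.regulation == "positive" and t.binding == "promoter" for t in direct
        )
        pos = {t.gene_id for t in direct if t.regulation == "positive"}
        neg = {t.gene_id for t in direct if t.regulation == "negative"}
        assert not (pos & neg)


class TestPipeline:
    def test_end_to_end_summary_consistent_with_truth(self, sim_bundle, tmp_path):
        cfg, bundle_dir, truth = sim_bundle
        pc = default_pipeline_config(cfg, bundle_dir, seed=7)
        summary = run_pipeline(pc, tmp_path / "out")
        t = summary["targets"]
        # planted counts recovered within DE sensitivity slack
        assert t["direct_positive_promoter"] >= 0.85 * cfg.n_direct_pos
        assert t["direct_negative_promoter"] >= 0.85 * cfg.n_direct_neg
        assert t["direct_positive_distal"] >= 0.8 * cfg.n_distal_pos
        assert t["direct_negative_distal"] >= 0.8 * cfg.n_distal_neg
        assert (tmp_path / "out" / "target_calls.tsv").exists()
        assert (tmp_path / "out" / "summary.json").exists()

    def test_rerun_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=3, n_genes=300, n_direct_pos=8, n_direct_neg=8,
                        n_distal_pos=3, n_distal_neg=3, n_indirect=10,
                        n_null_bound=20, background_peak_count=60,
                        clinical_n_gcb=30, clinical_n_abc=30)
        blobs = []
        for run in ("a", "b"):
            d = tmp_path / run
            simulate_dataset(cfg, d)
            pc = default_pipeline_config(cfg, d, seed=3)
            run_pipeline(pc, d / "out")
            blobs.append(
                (
                    (d / "truth.tsv").read_bytes(),
                    (d / "out" / "summary.json").read_bytes(),
                )
            )
        assert blobs[0] == blobs[1]

    def test_missing_input_fails_before_compute(self, sim_bundle, tmp_path):
        cfg, bundle_dir, _ = sim_bundle
        pc = default_pipeline_config(cfg, bundle_dir, seed=7)
        pc["interactions"] = str(bundle_dir / "does_not_exist.tsv")
        with pytest.raises(PipelineConfigError):
            run_pipeline(pc, tmp_path / "out")
        assert not (tmp_path / "out" / "summary.json").exists()

    def test_missing_required_key_rejected(self, tmp_path):
        with pytest.raises(PipelineConfigError):
            run_pipeline({"annotation": "x"}, tmp_path / "out")


def test_essential_list_requires_genes():
    with pytest.raises(ValueError):
        EssentialGeneList(frozenset())
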