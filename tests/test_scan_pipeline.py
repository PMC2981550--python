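import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from hetphos import (
    SynthConfig,
    build_model,
    generate_dataset,
    run_pipeline,
    scan,
    score_dataset,
    train_final,
    withhold_substrates,
)
from hetphos.cli import main as cli_main
from hetphos.io import read_predictions

SMALL = dict(n_background=120, n_substrates=15, protein_length=60)

PIPE_CFG = {
    "seed": "17",
    "n_background": "120",
    "n_substrates": "15",
    "reps": "2",
}


@pytest.fixture(scope="module")
def scan_setup():
    ds_full = generate_dataset(SynthConfig(seed=51, **SMALL))
    hidden_ids = [f"sub{i:04d}" for i in range(13, 16)]
    ds, hidden = withhold_substrates(ds_full, hidden_ids)
    model, _ = build_model(ds, "CDK")
    scores = score_dataset(ds, "CDK", model)
    svm = train_final(ds, "CDK", seed=51)
    return ds, hidden, scores, svm


class TestScan:
    def test_bookkeeping_identity(self, scan_setup):
        ds, _, scores, svm = scan_setup
        predictions, summary = scan(ds, "CDK", svm, scores)
        per_protein = {}
        for p in predictions:
            per_protein[p.protein_id] = per_protein.get(p.protein_id, 0) + 1
        assert sum(per_protein.values()) == summary.n_predicted_sites
        assert len(per_protein) == summary.n_predicted_proteins
        assert summary.n_predicted_sites <= summary.n_candidate_sites

    def test_known_sites_never_predicted(self, scan_setup):
        ds, _, scores, svm = scan_setup
        predictions, _ = scan(ds, "CDK", svm, scores)
        known = ds.known_positions()
        assert not {(p.protein_id, p.position) for p in predictions} & known

    def test_predictions_only_on_candidates(self, scan_setup):
        ds, _, scores, svm = scan_setup
        from hetphos import candidate_set

        predictions, _ = scan(ds, "CDK", svm, scores)
        sub = scores[scores.is_substrate]
        bg = scores[~scores.is_substrate]
        cand = candidate_set(dict(zip(bg.protein_id, bg.score)), list(sub.score))
        assert {p.protein_id for p in predictions} <= cand

    def test_empty_candidate_set(self, scan_setup):
        ds, _, scores, svm = scan_setup
        # push every background score below the substrate median
        lowered = scores.copy()
        lowered.loc[~lowered.is_substrate, "score"] = -1e9
        predictions, summary = scan(ds, "CDK", svm, lowered)
        assert predictions == [] and summary.n_candidate_sites == 0

    def test_family_mismatch_errors(self, scan_setup):
        ds, _, scores, svm = scan_setup
        with pytest.raises(ValueError, match="family"):
            scan(ds, "PKA", svm, scores)


def test_scan_recovers_withheld_substrates_under_moderate_planting():
    """With moderate functional planting (OR 4), withheld substrates re-enter
    the candidate set and their planted sites are recovered: pooled recall
    above 0.6 and true sites enriched among predictions beyond 2x chance."""
    from hetphos import NamespaceConfig, candidate_set

    namespaces = [
        NamespaceConfig(
            n,
            n_enriched_terms=2,
            enriched_odds_ratio=4.0,
            n_depleted_terms=1,
            depleted_odds_ratio=0.25,
        )
        for n in ("kegg", "go_bp", "go_cc", "go_mf", "pfam", "interpro", "string_ppi")
    ]
    hit = denom = n_pred = n_cand = 0
    for seed in range(10):
        cfg = SynthConfig(seed=seed, namespaces=namespaces)
        ds_full = generate_dataset(cfg)
        ds, hidden = withhold_substrates(
            ds_full, [f"sub{i:04d}" for i in range(41, 51)]
        )
        model, _ = build_model(ds, "CDK")
        scores = score_dataset(ds, "CDK", model)
        svm = train_final(ds, "CDK", seed=seed)
        predictions, summary = scan(ds, "CDK", svm, scores)
        pred = {(p.protein_id, p.position) for p in predictions}
        sub = scores[scores.is_substrate]
        bg = scores[~scores.is_substrate]
        cand = candidate_set(dict(zip(bg.protein_id, bg.score)), list(sub.score))
        hidden_in_cand = {
            (x.protein_id, x.position) for x in hidden if x.protein_id in cand
        }
        hit += len(pred & hidden_in_cand)
        denom += len(hidden_in_cand)
        n_pred += len(pred)
        n_cand += summary.n_candidate_sites
    assert denom > 0 and n_pred > 0
    recall = hit / denom
    fold_enrichment = (hit / n_pred) / (denom / n_cand)
    assert recall > 0.6
    assert fold_enrichment > 2.0


class TestPipeline:
    def test_full_run_emits_artifacts(self, tmp_path):
        out = run_pipeline({**PIPE_CFG, "out": str(tmp_path / "run")})
        for name in (
            "dataset/proteome.fasta",
            "enrichment.tsv",
            "scores.tsv",
            "cv_report.tsv",
            "model.joblib",
            "predictions.tsv",
            "summary.tsv",
            "run_log.txt",
        ):
            assert (out / name).exists(), name

    def test_summary_recomputable_from_predictions(self, tmp_path):
        out = run_pipeline({**PIPE_CFG, "out": str(tmp_path / "run")})
        preds = read_predictions(out / "predictions.tsv")
        summary = pd.read_csv(out / "summary.tsv", sep="\t").iloc[0]
        assert summary.n_predicted_sites == len(preds)
        assert summary.n_predicted_proteins == len({p.protein_id for p in preds})

    def test_byte_identical_reruns(self, tmp_path):
        out1 = run_pipeline({**PIPE_CFG, "out": str(tmp_path / "r1")})
        out2 = run_pipeline({**PIPE_CFG, "out": str(tmp_path / "r2")})
        files1 = sorted(p.relative_to(out1) for p in out1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(out2) for p in out2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes(), rel

    def test_stage_without_dataset_errors(self, tmp_path):
        with pytest.raises(ValueError, match="dataset"):
            run_pipeline({"stages": "enrich", "out": str(tmp_path / "x")})

    def test_unknown_stage_errors(self, tmp_path):
        with pytest.raises(ValueError, match="stage"):
            run_pipeline({"stages": "simulate,frobnicate", "out": str(tmp_path / "x")})


class TestCLI:
    def test_simulate_then_enrich(self, tmp_path):
        runner = CliRunner()
        ds_dir = tmp_path / "ds"
        r = runner.invoke(
            cli_main,
            ["simulate", "--seed", "3", "--out", str(ds_dir)],
        )
        assert r.exit_code == 0, r.output
        out = tmp_path / "enrichment.tsv"
        r = runner.invoke(
            cli_main,
            ["enrich", "--dataset", str(ds_dir), "--family", "CDK", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert out.exists()
        table = pd.read_csv(out, sep="\t")
        assert {"namespace", "term_id", "p_corrected", "direction"} <= set(table.columns)

    def test_run_command_with_config_file(self, tmp_path):
        cfg = tmp_path / "pipeline.cfg"
        cfg.write_text(
            "out = {}\nseed = 5\nn_background = 100\nn_substrates = 12\nreps = 1\n".format(
                tmp_path / "run"
            )
        )
        r = CliRunner().invoke(cli_main, ["run", "--config", str(cfg)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "run" / "summary.tsv").exists()
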