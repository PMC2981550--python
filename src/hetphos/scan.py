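"""End-to-end proteome scan and pipeline orchestration.

The scan restricts attention to candidate proteins — background proteins
whose functional log-odds score exceeds the median score of the known
substrates — and classifies every S/T-centered window in them (known
training sites excluded) with the trained site classifier. Windows with a
positive decision value become predicted sites. The pipeline runner chains
simulate -> enrich -> score -> cv -> train -> scan, writing every
intermediate table, and is byte-for-byte reproducible for a fixed
config+seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .classify import TrainedModel, build_background_pool, run_cv, train_final
from .datatypes import Dataset
from .enrichment import DEFAULT_ALPHA
from .features import extract_window
from .io import PredictionRecord, read_dataset, write_dataset, write_predictions
from .scoring import build_model, candidate_set, ks_compare, score_dataset
from .synthetic import NamespaceConfig, SynthConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanSummary:
    """Tallies of a proteome scan for one kinase family."""

    family: str
    n_candidate_sites: int  # S/T windows examined in candidate proteins
    n_predicted_proteins: int  # proteins with >= 1 predicted site
    n_predicted_sites: int


def scan(
    dataset: Dataset,
    family: str,
    model: TrainedModel,
    scores: pd.DataFrame,
    include_known: bool = False,
) -> Tuple[List[PredictionRecord], ScanSummary]:
    """Classify all candidate-protein S/T windows with a trained model.

    ``scores`` is the table from :func:`hetphos.scoring.score_dataset`.
    Candidates are non-substrate proteins scoring strictly above the median
    substrate score. Known sites are excluded unless ``include_known``.
    """
    if model.family != family:
        raise ValueError(
            f"model was trained for family {model.family!r}, not {family!r}"
        )
    for ns in model.namespaces:
        if ns not in dataset.matrices:
            raise ValueError(f"model needs namespace {ns!r} absent from dataset")
        missing = [
            t for t in model.selected.get(ns, ())
            if t not in dataset.matrices[ns]._tcol
        ]
        if missing:
            raise ValueError(
                f"model features missing from {ns} matrix: {missing[:5]}"
            )

    sub = scores[scores.is_substrate]
    bg = scores[~scores.is_substrate]
    candidates = candidate_set(
        dict(zip(bg.protein_id, bg.score)), list(sub.score)
    )
    score_of = dict(zip(scores.protein_id, scores.score))
    known = dataset.known_positions()

    windows = []
    for pid in sorted(candidates):
        prot = dataset.proteome[pid]
        for pos0, aa in enumerate(prot.sequence):
            pos = pos0 + 1
            if aa in ("S", "T") and (include_known or (pid, pos) not in known):
                windows.append(extract_window(prot, pos, model.h))

    predictions: List[PredictionRecord] = []
    if windows:
        decisions = model.decision_values(windows, dataset)
        for w, d in zip(windows, decisions):
            if d > 0:
                predictions.append(
                    PredictionRecord(
                        w.protein_id,
                        w.position,
                        w.center,
                        family,
                        float(d),
                        score_of[w.protein_id],
                    )
                )
    summary = ScanSummary(
        family=family,
        n_candidate_sites=len(windows),
        n_predicted_proteins=len({p.protein_id for p in predictions}),
        n_predicted_sites=len(predictions),
    )
    logger.info(
        "scan %s: %d candidate proteins, %d candidate sites, %d predicted sites "
        "on %d proteins",
        family,
        len(candidates),
        summary.n_candidate_sites,
        summary.n_predicted_sites,
        summary.n_predicted_proteins,
    )
    return predictions, summary


ALL_STAGES = ("simulate", "enrich", "score", "cv", "train", "scan")


def _synth_config_from(config: Mapping[str, str]) -> SynthConfig:
    kwargs = {}
    for key in (
        "n_background",
        "n_substrates",
        "protein_length",
        "sites_per_substrate",
        "seed",
    ):
        if key in config:
            kwargs[key] = int(config[key])
    if "motif_strength" in config:
        kwargs["motif_strength"] = float(config["motif_strength"])
    if "family" in config:
        kwargs["family"] = str(config["family"])
    return SynthConfig(**kwargs)


def parse_config_file(path) -> Dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: Dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def run_pipeline(config: Mapping[str, str], out_dir=None) -> Path:
    """Run the requested stages, writing all artifacts under the output dir.

    Recognized keys: out, stages (comma list), seed, family, dataset (path to
    an existing dataset dir; otherwise the simulate stage must be first),
    synthetic generator overrides (n_background, n_substrates,
    protein_length, sites_per_substrate, motif_strength), alpha, reps, folds,
    split, group.
    """
    out = Path(out_dir or config.get("out", "hetphos_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = [
        s.strip() for s in config.get("stages", ",".join(ALL_STAGES)).split(",") if s.strip()
    ]
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}; expected one of {ALL_STAGES}")
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", DEFAULT_ALPHA))
    log_lines: List[str] = [
        f"hetphos {__version__}",
        f"seed {seed}",
        f"stages {','.join(stages)}",
    ]

    dataset: Optional[Dataset] = None
    family = config.get("family")

    def need_dataset(stage: str) -> Dataset:
        nonlocal dataset
        if dataset is None:
            src = config.get("dataset") or (
                out / "dataset" if (out / "dataset" / "proteome.fasta").exists() else None
            )
            if src is None:
                raise ValueError(f"stage {stage!r} requires a dataset; run simulate "
                                 "first or set the 'dataset' key")
            dataset = read_dataset(src)
        return dataset

    if "simulate" in stages:
        cfg = _synth_config_from({**config, "seed": str(seed)})
        dataset = generate_dataset(cfg)
        family = family or cfg.family
        write_dataset(out / "dataset", dataset)
        log_lines.append(
            f"simulate n_proteins={len(dataset.proteome)} n_sites={len(dataset.sites)}"
        )

    if family is None and any(s in stages for s in ("enrich", "score", "cv", "train", "scan")):
        ds = need_dataset(stages[0])
        fams = ds.families()
        if len(fams) != 1:
            raise ValueError(f"ambiguous family; set the 'family' key (found {fams})")
        family = fams[0]

    prob_model = None
    scores = None
    if "enrich" in stages or "score" in stages:
        ds = need_dataset("enrich")
        prob_model, results = build_model(ds, family, alpha=alpha)
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        log_lines.append(f"enrich n_significant={len(results)}")

    if "score" in stages:
        ds = need_dataset("score")
        scores = score_dataset(ds, family, prob_model)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        sub = scores[scores.is_substrate].score
        bg = scores[~scores.is_substrate].score
        D, p = ks_compare(list(sub), list(bg))
        (out / "ks_report.tsv").write_text(
            "family\tks_D\tks_p\n" + f"{family}\t{D:.6g}\t{p:.6g}\n"
        )
        log_lines.append(f"score ks_D={D:.4f} ks_p={p:.3g}")

    if "cv" in stages:
        ds = need_dataset("cv")
        report = run_cv(
            ds,
            family,
            split_mode=config.get("split", "site"),
            folds=int(config.get("folds", 5)),
            reps=int(config.get("reps", 10)),
            seed=seed,
            alpha=alpha,
        )
        pd.DataFrame([report.to_row()]).to_csv(out / "cv_report.tsv", sep="\t", index=False)
        log_lines.append(
            f"cv n_pos={report.n_pos} all={report.accuracy.get('all'):.2f} "
            f"sequence={report.accuracy.get('sequence'):.2f}"
        )

    model = None
    if "train" in stages or "scan" in stages:
        ds = need_dataset("train")
        model = train_final(
            ds, family, group=config.get("group", "all"), seed=seed, alpha=alpha
        )
        model.save(out / "model.joblib")
        log_lines.append(
            f"train group={model.group} n_features="
            f"{sum(len(v) for v in model.selected.values())}"
        )

    if "scan" in stages:
        ds = need_dataset("scan")
        if scores is None:
            if prob_model is None:
                prob_model, _ = build_model(ds, family, alpha=alpha)
            scores = score_dataset(ds, family, prob_model)
        predictions, summary = scan(ds, family, model, scores)
        write_predictions(out / "predictions.tsv", predictions)
        pd.DataFrame([dataclasses.asdict(summary)]).to_csv(
            out / "summary.tsv", sep="\t", index=False
        )
        log_lines.append(
            f"scan candidate_sites={summary.n_candidate_sites} "
            f"predicted_sites={summary.n_predicted_sites} "
            f"predicted_proteins={summary.n_predicted_proteins}"
        )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
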