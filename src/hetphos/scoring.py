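"""Redundancy-weighted log-odds scoring of candidate substrate proteins.

Each significant binary functional feature i contributes the log ratio of
its value's probability in known substrates, f(x_i), to its probability in
the background proteome, g(x_i). Correlated features (e.g. near-identical
pathway and process terms) would otherwise be double counted, so each
contribution is divided by a redundancy weight w_i: one plus the sum of the
feature's Jaccard similarities to the other selected features, measured on
the background incidence columns. The self-inclusive weight keeps w_i >= 1
and makes a duplicated feature pair contribute exactly once in total.

    score(x) = sum_i (1 / w_i) * ln( f(x_i) / g(x_i) )

Probabilities are Laplace-smoothed so no feature value has probability 0.
Substrate and background score distributions are compared with a two-sample
Kolmogorov-Smirnov test, and proteome-scan candidates are the background
proteins scoring strictly above the median substrate score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .datatypes import Dataset, FeatureMatrix
from .enrichment import DEFAULT_ALPHA, EnrichmentResult, select_features

logger = logging.getLogger(__name__)


@dataclass
class ProbWeightModel:
    """Per-feature probability tables and redundancy weights."""

    feature_ids: List[Tuple[str, str]]  # (namespace, term_id)
    f1: np.ndarray  # P(x_i = 1 | substrate)
    g1: np.ndarray  # P(x_i = 1 | background)
    w: np.ndarray  # redundancy weights, >= 1

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.g1 = np.asarray(self.g1, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.feature_ids) == self.f1.size == self.g1.size == self.w.size):
            raise ValueError("model arrays not aligned with feature_ids")
        for name, arr in (("f1", self.f1), ("g1", self.g1)):
            if arr.size and not ((arr > 0) & (arr < 1)).all():
                raise ValueError(f"{name} probabilities must lie strictly in (0,1)")
        if self.w.size and (self.w < 1 - 1e-12).any():
            raise ValueError("weights must be >= 1")


def estimate_probs(
    feature_ids: Sequence[Tuple[str, str]],
    positive_ids: Iterable[str],
    background_ids: Iterable[str],
    matrices: Mapping[str, FeatureMatrix],
    pseudocount: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Smoothed per-feature probabilities of value 1 in positives/background.

    f1_i = (#positives with feature i + pc) / (n_pos + 2 pc), likewise g1 over
    the background; f(0) = 1 - f(1). With the default pseudocount of 1 no
    probability can reach 0 or 1.
    """
    pos = list(positive_ids)
    bg = list(background_ids)
    if not pos:
        raise ValueError("empty positive set")
    f1 = np.empty(len(feature_ids))
    g1 = np.empty(len(feature_ids))
    for i, (ns, term) in enumerate(feature_ids):
        mat = matrices[ns]
        f1[i] = (sum(mat.has_term(p, term) for p in pos) + pseudocount) / (
            len(pos) + 2 * pseudocount
        )
        g1[i] = (sum(mat.has_term(p, term) for p in bg) + pseudocount) / (
            len(bg) + 2 * pseudocount
        )
    return f1, g1


def jaccard_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Fraction of coordinates, among those nonzero in either vector, that
    differ. Two all-zero vectors are treated as identical (distance 0)."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("vector length mismatch")
    union = int(((u != 0) | (v != 0)).sum())
    if union == 0:
        logger.warning("jaccard_distance of two all-zero vectors; defined as 0")
        return 0.0
    return float((u != v).sum()) / union


def feature_weights(columns: np.ndarray) -> np.ndarray:
    """Redundancy weights from binary feature columns over a protein sample.

    ``columns`` has shape (n_proteins, n_features). w_i = 1 + sum over the
    other features of (1 - Jaccard distance); the leading 1 is the feature's
    self-similarity, so a lone feature gets weight 1 and two identical
    columns get weight 2 each.
    """
    X = np.asarray(columns, dtype=bool)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D array with at least one feature column")
    F = X.T.astype(np.float64)  # features x proteins
    inter = F @ F.T
    sizes = F.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(union > 0, (union - inter) / np.where(union > 0, union, 1), 0.0)
    sim = 1.0 - dist
    np.fill_diagonal(sim, 1.0)  # self-similarity, also for all-zero columns
    return sim.sum(axis=1)


def score_protein(x: np.ndarray, model: ProbWeightModel) -> float:
    """Summed weighted log-odds of a protein's binary feature values."""
    x = np.asarray(x)
    if x.size != len(model.feature_ids):
        raise ValueError("feature value vector does not match model")
    num = np.where(x == 1, model.f1, 1.0 - model.f1)
    den = np.where(x == 1, model.g1, 1.0 - model.g1)
    return float(np.sum(np.log(num / den) / model.w))


def build_model(
    dataset: Dataset,
    family: str,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = 1.0,
    namespaces: Sequence[str] | None = None,
) -> Tuple[ProbWeightModel, List[EnrichmentResult]]:
    """Select significant features for a family and fit the scoring model.

    Features are selected per namespace by the two-sided hypergeometric test;
    probabilities come from substrates (f) and the full background proteome
    (g); weights from the background incidence columns of the selected
    features.
    """
    substrates = dataset.substrate_ids(family)
    if not substrates:
        raise ValueError(f"no substrates for family {family!r}")
    ns_names = list(namespaces) if namespaces is not None else list(dataset.matrices)
    results: List[EnrichmentResult] = []
    for ns in ns_names:
        results.extend(select_features(substrates, dataset.matrices[ns], alpha))
    feature_ids = [(r.namespace, r.term_id) for r in results]
    background = list(dataset.proteome)
    if feature_ids:
        f1, g1 = estimate_probs(feature_ids, substrates, background, dataset.matrices, pseudocount)
        cols = np.column_stack(
            [
                dataset.matrices[ns].incidence[:, dataset.matrices[ns].term_col(term)]
                for ns, term in feature_ids
            ]
        )
        w = feature_weights(cols)
    else:
        f1 = g1 = w = np.empty(0)
    model = ProbWeightModel(feature_ids, f1, g1, w)
    return model, results


def score_dataset(dataset: Dataset, family: str, model: ProbWeightModel) -> pd.DataFrame:
    """Score every proteome protein; columns protein_id, score, is_substrate."""
    substrates = set(dataset.substrate_ids(family))
    pids = list(dataset.proteome)
    if model.feature_ids:
        xs = np.column_stack(
            [
                dataset.matrices[ns].align(pids).incidence[:, dataset.matrices[ns].term_col(term)]
                if dataset.matrices[ns].protein_ids != pids
                else dataset.matrices[ns].incidence[:, dataset.matrices[ns].term_col(term)]
                for ns, term in model.feature_ids
            ]
        )
        scores = [score_protein(xs[i], model) for i in range(len(pids))]
    else:
        scores = [0.0] * len(pids)
    return pd.DataFrame(
        {
            "protein_id": pids,
            "score": scores,
            "is_substrate": [pid in substrates for pid in pids],
        }
    )


def ks_compare(
    scores_substrates: Sequence[float], scores_background: Sequence[float]
) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic D and asymptotic p-value."""
    if len(scores_substrates) == 0 or len(scores_background) == 0:
        raise ValueError("both samples must be nonempty")
    res = ks_2samp(scores_substrates, scores_background, method="asymp")
    return float(res.statistic), float(res.pvalue)


def candidate_set(
    background_scores: Mapping[str, float], substrate_scores: Sequence[float]
) -> Set[str]:
    """Background proteins scoring strictly above the median substrate score."""
    if len(substrate_scores) == 0:
        raise ValueError("substrate score list is empty")
    med = float(np.median(np.asarray(substrate_scores, dtype=float)))
    return {pid for pid, s in background_scores.items() if s > med}
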