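"""Feature-group assembly, negative sampling and SVM cross-validation.

Positive examples are a family's known phosphosite windows after 70%
identity filtering; negatives are drawn uniformly from the background pool
(every S/T-centered window of the proteome minus known sites), with the same
identity rejection, to the same sample size. Nine feature groups are
evaluated on identical train/test partitions: the sequence+structure block
alone, that block plus each functional namespace's significant terms, and
all namespaces combined. Significant terms are re-selected within each
training fold, so no test information can leak into feature selection.
Accuracy is the plain fraction of correct predictions over positive and
negative test samples; "minus" is the all-group accuracy minus the
sequence-only accuracy.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import joblib
import numpy as np
from sklearn.svm import SVC

from .datatypes import Dataset, FeatureMatrix, PhosphoSite, Protein, StructureTable
from .enrichment import DEFAULT_ALPHA, EnrichmentResult, select_features
from .features import (
    PeptideWindow,
    extract_window,
    greedy_homology_filter,
    pairwise_identity,
    sequence_struct_length,
    site_vector,
)

logger = logging.getLogger(__name__)

#: Feature-group name -> functional namespaces added to sequence+structure.
FEATURE_GROUPS: Dict[str, Tuple[str, ...]] = {
    "sequence": (),
    "kegg": ("kegg",),
    "bp": ("go_bp",),
    "cc": ("go_cc",),
    "mf": ("go_mf",),
    "pfam": ("pfam",),
    "ipr": ("interpro",),
    "string": ("string_ppi",),
    "all": ("kegg", "go_bp", "go_cc", "go_mf", "pfam", "interpro", "string_ppi"),
}

DEFAULT_IDENTITY_THRESHOLD = 0.7


def build_background_pool(
    proteome: Mapping[str, Protein],
    known_sites: Iterable[PhosphoSite],
    residues: Set[str] = frozenset("ST"),
    h: int = 4,
) -> List[PeptideWindow]:
    """All S/T-centered windows in the proteome, minus known sites (any family)."""
    known = {(s.protein_id, s.position) for s in known_sites}
    pool: List[PeptideWindow] = []
    for prot in proteome.values():
        for pos0, aa in enumerate(prot.sequence):
            if aa in residues and (prot.id, pos0 + 1) not in known:
                pool.append(extract_window(prot, pos0 + 1, h))
    return pool


def sample_negatives(
    pool: Sequence[PeptideWindow],
    n: int,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    rng: Optional[np.random.Generator] = None,
) -> List[PeptideWindow]:
    """Sequential uniform draws without replacement, rejecting any draw over
    ``threshold`` identity to a previously accepted one, until n accepted."""
    if n == 0:
        return []
    if rng is None:
        rng = np.random.default_rng()
    accepted: List[PeptideWindow] = []
    for idx in rng.permutation(len(pool)):
        w = pool[int(idx)]
        if all(pairwise_identity(w, a) <= threshold for a in accepted):
            accepted.append(w)
            if len(accepted) == n:
                return accepted
    raise ValueError(
        f"background pool exhausted: accepted {len(accepted)} of {n} requested"
    )


def _group_namespaces(group: str) -> Tuple[str, ...]:
    try:
        return FEATURE_GROUPS[group]
    except KeyError:
        raise ValueError(
            f"unknown feature group {group!r}; expected one of {list(FEATURE_GROUPS)}"
        ) from None


def assemble_vector(
    window: PeptideWindow,
    group: str,
    enriched_features: Mapping[str, Sequence[str]],
    matrices: Mapping[str, FeatureMatrix],
    structure: Optional[StructureTable],
) -> np.ndarray:
    """Sequence+structure block plus one indicator per significant term of the
    group's namespaces (a protein absent from a matrix contributes zeros)."""
    namespaces = _group_namespaces(group)
    parts = [site_vector(window, structure).values]
    for ns in namespaces:
        terms = enriched_features.get(ns, ())
        block = np.array(
            [matrices[ns].has_term(window.protein_id, t) for t in terms], dtype=np.float64
        )
        parts.append(block)
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


@dataclass
class CVReport:
    """Mean per-group accuracies (%) over repeated k-fold cross-validation."""

    family: str
    accuracy: Dict[str, float]  # group -> mean accuracy in percent
    accuracy_std: Dict[str, float]  # group -> std over repetitions
    minus: Optional[float]  # all - sequence, when both groups were run
    n_pos: int
    n_neg: int
    reps: int
    folds: int
    seed: int
    split_mode: str
    fold_log: List[dict] = field(default_factory=list)

    def to_row(self) -> Dict[str, float]:
        row: Dict[str, float] = {"family": self.family}
        for g in ("all", "sequence"):
            if g in self.accuracy:
                row[g] = self.accuracy[g]
        if self.minus is not None:
            row["minus"] = self.minus
        for g, acc in self.accuracy.items():
            if g not in ("all", "sequence"):
                row[g] = acc
        return row


def _fold_assignment(rng: np.random.Generator, n: int, folds: int) -> np.ndarray:
    """Shuffle then deal round-robin: per-fold counts differ by at most 1."""
    order = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[order] = np.arange(n) % folds
    return fold


def _group_fold_assignment(
    rng: np.random.Generator, keys: Sequence[str], folds: int
) -> Dict[str, int]:
    uniq = sorted(set(keys))
    fold = _fold_assignment(rng, len(uniq), folds)
    return {k: int(f) for k, f in zip(uniq, fold)}


def _seq_struct_matrix(
    windows: Sequence[PeptideWindow], structure: Optional[StructureTable]
) -> np.ndarray:
    if not windows:
        return np.empty((0, sequence_struct_length()))
    return np.stack([site_vector(w, structure).values for w in windows])


def _functional_columns(
    windows: Sequence[PeptideWindow],
    matrices: Mapping[str, FeatureMatrix],
    selected: Mapping[str, Sequence[str]],
    namespaces: Sequence[str],
) -> np.ndarray:
    cols: List[np.ndarray] = []
    for ns in namespaces:
        for term in selected.get(ns, ()):
            mat = matrices[ns]
            cols.append(
                np.array([mat.has_term(w.protein_id, term) for w in windows], dtype=np.float64)
            )
    if not cols:
        return np.empty((len(windows), 0))
    return np.column_stack(cols)


def _make_svm() -> SVC:
    # Cost 1, RBF kernel with width 1/n_features; binary inputs are not rescaled.
    return SVC(C=1.0, kernel="rbf", gamma="auto")


def run_cv(
    dataset: Dataset,
    family: str,
    split_mode: str = "site",
    folds: int = 5,
    reps: int = 10,
    seed: int = 0,
    groups: Sequence[str] = tuple(FEATURE_GROUPS),
    alpha: float = DEFAULT_ALPHA,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    record_folds: bool = False,
) -> CVReport:
    """Repeated k-fold cross-validation with in-fold feature re-selection.

    ``split_mode`` "site" partitions sites directly (classes balanced per
    fold); "protein" partitions source proteins first so no protein
    contributes sites to both train and test. The per-repetition RNG is used
    only for negative sampling and fold shuffles, never conditioned on
    annotation content, so fold assignments depend only on (dataset
    sequences/sites, seed).
    """
    if split_mode not in ("site", "protein"):
        raise ValueError(f"split_mode must be 'site' or 'protein', got {split_mode!r}")
    for g in groups:
        _group_namespaces(g)

    pos_sites = dataset.family_sites(family)
    if not pos_sites:
        raise ValueError(f"no known sites for family {family!r}")
    pos_windows_all = [
        extract_window(dataset.proteome[s.protein_id], s.position) for s in pos_sites
    ]
    pos_windows: List[PeptideWindow] = greedy_homology_filter(
        pos_windows_all, identity_threshold
    )
    n_pos = len(pos_windows)
    if n_pos < folds:
        raise ValueError(
            f"family {family!r}: only {n_pos} positives after homology "
            f"filtering, need at least {folds}"
        )
    pool = build_background_pool(dataset.proteome, dataset.sites)

    needed_ns = sorted({ns for g in groups for ns in _group_namespaces(g)})
    pos_seq = _seq_struct_matrix(pos_windows, dataset.structure)
    pos_proteins = np.array([w.protein_id for w in pos_windows])

    group_acc: Dict[str, List[float]] = {g: [] for g in groups}
    fold_log: List[dict] = []

    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        negatives = sample_negatives(pool, n_pos, identity_threshold, rng)
        neg_seq = _seq_struct_matrix(negatives, dataset.structure)
        neg_proteins = np.array([w.protein_id for w in negatives])

        if split_mode == "site":
            pos_fold = _fold_assignment(rng, n_pos, folds)
            neg_fold = _fold_assignment(rng, n_pos, folds)
        else:
            pmap = _group_fold_assignment(rng, list(pos_proteins), folds)
            nmap = _group_fold_assignment(rng, list(neg_proteins), folds)
            pos_fold = np.array([pmap[p] for p in pos_proteins])
            neg_fold = np.array([nmap[p] for p in neg_proteins])

        correct = {g: 0 for g in groups}
        total = 0
        for f in range(folds):
            pos_tr, pos_te = pos_fold != f, pos_fold == f
            neg_tr, neg_te = neg_fold != f, neg_fold == f
            if pos_te.sum() == 0 and neg_te.sum() == 0:
                continue
            train_study = sorted(set(pos_proteins[pos_tr]))
            selected: Dict[str, List[str]] = {
                ns: [r.term_id for r in select_features(train_study, dataset.matrices[ns], alpha)]
                for ns in needed_ns
            }
            func_pos = _functional_columns(pos_windows, dataset.matrices, selected, needed_ns)
            func_neg = _functional_columns(negatives, dataset.matrices, selected, needed_ns)
            # column offsets of each namespace within the assembled func block
            offsets: Dict[str, slice] = {}
            start = 0
            for ns in needed_ns:
                width = len(selected.get(ns, ()))
                offsets[ns] = slice(start, start + width)
                start += width

            y_train = np.concatenate(
                [np.ones(int(pos_tr.sum())), np.zeros(int(neg_tr.sum()))]
            )
            y_test = np.concatenate(
                [np.ones(int(pos_te.sum())), np.zeros(int(neg_te.sum()))]
            )
            total += y_test.size
            for g in groups:
                ns_list = _group_namespaces(g)
                cols = [offsets[ns] for ns in ns_list]
                Xp = np.hstack([pos_seq] + [func_pos[:, c] for c in cols])
                Xn = np.hstack([neg_seq] + [func_neg[:, c] for c in cols])
                X_train = np.vstack([Xp[pos_tr], Xn[neg_tr]])
                X_test = np.vstack([Xp[pos_te], Xn[neg_te]])
                clf = _make_svm()
                clf.fit(X_train, y_train)
                correct[g] += int((clf.predict(X_test) == y_test).sum())
            if record_folds:
                fold_log.append(
                    {
                        "rep": rep,
                        "fold": f,
                        "train_proteins": set(train_study),
                        "test_proteins": set(pos_proteins[pos_te]),
                        "selected": {ns: list(ts) for ns, ts in selected.items()},
                    }
                )
        for g in groups:
            group_acc[g].append(100.0 * correct[g] / total)

    accuracy = {g: float(np.mean(a)) for g, a in group_acc.items()}
    accuracy_std = {g: float(np.std(a)) for g, a in group_acc.items()}
    minus = (
        accuracy["all"] - accuracy["sequence"]
        if "all" in accuracy and "sequence" in accuracy
        else None
    )
    return CVReport(
        family=family,
        accuracy=accuracy,
        accuracy_std=accuracy_std,
        minus=minus,
        n_pos=n_pos,
        n_neg=n_pos,
        reps=reps,
        folds=folds,
        seed=seed,
        split_mode=split_mode,
        fold_log=fold_log,
    )


@dataclass
class TrainedModel:
    """A fitted site classifier plus everything needed to encode new windows."""

    family: str
    group: str
    selected: Dict[str, List[str]]
    svc: SVC
    seed: int
    h: int = 4
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    @property
    def namespaces(self) -> Tuple[str, ...]:
        return _group_namespaces(self.group)

    def encode(self, windows: Sequence[PeptideWindow], dataset: Dataset) -> np.ndarray:
        seq = _seq_struct_matrix(windows, dataset.structure)
        func = _functional_columns(windows, dataset.matrices, self.selected, self.namespaces)
        return np.hstack([seq, func])

    def decision_values(
        self, windows: Sequence[PeptideWindow], dataset: Dataset
    ) -> np.ndarray:
        if not windows:
            return np.empty(0)
        return self.svc.decision_function(self.encode(windows, dataset))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def train_final(
    dataset: Dataset,
    family: str,
    group: str = "all",
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> TrainedModel:
    """Train on all (homology-filtered) positives plus fresh negatives, with
    features selected on the full positive substrate set."""
    namespaces = _group_namespaces(group)
    pos_sites = dataset.family_sites(family)
    if not pos_sites:
        raise ValueError(f"no known sites for family {family!r}")
    pos_windows = greedy_homology_filter(
        [extract_window(dataset.proteome[s.protein_id], s.position) for s in pos_sites],
        identity_threshold,
    )
    rng = np.random.default_rng(seed)
    pool = build_background_pool(dataset.proteome, dataset.sites)
    negatives = sample_negatives(pool, len(pos_windows), identity_threshold, rng)
    study = sorted({w.protein_id for w in pos_windows})
    selected = {
        ns: [r.term_id for r in select_features(study, dataset.matrices[ns], alpha)]
        for ns in namespaces
    }
    model = TrainedModel(family, group, selected, _make_svm(), seed)
    X = np.vstack(
        [model.encode(pos_windows, dataset), model.encode(negatives, dataset)]
    )
    y = np.concatenate([np.ones(len(pos_windows)), np.zeros(len(negatives))])
    model.svc.fit(X, y)
    logger.info(
        "trained %s/%s on %d positives + %d negatives, %d functional features",
        family,
        group,
        len(pos_windows),
        len(negatives),
        sum(len(t) for t in selected.values()),
    )
    return model
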